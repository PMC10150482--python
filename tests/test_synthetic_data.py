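import numpy as np
import pandas as pd
import pytest
import scipy.stats

from trophostab import (
    BiomassDesignSpec,
    CommunitySpec,
    FieldDesignSpec,
    GroundTruth,
    generate_biolog_timeseries,
    generate_biomass,
    generate_field_design,
    generate_field_study,
    generate_multikingdom_counts,
    generate_trait_frequencies,
)
from trophostab.core_io import ConfigurationError
from trophostab.microcosm import awcd_table, stability_table


class TestFieldDesign:
    def test_default_design_has_60_samples(self):
        meta, soil, truth = generate_field_design(FieldDesignSpec(seed=0))
        assert len(meta) == 60  # 5 sites x 4 treatments x 3 replicates
        assert len(soil) == 60
        assert set(truth.resource_levels.values()) == {"low", "high"}

    def test_minimal_design_has_one_sample(self):
        spec = FieldDesignSpec(n_sites=1, treatments=("C",), n_replicates=1,
                               seed=0)
        meta, soil, _ = generate_field_design(spec)
        assert len(meta) == 1 and len(soil) == 1

    def test_same_seed_is_identical(self):
        a = generate_field_design(FieldDesignSpec(seed=11))
        b = generate_field_design(FieldDesignSpec(seed=11))
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_planted_gradient_is_monotone_in_expectation(self):
        _, soil, _ = generate_field_design(FieldDesignSpec(seed=3))
        sites = {s.split("_")[0] for s in soil.index}
        for site in sites:
            means = {
                t: soil.loc[[i for i in soil.index
                             if i.startswith(f"{site}_{t}_")], "AP"].mean()
                for t in ("C", "NK", "NPK", "NPKM")
            }
            assert means["C"] < means["NK"] < means["NPK"] < means["NPKM"]


class TestCommunities:
    def test_planted_pair_exceeds_network_threshold(self, field_study):
        """A pair planted at rank correlation 0.9 shows sample Spearman
        above the 0.6 network threshold in its active arm."""
        truth = field_study.truth
        checked = 0
        for pair in truth.planted_pairs[:12]:
            arm = [s for s, lv in truth.resource_levels.items()
                   if lv == pair["arm"]]
            ka, oa = pair["otu_a"].split("|")
            kb, ob = pair["otu_b"].split("|")
            x = field_study.tables[ka].counts.loc[oa, arm]
            y = field_study.tables[kb].counts.loc[ob, arm]
            rho = scipy.stats.spearmanr(x, y).statistic
            if pair["sign"] == "negative":
                rho = -rho
            assert rho > 0.6
            checked += 1
        assert checked == 12

    def test_unplanted_pairs_behave_like_null(self, field_study):
        """OTUs outside the planted structure exceed |rho| > 0.6 about as
        rarely as independent noise would."""
        rng = np.random.default_rng(0)
        planted = {otu for p in field_study.truth.planted_pairs
                   for otu in (p["otu_a"], p["otu_b"])}
        counts = field_study.tables["bacteria"].counts
        free = [o for o in counts.index if f"bacteria|{o}" not in planted]
        exceed = 0
        trials = 300
        for _ in range(trials):
            a, b = rng.choice(len(free), size=2, replace=False)
            rho = scipy.stats.spearmanr(counts.loc[free[a]],
                                        counts.loc[free[b]]).statistic
            exceed += abs(rho) > 0.6
        assert exceed / trials < 0.02

    def test_same_seed_identical_counts(self, field_study):
        spec = CommunitySpec(seed=2)
        a, _ = generate_multikingdom_counts(
            field_study.meta, spec,
            resource_levels=field_study.truth.resource_levels)
        b, _ = generate_multikingdom_counts(
            field_study.meta, spec,
            resource_levels=field_study.truth.resource_levels)
        for kingdom in a:
            pd.testing.assert_frame_equal(a[kingdom].counts,
                                          b[kingdom].counts)

    def test_depth_too_small_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="depth"):
            CommunitySpec(depth_per_kingdom={"bacteria": 100, "fungi": 100,
                                             "protists": 100,
                                             "nematodes": 100})

    def test_column_sums_equal_kingdom_depth(self, field_study):
        spec = CommunitySpec()
        for kingdom, table in field_study.tables.items():
            assert (table.counts.sum(axis=0)
                    == spec.depth_per_kingdom[kingdom]).all()


class TestTraits:
    def test_shape_and_nonnegativity(self, field_study):
        table = field_study.traits
        assert table.frequencies.shape == (10, 60)
        assert (table.frequencies.to_numpy() >= 0).all()

    def test_fewer_than_two_traits_rejected(self, field_study):
        with pytest.raises(ConfigurationError):
            generate_trait_frequencies(field_study.meta, n_traits=1, seed=0,
                                       resource_levels=field_study.truth
                                       .resource_levels)

    def test_same_seed_identical(self, field_study):
        levels = field_study.truth.resource_levels
        a, _ = generate_trait_frequencies(field_study.meta, seed=5,
                                          resource_levels=levels)
        b, _ = generate_trait_frequencies(field_study.meta, seed=5,
                                          resource_levels=levels)
        pd.testing.assert_frame_equal(a.frequencies, b.frequencies)


class TestBiolog:
    def test_every_plate_has_96_wells(self):
        plates, _ = generate_biolog_timeseries(seed=0)
        assert all(p.n_wells == 96 for p in plates)
        # 4 arms x 6 replicates x 3 subcultures
        assert len(plates) == 72

    def test_zero_noise_arm_is_degenerate_for_stability(self):
        plates, _ = generate_biolog_timeseries(
            arms={"flat": (0.5, 0.0)}, n_replicates=2, seed=0)
        table = stability_table(awcd_table(plates))
        assert table["degenerate"].all()

    def test_planted_low_cv_arm_ranks_higher_in_stability(self):
        plates, truth = generate_biolog_timeseries(seed=4)
        stab = stability_table(awcd_table(plates))
        mean_stab = stab.groupby("arm")["stability"].mean()
        cv = {a: p["temporal_cv"] for a, p in truth.biolog_arms.items()}
        assert mean_stab["M-High"] > mean_stab["M-Low"]
        assert cv["M-High"] < cv["M-Low"]

    def test_same_seed_identical(self):
        a, _ = generate_biolog_timeseries(seed=9)
        b, _ = generate_biolog_timeseries(seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.substrate_od, pb.substrate_od)


class TestBiomass:
    def test_default_design_counts(self):
        records, _ = generate_biomass(seed=0)
        assert len(records) == 576  # seedlings
        assert records["well_id"].nunique() == 144

    def test_full_resistance_arm_has_identical_means(self):
        means = {("I", "low", 20.0): 10.0, ("I", "low", 15.0): 10.0}
        spec = BiomassDesignSpec(means=means, noise_sd=0.0)
        records, _ = generate_biomass(spec, seed=0)
        by_temp = records.groupby("temperature")["biomass_mg"].mean()
        assert by_temp[15.0] == by_temp[20.0]

    def test_same_seed_identical(self):
        a, _ = generate_biomass(seed=3)
        b, _ = generate_biomass(seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGroundTruth:
    def test_round_trips_through_json(self, field_study, tmp_path):
        path = field_study.truth.to_json(tmp_path / "truth.json")
        back = GroundTruth.from_json(path)
        assert back.resource_levels == field_study.truth.resource_levels
        assert back.planted_pairs == field_study.truth.planted_pairs

    def test_whole_study_is_pure_function_of_seed(self):
        a = generate_field_study(seed=21)
        b = generate_field_study(seed=21)
        pd.testing.assert_frame_equal(a.soil, b.soil)
        pd.testing.assert_frame_equal(a.traits.frequencies,
                                      b.traits.frequencies)
        for kingdom in a.tables:
            pd.testing.assert_frame_equal(a.tables[kingdom].counts,
                                          b.tables[kingdom].counts)
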