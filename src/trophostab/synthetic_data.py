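"""Synthetic field and microcosm studies with planted ground truth.

The generators emulate the study design the pipeline targets: a field survey
of 5 long-term fertilisation sites x 4 treatments (C, NK, NPK, NPKM) x 3
replicates (60 samples), sequenced for four kingdoms spanning a basal
(bacteria, fungi) and a high (protists, nematodes) trophic level, plus a
liquid-culture microcosm arm with Biolog EcoPlate AWCD trajectories over 3
subcultures and Arabidopsis biomass at two temperatures.

Planted structure, recorded in :class:`GroundTruth` so recovery can be
scored:

* a monotone resource gradient (NPKM > NPK > NK > C in resource-relevant
  soil means within every site) with C/NK the true low-resource and
  NPK/NPKM the true high-resource arm;
* correlated OTU groups realised through a latent Gaussian copula on
  log-abundances, so their *rank* correlation is controlled directly:
  within-trophic blocks are predominantly coupled in the low-resource arm
  and cross-trophic pairs in the high-resource arm;
* higher trait-frequency means with lower cross-trait dispersion in the
  high-resource arm (higher functional trait stability);
* lower temporal AWCD variation in high-resource incubations;
* biomass effects: the multi-trophic system III with high resources grows
  most at both temperatures, while the bacteria-only system II loses more
  biomass under cooling when resources are high.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    BiologPlate,
    ConfigurationError,
    KINGDOMS,
    KingdomCountTable,
    N_BLANKS,
    N_SUBSTRATES,
    N_SUBSTRATE_REPLICATES,
    SampleMetadata,
    TROPHIC_LEVEL,
)

DEFAULT_SITES: tuple[str, ...] = ("FQ", "QY", "CW", "YT", "FK")

#: True resource level implied by the planted treatment gradient.
TRUE_LEVEL_BY_TREATMENT: Mapping[str, str] = {
    "C": "low", "NK": "low", "NPK": "high", "NPKM": "high",
}


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    resource_levels: dict[str, str] = dc_field(default_factory=dict)
    #: planted correlated OTU pairs: namespaced ids, expected sign,
    #: trophic scope ("within"/"cross") and the arm the coupling is active in
    planted_pairs: list[dict] = dc_field(default_factory=list)
    trait_params: dict = dc_field(default_factory=dict)
    biolog_arms: dict = dc_field(default_factory=dict)
    biomass_means: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "resource_levels": self.resource_levels,
            "planted_pairs": self.planted_pairs,
            "trait_params": self.trait_params,
            "biolog_arms": self.biolog_arms,
            "biomass_means": {"|".join(k): v
                              for k, v in self.biomass_means.items()},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            resource_levels=payload["resource_levels"],
            planted_pairs=payload["planted_pairs"],
            trait_params=payload["trait_params"],
            biolog_arms=payload["biolog_arms"],
            biomass_means={tuple(k.split("|")): v
                           for k, v in payload["biomass_means"].items()},
        )


# ---------------------------------------------------------------------------
# Field design and soil properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldDesignSpec:
    n_sites: int = 5
    treatments: tuple[str, ...] = ("C", "NK", "NPK", "NPKM")
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_sites and n_replicates must be >= 1")
        if not self.treatments:
            raise ConfigurationError("need at least one treatment")

    @property
    def site_names(self) -> list[str]:
        if self.n_sites <= len(DEFAULT_SITES):
            return list(DEFAULT_SITES[: self.n_sites])
        extra = [f"S{i}" for i in range(len(DEFAULT_SITES) + 1,
                                        self.n_sites + 1)]
        return list(DEFAULT_SITES) + extra


# Treatment multipliers on soil pools: totals respond moderately, readily
# available pools (mineral N, AP, AK) more strongly, so the availability
# ratios rise along the gradient as well.
_TOTAL_GAIN = {"C": 1.00, "NK": 1.12, "NPK": 1.28, "NPKM": 1.55}
_AVAILABLE_GAIN = {"C": 1.00, "NK": 1.35, "NPK": 1.80, "NPKM": 2.40}
_SOIL_NOISE_SD = 0.06  # lognormal sd of replicate-level variation


def _treatment_gain(table: Mapping[str, float], treatment: str,
                    rank: int, n: int) -> float:
    if treatment in table:
        return table[treatment]
    # unknown treatment names fall back to an evenly spaced monotone ramp
    lo, hi = min(table.values()), max(table.values())
    return lo + (hi - lo) * rank / max(n - 1, 1)


def generate_field_design(spec: FieldDesignSpec
                          ) -> tuple[list[SampleMetadata], pd.DataFrame,
                                     GroundTruth]:
    """Sample metadata, soil property table and ground truth for a field study.

    Soil properties carry a planted monotone resource gradient
    (NPKM > NPK > NK > C in expectation within every site).
    """
    rng = np.random.default_rng(spec.seed)
    sites = spec.site_names
    # site-level baselines (concentrations: g/kg for SOC/TN/TP/TK and OM,
    # mg/kg for mineral N, AP, AK)
    base = {
        site: {
            "SOC": rng.uniform(8.0, 20.0),
            "TN": rng.uniform(0.8, 2.0),
            "TP": rng.uniform(0.5, 1.2),
            "TK": rng.uniform(10.0, 22.0),
            "NH4_N": rng.uniform(4.0, 12.0),
            "NO3_N": rng.uniform(8.0, 30.0),
            "AP": rng.uniform(6.0, 20.0),
            "AK": rng.uniform(60.0, 140.0),
            "pH": rng.uniform(5.5, 8.2),
            "MAT": rng.uniform(6.0, 18.0),
            "MAP": rng.uniform(250.0, 1400.0),
        }
        for site in sites
    }
    meta: list[SampleMetadata] = []
    soil_rows: dict[str, dict[str, float]] = {}
    truth = GroundTruth()
    n_treat = len(spec.treatments)
    for site in sites:
        for rank, treatment in enumerate(spec.treatments):
            g_tot = _treatment_gain(_TOTAL_GAIN, treatment, rank, n_treat)
            g_avail = _treatment_gain(_AVAILABLE_GAIN, treatment, rank, n_treat)
            level = TRUE_LEVEL_BY_TREATMENT.get(
                treatment, "low" if rank < n_treat / 2 else "high")
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{site}_{treatment}_{rep}"
                meta.append(SampleMetadata(sample_id=sid, site=site,
                                           treatment=treatment, replicate=rep))
                truth.resource_levels[sid] = level
                noise = rng.lognormal(0.0, _SOIL_NOISE_SD, size=9)
                b = base[site]
                soc = b["SOC"] * g_tot * noise[0]
                row = {
                    "SOC": soc,
                    "TN": b["TN"] * g_tot * noise[1],
                    "TP": b["TP"] * g_tot * noise[2],
                    "TK": b["TK"] * (1 + (g_tot - 1) * 0.3) * noise[3],
                    "NH4_N": b["NH4_N"] * g_avail * noise[4],
                    "NO3_N": b["NO3_N"] * g_avail * noise[5],
                    "AP": b["AP"] * g_avail * noise[6],
                    "AK": b["AK"] * g_avail * noise[7],
                    "OM": 1.724 * soc * noise[8],
                    "pH": float(np.clip(b["pH"] + rng.normal(0.0, 0.12),
                                        3.5, 9.5)),
                    "MAT": b["MAT"],
                    "MAP": b["MAP"],
                }
                soil_rows[sid] = row
    soil = pd.DataFrame.from_dict(soil_rows, orient="index")
    soil.index.name = "sample_id"
    return meta, soil, truth


# ---------------------------------------------------------------------------
# Multi-kingdom communities with planted correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    """Community sizes, sequencing depths and planted correlation structure."""

    otus_per_kingdom: Mapping[str, int] = dc_field(default_factory=lambda: {
        "bacteria": 400, "fungi": 150, "protists": 80, "nematodes": 40})
    depth_per_kingdom: Mapping[str, int] = dc_field(default_factory=lambda: {
        "bacteria": 20000, "fungi": 10000, "protists": 6000,
        "nematodes": 3000})
    rho_plant: float = 0.9
    #: within-trophic correlated blocks active per arm (members of a block
    #: share one latent factor; every intra-block pair is a planted pair)
    n_within_blocks_low: int = 10
    n_within_blocks_high: int = 4
    block_size: int = 3
    #: cross-trophic correlated pairs active per arm
    n_cross_pairs_high: int = 30
    n_cross_pairs_low: int = 10
    #: fraction of planted couplings with negative sign
    negative_fraction: float = 0.25
    #: spread of OTU base log-abundances (community heterogeneity)
    heterogeneity: float = 1.2
    #: sd of the per-sample latent fluctuation entering the copula
    latent_sd: float = 1.0
    #: shrink factor on heterogeneity in the high-resource arm (-> more even
    #: communities, hence the planted diversity offset)
    high_arm_evenness: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.rho_plant < 1:
            raise ConfigurationError("rho_plant must lie in (-1, 1)")
        if self.block_size < 2:
            raise ConfigurationError("block_size must be >= 2")
        for kingdom in KINGDOMS:
            n = self.otus_per_kingdom[kingdom]
            d = self.depth_per_kingdom[kingdom]
            if d < 10 * n:
                raise ConfigurationError(
                    f"{kingdom}: depth {d} too small for {n} OTUs; planted "
                    "correlations need mean counts >= 10 per OTU")


def _allocate_planted(spec: CommunitySpec, rng: np.random.Generator
                      ) -> list[dict]:
    """Choose disjoint OTU index sets for blocks and pairs, deterministically.

    Returns coupling descriptors: {"kind": "block"|"pair", "members":
    [(kingdom, index), ...], "signs": [...], "arm": "low"|"high"}.
    """
    cursor = {k: 0 for k in KINGDOMS}

    def take(kingdom: str) -> tuple[str, int]:
        i = cursor[kingdom]
        if i >= spec.otus_per_kingdom[kingdom]:
            raise ConfigurationError(
                f"not enough {kingdom} OTUs for the planted structure")
        cursor[kingdom] = i + 1
        return (kingdom, i)

    couplings: list[dict] = []
    basal_cycle = ("bacteria", "bacteria", "fungi")
    high_cycle = ("protists", "nematodes")

    def block_members(idx: int, level: str) -> list[tuple[str, int]]:
        # most blocks sit in the basal level; every 4th in the high level so
        # all within-trophic kingdom pairs occur
        if level == "basal":
            cycle = basal_cycle
        else:
            cycle = ("protists", "protists", "nematodes")
        return [take(cycle[j % len(cycle)]) for j in range(spec.block_size)]

    for arm, n_blocks in (("low", spec.n_within_blocks_low),
                          ("high", spec.n_within_blocks_high)):
        for b in range(n_blocks):
            level = "high" if b % 4 == 3 else "basal"
            members = block_members(b, level)
            signs = [1] * len(members)
            if rng.random() < spec.negative_fraction:
                signs[-1] = -1  # one anti-correlated member
            couplings.append({"kind": "block", "members": members,
                              "signs": signs, "arm": arm})
    for arm, n_pairs in (("high", spec.n_cross_pairs_high),
                         ("low", spec.n_cross_pairs_low)):
        for j in range(n_pairs):
            basal = take(basal_cycle[j % len(basal_cycle)])
            high = take(high_cycle[j % len(high_cycle)])
            sign = -1 if rng.random() < spec.negative_fraction else 1
            couplings.append({"kind": "pair", "members": [basal, high],
                              "signs": [1, sign], "arm": arm})
    return couplings


def generate_multikingdom_counts(
    meta: Sequence[SampleMetadata],
    spec: CommunitySpec,
    resource_levels: Mapping[str, str] | None = None,
) -> tuple[dict[str, KingdomCountTable], GroundTruth]:
    """Four kingdom count tables with planted rank-correlated OTU groups.

    ``resource_levels`` maps sample id -> "low"/"high" (defaults to the
    metadata's own ``resource_level``). Counts are multinomial draws at a
    fixed per-kingdom depth from a latent log-normal abundance model; planted
    groups share a latent Gaussian factor only in the samples of their active
    arm, so the sample Spearman correlation there approaches ``rho_plant``.
    """
    if resource_levels is None:
        resource_levels = {m.sample_id: m.resource_level for m in meta}
    unknown = {s for s, lv in resource_levels.items() if lv not in ("low", "high")}
    if unknown:
        raise ConfigurationError(
            f"samples without a low/high resource level: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    samples = [m.sample_id for m in meta]
    arm_index = {"low": [i for i, s in enumerate(samples)
                         if resource_levels[s] == "low"],
                 "high": [i for i, s in enumerate(samples)
                          if resource_levels[s] == "high"]}

    couplings = _allocate_planted(spec, rng)
    truth = GroundTruth(resource_levels=dict(resource_levels))

    tables: dict[str, KingdomCountTable] = {}
    latent: dict[str, np.ndarray] = {}
    mu: dict[str, np.ndarray] = {}
    for kingdom in KINGDOMS:
        n_otus = spec.otus_per_kingdom[kingdom]
        mu_k = rng.normal(0.0, spec.heterogeneity, size=n_otus)
        latent[kingdom] = rng.normal(0.0, 1.0, size=(n_otus, len(samples)))
        mu[kingdom] = mu_k

    # overwrite latent rows of planted OTUs inside their active arm
    a_block = np.sqrt(abs(spec.rho_plant))  # block loading; pairwise |rho| = a^2
    for coupling in couplings:
        cols = arm_index[coupling["arm"]]
        if not cols:
            continue
        factor = rng.normal(0.0, 1.0, size=len(cols))
        if coupling["kind"] == "block":
            a = a_block
            for (kingdom, idx), sign in zip(coupling["members"],
                                            coupling["signs"]):
                eps = rng.normal(0.0, 1.0, size=len(cols))
                latent[kingdom][idx, cols] = (
                    sign * a * factor + np.sqrt(1 - a * a) * eps)
        else:  # pair: couple the second member directly to the first
            (k1, i1), (k2, i2) = coupling["members"]
            sign = coupling["signs"][1]
            z1 = rng.normal(0.0, 1.0, size=len(cols))
            eps = rng.normal(0.0, 1.0, size=len(cols))
            r = spec.rho_plant
            latent[k1][i1, cols] = z1
            latent[k2][i2, cols] = (
                sign * r * z1 + np.sqrt(1 - r * r) * eps)
        # record planted pairs (all intra-group pairs) in the ground truth
        members = coupling["members"]
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                (ka, ia), (kb, ib) = members[a_i], members[b_i]
                pair_sign = coupling["signs"][a_i] * coupling["signs"][b_i]
                scope = ("within"
                         if TROPHIC_LEVEL[ka] == TROPHIC_LEVEL[kb] else "cross")
                truth.planted_pairs.append({
                    "otu_a": f"{ka}|{_otu_name(ka, ia)}",
                    "otu_b": f"{kb}|{_otu_name(kb, ib)}",
                    "sign": "positive" if pair_sign > 0 else "negative",
                    "scope": scope,
                    "arm": coupling["arm"],
                    "rho_plant": (spec.rho_plant if coupling["kind"] == "pair"
                                  else pair_sign * abs(spec.rho_plant)),
                })

    # planted OTUs must be comfortably abundant so multinomial noise does not
    # drown the coupling: lift their base log-abundance above the median
    planted_idx: dict[str, set[int]] = {k: set() for k in KINGDOMS}
    for coupling in couplings:
        for kingdom, idx in coupling["members"]:
            planted_idx[kingdom].add(idx)
    for kingdom in KINGDOMS:
        idx = sorted(planted_idx[kingdom])
        if idx:
            mu[kingdom][idx] = np.abs(mu[kingdom][idx]) + 0.5

    evenness_scale = np.array([
        spec.high_arm_evenness if resource_levels[s] == "high" else 1.0
        for s in samples])
    for kingdom in KINGDOMS:
        n_otus = spec.otus_per_kingdom[kingdom]
        depth = spec.depth_per_kingdom[kingdom]
        log_ab = (mu[kingdom][:, None] * evenness_scale[None, :]
                  + spec.latent_sd * latent[kingdom])
        weights = np.exp(log_ab)
        weights /= weights.sum(axis=0)
        counts = np.empty((n_otus, len(samples)), dtype=np.int64)
        for j in range(len(samples)):
            counts[:, j] = rng.multinomial(depth, weights[:, j])
        df = pd.DataFrame(counts,
                          index=[_otu_name(kingdom, i) for i in range(n_otus)],
                          columns=samples)
        tables[kingdom] = KingdomCountTable(kingdom=kingdom, counts=df)
    return tables, truth


def _otu_name(kingdom: str, index: int) -> str:
    return f"{kingdom[:3].upper()}{index + 1:04d}"


# ---------------------------------------------------------------------------
# Trait frequencies
# ---------------------------------------------------------------------------

def generate_trait_frequencies(
    meta: Sequence[SampleMetadata],
    n_traits: int = 10,
    seed: int = 0,
    resource_levels: Mapping[str, str] | None = None,
):
    """Trait (functional gene) frequency table with a planted stability
    contrast: high-resource samples have larger trait means and smaller
    cross-trait dispersion, so both s(R) and 1/CV are higher there.
    """
    from .core_io import TraitFrequencyTable  # local import avoids cycle noise

    if n_traits < 2:
        raise ConfigurationError("n_traits must be >= 2 (1/CV undefined)")
    if resource_levels is None:
        resource_levels = {m.sample_id: m.resource_level for m in meta}
    unknown = {s for s, lv in resource_levels.items()
               if lv not in ("low", "high")}
    if unknown:
        raise ConfigurationError(
            f"samples without a low/high resource level: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    trait_means = rng.uniform(30.0, 70.0, size=n_traits)
    grand = trait_means.mean()
    params = {"gain_high": 1.35, "compress_high": 0.5,
              "noise_low": 0.30, "noise_high": 0.10}
    data = {}
    for m in meta:
        if resource_levels[m.sample_id] == "high":
            center = grand + params["compress_high"] * (trait_means - grand)
            vals = (center * params["gain_high"]
                    * (1 + rng.normal(0.0, params["noise_high"], n_traits)))
        else:
            vals = trait_means * (1 + rng.normal(0.0, params["noise_low"],
                                                 n_traits))
        data[m.sample_id] = np.clip(vals, 0.0, None)
    freq = pd.DataFrame(data, index=[f"gene{i + 1:02d}" for i in range(n_traits)])
    table = TraitFrequencyTable(frequencies=freq)
    return table, params


# ---------------------------------------------------------------------------
# Microcosm: Biolog plates and biomass
# ---------------------------------------------------------------------------

#: Default microcosm arms: (mean AWCD, planted temporal CV). High-resource
#: incubations develop more colour and vary less over subculturing.
DEFAULT_BIOLOG_ARMS: Mapping[str, tuple[float, float]] = {
    "C-Low": (0.45, 0.22),
    "C-High": (0.85, 0.10),
    "M-Low": (0.55, 0.20),
    "M-High": (1.00, 0.07),
}

SUBSTRATE_IDS: tuple[str, ...] = tuple(f"substrate{i + 1:02d}"
                                       for i in range(N_SUBSTRATES))


def generate_biolog_timeseries(
    n_subcultures: int = 3,
    arms: Mapping[str, tuple[float, float]] | None = None,
    n_replicates: int = 6,
    seed: int = 0,
) -> tuple[list[BiologPlate], GroundTruth]:
    """Biolog EcoPlates per arm x replicate x subculture.

    Each arm is parameterised by (mean AWCD, temporal CV). A CV of exactly 0
    produces noise-free constant plates, the degenerate case where the
    inverse-CV stability diverges.
    """
    if n_subcultures < 2:
        raise ConfigurationError("need >= 2 subcultures for temporal stability")
    arms = dict(arms) if arms is not None else dict(DEFAULT_BIOLOG_ARMS)
    rng = np.random.default_rng(seed)
    truth = GroundTruth(biolog_arms={a: {"mean_awcd": m, "temporal_cv": cv}
                                     for a, (m, cv) in arms.items()})
    # fixed substrate utilisation profile (mean 1) shared across plates
    profile = rng.lognormal(0.0, 0.4, size=N_SUBSTRATES)
    profile /= profile.mean()
    plates: list[BiologPlate] = []
    for arm, (mean_awcd, cv) in arms.items():
        for rep in range(1, n_replicates + 1):
            for sub in range(1, n_subcultures + 1):
                awcd = mean_awcd * (1 + cv * rng.normal()) if cv > 0 else mean_awcd
                awcd = max(awcd, 0.02)
                blank = 0.08
                od = blank + awcd * profile[:, None] * np.ones(
                    (N_SUBSTRATES, N_SUBSTRATE_REPLICATES))
                if cv > 0:
                    od = od + rng.normal(0.0, 0.01,
                                         size=(N_SUBSTRATES,
                                               N_SUBSTRATE_REPLICATES))
                plates.append(BiologPlate(
                    arm=arm, replicate=rep, subculture_index=sub,
                    substrate_ids=SUBSTRATE_IDS,
                    substrate_od=np.clip(od, 0.0, None),
                    blank_od=np.full(N_BLANKS, blank),
                ))
    return plates, truth


@dataclass(frozen=True)
class BiomassDesignSpec:
    """Mean seedling fresh biomass (mg) per (system, resource, temperature)."""

    wells_per_arm: int = 12
    plants_per_well: int = 4
    noise_sd: float = 1.5
    #: planted means: system III + high resources dominates at both
    #: temperatures; system II loses more under cooling when resources are
    #: high (lower resistance) — system I (axenic) shows no resource effect
    means: Mapping[tuple[str, str, float], float] = dc_field(
        default_factory=lambda: {
            ("I", "low", 20.0): 18.0, ("I", "low", 15.0): 16.5,
            ("I", "high", 20.0): 18.0, ("I", "high", 15.0): 16.5,
            ("II", "low", 20.0): 20.0, ("II", "low", 15.0): 18.0,
            ("II", "high", 20.0): 22.0, ("II", "high", 15.0): 14.0,
            ("III", "low", 20.0): 24.0, ("III", "low", 15.0): 19.0,
            ("III", "high", 20.0): 32.0, ("III", "high", 15.0): 30.0,
        })


def generate_biomass(design: BiomassDesignSpec | None = None,
                     seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Seedling fresh-biomass records: 3 systems x 2 resources x 2
    temperatures x 12 wells x 4 plants = 576 seedlings in 144 wells."""
    design = design or BiomassDesignSpec()
    rng = np.random.default_rng(seed)
    rows = []
    well_counter = 0
    for (system, resource, temp), mean in design.means.items():
        for w in range(1, design.wells_per_arm + 1):
            well_counter += 1
            well_id = f"{system}_{resource}_{int(temp)}C_w{w:02d}"
            for p in range(1, design.plants_per_well + 1):
                biomass = mean + rng.normal(0.0, design.noise_sd)
                rows.append({"system": system, "resource": resource,
                             "temperature": temp, "well_id": well_id,
                             "plant_index": p,
                             "biomass_mg": max(biomass, 0.1)})
    records = pd.DataFrame(rows)
    truth = GroundTruth(biomass_means={k: v for k, v in design.means.items()})
    return records, truth


# ---------------------------------------------------------------------------
# Convenience: a complete synthetic field study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFieldStudy:
    meta: list[SampleMetadata]
    soil: pd.DataFrame
    tables: dict[str, KingdomCountTable]
    traits: object  # TraitFrequencyTable
    truth: GroundTruth


def generate_field_study(field_spec: FieldDesignSpec | None = None,
                         community_spec: CommunitySpec | None = None,
                         n_traits: int = 10,
                         seed: int = 0) -> SyntheticFieldStudy:
    """One call producing metadata, soil, counts, traits and merged truth.

    Sub-generators get seeds derived from ``seed`` so the whole study is a
    pure function of its specs and ``seed``.
    """
    field_spec = field_spec or FieldDesignSpec(seed=seed)
    meta, soil, truth = generate_field_design(field_spec)
    community_spec = community_spec or CommunitySpec(seed=seed + 1)
    tables, community_truth = generate_multikingdom_counts(
        meta, community_spec, resource_levels=truth.resource_levels)
    traits, trait_params = generate_trait_frequencies(
        meta, n_traits=n_traits, seed=seed + 2,
        resource_levels=truth.resource_levels)
    truth.planted_pairs = community_truth.planted_pairs
    truth.trait_params = trait_params
    return SyntheticFieldStudy(meta=meta, soil=soil, tables=tables,
                               traits=traits, truth=truth)
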