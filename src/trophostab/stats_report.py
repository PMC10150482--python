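"""Group comparisons, linear fits, and end-to-end pipeline orchestration.

``run_field_pipeline`` chains the field stages — resource classification,
diversity, trait stability, per-arm co-occurrence networks, comparisons —
and ``run_microcosm_pipeline`` the microcosm stages (AWCD, temporal
stability, resistance). Both write TSV outputs plus a JSON run manifest
(config hash, seed, stages) so a run can be replayed exactly.

Random-forest predictor ranking, PLS-SEM path modelling and ANOVA/Tukey
multiple comparisons are deliberately not implemented here; register a
callable in :data:`POST_PIPELINE_HOOKS` to hand the bundled output tables to
any such external fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import diversity as dv
from . import microcosm as mc
from . import resource_index as ri
from . import synthetic_data as sd
from . import trait_stability as ts
from . import trophic_network as tn
from .core_io import (
    ConfigurationError,
    DegenerateInputError,
    KINGDOMS,
    TrophostabError,
    ValidationError,
    write_biolog_plates,
    write_biomass,
    write_count_table,
    write_integrated_table,
    write_metadata,
    write_network,
    write_soil_table,
    write_trait_table,
)

logger = logging.getLogger(__name__)

#: Extension hooks: name -> callable(bundle) run after a pipeline finishes.
#: Intended for off-the-shelf model fits (random forest importance, PLS-SEM,
#: ANOVA + Tukey HSD) that consume the pipeline's output tables.
POST_PIPELINE_HOOKS: dict[str, Callable] = {}


def significance_stars(p: float) -> str:
    """Render the conventional significance stars (0.05 / 0.01 / 0.001)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value out of [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    statistic_name: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    stars: str
    method: str


def wilcoxon_rank_sum(a, b, statistic_name: str = "",
                      group_a: str = "a", group_b: str = "b"
                      ) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is <= 10 and there are
    no ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method)
    p = float(res.pvalue)
    return ComparisonResult(
        statistic_name=statistic_name,
        group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=a.size, n_b=b.size,
        u_statistic=float(res.statistic),
        p_value=p, stars=significance_stars(p), method=method,
    )


@dataclass
class RegressionResult:
    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    stars: str


def linear_fit(x, y, predictor: str = "x", response: str = "y"
               ) -> RegressionResult:
    """Ordinary least squares y ~ x with R^2, F = (n-2) R^2 / (1 - R^2) and
    the two-sided p from F(1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need n >= 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor: slope undefined")
    fit = scipy.stats.linregress(x, y)
    n = x.size
    r2 = float(fit.rvalue ** 2)
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (n - 2) * r2 / (1.0 - r2)
        p = float(scipy.stats.f.sf(f_stat, 1, n - 2))
    return RegressionResult(
        predictor=predictor, response=response,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, f_statistic=f_stat, p_value=p, n=n,
        stars=significance_stars(p),
    )


# ---------------------------------------------------------------------------
# Configuration and manifests
# ---------------------------------------------------------------------------

DEFAULT_FIELD_CONFIG: dict = {
    "resource": {
        "degenerate_policy": "error",
        "treatment_override": None,  # e.g. {"C": "low", ...} bypasses the split
    },
    "diversity": {
        "depth": None,   # None -> per-kingdom minimum sample total
        "log_base": None,  # None -> natural log
        "renormalize": True,
    },
    "stability": {"sd_denominator": 0, "aggregate": "standardize-then-mean"},
    "network": {
        "rho_threshold": 0.6,
        "alpha": 0.05,
        "min_occurrence": 20,
        "occurrence_window": 30,
    },
    "simulate": {"n_traits": 10},
}

DEFAULT_MICROCOSM_CONFIG: dict = {
    "n_subcultures": 3,
    "n_replicates": 6,
    "sd_denominator": 0,
}


def _deep_merge(base: dict, override: Mapping | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for key, value in (override or {}).items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    loaded = yaml.safe_load(Path(path).read_text())
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    return loaded


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_manifest(out_dir: Path, name: str, config: Mapping, seed: int,
                    stages: Sequence[str], outputs: Sequence[str]) -> Path:
    manifest = {
        "pipeline": name,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "stages_completed": list(stages),
        "outputs": sorted(outputs),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


class StageError(TrophostabError):
    """A pipeline stage failed; the message carries the stage tag."""


# ---------------------------------------------------------------------------
# Field pipeline
# ---------------------------------------------------------------------------

@dataclass
class FieldResultBundle:
    meta: list
    soil: pd.DataFrame
    crai: pd.Series
    sfi: pd.Series
    classification: pd.DataFrame
    diversity_per_kingdom: pd.DataFrame
    diversity_integrated: pd.DataFrame
    stability: pd.DataFrame
    networks: dict
    network_properties: pd.DataFrame
    subnetworks: pd.DataFrame
    comparisons: pd.DataFrame
    regressions: pd.DataFrame
    truth: sd.GroundTruth | None
    manifest_path: Path | None
    extras: dict = field(default_factory=dict)


def run_field_pipeline(config: Mapping | None = None,
                       out_dir: str | Path | None = None,
                       seed: int = 0) -> FieldResultBundle:
    """Run the full field analysis on a simulated study.

    Stages: simulate -> resource classification -> diversity -> trait
    stability -> per-arm networks -> comparisons/regressions. Writes TSVs,
    GraphML networks, ground truth and a JSON manifest when ``out_dir`` is
    given. Deterministic given (config, seed).
    """
    cfg = _deep_merge(DEFAULT_FIELD_CONFIG, config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: list[str] = []

    def _stage(name: str):
        logger.info("field pipeline stage: %s", name)
        stages.append(name)

    def _save(obj_writer: Callable[[Path], object], filename: str) -> None:
        if out is not None:
            obj_writer(out / filename)
            outputs.append(filename)

    try:
        _stage("simulate")
        study = sd.generate_field_study(seed=seed,
                                        n_traits=cfg["simulate"]["n_traits"])
        _save(lambda p: write_metadata(study.meta, p), "metadata.tsv")
        _save(lambda p: write_soil_table(study.soil, p), "soil.tsv")
        _save(lambda p: write_trait_table(study.traits, p), "traits.tsv")
        _save(lambda p: study.truth.to_json(p), "ground_truth.json")
        for kingdom in KINGDOMS:
            _save(lambda p, k=kingdom: write_count_table(study.tables[k], p),
                  f"counts_{kingdom}.tsv")
    except TrophostabError as exc:
        raise StageError(f"[simulate] {exc}") from exc

    try:
        _stage("resource_index")
        policy = cfg["resource"]["degenerate_policy"]
        crai = ri.compute_crai_from_soil(study.soil, policy=policy)
        sfi = ri.compute_iqi(study.soil)
        meta = ri.classify_resource_levels(
            crai, study.meta,
            treatment_override=cfg["resource"]["treatment_override"])
        levels = {m.sample_id: m.resource_level for m in meta}
        classification = pd.DataFrame({
            "crai": crai,
            "sfi": sfi,
            "resource_level": pd.Series(levels),
            "true_level": pd.Series(study.truth.resource_levels),
        })
        classification.index.name = "sample_id"
        classification["correct"] = (classification["resource_level"]
                                     == classification["true_level"])
        _save(lambda p: crai.to_csv(p, sep="\t", float_format="%.12g"),
              "crai.tsv")
        _save(lambda p: sfi.to_csv(p, sep="\t", float_format="%.12g"),
              "sfi.tsv")
        _save(lambda p: classification.to_csv(p, sep="\t",
                                              float_format="%.12g"),
              "classification.tsv")
    except TrophostabError as exc:
        raise StageError(f"[resource_index] {exc}") from exc

    try:
        _stage("diversity")
        depth_cfg = cfg["diversity"]["depth"]
        rarefied = {}
        for i, kingdom in enumerate(KINGDOMS):
            table = study.tables[kingdom]
            depth = depth_cfg or dv.default_rarefaction_depth(table)
            rarefied[kingdom] = dv.rarefy(table, depth, seed=seed + 10 + i)
        integrated = dv.merge_integrated(
            rarefied, renormalize=cfg["diversity"]["renormalize"])
        per_kingdom = pd.concat(
            {k: dv.alpha_diversity(rarefied[k]) for k in KINGDOMS},
            names=["kingdom", "sample_id"])
        shannon_by_kingdom = per_kingdom["shannon"].unstack(level="kingdom").T
        div_int = pd.DataFrame({
            "integrated_shannon": dv.integrated_shannon(
                integrated, base=cfg["diversity"]["log_base"]),
            "bioref_shannon": dv.bioref(shannon_by_kingdom),
        })
        div_int.index.name = "sample_id"
        _save(lambda p: per_kingdom.to_csv(p, sep="\t", float_format="%.12g"),
              "diversity_per_kingdom.tsv")
        _save(lambda p: div_int.to_csv(p, sep="\t", float_format="%.12g"),
              "diversity_integrated.tsv")
        _save(lambda p: write_integrated_table(integrated, p),
              "integrated_table.tsv")
    except TrophostabError as exc:
        raise StageError(f"[diversity] {exc}") from exc

    try:
        _stage("trait_stability")
        stab = ts.functional_trait_stability(
            study.traits,
            ddof=cfg["stability"]["sd_denominator"],
            aggregate=cfg["stability"]["aggregate"]).records
        _save(lambda p: stab.to_csv(p, sep="\t", float_format="%.12g"),
              "stability.tsv")
    except TrophostabError as exc:
        raise StageError(f"[trait_stability] {exc}") from exc

    try:
        _stage("trophic_network")
        net_cfg = tn.NetworkConfig(
            rho_threshold=cfg["network"]["rho_threshold"],
            alpha=cfg["network"]["alpha"],
            min_occurrence=cfg["network"]["min_occurrence"],
            occurrence_window=cfg["network"]["occurrence_window"],
        )
        networks = {}
        prop_rows = {}
        sub_frames = []
        for level in ("low", "high"):
            samples = [s for s, lv in levels.items() if lv == level]
            arm_table = tn.IntegratedAbundanceTable(
                abundances=integrated.abundances[samples],
                kingdoms=integrated.kingdoms)
            filtered = tn.filter_by_occurrence(arm_table, net_cfg)
            net = tn.build_network(filtered, net_cfg, name=f"{level}_resource")
            networks[level] = net
            prop_rows[level] = tn.network_properties(net)
            subs = tn.sample_association_table(net, filtered)
            subs.insert(0, "resource_level", level)
            sub_frames.append(subs)
            _save(lambda p, n=net: write_network(n, p, "graphml"),
                  f"network_{level}.graphml")
            _save(lambda p, n=net: write_network(n, p, "edge_tsv"),
                  f"network_{level}_edges.tsv")
        net_props = pd.DataFrame(prop_rows).T
        net_props.index.name = "resource_level"
        subnetworks = pd.concat(sub_frames)
        _save(lambda p: net_props.to_csv(p, sep="\t", float_format="%.12g"),
              "network_properties.tsv")
        _save(lambda p: subnetworks.to_csv(p, sep="\t", float_format="%.12g"),
              "subnetwork_summary.tsv")
    except TrophostabError as exc:
        raise StageError(f"[trophic_network] {exc}") from exc

    try:
        _stage("stats_report")
        level_series = classification["resource_level"]
        metrics = {
            "crai": crai,
            "sfi": sfi,
            "integrated_shannon": div_int["integrated_shannon"],
            "stability": stab["stability"],
            "cta_proportion": subnetworks["cta_proportion"],
            "wta_proportion": subnetworks["wta_proportion"],
        }
        comp_rows = []
        for name, series in metrics.items():
            idx = series.dropna().index
            low = series[[s for s in idx if level_series.get(s) == "low"]]
            high = series[[s for s in idx if level_series.get(s) == "high"]]
            if len(low) >= 3 and len(high) >= 3:
                comp_rows.append(vars(wilcoxon_rank_sum(
                    low, high, statistic_name=name,
                    group_a="low", group_b="high")))
        comparisons = pd.DataFrame(comp_rows)

        reg_rows = []
        common = stab.index.intersection(div_int.index)
        for level in ("low", "high", "all"):
            if level == "all":
                sel = list(common)
            else:
                sel = [s for s in common if level_series.get(s) == level]
            if len(sel) >= 3:
                fit = linear_fit(div_int.loc[sel, "integrated_shannon"],
                                 stab.loc[sel, "stability"],
                                 predictor=f"integrated_shannon[{level}]",
                                 response="stability")
                reg_rows.append(vars(fit))
        regressions = pd.DataFrame(reg_rows)
        _save(lambda p: comparisons.to_csv(p, sep="\t", index=False,
                                           float_format="%.12g"),
              "comparisons.tsv")
        _save(lambda p: regressions.to_csv(p, sep="\t", index=False,
                                           float_format="%.12g"),
              "regressions.tsv")
    except TrophostabError as exc:
        raise StageError(f"[stats_report] {exc}") from exc

    manifest_path = None
    if out is not None:
        manifest_path = _write_manifest(out, "field", cfg, seed, stages,
                                        outputs)

    bundle = FieldResultBundle(
        meta=meta, soil=study.soil, crai=crai, sfi=sfi,
        classification=classification,
        diversity_per_kingdom=per_kingdom,
        diversity_integrated=div_int,
        stability=stab, networks=networks,
        network_properties=net_props, subnetworks=subnetworks,
        comparisons=comparisons, regressions=regressions,
        truth=study.truth, manifest_path=manifest_path,
    )
    for name, hook in POST_PIPELINE_HOOKS.items():
        bundle.extras[name] = hook(bundle)
    return bundle


# ---------------------------------------------------------------------------
# Microcosm pipeline
# ---------------------------------------------------------------------------

@dataclass
class MicrocosmResultBundle:
    awcd: pd.DataFrame
    stability: pd.DataFrame
    resistance: pd.DataFrame
    biomass: pd.DataFrame
    comparisons: pd.DataFrame
    truth: sd.GroundTruth
    manifest_path: Path | None
    extras: dict = field(default_factory=dict)


def run_microcosm_pipeline(config: Mapping | None = None,
                           out_dir: str | Path | None = None,
                           seed: int = 0) -> MicrocosmResultBundle:
    """AWCD, temporal stability and biomass resistance on simulated microcosms."""
    cfg = _deep_merge(DEFAULT_MICROCOSM_CONFIG, config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: list[str] = []

    try:
        stages.append("simulate")
        plates, truth = sd.generate_biolog_timeseries(
            n_subcultures=cfg["n_subcultures"],
            n_replicates=cfg["n_replicates"], seed=seed)
        biomass, biomass_truth = sd.generate_biomass(seed=seed + 1)
        truth.biomass_means = biomass_truth.biomass_means
        if out is not None:
            write_biolog_plates(plates, out / "biolog_plates.tsv")
            write_biomass(biomass, out / "biomass.tsv")
            outputs += ["biolog_plates.tsv", "biomass.tsv"]
    except TrophostabError as exc:
        raise StageError(f"[simulate] {exc}") from exc

    try:
        stages.append("awcd")
        awcd = mc.awcd_table(plates)
        stability = mc.stability_table(awcd, ddof=cfg["sd_denominator"])
    except TrophostabError as exc:
        raise StageError(f"[awcd] {exc}") from exc

    try:
        stages.append("resistance")
        resist = mc.resistance_table(biomass)
    except TrophostabError as exc:
        raise StageError(f"[resistance] {exc}") from exc

    try:
        stages.append("stats_report")
        comp_rows = []
        for prefix in sorted({a.split("-")[0] for a in stability["arm"]}):
            low = stability.loc[stability["arm"] == f"{prefix}-Low",
                                "stability"].dropna()
            high = stability.loc[stability["arm"] == f"{prefix}-High",
                                 "stability"].dropna()
            if len(low) >= 3 and len(high) >= 3:
                comp_rows.append(vars(wilcoxon_rank_sum(
                    low, high, statistic_name=f"awcd_stability[{prefix}]",
                    group_a=f"{prefix}-Low", group_b=f"{prefix}-High")))
        for system in sorted(resist["system"].unique()):
            low = resist.loc[(resist["system"] == system)
                             & (resist["resource"] == "low"), "resistance"]
            high = resist.loc[(resist["system"] == system)
                              & (resist["resource"] == "high"), "resistance"]
            if len(low) >= 3 and len(high) >= 3:
                comp_rows.append(vars(wilcoxon_rank_sum(
                    low, high, statistic_name=f"resistance[system {system}]",
                    group_a=f"{system}-low", group_b=f"{system}-high")))
        comparisons = pd.DataFrame(comp_rows)
        if out is not None:
            awcd.to_csv(out / "awcd.tsv", sep="\t", index=False,
                        float_format="%.12g")
            stability.to_csv(out / "microcosm_stability.tsv", sep="\t",
                             index=False, float_format="%.12g")
            resist.to_csv(out / "resistance.tsv", sep="\t", index=False,
                          float_format="%.12g")
            comparisons.to_csv(out / "microcosm_comparisons.tsv", sep="\t",
                               index=False, float_format="%.12g")
            outputs += ["awcd.tsv", "microcosm_stability.tsv",
                        "resistance.tsv", "microcosm_comparisons.tsv"]
    except TrophostabError as exc:
        raise StageError(f"[stats_report] {exc}") from exc

    manifest_path = None
    if out is not None:
        manifest_path = _write_manifest(out, "microcosm", cfg, seed, stages,
                                        outputs)
    bundle = MicrocosmResultBundle(
        awcd=awcd, stability=stability, resistance=resist, biomass=biomass,
        comparisons=comparisons, truth=truth, manifest_path=manifest_path,
    )
    for name, hook in POST_PIPELINE_HOOKS.items():
        bundle.extras[name] = hook(bundle)
    return bundle
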