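"""Composite resource availability (CRAI) and soil fertility (IQI/SFI) indices.

CRAI is the unweighted mean, per sample, of min-max standardized
resource-relevant soil properties: SOC, TN, TP, TK, the mineral-N fraction
(NH4-N + NO3-N):TN, AP:TP and AK:TK. Each property is standardized across
*all* samples pooled over sites,

    S = (x - min) / (max - min),

and samples are classified low/high resource within each site by a median
split of CRAI (a fixed treatment->level mapping may override the split).

The soil fertility index is an Integrated Quality Index: a weighted sum of
piecewise-linear scores of common chemical indicators (OM, AP, AK, pH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ConfigurationError,
    DegenerateInputError,
    SampleMetadata,
    TREATMENT_ORDER,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Resource-relevant indicators: four totals plus three availability ratios.
CRAI_INDICATORS: tuple[str, ...] = (
    "SOC", "TN", "TP", "TK", "mineral_N_to_TN", "AP_to_TP", "AK_to_TK",
)


def minmax_standardize(values, policy: str = "error") -> np.ndarray:
    """Min-max standardize a vector to [0, 1].

    ``policy`` controls the degenerate constant-vector case: ``"error"``
    raises, ``"midpoint"`` emits 0.5 for every entry.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to standardize")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        if policy == "midpoint":
            return np.full_like(x, 0.5)
        raise DegenerateInputError(
            "constant vector has zero range; set policy='midpoint' to emit 0.5")
    return (x - lo) / (hi - lo)


def resource_indicators(soil: pd.DataFrame) -> pd.DataFrame:
    """Derive the 7 resource-relevant indicators from a soil property table.

    Samples with a missing value or a non-positive ratio denominator are
    excluded with a warning.
    """
    needed = ["SOC", "TN", "TP", "TK", "NH4_N", "NO3_N", "AP", "AK"]
    sub = soil[needed].copy()
    bad_na = sub.isna().any(axis=1)
    denom_bad = (sub["TN"] <= 0) | (sub["TP"] <= 0) | (sub["TK"] <= 0)
    drop = bad_na | denom_bad.fillna(True)
    if drop.any():
        logger.warning("excluding %d sample(s) with missing values or zero "
                       "ratio denominators: %s", int(drop.sum()),
                       list(soil.index[drop]))
        sub = sub[~drop]
    out = pd.DataFrame(index=sub.index)
    out["SOC"] = sub["SOC"]
    out["TN"] = sub["TN"]
    out["TP"] = sub["TP"]
    out["TK"] = sub["TK"]
    out["mineral_N_to_TN"] = (sub["NH4_N"] + sub["NO3_N"]) / sub["TN"]
    out["AP_to_TP"] = sub["AP"] / sub["TP"]
    out["AK_to_TK"] = sub["AK"] / sub["TK"]
    return out


def compute_crai(indicators: pd.DataFrame, policy: str = "error") -> pd.Series:
    """Composite resource availability: standardize each indicator across all
    samples, then average over indicators per sample."""
    missing = set(CRAI_INDICATORS) - set(indicators.columns)
    if missing:
        raise ValidationError(f"missing indicators: {sorted(missing)}")
    scores = np.column_stack([
        minmax_standardize(indicators[c].to_numpy(), policy=policy)
        for c in CRAI_INDICATORS
    ])
    return pd.Series(scores.mean(axis=1), index=indicators.index, name="CRAI")


def compute_crai_from_soil(soil: pd.DataFrame, policy: str = "error") -> pd.Series:
    return compute_crai(resource_indicators(soil), policy=policy)


def classify_resource_levels(
    crai: pd.Series,
    meta: Sequence[SampleMetadata],
    treatment_override: Mapping[str, str] | None = None,
) -> list[SampleMetadata]:
    """Assign low/high resource levels within each site.

    Within a site, samples at or below the site median CRAI are low, the rest
    high; ties at the median are broken by treatment order (C < NK < NPK <
    NPKM) so an even site splits into equal halves. ``treatment_override``
    maps treatments directly to levels and bypasses the median split.
    """
    if treatment_override is not None:
        bad = set(treatment_override.values()) - {"low", "high"}
        if bad:
            raise ConfigurationError(f"override levels must be low/high: {bad}")
        return [m.with_resource_level(treatment_override[m.treatment])
                for m in meta]

    by_site: dict[str, list[SampleMetadata]] = {}
    for m in meta:
        by_site.setdefault(m.site, []).append(m)

    assigned: dict[str, str] = {}
    for site, members in by_site.items():
        if len(members) < 2:
            raise DegenerateInputError(
                f"site {site!r} has {len(members)} sample(s); need >= 2 to split")
        missing = [m.sample_id for m in members if m.sample_id not in crai.index]
        if missing:
            raise ValidationError(f"no CRAI value for samples {missing}")
        order = sorted(
            members,
            key=lambda m: (crai[m.sample_id],
                           TREATMENT_ORDER.get(m.treatment, len(TREATMENT_ORDER)),
                           m.sample_id),
        )
        n = len(order)
        if n % 2 == 0:
            n_low = n // 2
        else:
            med = float(np.median([crai[m.sample_id] for m in members]))
            n_low = sum(crai[m.sample_id] <= med for m in members)
        for i, m in enumerate(order):
            assigned[m.sample_id] = "low" if i < n_low else "high"
    return [m.with_resource_level(assigned[m.sample_id]) for m in meta]


# ---------------------------------------------------------------------------
# Integrated Quality Index (soil fertility)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreFunction:
    """Piecewise-linear indicator score: breakpoints map raw value -> [0, 1].

    Values outside the breakpoint range are clamped to the terminal scores.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        xs = [b[0] for b in self.breakpoints]
        ss = [b[1] for b in self.breakpoints]
        if len(xs) < 2:
            raise ConfigurationError("score function needs >= 2 breakpoints")
        if any(b >= a for a, b in zip(xs[1:], xs[:-1])):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if any(s < 0 or s > 1 for s in ss):
            raise ConfigurationError("scores must lie in [0, 1]")

    def __call__(self, value) -> np.ndarray | float:
        xs = np.array([b[0] for b in self.breakpoints])
        ss = np.array([b[1] for b in self.breakpoints])
        return np.interp(value, xs, ss)


def score_indicator(value, fn: ScoreFunction):
    """Score a raw indicator value through a piecewise-linear score function."""
    return fn(value)


# Default scoring curves: monotone 3-breakpoint ramps over agronomically
# plausible ranges (OM in g/kg, AP and AK in mg/kg). Site-specific weight
# tables can replace these wholesale through IqiSpec.
DEFAULT_SCORE_FUNCTIONS: Mapping[str, ScoreFunction] = {
    "OM": ScoreFunction(((5.0, 0.1), (20.0, 0.6), (40.0, 1.0))),
    "AP": ScoreFunction(((5.0, 0.1), (20.0, 0.6), (60.0, 1.0))),
    "AK": ScoreFunction(((30.0, 0.1), (100.0, 0.6), (200.0, 1.0))),
    "pH": ScoreFunction(((4.5, 0.2), (6.5, 0.8), (7.5, 1.0))),
}


@dataclass
class IqiSpec:
    """Indicators, weights (summing to 1) and score functions for the IQI."""

    weights: Mapping[str, float] = field(
        default_factory=lambda: {"OM": 0.25, "AP": 0.25, "AK": 0.25, "pH": 0.25})
    score_functions: Mapping[str, ScoreFunction] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_FUNCTIONS))

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"IQI weights must sum to 1, got {total}")
        missing = set(self.weights) - set(self.score_functions)
        if missing:
            raise ConfigurationError(
                f"no score function for indicators: {sorted(missing)}")


def compute_iqi(soil: pd.DataFrame, spec: IqiSpec | None = None) -> pd.Series:
    """Soil fertility index: IQI = sum_i W_i * S_i(raw_i) per sample.

    Samples missing any scored indicator are excluded with a warning.
    """
    spec = spec or IqiSpec()
    indicators = list(spec.weights)
    missing_cols = set(indicators) - set(soil.columns)
    if missing_cols:
        raise ValidationError(f"soil table missing indicators: {sorted(missing_cols)}")
    sub = soil[indicators]
    drop = sub.isna().any(axis=1)
    if drop.any():
        logger.warning("excluding %d sample(s) with missing IQI indicators",
                       int(drop.sum()))
        sub = sub[~drop]
    total = np.zeros(len(sub))
    for name, weight in spec.weights.items():
        total = total + weight * np.asarray(
            spec.score_functions[name](sub[name].to_numpy()))
    return pd.Series(total, index=sub.index, name="SFI")
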