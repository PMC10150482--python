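"""Functional trait stability from trait redundancy and the inverse CV.

Each sample carries a vector of functional-trait redundancy frequencies
(one per functional gene). Two per-sample summaries are combined:

* ``1/CV`` — the mean over traits divided by the (population) standard
  deviation over traits; larger when trait frequencies are uniform.
* ``s(R)`` — each trait's frequency min-max standardized across samples,
  averaged over traits.

Functional trait stability = (s(R) + s(1/CV)) / 2, with 1/CV itself
min-max standardized across samples before averaging, so the result lies
in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DegenerateInputError, TraitFrequencyTable
from .resource_index import minmax_standardize

logger = logging.getLogger(__name__)


def inverse_cv(frequencies, ddof: int = 0) -> float:
    """Inverse coefficient of variation mu/sigma of a trait-frequency vector.

    ``ddof=0`` (population standard deviation, denominator n) is the default;
    ``ddof=1`` gives the sample version.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size < 2:
        raise DegenerateInputError("1/CV needs >= 2 traits")
    sigma = f.std(ddof=ddof)
    mean = f.mean()
    # constant vectors can leave a ~1e-17 residual sigma in floating point
    if sigma <= 1e-12 * max(abs(mean), 1e-300):
        raise DegenerateInputError("all trait frequencies equal: sigma = 0")
    return float(mean / sigma)


def standardized_redundancy(table: TraitFrequencyTable,
                            policy: str = "error",
                            aggregate: str = "standardize-then-mean") -> pd.Series:
    """Per-sample standardized redundancy s(R).

    Default: each trait is min-max standardized across samples, then averaged
    over traits. ``aggregate="mean-then-standardize"`` instead standardizes
    the per-sample mean frequency (identical rank order when traits are
    comonotone).
    """
    freq = table.frequencies
    if freq.shape[1] < 2:
        raise DegenerateInputError("s(R) needs >= 2 samples")
    if aggregate == "standardize-then-mean":
        rows = np.vstack([
            minmax_standardize(freq.loc[t].to_numpy(), policy=policy)
            for t in freq.index
        ])
        values = rows.mean(axis=0)
    elif aggregate == "mean-then-standardize":
        values = minmax_standardize(freq.mean(axis=0).to_numpy(), policy=policy)
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return pd.Series(values, index=freq.columns, name="s_R")


@dataclass
class StabilityResult:
    """Per-sample stability components plus the ids of excluded samples."""

    records: pd.DataFrame  # columns: s_R, inv_cv, s_inv_cv, stability
    degenerate_samples: list[str]


def functional_trait_stability(table: TraitFrequencyTable,
                               ddof: int = 0,
                               policy: str = "error",
                               aggregate: str = "standardize-then-mean"
                               ) -> StabilityResult:
    """Functional trait stability = (s(R) + s(1/CV)) / 2 per sample.

    Samples whose trait vector has zero variance (1/CV undefined) are
    excluded and reported in ``degenerate_samples``.
    """
    freq = table.frequencies
    if freq.shape[0] < 2:
        raise DegenerateInputError("need >= 2 traits")
    inv, degenerate = {}, []
    for sample in freq.columns:
        try:
            inv[sample] = inverse_cv(freq[sample].to_numpy(), ddof=ddof)
        except DegenerateInputError:
            degenerate.append(sample)
    if degenerate:
        logger.warning("excluding %d sample(s) with zero trait variance: %s",
                       len(degenerate), degenerate)
    kept = [s for s in freq.columns if s not in set(degenerate)]
    if len(kept) < 2:
        raise DegenerateInputError("fewer than 2 samples with defined 1/CV")
    sub = TraitFrequencyTable(frequencies=freq[kept])
    s_r = standardized_redundancy(sub, policy=policy, aggregate=aggregate)
    inv_series = pd.Series({s: inv[s] for s in kept}, name="inv_cv")
    s_inv = pd.Series(minmax_standardize(inv_series.to_numpy(), policy=policy),
                      index=kept, name="s_inv_cv")
    records = pd.DataFrame({
        "s_R": s_r,
        "inv_cv": inv_series,
        "s_inv_cv": s_inv,
        "stability": 0.5 * (s_r + s_inv),
    })
    records.index.name = "sample_id"
    return StabilityResult(records=records, degenerate_samples=degenerate)
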