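"""Rarefaction, four-kingdom merge, and biodiversity indices.

The integrated community table is built the way multi-amplicon studies merge
independently sequenced kingdoms: each kingdom's counts are rarefied,
transformed to within-kingdom relative abundances, concatenated with
kingdom-namespaced OTU ids, and (by default) renormalized so every sample is
again a probability vector. Diversity is summarised by Chao1 richness,
Shannon entropy (natural log by default) and Pielou evenness, plus the
standardized multi-kingdom reference diversity Bio_ref: each kingdom's
per-sample diversity is min-max standardized across samples and the four
standardized values are averaged.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DegenerateInputError,
    IntegratedAbundanceTable,
    KINGDOMS,
    KingdomCountTable,
    ValidationError,
)
from .resource_index import minmax_standardize

logger = logging.getLogger(__name__)


def rarefy(table: KingdomCountTable, depth: int, seed: int) -> KingdomCountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning;
    deterministic given ``seed``.
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = [s for s in counts.columns if s not in set(keep)]
    if dropped:
        logger.warning("rarefy(%s, depth=%d): dropping %d sample(s) below "
                       "depth: %s", table.kingdom, depth, len(dropped), dropped)
    if len(keep) == 0:
        raise DegenerateInputError(
            f"all {table.kingdom} samples are below depth {depth}")
    out = {}
    for sample in keep:
        col = counts[sample].to_numpy()
        if col.sum() == depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=counts.index)[list(keep)]
    return KingdomCountTable(kingdom=table.kingdom, counts=rarefied)


def default_rarefaction_depth(table: KingdomCountTable) -> int:
    """Standard practice: rarefy to the smallest per-sample total."""
    return int(table.counts.sum(axis=0).min())


def merge_integrated(tables: Mapping[str, KingdomCountTable],
                     renormalize: bool = True) -> IntegratedAbundanceTable:
    """Merge the four kingdoms into one integrated relative-abundance table.

    Each kingdom is first transformed to within-kingdom relative abundances
    (each kingdom sums to 1 per sample); the blocks are concatenated with
    kingdom-prefixed OTU ids; with ``renormalize`` (default) every sample
    column is rescaled to sum to 1 — otherwise a sample covered by all four
    kingdoms sums to 4.
    """
    if not tables:
        raise ValidationError("no kingdom tables to merge")
    unknown = set(tables) - set(KINGDOMS)
    if unknown:
        raise ValidationError(f"unknown kingdoms: {sorted(unknown)}")
    sample_sets = {k: tuple(t.sample_ids) for k, t in tables.items()}
    ref = set(next(iter(sample_sets.values())))
    for k, ids in sample_sets.items():
        if set(ids) != ref:
            raise ValidationError(
                f"sample sets differ between kingdoms (e.g. {k}); "
                "run validate_dataset for details")
    samples = sorted(ref)
    blocks, kingdom_labels = [], []
    for kingdom in (k for k in KINGDOMS if k in tables):
        counts = tables[kingdom].counts[samples].astype(float)
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValidationError(f"{kingdom} has empty samples: {empty}")
        rel = counts / totals
        rel.index = [f"{kingdom}|{otu}" for otu in rel.index]
        blocks.append(rel)
        kingdom_labels.extend([kingdom] * rel.shape[0])
    merged = pd.concat(blocks, axis=0)
    if renormalize:
        merged = merged / merged.sum(axis=0)
    return IntegratedAbundanceTable(
        abundances=merged,
        kingdoms=pd.Series(kingdom_labels, index=merged.index, name="kingdom"),
    )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(p: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i of a probability vector.

    Natural log by default; zeros contribute nothing. The vector must sum to
    1 within 1e-6.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("abundances must be >= 0")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"abundances must sum to 1 (got {total!r})")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts: Sequence[int]) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2); bias-corrected
    S_obs + F1(F1-1)/2 when no doubletons exist."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValidationError("counts must be >= 0")
    c = c[c > 0]
    if c.size == 0:
        raise DegenerateInputError("empty sample: Chao1 undefined")
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def pielou(p: Sequence[float]) -> float:
    """Pielou evenness J = H / ln(S_obs), in [0, 1]; needs >= 2 nonzero taxa."""
    p = np.asarray(p, dtype=float)
    s_obs = int((p > 0).sum())
    if s_obs < 2:
        raise DegenerateInputError("evenness undefined for < 2 taxa")
    return shannon(p) / np.log(s_obs)


def alpha_diversity(table: KingdomCountTable) -> pd.DataFrame:
    """Chao1, Shannon and Pielou per sample of a kingdom count table."""
    rows = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = col.sum()
        if total == 0:
            raise DegenerateInputError(f"sample {sample!r} is empty")
        p = col / total
        rows[sample] = {
            "chao1": chao1(col),
            "shannon": shannon(p),
            "evenness": pielou(p),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def integrated_shannon(table: IntegratedAbundanceTable,
                       base: float | None = None) -> pd.Series:
    """Shannon entropy of each sample's integrated abundance vector."""
    vals = {s: shannon(table.abundances[s].to_numpy() /
                       table.abundances[s].sum(), base=base)
            for s in table.sample_ids}
    return pd.Series(vals, name="integrated_shannon")


def bioref(per_kingdom: pd.DataFrame, policy: str = "error") -> pd.Series:
    """Standardized multi-kingdom diversity Bio_ref.

    ``per_kingdom`` is kingdom x sample (one diversity index). Each kingdom
    row is min-max standardized across samples, then the four standardized
    values are averaged per sample.
    """
    missing = set(KINGDOMS) - set(per_kingdom.index)
    if missing:
        raise ValidationError(f"missing kingdom rows: {sorted(missing)}")
    if per_kingdom.shape[1] < 2:
        raise DegenerateInputError("need >= 2 samples for standardization")
    rows = np.vstack([
        minmax_standardize(per_kingdom.loc[k].to_numpy(), policy=policy)
        for k in KINGDOMS
    ])
    return pd.Series(rows.mean(axis=0), index=per_kingdom.columns,
                     name="bioref")
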