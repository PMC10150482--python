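"""Multi-kingdom co-occurrence networks and trophic association taxonomy.

Networks are inferred from the integrated abundance table: OTUs passing an
occurrence filter are correlated pairwise by Spearman's rho (average ranks
for ties; two-sided p from the t approximation on n - 2 df), all raw p-values
are adjusted with the Benjamini-Hochberg step-up procedure across every
tested pair, and an edge is retained when BOTH |rho| exceeds the threshold
(default 0.6) and the adjusted p falls below alpha (default 0.05).

Every retained edge is classified into one of 20 (kingdom pair, sign) types
and 4 categories — positive/negative within-trophic and cross-trophic —
where bacteria and fungi form the basal trophic level and protists and
nematodes the high trophic level; an edge is "within" exactly when its
endpoints share a trophic level. Per-sample subnetworks (induced subgraphs
on the OTUs present in that sample) yield per-sample association proportions
(WTA/CTA) and conventional network properties.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    AssociationNetwork,
    ConfigurationError,
    DegenerateInputError,
    IntegratedAbundanceTable,
    KINGDOMS,
    TROPHIC_LEVEL,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """Thresholds for co-occurrence network construction."""

    rho_threshold: float = 0.6
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    min_occurrence: int = 20
    occurrence_window: int = 30  # documented group size the filter refers to

    def __post_init__(self) -> None:
        if not 0 < self.rho_threshold < 1:
            raise ConfigurationError("rho_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.min_occurrence < 0:
            raise ConfigurationError("min_occurrence must be >= 0")


@dataclass(frozen=True)
class EdgeType:
    """One of the 20 (unordered kingdom pair, sign) association types."""

    kingdom_a: str
    kingdom_b: str
    sign: str      # "positive" | "negative"
    category: str  # e.g. "positive-within"

    @property
    def label(self) -> str:
        return f"{self.kingdom_a}-{self.kingdom_b}:{self.sign}"


CATEGORIES: tuple[str, ...] = (
    "positive-within", "negative-within", "positive-cross", "negative-cross",
)


def classify_edge(kingdom_a: str, kingdom_b: str, rho: float) -> EdgeType:
    """Map an edge's endpoint kingdoms and correlation sign to its type.

    Within-trophic iff both endpoints are basal (bacteria/fungi) or both high
    (protists/nematodes); sign follows sign(rho).
    """
    for k in (kingdom_a, kingdom_b):
        if k not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {k!r}")
    if rho == 0:
        raise ValidationError("cannot classify an edge with rho = 0")
    a, b = sorted((kingdom_a, kingdom_b), key=KINGDOMS.index)
    sign = "positive" if rho > 0 else "negative"
    scope = "within" if TROPHIC_LEVEL[a] == TROPHIC_LEVEL[b] else "cross"
    return EdgeType(a, b, sign, f"{sign}-{scope}")


def enumerate_edge_types() -> list[EdgeType]:
    """All 20 types: 10 unordered kingdom pairs (self-pairs included) x 2 signs."""
    types = []
    for a, b in itertools.combinations_with_replacement(KINGDOMS, 2):
        for rho in (1.0, -1.0):
            types.append(classify_edge(a, b, rho))
    return types


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def spearman_with_p(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman's rho with a two-sided p-value.

    ``method``: ``"t"`` uses the t approximation on n - 2 df; ``"exact"``
    enumerates all rank permutations (n <= 9); ``"auto"`` picks "t".
    Constant input is undefined and raises ``DegenerateInputError`` — callers
    building networks drop constant OTUs beforehand.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    if x.size < 3:
        raise ValidationError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: Spearman undefined")
    if method in ("auto", "t"):
        rho, p = scipy.stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "exact":
        if x.size > 9:
            raise ConfigurationError("exact permutation p limited to n <= 9")
        rho = float(scipy.stats.spearmanr(x, y).statistic)
        ry = scipy.stats.rankdata(y)
        rx = scipy.stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(range(x.size)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    raise ConfigurationError(f"unknown method {method!r}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p for row vectors."""
    n = values.shape[1]
    ranks = scipy.stats.rankdata(values, axis=1)
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1
    return rho, p


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def filter_by_occurrence(table: IntegratedAbundanceTable,
                         cfg: NetworkConfig) -> IntegratedAbundanceTable:
    """Keep OTUs with nonzero abundance in at least ``min_occurrence`` samples."""
    n_samples = table.abundances.shape[1]
    if cfg.min_occurrence > n_samples:
        raise ConfigurationError(
            f"min_occurrence {cfg.min_occurrence} exceeds sample count {n_samples}")
    occurrence = (table.abundances > 0).sum(axis=1)
    keep = occurrence[occurrence >= cfg.min_occurrence].index
    if len(keep) == 0:
        raise DegenerateInputError("no OTU passes the occurrence filter")
    return IntegratedAbundanceTable(
        abundances=table.abundances.loc[keep],
        kingdoms=table.kingdoms.loc[keep],
    )


def build_network(table: IntegratedAbundanceTable, cfg: NetworkConfig,
                  name: str = "network") -> AssociationNetwork:
    """Construct the co-occurrence network from a filtered abundance table.

    All OTU pairs are tested; BH adjustment runs across every tested pair;
    an edge needs both |rho| > ``rho_threshold`` and adjusted p < ``alpha``.
    Constant OTUs (Spearman undefined) are skipped with a warning. Nodes are
    restricted to OTUs with at least one retained edge.
    """
    abund = table.abundances
    if abund.shape[0] < 2:
        raise DegenerateInputError("need >= 2 OTUs to build a network")
    values = abund.to_numpy()
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        logger.warning("skipping %d constant OTU(s) with undefined Spearman",
                       int(constant.sum()))
        abund = abund.loc[~constant]
        values = abund.to_numpy()
        if values.shape[0] < 2:
            raise DegenerateInputError("fewer than 2 non-constant OTUs")
    otus = list(abund.index)
    rho_mat, p_mat = _spearman_matrix(values)
    iu, ju = np.triu_indices(len(otus), k=1)
    raw_p = p_mat[iu, ju]
    adj_p = bh_adjust(raw_p)
    rho = rho_mat[iu, ju]
    keep = (np.abs(rho) > cfg.rho_threshold) & (adj_p < cfg.alpha)

    graph = nx.Graph(name=name)
    kingdoms = table.kingdoms
    for idx in np.flatnonzero(keep):
        a, b = otus[iu[idx]], otus[ju[idx]]
        etype = classify_edge(kingdoms[a], kingdoms[b], rho[idx])
        for node in (a, b):
            if node not in graph:
                graph.add_node(node, kingdom=kingdoms[node],
                               trophic_level=TROPHIC_LEVEL[kingdoms[node]])
        graph.add_edge(a, b,
                       rho=float(rho[idx]),
                       raw_p=float(raw_p[idx]),
                       adjusted_p=float(adj_p[idx]),
                       sign=etype.sign,
                       type=etype.label,
                       category=etype.category)
    return AssociationNetwork(graph=graph, name=name)


def extract_sample_subnetwork(net: AssociationNetwork,
                              sample_abundances: pd.Series) -> AssociationNetwork:
    """Induced subgraph on the OTUs with nonzero abundance in one sample."""
    present = set(sample_abundances.index[sample_abundances > 0])
    nodes = [n for n in net.graph.nodes if n in present]
    sub = net.graph.subgraph(nodes).copy()
    return AssociationNetwork(graph=sub, name=f"{net.name}:subnetwork")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class SubnetworkSummary:
    """Association category/type counts and proportions for one subnetwork."""

    sample_id: str
    n_nodes: int
    n_links: int
    category_counts: Mapping[str, int]
    category_proportions: Mapping[str, float]  # NaN when n_links == 0
    type_counts: Mapping[str, int]
    type_proportions: Mapping[str, float]
    mean_degree: float
    density: float
    clustering: float

    @property
    def wta_proportion(self) -> float:
        return (self.category_proportions["positive-within"]
                + self.category_proportions["negative-within"])

    @property
    def cta_proportion(self) -> float:
        return (self.category_proportions["positive-cross"]
                + self.category_proportions["negative-cross"])


def association_proportions(sub: AssociationNetwork,
                            sample_id: str = "") -> SubnetworkSummary:
    """Category and type proportions plus basic properties of a subnetwork."""
    graph = sub.graph
    all_types = [t.label for t in enumerate_edge_types()]
    cat_counts = dict.fromkeys(CATEGORIES, 0)
    type_counts = dict.fromkeys(all_types, 0)
    for _, _, data in graph.edges(data=True):
        cat_counts[data["category"]] += 1
        type_counts[data["type"]] += 1
    n_links = graph.number_of_edges()
    n_nodes = graph.number_of_nodes()
    if n_links:
        cat_prop = {k: v / n_links for k, v in cat_counts.items()}
        type_prop = {k: v / n_links for k, v in type_counts.items()}
    else:
        cat_prop = dict.fromkeys(CATEGORIES, math.nan)
        type_prop = dict.fromkeys(all_types, math.nan)
    return SubnetworkSummary(
        sample_id=sample_id,
        n_nodes=n_nodes,
        n_links=n_links,
        category_counts=cat_counts,
        category_proportions=cat_prop,
        type_counts=type_counts,
        type_proportions=type_prop,
        mean_degree=(2 * n_links / n_nodes) if n_nodes else 0.0,
        density=nx.density(graph) if n_nodes > 1 else 0.0,
        clustering=nx.average_clustering(graph) if n_nodes else 0.0,
    )


def sample_association_table(net: AssociationNetwork,
                             table: IntegratedAbundanceTable) -> pd.DataFrame:
    """Per-sample subnetwork summaries as one tidy frame (row per sample)."""
    rows = []
    for sample in table.sample_ids:
        summary = association_proportions(
            extract_sample_subnetwork(net, table.abundances[sample]),
            sample_id=sample)
        row = {
            "sample_id": sample,
            "n_nodes": summary.n_nodes,
            "n_links": summary.n_links,
            "mean_degree": summary.mean_degree,
            "density": summary.density,
            "clustering": summary.clustering,
            "wta_proportion": summary.wta_proportion,
            "cta_proportion": summary.cta_proportion,
        }
        for cat in CATEGORIES:
            row[f"prop_{cat}"] = summary.category_proportions[cat]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def network_properties(net: AssociationNetwork) -> dict[str, float]:
    """Conventional whole-network properties; path length on the largest
    connected component."""
    graph = net.graph
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    props: dict[str, float] = {
        "n_nodes": n,
        "n_links": m,
        "mean_degree": (2 * m / n) if n else 0.0,
        "density": nx.density(graph) if n > 1 else 0.0,
        "clustering": nx.average_clustering(graph) if n else 0.0,
    }
    if n:
        components = list(nx.connected_components(graph))
        giant = graph.subgraph(max(components, key=len))
        props["n_components"] = len(components)
        props["avg_path_length_lcc"] = (
            nx.average_shortest_path_length(giant)
            if giant.number_of_nodes() > 1 else 0.0)
    else:
        props["n_components"] = 0
        props["avg_path_length_lcc"] = math.nan
    return props
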