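"""Data model, validation, and readers/writers for the pipeline's tables and networks.

All tabular formats are TSV (UTF-8, '.' decimal): samples in columns, first
column the feature id. Networks round-trip through GraphML or a flat edge TSV.
Validation reports are plain dataclasses serialisable to JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINGDOMS: tuple[str, ...] = ("bacteria", "fungi", "protists", "nematodes")

#: Trophic position of each kingdom: bacteria and fungi form the basal
#: (decomposer) level, protists and nematodes the high (consumer) level.
TROPHIC_LEVEL: Mapping[str, str] = {
    "bacteria": "basal",
    "fungi": "basal",
    "protists": "high",
    "nematodes": "high",
}

TREATMENTS: tuple[str, ...] = ("C", "NK", "NPK", "NPKM")

#: Canonical treatment ordering used for tie-breaks (ascending resource input).
TREATMENT_ORDER: Mapping[str, int] = {t: i for i, t in enumerate(TREATMENTS)}

SOIL_COLUMNS: tuple[str, ...] = (
    "SOC", "TN", "TP", "TK", "NH4_N", "NO3_N", "AP", "AK", "OM", "pH",
    "MAT", "MAP",
)

RESOURCE_LEVELS: tuple[str, ...] = ("low", "high", "unassigned")

N_SUBSTRATES = 31
N_SUBSTRATE_REPLICATES = 3
N_BLANKS = 3
WELLS_PER_PLATE = N_SUBSTRATES * N_SUBSTRATE_REPLICATES + N_BLANKS  # 96


class TrophostabError(Exception):
    """Base class for package errors."""


class FormatError(TrophostabError):
    """A file does not parse as the expected on-disk format."""


class ValidationError(TrophostabError):
    """Parsed data violates a type invariant."""


class ConfigurationError(TrophostabError):
    """An analysis was configured inconsistently."""


class DegenerateInputError(TrophostabError):
    """Input is structurally valid but the requested statistic is undefined
    on it (zero range, zero variance, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMetadata:
    """One field or microcosm sample: site, treatment, replicate."""

    sample_id: str
    site: str
    treatment: str
    replicate: int
    resource_level: str = "unassigned"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.resource_level not in RESOURCE_LEVELS:
            raise ValidationError(
                f"resource_level must be one of {RESOURCE_LEVELS}, "
                f"got {self.resource_level!r}"
            )

    def with_resource_level(self, level: str) -> "SampleMetadata":
        return SampleMetadata(self.sample_id, self.site, self.treatment,
                              self.replicate, level)


def check_unique_sample_ids(meta: Sequence[SampleMetadata]) -> None:
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate sample ids: {dupes}")


@dataclass
class KingdomCountTable:
    """Nonnegative integer OTU x sample count matrix for a single kingdom."""

    kingdom: str
    counts: pd.DataFrame  # index: otu ids; columns: sample ids; dtype int

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {self.kingdom!r}")
        if self.counts.index.has_duplicates:
            raise ValidationError(
                f"duplicate OTU ids in {self.kingdom} table: "
                f"{sorted(self.counts.index[self.counts.index.duplicated()])}"
            )
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError(f"{self.kingdom} counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError(f"{self.kingdom} counts must be >= 0")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]


@dataclass
class IntegratedAbundanceTable:
    """Four-kingdom merged relative abundance table.

    Each OTU id is namespaced by its kingdom (``bacteria|OTU0001``) so that
    independently picked OTU sets cannot collide after the merge.
    """

    abundances: pd.DataFrame  # index: namespaced otu ids; columns: samples
    kingdoms: pd.Series       # index: namespaced otu ids -> kingdom name

    def __post_init__(self) -> None:
        values = self.abundances.to_numpy()
        if ((values < 0) | (values > 1)).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        if not self.kingdoms.index.equals(self.abundances.index):
            raise ValidationError("kingdom annotation does not match OTU index")
        unknown = set(self.kingdoms.unique()) - set(KINGDOMS)
        if unknown:
            raise ValidationError(f"unknown kingdoms: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass
class TraitFrequencyTable:
    """Functional trait redundancy frequencies R (trait x sample, >= 0)."""

    frequencies: pd.DataFrame  # index: trait ids; columns: sample ids

    def __post_init__(self) -> None:
        if self.frequencies.index.has_duplicates:
            raise ValidationError("duplicate trait ids")
        if (self.frequencies.to_numpy() < 0).any():
            raise ValidationError("trait frequencies must be >= 0")

    @property
    def trait_ids(self) -> list[str]:
        return list(self.frequencies.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frequencies.columns)


@dataclass
class AssociationNetwork:
    """Undirected co-occurrence network over namespaced OTUs.

    Node attributes: ``kingdom``, ``trophic_level``. Edge attributes: ``rho``,
    ``raw_p``, ``adjusted_p``, ``sign``, ``type``, ``category``.
    """

    graph: nx.Graph
    name: str = "network"

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_records(self) -> pd.DataFrame:
        rows = [
            {"otu_a": u, "otu_b": v, **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        cols = ["otu_a", "otu_b", "rho", "raw_p", "adjusted_p", "sign",
                "type", "category"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class BiologPlate:
    """One Biolog EcoPlate reading: 31 substrates x 3 wells + 3 blank wells."""

    arm: str
    replicate: int
    subculture_index: int
    substrate_ids: Sequence[str]
    substrate_od: np.ndarray  # (31, 3) optical densities
    blank_od: np.ndarray      # (3,)

    def __post_init__(self) -> None:
        self.substrate_od = np.asarray(self.substrate_od, dtype=float)
        self.blank_od = np.asarray(self.blank_od, dtype=float)
        if self.subculture_index < 1:
            raise ValidationError("subculture_index must be >= 1")
        if len(self.substrate_ids) != N_SUBSTRATES:
            raise ValidationError(
                f"expected {N_SUBSTRATES} substrates, got {len(self.substrate_ids)}")
        if self.substrate_od.shape != (N_SUBSTRATES, N_SUBSTRATE_REPLICATES):
            raise ValidationError(
                f"substrate OD must be {N_SUBSTRATES}x{N_SUBSTRATE_REPLICATES}")
        if self.blank_od.shape != (N_BLANKS,):
            raise ValidationError(f"expected {N_BLANKS} blank wells")
        if (self.substrate_od < 0).any() or (self.blank_od < 0).any():
            raise ValidationError("optical densities must be >= 0")

    @property
    def n_wells(self) -> int:
        return self.substrate_od.size + self.blank_od.size


BIOMASS_COLUMNS = ("system", "resource", "temperature", "well_id",
                   "plant_index", "biomass_mg")


def validate_biomass(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a seedling fresh-biomass table (one row per seedling)."""
    missing = set(BIOMASS_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"biomass table missing columns: {sorted(missing)}")
    if (records["biomass_mg"] < 0).any():
        raise ValidationError("biomass must be >= 0")
    bad_sys = set(records["system"].unique()) - {"I", "II", "III"}
    if bad_sys:
        raise ValidationError(f"unknown culture systems: {sorted(bad_sys)}")
    bad_res = set(records["resource"].unique()) - {"low", "high"}
    if bad_res:
        raise ValidationError(f"unknown resource levels: {sorted(bad_res)}")
    return records


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def _read_tsv_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: no sample columns found")
    if any(str(c).startswith("Unnamed") for c in df.columns):
        raise FormatError(f"{path}: missing or malformed header row")

    def _numeric(label: str) -> bool:
        try:
            float(label)
        except ValueError:
            return False
        return True

    if all(_numeric(str(c)) for c in df.columns):
        raise FormatError(
            f"{path}: first row looks like data, not a header of sample ids")
    df.index = df.index.astype(str)
    df.index.name = index_name
    df.columns = df.columns.astype(str)
    return df


def read_count_table(path: str | Path, kingdom: str) -> KingdomCountTable:
    """Read an OTU x sample TSV of raw counts for one kingdom."""
    df = _read_tsv_matrix(path, "otu_id")
    if df.isna().to_numpy().any():
        raise ValidationError(f"{path}: missing cells are not allowed")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric cells")
    if np.any(values != np.floor(values)):
        raise ValidationError(f"{path}: counts must be integers")
    if np.any(values < 0):
        raise ValidationError(f"{path}: counts must be >= 0")
    return KingdomCountTable(kingdom=kingdom, counts=df.astype(np.int64))


def write_count_table(table: KingdomCountTable, path: str | Path) -> Path:
    path = Path(path)
    table.counts.to_csv(path, sep="\t", index_label="otu_id")
    return path


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "site", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    meta = [
        SampleMetadata(
            sample_id=row["sample_id"],
            site=row["site"],
            treatment=row["treatment"],
            replicate=int(row["replicate"]),
            resource_level=row.get("resource_level", "unassigned") or "unassigned",
        )
        for row in df.to_dict("records")
    ]
    check_unique_sample_ids(meta)
    return meta


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, sep="\t", index=False)
    return path


def read_soil_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample soil property table (samples in rows).

    Missing cells are tolerated here (NA excludes the sample from index
    computation downstream, with a warning); every present value must satisfy
    the physical invariants (concentrations >= 0, pH in (0, 14)).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return validate_soil_table(df)


def validate_soil_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SOIL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"soil table missing columns: {sorted(missing)}")
    conc = [c for c in SOIL_COLUMNS if c not in ("pH", "MAT")]
    if (df[conc].to_numpy() < 0).any():
        raise ValidationError("soil concentrations must be >= 0")
    ph = df["pH"].dropna()
    if ((ph <= 0) | (ph >= 14)).any():
        raise ValidationError("pH must lie in (0, 14)")
    if df.isna().to_numpy().any():
        n_bad = int(df.isna().any(axis=1).sum())
        logger.warning("soil table has missing values in %d sample(s); those "
                       "samples are excluded from index computation", n_bad)
    return df


def write_soil_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)
    return path


def read_trait_table(path: str | Path) -> TraitFrequencyTable:
    df = _read_tsv_matrix(path, "trait_id")
    if df.isna().to_numpy().any():
        raise ValidationError(f"{path}: missing cells are not allowed")
    return TraitFrequencyTable(frequencies=df.astype(float))


def write_trait_table(table: TraitFrequencyTable, path: str | Path) -> Path:
    path = Path(path)
    table.frequencies.to_csv(path, sep="\t", index_label="trait_id",
                             float_format=_FLOAT_FMT)
    return path


def write_integrated_table(table: IntegratedAbundanceTable,
                           path: str | Path) -> Path:
    path = Path(path)
    out = table.abundances.copy()
    out.insert(0, "kingdom", table.kingdoms)
    out.to_csv(path, sep="\t", index_label="otu_id", float_format=_FLOAT_FMT)
    return path


def read_integrated_table(path: str | Path) -> IntegratedAbundanceTable:
    df = _read_tsv_matrix(path, "otu_id")
    if "kingdom" not in df.columns:
        raise FormatError(f"{path}: integrated table needs a 'kingdom' column")
    kingdoms = df.pop("kingdom").astype(str)
    return IntegratedAbundanceTable(abundances=df.astype(float), kingdoms=kingdoms)


# --- Biolog plates (long TSV: arm, replicate, subculture, substrate, well, od)

def write_biolog_plates(plates: Sequence[BiologPlate], path: str | Path) -> Path:
    rows = []
    for plate in plates:
        for i, sid in enumerate(plate.substrate_ids):
            for j in range(N_SUBSTRATE_REPLICATES):
                rows.append((plate.arm, plate.replicate, plate.subculture_index,
                             sid, j + 1, plate.substrate_od[i, j]))
        for j in range(N_BLANKS):
            rows.append((plate.arm, plate.replicate, plate.subculture_index,
                         "blank", j + 1, plate.blank_od[j]))
    df = pd.DataFrame(rows, columns=["arm", "replicate", "subculture",
                                     "substrate", "well_replicate", "od"])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_biolog_plates(path: str | Path) -> list[BiologPlate]:
    df = pd.read_csv(path, sep="\t")
    plates: list[BiologPlate] = []
    for (arm, rep, sub), grp in df.groupby(["arm", "replicate", "subculture"],
                                           sort=True):
        blanks = grp[grp["substrate"] == "blank"].sort_values("well_replicate")
        subs = grp[grp["substrate"] != "blank"]
        substrate_ids = sorted(subs["substrate"].unique())
        od = (subs.pivot_table(index="substrate", columns="well_replicate",
                               values="od")
              .loc[substrate_ids]
              .to_numpy())
        plates.append(BiologPlate(arm=str(arm), replicate=int(rep),
                                  subculture_index=int(sub),
                                  substrate_ids=substrate_ids,
                                  substrate_od=od,
                                  blank_od=blanks["od"].to_numpy()))
    return plates


def write_biomass(records: pd.DataFrame, path: str | Path) -> Path:
    validate_biomass(records)
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_biomass(path: str | Path) -> pd.DataFrame:
    return validate_biomass(pd.read_csv(path, sep="\t"))


# --- Networks ---------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "edge_tsv")


def write_network(net: AssociationNetwork, path: str | Path,
                  format: str = "graphml") -> Path:
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_tsv":
        net.edge_records().to_csv(path, sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
    else:
        raise ConfigurationError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    return path


def read_network(path: str | Path, name: str = "network") -> AssociationNetwork:
    graph = nx.read_graphml(Path(path))
    graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    return AssociationNetwork(graph=nx.Graph(graph), name=name)


# ---------------------------------------------------------------------------
# Cross-dataset validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationIssue:
    severity: str  # "fatal" | "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity in ("fatal", "error") for i in self.issues)

    def to_dict(self) -> dict:
        return {"ok": self.ok,
                "issues": [vars(i) for i in self.issues]}


def validate_dataset(meta: Sequence[SampleMetadata],
                     tables: Mapping[str, KingdomCountTable],
                     soil: pd.DataFrame | None = None) -> ValidationReport:
    """Cross-reference sample ids across metadata, count tables and soil data.

    Returns a report; callers should refuse to run the pipeline when
    ``report.ok`` is False.
    """
    report = ValidationReport()
    meta_ids = {m.sample_id for m in meta}
    for kingdom in KINGDOMS:
        if kingdom not in tables:
            report.issues.append(ValidationIssue(
                "fatal", f"count table for kingdom {kingdom!r} is missing"))
    for kingdom, table in tables.items():
        if table.kingdom != kingdom:
            report.issues.append(ValidationIssue(
                "error", f"table registered as {kingdom!r} reports kingdom "
                         f"{table.kingdom!r}"))
        extra = set(table.sample_ids) - meta_ids
        for sid in sorted(extra):
            report.issues.append(ValidationIssue(
                "error", f"sample {sid!r} in {kingdom} counts but not metadata"))
        missing = meta_ids - set(table.sample_ids)
        for sid in sorted(missing):
            report.issues.append(ValidationIssue(
                "warning", f"sample {sid!r} has metadata but no {kingdom} counts"))
    if soil is not None:
        extra = set(soil.index) - meta_ids
        for sid in sorted(extra):
            report.issues.append(ValidationIssue(
                "error", f"sample {sid!r} in soil table but not metadata"))
        missing = meta_ids - set(soil.index)
        for sid in sorted(missing):
            report.issues.append(ValidationIssue(
                "warning", f"sample {sid!r} has metadata but no soil data"))
    return report
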