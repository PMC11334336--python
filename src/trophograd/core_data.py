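"""Community count tables, site metadata and distance matrices.

The unit of community data is the :class:`AsvTable`: an integer count
matrix of samples (rows) by ASVs (columns) carrying a kingdom label.
This module provides TSV I/O, rarefaction, prevalence filtering and
relative-abundance conversion; everything downstream consumes these
types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINGDOMS = ("bacteria", "protist", "virus")

#: Fixed metadata column order for the TSV dialect.
METADATA_COLUMNS = (
    "site_id", "latitude", "longitude", "elevation",
    "MAT", "MAP", "MTCM", "PSCV",
    "pH", "SWC", "SOM", "TN", "TC", "NO3", "NH4", "AP", "C_N",
)

CLIMATIC_VARS = ("MAT", "MAP", "MTCM", "PSCV")
EDAPHIC_VARS = ("pH", "SWC", "SOM", "TN", "TC", "NO3", "NH4", "AP", "C_N")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with a kingdom label.

    Parameters
    ----------
    sample_ids : sequence of str
        Ordered, unique sample (site) identifiers; one per row.
    asv_ids : sequence of str
        Ordered, unique ASV identifiers; one per column.
    counts : ndarray of int, shape (n_samples, n_asvs)
        Non-negative read counts.
    kingdom : {'bacteria', 'protist', 'virus'}
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray
    kingdom: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise DataValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise DataValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise DataValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.size and (self.counts < 0).any():
            raise DataValidationError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise DataValidationError("duplicate ASV ids")
        if self.kingdom not in KINGDOMS:
            raise DataValidationError(
                f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}"
            )

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def richness(self) -> np.ndarray:
        """Observed ASV count per sample."""
        return (self.counts > 0).sum(axis=1)

    def presence(self) -> np.ndarray:
        """Binary presence/absence matrix (int8)."""
        return (self.counts > 0).astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AsvTable(list(sample_ids), list(self.asv_ids),
                        self.counts[idx], self.kingdom)


@dataclass
class SiteMetadata:
    """Per-site geographic coordinates plus climatic and edaphic covariates."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float | None = None
    climatic: Mapping[str, float] = field(default_factory=dict)
    edaphic: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        swc = self.edaphic.get("SWC")
        if swc is not None and np.isfinite(swc) and not (0.0 <= swc <= 100.0):
            raise DataValidationError(f"SWC out of range [0, 100]: {swc}")
        ph = self.edaphic.get("pH")
        if ph is not None and np.isfinite(ph) and not (0.0 <= ph <= 14.0):
            raise DataValidationError(f"pH out of range [0, 14]: {ph}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered identifiers."""

    ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataValidationError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise DataValidationError("ids do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise DataValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise DataValidationError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise DataValidationError("distances must be non-negative")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def filter(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_asv_table(path: str | Path, kingdom: str, transpose: bool = False) -> AsvTable:
    """Read a TSV count table (header row of ASV ids, first column sample ids).

    With ``transpose=True`` the file is interpreted in the transposed
    dialect (rows are ASVs, columns are samples).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.shape[0] == 0:
        raise DataValidationError("no samples in ASV table")
    if df.shape[1] == 0:
        raise DataValidationError("no ASVs in ASV table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataValidationError("non-numeric cells in ASV table")
    if not np.allclose(values, np.round(values)):
        raise DataValidationError("non-integer cells in ASV table")
    if (values < 0).any():
        raise DataValidationError("negative counts in ASV table")
    return AsvTable(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        values.astype(np.int64),
        kingdom,
    )


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> list[SiteMetadata]:
    """Read the fixed-column site metadata TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = {"site_id", "latitude", "longitude"} - set(df.columns)
    if missing:
        raise DataValidationError(f"metadata missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(SiteMetadata(
            site_id=str(row["site_id"]),
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            elevation=float(row["elevation"]) if "elevation" in df.columns else None,
            climatic={v: float(row[v]) for v in CLIMATIC_VARS if v in df.columns},
            edaphic={v: float(row[v]) for v in EDAPHIC_VARS if v in df.columns},
        ))
    if len({m.site_id for m in records}) != len(records):
        raise DataValidationError("duplicate site ids in metadata")
    return records


def metadata_frame(records: Sequence[SiteMetadata]) -> pd.DataFrame:
    """Flatten metadata records to a DataFrame indexed by site_id."""
    rows = []
    for m in records:
        row: dict[str, float | str | None] = {
            "site_id": m.site_id, "latitude": m.latitude,
            "longitude": m.longitude, "elevation": m.elevation,
        }
        row.update(m.climatic)
        row.update(m.edaphic)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("site_id")
    return df


def write_metadata(records: Sequence[SiteMetadata], path: str | Path) -> None:
    df = metadata_frame(records).reset_index()
    cols = [c for c in METADATA_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.ids, columns=d.ids).to_csv(
        path, sep="\t", index_label="id")


def read_distance_matrix(path: str | Path, metric: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix([str(i) for i in df.index], df.to_numpy(), metric)


def rarefy(table: AsvTable, depth: int | str = "min", seed: int = 0) -> AsvTable:
    """Subsample each sample without replacement to a common depth.

    ``depth='min'`` uses the minimum sample sum.  With an explicit depth,
    samples whose total is below the depth are dropped with a warning.
    Subsampling is multivariate-hypergeometric and reproducible under
    ``seed``.
    """
    sums = table.sample_sums()
    if depth == "min":
        if (sums == 0).any():
            raise DataValidationError("cannot rarefy: sample with zero total count")
        target = int(sums.min())
    else:
        target = int(depth)
        if target <= 0:
            raise DataValidationError("rarefaction depth must be positive")
    keep = sums >= target
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth "
            f"{target}: {dropped}", stacklevel=2)
    if not keep.any():
        raise DataValidationError("no samples pass the rarefaction depth")
    rng = np.random.default_rng(seed)
    kept_counts = table.counts[keep]
    out = np.empty_like(kept_counts)
    for i, row in enumerate(kept_counts):
        out[i] = rng.multivariate_hypergeometric(row, target)
    return AsvTable(
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.asv_ids), out, table.kingdom)


def prevalence_filter(table: AsvTable, threshold: float = 0.3) -> AsvTable:
    """Keep ASVs detected in strictly more than ``threshold`` of samples."""
    if not 0.0 < threshold < 1.0:
        raise DataValidationError("prevalence threshold must be in (0, 1)")
    n_present = (table.counts > 0).sum(axis=0)
    keep = n_present > threshold * table.n_samples
    if not keep.any():
        raise DataValidationError("empty table after filtering")
    return AsvTable(
        list(table.sample_ids),
        [a for a, k in zip(table.asv_ids, keep) if k],
        table.counts[:, keep], table.kingdom)


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Row-normalized fractions (each row sums to 1)."""
    sums = table.sample_sums().astype(float)
    if (sums == 0).any():
        raise DataValidationError("all-zero sample row; cannot normalize")
    frac = table.counts / sums[:, None]
    return pd.DataFrame(frac, index=table.sample_ids, columns=table.asv_ids)


def harmonize(tables: Sequence[AsvTable],
              metadata: Sequence[SiteMetadata]) -> tuple[list[AsvTable], list[SiteMetadata]]:
    """Restrict tables and metadata to their common samples, in table order."""
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    common &= {m.site_id for m in metadata}
    if not common:
        raise DataValidationError("no common samples between tables and metadata")
    order = [s for s in tables[0].sample_ids if s in common]
    meta_by_id = {m.site_id: m for m in metadata}
    return ([t.select_samples(order) for t in tables],
            [meta_by_id[s] for s in order])
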