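"""Core data containers: region atlas, regional matrices, distances.

All tabular I/O is UTF-8, tab-delimited with a mandatory header row;
``region_id`` is the join key everywhere. A :class:`RegionalMatrix` keeps
missingness explicit (boolean mask) rather than relying on silent NaN
propagation; operations that cannot handle missing entries reject them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

STRUCTURES = ("cortex", "subcortex", "hypothalamus")
HEMISPHERES = ("L", "R", "M")

ATLAS_COLUMNS = ["region_id", "name", "structure", "stratum", "hemisphere", "x", "y", "z"]


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclass(frozen=True)
class RegionAtlas:
    """Index of brain regions with structure class, stratum and centroid.

    ``structure`` is a closed vocabulary (cortex / subcortex / hypothalamus);
    ``stratum`` is free text (intrinsic network, anatomical structure or
    hypothalamic nucleus depending on the structure class).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"atlas table missing columns: {missing}")
        if len(t) == 0:
            raise ValidationError("atlas table is empty")
        if t["region_id"].duplicated().any():
            dupes = sorted(t.loc[t["region_id"].duplicated(), "region_id"].unique())
            raise ValidationError(f"duplicate region_ids: {dupes}")
        bad_struct = set(t["structure"]) - set(STRUCTURES)
        if bad_struct:
            raise ValidationError(f"unknown structure labels: {sorted(bad_struct)}")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        if (t["stratum"].astype(str).str.len() == 0).any():
            raise ValidationError("empty stratum label")
        coords = t[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite centroid coordinates")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def structures(self) -> pd.Series:
        return self.table["structure"]

    @property
    def strata(self) -> pd.Series:
        return self.table["stratum"]

    def structure_counts(self) -> dict[str, int]:
        counts = self.table["structure"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in STRUCTURES}

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class RegionalMatrix:
    """Regions x variables matrix aligned row-for-row with a RegionAtlas.

    ``mask`` marks observed entries (True = present). Missing cells are
    stored as NaN under a False mask; consumers must opt in to masked input.
    """

    atlas: RegionAtlas
    columns: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape != (self.atlas.n_regions, len(self.columns)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"({self.atlas.n_regions}, {len(self.columns)})"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValidationError("duplicate column names")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape mismatch")
        if np.isfinite(self.values[~self.mask]).any():
            # canonicalize: unobserved cells are NaN
            self.values = self.values.copy()
            self.values[~self.mask] = np.nan
        if not np.isfinite(self.values[self.mask]).all():
            raise ValidationError("non-finite value flagged as observed")

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def require_complete(self, what: str = "operation") -> np.ndarray:
        if not self.is_complete:
            raise ValidationError(f"{what} does not accept missing entries")
        return self.values

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "region_id", self.atlas.region_ids)
        return df

    def save(self, path: str | Path, float_format: str = "%.10g") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format=float_format)


ANNOTATION_METRICS = [
    "mean_intensity",
    "rnaseq_correlation",
    "differential_stability",
    "mean_expr_cortex",
    "mean_expr_hypothalamus",
    "mean_expr_subcortex",
]


@dataclass(frozen=True)
class ReceptorAnnotation:
    """Per-gene family membership and QC metrics (all metrics in [0, 1])."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene", "full_name", "family"] + ANNOTATION_METRICS
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if t["gene"].duplicated().any():
            raise ValidationError("duplicate gene symbols in annotation")
        metrics = t[ANNOTATION_METRICS].to_numpy(float)
        finite = metrics[np.isfinite(metrics)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValidationError("annotation metrics must lie in [0, 1]")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def families(self, include_unclassified: bool = False) -> list[str]:
        fams = self.table["family"].unique().tolist()
        if not include_unclassified:
            fams = [f for f in fams if f != "Unclassified"]
        return sorted(fams)


def load_receptor_annotation(path: str | Path) -> ReceptorAnnotation:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return ReceptorAnnotation(pd.read_csv(path, sep=sep))


# single-column matrices double as regional maps
RegionalMap = RegionalMatrix


def as_map(matrix: RegionalMatrix, name: str | None = None) -> np.ndarray:
    """Return the single column of a regional map as a flat vector."""
    if name is not None:
        return matrix.column(name)
    if len(matrix.columns) != 1:
        raise ValidationError("expected a one-column regional map")
    return matrix.values[:, 0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative inter-region distance matrix (millimetres)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("negative distance")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def load_region_atlas(path: str | Path) -> RegionAtlas:
    """Read a region index table (TSV/CSV) and validate its invariants."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    if len(table) == 0:
        raise ValidationError(f"{path}: empty atlas file")
    return RegionAtlas(table)


def load_matrix(path: str | Path, atlas: RegionAtlas) -> RegionalMatrix:
    """Read a regions x variables table and re-order rows to atlas order.

    The file's first column must be ``region_id`` and must cover the atlas
    exactly. Empty cells become explicit missing entries.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.columns[0] != "region_id":
        raise ValidationError(f"{path}: first column must be region_id")
    file_ids = df["region_id"].to_numpy()
    atlas_ids = atlas.region_ids
    missing = sorted(set(atlas_ids) - set(file_ids))
    if missing:
        raise ValidationError(f"{path}: missing regions {missing}")
    extra = sorted(set(file_ids) - set(atlas_ids))
    if extra:
        raise ValidationError(f"{path}: regions not in atlas {extra}")
    df = df.set_index("region_id").loc[atlas_ids]
    columns = list(df.columns)
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric cell at region_id={df.index[i]}, column={col!r}"
            )
        values[:, j] = numeric.to_numpy(float)
    return RegionalMatrix(atlas, columns, values)


def pairwise_distances(atlas: RegionAtlas) -> DistanceMatrix:
    """Euclidean distances between region centroids."""
    return DistanceMatrix(squareform(pdist(atlas.centroids)))
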