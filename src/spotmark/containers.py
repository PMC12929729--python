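"""Core in-memory containers shared across the pipeline.

The spatial stage works on a :class:`CellTable` (per-cell geometry plus a
sparse cell x gene count matrix over a targeted panel), region annotations
live in a :class:`RegionSet` (labeled polygons in micron coordinates, image
convention: origin top-left, y increasing downward), and the bulk stage works
on a :class:`BulkCohort` (per-patient expression plus clinical covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from shapely.geometry import Polygon

#: Controlled vocabulary for region histology labels.
HISTOLOGY_LABELS = ("ADC", "SCC", "TTF1neg_p40neg", "normal", "non_tumor", "ROI")

#: Labels counted as tumor when computing the true tumor fraction.
TUMOR_LABELS = ("ADC", "SCC", "TTF1neg_p40neg")


@dataclass
class CellTable:
    """Per-cell geometry and expression over a gene panel.

    Attributes
    ----------
    cells
        DataFrame indexed 0..n-1 with columns ``cell_id`` (unique str),
        ``x``, ``y`` (centroid, micron), ``cell_area`` (micron^2, > 0),
        ``nucleus_area`` (micron^2, >= 0, <= cell_area) and
        ``total_counts``. Extra columns are passed through untouched.
    genes
        Panel gene names in file order (never silently sorted).
    raw
        Sparse integer count matrix, cells x genes.
    norm
        Area-normalized expression (counts per 100 micron^2), filled by
        :func:`spotmark.tumor.normalize_by_area`; ``None`` until then.
    """

    cells: pd.DataFrame
    genes: list[str]
    raw: sparse.csr_matrix
    norm: sparse.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.raw = sparse.csr_matrix(self.raw)
        self.genes = list(self.genes)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} is not in the panel") from None

    def validate(self) -> None:
        required = {"cell_id", "x", "y", "cell_area", "nucleus_area"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing required columns: {sorted(missing)}")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate cell_id {dup!r}")
        bad = np.flatnonzero(~(self.cells["cell_area"].to_numpy() > 0))
        if bad.size:
            raise ValueError(f"non-positive cell_area at rows {bad[:10].tolist()}")
        bad = np.flatnonzero(
            self.cells["nucleus_area"].to_numpy() > self.cells["cell_area"].to_numpy()
        )
        if bad.size:
            raise ValueError(f"nucleus_area exceeds cell_area at rows {bad[:10].tolist()}")
        for col in ("x", "y"):
            bad = np.flatnonzero(~np.isfinite(self.cells[col].to_numpy(float)))
            if bad.size:
                raise ValueError(f"non-finite {col} at rows {bad[:10].tolist()}")
        if self.raw.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"count matrix shape {self.raw.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.raw.nnz and (self.raw.data < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.raw.nnz and not np.issubdtype(self.raw.dtype, np.integer):
            if np.any(self.raw.data != np.round(self.raw.data)):
                raise ValueError("raw counts must be integers")

    def subset(self, row_mask: np.ndarray) -> "CellTable":
        """Row subset (boolean mask or integer positions); norm follows."""
        cells = self.cells.iloc[row_mask].reset_index(drop=True)
        raw = self.raw[row_mask]
        norm = self.norm[row_mask] if self.norm is not None else None
        return CellTable(cells=cells, genes=self.genes, raw=raw, norm=norm)


@dataclass
class Region:
    region_id: str
    polygon: Polygon
    label: str
    note: str = ""


@dataclass
class RegionSet:
    """Labeled annotation polygons (histology subtypes, ROIs)."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def validate(self) -> None:
        seen = set()
        for r in self.regions:
            if r.label not in HISTOLOGY_LABELS:
                raise ValueError(
                    f"region {r.region_id!r}: label {r.label!r} not in {HISTOLOGY_LABELS}"
                )
            if r.region_id in seen:
                raise ValueError(f"duplicate region_id {r.region_id!r}")
            seen.add(r.region_id)
            coords = list(r.polygon.exterior.coords) if not r.polygon.is_empty else []
            if len(coords) < 4 or r.polygon.area <= 0:  # closed ring repeats 1st vertex
                raise ValueError(f"region {r.region_id!r}: degenerate polygon")
            if not r.polygon.is_simple or not r.polygon.is_valid:
                raise ValueError(f"region {r.region_id!r}: polygon is self-intersecting")

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def get(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"unknown region_id {region_id!r}")

    def contains_points(self, region: Region, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon, boundary counted as inside."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(region.polygon, pts)


@dataclass
class BulkCohort:
    """Bulk expression cohort with survival follow-up.

    ``expression``: samples x genes DataFrame (index = sample id).
    ``clinical``: one row per sample with columns ``time`` (months, > 0),
    ``event`` (1 = death), ``stage`` (1-4), ``age``, ``smoking`` (0/1),
    ``sex`` (0/1), optional ``histology`` and ``mut_<GENE>`` 0/1 flags.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def validate(self) -> None:
        required = {"time", "event", "stage", "age", "smoking", "sex"}
        missing = required - set(self.clinical.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if not self.expression.index.equals(self.clinical.index):
            raise ValueError("expression and clinical sample ids do not match")
        t = self.clinical["time"].to_numpy(float)
        bad = np.flatnonzero(~(t > 0))
        if bad.size:
            raise ValueError(f"non-positive survival time at rows {bad[:10].tolist()}")
        ev = self.clinical["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def marker(self, gene: str) -> pd.Series:
        if gene not in self.expression.columns:
            raise KeyError(f"marker gene {gene!r} absent from bulk expression matrix")
        return self.expression[gene]

    def mutation_genes(self) -> list[str]:
        return [c[4:] for c in self.clinical.columns if c.startswith("mut_")]
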