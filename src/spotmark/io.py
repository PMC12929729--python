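"""Readers and writers for every on-disk format the pipeline touches.

Formats follow the conventions of imaging-based spatial transcriptomics
tooling: the count matrix is Matrix Market coordinate format (genes x cells,
1-based indices) with ``features.tsv`` / ``barcodes.tsv`` sidecars, cell
metadata is a plain CSV, and region annotations are exchanged as GeoJSON with
the histology label under ``properties.histology``. Every writer produces a
file its paired reader accepts unchanged.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse
from shapely.geometry import Polygon, mapping, shape

from .containers import HISTOLOGY_LABELS, BulkCohort, CellTable, Region, RegionSet

CELLS_REQUIRED = ["cell_id", "x", "y", "cell_area", "nucleus_area", "total_counts"]


# ---------------------------------------------------------------------------
# cell-feature matrix (MTX + TSVs)
# ---------------------------------------------------------------------------

def _find_bad_mtx_line(matrix_path: str | Path) -> str:
    """Locate the first non-integer data line of an MTX file for reporting."""
    with open(matrix_path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("%"):
                continue
            if not header_seen:  # dimensions line
                header_seen = True
                continue
            parts = line.split()
            if len(parts) >= 3:
                try:
                    int(parts[2])
                except ValueError:
                    return f"line {lineno}: {line.strip()!r}"
    return "unknown line"


def read_cell_feature_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Read an MTX cell-feature matrix with its feature/barcode sidecars.

    Returns ``(counts, genes, cell_ids)`` with ``counts`` as a sparse
    cells x genes integer matrix (the on-disk orientation is genes x cells).
    Explicit zero entries are accepted and treated as structural zeros.
    """
    mat = scipy_io.mmread(str(matrix_path))
    data = np.asarray(mat.data)
    if data.size and (not np.issubdtype(data.dtype, np.integer)) and np.any(
        data != np.round(data)
    ):
        raise ValueError(
            f"{matrix_path}: non-integer count value at {_find_bad_mtx_line(matrix_path)}"
        )
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    genes = feats.iloc[:, 1].tolist() if feats.shape[1] >= 2 else feats.iloc[:, 0].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    dup = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup):
        row = genes.index(dup[0]) + 1
        raise ValueError(f"{features_path}: duplicate gene name {dup[0]!r} (line {row})")
    if mat.shape[0] != len(genes):
        raise ValueError(
            f"{matrix_path}: matrix has {mat.shape[0]} rows but "
            f"{features_path} lists {len(genes)} features"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"{matrix_path}: matrix has {mat.shape[1]} columns but "
            f"{barcodes_path} lists {len(barcodes)} barcodes"
        )
    counts = sparse.csr_matrix(mat.T.astype(np.int64))
    return counts, genes, barcodes


def write_cell_feature_matrix(
    counts: sparse.spmatrix,
    genes: list[str],
    cell_ids: list[str],
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write ``counts`` (cells x genes) as genes x cells MTX plus sidecars."""
    counts = sparse.coo_matrix(counts)
    if counts.shape != (len(cell_ids), len(genes)):
        raise ValueError("counts shape does not match cell_ids x genes")
    scipy_io.mmwrite(str(matrix_path), counts.T.astype(np.int64), field="integer")
    feats = pd.DataFrame(
        {"id": [f"G{i:05d}" for i in range(len(genes))],
         "name": genes,
         "type": "Gene Expression"}
    )
    feats.to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(cell_ids).to_csv(barcodes_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cells CSV
# ---------------------------------------------------------------------------

def read_cells_csv(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata (geometry only); unknown columns pass through."""
    df = pd.read_csv(path)
    missing = [c for c in CELLS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["cell_id"] = df["cell_id"].astype(str)
    bad = np.flatnonzero(~(df["cell_area"].to_numpy(float) > 0))
    if bad.size:
        raise ValueError(f"{path}: non-positive cell_area at rows {bad[:10].tolist()}")
    for col in ("x", "y"):
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(float)))
        if bad.size:
            raise ValueError(f"{path}: non-finite {col} at rows {bad[:10].tolist()}")
    bad = np.flatnonzero(df["nucleus_area"].to_numpy(float) < 0)
    if bad.size:
        raise ValueError(f"{path}: negative nucleus_area at rows {bad[:10].tolist()}")
    return df


def write_cells_csv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(directory: str | Path) -> CellTable:
    """Read a full CellTable from a directory written by :func:`write_cell_table`."""
    d = Path(directory)
    counts, genes, cell_ids = read_cell_feature_matrix(
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
    )
    cells = read_cells_csv(d / "cells.csv")
    if cells["cell_id"].tolist() != list(cell_ids):
        raise ValueError(f"{d}: cells.csv ids do not match barcodes.tsv")
    return CellTable(cells=cells, genes=genes, raw=counts)


def write_cell_table(table: CellTable, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_cell_feature_matrix(
        table.raw, table.genes, table.cells["cell_id"].tolist(),
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
    )
    write_cells_csv(table.cells, d / "cells.csv")


# ---------------------------------------------------------------------------
# regions GeoJSON
# ---------------------------------------------------------------------------

def read_regions_geojson(path: str | Path) -> RegionSet:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {}) or {}
        geom = feat.get("geometry")
        if geom is None or geom.get("type") != "Polygon":
            raise ValueError(f"{path}: feature {i} is not a Polygon")
        n_vertices = len(geom.get("coordinates", [[]])[0])
        if n_vertices < 4:  # GeoJSON rings repeat the first vertex
            raise ValueError(f"{path}: feature {i}: degenerate polygon "
                             f"({n_vertices} ring coordinates)")
        poly = shape(geom)
        label = props.get("histology")
        if label not in HISTOLOGY_LABELS:
            raise ValueError(
                f"{path}: feature {i}: histology {label!r} not in {HISTOLOGY_LABELS}"
            )
        regions.append(Region(
            region_id=str(props.get("region_id", f"region_{i}")),
            polygon=Polygon(poly.exterior.coords),
            label=label,
            note=str(props.get("note", "")),
        ))
    return RegionSet(regions=regions)


def write_regions_geojson(regions: RegionSet, path: str | Path) -> None:
    features = []
    for r in regions:
        features.append({
            "type": "Feature",
            "properties": {"region_id": r.region_id, "histology": r.label, "note": r.note},
            "geometry": mapping(r.polygon),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def read_bulk(expr_path: str | Path, clinical_path: str | Path) -> BulkCohort:
    """Read a bulk cohort: expression CSV (samples x genes) + clinical CSV."""
    expr = pd.read_csv(expr_path, index_col=0)
    clin = pd.read_csv(clinical_path, index_col=0)
    expr.index = expr.index.astype(str)
    clin.index = clin.index.astype(str)
    if set(expr.index) != set(clin.index):
        only = sorted(set(expr.index) ^ set(clin.index))[:5]
        raise ValueError(f"sample ids differ between {expr_path} and {clinical_path}: {only}")
    clin = clin.loc[expr.index]
    return BulkCohort(expression=expr, clinical=clin)


def write_bulk(cohort: BulkCohort, expr_path: str | Path, clinical_path: str | Path) -> None:
    cohort.expression.to_csv(expr_path, index_label="sample_id")
    cohort.clinical.to_csv(clinical_path, index_label="sample_id")


# ---------------------------------------------------------------------------
# results report
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_report(results: dict, path: str | Path) -> None:
    """Serialize a results dictionary to JSON (numpy/pandas-aware)."""
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, default=_jsonable, sort_keys=True)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
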