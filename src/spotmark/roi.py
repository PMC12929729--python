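"""ROI audit: flag and exclude histologically normal cells.

Normal epithelial foci can share keratin expression with tumor cells and land
in keratin-positive clusters, yet show depressed positivity for epithelial
tumor markers such as EPCAM. Cells are assigned to annotated ROIs by
point-in-polygon tests (boundary counted as inside); per cluster, marker
positivity inside vs outside an ROI is compared with a two-sided Fisher exact
test and Benjamini-Hochberg correction across clusters, and flagged ROIs are
excluded from downstream tumor-specific analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellTable, RegionSet
from .stats import bh_adjust


@dataclass
class ROIReport:
    roi_id: str
    gene: str
    cluster_counts_inside: dict[int, int]
    per_cluster: pd.DataFrame   # cluster, rate_inside, rate_outside, p, q
    pooled_p: float
    excluded_cell_ids: list[str] = field(default_factory=list)


def assign_rois(cells: pd.DataFrame, regions: RegionSet,
                roi_ids: list[str] | None = None) -> pd.Series:
    """Per-cell ROI membership (region_id or None).

    Boundary points count as inside. A cell belongs to at most one ROI;
    overlapping ROI polygons are rejected.
    """
    rois = [r for r in regions if roi_ids is None or r.region_id in roi_ids]
    if roi_ids is not None:
        known = {r.region_id for r in regions}
        missing = [i for i in roi_ids if i not in known]
        if missing:
            raise KeyError(f"unknown ROI ids: {missing}")
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            if rois[i].polygon.intersection(rois[j].polygon).area > 1e-9:
                raise ValueError(
                    f"ROI polygons {rois[i].region_id!r} and "
                    f"{rois[j].region_id!r} overlap"
                )
    x = cells["x"].to_numpy(float)
    y = cells["y"].to_numpy(float)
    membership = np.full(len(cells), None, dtype=object)
    for r in rois:  # first match by region order
        inside = regions.contains_points(r, x, y)
        unassigned = inside & pd.isna(membership)
        membership[unassigned] = r.region_id
    return pd.Series(membership, index=cells.index, name="roi")


def positivity_rate(raw_counts, gene_index: int) -> float:
    """Fraction of cells with >= 1 raw transcript of the gene (detection is a
    raw-count statement; area normalization never changes it)."""
    from scipy import sparse

    raw = sparse.csr_matrix(raw_counts)
    if raw.shape[0] == 0:
        raise ValueError("empty cell subset")
    col = raw[:, gene_index]
    return float((col > 0).sum() / raw.shape[0])


def compare_positivity(
    table: CellTable,
    inside_mask: np.ndarray,
    cluster_labels: np.ndarray,
    gene: str,
    pooled: bool = False,
) -> pd.DataFrame:
    """Marker positivity inside vs outside an ROI, per cluster.

    For every cluster with members on both sides, a 2x2 table
    (positive/negative x inside/outside) is tested with a two-sided Fisher
    exact test; BH adjustment runs across the tested clusters. ``pooled=True``
    additionally ignores cluster structure (single 2x2 test, reported under
    cluster id 0).
    """
    inside_mask = np.asarray(inside_mask, dtype=bool)
    if inside_mask.sum() == 0 or (~inside_mask).sum() == 0:
        raise ValueError("both inside and outside groups must be non-empty")
    gi = table.gene_index(gene)
    positive = np.asarray((table.raw[:, gi] > 0).todense()).ravel()
    labels = np.asarray(cluster_labels)

    rows = []
    groups = [(0, np.ones(len(labels), dtype=bool))] if pooled else [
        (int(k), labels == k) for k in np.unique(labels)
    ]
    for k, kmask in groups:
        n_in = int((kmask & inside_mask).sum())
        n_out = int((kmask & ~inside_mask).sum())
        if n_in == 0 or n_out == 0:
            continue
        pos_in = int((kmask & inside_mask & positive).sum())
        pos_out = int((kmask & ~inside_mask & positive).sum())
        tab = [[pos_in, n_in - pos_in], [pos_out, n_out - pos_out]]
        if (pos_in + pos_out == 0) or (pos_in + pos_out == n_in + n_out):
            warnings.warn(f"cluster {k}: a positivity margin is zero; p set to 1")
            p = 1.0
            orat = np.nan
        else:
            orat, p = stats.fisher_exact(tab, alternative="two-sided")
        rows.append({
            "cluster": k,
            "n_inside": n_in, "n_outside": n_out,
            "rate_inside": pos_in / n_in, "rate_outside": pos_out / n_out,
            "odds_ratio": orat, "p": float(p),
        })
    if not rows:
        raise ValueError("no cluster has cells on both sides of the ROI")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def exclude_cells(
    table: CellTable,
    roi_membership: pd.Series,
    roi_ids: list[str],
    reason: str = "histologically normal epithelium",
    regions: RegionSet | None = None,
) -> tuple[CellTable, pd.DataFrame]:
    """Drop every member of the listed ROIs; return the filtered table plus an
    audit log (cell_id, roi, reason). Conserves cells: |in| = |out| + |log|.
    Idempotent: excluding twice equals excluding once. An ROI that exists but
    has no member cells is a no-op; an unknown ROI id is an error."""
    known = set(pd.unique(roi_membership.dropna()))
    if regions is not None:
        known |= {r.region_id for r in regions}
    membership = roi_membership.to_numpy(object)
    for rid in roi_ids:
        if rid not in known:
            raise KeyError(f"unknown roi id {rid!r}")
    drop = np.isin(membership, list(roi_ids))
    log = pd.DataFrame({
        "cell_id": table.cells.loc[drop, "cell_id"].to_numpy(),
        "roi": membership[drop],
        "reason": reason,
    })
    return table.subset(~drop), log


def audit_roi(
    table: CellTable,
    clusters,
    regions: RegionSet,
    roi_ids: list[str],
    gene: str = "EPCAM",
) -> tuple[pd.Series, list[ROIReport]]:
    """Full audit: assign ROIs, compare marker positivity per ROI, report."""
    membership = assign_rois(table.cells, regions, roi_ids=roi_ids)
    reports = []
    for rid in roi_ids:
        inside = (membership == rid).to_numpy()
        if inside.sum() == 0:
            warnings.warn(f"ROI {rid!r} contains no cells")
            continue
        per_cluster = compare_positivity(table, inside, clusters.labels, gene)
        counts = pd.Series(clusters.labels[inside]).value_counts().to_dict()
        pooled = compare_positivity(table, inside, clusters.labels, gene, pooled=True)
        reports.append(ROIReport(
            roi_id=rid, gene=gene,
            cluster_counts_inside={int(k): int(v) for k, v in counts.items()},
            per_cluster=per_cluster,
            pooled_p=float(pooled["p"].iloc[0]),
            excluded_cell_ids=table.cells.loc[inside, "cell_id"].tolist(),
        ))
    return membership, reports
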