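"""Dropout-rate marker screening and subtype characterization.

The dropout rate of a gene in a cell fraction is the proportion of cells in
which the gene is undetectable (zero raw transcripts). Plotting dropout in
non-tumor cells against dropout in tumor (keratin-positive, post-exclusion)
cells partitions the panel into four quadrants at a 75% threshold:

* tumor-specific: detected in tumor (d_T < tau), dropped out in non-tumor
* normal-specific: the converse
* common-positive: detected in both fractions
* common-negative: dropped out in both

Tumor-specific candidates are ranked by total raw expression in tumor cells,
summarized per cluster as gene-wise z-scores of cluster-mean normalized
expression, intersected across samples, and profiled per histological subtype
(positive-cell fraction and mean normalized expression, with between-subtype
differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import CellTable, RegionSet

SUBTYPES = ("ADC", "TTF1neg_p40neg", "SCC")


@dataclass
class DropoutProfile:
    """Per-gene dropout rates, quadrant category and tumor expression total."""

    table: pd.DataFrame  # index gene; d_T, d_N, category, total_tumor_expression
    tau: float

    def tumor_specific(self) -> list[str]:
        return self.table.index[self.table["category"] == "tumor_specific"].tolist()


def dropout_rates(raw_counts: sparse.spmatrix, tumor_mask: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene dropout rate in the tumor and non-tumor fractions.

    d = (#cells with zero raw count) / (#cells in fraction).
    """
    mask = np.asarray(tumor_mask, dtype=bool)
    raw = sparse.csr_matrix(raw_counts)
    n_t, n_n = int(mask.sum()), int((~mask).sum())
    if n_t == 0 or n_n == 0:
        raise ValueError("both tumor and non-tumor fractions must be non-empty")
    detected_t = np.asarray((raw[mask] > 0).sum(axis=0)).ravel()
    detected_n = np.asarray((raw[~mask] > 0).sum(axis=0)).ravel()
    return 1.0 - detected_t / n_t, 1.0 - detected_n / n_n


def classify_dropout(d_t: float | np.ndarray, d_n: float | np.ndarray,
                     tau: float = 0.75) -> np.ndarray:
    """Quadrant category from (tumor, non-tumor) dropout rates.

    The 'expressed' side is strict (< tau), the 'dropout' side inclusive
    (>= tau); the four categories partition [0,1]^2 for any tau.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must lie strictly between 0 and 1")
    d_t = np.atleast_1d(np.asarray(d_t, dtype=float))
    d_n = np.atleast_1d(np.asarray(d_n, dtype=float))
    out = np.where(
        d_t < tau,
        np.where(d_n >= tau, "tumor_specific", "common_positive"),
        np.where(d_n < tau, "normal_specific", "common_negative"),
    )
    return out


def dropout_profile(
    table: CellTable,
    tumor_mask: np.ndarray,
    tau: float = 0.75,
) -> DropoutProfile:
    """Screen the whole panel: rates, categories and tumor expression totals."""
    d_t, d_n = dropout_rates(table.raw, tumor_mask)
    mask = np.asarray(tumor_mask, dtype=bool)
    totals = np.asarray(table.raw[mask].sum(axis=0)).ravel()
    df = pd.DataFrame({
        "d_T": d_t,
        "d_N": d_n,
        "category": classify_dropout(d_t, d_n, tau),
        "total_tumor_expression": totals.astype(int),
    }, index=pd.Index(table.genes, name="gene"))
    return DropoutProfile(table=df, tau=tau)


def top_tumor_specific(profile: DropoutProfile, k: int = 20,
                       strict: bool = False) -> pd.DataFrame:
    """Top-k genes by total tumor expression (ties broken alphabetically).

    Default ranks over all genes, retaining each gene's category label;
    ``strict=True`` filters to the tumor-specific quadrant before ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = profile.table
    if strict:
        df = df[df["category"] == "tumor_specific"]
    df = df.reset_index().sort_values(
        by=["total_tumor_expression", "gene"], ascending=[False, True]
    ).set_index("gene")
    return df.head(k)


def cluster_zscore_matrix(
    norm_counts: sparse.spmatrix,
    cluster_labels: np.ndarray,
    gene_names: list[str],
    genes: list[str] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Gene x cluster z-scores of cluster-mean normalized expression.

    Per gene, cluster means are z-scored across clusters using the population
    SD convention (ddof=0; recorded in output metadata by callers). Each row
    then has mean 0 and SD 1 unless the cluster means are constant.
    """
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("z-scores across clusters need at least 2 clusters")
    X = sparse.csr_matrix(norm_counts)
    if genes is None:
        genes = list(gene_names)
    idx = [gene_names.index(g) for g in genes]
    means = np.zeros((len(genes), len(uniq)))
    for j, k in enumerate(uniq):
        mask = labels == k
        means[:, j] = np.asarray(X[mask][:, idx].mean(axis=0)).ravel()
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    return pd.DataFrame(z, index=pd.Index(genes, name="gene"),
                        columns=[int(k) for k in uniq])


def intersect_samples(genes_a: list[str], genes_b: list[str]) -> list[str]:
    """Marker genes shared between two samples (sorted alphabetically).

    Commutative and idempotent."""
    return sorted(set(genes_a) & set(genes_b))


def annotate_subtypes(cells: pd.DataFrame, regions: RegionSet) -> pd.Series:
    """Per-cell histological subtype from the containing tumor region.

    Cells in no tumor region are left unlabeled (None) and drop out of
    subtype analyses. Overlapping tumor regions with different labels are
    rejected."""
    tumor_regions = [r for r in regions if r.label in SUBTYPES]
    for i in range(len(tumor_regions)):
        for j in range(i + 1, len(tumor_regions)):
            a, b = tumor_regions[i], tumor_regions[j]
            if a.label != b.label and a.polygon.intersection(b.polygon).area > 1e-9:
                raise ValueError(
                    f"tumor regions {a.region_id!r} ({a.label}) and "
                    f"{b.region_id!r} ({b.label}) overlap with different labels"
                )
    x = cells["x"].to_numpy(float)
    y = cells["y"].to_numpy(float)
    out = np.full(len(cells), None, dtype=object)
    for r in tumor_regions:
        inside = regions.contains_points(r, x, y)
        out[inside & pd.isna(out)] = r.label
    return pd.Series(out, index=cells.index, name="subtype")


def subtype_positivity(
    table: CellTable,
    subtype_labels: pd.Series,
    genes: list[str],
) -> pd.DataFrame:
    """Per gene and subtype: positive-cell fraction (raw count >= 1) and mean
    normalized expression, plus between-subtype differences.

    delta1 = frac(ADC) - frac(TTF1neg_p40neg);
    delta2 = frac(TTF1neg_p40neg) - frac(SCC).
    Output is sorted by descending positivity in the ADC subtype.
    """
    if table.norm is None:
        raise ValueError("normalized counts required (run normalize_by_area)")
    labels = subtype_labels.to_numpy(object)
    present = {s for s in SUBTYPES if (labels == s).sum() > 0}
    missing = [s for s in SUBTYPES if s not in present]
    if missing:
        raise ValueError(f"subtype(s) with no cells: {missing}")
    idx = [table.gene_index(g) for g in genes]
    rows = []
    for g, gi in zip(genes, idx):
        pos = np.asarray((table.raw[:, gi] > 0).todense()).ravel()
        expr = np.asarray(table.norm[:, gi].todense()).ravel()
        rec: dict = {"gene": g}
        for s in SUBTYPES:
            m = labels == s
            rec[f"frac_{s}"] = float(pos[m].mean())
            rec[f"mean_expr_{s}"] = float(expr[m].mean())
        rec["delta1"] = rec["frac_ADC"] - rec["frac_TTF1neg_p40neg"]
        rec["delta2"] = rec["frac_TTF1neg_p40neg"] - rec["frac_SCC"]
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("gene")
    return out.sort_values("frac_ADC", ascending=False)
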