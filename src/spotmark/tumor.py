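"""Tumor-fraction calling from keratin expression.

Expression is normalized to counts per 100 micron^2 of cell area to remove
size-dependent effects (tumor cells are hypertrophic and carry more
transcripts per cell). Cells are clustered by Leiden community detection on a
k-nearest-neighbor graph in PCA space; clusters whose summed epithelial
keratin (KRT7 + KRT15) expression exceeds that of all remaining cells
(positive log2 fold change) are called keratin-positive and treated as the
tumor fraction, the operational analogue of pan-keratin IHC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .containers import CellTable

EPS = 1e-9  # pseudocount guarding empty complements in the keratin fold change


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels with the per-cluster keratin call.

    Cluster ids are contiguous integers starting at 1, renumbered in
    descending order of cell count (cluster 1 is the largest).
    """

    labels: np.ndarray                       # per-cell cluster id, int, >= 1
    keratin_log2fc: pd.Series | None = None  # cluster id -> log2 fold change
    keratin_positive: pd.Series | None = None  # cluster id -> bool

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def cell_flags(self) -> np.ndarray:
        """Per-cell keratin-positive flag."""
        if self.keratin_positive is None:
            raise ValueError("keratin call has not been made yet")
        return self.keratin_positive.reindex(self.labels).to_numpy()


def normalize_by_area(raw_counts: sparse.spmatrix, cell_areas: np.ndarray
                      ) -> sparse.csr_matrix:
    """Scale each cell's counts to counts per 100 micron^2: e = 100 * x / A.

    The sparsity pattern is unchanged; multiplying back by A/100 recovers the
    raw integer counts exactly.
    """
    areas = np.asarray(cell_areas, dtype=float)
    if np.any(~(areas > 0)):
        raise ValueError("cell areas must be strictly positive")
    raw = sparse.csr_matrix(raw_counts)
    scale = sparse.diags(100.0 / areas)
    return sparse.csr_matrix(scale @ raw)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K in descending order of cell count (ties by
    first appearance)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    mapping = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels], dtype=int)


def cluster_cells(
    norm_counts: sparse.spmatrix,
    n_pcs: int = 50,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden community detection on a kNN graph built in PCA space.

    Deterministic for a fixed seed. Clusters are renumbered in descending
    order of total cell count, starting at 1.
    """
    import anndata as ad
    import scanpy as sc

    X = sparse.csr_matrix(norm_counts).astype(np.float32)
    n_cells, n_genes = X.shape
    if n_cells < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n_cells}"
        )
    # degenerate case: all rows identical -> a single cluster
    col_max = np.asarray(X.max(axis=0).todense()).ravel()
    col_min = np.asarray(X.min(axis=0).todense()).ravel()
    if np.array_equal(col_max, col_min):
        return ClusterAssignment(labels=np.ones(n_cells, dtype=int))
    max_pcs = min(n_cells - 1, n_genes - 1)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {max_pcs} (too few cells/genes)")
        n_pcs = max_pcs
    adata = ad.AnnData(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=k_neighbors, use_rep="X_pca",
                        random_state=seed)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg", key_added="leiden")
    labels = adata.obs["leiden"].astype(int).to_numpy()
    return ClusterAssignment(labels=_renumber_by_size(labels))


def keratin_log2fc(
    norm_counts: sparse.spmatrix,
    clusters: ClusterAssignment,
    gene_names: list[str],
    keratin_genes: tuple[str, ...] = ("KRT7", "KRT15"),
) -> pd.Series:
    """Per-cluster log2 fold change of summed keratin expression vs the rest.

    For cluster k: FC = (mean summed keratin signal over k's cells + eps) /
    (same mean over all other cells + eps), on area-normalized counts.
    """
    for g in keratin_genes:
        if g not in gene_names:
            raise ValueError(f"keratin gene {g!r} absent from panel")
    idx = [gene_names.index(g) for g in keratin_genes]
    signal = np.asarray(sparse.csr_matrix(norm_counts)[:, idx].sum(axis=1)).ravel()
    labels = clusters.labels
    out = {}
    total_sum = signal.sum()
    n = len(signal)
    for k in np.unique(labels):
        mask = labels == k
        mean_in = signal[mask].mean()
        n_out = n - mask.sum()
        mean_out = (total_sum - signal[mask].sum()) / n_out if n_out else 0.0
        out[int(k)] = float(np.log2((mean_in + EPS) / (mean_out + EPS)))
    return pd.Series(out).sort_index()


def classify_keratin_clusters(log2fc: pd.Series) -> pd.Series:
    """Keratin-positive iff log2FC strictly greater than zero."""
    vals = log2fc.to_numpy(float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("keratin log2FC contains non-finite values")
    return log2fc > 0


def tumor_content(flags: pd.Series, clusters: ClusterAssignment) -> float:
    """Fraction of cells in keratin-positive clusters (operational tumor
    purity)."""
    labels = clusters.labels
    if len(labels) == 0:
        raise ValueError("empty cell table")
    per_cell = flags.reindex(labels).to_numpy()
    return float(np.mean(per_cell))


def call_tumor_fraction(
    table: CellTable,
    clusters: ClusterAssignment,
    keratin_genes: tuple[str, ...] = ("KRT7", "KRT15"),
) -> ClusterAssignment:
    """Convenience wrapper: attach keratin log2FC and flags to a clustering."""
    if table.norm is None:
        raise ValueError("normalize_by_area must run before the keratin call")
    lfc = keratin_log2fc(table.norm, clusters, table.genes, keratin_genes)
    flags = classify_keratin_clusters(lfc)
    return ClusterAssignment(labels=clusters.labels, keratin_log2fc=lfc,
                             keratin_positive=flags)


def compare_cytology(values_a: np.ndarray, values_b: np.ndarray
                     ) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test between two groups of
    per-cell cytological measurements (areas, transcript totals, ...)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both groups are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
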