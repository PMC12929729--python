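"""Biweight midcorrelation (bicor) coexpression networks per tumor subtype.

Bicor is an outlier-robust correlation built from Tukey biweights around the
median: for a vector x with median med_x and (unscaled) median absolute
deviation MAD_x,

    u_i = (x_i - med_x) / (9 * MAD_x)
    w_i = (1 - u_i^2)^2  if |u_i| < 1, else 0
    a_i = (x_i - med_x) * w_i

and bicor(x, y) = sum(a_i b_i) / sqrt(sum(a_i^2) sum(b_i^2)), clamped to
[-1, 1]. The tuning constant 9 and the unscaled MAD follow the published
definition. A vector with zero MAD (e.g. a gene detected in under half the
cells of a subtype) carries no biweight information; such variables fall back
to Pearson centering/scaling for their pairs and are flagged.

Networks keep an undirected signed edge for every gene pair with
|bicor| >= threshold; node size is the gene's mean normalized expression in
the subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class CoexpressionNetwork:
    subtype: str
    nodes: pd.DataFrame          # index gene; node_size, pearson_fallback
    edges: pd.DataFrame          # gene_a, gene_b, bicor, sign
    threshold: float = 0.2


def _biweights(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Biweight-centered vector a_i; returns (a, used_pearson_fallback)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        # no dispersion around the median: Pearson fallback for this variable
        return x - np.mean(x), True
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return (x - med) * w, False


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two equal-length vectors (n >= 4).

    Falls back to Pearson for a variable with zero MAD (flagged with a
    warning). Result clamped to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("bicor needs at least 4 observations")
    a, fb_x = _biweights(x)
    b, fb_y = _biweights(y)
    if fb_x or fb_y:
        which = [n for n, f in (("x", fb_x), ("y", fb_y)) if f]
        warnings.warn(f"zero MAD for {', '.join(which)}; Pearson fallback used")
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def bicor_matrix(
    norm_counts: sparse.spmatrix | np.ndarray,
    gene_names: list[str],
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise bicor over the cells of one subtype.

    Returns the symmetric gene x gene matrix (unit diagonal) and a boolean
    Series flagging genes that used the Pearson fallback.
    """
    X = norm_counts.toarray() if sparse.issparse(norm_counts) else np.asarray(norm_counts)
    X = X.astype(float)
    if X.shape[0] < 4:
        raise ValueError(f"subtype has {X.shape[0]} cells; bicor needs >= 4")
    if genes is None:
        genes = list(gene_names)
    idx = [gene_names.index(g) for g in genes]
    cols = np.empty((X.shape[0], len(genes)))
    fallback = np.zeros(len(genes), dtype=bool)
    for j, gi in enumerate(idx):
        a, fb = _biweights(X[:, gi])
        cols[:, j] = a
        fallback[j] = fb
    norms = np.sqrt((cols**2).sum(axis=0))
    norms[norms == 0] = 1.0
    unit = cols / norms
    mat = np.clip(unit.T @ unit, -1.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    mat = (mat + mat.T) / 2.0  # exact symmetry
    gi = pd.Index(genes, name="gene")
    return pd.DataFrame(mat, index=gi, columns=gi), pd.Series(fallback, index=gi)


def build_network(
    matrix: pd.DataFrame,
    node_sizes: pd.Series,
    threshold: float = 0.2,
    subtype: str = "",
    pearson_fallback: pd.Series | None = None,
) -> CoexpressionNetwork:
    """Threshold a bicor matrix into an undirected signed network.

    An edge is kept iff |bicor| >= threshold; its sign is retained. No
    self-edges. Edge count is non-increasing in the threshold.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    genes = list(matrix.index)
    rows = []
    vals = matrix.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            v = vals[i, j]
            if abs(v) >= threshold:
                rows.append({"gene_a": genes[i], "gene_b": genes[j],
                             "bicor": float(v), "sign": int(np.sign(v))})
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "bicor", "sign"])
    nodes = pd.DataFrame({
        "node_size": node_sizes.reindex(genes).to_numpy(float),
        "pearson_fallback": (
            pearson_fallback.reindex(genes).to_numpy(bool)
            if pearson_fallback is not None else False
        ),
    }, index=pd.Index(genes, name="gene"))
    return CoexpressionNetwork(subtype=subtype, nodes=nodes, edges=edges,
                               threshold=threshold)


def subtype_networks(
    norm_counts: sparse.spmatrix,
    gene_names: list[str],
    subtype_labels: pd.Series,
    genes: list[str],
    threshold: float = 0.2,
) -> dict[str, CoexpressionNetwork]:
    """One coexpression network per subtype population (cells pooled across
    samples upstream)."""
    out = {}
    labels = subtype_labels.to_numpy(object)
    X = sparse.csr_matrix(norm_counts)
    for s in pd.unique(pd.Series(labels).dropna()):
        mask = labels == s
        sub = X[mask]
        mat, fallback = bicor_matrix(sub, gene_names, genes)
        idx = [gene_names.index(g) for g in genes]
        sizes = pd.Series(
            np.asarray(sub[:, idx].mean(axis=0)).ravel(),
            index=pd.Index(genes, name="gene"),
        )
        out[str(s)] = build_network(mat, sizes, threshold, subtype=str(s),
                                    pearson_fallback=fallback)
    return out


def network_to_dict(net: CoexpressionNetwork) -> dict:
    return {
        "subtype": net.subtype,
        "threshold": net.threshold,
        "nodes": [
            {"gene": g, "node_size": float(r["node_size"]),
             "pearson_fallback": bool(r["pearson_fallback"])}
            for g, r in net.nodes.iterrows()
        ],
        "edges": net.edges.to_dict(orient="records"),
    }
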