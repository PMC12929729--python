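"""Shared fixtures: handcrafted micro-tables and one session-scoped run of
the default synthetic tissue through the spatial stage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from spotmark import synthetic, tumor
from spotmark.containers import CellTable
from spotmark.pipeline import RunConfig, run_spatial_stage

STUDY_SEED = 0


def make_table(counts: np.ndarray, areas=None, genes=None, x=None, y=None) -> CellTable:
    """Build a CellTable from a dense count array with minimal geometry."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if areas is None:
        areas = np.full(n, 100.0)
    genes = genes or [f"g{i}" for i in range(g)]
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": np.arange(n, dtype=float) if x is None else np.asarray(x, float),
        "y": np.zeros(n) if y is None else np.asarray(y, float),
        "cell_area": np.asarray(areas, float),
        "nucleus_area": np.asarray(areas, float) * 0.3,
        "total_counts": counts.sum(axis=1),
    })
    return CellTable(cells=cells, genes=genes, raw=sparse.csr_matrix(counts))


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic tissue with ground truth (the study conditions)."""
    cfg = synthetic.default_config(seed=STUDY_SEED)
    table, truth = synthetic.simulate_cells(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def spatial_run(tmp_path_factory):
    """One full spatial-stage run on the default tissue (PCA reducer for
    speed; the embedding backend does not affect calling or screening)."""
    cfg = RunConfig(seed=STUDY_SEED, embedding="pca")
    out = tmp_path_factory.mktemp("spatial_run")
    report = run_spatial_stage(cfg, out)
    return cfg, out, report


@pytest.fixture(scope="session")
def clustered_tissue(sim_default):
    """Default tissue with normalization, clustering and the keratin call."""
    cfg, table, truth = sim_default
    table = CellTable(cells=table.cells.copy(), genes=table.genes, raw=table.raw)
    table.norm = tumor.normalize_by_area(table.raw, table.cells["cell_area"].to_numpy())
    clusters = tumor.cluster_cells(table.norm, seed=STUDY_SEED)
    clusters = tumor.call_tumor_fraction(table, clusters)
    return cfg, table, truth, clusters
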