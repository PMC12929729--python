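"""Synthetic spatial tissues and bulk survival cohorts with known ground truth.

The spatial generator emulates an imaging-based spatial transcriptomics run
over an adenosquamous lung tumor section: rectangular tissue containing
intermixed ADC / SCC / TTF-1-negative-p40-negative tumor blocks, a stromal
(non-tumor) block, and two small circular normal-epithelium foci. Cells are
placed by a homogeneous Poisson point process per region, cell areas follow a
per-label log-normal (tumor cells hypertrophic relative to stroma), and gene
counts are Poisson with mean proportional to cell area, so per-cell transcript
totals increase with cell size. Planted marker genes with known dropout-rate
quadrants (tumor-specific, normal-specific, common-positive, common-negative)
provide recovery oracles for the screening stage, and an optional shared
log-normal latent factor induces within-subtype gene-gene coexpression.

The bulk generator draws exponential survival times whose log hazard is a
planted coefficient on the above/below-median marker indicator plus linear
clinical covariate effects, with independent uniform censoring calibrated to a
requested censoring fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, optimize
from shapely.geometry import Point, Polygon, box

from .containers import TUMOR_LABELS, BulkCohort, CellTable, Region, RegionSet

CATEGORIES = ("tumor_specific", "normal_specific", "common_negative", "common_positive")

# Sub-stream offsets: one global seed drives all RNG streams.
_STREAM_CELLS = 0
_STREAM_AREAS = 1
_STREAM_COUNTS = 2
_STREAM_BULK = 3


@dataclass
class CoexpressionFactor:
    """Shared log-normal latent factor multiplying the Poisson mean of
    ``genes`` for cells of each label in ``labels`` (E[factor] = 1)."""

    genes: tuple[str, ...]
    labels: tuple[str, ...]
    sigma: float = 0.8


@dataclass
class SimConfig:
    """Full description of one synthetic tissue.

    ``rates`` holds the expected counts per 100 micron^2 of cell area for
    every (gene, label); the per-cell Poisson mean is
    ``rate * library_size_slope * area / 100``.
    """

    seed: int
    domain_size: tuple[float, float]
    regions: RegionSet
    cell_density: dict[str, float]           # cells per 1e4 micron^2, per label
    area_model: dict[str, tuple[float, float]]  # label -> (mu, sigma) of ln(area)
    rates: pd.DataFrame                      # genes x labels
    marker_truth: dict[str, str]             # gene -> intended quadrant category
    library_size_slope: float = 1.0
    dropout_extra: dict[tuple[str, str], float] = field(default_factory=dict)
    coexpression: list[CoexpressionFactor] = field(default_factory=list)
    keratin_genes: tuple[str, str] = ("KRT7", "KRT15")
    epcam_gene: str = "EPCAM"
    glut1_gene: str = "SLC2A1"

    @property
    def panel(self) -> list[str]:
        return list(self.rates.index)

    def validate(self) -> None:
        w, h = self.domain_size
        if not (w > 0 and h > 0):
            raise ValueError("domain_size must be positive")
        labels = {r.label for r in self.regions}
        for lab in labels:
            if self.cell_density.get(lab, 0) <= 0:
                raise ValueError(f"cell_density for label {lab!r} must be > 0")
            if lab not in self.area_model:
                raise ValueError(f"area_model missing label {lab!r}")
            if lab not in self.rates.columns:
                raise ValueError(f"rates missing a column for label {lab!r}")
        dom = box(0, 0, w, h)
        for r in self.regions:
            if not dom.covers(r.polygon):
                raise ValueError(f"region {r.region_id!r} extends outside the domain")
        if self.rates.isna().any().any():
            raise ValueError("every panel gene needs a rate for every label")
        # tumor hypertrophy: tumor labels strictly larger than stroma
        if "non_tumor" in self.area_model:
            mu_stroma = self.area_model["non_tumor"][0]
            for lab in TUMOR_LABELS:
                if lab in self.area_model and self.area_model[lab][0] <= mu_stroma:
                    raise ValueError(
                        f"area_model mu for tumor label {lab!r} must exceed non_tumor's"
                    )
        for g in (*self.keratin_genes, self.epcam_gene, self.glut1_gene):
            if g not in self.rates.index:
                raise ValueError(f"required gene {g!r} absent from panel")
        if "normal" in self.rates.columns:
            g = self.glut1_gene
            if not (
                self.rates.loc[g, "SCC"] > self.rates.loc[g, "normal"]
                and self.rates.loc[g, "TTF1neg_p40neg"] > self.rates.loc[g, "normal"]
            ):
                raise ValueError(
                    f"{g!r} must be high in SCC and TTF1neg_p40neg and near-zero in normal"
                )
        unknown = set(self.marker_truth.values()) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown marker_truth categories: {sorted(unknown)}")
        # overlapping regions with conflicting labels are ambiguous -> reject
        regs = self.regions.regions
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                if regs[i].label != regs[j].label:
                    inter = regs[i].polygon.intersection(regs[j].polygon)
                    if inter.area > 1e-9:
                        raise ValueError(
                            f"regions {regs[i].region_id!r} and {regs[j].region_id!r} "
                            f"overlap with conflicting labels "
                            f"({regs[i].label!r} vs {regs[j].label!r})"
                        )


@dataclass
class GroundTruth:
    """Generator-side truth used by parameter-recovery tests."""

    cell_labels: pd.Series | None = None      # per-cell true histology label
    cell_regions: pd.Series | None = None     # per-cell source region id
    gene_categories: dict[str, str] | None = None
    tumor_fraction: float | None = None
    # bulk stage
    beta: float | None = None                 # true log hazard ratio of the marker
    covariate_effects: dict[str, float] | None = None
    censor_rate: float | None = None

    def to_json_dict(self) -> dict:
        out: dict = {}
        if self.cell_labels is not None:
            out["cell_labels"] = self.cell_labels.tolist()
        if self.cell_regions is not None:
            out["cell_regions"] = self.cell_regions.tolist()
        if self.gene_categories is not None:
            out["gene_categories"] = self.gene_categories
        if self.tumor_fraction is not None:
            out["tumor_fraction"] = float(self.tumor_fraction)
        if self.beta is not None:
            out["beta"] = float(self.beta)
        if self.covariate_effects is not None:
            out["covariate_effects"] = {k: float(v) for k, v in self.covariate_effects.items()}
        if self.censor_rate is not None:
            out["censor_rate"] = float(self.censor_rate)
        return out


# ---------------------------------------------------------------------------
# default panel and tissue layout
# ---------------------------------------------------------------------------

LABELS = ("ADC", "SCC", "TTF1neg_p40neg", "normal", "non_tumor")


def default_panel() -> tuple[pd.DataFrame, dict[str, str]]:
    """120-gene panel (desk-scale stand-in for a ~400-gene lung cancer panel).

    Planted structure (rates are expected counts per 100 micron^2):

    * 20 tumor-specific genes: the two epithelial keratins, an EPCAM-like
      epithelial marker, a GLUT1-like squamous-skewed gene and 16 lineage
      signature genes (pan-tumor / ADC-high / SCC-high / shared-with-TTF).
    * 20 common-positive genes (stroma and tumor both express; four carry the
      canonical mesenchymal/housekeeping names they mimic).
    * 20 common-negative genes (near-zero everywhere).
    * 10 normal-/stroma-specific genes.
    * 50 housekeeping filler genes with moderate label-varying rates.

    Normal-epithelium rates copy the ADC profile except for the EPCAM-like and
    GLUT1-like genes, so normal foci co-cluster with tumor cells (keratin-high)
    yet remain separable by the EPCAM positivity audit.
    """
    rows: dict[str, dict[str, float]] = {}
    truth: dict[str, str] = {}

    def add(gene, adc, scc, ttf, normal, stroma, category):
        rows[gene] = {"ADC": adc, "SCC": scc, "TTF1neg_p40neg": ttf,
                      "normal": normal, "non_tumor": stroma}
        truth[gene] = category

    # epithelial anchors: keratins high in all keratin-positive populations,
    # including normal epithelium (the audit's deliberate failure mode)
    add("KRT7", 2.5, 2.5, 2.5, 2.5, 0.05, "tumor_specific")
    add("KRT15", 2.5, 2.5, 2.5, 2.5, 0.05, "tumor_specific")
    # EPCAM-like: high in tumor, low in normal foci -> ROI audit target
    add("EPCAM", 3.0, 3.0, 3.0, 0.15, 0.05, "tumor_specific")
    # GLUT1-like: monotone SCC > TTF1neg > ADC, near-zero in normal
    add("SLC2A1", 0.35, 3.0, 1.2, 0.02, 0.02, "tumor_specific")
    for i in range(5):   # pan-tumor
        add(f"TSP{i+1:02d}", 2.0, 2.0, 2.0, 2.0, 0.05, "tumor_specific")
    for i in range(4):   # ADC-skewed (ERBB2-like: ADC ~ TTF1neg > SCC)
        add(f"TSA{i+1:02d}", 3.0, 0.2, 1.5, 3.0, 0.05, "tumor_specific")
    for i in range(4):   # SCC-skewed
        add(f"TSS{i+1:02d}", 0.2, 3.0, 1.5, 0.2, 0.05, "tumor_specific")
    for i in range(3):   # shared tumor, strongest in TTF1neg
        add(f"TSM{i+1:02d}", 1.5, 1.5, 2.5, 1.5, 0.05, "tumor_specific")

    for i, name in enumerate(
        ["VIM", "SPARC", "GNAS", "ENAH"] + [f"CP{i+1:02d}" for i in range(16)]
    ):
        add(name, 2.0, 2.0, 2.0, 2.0, 2.0, "common_positive")
    for i in range(20):
        add(f"NEG{i+1:02d}", 0.01, 0.01, 0.01, 0.01, 0.01, "common_negative")
    for i in range(10):
        add(f"NS{i+1:02d}", 0.02, 0.02, 0.02, 0.02, 2.0, "normal_specific")
    # housekeeping filler: moderate, mildly label-varying, clearly expressed
    hk_rng = np.random.default_rng(20260101)  # fixed: part of the panel definition
    for i in range(50):
        base = float(hk_rng.uniform(0.8, 3.0))
        jitter = hk_rng.uniform(0.85, 1.15, size=4)
        add(f"HK{i+1:02d}", base * jitter[0], base * jitter[1], base * jitter[2],
            base * jitter[0], base * jitter[3], "common_positive")

    rates = pd.DataFrame.from_dict(rows, orient="index")[list(LABELS)]
    # normal foci mimic ADC transcriptomes apart from the planted exceptions,
    # so they land inside keratin-positive clusters
    exceptions = {"EPCAM", "SLC2A1"}
    for g in rates.index:
        if g not in exceptions:
            rates.loc[g, "normal"] = rates.loc[g, "ADC"]
    return rates, truth


def default_regions(domain_size: tuple[float, float] = (3000.0, 2000.0)) -> RegionSet:
    """Four labeled blocks plus two circular normal-epithelium foci."""
    w, h = domain_size
    def rect(x0, y0, x1, y1):
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    circle1 = Point(w / 2, 0.25 * h).buffer(250.0, quad_segs=32)
    circle2 = Point(w / 2, 0.75 * h).buffer(250.0, quad_segs=32)
    return RegionSet(regions=[
        Region("block_ADC", rect(0, 0, 0.41 * w, 0.475 * h), "ADC"),
        Region("block_SCC", rect(0.59 * w, 0, w, 0.475 * h), "SCC"),
        Region("block_TTF", rect(0, 0.525 * h, 0.41 * w, h), "TTF1neg_p40neg"),
        Region("block_stroma", rect(0.59 * w, 0.525 * h, w, h), "non_tumor"),
        Region("normal_focus_1", circle1, "normal", note="normal epithelium"),
        Region("normal_focus_2", circle2, "normal", note="normal epithelium"),
    ])


def default_config(seed: int = 0) -> SimConfig:
    rates, truth = default_panel()
    cfg = SimConfig(
        seed=seed,
        domain_size=(3000.0, 2000.0),
        regions=default_regions(),
        cell_density={"ADC": 11.0, "SCC": 9.0, "TTF1neg_p40neg": 8.0,
                      "normal": 12.0, "non_tumor": 13.0},
        area_model={"ADC": (math.log(180.0), 0.35),
                    "SCC": (math.log(180.0), 0.35),
                    "TTF1neg_p40neg": (math.log(180.0), 0.35),
                    "normal": (math.log(140.0), 0.30),
                    "non_tumor": (math.log(95.0), 0.30)},
        rates=rates,
        marker_truth=truth,
        coexpression=[CoexpressionFactor(
            genes=("SLC2A1", "TSS01", "TSS02"),
            labels=("SCC", "TTF1neg_p40neg"),
            sigma=0.8,
        )],
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# spatial simulation
# ---------------------------------------------------------------------------

def _sample_points_in_polygon(poly: Polygon, n: int, rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points in a polygon by rejection sampling in its bbox."""
    minx, miny, maxx, maxy = poly.bounds
    xs, ys = [], []
    remaining = n
    while remaining > 0:
        m = max(32, int(remaining / max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-6)))
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        import shapely
        keep = shapely.covers(poly, shapely.points(cx, cy))
        cx, cy = cx[keep], cy[keep]
        take = min(remaining, len(cx))
        xs.append(cx[:take]); ys.append(cy[:take])
        remaining -= take
    return np.concatenate(xs) if xs else np.empty(0), np.concatenate(ys) if ys else np.empty(0)


def simulate_cells(config: SimConfig) -> tuple[CellTable, GroundTruth]:
    """Draw a synthetic tissue: cells, geometry and panel counts.

    Deterministic for a fixed ``config.seed``; all RNG streams derive from it
    by fixed offsets.
    """
    config.validate()
    rng_cells = np.random.default_rng([config.seed, _STREAM_CELLS])
    rng_areas = np.random.default_rng([config.seed, _STREAM_AREAS])
    rng_counts = np.random.default_rng([config.seed, _STREAM_COUNTS])

    genes = config.panel
    xs, ys, labels, region_ids = [], [], [], []
    for region in config.regions:
        density = config.cell_density[region.label]
        n = int(rng_cells.poisson(density * region.polygon.area / 1e4))
        if n == 0:
            warnings.warn(f"region {region.region_id!r} received zero cells")
            continue
        px, py = _sample_points_in_polygon(region.polygon, n, rng_cells)
        xs.append(px); ys.append(py)
        labels.extend([region.label] * n)
        region_ids.extend([region.region_id] * n)
    if not xs:
        raise ValueError("simulation produced no cells; check densities and regions")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    labels = np.array(labels)
    region_ids = np.array(region_ids)
    n_cells = len(x)

    areas = np.empty(n_cells)
    for lab in np.unique(labels):
        mask = labels == lab
        mu, sig = config.area_model[lab]
        areas[mask] = rng_areas.lognormal(mu, sig, mask.sum())
    nucleus = areas * rng_areas.uniform(0.15, 0.45, n_cells)

    # Poisson means: rate (per 100 um^2) * slope * area / 100
    lam = np.empty((n_cells, len(genes)))
    rate_cols = {lab: config.rates[lab].to_numpy(float) for lab in config.rates.columns}
    for lab in np.unique(labels):
        mask = labels == lab
        lam[mask] = np.outer(
            config.library_size_slope * areas[mask] / 100.0, rate_cols[lab]
        )
    gene_pos = {g: i for i, g in enumerate(genes)}
    for factor in config.coexpression:
        mask = np.isin(labels, factor.labels)
        if not mask.any():
            continue
        f = rng_counts.lognormal(-factor.sigma**2 / 2.0, factor.sigma, mask.sum())
        for g in factor.genes:
            lam[mask, gene_pos[g]] *= f
    counts = rng_counts.poisson(lam)
    for (gene, lab), p in config.dropout_extra.items():
        if p <= 0:
            continue
        mask = labels == lab
        keep = rng_counts.random(mask.sum()) >= p
        counts[np.flatnonzero(mask)[~keep], gene_pos[gene]] = 0

    cells = pd.DataFrame({
        "cell_id": [f"cell_{i:06d}" for i in range(n_cells)],
        "x": x, "y": y,
        "cell_area": areas,
        "nucleus_area": nucleus,
        "total_counts": counts.sum(axis=1),
    })
    table = CellTable(cells=cells, genes=genes, raw=sparse.csr_matrix(counts))
    truth = GroundTruth(
        cell_labels=pd.Series(labels, name="label"),
        cell_regions=pd.Series(region_ids, name="region_id"),
        gene_categories=dict(config.marker_truth),
        tumor_fraction=float(np.isin(labels, TUMOR_LABELS).mean()),
    )
    return table, truth


# ---------------------------------------------------------------------------
# bulk cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_EFFECTS = {
    "stage_34": math.log(1.8),   # stage III/IV vs I/II
    "age": 0.015,                # per year, centered at 65
    "smoking": math.log(1.3),
    "sex": math.log(1.1),
}

MUTATION_RATES = {
    # gene: (P(mut | marker high), P(mut | marker low)); squamous-like genes
    # enriched in the high group, EGFR in the low group
    "TP53": (0.55, 0.30),
    "KEAP1": (0.25, 0.08),
    "RB1": (0.18, 0.06),
    "KRAS": (0.25, 0.12),
    "EGFR": (0.25, 0.50),
}


def _calibrate_uniform_censoring(t: np.ndarray, censor_rate: float) -> float:
    """Upper bound C of Uniform(0, C) censoring so that the expected censored
    fraction equals ``censor_rate`` for the realized event times ``t``."""
    # P(censored | T=t) = P(U < t) = min(t/C, 1); average over the sample.
    def expected(c):
        return np.minimum(t / c, 1.0).mean() - censor_rate
    lo, hi = float(np.min(t)) * 1e-3, float(np.max(t)) * 1e4
    return float(optimize.brentq(expected, lo, hi))


def simulate_bulk_cohort(
    n_patients: int,
    beta: float,
    covariate_spec: dict[str, float] | None = None,
    censor_rate: float = 0.3,
    seed: int = 0,
    marker_gene: str = "SLC2A1",
    n_noise_genes: int = 20,
    with_mutations: bool = True,
) -> tuple[BulkCohort, GroundTruth]:
    """Simulate a bulk cohort whose hazard depends log-linearly on the
    above-median marker indicator plus clinical covariates.

    Marker expression is log-normal; event times are exponential with
    log-hazard ``beta * I(expr > median) + covariate terms``; censoring is
    independent Uniform(0, C) with C calibrated to ``censor_rate``.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    effects = dict(DEFAULT_COVARIATE_EFFECTS if covariate_spec is None else covariate_spec)
    rng = np.random.default_rng([seed, _STREAM_BULK])

    expr = rng.lognormal(2.0, 0.8, n_patients)
    stage = rng.choice([1, 2, 3, 4], n_patients, p=[0.35, 0.2, 0.3, 0.15])
    age = rng.normal(68.0, 9.0, n_patients)
    smoking = rng.binomial(1, 0.6, n_patients)
    sex = rng.binomial(1, 0.55, n_patients)
    histology = rng.choice(["ADC", "SCC", "ASC"], n_patients, p=[0.8, 0.17, 0.03])

    high = expr > np.median(expr)
    linpred = beta * high.astype(float)
    linpred += effects.get("stage_34", 0.0) * (stage >= 3)
    linpred += effects.get("age", 0.0) * (age - 65.0)
    linpred += effects.get("smoking", 0.0) * smoking
    linpred += effects.get("sex", 0.0) * sex
    base_hazard = math.log(2.0) / 40.0  # months^-1: 40-month baseline median
    t_event = rng.exponential(1.0 / (base_hazard * np.exp(linpred)))

    if censor_rate == 0:
        time, event = t_event, np.ones(n_patients, dtype=int)
    else:
        c_max = _calibrate_uniform_censoring(t_event, censor_rate)
        u = rng.uniform(0.0, c_max, n_patients)
        event = (t_event <= u).astype(int)
        time = np.minimum(t_event, u)
    time = np.maximum(time, 1e-6)

    sample_ids = [f"P{i:04d}" for i in range(n_patients)]
    clinical = pd.DataFrame({
        "time": time, "event": event, "stage": stage, "age": age,
        "smoking": smoking, "sex": sex, "histology": histology,
    }, index=pd.Index(sample_ids, name="sample_id"))
    if with_mutations:
        for gene, (p_hi, p_lo) in MUTATION_RATES.items():
            p = np.where(high, p_hi, p_lo)
            clinical[f"mut_{gene}"] = rng.binomial(1, p)

    expr_mat = pd.DataFrame(
        {marker_gene: expr}, index=clinical.index
    )
    # NKX2-1-like gene weakly anti-correlated with the marker, plus noise genes
    expr_mat["NKX2-1"] = rng.lognormal(3.0, 0.6, n_patients) / np.sqrt(expr / np.median(expr))
    for i in range(n_noise_genes):
        expr_mat[f"BGN{i+1:03d}"] = rng.lognormal(2.5, 0.7, n_patients)

    cohort = BulkCohort(expression=expr_mat, clinical=clinical)
    truth = GroundTruth(beta=float(beta), covariate_effects=effects,
                        censor_rate=float(censor_rate))
    return cohort, truth
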