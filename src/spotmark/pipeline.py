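"""End-to-end orchestration of the spatial and bulk stages.

The spatial stage runs: area normalization -> Leiden clustering -> keratin
call -> RGB-UMAP -> ROI audit and normal-cell exclusion -> dropout screen ->
subtype positivity -> bicor networks, writing every intermediate artifact and
a machine-readable run report. The bulk stage runs: median split -> KM /
log-rank (overall and configured subgroups) -> multivariable Cox -> mutation
enrichment. All randomness flows from the config seeds; rerunning the same
config reproduces hash-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bulk as bulk_mod, io, markers, network, rgbmap, roi, synthetic, tumor
from .containers import BulkCohort, CellTable, RegionSet

log = logging.getLogger("spotmark")


@dataclasses.dataclass
class RunConfig:
    """Effective parameters of one pipeline run (after defaulting)."""

    seed: int = 0
    simulate: bool = True
    # paths used when simulate is false
    cell_dir: str | None = None
    regions_path: str | None = None
    bulk_expression: str | None = None
    bulk_clinical: str | None = None
    # spatial-stage parameters
    n_pcs: int = 50
    k_neighbors: int = 15
    resolution: float = 1.0
    keratin_genes: tuple[str, str] = ("KRT7", "KRT15")
    audit_gene: str = "EPCAM"
    tau: float = 0.75
    top_k: int = 20
    embedding: str = "umap"
    grid: tuple[int, int] = (8, 8)
    bicor_threshold: float = 0.2
    network_genes: list[str] | None = None
    # bulk-stage parameters
    marker_gene: str = "SLC2A1"
    bulk_n_patients: int = 722
    bulk_beta: float = float(np.log(2.64))
    bulk_censor_rate: float = 0.3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.keratin_genes, list):
            cfg.keratin_genes = tuple(cfg.keratin_genes)
        if isinstance(cfg.grid, list):
            cfg.grid = tuple(cfg.grid)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["keratin_genes"] = list(self.keratin_genes)
        d["grid"] = list(self.grid)
        return d

    def validate_paths(self) -> None:
        if self.simulate:
            return
        for name in ("cell_dir", "regions_path"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config {name}={p!r} does not exist")


def _load_spatial_inputs(config: RunConfig
                         ) -> tuple[CellTable, RegionSet, synthetic.GroundTruth | None]:
    if config.simulate:
        sim = synthetic.default_config(seed=config.seed)
        table, truth = synthetic.simulate_cells(sim)
        return table, sim.regions, truth
    config.validate_paths()
    table = io.read_cell_table(config.cell_dir)
    regions = io.read_regions_geojson(config.regions_path)
    return table, regions, None


def run_spatial_stage(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full spatial stage; returns the run report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stage": "spatial", "version": __version__,
                    "parameters": config.to_dict(), "artifacts": {}}

    def stage(name):
        log.info("spatial stage: %s", name)

    try:
        stage("load inputs")
        table, regions, truth = _load_spatial_inputs(config)
        report["n_cells"] = table.n_cells
        report["n_genes"] = table.n_genes
        if config.simulate:
            io.write_cell_table(table, out / "simulated")
            io.write_regions_geojson(regions, out / "simulated" / "regions.geojson")
            io.write_report(truth.to_json_dict(), out / "simulated" / "ground_truth.json")
            report["artifacts"]["simulated"] = "simulated"

        stage("normalize by cell area")
        table.norm = tumor.normalize_by_area(table.raw, table.cells["cell_area"].to_numpy())

        stage("cluster and call keratin-positive tumor fraction")
        clusters = tumor.cluster_cells(
            table.norm, n_pcs=config.n_pcs, k_neighbors=config.k_neighbors,
            resolution=config.resolution, seed=config.seed,
        )
        clusters = tumor.call_tumor_fraction(table, clusters, config.keratin_genes)
        cell_flags = clusters.cell_flags()
        report["n_clusters"] = clusters.n_clusters
        report["tumor_content_raw"] = tumor.tumor_content(
            clusters.keratin_positive, clusters)
        clusters_df = pd.DataFrame({
            "cell_id": table.cells["cell_id"],
            "cluster": clusters.labels,
            "keratin_positive": cell_flags,
        })
        clusters_df.to_csv(out / "clusters.csv", index=False)
        io.write_report({
            "sizes": clusters.sizes(),
            "keratin_log2fc": clusters.keratin_log2fc,
            "keratin_positive": clusters.keratin_positive.astype(bool),
        }, out / "cluster_summary.json")
        report["artifacts"]["clusters"] = "clusters.csv"

        stage("ROI audit of normal foci")
        roi_ids = [r.region_id for r in regions.by_label("normal")]
        excluded_log = pd.DataFrame(columns=["cell_id", "roi", "reason"])
        if roi_ids:
            membership, reports = roi.audit_roi(
                table, clusters, regions, roi_ids, gene=config.audit_gene)
            report["roi_audit"] = {
                r.roi_id: {
                    "n_inside": len(r.excluded_cell_ids),
                    "min_q": float(r.per_cluster["q"].min()),
                    "pooled_p": r.pooled_p,
                } for r in reports
            }
            table_kept, excluded_log = roi.exclude_cells(
                table, membership, roi_ids, regions=regions)
            kept_mask = ~table.cells["cell_id"].isin(excluded_log["cell_id"]).to_numpy()
        else:
            table_kept = table
            kept_mask = np.ones(table.n_cells, dtype=bool)
        excluded_log.to_csv(out / "excluded_cells.csv", index=False)
        report["n_excluded"] = int(len(excluded_log))
        # post-exclusion tumor content over the full denominator: excluded
        # normal cells no longer count as tumor but remain in the sample
        flags_adj = cell_flags & kept_mask
        report["tumor_content"] = float(flags_adj.mean())

        stage("RGB-UMAP embedding of tumor cells")
        flags_kept = cell_flags[kept_mask]
        labels_kept = clusters.labels[kept_mask]
        tumor_rows = np.flatnonzero(flags_kept)
        emb = rgbmap.embed3(
            table_kept.norm[tumor_rows],
            keratin_positive=flags_kept[tumor_rows],
            seed=config.seed,
            method=config.embedding,
            sample_id="sample",
            cell_ids=table_kept.cells.loc[tumor_rows, "cell_id"],
        )
        rgb_table = rgbmap.spatial_rgb_table(
            table_kept.cells.iloc[tumor_rows], emb)
        rgb_table.to_csv(out / "rgb_cells.csv", index=False)
        report["artifacts"]["rgb_cells"] = "rgb_cells.csv"
        summary = rgbmap.treemap_summary(
            table_kept.cells.iloc[tumor_rows].reset_index(drop=True),
            labels_kept[tumor_rows], emb.rgb, grid=config.grid)
        io.write_report(rgbmap.treemap_to_dict(summary), out / "treemap.json")

        stage("dropout-rate marker screen")
        profile = markers.dropout_profile(table_kept, flags_kept, tau=config.tau)
        profile.table.to_csv(out / "dropout_profiles.csv")
        top = markers.top_tumor_specific(profile, k=config.top_k)
        top_strict = markers.top_tumor_specific(profile, k=config.top_k, strict=True)
        top.to_csv(out / "markers_topK.csv")
        tumor_specific = profile.tumor_specific()
        report["n_tumor_specific"] = len(tumor_specific)
        report["top_k"] = top.index.tolist()
        report["top_k_tumor_specific"] = top_strict.index.tolist()

        stage("per-cluster z-score heatmap matrix")
        if clusters.n_clusters >= 2:
            z = markers.cluster_zscore_matrix(
                table_kept.norm, labels_kept, table_kept.genes,
                genes=top_strict.index.tolist())
            z.to_csv(out / "zscore_matrix.csv")
            report["zscore_convention"] = "population SD across cluster means (ddof=0)"

        stage("subtype positivity")
        subtypes = markers.annotate_subtypes(table_kept.cells, regions)
        labeled = subtypes.notna() & flags_kept
        report["subtype_cell_counts"] = (
            subtypes[labeled].value_counts().to_dict())
        pos = markers.subtype_positivity(
            table_kept.subset(labeled.to_numpy()),
            subtypes[labeled].reset_index(drop=True),
            genes=tumor_specific if tumor_specific else table_kept.genes[:10],
        )
        pos.to_csv(out / "subtype_positivity.csv")

        stage("bicor coexpression networks")
        net_genes = config.network_genes or tumor_specific[: min(25, len(tumor_specific))]
        sub_table = table_kept.subset(labeled.to_numpy())
        nets = network.subtype_networks(
            sub_table.norm, sub_table.genes,
            subtypes[labeled].reset_index(drop=True),
            genes=net_genes, threshold=config.bicor_threshold)
        for s, net in nets.items():
            io.write_report(network.network_to_dict(net), out / f"network_{s}.json")
        report["network_subtypes"] = sorted(nets)

        if truth is not None:
            stage("recovery metrics against ground truth")
            truth_ts = {g for g, c in truth.gene_categories.items()
                        if c == "tumor_specific"}
            pred_ts = set(tumor_specific)
            tp = len(truth_ts & pred_ts)
            report["recovery"] = {
                "true_tumor_fraction": truth.tumor_fraction,
                "tumor_fraction_error": float(
                    report["tumor_content"] - truth.tumor_fraction),
                "screen_precision": tp / len(pred_ts) if pred_ts else 0.0,
                "screen_recall": tp / len(truth_ts) if truth_ts else 0.0,
            }
    except Exception as err:
        report["error"] = str(err)
        io.write_report(report, out / "run_report.json")
        raise RuntimeError(f"spatial stage failed at step: {err}") from err

    io.write_report(report, out / "run_report.json")
    return report


def run_bulk_stage(config: RunConfig, outdir: str | Path,
                   cohort: BulkCohort | None = None) -> dict:
    """Execute the bulk stage; returns the run report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stage": "bulk", "version": __version__,
                    "parameters": config.to_dict(), "artifacts": {}}
    try:
        if cohort is None:
            if config.simulate:
                cohort, truth = synthetic.simulate_bulk_cohort(
                    n_patients=config.bulk_n_patients,
                    beta=config.bulk_beta,
                    censor_rate=config.bulk_censor_rate,
                    seed=config.seed,
                    marker_gene=config.marker_gene,
                )
                io.write_bulk(cohort, out / "bulk_expression.csv",
                              out / "clinical.csv")
                io.write_report(truth.to_json_dict(), out / "bulk_ground_truth.json")
            else:
                config_paths = (config.bulk_expression, config.bulk_clinical)
                for p in config_paths:
                    if p is None or not Path(p).exists():
                        raise FileNotFoundError(f"bulk input {p!r} does not exist")
                cohort = io.read_bulk(*config_paths)
        report["n_patients"] = cohort.n_patients

        overall = bulk_mod.survival_analysis(cohort, config.marker_gene)
        report["logrank_p"] = overall.logrank_p
        report["logrank_statistic"] = overall.logrank_statistic
        km = pd.concat([
            overall.km_high.assign(group="high"),
            overall.km_low.assign(group="low"),
        ], ignore_index=True)
        km.to_csv(out / "km_curves.csv", index=False)
        overall.cox_table.to_csv(out / "cox_table.csv", index=False)
        marker_row = overall.cox_table.set_index("term").loc["marker_high"]
        report["cox_marker"] = {
            "HR": float(marker_row["HR"]),
            "ci_low": float(marker_row["ci_low"]),
            "ci_high": float(marker_row["ci_high"]),
            "p": float(marker_row["p"]),
        }

        # subgroup analyses: stage strata and EGFR/KRAS wild-type
        clin = cohort.clinical
        subgroups = {
            "stage_1_2": clin["stage"].to_numpy(int) <= 2,
            "stage_3_4": clin["stage"].to_numpy(int) >= 3,
        }
        if {"mut_EGFR", "mut_KRAS"} <= set(clin.columns):
            subgroups["egfr_kras_wt"] = (
                (clin["mut_EGFR"].to_numpy(int) == 0)
                & (clin["mut_KRAS"].to_numpy(int) == 0))
        report["subgroups"] = {}
        for name, mask in subgroups.items():
            if mask.sum() < 4:
                log.warning("subgroup %s empty or too small; skipped", name)
                continue
            try:
                res = bulk_mod.survival_analysis(
                    cohort, config.marker_gene, subgroup=pd.Series(mask),
                    with_cox=False)
            except ValueError as err:
                log.warning("subgroup %s skipped: %s", name, err)
                continue
            report["subgroups"][name] = {
                "n": int(mask.sum()), "logrank_p": res.logrank_p}

        mut_genes = cohort.mutation_genes()
        if mut_genes:
            high = bulk_mod.median_split(cohort.marker(config.marker_gene).to_numpy())
            flags = clin[[f"mut_{g}" for g in mut_genes]]
            flags = flags.rename(columns=lambda c: c[4:])
            enr = bulk_mod.fisher_enrichment(flags[high], flags[~high])
            enr.to_csv(out / "enrichment.csv")
            report["n_enriched_q05"] = int((enr["q"] < 0.05).sum())
    except Exception as err:
        report["error"] = str(err)
        io.write_report(report, out / "bulk_report.json")
        raise RuntimeError(f"bulk stage failed: {err}") from err

    io.write_report(report, out / "bulk_report.json")
    return report
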