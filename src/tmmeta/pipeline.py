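"""Stage drivers chaining the pipeline on disk artifacts.

Each stage reads and writes documented TSV/GMT/GraphML files so runs are
auditable and resumable; the CLI and the analysis scripts are thin
wrappers over these functions. All outputs carry provenance headers and
fixed numeric formatting, so a repeated run with the same seed is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import contrast as contrast_mod
from . import enrichment as enr
from . import io
from . import network as net
from . import normalize, simulate, study_stats
from .integrate import IntegrationConfig, integrate_studies

log = logging.getLogger(__name__)


def stage_simulate(outdir, cfg: simulate.SimulationConfig):
    """Write synthetic studies, probe map, pathways, responder table, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate.simulate_studies(cfg)
    params = cfg.as_dict()
    for m in sim.studies:
        io.write_expression(m, outdir / f"{m.study_id}_expression.tsv", seed=cfg.seed, params=params)
        io.write_metadata(m, outdir / f"{m.study_id}_metadata.tsv", seed=cfg.seed, params=params)
    io.write_tsv(sim.probe_gene_map, outdir / "probe_gene_map.tsv", index=False,
                 seed=cfg.seed, params=params)
    enr.write_gmt(sim.pathways, outdir / "pathways.gmt")
    truth_df = pd.DataFrame(
        {
            "gene_id": sorted(sim.truth.true_log2fc),
            "true_log2fc": [sim.truth.true_log2fc[g] for g in sorted(sim.truth.true_log2fc)],
        }
    )
    io.write_tsv(truth_df, outdir / "ground_truth.tsv", index=False, seed=cfg.seed, params=params)
    table, rtruth = simulate.simulate_responder_table(cfg)
    io.write_tsv(table, outdir / "responder_abundance.tsv", seed=cfg.seed, params=params)
    io.write_tsv(
        pd.DataFrame({"gene_id": sorted(rtruth.responder_specific_gene_ids)}),
        outdir / "responder_truth.tsv", index=False, seed=cfg.seed, params=params,
    )
    return sim


def load_study(expr_path, meta_path, study_id="") -> normalize.ExpressionMatrix:
    values = io.read_tsv(expr_path, index_col=0)
    metadata = io.read_tsv(meta_path, index_col=0)
    return normalize.ExpressionMatrix(values, metadata, study_id=study_id)


def stage_prep(
    study_paths,
    probe_map_path,
    outdir,
    drop_flagged: bool = False,
    min_median_correlation: float = 0.8,
    moderate: bool = True,
    paired: bool = False,
    seed=None,
):
    """Normalize, QC, average replicates and compute per-study gene stats.

    ``study_paths`` is a list of (expression_tsv, metadata_tsv, study_id).
    Returns the concatenated deduplicated per-study gene statistics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe_map = io.read_tsv(probe_map_path)
    all_stats, qc_rows = [], []
    for expr_path, meta_path, study_id in study_paths:
        m = load_study(expr_path, meta_path, study_id)
        m = normalize.quantile_normalize(m)
        if len(m.sample_ids) >= 3:
            report = normalize.qc_flag_samples(m, min_median_correlation)
            qc = report.metrics.copy()
            qc.insert(0, "study_id", study_id)
            qc_rows.append(qc)
            if drop_flagged and report.flagged_samples:
                log.info("%s: dropping flagged samples %s", study_id, sorted(report.flagged_samples))
                m = m.drop_samples(report.flagged_samples)
        averaged = study_stats.average_replicates(m)
        stats = study_stats.differential_stats(averaged, moderate=moderate, paired=paired)
        n_ind = averaged.metadata["individual"].nunique()
        gene_stats, summary = study_stats.map_and_deduplicate(
            stats, probe_map, study_id=study_id, n_individuals=n_ind
        )
        log.info("%s: %d probes -> %d genes (%d unmapped)", study_id,
                 summary["n_probes"], summary["n_genes"], summary["n_unmapped"])
        io.write_tsv(gene_stats, outdir / f"{study_id}_gene_stats.tsv", index=False, seed=seed)
        all_stats.append(gene_stats)
    if qc_rows:
        io.write_tsv(pd.concat(qc_rows), outdir / "qc_report.tsv", seed=seed)
    combined = pd.concat(all_stats, ignore_index=True)
    io.write_tsv(combined, outdir / "all_gene_stats.tsv", index=False, seed=seed)
    return combined


def stage_integrate(stats: pd.DataFrame, outdir, cfg: IntegrationConfig, seed=None) -> pd.DataFrame:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    integrated = integrate_studies(stats, cfg)
    io.write_tsv(integrated, outdir / "integrated_gene_stats.tsv", seed=seed, params=cfg.as_dict())
    return integrated


def stage_contrast(table_path, outdir, logfc_cutoff: float = 0.58, seed=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = io.read_tsv(table_path, index_col=0)
    records = contrast_mod.contrast_table(table)
    io.write_tsv(records, outdir / "responder_contrast.tsv", seed=seed)
    calls = {}
    for which in ("diff", "mean"):
        up, down = contrast_mod.call_changed_genes(records, which=which, logfc_cutoff=logfc_cutoff)
        calls[which] = (up, down)
        df = pd.DataFrame(
            sorted([(g, "up") for g in up] + [(g, "down") for g in down]),
            columns=["gene_id", "direction"],
        )
        io.write_tsv(df, outdir / f"changed_genes_{which}.tsv", index=False, seed=seed)
    return records, calls


def stage_enrich(changed, universe, gmt_paths, outdir, label, n_perm=1000, seed=0):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection = enr.merge_collections(
        *[enr.read_gmt(p, source=Path(p).stem) for p in gmt_paths]
    )
    results = enr.run_enrichment(changed, universe, collection, n_perm=n_perm, seed=seed)
    io.write_tsv(results, outdir / f"enrichment_{label}.tsv", index=False, seed=seed)
    return results, collection


def stage_network(
    results: pd.DataFrame,
    collection: enr.PathwayCollection,
    changed,
    gene_logfc: dict,
    outdir,
    mapping: dict | None = None,
    display_cutoff: float = 0.58,
    jaccard_threshold: float = 0.3,
    seed=None,
):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig = results[results["significant"]]
    gene_sets = collection.gene_sets()
    changed = set(changed)
    pathway_changed = {pid: set(gene_sets[pid]) & changed for pid in sig["pathway_id"]}
    assignment = net.assign_categories(
        sig, pathway_changed, mapping=mapping, jaccard_threshold=jaccard_threshold,
        pathway_names={p.pathway_id: p.name for p in collection},
    )
    graph = net.build_network(assignment, sig, pathway_changed, gene_logfc, display_cutoff)
    net.write_graphml(graph, outdir / "cluster_network.graphml")
    net.write_sif(graph, outdir / "cluster_network.sif")
    table = net.shared_gene_table(graph, min_clusters=2)
    io.write_tsv(table, outdir / "shared_gene_table.tsv", index=False, seed=seed)
    assign_df = pd.DataFrame(
        sorted(assignment.mapping.items()), columns=["pathway_id", "category"]
    )
    assign_df["provenance"] = assignment.provenance
    io.write_tsv(assign_df, outdir / "category_assignment.tsv", index=False, seed=seed)
    return graph, table, assignment


def run_all(
    outdir,
    sim_cfg: simulate.SimulationConfig | None = None,
    int_cfg: IntegrationConfig | None = None,
    n_perm: int = 200,
    drop_flagged: bool = False,
):
    """End-to-end synthetic run: simulate -> prep -> integrate -> contrast
    -> enrichment (integrated + responder branches) -> network.

    Returns a dict of the in-memory stage results.
    """
    outdir = Path(outdir)
    sim_cfg = sim_cfg or simulate.SimulationConfig()
    int_cfg = int_cfg or IntegrationConfig(n_total=sim_cfg.n_studies)
    seed = sim_cfg.seed
    data_dir, res_dir = outdir / "data", outdir / "results"
    sim = stage_simulate(data_dir, sim_cfg)
    study_paths = [
        (data_dir / f"{m.study_id}_expression.tsv", data_dir / f"{m.study_id}_metadata.tsv", m.study_id)
        for m in sim.studies
    ]
    stats = stage_prep(study_paths, data_dir / "probe_gene_map.tsv", res_dir,
                       drop_flagged=drop_flagged, seed=seed)
    integrated = stage_integrate(stats, res_dir, int_cfg, seed=seed)

    changed_int = set(integrated.index[integrated["is_differentially_expressed"]])
    universe_int = set(integrated.index)
    enr_int, coll = stage_enrich(changed_int, universe_int, [data_dir / "pathways.gmt"],
                                 res_dir, "integrated", n_perm=n_perm, seed=seed)

    records, calls = stage_contrast(data_dir / "responder_abundance.tsv", res_dir,
                                    logfc_cutoff=int_cfg.logfc_cutoff, seed=seed)
    up, down = calls["diff"]
    changed_resp = up | down
    enr_resp, coll_r = stage_enrich(changed_resp, set(records.index),
                                    [data_dir / "pathways.gmt"], res_dir, "responder",
                                    n_perm=n_perm, seed=seed)

    graph = table = None
    if enr_resp["significant"].any():
        gene_logfc = records["diff_R_minus_NR"].to_dict()
        graph, table, _ = stage_network(enr_resp, coll_r, changed_resp, gene_logfc,
                                        res_dir, display_cutoff=int_cfg.logfc_cutoff, seed=seed)
    elif enr_int["significant"].any():
        gene_logfc = integrated["weighted_logFC"].to_dict()
        graph, table, _ = stage_network(enr_int, coll, changed_int, gene_logfc,
                                        res_dir, display_cutoff=int_cfg.logfc_cutoff, seed=seed)
    return {
        "sim": sim,
        "stats": stats,
        "integrated": integrated,
        "enrichment_integrated": enr_int,
        "contrast": records,
        "enrichment_responder": enr_resp,
        "network": graph,
        "shared_gene_table": table,
    }
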