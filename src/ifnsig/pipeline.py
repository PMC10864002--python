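"""End-to-end pipelines tying the stages together.

``run_sc_pipeline`` derives a compact marker signature from a (synthetic or
provided) single-cell matrix: functional-signature scoring, enriched-cluster
detection, marker derivation, exclusivity filtering.  ``run_bulk_pipeline``
runs the bulk panel: deconvolution, group-profile imputation, NB dispersion,
model-based replicate simulation, enrichment scoring and NR/R comparison,
plus flow-style biomarker evaluation.  Every run writes a manifest
sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, packaged_gmt
from .biomarkers import evaluate_biomarkers
from .config import PipelineConfig
from .core_io import ExpressionMatrix, GeneSet, normalize, read_expression, read_gmt, write_gmt
from .deconv import SignatureMatrixRef, estimate_fractions, impute_group_profiles
from .markers import (
    build_functional_signature,
    derive_exclusive_signature,
    derive_markers,
    find_enriched_cluster,
    markers_to_frame,
)
from .nbboot import PanelConfig, estimate_dispersion, run_dataset_panel
from .scoring import module_score
from .synthetic import (
    IFNHI_LABEL,
    NEUTROPHIL_TYPE,
    BulkEffect,
    load_signature_matrix,
    simulate_bulk_cohort,
    simulate_flow_table,
    simulate_single_cell,
    spawn_seeds,
)

logger = logging.getLogger(__name__)


def _write_manifest(out_dir: Path, config: PipelineConfig, stage_seeds: list[int]) -> Path:
    manifest = {
        "ifnsig_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return path


def _planted_gene_set(n_planted: int) -> GeneSet:
    return GeneSet("planted", tuple(f"GENE{i:04d}" for i in range(1, n_planted + 1)))


def _synthetic_functional_sets(planted: GeneSet, n_genes: int) -> list[GeneSet]:
    """Three overlapping pathway-style sets whose union covers the planted genes."""
    extras = [f"GENE{i:04d}" for i in range(n_genes - 30, n_genes + 1)]
    half = len(planted.genes) // 2
    return [
        GeneSet("ifn_alpha_like", tuple(planted.genes[: half + 3]) + tuple(extras[:5])),
        GeneSet("ifn_gamma_like", tuple(planted.genes[half - 2 :]) + tuple(extras[5:10])),
        GeneSet("tnfa_like", tuple(extras[10:25])),
    ]


def run_sc_pipeline(config: PipelineConfig) -> tuple[GeneSet, dict[str, Path]]:
    """Derive an exclusive marker signature from single-cell data.

    Returns the derived gene set and the paths of the written artifacts
    (signature GMT, marker CSV, score CSV, cluster summary, manifest).
    """
    sc = config.sc
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, 2)

    if sc.synthetic:
        planted = _planted_gene_set(sc.n_planted)
        props = {
            NEUTROPHIL_TYPE: sc.neutrophil_prop,
            "monocyte": (1 - sc.neutrophil_prop) * 0.55,
            "t_cell": (1 - sc.neutrophil_prop) * 0.45,
        }
        matrix, labels, _truth = simulate_single_cell(
            n_cells=sc.n_cells,
            cell_type_props=props,
            ifnhi_share_of_neutrophils=sc.ifnhi_share,
            signature=planted,
            shift_log2=sc.shift_log2,
            n_genes=sc.n_genes,
            seed=seeds[0],
            signature_base_mean=sc.signature_base_mean,
        )
        clusters = dict(zip(matrix.sample_ids, labels))
        functional_sets = _synthetic_functional_sets(planted, sc.n_genes)
        marker_universe = [
            u for u, lab in clusters.items() if lab in (NEUTROPHIL_TYPE, IFNHI_LABEL)
        ]
    else:
        if sc.matrix_path is None or sc.clusters_path is None or sc.gmt_path is None:
            raise FileNotFoundError("non-synthetic sc pipeline needs matrix, clusters and gmt paths")
        matrix = read_expression(sc.matrix_path)
        cl = pd.read_csv(sc.clusters_path, dtype=str)
        clusters = dict(zip(cl.iloc[:, 0], cl.iloc[:, 1]))
        functional_sets = read_gmt(sc.gmt_path)
        marker_universe = list(matrix.sample_ids)

    logm = normalize(matrix, "logcpm")
    functional = build_functional_signature(functional_sets[:3])
    scores = module_score(logm, functional, n_bins=sc.n_bins, n_ctrl=sc.n_ctrl, seed=seeds[1])
    winner, summary = find_enriched_cluster(scores, clusters)
    logger.info("enriched cluster: %s", winner)

    universe = logm.subset_samples(marker_universe)
    target = [u for u in marker_universe if clusters[u] == winner]
    markers = derive_markers(
        universe, target, fc_min=sc.fc_min, alpha=sc.alpha, adjust=sc.adjust
    )
    derived = derive_exclusive_signature(
        markers, k=sc.k, frac_in_min=sc.frac_in_min, frac_out_max=sc.frac_out_max
    )

    artifacts: dict[str, Path] = {}
    artifacts["signature"] = out_dir / "derived_signature.gmt"
    write_gmt([derived] if derived.genes else [], artifacts["signature"])
    if not derived.genes:
        artifacts["signature"].write_text("", encoding="utf-8")
    artifacts["markers"] = out_dir / "markers.csv"
    markers_to_frame(markers).to_csv(artifacts["markers"], index=False)
    artifacts["scores"] = out_dir / "scores.csv"
    scores.to_tidy(clusters).to_csv(artifacts["scores"], index=False)
    artifacts["cluster_summary"] = out_dir / "cluster_summary.csv"
    summary.to_csv(artifacts["cluster_summary"], index=False)
    artifacts["manifest"] = _write_manifest(out_dir, config, seeds)
    return derived, artifacts


def run_bulk_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict[str, Path]]:
    """Run the synthetic bulk panel and biomarker evaluation.

    Returns the panel table and the written artifact paths (fractions,
    group profiles, dispersion tables, bootstrap panel, biomarker
    comparison, manifest).  Per-dataset failures are recorded in the status
    artifact without aborting the run.
    """
    bulk_cfg = config.bulk
    seeds = spawn_seeds(config.seed, bulk_cfg.n_datasets + 2)
    # validate stage parameters before any computation
    panel_cfg = PanelConfig(
        cell_type=bulk_cfg.cell_type,
        n_reps=bulk_cfg.n_reps,
        tau=bulk_cfg.tau,
        norm_method=bulk_cfg.norm_method,
        seed=seeds[-2],
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref_expr = load_signature_matrix()
    ref = SignatureMatrixRef.from_expression(ref_expr)
    neut15 = packaged_gmt("neut_ifn15")[0]
    ifng6 = packaged_gmt("ifng6")[0]

    cohorts = []
    for d in range(bulk_cfg.n_datasets):
        planted = d < bulk_cfg.n_planted_datasets
        effect = BulkEffect(
            signature_genes=tuple(neut15.genes),
            shift_log2=bulk_cfg.shift_log2 if planted else 0.0,
            ifnhi_fraction_nr=bulk_cfg.ifnhi_fraction_nr,
            ifnhi_fraction_r=bulk_cfg.ifnhi_fraction_r if planted else bulk_cfg.ifnhi_fraction_nr,
        )
        cohorts.append(
            simulate_bulk_cohort(
                (bulk_cfg.n_per_group, bulk_cfg.n_per_group),
                ref_expr,
                effect,
                bulk_cfg.noise_alpha,
                seeds[d],
                ifnhi_type=bulk_cfg.cell_type,
                dataset=f"DS{d + 1}",
                concentration=bulk_cfg.concentration,
            )[:2]
            + (f"DS{d + 1}",)
        )

    panel = run_dataset_panel(cohorts, ref, [neut15, ifng6], panel_cfg)
    table = panel.table()

    # intermediate artifacts, written per dataset (failures skipped)
    frames, profile_frames, disp_frames = [], [], []
    for bulk, meta, dataset in cohorts:
        try:
            fractions = estimate_fractions(bulk, ref)
            fr = fractions.to_frame()
            fr.insert(0, "dataset", dataset)
            frames.append(fr)
            profiles = impute_group_profiles(bulk, fractions, meta, bulk_cfg.cell_type)
            for group, prof in profiles.items():
                pf = prof.to_frame()
                pf.insert(0, "dataset", dataset)
                profile_frames.append(pf)
                df = estimate_dispersion(prof).to_frame()
                df.insert(0, "dataset", dataset)
                disp_frames.append(df)
        except Exception as exc:  # noqa: BLE001 - mirror the panel's isolation
            logger.warning("artifact stage failed for %s: %s", dataset, exc)
    fractions_df = pd.concat(frames) if frames else pd.DataFrame()
    profiles_df = pd.concat(profile_frames) if profile_frames else pd.DataFrame()
    disp_df = pd.concat(disp_frames) if disp_frames else pd.DataFrame()

    flow = simulate_flow_table(
        (bulk_cfg.flow_n_per_group, bulk_cfg.flow_n_per_group),
        (bulk_cfg.flow_mean_nr, bulk_cfg.flow_mean_r),
        bulk_cfg.flow_concentration,
        seeds[-1],
    )
    evaluation = evaluate_biomarkers(
        flow.table, ["ly6e_hi_freq"], n_boot=bulk_cfg.n_boot, seed=seeds[-1]
    )

    artifacts: dict[str, Path] = {}
    artifacts["fractions"] = out_dir / "fractions.csv"
    fractions_df.to_csv(artifacts["fractions"])
    artifacts["group_profiles"] = out_dir / "group_profiles.csv"
    profiles_df.to_csv(artifacts["group_profiles"], index=False)
    artifacts["dispersion"] = out_dir / "dispersion.csv"
    disp_df.to_csv(artifacts["dispersion"], index=False)
    artifacts["panel"] = out_dir / "bootstrap_panel.csv"
    table.to_csv(artifacts["panel"], index=False)
    artifacts["evaluation"] = out_dir / "biomarker_evaluation.csv"
    evaluation.to_csv(artifacts["evaluation"], index=False)
    artifacts["status"] = out_dir / "panel_status.csv"
    status = pd.DataFrame(
        [{"dataset": d, "status": "failed", "error": e} for d, e in panel.failures.items()]
        + [{"dataset": r.dataset, "status": "ok", "error": ""} for r in panel.results]
    ).drop_duplicates(subset=["dataset"])
    status.to_csv(artifacts["status"], index=False)
    artifacts["manifest"] = _write_manifest(out_dir, config, seeds)
    return table, artifacts
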