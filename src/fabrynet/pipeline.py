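"""End-to-end orchestration: simulate/ingest -> preprocess -> differential ->
explore -> network -> classify, with a manifest and a markdown summary."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    MetaboliteMatrix,
    SampleMetadata,
    MetaboliteAnnotation,
    align,
    read_annotation,
    read_matrix,
    read_metadata,
    write_matrix,
    write_metadata,
    write_annotation,
)
from .synthetic import SimulationConfig, simulate_cohort, attach_biomarkers
from .preprocessing import PreprocessConfig, preprocess
from .differential import differential_pipeline
from .multivariate import run_pca, spearman_biomarker_screen
from .network import (
    NetworkConfig,
    control_network,
    disease_specific_network,
    patient_specific_signatures,
    consensus_signature,
)
from .classify import CvConfig, evaluate_all_subsets, rank_models

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration of a full run.

    Either ``matrix_path``/``metadata_path``/``annotation_path`` point at an
    ingested study, or (default) a cohort is simulated from ``simulation``.
    """

    out_dir: str = "results/run"
    seed: int = 0
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alpha: float = 0.05
    fdr_method: str = "by"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    max_consensus_for_subsets: int = 13
    max_subset_size: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_config(path) -> RunConfig:
    """Build a RunConfig from a flat YAML file.

    Top-level keys map onto RunConfig fields; the nested sections
    ``simulation``, ``preprocess``, ``network`` and ``cv`` map onto the
    corresponding config dataclasses.  Unknown keys raise.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    sections = {
        "simulation": cfg.simulation,
        "preprocess": cfg.preprocess,
        "network": cfg.network,
        "cv": cfg.cv,
    }
    for key, value in raw.items():
        if key in sections:
            for k, v in (value or {}).items():
                if not hasattr(sections[key], k):
                    raise ValueError(f"unknown config key {key}.{k}")
                setattr(sections[key], k, v)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config key {key}")
    return cfg


def _hash_config(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_inputs(cfg: RunConfig):
    """Load or simulate the cohort; returns aligned (matrix, meta, anno, truth)."""
    if cfg.matrix_path:
        if not (cfg.metadata_path and cfg.annotation_path):
            raise ValueError("matrix_path requires metadata_path and annotation_path")
        matrix = read_matrix(cfg.matrix_path)
        meta = read_metadata(cfg.metadata_path)
        anno = read_annotation(cfg.annotation_path)
        truth = None
    else:
        sim = cfg.simulation
        sim.seed = cfg.seed
        matrix, meta, anno, truth = simulate_cohort(sim)
        meta = attach_biomarkers(meta, matrix, truth, seed=cfg.seed + 1)
    matrix, meta, anno, _ = align(matrix, meta, anno, permissive=True)
    return matrix, meta, anno, truth


def run_all(cfg: RunConfig) -> Path:
    """Execute every stage and write all artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    summary_lines = [f"# fabrynet run (seed {cfg.seed})", ""]
    try:
        stage = "ingest"
        matrix, meta, anno, truth = load_inputs(cfg)
        write_matrix(matrix, out / "matrix_raw.csv")
        write_metadata(meta, out / "metadata.csv")
        write_annotation(anno, out / "annotation.csv")
        if truth is not None:
            truth.to_json(out / "truth.json")
        counts = meta.group_counts()
        summary_lines += [
            f"- cohort: {counts.get('control', 0)} controls, {counts.get('fabry', 0)} patients, "
            f"{len(matrix.metabolite_ids)} metabolites, {matrix.n_missing} missing cells"
        ]

        stage = "preprocess"
        processed, prep_report = preprocess(matrix, cfg.preprocess)
        write_matrix(processed, out / "matrix_processed.csv")
        (out / "preprocess_report.json").write_text(
            json.dumps(
                {
                    "n_imputed": prep_report.n_imputed,
                    "n_row_fallbacks": prep_report.n_row_fallbacks,
                    "zero_variance_columns": prep_report.zero_variance_columns,
                },
                indent=1,
            )
        )

        stage = "differential"
        table, diff_summary = differential_pipeline(
            processed, meta, anno, alpha=cfg.alpha, fdr_method=cfg.fdr_method
        )
        table.to_csv(out / "differential.csv")
        (out / "differential_summary.json").write_text(json.dumps(diff_summary, indent=1, default=str))
        summary_lines += [
            f"- differential: {diff_summary['n_significant']} significant at "
            f"adjusted p < {cfg.alpha} ({cfg.fdr_method.upper()}); "
            f"composition {diff_summary['composition']}"
        ]

        stage = "explore"
        pca = run_pca(processed)
        pca.scores.to_csv(out / "pca_scores.csv")
        pca.loadings.to_csv(out / "pca_loadings.csv")
        pc1 = float(pca.explained_ratio[0]) * 100
        (out / "pca_explained.json").write_text(
            json.dumps({"explained_ratio": list(map(float, pca.explained_ratio))})
        )
        summary_lines += [f"- PCA: PC1 explains {pc1:.1f}% of variance"]
        if meta.table["lysoGb3"].notna().any():
            screens = spearman_biomarker_screen(processed, meta)
            for name, scr in screens.items():
                scr.to_csv(out / f"spearman_{name}.csv")

        stage = "network"
        ncfg = cfg.network
        ctrl_net = control_network(processed, meta, ncfg, for_pruning=True)
        disease_net = disease_specific_network(processed, meta, ncfg, _control_net=ctrl_net)
        disease_net.write_edge_list(out / "disease_specific_edges.csv")
        disease_net.write_graphml(out / "disease_specific.graphml")
        sigs = patient_specific_signatures(processed, meta, ncfg)
        consensus = consensus_signature(sigs, fraction=ncfg.min_signature_fraction, fallback_to_top=True)
        (out / "signatures.json").write_text(
            json.dumps(
                {
                    "per_patient": sigs.per_patient,
                    "signatures": sigs.signatures,
                    "consensus": consensus.members,
                    "frequency": consensus.frequency,
                },
                indent=1,
            )
        )
        summary_lines += [
            f"- network: {disease_net.n_edges} disease-specific edges; "
            f"{sigs.n_signatures} deduplicated patient signatures; "
            f"consensus of {len(consensus.members)}: {consensus.members}"
        ]

        stage = "classify"
        members = consensus.members
        if len(members) > cfg.max_consensus_for_subsets:
            ranked = sorted(members, key=lambda m: (-consensus.frequency[m], m))
            members = sorted(ranked[: cfg.max_consensus_for_subsets])
        evaluations = evaluate_all_subsets(
            processed, meta, members, cv=cfg.cv, seed=cfg.seed, max_size=cfg.max_subset_size
        )
        leaderboard = rank_models(evaluations)
        leaderboard.to_csv(out / "leaderboard.csv", index=False)
        full = next(e for e in evaluations if len(e.subset) == len(members))
        pd.DataFrame({"fpr": full.roc_fpr, "tpr": full.roc_tpr}).to_csv(
            out / "roc_full_model.csv", index=False
        )
        singles = leaderboard[leaderboard["size"] == 1]
        summary_lines += [
            f"- classification: full {len(members)}-metabolite model AUC {full.auc:.3f} "
            f"(CI {full.ci_low:.3f}-{full.ci_high:.3f}); best model AUC {leaderboard['auc'].iloc[0]:.3f}; "
            f"median single-metabolite AUC {singles['auc'].median():.3f}"
        ]
    except Exception as exc:  # persist partial outputs, then re-raise with stage
        (out / "FAILED.txt").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": _hash_config(cfg),
        "stages": ["ingest", "preprocess", "differential", "explore", "network", "classify"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "summary.md").write_text("\n".join(summary_lines) + "\n")
    logger.info("run complete: %s", out)
    return out
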