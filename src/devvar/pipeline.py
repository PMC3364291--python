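"""End-to-end orchestration of the differential-variability pipeline.

Stages: (simulate or load) -> detection filter -> offset/log2 ->
quantile normalize -> replicate average -> sex adjust -> variance screen
-> age-trajectory exclusion -> enrichment (when annotations are given).
Every run writes a machine-readable manifest (parameters, seed, library
versions, stage provenance, probe-count funnel) so a rerun with the same
config reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .enrichment import enrichment_report
from .io import StudyConfig, load_study, write_study_bundle
from .matrix import ExpressionMatrix, SampleTable
from .preprocess import (
    adjust_group_means,
    average_technical_replicates,
    filter_by_detection,
    offset_and_log2,
    quantile_normalize,
)
from .synthetic import simulate_expression_study, simulate_gene_sets
from .trajectory import screen_age_regulated
from .variance import run_variance_screen, screen_summary

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def preprocess_study(
    matrix: ExpressionMatrix, samples: SampleTable, config: StudyConfig
) -> tuple[ExpressionMatrix, SampleTable, dict[str, int]]:
    """Run the preprocessing stages; returns the probe-count funnel too."""
    funnel = {"input_probes": matrix.n_probes, "input_arrays": matrix.n_samples}
    if matrix.detection_p is not None:
        min_ind = config.min_individuals
        if min_ind is None:
            min_ind = samples.n_subjects // 2
        matrix = filter_by_detection(
            matrix,
            config.detection_p_threshold,
            min_ind,
            samples,
            vote=config.detection_vote,
        )
        funnel["detected_probes"] = matrix.n_probes
    if matrix.scale == "raw":
        matrix = offset_and_log2(matrix)
    matrix = quantile_normalize(matrix)
    matrix, samples = average_technical_replicates(matrix, samples)
    funnel["unique_subjects"] = matrix.n_samples
    if config.adjust_sex:
        matrix = adjust_group_means(matrix, samples, factor="sex")
    return matrix, samples, funnel


def run_pipeline(config: StudyConfig, write_outputs: bool = True) -> dict:
    """Execute the full pipeline; returns the in-memory result bundle.

    The returned dict holds the processed matrix and samples, the screen
    and trajectory tables, the enrichment report (or None), the summary
    dict, and (when ``write_outputs``) the paths written under
    ``config.output_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.simulation is not None:
            sim_cfg = replace(config.simulation, seed=config.seed)
            matrix, samples, truth = simulate_expression_study(sim_cfg)
            gene_sets = simulate_gene_sets(
                truth, n_terms=50, planted_odds_ratio=10.0, seed=config.seed + 1
            )
            probe_gene_map = truth.probe_gene_map
            if write_outputs:
                write_study_bundle(
                    out_dir / "simulated_study", matrix, samples, truth=truth,
                    gene_sets=gene_sets,
                )
        else:
            truth = None
            matrix, samples, gene_sets, probe_gene_map = load_study(config)
            samples = replace(samples, age_cutoff=config.age_cutoff)

        stage = "preprocess"
        matrix, samples, funnel = preprocess_study(matrix, samples, config)

        stage = "variance_screen"
        screen = run_variance_screen(
            matrix,
            samples,
            fraction=config.top_fraction,
            k=config.top_k,
            q_cutoff=config.q_cutoff,
            fdr_method=config.fdr_method,
        )
        funnel["selected_top_variance"] = int(screen["selected_top_variance"].sum())
        funnel["significant"] = int(screen["significant"].sum())
        summary = screen_summary(screen, q_cutoff=config.q_cutoff)

        stage = "age_trajectory"
        sig_probes = list(screen.index[screen["significant"]])
        trajectory = screen_age_regulated(
            matrix, samples, probes=sig_probes, q_cutoff=config.q_cutoff
        )
        summary["n_developmentally_regulated"] = int(
            trajectory["developmentally_regulated"].sum()
        )

        stage = "enrichment"
        report = None
        if gene_sets is not None and probe_gene_map is not None and sig_probes:
            report = enrichment_report(
                screen,
                gene_sets,
                probe_gene_map,
                q_report_cutoff=config.enrichment_q_cutoff,
            )
            summary["n_enriched_terms_vs_all"] = len(report.significant_vs_all)
            summary["n_enriched_terms_vs_top"] = len(report.significant_vs_top)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    summary["funnel"] = funnel
    result = {
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "screen": screen,
        "trajectory": trajectory,
        "enrichment": report,
        "summary": summary,
        "paths": {},
    }
    if write_outputs:
        result["paths"] = _write_result_bundle(out_dir, config, result)
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_result_bundle(out_dir: Path, config: StudyConfig, result: dict) -> dict:
    paths = {
        "screen": out_dir / "variance_screen.csv",
        "trajectory": out_dir / "age_trajectory.csv",
        "summary": out_dir / "summary.json",
        "manifest": out_dir / "manifest.json",
    }
    result["screen"].to_csv(paths["screen"], index_label="probe_id")
    result["trajectory"].to_csv(paths["trajectory"], index_label="probe_id")
    if result["enrichment"] is not None:
        rep = result["enrichment"]
        paths["enrichment_vs_all"] = out_dir / "enrichment_vs_all_present.csv"
        paths["enrichment_vs_top"] = out_dir / "enrichment_vs_top_variance.csv"
        paths["enrichment_plot_data"] = out_dir / "enrichment_plot_data.csv"
        rep.vs_all_present.to_csv(paths["enrichment_vs_all"], index_label="term_id")
        rep.vs_top_variance.to_csv(paths["enrichment_vs_top"], index_label="term_id")
        pd.concat(
            [rep.plot_data("all_present"), rep.plot_data("top_variance")]
        ).to_csv(paths["enrichment_plot_data"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(result["summary"], fh, indent=2, default=_json_default)
    manifest = {
        "devvar_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": _config_dict(config),
        "provenance": list(result["matrix"].provenance),
        "funnel": result["summary"]["funnel"],
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return {k: str(v) for k, v in paths.items()}


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    if config.simulation is not None:
        d["simulation"] = asdict(config.simulation)
    return d
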