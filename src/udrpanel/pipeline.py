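"""End-to-end pipeline orchestration and tab-separated report bundle.

``run_pipeline`` sequences whatever stages its inputs support:

* discovery (counts + metadata): prevalence cascade, dual differential
  testing, candidate selection;
* validation (Ct + metadata): spike-in dCt normalization, per-marker
  filter and ROC;
* optimization (after validation): direction assignment, panel search on
  the validation cohort and, when discovery data is present, re-evaluation
  of the selected panels on the discovery cohort;
* reporting: cohort summary tables.

Outputs are deterministic given (inputs, config): all randomness (the
bootstrap CIs) is driven by ``config.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .discovery import (
    CandidateSet,
    cpm_normalize,
    discovery_de,
    hit_sets,
    prevalence_filter,
    select_candidates,
    stagewise_pvalues,
)
from .matrix import ExpressionMatrix
from .panels import (
    EXHAUSTIVE_LIMIT,
    PanelEvaluation,
    assign_directions,
    backward_search,
    evaluate_panel,
    exhaustive_search,
    select_optimal,
)
from .samples import Cohort
from .stats import cohort_summary
from .validation import normalize_delta_ct, validate_candidates

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "optimize_panels", "delta_ct_to_linear"]


def delta_ct_to_linear(delta_ct: ExpressionMatrix) -> ExpressionMatrix:
    """Linear relative expression 2**dCt (UDR needs positive values)."""
    if delta_ct.scale != "delta_ct":
        raise ValueError(f"expected scale='delta_ct', got {delta_ct.scale!r}")
    return ExpressionMatrix(np.exp2(delta_ct.data), "linear")


@dataclass
class PipelineResult:
    config: RunConfig
    filtered_counts: ExpressionMatrix | None = None
    de_discovery: pd.DataFrame | None = None
    candidates: CandidateSet | None = None
    de_validation: pd.DataFrame | None = None
    validated: list[str] = field(default_factory=list)
    panel_evaluations: list[PanelEvaluation] = field(default_factory=list)
    optimal_panels: list[PanelEvaluation] = field(default_factory=list)
    cohort_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)


def optimize_panels(
    expr_linear: ExpressionMatrix,
    meta: Cohort,
    up: set[str],
    down: set[str],
    config: RunConfig,
    contrast,
    cohort_tag: str = "",
) -> tuple[list[PanelEvaluation], list[PanelEvaluation]]:
    """Search the panel space and pick parsimonious near-best panels.

    Exhaustive when the space has at most ``EXHAUSTIVE_LIMIT`` panels,
    sequential backward elimination otherwise.
    """
    space = (2 ** len(up) - 1) * (2 ** len(down) - 1)
    kwargs = dict(
        cohort_tag=cohort_tag,
        log_scale=config.udr_log_scale,
        n_boot=0,
        seed=config.seed,
    )
    if space <= EXHAUSTIVE_LIMIT:
        logger.info("panel search: exhaustive over %d panels", space)
        evaluations = exhaustive_search(expr_linear, meta, up, down, contrast, **kwargs)
    else:
        logger.info("panel search: backward elimination (space %d)", space)
        evaluations = backward_search(expr_linear, meta, up, down, contrast, **kwargs)
    optimal = select_optimal(evaluations, config.parsimony_epsilon)
    # re-evaluate the selected panels with bootstrap CIs
    optimal = [
        evaluate_panel(
            expr_linear, meta, e.panel, contrast,
            cohort_tag=cohort_tag, log_scale=config.udr_log_scale,
            n_boot=config.n_boot, seed=config.seed,
        )
        for e in optimal
    ]
    return evaluations, optimal


def run_pipeline(
    config: RunConfig,
    *,
    discovery_counts: ExpressionMatrix | None = None,
    discovery_meta: Cohort | None = None,
    validation_ct: ExpressionMatrix | None = None,
    validation_meta: Cohort | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run every stage the provided inputs allow; optionally write the
    TSV report bundle to ``out_dir``."""
    if discovery_counts is not None and discovery_meta is None:
        raise ValueError("discovery counts provided without metadata")
    if validation_ct is not None and validation_meta is None:
        raise ValueError("validation Ct matrix provided without metadata")
    if discovery_counts is None and validation_ct is None:
        raise ValueError("no inputs: provide discovery counts and/or validation Ct data")

    result = PipelineResult(config=config)
    early = list(config.stage_grouping["early"])

    # ---- discovery --------------------------------------------------------
    if discovery_counts is not None:
        logger.info("discovery: %d features x %d samples",
                    discovery_counts.n_features, discovery_counts.n_samples)
        stage1 = prevalence_filter(discovery_counts, config.prevalence_stage1)
        stage2 = prevalence_filter(stage1, config.prevalence_stage2)
        result.filtered_counts = stage2
        table_nb, table_mw = discovery_de(stage2, discovery_meta, early, config)
        nb_hits, mw_hits = hit_sets(table_nb, table_mw, config)
        stagewise = stagewise_pvalues(stage2, discovery_meta, config)
        result.candidates = select_candidates(
            nb_hits, mw_hits, stagewise, config.literature, config,
            universe=stage2.feature_ids,
        )
        merged = pd.concat([table_nb, table_mw], ignore_index=True)
        result.de_discovery = merged

    # ---- validation -------------------------------------------------------
    if validation_ct is not None:
        delta = normalize_delta_ct(validation_ct, config.spike_in_id)
        if result.candidates is not None:
            candidates = [
                m for m in result.candidates.members if m in delta.data.index
            ] or list(delta.data.index)
        else:
            candidates = list(delta.data.index)
        result.de_validation, result.validated = validate_candidates(
            delta, validation_meta, candidates, early, config
        )

        # ---- optimization -------------------------------------------------
        if len(result.validated) >= 2:
            sub = result.de_validation.set_index("feature_id").loc[result.validated]
            try:
                up, down = assign_directions(sub.reset_index())
            except ValueError as exc:
                logger.warning("panel optimization skipped: %s", exc)
            else:
                linear = delta_ct_to_linear(delta)
                evaluations, optimal = optimize_panels(
                    linear, validation_meta, up, down, config, early, "validation"
                )
                result.panel_evaluations = list(evaluations)
                result.optimal_panels = list(optimal)
                if discovery_counts is not None and result.filtered_counts is not None:
                    cpm = cpm_normalize(result.filtered_counts, config.pseudocount)
                    for e in optimal:
                        members = set(e.panel.members)
                        if members <= set(cpm.feature_ids):
                            result.panel_evaluations.append(
                                evaluate_panel(
                                    cpm, discovery_meta, e.panel, early,
                                    cohort_tag="discovery",
                                    log_scale=config.udr_log_scale,
                                    n_boot=config.n_boot, seed=config.seed,
                                )
                            )

    # ---- reporting --------------------------------------------------------
    if discovery_meta is not None:
        result.cohort_summaries["discovery"] = cohort_summary(discovery_meta)
    if validation_meta is not None:
        result.cohort_summaries["validation"] = cohort_summary(validation_meta)

    if out_dir is not None:
        write_report_bundle(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _evaluations_frame(evaluations: list[PanelEvaluation]) -> pd.DataFrame:
    rows = [
        {
            "panel_members": e.panel.label(),
            "n_up": len(e.panel.up),
            "n_down": len(e.panel.down),
            "auc": e.roc.auc,
            "ci_low": e.roc.ci_low,
            "ci_high": e.roc.ci_high,
            "n_evaluable": e.roc.n_case + e.roc.n_control,
            "cohort": e.cohort_tag,
        }
        for e in evaluations
    ]
    return pd.DataFrame(rows)


def write_report_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False)

    if result.de_discovery is not None:
        dump(result.de_discovery, "de_discovery.tsv")
    if result.candidates is not None:
        cand = result.candidates
        rows = [
            {"feature_id": f, "provenance": cand.provenance[f], "excluded_reason": ""}
            for f in cand.members
        ] + [
            {"feature_id": f, "provenance": "excluded", "excluded_reason": reason}
            for f, reason in sorted(cand.excluded.items())
        ]
        dump(pd.DataFrame(rows), "candidates.tsv")
    if result.de_validation is not None:
        dump(result.de_validation, "de_validation.tsv")
    if result.panel_evaluations:
        dump(_evaluations_frame(result.panel_evaluations), "panel_evaluations.tsv")
        scores = []
        for e in result.optimal_panels or result.panel_evaluations:
            for sample_id, udr in e.udr_scores.items():
                scores.append(
                    {"sample_id": sample_id, "panel_id": e.panel.label(), "udr": udr}
                )
        dump(pd.DataFrame(scores), "panel_scores.tsv")
        points = []
        for e in result.optimal_panels:
            for fpr, tpr in e.roc.points:
                points.append(
                    {"panel_id": e.panel.label(), "cohort": e.cohort_tag,
                     "fpr": fpr, "tpr": tpr}
                )
        dump(pd.DataFrame(points), "roc_points.tsv")
    if result.cohort_summaries:
        frames = []
        for tag, df in result.cohort_summaries.items():
            df = df.copy()
            df.insert(0, "cohort", tag)
            frames.append(df)
        dump(pd.concat(frames, ignore_index=True), "cohort_summary.tsv")
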