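"""UDR (up-down ratio) scoring and panel optimization.

The UDR is a per-sample diagnostic score for a panel whose members are
split into an up-regulated set (N members) and a down-regulated set
(M members):

    UDR = (sum of up-member expression / N) / (sum of down-member expression / M)

i.e. the mean expression of the up-regulated members divided by the mean
expression of the down-regulated ones.  In disease samples the numerator
rises and the denominator falls, so the ratio amplifies the group
difference while cancelling sample-wide scale factors (the score is
invariant under multiplying every expression value by a constant).

Expression must be on a linear scale (strictly positive): CPM + pseudo-
count for NGS data, or ``2**dCt`` for spike-in-normalized qPCR data --
dCt itself can be negative, which would break the ratio.  A ``log_scale``
switch computes the log-UDR instead (difference of mean log2 expression,
i.e. the log of the geometric-mean ratio) for sensitivity analysis.

Panel search: directions are fixed per marker from the validation
contrast; the search explores subsets only.  Exhaustive enumeration is
used when the panel space is small ((2^N - 1)(2^M - 1) <= 4096 panels);
sequential backward elimination -- repeatedly removing the member whose
removal most improves the AUC -- is available for larger spaces.  Optimal
panels are the smallest panels whose AUC is within ``parsimony_epsilon``
of the best.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .samples import Cohort, split_groups
from .stats import DifferentialResult, RocResult, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "PanelAssignment",
    "PanelEvaluation",
    "udr_score",
    "udr_scores",
    "assign_directions",
    "enumerate_panels",
    "evaluate_panel",
    "exhaustive_search",
    "backward_search",
    "select_optimal",
    "EXHAUSTIVE_LIMIT",
]

#: largest panel-space size still searched exhaustively by default
EXHAUSTIVE_LIMIT = 4096


@dataclass(frozen=True)
class PanelAssignment:
    """Disjoint, non-empty up- and down-regulated member sets."""

    up: frozenset[str]
    down: frozenset[str]

    def __init__(self, up: Iterable[str], down: Iterable[str]):
        object.__setattr__(self, "up", frozenset(up))
        object.__setattr__(self, "down", frozenset(down))
        if not self.up or not self.down:
            raise ValueError("panel requires at least one up and one down member")
        if self.up & self.down:
            raise ValueError(f"up/down sets overlap: {sorted(self.up & self.down)}")

    @property
    def members(self) -> list[str]:
        return sorted(self.up) + sorted(self.down)

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)

    def label(self) -> str:
        ups = ";".join(f"{m}+" for m in sorted(self.up))
        downs = ";".join(f"{m}-" for m in sorted(self.down))
        return f"{ups};{downs}"


@dataclass
class PanelEvaluation:
    """One panel scored on one cohort: per-sample UDR values plus ROC."""

    panel: PanelAssignment
    udr_scores: pd.Series
    roc: RocResult
    cohort_tag: str = ""
    skipped_samples: list[str] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return self.roc.auc


def _member_values(expr: ExpressionMatrix, panel: PanelAssignment) -> pd.DataFrame:
    if expr.scale != "linear":
        raise ValueError(
            f"UDR requires linear-scale expression, got scale={expr.scale!r} "
            "(convert dCt with 2**dCt, counts with CPM + pseudocount)"
        )
    missing = [m for m in panel.members if m not in expr.data.index]
    if missing:
        raise KeyError(f"panel members absent from expression matrix: {missing}")
    return expr.data.loc[panel.members]


def udr_scores(
    expr: ExpressionMatrix,
    panel: PanelAssignment,
    *,
    log_scale: bool = False,
) -> tuple[pd.Series, list[str]]:
    """UDR for every evaluable sample.

    Samples with a missing value for any panel member are skipped (second
    return value), not imputed.  ``log_scale=True`` returns the log-UDR:
    mean log2(up) - mean log2(down).
    """
    vals = _member_values(expr, panel)
    evaluable = ~vals.isna().any(axis=0)
    skipped = list(vals.columns[~evaluable])
    if skipped:
        logger.info("udr_scores: skipped %d samples with missing members", len(skipped))
    vals = vals.loc[:, evaluable]
    up = vals.loc[sorted(panel.up)]
    down = vals.loc[sorted(panel.down)]
    if log_scale:
        scores = np.log2(up).mean(axis=0) - np.log2(down).mean(axis=0)
    else:
        scores = up.mean(axis=0) / down.mean(axis=0)
    scores.name = "udr"
    return scores, skipped


def udr_score(expr: ExpressionMatrix, panel: PanelAssignment, sample_id: str) -> float:
    """UDR of one sample; raises if any panel member is missing for it."""
    vals = _member_values(expr, panel)
    if sample_id not in vals.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    col = vals[sample_id]
    if col.isna().any():
        absent = list(col.index[col.isna()])
        raise ValueError(f"sample {sample_id!r} missing panel members {absent}")
    return float(col[sorted(panel.up)].mean() / col[sorted(panel.down)].mean())


def assign_directions(
    validation_results: pd.DataFrame | Iterable[DifferentialResult],
) -> tuple[set[str], set[str]]:
    """Fixed up/down membership from a differential table.

    Accepts the validation result table (``feature_id``/``direction``
    columns) or an iterable of :class:`DifferentialResult`.  Any flat
    feature is an error, as is an empty up or down set (the UDR needs at
    least one member on each side).
    """
    if isinstance(validation_results, pd.DataFrame):
        pairs = list(zip(validation_results["feature_id"], validation_results["direction"]))
    else:
        pairs = [(r.feature_id, r.direction) for r in validation_results]
    up = {f for f, d in pairs if d == "up"}
    down = {f for f, d in pairs if d == "down"}
    flat = [f for f, d in pairs if d not in ("up", "down")]
    if flat:
        raise ValueError(f"flat features cannot be assigned a direction: {sorted(flat)}")
    if not up or not down:
        raise ValueError(
            f"UDR requires both directions represented (up={len(up)}, down={len(down)})"
        )
    return up, down


def enumerate_panels(up: Iterable[str], down: Iterable[str]) -> list[PanelAssignment]:
    """All (2^N - 1)(2^M - 1) panels from non-empty subsets of up x down."""
    up, down = sorted(set(up)), sorted(set(down))
    if not up or not down:
        raise ValueError("both direction sets must be non-empty")
    panels = []
    for i in range(1, len(up) + 1):
        for usub in itertools.combinations(up, i):
            for j in range(1, len(down) + 1):
                for dsub in itertools.combinations(down, j):
                    panels.append(PanelAssignment(usub, dsub))
    return panels


def evaluate_panel(
    expr: ExpressionMatrix,
    meta: Cohort,
    panel: PanelAssignment,
    contrast: Sequence[str] = ("I", "II"),
    *,
    cohort_tag: str = "",
    log_scale: bool = False,
    n_boot: int = 0,
    seed: int = 0,
) -> PanelEvaluation:
    """UDR scores and ROC for one panel, case = NSCLC stages in ``contrast``
    vs benign.  Requires >= 2 evaluable samples in each group."""
    scores, skipped = udr_scores(expr, panel, log_scale=log_scale)
    benign, cases = split_groups(meta, contrast)
    b_ids = [r.sample_id for r in benign if r.sample_id in scores.index]
    c_ids = [r.sample_id for r in cases if r.sample_id in scores.index]
    if len(b_ids) < 2 or len(c_ids) < 2:
        raise ValueError(
            f"panel {panel.label()}: fewer than 2 evaluable samples in a group "
            f"(benign={len(b_ids)}, case={len(c_ids)})"
        )
    s = np.concatenate([scores[c_ids].to_numpy(), scores[b_ids].to_numpy()])
    labels = np.concatenate([np.ones(len(c_ids), bool), np.zeros(len(b_ids), bool)])
    roc = roc_auc(s, labels, n_boot=n_boot, seed=seed)
    return PanelEvaluation(
        panel=panel,
        udr_scores=scores[c_ids + b_ids],
        roc=roc,
        cohort_tag=cohort_tag,
        skipped_samples=skipped,
    )


def exhaustive_search(
    expr: ExpressionMatrix,
    meta: Cohort,
    up: Iterable[str],
    down: Iterable[str],
    contrast: Sequence[str] = ("I", "II"),
    **eval_kwargs,
) -> list[PanelEvaluation]:
    """Evaluate every panel in the up x down subset space."""
    return [
        evaluate_panel(expr, meta, panel, contrast, **eval_kwargs)
        for panel in enumerate_panels(up, down)
    ]


def backward_search(
    expr: ExpressionMatrix,
    meta: Cohort,
    full_up: Iterable[str],
    full_down: Iterable[str],
    contrast: Sequence[str] = ("I", "II"),
    **eval_kwargs,
) -> list[PanelEvaluation]:
    """Sequential backward elimination from the full panel.

    At each step the single member (keeping both sides non-empty) whose
    removal yields the largest AUC is dropped; the search stops when no
    removal strictly increases the AUC or no removal is legal.  AUC ties
    between removals are broken by removing the lexicographically smallest
    feature ID, making the path deterministic.  Returns the evaluation
    path starting with the full panel.
    """
    current = PanelAssignment(full_up, full_down)
    path = [evaluate_panel(expr, meta, current, contrast, **eval_kwargs)]
    while True:
        candidates: list[tuple[str, PanelAssignment]] = []
        if len(current.up) > 1:
            candidates += [
                (m, PanelAssignment(current.up - {m}, current.down))
                for m in sorted(current.up)
            ]
        if len(current.down) > 1:
            candidates += [
                (m, PanelAssignment(current.up, current.down - {m}))
                for m in sorted(current.down)
            ]
        if not candidates:
            break
        evals = [
            (member, evaluate_panel(expr, meta, panel, contrast, **eval_kwargs))
            for member, panel in sorted(candidates, key=lambda t: t[0])
        ]
        best_member, best_eval = max(evals, key=lambda t: t[1].auc)
        # max() keeps the first (lexicographically smallest) on exact ties
        if best_eval.auc <= path[-1].auc:
            break
        logger.info(
            "backward_search: removed %s (AUC %.4f -> %.4f)",
            best_member, path[-1].auc, best_eval.auc,
        )
        current = best_eval.panel
        path.append(best_eval)
    return path


def select_optimal(
    evaluations: Sequence[PanelEvaluation],
    parsimony_epsilon: float = 0.02,
) -> list[PanelEvaluation]:
    """Rank panels preferring small size at near-best AUC.

    Keeps panels with AUC >= (best AUC - epsilon), sorted by panel size
    ascending, then AUC descending, then members lexicographically.
    """
    if not evaluations:
        raise ValueError("no panel evaluations to select from")
    best = max(e.auc for e in evaluations)
    kept = [e for e in evaluations if e.auc >= best - parsimony_epsilon]
    return sorted(kept, key=lambda e: (e.panel.size, -e.auc, e.panel.members))
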