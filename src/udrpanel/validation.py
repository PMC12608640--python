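"""Validation stage: spike-in dCt normalization, per-marker differential
filter, and per-marker ROC.

qPCR Ct values are normalized against a constant-copy-number exogenous
spike-in: ``dCt = Ct(spike) - Ct(miRNA)``, so higher dCt means higher
abundance and one dCt unit is one doubling (log2 scale).  A candidate
validates when its rank-sum p is below ``val_p_max`` and its linear fold
change magnitude is at least ``val_fc_min``.  The fold-change gate is
inclusive: published candidate lists retain markers whose rounded fold
change sits exactly at the cutoff, implying the comparison is made on the
unrounded value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .discovery import CandidateSet
from .matrix import ExpressionMatrix
from .samples import Cohort, split_groups
from .stats import RocResult, mann_whitney, qpcr_fold_change, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeInError",
    "MarkerRoc",
    "normalize_delta_ct",
    "validate_candidates",
    "per_marker_roc",
]

#: a candidate whose missing-measurement rate exceeds this in either group
#: is reported as undetermined and kept out of the validated subset
UNDETERMINED_MISSING_RATE = 0.5


class SpikeInError(ValueError):
    """Spike-in row missing or unusable."""


@dataclass(frozen=True)
class MarkerRoc:
    """Per-marker ROC with orientation bookkeeping.

    ``roc`` is computed on the oriented score (sign flipped if needed so
    the case group's mean is the higher one), hence ``roc.auc >= 0.5``
    unless the scores are degenerate; ``raw_auc`` is the AUC of the
    unoriented dCt score.
    """

    feature_id: str
    roc: RocResult
    orientation: str  # "case_high" or "case_low"
    raw_auc: float


def normalize_delta_ct(ct_matrix: ExpressionMatrix, spike_in_id: str) -> ExpressionMatrix:
    """Spike-in normalization: ``dCt(f, s) = Ct(spike, s) - Ct(f, s)``.

    The spike-in row must be present with no missing values; it is removed
    from the output.  Adding any per-sample constant to all Ct values
    (spike included) leaves the result unchanged.
    """
    if ct_matrix.scale != "ct":
        raise ValueError(f"normalize_delta_ct requires scale='ct', got {ct_matrix.scale!r}")
    if spike_in_id not in ct_matrix.data.index:
        raise SpikeInError(f"spike-in row {spike_in_id!r} absent from Ct matrix")
    spike = ct_matrix.data.loc[spike_in_id]
    if spike.isna().any():
        bad = list(spike.index[spike.isna()])
        raise SpikeInError(f"spike-in {spike_in_id!r} has missing Ct in samples {bad}")
    delta = spike - ct_matrix.data.drop(index=spike_in_id)
    return ExpressionMatrix(delta, "delta_ct")


def _group_values(
    delta_ct: ExpressionMatrix, meta: Cohort, contrast: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    benign, cases = split_groups(meta, contrast)
    if not benign or not cases:
        raise ValueError("contrast requires non-empty benign and case groups")
    b_ids = [r.sample_id for r in benign]
    c_ids = [r.sample_id for r in cases]
    return delta_ct.data[b_ids], delta_ct.data[c_ids]


def validate_candidates(
    delta_ct: ExpressionMatrix,
    meta: Cohort,
    candidates: CandidateSet | Sequence[str],
    contrast: Sequence[str] = ("I", "II"),
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Differential filter over the candidate markers on dCt data.

    Per candidate: fold change from group dCt means, rank-sum p, and the
    oriented per-marker ROC.  Status is ``validated`` (p < val_p_max and
    linear FC >= val_fc_min), ``rejected``, or ``undetermined`` (missing
    rate above 50% in either group, or marker absent from the matrix).
    Returns the result table and the validated member list; both are
    invariant to sample and feature ordering (the table is sorted by
    ascending p with undetermined markers last).
    """
    config = config or RunConfig()
    members = list(candidates.members) if isinstance(candidates, CandidateSet) else list(candidates)
    if not members:
        raise ValueError("no candidates to validate")
    bvals, cvals = _group_values(delta_ct, meta, contrast)

    rows = []
    for fid in sorted(members):
        if fid not in delta_ct.data.index:
            rows.append(_undetermined_row(fid, "absent from expression matrix"))
            continue
        b = bvals.loc[fid].to_numpy(dtype=float)
        c = cvals.loc[fid].to_numpy(dtype=float)
        miss_b = float(np.isnan(b).mean())
        miss_c = float(np.isnan(c).mean())
        if miss_b > UNDETERMINED_MISSING_RATE or miss_c > UNDETERMINED_MISSING_RATE:
            rows.append(
                _undetermined_row(fid, f"missing rate benign={miss_b:.2f}, case={miss_c:.2f}")
            )
            continue
        fc = qpcr_fold_change(c, b, feature_id=fid)
        _, p = mann_whitney(c, b)
        mroc = per_marker_roc(
            delta_ct, meta, [fid], contrast, n_boot=config.n_boot, seed=config.seed
        )[fid]
        status = (
            "validated"
            if (p < config.val_p_max and fc.fc_linear >= config.val_fc_min)
            else "rejected"
        )
        rows.append(
            {
                "feature_id": fid,
                "log2_fc": fc.log2_fc,
                "fc_linear": fc.fc_linear,
                "direction": fc.direction,
                "p_value": p,
                "auc": mroc.roc.auc,
                "ci_low": mroc.roc.ci_low,
                "ci_high": mroc.roc.ci_high,
                "orientation": mroc.orientation,
                "status": status,
                "note": "",
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["p_value", "feature_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    validated = sorted(table.loc[table["status"] == "validated", "feature_id"])
    logger.info(
        "validation: %d candidates -> %d validated, %d undetermined",
        len(members), len(validated), int((table["status"] == "undetermined").sum()),
    )
    return table, validated


def _undetermined_row(fid: str, note: str) -> dict:
    return {
        "feature_id": fid,
        "log2_fc": np.nan,
        "fc_linear": np.nan,
        "direction": "",
        "p_value": np.nan,
        "auc": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "orientation": "",
        "status": "undetermined",
        "note": note,
    }


def per_marker_roc(
    delta_ct: ExpressionMatrix,
    meta: Cohort,
    features: Sequence[str],
    contrast: Sequence[str] = ("I", "II"),
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> Mapping[str, MarkerRoc]:
    """Oriented single-marker ROC for each requested feature.

    The dCt score is oriented so the case group's mean is the higher one
    (recorded as ``case_high``/``case_low``); the oriented AUC is therefore
    never below 0.5 except for degenerate (constant) scores, which report
    AUC 0.5 with the degenerate flag set.
    """
    bvals, cvals = _group_values(delta_ct, meta, contrast)
    out: dict[str, MarkerRoc] = {}
    for fid in features:
        b = bvals.loc[fid].to_numpy(dtype=float)
        c = cvals.loc[fid].to_numpy(dtype=float)
        scores = np.concatenate([c, b])
        labels = np.concatenate([np.ones(c.size, bool), np.zeros(b.size, bool)])
        raw = roc_auc(scores, labels, n_boot=0)
        case_high = np.nanmean(c) >= np.nanmean(b)
        oriented = roc_auc(scores if case_high else -scores, labels, n_boot=n_boot, seed=seed)
        out[fid] = MarkerRoc(
            feature_id=fid,
            roc=oriented,
            orientation="case_high" if case_high else "case_low",
            raw_auc=raw.auc,
        )
    return out
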