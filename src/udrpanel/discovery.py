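"""Discovery stage: from a raw NGS count matrix to a candidate marker set.

The cascade mirrors the published protocol:

1. prevalence filter at zero-fraction > 0.50, then a stricter pass at
   > 0.45 (run as two stages for audit parity; mathematically the second
   subsumes the first),
2. CPM normalization,
3. two differential tests run in parallel on early-stage NSCLC vs benign:
   an exact conditional negative-binomial test on counts and a
   Mann-Whitney rank-sum test on log-CPM,
4. intersection of the two hit lists (|log2 FC| > 2, p < 0.05 for both),
5. exclusion of intersection members that are not also significant when
   all NSCLC stages are pooled against benign (stage-consistency rule),
6. injection of literature-reported markers.

Every filter logs its before/after feature counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .matrix import ExpressionMatrix
from .samples import Cohort, split_groups
from .stats import estimate_dispersion, exact_nb_test, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "prevalence_filter",
    "cpm_normalize",
    "discovery_de",
    "stagewise_pvalues",
    "hit_sets",
    "select_candidates",
]


@dataclass
class CandidateSet:
    """Outcome of candidate selection.

    ``members`` is ordered (dual-test hits first, then literature
    injections, each alphabetically); ``provenance`` maps each member to
    ``'dual_test'`` or ``'literature'``; ``excluded`` maps removed features
    to the reason; ``warnings`` lists literature members absent from the
    expression universe (included, but flagged).
    """

    members: list[str]
    provenance: dict[str, str]
    excluded: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.members) & set(self.excluded)
        if overlap:
            raise ValueError(f"members and excluded overlap: {sorted(overlap)}")
        missing = [m for m in self.members if m not in self.provenance]
        if missing:
            raise ValueError(f"members without provenance: {missing}")


def prevalence_filter(matrix: ExpressionMatrix, max_zero_frac: float) -> ExpressionMatrix:
    """Drop features whose zero-count fraction is strictly above the cap.

    Strict inequality: a feature at exactly the threshold is retained.
    Samples are untouched.  Idempotent.
    """
    if matrix.scale != "counts":
        raise ValueError(f"prevalence_filter requires counts, got scale={matrix.scale!r}")
    zero_frac = (matrix.data == 0).sum(axis=1) / matrix.n_samples
    keep = zero_frac <= max_zero_frac
    out = ExpressionMatrix(matrix.data.loc[keep].copy(), "counts")
    logger.info(
        "prevalence_filter(>%s): %d -> %d features (%d removed)",
        max_zero_frac, matrix.n_features, out.n_features, int((~keep).sum()),
    )
    return out


def cpm_normalize(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    libsizes: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Counts-per-million with a pseudocount, on the linear scale.

    ``value = count / library_size * 1e6 + pseudocount``; library sizes
    default to the column sums.  A sample with zero total is an error.
    """
    if matrix.scale != "counts":
        raise ValueError(f"cpm_normalize requires counts, got scale={matrix.scale!r}")
    if libsizes is None:
        libsizes = matrix.data.sum(axis=0).to_numpy()
    libsizes = np.asarray(libsizes, dtype=float)
    if np.any(libsizes <= 0):
        bad = [s for s, l in zip(matrix.sample_ids, libsizes) if l <= 0]
        raise ValueError(f"samples with zero library size: {bad}")
    cpm = matrix.data / libsizes * 1e6 + pseudocount
    return ExpressionMatrix(cpm, "linear")


def _contrast_samples(meta: Cohort, stages: Sequence[str]):
    benign, cases = split_groups(meta, stages)
    return [r.sample_id for r in benign], [r.sample_id for r in cases]


def discovery_de(
    matrix: ExpressionMatrix,
    meta: Cohort,
    contrast: Sequence[str],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dual differential tables for case stages ``contrast`` vs benign.

    Returns ``(exact_nb_table, mann_whitney_table)``; both cover exactly
    the features of ``matrix`` and share the CPM-based log2 fold change.
    The exact test uses a pooled common dispersion estimated within each
    group (method of moments, df-weighted).  The rank-sum test runs on
    log2-CPM (rank-equivalent to CPM itself).
    """
    config = config or RunConfig()
    benign_ids, case_ids = _contrast_samples(meta, contrast)
    if len(benign_ids) < 2 or len(case_ids) < 2:
        raise ValueError(
            f"contrast requires >= 2 samples per group "
            f"(benign={len(benign_ids)}, case={len(case_ids)})"
        )
    counts_b = matrix.data[benign_ids].to_numpy()
    counts_c = matrix.data[case_ids].to_numpy()
    lib_b = counts_b.sum(axis=0)
    lib_c = counts_c.sum(axis=0)

    _, phi_b = estimate_dispersion(counts_b, lib_b)
    _, phi_c = estimate_dispersion(counts_c, lib_c)
    df_b, df_c = len(benign_ids) - 1, len(case_ids) - 1
    common_phi = (phi_b * df_b + phi_c * df_c) / (df_b + df_c)
    logger.info("common NB dispersion: %.4f (benign %.4f, case %.4f)", common_phi, phi_b, phi_c)

    cpm = cpm_normalize(matrix, pseudocount=config.pseudocount)
    cpm_b = cpm.data[benign_ids].to_numpy()
    cpm_c = cpm.data[case_ids].to_numpy()
    log2_fc = np.log2(cpm_c.mean(axis=1) / cpm_b.mean(axis=1))
    log_cpm = np.log2(cpm.data.to_numpy())
    col_index = {s: j for j, s in enumerate(matrix.sample_ids)}
    case_idx = [col_index[s] for s in case_ids]
    benign_idx = [col_index[s] for s in benign_ids]

    rows_nb, rows_mw = [], []
    for i, fid in enumerate(matrix.feature_ids):
        nb = exact_nb_test(counts_c[i], counts_b[i], lib_c, lib_b, dispersion=common_phi)
        rows_nb.append(
            {
                "feature_id": fid,
                "log2_fc": float(log2_fc[i]),
                "fc_linear": float(2.0 ** abs(log2_fc[i])),
                "direction": "up" if log2_fc[i] > 0 else ("down" if log2_fc[i] < 0 else "flat"),
                "p_value": nb.p_value,
                "test": "exact_nb",
                "flat": nb.flat,
            }
        )
        lc = log_cpm[i]
        xc = lc[case_idx]
        xb = lc[benign_idx]
        _, p_mw = mann_whitney(xc, xb)
        rows_mw.append(
            {
                "feature_id": fid,
                "log2_fc": float(log2_fc[i]),
                "fc_linear": float(2.0 ** abs(log2_fc[i])),
                "direction": "up" if log2_fc[i] > 0 else ("down" if log2_fc[i] < 0 else "flat"),
                "p_value": p_mw,
                "test": "mann_whitney",
            }
        )
    table_nb = pd.DataFrame(rows_nb)
    table_mw = pd.DataFrame(rows_mw)
    if config.bh_correction:
        for table in (table_nb, table_mw):
            table["p_adjusted"] = _benjamini_hochberg(table["p_value"].to_numpy())
    return table_nb, table_mw


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def stagewise_pvalues(
    matrix: ExpressionMatrix,
    meta: Cohort,
    config: RunConfig | None = None,
) -> Mapping[str, float]:
    """Per-feature p for the stage-consistency rule.

    ``stage_rule='pooled'``: rank-sum on log-CPM, all NSCLC stages pooled
    against benign (one p per feature).  ``'per_stage'``: the worst (max)
    p across the four single-stage contrasts, so requiring p < 0.05 means
    every stage must pass.
    """
    config = config or RunConfig()
    cpm = cpm_normalize(matrix, pseudocount=config.pseudocount)
    log_cpm = np.log2(cpm.data)

    def contrast_p(stages: Sequence[str]) -> pd.Series:
        benign_ids, case_ids = _contrast_samples(meta, stages)
        if not benign_ids or not case_ids:
            return pd.Series(np.nan, index=cpm.data.index)
        return pd.Series(
            [
                mann_whitney(log_cpm.loc[f, case_ids], log_cpm.loc[f, benign_ids])[1]
                for f in cpm.feature_ids
            ],
            index=cpm.data.index,
        )

    if config.stage_rule == "pooled":
        pvals = contrast_p(list(config.stage_grouping["all"]))
    else:
        per_stage = [contrast_p([st]) for st in config.stage_grouping["all"]]
        pvals = pd.concat(per_stage, axis=1).max(axis=1)
    return pvals.to_dict()


def hit_sets(
    table_nb: pd.DataFrame,
    table_mw: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[set[str], set[str]]:
    """Hit sets from the dual tables: exact-test hits require p < edge_p_max
    AND |log2 FC| > edge_fc_min (strict, on unrounded values); rank-sum
    hits require p < mw_p_max."""
    config = config or RunConfig()
    p_col = "p_adjusted" if config.bh_correction and "p_adjusted" in table_nb else "p_value"
    nb_hits = set(
        table_nb.loc[
            (table_nb[p_col] < config.edge_p_max)
            & (table_nb["log2_fc"].abs() > config.edge_fc_min),
            "feature_id",
        ]
    )
    mw_hits = set(table_mw.loc[table_mw[p_col] < config.mw_p_max, "feature_id"])
    logger.info("hit sets: exact_nb %d, mann_whitney %d", len(nb_hits), len(mw_hits))
    return nb_hits, mw_hits


def select_candidates(
    edge_hits: set[str],
    mw_hits: set[str],
    stagewise_p: Mapping[str, float],
    literature: Sequence[str],
    config: RunConfig | None = None,
    universe: Sequence[str] | None = None,
) -> CandidateSet:
    """Intersect the dual hit lists, apply the stage-consistency exclusion,
    and inject literature markers.

    ``members = (edge_hits & mw_hits) - {f : stagewise_p[f] >= 0.05}
    + literature`` (deduplicated).  A literature marker absent from the
    expression universe is included with a warning, not an error.  The
    result is independent of input ordering.
    """
    config = config or RunConfig()
    common = set(edge_hits) & set(mw_hits)
    excluded = {
        f: f"stage-consistency p={stagewise_p[f]:.4g} >= {config.mw_p_max}"
        for f in common
        if f in stagewise_p and not (stagewise_p[f] < config.mw_p_max)
    }
    dual = sorted(common - set(excluded))
    provenance = {f: "dual_test" for f in dual}
    warnings = []
    members = list(dual)
    for f in sorted(set(literature)):
        if f in provenance:
            continue
        provenance[f] = "literature"
        members.append(f)
        if universe is not None and f not in set(universe):
            warnings.append(f"literature marker {f!r} absent from expression data")
            logger.warning("literature marker %r absent from expression data", f)
    logger.info(
        "candidate selection: %d common, %d stage-excluded, %d literature -> %d members",
        len(common), len(excluded), len(members) - len(dual), len(members),
    )
    return CandidateSet(members=members, provenance=provenance,
                        excluded=excluded, warnings=warnings)
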