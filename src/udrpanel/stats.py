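"""Statistical primitives shared by every pipeline stage.

Contents
--------
* :func:`mann_whitney` -- two-sided rank-sum test (exact for small untied
  samples, normal approximation with tie and continuity corrections
  otherwise).
* :func:`exact_nb_test` -- exact conditional negative-binomial test for
  two-group count data.  This is the differential-count test used by the
  discovery stage: the group-1 sum is compared against its conditional
  distribution given the overall sum, under equal expression proportions.
  With dispersion 0 it reduces to a conditional binomial (Poisson limit).
* :func:`estimate_dispersion` -- method-of-moments negative-binomial
  dispersion on library-size-scaled counts.
* :func:`roc_auc` -- ROC curve, tie-adjusted AUC, and stratified bootstrap
  percentile confidence interval.
* :func:`qpcr_fold_change` -- fold change from spike-in-normalized dCt
  values (dCt is a log2-scale abundance: one PCR cycle = one doubling).
* :func:`cohort_summary` -- demographic/clinical summary table with
  between-group tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from sklearn.metrics import roc_curve as _sk_roc_curve

from .samples import Cohort, metadata_frame

__all__ = [
    "DifferentialResult",
    "RocResult",
    "ExactNbResult",
    "mann_whitney",
    "exact_nb_test",
    "estimate_dispersion",
    "roc_auc",
    "qpcr_fold_change",
    "cohort_summary",
]

#: largest n1+n2 for which the rank-sum test enumerates exactly (no ties)
EXACT_RANKSUM_MAX_N = 12

#: largest overall total for which the conditional count test enumerates the
#: full conditional pmf; beyond this a normal approximation with continuity
#: correction is used (the conditional law is essentially Gaussian there)
EXACT_NB_MAX_TOTAL = 200_000


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature effect estimate and test result (case vs control).

    ``log2_fc`` is signed (positive = up in cases); ``fc_linear`` is the
    linear-scale magnitude ``2**abs(log2_fc) >= 1``.
    """

    feature_id: str
    log2_fc: float
    p_value: float | None
    test: str

    @property
    def fc_linear(self) -> float:
        return float(2.0 ** abs(self.log2_fc))

    @property
    def direction(self) -> str:
        if self.log2_fc > 0:
            return "up"
        if self.log2_fc < 0:
            return "down"
        return "flat"


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC and a 95% bootstrap confidence interval.

    ``points`` is an (k, 2) array of (false-positive rate, true-positive
    rate) pairs running from (0, 0) to (1, 1).  ``ci_low``/``ci_high`` are
    NaN when the bootstrap was skipped (``n_boot=0``).
    """

    points: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int
    degenerate: bool = False


class ExactNbResult(NamedTuple):
    p_value: float
    flat: bool  # True when both groups have zero total counts


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where ``U`` counts pairs ``(x_i, y_j)`` with
    ``x_i > y_j`` plus half of the tied pairs.  The p-value is computed by
    exact enumeration when ``len(x) + len(y) <= 12`` and there are no ties,
    and by the normal approximation with tie and continuity corrections
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty groups after dropping NaN")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# exact conditional negative-binomial test
# ---------------------------------------------------------------------------

def exact_nb_test(
    counts1,
    counts2,
    libsizes1,
    libsizes2,
    dispersion: float = 0.0,
) -> ExactNbResult:
    """Exact conditional test of equal expression proportions in two groups.

    The group-1 total is compared with its conditional distribution given
    the overall total.  With ``dispersion == 0`` the counts are Poisson and
    the conditional law is Binomial(total, L1/(L1+L2)) with ``L`` the summed
    library sizes.  With ``dispersion > 0`` each sample count is negative
    binomial with common dispersion; counts are first scaled to a common
    library size, and the group sums are then negative binomial with sizes
    ``n_g / dispersion``, giving the conditional law by convolution.
    Two-sided p-value: twice the smaller tail (observed point included),
    capped at 1.

    Returns :class:`ExactNbResult`; ``flat=True`` (with p = 1) flags a
    feature with zero counts in every sample, which is not an error.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    l1 = np.asarray(libsizes1, dtype=float)
    l2 = np.asarray(libsizes2, dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("counts must be non-negative")
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("library sizes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    n1, n2 = c1.size, c2.size

    if c1.sum() + c2.sum() == 0:
        return ExactNbResult(1.0, True)

    if dispersion == 0.0:
        s1 = int(round(c1.sum()))
        s = s1 + int(round(c2.sum()))
        pi = l1.sum() / (l1.sum() + l2.sum())
        if s > EXACT_NB_MAX_TOTAL:
            return _normal_tail_p(s1, s * pi, s * pi * (1 - pi))
        k = np.arange(s + 1)
        logpmf = sps.binom.logpmf(k, s, pi)
    else:
        # equalize library sizes (geometric-mean reference), then convolve
        ref = math.exp(np.mean(np.log(np.concatenate([l1, l2]))))
        s1 = int(round(float((c1 * ref / l1).sum())))
        s2 = int(round(float((c2 * ref / l2).sum())))
        s = s1 + s2
        if s == 0:
            return ExactNbResult(1.0, True)
        mu = s / (n1 + n2)  # common per-sample mean under the null
        r1, r2 = n1 / dispersion, n2 / dispersion
        if s > EXACT_NB_MAX_TOTAL:
            v1 = n1 * mu * (1 + dispersion * mu)
            v2 = n2 * mu * (1 + dispersion * mu)
            return _normal_tail_p(s1, s * n1 / (n1 + n2), v1 * v2 / (v1 + v2))
        k = np.arange(s + 1)
        logpmf = sps.nbinom.logpmf(k, r1, r1 / (r1 + n1 * mu)) + sps.nbinom.logpmf(
            s - k, r2, r2 / (r2 + n2 * mu)
        )
        logpmf = logpmf - logsumexp(logpmf)

    log_lower = logsumexp(logpmf[: s1 + 1])
    log_upper = logsumexp(logpmf[s1:])
    p = 2.0 * math.exp(min(log_lower, log_upper))
    return ExactNbResult(min(1.0, p), False)


def _normal_tail_p(s1: int, mean: float, var: float) -> ExactNbResult:
    """Doubled-tail p from a normal approximation with continuity correction."""
    sd = math.sqrt(max(var, 1e-300))
    lower = sps.norm.cdf((s1 + 0.5 - mean) / sd)
    upper = sps.norm.sf((s1 - 0.5 - mean) / sd)
    return ExactNbResult(min(1.0, 2.0 * min(lower, upper)), False)


def estimate_dispersion(counts, libsizes) -> tuple[np.ndarray, float]:
    """Method-of-moments NB dispersion on library-size-scaled counts.

    For each feature, counts are rescaled to the mean library size and the
    dispersion is estimated as ``max(0, (s2 - m) / m**2)`` with ``m`` and
    ``s2`` the per-feature mean and variance.  Returns the per-feature
    vector and the pooled common dispersion (median over features with
    positive mean).  Requires at least two samples.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    libsizes = np.asarray(libsizes, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation requires at least 2 samples")
    if np.any(libsizes <= 0):
        raise ValueError("library sizes must be positive")
    scaled = counts / libsizes * libsizes.mean()
    m = scaled.mean(axis=1)
    s2 = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, (s2 - m) / np.square(m), 0.0)
    phi = np.maximum(phi, 0.0)
    informative = phi[m > 0]
    common = float(np.median(informative)) if informative.size else 0.0
    return phi, common


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _rank_auc(case: np.ndarray, control: np.ndarray) -> float:
    """Tie-adjusted AUC: (concordant + 0.5 * tied) / (n_case * n_control)."""
    pooled = np.concatenate([case, control])
    ranks = sps.rankdata(pooled)
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def roc_auc(
    scores,
    labels,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve and AUC, with a seeded stratified bootstrap percentile CI.

    ``labels`` is a boolean array (True = case) or an array of
    ``{'case', 'control'}`` strings.  Higher scores are taken to indicate
    the case class.  Missing scores are dropped together with their labels.
    ``n_boot=0`` skips the CI (NaN bounds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = np.asarray([str(v).lower() in ("case", "true", "1", "nsclc") for v in labels])
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    if scores.size == 0:
        raise ValueError("all scores missing")
    case = scores[labels]
    control = scores[~labels]
    if case.size == 0 or control.size == 0:
        raise ValueError("roc_auc requires both classes present")

    auc = _rank_auc(case, control)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    degenerate = np.unique(scores).size == 1

    ci_low = ci_high = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        # vectorized stratified resampling in blocks to bound memory
        block = max(1, min(n_boot, int(5e6 // max(scores.size, 1)) or 1))
        done = 0
        while done < n_boot:
            b = min(block, n_boot - done)
            cs = case[rng.integers(0, case.size, size=(b, case.size))]
            ct = control[rng.integers(0, control.size, size=(b, control.size))]
            pooled = np.concatenate([cs, ct], axis=1)
            ranks = sps.rankdata(pooled, axis=1)
            u = ranks[:, : case.size].sum(axis=1) - case.size * (case.size + 1) / 2.0
            boot[done : done + b] = u / (case.size * control.size)
            done += b
        ci_low, ci_high = (float(q) for q in np.percentile(boot, [2.5, 97.5]))
        # percentile CI of a bounded statistic; clip tiny numeric overshoot
        ci_low = min(ci_low, auc)
        ci_high = max(ci_high, auc)

    return RocResult(
        points=points,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_case=int(case.size),
        n_control=int(control.size),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# qPCR fold change
# ---------------------------------------------------------------------------

def qpcr_fold_change(delta_ct_case, delta_ct_control, feature_id: str = "") -> DifferentialResult:
    """Fold change between groups of spike-in-normalized dCt values.

    dCt is already a log2-scale abundance (one PCR cycle = one doubling),
    so ``log2_fc = mean(case) - mean(control)`` and the linear fold change
    is ``2**abs(log2_fc)`` (the 2^ddCt convention).  The returned record has
    no p-value; combine with :func:`mann_whitney` for significance.
    """
    case = np.asarray(delta_ct_case, dtype=float)
    control = np.asarray(delta_ct_control, dtype=float)
    case = case[np.isfinite(case)]
    control = control[np.isfinite(control)]
    if case.size == 0 or control.size == 0:
        raise ValueError("qpcr_fold_change requires non-empty groups")
    return DifferentialResult(
        feature_id=feature_id,
        log2_fc=float(case.mean() - control.mean()),
        p_value=None,
        test="delta_ct_means",
    )


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def _categorical_p(benign: pd.Series, nsclc: pd.Series, level: str) -> tuple[float, str]:
    """2x2 between-group test: chi-squared with continuity correction, or
    Fisher's exact test when any expected cell count is below 5."""
    table = np.array(
        [
            [(benign == level).sum(), (benign != level).sum()],
            [(nsclc == level).sum(), (nsclc != level).sum()],
        ],
        dtype=float,
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return float("nan"), "none"
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        return float(sps.fisher_exact(table)[1]), "fisher_exact"
    chi2 = sps.chi2_contingency(table, correction=True)
    return float(chi2.pvalue), "chi2_yates"


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Demographic/clinical summary with between-group p-values.

    One row per variable level with counts and percentages (one decimal)
    for the whole cohort, the benign group and the NSCLC group.  Age is
    reported as mean and SD with a two-sided rank-sum p-value; categorical
    variables get a chi-squared test with continuity correction (Fisher's
    exact test when any expected cell < 5).  Stage and histology are
    tabulated for the NSCLC group only.  For the age rows the ``*_count``
    columns carry the statistic value itself.
    """
    if len(cohort) == 0:
        raise ValueError("cohort_summary requires a non-empty cohort")
    df = metadata_frame(cohort)
    ben = df[df["group"] == "benign"]
    nsc = df[df["group"] == "nsclc"]
    n_all, n_ben, n_nsc = len(df), len(ben), len(nsc)
    both = n_ben > 0 and n_nsc > 0

    def pct(count: int, denom: int) -> float:
        return round(100.0 * count / denom, 1) if denom else float("nan")

    rows: list[dict] = []

    # age: mean and SD rows, rank-sum p on the mean row
    if both:
        _, age_p = mann_whitney(ben["age"], nsc["age"])
        age_test = "mann_whitney"
    else:
        age_p, age_test = float("nan"), "none"
    for stat, fn in (("mean", np.mean), ("sd", lambda v: np.std(v, ddof=1) if len(v) > 1 else float("nan"))):
        rows.append(
            {
                "variable": "age",
                "level": stat,
                "whole_count": round(float(fn(df["age"])), 1),
                "whole_pct": float("nan"),
                "benign_count": round(float(fn(ben["age"])), 1) if n_ben else float("nan"),
                "benign_pct": float("nan"),
                "nsclc_count": round(float(fn(nsc["age"])), 1) if n_nsc else float("nan"),
                "nsclc_pct": float("nan"),
                "p_value": age_p if stat == "mean" else float("nan"),
                "test": age_test if stat == "mean" else "",
            }
        )

    categorical = [
        ("sex", ["male", "female"]),
        ("smoking", ["no", "yes"]),
        ("comorbidity", ["no", "yes"]),
    ]
    for var, levels in categorical:
        p, test = _categorical_p(ben[var], nsc[var], levels[0]) if both else (float("nan"), "none")
        for i, level in enumerate(levels):
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "whole_count": int((df[var] == level).sum()),
                    "whole_pct": pct((df[var] == level).sum(), n_all),
                    "benign_count": int((ben[var] == level).sum()),
                    "benign_pct": pct((ben[var] == level).sum(), n_ben),
                    "nsclc_count": int((nsc[var] == level).sum()),
                    "nsclc_pct": pct((nsc[var] == level).sum(), n_nsc),
                    "p_value": p if i == 0 else float("nan"),
                    "test": test if i == 0 else "",
                }
            )

    # stage and histology: NSCLC only
    nsclc_only = [("stage", ["I", "II", "III", "IV"])]
    if (nsc["histology"] != "none").any():
        nsclc_only.append(("histology", ["adeno", "sqcc", "nsclc_nos"]))
    for var, levels in nsclc_only:
        for level in levels:
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "whole_count": float("nan"),
                    "whole_pct": float("nan"),
                    "benign_count": float("nan"),
                    "benign_pct": float("nan"),
                    "nsclc_count": int((nsc[var] == level).sum()),
                    "nsclc_pct": pct((nsc[var] == level).sum(), n_nsc),
                    "p_value": float("nan"),
                    "test": "",
                }
            )

    return pd.DataFrame(rows)
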