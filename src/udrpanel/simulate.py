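"""Synthetic serum-cohort generator.

Real serum miRNA data for this problem is not publicly deposited, so every
downstream stage is exercised on synthetic cohorts that emulate the two
measurement technologies:

* **qPCR cohorts** (:func:`gen_qpcr_cohort`): per-sample Ct values with a
  constant exogenous spike-in row.  A feature's spike-in-normalized dCt is
  Normal(baseline + planted shift, sigma); the planted shift is a log2 fold
  change because one PCR cycle is one doubling.
* **NGS cohorts** (:func:`gen_ngs_cohort`): negative-binomial read counts
  with per-sample library-size variation and per-feature structural zero
  inflation, so the prevalence filters of the discovery stage have
  something to remove.

Calibration helpers link planted shifts to the quantities the field
reports: :func:`calibrate_effect_from_auc` gives the equal-variance normal
shift whose population AUC is a target value, and
:func:`calibrate_effect_from_p` inverts the rank-sum normal approximation
to hit a target p-value at given group sizes.

Every random draw is derived from a per-feature substream seeded by
``(seed, hash(feature_id))``, so adding or removing a feature never
perturbs the values of the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .matrix import ExpressionMatrix
from .samples import SampleMeta

__all__ = [
    "FeatureSpec",
    "SyntheticDesign",
    "gen_qpcr_cohort",
    "gen_ngs_cohort",
    "calibrate_effect_from_auc",
    "calibrate_effect_from_p",
    "validation_study_design",
    "discovery_study_design",
    "QPCR_MARKER_PROFILES",
    "NGS_HIT_PROFILES",
    "LITERATURE_MARKERS",
]

_STAGE_ORDER = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class FeatureSpec:
    """Generative parameters for one miRNA feature.

    ``effect_log2fc`` is the planted case-vs-benign shift on the log2 /
    dCt scale; either a single number (applied to every NSCLC stage) or a
    mapping from stage label to shift (absent stages get 0), which lets
    early-only effects be planted.  ``sigma`` is the within-group SD on the
    dCt scale (qPCR only); ``dispersion`` and ``zero_prob`` shape the NB
    counts (NGS only); ``missing_prob`` plants undetermined qPCR reactions.
    """

    feature_id: str
    baseline: float = 0.0
    effect_log2fc: float | Mapping[str, float] = 0.0
    sigma: float = 1.0
    dispersion: float = 0.1
    zero_prob: float = 0.0
    missing_prob: float = 0.0

    def effect_for(self, stage: str) -> float:
        if isinstance(self.effect_log2fc, Mapping):
            return float(self.effect_log2fc.get(stage, 0.0))
        return float(self.effect_log2fc)


@dataclass
class SyntheticDesign:
    """A cohort blueprint: group sizes, feature specs, technology settings."""

    features: Sequence[FeatureSpec]
    n_benign: int = 35
    n_stage: Mapping[str, int] = field(
        default_factory=lambda: {"I": 10, "II": 10, "III": 10, "IV": 10}
    )
    libsize_range: tuple[int, int] = (800_000, 2_000_000)
    spike_in_ct: float = 21.0
    spike_in_id: str = "cel-miR-2-3p"
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature_ids must be unique")
        if self.n_benign < 0 or any(n < 0 for n in self.n_stage.values()):
            raise ValueError("sample counts must be >= 0")
        for f in self.features:
            if f.sigma <= 0:
                raise ValueError(f"{f.feature_id}: sigma must be > 0")
            if f.dispersion < 0:
                raise ValueError(f"{f.feature_id}: dispersion must be >= 0")
            if not (0 <= f.zero_prob < 1):
                raise ValueError(f"{f.feature_id}: zero_prob must be in [0, 1)")
            if not (0 <= f.missing_prob < 1):
                raise ValueError(f"{f.feature_id}: missing_prob must be in [0, 1)")
        if self.libsize_range[0] <= 0 or self.libsize_range[0] > self.libsize_range[1]:
            raise ValueError("libsize_range must be a positive, ordered interval")

    @property
    def n_total(self) -> int:
        return self.n_benign + sum(self.n_stage.values())


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG substream keyed by (seed, stable hash of label)."""
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _sample_frame(design: SyntheticDesign) -> list[SampleMeta]:
    """Deterministic clinical metadata for the designed cohort."""
    rng = _substream(design.seed, "__sample_metadata__")
    records: list[SampleMeta] = []

    def covariates(is_case: bool) -> dict:
        age = float(np.clip(np.round(rng.normal(73.5, 10.5), 1), 40.0, 95.0))
        sex = "male" if rng.random() < 0.68 else "female"
        smoking = "yes" if rng.random() < 0.66 else "no"
        comorbidity = "yes" if rng.random() < 0.12 else "no"
        if is_case:
            u = rng.random()
            histology = "adeno" if u < 0.50 else ("sqcc" if u < 0.97 else "nsclc_nos")
        else:
            histology = "none"
        return dict(age=age, sex=sex, smoking=smoking, comorbidity=comorbidity, histology=histology)

    for i in range(design.n_benign):
        records.append(
            SampleMeta(sample_id=f"B{i + 1:03d}", group="benign", stage="none", **covariates(False))
        )
    for stage in _STAGE_ORDER:
        for i in range(design.n_stage.get(stage, 0)):
            records.append(
                SampleMeta(
                    sample_id=f"S{stage}{i + 1:03d}", group="nsclc", stage=stage, **covariates(True)
                )
            )
    if not records:
        raise ValueError("design yields zero samples")
    return records


def _effect_vector(spec: FeatureSpec, meta: Sequence[SampleMeta]) -> np.ndarray:
    return np.array(
        [spec.effect_for(r.stage) if r.group == "nsclc" else 0.0 for r in meta]
    )


def gen_qpcr_cohort(design: SyntheticDesign) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """Simulate a qPCR Ct matrix (spike-in row included) plus metadata.

    For sample ``s`` in group ``g``:
    ``Ct(f, s) = spike_in_ct - (baseline_f + effect_f(stage) + N(0, sigma_f))``
    so that the recovered dCt = Ct(spike) - Ct(f) carries the planted
    log2-scale shift.  The spike-in row is constant.  Deterministic given
    the design seed.
    """
    meta = _sample_frame(design)
    n = len(meta)
    rows = {design.spike_in_id: np.full(n, float(design.spike_in_ct))}
    for spec in design.features:
        rng = _substream(design.seed, f"qpcr::{spec.feature_id}")
        delta_ct = spec.baseline + _effect_vector(spec, meta) + rng.normal(0.0, spec.sigma, n)
        ct = design.spike_in_ct - delta_ct
        if spec.missing_prob > 0:
            ct[rng.random(n) < spec.missing_prob] = np.nan
        rows[spec.feature_id] = ct
    data = pd.DataFrame(rows, index=[r.sample_id for r in meta]).T
    return ExpressionMatrix(data, "ct"), meta


def gen_ngs_cohort(design: SyntheticDesign) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """Simulate an NGS count matrix plus metadata.

    Per-sample library sizes are uniform over ``libsize_range``.  A
    feature's expected count is ``libsize * proportion * 2**effect`` where
    proportions derive from the feature baselines (treated as relative
    abundance weights); counts are negative binomial with the feature's
    dispersion (Poisson when 0), with structural zeros planted at
    ``zero_prob``.  Deterministic given the design seed.
    """
    if not design.features:
        raise ValueError("gen_ngs_cohort requires a non-empty feature list")
    meta = _sample_frame(design)
    n = len(meta)
    rng_lib = _substream(design.seed, "__library_sizes__")
    libsizes = rng_lib.integers(design.libsize_range[0], design.libsize_range[1] + 1, n)
    weights = np.array([max(f.baseline, 0.0) for f in design.features], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("feature baselines must include positive abundance weights")
    props = weights / weights.sum()

    rows = {}
    for spec, prop in zip(design.features, props):
        rng = _substream(design.seed, f"ngs::{spec.feature_id}")
        mu = libsizes * prop * np.exp2(_effect_vector(spec, meta))
        if spec.dispersion > 0:
            r = 1.0 / spec.dispersion
            counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
        else:
            counts = rng.poisson(mu)
        if spec.zero_prob > 0:
            counts = np.where(rng.random(n) < spec.zero_prob, 0, counts)
        rows[spec.feature_id] = counts.astype(np.int64)
    data = pd.DataFrame(rows, index=[r.sample_id for r in meta]).T
    return ExpressionMatrix(data, "counts"), meta


# ---------------------------------------------------------------------------
# calibration links
# ---------------------------------------------------------------------------

def calibrate_effect_from_auc(target_auc: float, sigma: float) -> float:
    """Normal-model shift whose population AUC equals ``target_auc``.

    For two equal-variance normal groups separated by ``beta``, the AUC is
    ``Phi(beta / (sqrt(2) * sigma))``; inverting gives
    ``beta = sqrt(2) * sigma * Phi^-1(target_auc)``.
    """
    if not (0.5 < target_auc < 1.0):
        raise ValueError("target_auc must lie in (0.5, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(math.sqrt(2.0) * sigma * ndtri(target_auc))


def calibrate_effect_from_p(target_p: float, n1: int, n2: int, sigma: float) -> float:
    """Shift for which the expected rank-sum z-score yields ``target_p``.

    Under a location shift ``beta`` between equal-variance normal groups,
    ``P(case > control) = Phi(beta / (sqrt(2) sigma))`` and the expected
    rank-sum z is ``(theta - 1/2) * n1 * n2 / sqrt(n1 n2 (n1+n2+1)/12)``.
    Setting that equal to ``Phi^-1(1 - p/2)`` and solving gives the shift.
    Raises when the target p is unattainable at the given group sizes
    (i.e. would require theta >= 1).
    """
    if not (0.0 < target_p <= 1.0):
        raise ValueError("target_p must lie in (0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if target_p == 1.0:
        return 0.0
    z = ndtri(1.0 - target_p / 2.0)
    theta = 0.5 + z * math.sqrt((n1 + n2 + 1) / (12.0 * n1 * n2))
    if theta >= 1.0:
        raise ValueError(
            f"target_p={target_p} is unattainable at group sizes {n1}/{n2}"
        )
    if theta <= 0.5:
        return 0.0
    return float(math.sqrt(2.0) * sigma * ndtri(theta))


# ---------------------------------------------------------------------------
# study-condition designs
# ---------------------------------------------------------------------------

#: Published qPCR profiles (early-stage NSCLC vs benign) of the 15 candidate
#: markers: linear fold-change magnitude, rank-sum p, direction in cases,
#: and whether the marker entered the candidate list from the literature.
#: A missing fold change marks a marker undetermined in the qPCR assay.
QPCR_MARKER_PROFILES: dict[str, dict] = {
    "hsa-miR-497-5p": {"fc": 2.5, "p": 0.00004, "direction": "down", "literature": True},
    "hsa-miR-369-3p": {"fc": 3.2, "p": 0.00266, "direction": "down", "literature": False},
    "hsa-miR-301b-3p": {"fc": 1.9, "p": 0.01149, "direction": "down", "literature": False},
    "hsa-miR-1976": {"fc": 1.5, "p": 0.02746, "direction": "down", "literature": False},
    "hsa-miR-610": {"fc": 3.4, "p": 0.03188, "direction": "down", "literature": False},
    "hsa-miR-150-5p": {"fc": 1.6, "p": 0.00027, "direction": "up", "literature": False},
    "hsa-miR-21-5p": {"fc": 1.2, "p": 0.00015, "direction": "up", "literature": True},
    "hsa-miR-190a-5p": {"fc": 1.5, "p": 0.06202, "direction": "down", "literature": False},
    "hsa-miR-769-3p": {"fc": 3.5, "p": 0.26385, "direction": "down", "literature": False},
    "hsa-miR-5585-3p": {"fc": 197.7, "p": 0.40000, "direction": "down", "literature": False},
    "hsa-miR-6873-3p": {"fc": 1.3, "p": 0.43047, "direction": "down", "literature": False},
    "hsa-miR-202-3p": {"fc": 480.1, "p": 0.70000, "direction": "down", "literature": False},
    "hsa-miR-205-5p": {"fc": 1.3, "p": 0.80148, "direction": "down", "literature": True},
    "hsa-miR-3605-3p": {"fc": 1.3, "p": 1.00000, "direction": "down", "literature": False},
    "hsa-miR-128-1-5p": {"fc": None, "p": None, "direction": "down", "literature": False},
}

#: The markers conventionally injected into the candidate list from the
#: lung-cancer literature rather than from the dual-test intersection.
LITERATURE_MARKERS = ("hsa-miR-497-5p", "hsa-miR-21-5p", "hsa-miR-205-5p")

#: Published NGS discovery hits (early-stage vs benign): |log2 fold change|
#: (the discovery threshold is |log2 FC| > 2.0, so all magnitudes are >= 2)
#: and exact-test p.  miR-150-5p is up in cases, the rest down.
NGS_HIT_PROFILES: dict[str, tuple[float, float]] = {
    "hsa-miR-128-1-5p": (3.1, 0.0198),
    "hsa-miR-150-5p": (2.0, 0.0029),
    "hsa-miR-190a-5p": (2.1, 0.0123),
    "hsa-miR-193b-3p": (2.4, 0.0398),
    "hsa-miR-1972": (2.4, 0.0085),
    "hsa-miR-1976": (3.0, 0.0004),
    "hsa-miR-202-3p": (4.3, 0.0010),
    "hsa-miR-20a-3p": (2.4, 0.0462),
    "hsa-miR-2355-5p": (2.0, 0.0214),
    "hsa-miR-301a-3p": (2.1, 0.0086),
    "hsa-miR-301b-3p": (3.9, 0.0001),
    "hsa-miR-3605-3p": (2.6, 0.0126),
    "hsa-miR-369-3p": (2.6, 0.0338),
    "hsa-miR-4444": (3.9, 0.0081),
    "hsa-miR-4732-3p": (2.0, 0.0366),
    "hsa-miR-5585-3p": (3.0, 0.0071),
    "hsa-miR-610": (2.5, 0.0234),
    "hsa-miR-6807-5p": (2.8, 0.0057),
    "hsa-miR-6873-3p": (2.1, 0.0431),
    "hsa-miR-769-3p": (2.8, 0.0098),
    "hsa-miR-874-5p": (2.0, 0.0234),
}


def _sigma_from_fc_p(fc: float, p: float, n1: int, n2: int) -> float:
    """Within-group SD that makes the expected rank-sum p of a log2(fc)
    shift equal the published p at the given group sizes."""
    delta = abs(math.log2(fc))
    if p >= 0.999 or delta == 0:
        return 1.0
    unit = calibrate_effect_from_p(p, n1, n2, 1.0)
    if unit <= 0:
        return 1.0
    return delta / unit


def validation_study_design(seed: int = 0) -> SyntheticDesign:
    """The qPCR validation cohort under published study conditions.

    35 benign nodules and 10 NSCLC samples per stage I-IV; the 15 candidate
    markers planted at their published early-stage-vs-benign fold changes,
    with the within-group SD of each marker calibrated so that the expected
    rank-sum p matches its published p-value (this also reproduces the
    published per-marker AUC range, since the rank-sum z and the AUC are
    two views of the same statistic).  Late-stage (III-IV) shifts are
    attenuated to 60% of the early-stage shift, reflecting the early-stage
    focus of the candidate filtering.  The undetermined marker is planted
    with a 70% missing-reaction probability.
    """
    n_benign, n_early = 35, 20
    features = []
    for fid, prof in QPCR_MARKER_PROFILES.items():
        if prof["fc"] is None:
            features.append(
                FeatureSpec(feature_id=fid, baseline=-2.0, effect_log2fc=0.0,
                            sigma=1.0, missing_prob=0.7)
            )
            continue
        delta = math.log2(prof["fc"])
        if prof["direction"] == "down":
            delta = -delta
        sigma = _sigma_from_fc_p(prof["fc"], prof["p"], n_early, n_benign)
        effect = {"I": delta, "II": delta, "III": 0.6 * delta, "IV": 0.6 * delta}
        features.append(
            FeatureSpec(feature_id=fid, baseline=-3.0, effect_log2fc=effect, sigma=sigma)
        )
    return SyntheticDesign(
        features=features,
        n_benign=n_benign,
        n_stage={"I": 10, "II": 10, "III": 10, "IV": 10},
        seed=seed,
    )


def discovery_study_design(seed: int = 0, n_features: int = 2656) -> SyntheticDesign:
    """The NGS discovery cohort under published study conditions.

    16 benign and 60 NSCLC samples (19/8/12/21 across stages I-IV); the 21
    published discovery hits planted at their fold changes with moderate NB
    dispersion, embedded in a long-tailed background whose structural-zero
    probabilities are tiered so the two prevalence filters (50% then 45%)
    have realistic work to do (roughly three quarters of features mostly
    absent, a thin near-threshold band, and a well-detected remainder).
    Two of the planted hits carry stage-I-only shifts so the stage
    consistency exclusion rule has candidates to remove.
    """
    if n_features < len(NGS_HIT_PROFILES):
        raise ValueError("n_features smaller than the planted hit list")
    rng = _substream(seed, "__discovery_background__")
    features: list[FeatureSpec] = []
    early_only = {"hsa-miR-6807-5p", "hsa-miR-874-5p"}
    for fid, (log2fc, _p) in NGS_HIT_PROFILES.items():
        delta = log2fc if fid == "hsa-miR-150-5p" else -log2fc
        if fid in early_only:
            effect: float | dict = {"I": delta}
        else:
            effect = {"I": delta, "II": delta, "III": 0.6 * delta, "IV": 0.6 * delta}
        features.append(
            FeatureSpec(
                feature_id=fid,
                baseline=float(rng.lognormal(mean=4.0, sigma=1.0)),
                effect_log2fc=effect,
                dispersion=0.2,
                zero_prob=float(rng.uniform(0.0, 0.2)),
            )
        )
    # literature markers are present but unremarkable in the NGS data
    # (that is why they enter the candidate list from the literature)
    for fid in LITERATURE_MARKERS:
        features.append(
            FeatureSpec(
                feature_id=fid,
                baseline=float(rng.lognormal(mean=4.0, sigma=1.0)),
                effect_log2fc=0.0,
                dispersion=0.2,
                zero_prob=float(rng.uniform(0.0, 0.2)),
            )
        )
    n_bg = n_features - len(features)
    # tiered zero inflation: ~75% mostly-absent, a thin near-threshold band,
    # and a detected remainder, mirroring realistic serum smRNA-seq sparsity
    n_high = int(round(n_bg * 0.755))
    n_mid = int(round(n_bg * 0.027))
    tiers = (
        [("absent", (0.55, 0.97))] * n_high
        + [("borderline", (0.44, 0.55))] * n_mid
        + [("detected", (0.0, 0.40))] * (n_bg - n_high - n_mid)
    )
    for i, (_tier, (lo, hi)) in enumerate(tiers):
        features.append(
            FeatureSpec(
                feature_id=f"hsa-miR-bg-{i + 1:04d}",
                baseline=float(rng.lognormal(mean=2.5, sigma=1.5)),
                effect_log2fc=0.0,
                dispersion=float(rng.uniform(0.05, 0.5)),
                zero_prob=float(rng.uniform(lo, hi)),
            )
        )
    return SyntheticDesign(
        features=features,
        n_benign=16,
        n_stage={"I": 19, "II": 8, "III": 12, "IV": 21},
        libsize_range=(800_000, 2_000_000),
        seed=seed,
    )
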