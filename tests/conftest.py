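import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from udrpanel import ExpressionMatrix, SampleMeta

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _assign(n: int, n_yes: int, yes: str, no: str) -> list[str]:
    return [yes] * n_yes + [no] * (n - n_yes)


def build_demographics(
    *,
    prefix: str,
    n_benign: int,
    benign_male: int,
    benign_smoker: int,
    benign_comorbid: int,
    stage_counts: dict[str, int],
    nsclc_male: int,
    nsclc_smoker: int,
    nsclc_comorbid: int,
    histology_counts: dict[str, int],
) -> list[SampleMeta]:
    """Cohort with exactly the given marginal counts per group.

    Covariates are assigned independently (the published summary only
    reports marginals), ages deterministically around the group means.
    """
    n_nsclc = sum(stage_counts.values())
    records = []
    sexes = _assign(n_benign, benign_male, "male", "female")
    smoke = _assign(n_benign, benign_smoker, "yes", "no")
    com = _assign(n_benign, benign_comorbid, "yes", "no")
    for i in range(n_benign):
        records.append(
            SampleMeta(
                sample_id=f"{prefix}B{i:03d}", group="benign", stage="none",
                age=70.0 + (i % 9), sex=sexes[i], smoking=smoke[i], comorbidity=com[i],
            )
        )
    stages = [s for s, k in stage_counts.items() for _ in range(k)]
    hist = [h for h, k in histology_counts.items() for _ in range(k)]
    hist += ["none"] * (n_nsclc - len(hist))
    sexes = _assign(n_nsclc, nsclc_male, "male", "female")
    smoke = _assign(n_nsclc, nsclc_smoker, "yes", "no")
    com = _assign(n_nsclc, nsclc_comorbid, "yes", "no")
    for i in range(n_nsclc):
        records.append(
            SampleMeta(
                sample_id=f"{prefix}T{i:03d}", group="nsclc", stage=stages[i],
                age=71.0 + (i % 10), sex=sexes[i], smoking=smoke[i],
                comorbidity=com[i], histology=hist[i],
            )
        )
    return records


@pytest.fixture(scope="session")
def discovery_demographics() -> list[SampleMeta]:
    """The published discovery cohort margins: 76 samples, 16 benign."""
    return build_demographics(
        prefix="D",
        n_benign=16, benign_male=10, benign_smoker=8, benign_comorbid=3,
        stage_counts={"I": 19, "II": 8, "III": 12, "IV": 21},
        nsclc_male=42, nsclc_smoker=42, nsclc_comorbid=6,
        histology_counts={"adeno": 28, "sqcc": 31, "nsclc_nos": 1},
    )


@pytest.fixture(scope="session")
def validation_demographics() -> list[SampleMeta]:
    """The published validation cohort margins: 75 samples, 35 benign."""
    return build_demographics(
        prefix="V",
        n_benign=35, benign_male=23, benign_smoker=22, benign_comorbid=4,
        stage_counts={"I": 10, "II": 10, "III": 10, "IV": 10},
        nsclc_male=29, nsclc_smoker=29, nsclc_comorbid=4,
        histology_counts={"adeno": 22, "sqcc": 18},
    )


def toy_matrix(values: dict[str, list[float]], sample_ids: list[str], scale: str) -> ExpressionMatrix:
    """Small literal expression matrix; keys = feature IDs, rows = values."""
    return ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids).T.astype(float), scale
    )


def toy_cohort(n_benign: int, n_case: int, stage: str = "I", prefix: str = "") -> list[SampleMeta]:
    """Minimal benign/case cohort with boilerplate covariates."""
    recs = [
        SampleMeta(f"{prefix}B{i}", "benign", "none", 70.0, "male", "no")
        for i in range(n_benign)
    ]
    recs += [
        SampleMeta(f"{prefix}T{i}", "nsclc", stage, 72.0, "male", "yes")
        for i in range(n_case)
    ]
    return recs
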