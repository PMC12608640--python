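"""Per-sample clinical metadata.

A cohort is a list of :class:`SampleMeta` records: diagnostic group
(``benign`` lung nodule vs ``nsclc``), tumor stage for the cancer group,
and the demographic covariates summarized in cohort reports (age, sex,
smoking history, pulmonary comorbidity, histology).

The on-disk format is a plain CSV with columns
``sample_id,group,stage,age,sex,smoking,comorbidity[,histology]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

GROUPS = ("benign", "nsclc")
STAGES = ("I", "II", "III", "IV", "none")
HISTOLOGIES = ("adeno", "sqcc", "nsclc_nos", "none")


class MetadataError(ValueError):
    """Inconsistent or malformed sample metadata."""


@dataclass(frozen=True)
class SampleMeta:
    """One sample's clinical record.

    Invariants: a benign sample has ``stage='none'``; an NSCLC sample has a
    stage in I-IV.  ``histology`` is optional clinical detail ('none' for
    benign samples or when unknown).
    """

    sample_id: str
    group: str
    stage: str
    age: float
    sex: str
    smoking: str
    comorbidity: str = "no"
    histology: str = "none"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MetadataError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.stage not in STAGES:
            raise MetadataError(f"{self.sample_id}: unknown stage {self.stage!r}")
        if self.group == "benign" and self.stage != "none":
            raise MetadataError(
                f"{self.sample_id}: benign sample must not carry a stage "
                f"(got {self.stage!r})"
            )
        if self.group == "nsclc" and self.stage == "none":
            raise MetadataError(f"{self.sample_id}: NSCLC sample requires a stage I-IV")
        if self.sex not in ("male", "female"):
            raise MetadataError(f"{self.sample_id}: unknown sex {self.sex!r}")
        for attr in ("smoking", "comorbidity"):
            if getattr(self, attr) not in ("yes", "no"):
                raise MetadataError(
                    f"{self.sample_id}: {attr} must be yes/no, got {getattr(self, attr)!r}"
                )
        if self.histology not in HISTOLOGIES:
            raise MetadataError(
                f"{self.sample_id}: unknown histology {self.histology!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.group == "nsclc"


Cohort = Sequence[SampleMeta]


def _check_unique(cohort: Iterable[SampleMeta]) -> None:
    seen = set()
    for rec in cohort:
        if rec.sample_id in seen:
            raise MetadataError(f"duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)


def metadata_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame indexed by sample_id (column order fixed)."""
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "stage": r.stage,
                "age": r.age,
                "sex": r.sex,
                "smoking": r.smoking,
                "comorbidity": r.comorbidity,
                "histology": r.histology,
            }
            for r in cohort
        ]
    )
    return df.set_index("sample_id")


def read_metadata(path) -> list[SampleMeta]:
    """Read a cohort CSV; enforces group/stage consistency and unique IDs."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["sample_id", "group", "stage", "age", "sex", "smoking", "comorbidity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata file {path} lacks columns {missing}")
    records = []
    for _, row in df.iterrows():
        stage = row["stage"].strip() or "none"
        try:
            age = float(row["age"])
        except ValueError as exc:
            raise MetadataError(
                f"{row['sample_id']}: non-numeric age {row['age']!r}"
            ) from exc
        records.append(
            SampleMeta(
                sample_id=row["sample_id"].strip(),
                group=row["group"].strip().lower(),
                stage=stage,
                age=age,
                sex=row["sex"].strip().lower(),
                smoking=row["smoking"].strip().lower(),
                comorbidity=row["comorbidity"].strip().lower(),
                histology=(row.get("histology", "none") or "none").strip().lower(),
            )
        )
    _check_unique(records)
    return records


def write_metadata(cohort: Cohort, path) -> None:
    _check_unique(cohort)
    df = metadata_frame(cohort).reset_index()
    df["stage"] = df["stage"].replace("none", "")
    df.to_csv(path, index=False)


def split_groups(cohort: Cohort, stages: Sequence[str] | None = None):
    """(benign records, case records), cases restricted to ``stages`` if given."""
    benign = [r for r in cohort if r.group == "benign"]
    cases = [
        r
        for r in cohort
        if r.group == "nsclc" and (stages is None or r.stage in stages)
    ]
    return benign, cases
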