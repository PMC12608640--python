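"""Run configuration: thresholds and switches for every pipeline stage.

Defaults encode the published study protocol: two prevalence filters at
zero-fractions 0.50 and 0.45, discovery significance at |log2 FC| > 2.0
and p < 0.05 for both the exact count test and the rank-sum test, and
validation significance at linear FC >= 1.5 with p < 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from .simulate import LITERATURE_MARKERS


@dataclass
class RunConfig:
    # discovery-stage prevalence filters (max allowed zero-count fraction)
    prevalence_stage1: float = 0.50
    prevalence_stage2: float = 0.45
    # discovery differential thresholds
    edge_fc_min: float = 2.0      # |log2 FC|, strict
    edge_p_max: float = 0.05      # exact count test, strict
    mw_p_max: float = 0.05        # rank-sum test, strict
    # validation thresholds
    val_fc_min: float = 1.5       # linear FC, inclusive
    val_p_max: float = 0.05       # strict
    # panel selection
    parsimony_epsilon: float = 0.02     # AUC slack for preferring small panels
    # normalization / assay
    spike_in_id: str = "cel-miR-2-3p"
    pseudocount: float = 1.0
    # stage grouping used for contrasts
    stage_grouping: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "early": ("I", "II"),
            "late": ("III", "IV"),
            "all": ("I", "II", "III", "IV"),
        }
    )
    # stage-consistency exclusion: "pooled" tests stages I-IV pooled against
    # benign; "per_stage" requires p < 0.05 for every stage separately
    stage_rule: str = "pooled"
    literature: Sequence[str] = field(default_factory=lambda: list(LITERATURE_MARKERS))
    # scoring / inference options
    udr_log_scale: bool = False   # log-UDR (difference of mean log2) variant
    bh_correction: bool = False   # Benjamini-Hochberg on discovery p-values
    n_boot: int = 2000            # bootstrap resamples for AUC CIs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_p_max", "mw_p_max", "val_p_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("prevalence_stage1", "prevalence_stage2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.parsimony_epsilon < 0:
            raise ValueError("parsimony_epsilon must be >= 0")
        if self.stage_rule not in ("pooled", "per_stage"):
            raise ValueError("stage_rule must be 'pooled' or 'per_stage'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_grouping"] = {k: list(v) for k, v in self.stage_grouping.items()}
        d["literature"] = list(self.literature)
        return d


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config file with flat RunConfig keys."""
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
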