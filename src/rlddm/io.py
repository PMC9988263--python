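"""Trial-table I/O, validation, and pipeline configuration.

The canonical trial CSV has one row per trial with the columns in
:data:`rlddm.tasks.COLUMNS`.  Real exports with different column names can
be adapted at load time through a ``column_map`` (``{"canonical": "theirs"}``).
Validation enforces the schema and value ranges; test trials without a
button press are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tasks import COLUMNS, GenerativeConfig, TaskConfig

__all__ = ["read_trials", "write_trials", "PipelineConfig", "load_config", "save_config"]

log = logging.getLogger("rlddm")

_CATEGORICAL = {
    "trial_type": {"test", "control", "neutral"},
    "choice": {"high", "low", "none"},
    "outcome": {"win", "lose", "neutral"},
}
# unicode minus variants occasionally found in exported tables
_MINUS_CHARS = {"−": "-", "–": "-", "—": "-"}


def read_trials(path, column_map: dict | None = None, drop_no_response: bool = True) -> pd.DataFrame:
    """Load and validate a canonical trial CSV.

    Raises ``ValueError`` listing the offending rows on any schema violation
    (unknown categories, VAS outside [0, 200], non-positive RTs on completed
    test trials).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[COLUMNS].copy()
    for col in ("rt_s", "vas_rating", "beh_delta_c"):
        if df[col].dtype == object:
            s = df[col].astype(str)
            for ch, rep in _MINUS_CHARS.items():
                s = s.str.replace(ch, rep, regex=False)
            df[col] = pd.to_numeric(s.str.strip(), errors="coerce")
    _validate(df, str(path))
    if drop_no_response:
        miss = (df["trial_type"] == "test") & (
            (df["choice"] == "none") | ~np.isfinite(df["rt_s"])
        )
        if miss.any():
            log.info("dropped %d no-response test trials from %s", miss.sum(), path)
            df = df[~miss]
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame, src: str) -> None:
    problems = []
    for col, allowed in _CATEGORICAL.items():
        bad = df.index[~df[col].isin(allowed)]
        if len(bad):
            problems.append(f"{col} outside {sorted(allowed)} at rows {bad.tolist()[:10]}")
    vas = df["vas_rating"]
    bad = df.index[np.isfinite(vas) & ((vas < 0) | (vas > 200))]
    if len(bad):
        problems.append(f"vas_rating outside [0, 200] at rows {bad.tolist()[:10]}")
    rt = df["rt_s"]
    done = (df["trial_type"] == "test") & (df["choice"] != "none")
    bad = df.index[done & np.isfinite(rt) & (rt <= 0)]
    if len(bad):
        problems.append(f"non-positive rt_s at rows {bad.tolist()[:10]}")
    if problems:
        raise ValueError(f"{src}: schema validation failed: " + "; ".join(problems))


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the canonical trial CSV (stable column order, no index)."""
    df[COLUMNS].to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """End-to-end settings; round-trips losslessly through YAML."""

    task: TaskConfig = field(default_factory=TaskConfig)
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    model_id: int = 4
    fit_profile: str = "desk"
    drug_reference: str = "placebo"
    seed: int = 0
    output_dir: str = "outputs"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task"] = asdict(self.task)
        d["generative"] = asdict(self.generative)
        d["generative"]["drugs"] = list(self.generative.drugs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        task = TaskConfig(**d.pop("task", {}))
        gen = d.pop("generative", {})
        if "drugs" in gen:
            gen["drugs"] = tuple(gen["drugs"])
        if "group_params" in gen:  # YAML has no tuples
            gen["group_params"] = {k: tuple(v) for k, v in gen["group_params"].items()}
        return cls(task=task, generative=GenerativeConfig(**gen), **d)


def load_config(path) -> PipelineConfig:
    with open(path) as f:
        return PipelineConfig.from_dict(yaml.safe_load(f) or {})


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
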