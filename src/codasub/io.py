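"""Readers, writers, derived variables and pipeline configuration.

The participant table arrives as delimited text (or a spreadsheet, for
deposited study files); column names are mapped through the config
rather than assumed, since deposited files rarely match a fixed schema.
Row-level validation problems (nonpositive durations, missing values)
are collected with row numbers and reported, not silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .composition import DEFAULT_PARTS, MINUTES_PER_DAY

__all__ = [
    "PipelineConfig",
    "ReadIssue",
    "read_records",
    "derive_whtr",
]

logger = logging.getLogger(__name__)

#: Default mapping from canonical names to input-file column names.
DEFAULT_COLUMNS: dict[str, str] = {
    "id": "id",
    "sleep": "sleep_min", "st": "st_min", "lpa": "lpa_min", "mvpa": "mvpa_min",
    "sex": "sex", "age": "age", "imd_decile": "imd_decile",
    "weight_status": "weight_status",
    "zbmi": "zbmi", "whtr_pct": "whtr_pct", "vo2peak": "vo2peak",
    "height_cm": "height_cm", "waist_cm": "waist_cm",
}


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one serialisable object."""

    input_path: str = "data.csv"
    input_format: str = "auto"          # auto | csv | xlsx
    sheet: str | int = 0                # spreadsheet sheet name/index
    columns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    parts: tuple[str, ...] = DEFAULT_PARTS
    kappa: float = MINUTES_PER_DAY
    sbp: str = "pivot"                  # pivot | pivot_reversed
    outcomes: tuple[str, ...] = ("zbmi", "whtr_pct", "vo2peak", "vo2peak_adj")
    covariates: tuple[str, ...] = ("sex", "age", "imd_decile")
    group_column: str = "weight_status"
    durations: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)
    table_minutes: float = 15.0
    output_dir: str = "codasub_output"
    seed: int = 20170510
    zero_policy: str = "error"          # error | replace
    zero_delta: float = 0.5

    def __post_init__(self) -> None:
        self.parts = tuple(self.parts)
        self.outcomes = tuple(self.outcomes)
        self.covariates = tuple(self.covariates)
        self.durations = tuple(float(t) for t in self.durations)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(t < 0 for t in self.durations):
            raise ValueError("durations must be nonnegative")
        if self.zero_policy not in ("error", "replace"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["parts"] = list(self.parts)
        d["outcomes"] = list(self.outcomes)
        d["covariates"] = list(self.covariates)
        d["durations"] = list(self.durations)
        return d


@dataclass(frozen=True)
class ReadIssue:
    """One rejected row: its position (0-based data row), column, reason."""

    row: int
    column: str
    reason: str


def read_records(path: str | Path, cfg: PipelineConfig | None = None
                 ) -> tuple[pd.DataFrame, list[ReadIssue]]:
    """Read and validate a participant table.

    Returns the validated table with canonical column names plus the
    list of row-level issues.  Rows with nonpositive durations are
    rejected (or zero-replaced under ``zero_policy="replace"``); missing
    required columns are fatal.
    """
    cfg = cfg or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = cfg.input_format
    if fmt == "auto":
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=cfg.sheet)
    else:
        df = pd.read_csv(path)

    required = ["id", *cfg.parts]
    mapping = {canon: cfg.columns.get(canon, canon) for canon in cfg.columns}
    missing = [mapping.get(c, c) for c in required
               if mapping.get(c, c) not in df.columns]
    if missing:
        raise KeyError(f"input file {path} is missing required columns: {missing}")

    rename = {src: canon for canon, src in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)

    issues: list[ReadIssue] = []
    keep = np.ones(len(df), dtype=bool)
    for part in cfg.parts:
        col = pd.to_numeric(df[part], errors="coerce")
        df[part] = col
        bad_na = col.isna()
        for i in np.nonzero(bad_na.to_numpy())[0]:
            issues.append(ReadIssue(int(i), part, "missing/non-numeric duration"))
        keep &= ~bad_na.to_numpy()
        if cfg.zero_policy == "replace":
            invalid = (col < 0).to_numpy()
            reason = "negative duration"
        else:
            invalid = (col <= 0).fillna(False).to_numpy()
            reason = "nonpositive duration"
        for i in np.nonzero(invalid)[0]:
            issues.append(ReadIssue(int(i), part, reason))
        keep &= ~invalid
    if issues:
        logger.warning("rejected %d row(s) during read: %s", int((~keep).sum()),
                       "; ".join(f"row {it.row} [{it.column}]: {it.reason}"
                                 for it in issues[:10]))
    return df.loc[keep].reset_index(drop=True), issues


def derive_whtr(waist_cm, height_cm):
    """Waist circumference as a percentage of height: 100 * waist / height.

    A simple central-adiposity index; both inputs must be positive and
    in the same length unit.
    """
    waist = np.asarray(waist_cm, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(waist <= 0) or np.any(height <= 0):
        raise ValueError("waist and height must be strictly positive")
    out = 100.0 * waist / height
    return float(out) if out.ndim == 0 else out
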