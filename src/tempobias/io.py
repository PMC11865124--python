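"""Trial-table schema, validated CSV/JSON readers and writers, provenance.

All artifacts are plain text.  CSV files may carry a leading ``# meta:``
comment line embedding the run configuration hash and seed; JSON results
carry the same information under a ``meta`` key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "TRIAL_COLUMNS",
    "RunConfig",
    "config_hash",
    "read_trials",
    "write_trials",
    "analysis_trials",
    "write_csv",
    "read_csv",
    "write_results_json",
    "read_results_json",
]

TRIAL_COLUMNS = (
    "participant_id",
    "experiment",
    "tap_instruction",
    "timbre",
    "register",
    "block",
    "trial",
    "pitch_label",
    "pitch_code",
    "f0_hz",
    "ioi_ms",
    "loudness_db",
    "rating",
    "tapped",
    "practice",
)

_ALLOWED_LOUDNESS = (-3.0, 0.0, 3.0)


@dataclass(frozen=True)
class RunConfig:
    """Serializable run parameters, hashed into every artifact."""

    ref_ioi_ms: int = 550
    alpha: float = 0.05
    omnibus_degree: int = 5
    slice_degree: int = 2
    min_truth_correlation: float = 0.5
    discrete_rule: bool = True
    correction_policy: str = "auto"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config) -> str:
    """Stable short hash of a config mapping or dataclass."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _meta_line(meta: dict | None) -> str:
    return "# meta: " + json.dumps(meta or {}, sort_keys=True, default=str) + "\n"


def write_csv(path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a DataFrame as UTF-8 CSV with a ``# meta:`` provenance line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_line(meta))
        frame.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# "n/a" is a meaningful categorical level (e.g. tap_instruction), not missing
_NA_VALUES = [""]


def write_trials(path, trials: pd.DataFrame, meta: dict | None = None) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    write_csv(path, trials[list(TRIAL_COLUMNS)], meta=meta)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV; raises with row numbers on bad data."""
    df = pd.read_csv(path, comment="#", keep_default_na=False, na_values=_NA_VALUES)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    problems = []

    def check(mask: pd.Series, message: str) -> None:
        bad = df.index[mask].tolist()
        if bad:
            problems.append(f"{message} (rows {bad[:10]})")

    rating = pd.to_numeric(df["rating"], errors="coerce")
    check(rating.isna(), "non-numeric rating")
    check((rating < 0) | (rating > 100), "rating outside [0, 100]")
    ioi = pd.to_numeric(df["ioi_ms"], errors="coerce")
    check(ioi.isna() | (ioi <= 0), "non-positive or non-numeric ioi_ms")
    loud = pd.to_numeric(df["loudness_db"], errors="coerce")
    check(~loud.isin(_ALLOWED_LOUDNESS), f"loudness_db not in {_ALLOWED_LOUDNESS}")
    check(
        ~df["tap_instruction"].isin(["tap", "no_tap", "n/a"]),
        "tap_instruction not in {tap, no_tap, n/a}",
    )
    bool_map = {"True": True, "False": False, True: True, False: False}
    practice = df["practice"].map(bool_map)
    check(practice.isna(), "practice flag not a boolean")
    tapped = df["tapped"].map({**bool_map, "n/a": "n/a"})
    check(tapped.isna(), "tapped flag not a boolean or n/a")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    df["rating"] = rating
    df["ioi_ms"] = ioi
    df["loudness_db"] = loud
    df["practice"] = practice.astype(bool)
    df["tapped"] = tapped
    return df


def analysis_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials; they never enter analysis."""
    return trials[~trials["practice"].astype(bool)].copy()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results_json(path, results: dict, meta: dict | None = None) -> None:
    payload = {"meta": meta or {}, **results}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_results_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
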