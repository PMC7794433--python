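"""CSV readers/writers with invariant validation.

All tables are plain comma-separated UTF-8 with a header row and '.'
decimals.  Readers validate the structural invariants the analysis relies
on (strictly increasing time, non-negative measurements, required
columns) and raise DomainError on violation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "read_sm_series",
    "read_dose_response",
    "read_growth_curve",
    "read_competition",
    "read_trajectory",
    "read_cell_table",
    "write_table",
]


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DomainError(f"{what} is missing column(s): {', '.join(missing)}")


def _check_increasing(values, what: str) -> None:
    v = np.asarray(values, dtype=float)
    if len(v) > 1 and np.any(np.diff(v) <= 0):
        raise DomainError(f"{what} must be strictly increasing")


def read_sm_series(path: str | Path) -> pd.DataFrame:
    """Signal time series: time_h, od650, sm_nM[, sm_se_nM, below_lod]."""
    df = pd.read_csv(path)
    _require(df, ["time_h", "od650", "sm_nM"], "SM series")
    _check_increasing(df["time_h"], "time_h")
    if (df["od650"] < 0).any():
        raise DomainError("od650 must be non-negative")
    if "below_lod" not in df.columns:
        df["below_lod"] = False
    df["below_lod"] = df["below_lod"].astype(bool)
    if (df.loc[~df["below_lod"], "sm_nM"] < 0).any():
        raise DomainError("sm_nM must be non-negative above the detection limit")
    return df


def read_dose_response(path: str | Path) -> pd.DataFrame:
    """Long-format dose-response table: sm_nM, replicate_id, response."""
    df = pd.read_csv(path)
    _require(df, ["sm_nM", "replicate_id", "response"], "dose-response table")
    if (df["sm_nM"] < 0).any():
        raise DomainError("sm_nM must be non-negative")
    return df


def read_growth_curve(path: str | Path) -> pd.DataFrame:
    """Growth curve: time_h, od650[, do_percent]."""
    df = pd.read_csv(path)
    _require(df, ["time_h", "od650"], "growth curve")
    _check_increasing(df["time_h"], "time_h")
    if (df["od650"] <= 0).any():
        raise DomainError("od650 must be positive")
    return df


def read_competition(path: str | Path) -> pd.DataFrame:
    """Competition series: transfer, cfu_a, cfu_b."""
    df = pd.read_csv(path)
    _require(df, ["transfer", "cfu_a", "cfu_b"], "competition series")
    if (df[["cfu_a", "cfu_b"]] < 0).to_numpy().any():
        raise DomainError("CFU counts must be non-negative")
    return df


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Per-cell response trajectory: time_h, od650, response_per_cell[, se]."""
    df = pd.read_csv(path)
    _require(df, ["time_h", "od650", "response_per_cell"], "response trajectory")
    _check_increasing(df["time_h"], "time_h")
    if (df["response_per_cell"] < 0).any():
        raise DomainError("response_per_cell must be non-negative")
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Per-cell intensities: cell_id, channel, intensity, timepoint, tagged."""
    df = pd.read_csv(path)
    _require(df, ["cell_id", "channel", "intensity", "timepoint", "tagged"], "cell table")
    if (df["intensity"] < 0).any():
        raise DomainError("intensities must be non-negative")
    df["tagged"] = df["tagged"].astype(bool)
    for tp, grp in df.groupby("timepoint"):
        if not (~grp["tagged"]).any():
            raise DomainError(f"timepoint {tp!r} lacks autofluorescence controls")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any package table as plain CSV (UTF-8, header, '.' decimal)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
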