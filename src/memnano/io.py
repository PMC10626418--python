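"""Localization-table and pipeline-table I/O.

The canonical localization dialect is a comma-separated file with header
``frame,x_nm,y_nm,sigma_nm,uncertainty_nm,intensity`` (frames 1-based,
continuous nm coordinates with origin at the lower-left ROI corner).  A
ThunderSTORM-style dialect (``x [nm]``, ``y [nm]``, ``sigma [nm]``,
``uncertainty_xy [nm]``) is mapped onto the same columns so that tables
exported by that spot fitter can be consumed directly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("memnano")

CANONICAL_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "uncertainty_nm", "intensity"]

_THUNDERSTORM_MAP = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "uncertainty_xy [nm]": "uncertainty_nm",
    "uncertainty [nm]": "uncertainty_nm",
    "intensity [photon]": "intensity",
    "intensity [photons]": "intensity",
}

MANDATORY = ["frame", "x_nm", "y_nm", "sigma_nm", "uncertainty_nm"]


class FormatError(ValueError):
    """Raised when a localization file does not match the expected dialect."""


def read_localizations(path, dialect: str = "canonical") -> pd.DataFrame:
    """Read a localization table; rows failing numeric parse are dropped with
    a logged count.  ``dialect`` is ``canonical`` or ``thunderstorm``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if dialect == "thunderstorm":
        df = df.rename(columns={k: v for k, v in _THUNDERSTORM_MAP.items() if k in df.columns})
    elif dialect != "canonical":
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    if "intensity" not in df.columns:
        df["intensity"] = np.nan
    df = df[CANONICAL_COLUMNS]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric[MANDATORY].isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("dropped %d malformed row(s) from %s", n_bad, path.name)
    out = numeric.loc[~bad].reset_index(drop=True)
    out["frame"] = out["frame"].astype(int)
    out.attrs["n_dropped"] = n_bad
    return out


def write_localizations(df: pd.DataFrame, path) -> None:
    """Write a canonical localization CSV (lossless round-trip)."""
    df = df[CANONICAL_COLUMNS]
    df.to_csv(path, index=False)


def filter_localizations(
    df: pd.DataFrame, max_sigma_nm: float = 320.0, max_uncertainty_nm: float = 150.0
) -> pd.DataFrame:
    """Quality-filter localizations on PSF width and positional accuracy.

    Defaults match the acquisition filters used for high-speed PALM maps:
    sigma < 320 nm and localization precision < 150 nm.  Row order preserved.
    """
    if max_sigma_nm <= 0 or max_uncertainty_nm <= 0:
        raise ValueError("thresholds must be > 0")
    keep = (df["sigma_nm"] < max_sigma_nm) & (df["uncertainty_nm"] < max_uncertainty_nm)
    return df.loc[keep].reset_index(drop=True)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ["track_id", "frame", "x_nm", "y_nm"]:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return df


def write_trajectories(df: pd.DataFrame, path) -> None:
    df[["track_id", "frame", "x_nm", "y_nm"]].to_csv(path, index=False)


def read_brightness(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "brightness" not in df.columns:
        raise FormatError("missing mandatory column 'brightness'")
    return df["brightness"].to_numpy(float)


def write_brightness(values, path) -> None:
    pd.DataFrame({"brightness": np.asarray(values, float)}).to_csv(path, index=False)


def read_calcium(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ["cell_id", "frame", "ratio"]:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return df


def write_calcium(df: pd.DataFrame, path) -> None:
    df[["cell_id", "frame", "ratio"]].to_csv(path, index=False)
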