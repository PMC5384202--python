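"""Bayesian-skyline post-processing.

Skyline exports (the tab-separated tables phylodynamics GUIs write: time,
mean, median, upper, lower) are parsed, validated, and their time axes
rescaled through the same monotone clock correction used for rho dating.
Effective population sizes are never touched by the rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time", "mean", "median", "upper", "lower")


@dataclass
class SkylineTrack:
    """N_e through time: grid in years before present plus HPD band."""

    time_grid: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    hpd_low: np.ndarray
    hpd_high: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.time_grid, self.mean, self.median, self.hpd_low, self.hpd_high]
        n = len(self.time_grid)
        if any(len(a) != n for a in arrays):
            raise ValueError("all skyline columns must have equal length")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, a in (
            ("mean", self.mean),
            ("median", self.median),
            ("hpd_low", self.hpd_low),
            ("hpd_high", self.hpd_high),
        ):
            if np.any(np.asarray(a) <= 0):
                raise ValueError(f"non-positive N_e in column {name}")
        bad = np.flatnonzero(
            (self.hpd_low > self.median) | (self.median > self.hpd_high)
        )
        if bad.size:
            raise ValueError(
                f"HPD bounds do not bracket the median at row(s) {(bad + 1).tolist()}"
            )

    def __len__(self) -> int:
        return len(self.time_grid)


def read_skyline(path) -> SkylineTrack:
    """Read a skyline export; rejects rows with non-numeric fields and
    names any missing column."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"skyline export missing column(s): {missing}")
    numeric = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    if bad_rows.any():
        lines = (numeric.index[bad_rows] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"non-numeric skyline fields at line(s) {lines}")
    return SkylineTrack(
        time_grid=numeric["time"].to_numpy(),
        mean=numeric["mean"].to_numpy(),
        median=numeric["median"].to_numpy(),
        hpd_low=numeric["lower"].to_numpy(),
        hpd_high=numeric["upper"].to_numpy(),
    )


def write_skyline(track: SkylineTrack, path) -> None:
    pd.DataFrame(
        {
            "time": track.time_grid,
            "mean": track.mean,
            "median": track.median,
            "upper": track.hpd_high,
            "lower": track.hpd_low,
        }
    ).to_csv(path, sep="\t", index=False)


def correct_timescale(
    track: SkylineTrack, correction: Callable[[float], float]
) -> SkylineTrack:
    """Map the time grid through a strictly increasing correction with
    correction(0)=0; N_e columns pass through unchanged."""
    new_grid = np.array([float(correction(t)) for t in track.time_grid])
    if np.any(np.diff(new_grid) <= 0):
        raise ValueError("correction is not strictly increasing on this grid")
    return SkylineTrack(
        time_grid=new_grid,
        mean=track.mean.copy(),
        median=track.median.copy(),
        hpd_low=track.hpd_low.copy(),
        hpd_high=track.hpd_high.copy(),
    )
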