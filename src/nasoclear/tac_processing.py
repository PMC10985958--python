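"""Time-activity-curve (TAC) processing: SUV conversion and resampling.

Raw regional TACs carry one activity concentration (Bq/cc) per acquisition
frame, anchored at the frame midpoint.  This module converts them to
standardized uptake values (SUV) — concentration normalized by injected dose
per body weight — and resamples them onto the uniform 10-s analysis grid
covering 0-3600 s (361 points) on which all clearance metrics and statistics
operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import FrameSchedule, frame_midpoints  # noqa: F401  (re-export)

__all__ = [
    "RegionTAC",
    "UniformTAC",
    "GRID_STEP_S",
    "GRID_END_S",
    "GRID_N",
    "uniform_grid",
    "frame_midpoints",
    "to_suv",
    "resample_10s",
    "read_tacs_csv",
    "write_tacs_csv",
]

#: uniform analysis grid: 0, 10, ..., 3600 s — 361 samples
GRID_STEP_S = 10.0
GRID_END_S = 3600.0
GRID_N = 361


def uniform_grid() -> np.ndarray:
    return np.arange(GRID_N) * GRID_STEP_S


@dataclass
class RegionTAC:
    """One region's activity series at frame midpoints.

    ``values`` are in Bq/cc for raw curves or dimensionless after SUV
    conversion; ``units`` records which.
    """

    region: str
    subject_id: str
    frame_mid_s: np.ndarray
    values: np.ndarray
    units: str = "Bq/cc"

    def __post_init__(self) -> None:
        self.frame_mid_s = np.asarray(self.frame_mid_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_mid_s.shape != self.values.shape:
            raise ValueError("frame_mid_s and values must have equal length")
        if self.frame_mid_s.size < 2:
            raise ValueError("a TAC needs at least two frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")


@dataclass
class UniformTAC:
    """SUV curve on the uniform 10-s grid, 0-3600 s (361 samples)."""

    region: str
    subject_id: str
    suv: np.ndarray
    times_s: np.ndarray = field(default_factory=uniform_grid)

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.shape != (GRID_N,) or self.suv.shape != (GRID_N,):
            raise ValueError(f"uniform TAC must have exactly {GRID_N} samples")
        if not np.allclose(np.diff(self.times_s), GRID_STEP_S):
            raise ValueError("uniform TAC grid must have 10-s spacing")
        if np.any(self.suv < 0):
            raise ValueError("SUV values must be nonnegative")


def to_suv(tac: RegionTAC, meta) -> RegionTAC:
    """Convert a Bq/cc TAC to dose/weight-normalized SUV.

    SUV_i = C_i / (dose / weight), with injected dose in Bq and body weight
    in grams, treating 1 cc of tissue as 1 g.  ``meta`` needs ``dose_MBq``
    and ``weight_kg`` attributes.
    """
    dose_MBq = float(meta.dose_MBq)
    weight_kg = float(meta.weight_kg)
    if dose_MBq <= 0 or weight_kg <= 0:
        raise ValueError("dose_MBq and weight_kg must be positive")
    norm = dose_MBq * 1e6 / (weight_kg * 1e3)  # Bq per gram of body mass
    return replace(tac, values=tac.values / norm, units="SUV")


def resample_10s(tac: RegionTAC) -> UniformTAC:
    """Linearly resample an SUV TAC onto the 10-s grid.

    The curve is exact at every frame midpoint and linear in between.  Before
    the first midpoint it rises linearly from (0, 0) — no tracer before the
    bolus; after the last midpoint (3450 s for the default schedule) it is
    held at the last value.
    """
    mids = tac.frame_mid_s
    if np.any(np.diff(mids) <= 0):
        raise ValueError("frame midpoints must be strictly increasing")
    if mids[0] < 0 or mids[-1] > GRID_END_S:
        raise ValueError("frame midpoints must lie within [0, 3600] s")
    x, y = mids, tac.values
    if mids[0] > 0:
        x = np.concatenate(([0.0], x))
        y = np.concatenate(([0.0], y))
    grid = uniform_grid()
    suv = np.interp(grid, x, y)  # right edge held at the last value
    return UniformTAC(region=tac.region, subject_id=tac.subject_id, suv=suv)


# -- CSV dialect ---------------------------------------------------------

_TAC_COLUMNS = [
    "region",
    "frame_start_s",
    "frame_duration_s",
    "frame_mid_s",
    "concentration_Bq_cc",
]


def write_tacs_csv(path, tacs: dict[str, RegionTAC], schedule: FrameSchedule) -> None:
    """Write one subject's regional TACs in the package CSV dialect."""
    rows = []
    for region, tac in tacs.items():
        for start, dur, mid, val in zip(
            schedule.starts_s, schedule.durations_s, tac.frame_mid_s, tac.values
        ):
            rows.append((region, start, dur, mid, val))
    pd.DataFrame(rows, columns=_TAC_COLUMNS).to_csv(path, index=False)


def read_tacs_csv(path, subject_id: str) -> dict[str, RegionTAC]:
    df = pd.read_csv(path)
    missing = set(_TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tacs CSV missing columns: {sorted(missing)}")
    out: dict[str, RegionTAC] = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("frame_mid_s")
        out[str(region)] = RegionTAC(
            region=str(region),
            subject_id=subject_id,
            frame_mid_s=grp["frame_mid_s"].to_numpy(),
            values=grp["concentration_Bq_cc"].to_numpy(),
        )
    return out
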