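"""Clearance summaries of uniform SUV TACs.

Three quantities characterize tracer passage through a region over the
0-60 min scan:

* trapezoid-rule areas under the curve (AUC), total and split into an early
  influx window and a late egress window (default split 300 s; 30 s for the
  carotid artery, whose peak falls inside the first minute);
* ``t75``, the time at which the cumulative integral of C(t) first reaches
  75% of the full 0-3600 s integral — a single clearance-time statistic;
* the egress/influx AUC ratio, a dimensionless measure of how much of the
  exposure falls after the influx window.

All operations require window endpoints on the 10-s analysis grid; nothing
is snapped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .tac_processing import GRID_END_S, GRID_STEP_S, UniformTAC

__all__ = [
    "ClearanceSummary",
    "UndefinedStatisticError",
    "DEFAULT_SPLIT_S",
    "CAROTID_SPLIT_S",
    "SENSITIVITY_SPLIT_S",
    "auc",
    "t75",
    "split_influx_egress",
    "normalized_egress",
    "summarize_region",
    "split_for_region",
    "summarize_cohort",
]

DEFAULT_SPLIT_S = 300.0  # 5-min influx/egress boundary for tissue
CAROTID_SPLIT_S = 30.0  # carotid artery boundary (peaks in under 1 min)
SENSITIVITY_SPLIT_S = 120.0  # 2-min variant for the threshold sensitivity check


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given TAC (e.g. all-zero)."""


@dataclass(frozen=True)
class ClearanceSummary:
    region: str
    subject_id: str
    split_s: float
    auc_total: float  # SUV*s over 0-3600 s
    auc_influx: float  # SUV*s over [0, split)
    auc_egress: float  # SUV*s over [split, 3600]
    t75_s: float
    egress_influx_ratio: float


def _grid_index(t_s: float) -> int:
    if not 0 <= t_s <= GRID_END_S:
        raise ValueError(f"time {t_s} s outside [0, {GRID_END_S:.0f}] s")
    idx = t_s / GRID_STEP_S
    if abs(idx - round(idx)) > 1e-9:
        raise ValueError(f"time {t_s} s is not on the 10-s analysis grid")
    return int(round(idx))


def auc(tac: UniformTAC, t_start: float = 0.0, t_end: float = GRID_END_S) -> float:
    """Composite trapezoid-rule AUC of the SUV curve over [t_start, t_end]."""
    i0, i1 = _grid_index(t_start), _grid_index(t_end)
    if i0 >= i1:
        raise ValueError("t_start must be strictly less than t_end")
    return float(np.trapezoid(tac.suv[i0:i1 + 1], tac.times_s[i0:i1 + 1]))


def t75(tac: UniformTAC, fraction: float = 0.75) -> float:
    """Time at which the cumulative integral first reaches ``fraction`` of
    the full 0-3600 s integral.

    The cumulative trapezoid integral is evaluated at grid points and the
    crossing located by linear interpolation between them, so the statistic
    is continuous in the data.  Returns seconds in (0, 3600].
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    cum = cumulative_trapezoid(tac.suv, tac.times_s, initial=0.0)
    total = cum[-1]
    if total <= 0.0:
        raise UndefinedStatisticError("t75 undefined for an all-zero TAC")
    target = fraction * total
    idx = int(np.searchsorted(cum, target, side="left"))
    idx = min(max(idx, 1), cum.size - 1)
    c0, c1 = cum[idx - 1], cum[idx]
    t0, t1 = tac.times_s[idx - 1], tac.times_s[idx]
    if c1 == c0:  # flat cumulative stretch: first time it is reached
        return float(t0)
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def split_influx_egress(tac: UniformTAC, split_s: float) -> tuple[float, float]:
    """Trapezoid AUCs of the influx [0, split] and egress [split, 3600]
    windows; the two windows share the sample at the split so they sum to
    the total AUC exactly."""
    if not 0.0 < split_s < GRID_END_S:
        raise ValueError("split_s must lie strictly inside (0, 3600) s")
    _grid_index(split_s)  # raises off-grid
    return auc(tac, 0.0, split_s), auc(tac, split_s, GRID_END_S)


def normalized_egress(summary: ClearanceSummary) -> float:
    """Egress AUC normalized by influx AUC."""
    if summary.auc_influx <= 0:
        raise UndefinedStatisticError("egress/influx ratio undefined: "
                                      "influx AUC is zero")
    return summary.auc_egress / summary.auc_influx


def split_for_region(region: str, split_s: float | None = None,
                     carotid_split_s: float = CAROTID_SPLIT_S) -> float:
    """Per-region split rule: carotid at 30 s, tissue at the given split."""
    if region == "carotid":
        return carotid_split_s
    return DEFAULT_SPLIT_S if split_s is None else split_s


def summarize_region(tac: UniformTAC, split_s: float | None = None,
                     carotid_split_s: float = CAROTID_SPLIT_S) -> ClearanceSummary:
    """Full clearance summary of one uniform TAC."""
    split = split_for_region(tac.region, split_s, carotid_split_s)
    total = auc(tac)
    if total <= 0:
        raise UndefinedStatisticError(
            f"clearance summary undefined for all-zero TAC "
            f"({tac.subject_id}/{tac.region})")
    influx, egress = split_influx_egress(tac, split)
    t75_s = t75(tac)
    summary = ClearanceSummary(region=tac.region, subject_id=tac.subject_id,
                               split_s=split, auc_total=total,
                               auc_influx=influx, auc_egress=egress,
                               t75_s=t75_s, egress_influx_ratio=np.nan)
    ratio = normalized_egress(summary)
    return ClearanceSummary(**{**summary.__dict__, "egress_influx_ratio": ratio})


def summarize_cohort(uniform_tacs, split_s: float | None = None,
                     carotid_split_s: float = CAROTID_SPLIT_S) -> pd.DataFrame:
    """Clearance table: one row per (subject, region).

    ``uniform_tacs`` is an iterable of UniformTAC.  Columns match the
    clearance CSV dialect: subject_id, region, split_s, auc_total,
    auc_influx, auc_egress, t75_s, egress_influx_ratio.
    """
    rows = []
    for tac in uniform_tacs:
        s = summarize_region(tac, split_s, carotid_split_s)
        rows.append({"subject_id": s.subject_id, "region": s.region,
                     "split_s": s.split_s, "auc_total": s.auc_total,
                     "auc_influx": s.auc_influx, "auc_egress": s.auc_egress,
                     "t75_s": s.t75_s,
                     "egress_influx_ratio": s.egress_influx_ratio})
    return pd.DataFrame(rows)
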