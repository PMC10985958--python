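"""Synthetic dynamic-PET cohorts for a brain-to-nose clearance study.

The generator emulates the statistical structure of a 60-min dynamic scan
with a freely diffusible, non-binding flow tracer delivered as an
intravenous bolus:

* an arterial input function (AIF) modeled as a gamma-variate bolus peaking
  within 30 s of arrival plus a slowly decaying recirculation plateau;
* regional tissue curves from a one-tissue compartment model
  ``C_T(t) = (1 - vb) * k1 * [u * exp(-k2 t)](t) + vb * u(t)`` where ``u``
  is the (delayed, dispersed) input feeding the region;
* nasal regions (turbinates, cribriform plate) fed by a mixture of arterial
  blood and the brain (lateral orbitofrontal, LOF) curve, so that brain and
  nose kinetics are correlated across subjects;
* an amyloid-positive (Ab+) effect expressed as multiplicative reductions of
  k1 and k2 in the LOF and nasal regions — reduced influx and slowed egress;
* frame-integrated acquisition on a 45-frame schedule with Gaussian noise
  whose standard deviation scales like ``sqrt(value / duration)``.

Cohorts default to the study composition of 24 subjects, 16 amyloid-negative
and 8 amyloid-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .schedule import FrameSchedule, default_schedule
from .tac_processing import RegionTAC

__all__ = [
    "AifParams",
    "TissueParams",
    "SubjectMeta",
    "CohortConfig",
    "REGIONS",
    "NASAL_REGIONS",
    "TURBINATE_REGIONS",
    "TURBINATE_VOLUMES_CC",
    "make_aif",
    "aif_peak_time",
    "tissue_curve",
    "frame_average",
    "add_frame_noise",
    "generate_subject",
    "generate_cohort",
    "all_turbinates_tac",
    "make_phantom",
    "make_structural_phantom",
    "default_region_params",
    "write_cohort",
    "read_cohort",
]

# Region labels.  "lof" is the lateral orbitofrontal cortex; turbinates and
# the cribriform plate form the nasal compartment; jugular vein and
# temporalis muscle are control regions.
TURBINATE_REGIONS = ("superior_turbinate", "middle_turbinate", "inferior_turbinate")
NASAL_REGIONS = TURBINATE_REGIONS + ("cribriform",)
REGIONS = ("carotid", "jugular", "lof") + NASAL_REGIONS + ("temporalis",)

#: approximate ROI volumes used to weight the combined All-turbinates curve
TURBINATE_VOLUMES_CC = {
    "superior_turbinate": 1.0,
    "middle_turbinate": 2.5,
    "inferior_turbinate": 4.0,
}

#: frame-noise variance floor (Bq/cc), so empty frames still carry noise
NOISE_FLOOR_BQ_CC = 10.0

#: AIF peak amplitude per unit dose/weight: 480 MBq into 75 kg gives a
#: ~20 kBq/cc arterial peak (SUV ~ 3.1), a realistic bolus magnitude.
AIF_AMPLITUDE_PER_MBQ_PER_KG = 3125.0


# ----------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus + recirculation arterial input function.

    The bolus term is ``amplitude * (t'/tp)^shape * exp(shape (1 - t'/tp))``
    with ``t' = t - onset_s`` and peak time ``tp = shape / rate`` after
    onset; the recirculation term rises with the bolus and decays at
    ``recirc_decay`` towards zero, with plateau ``recirc_fraction`` of the
    peak.
    """

    amplitude: float = 20000.0  # Bq/cc at the bolus peak
    onset_s: float = 10.0
    shape: float = 3.0  # dimensionless, > 0; peak at shape/rate s after onset
    rate: float = 0.2  # 1/s
    recirc_fraction: float = 0.15
    recirc_decay: float = 3.0e-4  # 1/s

    def __post_init__(self) -> None:
        vals = (self.amplitude, self.onset_s, self.shape, self.rate,
                self.recirc_fraction, self.recirc_decay)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("AIF parameters must be finite")
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("shape and rate must be positive")
        if not 0 <= self.recirc_fraction < 1:
            raise ValueError("recirc_fraction must be in [0, 1)")
        if self.amplitude < 0 or self.onset_s < 0 or self.recirc_decay < 0:
            raise ValueError("amplitude, onset_s, recirc_decay must be >= 0")


@dataclass(frozen=True)
class TissueParams:
    """One-tissue-compartment kinetics for a region.

    k1 is the influx rate (mL fluid per cc tissue per minute), k2 the egress
    rate (1/min), vb the fractional blood volume, delay_s the arrival delay
    of the input and dispersion_s the time constant of a single-exponential
    smoothing of the input.
    """

    k1: float  # mL/cc/min
    k2: float  # 1/min
    vb: float = 0.05
    delay_s: float = 0.0
    dispersion_s: float = 0.0
    brain_mix: float = 0.0  # fraction of input drawn from the brain curve

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be nonnegative")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must be in [0, 1)")
        if self.delay_s < 0 or self.dispersion_s < 0:
            raise ValueError("delay_s and dispersion_s must be nonnegative")
        if not 0 <= self.brain_mix <= 1:
            raise ValueError("brain_mix must be in [0, 1]")


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    weight_kg: float
    dose_MBq: float
    amyloid: str  # "positive" | "negative"
    apoe_e4: str  # "carrier" | "noncarrier"
    age_y: float
    sex: str  # "F" | "M"

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.dose_MBq <= 0:
            raise ValueError("weight_kg and dose_MBq must be positive")
        if self.amyloid not in ("positive", "negative"):
            raise ValueError("amyloid must be 'positive' or 'negative'")


def default_region_params() -> dict[str, TissueParams]:
    """Amyloid-negative kinetic defaults, literature-plausible flow values.

    The LOF uses gray-matter flow-tracer constants (k1 ~ 0.6 mL/cc/min,
    k2 ~ 0.7 /min); muscle is slower; turbinates and cribriform plate are
    low-perfusion, slow-draining compartments (k2 ~ 0.15 /min, e-fold
    washout ~7 min) fed by a delayed, dispersed mixture of arterial input
    and the brain curve (brain_mix), which couples nasal to brain kinetics.
    Carotid and jugular are (partial-volume scaled) blood pools.
    """
    return {
        "carotid": TissueParams(k1=0.0, k2=0.0, vb=0.85, dispersion_s=2.0),
        "jugular": TissueParams(k1=0.0, k2=0.0, vb=0.80, delay_s=10.0,
                                dispersion_s=8.0),
        "lof": TissueParams(k1=0.60, k2=0.70, vb=0.05, delay_s=2.0,
                            dispersion_s=3.0),
        "superior_turbinate": TissueParams(k1=0.08, k2=0.13, vb=0.06,
                                           delay_s=4.0, dispersion_s=6.0,
                                           brain_mix=0.4),
        "middle_turbinate": TissueParams(k1=0.10, k2=0.15, vb=0.06,
                                         delay_s=4.0, dispersion_s=6.0,
                                         brain_mix=0.4),
        "inferior_turbinate": TissueParams(k1=0.12, k2=0.17, vb=0.06,
                                           delay_s=4.0, dispersion_s=6.0,
                                           brain_mix=0.4),
        "cribriform": TissueParams(k1=0.08, k2=0.15, vb=0.05, delay_s=3.0,
                                   dispersion_s=5.0, brain_mix=0.5),
        "temporalis": TissueParams(k1=0.10, k2=0.15, vb=0.03, delay_s=3.0,
                                   dispersion_s=5.0),
    }


def _default_effect() -> dict[str, tuple[float, float]]:
    # multiplicative (k1_factor, k2_factor) applied to Ab+ subjects
    eff = {r: (0.8, 0.8) for r in ("lof",) + NASAL_REGIONS}
    return eff


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study composition: 24 elderly subjects, 16
    amyloid-negative and 8 amyloid-positive, ~480 MBq injections, and the
    group weight/age distributions of the demographics table.
    """

    n_neg: int = 16
    n_pos: int = 8
    region_params: dict[str, TissueParams] = field(default_factory=default_region_params)
    effect: dict[str, tuple[float, float]] = field(default_factory=_default_effect)
    #: Ab+ systemic effect: multiplies the AIF recirculation fraction,
    #: emulating reduced recirculating tracer (lower carotid egress with
    #: unchanged bolus influx); 1.0 disables it.
    recirc_factor_pos: float = 0.8
    noise_scale: float = 20.0
    dose_mean_MBq: float = 480.0
    dose_sd_MBq: float = 48.0
    # per-group metadata distributions (demographics table)
    weight_mean_kg: dict[str, float] = field(
        default_factory=lambda: {"negative": 76.7, "positive": 59.8})
    weight_sd_kg: dict[str, float] = field(
        default_factory=lambda: {"negative": 15.8, "positive": 8.52})
    age_mean_y: dict[str, float] = field(
        default_factory=lambda: {"negative": 76.1, "positive": 73.3})
    age_sd_y: dict[str, float] = field(
        default_factory=lambda: {"negative": 7.2, "positive": 4.3})
    female_p: dict[str, float] = field(
        default_factory=lambda: {"negative": 9 / 16, "positive": 5 / 8})
    apoe_carrier_p: dict[str, float] = field(
        default_factory=lambda: {"negative": 2 / 16, "positive": 7 / 8})
    # between-subject kinetic variability (lognormal sigmas)
    subject_cv: float = 0.12
    region_cv: float = 0.08
    amplitude_cv: float = 0.10
    onset_jitter_s: float = 2.0
    aif: AifParams = field(default_factory=AifParams)
    schedule: FrameSchedule = field(default_factory=default_schedule)
    sim_dt_s: float = 1.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_neg < 1 or self.n_pos < 1:
            raise ValueError("n_neg and n_pos must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        for k1f, k2f in self.effect.values():
            if k1f <= 0 or k2f <= 0:
                raise ValueError("effect factors must be positive")
        if self.recirc_factor_pos <= 0:
            raise ValueError("recirc_factor_pos must be positive")

    @classmethod
    def null(cls, **kwargs) -> "CohortConfig":
        """Config with all amyloid effects switched off (factors 1.0), so
        both groups draw from identical kinetic distributions."""
        effect = {r: (1.0, 1.0) for r in ("lof",) + NASAL_REGIONS}
        return cls(effect=effect, recirc_factor_pos=1.0, **kwargs)


# ----------------------------------------------------------------------
# curve generation
# ----------------------------------------------------------------------

def make_aif(params: AifParams, times) -> np.ndarray:
    """Evaluate the arterial input function at the given times (s)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or (t.size and t[0] < 0):
        raise ValueError("times must be sorted and nonnegative")
    tau = t - params.onset_s
    out = np.zeros_like(t)
    pos = tau > 0
    tp = params.shape / params.rate  # peak time after onset
    x = tau[pos] / tp
    bolus = params.amplitude * x**params.shape * np.exp(params.shape * (1.0 - x))
    recirc = (params.amplitude * params.recirc_fraction
              * (1.0 - np.exp(-tau[pos] / tp))
              * np.exp(-params.recirc_decay * tau[pos]))
    out[pos] = bolus + recirc
    return out


def aif_peak_time(params: AifParams, resolution_s: float = 0.01,
                  horizon_s: float = 300.0) -> float:
    """Time of the AIF's global maximum, located on a dense grid.

    At default parameters the peak falls within 30 s of bolus onset.
    """
    t = np.arange(0.0, horizon_s + resolution_s / 2, resolution_s)
    return float(t[np.argmax(make_aif(params, t))])


def _exp_conv(u: np.ndarray, dt: float, k1: float, k2: float) -> np.ndarray:
    """``y(t) = k1 * int_0^t u(s) exp(-k2 (t - s)) ds`` on a uniform grid.

    Exact for piecewise-linear ``u`` (exponential-integrator recursion run
    through an IIR filter), so accuracy is limited only by how well the grid
    resolves ``u``.
    """
    if k1 == 0.0:
        return np.zeros_like(u)
    if k2 == 0.0:
        c_next = c_cur = k1 * dt / 2.0
        e = 1.0
    else:
        e = math.exp(-k2 * dt)
        j0 = (1.0 - e) / k2
        j1 = 1.0 / k2 - (1.0 - e) / (k2 * k2 * dt)  # weight of u_{n+1}
        c_next = k1 * j1
        c_cur = k1 * (j0 - j1)
    b = np.array([c_next, c_cur])
    a = np.array([1.0, -e])
    zi = np.array([-c_next * u[0]])  # enforce y(0) = 0
    y, _ = lfilter(b, a, u, zi=zi)
    return y


def _disperse(u: np.ndarray, dt: float, tau_s: float) -> np.ndarray:
    """Single-exponential dispersion of an input curve (unit-gain)."""
    if tau_s <= 0:
        return u
    return _exp_conv(u, dt, 1.0 / tau_s, 1.0 / tau_s)


def _uniform_dt(times: np.ndarray) -> float:
    dt = np.diff(times)
    if dt.size == 0 or not np.allclose(dt, dt[0]):
        raise ValueError("times must form a uniform grid")
    return float(dt[0])


def tissue_curve(aif, params: TissueParams, times) -> np.ndarray:
    """One-tissue-compartment curve driven by a sampled input.

    ``C_T(t) = (1 - vb) * k1 * int u(tau) exp(-k2 (t - tau)) dtau + vb u(t)``
    where ``u`` is the input after applying the region's arrival delay and
    dispersion.  ``k1``/``k2`` are per-minute and converted internally.
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(aif, dtype=float)
    if u.shape != t.shape:
        raise ValueError("aif and times grids must match")
    dt = _uniform_dt(t)
    if params.delay_s > 0:
        u = np.interp(t - params.delay_s, t, u, left=0.0)
    u = _disperse(u, dt, params.dispersion_s)
    k1_s = params.k1 / 60.0
    k2_s = params.k2 / 60.0
    extravascular = _exp_conv(u, dt, k1_s, k2_s)
    return (1.0 - params.vb) * extravascular + params.vb * u


def frame_average(times, curve, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a finely sampled curve over each acquisition frame.

    Frame edges must coincide with grid samples (the curve is treated as
    piecewise linear; each frame value is its exact trapezoid mean).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(curve, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and curve must have equal length")
    dt = _uniform_dt(t)
    out = np.empty(schedule.n_frames)
    for i, (start, dur) in enumerate(schedule.frames):
        if start < t[0] - 1e-9 or start + dur > t[-1] + 1e-9:
            raise ValueError("frame extends beyond curve support")
        i0 = int(round((start - t[0]) / dt))
        i1 = int(round((start + dur - t[0]) / dt))
        if not (math.isclose(t[i0], start, abs_tol=1e-6)
                and math.isclose(t[i1], start + dur, abs_tol=1e-6)):
            raise ValueError("frame edges must align with the curve grid")
        out[i] = np.trapezoid(c[i0:i1 + 1], t[i0:i1 + 1]) / dur
    return out


def add_frame_noise(frame_values, schedule: FrameSchedule, noise_scale: float,
                    rng_seed) -> np.ndarray:
    """Add frame-duration-weighted Gaussian noise, clipped at zero.

    Per-frame sd is ``noise_scale * sqrt(max(value, floor) / duration)`` —
    short early frames are noisier, mimicking count statistics after decay
    correction.
    """
    v = np.asarray(frame_values, dtype=float)
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    if noise_scale == 0:
        return v.copy()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    sd = noise_scale * np.sqrt(np.maximum(v, NOISE_FLOOR_BQ_CC)
                               / schedule.durations_s)
    return np.clip(v + rng.normal(0.0, 1.0, v.shape) * sd, 0.0, None)


# ----------------------------------------------------------------------
# subjects and cohorts
# ----------------------------------------------------------------------

def _apply_effect(params: TissueParams, effect) -> TissueParams:
    if effect is None:
        return params
    k1f, k2f = effect
    return replace(params, k1=params.k1 * k1f, k2=params.k2 * k2f)


def _jitter(params: TissueParams, flow_factor: float, rng,
            region_cv: float) -> TissueParams:
    k1 = params.k1 * flow_factor * float(np.exp(rng.normal(0.0, region_cv)))
    k2 = params.k2 * float(np.exp(rng.normal(0.0, region_cv)))
    return replace(params, k1=k1, k2=k2)


def generate_subject(meta: SubjectMeta, config: CohortConfig,
                     rng_seed) -> dict[str, RegionTAC]:
    """Simulate one subject's regional frame TACs (Bq/cc).

    Returns a map region-label -> RegionTAC for all configured regions.
    Amyloid-positive subjects have the configured multiplicative k1/k2
    modifiers applied before between-subject jitter.
    """
    unknown = set(config.region_params) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    if "lof" not in config.region_params:
        raise ValueError("region_params must include 'lof'")
    rng = np.random.default_rng(rng_seed)
    sched = config.schedule
    dt = config.sim_dt_s
    t = np.arange(0.0, sched.end_s + dt / 2, dt)

    amp = (AIF_AMPLITUDE_PER_MBQ_PER_KG * meta.dose_MBq / meta.weight_kg
           * float(np.exp(rng.normal(0.0, config.amplitude_cv))))
    onset = config.aif.onset_s + float(rng.uniform(-config.onset_jitter_s,
                                                   config.onset_jitter_s))
    is_pos = meta.amyloid == "positive"
    recirc = config.aif.recirc_fraction
    if is_pos:
        recirc *= config.recirc_factor_pos
    aif = make_aif(replace(config.aif, amplitude=amp, onset_s=max(onset, 0.0),
                           recirc_fraction=recirc), t)
    flow = float(np.exp(rng.normal(0.0, config.subject_cv)))

    def region_kinetics(region: str) -> TissueParams:
        p = config.region_params[region]
        if is_pos:
            p = _apply_effect(p, config.effect.get(region))
        return _jitter(p, flow, rng, config.region_cv)

    # brain curve first: it feeds the nasal-region inputs
    curves: dict[str, np.ndarray] = {}
    lof_params = region_kinetics("lof")
    curves["lof"] = tissue_curve(aif, lof_params, t)

    for region in config.region_params:
        if region == "lof":
            continue
        p = region_kinetics(region)
        if p.brain_mix > 0:
            u = (1.0 - p.brain_mix) * aif + p.brain_mix * curves["lof"]
        else:
            u = aif
        curves[region] = tissue_curve(u, p, t)

    tacs: dict[str, RegionTAC] = {}
    for region, curve in curves.items():
        frames = frame_average(t, curve, sched)
        frames = add_frame_noise(frames, sched, config.noise_scale, rng)
        tacs[region] = RegionTAC(region=region, subject_id=meta.subject_id,
                                 frame_mid_s=sched.midpoints_s, values=frames)
    return tacs


def all_turbinates_tac(tacs: dict[str, RegionTAC],
                       volumes_cc: dict[str, float] | None = None) -> RegionTAC:
    """Volume-weighted mean of the three turbinate TACs (All-turbinates)."""
    vols = volumes_cc or TURBINATE_VOLUMES_CC
    missing = [r for r in TURBINATE_REGIONS if r not in tacs]
    if missing:
        raise ValueError(f"missing turbinate TACs: {missing}")
    total = sum(vols[r] for r in TURBINATE_REGIONS)
    values = sum(vols[r] * tacs[r].values for r in TURBINATE_REGIONS) / total
    ref = tacs[TURBINATE_REGIONS[0]]
    return RegionTAC(region="all_turbinates", subject_id=ref.subject_id,
                     frame_mid_s=ref.frame_mid_s.copy(), values=values,
                     units=ref.units)


def _truncated_normal(rng, mean, sd, lo) -> float:
    for _ in range(100):
        v = float(rng.normal(mean, sd))
        if v > lo:
            return v
    return float(lo + abs(rng.normal(0.0, sd)))


def _sample_meta(group: str, idx: int, config: CohortConfig, rng) -> SubjectMeta:
    weight = _truncated_normal(rng, config.weight_mean_kg[group],
                               config.weight_sd_kg[group], 30.0)
    dose = _truncated_normal(rng, config.dose_mean_MBq, config.dose_sd_MBq, 50.0)
    age = _truncated_normal(rng, config.age_mean_y[group],
                            config.age_sd_y[group], 40.0)
    sex = "F" if rng.random() < config.female_p[group] else "M"
    apoe = "carrier" if rng.random() < config.apoe_carrier_p[group] else "noncarrier"
    return SubjectMeta(subject_id=f"S{idx + 1:03d}", weight_kg=weight,
                       dose_MBq=dose, amyloid=group, apoe_e4=apoe,
                       age_y=age, sex=sex)


def generate_cohort(config: CohortConfig) -> list[tuple[SubjectMeta, dict[str, RegionTAC]]]:
    """Simulate a full cohort: ``n_neg`` Ab- then ``n_pos`` Ab+ subjects.

    Per-subject randomness derives from ``SeedSequence((config.seed, i))``
    so that changing the cohort size never reshuffles earlier subjects.
    """
    cohort = []
    groups = ["negative"] * config.n_neg + ["positive"] * config.n_pos
    for i, group in enumerate(groups):
        ss = np.random.SeedSequence((config.seed, i))
        rng = np.random.default_rng(ss)
        meta = _sample_meta(group, i, config, rng)
        tacs = generate_subject(meta, config, rng)
        cohort.append((meta, tacs))
    return cohort


# ----------------------------------------------------------------------
# phantoms
# ----------------------------------------------------------------------

def make_phantom(shape, regions: dict[str, np.ndarray],
                 schedule: FrameSchedule, config: CohortConfig, rng_seed,
                 meta: SubjectMeta | None = None):
    """Build a small 4D dynamic phantom plus its ground-truth label volume.

    ``regions`` maps region labels (from REGIONS) to ``(n, 3)`` arrays of
    voxel indices; voxel sets must be disjoint and inside ``shape``.  Every
    voxel of a region carries that region's frame series with independent
    per-voxel noise at ``config.noise_scale``; background is zero.

    Returns ``(pet4d, labelvol, label_map, tacs)`` where ``label_map`` maps
    region name to the integer code used in ``labelvol`` and ``tacs`` are
    the noiseless generating RegionTACs.
    """
    shape = tuple(int(s) for s in shape)
    meta = meta or SubjectMeta(subject_id="phantom", weight_kg=75.0,
                               dose_MBq=480.0, amyloid="negative",
                               apoe_e4="noncarrier", age_y=75.0, sex="F")
    rng = np.random.default_rng(rng_seed)
    noiseless = replace(config, noise_scale=0.0)
    tacs = generate_subject(meta, noiseless, rng_seed=rng)

    pet4d = np.zeros(shape + (schedule.n_frames,), dtype=float)
    labelvol = np.zeros(shape, dtype=np.int16)
    label_map: dict[str, int] = {}
    seen = np.zeros(shape, dtype=bool)
    for code, (name, vox) in enumerate(regions.items(), start=1):
        if name not in tacs:
            raise ValueError(f"unknown region label: {name}")
        vox = np.asarray(vox, dtype=int)
        if vox.ndim != 2 or vox.shape[1] != 3:
            raise ValueError("voxel sets must be (n, 3) index arrays")
        if np.any(vox < 0) or np.any(vox >= np.array(shape)):
            raise ValueError(f"region {name} has voxels outside the volume")
        idx = tuple(vox.T)
        if np.any(seen[idx]):
            raise ValueError("region voxel sets must be disjoint")
        seen[idx] = True
        labelvol[idx] = code
        label_map[name] = code
        base = tacs[name].values
        for v in vox:
            pet4d[tuple(v)] = add_frame_noise(base, schedule,
                                              config.noise_scale, rng)
    return pet4d, labelvol, label_map, {n: tacs[n] for n in regions}


def make_structural_phantom(shape, blobs, tissue_intensity: float = 100.0,
                            air_intensity: float = 10.0, noise_sd: float = 0.0,
                            rng_seed=0):
    """Synthetic T2-like structural volume with ellipsoidal tissue blobs.

    ``blobs`` is a list of ``(center_vox, semiaxes_vox)`` tuples.  Returns
    ``(volume, truth_mask)`` with tissue at ``tissue_intensity`` against an
    air-like background — a stand-in for a structural MRI used to exercise
    the segmentation pipeline.
    """
    shape = tuple(int(s) for s in shape)
    vol = np.full(shape, air_intensity, dtype=float)
    truth = np.zeros(shape, dtype=bool)
    grids = np.indices(shape).astype(float)
    for center, semi in blobs:
        d2 = sum(((grids[a] - center[a]) / semi[a]) ** 2 for a in range(3))
        truth |= d2 <= 1.0
    vol[truth] = tissue_intensity
    if noise_sd > 0:
        vol += np.random.default_rng(rng_seed).normal(0.0, noise_sd, shape)
    return vol, truth


# ----------------------------------------------------------------------
# cohort I/O
# ----------------------------------------------------------------------

_SUBJECT_COLUMNS = ["subject_id", "weight_kg", "dose_MBq", "amyloid",
                    "apoe_e4", "age_y", "sex"]


def write_cohort(cohort, config: CohortConfig, outdir) -> None:
    """Write subjects.csv, per-subject tacs CSVs and a config echo."""
    from pathlib import Path

    from .tac_processing import write_tacs_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{c: getattr(meta, c) for c in _SUBJECT_COLUMNS}
            for meta, _ in cohort]
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    for meta, tacs in cohort:
        write_tacs_csv(out / f"tacs_{meta.subject_id}.csv", tacs, config.schedule)
    echo = {
        "n_neg": config.n_neg, "n_pos": config.n_pos,
        "noise_scale": config.noise_scale, "seed": config.seed,
        "dose_mean_MBq": config.dose_mean_MBq,
        "sim_dt_s": config.sim_dt_s,
        "effect": {k: list(v) for k, v in config.effect.items()},
        "recirc_factor_pos": config.recirc_factor_pos,
        "schedule": [[s, d] for s, d in config.schedule.frames],
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh)


def read_cohort(indir) -> list[tuple[SubjectMeta, dict[str, RegionTAC]]]:
    from pathlib import Path

    from .tac_processing import read_tacs_csv

    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.csv")
    cohort = []
    for _, row in subjects.iterrows():
        meta = SubjectMeta(subject_id=str(row["subject_id"]),
                           weight_kg=float(row["weight_kg"]),
                           dose_MBq=float(row["dose_MBq"]),
                           amyloid=str(row["amyloid"]),
                           apoe_e4=str(row["apoe_e4"]),
                           age_y=float(row["age_y"]), sex=str(row["sex"]))
        tacs = read_tacs_csv(indir / f"tacs_{meta.subject_id}.csv",
                             meta.subject_id)
        cohort.append((meta, tacs))
    return cohort
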