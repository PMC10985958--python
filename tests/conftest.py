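import numpy as np
import pytest

from nasoclear.schedule import default_schedule
from nasoclear.synthetic_cohort import AifParams, CohortConfig, SubjectMeta
from nasoclear.tac_processing import GRID_N, UniformTAC, uniform_grid


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(20240402)


@pytest.fixture
def small_config():
    """Fast cohort config: 2 + 2 subjects, noiseless, deterministic kinetics."""
    return CohortConfig(n_neg=2, n_pos=2, noise_scale=0.0, seed=7)


@pytest.fixture
def meta():
    return SubjectMeta(subject_id="S001", weight_kg=75.0, dose_MBq=480.0,
                       amyloid="negative", apoe_e4="noncarrier",
                       age_y=75.0, sex="F")


def gamma_tac(rng, region="roi", subject_id="s"):
    """Random gamma-variate SUV curve on the uniform 10-s grid."""
    amp = rng.uniform(0.5, 4.0)
    shape = rng.uniform(1.5, 6.0)
    rate = rng.uniform(0.002, 0.05)
    onset = rng.uniform(0.0, 60.0)
    recirc = rng.uniform(0.0, 0.3)
    t = uniform_grid()
    suv = gamma_curve(t, amp, shape, rate, onset, recirc)
    return UniformTAC(region=region, subject_id=subject_id, suv=suv), \
        (amp, shape, rate, onset, recirc)


def gamma_curve(t, amp, shape, rate, onset, recirc=0.0):
    """Analytic gamma-variate + plateau, evaluable on any grid (oracle side)."""
    tau = np.maximum(np.asarray(t, float) - onset, 0.0)
    x = tau * rate / shape
    bolus = amp * x**shape * np.exp(shape * (1.0 - x))
    plateau = amp * recirc * (1.0 - np.exp(-x))
    return np.where(tau > 0, bolus + plateau, 0.0)


@pytest.fixture
def random_gamma_tacs(rng):
    out = []
    for _ in range(100):
        tac, params = gamma_tac(rng)
        out.append((tac, params))
    return out


def constant_tac(value=1.0):
    return UniformTAC(region="roi", subject_id="s",
                      suv=np.full(GRID_N, float(value)))
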