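import dataclasses

import numpy as np
import pytest

from nasoclear.schedule import FrameSchedule
from nasoclear.synthetic_cohort import (AifParams, CohortConfig, SubjectMeta,
                                        TissueParams, add_frame_noise,
                                        aif_peak_time, all_turbinates_tac,
                                        frame_average, generate_cohort,
                                        generate_subject, make_aif,
                                        make_phantom, tissue_curve,
                                        write_cohort)

from conftest import gamma_curve


# ----------------------------------------------------------------------
# arterial input function
# ----------------------------------------------------------------------

class TestAif:
    def test_zero_amplitude_gives_zero_curve(self):
        t = np.linspace(0, 3600, 361)
        assert np.all(make_aif(AifParams(amplitude=0.0), t) == 0.0)

    def test_zero_before_onset_and_nonnegative(self):
        p = AifParams()
        t = np.arange(0.0, 3600.0, 0.5)
        c = make_aif(p, t)
        assert np.all(c[t <= p.onset_s] == 0.0)
        assert np.all(c >= 0.0)

    def test_pure_gamma_tail_decreases_monotonically(self):
        p = AifParams(recirc_fraction=0.0)
        t = np.arange(0.0, 3600.0, 1.0)
        c = make_aif(p, t)
        peak = np.argmax(c)
        assert np.all(np.diff(c[peak:]) <= 0.0)
        assert c[-1] < 1e-6 * c[peak]

    def test_peak_matches_dense_grid_search(self):
        # independent brute-force oracle: argmax on a 0.1-s grid
        p = AifParams()
        t = np.arange(0.0, 120.0, 0.1)
        oracle = t[np.argmax(make_aif(p, t))]
        assert abs(aif_peak_time(p) - oracle) <= 0.1
        assert aif_peak_time(p) < p.onset_s + 30.0

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            AifParams(amplitude=np.nan)
        with pytest.raises(ValueError):
            AifParams(rate=np.inf)


# ----------------------------------------------------------------------
# one-tissue compartment curve
# ----------------------------------------------------------------------

class TestTissueCurve:
    def test_no_exchange_limit_returns_scaled_input(self):
        t = np.arange(0.0, 600.0, 0.5)
        aif = make_aif(AifParams(), t)
        p = TissueParams(k1=0.0, k2=0.5, vb=0.05)
        assert np.allclose(tissue_curve(aif, p, t), 0.05 * aif, atol=1e-12)

    def test_all_zero_input_gives_all_zero_output(self):
        t = np.arange(0.0, 100.0, 1.0)
        p = TissueParams(k1=0.5, k2=0.5, vb=0.1)
        assert np.all(tissue_curve(np.zeros_like(t), p, t) == 0.0)

    def test_boxcar_closed_form_washout(self):
        # extravascular response to a boxcar input has an exact closed form
        dt, T_box = 0.1, 100.0
        t = np.arange(0.0, 600.0 + dt / 2, dt)
        A = 1000.0
        aif = np.where(t <= T_box, A, 0.0)
        p = TissueParams(k1=0.3, k2=0.4, vb=0.1)
        out = tissue_curve(aif, p, t)
        k1s, k2s = p.k1 / 60.0, p.k2 / 60.0
        late = t > T_box + 5.0
        expected = ((1 - p.vb) * (k1s / k2s) * A
                    * (1 - np.exp(-k2s * T_box))
                    * np.exp(-k2s * (t[late] - T_box)))
        assert np.allclose(out[late], expected, rtol=5e-3)

    def test_zero_k2_extravascular_term_nondecreasing(self):
        t = np.arange(0.0, 1200.0, 0.5)
        aif = make_aif(AifParams(), t)
        p = TissueParams(k1=0.5, k2=0.0, vb=0.0)
        out = tissue_curve(aif, p, t)
        assert np.all(np.diff(out) >= -1e-9)

    def test_grid_mismatch_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            tissue_curve(np.zeros(50), TissueParams(k1=0.1, k2=0.1), t)


# ----------------------------------------------------------------------
# frame integration and noise
# ----------------------------------------------------------------------

class TestFrameAverage:
    def test_constant_curve(self, schedule):
        t = np.arange(0.0, 3600.5, 0.5)
        vals = frame_average(t, np.full_like(t, 3.5), schedule)
        assert np.allclose(vals, 3.5)

    def test_linear_ramp_first_frame(self, schedule):
        t = np.arange(0.0, 3600.5, 0.5)
        vals = frame_average(t, t / 3600.0, schedule)
        assert np.isclose(vals[0], 5.0 / 3600.0)  # mean of ramp on [0, 10)

    def test_gamma_curve_matches_riemann_oracle(self, schedule):
        params = (2.0, 3.0, 0.01, 20.0, 0.2)
        t = np.arange(0.0, 3600.25, 0.25)
        vals = frame_average(t, gamma_curve(t, *params), schedule)
        # independent oracle: 0.01-s midpoint Riemann average per frame
        for i, (start, dur) in enumerate(schedule.frames):
            tt = np.arange(start, start + dur, 0.01) + 0.005
            oracle = gamma_curve(tt, *params).mean()
            assert vals[i] == pytest.approx(oracle, rel=1e-3)

    def test_frame_beyond_support_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        sched = FrameSchedule(((0.0, 200.0),))
        with pytest.raises(ValueError):
            frame_average(t, np.ones_like(t), sched)


class TestFrameNoise:
    def test_zero_scale_is_identity(self, schedule):
        v = np.linspace(0, 1000, 45)
        out = add_frame_noise(v, schedule, 0.0, rng_seed=1)
        assert np.array_equal(out, v)

    def test_same_seed_reproducible(self, schedule):
        v = np.full(45, 5000.0)
        a = add_frame_noise(v, schedule, 20.0, rng_seed=42)
        b = add_frame_noise(v, schedule, 20.0, rng_seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, v)

    def test_empirical_sd_matches_model(self):
        # Monte-Carlo check of the sqrt(value/duration) scaling
        sched = FrameSchedule(tuple((i * 10.0, 10.0) for i in range(1000)))
        value, scale = 10000.0, 20.0
        v = np.full(1000, value)
        draws = np.concatenate([
            add_frame_noise(v, sched, scale, rng_seed=seed) - value
            for seed in range(10)])
        expected_sd = scale * np.sqrt(value / 10.0)
        assert draws.std() == pytest.approx(expected_sd, rel=0.05)

    def test_clipped_at_zero(self, schedule):
        v = np.zeros(45)
        out = add_frame_noise(v, schedule, 50.0, rng_seed=3)
        assert np.all(out >= 0.0)


# ----------------------------------------------------------------------
# subjects and cohorts
# ----------------------------------------------------------------------

class TestGenerateSubject:
    def test_produces_all_regions(self, meta):
        cfg = CohortConfig(noise_scale=0.0)
        tacs = generate_subject(meta, cfg, rng_seed=0)
        assert set(tacs) == {"carotid", "jugular", "lof", "temporalis",
                             "superior_turbinate", "middle_turbinate",
                             "inferior_turbinate", "cribriform"}
        for tac in tacs.values():
            assert tac.values.shape == (45,)
            assert np.all(tac.values >= 0)

    def test_unknown_region_label_rejected(self, meta):
        cfg = CohortConfig()
        cfg.region_params["not_a_region"] = TissueParams(k1=0.1, k2=0.1)
        with pytest.raises(ValueError):
            generate_subject(meta, cfg, rng_seed=0)

    def test_deterministic_given_seed(self, meta):
        cfg = CohortConfig(noise_scale=0.0)
        a = generate_subject(meta, cfg, rng_seed=11)
        b = generate_subject(meta, cfg, rng_seed=11)
        for r in a:
            assert np.array_equal(a[r].values, b[r].values)

    def test_null_effect_groups_identical(self, meta):
        # with all effect factors 1.0, amyloid status changes nothing
        cfg = CohortConfig.null(noise_scale=0.0)
        pos = dataclasses.replace(meta, amyloid="positive")
        a = generate_subject(meta, cfg, rng_seed=5)
        b = generate_subject(pos, cfg, rng_seed=5)
        for r in a:
            assert np.array_equal(a[r].values, b[r].values)

    def test_amyloid_lowers_noiseless_turbinate_auc(self, meta):
        cfg = CohortConfig(noise_scale=0.0, subject_cv=0.0, region_cv=0.0,
                           amplitude_cv=0.0, onset_jitter_s=0.0)
        pos = dataclasses.replace(meta, amyloid="positive")
        neg_tacs = generate_subject(meta, cfg, rng_seed=0)
        pos_tacs = generate_subject(pos, cfg, rng_seed=0)
        neg = all_turbinates_tac(neg_tacs)
        posc = all_turbinates_tac(pos_tacs)
        auc_neg = np.trapezoid(neg.values, neg.frame_mid_s)
        auc_pos = np.trapezoid(posc.values, posc.frame_mid_s)
        assert auc_pos < auc_neg


class TestGenerateCohort:
    def test_default_composition(self):
        cohort = generate_cohort(CohortConfig(noise_scale=0.0, sim_dt_s=2.0))
        assert len(cohort) == 24
        assert sum(m.amyloid == "positive" for m, _ in cohort) == 8

    def test_minimal_cohort(self):
        cohort = generate_cohort(CohortConfig(n_neg=1, n_pos=1,
                                              noise_scale=0.0))
        assert len(cohort) == 2
        assert {m.amyloid for m, _ in cohort} == {"negative", "positive"}

    def test_serialized_cohort_byte_identical(self, tmp_path, small_config):
        for d in ("a", "b"):
            write_cohort(generate_cohort(small_config), small_config,
                         tmp_path / d)
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name

    def test_earlier_subjects_stable_under_size_change(self, small_config):
        big = dataclasses.replace(small_config, n_neg=3)
        a = generate_cohort(small_config)
        b = generate_cohort(big)
        # first two (negative) subjects unchanged when the cohort grows
        for i in range(2):
            assert a[i][0] == b[i][0]
            for r in a[i][1]:
                assert np.array_equal(a[i][1][r].values, b[i][1][r].values)


def test_all_turbinates_is_volume_weighted_mean(meta):
    cfg = CohortConfig(noise_scale=0.0)
    tacs = generate_subject(meta, cfg, rng_seed=1)
    combined = all_turbinates_tac(tacs)
    vols = {"superior_turbinate": 1.0, "middle_turbinate": 2.5,
            "inferior_turbinate": 4.0}
    expected = sum(vols[r] * tacs[r].values for r in vols) / sum(vols.values())
    assert np.array_equal(combined.values, expected)


# ----------------------------------------------------------------------
# phantoms
# ----------------------------------------------------------------------

class TestPhantom:
    def _regions(self):
        a = np.argwhere(np.pad(np.ones((3, 3, 2), bool),
                               ((0, 5), (0, 5), (0, 2))))
        b = np.argwhere(np.pad(np.ones((2, 2, 2), bool),
                               ((5, 1), (5, 1), (1, 1))))
        return {"lof": a, "inferior_turbinate": b}

    def test_round_trip_recovers_generating_tac(self, schedule):
        cfg = CohortConfig(noise_scale=0.0)
        pet4d, labels, label_map, tacs = make_phantom(
            (8, 8, 4), self._regions(), schedule, cfg, rng_seed=0)
        for name, code in label_map.items():
            mask = labels == code
            extracted = pet4d[mask].mean(axis=0)
            assert np.allclose(extracted, tacs[name].values, atol=1e-9)

    def test_background_is_zero(self, schedule):
        cfg = CohortConfig(noise_scale=0.0)
        pet4d, labels, _, _ = make_phantom((8, 8, 4), self._regions(),
                                           schedule, cfg, rng_seed=0)
        assert np.all(pet4d[labels == 0] == 0.0)

    def test_empty_region_map_gives_background_volume(self, schedule):
        cfg = CohortConfig(noise_scale=0.0)
        pet4d, labels, label_map, _ = make_phantom((4, 4, 2), {}, schedule,
                                                   cfg, rng_seed=0)
        assert np.all(pet4d == 0.0) and np.all(labels == 0)
        assert label_map == {}

    def test_overlapping_regions_rejected(self, schedule):
        cfg = CohortConfig(noise_scale=0.0)
        vox = np.argwhere(np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            make_phantom((4, 4, 4), {"lof": vox, "cribriform": vox},
                         schedule, cfg, rng_seed=0)
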