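"""Dynamic index, initial-burst detection, and burst regressions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindlefit.exceptions import DegenerateTarget, InvalidInput
from spindlefit.metrics import (NotComputable, detect_initial_burst,
                                dynamic_index, iba_regression,
                                velocity_bin_label)
from spindlefit.signals import IFRSeries, TrialRecord, compute_ifr
from spindlefit.simulate import (GroundTruthSpindle, StretchProtocol,
                                 default_truth, make_trial)

FS = 2000.0


def _ramp_trial_with_spikes(spikes, ramp_end=1.0, hold_end=2.0, dur=3.0,
                            v=20.0):
    t = np.arange(int(dur * FS) + 1) / FS
    return TrialRecord("m1", "affM", FS, t, np.zeros_like(t),
                       np.full_like(t, 0.1), np.asarray(spikes),
                       stretch_type="ramp_hold_release",
                       peak_velocity_mm_s=v, ramp_end_time_s=ramp_end,
                       hold_end_time_s=hold_end)


def test_dynamic_index_is_peak_minus_rate_half_second_later():
    # 100 imp/s at the ramp end, 40 imp/s around +0.5 s -> DI = 60
    pre = np.arange(0.96, 1.0001, 0.01)          # 100 imp/s into ramp end
    hold = 1.0 + np.arange(0.025, 0.6, 0.025)    # 40 imp/s through the hold
    trial = _ramp_trial_with_spikes(np.concatenate([pre, hold]))
    res = dynamic_index(trial)
    assert res.peak_ifr_ramp_end == pytest.approx(100.0, rel=1e-6)
    assert res.ifr_at_hold == pytest.approx(40.0, rel=1e-6)
    assert res.di == pytest.approx(60.0, rel=1e-6)
    assert res.velocity_bin == "20-30"


def test_dynamic_index_zero_for_constant_rate_train():
    spikes = np.arange(0.5, 2.5, 0.02)  # 50 imp/s throughout
    res = dynamic_index(_ramp_trial_with_spikes(spikes))
    assert res.di == pytest.approx(0.0, abs=1e-9)


def test_dynamic_index_invariant_to_constant_rate_offset():
    spikes = np.concatenate([np.arange(0.96, 1.0001, 0.01),
                             1.0 + np.arange(0.025, 0.6, 0.025)])
    trial = _ramp_trial_with_spikes(spikes)
    ifr = compute_ifr(trial.spike_times)
    shifted = IFRSeries(times=ifr.times, rates=ifr.rates + 17.0)
    assert dynamic_index(trial, shifted).di == pytest.approx(
        dynamic_index(trial, ifr).di, abs=1e-9)


def test_dynamic_index_requires_long_enough_hold():
    trial = _ramp_trial_with_spikes(np.arange(0.5, 2.5, 0.02), hold_end=1.3)
    with pytest.raises(NotComputable):
        dynamic_index(trial)


def test_dynamic_index_needs_ramp_hold_release():
    trial = _ramp_trial_with_spikes(np.arange(0.5, 2.5, 0.02))
    trial.stretch_type = "sawtooth"
    with pytest.raises(NotComputable):
        dynamic_index(trial)


def test_velocity_bins_cover_0_to_50():
    assert velocity_bin_label(4.0) == "0-10"
    assert velocity_bin_label(20.0) == "20-30"
    assert velocity_bin_label(50.0) == "40-50"
    with pytest.raises(InvalidInput):
        velocity_bin_label(55.0)


def test_dynamic_index_increases_with_stretch_velocity(force_params):
    """The classical signature on a dynamic (dF/dt-weighted) afferent."""
    truth = default_truth("FORCE", spike_mode="isi_consistent")
    dis = []
    for v, a in [(10.0, 1400.0), (40.0, 2800.0)]:
        tr = make_trial(StretchProtocol("ramp_hold_release", 3.0, v, a),
                        truth, force_params, f"di{v}", "affD")
        dis.append(dynamic_index(tr).di)
    assert dis[0] < dis[1]


# ------------------------------------------------------------ initial burst
def test_initial_burst_scales_with_onset_acceleration(force_params):
    """On a dynamic (dF/dt-dominated) afferent, doubling the onset
    acceleration at fixed length and velocity raises the burst peak."""
    truth = GroundTruthSpindle("FORCE", k=(10.0, 2.0), b=(0.6, 0.0),
                               spike_mode="isi_consistent")
    ibas = []
    for a in (700.0, 1400.0, 2800.0):
        tr = make_trial(StretchProtocol("ramp_hold_release", 3.0, 20.0, a),
                        truth, force_params, f"ib{a}", "affB")
        res = detect_initial_burst(tr)
        assert res.has_burst_spikes
        ibas.append(res.iba)
    assert ibas[0] < ibas[1] < ibas[2]


def test_initial_burst_window_excludes_release_transient(force_params):
    truth = default_truth("FORCE", spike_mode="isi_consistent")
    tr = make_trial(StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0),
                    truth, force_params, "ibw", "affB")
    res = detect_initial_burst(tr)
    # the detection window sits at stretch onset, well before the release
    assert res.window[1] < tr.ramp_end_time_s
    assert res.window[1] - res.window[0] < 0.2


def test_initial_burst_absent_without_dfdt_pathway(force_params):
    truth = GroundTruthSpindle("FORCE", k=(30.0, 0.0), b=(0.4, 0.0),
                               spike_mode="isi_consistent")
    tr = make_trial(StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0),
                    truth, force_params, "nb", "affB")
    res = detect_initial_burst(tr)
    # without the dF/dt pathway the "burst" is just the early ramp rate
    assert res.iba < 25.0


# -------------------------------------------------------------- regression
def test_regression_hand_computed_ols():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 4.0, 7.0])
    slope, intercept, r2, p = iba_regression(y, x, min_points=3)
    assert slope == pytest.approx(2.5)
    assert intercept == pytest.approx(-2.0 / 3.0)
    assert r2 == pytest.approx(25.0 / (2.0 * 114.0 / 9.0), rel=1e-6)


def test_regression_collinear_points():
    x = np.linspace(1, 12, 12)
    slope, intercept, r2, p = iba_regression(3 * x + 1, x)
    assert slope == pytest.approx(3.0)
    assert intercept == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-12


def test_regression_shuffled_pairs_lose_association(rng):
    x = np.linspace(1, 20, 20)
    y = 3 * x + 1
    _, _, r2, _ = iba_regression(rng.permutation(y), x)
    assert r2 < 0.3


def test_regression_minimum_points_and_degenerate_predictor():
    x = np.linspace(1, 11, 11)
    with pytest.raises(InvalidInput):
        iba_regression(2 * x, x)  # 11 < 12 trials
    with pytest.raises(DegenerateTarget):
        iba_regression(np.arange(12.0), np.ones(12))


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(deadline=None, max_examples=25)
def test_regression_matches_normal_equations(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=15)
    if np.ptp(x) == 0.0:
        return
    y = rng.normal(size=15)
    slope, intercept, r2, _ = iba_regression(y, x, min_points=12)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    assert slope == pytest.approx(sxy / sxx, rel=1e-10, abs=1e-10)
    assert intercept == pytest.approx(y.mean() - slope * x.mean(),
                                      rel=1e-10, abs=1e-10)
    if syy > 0:
        assert r2 == pytest.approx(sxy ** 2 / (sxx * syy), rel=1e-8,
                                   abs=1e-10)


def test_burst_regression_prefers_dfdt_over_matched_acceleration(
        force_params):
    """With matched stretch kinematics but varying force history (the
    rested cross-bridge pool differs trial to trial), burst size tracks
    peak dF/dt, while the acceleration peak carries no information."""
    import dataclasses
    truth = default_truth("FORCE", spike_mode="isi_consistent")
    ibas, dfdts, accs = [], [], []
    for i in range(12):
        fpi = dataclasses.replace(force_params, k_rested=0.3 + 0.12 * i)
        a = 1400.0 + 25.0 * (i % 3)   # tiny jitter avoids zero variance
        tr = make_trial(StretchProtocol("ramp_hold_release", 3.0, 20.0, a),
                        truth, fpi, f"r{i}", "affR")
        res = detect_initial_burst(tr)
        ibas.append(res.iba)
        dfdts.append(res.peak_dFdt)
        accs.append(res.peak_accel)
    _, _, r2_df, _ = iba_regression(ibas, dfdts)
    _, _, r2_ac, _ = iba_regression(ibas, accs)
    assert r2_df > 0.9 > r2_ac
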