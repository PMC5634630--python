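"""Stretch protocols, history-dependent force, and spike generation."""

import dataclasses

import numpy as np
import pytest

from spindlefit.exceptions import InfeasibleProtocol, InvalidInput
from spindlefit.signals import compute_ifr, derive_channels, trial_qc
from spindlefit.simulate import (GroundTruthSpindle, MuscleForceParams,
                                 StretchProtocol, default_protocol_grid,
                                 default_truth, generate_spikes,
                                 make_dataset, make_length_profile,
                                 make_trial, simulate_force)

FS = 2000.0


# --------------------------------------------------------------- protocols
def test_profile_achieves_specified_peaks():
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    prof = make_length_profile(proto)
    v = np.gradient(prof.length) * FS
    a = np.gradient(v) * FS
    assert abs(v.max() - 20.0) < 0.1
    assert abs(a.max() - 1400.0) / 1400.0 < 0.01
    assert prof.length.max() == pytest.approx(3.0, abs=1e-9)


def test_profile_hold_phase_is_isometric():
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    prof = make_length_profile(proto)
    hold = ((prof.t > prof.ramp_end_time_s + 1e-6)
            & (prof.t < prof.hold_end_time_s - 1e-6))
    assert np.ptp(prof.length[hold]) < 1e-9


def test_profile_acceleration_dissociated_from_velocity():
    slow = make_length_profile(
        StretchProtocol("ramp_hold_release", 3.0, 20.0, 700.0))
    fast = make_length_profile(
        StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0))
    for prof, accel in ((slow, 700.0), (fast, 1400.0)):
        v = np.gradient(prof.length) * FS
        a = np.gradient(v) * FS
        assert abs(v.max() - 20.0) < 0.1
        assert abs(a.max() - accel) / accel < 0.01


def test_sawtooth_repeats_without_holds():
    proto = StretchProtocol("sawtooth", 2.0, 20.0, 1400.0, n_repeats=5)
    prof = make_length_profile(proto)
    # five distinct stretch peaks: five upward half-amplitude crossings
    high = prof.length > proto.peak_length_mm / 2
    assert (np.diff(high.astype(int)) == 1).sum() == 5


def test_infeasible_protocol_rejected():
    with pytest.raises(InfeasibleProtocol):
        StretchProtocol("ramp_hold_release", 1.0, 50.0, 700.0)


def test_rest_period_floor_enforced():
    with pytest.raises(InvalidInput):
        StretchProtocol("ramp_hold_release", 2.0, 20.0, 1400.0, rest_s=2.0)


# ------------------------------------------------------------------- force
def test_isometric_force_settles_to_elastic_value():
    params = MuscleForceParams()
    L = np.zeros(int(6 * FS))
    F = simulate_force(L, params, FS)
    np.testing.assert_allclose(F, params.f_rest, rtol=1e-9)


def test_force_short_range_stiffness_transient(force_params):
    """dF/dt peaks within 50 ms of stretch onset after rest, exceeding the
    mid-ramp dF/dt by well over 1.5x."""
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    prof = make_length_profile(proto)
    F = simulate_force(prof.length, force_params, FS)
    dfdt = np.gradient(F) * FS
    t = prof.t
    onset = prof.onset_time_s
    mid = onset + (prof.ramp_end_time_s - onset) / 2
    peak_onset = dfdt[(t >= onset) & (t <= onset + 0.05)].max()
    mid_val = dfdt[(t >= mid - 0.01) & (t <= mid + 0.01)].max()
    assert peak_onset > 1.5 * mid_val


def test_force_relaxes_monotonically_during_hold(force_params):
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    prof = make_length_profile(proto)
    F = simulate_force(prof.length, force_params, FS)
    hold = ((prof.t >= prof.ramp_end_time_s + 0.02)
            & (prof.t <= prof.hold_end_time_s - 0.005))
    assert np.all(np.diff(F[hold]) <= 1e-10)
    # decays toward the elastic asymptote, never below it
    asymptote = force_params.f_rest + force_params.k_passive * 3.0
    assert F[hold][-1] >= asymptote - 1e-9


def test_first_sawtooth_stretch_carries_greatest_force(force_params):
    proto = StretchProtocol("sawtooth", 2.0, 20.0, 1400.0, n_repeats=5)
    prof = make_length_profile(proto)
    F = simulate_force(prof.length, force_params, FS)
    T = proto.ramp_duration_s
    peaks = []
    for r in range(proto.n_repeats):
        end = proto.rest_s + (2 * r + 1) * T
        w = (prof.t >= end - 0.02) & (prof.t <= end + 0.02)
        peaks.append(F[w].max())
    assert peaks[0] > max(peaks[1:])


def test_higher_onset_acceleration_raises_onset_dfdt(force_params):
    peaks = []
    for a in (700.0, 1400.0):
        prof = make_length_profile(
            StretchProtocol("ramp_hold_release", 3.0, 20.0, a))
        F = simulate_force(prof.length, force_params, FS)
        dfdt = np.gradient(F) * FS
        w = (prof.t >= prof.onset_time_s) & (prof.t <= prof.onset_time_s + 0.06)
        peaks.append(dfdt[w].max())
    assert peaks[0] < peaks[1]


def test_history_free_variant_is_purely_elastic(force_params):
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    prof = make_length_profile(proto)
    F = simulate_force(prof.length, force_params.without_history(), FS)
    expected = force_params.f_rest + force_params.k_passive * prof.length
    np.testing.assert_allclose(F, expected, rtol=1e-9)


# ------------------------------------------------------------------ spikes
def test_integrator_constant_rate_counts_and_isi():
    t = np.arange(int(FS) + 1) / FS
    spikes = generate_spikes(t, np.full(t.size, 10.0),
                             "deterministic_integrator")
    assert spikes.size == 10
    np.testing.assert_allclose(np.diff(spikes), 0.1, rtol=1e-9)


def test_integrator_doubling_rate_halves_isi():
    t = np.arange(int(2 * FS)) / FS
    s1 = generate_spikes(t, np.full(t.size, 8.0), "deterministic_integrator")
    s2 = generate_spikes(t, np.full(t.size, 16.0), "deterministic_integrator")
    assert np.mean(np.diff(s2)) == pytest.approx(np.mean(np.diff(s1)) / 2,
                                                 rel=1e-9)


def test_isi_consistent_reciprocal_isi_equals_rate():
    """The defining property: 1/ISI equals the generating rate at the
    later spike, even for a strongly time-varying rate."""
    t = np.arange(int(4 * FS)) / FS
    rate = 20.0 + 15.0 * np.sin(2 * np.pi * 0.7 * t)
    spikes = generate_spikes(t, rate, "isi_consistent")
    ifr = compute_ifr(spikes)
    np.testing.assert_allclose(ifr.rates, np.interp(ifr.times, t, rate),
                               rtol=1e-6)


def test_poisson_count_within_three_sigma():
    t = np.arange(int(100 * FS)) / FS
    spikes = generate_spikes(t, np.full(t.size, 10.0), "poisson", seed=12345)
    assert abs(spikes.size - 1000) < 3 * np.sqrt(1000)


def test_zero_rate_produces_no_spikes():
    t = np.arange(100) / FS
    assert generate_spikes(t, np.zeros(100), "poisson", seed=1).size == 0
    with pytest.raises(InvalidInput):
        generate_spikes(t, -np.ones(100), "poisson", seed=1)


# ----------------------------------------------------------------- dataset
def test_dataset_trials_pass_qc_and_are_reproducible():
    truth = default_truth("FORCE")
    ds1 = make_dataset(1, 13, [truth], seed=5)
    ds2 = make_dataset(1, 13, [truth], seed=5)
    trials = ds1.afferents["syn01"]
    assert len(trials) == 13
    for tr in trials:
        assert trial_qc(tr)[0], tr.trial_id
    for a, b in zip(trials, ds2.afferents["syn01"]):
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        np.testing.assert_array_equal(a.force, b.force)


def test_dataset_covers_both_stretch_types():
    ds = make_dataset(1, 13, [default_truth("FORCE")], seed=5)
    types = {tr.stretch_type for tr in ds.afferents["syn01"]}
    assert types == {"ramp_hold_release", "sawtooth"}


def test_dfdt_weight_ordering_appears_in_dynamic_index(force_params):
    """Afferents built with increasing dF/dt weight show increasing DI."""
    from spindlefit.metrics import dynamic_index
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    dis = []
    for k_df in (0.1, 0.4, 0.8):
        truth = GroundTruthSpindle("FORCE", k=(30.0, k_df), b=(0.4, 0.0),
                                   spike_mode="isi_consistent")
        tr = make_trial(proto, truth, force_params, f"kd{k_df}", "affK")
        dis.append(dynamic_index(tr).di)
    assert dis[0] < dis[1] < dis[2]


def test_ground_truth_roundtrips_through_dict():
    truth = default_truth("FORCE", lambda_ms=7)
    again = GroundTruthSpindle.from_dict(truth.to_dict())
    assert again == truth
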