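"""Cost functions, lag sweeps, pooled fits, and parameter recovery."""

import numpy as np
import pytest

from spindlefit.config import RunConfig
from spindlefit.encoders import MODEL_SPECS, ModelParams, build_channels
from spindlefit.exceptions import DegenerateTarget, InvalidInput
from spindlefit.fitting import (SpindleEncodingModel, compare_force_variants,
                                consolidate_lag, cost_J, evaluate_params,
                                fit_pooled, fit_trial, make_design, r_squared)
from spindlefit.simulate import (GroundTruthSpindle, MuscleForceParams,
                                 StretchProtocol, default_truth, make_trial)


# ------------------------------------------------------------------- costs
def test_cost_is_zero_for_perfect_fit():
    y = np.array([1.0, 2.0, 5.0])
    assert cost_J(y, y) == 0.0
    assert r_squared(y, y) == 1.0


def test_cost_is_one_for_mean_predictor():
    y = np.array([1.0, 2.0, 3.0])
    f = np.full(3, y.mean())
    assert cost_J(y, f) == pytest.approx(1.0)
    assert r_squared(y, f) == pytest.approx(0.0)


def test_cost_hand_computed_values():
    assert cost_J(np.array([1.0, 2.0, 3.0]),
                  np.array([2.0, 2.0, 2.0])) == pytest.approx(1.0)
    assert r_squared(np.array([0.0, 1.0, 2.0]),
                     np.zeros(3)) == pytest.approx(-1.5)


def test_cost_rejects_degenerate_target():
    with pytest.raises(DegenerateTarget):
        cost_J(np.array([2.0, 2.0]), np.array([1.0, 2.0]))


def test_cost_rejects_mismatched_series():
    with pytest.raises(InvalidInput):
        cost_J(np.array([1.0, 2.0]), np.array([1.0]))


# ---------------------------------------------------------------- lag sweep
def test_lag_sweep_evaluates_sixteen_lags(recovery_trials):
    fr = fit_trial("FORCE", recovery_trials[0])
    assert fr.n_lags_evaluated == 16
    assert fr.J == pytest.approx(1.0 - fr.r2)


def test_consolidate_lag_rounding():
    assert consolidate_lag([10, 10, 10]) == 10
    assert consolidate_lag([9, 10, 11]) == 10
    assert consolidate_lag([9, 10]) == 10  # 9.5 rounds half up
    with pytest.raises(InvalidInput):
        consolidate_lag([])


def test_noiseless_trial_recovers_lag_and_weights(recovery_trials,
                                                  recovery_truth):
    fr = fit_trial("FORCE", recovery_trials[1])
    assert fr.lag_ms_best == recovery_truth.lambda_ms
    np.testing.assert_allclose(fr.params.k, recovery_truth.k, rtol=0.01)
    assert fr.r2 > 0.9999


# --------------------------------------------------------------- oracle fit
def _toy_trial(n=200, seed=0):
    """200-sample trial with force/dFdt channels and a known encoder."""
    fs = 2000.0
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    force = 0.1 + 1.5 * (1 - np.cos(2 * np.pi * 4.0 * t)) / 2
    length = force * 0.5
    from spindlefit.signals import TrialRecord
    spikes = np.sort(rng.uniform(t[5], t[-1], size=40))
    spikes = np.unique(np.round(spikes, 5))
    return TrialRecord("toy", "affT", fs, t, length, force, spikes)


def run_grid_oracle_check():
    """Bounded least squares must reach at most the best cost found by
    exhaustive search over a coarse (k1, k2, b1) lattice, at each of the
    16 candidate lags."""
    from spindlefit.fitting import (_predict_points, _shift_samples, _stack,
                                    default_bounds, _fit_at_lag)
    cfg = RunConfig()
    trial = _toy_trial()
    design = make_design(trial)
    spec = MODEL_SPECS["FORCE"]
    y = design.y
    ssm = np.sum((y - y.mean()) ** 2)
    bounds = default_bounds([design], spec)
    for lag in cfg.lag_grid_ms():
        shift = _shift_samples(lag, trial.fs)
        _, X0, X1, w0, w1 = _stack([design], spec, shift, None)
        best_oracle = np.inf
        for k1 in np.linspace(0, bounds.k_max[0], 6):
            for k2 in np.linspace(0, bounds.k_max[1], 6):
                for b1 in np.linspace(-bounds.b_max[0], bounds.b_max[0], 5):
                    theta = np.array([k1, k2, b1, 0.0])
                    yhat, _ = _predict_points(theta, X0, X1, w0, w1,
                                              cfg.rectify_order)
                    best_oracle = min(best_oracle,
                                      np.sum((yhat - y) ** 2) / ssm)
        _, J_opt = _fit_at_lag([design], spec, shift, cfg, bounds, None)
        assert J_opt <= best_oracle + 1e-9


def test_optimizer_beats_coarse_grid_oracle_at_every_lag():
    run_grid_oracle_check()


# -------------------------------------------------------------- pooled fits
def test_pooled_single_trial_equals_per_trial_fit(recovery_trials):
    fr_trial = fit_trial("FORCE", recovery_trials[0],
                         lags_ms=[10])
    fr_pooled = fit_pooled("FORCE", recovery_trials[:1], 10)
    assert fr_pooled.r2 == pytest.approx(fr_trial.r2, abs=1e-9)
    np.testing.assert_allclose(fr_pooled.params.k, fr_trial.params.k,
                               rtol=1e-6, atol=1e-9)


def test_pooled_fit_cannot_beat_trial_specific_fits(poisson_recovery_trials):
    """Optimization nesting: one shared parameter set cannot achieve a
    smaller total squared error than per-trial parameter sets (checked on
    noisy data, where the noise dwarfs any optimizer convergence gap)."""
    trials = poisson_recovery_trials[:6]
    designs = [make_design(tr) for tr in trials]
    per = [fit_pooled("FORCE", [tr], 10, designs=[d])
           for tr, d in zip(trials, designs)]
    pooled = fit_pooled("FORCE", trials, 10, designs=designs)
    ssm = [np.sum((d.y - d.y.mean()) ** 2) for d in designs]
    sse_per_trial = sum(fr.J * s for fr, s in zip(per, ssm))
    y_all = np.concatenate([d.y for d in designs])
    sse_pooled = pooled.J * np.sum((y_all - y_all.mean()) ** 2)
    assert sse_pooled >= sse_per_trial - 1e-6 * sse_per_trial


def test_pooled_recovers_truth_from_many_trials(recovery_trials,
                                                recovery_truth):
    pooled = fit_pooled("FORCE", recovery_trials, recovery_truth.lambda_ms)
    np.testing.assert_allclose(pooled.params.k, recovery_truth.k, rtol=0.01)
    np.testing.assert_allclose(pooled.params.b[0], recovery_truth.b[0],
                               rtol=0.01)


# ----------------------------------------------------------- model facade
def test_encoding_model_fit_and_summary(recovery_trials):
    model = SpindleEncodingModel(recovery_trials, "FORCE")
    res = model.fit(lag="sweep")
    assert res.lag_ms == 10
    assert res.r2 > 0.999
    text = res.summary()
    assert "FORCE" in text and "lag (ms):       10" in text
    pred = res.predict(recovery_trials[0])
    assert pred.shape == recovery_trials[0].t.shape
    assert np.all(pred >= 0.0)


def test_encoding_model_rejects_all_failing_trials(recovery_trials):
    import dataclasses
    bad = [dataclasses.replace(tr, exclude=True) for tr in recovery_trials]
    with pytest.raises(InvalidInput):
        SpindleEncodingModel(bad, "FORCE")


# ---------------------------------------------------------------- competing
def test_variant_choice_tracks_generating_process(force_params):
    from spindlefit.simulate import default_protocol_grid
    grid = default_protocol_grid()
    plain_truth = default_truth("FORCE", spike_mode="isi_consistent")
    comp_truth = GroundTruthSpindle("FORCE", k=(30.0, 0.6), b=(0.4, 0.05),
                                    competing=True,
                                    spike_mode="isi_consistent")
    for truth, expected in ((comp_truth, "competing"), (plain_truth, "plain")):
        trials = [make_trial(grid[i % len(grid)], truth, force_params,
                             f"v{i}", "affV") for i in range(8)]
        variant, r2p, r2c = compare_force_variants(trials, truth.lambda_ms)
        assert variant == expected, (r2p, r2c)
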