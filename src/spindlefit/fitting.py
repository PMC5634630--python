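"""Constrained least-squares fitting of the candidate encoding models.

Observations are the instantaneous firing-rate samples at spike times; the
model prediction is evaluated on the trial's sample grid and linearly
interpolated to those times.  For each candidate lag (0-15 ms in 1 ms steps)
the weights and offsets are found by bounded nonlinear least squares
(``scipy.optimize.least_squares``, trust-region reflective, analytic
Jacobian) from a deterministic multi-start: a near-zero start, the bound
midpoints, and optionally the exploratory-fit values.  The quality measure
is the variance-normalised cost

    J = SSE / SSM = sum (y_i - f_i)^2 / sum (y_i - ybar)^2,     R^2 = 1 - J.

Per-trial fits sweep the full lag grid; the per-afferent lag is the
arithmetic mean of per-trial best lags, rounded to the nearest integer ms
(half up), and is then frozen for pooled fits and cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import RunConfig, DEFAULT_CONFIG
from .encoders import MODEL_SPECS, ModelParams, ModelSpec, build_channels
from .exceptions import DegenerateTarget, FitFailure, InvalidInput
from .signals import DerivedChannels, TrialRecord, compute_ifr

__all__ = [
    "cost_J", "r_squared", "FitResult", "ParamBounds", "TrialDesign",
    "make_design", "fit_trial", "fit_pooled", "consolidate_lag",
    "evaluate_params", "SpindleEncodingModel", "SpindleEncodingResults",
]


# ------------------------------------------------------------------- costs
def cost_J(y: np.ndarray, f: np.ndarray) -> float:
    """Normalised cost SSE/SSM of prediction ``f`` against target ``y``."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise InvalidInput("cost_J needs two equal-length series (n >= 2)")
    ssm = float(np.sum((y - y.mean()) ** 2))
    if ssm == 0.0:
        raise DegenerateTarget("target series has zero variance")
    sse = float(np.sum((y - f) ** 2))
    return sse / ssm


def r_squared(y: np.ndarray, f: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SSM (may be negative)."""
    return 1.0 - cost_J(y, f)


# ------------------------------------------------------------------ design
#: all channels a design carries, in fixed column order
CHANNEL_ORDER = ("force", "dFdt", "length", "velocity", "acceleration",
                 "fasc_low_length", "fasc_low_velocity", "fasc_low_acceleration",
                 "fasc_high_length", "fasc_high_velocity", "fasc_high_acceleration")
_COL = {name: i for i, name in enumerate(CHANNEL_ORDER)}


@dataclass
class TrialDesign:
    """Per-trial fitting substrate.

    ``C`` holds every predictor channel on the grid; the IFR observations are
    mapped to pairs of bracketing grid indices (``i0``, ``i1``) with linear
    interpolation weights, so that a lag shift of ``s`` samples only changes
    which rows are gathered.
    """

    trial_id: str
    y: np.ndarray           # IFR observations, imp/s
    i0: np.ndarray
    i1: np.ndarray
    w0: np.ndarray
    w1: np.ndarray
    C: np.ndarray           # n_grid x len(CHANNEL_ORDER)

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    def gather(self, cols: np.ndarray, shift: int
               ) -> tuple[np.ndarray, np.ndarray]:
        """Channel values at the bracketing grid points under a lag shift."""
        j0 = np.maximum(self.i0 - shift, 0)
        j1 = np.maximum(self.i1 - shift, 0)
        return self.C[np.ix_(j0, cols)], self.C[np.ix_(j1, cols)]


def make_design(trial: TrialRecord,
                channels: Optional[DerivedChannels] = None,
                config: RunConfig = DEFAULT_CONFIG) -> TrialDesign:
    """Build the fitting substrate for one trial (>= 2 IFR samples)."""
    if channels is None:
        channels = build_channels(trial, config)
    ifr = compute_ifr(trial.spike_times)
    if len(ifr) < 2:
        raise InvalidInput(f"trial {trial.trial_id}: fewer than 2 IFR samples")
    t = channels.t
    idx = np.searchsorted(t, ifr.times)
    i1 = np.clip(idx, 1, t.size - 1)
    i0 = i1 - 1
    w1 = (ifr.times - t[i0]) / (t[i1] - t[i0])
    w1 = np.clip(w1, 0.0, 1.0)
    C = np.column_stack([channels[name] for name in CHANNEL_ORDER])
    return TrialDesign(trial_id=trial.trial_id, y=ifr.rates,
                       i0=i0, i1=i1, w0=1.0 - w1, w1=w1, C=C)


def _stack(designs: Sequence[TrialDesign], spec: ModelSpec, shift: int,
           a: Optional[float]) -> tuple[np.ndarray, ...]:
    cols = np.array([_COL[name] for name in spec.predictors])
    ys, X0s, X1s, w0s, w1s = [], [], [], [], []
    for d in designs:
        x0, x1 = d.gather(cols, shift)
        ys.append(d.y)
        X0s.append(x0)
        X1s.append(x1)
        w0s.append(d.w0)
        w1s.append(d.w1)
    y = np.concatenate(ys)
    X0 = np.vstack(X0s)
    X1 = np.vstack(X1s)
    if spec.power_velocity:
        v = spec.predictors.index("velocity")
        X0 = X0.copy()
        X1 = X1.copy()
        X0[:, v] = np.maximum(X0[:, v], 0.0) ** a
        X1[:, v] = np.maximum(X1[:, v], 0.0) ** a
    return y, X0, X1, np.concatenate(w0s), np.concatenate(w1s)


# --------------------------------------------------------------- optimizer
@dataclass
class ParamBounds:
    """Box bounds for the optimizer: k in [0, k_max], b in [-b_max, b_max]."""

    k_max: np.ndarray
    b_max: np.ndarray

    def for_spec(self, spec: ModelSpec) -> "ParamBounds":
        if self.k_max.size == spec.n_predictors:
            return self
        raise InvalidInput("bounds do not match the model's predictor count")


def default_bounds(designs: Sequence[TrialDesign], spec: ModelSpec,
                   a: Optional[float] = None) -> ParamBounds:
    """Scale-aware fallback bounds from the data ranges.

    Weight ceiling: ten times the rate range divided by the channel range;
    offset bound: the channel's maximum absolute value.
    """
    y, X0, X1, _, _ = _stack(designs, spec, 0, a if a is not None else 0.5)
    y_range = float(np.ptp(y)) + float(np.abs(y).max()) + 1.0
    x_absmax = np.maximum(np.abs(X0).max(axis=0), np.abs(X1).max(axis=0))
    x_range = np.maximum(X0.max(axis=0) - X0.min(axis=0), 1e-9)
    k_max = 10.0 * y_range / x_range
    b_max = np.maximum(x_absmax, 1e-6)
    return ParamBounds(k_max=k_max, b_max=b_max)


def _predict_points(theta: np.ndarray, X0: np.ndarray, X1: np.ndarray,
                    w0: np.ndarray, w1: np.ndarray, rectify: str
                    ) -> tuple[np.ndarray, tuple]:
    p = X0.shape[1]
    k, b = theta[:p], theta[p:]
    if rectify == "threshold":
        G0 = np.maximum(X0 + b, 0.0)
        G1 = np.maximum(X1 + b, 0.0)
    else:  # as_printed
        G0 = np.maximum(X0, 0.0) + b
        G1 = np.maximum(X1, 0.0) + b
    p0 = G0 @ k
    p1 = G1 @ k
    m0 = p0 > 0.0
    m1 = p1 > 0.0
    yhat = w0 * np.where(m0, p0, 0.0) + w1 * np.where(m1, p1, 0.0)
    return yhat, (k, G0, G1, m0, m1)


def _jac_points(cache: tuple, X0, X1, w0, w1, rectify: str) -> np.ndarray:
    k, G0, G1, m0, m1 = cache
    a0 = (w0 * m0)[:, None]
    a1 = (w1 * m1)[:, None]
    Jk = a0 * G0 + a1 * G1
    if rectify == "threshold":
        Jb = (a0 * (G0 > 0.0) + a1 * (G1 > 0.0)) * k
    else:
        Jb = (a0 + a1) * k
    return np.hstack([Jk, Jb])


def _linear_start(y, X0, X1, w0, w1, lo, hi) -> np.ndarray:
    """Start from ordinary linear least squares ignoring rectification.

    Solves y ~ Xbar k + c with Xbar the interpolated channel values, then
    spreads the intercept c over the offsets (k_i b_i summing to c).  In
    the regime where rectification rarely binds this lands on the optimal
    ridge, which the rectified refinement then pins down.
    """
    p = X0.shape[1]
    Xbar = w0[:, None] * X0 + w1[:, None] * X1
    A = np.column_stack([Xbar, np.ones(y.size)])
    try:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    except np.linalg.LinAlgError:
        return None
    k = np.clip(coef[:p], lo[:p] + 1e-12, hi[:p])
    c = coef[p]
    b = np.zeros(p)
    active = k > 1e-12
    n_act = int(active.sum())
    if n_act:
        b[active] = c / (n_act * k[active])
    theta = np.concatenate([k, np.clip(b, lo[p:], hi[p:])])
    return theta


def _fit_stacked(y, X0, X1, w0, w1, bounds: ParamBounds, rectify: str,
                 extra_starts: Sequence[np.ndarray] = (),
                 starts_only: bool = False,
                 light: bool = False) -> tuple[np.ndarray, float]:
    """Multi-start bounded least squares; returns (theta, J).

    Default starts: the unrectified linear solution, a near-zero start and
    the bound midpoints, plus any ``extra_starts``.  ``light=True`` keeps
    only the linear start and the extras (lag sweeps, where the previous
    lag's solution is chained in); ``starts_only=True`` restricts to the
    extras (warm-started cross-validation refits, with a fallback to the
    full multi-start if the warm fit is no better than the mean rate).
    """
    p = X0.shape[1]
    ssm = float(np.sum((y - y.mean()) ** 2))
    if ssm == 0.0:
        raise DegenerateTarget("pooled IFR observations have zero variance")
    lo = np.concatenate([np.zeros(p), -bounds.b_max])
    hi = np.concatenate([bounds.k_max, bounds.b_max])

    def resid(theta):
        yhat, _ = _predict_points(theta, X0, X1, w0, w1, rectify)
        return yhat - y

    def jac(theta):
        _, cache = _predict_points(theta, X0, X1, w0, w1, rectify)
        return _jac_points(cache, X0, X1, w0, w1, rectify)

    starts = []
    for s in extra_starts:
        if s is not None:
            starts.append(np.clip(s, lo, hi))
    if not starts_only or not starts:
        lin = _linear_start(y, X0, X1, w0, w1, lo, hi)
        if lin is not None:
            starts.append(lin)
        if not light or not starts:
            starts += [
                np.concatenate([0.01 * bounds.k_max, np.zeros(p)]),  # near 0
                np.concatenate([0.5 * bounds.k_max, np.zeros(p)]),   # midpoint
            ]

    best_theta, best_sse = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                                method="trf", x_scale="jac", max_nfev=300)
        except Exception:
            continue
        sse = 2.0 * sol.cost
        if np.isfinite(sse) and sse < best_sse:
            best_sse, best_theta = sse, sol.x
    if best_theta is None:
        raise FitFailure("optimizer failed from every start")
    if starts_only and starts and best_sse / ssm >= 1.0:
        # warm start led nowhere useful: fall back to the full multi-start
        return _fit_stacked(y, X0, X1, w0, w1, bounds, rectify,
                            extra_starts, starts_only=False)
    return best_theta, best_sse / ssm


def _a_grid(config: RunConfig) -> np.ndarray:
    n = int(round((config.power_a_max - config.power_a_min) / config.power_a_step))
    return np.round(config.power_a_min + config.power_a_step * np.arange(n + 1), 10)


def _fit_at_lag(designs, spec, shift, config, bounds, extra_start,
                warm_only: bool = False,
                light: bool = False) -> tuple[ModelParams, float]:
    """Fit weights/offsets (and exponent) at a fixed integer-sample shift.

    ``warm_only`` restricts each inner fit to the provided start (cross-
    validation refits, where the exploratory solution is a good start); the
    exponent grid always warm-chains from the previous grid point.
    """
    if spec.power_velocity:
        best = None
        prev = extra_start
        for i, a in enumerate(_a_grid(config)):
            y, X0, X1, w0, w1 = _stack(designs, spec, shift, float(a))
            bds = bounds if bounds is not None else default_bounds(
                designs, spec, float(a))
            theta, J = _fit_stacked(
                y, X0, X1, w0, w1, bds, config.rectify_order,
                [prev] if prev is not None else [],
                starts_only=(warm_only or i > 0) and prev is not None,
                light=light)
            if best is None or J < best[2]:
                best = (theta, float(a), J)
            prev = theta
        theta, a_best, J = best
        p = spec.n_predictors
        params = ModelParams(spec.model_id, theta[:p], theta[p:], a=a_best)
        return params, J
    y, X0, X1, w0, w1 = _stack(designs, spec, shift, None)
    bds = bounds if bounds is not None else default_bounds(designs, spec)
    theta, J = _fit_stacked(y, X0, X1, w0, w1, bds, config.rectify_order,
                            [extra_start] if extra_start is not None else [],
                            starts_only=warm_only, light=light)
    p = spec.n_predictors
    return ModelParams(spec.model_id, theta[:p], theta[p:]), J


# ------------------------------------------------------------------ results
@dataclass
class FitResult:
    """Goodness of fit of one model on one trial (or one pooled fit)."""

    model_id: str
    params: ModelParams
    r2: float
    n_obs: int
    lag_ms_best: int
    n_lags_evaluated: int = 1

    @property
    def J(self) -> float:
        return 1.0 - self.r2


def _shift_samples(lag_ms: int, fs: float) -> int:
    s = lag_ms * fs / 1000.0
    si = int(round(s))
    if abs(s - si) > 1e-9:
        raise InvalidInput(f"lag {lag_ms} ms is not integral at fs={fs}")
    return si


def _sweep_lags(designs: Sequence[TrialDesign], spec: ModelSpec, fs: float,
                config: RunConfig, bounds: Optional[ParamBounds],
                lags: Sequence[int], n_polish: int = 3
                ) -> tuple[ModelParams, float]:
    """Lag sweep: a fast warm-chained pass over the grid, then a full
    multi-start polish of the leading lags, cross-seeded with the overall
    best solution so near-ties are resolved by fit quality rather than by
    incidental under-convergence."""
    results: dict[int, tuple[ModelParams, float]] = {}
    prev = None
    for lag in lags:
        shift = _shift_samples(lag, fs)
        params, J = _fit_at_lag(designs, spec, shift, config, bounds, prev,
                                light=True)
        prev = np.concatenate([params.k, params.b])
        results[lag] = (params, J)
    if len(lags) > 1 and n_polish > 0:
        order = sorted(lags, key=lambda l: results[l][1])
        lead = results[order[0]][0]
        seed = np.concatenate([lead.k, lead.b])
        for lag in order[:n_polish]:
            shift = _shift_samples(lag, fs)
            params, J = _fit_at_lag(designs, spec, shift, config, bounds,
                                    seed)
            if J < results[lag][1]:
                results[lag] = (params, J)
    best_lag = min(lags, key=lambda l: results[l][1])
    params, J = results[best_lag]
    params.lambda_ms = int(best_lag)
    return params, J


def fit_trial(spec: ModelSpec | str, trial: TrialRecord,
              channels: Optional[DerivedChannels] = None,
              config: RunConfig = DEFAULT_CONFIG,
              bounds: Optional[ParamBounds] = None,
              lags_ms: Optional[Sequence[int]] = None) -> FitResult:
    """Sweep the lag grid on a single trial; keep the highest-R^2 lag."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    design = make_design(trial, channels, config)
    fs = 1.0 / (channels.t[1] - channels.t[0]) if channels is not None else trial.fs
    lags = list(lags_ms) if lags_ms is not None else config.lag_grid_ms()
    params, J = _sweep_lags([design], spec, fs, config, bounds, lags)
    return FitResult(model_id=spec.model_id, params=params, r2=1.0 - J,
                     n_obs=design.n_obs, lag_ms_best=params.lambda_ms,
                     n_lags_evaluated=len(lags))


def consolidate_lag(per_trial_best_lags_ms: Sequence[float]) -> int:
    """Afferent-level lag: arithmetic mean, rounded half up to integer ms."""
    lags = list(per_trial_best_lags_ms)
    if not lags:
        raise InvalidInput("no per-trial lags to consolidate")
    return int(math.floor(float(np.mean(lags)) + 0.5))


def fit_pooled(spec: ModelSpec | str, trials: Sequence[TrialRecord],
               lambda_ms: int,
               designs: Optional[Sequence[TrialDesign]] = None,
               config: RunConfig = DEFAULT_CONFIG,
               bounds: Optional[ParamBounds] = None,
               extra_start: Optional[np.ndarray] = None,
               warm_only: bool = False) -> FitResult:
    """One parameter set over the concatenated observations of all trials."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if designs is None:
        if not trials:
            raise InvalidInput("fit_pooled: no trials")
        designs = [make_design(tr, None, config) for tr in trials]
    fs = trials[0].fs if trials else 2000.0
    shift = _shift_samples(lambda_ms, fs)
    params, J = _fit_at_lag(designs, spec, shift, config, bounds, extra_start,
                            warm_only=warm_only)
    params.lambda_ms = int(lambda_ms)
    n_obs = int(sum(d.n_obs for d in designs))
    return FitResult(model_id=spec.model_id, params=params, r2=1.0 - J,
                     n_obs=n_obs, lag_ms_best=int(lambda_ms))


def evaluate_params(params: ModelParams, designs: Sequence[TrialDesign],
                    fs: float, config: RunConfig = DEFAULT_CONFIG) -> float:
    """Cost J of fixed parameters on the concatenated observations."""
    spec = params.spec
    shift = _shift_samples(params.lambda_ms, fs)
    y, X0, X1, w0, w1 = _stack(designs, spec, shift, params.a)
    theta = np.concatenate([params.k, params.b])
    yhat, _ = _predict_points(theta, X0, X1, w0, w1, config.rectify_order)
    return cost_J(y, yhat)


# ---------------------------------------------------- FORCE competing fits
def _competing_points(theta, X0, X1, w0, w1, rectify: str,
                      threshold: float) -> np.ndarray:
    from .encoders import competing_components
    k, b = theta[:2], theta[2:]
    out = 0.0
    for X, w in ((X0, w0), (X1, w1)):
        if rectify == "threshold":
            c1 = k[0] * np.maximum(X[:, 0] + b[0], 0.0)
            c2 = k[1] * np.maximum(X[:, 1] + b[1], 0.0)
        else:
            c1 = k[0] * (np.maximum(X[:, 0], 0.0) + b[0])
            c2 = k[1] * (np.maximum(X[:, 1], 0.0) + b[1])
        c1, c2 = competing_components(c1, c2, threshold)
        out = out + w * np.maximum(c1 + c2, 0.0)
    return out


def fit_pooled_competing(trials: Sequence[TrialRecord], lambda_ms: int,
                         designs: Optional[Sequence[TrialDesign]] = None,
                         config: RunConfig = DEFAULT_CONFIG,
                         bounds: Optional[ParamBounds] = None,
                         plain_start: Optional[np.ndarray] = None
                         ) -> FitResult:
    """Pooled fit of the FORCE model's competing variant.

    The competing rule is non-smooth, so the optimizer uses finite-
    difference derivatives; the plain FORCE solution (if given) seeds the
    search alongside the standard starts.
    """
    spec = MODEL_SPECS["FORCE"]
    if designs is None:
        designs = [make_design(tr, None, config) for tr in trials]
    fs = trials[0].fs
    shift = _shift_samples(lambda_ms, fs)
    y, X0, X1, w0, w1 = _stack(designs, spec, shift, None)
    bds = bounds if bounds is not None else default_bounds(designs, spec)
    lo = np.concatenate([np.zeros(2), -bds.b_max])
    hi = np.concatenate([bds.k_max, bds.b_max])
    ssm = float(np.sum((y - y.mean()) ** 2))
    if ssm == 0.0:
        raise DegenerateTarget("pooled IFR observations have zero variance")

    def resid(theta):
        return _competing_points(theta, X0, X1, w0, w1,
                                 config.rectify_order,
                                 config.competing_threshold) - y

    starts = [np.concatenate([0.01 * bds.k_max, np.zeros(2)]),
              np.concatenate([0.5 * bds.k_max, np.zeros(2)])]
    lin = _linear_start(y, X0, X1, w0, w1, lo, hi)
    if lin is not None:
        starts.insert(0, lin)
    if plain_start is not None:
        starts.insert(0, np.clip(plain_start, lo, hi))
    best_theta, best_sse = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                x_scale="jac", max_nfev=300)
        except Exception:
            continue
        sse = 2.0 * sol.cost
        if np.isfinite(sse) and sse < best_sse:
            best_sse, best_theta = sse, sol.x
    if best_theta is None:
        raise FitFailure("competing fit failed from every start")
    params = ModelParams("FORCE", best_theta[:2], best_theta[2:],
                         lambda_ms=int(lambda_ms))
    return FitResult("FORCE", params, 1.0 - best_sse / ssm,
                     int(sum(d.n_obs for d in designs)), int(lambda_ms))


def compare_force_variants(trials: Sequence[TrialRecord], lambda_ms: int,
                           designs: Optional[Sequence[TrialDesign]] = None,
                           config: RunConfig = DEFAULT_CONFIG,
                           bounds: Optional[ParamBounds] = None
                           ) -> tuple[str, float, float]:
    """Fit both FORCE variants over all observations and pick one.

    Returns (variant, r2_plain, r2_competing); the competing variant is
    kept only on a strict mean-R^2 improvement.
    """
    from .encoders import choose_competing
    if designs is None:
        designs = [make_design(tr, None, config) for tr in trials]
    plain = fit_pooled("FORCE", trials, lambda_ms, designs=designs,
                       config=config, bounds=bounds)
    comp = fit_pooled_competing(
        trials, lambda_ms, designs=designs, config=config, bounds=bounds,
        plain_start=np.concatenate([plain.params.k, plain.params.b]))
    return choose_competing(plain.r2, comp.r2), plain.r2, comp.r2


# ----------------------------------------------------- model/results facade
class SpindleEncodingModel:
    """A candidate encoding model bound to one afferent's trials.

    Parameters
    ----------
    trials : sequence of TrialRecord
        Trials of a single afferent.  Trials failing QC (fewer than 50
        spikes, or flagged) are dropped with ``drop_failing=True``.
    model : str
        One of FORCE, LENGTH, LENGTH_POWER, FASCICLE_LOW, FASCICLE_HIGH, ALL.
    """

    def __init__(self, trials: Sequence[TrialRecord], model: str = "FORCE",
                 config: RunConfig = DEFAULT_CONFIG, drop_failing: bool = True):
        from .signals import passing_trials
        self.spec = MODEL_SPECS[model.upper()] if isinstance(model, str) else model
        self.config = config
        self.trials = (passing_trials(list(trials), config.min_spikes_per_trial)
                       if drop_failing else list(trials))
        if not self.trials:
            raise InvalidInput("no QC-passing trials")
        self._designs: Optional[list[TrialDesign]] = None

    @classmethod
    def from_manifest(cls, manifest_path, afferent_id=None, **kw):
        from .io import read_dataset
        afferents = read_dataset(manifest_path)
        if afferent_id is None:
            afferent_id = sorted(afferents)[0]
        return cls(afferents[afferent_id], **kw)

    @property
    def designs(self) -> list[TrialDesign]:
        if self._designs is None:
            self._designs = [make_design(tr, None, self.config)
                             for tr in self.trials]
        return self._designs

    def fit(self, lag: int | str = "sweep",
            explore_n: Optional[int] = None) -> "SpindleEncodingResults":
        """Fit the model.

        ``lag="sweep"`` runs per-trial lag sweeps on an exploratory subset,
        consolidates the afferent lag and derives parameter bounds, then
        fits one pooled parameter set at the frozen lag.  An integer ``lag``
        skips the sweep.
        """
        cfg = self.config
        explore_n = explore_n or cfg.explore_n_trials
        per_trial: list[FitResult] = []
        bounds = None
        if lag == "sweep":
            subset = self.trials[:explore_n]
            sub_designs = self.designs[:explore_n]
            for tr, d in zip(subset, sub_designs):
                per_trial.append(self._fit_trial_design(d, tr, cfg))
            lam = consolidate_lag([fr.lag_ms_best for fr in per_trial])
            bounds = bounds_from_fits(per_trial, self.designs, self.spec, cfg)
        else:
            lam = int(lag)
        pooled = fit_pooled(self.spec, self.trials, lam,
                            designs=self.designs, config=cfg, bounds=bounds)
        return SpindleEncodingResults(model=self, pooled=pooled,
                                      per_trial=per_trial, bounds=bounds)

    def _fit_trial_design(self, design: TrialDesign, trial: TrialRecord,
                          cfg: RunConfig) -> FitResult:
        params, J = _sweep_lags([design], self.spec, trial.fs, cfg, None,
                                cfg.lag_grid_ms())
        return FitResult(self.spec.model_id, params, 1.0 - J, design.n_obs,
                         params.lambda_ms, len(cfg.lag_grid_ms()))


def bounds_from_fits(per_trial: Sequence[FitResult],
                     designs: Sequence[TrialDesign], spec: ModelSpec,
                     config: RunConfig = DEFAULT_CONFIG) -> ParamBounds:
    """Search limits from exploratory fits: [0, m * max k-hat] for weights,
    [-max|x|, max|x|] for offsets, with a floor so an exploratory zero does
    not freeze a weight at zero."""
    fallback = default_bounds(designs, spec)
    if not per_trial:
        return fallback
    k_hat = np.vstack([fr.params.k for fr in per_trial]).max(axis=0)
    k_max = np.maximum(config.bound_multiplier * k_hat, 0.02 * fallback.k_max)
    return ParamBounds(k_max=k_max, b_max=fallback.b_max)


@dataclass
class SpindleEncodingResults:
    """Pooled-fit results of a candidate model on one afferent."""

    model: SpindleEncodingModel
    pooled: FitResult
    per_trial: list = field(default_factory=list)
    bounds: Optional[ParamBounds] = None

    @property
    def params(self) -> ModelParams:
        return self.pooled.params

    @property
    def r2(self) -> float:
        return self.pooled.r2

    @property
    def J(self) -> float:
        return self.pooled.J

    @property
    def lag_ms(self) -> int:
        return self.pooled.params.lambda_ms

    def predict(self, trial: TrialRecord, t_eval=None) -> np.ndarray:
        from .encoders import predict_grid, predict_ifr
        channels = build_channels(trial, self.model.config)
        if t_eval is None:
            return predict_grid(self.params, channels,
                                self.model.config.rectify_order)
        return predict_ifr(self.params, channels, t_eval,
                           self.model.config.rectify_order)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Spindle encoding model fit",
            "=" * 54,
            f"model:          {spec.model_id}",
            f"trials:         {len(self.model.trials)}",
            f"observations:   {self.pooled.n_obs}",
            f"lag (ms):       {self.lag_ms}",
            f"R^2:            {self.r2:.4f}",
            f"J (SSE/SSM):    {self.J:.4f}",
            "-" * 54,
            f"{'predictor':<24}{'weight k':>14}{'offset b':>14}",
        ]
        for name, k, b in zip(spec.predictors, self.params.k, self.params.b):
            lines.append(f"{name:<24}{k:>14.5g}{b:>14.5g}")
        if self.params.a is not None:
            lines.append(f"{'velocity exponent a':<24}{self.params.a:>14.3g}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_fit(self, trial: TrialRecord, ax=None):
        """Overlay the predicted rate on the trial's IFR (matplotlib)."""
        import matplotlib.pyplot as plt
        ifr = compute_ifr(trial.spike_times)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(trial.t, self.predict(trial), label=f"{self.pooled.model_id} fit")
        ax.plot(ifr.times, ifr.rates, "k.", ms=3, label="IFR")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("rate (imp/s)")
        ax.legend()
        return ax
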