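"""Synthetic stretch trials with history-dependent muscle force.

The generator produces the study's stretch conditions — ramp-hold-release
and repeated ramp-release ("sawtooth") perturbations spanning 1-4 mm,
4-50 mm/s and 200-3500 mm/s^2 with >= 5 s rests — drives a phenomenological
whole-muscle force model with them, converts force/length channels to a
firing rate through a known ground-truth pseudolinear encoder, and emits
spike trains.  Every pipeline stage is therefore testable against a
recoverable truth.

Force model
-----------
A parallel elastic element plus a Maxwell-slip cross-bridge element with a
movement-depletable "rested" stiffness pool:

    F(t)      = f_rest + k_passive (L - L0) + F_xb(t)
    dF_xb/dt  = (k_xb + k_A) v - |v| F_xb / s0 - F_xb / tau
    dk_A/dt   = (k_rested - k_A) / tau_recover - |v| k_A / s_deplete

The slip length ``s0`` yields short-range stiffness (a dF/dt transient at
stretch onset after rest), ``tau`` yields force relaxation during holds,
and the ``k_A`` pool — fully recovered after a long rest, destroyed by
movement — makes the first stretch of a sawtooth carry the greatest force,
as in thixotropic muscle.

Spike modes
-----------
``deterministic_integrator``  spike whenever the integrated rate crosses an
                              integer (IFR approximates the ISI-averaged
                              rate);
``isi_consistent``            solve t_i - t_{i-1} = 1/r(t_i) so that the
                              recorded IFR equals the generating rate
                              exactly (the noiseless recovery substrate);
``poisson``                   inhomogeneous Poisson by time rescaling;
``poisson_jittered``          rate-consistent spike times with +-1 ms of
                              uniform timing jitter (the noisy recovery
                              substrate: a true Poisson train has no finite
                              mean reciprocal ISI, so IFR regression cannot
                              recover from it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .config import RunConfig, DEFAULT_CONFIG
from .encoders import (MODEL_SPECS, ModelParams, build_channels,
                       competing_predict, predict_grid)
from .exceptions import (InfeasibleProtocol, IntegrationFailure, InvalidInput)
from .signals import TrialRecord

__all__ = [
    "StretchProtocol", "MuscleForceParams", "GroundTruthSpindle",
    "LengthProfile", "make_length_profile", "simulate_force",
    "generate_spikes", "make_trial", "make_dataset", "SyntheticDataset",
    "default_truth", "default_protocol_grid",
]


# ---------------------------------------------------------------- protocols
@dataclass(frozen=True)
class StretchProtocol:
    """Kinematic prescription for one stretch perturbation."""

    stretch_type: str            # "ramp_hold_release" | "sawtooth"
    peak_length_mm: float
    peak_velocity_mm_s: float
    peak_accel_mm_s2: float
    hold_s: float = 1.0
    n_repeats: int = 5           # sawtooth only
    rest_s: float = 5.0          # pre-trial isometric rest
    post_s: float = 1.5          # post-release padding
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if self.stretch_type not in ("ramp_hold_release", "sawtooth"):
            raise InvalidInput(f"stretch_type: {self.stretch_type!r}")
        for name in ("peak_length_mm", "peak_velocity_mm_s",
                     "peak_accel_mm_s2", "fs"):
            if getattr(self, name) <= 0:
                raise InvalidInput(f"{name} must be positive")
        if self.rest_s < 5.0:
            raise InvalidInput("rest_s must be >= 5 s")
        L, v, a = (self.peak_length_mm, self.peak_velocity_mm_s,
                   self.peak_accel_mm_s2)
        if v * v / a > L + 1e-12:
            raise InfeasibleProtocol(
                f"peak velocity {v} mm/s unreachable within {L} mm "
                f"at {a} mm/s^2")

    @property
    def ramp_duration_s(self) -> float:
        L, v, a = (self.peak_length_mm, self.peak_velocity_mm_s,
                   self.peak_accel_mm_s2)
        return 2.0 * v / a + (L - v * v / a) / v


@dataclass
class LengthProfile:
    t: np.ndarray
    length: np.ndarray           # mm, displacement from rest
    onset_time_s: float
    ramp_end_time_s: float
    hold_end_time_s: float


def _ramp_displacement(tau: np.ndarray, L: float, v: float, a: float
                       ) -> np.ndarray:
    """Displacement along an acceleration-limited trapezoidal-velocity ramp."""
    t_acc = v / a
    d_acc = 0.5 * v * v / a
    t_cruise = (L - v * v / a) / v
    T = 2.0 * t_acc + t_cruise
    tau = np.clip(tau, 0.0, T)
    out = np.where(
        tau < t_acc, 0.5 * a * tau ** 2,
        np.where(tau < t_acc + t_cruise, d_acc + v * (tau - t_acc),
                 L - 0.5 * a * (T - tau) ** 2))
    return out


def make_length_profile(protocol: StretchProtocol) -> LengthProfile:
    """Sample the protocol's length trajectory on the 1/fs grid."""
    p = protocol
    T_ramp = p.ramp_duration_s
    if p.stretch_type == "ramp_hold_release":
        segs = [("rest", p.rest_s), ("up", T_ramp), ("hold", p.hold_s),
                ("down", T_ramp), ("post", p.post_s)]
    else:
        segs = [("rest", p.rest_s)]
        segs += [("up", T_ramp), ("down", T_ramp)] * p.n_repeats
        segs += [("post", p.post_s)]
    total = sum(d for _, d in segs)
    n = int(round(total * p.fs)) + 1
    t = np.arange(n) / p.fs
    x = np.zeros(n)
    t0 = 0.0
    onset = ramp_end = hold_end = math.nan
    for kind, dur in segs:
        sl = (t >= t0 - 1e-12) & (t < t0 + dur - 1e-12)
        tau = t[sl] - t0
        if kind == "up":
            x[sl] = _ramp_displacement(tau, p.peak_length_mm,
                                       p.peak_velocity_mm_s,
                                       p.peak_accel_mm_s2)
            if math.isnan(onset):
                onset = t0
            if math.isnan(ramp_end):
                ramp_end = t0 + dur  # first ramp's end (DI reference)
        elif kind == "down":
            x[sl] = p.peak_length_mm - _ramp_displacement(
                tau, p.peak_length_mm, p.peak_velocity_mm_s,
                p.peak_accel_mm_s2)
            if math.isnan(hold_end):
                hold_end = t0
        elif kind == "hold":
            x[sl] = p.peak_length_mm
            hold_end = t0 + dur
        else:
            x[sl] = 0.0
        t0 += dur
    x[t >= t0 - 1e-12] = 0.0
    return LengthProfile(t=t, length=x, onset_time_s=onset,
                         ramp_end_time_s=ramp_end, hold_end_time_s=hold_end)


# -------------------------------------------------------------- force model
@dataclass(frozen=True)
class MuscleForceParams:
    """Parameters of the synthetic whole-muscle force model."""

    k_passive: float = 0.5      # N/mm, parallel elastic stiffness
    k_xb: float = 3.0           # N/mm, baseline cross-bridge stiffness
    s0: float = 0.5             # mm, short-range slip length
    tau: float = 0.5            # s, isometric relaxation time
    f_rest: float = 0.1         # N, resting tension
    k_rested: float = 1.5       # N/mm, movement-depletable stiffness pool
    tau_recover: float = 2.0    # s, rest recovery time of the pool
    s_deplete: float = 0.5      # mm, movement depletion length of the pool
    f_slack: float = 0.05       # N, slack floor (musculotendon cannot push)

    def __post_init__(self) -> None:
        for name in ("k_passive", "s0", "tau", "f_rest",
                     "tau_recover", "s_deplete"):
            if getattr(self, name) <= 0:
                raise InvalidInput(f"{name} must be positive")
        if self.k_xb < 0 or self.k_rested < 0:
            raise InvalidInput("stiffnesses must be non-negative")

    def without_history(self) -> "MuscleForceParams":
        """Purely elastic variant (no cross-bridge element)."""
        return replace(self, k_xb=0.0, k_rested=0.0)


def simulate_force(length: np.ndarray, params: MuscleForceParams,
                   fs: float) -> np.ndarray:
    """Integrate the force model along a length trajectory.

    The initial state is equilibrated at rest (F_xb = 0, rested pool full),
    which is the state reached after the >= 5 s inter-trial rest.  Each
    state uses an exact exponential step for its linear relaxation, with
    velocity held constant over the 1/fs step.
    """
    L = np.asarray(length, dtype=float)
    if L.ndim != 1 or L.size < 2:
        raise InvalidInput("length series must be 1-D with >= 2 samples")
    dt = 1.0 / fs
    v = np.diff(L) * fs
    av = np.abs(v)

    # rested-pool recurrence (independent of F_xb): exact exponential steps
    r = 1.0 / params.tau_recover + av / params.s_deplete
    target = (params.k_rested / params.tau_recover) / r
    Er = np.exp(-r * dt)
    kA = np.empty(L.size)
    kA[0] = params.k_rested
    for i in range(v.size):
        kA[i + 1] = target[i] + (kA[i] - target[i]) * Er[i]

    # cross-bridge force recurrence with stiffness (k_xb + k_A)
    c = av / params.s0 + 1.0 / params.tau
    Ec = np.exp(-c * dt)
    gain = (params.k_xb + kA[:-1]) * v / c * (1.0 - Ec)
    F_xb = np.empty(L.size)
    F_xb[0] = 0.0
    for i in range(v.size):
        F_xb[i + 1] = F_xb[i] * Ec[i] + gain[i]

    force = params.f_rest + params.k_passive * (L - L[0]) + F_xb
    np.maximum(force, params.f_slack, out=force)  # slack: no pushing force
    if not np.all(np.isfinite(force)):
        raise IntegrationFailure("non-finite force state")
    return force


# ------------------------------------------------------------- spike trains
def generate_spikes(t: np.ndarray, rate: np.ndarray, mode: str,
                    seed: Optional[int] = None) -> np.ndarray:
    """Draw spike times (s) from a rate trace (imp/s) on the grid ``t``."""
    t = np.asarray(t, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise InvalidInput("rate must be non-negative")
    if not np.any(rate > 0):
        return np.empty(0)
    if mode == "deterministic_integrator":
        lam = _cumtrapz(rate, t)
        marks = np.arange(1.0, math.floor(lam[-1] + 1e-9) + 0.5)
        return np.interp(marks, lam, t)
    if mode == "poisson":
        lam = _cumtrapz(rate, t)
        rng = np.random.default_rng(seed)
        # time rescaling: unit-rate arrivals mapped through Lambda^-1
        n_max = int(lam[-1] + 10.0 * math.sqrt(lam[-1] + 1.0) + 10)
        arrivals = np.cumsum(rng.exponential(1.0, size=n_max))
        arrivals = arrivals[arrivals < lam[-1]]
        return np.interp(arrivals, lam, t)
    if mode == "poisson_jittered":
        # rate-consistent spike times, each displaced by +-1 ms of uniform
        # timing jitter (about the timing precision of a primary afferent).
        # Unlike a true Poisson process — whose reciprocal ISI has no
        # finite mean — this keeps the IFR a consistent rate estimate, so
        # it is a usable noisy substrate for IFR regression (methods note).
        base = _isi_consistent_spikes(t, rate)
        if base.size == 0:
            return base
        rng = np.random.default_rng(seed)
        jit = np.sort(base + rng.uniform(-1e-3, 1e-3, size=base.size))
        keep = np.concatenate([[True], np.diff(jit) > 1e-6])
        return np.clip(jit[keep], t[0], t[-1])
    if mode == "isi_consistent":
        return _isi_consistent_spikes(t, rate)
    raise InvalidInput(f"unknown spike mode {mode!r}")


def _cumtrapz(rate: np.ndarray, t: np.ndarray) -> np.ndarray:
    lam = np.empty(t.size)
    lam[0] = 0.0
    np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t), out=lam[1:])
    return lam


def _isi_consistent_spikes(t: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Spike times where the reciprocal ISI equals the rate at the later
    spike: solves t_i - t_{i-1} = 1 / r(t_i) by bracketed root finding on
    the piecewise-linear rate."""
    r_min = float(rate.min())
    if r_min <= 0:
        raise InvalidInput("isi_consistent mode requires a positive rate")
    dt = t[1] - t[0]
    max_isi = 1.0 / r_min

    def r_of(x):
        return np.interp(x, t, rate)

    spikes = []
    t_prev = float(t[0])
    t_end = float(t[-1])
    while True:
        hi = min(t_prev + max_isi + 2 * dt, t_end)
        if hi <= t_prev:
            break
        grid = np.arange(t_prev + dt, hi + 0.5 * dt, dt)
        if grid.size == 0:
            grid = np.array([hi])
        f = (grid - t_prev) - 1.0 / r_of(grid)
        pos = np.flatnonzero(f >= 0.0)
        if pos.size == 0:
            break  # trial ends before the next spike
        j = int(pos[0])
        lo = grid[j - 1] if j > 0 else t_prev + 1e-12
        t_next = brentq(lambda x: (x - t_prev) - 1.0 / r_of(x),
                        lo, grid[j], xtol=1e-12)
        if t_next > t_end:
            break
        spikes.append(t_next)
        t_prev = t_next
    return np.asarray(spikes)


# ------------------------------------------------------------ ground truth
@dataclass(frozen=True)
class GroundTruthSpindle:
    """Generative twin of a candidate model's parameters."""

    model_id: str
    k: tuple
    b: tuple
    lambda_ms: int = 5
    a: Optional[float] = None
    competing: bool = False
    spike_mode: str = "deterministic_integrator"
    rate_floor: float = 5.0      # imp/s, resting-discharge floor

    def params(self) -> ModelParams:
        return ModelParams(self.model_id, np.array(self.k), np.array(self.b),
                           lambda_ms=self.lambda_ms, a=self.a)

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "k": list(self.k),
                "b": list(self.b), "lambda_ms": self.lambda_ms,
                "a": self.a, "competing": self.competing,
                "spike_mode": self.spike_mode, "rate_floor": self.rate_floor}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthSpindle":
        d = dict(d)
        d["k"] = tuple(d["k"])
        d["b"] = tuple(d["b"])
        return cls(**d)


def default_truth(model_id: str = "FORCE", **overrides) -> GroundTruthSpindle:
    """Plausible Ia-like ground-truth encoders for the synthetic datasets."""
    presets = {
        "FORCE": dict(k=(30.0, 0.6), b=(0.4, 0.0)),
        "LENGTH": dict(k=(8.0, 1.2, 0.015), b=(0.7, 0.0, 0.0)),
        "LENGTH_POWER": dict(k=(8.0, 6.0, 0.015), b=(0.7, 0.0, 0.0), a=0.5),
    }
    if model_id not in presets:
        raise InvalidInput(f"no default truth for model {model_id!r}")
    kw = dict(model_id=model_id, **presets[model_id])
    kw.update(overrides)
    return GroundTruthSpindle(**kw)


# ----------------------------------------------------------------- dataset
@dataclass
class SyntheticDataset:
    afferents: dict              # afferent_id -> list[TrialRecord]
    truths: dict                 # afferent_id -> GroundTruthSpindle
    protocols: dict              # afferent_id -> list[StretchProtocol]
    force_params: MuscleForceParams
    seed: int


def default_protocol_grid(fs: float = 2000.0) -> list[StretchProtocol]:
    """The protocol mix emulating the study's perturbation diversity."""
    protos: list[StretchProtocol] = []
    for L, v, a in [(3.0, 4.0, 350.0),
                    (2.0, 10.0, 700.0), (3.0, 10.0, 1400.0),
                    (2.0, 20.0, 700.0), (3.0, 20.0, 1400.0),
                    (3.0, 20.0, 2800.0), (3.0, 30.0, 1400.0),
                    (3.0, 40.0, 1400.0), (3.0, 40.0, 2800.0),
                    (4.0, 50.0, 3500.0)]:
        protos.append(StretchProtocol("ramp_hold_release", L, v, a, fs=fs))
    for L, v, a in [(2.0, 10.0, 1400.0), (2.0, 20.0, 1400.0),
                    (2.0, 40.0, 2800.0)]:
        protos.append(StretchProtocol("sawtooth", L, v, a, fs=fs))
    return protos


def make_trial(protocol: StretchProtocol, truth: GroundTruthSpindle,
               force_params: MuscleForceParams, trial_id: str,
               afferent_id: str, seed: Optional[int] = None,
               config: RunConfig = DEFAULT_CONFIG) -> TrialRecord:
    """Generate one trial: profile -> force -> encoder rate -> spikes."""
    prof = make_length_profile(protocol)
    force = simulate_force(prof.length, force_params, protocol.fs)
    shell = TrialRecord(
        trial_id=trial_id, afferent_id=afferent_id, fs=protocol.fs,
        t=prof.t, length=prof.length, force=force,
        spike_times=np.empty(0), stretch_type=protocol.stretch_type,
        peak_length_mm=protocol.peak_length_mm,
        peak_velocity_mm_s=protocol.peak_velocity_mm_s,
        peak_accel_mm_s2=protocol.peak_accel_mm_s2,
        ramp_end_time_s=prof.ramp_end_time_s,
        hold_end_time_s=prof.hold_end_time_s)
    channels = build_channels(shell, config)
    params = truth.params()
    if truth.competing:
        pred = competing_predict(params, channels,
                                 rectify_order=config.rectify_order,
                                 threshold=config.competing_threshold)
    else:
        pred = predict_grid(params, channels, config.rectify_order)
    rate = np.maximum(pred, truth.rate_floor)
    spikes = generate_spikes(prof.t, rate, truth.spike_mode, seed)
    return replace(shell, spike_times=spikes)


def make_dataset(n_afferents: int = 1, trials_per_afferent: int = 104,
                 truths: Optional[Sequence[GroundTruthSpindle]] = None,
                 seed: int = 0, history: bool = True,
                 force_params: Optional[MuscleForceParams] = None,
                 protocols: Optional[Sequence[StretchProtocol]] = None,
                 config: RunConfig = DEFAULT_CONFIG,
                 fs: float = 2000.0) -> SyntheticDataset:
    """Reproducible multi-afferent synthetic dataset.

    Trials cycle through the protocol grid; the same master seed always
    regenerates the identical dataset.  ``history=False`` switches the
    force model to its purely elastic variant (no short-range stiffness,
    no relaxation, no thixotropy).
    """
    if trials_per_afferent < 1:
        raise InvalidInput("trials_per_afferent must be >= 1")
    if force_params is None:
        force_params = MuscleForceParams()
    if not history:
        force_params = force_params.without_history()
    if truths is None:
        truths = [default_truth("FORCE") for _ in range(n_afferents)]
    if len(truths) != n_afferents:
        raise InvalidInput("need one ground truth per afferent")
    grid = list(protocols) if protocols is not None else default_protocol_grid(fs)
    rng = np.random.default_rng(seed)
    afferents: dict = {}
    truth_map: dict = {}
    proto_map: dict = {}
    for ai in range(n_afferents):
        aff_id = f"syn{ai + 1:02d}"
        truth = truths[ai]
        trials = []
        plist = []
        for ti in range(trials_per_afferent):
            proto = grid[ti % len(grid)]
            spike_seed = int(rng.integers(0, 2 ** 31 - 1))
            trials.append(make_trial(
                proto, truth, force_params,
                trial_id=f"{aff_id}_t{ti + 1:03d}", afferent_id=aff_id,
                seed=spike_seed, config=config))
            plist.append(proto)
        afferents[aff_id] = trials
        truth_map[aff_id] = truth
        proto_map[aff_id] = plist
    return SyntheticDataset(afferents=afferents, truths=truth_map,
                            protocols=proto_map, force_params=force_params,
                            seed=seed)
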