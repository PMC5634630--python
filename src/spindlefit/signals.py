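"""Trial data model and signal conditioning.

A :class:`TrialRecord` holds one stretch perturbation: musculotendon length
(mm) and force (N) sampled at ``fs`` (2 kHz in the study conditions), the
afferent's spike times (s), and stretch metadata.  From it we derive
instantaneous firing rates (IFR, the reciprocal inter-spike interval assigned
at the later spike of each pair), filtered kinematic/kinetic channels, and the
lag-shifted predictor channels used by the encoding models.

Conventions pinned here:

* derivatives are second-order central differences (``numpy.gradient``),
  computed after filtering the parent channel and then filtered at their own
  cutoff;
* low-pass filtering is a 4th-order Butterworth applied forward-backward
  (zero phase) so that all latency is absorbed by the model lag parameter;
* lag shifting delays a channel by an integer number of samples, holding the
  first value over the leading gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _sig

from .config import DEFAULT_CUTOFFS
from .exceptions import InvalidInput

__all__ = [
    "TrialRecord",
    "IFRSeries",
    "DerivedChannels",
    "compute_ifr",
    "differentiate",
    "lowpass",
    "lag_shift",
    "trial_qc",
    "afferent_qc",
    "derive_channels",
]


# --------------------------------------------------------------------- types
@dataclass
class TrialRecord:
    """One stretch trial: synchronized length/force series plus spikes."""

    trial_id: str
    afferent_id: str
    fs: float
    t: np.ndarray            # s, strictly increasing, spacing 1/fs
    length: np.ndarray       # mm, musculotendon length change
    force: np.ndarray        # N, musculotendon force
    spike_times: np.ndarray  # s, sorted, within [t[0], t[-1]]
    stretch_type: str = "ramp_hold_release"   # or "sawtooth"
    peak_length_mm: float = float("nan")
    peak_velocity_mm_s: float = float("nan")
    peak_accel_mm_s2: float = float("nan")
    ramp_end_time_s: float = float("nan")
    hold_end_time_s: float = float("nan")
    exclude: bool = False    # manual exclusion flag (visual-SNR surrogate)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.fs <= 0:
            raise InvalidInput("fs must be positive")
        if self.t.ndim != 1 or self.t.size < 2:
            raise InvalidInput("time vector must be 1-D with >= 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InvalidInput("time vector must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise InvalidInput("time spacing inconsistent with fs")
        if self.length.shape != self.t.shape or self.force.shape != self.t.shape:
            raise InvalidInput("length/force must match the time vector")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise InvalidInput("spike times must be sorted")
            if (self.spike_times[0] < self.t[0] - 1e-12
                    or self.spike_times[-1] > self.t[-1] + 1e-12):
                raise InvalidInput("spike times outside the trial span")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class IFRSeries:
    """Instantaneous firing rate samples (imp/s) stamped at spike times."""

    times: np.ndarray
    rates: np.ndarray

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class DerivedChannels:
    """Named predictor channels on the trial's time grid.

    ``channels`` maps channel name -> array aligned with ``t``; ``cutoffs``
    records the low-pass cutoff (Hz) actually applied to each channel (None
    for unfiltered channels).
    """

    t: np.ndarray
    fs: float
    channels: dict = field(default_factory=dict)
    cutoffs: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def names(self) -> list:
        return list(self.channels)

    def add(self, name: str, x: np.ndarray, cutoff_hz: Optional[float]) -> None:
        x = np.asarray(x, dtype=float)
        if x.shape != self.t.shape:
            raise InvalidInput(f"channel {name!r} length mismatch")
        self.channels[name] = x
        self.cutoffs[name] = cutoff_hz


# ---------------------------------------------------------------- operations
def compute_ifr(spike_times: np.ndarray) -> IFRSeries:
    """IFR = 1/ISI, assigned at the later spike of each interval.

    Fewer than two spikes yield an empty series; duplicate spike times are
    rejected because they would imply an infinite rate.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 2:
        return IFRSeries(times=np.empty(0), rates=np.empty(0))
    isi = np.diff(st)
    if np.any(isi < 0):
        raise InvalidInput("spike times must be sorted")
    if np.any(isi == 0):
        raise InvalidInput("duplicate spike times")
    return IFRSeries(times=st[1:].copy(), rates=1.0 / isi)


def differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    """Time derivative: central differences interior, one-sided at the ends."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidInput("differentiate needs >= 3 samples")
    return np.gradient(x) * fs


def lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (unit DC gain)."""
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise InvalidInput("cutoff must lie in (0, Nyquist)")
    sos = _sig.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def lag_shift(x: np.ndarray, lambda_ms: float, fs: float) -> np.ndarray:
    """Return x(t - lambda) on the original grid, holding the first value.

    The shift must land on an integer number of samples (e.g. 1 ms at 2 kHz
    is exactly 2 samples).
    """
    x = np.asarray(x, dtype=float)
    n_float = lambda_ms * fs / 1000.0
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise InvalidInput(
            f"lag {lambda_ms} ms is not an integer number of samples at fs={fs}")
    if n < 0:
        raise InvalidInput("negative lags are not supported")
    if n == 0:
        return x.copy()
    out = np.empty_like(x)
    out[:n] = x[0]
    out[n:] = x[:-n]
    return out


def trial_qc(trial: TrialRecord, min_spikes: int = 50) -> tuple[bool, str]:
    """Inclusion rule: >= ``min_spikes`` recorded spikes and no manual flag."""
    if trial.exclude:
        return False, "excluded by flag"
    if trial.n_spikes < min_spikes:
        return False, f"only {trial.n_spikes} spikes (< {min_spikes})"
    return True, "ok"


def afferent_qc(trials: list[TrialRecord], min_trials: int = 40,
                min_spikes: int = 50) -> tuple[bool, str]:
    """Afferent inclusion: >= ``min_trials`` QC-passing trials."""
    if not trials:
        raise InvalidInput("afferent_qc: empty trial list")
    aff = {tr.afferent_id for tr in trials}
    if len(aff) != 1:
        raise InvalidInput("afferent_qc: trials from multiple afferents")
    n_pass = sum(trial_qc(tr, min_spikes)[0] for tr in trials)
    if n_pass < min_trials:
        return False, f"only {n_pass} passing trials (< {min_trials})"
    return True, "ok"


def passing_trials(trials: list[TrialRecord], min_spikes: int = 50
                   ) -> list[TrialRecord]:
    return [tr for tr in trials if trial_qc(tr, min_spikes)[0]]


def derive_channels(trial: TrialRecord, cutoffs: Optional[dict] = None
                    ) -> DerivedChannels:
    """Build the musculotendon predictor channels for one trial.

    Channels: ``length`` (unfiltered), ``velocity`` and ``acceleration``
    (successive derivatives, each filtered at its cutoff), ``force``
    (filtered) and ``dFdt`` (derivative of the filtered force, filtered at
    its own cutoff).
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    ch = DerivedChannels(t=trial.t, fs=trial.fs)
    ch.add("length", trial.length, None)
    vel = lowpass(differentiate(trial.length, trial.fs), cut["velocity"], trial.fs)
    ch.add("velocity", vel, cut["velocity"])
    acc = lowpass(differentiate(vel, trial.fs), cut["acceleration"], trial.fs)
    ch.add("acceleration", acc, cut["acceleration"])
    force = lowpass(trial.force, cut["force"], trial.fs)
    ch.add("force", force, cut["force"])
    dfdt = lowpass(differentiate(force, trial.fs), cut["dFdt"], trial.fs)
    ch.add("dFdt", dfdt, cut["dFdt"])
    return ch
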