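"""Classical spindle characterisation: dynamic index and initial burst.

Dynamic index (DI) is the peak IFR at the end of the ramp phase minus the
IFR measured 0.5 s into the hold; trials are binned by peak stretch
velocity into five 10 mm/s bins over 0-50 mm/s.  The initial burst is the
transient high-frequency spiking at stretch onset after an isometric rest;
its amplitude (IBA, peak IFR in the onset window) is regressed on the
preceding peaks of dF/dt and of acceleration by ordinary least squares.

Window conventions (the source data never pin them; all overridable):

* onset window = stretch onset to the first zero-crossing of acceleration
  after onset (the end of the initial acceleration transient);
* "IFR at 0.5 s after ramp end" = the rate of the last spike at or before
  that instant;
* "peak IFR at ramp end" = maximum IFR within 50 ms before to 5 ms after
  the ramp end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .config import RunConfig, DEFAULT_CONFIG
from .exceptions import DegenerateTarget, InvalidInput, SpindleError
from .signals import (DerivedChannels, IFRSeries, TrialRecord, compute_ifr,
                      derive_channels)

__all__ = ["DynamicIndexResult", "InitialBurstResult", "dynamic_index",
           "detect_initial_burst", "iba_regression", "velocity_bin_label"]

VELOCITY_BIN_EDGES = np.arange(0.0, 60.0, 10.0)  # five 10 mm/s bins, 0-50
MIN_REGRESSION_TRIALS = 12


class NotComputable(SpindleError, ValueError):
    """Metric undefined for this trial (e.g. hold shorter than 0.5 s)."""


def velocity_bin_label(peak_velocity_mm_s: float) -> str:
    v = float(peak_velocity_mm_s)
    if not 0.0 <= v <= 50.0:
        raise InvalidInput("peak velocity outside 0-50 mm/s binning range")
    lo = min(int(v // 10) * 10, 40)
    return f"{lo}-{lo + 10}"


@dataclass
class DynamicIndexResult:
    di: float                  # imp/s
    peak_ifr_ramp_end: float   # imp/s
    ifr_at_hold: float         # imp/s
    velocity_bin: str


@dataclass
class InitialBurstResult:
    iba: float                 # imp/s, peak IFR in the onset window
    peak_dFdt: float           # N/s
    peak_accel: float          # mm/s^2
    window: tuple              # (t_onset, t_end) of the detection window, s
    has_burst_spikes: bool


def dynamic_index(trial: TrialRecord, ifr: Optional[IFRSeries] = None,
                  peak_window_s: float = 0.050,
                  hold_offset_s: float = 0.5) -> DynamicIndexResult:
    """DI = peak IFR at ramp end minus the rate ``hold_offset_s`` later."""
    if trial.stretch_type != "ramp_hold_release":
        raise NotComputable("dynamic index needs a ramp-hold-release trial")
    t_ramp_end = trial.ramp_end_time_s
    if not np.isfinite(t_ramp_end):
        raise NotComputable("ramp end time unknown")
    t_hold = t_ramp_end + hold_offset_s
    hold_end = trial.hold_end_time_s
    if np.isfinite(hold_end) and hold_end < t_hold - 1e-9:
        raise NotComputable("hold phase shorter than the 0.5 s DI offset")
    if t_hold > trial.t[-1]:
        raise NotComputable("trial ends before the 0.5 s DI measurement")
    if ifr is None:
        ifr = compute_ifr(trial.spike_times)
    if len(ifr) == 0:
        raise NotComputable("no IFR samples")
    in_peak = ((ifr.times >= t_ramp_end - peak_window_s)
               & (ifr.times <= t_ramp_end + 0.005))
    if not np.any(in_peak):
        raise NotComputable("no spikes near the ramp end")
    peak = float(ifr.rates[in_peak].max())
    before_hold = ifr.times <= t_hold + 1e-12
    if not np.any(before_hold):
        raise NotComputable("no spikes before the hold measurement point")
    at_hold = float(ifr.rates[np.flatnonzero(before_hold)[-1]])
    return DynamicIndexResult(
        di=peak - at_hold, peak_ifr_ramp_end=peak, ifr_at_hold=at_hold,
        velocity_bin=velocity_bin_label(trial.peak_velocity_mm_s))


def detect_initial_burst(trial: TrialRecord,
                         ifr: Optional[IFRSeries] = None,
                         channels: Optional[DerivedChannels] = None,
                         config: RunConfig = DEFAULT_CONFIG,
                         accel_threshold: Optional[float] = None
                         ) -> InitialBurstResult:
    """Initial-burst amplitude and the paired channel peaks at onset.

    The window runs from stretch onset (acceleration first exceeding a
    threshold, default 2% of its maximum) to the first acceleration
    zero-crossing after onset; detection never extends to the release
    transient.  If no spikes fall inside the window, iba = 0 with a flag.
    """
    if channels is None:
        channels = derive_channels(trial, config.cutoffs_hz)
    acc = channels["acceleration"]
    dfdt = channels["dFdt"]
    t = channels.t
    if accel_threshold is None:
        accel_threshold = 0.05 * float(acc.max())
    above = np.flatnonzero(acc > accel_threshold)
    if above.size == 0:
        raise NotComputable("no stretch onset found in acceleration channel")
    i_on = int(above[0])
    # end of the onset transient: first zero-crossing after the transient's
    # peak (not after the first threshold crossing, which filter ripple can
    # cut short)
    i_stop = above[np.flatnonzero(np.diff(above) > 1)]
    i_peak = i_on + int(np.argmax(acc[i_on:int(i_stop[0]) + 1] if i_stop.size
                                  else acc[i_on:]))
    after = np.flatnonzero(acc[i_peak:] <= 0.0)
    i_end = int(i_peak + after[0]) if after.size else acc.size - 1
    t_on, t_end = float(t[i_on]), float(t[i_end])
    if ifr is None:
        ifr = compute_ifr(trial.spike_times)
    in_win = (ifr.times >= t_on) & (ifr.times <= t_end)
    if np.any(in_win):
        iba = float(ifr.rates[in_win].max())
        has = True
    else:
        iba, has = 0.0, False
    sl = slice(i_on, i_end + 1)
    return InitialBurstResult(
        iba=iba, peak_dFdt=float(dfdt[sl].max()),
        peak_accel=float(acc[sl].max()), window=(t_on, t_end),
        has_burst_spikes=has)


def iba_regression(iba: Sequence[float], predictor_peaks: Sequence[float],
                   min_points: int = MIN_REGRESSION_TRIALS
                   ) -> tuple[float, float, float, float]:
    """OLS of burst amplitude on a channel peak: (slope, intercept, r2, p).

    Requires at least ``min_points`` paired trials; the p-value is the
    two-sided t-test on the slope.
    """
    y = np.asarray(iba, dtype=float)
    x = np.asarray(predictor_peaks, dtype=float)
    if y.shape != x.shape:
        raise InvalidInput("iba and predictor peaks must pair one-to-one")
    if y.size < min_points:
        raise InvalidInput(
            f"regression needs >= {min_points} trials, got {y.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateTarget("predictor peaks have zero variance")
    res = _stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))
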