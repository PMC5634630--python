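"""Exponential series-elastic tendon and fascicle channel estimation.

The Achilles tendon is modelled in series with the muscle fascicles, with
stiffness rising linearly with force, dF/dl = c * F.  Integrating gives the
elongation at force F relative to the reference (resting) tension f_ref:

    dl(F) = (1/c) * ln(F / f_ref)   for F >= f_ref, else 0.

``c`` is the stiffness constant in mm^-1; the study conditions bracket it
with c = 2 (compliant) and c = 6 (stiff).  Fascicle length is musculotendon
length minus tendon elongation; fascicle velocity and acceleration follow by
numerical differentiation with the same cutoffs as the musculotendon
channels.  Pinnation is ignored (a constant pinnation angle only rescales
the channels, which the model weights absorb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULT_CUTOFFS
from .exceptions import InvalidInput
from .signals import DerivedChannels, TrialRecord, differentiate, lowpass

__all__ = ["TendonModel", "tendon_elongation", "fascicle_channels",
           "add_fascicle_channels"]


@dataclass(frozen=True)
class TendonModel:
    """Exponential elastic tendon: stiffness = compliance_c * force."""

    compliance_c: float        # mm^-1
    f_ref: float = 0.1         # N, force at which elongation is zero

    def __post_init__(self) -> None:
        if self.compliance_c <= 0:
            raise InvalidInput("compliance_c must be positive")
        if self.f_ref <= 0:
            raise InvalidInput("f_ref must be positive")


def tendon_elongation(force: np.ndarray, model: TendonModel) -> np.ndarray:
    """Tendon elongation (mm) under the given force trace (N).

    Below ``f_ref`` the tendon is treated as slack (zero elongation);
    non-positive force samples are clamped to ``f_ref`` with a warning.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        warnings.warn("non-positive force samples clamped to f_ref",
                      RuntimeWarning, stacklevel=2)
        f = np.maximum(f, model.f_ref)
    out = np.log(np.maximum(f, model.f_ref) / model.f_ref) / model.compliance_c
    return out


def fascicle_channels(trial: TrialRecord, model: TendonModel,
                      cutoffs: Optional[dict] = None,
                      force_filtered: Optional[np.ndarray] = None
                      ) -> DerivedChannels:
    """Estimate fascicle length/velocity/acceleration for one trial.

    ``force_filtered`` lets the caller reuse an already low-passed force
    trace; otherwise the raw trial force is filtered at the force cutoff.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    if force_filtered is None:
        force_filtered = lowpass(trial.force, cut["force"], trial.fs)
    dl = tendon_elongation(force_filtered, model)
    ch = DerivedChannels(t=trial.t, fs=trial.fs)
    l_fasc = trial.length - dl
    ch.add("fasc_length", l_fasc, None)
    vel = lowpass(differentiate(l_fasc, trial.fs), cut["velocity"], trial.fs)
    ch.add("fasc_velocity", vel, cut["velocity"])
    acc = lowpass(differentiate(vel, trial.fs), cut["acceleration"], trial.fs)
    ch.add("fasc_acceleration", acc, cut["acceleration"])
    return ch


def add_fascicle_channels(channels: DerivedChannels, trial: TrialRecord,
                          model: TendonModel, prefix: str,
                          cutoffs: Optional[dict] = None) -> None:
    """Attach fascicle channels under ``<prefix>_length`` etc. (in place)."""
    fch = fascicle_channels(trial, model, cutoffs,
                            force_filtered=channels["force"]
                            if "force" in channels else None)
    for name in ("length", "velocity", "acceleration"):
        channels.add(f"{prefix}_{name}", fch[f"fasc_{name}"],
                     fch.cutoffs[f"fasc_{name}"])
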