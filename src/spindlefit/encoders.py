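"""The six pseudolinear candidate encoding models.

Each model predicts the instantaneous firing rate as a lagged, rectified,
weighted sum of muscle mechanical channels:

    IFR(t) = sum_i  k_i * g(x_i(t - lambda), b_i)

where the rectification g comes in two pinned orders:

* ``threshold`` (default): g = max(x + b, 0) -- the offset acts as a
  threshold below which the channel contributes nothing;
* ``as_printed``: g = max(x, 0) + b -- rectify first, then offset.

The final predicted rate is floored at zero.  The candidate set:

========  ===========================================================
FORCE           whole-muscle force and dF/dt (optionally "competing")
LENGTH          musculotendon length, velocity, acceleration
LENGTH_POWER    as LENGTH with velocity raised to a fractional power a
FASCICLE_LOW    fascicle L/V/A with the compliant tendon (c = 2 mm^-1)
FASCICLE_HIGH   fascicle L/V/A with the stiff tendon (c = 6 mm^-1)
ALL             all 11 predictors pooled
========  ===========================================================

The FORCE model's competing variant treats force and dF/dt as competing
influences: wherever both components are simultaneously significant, the
smaller-magnitude one is iteratively zeroed before summation (ties keep the
force component, the carrier of the tonic rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .exceptions import ConfigurationError, InvalidInput
from .signals import DerivedChannels, TrialRecord, derive_channels, lag_shift
from .tendon import TendonModel, add_fascicle_channels

__all__ = [
    "ModelSpec", "ModelParams", "MODEL_SPECS", "MODEL_ORDER",
    "build_channels", "predictor_matrix", "predict_grid", "predict_ifr",
    "competing_components", "competing_predict", "choose_competing",
]


MT_CHANNELS = ("length", "velocity", "acceleration")
FASC_LOW = ("fasc_low_length", "fasc_low_velocity", "fasc_low_acceleration")
FASC_HIGH = ("fasc_high_length", "fasc_high_velocity", "fasc_high_acceleration")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: predictor set plus structural options."""

    model_id: str
    predictors: tuple
    power_velocity: bool = False      # LENGTH_POWER: velocity -> relu(v)^a
    competing_allowed: bool = False   # FORCE only

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def n_params(self) -> int:
        """Estimable parameters: one weight + one offset per predictor,
        plus the exponent for the fractional-power model.  The lag is
        frozen before cross-validation and not counted."""
        return 2 * self.n_predictors + (1 if self.power_velocity else 0)


MODEL_SPECS: dict[str, ModelSpec] = {
    "FORCE": ModelSpec("FORCE", ("force", "dFdt"), competing_allowed=True),
    "LENGTH": ModelSpec("LENGTH", MT_CHANNELS),
    "LENGTH_POWER": ModelSpec("LENGTH_POWER", MT_CHANNELS, power_velocity=True),
    "FASCICLE_LOW": ModelSpec("FASCICLE_LOW", FASC_LOW),
    "FASCICLE_HIGH": ModelSpec("FASCICLE_HIGH", FASC_HIGH),
    "ALL": ModelSpec("ALL", ("force", "dFdt") + MT_CHANNELS + FASC_LOW + FASC_HIGH),
}

#: fixed evaluation/tie-break order
MODEL_ORDER = ("FORCE", "LENGTH", "LENGTH_POWER",
               "FASCICLE_LOW", "FASCICLE_HIGH", "ALL")

assert MODEL_SPECS["ALL"].n_predictors == 11


@dataclass
class ModelParams:
    """Fitted (or ground-truth) parameters of a candidate model."""

    model_id: str
    k: np.ndarray             # weight per predictor, imp/s per channel unit
    b: np.ndarray             # offset per predictor, channel units
    lambda_ms: int = 0        # shared lag, integer ms in [0, 15]
    a: Optional[float] = None  # velocity exponent (LENGTH_POWER only)

    def __post_init__(self) -> None:
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        spec = MODEL_SPECS[self.model_id]
        if self.k.size != spec.n_predictors or self.b.size != spec.n_predictors:
            raise InvalidInput(
                f"{self.model_id} expects {spec.n_predictors} weights/offsets")
        if spec.power_velocity:
            if self.a is None:
                raise InvalidInput("LENGTH_POWER requires exponent a")
            if not 0.1 <= self.a <= 1.0:
                raise InvalidInput("exponent a must lie in [0.1, 1]")

    @property
    def spec(self) -> ModelSpec:
        return MODEL_SPECS[self.model_id]


# ----------------------------------------------------------------- channels
def build_channels(trial: TrialRecord, config: RunConfig = DEFAULT_CONFIG
                   ) -> DerivedChannels:
    """All 11 predictor channels for one trial (musculotendon + fascicle)."""
    ch = derive_channels(trial, config.cutoffs_hz)
    low = TendonModel(config.tendon_c_low_stiffness, config.tendon_f_ref_n)
    high = TendonModel(config.tendon_c_high_stiffness, config.tendon_f_ref_n)
    add_fascicle_channels(ch, trial, low, "fasc_low", config.cutoffs_hz)
    add_fascicle_channels(ch, trial, high, "fasc_high", config.cutoffs_hz)
    return ch


def predictor_matrix(spec: ModelSpec, channels: DerivedChannels,
                     lambda_ms: float, a: Optional[float] = None
                     ) -> np.ndarray:
    """Stack the model's lag-shifted predictors as columns (n_samples x p).

    For the fractional-power model the velocity column is rectified and
    raised to ``a`` before use.
    """
    cols = []
    for name in spec.predictors:
        if name not in channels:
            raise ConfigurationError(f"unknown predictor channel {name!r}")
        x = lag_shift(channels[name], lambda_ms, channels.fs)
        if spec.power_velocity and name == "velocity":
            if a is None:
                raise InvalidInput("power model evaluated without exponent a")
            x = np.maximum(x, 0.0) ** a
        cols.append(x)
    return np.column_stack(cols)


def _components(X: np.ndarray, k: np.ndarray, b: np.ndarray,
                rectify_order: str) -> np.ndarray:
    if rectify_order == "threshold":
        return k * np.maximum(X + b, 0.0)
    if rectify_order == "as_printed":
        return k * (np.maximum(X, 0.0) + b)
    raise ConfigurationError(f"rectify_order: {rectify_order!r}")


def predict_grid(params: ModelParams, channels: DerivedChannels,
                 rectify_order: str = "threshold") -> np.ndarray:
    """Predicted rate on the trial grid, floored at 0 imp/s."""
    X = predictor_matrix(params.spec, channels, params.lambda_ms, params.a)
    comp = _components(X, params.k, params.b, rectify_order)
    return np.maximum(comp.sum(axis=1), 0.0)


def predict_ifr(params: ModelParams, channels: DerivedChannels,
                t_eval: np.ndarray, rectify_order: str = "threshold"
                ) -> np.ndarray:
    """Predicted rate at arbitrary times (linear interpolation on the grid)."""
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval.min() < channels.t[0] - 1e-12
                        or t_eval.max() > channels.t[-1] + 1e-12):
        raise InvalidInput("evaluation times outside channel coverage")
    grid = predict_grid(params, channels, rectify_order)
    return np.interp(t_eval, channels.t, grid)


# ---------------------------------------------------------------- competing
def competing_components(comp_force: np.ndarray, comp_dfdt: np.ndarray,
                         threshold: float = 0.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the competing rule to the two FORCE-model component traces.

    Wherever both components exceed ``threshold`` simultaneously, the
    smaller-magnitude one is set to zero; the process iterates to a fixed
    point (one pass suffices, but convergence is checked).  Ties keep the
    force component.
    """
    c1 = np.array(comp_force, dtype=float, copy=True)
    c2 = np.array(comp_dfdt, dtype=float, copy=True)
    for _ in range(8):
        both = (c1 > threshold) & (c2 > threshold)
        if not np.any(both):
            break
        drop_force = both & (np.abs(c1) < np.abs(c2))
        drop_dfdt = both & ~drop_force  # ties resolved toward keeping force
        c1[drop_force] = 0.0
        c2[drop_dfdt] = 0.0
    return c1, c2


def competing_predict(params: ModelParams, channels: DerivedChannels,
                      t_eval: Optional[np.ndarray] = None,
                      rectify_order: str = "threshold",
                      threshold: float = 0.0) -> np.ndarray:
    """FORCE-model prediction with force/dF-dt treated as competing inputs."""
    if not params.spec.competing_allowed:
        raise ConfigurationError(
            f"competing variant undefined for model {params.model_id}")
    X = predictor_matrix(params.spec, channels, params.lambda_ms)
    comp = _components(X, params.k, params.b, rectify_order)
    c1, c2 = competing_components(comp[:, 0], comp[:, 1], threshold)
    grid = np.maximum(c1 + c2, 0.0)
    if t_eval is None:
        return grid
    return np.interp(np.asarray(t_eval, dtype=float), channels.t, grid)


def choose_competing(mean_r2_plain: float, mean_r2_competing: float) -> str:
    """Pick the FORCE variant: 'competing' only on a strict R^2 improvement."""
    return "competing" if mean_r2_competing > mean_r2_plain else "plain"
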