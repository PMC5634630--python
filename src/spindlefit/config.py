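"""Run configuration.

All analysis constants live here with the values used throughout: low-pass
cutoffs (velocity 40 Hz, acceleration 40 Hz, force 50 Hz, dF/dt 100 Hz), the
0-15 ms lag grid, the ~75/25 cross-validation split repeated 100 times, the
two series-tendon stiffness constants (2 and 6 mm^-1) with a 0.1 N reference
tension, and the switches for the rectification order and AICc form.

The config round-trips losslessly through a flat TOML file (sections map to
the dataclass fields); CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import InvalidInput

#: channel -> low-pass cutoff in Hz (length is left unfiltered)
DEFAULT_CUTOFFS = {
    "velocity": 40.0,
    "acceleration": 40.0,
    "force": 50.0,
    "dFdt": 100.0,
}


@dataclass
class RunConfig:
    """Pipeline-wide tunables.  Defaults follow the study conditions."""

    # signal conditioning
    cutoffs_hz: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    # lag sweep (ms), inclusive bounds, 1 ms step -> 16 candidate lags
    lag_min_ms: int = 0
    lag_max_ms: int = 15
    lag_step_ms: int = 1
    # cross-validation
    cv_n_iter: int = 100
    cv_train_frac: float = 0.75
    # series-elastic tendon
    tendon_c_low_stiffness: float = 2.0   # mm^-1, compliant bound
    tendon_c_high_stiffness: float = 6.0  # mm^-1, stiff bound
    tendon_f_ref_n: float = 0.1           # N, resting tension reference
    # model evaluation
    rectify_order: str = "threshold"      # {"threshold", "as_printed"}
    competing_threshold: float = 0.0      # component significance level, imp/s
    power_a_min: float = 0.1
    power_a_max: float = 1.0
    power_a_step: float = 0.05
    # model selection
    aicc_form: str = "standard"           # {"standard", "as_printed"}
    # test-set costs below this are "numerically converged": the likelihood
    # proxy L = 1/J is capped so optimizer noise among exact fits cannot
    # drive selection (the parameter penalty decides instead)
    likelihood_j_floor: float = 1e-6
    # exploratory (lag/bounds) phase
    explore_n_trials: int = 12
    bound_multiplier: float = 3.0         # weight bound = multiplier * max k-hat
    # inclusion rules
    min_spikes_per_trial: int = 50
    min_trials_per_afferent: int = 40

    def lag_grid_ms(self) -> list[int]:
        return list(range(self.lag_min_ms, self.lag_max_ms + 1, self.lag_step_ms))

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInput(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key != "cutoffs_hz":
                flat.update(val)
            else:
                flat[key] = val
        return cls.from_dict(flat)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if isinstance(val, dict):
                lines.append(f"[{f.name}]")
                for k, v in val.items():
                    lines.append(f"{k} = {v}")
                lines.append("")
            elif isinstance(val, str):
                lines.append(f'{f.name} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{f.name} = {str(val).lower()}")
            else:
                lines.append(f"{f.name} = {val}")
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        """Short stable hash of the effective configuration (for run logs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def __post_init__(self) -> None:
        if self.rectify_order not in ("threshold", "as_printed"):
            raise InvalidInput(f"rectify_order: {self.rectify_order!r}")
        if self.aicc_form not in ("standard", "as_printed"):
            raise InvalidInput(f"aicc_form: {self.aicc_form!r}")
        if not 0.0 < self.cv_train_frac < 1.0:
            raise InvalidInput("cv_train_frac must be in (0, 1)")


DEFAULT_CONFIG = RunConfig()
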