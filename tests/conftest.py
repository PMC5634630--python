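"""Shared fixtures: small synthetic datasets with known ground truth.

Heavy end-to-end artifacts (the two full cross-validation runs, the
parameter-recovery dataset) are session-scoped so that every test reuses
one generation + fit.
"""

import warnings

import numpy as np
import pytest

from spindlefit.config import RunConfig
from spindlefit.selection import CandidateSelection
from spindlefit.simulate import (GroundTruthSpindle, MuscleForceParams,
                                 StretchProtocol, default_protocol_grid,
                                 default_truth, make_dataset, make_trial)

# tendon clamp warnings from slack-force samples are expected in synthesis
warnings.filterwarnings("ignore", message="non-positive force samples")


@pytest.fixture(scope="session")
def force_params():
    return MuscleForceParams()


@pytest.fixture(scope="session")
def ramp_trial(force_params):
    """One ramp-hold-release trial from a FORCE-truth encoder (exact IFR)."""
    truth = default_truth("FORCE", spike_mode="isi_consistent")
    proto = StretchProtocol("ramp_hold_release", 3.0, 20.0, 1400.0)
    return make_trial(proto, truth, force_params, "ramp01", "affA", seed=0)


@pytest.fixture(scope="session")
def small_force_trials(force_params):
    """Eight mixed-protocol trials from the FORCE-truth encoder."""
    truth = default_truth("FORCE", spike_mode="isi_consistent")
    grid = default_protocol_grid()
    return [make_trial(grid[i % len(grid)], truth, force_params,
                       f"sf{i:02d}", "affA") for i in range(8)]


@pytest.fixture(scope="session")
def recovery_truth():
    return default_truth("FORCE", spike_mode="isi_consistent", lambda_ms=10)


@pytest.fixture(scope="session")
def recovery_trials(recovery_truth):
    """Twenty noiseless trials for exact parameter recovery."""
    ds = make_dataset(1, 20, [recovery_truth], seed=3)
    return ds.afferents["syn01"]


@pytest.fixture(scope="session")
def poisson_recovery_trials(recovery_truth):
    """Twenty Poisson-jittered trials from the same ground truth."""
    import dataclasses
    truth = dataclasses.replace(recovery_truth, spike_mode="poisson_jittered")
    ds = make_dataset(1, 20, [truth], seed=4)
    return ds.afferents["syn01"]


def _run_selection(model_id, history, seed, cv_seed):
    truth = default_truth(model_id, spike_mode="isi_consistent")
    ds = make_dataset(1, 104, [truth], seed=seed, history=history)
    sel = CandidateSelection(ds.afferents["syn01"])
    return sel.fit(n_iter=100, seed=cv_seed), truth


@pytest.fixture(scope="session")
def force_truth_selection():
    """Full 100-iteration CV on a FORCE-truth afferent (history on)."""
    return _run_selection("FORCE", history=True, seed=7, cv_seed=1)


@pytest.fixture(scope="session")
def length_truth_selection():
    """Full 100-iteration CV on a LENGTH-truth afferent (history off)."""
    return _run_selection("LENGTH", history=False, seed=11, cv_seed=2)


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
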