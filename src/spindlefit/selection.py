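"""Cross-validated model selection with AICc and Akaike weights.

For one afferent the procedure is:

1. exploratory per-trial fits on a deterministic subset sweep the 0-15 ms
   lag grid for each candidate model; per-trial best lags are averaged into
   a single frozen lag per model, and the fitted weights set the parameter
   search limits for cross-validation;
2. the QC-passing trials are split at random into ~75% training / ~25% test
   sets (stratified by stretch type, rounding toward train), 100 times;
3. per iteration and model, one pooled parameter set is fitted on the
   training observations and scored on the concatenated test observations
   with J = SSE/SSM; the likelihood proxy is L = 1/J_test and

       AICc_standard   = 2k - 2 ln L + 2 k(k+1)/(n-k-1)
       AICc_as_printed = 2 (k - ln L - k(k+1)/(n-k-1))

   with k the number of fitted weights/offsets (+1 for the velocity
   exponent; the frozen lag is not counted) and n the number of test
   trials.  The as-printed variant reproduces a published formula whose
   small-sample term enters with the opposite sign; the standard form is
   the default (see docs/methods.md);
4. per iteration the winner is the minimum-AICc model (ties break toward
   fewer parameters, then fixed model order); Akaike weights
   w_j = exp(-Delta_j/2) / sum_r exp(-Delta_r/2) summarise relative
   likelihoods.

Population aggregation averages per-afferent mean R^2 and mean AICc without
weighting and recomputes weights from the averaged AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .encoders import MODEL_ORDER, MODEL_SPECS
from .exceptions import InvalidInput, SmallSampleError
from .fitting import (FitResult, ParamBounds, TrialDesign, bounds_from_fits,
                      consolidate_lag, evaluate_params, fit_pooled,
                      make_design, SpindleEncodingModel)
from .signals import TrialRecord, afferent_qc, passing_trials

__all__ = [
    "SplitPlan", "make_splits", "aicc", "akaike_weights",
    "select_per_iteration", "CandidateSelection", "SelectionResults",
    "population_summary",
]


# ------------------------------------------------------------------- splits
@dataclass(frozen=True)
class SplitPlan:
    seed: int
    iteration: int
    train_ids: tuple
    test_ids: tuple


def make_splits(trial_ids: Sequence[str], n_iter: int = 100, seed: int = 0,
                train_frac: float = 0.75,
                stratify: Optional[Sequence[str]] = None,
                min_trials: int = 40) -> list[SplitPlan]:
    """Reproducible random train/test splits, rounding toward train."""
    ids = list(trial_ids)
    if len(set(ids)) != len(ids):
        raise InvalidInput("duplicate trial ids")
    if len(ids) < min_trials:
        raise InvalidInput(f"need >= {min_trials} trials, got {len(ids)}")
    strata: dict[str, list[str]] = {}
    labels = stratify if stratify is not None else ["all"] * len(ids)
    for tid, lab in zip(ids, labels):
        strata.setdefault(lab, []).append(tid)
    rng = np.random.default_rng(seed)
    plans = []
    for it in range(n_iter):
        test: list[str] = []
        for lab in sorted(strata):
            members = strata[lab]
            n_test = int(np.floor((1.0 - train_frac) * len(members)))
            perm = rng.permutation(len(members))
            test.extend(members[j] for j in perm[:n_test])
        if not test:  # guarantee a nonempty test set for tiny strata
            test = [ids[int(rng.integers(len(ids)))]]
        test_set = set(test)
        train = tuple(tid for tid in ids if tid not in test_set)
        test_t = tuple(tid for tid in ids if tid in test_set)
        plans.append(SplitPlan(seed=seed, iteration=it + 1,
                               train_ids=train, test_ids=test_t))
    return plans


# ---------------------------------------------------------------- criteria
def aicc(k_params: int, L_hat: float, n: int, form: str = "standard") -> float:
    """Corrected Akaike information criterion.

    ``form="standard"``: 2k - 2 ln(L) + 2k(k+1)/(n-k-1).
    ``form="as_printed"``: 2(k - ln(L) - k(k+1)/(n-k-1)), the published
    arithmetic with the small-sample term subtracted.
    """
    if L_hat <= 0:
        raise InvalidInput("likelihood proxy must be positive")
    if n <= k_params + 1:
        raise SmallSampleError(
            f"AICc undefined for n={n} <= k+1={k_params + 1}")
    corr = k_params * (k_params + 1) / (n - k_params - 1)
    if form == "as_printed":
        return 2.0 * (k_params - np.log(L_hat) - corr)
    if form == "standard":
        return 2.0 * k_params - 2.0 * np.log(L_hat) + 2.0 * corr
    raise InvalidInput(f"unknown aicc form {form!r}")


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalised relative likelihoods; shift-invariant, summing to one."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 2:
        raise InvalidInput("need at least two AICc values")
    if not np.all(np.isfinite(a)):
        raise InvalidInput("non-finite AICc value")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def _weights_allow_inf(a: np.ndarray) -> np.ndarray:
    """Akaike weights where +inf AICc (unscorable model) gets weight 0."""
    finite = np.isfinite(a)
    w = np.zeros_like(a)
    if finite.any():
        w[finite] = akaike_weights(a[finite]) if finite.sum() > 1 else 1.0
    return w


def select_per_iteration(aicc_by_model: dict[str, float],
                         model_order: Sequence[str] = MODEL_ORDER) -> str:
    """Winner = minimum AICc; ties to fewer parameters, then fixed order."""
    order = [m for m in model_order if m in aicc_by_model]
    if not order:
        raise InvalidInput("no models to select among")
    best = min(aicc_by_model[m] for m in order)
    tied = [m for m in order if aicc_by_model[m] <= best + 1e-12]
    tied.sort(key=lambda m: (MODEL_SPECS[m].n_params, order.index(m)))
    return tied[0]


# ------------------------------------------------------------ orchestration
@dataclass
class SelectionResults:
    """Cross-validation outcome for one afferent."""

    afferent_id: str
    model_ids: tuple
    lags_ms: dict
    r2_test: dict           # model -> array over iterations
    aicc_values: dict       # model -> array over iterations (may hold inf)
    winners: list
    n_test_trials: np.ndarray
    force_variant: str = "plain"
    scope: str = "afferent"

    @property
    def n_iter(self) -> int:
        return len(self.winners)

    @property
    def mean_r2(self) -> dict:
        return {m: float(np.mean(self.r2_test[m])) for m in self.model_ids}

    @property
    def sd_r2(self) -> dict:
        return {m: float(np.std(self.r2_test[m], ddof=1)) for m in self.model_ids}

    @property
    def mean_aicc(self) -> dict:
        return {m: float(np.mean(self.aicc_values[m])) for m in self.model_ids}

    @property
    def weights(self) -> dict:
        a = np.array([self.mean_aicc[m] for m in self.model_ids])
        w = _weights_allow_inf(a)
        return dict(zip(self.model_ids, w.tolist()))

    @property
    def selection_frequency(self) -> dict:
        wins = {m: 0 for m in self.model_ids}
        for w in self.winners:
            wins[w] += 1
        return {m: wins[m] / self.n_iter for m in self.model_ids}

    def table(self) -> pd.DataFrame:
        a = np.array([self.mean_aicc[m] for m in self.model_ids])
        fin = a[np.isfinite(a)]
        delta = a - (fin.min() if fin.size else np.nan)
        df = pd.DataFrame({
            "model": list(self.model_ids),
            "mean_r2": [self.mean_r2[m] for m in self.model_ids],
            "sd_r2": [self.sd_r2[m] for m in self.model_ids],
            "mean_aicc": a,
            "delta_aicc": delta,
            "akaike_weight": [self.weights[m] for m in self.model_ids],
            "selection_frequency": [self.selection_frequency[m]
                                    for m in self.model_ids],
        })
        return df

    def summary(self) -> str:
        head = (f"Candidate-model selection — {self.scope} "
                f"{self.afferent_id} ({self.n_iter} CV iterations)")
        body = self.table().to_string(
            index=False, float_format=lambda v: f"{v:.4f}")
        return head + "\n" + "-" * len(head) + "\n" + body

    def to_dict(self) -> dict:
        return {
            "afferent_id": self.afferent_id,
            "scope": self.scope,
            "n_iter": self.n_iter,
            "force_variant": self.force_variant,
            "lags_ms": {m: int(v) for m, v in self.lags_ms.items()},
            "models": {
                m: {
                    "mean_r2": self.mean_r2[m],
                    "sd_r2": self.sd_r2[m],
                    "mean_aicc": self.mean_aicc[m],
                    "akaike_weight": self.weights[m],
                    "selection_frequency": self.selection_frequency[m],
                } for m in self.model_ids
            },
        }


class CandidateSelection:
    """Run the full lag-sweep + cross-validation comparison on one afferent.

    Parameters
    ----------
    trials : sequence of TrialRecord
        One afferent's trials (QC applied internally).
    models : sequence of str
        Candidate models to compare (default: all six).
    min_trials : int, optional
        Afferent inclusion threshold; defaults to the configured 40.
    """

    def __init__(self, trials: Sequence[TrialRecord],
                 models: Sequence[str] = MODEL_ORDER,
                 config: RunConfig = DEFAULT_CONFIG,
                 min_trials: Optional[int] = None):
        self.config = config
        self.model_ids = tuple(m.upper() for m in models)
        min_trials = (config.min_trials_per_afferent
                      if min_trials is None else min_trials)
        ok, reason = afferent_qc(list(trials), min_trials,
                                 config.min_spikes_per_trial)
        if not ok:
            raise InvalidInput(f"afferent excluded: {reason}")
        self.trials = passing_trials(list(trials), config.min_spikes_per_trial)
        self.afferent_id = self.trials[0].afferent_id
        self.min_trials = min_trials
        self._designs: Optional[list[TrialDesign]] = None

    @property
    def designs(self) -> list[TrialDesign]:
        if self._designs is None:
            self._designs = [make_design(tr, None, self.config)
                             for tr in self.trials]
        return self._designs

    # ------------------------------------------------------------- phases
    def _explore_indices(self) -> np.ndarray:
        n = len(self.trials)
        m = min(self.config.explore_n_trials, n)
        return np.unique(np.linspace(0, n - 1, m).astype(int))

    def explore(self) -> dict:
        """Per-model lag consolidation and bounds from exploratory fits."""
        idx = self._explore_indices()
        helper = SpindleEncodingModel(self.trials, self.model_ids[0],
                                      self.config, drop_failing=False)
        out = {}
        for mid in self.model_ids:
            helper.spec = MODEL_SPECS[mid]
            fits: list[FitResult] = []
            for i in idx:
                fits.append(helper._fit_trial_design(
                    self.designs[i], self.trials[i], self.config))
            lam = consolidate_lag([fr.lag_ms_best for fr in fits])
            bounds = bounds_from_fits(fits, self.designs,
                                      MODEL_SPECS[mid], self.config)
            start = self._start_from_fits(fits, mid)
            out[mid] = {"lag": lam, "bounds": bounds, "start": start,
                        "fits": fits}
        self._add_embedding_start(out)
        return out

    @staticmethod
    def _start_from_fits(fits: list[FitResult], mid: str) -> np.ndarray:
        K = np.vstack([fr.params.k for fr in fits])
        B = np.vstack([fr.params.b for fr in fits])
        return np.concatenate([np.median(K, axis=0), np.median(B, axis=0)])

    def _add_embedding_start(self, explored: dict) -> None:
        """Seed the ALL model with the FORCE/LENGTH exploratory solutions so
        the nested model starts from (at least) their achievable fit."""
        if "ALL" not in explored:
            return
        spec = MODEL_SPECS["ALL"]
        k = np.zeros(spec.n_predictors)
        b = np.zeros(spec.n_predictors)
        for sub in ("FORCE", "LENGTH"):
            if sub not in explored:
                continue
            sub_spec = MODEL_SPECS[sub]
            theta = explored[sub]["start"]
            for j, name in enumerate(sub_spec.predictors):
                i = spec.predictors.index(name)
                k[i] = theta[j]
                b[i] = theta[sub_spec.n_predictors + j]
        explored["ALL"]["embed_start"] = np.concatenate([k, b])

    def fit(self, n_iter: Optional[int] = None, seed: int = 0,
            explored: Optional[dict] = None) -> SelectionResults:
        cfg = self.config
        n_iter = cfg.cv_n_iter if n_iter is None else n_iter
        if explored is None:
            explored = self.explore()
        plans = make_splits([tr.trial_id for tr in self.trials],
                            n_iter=n_iter, seed=seed,
                            train_frac=cfg.cv_train_frac,
                            stratify=[tr.stretch_type for tr in self.trials],
                            min_trials=self.min_trials)
        by_id = {tr.trial_id: d for tr, d in zip(self.trials, self.designs)}
        fs = self.trials[0].fs
        r2_test = {m: np.empty(n_iter) for m in self.model_ids}
        aicc_values = {m: np.empty(n_iter) for m in self.model_ids}
        winners = []
        n_test = np.empty(n_iter, dtype=int)
        warm: dict = {m: None for m in self.model_ids}
        for it, plan in enumerate(plans):
            train = [by_id[t] for t in plan.train_ids]
            test = [by_id[t] for t in plan.test_ids]
            n_test[it] = len(plan.test_ids)
            it_aicc = {}
            for mid in self.model_ids:
                spec = MODEL_SPECS[mid]
                info = explored[mid]
                start = warm[mid]
                if start is None:
                    start = info.get("embed_start", info["start"])
                fr = fit_pooled(spec, self.trials, info["lag"],
                                designs=train, config=cfg,
                                bounds=info["bounds"],
                                extra_start=start,
                                warm_only=it > 0)
                warm[mid] = np.concatenate([fr.params.k, fr.params.b])
                J_test = evaluate_params(fr.params, test, fs, cfg)
                r2_test[mid][it] = 1.0 - J_test
                L_hat = 1.0 / max(J_test, cfg.likelihood_j_floor)
                try:
                    it_aicc[mid] = aicc(spec.n_params, L_hat, n_test[it],
                                        cfg.aicc_form)
                except SmallSampleError:
                    it_aicc[mid] = np.inf
                aicc_values[mid][it] = it_aicc[mid]
            winners.append(select_per_iteration(it_aicc, self.model_ids))
        return SelectionResults(
            afferent_id=self.afferent_id, model_ids=self.model_ids,
            lags_ms={m: explored[m]["lag"] for m in self.model_ids},
            r2_test=r2_test, aicc_values=aicc_values, winners=winners,
            n_test_trials=n_test)


def population_summary(per_afferent: Sequence[SelectionResults]
                       ) -> SelectionResults:
    """Population aggregate: unweighted means of per-afferent mean R^2 and
    mean AICc, weights from the averaged AICc, selection frequency as total
    wins over total iterations."""
    if len(per_afferent) < 1:
        raise InvalidInput("population_summary: no afferents")
    model_ids = per_afferent[0].model_ids
    for res in per_afferent:
        if res.model_ids != model_ids:
            raise InvalidInput("mismatched model sets across afferents")
    r2 = {m: np.array([res.mean_r2[m] for res in per_afferent])
          for m in model_ids}
    aicc_m = {m: np.array([res.mean_aicc[m] for res in per_afferent])
              for m in model_ids}
    winners = [w for res in per_afferent for w in res.winners]
    n_test = np.concatenate([res.n_test_trials for res in per_afferent])
    return SelectionResults(
        afferent_id="population", model_ids=model_ids,
        lags_ms={m: 0 for m in model_ids},
        r2_test=r2, aicc_values=aicc_m, winners=winners,
        n_test_trials=n_test, scope="population")
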