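# Methods

## The scientific question and the model family

Muscle spindle Ia (primary) afferents fire during stretch of passive
(electrically quiescent) muscle with prominent history-dependent
transients: an initial burst at stretch onset after an isometric rest, an
elevated dynamic response during the ramp, and rate relaxation during the
hold.  These transients are not unique functions of muscle length and its
derivatives, but they do track whole-muscle *force* and its first time
derivative, dF/dt, because passive muscle exhibits short-range stiffness
and force relaxation from cross-bridge dynamics.  The package implements
the quantitative form of that comparison: six pseudolinear candidate
models of the instantaneous firing rate (IFR),

    IFR(t) = sum_i  k_i * g( x_i(t - lambda), b_i ),        g = rectification

with candidate predictor sets

| model          | predictors x_i                                | parameters |
|----------------|-----------------------------------------------|-----------|
| FORCE          | whole-muscle force, dF/dt                     | 4         |
| LENGTH         | musculotendon length, velocity, acceleration  | 6         |
| LENGTH_POWER   | as LENGTH, velocity raised to a power a       | 7         |
| FASCICLE_LOW   | fascicle L/V/A, compliant tendon (c = 2 mm⁻¹) | 6         |
| FASCICLE_HIGH  | fascicle L/V/A, stiff tendon (c = 6 mm⁻¹)     | 6         |
| ALL            | all 11 predictors                             | 22        |

fitted per afferent across a library of ramp-hold-release and sawtooth
stretches, and compared by cross-validated AICc with Akaike weights.

## Signal conventions

* IFR is the reciprocal inter-spike interval, stamped at the **later**
  spike of each pair, so that lagged predictors causally precede the rate
  sample they explain.
* Derivatives are second-order central differences, computed after
  low-pass filtering the parent channel and then filtered at their own
  cutoff.  Cutoffs: velocity 40 Hz, acceleration 40 Hz, force 50 Hz,
  dF/dt 100 Hz; length unfiltered; sampling 2 kHz.
* Filtering is a 4th-order Butterworth applied forward-backward (zero
  phase), so all latency is absorbed by the model lag λ.
* Lag shifts move a channel by an integer number of samples; the leading
  gap holds the first value.
* Rectification order.  Two readings of the model equation are
  implemented and pinned by tests: `threshold` (default), where
  g = max(x + b, 0) and the offset acts as a threshold below which a
  channel contributes nothing; and `as_printed`, g = max(x, 0) + b.
  The final predicted rate is floored at 0 imp/s in both.

## Tendon and fascicle estimation

The Achilles tendon is an exponential series-elastic element whose
stiffness grows linearly with force, dF/dl = c·F, giving elongation
Δl(F) = ln(F/f_ref)/c above the resting tension f_ref (default 0.1 N,
the typical resting tension of the preparation), and 0 below it (slack).
Fascicle length is musculotendon length minus Δl; fascicle velocity and
acceleration follow by the same differentiation/filtering scheme.  The
two stiffness constants c = 2 and 6 mm⁻¹ bracket the plausible range.
Pinnation is ignored: a constant pinnation angle rescales the fascicle
channels by a constant, which the fitted weights absorb.

## Fitting

Observations are the IFR samples at spike times; the model is evaluated
on the sample grid and linearly interpolated to those times (the same
composition the synthetic generator uses, so noiseless recovery is exact).
For each candidate lag λ ∈ {0, …, 15} ms the weights and offsets solve a
bounded least-squares problem (`scipy.optimize.least_squares`,
trust-region reflective, analytic Jacobian).  Because k_i·g(x_i, b_i) has
a near-degenerate ridge (k_i·b_i trades against other offsets wherever
rectification does not bind), the multi-start includes the *unrectified
linear solution* (ordinary least squares of the rate on the raw channels,
intercept spread across the offsets), plus a near-zero start and the
bound midpoints.  Lag sweeps run a fast pass that warm-chains each lag
from its neighbour, then re-polish the three leading lags with the full
multi-start, cross-seeded with the overall best solution; this resolves
near-ties by fit quality rather than by incidental under-convergence.

The velocity exponent of LENGTH_POWER is fitted by nested grid search
over a ∈ [0.1, 1] in steps of 0.05 (velocity is rectified before
exponentiation), warm-chaining along the grid.

Per-afferent lag: the best per-trial lags from an exploratory subset
(default 12 trials, evenly spaced through the trial list) are averaged
and rounded to the nearest ms (half up); that λ is frozen for pooled
fits and cross-validation.  The exploratory fits also set the search
limits: weights in [0, 3 × max fitted weight] (with a small floor so an
exploratory zero does not freeze a parameter), offsets in ±max|x|.

The FORCE model has a *competing* variant: wherever the force and dF/dt
components are simultaneously above a significance threshold (default 0),
the smaller-magnitude component is zeroed iteratively; ties keep the
force component (the tonic-rate carrier).  The variant is kept only when
its mean R² across all observations strictly beats the plain variant.
Because the rule is non-smooth, its fit uses finite-difference
derivatives seeded with the plain solution.

## Cross-validation and model selection

Trials are split ~75 % train / 25 % test (rounding toward train),
stratified by stretch type so test sets always contain unseen waveforms;
100 random splits per afferent.  Quality is J = SSE/SSM (R² = 1 − J) over
the concatenated test observations.  The likelihood proxy is L̂ = 1/J_test
— not a true likelihood; no distributional assumption is made — and

    AICc(standard)   = 2k − 2 ln L̂ + 2 k(k+1)/(n−k−1)
    AICc(as_printed) = 2 (k − ln L̂ − k(k+1)/(n−k−1))

with k the number of fitted weights/offsets (+1 for the exponent; the
frozen λ is not counted) and n the number of *trials* in the test set.
The `as_printed` form reproduces a published formula whose small-sample
term enters with the opposite sign; taken literally it *rewards* extra
parameters at attainable test-set sizes (for n_test ≲ 50 the 22-parameter
ALL model always wins).  We read that as a typographic sign error and
default to the standard form; both are implemented and test-pinned.

Two numerical guards keep selection meaningful at the boundaries: a model
whose AICc is undefined (n ≤ k + 1) receives +∞ and Akaike weight 0
instead of aborting the run; and J_test is floored at 10⁻⁶ inside L̂, so
that models which have converged to an exact fit tie on likelihood and
the parameter penalty decides between them, rather than optimizer noise
in the 10⁻⁸ digits.

Winners per iteration are minimum-AICc (ties break toward fewer
parameters, then fixed model order).  Population aggregation: unweighted
means of per-afferent mean R² and mean AICc, weights recomputed from the
averaged AICc, selection frequency pooled over all iterations.

## Spindle metrics

* Dynamic index: peak IFR within [ramp end − 50 ms, ramp end + 5 ms]
  minus the rate of the last spike at or before ramp end + 0.5 s;
  requires a ramp-hold-release trial with ≥ 0.5 s of hold.  Trials are
  binned by peak velocity into five 10 mm/s bins over 0–50 mm/s.
* Initial burst: the detection window runs from stretch onset (filtered
  acceleration first exceeding 5 % of its maximum) to the first
  zero-crossing after the onset transient's peak; the burst amplitude is
  the maximum IFR in that window, paired with the window's peak dF/dt and
  peak acceleration.  Burst regressions are ordinary least squares with
  the slope t-test p-value, requiring ≥ 12 trials and non-degenerate
  predictors.

## Synthetic data generator

The generator defines the study conditions: ramp-hold-release (1 s hold)
and five-repeat sawtooth stretches over 1–4 mm, 4–50 mm/s,
200–3500 mm/s², each preceded by a 5 s isometric rest, sampled at 2 kHz.
Length profiles are acceleration-limited trapezoidal-velocity ramps that
achieve the prescribed peaks exactly; infeasible combinations (peak
velocity unreachable within the excursion) are rejected.

Whole-muscle force is a deliberately phenomenological model — a parallel
elastic element plus a Maxwell-slip cross-bridge element with a
movement-depletable "rested" stiffness pool:

    F        = f_rest + k_passive (L − L0) + F_xb,     floored at f_slack
    dF_xb/dt = (k_xb + k_A) v − |v| F_xb / s0 − F_xb / τ
    dk_A/dt  = (k_rested − k_A) / τ_rec − |v| k_A / s_dep

Defaults: k_passive = 0.5 N/mm, k_xb = 3 N/mm, s0 = 0.5 mm, τ = 0.5 s,
f_rest = 0.1 N, k_rested = 1.5 N/mm, τ_rec = 2 s, s_dep = 0.5 mm,
f_slack = 0.05 N.  The slip length produces short-range stiffness (an
onset dF/dt transient after rest, several-fold above the mid-ramp
dF/dt); τ produces monotone force relaxation during holds; the rested
pool — full after a ≥ 5 s rest, destroyed by movement, recovering over
seconds — makes the first sawtooth stretch carry a strictly greater peak
force, as in thixotropic muscle.  The slip length was set at 0.5 mm
(rather than a much smaller value) so the first-stretch enhancement
survives to the end of millimetre-scale ramps instead of being slipped
away; integration uses exact exponential steps for each state's linear
relaxation at 2 kHz.  These magnitudes are order-of-magnitude plausible
for a small passive triceps surae, not calibrated to any recording.

Ground-truth encoders mirror the candidate models (default FORCE truth:
k = (30 imp·s⁻¹/N, 0.6 imp·s⁻¹/(N·s⁻¹)), b = (0.4 N, 0), λ = 5 ms, rate
floor 5 imp/s for resting discharge; LENGTH truth: k = (8, 1.2, 0.015)
against mm, mm/s, mm/s²).  Three spike modes:

* `deterministic_integrator` (default): spike when ∫r dt crosses an
  integer.  The recorded IFR is then the ISI-averaged rate, which lags
  the instantaneous rate by about half an ISI during transients — a
  realistic sampling distortion, but not an exact substrate.
* `isi_consistent`: solves t_i − t_{i−1} = 1/r(t_i), so the recorded IFR
  equals the generating rate exactly at every spike.  This is the
  noiseless substrate for parameter-recovery and selection checks, where
  exact lag and weight recovery is the property under test.
* `poisson`: inhomogeneous Poisson by time rescaling.  Note that the
  reciprocal ISI of a Poisson train has no finite mean (ISIs can be
  arbitrarily short), so spike-time IFR regression is *inconsistent* on
  this substrate — fits on it degrade gracelessly, which is itself a
  useful negative control, but it is not a recovery substrate.
* `poisson_jittered`: the rate-consistent spike times displaced by ±1 ms
  of uniform timing jitter (about the timing precision of a primary
  afferent).  This is the noisy substrate on which weight recovery to
  within 10 % is checked; larger jitter attenuates the dF/dt weight by
  errors-in-variables on the fast onset transient.

All randomness flows from one master seed; regeneration is byte-stable,
and datasets round-trip through the CSV/JSON disk format losslessly
(floats written with 17 significant digits).

## What the synthetic data do and do not show

The generator reproduces the *qualitative* history-dependent force
signatures and an exactly known encoder, so passing tests demonstrate
that the pipeline recovers truth when its assumptions hold: correct
formula arithmetic, optimizer adequacy, exact lag/weight recovery, and
correct model ranking under the stated selection rules.  They do not
show that biological afferents are force-encoders: real recordings have
measurement noise, drifting excitability, fusimotor effects, and force
transients the Maxwell-slip model does not capture (stretch-velocity-
dependent short-range stiffness magnitude, long-timescale creep).
Reported R² and selection frequencies on synthetic data are therefore
properties of the pipeline, not re-estimates of the physiological values.

## Problem sizes used in tests and the acceptance script

Selection runs use one afferent of 104 trials (26 test trials per split)
per ground truth and the full 100 cross-validation iterations.  104
trials keeps n_test above k + 1 = 23 so AICc is defined for the ALL
model.  Recovery runs use 20 trials.  Population, competing-variant and
end-to-end reproducibility checks use 2–8 trials or afferents and 5–10
CV iterations — scaled-down designs chosen so the whole suite exercises
every stage at full fidelity where the property demands it (formula
values, recovery, the two full selection runs) and at reduced size
elsewhere.

## Known limitations

* The likelihood proxy 1/J makes AICc differences shallow; model ranking
  leans on the parameter penalty when fits are close.  This mirrors the
  selection rule the pipeline implements rather than a statistically
  calibrated likelihood.
* One λ per model (no per-predictor lags); λ is not counted as a fitted
  parameter in AICc.
* The competing-variant significance threshold and iteration rule are
  the simplest deterministic reading of the stated procedure.
* Visual signal-to-noise exclusion of trials is replaced by an explicit
  boolean flag on the trial record.
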