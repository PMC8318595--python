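# Methods

## The model

`tdlm` measures *sequenceness*: the average tendency of decoded neural
states to follow each other, at a fixed time lag, in an order prescribed by
a hypothesis graph.  The input is always a state space `X` (samples ×
states) of decoded reactivation evidence — sigmoid outputs of per-state
classifiers for human MEG/EEG-style data, or row-normalised Bayesian
position posteriors for rodent spiking data.

**First level.** For each lag Δt, every state's Δt-shifted time course is
regressed by OLS on *all* states' unshifted time courses jointly,

    X(t + Δt) = X(t) · β(Δt) + controls + ε,

yielding the n×n *empirical transition matrix* β(Δt).  The joint (rather
than pairwise) regression is the essential confound control: decoded states
are both temporally autocorrelated and mutually correlated, and any spurious
lagged association mediated by the decoded subspace at time t is absorbed by
the co-regressors.  A pairwise estimator is retained
(`simple_pairwise_transitions`) purely as a negative control; on a shared
autocorrelated background its off-diagonal coefficients are an order of
magnitude larger than the joint estimator's.

**Second level.** β(Δt) is vectorised (all n² cells by default) and
regressed on four vectorised templates: the forward hypothesis matrix T_F,
its transpose T_B, the identity T_auto (self-transitions / autocorrelation)
and the all-ones T_const (mean transition level).  The coefficients Z_F(Δt)
and Z_B(Δt) are forward and backward sequenceness; D = Z_F − Z_B contrasts
the directions.  A drop-diagonal variant omits the diagonal cells and
T_auto; for off-diagonal templates on full-rank designs the two conventions
give identical Z_F/Z_B (verified by test).  The classical OLS coefficient
variance of (Z_F, Z_B) from this fit is carried along as the per-scale
precision for the multi-scale combination.

**Boundaries.** Lags are integer sample counts; the shift convention pairs
X[t] (predictor) with X[t+Δt] (outcome), with no wraparound and the trailing
rows dropped.  Segment ids are first-class: concatenated candidate replay
events are regressed jointly, but no predictor/outcome pair ever crosses an
event boundary.  Joint estimation over segments equals the Gram-weighted
(precision-weighted) combination of per-segment fits (oracle test).

## Inference

State-identity permutation is the primary test: the *hypothesis matrix* is
relabelled (T_π[i,j] = T[π(i),π(j)]), never the data, so the temporal
structure of the noise is preserved under the null.  With the lag unknown,
family-wise error over lags is controlled by the max statistic: per
permutation the maximum of the curve is taken and the threshold is the
nearest-rank (1−α) quantile of those maxima.  Null maxima use signed Z by
default (directional hypothesis); the absolute-value option gives a
two-sided, mildly conservative test and is what the null-calibration
acceptance run uses.  Group-level statistics are subject means per lag (a
one-sample t statistic is available as an option), with
the same permutation applied to every subject within one null sample
(because the second level is linear in β, the group curve is computed from
the mean β — an exact identity, verified by test).

Two permutation sets are available: all n!−1 non-identity relabellings, or
only those whose permuted transitions connect states from different
sequences (guaranteed zero edge overlap with the hypothesis; more sensitive
in the presence of signal).  A uniform time-shuffle test is included only as
a negative control and warns when called: it destroys temporal smoothness
and rejects far above its nominal level on autocorrelated data
(reproduced in the acceptance suite).

## Simulated study conditions

The generators are pure functions of (config, seed).

* **Task data** — per-state ground-truth sensor patterns plus Gaussian
  noise with the same spatial covariance as the rest data, sd = 1 /
  `pattern_snr`.  Patterns are *focal*: each state loads on a random 25% of
  sensors (rescaled to keep overall pattern energy constant), reflecting
  the spatial localisation of evoked fields.  An equal-sized block of
  pure-noise rows is produced for null-data mixing.
* **Rest data** — multivariate AR(1) background (coefficient 0.9 at 100 Hz;
  the simplest process exhibiting the temporal-smoothness confound) with
  innovations correlated across sensors as ρ^{|i−j|}, ρ = 0.5; optionally a
  sinusoid with a linear 0–2π phase gradient across sensors (a
  travelling-wave analogue, so different decoded states experience the
  rhythm at different phases); optionally injected sequences.  Each
  injection adds the full state-pattern at single samples whose successive
  gaps are Gamma(shape 10, scale 0.4) draws — mean 4 samples = 40 ms at
  100 Hz — following the configured transition graph (uniform choice among
  successors; a traversal ends at a state with no successors).
* **Defaults** — 8 states, 64 sensors, 50 task observations per state,
  pattern SNR 0.5, 30 s of rest at 100 Hz.  These are desk-scale: large
  enough that the pipeline's qualitative behaviour (peak recovery,
  calibration, regularization ordering) is stable across seeds, small
  enough that a 24-subject × 200-run calibration study completes in
  minutes on one CPU.  The calibration tests in the suite further reduce
  to 32 sensors, 25 observations/state and 10–15 s of rest.
* **Linear track** — Gaussian tuning curves (σ 10 cm, peak 20 Hz) tiling a
  600 cm track; constant-speed running generates Poisson spikes; rest
  contains burst events (gain ×5 over tuning, 100 ms) whose latent decoded
  position advances at ± the configured replay speed, on a 0.5 Hz Poisson
  background.  `noise=0` switches to deterministic expected-count emission
  for exact decoding checks.

What the simulations do *not* emulate: realistic MEG leadfields or source
geometry, 1/f spectra, artefacts, non-Poisson spike statistics, theta
phase structure, or behavioural variability.  Passing tests therefore
demonstrate the estimator's statistical properties under its assumed
generative structure, not end-to-end performance on recorded data.

## Decoding

One-vs-rest binomial logistic classifiers (scikit-learn), one per state;
positives are the state's task rows, negatives the remaining task rows plus
`round(null_ratio · b)` null rows.  The penalty follows the per-observation
convention b·λ‖W‖ (so sklearn's C = 1/(bλ)); L1 uses liblinear with a large
intercept scaling (the bias is effectively unpenalised, preserving
σ(0) = 0.5 calibration), L2/none use lbfgs; tolerance 1e-6, max 1000
iterations, fixed solver seed.  Sensors are z-scored with training
statistics stored in the model and re-applied at decode time.

The null:task mixing ratio steers the spatial correlation of the trained
weight maps — none drives states negatively correlated, a large ratio
positively — and `tune_null_ratio` picks the grid value nearest zero mean
off-diagonal correlation, which is where sequence detection is most
sensitive.  L1 regularization lowers inter-state weight correlation and, in
the sparse-pattern/limited-data condition documented in the acceptance
suite (100 sensors, 10% pattern density, 15 observations/state, SNR 0.3),
yields higher sequenceness at the true lag than L2 or no regularization,
with L2 ≈ none.

## Oscillation controls

A background rhythm experienced at different phases by different states
leaks an oscillation into the sequenceness curve that the co-regressors at
time t cannot fully absorb (each regressor measures the oscillatory
subspace with noise).  Phase-shifted copies X(t+τ) added as nuisance blocks
shrink the leak by supplying further measurements of that subspace.  One
full-period copy (τ = 100 ms for 10 Hz) can at most halve the oscillatory
coefficient component — it duplicates each state's phase — and measures
≈ 30–40% attenuation in simulation; the control block used in the
acceptance test adds copies at 50 ms and 100 ms and attenuates the 10 Hz
component of Z_F by ≥ 50%.  A τ equal to the outcome lag would duplicate
the outcome and is skipped for that lag (recorded), or raises in a
single-lag fit.

## Multi-scale combination

For continuous 1D spaces the track is discretised at several bin widths
(default 5, 10, 20, 40 cm; a trailing bin shorter than half a width merges
into its neighbour).  A replay speed maps to an integer decode-bin lag per
scale, lag = bin_width / (speed · decode_bin); a scale is excluded for a
speed when the rounded lag is below 1 or misrepresents the speed by 25% or
more (beyond that the scale misstates the nominal speed by more than half a
bin).  Valid scales are combined per speed by inverse-variance weighting
β_M = Σ(β_i/V_i)/Σ(1/V_i) with V_i the second-level OLS coefficient
variance; weights sum to one and β_M always lies within [min β_i, max β_i].
Significance over the speed grid reuses the max-statistic machinery with
one independent state permutation per scale per null sample, recomputed
through the same combination.  Because posterior rows sum to one, the
first level on posterior data is fit without an intercept (the constant is
already in the predictor span; with one it would be exactly collinear).

At speeds where only a weakly determined scale is valid (few lagged pairs
relative to states), both the observed and the null estimates are noisy and
the max-corrected threshold rises accordingly — the test stays valid but
loses power; the synthetic recovery study therefore uses sessions with
≈ 200 candidate events.

## Rodent front-end

Rate maps: spikes and dwell binned at 2 cm, both smoothed with the same
Gaussian kernel (σ = 5 bins; identical smoothing of numerator and
denominator conserves total spike mass), samples slower than 3 cm/s and
masked track zones excluded, separate outbound/inbound maps (outbound =
increasing linearised position); unoccupied bins are NaN, never zero.
Place cells: peak rate above 1 Hz and a half-peak field width of at least
20 cm (width = contiguous span around the peak at ≥ 50% of peak; the
convention is configurable).  Candidate events: place-cell multi-unit
activity in 1 ms bins smoothed with σ = 10 ms; spans above mean + 3 SD
whose *above-threshold core* lasts ≥ 40 ms are extended outward to the mean
crossing, merged, and kept if ≥ 15% of the ensemble participates.
Applying the duration rule to the core keeps chance excursions of smoothed
Poisson noise below one false event per 10 minutes (verified by test).
Decoding: per 10 ms bin, Poisson likelihood with uniform prior,
posterior(k) ∝ Π_c rate_c(k)^{n_c} · exp(−τ Σ_c rate_c(k)), rates floored
at 0.01 Hz; one segment per event.  Baselines for comparison: discrete
Radon best-line integral (position-shuffle null; ties prefer the steepest
line) and the posterior-weighted time-position correlation.

## Second-order inference

Linear contrasts c'β of effect estimates are tested by recomputing the
contrast under each permuted template (two-sided, 2.5/97.5 nearest-rank
percentile bounds).  The time interaction augments the first level with
X(t) .* z-scored time (z-scoring demeans, rendering the block approximately
orthogonal to the main effect for stationary data); its second-level
projection measures drift of *conditional* transition strength over the
session — a change in event rate alone with constant per-event strength
does not move it, by construction.  ROI logic: effects averaged over a
data-selected region admit unbiased inference only when orthogonal to the
selection statistic; with selection on F+B, the difference F−B, any time
interaction and between-transition trend contrasts are certified, while F
or B alone are refused with the reason (the suite demonstrates the
inflation the guard prevents).

## Numerical choices and limitations

First-level solves use normal equations with an eigenvalue conditioning
check (relative threshold 1e-10); rank deficiency raises an error naming
the offending column (constant state, duplicated control), with an explicit
pseudo-inverse opt-in.  One-hot state spaces are exactly collinear with an
intercept — fit those without one.  Nearest-rank percentiles everywhere a
quantile is taken.  Permutations are sampled without replacement (exact
enumeration up to 9 states).  Thresholds from ~200 permutations carry
Monte-Carlo granularity of order 1/200 in the attained level.

The package analyses average sequence strength across many events; it does
not score individual replay events as significant/insignificant, does not
implement multi-step (three-state) sequence regressors, and performs no
sensor-level preprocessing or source reconstruction.
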