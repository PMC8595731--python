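# Methods

`pursuithist` analyzes predictive (anticipatory) smooth-pursuit eye movements
recorded while an observer tracks a horizontal triangular-wave target: a
rightward ramp at a fixed 16 deg/s over 24 deg, followed immediately by a
leftward ramp at one of seven velocities (4, 8, 12, 16, 20, 24, 28 deg/s).
Because the package must be verifiable without human recordings, it pairs the
analysis pipeline with a synthetic-cohort generator whose ground truth every
stage can be checked against.

## The behavioral measures

All event times are signed milliseconds relative to the right-to-left target
reversal (time zero; rightward motion is positive).

* **Eye deceleration onset** — the first time the eye velocity falls below a
  threshold of 80% of the steady-state velocity and stays below it until the
  eye reverses.  The steady-state velocity is the mean eye velocity 700–500 ms
  before the reversal, pooled over all analyzed trials of one observer and
  condition (pooling per observer because pursuit gain differs across
  observers).
* **Timing of eye reversal** — the first zero crossing of the eye velocity
  after the onset, interpolated between the bracketing samples (sub-millisecond
  resolution; this timing is the primary outcome of the history analyses).
* **Mean eye deceleration** — the average eye acceleration between the two
  events.

Trials are excluded when the onset precedes −300 ms (typically contaminated by
an anticipatory saccade toward the reversal point), when the reversal falls
after +100 ms (visual feedback has arrived), or when either event is
undetected.

The *sustained-crossing* rule for the onset deserves a note: "falls below the
threshold" is ambiguous under noise, so the onset is defined as the first
sample of the below-threshold run that actually reaches the zero crossing.
Transient noise dips that recover above threshold are thereby ignored.  A
brute-force sample-scan oracle in the test suite applies the same predicates
independently and must agree exactly.

## Preprocessing

The pipeline order is fixed and no stage changes the time grid or length:

1. central-difference differentiation of the 1 kHz position trace (one-sided
   differences at the endpoints);
2. an 80th-order Hamming-window FIR low-pass with 30 Hz cutoff, applied
   forward–backward.  Zero-phase filtering is chosen because event *timings*
   are the outcome; any single-pass group delay (40 ms at this order) would
   bias every event by a constant;
3. saccade detection on the filtered acceleration with a 1000 deg/s²
   criterion; supra-threshold runs are padded by 10 ms per side and merged;
4. linear interpolation of the velocity across the detected saccade gaps
   (samples flagged as interpolated), acceleration recomputed from the
   cleaned velocity;
5. a 40 ms centered moving average (rounded up to an odd 41 samples so the
   smoother is symmetric), with shrinking windows at the edges.

Residual error after saccade removal is dominated by filter spread at the gap
endpoints: for 1–2 deg catch-up saccades the reconstructed velocity differs
from a saccade-free twin trace by ~1.5 deg/s RMS over the gap — an order of
magnitude better than not removing the saccade, and well inside the 20%
threshold margin used for onset detection, but not negligible.  Enlarging the
pad would trade gap width for endpoint cleanliness; the default keeps the
stated 10 ms.

## Trial-history analyses

Two complementary analyses quantify serial dependence of the reversal timing
in the unpredictable condition.

**Node (tree) method.**  Within each (observer × target velocity) cell the
included timings are ranked ascending; the earliest 20% are labelled UPPER and
the latest 20% LOWER (`floor(0.2·n)` per side, stable tie-break by trial
order).  Current-trial timings are then grouped by a property of the n−1 or
n−2 trial — its classification (behavioral history) or whether its target
velocity was the slowest/fastest level (stimulus history) — and the
per-observer group means are compared with a paired t test (Cohen's d on the
paired differences).  Lags never cross block boundaries.

**Mixed-model grid.**  Fifteen random-intercept linear mixed-effects models
regress the current timing T_n on lagged target velocities V_{n−k} and lagged
timings T_{n−k}: models 1–5 use stimulus lags 1..k, 6–10 behavioral lags
1..k, 11–15 both sets.  Estimation is by maximum likelihood (not REML) so that
AIC = 2k − 2·logLik is comparable across fixed-effect sets; k counts the fixed
effects plus the two variance parameters.  All 15 models are fitted on the row
set of the largest model (every lag to n−5 available and included) so the AICs
compare like with like; the first five trials of each block therefore serve as
predictors only.  Rows whose behavioral lag references an excluded trial are
dropped (complete case).  Wald t statistics use residual degrees of freedom
n − k_fixed, matching the convention of reporting t with thousands of degrees
of freedom.  Variance inflation factors (1/(1−R²) of each predictor on the
rest) are reported as the collinearity diagnostic; at cohort scale they stay
below ~1.2 because the lagged velocities are randomized by design.

Gradient-based ML optimization of the random-intercept model occasionally
stalls on the zero-variance boundary with a spuriously infinite likelihood;
the fitter detects non-finite results and restarts with derivative-free
optimizers (Powell, then Nelder–Mead), raising a diagnostic error if the fit
remains singular rather than letting such a model win the AIC comparison.

**Within-subject correlation.**  For the predictable condition the association
between timing and target velocity is summarized by the repeated-observations
correlation: the correlation of subject-mean-centered variables, computed from
the pooled within-subject sums of products, with N − n_subjects − 1 degrees of
freedom.  This isolates within-observer covariation from between-observer
offsets (a Simpson's-paradox construction in the tests verifies exactly that).

## Distribution stage

Reversal-timing distributions differ across observers, so each observer's
timings are normalized over *all* of their included trials from both
conditions combined before pooling.  The default is a z-score with the pooled
mean and population SD; a center-only variant (subtract the mean, keep ms
units) is available by configuration, since either reading of "normalized by
the mean" is defensible.  Pooled histograms use a fixed 0.25 bin width with
edges anchored at 0.

Unimodality of the pooled unpredictable-condition distribution — the
signature of a weighted-averaging strategy, as opposed to the multimodal
pattern a discrete velocity-expectation (Markov) strategy would produce — is
quantified with Hartigan's dip statistic.  The dip (the sup-distance between
the empirical CDF and the closest unimodal CDF) is computed with the
greatest-convex-minorant / least-concave-majorant iteration; no installed
package provides it, so it is implemented here and cross-checked in the test
suite against an exact linear-programming solution of the best-unimodal-fit
problem at small n.  The p value is bootstrapped against the uniform null
(the least favorable unimodal distribution), 200 replicates by default.  This
operationalizes what is otherwise a visual judgment; it is deliberately
conservative.

## The synthetic cohort

The generator mirrors the experiment's design: 7 blocks × 30 trials with one
fixed leftward velocity per block (predictable) and 5 blocks × 49 trials with
each velocity exactly 7 times in shuffled order (unpredictable).

Reversal timings follow the generative twin of the mixed model:

    T_n = β₀ + b_obs + Σ_k βstim_k·V_{n−k} + Σ_k βbehav_k·T_{n−k} + ε_n

with a per-observer intercept b_obs ~ N(0, 10² ms²) and ε_n ~ N(0, 30² ms²).
History resets at block boundaries; missing lags at a block start contribute
zero (truncated sums) and those trials are flagged burn-in, mirroring the
design-matrix convention.  The default history weights are the group-level
estimates of the full lag-5 combined model (intercept 30.62 ms; stimulus lags
−0.096, −0.417, −0.215, 0.034, −0.074 ms per deg/s; behavior lags 0.078,
0.093, 0.029, 0.001, 0.029), so the simulated cohort reproduces the
phenomenon under study: velocity-dependent timing in predictable blocks and
centered, history-dependent timing in unpredictable ones.  The residual SD of
30 ms was calibrated so that fixed-effect standard errors at cohort scale
(12 × 245 trials) land at the magnitude a real cohort of this design
produces (~0.08 ms/(deg/s) for stimulus lags, ~0.018 for behavior lags);
the model's log-likelihood scale follows.

Eye traces realize those timings: steady-state velocity is `pursuit_gain`
(default 0.95) times target velocity; around each right-to-left reversal the
velocity follows a single raised-cosine sweep from the rightward to the
leftward steady state whose zero crossing falls *exactly* at T_n — smooth,
monotone, and analytically invertible, which is what makes ground-truth
recovery testable.  The true deceleration onset is placed 100–250 ms
(uniform) before the reversal.  Left-to-right transitions (not analyzed) are
reactive: a raised-cosine ramp starting 100 ms after the target turn.
Catch-up saccades are injected as minimum-jerk position steps (20–40 ms,
0.5–2.5 deg, directed at the current position error) at ~1 per second, which
guarantees supra-threshold acceleration without discontinuities; Gaussian
position noise (0.05 deg SD) is added last.  Gain and noise defaults are
configuration values, not claims about any particular dataset.

What the generator does **not** emulate: blinks and pupil artifacts, vertical
eye movements, drift or calibration error, the build-up of anticipation over
the first trials of a predictable block beyond what the history weights
produce, and anticipatory saccades toward the reversal location — the main
real-world source of early-onset exclusions.  Synthetic inclusion rates
(~97–99%) are therefore higher than real cohorts (~92–94%), and the
within-subject correlation between timing and velocity in predictable blocks
is weaker than in real observers, who exploit explicit knowledge of the
block's velocity rather than only trial history.  Passing tests demonstrate
that the pipeline measures what it claims to measure, not that real eyes
behave like the simulator.

## Numerical choices and degenerate inputs

* Sample-resolution onsets; sub-sample reversals (the regression outcome).
* A velocity sample exactly at 0 counts as the crossing.
* Saccade gaps touching a trace boundary are filled with the nearest retained
  value (with a warning); an all-gap trace is an error.
* Zero-variance paired differences yield an explicit edge-case p (0 or 1)
  with a warning; zero pooled SD rejects z-normalization.
* Perfect predictor collinearity reports infinite VIF and names the set.
* The dip of a degenerate (constant or single-point) sample is 0.
* Cohort simulations at full scale in the tests use 12 observers × 245
  unpredictable trials; recovery simulations use 200 replicates (bias) and
  100 replicates (model selection).  Near-zero generating weights (≤ ~0.03)
  cannot be bias-tested at 10% relative precision with 200 replicates — the
  Monte-Carlo SE of the mean exceeds the band — and the suite documents that
  limit rather than relaxing it.

## Known limitations

* The dip-test p value is bootstrap-based and slightly conservative for
  strongly peaked unimodal data.
* The 10 ms saccade pad leaves filter-spread residue at gap endpoints
  (~1.5 deg/s RMS); event detection is robust to it, but per-trial mean
  deceleration on saccade-contaminated trials inherits a small bias.
* AIC comparability requires the shared row set; absolute AIC values are not
  comparable across cohorts of different sizes.
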