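# Methods

This note documents the models, defaults and numerical choices behind
`gripshift`, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Trial-sequence design

The unit of analysis is the transition between consecutive lifts:
previous weight (light/heavy) x current weight (light/heavy) x hand
order (same/different), restricted to trials whose current lift uses the
group's analysis hand. The default specification asks for 151 trials
with 15 dummy-object (317 g) lifts and at least 10 analyzable
repetitions per condition.

The generator is constructive rather than search-based:

1. **Same-hand conditions** form a random Eulerian circuit over the
   two-object transition multigraph (10 edges per ordered object pair),
   giving 41 analysis-hand trials whose 40 consecutive pairs realise
   exactly 10 of each same-hand condition. Hierholzer's algorithm with
   shuffled adjacency lists randomises the circuit.
2. **Different-hand conditions** are atomic (other-hand setup,
   analysis-hand lift) pairs inserted at gaps where the insertion cannot
   disturb an existing transition (the pair's final object must equal
   the left neighbour's object whenever the right neighbour is a
   same-hand trial). The 40 setup lifts are exactly the "wrong hand
   order" trials that are discarded at labeling.
3. **Dummy lifts** are inserted together with a clone of their left
   neighbour. The clone restores the previous-lift state for the trial
   that follows, and is itself always discarded (it follows a dummy), so
   no planned transition is lost.

For the default specification this yields 41 + 80 + 30 = 151 trials and
*exactly* 80 analyzable trials (10 per condition); discard categories
partition the rest (1 first trial, 15 dummies, 15 dummy-followers, 40
wrong-hand lifts). Infeasible specifications (too few total trials for
the requested repetitions and dummies) are detected arithmetically and
raise, with no bounded-restart loop to tune. Ten practice lifts of the
260 g object (5 per hand) are available via `practice_block` and are
never counted.

Labeling precedence for discard reasons is: first trial, dummy, follows
dummy, wrong hand order. A trial is analyzable only if no reason
applies.

**Apparatus arithmetic.** Sensor-side weights are
`(object mass + 120 g manipulandum) / 1000 x 9.81 m/s^2`: 2.21, 4.29 and
6.33 N for the three test objects (2.2 / 4.3 / 6.3 N at one decimal).
The computed practice-object weight is 3.73 -> 3.7 N; the package
reports the computed value (a nominal 3.8 N is sometimes quoted for this
mass, which is inconsistent with the arithmetic above by about 0.1 N).

## 2. Force-kinetics extraction

* **Filtering.** Zero-phase (forward-backward) Butterworth low-pass,
  design order 2 per pass, cut-off 15 Hz at 1000 Hz sampling. The
  bidirectional digital filter's squared magnitude is
  `1/(1 + (tan(pi f/fs)/tan(pi fc/fs))^4)`; at 50 Hz this is 0.0078,
  within a few percent of the continuous-time idealization
  `1/(1 + (f/fc)^4) = 0.0080`. Filtering precedes combination and
  differentiation; because all three operations are linear, filtering
  per raw channel and then combining equals combining first (tested).
* **Axis convention.** z is vertical (gravity), x the grip normal; the
  simulator and extractor share this convention, and a trace table
  missing the declared channels is rejected.
* **Differentiation.** Central differences on the filtered signal
  (`numpy.gradient`), one-sided at the edges.
* **Events.** First-sample threshold semantics, scanned left to right:
  contact = first GF > 0.1 N, onset = first LF > 0.1 N, lift-off =
  first LF >= object weight (the two common phrasings "equals" and
  "exceeds" are reconciled as >=). The peak-search window is
  [contact, lift-off + 50 ms], clamped to the trace end with a flag; the
  same window serves both force rates. No hysteresis or debouncing is
  applied — the filtered signals are smooth — and no baseline re-zeroing
  is performed, so slow sensor drift would shift the 0.1 N crossings
  (flagged here as a known limitation).
* **First peak.** Local maxima are strict sign changes of the first
  difference; plateaus contribute their first sample. The earliest local
  maximum of at least 30% of the window maximum is returned; if every
  earlier peak is smaller than that, the window maximum is used and the
  per-channel `used_max_fallback` flag is set. Maxima below 1e-8 of the
  window maximum are treated as numerical ripple, not peaks.
* **Exclusions.** Procedure errors (wrong object, wrong hand, object not
  lifted) invalidate the trial and its successor for both analyses;
  lifting errors (double lift, premature lift, push before lift)
  additionally invalidate the trial itself for the force analysis only.

## 3. Perception

Reports are standardized within participant with the sample SD
(ddof = 1) over the participant's valid trials, **including**
dummy-object lifts by default (they are real lifts with real reports;
`include_dummy=False` restricts to light/heavy trials). Invalid trials
are excluded from the mean/SD and left unscored. Zero-variance or
too-few-trial participants raise with the participant named.

Contrast sign conventions: `perceptual_bias` = previous-light minus
previous-heavy mean z (positive = object feels heavier after a light
lift, the expected direction); `force_diff_*` = previous-heavy minus
previous-light z-scored peak (positive = higher planned rates after a
heavy lift, the expected sensorimotor-memory direction).

## 4. Split-plot ANOVA

With all within factors at two levels, each within effect is one
orthonormal contrast over the 8 within-cell means, and the design
decomposes into 8 independent between-subject strata: the cell average
carries the between effects (handedness, current hand, their
interaction) against the subject stratum; each within contrast carries
that effect and its interactions with the between factors against the
contrast x subject-within-group stratum. Within each stratum a Type III
analysis with sum-to-zero contrasts is used — required because the
between cells are unbalanced (20/20/10/10) — so every effect has
df1 = 1 and df2 = N - 4 (= 56 at the published group sizes). Sphericity
corrections are moot at two levels. Effect sizes are partial eta
squared; the identity `eta_p^2 = F df1/(F df1 + df2)` is asserted for
every emitted effect. With unbalanced cells Type III sums of squares do
not add to the total SS (they do, and equal Type I, for balanced data —
both tested). Degenerate strata with zero error variance report F = 0
when the effect SS is also zero.

Post-hoc families are explicitly enumerated sets of simple-effect
comparisons (paired t within subjects, Welch t between groups),
Bonferroni-corrected by the family size, which is recorded in the
output. Per-condition perception/force correlations form a 16-test
family per force parameter.

## 5. AR(1)-error regression

The perception/force coupling models are fixed-effects linear models
with AR(1)-correlated errors within participant, estimated by maximum
likelihood: for fixed rho a Prais-Winsten whitening reduces the fit to
OLS; the profile likelihood over rho is scanned on a grid in
(-0.98, 0.98) and refined with a bounded scalar minimizer. At rho = 0
the fit coincides with OLS exactly, and the optimal log-likelihood
dominates the rho = 0 value (both tested; coefficients at fixed rho are
cross-checked against GLS with an explicit AR(1) covariance). Term
tests are Wald F against the residual df (n - p); no
Satterthwaite-style adjustment is attempted, so denominator dfs are
approximate and will differ from software that estimates them.
Single-observation participants are treated as serially independent.

This "fixed effects + AR(1) errors" reading is the minimal model
consistent with a first-order autoregressive ML specification; no
additional random-effect structure is assumed.

## 6. Synthetic cohorts

The generative model makes every measured quantity analytically known.

* **Force plan.** The planned load-rate pulse is
  `LFR(tau) = R1 sin^2(pi tau/T1)` integrating to
  `W_plan = W_exp + overshoot` (one plans to exceed the expected weight,
  otherwise nothing lifts off); the planned peak rate is
  `R1 = alpha W_exp`. Expectation mixes memory and prior:
  `W_exp = lam_eff W_prev + (1 - lam_eff) W_baseline`, with
  `lam_eff = lambda_mem` on same-hand and
  `lambda_mem x gamma_transfer` on hand-change trials;
  `W_baseline` is the midpoint of the light/heavy sensor weights. An
  undershoot (`W_exp < W_true`) triggers a slower corrective pulse
  (peak rate capped below `0.8 R1`), lengthening the loading phase.
  Grip force is `gf_margin + gf_ratio x LF` after its own pre-loading
  ramp from contact, so the planted `peakGFR1 = gf_ratio R1`. Onset and
  lift-off crossing times follow in closed form from the integrated
  sin^2 pulse (inverted via a brentq root or a fine interpolation grid).
* **Percept plan.**
  `latent = beta log(W_true/W_ref) + delta_right [right hand]
  - kappa_bias [prev heavy][same hand] gate + noise`, with the gate
  encoding the planted handedness asymmetry (right-handers biased for
  light and heavy current objects, left-handers for light only) and
  `W_ref` the geometric mean of the two test weights. The report is a
  participant-specific positive affine transform of the latent — the
  self-chosen magnitude-estimation scale — which the pipeline's
  z-scoring removes exactly. With the default `beta = 1.8` and report
  noise 0.3 the latent spread is near 1, so `kappa_bias` is
  approximately the bias magnitude in z-units after standardization.
* **Defaults.** `alpha = 8 (N/s)/N` puts first peaks at 17-50 N/s and
  loading phases at 80-600 ms for the 2.2-6.3 N objects — the orders of
  magnitude typical of precision-grip lifts; `lambda_mem = 0.4` plants
  a strong sensorimotor-memory effect, consistent with the very large
  reported effect sizes this design targets (eta_p^2 well above 0.5);
  `gamma_transfer = 1` plants full interlimb transfer of the memory and
  `kappa_bias = 0.35` a same-hand-only perceptual bias, the planted
  dissociation the recovery tests look for. Participant heterogeneity
  is lognormal on `alpha` and `gf_ratio` and additive (clipped) on
  `lambda_mem`; error trials are injected at 0.5% (procedure) and 1%
  (lifting), mirroring low laboratory error rates. Note the clipping at
  0 means a *null* memory cohort must also set `sd_lambda = 0`.
* **Two metric modes.** `mode='traces'` synthesizes raw two-sensor
  traces (regenerable deterministically per trial) for the extraction
  pipeline; `mode='analytic'` emits observed metrics directly from the
  generative ground truth plus measurement noise. The large repeated
  cohort studies (power and calibration, 200 cohorts each) use the
  analytic mode; its equivalence to trace-level extraction is
  established separately by the noise-free recovery tests (first peaks
  within 5%, loading-phase durations within 2 samples of the analytic
  crossing times).
* **What the simulator does not emulate.** First force-rate peaks depend
  only on the expectation, so current-weight effects on the *first*
  peaks (reported in real data, where expectations are partly informed)
  are not planted; no digit kinematics, friction/slip margins, sensor
  drift, fatigue or learning trends; reports have no serial correlation
  beyond the planted sequential bias. Passing recovery tests therefore
  demonstrate pipeline correctness under the stated generative
  assumptions, not validity for any particular laboratory data set.

## 7. Recovery and calibration studies

Run by the test suite at the published group sizes (20/20/10/10, 60
participants):

* **Power.** Over 200 simulated cohorts with the default planted
  effects, the previous-weight effect on both force-rate peaks must be
  detected (alpha = 0.05) in at least 90% of cohorts in both hand-order
  strata, and the previous-hand x previous-weight interaction on
  percepts in at least 90% — the planted perception/action dissociation
  as a power property.
* **Type-I calibration.** Over 200 null cohorts (no memory, no bias, no
  hand offset, no weight coding), each of the 31 ANOVA terms must
  reject at a rate inside its 99.9% binomial band around 5% (the
  per-term multiplicity across 31 simultaneous bands makes a 95% band
  statistically incoherent), and the pooled rate inside [0.03, 0.07].
* **Scale choices.** 200 cohorts keep the binomial bands tight enough
  to be informative while the whole suite runs in a few minutes;
  smaller scaled-down designs (2 repetitions per condition, 31 trials)
  are used wherever the full 151-trial sequence is not itself under
  test.

## 8. Known limitations

* The split-plot engine requires two-level factors (the design analysed
  here has no others); multi-level within factors would need sphericity
  handling it deliberately omits.
* AR(1) denominator dfs are residual-based approximations.
* The 0.1 N event thresholds assume drift-free, baseline-zeroed
  sensors.
* The generative percept model is log-linear with an affine report
  scale; real magnitude estimation can be noisier and nonlinear in ways
  the affine-invariance tests do not probe.
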