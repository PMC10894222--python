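# Methods

This note documents the models implemented in `tactime`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Stimuli and trial design

Vibrations are i.i.d. zero-mean Gaussian velocity samples at 1 kHz; trace
length is the floor of duration × sample rate.  Intensity is defined as the
*nominal* half-normal mean σ√(2/π) when labeling trials, not the per-trace
empirical mean speed, since resampled traces ("seeds", 50 by default) share
a nominal intensity.  The psychometric design fixes stimulus 1 at 334 ms
and 64 mm/s and spans seven comparison levels per feature as a geometric
series between the design extremes (161–694 ms, 34–119 mm/s); with only
the extremes and the references pinned down, log spacing between them is
the natural reconstruction, and it makes the reference the geometric mean
of the extremes (334 ms, 64 mm/s after rounding).  The reference intensity
is sometimes quoted as 65 mm/s; we default to 64 mm/s and expose it as a
parameter.  Congruence of a
trial is the sign product of ΔT and ΔI; zero on either axis is neutral.

## LNP neuron model

Currents and the I/F curve are as given in the README.  Conventions:

- Time is in ms everywhere, including the arguments of the logistic gates
  (so the window edges have ~1 ms transition scale).
- λ (maximum rate) is kept in spikes per 1-ms bin throughout; simulation
  runs at 1 ms and the fitter aggregates per-ms expected counts into 10-ms
  bins, so no unit conversion ever touches the likelihood.  `lambda_max_hz`
  reports spikes/s.
- The exponential decay terms are clipped at the current onset (no growth
  before the gate opens); the gate itself suppresses earlier times.
- The 10⁻⁴ rate floor and the ×10 current scaling are always applied.

Fitting is penalized Poisson maximum likelihood on 10-ms binned counts with
L-BFGS-B, multi-start (a heuristic start from inverting the I/F curve at
the baseline/peak/steady-state rates, plus restarts that specifically vary
the nonlinearity scale υ, whose likelihood basins are shallow).  A small
ridge (weight 0.1) on the gated current parameters settles directions the
data leave flat — e.g. a flat PSTH says nothing about gated currents, and
the ridge then pulls them to zero rather than leaving them at arbitrary
values.  Currents are bounded to ±5 a.u., λ to [10⁻⁴, 1] spikes/ms, υ to
[0.05, 20].  The decay constants are fixed at the population medians
(τ_M = 48 ms, τ_O = 49 ms, τ_I = 28 ms) unless `fix_taus=False`.  Standard
errors come from the inverse numerical Hessian; a fit-quality score
(variance explained of the PSTH) is reported.  The light window defaults to
the stimulus window and is configurable (e.g. 50 ms early onset for
photoinhibition protocols); the post-light current i3 may be positive
(rebound) or negative (post-stimulation suppression).

Identifiability note: with all conditions at a single drive level, υ trades
off against the current amplitudes.  The recovery harness therefore probes
several vibrissal gains and a light-only condition, mirroring the multiple
intensities and light calibrations of a real session; with those probes all
eight free parameters recover to within 20% at 200 trials/condition for a
neuron whose parameters each visibly shape the PSTH.  Parameters that do
not express in rate (e.g. suppression below an already silent baseline)
cannot be recovered by any method — a property of the data, not the fitter.

## Mixture population

The eight free parameters of fitted units enter a
`sklearn.BayesianGaussianMixture` with Dirichlet-process weights, truncation
G = 5 and concentration 10⁻⁶.  Two numerical choices matter: `reg_covar` is
raised to 10⁻⁴ (the default floor lets near-singleton components survive
with degenerate covariances) and `n_init=10` (the variational optimum is
init-sensitive).  Weight consolidation onto the true number of classes is
asymptotic: with a few dozen vectors per class the fitted weights can split
across near-identical components even when assignment is perfect, which is
why the single-class weight test uses a large sample while the two-cluster
test checks assignment accuracy.  Sampling a population draws a class per
neuron by weight, then a Gaussian vector; draws with non-positive λ or υ
are rejected and redrawn (the count is logged).  Rejection keeps the
Gaussian class model intact rather than warping it with a log transform;
for the default mixtures the rejection rate is negligible, so the induced
truncation bias is too.  The decay constants and current onsets are
population-level constants outside the mixture space.

## Percept and choice

The closed-form moments of the integrator are evaluated as discrete sums on
the 1-ms grid at bin centers; the drive's Poisson character contributes the
rate to both the mean and the variance integrals (the variance integrand
uses the integration variable).  The background component enters as its
stationary moments (μ_b, σ²_b) with the relaxation factors
(1 − e^(−t/τ)) and (1 − e^(−2t/τ)).  The independent cross-check simulates
trajectories stepwise with exact per-step decay e^(−dt/τ) and the drive
entered at bin midpoints, which makes the two computations agree in
expectation exactly, leaving only Monte-Carlo error.  ϒ resets to 0 with
zero variance at each stimulus onset: the inter-stimulus delay is not
modeled, and only ϒ at each offset enters the comparison.

Behavioral fitting maximizes the binomial likelihood of per-cell choice
counts (identical to per-trial Bernoulli) over (log τ, μ_b, log σ²_b,
logit p_L, logit b_L), multi-start, with the L2 pull on τ applied as
0.01·((τ−600)/600)² — the penalty's weight and center are given, its scale
is not, so the center doubles as the normalization; both are configurable.
When several population proxies are supplied the likelihood sums over
proxies (one common parameter set).

## Psychometrics

The four-parameter logistic is fitted by bounded nonlinear least squares
(γ, λ ∈ [0, 0.5]), multi-start, on 0–1 proportions (×100 only for display).
The PSE is where the *fitted* curve crosses 50%, u + ν·logit((0.5−γ)/(1−λ−γ)),
which differs from u when the asymptotes are asymmetric.  The slope is
reported as 1/ν.

The irrelevant-feature bias sorts trials by the irrelevant Δ, pools the
relevant levels, and subtracts the level nearest zero (the log-spaced
design's middle level sits at |Δ| < 0.01, not exactly 0; the normalization
tolerance is 0.02).  Easy trials — the relevant-feature extremes, where the
irrelevant feature cannot flip the choice — are excluded using thresholds
just below the design extremes (0.34 for ΔT, 0.29 for ΔI).

The condition-comparison test resamples both tables at the trial level with
replacement (binomial per cell, cell sizes preserved), takes the difference
in mean percent choice per iteration (easy trials excluded), and reports
the one-sided p as the fraction of iterations with difference ≥ 0, 1000
iterations by default.  Curve-shift clouds are built by refitting the
logistic on 1000 bootstrap resamples and summarized as (PSE, mean % choice)
points; separation between conditions is the 10-fold cross-validated error
of a linear SVM (C = 1, our choice).

Congruence accuracy scores each cell against the sign of the relevant Δ,
reports per-class accuracy with a binomial-bootstrap STD, and tests
congruent > incongruent by permuting cell congruence labels (one-sided).

## Spike-train analyses

Rates are trial-averaged in 1-ms steps with a centered 40-ms sliding
window.  The response normalization subtracts the spontaneous rate
(baseline −800 to 0 ms) and divides by the baseline *variance*; a `divisor="std"` switch gives the
conventional z-score.  A zero-variance baseline raises, flagging the neuron
for exclusion.

Population PSTHs are smoothed with a normalized half-Gaussian (σ = 25 ms,
support 4σ): causal (tail into the past) over the first half of the
stimulus epoch, anti-causal over the second, so no smoothed mass crosses
the onset or offset boundary.  Onset/offset detection thresholds the
smoothed rate at baseline mean + 2.2 × baseline STD (baseline −480 to
−20 ms, a second, narrower window than the z-score baseline — both
configurable).  Because the smoothed noise is autocorrelated
on the kernel scale, threshold runs shorter than 25 ms are suppressed, and
the response epoch is taken as the supra-threshold run containing the peak
rate: its opening crossing is the onset, its closing crossing the offset
(sub-bin timing by linear interpolation).  This is a robust reading of
"first upward / last downward crossing" that ignores isolated noise
excursions; detections more than 25 ms from the true stimulus boundary are
flagged as outliers and invalidated.  For the intensity-coding
classification, a neuron's firing rate is its whole-stimulus mean per trial
(a windowing choice); the label-shuffle test is
two-sided with the +1 small-sample correction.

## Synthetic data and what the tests show

The generator's default conditions are the study's: the 7×7 generalization
design around (334 ms, 64 mm/s), a three-class neuron mixture (transient
light-driven, sustained sensory, weakly responsive) whose light currents
produce a clear but non-saturating curve shift, observer τ = 500 ms with
lapse rate 0.1 and unbiased lapses, 100 trials per cell, and a 200-neuron
desk-scale population (5000 and 100 proxies at full scale).  The background
variance σ²_b = 5·10⁴ is set so the no-light accuracy on non-easy
comparisons lands in the high-70s percent range, matching trained-rat
performance, and the intensity→duration coupling (0.10) scales the
mechanoreceptor currents as (I/64)^0.1 — the model's own proposed
mechanism, producing a bias of roughly ±10–15 percentage points across the
ΔI range and a congruent/incongruent accuracy gap of several points.

What passes here shows that every stage is implemented consistently and
recoverable from data *generated by the model itself*.  It does not show
that real vS1 spike trains are Poisson, that real populations are Gaussian
mixtures in parameter space, or that rats integrate with a single common τ;
session drift, per-animal idiosyncrasies, correlated population noise and
stimulus-order effects are all outside the generator.

## Problem sizes and determinism

Default problem sizes (200 neurons, 100–200 trials per cell, 1000
resamples, 200-repetition calibration loops) keep the full suite and the
acceptance script to a few minutes on one CPU; all are arguments, and the
full-scale sizes are available through them.  Every random stage takes an
integer seed or a numpy Generator; a fixed seed reproduces outputs
byte-for-byte, and `GroundTruth` records serialize to JSON and regenerate
their populations identically.
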