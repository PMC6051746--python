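# Methods

## Population model

The core object is a two-pool ODE for cycling progenitors P(t) and
post-mitotic neurons N(t). Each progenitor divides at rate η per hour;
a division is PP with probability α_pp (P → P+1), PN with α_pn (N → N+1),
or NN with α_nn (P → P−1, N → N+2). The fractions sum to 1 and enter the
mean field only through γ = α_pp − α_nn:

    dP/dt = γηP,    dN/dt = (1−γ)ηP

with closed form P(t) = P(0)e^{γηt}, N(t) = N(0) + P(0)((1−γ)/γ)(e^{γηt}−1)
for γ ≠ 0. At |γ| < 1e-9 we switch to the analytic limit
(P constant, N accruing linearly at ηP(0)); the branch uses `expm1`, so the
two sides agree to ~1e-8 relative at the threshold. Assumptions: asynchronous
exponential (memoryless) cycling, no cell death, neurons never divide,
fractions and cycle time constant over the prediction window. All state
counts here are expectations (real-valued); integer realizations live in the
simulators.

**Rate convention.** η = 1/T_c by default — one division per mean cycle
time — with T_c = 12 h as the measured default. The alternative
η = ln2/T_c is exposed (`CycleTiming(rate_convention="log2")`) but the
reciprocal convention is what makes the deterministic-fate table
(T_mode = T_c/α_mode) self-consistent, so it is the default.

**Uncertainty.** Division-mode measurements are class counts, so the
prediction envelope is a percentile bootstrap: resample the counts
multinomially at their empirical fractions (default 2000 resamples,
seeded), propagate each resample through the closed form, take pointwise
2.5/97.5 percentiles of the neuron-fraction curves. A coverage simulation
in the test suite confirms ≥ 90% pointwise-curve coverage at n = 100
scored cells.

**A non-obvious property.** The neuron *fraction* N/(N+P) is not monotone
in general: with γ = 1 and N(0) > 0 it decays as P expands. Starting
neuron-free in a neurogenic regime (γ < 1, N(0) = 0) the ratio N/P rises
monotonically toward its equilibrium (1−γ)/γ, so there the fraction is
non-decreasing — the configuration used in the trajectory tests.

## Deterministic-fate alternative

The same data admit an extreme alternative reading: three progenitor
sub-populations with deterministic fates, cycling at mode-specific rates
α_mode·η. Each mode's putative cycle time is then T_mode = T_c/α_mode,
which satisfies the harmonic closure Σ T_c/T_mode = 1 exactly and inverts
back to the fractions. A 0% class maps to an infinite ("unachievable")
time rather than an error. Rendered tables round to 1 decimal; full
precision is kept internally. When comparing recomputed times to
published ones, note the conditioning: a putative time T computed from a
percentage printed to 1 d.p. carries an input-rounding uncertainty of
about T²/T_c · 0.0005 h, which exceeds 1 h for T ≳ 155 h — comparisons in
the tests use that propagated bound (floored at 0.3 h).

## Stochastic simulators

Both readings are realized as exact continuous-time Markov (Gillespie)
branching processes: waiting time to the next division ~ Exp(ηP), then
either a categorical fate draw (probabilistic-fates simulator) or an
explicit race of three exponential clocks at rates α_mode·η
(competing-clocks simulator; the argmin fixes the fate). By superposition
the two induce identical laws on (P, N) — the point being that
fate-specific rates are observationally hidden, and only the implied
per-mode cycle times distinguish the readings. The two code paths share no
sampling logic, so the suite's two-sample KS test on end-state P is a real
check, as is the z-test of replicate means against the closed form.
Replicates draw from independent streams spawned off one master seed. A
population cap (10⁶ cells) aborts runaway growth with a clear error.

## Percent-labeled-mitoses (PLM) and G2 length

Cumulative S-phase labeling with continuous label availability (re-dosing
every 2 h justifies ignoring label decay), asynchronous steady state
(mitotic ages uniform on [0, T_M]). A mitotic figure is labeled iff it left
S phase after label onset, giving the expected labeled fraction
clamp((t − T_G2)/T_M, 0, 1). Observations are independent binomial draws
per exposure time.

The conventional readout — the time at which the observed curve crosses
50%, linearly interpolated between the bracketing points — sits at
T_G2 + T_M/2 under this model, i.e. it *overestimates* G2 by half the
mitosis length. Both the conventional estimator (default) and a
bias-corrected variant (subtract T_M/2; `--correct-tm` on the CLI) are
provided. Linear interpolation is the declared convention (the published
curves are plotted as straight segments); no sigmoid is fitted. The
estimator raises a descriptive error when the curve never reaches 50% or
is already above it at the first point.

## INM track statistics

Tracks are 1-D apico-basal position series (µm from the apical surface,
5-min frames) anchored at cytokinesis (t = 0); lateral motion is ignored.

- **Classification.** A daughter is Bs iff its position at the nearest
  frame at or after 20 min strictly exceeds 10 µm ("more than" read
  strictly: exactly 10 µm → Ap). A relative-threshold mode (fraction of the
  apico-basal length) is available; the absolute 10 µm is the default used
  for quantification. Tracks ending before the assessment delay raise a
  classification failure rather than guessing.
- **MSD.** All overlapping same-track displacement pairs per lag, averaged
  within track first, then across nuclei; lags capped at min(max_lag, half
  the shortest track). The 95% CI bootstraps over nuclei (default 1000
  resamples) — the nucleus is the exchangeable unit, since within-track
  increments are dependent. The bootstrap curves are kept on the profile.
- **Motion fit.** Weighted least squares of MSD(τ) = 2Dτ vs
  MSD(τ) = v²τ² + 2Dτ (through the origin, non-negative coefficients via
  NNLS; weights from the bootstrap CI widths). The advective model is
  selected iff it lowers the weighted residual *and* the quadratic
  coefficient v² exceeds twice its standard error, where the SE is obtained
  by refitting on the bootstrap MSD curves — the analytic WLS covariance is
  anti-conservative here because per-lag errors are strongly correlated,
  and using it roughly decuples the false-advective rate on pure-diffusion
  data.
- **Speeds.** "Mean speed over the first 20 min" defaults to the mean
  per-frame speed |Δx|/Δt (a net-displacement variant is provided); the
  per-frame mean of drift-diffusion tracks follows the folded-normal
  increment mean, which the tests verify against `scipy.stats.foldnorm`.
- **Fate table.** Counts and row percentages of behaviour (Ap/Bs) ×
  outcome (S-phase re-entry, long G1 > 10 h, not determined).

## Synthetic data: what it does and does not emulate

Generators are deterministic under a fixed seed and write ground-truth JSON
sidecars next to generated files. Defaults are the study conditions:
T_c = 12 h; 365 scored progenitors / 387 clones per readout; 5-min frames;
basal drift 1.10 µm/min; a 50/50 Ap/Bs behaviour mix. Two defaults are
calibrations rather than measurements: basal diffusivity 0.2 µm²/min, and
apical diffusivity 0.35 µm²/min chosen so the generated apical mean
early frame-speed is ≈ 0.26 µm/min under 5-min framing with the apical
reflecting boundary. Nuclear tracks are Euler–Maruyama drift-diffusion
(10 substeps per frame) started at the apical surface with a reflecting
boundary there and an unbounded basal side.

The generators emulate sampling noise only: no embryo-to-embryo random
effects, no reporter misclassification (e.g. PN/NN ambiguity of the
double-positive class), no label-decay kinetics, no imaging noise or track
loss. Passing closed-loop tests therefore shows the estimators are correct
under the stated models, not that the models capture every feature of real
embryos. One physical caveat is load-bearing for tests: near the
reflecting apical boundary, diffusive motion is genuinely sub-diffusive
(the overlapping-pairs MSD of boundary-started tracks runs ~30% below 2Dτ),
so diffusion-estimator recovery is demonstrated on tracks away from the
boundary, and drift-parameter recovery on basal tracks, which escape it.

## Problem sizes and numerical choices

Simulation-based checks use 500–1000 replicates, 10⁴–10⁶ Bernoulli draws
per point, 200 tracks per MSD fit and 100-repetition coverage runs — sizes
at which the relevant Monte-Carlo errors are a few times smaller than the
tolerances asserted. Statistical equivalence tests run at α = 0.01.
Fraction sums are validated to 1e-9 (inputs are normalized counts, so this
only guards construction bypass); harmonic closure is asserted to 1e-9 on
computed outputs and to printed rounding on published tables.

## Known limitations

- No fitting of γ or η to longitudinal data; the model only
  forward-predicts from measured fractions.
- No age-structured (fixed cycle length) variant of the simulators;
  exponential waiting times are assumed throughout.
- The PLM module does not estimate T_S or T_G1 and ignores growth-fraction
  corrections.
- Track analyses assume constant framing and complete tracks over the
  assessment window; nuclei leaving the field raise errors instead of being
  imputed.
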