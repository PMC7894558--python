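# Methods

This note documents the models, defaults and design choices behind
`fermstate`, and what the synthetic experiments do and do not show.

## Kinetic model

States (g/L): glucose (Glu), xylose (Xyl), furfural (Fur), furfuryl
alcohol (FA), 5-hydroxymethylfurfural (5-HMF), acetic acid (HAc),
ethanol (EtOH), biomass (X). Five uptake processes drive the dynamics,
all biomass-specific (rate × X), so X = 0 freezes the system:

* Sugar uptake (S = Glu, Xyl): `v_max·S / (K_S + S + S²/K_i,S)` —
  Monod with substrate inhibition. `K_i = inf` is the documented
  sentinel for "no substrate inhibition".
* Inhibitor uptake (I = Fur, 5-HMF, HAc): `v_max·I / (K_SP + I)`.
* Multiplicative attenuation of sugar uptake: `1/(1 + I/K_i,I,S)` for
  I ∈ {Fur, FA, 5-HMF, HAc}; product inhibition `(1 − EtOH/P_max)^γ`
  (clamped to 0 above P_max to avoid complex powers for non-integer γ);
  xylose additionally carries the glucose competitive factor
  `1/(1 + Glu/K_i,Glu,Xyl)`.
* 5-HMF uptake is suppressed while furfural is present (furfural is
  detoxified first); the model reuses `ki_fur_glu` for this factor since
  the canonical parameter set defines furfural inhibition constants only
  against the two sugars.
* HAc uptake is uninhibited.

The stoichiometric matrix credits EtOH and X from the two sugar uptakes
(yields `y_etoh_*`, `y_x_*`), FA from Fur (`y_fa_fur`) and HAc from
5-HMF (`y_hac_hmf`); each process row consumes exactly one compound.
This yields 8 coupled ODEs with 31 parameters.

**Parameter defaults.** Literature-style initial values for this
organism/medium class were adjusted once so that a reference batch
(Glu 37, Xyl 22, inoculum 1 g/L, dilute-hydrolysate inhibitor levels)
exhausts glucose around 10 h and xylose by ~27 h, inside the 25–35 h
window typical of these fermentations, and so that the standard
identifiable subset (`vmax_glu`, `ki_hac_glu`, `ki_glu_xyl`) is actually
informative on hourly sampled data: acetate inhibition is strong enough
(`ki_hac_glu` = 5 g/L) that the declining HAc level modulates glucose
uptake over the batch, and the glucose-to-xylose transition
(`ki_glu_xyl` = 3 g/L) spans several sampling intervals. All defaults
are overridable through the flat YAML config.

**Numerics.** `simulate` integrates with LSODA (adaptive,
stiffness-switching) at rtol 1e-8 using the analytic Jacobian, assembled
by the product rule over the univariate factors of each rate; rates
evaluate `max(state, 0)` so integrator overshoot cannot feed back, and
outputs are floored at 0 (tolerance ~1e-9). Identification runs the
same integrator at rtol 1e-7 with a finite-difference step of 1e-5 so
optimizer gradients sit well above the integrator noise floor.

## Identification

Nonlinear least squares (scipy trust-region reflective, positivity
bounds, x-scaled by the initial guess) on unweighted concentration
residuals of the measured profiles (Glu, Xyl, Fur, EtOH by default).
Local sensitivities are central finite differences (relative step 1e-3),
scaled by θ_j and by the range of each output over the horizon; the
importance measure is the root-mean-square of the scaled sensitivities
and subset identifiability is the collinearity index
1/√λ_min of the normalized sensitivity Gram matrix.

The bootstrap resamples residuals with replacement *within each measured
state* (pools of different analytes are never mixed, preserving their
different error scales), adds them to the reference prediction
unclipped — flooring near-zero synthetic readouts at zero would bias the
profile tails upward — and re-estimates the free parameters starting
from the reference estimate. The population mean, SD and covariance are
reported. Note the population mean carries a visible positive skew-bias
for the inhibition constants (a property of the nonlinear estimator);
uncertainty statements should center on the reference estimate with the
bootstrap SD, which is what the recovery tests do. Monte Carlo
propagation draws parameter vectors from N(mean, covariance) truncated
at positivity and reports 2.5/50/97.5% bands per state.

## Chemometrics

Preprocessing: crop to 950–1550 cm⁻¹, first difference along wavenumber
(kills constant baselines; output length = window − 1), mean centering
with stored training means. PLS1 per analyte via scikit-learn's NIPALS
implementation; the latent-variable count minimizes leave-one-out
RMSECV, with a parsimony tie-break (smallest LV within 1% of the
minimum, plus a tiny absolute floor so exact-rank noiseless problems
choose the minimal rank). Explained variance in X is computed from the
score/loading reconstruction, in Y from the training R². Models
serialize to a versioned plain-text format (window, LV count, centering
vectors, coefficients) and predict without scikit-learn at run time.

## Calibration design

Latin hypercube over the box Glu 0–40, Xyl 0–25, EtOH 2.5–32.5 g/L:
one uniform draw per equal-width stratum per analyte, independently
permuted columns. Candidates are ranked by the mean *absolute* pairwise
Pearson correlation (a strong negative correlation is as harmful to a
calibration as a positive one) and the minimum is kept; candidate i is
drawn from the i-th spawn of the seed sequence, so enlarging the
candidate count with the same seed never worsens the selection.

## State estimator

Continuous-discrete EKF. Prediction jointly integrates the mean ODE and
the Lyapunov covariance ODE dP/dt = A(x)P + PA(x)ᵀ + Q with A the
Jacobian along the mean (a config switch provides the literal one-step
transition form P⁺ = e^{A dt} P e^{Aᵀ dt} + Q for comparison; the
continuous form is the default). The measurement is the per-analyte
median of the PLS predictions of the 15 spectra collected since the
last update — the median rejects isolated spikes; even counts average
the central pair. Update is the standard gain
K = PCᵀ(CPCᵀ + R)⁻¹ with C the (Glu, Xyl, EtOH) selector; the posterior
is symmetrized and floored at zero (covariance untouched); a singular
innovation covariance skips the update. An empty spectra window
degrades to a prediction-only step.

R1/R2: estimated from a clean tuning batch as the per-phase *mean
squared* PLS-vs-reference residual — the second moment about zero, so
the systematic matrix-interference bias of the glucose phase is
absorbed into R rather than averaged away. The phase switch (R1→R2)
latches the first time estimated Glu drops strictly below
K_i,Glu,Xyl/4; the biology is irreversible, so the filter never
switches back. Confidence bands are ±3σ from the posterior diagonal
(multiplier configurable, e.g. 1.96 for a nominal 95% band; 3σ is kept
as the default convention).

Initial covariance reflects how a batch is started: the t0 off-line
sample fixes the concentrations to HPLC repeatability (SD 0.3 g/L →
variance 0.09) and the inoculum dry weight fixes biomass to ~0.1 g/L
(variance 0.01). This matters: the linearized glucose subsystem is
unstable early in the batch (substrate inhibition plus autocatalytic
biomass growth), so initial uncertainty grows along the trajectory and
directly sets how much the filter trusts the spectral measurements.

Q tuning grows an isotropic q·I by √10 per step from 1e-7 until the
full-filter RMSE against off-line samples stops improving by >2% or
reaches the reference noise SD.

## Virtual plant

The synthetic generator emulates the fermenter plus ATR-MIR instrument:

* **Truth**: the kinetic model under "true" parameters — by default the
  estimator's parameters perturbed by 10–25% on five constants
  (`validation_params`), emulating batch-to-batch hydrolysate and
  inoculum variability.
* **Glycerol** (spectral interferent only, not a model state) rises in
  proportion to glucose consumption to a 3 g/L plateau and stays
  constant through the xylose phase.
* **Spectra**: Beer–Lambert sums of fixed Gaussian-band absorptivity
  profiles on the instrument grid (428–1833 cm⁻¹, 1 cm⁻¹). The analyte
  bands overlap strongly but remain identifiable (condition number ~4
  in the working window). Glycerol's C-O bands sit on top of the
  xylose/ethanol bands and the biomass profile combines broad
  scattering, an amide-II band and cell-wall glucan bands shadowing
  glucose. Calibration samples are prepared in the end-of-fermentation
  matrix (glycerol at plateau, residual biomass), so early-batch matrix
  changes are *not* represented in the calibration — this is what
  produces the characteristic artifacts: the predicted xylose drifts
  upward through the glucose phase and ethanol is biased early, while
  predictions recover in the xylose phase.
* **Noise**: calibration spectra 2e-5 a.u. (static, long-averaged
  samples); in-line batch spectra 1e-3 a.u. (flowing, solids-laden
  broth), which yields ~0.7–2 g/L per-spectrum prediction scatter —
  the error level at which a spectroscopic soft sensor on hydrolysate
  actually operates. Off-line samples carry 0.3 g/L HPLC noise.
* **Disturbances**: "clog" fades the live signal toward a stale
  spectrum attenuated by a fouling film plus an elevated broad
  baseline, with abrupt recovery at the window end — the PLS
  predictions collapse transiently; "bubble" injects isolated spikes.

What passing tests show — and don't. The virtual plant demonstrates the
estimator's mechanics (fusion, phase switching, disturbance rejection,
uncertainty bookkeeping) under a known ground truth with Gaussian
noise, linear mixing and a smooth interference structure. Real ATR-MIR
spectra have nonlinear baselines, temperature sensitivity, drift and
scattering physics none of which are modeled; real kinetic mismatch is
structural, not only parametric. Quantitative RMSE levels transfer to
real data only in order of magnitude.

## Problem sizes used by the test suite

The acceptance-style experiments run at the scale of the emulated
study: 30 h batches at one spectrum per minute, 21-sample calibration
with 2,000–10,000 design candidates (100,000 is the CLI default for
production use), 100 bootstrap replicates × 20 seeded experiments for
parameter recovery, and 20 seeded runs × 48 updates for filter
consistency. The full suite runs in roughly ten minutes on one core.

## Known limitations

* Batch operation only; the external-input hook u(t) for fed-batch is
  reserved but unimplemented.
* No temperature/pH dependence, oxygen, or glycerol as a modeled state.
* Q/R adaptation is limited to the iterative tuning rule; no innovation
  gating or outlier-robust update is applied, so a sufficiently long,
  severe measurement corruption will still pull the posterior.
* The bootstrap covers parameter uncertainty conditional on the model
  structure; structural mismatch is out of scope (and is exactly what
  the filter's Q must absorb in deployment).
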