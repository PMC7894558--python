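# fermstate

Hybrid soft sensor for real-time monitoring of lignocellulosic
(cellulose-to-ethanol) batch fermentations.

Fermentations of lignocellulosic hydrolysate co-consume glucose (Glu)
and xylose (Xyl) in the presence of inhibitors (furfural, 5-HMF, acetic
acid), and no single on-line measurement of the key concentrations is
reliable: ATR mid-infrared spectra read through a PLS calibration are
fast but biased by matrix effects (glycerol, biomass) and sensor faults
(bubbles, clogging of the recirculation loop), while a purely kinetic
model drifts whenever a batch deviates from the conditions it was
identified on. `fermstate` fuses the two with a continuous-discrete
extended Kalman filter (CD-EKF) so that process engineers get smooth,
disturbance-tolerant estimates of Glu, Xyl and ethanol (EtOH) every 15
minutes — the information needed for feed-rate or corrective control.

## The method

**Internal model.** Eight states x = (Glu, Xyl, Fur, FA, 5-HMF, HAc,
EtOH, X) in g/L evolve as dx/dt = f(x, p): five biomass-specific uptake
rates (Monod with substrate inhibition for the sugars, plain Monod for
the inhibitors), attenuated multiplicatively by inhibition factors
1/(1 + I/K_i), product inhibition (1 − P/P_max)^γ and the competitive
inhibition of xylose uptake by glucose, then mapped to the states
through a fixed stoichiometric (yield) matrix. The 31 parameters are
identified off-line by nonlinear least squares with a sensitivity /
collinearity analysis to pick an identifiable subset, and a residual
bootstrap for uncertainty.

**Data-driven model.** Three independent PLS1 regressions predict Glu,
Xyl and EtOH from the 950–1550 cm⁻¹ window of each spectrum (first
derivative + mean centering), calibrated on 21 semi-synthetic samples
laid out by a correlation-minimized Latin-hypercube design; latent
variables are chosen by leave-one-out RMSECV.

**Fusion.** Between updates, mean and covariance propagate through the
model (dP/dt = AP + PAᵀ + Q, A the model Jacobian); every 15 min the
median of the 15 per-minute PLS predictions forms the measurement
y = Cx + v, updated with the standard Kalman gain. The measurement
covariance switches once, from R1 to R2, when estimated Glu falls below
K_i,Glu,Xyl/4 (start of the xylose phase, where matrix interference is
weak); ±3σ bands come from the posterior covariance. Q is tuned by
growing an isotropic q·I from 1e-7 until the estimates match off-line
reference samples.

A built-in virtual plant (kinetic truth + Beer–Lambert spectra with
overlapping bands, glycerol/biomass matrix interference, per-minute
acquisition, hourly HPLC-style samples, clogging/bubble disturbances)
makes every part of the pipeline runnable and testable with no external
data.

## Worked example

```python
from fermstate import build_calibration, run_hybrid_comparison

# 21-sample Latin-hypercube calibration (10,000 candidates) + PLS models
design, cal, models = build_calibration(seed=2, n_candidates=10_000)
print("design score:", round(design.score, 4))
for analyte, model in models.items():
    print(f"{analyte}: {model.n_lv} LVs, X var {100*model.explained_x:.1f}%, "
          f"Y var {100*model.explained_y:.2f}%")

# 30 h virtual batch with matrix interference and a 30-min clog at 2 h,
# monitored with the CD-EKF; RMSE vs truth at the hourly sample times
cmp_ = run_hybrid_comparison(seed=1, models=models)
for a in ("glu", "xyl", "etoh"):
    print(f"{a}: PLS RMSE {cmp_.pls_rmse[a]:.2f} g/L, "
          f"hybrid RMSE {cmp_.hybrid_rmse[a]:.2f} g/L, ratio {cmp_.ratios[a]:.2f}")
```

prints

```
design score: 0.0091
glu: 4 LVs, X var 98.5%, Y var 100.00%
xyl: 4 LVs, X var 98.5%, Y var 100.00%
etoh: 4 LVs, X var 98.5%, Y var 100.00%
glu: PLS RMSE 3.83 g/L, hybrid RMSE 1.25 g/L, ratio 3.06
xyl: PLS RMSE 1.49 g/L, hybrid RMSE 0.83 g/L, ratio 1.78
etoh: PLS RMSE 1.59 g/L, hybrid RMSE 1.18 g/L, ratio 1.35
```

The design score is the mean absolute pairwise Pearson correlation of
the calibration concentrations (near zero = independent factors). Each
PLS model explains ≥95% of both the spectral (X) and concentration (Y)
variance at its cross-validated latent-variable count. On the disturbed
batch the raw PLS predictions carry the glycerol/biomass bias and the
clog transient; the hybrid filter suppresses both, improving RMSE by
1.3–3× per analyte.

## Command line

```bash
fermstate design   --samples 21 --candidates 100000 --seed 1 --out design.csv
fermstate simulate --config scenario.yaml --out batch/ --seed 1
fermstate calibrate --spectra cal_spectra/ --references refs.csv --out models/
fermstate monitor  --spectra batch/spectra --models models/ \
                   --config scenario.yaml --update-min 15 --out monitor.csv
fermstate identify --offline batch/offline.csv --config scenario.yaml
fermstate tune-q   --spectra batch/spectra --models models/ \
                   --config scenario.yaml --offline batch/offline.csv
```

Spectra are plain two-column text files (wavenumber cm⁻¹, absorbance),
one per minute; concentration tables are CSV with a `time_h` column;
configuration is flat YAML. Every command writes a JSON run log with the
seed, config hash and package version.

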