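# kpqspr

QSPR models of the gas/particulate partition coefficient (**K_P**) for
polycyclic aromatic hydrocarbons and their oxygen/nitrogen derivatives.

Semi-volatile aromatics — PAHs, their oxidized and nitrated derivatives,
and azaarenes — partition between the gas phase and suspended particles
in the atmosphere, which controls their transport, deposition and
exposure pathways. The equilibrium is characterized by

```
K_P = C_P / (C_A · TSP)      [m³/µg]
```

with C_P, C_A the particle- and gas-phase concentrations (ng/m³) and TSP
the total suspended particulate concentration (µg/m³). Measuring K_P is
slow and limited by standards for the rarer derivatives, so predictive
models from molecular descriptors fill the gaps for risk assessment.

This package implements, as a tested reusable library, a complete QSPR
workflow for log K_P over a canonical 50-compound dataset (22 PAHs, 15
O-PAHs, 9 N-PAHs, 4 azaarenes) that ships as a packaged CSV:

* **log K_OA surrogate model** — log K_P = 0.643·log K_OA − 8.287
  (R² = 0.801): the traditional one-descriptor route.
* **Two-descriptor MLR model** —
  log K_P = 0.031·α − 24.45·V_s.min − 9.36 (R² = 0.847), where α is the
  average molecular polarizability (a.u.; dispersion interaction with
  particles) and V_s.min the most negative molecular-surface
  electrostatic potential (eV; hydrogen-bond acceptance). Full
  diagnostics: SEs, t, p, VIF, 95 % prediction intervals.
* **Validation suite** — R²/Q²/RMSE/MAE/MPE/MNE/BIAS bundles, fixed
  35/15 external validation, leave-one-out CV, and the Roy et al.
  error-based criteria for systematic error and predictive ability.
* **Applicability domain** — Williams-plot data: leverages against
  h* = 3p/n = 0.180, standardized residuals against |StdR| < 3, and
  training descriptor ranges.
* **RBF-SVR counterpart** — γ/C grid search (10⁻²–10⁴) with seeded,
  class-stratified 10-fold CV and a contour-ready grid export.
* **Synthetic-data generator** — linear-Gaussian datasets over the real
  descriptor ranges for parameter-recovery and coverage calibration.

The modelling surface follows the Model/Results idiom: build a
`KpLinearModel`, call `.fit()`, and work with the returned `LinearFit`
(summary table, predictions, intervals). Convenience functions
(`fit_ols`, `fit_koa_model`, `external_validation`, …) wrap the same
objects, and a thin `kpqspr` CLI exposes the main operations.

## Worked example

```python
import kpqspr as k

ds = k.load_table1()          # the packaged 50-compound dataset
fit = k.fit_ols(ds)           # log K_P ~ alpha + vsmin
print(fit.summary())
```

```
OLS fit of log_kp_exp on alpha, vsmin
n = 50, parameters = 3, R² = 0.847, residual SD = 0.596

term                coef        SE         t           p     VIF
intercept        -9.3568    0.4334   -21.592    4.86e-26
alpha             0.0308    0.0019    15.832    1.83e-20   1.056
vsmin           -24.4434    3.6858    -6.632    2.96e-08   1.056
```

Each a.u. of polarizability raises log K_P by ~0.031 (larger molecules
bind particles more strongly through dispersion); a more negative
surface potential (stronger H-bond acceptor) likewise pushes the
compound toward the particle phase. Both descriptors are significant
(p < 0.001) and essentially uncorrelated (VIF = 1.056).

```python
ext = k.external_validation(ds)       # fixed 35/15 split
print(ext.validation_metrics.as_dict())
# {'n': 15, 'r2': 0.855, 'q2': 0.851, 'rmse': 0.537, 'mae': 0.44,
#  'mpe': 0.828, 'mne': -0.946, 'bias': 0.03}

iv = fit.predict_interval(ds["BaP"], level=0.95)[0]
print(f"{iv.point:.3f}  [{iv.lower:.3f}, {iv.upper:.3f}]")
# -1.017  [-1.382, -0.651]      # benzo[a]pyrene, 95% mean-response CI

ad = k.williams_report(ds, fit)
print(ad.h_star)                       # 0.18
max(abs(p.std_residual) for p in ad.points)   # 2.007 — all inside |StdR| < 3
```

External-set predictive power (R² ≈ 0.85 at RMSE ≈ 0.54 log units)
matches the training fit, and every compound sits inside the leverage
domain with standardized residuals under 3 — the model is applicable
across α ∈ [99.8, 280.6] a.u. and V_s.min ∈ [−0.095, −0.025] eV.

The reproduction workbench compares every recomputed statistic against
its published reference value:

```
kpqspr reproduce --format markdown
```

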