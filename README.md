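# stagefit

Staged fitting and validation of many-parameter physiological models.

Mechanistic models of integrated physiology — cardiorespiratory exercise
models in particular — routinely carry hundreds of parameters, far more
than any cardiopulmonary exercise test can constrain. `stagefit`
implements a complete strategy for calibrating such models against
per-subject steady-state data at incremental exercise levels:

1. **Role classification.** Every parameter is tagged as time constant,
   conversion constant, covariate, initial value, or gain/threshold.
   Only gains/thresholds are ever fitted; covariates are *standardized*
   (fixed from the recorded experimental conditions).
2. **Identifiability screening.** Per stimulus level k and perturbation
   h_l, the residual Jacobian `J_ij = ∂(y_exp,i − y_sim,i)/∂u_j` is
   decomposed by SVD; the numerical rank ρ is set by the tolerance
   `σ_ρ/σ_1 > ε`, and pivoted QR of the leading right singular vectors
   `V_ρᵀ` orders parameters by how well-conditioned their joint
   estimation is. Scores are RMS-aggregated over levels and
   perturbations into a ranking `Z_j`.
3. **Error-weighted sensitivity ranking.** Steady-state relative
   sensitivities `s_ijlk = |ΔY/Y| · |1/h_l|` are aggregated into
   per-variable (`s_ij`) and total (`s_j`) rankings, weighted by the
   nominal model's error shares `P_ik` and `P_i` (which sum to one) so
   that screening emphasises exactly what the fit must repair.
4. **Three sequential CMA-ES stages** — base (global accuracy), specific
   (one parameter per variable, chosen for specificity), and
   stimulus-related (one parameter per exercise mechanism and regulatory
   activity) — each freezing everything fitted before it, inside
   proportional bounds (±30% of nominal by default), minimizing the
   relative-RMSE cost

   ```
   CF = (1/I) Σ_i sqrt( (1/K) Σ_k ((y_exp,ik − y_sim,ik)/y_exp,ik)² )
   ```

5. **Validation**: prediction error
   `PE = (1/N) Σ_v Median_{s,l} |y_exp − y_sim|/|y_exp| × 100%`,
   percent change from rest, settling time into a ±5% band, and paired
   Wilcoxon signed-rank comparisons between consecutive stages.

Everything is exercised end to end on **MiniCR**, a bundled miniature
cardiorespiratory fixed-point model (chemoreflex ventilation control,
alveolar gas exchange, breathing-pattern and cardiovascular loops,
first-order transients) with a synthetic-cohort generator that has
known ground truth — so fitting accuracy is exactly measurable.

## Worked example

```python
from stagefit import minicr_model, fit_protocol, simulate_steady_state
from stagefit.benchmark import run_recovery_benchmark

model = minicr_model()
resp = simulate_steady_state(model, None, fit_protocol())
print(resp.values.round(2))

out = run_recovery_benchmark(seed=1, n_subjects=20, measurement_cv=0.05)
for st in out.result.stages:
    print(f"{st.stage:9s} CF {st.cf_initial:.4f} -> {st.cf_final:.4f}")
print(f"PE nominal {out.pe_nominal:.2f}% -> fitted {out.pe_fitted:.2f}%")
```

The steady-state table (variables × levels at V̇CO₂ = 0.3, 0.6,
0.9 L/min) shows textbook rest physiology in column 0 and a plausible
exercise response across columns:

```
            0       1       2
VE       9.19   16.46   23.22
VT       0.57    0.70    0.76
BF      16.13   23.52   30.39
TI       1.49    1.02    0.79
HR      70.18   91.35  112.53
PS     119.37  138.42  147.67
PD      79.28   87.75   86.41
PM      92.64  104.64  106.83
PAO2   104.25  102.13  100.26
PACO2   38.52   40.32   41.91
```

The recovery benchmark generates a 20-subject cohort from a truth whose
gains are perturbed away from nominal (heart-rate intercept/slope, CO₂
transfer efficiency, dead space, exercise vasodilation), then runs the
three stages:

```
base      CF 0.0556 -> 0.0516
specific  CF 0.0516 -> 0.0230
stimulus  CF 0.0230 -> 0.0142
PE nominal 5.81% -> fitted 3.46%
```

Each stage strictly reduces the cost; with 5% measurement noise all five
perturbed gains return within 3% of their true values, and the fitted
model roughly halves the nominal model's prediction error. With zero
noise the recovery is exact (final cost ~1e-10).

## Command line

```sh
stagefit --config config.yaml --seed 1 --out runs/demo all
```

runs synth → screen → select → fit → validate, writing tidy TSV/JSON
artifacts plus the fully resolved configuration at every step; each
subcommand can be rerun from the saved artifacts of the previous ones.

## Scope

The framework fits steady-state response magnitudes; parameters that
shape transient dynamics (time constants, initial values) are screened
out by design. See `docs/methods.md` for the model equations, the
screening and selection rules in detail, numerical choices, and known
limitations.
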