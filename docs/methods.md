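# Methods

## Problem setting

A physiological model exposes a parameter vector `u` (hundreds of
entries for full-scale cardiorespiratory models) and predicts a set of
observed variables `Y_i` at each exercise level `k`, specified as a
(V̇O₂, V̇CO₂) pair. Experimental data are per-subject steady-state
values of the same variables at the same levels, restricted to each
subject's anaerobic threshold (AT) because aerobic-exercise models are
not valid above it. The goal is to fit a *small, identifiable, and
physiologically interpretable* subset of parameters, then validate the
fitted model in both steady state and transient regimes.

## Parameter roles

Each parameter carries exactly one role:

| role | fitted? | rationale |
| --- | --- | --- |
| `gain_threshold` | candidate pool | modulates or saturates mechanisms; governs response magnitude |
| `covariate` | standardized | recorded experimental conditions (FiO₂, FiCO₂, Patm, rest metabolic rates) |
| `conversion` | never | physical constants |
| `time_constant` | never | shapes transients, invisible to steady-state data |
| `initial_value` | never | integrator state, invisible to steady-state data |

Clinically non-modifiable gains can be flagged `excluded`; they never
enter any candidate set (MiniCR flags its pulse-pressure offset `PP0`
to exercise this rule).

## Screening

Both screens run over a perturbation grid: the five-point uniform ±5%
grid is represented by its four nonzero fractions
h ∈ {−0.05, −0.025, +0.025, +0.05}, the nominal point serving as the
reference of every difference quotient (h = 0 would make the relative
sensitivity undefined).

**Subset selection.** Per (level k, variation l): SVD of the residual
Jacobian; numerical rank ρ = #{p : σ_p/σ_1 > ε} with
ε = √(optimizer function tolerance) = 1e-6; pivoted QR of `V_ρᵀ` orders
the columns; the parameter at pivot position p is assigned the
normalized singular value σ_p/σ_1 (zero where p exceeds the number of
singular values, hence below ε beyond the rank). Aggregation is RMS
over levels first (`Z_jl`), then over variations (`Z_j`). Jacobians use
forward differences with step 1e-6·|u| (floor 1e-9); a central-difference
oracle lives in the test suite, never in the implementation path.

**Sensitivity analysis.** `s_ijlk = |Y((1+h_l)u_j) − Y(u)| / |Y(u)| ·
1/|h_l|`, one parameter at a time. RMS over variations gives `s_ijk`.
Error weights are shares of the nominal model's relative error:
`P_ik = E_ik/(K·E_iT)` with `E_ik` the absolute relative error and
`E_iT` its mean over levels, so `Σ_k P_ik = 1` identically; the
per-variable weights use the mean *squared* relative error `E_i` and
its mean over variables `E_T`, giving `Σ_i P_i = 1`. Then
`s_ij = RMS_k(P_ik · s_ijk / max_j s_ijk)` and
`s_j = RMS_i(P_i · s_ij / max_j s_ij)`. All rankings break ties by
registry order (stable sorts), so results are deterministic.

Cells where every parameter has zero sensitivity are excluded with a
warning; a reference steady state below 1e-12 in magnitude is an error
(relative quantities are undefined there).

## Selection

* **Standardization** fixes covariates by direct equivalence with the
  dataset record.
* **Base set**: candidates with `Z_j > ε`, plus the total-sensitivity
  ranking walked in descending order taking a parameter only when its
  subsystem is not yet covered, until every declared subsystem and
  controller has at least one selected parameter.
* **Specific set**: one parameter per observed variable. The stated
  intent — high sensitivity for the variable of interest, low for the
  rest — is made monotone by a specificity score: with `s̃_ij` the
  per-variable max-normalized sensitivity,
  `score = s̃_ij − max_{i′ unrelated to i} s̃_i′j`, where relatedness is
  a model-declared subsystem adjacency (controller ↔ controlled
  system). Candidates from unrelated subsystems and base-set members
  are removed first; a parameter serves at most one variable, conflicts
  resolved in favour of the higher score (the loser takes its next
  admissible candidate); variables with no admissible candidate are
  left unassigned with a warning.
* **Stimulus set**: one remaining free parameter per (mechanism,
  regulatory-activity) tag, the one with the highest `s_j`.

Reduction percentages are reported to one decimal,
round-half-away-from-zero. On a full-scale registry layout (316
parameters: 12 covariates, 1 conversion, 239 gains/thresholds with one
excluded, 24 initial values, 40 time constants) the canonical counts —
216 candidates after standardization; 8, 9, and 15 parameters in the
three stages — give reductions of 31.6%, 97.5%, 97.2% and 95.3%.

## Fitting

Cost: `CF = (1/I) Σ_i sqrt((1/K) Σ_k rel_ik²)` against the
across-subject mean at each level of the AT-truncated dataset.

Bounds are proportional to nominal (±30% default), with per-parameter
literature-style overrides (e.g. an elastance allowed (−70%, +30%)) and
registry-level mechanism constraints. The optimizer works on
coordinates scaled to [0, 1] over the bound range.

CMA-ES settings (defaults): function tolerance 1e-12; step tolerance
1e-3 *relative to the run's initial step size* (an absolute step
tolerance on scaled coordinates would freeze refinement near 1e-4 and
contradict the exact-recovery behaviour the suite verifies); iteration
cap 100·N²; 500 function evaluations per restart; up to 10 restarts;
population 4 + ⌊3 ln N⌋; initial coordinate-wise step 0.2·(UB−LB).
Box constraints are handled by repair: out-of-box samples are clipped,
evaluated, and fed back, so every evaluated and reported point is
feasible (reported values are nudged strictly inside the box).
Restarts are *chained*: each resumes from the incumbent best with the
initial step shrunk by 0.35 per restart, making the small per-restart
budget cumulative — a deliberate design choice; independent random
restarts with a 500-evaluation budget cannot refine mid-sized stages to
the cost floor the recovery tests require. The best-ever candidate is
always reported, never the last.

The three stages run base → specific → stimulus; each freezes the
standardized covariates and all previously fitted values, so the cost
is non-increasing across stage boundaries (the next stage starts at the
previous stage's optimum). Stage seeds derive from the master seed via
a seed sequence; identical inputs and seed give identical results.

## Validation

* `PE` (%): per variable, the median absolute relative error jointly
  over subject × level pairs (median-of-medians is *not* used), then
  the mean over variables, ×100. Each subject is compared against the
  single cohort-level simulation on the eight-step validation grid
  (V̇CO₂ 0.3 → 1.0 L/min), after AT truncation.
* Percent change from rest: `(y(t) − y₀)/y₀`.
* Settling time: time from stimulus onset until the response
  *permanently* stays within ±5% of its final value (the last-minute
  average); permanence is defined by suffix containment, so a trace
  that re-exits the band settles only at its final entry. A final value
  indistinguishable from zero falls back to 5% of the step magnitude
  with a warning. First-order traces settle at τ·ln 20, which the suite
  checks across τ ∈ {10, 50, 100, 400} s.
* Stage comparison: paired two-sided Wilcoxon signed-rank on
  per-subject PE between consecutive stages (chosen because these
  errors are not normally distributed), flagged at 0.05/0.01; skipped
  below five subjects. Subsystem tables report mean ± SD across
  subjects of per-subject subsystem PE.

## The MiniCR demo model

A deliberately small fixed-point model preserving the subsystem
structure, observed-variable set (V̇E, VT, BF, TI, HR, PS, PD, PM,
PAO₂, PACO₂), and nonlinearity classes of full-scale cardiorespiratory
models: hyperbolic alveolar gas exchange
(PACO₂ = PICO₂ + 863·V̇CO₂/(co2_eff·V̇A)), a saturating ventilatory
controller with linear central CO₂ drive, exponential hypoxic drive and
linear metabolic drive, solved as a scalar fixed point in V̇A
(bracketed bisection then Newton polish, residual < 1e-10, unique for
positive chemoreflex gains because the drive is strictly decreasing in
V̇A), linear breathing-pattern and cardiovascular relations, and
first-order transients with one time constant per subsystem group
(respiratory 60 s, cardiovascular 40 s, gas stores 120 s). Transients
use the exact exponential update, so integration cannot fail and the
last-minute average of a long simulation matches the fixed point to
round-off. Nominal values were chosen once, inside textbook ranges, so
rest outputs are plausible (HR ≈ 70 bpm, PACO₂ ≈ 39 mmHg,
V̇E ≈ 9 L/min); they are frozen in `minicr.py` and tests depend on
them.

Default protocols: fitting uses three equidistant levels at V̇CO₂ =
0.3, 0.6, 0.9 L/min (rest, intermediate exercise, and the cohort's
expected mean AT — a top level of 1.0 would be emptied by AT truncation
for nearly every subject); validation uses eight equidistant steps from
0.3 to 1.0 L/min. V̇O₂ is derived from V̇CO₂ with a respiratory
exchange ratio of 0.85. Levels run 3000 s with steady state read as the
final-minute average.

## Synthetic cohorts

The generator emulates the structure of cardiopulmonary exercise
cohorts: per-subject steady-state observations at every grid level,
environment covariates, a per-subject AT (uniform over the top two
inter-level spans of the grid), and optional first-load-step transients.
Subject-level true gains scatter around the cohort truth with mean-one
multiplicative lognormal variability (default CV 8%); observations get
mean-one lognormal measurement noise (default CV 5%, typical of
metabolic-cart summary measurements). Both choices keep variables
positive and make errors scale with magnitude. Zero noise reproduces
the truth simulation exactly, so the fitting cost is zero at the true
parameters. Seeding is hierarchical — subject i draws from
`default_rng([seed, i])` — so enlarging a cohort never changes existing
subjects.

What the generator does *not* emulate: breath-by-breath and beat-by-beat
variability, drift or fatigue within a level, missing data, and
structural model error (the data-generating model is the model being
fitted). Passing recovery tests therefore demonstrate the correctness
of the screening/fitting machinery, not robustness to model
misspecification.

## The recovery benchmark

`stagefit.benchmark` fixes a truth with five gains perturbed away from
nominal (HR0 +5%, kHR +12%, co2_eff −10%, VD0 +20%, phi +15%) and a
hand-specified three-stage plan: base {HR0, kHR}, specific
{PACO₂ → co2_eff, V̇E → VD0}, stimulus {phi}. The plan is fixed rather
than taken from the screening pipeline because sequential freeze
semantics only reach the exact truth when stage sets respect the
model's output blocks: within each block of outputs, all perturbed
parameters must be fitted in one stage, and earlier stages must not fit
parameters whose outputs later-stage perturbed parameters also touch —
otherwise an early stage biases its values to compensate errors it
cannot fix, and the bias persists. With the block-compatible plan, each
stage strictly reduces the cost, noise-free recovery is exact (final
cost ~1e-10, parameter errors ~1e-7), and the 20-subject 5%-noise
setting recovers all perturbed gains within a few percent while roughly
halving the nominal model's PE. The full selection pipeline (screen →
select → fit) remains the CLI's default path.

## Numerical choices and degenerate inputs

* Fixed-point solver: bisection bracket [V̇A_min, 100] L/min (expanded
  ×2 up to 1e4 before erroring), 60 bisection iterations, Newton polish
  to residual 1e-10, cap 200 iterations; saturation at the ventilation
  floor returns exactly V̇A_min.
* Chemoreflex exponent clipped at 50 to avoid overflow during
  bracketing at extreme parameter draws.
* All-zero Jacobians, zero experimental values, and sub-1e-12 reference
  outputs are hard errors naming the offending variable/level; all-zero
  sensitivity slices and unassignable variables are warnings.
* Levels are 0-based internally and 1-based in every report and file.

## Known limitations

* Only steady-state magnitudes are fitted; transient-shape parameters
  are out of scope by design.
* The specificity score is a monotone surrogate for a qualitative rule;
  other surrogates could pick different specific-stage parameters when
  sensitivities are nearly tied.
* Pivoted QR is greedy: only its first pivot is provably the exhaustive
  optimum (over single columns of `V_ρᵀ`); deeper positions are
  heuristic, as in all published uses of this method.
* The statistical stage comparison assumes exchangeable per-subject
  errors; with fewer than ~8 subjects the signed-rank test has little
  power and is reported but rarely significant.
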