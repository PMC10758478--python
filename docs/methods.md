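# Methods

## Model structure and assumptions

The engine is a cohort partitioned survival model (PSM) with three mutually
exclusive states: progression-free (PF), progressed (PD), dead. Unlike a
state-transition model, the PSM never estimates transition probabilities:
occupancy is read directly off two independent survival curves,
`pf = min(S_PFS, S_OS)`, `pd = S_OS − pf`, `dead = 1 − S_OS`. The min()
clipping handles configurations where a fitted PFS curve crosses above OS
(logged, never an error, since independently fitted curves can cross in the
extrapolated tail). The price of the PSM's simplicity is its assumption
that the two curves can be varied independently — there is no structural
link between progression and death, and sensitivity analysis cannot
propagate efficacy uncertainty unless curve parameters themselves are
sampled.

Everyone starts in PF. An optional background-mortality floor
`S_OS'(t) = min(S_OS(t), (1−p)^(t/12))` with annual probability `p` caps
extrapolated survival; the default configuration sets `p = 0` because no
specific life table or cohort age is part of the published inputs, and at
any plausible general-population mortality the floor never binds inside the
10-year horizon (general-population 10-year survival ≈ 0.85 vs ≈ 0.03–0.06
for these cohorts).

## Time grid, discounting, evaluation conventions

One-month cycles, 120 cycles (10 years), discount factor
`(1 + r)^(−t/12)` with annual rate `r = 0.03` (range 0–5% in sensitivity
analysis). Three conventions are explicit configuration, because the
original analysis was produced in a GUI tool that does not document them:

- **eval_point** ∈ {start, mid, end}: where within each cycle occupancy and
  discounting are evaluated ("mid" is the classical half-cycle correction).
- **days_per_cycle** ∈ {30, 30.4375}: pricing basis for daily-dosed oral
  drugs (packs are priced per 30 tablets).
- **treatment_duration** ∈ {until_progression, until_death}: whether drug
  acquisition is charged on PF occupancy only, or on all alive patients.

`analysis/03_convention_grid.py` sweeps all 12 combinations against the
published base-case table. Two findings are frozen into the default
configuration: evaluation at cycle **end** with **30** days per cycle fits
best, and **until_death** is required — charging drug only during PF
reproduces barely half the published intervention-arm cost, despite the
published text's stated intent of treating until progression. The frozen
setting reproduces the intervention arm's overall-population cost within
−4.4%, its QALYs within −2.7%, its subgroup life-years within +0.6%, and
the subgroup ICER within +2.9%.

### Known reproduction gap

The overall-population ICER recomputes ≈ 39% above its published value
under every convention setting, and the cause is an internal inconsistency
of the published inputs, not a modelling degree of freedom: the published
overall-population SOC OS curve (log-normal, meanlog 3.09129, sdlog
1.09301) has a fatter tail than the intervention's OS curve (meanlog
3.192779, sdlog 0.851157), so by direct quadrature the comparator accrues
*more* discounted life-years (2.64 vs 2.59) — yet the published table
prints the ordering reversed (2.52 vs 2.53). The ICER divides by the small
QALY difference (≈ 0.06–0.09), so this sign flip in ΔLY inflates the
recomputed ratio far beyond what any evaluation convention can absorb. The
corresponding acceptance test is deliberately left failing rather than
tuned, and `survival_diagnostics` surfaces per-curve analytic medians and
restricted means so the discrepancy is visible in every run. Relatedly, the
published fitted-model medians do not equal the analytic medians of the
published distribution parameters under any standard parameterization
(e.g. the intervention's PFS median is exp(1.414933) = 4.12 months
analytically); the diagnostics table exists precisely so both numbers can
be inspected side by side without the model forcing agreement.

The fulvestrant arm has no published OS parameters of its own; the default
configuration assigns it the overall-population SOC OS curve in both
populations, the only assignment consistent with the published fulvestrant
life-year totals (≈ 2.5 in both populations, vs ≈ 2.1 for the subgroup SOC
curve).

## Survival distributions

Five families with standard survival-analysis parameterizations (time in
months): Weibull `exp(−(t/b)^a)`, log-logistic `1/(1+(t/b)^a)`, log-normal
`1−Φ((ln t−μ)/σ)`, Gompertz `exp(−(b/a)(e^{at}−1))`, gamma (shape/scale).
Four are thin wrappers over frozen `scipy.stats` distributions; Gompertz is
closed-form in-package because its shape parameter must be allowed to be
arbitrarily small (the `expm1` form keeps the shape→0 exponential limit
exact to machine precision) or negative (improper distribution with a
surviving fraction, median = ∞ when the plateau exceeds ½). Parameter
domains are enforced at construction. Restricted means use adaptive
quadrature of S; medians use closed forms with a root-finder guard.

## Kaplan–Meier reconstruction

`reconstruct_ipd` inverts a digitized step curve plus a number-at-risk
table into pseudo individual-patient data. Per risk-table interval: an
initial censoring count is guessed from the survival drop vs at-risk
attrition; censoring times are spread uniformly across the interval (the
canonical choice when nothing finer is known); event counts at each
digitized time are set so the running product-limit estimate tracks the
curve; the censoring count is then adjusted until the implied number at
risk at the next landmark matches the printed one (fixed-point iteration,
capped at 60 rounds). Beyond the last landmark censoring is assumed zero
within the interval and everyone still at risk is administratively censored
at the last digitized time, so records always sum to the enrolled n. On
synthetic curves the reconstructed KM agrees with the input within
max |ΔS| ≤ 0.02 at n = 200, tightening as digitization density grows.

Fitting maximizes the right-censored log-likelihood
`Σ_events ln f + Σ_censored ln S` with Nelder–Mead on an unconstrained
scale (log transform for positive parameters; Gompertz shape untransformed)
from three starts (moment-based plus ±0.5 perturbations), because the
Gompertz and gamma surfaces can be flat. Non-convergence raises; it is
never silently replaced by a fallback. AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ
with k = 2 free parameters per family; `select_best` takes minimum AIC,
ties broken by BIC then by fixed family order. Visual adequacy is left to
the analyst via the emitted overlay plot — it is never automated.

## Economics

Oral drugs cost `unit_cost × mg_per_day × days_per_cycle / unit_size`
(e.g. $2.175/mg × 400 mg × 30 d = $26,100 per cycle for the intervention).
Fulvestrant is priced per 500 mg injection with two injections mapped into
model cycle 1 (loading doses on days 1 and 15; the day-1 dose of clinical
cycle 2 opens model cycle 2) and one thereafter; a $702 administration fee
accompanies every injection, weighted by the component's mixture share. The
SOC comparator is a mixture: fulvestrant 69.33% and each aromatase
inhibitor 30.67%/3 (the published per-drug shares round to 10.22%; the
exact thirds are used so weights sum to 1). State costs per cycle:
follow-up $2,959 (PF), after-progression $6,549 + subsequent treatment
$9,061 (PD, both recurring), end-of-life $2,601 one-time on incident death.
Grade-3/4 adverse events enter as expected values — Σ risk × cost and
Σ risk × annual disutility / 12 — charged in cycle 1 only. Utilities:
PF 0.837/yr, PD 0.443/yr.

## Sensitivity analysis

One-way DSA sets each parameter to its published low/high bound (bounds
sorted at load — one published range is printed inverted), re-runs the full
model, and sorts by ICER spread. The recomputed tornado reproduces the
published driver ordering: intervention drug price first, then PF and PD
utilities.

PSA draws costs from gamma and probabilities/utilities from beta
distributions, moment-matched to mean = base and sd = (high − low)/3.92;
an infeasible beta match falls back to a range-fitted beta with a logged
warning, and a normal option (clipped to [0, 1]) is retained behind
`psa.utility_distribution` because published good-practice guidance is
quoted both ways. The discount rate is excluded from PSA (a policy choice,
not a sampling uncertainty), and survival-curve parameters are not varied —
no ranges are published for them, a faithful reflection of the original
scope. 1000 iterations, seeded `numpy` Generator, full model re-run per
draw. The CEAC reports, per WTP on a default $0–500k grid in $10k steps
(the published grid is unstated), the fraction of draws in which each
strategy has the highest net monetary benefit `WTP × QALY − cost`; ties
count for the comparator so probabilities sum to exactly 1.

## Synthetic data

`synthdata.simulate_km` emulates the manual digitization step that the
original workflow performed on published figures: event times drawn from a
known distribution, censoring either uniform (each subject censored with
the given probability at a uniform fraction of its event time) or
administrative at a cutoff, exact KM computed (lifelines), sampled on a
regular grid, optionally jittered on the survival axis and then
isotonically repaired (clip to [0,1], force S(0)=1, running minimum) so the
output is always a valid curve. It does not emulate pixel-level digitizer
artifacts, reader bias, or informative censoring — so passing recovery
tests demonstrate correctness of the inversion and fitting machinery, not
robustness to every real-world digitization pathology. Generator defaults
in the analysis scripts (n = 300 per arm, 15% censoring, 0.5-month grid,
0.005 jitter) mirror trial-arm-sized cohorts; the master recovery test uses
n = 5000 to separate estimator bias from sampling noise (±0.05 on
log-normal parameters).

## Numerical choices

Occupancy conservation holds to 1e−12 by construction. Incident deaths are
always differenced at cycle boundaries regardless of eval_point, keeping
the one-time end-of-life cost a telescoping sum bounded by its unit value.
ICER with ΔQALY = 0 is reported as undefined/dominance, never a division by
zero; sign-discordant increments carry an explicit dominance flag.
Degenerate DSA ranges (low = high = base) reproduce the base ICER exactly
(same code path, no re-randomization). All YAML inputs are validated with
field-path error messages before any computation.

## Limitations

Beyond the reproduction gap above: the model inherits every structural
limitation of the PSM (independent curves, no explicit transitions); the
subsequent-therapy mix is priced as a single pooled per-cycle cost;
grade-1/2 adverse events are excluded; treatment-switching adjustment,
cure/spline survival models, and value-of-information analysis are out of
scope.
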