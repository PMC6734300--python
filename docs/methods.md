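# Methods

## Scope

`hfcea` implements two linked economic models of diagnostic imaging for
early heart failure (HF), comparing strain-encoded cardiac magnetic
resonance (Fast-SENC), which is assumed to detect asymptomatic Stage B
disease, against resting echocardiography (ECHO), which is assumed to miss
it:

1. a **payer-perspective Markov cohort cost-effectiveness model** with
   annual cycles and a lifetime horizon, reporting discounted costs,
   life-years (LY), quality-adjusted life-years (QALY), percent cost
   differences at 1/3/5/10-year and lifetime horizons, cost per QALY/LY,
   and the incremental cost-effectiveness ratio (ICER) with dominance
   classification;
2. a **purchaser-perspective (hospital) one-year accounting model** of
   per-test contribution margins, scanner-hour productivity, annual test
   volume and downstream hospitalization/procedure effects.

A one-way sensitivity module produces tornado-diagram data and a
willingness-to-pay (WTP) verdict, and an individual-level Monte-Carlo
simulator acts as an independent validation oracle for the cohort engine.

## Disease process and state space

The Markov chain uses the ACCF/AHA HF stages: Stage B (structural disease,
asymptomatic), Stage C (symptomatic), Stage C+ (symptomatic with a prior HF
hospitalization), Stage D (refractory), and Dead. The model is strictly
progressive: each living state either persists, advances to the next-worse
state, or dies. Annual next-stage progression probabilities and a uniform
annual HF mortality are configured per strategy (the intervention's milder
transition profile encodes the assumed protective effect of early treatment
on disease progression). Death combines HF mortality with age-indexed
background mortality under independent competing risks:
q = 1 − (1 − q_HF)(1 − q_bg(age)).

The background-mortality table shipped with the package is a smooth
Gompertz-style approximation, q(a) = 3.8e−5 · e^(0.092·a) on a five-year
grid from age 60 to 110 with linear interpolation. It is *not* an official
life table; it reproduces the right order of magnitude (≈1.3% at 65, ≈8% at
85) and guarantees cohort extinction by the model's age cap of 110. It can
be replaced or disabled in the configuration.

## Stage-B detection substructure

The two cohorts differ at entry only in what the screening test can see.
To carry that through the cohort dynamics, Stage B is tracked in three
compartments (enabled by default, switchable off):

- **suspected** — screened patients without HF (80% of the cohort at the
  default 20% pre-test prevalence). They incur only the annual screening
  scan, face background mortality only, and convert to true Stage B at the
  annualized four-year incidence 1 − (1 − 0.154)^{1/4} ≈ 4.09%/yr, split
  into detected/undetected by the strategy's diagnostic accuracy;
- **detected** — diagnosed early HF under outpatient management: annual
  office visits ($165), standard HF drugs (12 × $367), and the annual scan;
  transitions follow the cohort's own (treated) rates;
- **undetected** — missed early HF: the annual scan plus the expected cost
  of unmanaged acute HF hospitalization, 0.3202 × $23,077 × (1 + 0.269)
  (rate × mean cost × 30-day readmission load). Transitions follow the
  comparator's standard-care rates. Undetected patients are found by the
  annual repeat scan (with the strategy's accuracy) or after an HF
  hospitalization event, with a post-hospitalization diagnosis probability
  (default 0.5, i.e. half of acute admissions in the undiagnosed pool lead
  to a recognized chronic-HF diagnosis; this unpublished rate is a primary
  sensitivity parameter).

Progression to Stage C or beyond implies clinical presentation and hence
diagnosis, so detection is not tracked past Stage B. The public cohort
trace aggregates the three compartments back to Stage B.

Without this substructure the two arms differ only through their matrices
and the Stage C+ hospitalization rate; the intervention arm's longer
survival then accrues more drug-years than the comparator saves in
hospitalizations, and the intervention cannot be cost saving over a
lifetime. The substructure is exactly the short-term diagnostic mechanism
that makes early detection valuable: unrecognized disease is expensive.

## Cohort entry

At screening, 20% of the cohort (mean age 64) has Stage B+ HF. The HF
fraction is split 50/25/25 across Stage B / Stage C / Stage C+, reflecting
that some patients present with symptomatic or post-hospitalization disease
already; the resulting five-state start vector is (0.90, 0.05, 0.05, 0, 0).
The split is not published and is fully configurable.

## Costs, utilities, discounting

State costs follow the stated composition: Stage B — visits, standard
drugs, imaging (strategy-specific: ECHO $231 + $45 contrast, Fast-SENC
$324); Stage C — visits, standard drugs, expected procedural intervention
(default probability 0.25 at the $14,989 ischemic-hospitalization cost — a
documented placeholder); Stage C+ — advanced drugs (12 × $580) plus
expected HF hospitalization, with the annual rate reduced 27.1% for the
intervention cohort (half of the 54.2% of HF admissions judged
preventable); Stage D — palliative care ($6,960/yr, set at the
advanced-drug level) plus expected assist-device implantation (default
probability 0.20 at the $23,077 hospitalization-cost level). The Stage D
components are unpublished placeholders and are flagged as such in the
configuration file.

Per-state costs are weighted by the probability of *remaining* in the state
for the cycle (the source model's stated "1 − transition probability" rule);
conventional occupancy weighting is available as a mode switch and every
rendered table records which mode produced it.

Utilities are 0.80 (Stage B and C), 0.65 (Stage C+), 0.30 (Stage D), 0
(Dead). QALYs accrue as occupancy-weighted state utilities; the alternative
"alive fraction × mean utility of the living" formulation is algebraically
identical when the mean is occupancy-weighted, so the mode switch is
accepted but maps to the same computation.

Costs and outcomes are discounted at 3%/yr with the first accrued cycle
undiscounted: cycle t is weighted (1 + r)^−(t−1).

## Accrual convention and stopping rule

Rewards accrue on **end-of-cycle occupancy**: the year-t summary reflects
the deaths and stage changes of year t. This is a standard alternative to
half-cycle correction and is what makes one-year summaries differ between
arms whose cohorts start identically distributed. A trapezoidal half-cycle
correction is available as a switch (default off). Under end-of-cycle
accrual the single-state closed form for life expectancy is
(1 − p)/p rather than 1/p — an O(p) difference that the validation suite
exercises at p = 0.005, where it is well inside a 1% tolerance.

The simulation stops when the alive fraction falls below 1e−9, the cohort
reaches age 110, or `max_cycles` elapses; hitting a cap with survivors
records a warning on the trace rather than raising.

## Hospital model

Per-visit cost = facility $/hr × machine-hours + contrast + reading fee +
per-test inventory + amortized ownership fee
((acquisition/lifetime + maintenance)/annual population, $4.67/test for
Fast-SENC at $40,000/10 yr + $10,000/yr over 3,000 tests). Margin per test
= reimbursement (+contrast reimbursement) − visit cost; per hour = margin /
machine-hours; annual = margin × volume, where volume adds two surveillance
scans per identified asymptomatic patient (3,000 + 600 × 2 = 4,200 for the
intervention; the comparator identifies none and stays at 3,000).

The Fast-SENC component sum is $218.67/visit, but the published downstream
margins ($115/test, $573/hr, $481,600/yr, $238,600 gain) are internally
consistent with $209.33; the shipped configuration therefore carries a
per-visit cost override of $209.33 and the audit table reports both figures
side by side. The comparator chain ($184 → $81 → $162/hr) needs no
calibration. The comparator's *annual* margin is $81 × 3,000 = $243,000
(one published table shows $24,300, inconsistent with its own per-test
margin and with the published $238,600 gain; the renderer shows the
computed value).

The emergency-to-planned hospitalization impact treats the expected
non-reimbursable 30-day readmission cost (0.269 × $7,463) as a cost inside
the per-conversion margin: (ER − planned) × (reimbursement − cost −
readmission). The published expression's precedence is ambiguous; its
literal form is implemented behind a flag. Planned-intervention volumes are
identified patients × procedure rate; they are priced only if per-procedure
margins are supplied (none are published).

## Sensitivity analysis

`one_way_sweep` re-runs the full payer comparison at the low and high end
of each parameter range with everything else at base, recording the
intervention's lifetime cost per QALY (ICER mode available). Default
ranges — repository defaults, not published values — are ±50% around base
(and [0.8, 1.0] for diagnostic accuracy) for: intervention diagnostic
accuracy, post-hospitalization diagnosis rate, preventable-hospitalization
reduction, and the intervention's test price. Entries sort by descending
excursion width; infeasible endpoints (e.g. a transition row
over-allocating) are flagged, not dropped. With perfect intervention
accuracy the intervention cohort has no undetected patients, so the
post-hospitalization diagnosis rate has zero width on this outcome — the
expected behaviour of a one-way design, retained deliberately. The WTP
verdict passes iff every swept outcome stays at or below $50,000/QALY
(cost-saving outcomes pass by definition).

## Microsimulation oracle and random scenarios

`simulate_individuals` draws per-patient categorical transitions from the
identical per-cycle matrices and applies the identical reward conventions,
so its mean is an unbiased estimate of the cohort engine's output with
binomial cell standard errors sqrt(p(1−p)/n). The validation suite checks
cost/QALY means within 3 SE and occupancy cell-wise against a 3-SE band at
n = 100,000; because one individual-level fluctuation persists down the
trace, cells are serially correlated and a small fraction of the ~230 cells
may sit just outside 3 SE — the suite allows up to 3% of cells between 3
and 5 SE and none beyond. Default n = 100,000 keeps per-cell SE ≲ 0.0016
and runtime in seconds.

`generate_scenario` produces random, always-valid configurations
(feasible progressive matrices by construction, positive costs,
monotone-decreasing utilities, Dead absorbing) for property tests —
probability conservation, discounting identities, oracle agreement — far
from the base case. Scenarios are time-homogeneous (background mortality
off) so closed-form checks apply, and are deterministic per seed.

## What the defaults do and do not represent

All published inputs enter the configuration verbatim. The unpublished
quantities (entry-stage split, post-hospitalization diagnosis rate,
Stage C intervention probability, Stage D cost components, background
mortality) are single, documented choices at clinically plausible values;
they were fixed once when the base case was assembled. The published
absolute payer results depend on a supplementary transition matrix that is
not reproduced in the source text and whose implied mortality is far higher
than the published annual probabilities (lifetime expectancies of 1.7–3.1
years at age 64); this package's base case therefore reproduces the
*structure* of those results — strict dominance of early detection at every
horizon, with the percent saving largest in year one (−14%) and narrowing
over the lifetime (−5%) — not their magnitudes. The hospital model's
published figures are reproduced exactly. Passing tests show internal
consistency and faithfulness to the published inputs, not validity of the
underlying clinical assumptions for real populations.

## Known limitations

- No probabilistic sensitivity analysis; one-way sweeps only.
- No tunnel states or time-varying treatment effects; age-indexed
  background mortality is the only non-homogeneity.
- A single blended reimbursement per test; no payer mix or capacity model.
- Stage D cost magnitudes and the Stage C intervention rate are
  placeholders; conclusions sensitive to them should be re-run with local
  data.
- The detection substructure treats any Stage C+ entrant as diagnosed and
  does not model late diagnosis beyond Stage B.
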