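# hfcea

Economic models of early heart-failure (HF) diagnostic imaging: a
payer-perspective Markov cohort cost-effectiveness model and a
hospital-perspective contribution-margin model comparing strain-encoded
cardiac MR (Fast-SENC), which can detect asymptomatic Stage B disease,
against resting echocardiography (ECHO), which cannot.

The package is aimed at health-economics and outcomes-research analysts who
want a tested, config-driven implementation of this decision problem: every
model input (transition probabilities, costs, utilities, reimbursements,
volumes) lives in one validated YAML file, every result is reproducible
from it, and an individual-level Monte-Carlo simulator independently
validates the cohort engine.

## The models

**Payer model.** A progressive five-state Markov chain over the ACCF/AHA
stages B → C → C+ → D → Dead with annual cycles. Each living state s has an
annual progression probability p_s to the next-worse state and dies with
probability 1 − (1 − q_HF)(1 − q_bg(age)); the cohort occupancy evolves as
x_{t+1} = x_t M_t until extinction. Rewards accrue per cycle and discount
at rate r with the first cycle undiscounted:

    Cost(T) = Σ_{t=1..T} (1+r)^-(t-1) Σ_s x_{t,s} c_s (1 − exit_s)
    QALY(T) = Σ_{t=1..T} (1+r)^-(t-1) Σ_s x_{t,s} u_s

Stage B is stratified into suspected / detected / undetected compartments
so that the value of early detection — outpatient management instead of
unmanaged acute hospitalization — propagates through the dynamics. The
comparison reports Δcost, ΔQALY, percent differences at 1/3/5/10-year and
lifetime horizons, cost per QALY, and the ICER = Δcost/ΔQALY with dominance
classification.

**Hospital model.** One-year linear accounting: per-visit cost build-up
(facility time, consumables, reading fee, amortized equipment ownership),
contribution margin per test / scanner-hour / year, surveillance-driven
test volume, emergency-to-planned hospitalization conversion margins, and
planned-intervention volumes.

**Sensitivity.** One-way sweeps over named parameters produce sorted
tornado entries and a $50,000/QALY willingness-to-pay verdict.

See `docs/methods.md` for assumptions, conventions, and which defaults are
published values versus documented placeholders.

## Worked example

Compare the strategies on the shipped base case:

    hfcea compare --out out/

    | Cumulative per person | FastSENC | ECHO | Difference | Percent difference |
    | --- | --- | --- | --- | --- |
    | 1-year horizon | $1,730 | $2,010 | ($280) | -14% |
    | 3-year horizon | $5,131 | $5,885 | ($755) | -13% |
    | 5-year horizon | $8,381 | $9,490 | ($1,109) | -12% |
    | 10-year horizon | $15,476 | $17,029 | ($1,553) | -9% |
    | Lifetime | $26,431 | $27,716 | ($1,284) | -5% |
    | Life Years | 11.37 | 10.98 | 0.38 | 3% |
    | QALY | 8.96 | 8.65 | 0.32 | 4% |
    | Cost per QALY | $2,950 | $3,206 | ($256) | -8% |
    | Cost per LY | $2,325 | $2,523 | ($198) | -8% |
    | ICER (FastSENC vs ECHO) | Savings ($4,069) per QALY — dominant (cost-saving) |

Early detection is cheaper *and* more effective at every horizon
("dominant"), with the largest percent saving in the first year — driven by
missed Stage B patients in the ECHO arm incurring unmanaged acute
hospitalizations — narrowing over the lifetime as the longer-lived
Fast-SENC cohort keeps accruing care costs.

The hospital view:

    hfcea hospital --out out/

    | Summary metrics | ECHO | FastSENC | Margin gain |
    | --- | --- | --- | --- |
    | Per-visit cost | $184 | $209 | $25 |
    | Contribution margin per HF imaging test | $81 | $115 | $34 |
    | Contribution margin per hour | $162 | $573 | $411 |
    | Annual test volume | $3,000 | $4,200 | $1,200 |
    | Annual contribution margin | $243,000 | $481,600 | $238,600 |

Each Fast-SENC test earns a higher margin in a fifth of the scanner time
($573 vs $162 per hour), and identifying asymptomatic patients adds 1,200
annual surveillance scans, for $238,600/yr of additional contribution
margin.

One-way sensitivity:

    hfcea owsa --out out/ --plot out/tornado.png

    willingness-to-pay threshold: 50,000 per QALY
    maximum swept outcome: 3,114 per QALY (strategies.FastSENC.test_cost)
    verdict: PASS

Other subcommands: `validate` (schema/invariant check, nonzero exit on
failure), `run` (per-cycle trace CSVs), `microsim --strategy FastSENC --n
100000 --seed 1` (Monte-Carlo oracle with standard-error columns). The
same functionality is available as a library:

```python
import hfcea

cfg = hfcea.default_config()
result = hfcea.run_cea(cfg)
print(result.lifetime.delta_cost, result.icer, result.dominance)
```

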