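"""Cost-effectiveness comparison of the two imaging strategies.

Builds incremental costs and effects, percent differences per horizon, cost
per QALY / life-year, the ICER, and the dominance classification. A strategy
"dominates" when it is both cheaper and more effective; its negative ICER is
reported as savings per QALY and is not a rankable ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .markov_engine import AccumulationResult, HorizonSummary, accumulate, run_cohort
from .parameters import ModelConfig

__all__ = [
    "HorizonComparison",
    "CEAResult",
    "compare",
    "percent_difference",
    "run_cea",
    "DOMINANT",
    "DOMINATED",
]

DOMINANT = "dominant (cost-saving)"
DOMINATED = "dominated"


def percent_difference(value_a: float, value_b: float) -> float:
    """(a - b) / b, the relative difference of a against comparator b."""
    if value_b == 0:
        raise ZeroDivisionError("comparator value is zero")
    return (value_a - value_b) / value_b


@dataclass
class HorizonComparison:
    horizon: str
    cost_a: float
    cost_b: float
    delta_cost: float
    percent_cost_difference: float
    ly_a: float
    ly_b: float
    delta_ly: float
    qaly_a: float
    qaly_b: float
    delta_qaly: float


@dataclass
class CEAResult:
    """Full comparison of intervention (a) against comparator (b)."""

    strategy_a: str
    strategy_b: str
    horizons: list[HorizonComparison]
    cost_per_qaly_a: float
    cost_per_qaly_b: float
    cost_per_ly_a: float
    cost_per_ly_b: float
    icer: float | None
    dominance: str | None
    cost_weighting: str | None = None
    qaly_mode: str | None = None

    def at(self, horizon: str) -> HorizonComparison:
        for h in self.horizons:
            if h.horizon == horizon:
                return h
        raise KeyError(horizon)

    @property
    def lifetime(self) -> HorizonComparison:
        return self.at("lifetime")

    def frame(self) -> pd.DataFrame:
        """Horizon table, intervention and comparator side by side."""
        rows = [
            {
                "horizon": h.horizon,
                self.strategy_a: h.cost_a,
                self.strategy_b: h.cost_b,
                "difference": h.delta_cost,
                "percent_difference": h.percent_cost_difference,
            }
            for h in self.horizons
        ]
        return pd.DataFrame(rows)


def _pair(a: list[HorizonSummary], b: list[HorizonSummary]) -> list[tuple[HorizonSummary, HorizonSummary]]:
    la = {h.horizon: h for h in a}
    lb = {h.horizon: h for h in b}
    if set(la) != set(lb):
        raise ValueError("horizon lists do not cover the same horizons")
    order = [h.horizon for h in a]
    return [(la[h], lb[h]) for h in order]


def compare(
    summaries_a: list[HorizonSummary] | AccumulationResult,
    summaries_b: list[HorizonSummary] | AccumulationResult,
    name_a: str = "intervention",
    name_b: str = "comparator",
) -> CEAResult:
    """Compare two strategies' horizon summaries (a = intervention).

    The ICER is the lifetime incremental cost per incremental QALY, sign
    preserved; it is None (undefined) when the QALY difference is zero. The
    dominance label is set when one strategy is simultaneously cheaper and
    more effective at lifetime.
    """
    meta_cw = meta_qm = None
    if isinstance(summaries_a, AccumulationResult):
        name_a = summaries_a.strategy
        meta_cw, meta_qm = summaries_a.cost_weighting, summaries_a.qaly_mode
        summaries_a = summaries_a.horizons
    if isinstance(summaries_b, AccumulationResult):
        name_b = summaries_b.strategy
        summaries_b = summaries_b.horizons

    rows = []
    for ha, hb in _pair(summaries_a, summaries_b):
        rows.append(
            HorizonComparison(
                horizon=ha.horizon,
                cost_a=ha.cost,
                cost_b=hb.cost,
                delta_cost=ha.cost - hb.cost,
                percent_cost_difference=percent_difference(ha.cost, hb.cost)
                if hb.cost != 0
                else math.nan,
                ly_a=ha.life_years,
                ly_b=hb.life_years,
                delta_ly=ha.life_years - hb.life_years,
                qaly_a=ha.qalys,
                qaly_b=hb.qalys,
                delta_qaly=ha.qalys - hb.qalys,
            )
        )
    life = rows[-1] if rows[-1].horizon == "lifetime" else None
    if life is None:
        life = next(r for r in rows if r.horizon == "lifetime")

    def ratio(num: float, den: float) -> float:
        return num / den if den != 0 else math.nan

    icer: float | None
    if life.delta_qaly == 0:
        icer = None
    else:
        icer = life.delta_cost / life.delta_qaly
    dominance = None
    if life.delta_cost < 0 and life.delta_qaly > 0:
        dominance = DOMINANT
    elif life.delta_cost > 0 and life.delta_qaly < 0:
        dominance = DOMINATED
    return CEAResult(
        strategy_a=name_a,
        strategy_b=name_b,
        horizons=rows,
        cost_per_qaly_a=ratio(life.cost_a, life.qaly_a),
        cost_per_qaly_b=ratio(life.cost_b, life.qaly_b),
        cost_per_ly_a=ratio(life.cost_a, life.ly_a),
        cost_per_ly_b=ratio(life.cost_b, life.ly_b),
        icer=icer,
        dominance=dominance,
        cost_weighting=meta_cw,
        qaly_mode=meta_qm,
    )


def run_cea(config: ModelConfig) -> CEAResult:
    """Run both cohorts on one configuration and compare them."""
    acc_i = accumulate(run_cohort(config, config.intervention), config)
    acc_c = accumulate(run_cohort(config, config.comparator), config)
    return compare(acc_i, acc_c)
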