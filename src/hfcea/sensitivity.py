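"""One-way (univariate) sensitivity analysis over payer-model parameters.

Each named configuration parameter is swept to its low and high value with
everything else held at base; the payer comparison is rerun at each endpoint
and the chosen outcome (cost per QALY of the intervention, or the ICER) is
recorded. Entries sorted by descending excursion width form the tornado
diagram, and a willingness-to-pay verdict checks that no swept outcome
crosses the threshold (dominant, cost-saving outcomes pass by definition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cea import CEAResult, run_cea
from .parameters import ConfigError, MatrixError, ModelConfig, ParamRange

__all__ = [
    "TornadoEntry",
    "ThresholdVerdict",
    "get_by_path",
    "with_value",
    "one_way_sweep",
    "threshold_verdict",
    "tornado_frame",
]


def _walk(container, parts):
    for p in parts:
        if isinstance(container, dict):
            if p not in container:
                raise KeyError(p)
            container = container[p]
        else:
            container = getattr(container, p)
    return container


def get_by_path(config: ModelConfig, path: str) -> float:
    """Resolve a dotted parameter path (e.g. ``costs.intervention_prob``)."""
    try:
        value = _walk(config, path.split("."))
    except (AttributeError, KeyError) as exc:
        raise ConfigError(f"parameter path {path!r} does not resolve") from exc
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"parameter path {path!r} is not numeric")
    return float(value)


def with_value(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """A new validated config with one parameter replaced."""
    get_by_path(config, path)  # verifies the path exists and is numeric
    data = config.model_dump(mode="python")
    parts = path.split(".")
    node = data
    for p in parts[:-1]:
        node = node[p]
    node[parts[-1]] = value
    return ModelConfig.model_validate(data)


@dataclass
class TornadoEntry:
    """One parameter's one-way outcome excursion."""

    parameter_path: str
    base: float
    low: float
    high: float
    outcome_at_low: float
    outcome_at_high: float
    base_outcome: float
    infeasible: bool = False
    note: str | None = None

    @property
    def width(self) -> float:
        if self.infeasible:
            return math.nan
        return abs(self.outcome_at_high - self.outcome_at_low)


def _outcome(result: CEAResult, which: str) -> float:
    if which == "cost_per_qaly":
        return result.cost_per_qaly_a
    if which == "icer":
        if result.icer is None:
            return math.nan
        return result.icer
    raise ValueError(f"unknown outcome: {which!r}")


def one_way_sweep(
    config: ModelConfig,
    ranges: list[ParamRange] | None = None,
    outcome: str = "cost_per_qaly",
) -> list[TornadoEntry]:
    """Sweep each parameter to its low/high value and rerun the comparison.

    Ranges default to the configuration's sensitivity block. A value that
    makes the model infeasible (e.g. a transition row over-allocating) flags
    the entry rather than dropping it. Entries are sorted by descending
    width; infeasible entries sort last.
    """
    if ranges is None:
        ranges = config.sensitivity.ranges
    base_result = run_cea(config)
    base_outcome = _outcome(base_result, outcome)
    entries: list[TornadoEntry] = []
    for rng in ranges:
        base_value = rng.base if rng.base is not None else get_by_path(config, rng.path)
        if not rng.low <= base_value <= rng.high:
            raise ConfigError(
                f"range for {rng.path}: base {base_value} outside "
                f"[{rng.low}, {rng.high}]"
            )
        vals = {}
        note = None
        infeasible = False
        for end, v in (("low", rng.low), ("high", rng.high)):
            if v == base_value:
                vals[end] = base_outcome
                continue
            try:
                vals[end] = _outcome(run_cea(with_value(config, rng.path, v)), outcome)
            except (MatrixError, ConfigError, ValueError) as exc:
                infeasible = True
                note = f"{end}={v}: {exc}"
                vals[end] = math.nan
        entries.append(
            TornadoEntry(
                parameter_path=rng.path,
                base=base_value,
                low=rng.low,
                high=rng.high,
                outcome_at_low=vals["low"],
                outcome_at_high=vals["high"],
                base_outcome=base_outcome,
                infeasible=infeasible,
                note=note,
            )
        )
    entries.sort(key=lambda e: (e.infeasible, -(e.width if e.width == e.width else -1)))
    return entries


@dataclass
class ThresholdVerdict:
    passed: bool
    wtp: float
    max_outcome: float
    max_parameter: str | None
    report: str


def threshold_verdict(entries: list[TornadoEntry], wtp: float) -> ThresholdVerdict:
    """True iff every swept outcome stays at or below the threshold.

    Negative outcomes (cost saving under dominance) pass by definition.
    Infeasible endpoints are excluded and noted in the report.
    """
    worst = -math.inf
    worst_param = None
    notes = []
    for e in entries:
        if e.infeasible:
            notes.append(f"{e.parameter_path}: infeasible ({e.note})")
            continue
        for v in (e.outcome_at_low, e.outcome_at_high):
            if v == v and v > worst:  # skip NaN
                worst = v
                worst_param = e.parameter_path
    passed = worst <= wtp
    lines = [
        f"willingness-to-pay threshold: {wtp:,.0f} per QALY",
        f"maximum swept outcome: {worst:,.0f} per QALY "
        f"({worst_param})" if worst_param else "no finite outcomes",
        "verdict: PASS" if passed else "verdict: FAIL",
    ]
    lines += notes
    return ThresholdVerdict(
        passed=passed,
        wtp=wtp,
        max_outcome=worst,
        max_parameter=worst_param,
        report="\n".join(lines),
    )


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado entries as a table (parameter, endpoints, outcomes, width)."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_path,
                "base": e.base,
                "low": e.low,
                "high": e.high,
                "outcome_at_low": e.outcome_at_low,
                "outcome_at_high": e.outcome_at_high,
                "base_outcome": e.base_outcome,
                "width": e.width,
                "infeasible": e.infeasible,
            }
            for e in entries
        ]
    )
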