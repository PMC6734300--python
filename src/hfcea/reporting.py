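"""Result renderers and run manifests.

CSV artifacts carry full-precision plain decimals; markdown renderings apply
display formatting only ($ with thousands separators, parentheses for
negative amounts). Every output directory gets a manifest recording the
configuration hash, mode flags, seeds and software version that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import CEAResult
from .hospital_model import TestEconomics
from .parameters import ModelConfig

__all__ = [
    "RunManifest",
    "write_manifest",
    "format_money",
    "markdown_table",
    "render_payer_table",
    "render_hospital_table",
]


def format_money(x: float, decimals: int = 0) -> str:
    """$-formatted with parentheses for negative amounts: -2294 -> ($2,294)."""
    if x != x:  # NaN
        return "n/a"
    s = f"${abs(x):,.{decimals}f}"
    return f"({s})" if x < 0 else s


def markdown_table(headers: list[str], rows: list[list[str]]) -> str:
    out = ["| " + " | ".join(headers) + " |"]
    out.append("|" + "|".join(" --- " for _ in headers) + "|")
    for row in rows:
        out.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(out)


@dataclass
class RunManifest:
    """Provenance record written next to every output artifact."""

    config_sha256: str
    command: str
    modes: dict
    seed: int | None
    version: str
    created: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def config_hash(config: ModelConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(
    outdir: Path, config: ModelConfig, command: str, seed: int | None = None
) -> RunManifest:
    manifest = RunManifest(
        config_sha256=config_hash(config),
        command=command,
        modes={
            "cost_weighting": config.engine.cost_weighting,
            "qaly_mode": config.engine.qaly_mode,
            "half_cycle_correction": config.engine.half_cycle_correction,
            "detection_enabled": config.detection.enabled,
        },
        seed=seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    )
    outdir.mkdir(parents=True, exist_ok=True)
    manifest.write(outdir / f"manifest_{command}.json")
    return manifest


def render_payer_table(result: CEAResult) -> tuple[pd.DataFrame, str]:
    """Cumulative-per-person payer table: horizons, LY, QALY, ratios, ICER.

    Returns the full-precision DataFrame and a formatted markdown block.
    """
    if not result.horizons:
        raise ValueError("empty comparison result; nothing to render")
    a, b = result.strategy_a, result.strategy_b
    life = result.lifetime
    rows = []
    for h in result.horizons:
        label = "Lifetime" if h.horizon == "lifetime" else f"{h.horizon[:-1]}-year horizon"
        rows.append(
            {
                "metric": label,
                a: h.cost_a,
                b: h.cost_b,
                "difference": h.delta_cost,
                "percent_difference": h.percent_cost_difference,
            }
        )
    rows.append(
        {
            "metric": "Life Years",
            a: life.ly_a,
            b: life.ly_b,
            "difference": life.delta_ly,
            "percent_difference": life.delta_ly / life.ly_b if life.ly_b else float("nan"),
        }
    )
    rows.append(
        {
            "metric": "QALY",
            a: life.qaly_a,
            b: life.qaly_b,
            "difference": life.delta_qaly,
            "percent_difference": life.delta_qaly / life.qaly_b
            if life.qaly_b
            else float("nan"),
        }
    )
    rows.append(
        {
            "metric": "Cost per QALY",
            a: result.cost_per_qaly_a,
            b: result.cost_per_qaly_b,
            "difference": result.cost_per_qaly_a - result.cost_per_qaly_b,
            "percent_difference": (result.cost_per_qaly_a - result.cost_per_qaly_b)
            / result.cost_per_qaly_b
            if result.cost_per_qaly_b
            else float("nan"),
        }
    )
    rows.append(
        {
            "metric": "Cost per LY",
            a: result.cost_per_ly_a,
            b: result.cost_per_ly_b,
            "difference": result.cost_per_ly_a - result.cost_per_ly_b,
            "percent_difference": (result.cost_per_ly_a - result.cost_per_ly_b)
            / result.cost_per_ly_b
            if result.cost_per_ly_b
            else float("nan"),
        }
    )
    df = pd.DataFrame(rows)

    md_rows = []
    for r in rows:
        if r["metric"] in ("Life Years", "QALY"):
            fmt = lambda v: f"{v:.2f}"
        else:
            fmt = format_money
        md_rows.append(
            [
                r["metric"],
                fmt(r[a]),
                fmt(r[b]),
                fmt(r["difference"]),
                f"{100 * r['percent_difference']:.0f}%"
                if r["percent_difference"] == r["percent_difference"]
                else "n/a",
            ]
        )
    if result.icer is None:
        icer_cell = "undefined (no QALY difference)"
    elif result.dominance and result.icer < 0:
        icer_cell = f"Savings {format_money(result.icer)} per QALY — {result.dominance}"
    else:
        icer_cell = f"{format_money(result.icer)} per QALY"
    md_rows.append([f"ICER ({a} vs {b})", icer_cell, "", "", ""])
    md = markdown_table(
        ["Cumulative per person", a, b, "Difference", "Percent difference"], md_rows
    )
    if result.cost_weighting:
        md += (
            f"\n\nCost weighting: {result.cost_weighting}; "
            f"QALY mode: {result.qaly_mode}."
        )
    return df, md


def render_hospital_table(
    econ: dict[str, TestEconomics],
    comparator: str,
    intervention: str,
    audits: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Summary-metrics table (per test / per hour / annual) plus audit note."""
    e, f = econ[comparator], econ[intervention]
    metrics = [
        ("Per-visit cost", e.per_visit_cost, f.per_visit_cost),
        ("Contribution margin per HF imaging test", e.per_test_margin, f.per_test_margin),
        ("Contribution margin per hour", e.margin_per_hour, f.margin_per_hour),
        ("Annual test volume", e.annual_volume, f.annual_volume),
        ("Annual contribution margin", e.annual_margin, f.annual_margin),
    ]
    df = pd.DataFrame(
        [
            {
                "metric": m,
                comparator: ve,
                intervention: vf,
                "margin_gain": vf - ve,
            }
            for m, ve, vf in metrics
        ]
    )
    md_rows = [
        [m, format_money(ve), format_money(vf), format_money(vf - ve)]
        for m, ve, vf in metrics
    ]
    md = markdown_table(
        ["Summary metrics", comparator, intervention, "Margin gain"], md_rows
    )
    notes = []
    for name, t in ((comparator, e), (intervention, f)):
        if t.override_applied:
            notes.append(
                f"{name}: per-visit cost {format_money(t.per_visit_cost, 2)} is a "
                f"configured override; the component sum is "
                f"{format_money(t.component_visit_cost, 2)} (both audited)."
            )
    if notes:
        md += "\n\n" + "\n".join(notes)
    if audits:
        for name, adf in audits.items():
            md += f"\n\nCost build-up — {name}:\n"
            md += markdown_table(
                ["component", "cost"],
                [[r.component, format_money(r.cost, 2)] for r in adf.itertuples()],
            )
    return df, md
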