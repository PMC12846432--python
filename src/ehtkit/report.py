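"""Report assembly: per-arm summary and non-inferiority decision tables.

Tables mirror the row/column layout conventional in hut-trial reports
(per-arm totals, percentages with 95% CI, relative endpoints against
the untreated control; decision tables with OR, CI, margin, verdict)
so published and computed tables can be eyeballed side by side.
Rendered as CSV-ready DataFrames or plain markdown.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Mapping

import pandas as pd

from . import endpoints as ep
from .noninferiority import NiDecision
from .trial_data import ArmTotals, TrialDataset

__all__ = [
    "arm_summary_table",
    "summary_from_totals",
    "decision_table",
    "to_markdown",
    "config_stamp",
]


def config_stamp(config: Mapping) -> str:
    """Short deterministic hash of a configuration mapping, embedded in
    every emitted report so reruns are attributable and diffable."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def summary_from_totals(
    totals: Mapping[str, ArmTotals],
    untreated: str,
    ci_method: str = "wald",
    nights: int | None = None,
) -> pd.DataFrame:
    """Per-arm summary table from arm totals.

    One row per arm: counts, arithmetic mean per night, exophily /
    blood-fed / mortality percentages with 95% CI, and the relative
    endpoints (blood-feeding inhibition, personal protection,
    deterrence, overall killing effect) against the untreated arm.
    """
    if untreated not in totals:
        raise KeyError(f"untreated arm {untreated!r} not in totals")
    control = totals[untreated]
    rows = []
    for arm, t in totals.items():
        n_nights = nights if nights is not None else t.nights
        row: dict = {
            "arm": arm,
            "caught": t.caught,
            "mean_per_night": ep.mean_per_night(t.caught, n_nights) if n_nights else float("nan"),
            "exited": t.exited,
            "fed": t.fed,
            "dead": t.dead,
        }
        for label, num in (("exophily", t.exited), ("blood_fed", t.fed), ("mortality", t.dead)):
            if t.caught > 0:
                est = ep.proportion_endpoint(num, t.caught, method=ci_method)
                row[f"{label}_pct"] = est.value
                row[f"{label}_ci_low"] = est.ci_low
                row[f"{label}_ci_high"] = est.ci_high
            else:
                row[f"{label}_pct"] = float("nan")
        if arm == untreated:
            row["blood_feeding_inhibition_pct"] = 0.0
            row["personal_protection_pct"] = 0.0
            row["deterrence_pct"] = 0.0
            row["overall_killing_effect_pct"] = 0.0
        else:
            row["blood_feeding_inhibition_pct"] = ep.blood_feeding_inhibition(t, control)
            row["personal_protection_pct"] = ep.personal_protection(t, control)
            row["deterrence_pct"] = ep.deterrence(t, control)
            row["overall_killing_effect_pct"] = ep.insecticidal_effect(t, control)
        rows.append(row)
    return pd.DataFrame(rows)


def arm_summary_table(
    ds: TrialDataset, untreated: str, ci_method: str = "wald"
) -> pd.DataFrame:
    """Per-arm summary table computed from a record-level dataset."""
    return summary_from_totals(ds.all_arm_totals(), untreated, ci_method=ci_method)


def decision_table(decisions: Iterable[NiDecision]) -> pd.DataFrame:
    """Non-inferiority decision table, one comparison per row."""
    rows = []
    for d in decisions:
        e = d.or_estimate
        rows.append(
            {
                "endpoint": d.endpoint,
                "reference": d.reference,
                "candidate": d.candidate,
                "or": e.oratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
                "z": e.z,
                "nim": d.nim,
                "verdict": d.verdict,
            }
        )
    return pd.DataFrame(rows)


def to_markdown(frame: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    """Minimal GitHub-style markdown rendering of a DataFrame."""

    def fmt(v) -> str:
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(frame.columns) + " |"
    sep = "| " + " | ".join("---" for _ in frame.columns) + " |"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in frame.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"
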