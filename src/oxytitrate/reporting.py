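"""Tabular and JSON outputs: scenario summaries, cumulative usage, cohorts.

Rounding happens only at serialization; all internal values are full
precision. Every summary embeds the seed, the distributions and the package
version so any output file can be reproduced from its own metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortResult, ReplicateSummary, ScenarioSpec, liters_to_hours_at_flow
from .patient_model import CohortDistributions, Patient


def cohort_to_frame(patients: list[Patient] | tuple[Patient, ...]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "v0_lpm": [p.v0 for p in patients],
            "duration_days": [p.duration_days for p in patients],
            "profile": [p.profile_id for p in patients],
        }
    )


def records_to_frame(result: CohortResult) -> pd.DataFrame:
    """Per-patient consumption for every scenario of one cohort."""
    rows = []
    for label, records in result.records.items():
        for rec in records:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "policy_label": label,
                    "interval_minutes": rec.policy.interval_minutes,
                    "volume_liters": rec.volume,
                }
            )
    return pd.DataFrame(rows)


def summary_to_frame(
    summary: ReplicateSummary,
    scenarios: tuple[ScenarioSpec, ...] | list[ScenarioSpec],
) -> pd.DataFrame:
    """Scenario-level results table (liters and 1 L/min hour-equivalents)."""
    ref = summary.reference_label
    rows = []
    for spec in scenarios:
        label = spec.label
        saved = summary.mean_total[ref] - summary.mean_total[label]
        rows.append(
            {
                "scenario_label": label,
                "interval_minutes": spec.policy.interval_minutes,
                "mean_total_liters": summary.mean_total[label],
                "sem_total_liters": summary.sem_total[label],
                "mean_savings_fraction": summary.mean_savings[label],
                "sem_savings_fraction": summary.sem_savings[label],
                "saved_liters_vs_reference": saved,
                "equivalent_hours_at_1lpm": liters_to_hours_at_flow(saved, 1.0),
                "base_seed": summary.base_seed,
            }
        )
    return pd.DataFrame(rows)


def cumulative_to_frame(cohorts: list[CohortResult]) -> pd.DataFrame:
    """Cumulative oxygen usage by patient, per scenario and replicate."""
    rows = []
    for replicate, result in enumerate(cohorts):
        for label, series in result.cumulative.items():
            for idx, value in enumerate(series):
                rows.append(
                    {
                        "replicate": replicate,
                        "seed": result.seed,
                        "patient_index": idx,
                        "scenario_label": label,
                        "cumulative_liters": float(value),
                    }
                )
    return pd.DataFrame(rows)


def summary_to_dict(
    summary: ReplicateSummary,
    scenarios: tuple[ScenarioSpec, ...] | list[ScenarioSpec],
    dists: CohortDistributions,
) -> dict:
    frame = summary_to_frame(summary, scenarios)
    return {
        "artifact_version": __version__,
        "base_seed": summary.base_seed,
        "n_patients": summary.n_patients,
        "n_replicates": summary.n_replicates,
        "reference_label": summary.reference_label,
        "distributions": dists.to_dict(),
        "scenarios": frame.to_dict(orient="records"),
        "replicates": summary.replicate_totals.to_dict(orient="records"),
    }


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def format_summary_lines(
    summary: ReplicateSummary,
    scenarios: tuple[ScenarioSpec, ...] | list[ScenarioSpec],
) -> list[str]:
    """Human-readable report: totals in kL, savings in one-decimal percent."""
    lines = []
    ref = summary.reference_label
    for spec in scenarios:
        label = spec.label
        total_kl = summary.mean_total[label] / 1000.0
        sem_kl = summary.sem_total[label] / 1000.0
        line = (
            f"Scenario {label} ({spec.policy.label_suffix()}): "
            f"{total_kl:.0f} ± {sem_kl:.0f} kL"
        )
        if label != ref:
            pct = 100.0 * summary.mean_savings[label]
            pct_sem = 100.0 * summary.sem_savings[label]
            line += f", savings {pct:.1f}% ± {pct_sem:.1f}%"
        lines.append(line)
    return lines
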