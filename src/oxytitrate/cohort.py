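"""Paired multi-scenario cohort simulation and replicate summaries.

A cohort of N patients is sampled once and every titration scenario is
evaluated on that identical patient list (common random numbers), so scenario
differences reflect the titration policy alone, never sampling noise.
Replicates are independent cohorts; savings are computed within each replicate
and then summarized as mean +/- SEM across replicates, matching how simulation
studies of this kind report a handful of repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patient_model import CohortDistributions, Patient, sample_cohort
from .titration import ConsumptionRecord, TitrationPolicy, consumed_volume


@dataclass(frozen=True)
class ScenarioSpec:
    """A labelled titration policy evaluated on the cohort."""

    label: str
    policy: TitrationPolicy


def paper_scenarios() -> tuple[ScenarioSpec, ...]:
    """The three reference scenarios: no titration, every 24 h, every 3 min."""
    return (
        ScenarioSpec("I", TitrationPolicy.initial_only()),
        ScenarioSpec("II", TitrationPolicy.periodic(1440.0)),
        ScenarioSpec("III", TitrationPolicy.periodic(3.0)),
    )


@dataclass(frozen=True)
class CohortResult:
    """One sampled cohort evaluated under every scenario (paired design)."""

    seed: int
    n_patients: int
    patients: tuple[Patient, ...]
    records: dict[str, tuple[ConsumptionRecord, ...]]
    totals: dict[str, float]
    cumulative: dict[str, np.ndarray]


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-replicate mean +/- SEM of totals and savings fractions."""

    n_replicates: int
    n_patients: int
    base_seed: int
    reference_label: str
    scenario_labels: tuple[str, ...]
    mean_total: dict[str, float]
    sem_total: dict[str, float]
    mean_savings: dict[str, float]
    sem_savings: dict[str, float]
    replicate_totals: pd.DataFrame = field(repr=False)


def run_cohort(
    dists: CohortDistributions,
    n: int,
    scenarios: list[ScenarioSpec] | tuple[ScenarioSpec, ...],
    seed: int,
) -> CohortResult:
    """Sample one cohort of ``n`` patients and evaluate every scenario on it.

    All randomness is in cohort sampling; scenario evaluation is
    deterministic, so scenario order never perturbs the draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scenarios = tuple(scenarios)
    if not scenarios:
        raise ValueError("at least one scenario is required")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")

    rng = np.random.default_rng(seed)
    patients = tuple(sample_cohort(dists, n, rng))

    records: dict[str, tuple[ConsumptionRecord, ...]] = {}
    totals: dict[str, float] = {}
    cumulative: dict[str, np.ndarray] = {}
    for spec in scenarios:
        volumes = np.array(
            [consumed_volume(p, spec.policy, dists.k) for p in patients]
        )
        records[spec.label] = tuple(
            ConsumptionRecord(p.id, spec.policy, float(v))
            for p, v in zip(patients, volumes)
        )
        totals[spec.label] = float(volumes.sum())
        cumulative[spec.label] = np.cumsum(volumes)

    return CohortResult(
        seed=seed, n_patients=n, patients=patients,
        records=records, totals=totals, cumulative=cumulative,
    )


def savings_fraction(total_ref: float, total_policy: float) -> float:
    """Fraction of the reference consumption avoided: 1 - policy/reference."""
    if total_ref <= 0:
        raise ValueError("reference total must be positive")
    if total_policy > total_ref:
        raise ValueError(
            "policy total exceeds reference total; savings undefined for "
            "profiles that increase oxygen need"
        )
    return 1.0 - total_policy / total_ref


def run_replicates(
    dists: CohortDistributions,
    n: int,
    scenarios: list[ScenarioSpec] | tuple[ScenarioSpec, ...],
    r: int,
    base_seed: int,
    reference_label: str | None = None,
) -> ReplicateSummary:
    """Run ``r`` independent cohorts (seeds ``base_seed + index``).

    Savings are computed per replicate against ``reference_label`` (default:
    the first scenario) and then averaged; SEM uses the n-1 sample standard
    deviation divided by sqrt(r).
    """
    if r < 2:
        raise ValueError("r must be >= 2 for a defined SEM")
    scenarios = tuple(scenarios)
    if not scenarios:
        raise ValueError("at least one scenario is required")
    if reference_label is None:
        reference_label = scenarios[0].label
    if reference_label not in {s.label for s in scenarios}:
        raise ValueError(f"reference label {reference_label!r} not among scenarios")

    rows = []
    for i in range(r):
        seed = base_seed + i
        result = run_cohort(dists, n, scenarios, seed)
        ref_total = result.totals[reference_label]
        for spec in scenarios:
            rows.append({
                "replicate": i,
                "seed": seed,
                "scenario_label": spec.label,
                "total_liters": result.totals[spec.label],
                "savings_fraction": savings_fraction(
                    ref_total, result.totals[spec.label]
                ),
            })
    table = pd.DataFrame(rows)

    mean_total: dict[str, float] = {}
    sem_total: dict[str, float] = {}
    mean_savings: dict[str, float] = {}
    sem_savings: dict[str, float] = {}
    for spec in scenarios:
        sub = table[table["scenario_label"] == spec.label]
        totals = sub["total_liters"].to_numpy()
        savings = sub["savings_fraction"].to_numpy()
        mean_total[spec.label] = float(totals.mean())
        sem_total[spec.label] = float(totals.std(ddof=1) / math.sqrt(r))
        mean_savings[spec.label] = float(savings.mean())
        sem_savings[spec.label] = float(savings.std(ddof=1) / math.sqrt(r))

    return ReplicateSummary(
        n_replicates=r, n_patients=n, base_seed=base_seed,
        reference_label=reference_label,
        scenario_labels=tuple(s.label for s in scenarios),
        mean_total=mean_total, sem_total=sem_total,
        mean_savings=mean_savings, sem_savings=sem_savings,
        replicate_totals=table,
    )


def liters_to_hours_at_flow(volume: float, flow: float) -> float:
    """Hours of therapy a volume (L) provides at a constant flow (L/min)."""
    if flow <= 0:
        raise ValueError("flow must be positive")
    return volume / flow / 60.0
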