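"""Exact expectations of per-patient consumption by support enumeration.

Because the sampling laws have finite support (3 starting flows x 5 durations
x 2 profiles = 30 combinations under the defaults) and consumption is a
deterministic function of the combination, the exact mean and variance of
per-patient oxygen use under any titration policy follow from a weighted sum
over the joint support. This closed-form twin of the Monte Carlo pipeline
validates every simulated total and savings fraction, and predicts the
standard error of replicate means without simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .patient_model import PROFILE_IDS, CohortDistributions, Patient
from .titration import TitrationPolicy, consumed_volume


@dataclass(frozen=True)
class ExpectationReport:
    """Exact first/second moments of per-patient consumption under a policy."""

    policy: TitrationPolicy
    expected_volume_per_patient: float
    variance_per_patient: float
    expected_savings_vs_initial_only: float

    def to_dict(self) -> dict:
        return {
            "policy_kind": self.policy.kind,
            "interval_minutes": self.policy.interval_minutes,
            "expected_volume_per_patient_liters": self.expected_volume_per_patient,
            "variance_per_patient_liters2": self.variance_per_patient,
            "expected_savings_vs_initial_only": self.expected_savings_vs_initial_only,
        }


def iter_joint_support(
    dists: CohortDistributions,
) -> Iterator[tuple[float, int, str, float]]:
    """Yield (v0, duration, profile, joint probability) over the full support."""
    for v0, pv in zip(dists.v0_support, dists.v0_probs):
        for d, pd_ in zip(dists.duration_support, dists.duration_probs):
            for profile, pp in zip(PROFILE_IDS, dists.profile_probs):
                yield v0, d, profile, pv * pd_ * pp


def expected_patient_consumption(
    dists: CohortDistributions, policy: TitrationPolicy
) -> ExpectationReport:
    """Exact E and Var of one patient's oxygen volume (liters) under ``policy``."""
    first = 0.0
    second = 0.0
    ref_first = 0.0
    reference = TitrationPolicy.initial_only()
    for v0, d, profile, w in iter_joint_support(dists):
        if w == 0.0:
            continue
        patient = Patient(id=0, v0=v0, duration_days=d, profile_id=profile)
        vol = consumed_volume(patient, policy, dists.k)
        first += w * vol
        second += w * vol * vol
        ref_first += w * consumed_volume(patient, reference, dists.k)
    variance = max(second - first * first, 0.0)
    savings = 1.0 - first / ref_first
    return ExpectationReport(
        policy=policy,
        expected_volume_per_patient=first,
        variance_per_patient=variance,
        expected_savings_vs_initial_only=savings,
    )


def predicted_replicate_sem(
    dists: CohortDistributions, policy: TitrationPolicy, n: int, r: int
) -> float:
    """Theoretical SEM (liters) of the mean cohort total over ``r`` replicates.

    The cohort total of ``n`` i.i.d. patients has variance n * Var_patient, so
    the replicate mean has standard error sqrt(n * Var_patient / r).
    """
    if n < 1 or r < 1:
        raise ValueError("n and r must be >= 1")
    report = expected_patient_consumption(dists, policy)
    return math.sqrt(n * report.variance_per_patient / r)
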