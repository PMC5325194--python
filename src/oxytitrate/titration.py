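"""Per-patient oxygen consumption under a titration policy.

Titration means re-reading the patient's current oxygen need and re-setting
the delivered flow to it. Between titrations the delivered flow is held
constant (zero-order hold), so a patient on a declining need profile receives
excess oxygen until the next adjustment. Three policy kinds are supported:

* ``initial-only`` — the flow is set once at t = 0 and held for the whole
  treatment (the no-routine-titration reference, delta-t = D);
* ``periodic`` — the flow is re-set every ``interval_minutes`` minutes;
* ``continuous`` — the delta-t -> 0 limit, evaluated as the exact integral of
  the need profile.

Internal time unit is minutes (1 day = 1440 min); the profile math works in
days and this module converts at the boundary. Volumes are liters:
(L/min) x minutes, with no hidden rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .patient_model import Patient, flow_at

MINUTES_PER_DAY = 1440.0

INITIAL_ONLY = "initial-only"
PERIODIC = "periodic"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class TitrationPolicy:
    """A titration schedule: never, every ``interval_minutes``, or continuous."""

    kind: str
    interval_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (INITIAL_ONLY, PERIODIC, CONTINUOUS):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == PERIODIC:
            if self.interval_minutes is None or self.interval_minutes <= 0:
                raise ValueError("periodic policy requires interval_minutes > 0")
        elif self.interval_minutes is not None:
            raise ValueError(f"{self.kind} policy takes no interval")

    @classmethod
    def initial_only(cls) -> "TitrationPolicy":
        return cls(INITIAL_ONLY)

    @classmethod
    def periodic(cls, interval_minutes: float) -> "TitrationPolicy":
        return cls(PERIODIC, float(interval_minutes))

    @classmethod
    def continuous(cls) -> "TitrationPolicy":
        return cls(CONTINUOUS)

    def label_suffix(self) -> str:
        if self.kind == PERIODIC:
            return f"dt={self.interval_minutes:g} min"
        return self.kind


@dataclass(frozen=True)
class ConsumptionRecord:
    """Oxygen volume (liters) one patient consumed under one policy."""

    patient_id: int
    policy: TitrationPolicy
    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@lru_cache(maxsize=4096)
def _zoh_volume(profile_id: str, v0: float, duration_days: int,
                interval_minutes: float, k: float) -> float:
    # Flow is sampled at each step start and held; the last step is truncated
    # to end exactly at the treatment duration.
    total_minutes = duration_days * MINUTES_PER_DAY
    n_steps = int(np.ceil(total_minutes / interval_minutes))
    starts = np.arange(n_steps) * interval_minutes
    ends = np.minimum(starts + interval_minutes, total_minutes)
    flows = flow_at(profile_id, v0, k, starts / MINUTES_PER_DAY)
    return float(np.sum(flows * (ends - starts)))


def consumed_volume(patient: Patient, policy: TitrationPolicy, k: float) -> float:
    """Total oxygen (liters) a patient consumes over treatment under ``policy``.

    Initial-only holds the t = 0 flow for the full duration, so the result is
    exactly ``v0 * duration_days * 1440``. Periodic policies apply a
    zero-order hold at each titration instant; an interval longer than the
    treatment degenerates to a single truncated step (initial-only). The
    continuous kind delegates to :func:`continuous_consumption`.
    """
    if policy.kind == INITIAL_ONLY:
        return flow_at(patient.profile_id, patient.v0, k, 0.0) * \
            patient.duration_days * MINUTES_PER_DAY
    if policy.kind == CONTINUOUS:
        return continuous_consumption(patient, k)
    return _zoh_volume(patient.profile_id, patient.v0, patient.duration_days,
                       float(policy.interval_minutes), k)


def _profile_integral_days(profile_id: str, v0: float, k: float, T: float) -> float:
    # Integral of the need profile over [0, T] days, in L/min * day.
    # Profile A subtracts k * integral of min(t, 3); profile B subtracts
    # k * integral of clip(t - 1, 0, 2).
    if T < 0:
        raise ValueError("duration must be >= 0")
    if profile_id == "A":
        s = min(T, 3.0)
        decrement = s * s / 2.0 + max(T - 3.0, 0.0) * 3.0
    elif profile_id == "B":
        s = min(max(T - 1.0, 0.0), 2.0)
        decrement = s * s / 2.0 + max(T - 3.0, 0.0) * 2.0
    else:
        raise ValueError(f"unknown profile {profile_id!r}")
    return v0 * T - k * decrement


def continuous_consumption(patient: Patient, k: float) -> float:
    """Exact oxygen volume (liters) under continuous titration.

    Closed-form integral of the piecewise-linear need profile over the
    treatment duration; the lower bound of any zero-order-hold policy.
    """
    return _profile_integral_days(
        patient.profile_id, patient.v0, k, float(patient.duration_days)
    ) * MINUTES_PER_DAY
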