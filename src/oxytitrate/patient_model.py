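"""Synthetic cohort of hypoxemic-pneumonia patients on oxygen therapy.

Each patient is described by a starting flow rate ``v0`` (L/min), a treatment
duration ``D`` (whole days) and one of two weaning profiles:

* Profile A — the flow declines linearly at rate ``k`` (L/min per day) from
  the start of therapy until day 3, then plateaus at ``v0 - 3k``.
* Profile B — the flow holds at ``v0`` for the first day, declines at rate
  ``k`` between days 1 and 3, then plateaus at ``v0 - 2k``.

Both profiles are continuous, non-increasing and strictly positive on the
five-day horizon provided ``3k < min(v0)``, which the distribution invariants
enforce. The default distributions describe children admitted with hypoxemic
pneumonia in low-resource settings: starting flows of 0.5 L/min (infants) or
1-2 L/min (older children) with equal probability, and a duration of 1-5 days
whose probabilities decline from 0.32 to 0.11, reflecting published weaning
times. The weaning constant defaults to 0.125 L/min/day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: End of the declining segment of both profiles, in days.
WEANING_END_DAY = 3.0
#: Horizon on which the profiles are defined, in days (max duration).
PROFILE_HORIZON_DAYS = 5.0

PROFILE_IDS = ("A", "B")

_PROB_TOL = 1e-12


def _check_probs(name: str, probs: tuple[float, ...], n: int) -> None:
    if len(probs) != n:
        raise ValueError(f"{name} must have length {n}, got {len(probs)}")
    if any(p < 0 for p in probs):
        raise ValueError(f"{name} must be non-negative")
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} must sum to 1 within {_PROB_TOL}")


@dataclass(frozen=True)
class CohortDistributions:
    """Sampling laws for (v0, D, profile) plus the weaning constant k.

    All supports are finite; probabilities must sum to one within 1e-12.
    ``k`` must satisfy ``3 * k < min(v0_support)`` so that every profile stays
    strictly positive over the five-day horizon.
    """

    v0_support: tuple[float, ...]
    v0_probs: tuple[float, ...]
    duration_support: tuple[int, ...]
    duration_probs: tuple[float, ...]
    profile_probs: tuple[float, float]
    k: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "v0_support", tuple(float(v) for v in self.v0_support))
        object.__setattr__(self, "v0_probs", tuple(float(p) for p in self.v0_probs))
        object.__setattr__(self, "duration_support", tuple(int(d) for d in self.duration_support))
        object.__setattr__(self, "duration_probs", tuple(float(p) for p in self.duration_probs))
        object.__setattr__(self, "profile_probs", tuple(float(p) for p in self.profile_probs))
        object.__setattr__(self, "k", float(self.k))

        if not self.v0_support:
            raise ValueError("v0_support must be non-empty")
        if any(v <= 0 for v in self.v0_support):
            raise ValueError("v0_support flows must be positive")
        _check_probs("v0_probs", self.v0_probs, len(self.v0_support))
        if not self.duration_support:
            raise ValueError("duration_support must be non-empty")
        if any(d < 1 for d in self.duration_support):
            raise ValueError("duration_support values must be integers >= 1")
        _check_probs("duration_probs", self.duration_probs, len(self.duration_support))
        _check_probs("profile_probs", self.profile_probs, 2)
        if self.k < 0:
            raise ValueError("weaning constant k must be >= 0")
        if self.k * WEANING_END_DAY >= min(self.v0_support):
            raise ValueError(
                "k too large: 3k must be < min(v0_support) to keep flows positive"
            )

    def to_dict(self) -> dict:
        return {
            "v0_support": list(self.v0_support),
            "v0_probs": list(self.v0_probs),
            "duration_support": list(self.duration_support),
            "duration_probs": list(self.duration_probs),
            "profile_probs": list(self.profile_probs),
            "k": self.k,
        }


@dataclass(frozen=True)
class Patient:
    """One synthetic patient: identifier, starting flow, duration, profile."""

    id: int
    v0: float
    duration_days: int
    profile_id: str

    def __post_init__(self) -> None:
        if self.profile_id not in PROFILE_IDS:
            raise ValueError(f"profile_id must be one of {PROFILE_IDS}")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")


def default_distributions() -> CohortDistributions:
    """Distributions for the reference cohort of hypoxemic-pneumonia patients.

    Starting flow uniform on {0.5, 1.0, 2.0} L/min, duration 1-5 days with
    probabilities 0.32/0.27/0.18/0.12/0.11, equiprobable profiles and
    k = 0.125 L/min/day.
    """
    return CohortDistributions(
        v0_support=(0.5, 1.0, 2.0),
        v0_probs=(1 / 3, 1 / 3, 1 / 3),
        duration_support=(1, 2, 3, 4, 5),
        duration_probs=(0.32, 0.27, 0.18, 0.12, 0.11),
        profile_probs=(0.5, 0.5),
        k=0.125,
    )


def flow_at(profile_id: str, v0: float, k: float, t):
    """Oxygen flow need (L/min) of a profile at time ``t`` days after start.

    ``t`` may be a scalar or an array; negative times are rejected. Profile A
    evaluates to ``v0 - k*min(t, 3)``; profile B to ``v0 - k*clip(t-1, 0, 2)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if profile_id == "A":
        flow = v0 - k * np.minimum(t_arr, WEANING_END_DAY)
    elif profile_id == "B":
        flow = v0 - k * np.clip(t_arr - 1.0, 0.0, WEANING_END_DAY - 1.0)
    else:
        raise ValueError(f"profile_id must be one of {PROFILE_IDS}")
    return float(flow) if np.isscalar(t) or t_arr.ndim == 0 else flow


def sample_cohort(
    dists: CohortDistributions,
    n: int,
    rng: np.random.Generator,
    start_id: int = 0,
) -> list[Patient]:
    """Draw ``n`` independent patients from ``dists``.

    v0, duration and profile are mutually independent. Draws are consumed in
    a fixed, documented order — all starting flows, then all durations, then
    all profiles — so a cohort is fully reproducible from the generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    v0s = rng.choice(dists.v0_support, size=n, p=dists.v0_probs)
    durations = rng.choice(dists.duration_support, size=n, p=dists.duration_probs)
    profiles = rng.choice(PROFILE_IDS, size=n, p=dists.profile_probs)
    return [
        Patient(id=start_id + i, v0=float(v0s[i]), duration_days=int(durations[i]),
                profile_id=str(profiles[i]))
        for i in range(n)
    ]


def sample_patient(dists: CohortDistributions, rng: np.random.Generator) -> Patient:
    """Draw a single patient (draw order v0, duration, profile)."""
    return sample_cohort(dists, 1, rng)[0]
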