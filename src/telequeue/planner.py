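"""Capacity planning: staffing levels that keep overburdening below a target.

Inverts the steady-state queue model into the questions a health planner
asks: how many doctors does a pooled office need for a given fleet, and how
many ambulances can a fixed staff serve?  Ambulance counts move in steps of
one district's worth of vehicles (6 by default), matching how districts
join a centralized office.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .presets import (
    AMBULANCES_PER_DISTRICT,
    CALLS_PER_DOCTOR,
    MU_EFFECTIVE,
    PER_AMBULANCE_RATE,
)
from .queueing import InvalidParameterError, QueueParameters, overburdening_probability

__all__ = ["CapacityPolicy", "min_teds", "max_ambulances", "overburdening_table"]


@dataclass(frozen=True)
class CapacityPolicy:
    """Service-level policy and rates used by the planning searches.

    Attributes
    ----------
    max_overburdening : float
        Tolerated probability that a call is put on hold (e.g. 0.05).
    per_ambulance_arrival_rate : float
        Peak-hour calls per hour contributed by one telemedical ambulance.
    service_rate : float
        Completed calls per hour per channel.
    calls_per_doctor : int
        Parallel calls one doctor can handle.
    ambulance_step : int
        Granularity of the ambulance search grid (one district's fleet).
    """

    max_overburdening: float = 0.05
    per_ambulance_arrival_rate: float = PER_AMBULANCE_RATE
    service_rate: float = MU_EFFECTIVE
    calls_per_doctor: int = CALLS_PER_DOCTOR
    ambulance_step: int = AMBULANCES_PER_DISTRICT

    def __post_init__(self) -> None:
        if not 0.0 < self.max_overburdening < 1.0:
            raise InvalidParameterError(
                f"max_overburdening must be in (0, 1), got {self.max_overburdening}"
            )
        if self.per_ambulance_arrival_rate <= 0:
            raise InvalidParameterError("per_ambulance_arrival_rate must be > 0")
        if self.ambulance_step < 1 or int(self.ambulance_step) != self.ambulance_step:
            raise InvalidParameterError("ambulance_step must be an integer >= 1")

    def probability(self, arrival_rate: float, doctors: int) -> float:
        """Overburdening probability for a total arrival rate and staff size."""
        params = QueueParameters(
            arrival_rate=arrival_rate,
            service_rate=self.service_rate,
            calls_per_doctor=self.calls_per_doctor,
            doctors=doctors,
        )
        return overburdening_probability(params)


def min_teds(total_arrival_rate: float, policy: CapacityPolicy) -> int:
    """Smallest number of doctors keeping overburdening within the policy.

    Scans ``n = 1, 2, ...`` upward; the overburdening probability is
    strictly decreasing in ``n``, so the first admissible ``n`` is optimal
    and a finite answer always exists.
    """
    if total_arrival_rate < 0:
        raise InvalidParameterError("total_arrival_rate must be >= 0")
    n = 1
    while policy.probability(total_arrival_rate, n) > policy.max_overburdening:
        n += 1
    return n


def max_ambulances(doctors: int, policy: CapacityPolicy) -> int:
    """Largest ambulance count (multiple of the step) a staff can serve.

    Returns 0 when even a single step of ambulances exceeds the tolerated
    overburdening probability.
    """
    if doctors < 1:
        raise InvalidParameterError("doctors must be >= 1")
    step = int(policy.ambulance_step)
    count = 0
    while True:
        candidate = count + step
        rate = candidate * policy.per_ambulance_arrival_rate
        if policy.probability(rate, doctors) > policy.max_overburdening:
            return count
        count = candidate


def overburdening_table(
    doctor_counts: Iterable[int],
    ambulance_grid: Iterable[int],
    policy: CapacityPolicy,
) -> pd.DataFrame:
    """Overburdening probability for every (doctors, ambulances) combination.

    Returns a tidy frame with columns ``doctors``, ``ambulances``,
    ``districts`` (ambulances divided by the policy step) and
    ``probability``; saturated cells carry probability 1.
    """
    doctor_counts = list(doctor_counts)
    ambulance_grid = list(ambulance_grid)
    if not doctor_counts or not ambulance_grid:
        raise InvalidParameterError("doctor_counts and ambulance_grid must be non-empty")
    rows = []
    for n in doctor_counts:
        for a in ambulance_grid:
            rows.append(
                {
                    "doctors": n,
                    "ambulances": a,
                    "districts": a / policy.ambulance_step,
                    "probability": policy.probability(
                        a * policy.per_ambulance_arrival_rate, n
                    )
                    if a > 0
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
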