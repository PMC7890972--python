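"""Annual cost model: decentralized per-district offices vs one pooled office.

Costs split into components that are fixed per office (rent, support,
quality management, supervision/administration) and components that jump
with each doctor working in parallel (salary, training, network, equipment
depreciation).  Variable per-emergency costs are identical under both
arrangements and are excluded from the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .planner import CapacityPolicy, min_teds
from .queueing import InvalidParameterError

__all__ = [
    "DEFAULT_FIXED_COMPONENTS",
    "DEFAULT_JUMP_FIXED_COMPONENTS",
    "CostStructure",
    "CentralizationScenario",
    "ScenarioReport",
    "decentral_cost",
    "central_cost",
    "evaluate_scenario",
    "round_to_hundred",
]

DEFAULT_FIXED_COMPONENTS: Mapping[str, float] = MappingProxyType(
    {
        "rent": 7_200.0,
        "support": 3_116.0,
        "quality_management": 27_560.0,
        "supervision_admin": 111_000.0,
    }
)

DEFAULT_JUMP_FIXED_COMPONENTS: Mapping[str, float] = MappingProxyType(
    {
        "salary": 508_144.0,
        "training": 6_924.0,
        "network": 20_797.0,
        "equipment_depreciation": 12_208.0,
    }
)


def round_to_hundred(amount: float) -> int:
    """Round a euro amount to the nearest 100, half away from zero."""
    return int(math.floor(amount / 100.0 + 0.5)) * 100


@dataclass(frozen=True)
class CostStructure:
    """Annual cost decomposition of one office.

    ``fixed_total`` is independent of staffing; ``per_doctor_total`` is the
    jump-fixed cost added by each doctor working in parallel, 24h/365d.
    """

    fixed_components: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_COMPONENTS)
    )
    jump_fixed_components: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JUMP_FIXED_COMPONENTS)
    )

    @property
    def fixed_total(self) -> float:
        return float(sum(self.fixed_components.values()))

    @property
    def per_doctor_total(self) -> float:
        return float(sum(self.jump_fixed_components.values()))

    @property
    def total_per_office(self) -> float:
        """Cost of one office with one doctor: fixed + one jump-fixed block."""
        return self.fixed_total + self.per_doctor_total


def decentral_cost(districts: int, cost_structure: CostStructure | None = None) -> float:
    """Total annual cost when every district runs its own one-doctor office."""
    if districts < 0:
        raise InvalidParameterError("districts must be >= 0")
    cs = cost_structure or CostStructure()
    return districts * cs.total_per_office


def central_cost(
    doctors_in_parallel: int, cost_structure: CostStructure | None = None
) -> float:
    """Total annual cost of one pooled office with ``e`` parallel doctors."""
    if doctors_in_parallel < 0:
        raise InvalidParameterError("doctors_in_parallel must be >= 0")
    cs = cost_structure or CostStructure()
    return cs.fixed_total + doctors_in_parallel * cs.per_doctor_total


@dataclass(frozen=True)
class CentralizationScenario:
    """A pooling arrangement: who shares one office and with what staffing.

    ``doctors_in_parallel`` may be left unset, in which case
    :func:`evaluate_scenario` plans it from a :class:`CapacityPolicy`.
    """

    districts: int
    ambulances_per_district: int = 26
    equipped_fraction: float = 1.0
    doctors_in_parallel: int | None = None
    cost_structure: CostStructure = field(default_factory=CostStructure)

    def __post_init__(self) -> None:
        if self.districts < 1:
            raise InvalidParameterError("districts must be >= 1")
        if not 0.0 < self.equipped_fraction <= 1.0:
            raise InvalidParameterError("equipped_fraction must be in (0, 1]")
        if self.doctors_in_parallel is not None and self.doctors_in_parallel < 1:
            raise InvalidParameterError("doctors_in_parallel must be >= 1")

    @property
    def equipped_ambulances(self) -> float:
        return self.districts * self.ambulances_per_district * self.equipped_fraction


@dataclass(frozen=True)
class ScenarioReport:
    """Evaluated costs of a centralization scenario (EUR per year)."""

    districts: int
    doctors_in_parallel: int
    total_central: float
    per_district: float
    per_district_rounded: int
    decentral_per_district: float
    ratio: float


def evaluate_scenario(
    scenario: CentralizationScenario, policy: CapacityPolicy | None = None
) -> ScenarioReport:
    """Cost report for a scenario, planning the staffing level if unset.

    ``ratio`` compares the centralized per-district cost with the cost of a
    stand-alone district office; ``per_district_rounded`` follows the
    nearest-100-euro reporting convention.
    """
    e = scenario.doctors_in_parallel
    if e is None:
        if policy is None:
            raise InvalidParameterError(
                "scenario has no doctors_in_parallel; supply a CapacityPolicy to plan it"
            )
        rate = scenario.equipped_ambulances * policy.per_ambulance_arrival_rate
        e = min_teds(rate, policy)
    cs = scenario.cost_structure
    total = central_cost(e, cs)
    per_district = total / scenario.districts
    return ScenarioReport(
        districts=scenario.districts,
        doctors_in_parallel=e,
        total_central=total,
        per_district=per_district,
        per_district_rounded=round_to_hundred(per_district),
        decentral_per_district=cs.total_per_office,
        ratio=per_district / cs.total_per_office,
    )
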