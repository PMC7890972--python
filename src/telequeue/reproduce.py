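"""One-shot reproduction report of every published figure the model yields.

Each row recomputes a published quantity from the model and reports the
published value, the recomputed value and the absolute deviation.  Rows
flagged ``expected_mismatch`` are documented non-reproductions (they do not
recompute from the published inputs under either service-rate preset) and
are excluded from the pass/fail verdict; their deviations are still shown.
"""

from __future__ import annotations

import pandas as pd

from .costs import CentralizationScenario, evaluate_scenario
from .planner import CapacityPolicy, max_ambulances, min_teds
from .presets import PER_AMBULANCE_RATE, resolve_mu
from .queueing import QueueParameters, overburdening_probability, solve_arrival_rate

__all__ = ["run_reproduction", "PUBLISHED_CAPACITY_ROWS"]

# Published maximum-ambulance sextuples for 1..6 doctors at each tolerance.
PUBLISHED_CAPACITY_ROWS: dict[float, tuple[int, ...]] = {
    0.05: (36, 96, 162, 240, 324, 408),
    0.10: (42, 114, 192, 270, 360, 456),
    0.20: (60, 138, 222, 318, 408, 504),
}

# Cells of the 5%/10% rows that do not recompute from the stated inputs
# under any service rate in [2.53, 2.57]; kept in the report, excluded from
# the verdict.  Keys: (tolerance, doctors).
_KNOWN_ROW_MISMATCHES = {(0.05, 3), (0.05, 4), (0.10, 4), (0.10, 6)}

_PUBLISHED_PROBABILITIES = [  # (ambulances, published %, two-decimal print)
    (6, 0.03),
    (12, 0.22),
    (26, 2.01),
    (60, 19.81),
    (90, 56.96),
    (114, 100.0),
]


def _prob_percent(ambulances: int, mu: float) -> float:
    params = QueueParameters(
        arrival_rate=ambulances * PER_AMBULANCE_RATE, service_rate=mu
    )
    return 100.0 * overburdening_probability(params)


def run_reproduction(mu_preset: str | float = "effective") -> pd.DataFrame:
    """Recompute all published figures under a service-rate preset.

    Returns a frame with columns ``quantity``, ``published``, ``computed``,
    ``deviation``, ``tolerance``, ``expected_mismatch`` and ``ok``.
    """
    mu = resolve_mu(mu_preset)
    rows: list[dict] = []

    def add(quantity, published, computed, tolerance, expected_mismatch=False):
        deviation = abs(computed - published)
        rows.append(
            {
                "quantity": quantity,
                "published": published,
                "computed": computed,
                "deviation": deviation,
                "tolerance": tolerance,
                "expected_mismatch": expected_mismatch,
                "ok": deviation <= tolerance,
            }
        )

    # -- overburdening probabilities (percent, printed to two decimals) --
    for ambulances, published in _PUBLISHED_PROBABILITIES:
        add(
            f"overburdening_pct_{ambulances}_ambulances",
            published,
            _prob_percent(ambulances, mu),
            0.005,
        )

    # -- empty-office probability w0 (documented non-reproduction) --
    params_vg = QueueParameters(arrival_rate=0.27, service_rate=mu)
    from .queueing import state_distribution

    w0 = float(state_distribution(params_vg).probabilities[0])
    add("w0_pct_single_district", 89.97, 100.0 * w0, 0.005, expected_mismatch=True)

    # -- inverse problem: arrival rate for 10% overburdening --
    add(
        "arrival_rate_at_10pct",
        2.093,
        solve_arrival_rate(0.10, mu),
        0.0015,
    )
    add(
        "overburdening_pct_at_lambda_2.093",
        10.0,
        100.0
        * overburdening_probability(QueueParameters(arrival_rate=2.093, service_rate=mu)),
        0.05,
    )

    # -- capacity rows --
    for tolerance_level, published_row in PUBLISHED_CAPACITY_ROWS.items():
        policy = CapacityPolicy(max_overburdening=tolerance_level, service_rate=mu)
        for doctors, published in enumerate(published_row, start=1):
            add(
                f"max_ambulances_{int(tolerance_level * 100)}pct_{doctors}_teds",
                published,
                max_ambulances(doctors, policy),
                0,
                expected_mismatch=(tolerance_level, doctors) in _KNOWN_ROW_MISMATCHES,
            )

    # -- staffing example: 240 ambulances at 10% needs 4 doctors --
    policy10 = CapacityPolicy(max_overburdening=0.10, service_rate=mu)
    add(
        "min_teds_240_ambulances_10pct",
        4,
        min_teds(240 * PER_AMBULANCE_RATE, policy10),
        0,
    )

    # -- costs (EUR, published to the nearest 100) --
    add(
        "cost_decentral_per_district",
        696_949,
        evaluate_scenario(
            CentralizationScenario(districts=1, doctors_in_parallel=1)
        ).per_district,
        0.5,
    )
    for quantity, published, districts, e in [
        ("cost_per_district_20x26_e6", 171_900, 20, 6),
        ("cost_per_district_60x6_e6", 57_300, 60, 6),
        ("cost_per_district_8x6_e1", 87_100, 8, 1),
        ("cost_per_district_8x26_e3", 224_100, 8, 3),
    ]:
        report = evaluate_scenario(
            CentralizationScenario(districts=districts, doctors_in_parallel=e)
        )
        add(quantity, published, report.per_district_rounded, 0)

    return pd.DataFrame(rows)


def reproduction_ok(report: pd.DataFrame) -> bool:
    """True when every non-flagged row is within its tolerance."""
    relevant = report[~report["expected_mismatch"]]
    return bool(relevant["ok"].all())
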