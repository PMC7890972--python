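"""Steady-state analytics of the M/M/k; ∞, FIFO tele-emergency office model.

An office with ``n`` doctors, each able to handle ``m`` calls in parallel,
is modelled as a multi-server Markovian queue with ``k = m*n`` channels,
Poisson arrivals at rate ``lambda`` and exponential service at rate ``mu``
per channel, unlimited waiting room and FIFO discipline.

The service-level statistic of interest is the *overburdening* probability

    P(i > k) = 1 - sum_{i=0}^{k} w_i,

the stationary probability that more than ``k`` calls are in the system, in
which case an arriving call is put on hold.  Note this is **not** the
textbook Erlang-C waiting probability ``P(i >= k)``; the latter is exposed
separately as :func:`erlang_c_waiting_probability`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InvalidParameterError",
    "SaturationError",
    "QueueParameters",
    "StateDistribution",
    "traffic_density",
    "state_distribution",
    "overburdening_probability",
    "erlang_c_waiting_probability",
    "solve_arrival_rate",
]


class InvalidParameterError(ValueError):
    """A queue parameter violates its domain (e.g. non-positive service rate)."""


class SaturationError(ValueError):
    """The offered load meets or exceeds capacity (rho >= k); no steady state."""


def traffic_density(arrival_rate: float, service_rate: float) -> float:
    """Offered load ``rho = arrival_rate / service_rate`` (dimensionless).

    Parameters
    ----------
    arrival_rate : float
        Calls per hour, ``>= 0``.
    service_rate : float
        Completed calls per hour per channel, ``> 0``.

    Raises
    ------
    InvalidParameterError
        If ``service_rate <= 0`` or ``arrival_rate < 0``.
    """
    if service_rate <= 0:
        raise InvalidParameterError(f"service_rate must be > 0, got {service_rate}")
    if arrival_rate < 0:
        raise InvalidParameterError(f"arrival_rate must be >= 0, got {arrival_rate}")
    return arrival_rate / service_rate


@dataclass(frozen=True)
class QueueParameters:
    """Parameter bundle ``(lambda, mu, m, n)`` with derived ``k`` and ``rho``.

    Attributes
    ----------
    arrival_rate : float
        Poisson arrival rate, calls per hour (``lambda``).
    service_rate : float
        Exponential service rate per channel, calls per hour (``mu``).
    calls_per_doctor : int
        Maximum parallel calls per doctor (``m``), default 2.
    doctors : int
        Doctors on duty in the office (``n``), default 1.
    """

    arrival_rate: float
    service_rate: float
    calls_per_doctor: int = 2
    doctors: int = 1

    def __post_init__(self) -> None:
        if self.arrival_rate < 0:
            raise InvalidParameterError(
                f"arrival_rate must be >= 0, got {self.arrival_rate}"
            )
        if self.service_rate <= 0:
            raise InvalidParameterError(
                f"service_rate must be > 0, got {self.service_rate}"
            )
        for name in ("calls_per_doctor", "doctors"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise InvalidParameterError(f"{name} must be an integer >= 1, got {value!r}")

    @property
    def channels(self) -> int:
        """Number of parallel channels, ``k = m * n``."""
        return self.calls_per_doctor * self.doctors

    @property
    def traffic_density(self) -> float:
        """Offered load ``rho = lambda / mu``."""
        return traffic_density(self.arrival_rate, self.service_rate)

    @property
    def is_stable(self) -> bool:
        """True when ``rho < k`` so a stationary distribution exists."""
        return self.traffic_density < self.channels


@dataclass(frozen=True)
class StateDistribution:
    """Stationary distribution ``w_0 .. w_imax`` with an analytic tail.

    ``probabilities[i]`` is the stationary probability of ``i`` calls in the
    system; ``tail_mass`` is the closed-form geometric remainder
    ``P(i > imax)`` so that the whole object sums to one.
    """

    probabilities: np.ndarray
    tail_mass: float
    params: QueueParameters = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=float)
        )

    @property
    def total(self) -> float:
        """``sum(probabilities) + tail_mass`` — equals 1 up to rounding."""
        return float(self.probabilities.sum() + self.tail_mass)


def _unnormalised_terms(rho: float, k: int, imax: int) -> np.ndarray:
    """Terms ``t_i = w_i / w_0`` for ``i = 0..imax`` via a running product.

    ``t_i = rho^i / i!`` below ``k`` and ``t_i = t_{i-1} * rho / k`` from
    ``k`` upward; the recurrence avoids explicit factorials so large channel
    counts stay finite.
    """
    t = np.empty(imax + 1)
    t[0] = 1.0
    for i in range(1, imax + 1):
        t[i] = t[i - 1] * rho / min(i, k)
    return t


def state_distribution(params: QueueParameters, imax: int | None = None) -> StateDistribution:
    """Stationary probabilities ``w_0 .. w_imax`` of the M/M/k queue.

    Parameters
    ----------
    params : QueueParameters
        Must describe a stable system (``rho < k``).
    imax : int, optional
        Largest explicitly computed state; defaults to ``channels + 20``.
        Must satisfy ``imax >= channels``.

    Returns
    -------
    StateDistribution
        With ``tail_mass`` equal to the geometric remainder
        ``w_imax * r / (1 - r)`` for ``r = rho / k``.

    Raises
    ------
    SaturationError
        If ``rho >= k``.  Use :func:`overburdening_probability`, which
        reports probability 1 for a saturated system.
    """
    k = params.channels
    if imax is None:
        imax = k + 20
    if imax < k:
        raise InvalidParameterError(f"imax must be >= channels ({k}), got {imax}")
    rho = params.traffic_density
    if rho >= k:
        raise SaturationError(
            f"offered load rho={rho:.4g} >= k={k}: no stationary distribution"
        )
    terms = _unnormalised_terms(rho, k, imax)
    r = rho / k
    # normalisation: sum_{i<k} t_i + t_k / (1 - r) covers the full infinite sum
    w0 = 1.0 / (terms[:k].sum() + terms[k] / (1.0 - r))
    probs = terms * w0
    tail = probs[imax] * r / (1.0 - r)
    return StateDistribution(probabilities=probs, tail_mass=tail, params=params)


def overburdening_probability(params: QueueParameters) -> float:
    """Probability an incoming call is put on hold, ``P(i > k)``.

    Returns ``1 - sum_{i=0}^{k} w_i`` for a stable system and exactly 1 for
    a saturated one (``rho >= k``), where the office fails to cover all
    incoming calls.  Evaluated through the equivalent geometric tail
    ``w_k * r / (1 - r)`` with ``r = rho/k``, which keeps tiny
    probabilities accurate where the literal ``1 - sum`` would cancel.
    """
    rho = params.traffic_density
    k = params.channels
    if rho == 0.0:
        return 0.0
    if rho >= k:
        return 1.0
    terms = _unnormalised_terms(rho, k, k)
    w0 = 1.0 / (terms[:k].sum() + terms[k] / (1.0 - rho / k))
    r = rho / k
    p = w0 * terms[k] * r / (1.0 - r)
    return min(1.0, p)


def erlang_c_waiting_probability(params: QueueParameters) -> float:
    """Textbook Erlang-C probability an arrival finds all channels busy.

    ``P(i >= k) = w_k / (1 - rho/k)``; always at least as large as the
    overburdening probability for the same parameters.  Returns 1 for a
    saturated system.
    """
    rho = params.traffic_density
    k = params.channels
    if rho == 0.0:
        return 0.0
    if rho >= k:
        return 1.0
    terms = _unnormalised_terms(rho, k, k)
    w0 = 1.0 / (terms[:k].sum() + terms[k] / (1.0 - rho / k))
    p = w0 * terms[k] / (1.0 - rho / k)
    return min(1.0, max(0.0, p))


def solve_arrival_rate(
    target_probability: float,
    service_rate: float,
    calls_per_doctor: int = 2,
    doctors: int = 1,
    xtol: float = 1e-12,
) -> float:
    """Arrival rate at which the overburdening probability hits a target.

    The forward map ``lambda -> P(i > k)`` is strictly increasing on
    ``(0, k*mu)`` and spans ``(0, 1)``, so the root is unique; it is
    bracketed and found by Brent's method to ``xtol`` absolute tolerance.

    Raises
    ------
    InvalidParameterError
        If ``target_probability`` is not strictly inside ``(0, 1)``.
    """
    if not 0.0 < target_probability < 1.0:
        raise InvalidParameterError(
            f"target_probability must be in (0, 1), got {target_probability}"
        )
    k = calls_per_doctor * doctors
    hi = k * service_rate

    def objective(lam: float) -> float:
        return (
            overburdening_probability(
                QueueParameters(lam, service_rate, calls_per_doctor, doctors)
            )
            - target_probability
        )

    lo = hi * 1e-12
    hi = hi * (1.0 - 1e-12)
    if objective(lo) > 0 or objective(hi) < 0:  # pragma: no cover - defensive
        raise InvalidParameterError("target probability not bracketable")
    return float(brentq(objective, lo, hi, xtol=xtol))
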