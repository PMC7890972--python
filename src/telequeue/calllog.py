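"""Call-log ingestion and parameter estimation for the queue model.

A call log is a delimited text table with one row per emergency: an
ISO-8601 ``start_time`` and a ``duration_seconds`` column.  From it we
derive the hourly arrival profile, the peak-hour arrival rate, the service
rate, and goodness-of-fit statistics for the Poisson-arrival and
exponential-service assumptions.

Exclusion rules for the service-time analysis: calls lasting one minute or
less (``duration <= 60 s``) and calls longer than four hours
(``duration > 14400 s``) are dropped; the arrival analysis keeps every
record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .queueing import InvalidParameterError

__all__ = [
    "SHORT_CALL_CUTOFF_SECONDS",
    "LONG_CALL_CUTOFF_SECONDS",
    "CallLogFormatError",
    "EmptyLogError",
    "CallRecord",
    "CallLog",
    "ExclusionCounts",
    "RateEstimates",
    "load_call_log",
    "write_call_log",
    "apply_exclusions",
    "estimate_rates",
    "goodness_of_fit",
]

logger = logging.getLogger(__name__)

SHORT_CALL_CUTOFF_SECONDS = 60.0  # "one minute or less" -> excluded
LONG_CALL_CUTOFF_SECONDS = 14_400.0  # "> 4 h" -> excluded


class CallLogFormatError(ValueError):
    """A call-log file is malformed; the message lists offending lines."""


class EmptyLogError(ValueError):
    """The call log contains no records."""


@dataclass(frozen=True)
class CallRecord:
    start_time: datetime
    duration_seconds: float


@dataclass
class CallLog:
    """An ordered set of emergency calls inside an observation window.

    ``frame`` holds columns ``start_time`` (datetime64) and
    ``duration_seconds`` (float), sorted by start time.  ``window`` is the
    half-open observation interval the rates are computed over.
    """

    frame: pd.DataFrame
    window: tuple[pd.Timestamp, pd.Timestamp]
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.frame = self.frame.sort_values("start_time", kind="stable").reset_index(
            drop=True
        )
        start, end = pd.Timestamp(self.window[0]), pd.Timestamp(self.window[1])
        if end <= start:
            raise InvalidParameterError("window end must be after window start")
        self.window = (start, end)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[CallRecord]:
        for row in self.frame.itertuples(index=False):
            yield CallRecord(row.start_time.to_pydatetime(), float(row.duration_seconds))

    @property
    def days(self) -> float:
        """Length of the observation window in days."""
        return (self.window[1] - self.window[0]) / pd.Timedelta(days=1)

    def to_csv(self, path) -> None:
        write_call_log(self, path)


def write_call_log(log: CallLog, path) -> None:
    """Write a log in the canonical CSV dialect (ISO timestamps, seconds)."""
    out = pd.DataFrame(
        {
            "start_time": log.frame["start_time"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "duration_seconds": log.frame["duration_seconds"].round().astype(int),
        }
    )
    out.to_csv(path, index=False)


def load_call_log(
    path,
    window: tuple | None = None,
    provenance: str = "observed",
) -> CallLog:
    """Parse a delimited call-log file into a :class:`CallLog`.

    Rows with unparseable timestamps or negative/non-numeric durations are
    reported with their 1-based line numbers; rows outside ``window`` are
    dropped (with a count in the log).  When ``window`` is omitted it is
    inferred as whole days covering the observed range.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = {"start_time", "duration_seconds"} - set(raw.columns)
    if missing:
        raise CallLogFormatError(f"missing required columns: {sorted(missing)}")
    if raw.empty:
        raise EmptyLogError(f"call log {path} contains no records")

    start = pd.to_datetime(raw["start_time"], errors="coerce", format="ISO8601")
    duration = pd.to_numeric(raw["duration_seconds"], errors="coerce")
    bad = start.isna() | duration.isna() | (duration < 0)
    if bad.any():
        lines = [int(i) + 2 for i in raw.index[bad]]  # +2: header + 1-based
        raise CallLogFormatError(
            f"malformed rows at line(s) {lines[:20]}"
            + (" ..." if len(lines) > 20 else "")
            + " (need ISO-8601 start_time and duration_seconds >= 0)"
        )

    frame = pd.DataFrame({"start_time": start, "duration_seconds": duration.astype(float)})
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        inside = (frame["start_time"] >= lo) & (frame["start_time"] < hi)
        n_dropped = int((~inside).sum())
        if n_dropped:
            logger.info("dropped %d records outside window [%s, %s)", n_dropped, lo, hi)
        frame = frame[inside]
        if frame.empty:
            raise EmptyLogError("no records inside the requested window")
    else:
        lo = frame["start_time"].min().normalize()
        hi = frame["start_time"].max().normalize() + pd.Timedelta(days=1)
        window = (lo, hi)
    return CallLog(frame=frame, window=(window[0], window[1]), provenance=provenance)


@dataclass(frozen=True)
class ExclusionCounts:
    n_short: int
    n_long: int
    n_kept: int

    @property
    def n_excluded(self) -> int:
        return self.n_short + self.n_long


def apply_exclusions(log: CallLog) -> tuple[pd.Series, ExclusionCounts]:
    """Service-time analysis set and exclusion tallies.

    Keeps durations strictly above 60 s and at most 14,400 s.  The
    operation is idempotent and order-independent; arrival analyses keep
    every record regardless.
    """
    d = log.frame["duration_seconds"]
    short = d <= SHORT_CALL_CUTOFF_SECONDS
    long_ = d > LONG_CALL_CUTOFF_SECONDS
    kept = d[~short & ~long_].reset_index(drop=True)
    return kept, ExclusionCounts(
        n_short=int(short.sum()), n_long=int(long_.sum()), n_kept=int(len(kept))
    )


@dataclass(frozen=True)
class RateEstimates:
    """Queue-model parameters estimated from a call log."""

    overall_arrival_rate: float
    peak_hour: int
    peak_arrival_rate: float
    service_rate: float
    mean_service_seconds: float
    sd_service_seconds: float
    n_total: int
    n_excluded_short: int
    n_excluded_long: int
    hourly_counts: pd.Series = field(repr=False)


def estimate_rates(log: CallLog, peak_window: tuple[int, int] | None = None) -> RateEstimates:
    """Hourly profile, overall/peak arrival rates and service rate.

    The hourly profile bins calls by the local-clock hour of their start
    time.  The peak hour is the busiest hour overall, or the busiest hour
    inside ``peak_window = (first_hour, last_hour_exclusive)`` if given.
    The service rate is ``3600 / mean`` of the post-exclusion durations.
    """
    if len(log) == 0:
        raise EmptyLogError("cannot estimate rates from an empty log")
    hours = log.frame["start_time"].dt.hour
    counts = hours.value_counts().reindex(range(24), fill_value=0).sort_index()
    days = log.days

    if peak_window is not None:
        lo, hi = peak_window
        candidates = counts.loc[lo : hi - 1]
    else:
        candidates = counts
    peak_hour = int(candidates.idxmax())

    service, excl = apply_exclusions(log)
    if excl.n_kept == 0:
        raise EmptyLogError("no records remain after exclusions")
    mean_s = float(service.mean())
    sd_s = float(service.std(ddof=1)) if excl.n_kept > 1 else 0.0

    return RateEstimates(
        overall_arrival_rate=len(log) / (24.0 * days),
        peak_hour=peak_hour,
        peak_arrival_rate=float(counts.loc[peak_hour]) / days,
        service_rate=3600.0 / mean_s,
        mean_service_seconds=mean_s,
        sd_service_seconds=sd_s,
        n_total=len(log),
        n_excluded_short=excl.n_short,
        n_excluded_long=excl.n_long,
        hourly_counts=counts,
    )


def _poisson_gof(counts_per_interval: np.ndarray) -> tuple[float, float]:
    """Chi-square test of interval counts against a fitted Poisson law.

    Bins the count histogram so every expected frequency is >= 5 and
    reduces the degrees of freedom by one for the estimated mean.
    """
    n = len(counts_per_interval)
    mean = counts_per_interval.mean()
    max_c = int(counts_per_interval.max())
    observed = np.bincount(counts_per_interval.astype(int), minlength=max_c + 1).astype(float)
    expected = stats.poisson.pmf(np.arange(max_c + 1), mean) * n
    expected[-1] += stats.poisson.sf(max_c, mean) * n  # fold the open tail in

    # merge sparse cells from the right, then from the left
    obs_b, exp_b = list(observed), list(expected)
    i = len(exp_b) - 1
    while i > 0 and exp_b[i] < 5:
        exp_b[i - 1] += exp_b.pop(i)
        obs_b[i - 1] += obs_b.pop(i)
        i -= 1
    while len(exp_b) > 2 and exp_b[0] < 5:
        exp_b[1] += exp_b.pop(0)
        obs_b[1] += obs_b.pop(0)
    obs_a, exp_a = np.array(obs_b), np.array(exp_b)
    dof = max(len(exp_a) - 2, 1)  # -1 constraint, -1 estimated mean
    chi2 = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    return chi2, float(stats.chi2.sf(chi2, dof))


def _exponential_gof(durations: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Chi-square test with equal-probability bins against a fitted exponential."""
    scale = durations.mean()
    edges = stats.expon.ppf(np.linspace(0, 1, n_bins + 1), scale=scale)
    edges[-1] = np.inf
    observed, _ = np.histogram(durations, bins=edges)
    expected = np.full(n_bins, len(durations) / n_bins)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = max(n_bins - 2, 1)
    return chi2, float(stats.chi2.sf(chi2, dof))


def goodness_of_fit(log: CallLog, min_records: int = 30) -> dict[str, float]:
    """Test the Markov assumptions on a call log.

    Returns chi-square statistics and p-values for hourly arrival counts
    vs a Poisson law, and chi-square plus Kolmogorov-Smirnov statistics for
    the post-exclusion service times vs an exponential law.  Both null
    distributions use estimated parameters; the KS p-value is conservative
    under the composite null.
    """
    if len(log) < min_records:
        raise InvalidParameterError(
            f"goodness_of_fit needs >= {min_records} records, got {len(log)}"
        )
    lo, hi = log.window
    hourly_index = pd.date_range(lo, hi, freq="h", inclusive="left")
    per_hour = (
        log.frame["start_time"]
        .dt.floor("h")
        .value_counts()
        .reindex(hourly_index, fill_value=0)
        .to_numpy()
    )
    poisson_chi2, poisson_p = _poisson_gof(per_hour)

    service, _ = apply_exclusions(log)
    durations = service.to_numpy(dtype=float)
    if len(durations) < min_records:
        raise InvalidParameterError("too few service records after exclusions")
    exp_chi2, exp_p = _exponential_gof(durations)
    ks = stats.kstest(durations, "expon", args=(0.0, durations.mean()))

    return {
        "poisson_chi2": poisson_chi2,
        "poisson_p": poisson_p,
        "exp_chi2": exp_chi2,
        "exp_p": exp_p,
        "exp_ks": float(ks.statistic),
        "exp_ks_p": float(ks.pvalue),
    }
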