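"""The contextual anomaly detection pipeline.

After an initialization period (default 10 days) the subject's days are
tiled into observation windows (default 5 days).  For each window an
expectation band is built from all data before the window; the observed
daily entropy-rate trace is then checked against the band, flagging the
window as a behavioral anomaly if the trace strictly exits the band on any
day.  The history is extended with the observed days before the next
window's band is computed, so expectations adapt to the subject's own
evolving behavior.  A behavioral shift is a run of at least two consecutive
anomalous windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import EntropyRatePoint, IngestionSequence, entropy_rate_trace
from .expectation import (
    ExpectationWindow,
    FutureOutcome,
    _enumerate_future_arrays,
    _weighted_moments,
)

__all__ = [
    "DetectionConfig",
    "AnomalyRecord",
    "BehavioralShift",
    "VolatilityReport",
    "CohortSummary",
    "run_detection",
    "detect_shifts",
    "classify_driver",
    "summarize_cohort",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection algorithm.

    ``init_days`` and ``window_days`` default to 10 and 5, chosen to evenly
    divide a 30-day treatment cycle.  ``min_sequence_days`` encodes the
    "more than 10 days of data" eligibility rule.  ``sd_multiplier`` scales
    the half-width of the expectation band (1 SD by default).
    """

    init_days: int = 10
    window_days: int = 5
    sd_multiplier: float = 1.0
    min_sequence_days: int = 11

    def __post_init__(self) -> None:
        if self.init_days < 2:
            raise ValueError("init_days must be >= 2 (need at least one transition)")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.min_sequence_days < self.init_days + 1:
            raise ValueError("min_sequence_days must be >= init_days + 1")


@dataclass(frozen=True)
class AnomalyRecord:
    """One observation window's band, excursions and classification."""

    window: ExpectationWindow
    flagged: bool
    excursion_days: tuple[int, ...]
    direction: str  # above | below | mixed | none
    driver: str  # success_driven | miss_driven | undetermined
    observed_successes: int
    expected_successes: float

    def __post_init__(self) -> None:
        if self.flagged != bool(self.excursion_days):
            raise ValueError("flagged must mirror non-empty excursion_days")


@dataclass(frozen=True)
class BehavioralShift:
    """A maximal run of >= 2 consecutive anomalous windows."""

    first_window: int
    last_window: int

    def __post_init__(self) -> None:
        if self.last_window < self.first_window + 1:
            raise ValueError("a shift spans at least two windows")

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1


@dataclass(frozen=True)
class VolatilityReport:
    """Per-subject detection output: trace, windows, anomalies and shifts."""

    subject_id: str
    eligible: bool
    n_days: int
    trace: tuple[EntropyRatePoint, ...]
    windows: tuple[AnomalyRecord, ...]
    shifts: tuple[BehavioralShift, ...]
    config: DetectionConfig = field(default_factory=DetectionConfig)

    @property
    def n_anomalies(self) -> int:
        return sum(r.flagged for r in self.windows)

    @property
    def has_anomaly(self) -> bool:
        return self.n_anomalies > 0


def _direction(above: bool, below: bool) -> str:
    if above and below:
        return "mixed"
    if above:
        return "above"
    if below:
        return "below"
    return "none"


def _driver_label(observed: int, expected: float) -> str:
    if observed > expected:
        return "success_driven"
    if observed < expected:
        return "miss_driven"
    return "undetermined"


def classify_driver(
    record: AnomalyRecord,
    futures: list[FutureOutcome],
    observed_window,
) -> str:
    """Label a flagged window as driven by successes or by missed doses.

    Compares the observed count of ingestion successes in the window with
    the weighted expected count under the enumerated futures:
    strictly more -> ``success_driven`` (the green case), strictly fewer ->
    ``miss_driven`` (red), exact equality -> ``undetermined``.
    """
    if not record.flagged:
        raise ValueError("driver classification is defined only for flagged windows")
    expected = float(
        sum(f.weight * sum(f.continuation) for f in futures)
    )
    observed = int(sum(int(o) for o in observed_window))
    return _driver_label(observed, expected)


def run_detection(
    seq: IngestionSequence, config: DetectionConfig | None = None
) -> VolatilityReport:
    """Run the full detection algorithm over one subject's sequence.

    The report is deterministic in the sequence and config.  Sequences
    shorter than ``init_days + 1`` yield an ineligible report with no
    windows rather than an exception.
    """
    if config is None:
        config = DetectionConfig()
    n = len(seq)
    eligible = n >= config.min_sequence_days
    trace = tuple(entropy_rate_trace(seq)) if n >= 2 else ()
    if n < config.init_days + 1:
        return VolatilityReport(seq.subject_id, False, n, trace, (), (), config)

    # trace value on day t (position p, 1-based): trace[p - 2]
    values = np.array([pt.value for pt in trace])
    records: list[AnomalyRecord] = []
    pos = config.init_days + 1
    w_idx = 0
    while pos <= n:
        w_idx += 1
        end = min(pos + config.window_days - 1, n)
        m = end - pos + 1
        history = seq.prefix(pos - 1)
        arr = _enumerate_future_arrays(history, m)
        stats = _weighted_moments(
            arr.weights, arr.terminal_entropies, config.sd_multiplier
        )
        window = ExpectationWindow(
            window_index=w_idx,
            start_day=seq.start_day + pos - 1,
            end_day=seq.start_day + end - 1,
            weighted_mean=stats.weighted_mean,
            weighted_sd=stats.weighted_sd,
            lower_bound=stats.lower_bound,
            upper_bound=stats.upper_bound,
        )
        vals = values[pos - 2 : end - 1]  # trace on days pos..end
        days = np.arange(window.start_day, window.end_day + 1)
        above = vals > stats.upper_bound
        below = vals < stats.lower_bound
        out = above | below
        excursions = tuple(int(d) for d in days[out])
        observed = seq.observations[pos - 1 : end]
        expected = float(arr.weights @ arr.continuations.sum(axis=1))
        flagged = bool(excursions)
        records.append(
            AnomalyRecord(
                window=window,
                flagged=flagged,
                excursion_days=excursions,
                direction=_direction(bool(above.any()), bool(below.any())),
                driver=_driver_label(sum(observed), expected) if flagged else "undetermined",
                observed_successes=int(sum(observed)),
                expected_successes=expected,
            )
        )
        pos = end + 1

    shifts = detect_shifts(records)
    return VolatilityReport(
        seq.subject_id, eligible, n, trace, tuple(records), tuple(shifts), config
    )


def detect_shifts(windows: list[AnomalyRecord]) -> list[BehavioralShift]:
    """Maximal runs of >= 2 consecutive flagged windows."""
    recs = list(windows)
    shifts: list[BehavioralShift] = []
    i = 0
    while i < len(recs):
        if not recs[i].flagged:
            i += 1
            continue
        j = i
        while j + 1 < len(recs) and recs[j + 1].flagged:
            j += 1
        if j > i:
            shifts.append(
                BehavioralShift(
                    recs[i].window.window_index, recs[j].window.window_index
                )
            )
        i = j + 1
    return shifts


@dataclass(frozen=True)
class CohortSummary:
    """Cohort roll-up of per-subject reports (eligible subjects only)."""

    n_subjects: int
    n_ineligible: int
    shift_counts: tuple[tuple[int, int], ...]  # (number of shifts, participants)
    shift_fractions: tuple[tuple[int, float], ...]  # fractions rounded to 2 dp
    pct_any_anomaly: float  # % subjects with >= 1 flagged window, 1 dp
    n_any_anomaly: int


def summarize_cohort(reports: list[VolatilityReport]) -> CohortSummary:
    """Distribution of behavioral-shift counts and anomaly prevalence.

    Ineligible subjects (fewer than ``min_sequence_days`` observations) are
    excluded from all denominators.
    """
    eligible = [r for r in reports if r.eligible]
    if not eligible:
        raise ValueError("no eligible reports in cohort")
    n = len(eligible)
    counts: dict[int, int] = {}
    for r in eligible:
        counts[len(r.shifts)] = counts.get(len(r.shifts), 0) + 1
    ordered = tuple(sorted(counts.items()))
    fractions = tuple((k, round(v / n, 2)) for k, v in ordered)
    n_any = sum(r.has_anomaly for r in eligible)
    return CohortSummary(
        n_subjects=n,
        n_ineligible=len(reports) - n,
        shift_counts=ordered,
        shift_fractions=fractions,
        pct_any_anomaly=round(100.0 * n_any / n, 1),
        n_any_anomaly=n_any,
    )
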