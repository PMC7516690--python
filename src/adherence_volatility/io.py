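"""Reading event logs and serialising detection reports.

Event logs are long-format tables (CSV or JSON records) with columns
``subject_id``, ``day`` (integer index or ISO-8601 date) and ``ingested``
(0/1).  Days must form a contiguous range per subject; calendar gaps are
rejected unless ``fill_missing_as_zero`` is set, which adopts the
convention that a day with no record is an unobserved ingestion.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .chain import EntropyRatePoint, IngestionSequence
from .detection import (
    AnomalyRecord,
    BehavioralShift,
    CohortSummary,
    DetectionConfig,
    VolatilityReport,
)
from .expectation import ExpectationWindow

__all__ = [
    "ValidationError",
    "read_events",
    "write_events",
    "write_report",
    "read_report",
    "cohort_table",
    "write_cohort_csv",
]

_REQUIRED = ("subject_id", "day", "ingested")


class ValidationError(ValueError):
    """An event log failed validation; the message names the offending rows."""


def _load_frame(path: Path, fmt: str | None) -> pd.DataFrame:
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
        return pd.DataFrame.from_records(records)
    raise ValueError(f"unknown format {fmt!r}")


def read_events(
    path, fmt: str | None = None, fill_missing_as_zero: bool = False
) -> list[IngestionSequence]:
    """Parse an event log into one :class:`IngestionSequence` per subject.

    Dates are converted to 1-based day indices from each subject's first
    record.  Raises :class:`ValidationError` naming the offending rows for
    missing columns, non-binary outcomes, duplicate subject-days, or gaps
    (unless ``fill_missing_as_zero``).
    """
    path = Path(path)
    df = _load_frame(path, fmt)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    df = df.copy()
    df["_row"] = df.index + 2  # 1-based, plus header line for CSVs

    bad = ~df["ingested"].isin([0, 1, "0", "1"])
    if bad.any():
        rows = df.loc[bad, "_row"].tolist()
        raise ValidationError(f"{path}: non-binary 'ingested' value at row(s) {rows}")
    df["ingested"] = df["ingested"].astype(int)

    # integer day indices, or ISO dates -> per-subject 1-based indices
    try:
        df["_day"] = df["day"].astype(int)
        dates = False
    except (ValueError, TypeError):
        try:
            df["_day"] = pd.to_datetime(df["day"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: 'day' must be integers or ISO dates: {exc}")
        dates = True

    sequences = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("_day")
        dupes = grp["_day"].duplicated()
        if dupes.any():
            rows = grp.loc[dupes, "_row"].tolist()
            raise ValidationError(
                f"{path}: duplicate day for subject {sid!r} at row(s) {rows}"
            )
        if dates:
            day_idx = (grp["_day"] - grp["_day"].iloc[0]).dt.days + 1
        else:
            day_idx = grp["_day"] - grp["_day"].iloc[0] + 1
        day_idx = day_idx.to_numpy()
        series = dict(zip(day_idx, grp["ingested"]))
        n = int(day_idx[-1])
        if len(series) != n:
            if not fill_missing_as_zero:
                gaps = sorted(set(range(1, n + 1)) - set(int(d) for d in day_idx))
                raise ValidationError(
                    f"{path}: subject {sid!r} has gap(s) at day offset(s) {gaps}; "
                    "pass fill_missing_as_zero to treat them as unobserved ingestions"
                )
            obs = tuple(int(series.get(d, 0)) for d in range(1, n + 1))
        else:
            obs = tuple(int(series[d]) for d in range(1, n + 1))
        sequences.append(IngestionSequence(str(sid), obs))
    return sequences


def write_events(sequences: list[IngestionSequence], path) -> None:
    """Write sequences as a long-format CSV event log."""
    rows = [
        {"subject_id": s.subject_id, "day": s.start_day + i, "ingested": o}
        for s in sequences
        for i, o in enumerate(s.observations)
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report serialization


def report_to_dict(report: VolatilityReport) -> dict:
    return dataclasses.asdict(report)


def _report_from_dict(d: dict) -> VolatilityReport:
    trace = tuple(EntropyRatePoint(int(p["day"]), float(p["value"])) for p in d["trace"])
    windows = tuple(
        AnomalyRecord(
            window=ExpectationWindow(**w["window"]),
            flagged=bool(w["flagged"]),
            excursion_days=tuple(int(x) for x in w["excursion_days"]),
            direction=w["direction"],
            driver=w["driver"],
            observed_successes=int(w["observed_successes"]),
            expected_successes=float(w["expected_successes"]),
        )
        for w in d["windows"]
    )
    shifts = tuple(
        BehavioralShift(int(s["first_window"]), int(s["last_window"])) for s in d["shifts"]
    )
    return VolatilityReport(
        subject_id=str(d["subject_id"]),
        eligible=bool(d["eligible"]),
        n_days=int(d["n_days"]),
        trace=trace,
        windows=windows,
        shifts=shifts,
        config=DetectionConfig(**d["config"]),
    )


def write_report(obj, path, fmt: str | None = None) -> None:
    """Serialise a report, list of reports, or cohort summary.

    Reports go to JSON (with trace, per-window bounds, flags, excursion
    days, drivers and shifts; an empty shift list is written explicitly).
    A :class:`CohortSummary` goes to JSON, or to a shift-distribution CSV
    when ``fmt='csv'`` / the path ends in ``.csv``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "json"
    if isinstance(obj, CohortSummary):
        if fmt == "csv":
            write_cohort_csv(obj, path)
        else:
            path.write_text(json.dumps(dataclasses.asdict(obj), indent=2) + "\n")
        return
    if fmt != "json":
        raise ValueError("per-subject reports are serialised as JSON")
    if isinstance(obj, VolatilityReport):
        payload = report_to_dict(obj)
    else:
        payload = [report_to_dict(r) for r in obj]
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path) -> VolatilityReport | list[VolatilityReport]:
    """Inverse of :func:`write_report` for JSON report files."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        return [_report_from_dict(d) for d in payload]
    return _report_from_dict(payload)


def cohort_table(summary: CohortSummary) -> pd.DataFrame:
    """Shift-count distribution as a table (shifts, participants, fraction)."""
    fractions = dict(summary.shift_fractions)
    return pd.DataFrame(
        {
            "number_of_shifts": [k for k, _ in summary.shift_counts],
            "participants": [v for _, v in summary.shift_counts],
            "fraction": [fractions[k] for k, _ in summary.shift_counts],
        }
    )


def write_cohort_csv(summary: CohortSummary, path) -> None:
    cohort_table(summary).to_csv(path, index=False)
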