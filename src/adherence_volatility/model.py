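"""Model/results interface over the volatility and anomaly machinery.

:class:`AdherenceVolatility` is constructed from one subject's binary
ingestion series; :meth:`~AdherenceVolatility.fit` estimates the Markov
chain by maximum likelihood day by day, runs the contextual anomaly
detector, and returns an :class:`AdherenceVolatilityResults` carrying the
volatility trace, the per-window expectation bands, flagged anomalies,
behavioral shifts, and a text summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chain import (
    IngestionSequence,
    StationaryDistribution,
    TransitionMatrix,
    count_transitions,
    entropy_rate,
    estimate_transition_matrix,
    stationary_distribution,
)
from .detection import DetectionConfig, VolatilityReport, run_detection

__all__ = ["AdherenceVolatility", "AdherenceVolatilityResults"]


class AdherenceVolatility:
    """Adherence-volatility model for one subject's daily ingestion series.

    Parameters
    ----------
    endog : array-like of 0/1 or IngestionSequence
        Daily ingestion outcomes (1 = observed ingestion).
    subject_id : str
        Identifier carried through to the results, ignored when ``endog``
        is already an :class:`IngestionSequence`.
    config : DetectionConfig, optional
        Detection parameters; keyword arguments ``init_days``,
        ``window_days``, ``sd_multiplier`` and ``min_sequence_days`` may be
        given instead.

    Examples
    --------
    >>> m = AdherenceVolatility([1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
    >>> res = m.fit()
    >>> res.n_windows
    1
    """

    def __init__(
        self,
        endog,
        subject_id: str = "subject",
        config: DetectionConfig | None = None,
        **config_kwargs,
    ):
        if isinstance(endog, IngestionSequence):
            self.sequence = endog
        else:
            self.sequence = IngestionSequence(subject_id, tuple(np.asarray(endog, dtype=int)))
        if config is not None and config_kwargs:
            raise ValueError("pass either config or keyword parameters, not both")
        self.config = config if config is not None else DetectionConfig(**config_kwargs)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        subject_id: str | None = None,
        value_col: str = "ingested",
        subject_col: str = "subject_id",
        day_col: str = "day",
        **config_kwargs,
    ) -> "AdherenceVolatility":
        """Build a model from a long-format event table.

        The frame needs subject, day and 0/1 outcome columns; when it holds
        several subjects, ``subject_id`` selects one.
        """
        df = data
        if subject_col in df.columns:
            if subject_id is not None:
                df = df[df[subject_col].astype(str) == str(subject_id)]
            elif df[subject_col].nunique() > 1:
                raise ValueError("multiple subjects in frame; pass subject_id")
            else:
                subject_id = str(df[subject_col].iloc[0])
        if df.empty:
            raise ValueError(f"no rows for subject {subject_id!r}")
        df = df.sort_values(day_col)
        seq = IngestionSequence(subject_id or "subject", tuple(df[value_col].astype(int)))
        return cls(seq, **config_kwargs)

    def fit(self) -> "AdherenceVolatilityResults":
        """Estimate the chain and run the anomaly detector."""
        report = run_detection(self.sequence, self.config)
        return AdherenceVolatilityResults(self, report)


class AdherenceVolatilityResults:
    """Fitted adherence-volatility results for one subject."""

    def __init__(self, model: AdherenceVolatility, report: VolatilityReport):
        self.model = model
        self.report = report

    # -- final-day chain estimates ------------------------------------

    @property
    def transition_matrix(self) -> TransitionMatrix:
        """ML transition probabilities from the full sequence."""
        return estimate_transition_matrix(count_transitions(self.model.sequence))

    @property
    def stationary_dist(self) -> StationaryDistribution:
        return stationary_distribution(
            self.transition_matrix, last_state=self.model.sequence.last_state
        )

    @property
    def entropy_rate(self) -> float:
        """Entropy rate (nats) of the chain estimated from all data."""
        return entropy_rate(self.transition_matrix, self.stationary_dist)

    # -- detection output ---------------------------------------------

    @property
    def trace(self) -> pd.Series:
        """Adherence-volatility trace, indexed by day."""
        return pd.Series(
            [p.value for p in self.report.trace],
            index=pd.Index([p.day for p in self.report.trace], name="day"),
            name="entropy_rate",
        )

    @property
    def n_windows(self) -> int:
        return len(self.report.windows)

    @property
    def n_anomalies(self) -> int:
        return self.report.n_anomalies

    @property
    def shifts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "first_window": s.first_window,
                    "last_window": s.last_window,
                    "n_windows": s.n_windows,
                }
                for s in self.report.shifts
            ],
            columns=["first_window", "last_window", "n_windows"],
        )

    def windows_frame(self) -> pd.DataFrame:
        """Per-window bands, flags and classifications as a table."""
        return pd.DataFrame(
            [
                {
                    "window": r.window.window_index,
                    "start_day": r.window.start_day,
                    "end_day": r.window.end_day,
                    "mean": r.window.weighted_mean,
                    "sd": r.window.weighted_sd,
                    "lower": r.window.lower_bound,
                    "upper": r.window.upper_bound,
                    "flagged": r.flagged,
                    "direction": r.direction,
                    "driver": r.driver,
                    "observed_successes": r.observed_successes,
                    "expected_successes": r.expected_successes,
                }
                for r in self.report.windows
            ]
        )

    def summary(self) -> str:
        """Human-readable fit and detection summary."""
        seq = self.model.sequence
        tp = self.transition_matrix
        pi = self.stationary_dist
        cfg = self.report.config
        adherence = sum(seq.observations) / len(seq) if len(seq) else float("nan")
        lines = [
            "      Adherence Volatility Results",
            "=" * 46,
            f"Subject:              {seq.subject_id}",
            f"Days observed:        {len(seq)}",
            f"Eligible (>{cfg.min_sequence_days - 1} days): {self.report.eligible}",
            f"Aggregate adherence:  {adherence:.3f}",
            "-" * 46,
            "ML transition matrix (rows: from state 0, 1)",
            f"  p00={tp.p_00:.4f}  p01={tp.p_01:.4f}",
            f"  p10={tp.p_10:.4f}  p11={tp.p_11:.4f}",
            f"Stationary dist:      pi0={pi.pi_0:.4f}  pi1={pi.pi_1:.4f}",
            f"Entropy rate (nats):  {self.entropy_rate:.5f}",
            "-" * 46,
            f"Init period {cfg.init_days} d, windows of {cfg.window_days} d, "
            f"band = mean +/- {cfg.sd_multiplier:g} SD",
            f"Observation windows:  {self.n_windows}",
            f"Anomalous windows:    {self.n_anomalies}",
            f"Behavioral shifts:    {len(self.report.shifts)}",
        ]
        for s in self.report.shifts:
            lines.append(f"  shift: windows {s.first_window}-{s.last_window}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Volatility trace with the per-window expectation bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3.5))
        tr = self.trace
        ax.plot(tr.index, tr.values, color="tab:blue", lw=1.5, label="entropy rate")
        for r in self.report.windows:
            days = [r.window.start_day - 0.5, r.window.end_day + 0.5]
            ax.fill_between(
                days,
                [r.window.lower_bound] * 2,
                [r.window.upper_bound] * 2,
                color="0.8" if not r.flagged else ("tab:green" if r.driver == "success_driven" else "tab:red"),
                alpha=0.5,
                linewidth=0,
            )
        ax.set_xlabel("day")
        ax.set_ylabel("entropy rate (nats)")
        ax.set_title(f"Adherence volatility — {self.model.sequence.subject_id}")
        return ax
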