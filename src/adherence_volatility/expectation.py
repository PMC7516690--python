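"""Adaptive expectation bounds for an upcoming observation window.

Given a subject's history, the engine enumerates all 2**n binary futures of
the next n days, weights each by its probability under the chain estimated
from the history (transition matrix frozen at the window start), and
re-estimates the entropy rate at the end of each hypothetical future.  The
weighted mean and SD of these terminal entropy rates define the expectation
band the observed volatility trace is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .chain import (
    IngestionSequence,
    count_transitions,
    estimate_transition_matrix,
    _entropy_batch,
    _matrices_from_count_rows,
    _stationary_batch,
)

__all__ = [
    "MAX_WINDOW_DAYS",
    "FutureOutcome",
    "ExpectationWindow",
    "WindowStats",
    "enumerate_futures",
    "window_bounds",
]

#: enumeration is 2**n; cap n to bound cost
MAX_WINDOW_DAYS = 20


@dataclass(frozen=True)
class FutureOutcome:
    """One hypothetical n-day continuation of a subject's history.

    ``weight`` is the probability of the continuation under the frozen
    transition matrix; ``terminal_entropy`` is the entropy rate of the chain
    re-estimated from history + continuation.
    """

    continuation: tuple[int, ...]
    weight: float
    terminal_entropy: float


@dataclass(frozen=True)
class ExpectationWindow:
    """Fixed expectation band for one observation window."""

    window_index: int
    start_day: int
    end_day: int
    weighted_mean: float
    weighted_sd: float
    lower_bound: float
    upper_bound: float

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1


class WindowStats(NamedTuple):
    """Weighted moments of the terminal entropy-rate distribution."""

    weighted_mean: float
    weighted_sd: float
    lower_bound: float
    upper_bound: float


class _FutureArrays(NamedTuple):
    continuations: np.ndarray  # (2**n, n) 0/1
    weights: np.ndarray  # (2**n,)
    terminal_entropies: np.ndarray  # (2**n,)


def _enumerate_future_arrays(history: IngestionSequence, n: int) -> _FutureArrays:
    if n < 1:
        raise ValueError("window length must be >= 1")
    if n > MAX_WINDOW_DAYS:
        raise ValueError(f"window length {n} exceeds enumeration cap {MAX_WINDOW_DAYS}")
    counts = count_transitions(history)  # raises on len < 2
    P = estimate_transition_matrix(counts).as_array()

    m = 1 << n
    bits = (np.arange(m)[:, None] >> np.arange(n - 1, -1, -1)) & 1  # (m, n)
    prev = np.concatenate(
        [np.full((m, 1), history.last_state, dtype=np.int64), bits[:, :-1]], axis=1
    )
    weights = P[prev, bits].prod(axis=1)

    # counts for history + each continuation, built incrementally
    base = np.array([counts.n_00, counts.n_01, counts.n_10, counts.n_11], dtype=np.int64)
    idx = 2 * prev + bits  # (m, n) flat transition indices
    delta = np.zeros((m, 4), dtype=np.int64)
    np.add.at(delta, (np.arange(m)[:, None], idx), 1)
    Pt = _matrices_from_count_rows(base[None, :] + delta)
    pi = _stationary_batch(Pt, last_states=bits[:, -1])
    h = _entropy_batch(Pt, pi)
    return _FutureArrays(bits, weights, h)


def enumerate_futures(history: IngestionSequence, n: int) -> list[FutureOutcome]:
    """All 2**n weighted futures of the next ``n`` days.

    Weights are products of one-step transition probabilities starting from
    the last observed state, under the matrix estimated from ``history``
    alone; they sum to 1.  Each terminal entropy is the entropy rate of the
    chain re-estimated from the concatenated sequence.

    Raises
    ------
    InsufficientDataError
        If the history is too short to estimate a chain.
    """
    arr = _enumerate_future_arrays(history, n)
    return [
        FutureOutcome(tuple(int(b) for b in c), float(w), float(h))
        for c, w, h in zip(arr.continuations, arr.weights, arr.terminal_entropies)
    ]


def _weighted_moments(
    weights: np.ndarray, values: np.ndarray, sd_multiplier: float
) -> WindowStats:
    mean = float(weights @ values)
    var = float(weights @ (values - mean) ** 2)
    sd = float(np.sqrt(max(var, 0.0)))
    return WindowStats(mean, sd, mean - sd_multiplier * sd, mean + sd_multiplier * sd)


def window_bounds(futures: list[FutureOutcome], sd_multiplier: float = 1.0) -> WindowStats:
    """Weighted mean, population SD and mean +/- k*SD band of the futures.

    Weights must already be normalised (they are, coming from
    :func:`enumerate_futures`); the SD is the plain weighted population form
    with no bias correction.
    """
    if not futures:
        raise ValueError("empty future set")
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    w = np.array([f.weight for f in futures], dtype=float)
    h = np.array([f.terminal_entropy for f in futures], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"future weights sum to {w.sum()}, expected 1")
    return _weighted_moments(w, h, sd_multiplier)
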