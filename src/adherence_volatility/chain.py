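"""Two-state Markov chain estimation and the empirical entropy rate.

A subject's daily ingestion record (1 = observed ingestion, 0 = unobserved)
is modelled as a first-order binary Markov chain.  Transition probabilities
are estimated by maximum likelihood from day-to-day transition counts, the
stationary distribution is obtained by eigendecomposition of the transition
matrix, and the entropy rate

    H = -sum_q pi_q sum_r p_qr ln(p_qr)        (nats, 0*ln 0 := 0)

quantifies how predictable tomorrow's observation is given today's state.
"Adherence volatility" is the longitudinal evolution of H as the chain is
re-estimated each day from all data observed so far.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LN2",
    "InsufficientDataError",
    "IngestionSequence",
    "TransitionCounts",
    "TransitionMatrix",
    "StationaryDistribution",
    "EntropyRatePoint",
    "count_transitions",
    "estimate_transition_matrix",
    "stationary_distribution",
    "entropy_rate",
    "entropy_rate_trace",
    "entropy_rate_from_sequence",
]

LN2 = math.log(2.0)

#: eigenvalue selection tolerance: the unit eigenvalue of a row-stochastic
#: matrix must be recovered within this distance
_EIGEN_TOL = 1e-8


class InsufficientDataError(ValueError):
    """Raised when a sequence is too short to estimate a transition model."""


@dataclass(frozen=True)
class IngestionSequence:
    """One subject's ordered daily binary ingestion observations.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    observations : sequence of int
        One 0/1 outcome per day, contiguous (no gaps).
    start_day : int
        Day index of the first observation (1-based by convention).
    """

    subject_id: str
    observations: tuple[int, ...]
    start_day: int = 1

    def __post_init__(self) -> None:
        obs = tuple(int(o) for o in self.observations)
        if any(o not in (0, 1) for o in obs):
            bad = next(o for o in obs if o not in (0, 1))
            raise ValueError(f"observations must be 0 or 1, got {bad!r}")
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def last_state(self) -> int:
        if not self.observations:
            raise InsufficientDataError("empty sequence has no last state")
        return self.observations[-1]

    @property
    def end_day(self) -> int:
        return self.start_day + len(self.observations) - 1

    def prefix(self, n: int) -> "IngestionSequence":
        """The first ``n`` observations as a new sequence."""
        return IngestionSequence(self.subject_id, self.observations[:n], self.start_day)

    def extended(self, continuation) -> "IngestionSequence":
        """This sequence with ``continuation`` appended."""
        return IngestionSequence(
            self.subject_id, self.observations + tuple(int(c) for c in continuation), self.start_day
        )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.observations, dtype=np.int64)

    def __str__(self) -> str:
        return "".join(str(o) for o in self.observations)


@dataclass(frozen=True)
class TransitionCounts:
    """Counts of observed day-to-day transitions q -> r."""

    n_00: int
    n_01: int
    n_10: int
    n_11: int

    def __post_init__(self) -> None:
        if min(self.n_00, self.n_01, self.n_10, self.n_11) < 0:
            raise ValueError("transition counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_00 + self.n_01 + self.n_10 + self.n_11

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_00, self.n_01], [self.n_10, self.n_11]], dtype=float)


@dataclass(frozen=True)
class TransitionMatrix:
    """Maximum-likelihood one-step transition probabilities.

    ``row_defined[q]`` is False when state q had no observed outgoing
    transitions; such rows are assigned self-transition probability 1 so the
    matrix stays row-stochastic (an unvisited or apparently absorbing state
    contributes zero entropy).
    """

    p_00: float
    p_01: float
    p_10: float
    p_11: float
    row_defined: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        for p in (self.p_00, self.p_01, self.p_10, self.p_11):
            if not (-1e-12 <= p <= 1 + 1e-12):
                raise ValueError(f"transition probability {p} outside [0, 1]")
        if abs(self.p_00 + self.p_01 - 1.0) > 1e-12 or abs(self.p_10 + self.p_11 - 1.0) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.p_00, self.p_01], [self.p_10, self.p_11]], dtype=float)

    @property
    def doubly_absorbing(self) -> bool:
        """True when both states self-absorb (stationary law not unique)."""
        return self.p_01 == 0.0 and self.p_10 == 0.0


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run occupancy probabilities of the two states."""

    pi_0: float
    pi_1: float

    def __post_init__(self) -> None:
        if abs(self.pi_0 + self.pi_1 - 1.0) > 1e-9:
            raise ValueError("stationary probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_0, self.pi_1], dtype=float)


@dataclass(frozen=True)
class EntropyRatePoint:
    """Empirical entropy rate (nats) of the chain estimated through ``day``."""

    day: int
    value: float


def count_transitions(seq: IngestionSequence) -> TransitionCounts:
    """Count adjacent ordered pairs q -> r in a sequence.

    Raises
    ------
    InsufficientDataError
        If the sequence has fewer than 2 observations.
    """
    if len(seq) < 2:
        raise InsufficientDataError(
            f"need >= 2 observations to count transitions, got {len(seq)}"
        )
    x = seq.as_array()
    idx = 2 * x[:-1] + x[1:]
    c = np.bincount(idx, minlength=4)
    return TransitionCounts(int(c[0]), int(c[1]), int(c[2]), int(c[3]))


def estimate_transition_matrix(counts: TransitionCounts) -> TransitionMatrix:
    """Maximum-likelihood transition probabilities p_qr = n_qr / n_q.

    Rows with no outgoing transitions are marked undefined and assigned
    self-transition probability 1.
    """
    if counts.total == 0:
        raise InsufficientDataError("no transitions observed")
    row0 = counts.n_00 + counts.n_01
    row1 = counts.n_10 + counts.n_11
    if row0 > 0:
        p_00, p_01 = counts.n_00 / row0, counts.n_01 / row0
    else:
        p_00, p_01 = 1.0, 0.0
    if row1 > 0:
        p_10, p_11 = counts.n_10 / row1, counts.n_11 / row1
    else:
        p_10, p_11 = 0.0, 1.0
    return TransitionMatrix(p_00, p_01, p_10, p_11, (row0 > 0, row1 > 0))


def stationary_distribution(
    tp: TransitionMatrix, last_state: int | None = None
) -> StationaryDistribution:
    """Stationary distribution via eigendecomposition.

    The left eigenvector of the transition matrix for the eigenvalue closest
    to 1 (within 1e-8), with components made non-negative and normalised to
    sum 1.  When both states self-absorb the stationary law is not unique;
    it is resolved as a point mass on ``last_state`` (the empirically
    occupied state), which must then be supplied.
    """
    if tp.doubly_absorbing:
        if last_state is None:
            raise ValueError(
                "doubly-absorbing matrix: stationary distribution not unique; "
                "supply last_state to resolve"
            )
        return StationaryDistribution(1.0 - last_state, float(last_state))
    pi = _stationary_batch(tp.as_array()[None, :, :])[0]
    return StationaryDistribution(float(pi[0]), float(pi[1]))


def entropy_rate(tp: TransitionMatrix, pi: StationaryDistribution) -> float:
    """Entropy rate -sum_q pi_q sum_r p_qr ln p_qr in nats (0*ln 0 := 0)."""
    h = _entropy_batch(tp.as_array()[None, :, :], pi.as_array()[None, :])[0]
    return float(h)


def entropy_rate_from_sequence(seq: IngestionSequence) -> float:
    """Entropy rate of the ML chain estimated from a whole sequence."""
    tp = estimate_transition_matrix(count_transitions(seq))
    pi = stationary_distribution(tp, last_state=seq.last_state)
    return entropy_rate(tp, pi)


def entropy_rate_trace(seq: IngestionSequence) -> list[EntropyRatePoint]:
    """The adherence-volatility trace: one entropy rate per day.

    For each day T from the second observed day onward, the entropy rate of
    the chain estimated by maximum likelihood from observations 1..T.  The
    first day carries no value (no transition has been observed yet).
    """
    if len(seq) < 2:
        raise InsufficientDataError("need >= 2 observations for a trace")
    x = seq.as_array()
    idx = 2 * x[:-1] + x[1:]
    # cumulative transition counts per prefix: row T-2 holds counts of x[1..T]
    onehot = np.zeros((len(idx), 4), dtype=np.int64)
    onehot[np.arange(len(idx)), idx] = 1
    cum = np.cumsum(onehot, axis=0)
    P = _matrices_from_count_rows(cum)
    pi = _stationary_batch(P, last_states=x[1:])
    h = _entropy_batch(P, pi)
    days = seq.start_day + 1 + np.arange(len(h))
    return [EntropyRatePoint(int(d), float(v)) for d, v in zip(days, h)]


# ---------------------------------------------------------------------------
# batched internals shared with the expectation engine


def _matrices_from_count_rows(counts: np.ndarray) -> np.ndarray:
    """(k, 4) count rows [n00, n01, n10, n11] -> (k, 2, 2) ML matrices.

    Zero-outgoing rows receive the self-absorbing assignment.
    """
    c = counts.reshape(-1, 2, 2).astype(float)
    rowsum = c.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(rowsum > 0, c / np.where(rowsum > 0, rowsum, 1.0), 0.0)
    # self-absorbing fill for empty rows
    empty = (rowsum[:, :, 0] == 0)
    P[empty[:, 0], 0, 0] = 1.0
    P[empty[:, 1], 1, 1] = 1.0
    return P


def _stationary_batch(P: np.ndarray, last_states: np.ndarray | None = None) -> np.ndarray:
    """Stationary distributions for stacked 2x2 row-stochastic matrices.

    Eigendecomposition of each transposed matrix; the eigenvector for the
    eigenvalue nearest 1 is taken in absolute value and normalised by its
    component sum.  Doubly-absorbing matrices are resolved as a point mass
    on the corresponding entry of ``last_states``.
    """
    vals, vecs = np.linalg.eig(np.swapaxes(P, -1, -2))
    pick = np.argmin(np.abs(vals - 1.0), axis=-1)
    k = np.arange(P.shape[0])
    if np.any(np.abs(vals[k, pick] - 1.0) > _EIGEN_TOL):
        raise ValueError("no eigenvalue within tolerance of 1; matrix not row-stochastic?")
    v = np.abs(np.real(vecs[k, :, pick]))
    pi = v / v.sum(axis=-1, keepdims=True)
    degenerate = (P[:, 0, 1] == 0.0) & (P[:, 1, 0] == 0.0)
    if np.any(degenerate):
        if last_states is None:
            raise ValueError(
                "doubly-absorbing matrix in batch: supply last_states to resolve"
            )
        ls = np.asarray(last_states, dtype=float)
        pi[degenerate, 0] = 1.0 - ls[degenerate]
        pi[degenerate, 1] = ls[degenerate]
    return pi


def _entropy_batch(P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Entropy rates (nats) for stacked matrices and stationary rows."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    h = -(pi[:, :, None] * plogp).sum(axis=(1, 2))
    # clip away negative rounding noise; ln 2 is the two-state ceiling
    # (+0.0 normalises -0.0)
    return np.clip(h, 0.0, LN2) + 0.0
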