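import math

import pytest

from adherence_volatility import IngestionSequence


def make_seq(bits: str, subject_id: str = "s") -> IngestionSequence:
    return IngestionSequence(subject_id, tuple(int(c) for c in bits))


def binary_entropy_nats(p: float) -> float:
    """Independent closed-form oracle for H(p) = -p ln p - (1-p) ln(1-p)."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log(p) + (1.0 - p) * math.log(1.0 - p))


def chain_entropy_oracle(p01: float, p10: float) -> float:
    """Closed-form entropy rate of a two-state chain: pi-weighted row entropies."""
    s = p01 + p10
    if s == 0.0:
        return 0.0
    pi1 = p01 / s
    return (1.0 - pi1) * binary_entropy_nats(p01) + pi1 * binary_entropy_nats(p10)


@pytest.fixture
def seq_factory():
    return make_seq
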