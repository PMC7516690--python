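"""Seeded simulation of binary ingestion sequences.

The clinical ingestion records the method was developed on are not public;
this module stands in for them with first-order two-state Markov chains
with constant transition probabilities — exactly the data-generating model
the estimator assumes.  Six presets reproduce the illustrative
high/low-adherence scenarios (60-day horizons, stationary initial state by
default).  Real ingestion data differ in ways the simulator does not
emulate: transition structure may drift over treatment, and unobserved
ingestions conflate missed doses with device non-compliance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chain import IngestionSequence

__all__ = [
    "SimulationScenario",
    "simulate_chain",
    "preset_scenarios",
    "synthetic_cohort",
]

_INIT_RULES = ("stationary", "fixed_0", "fixed_1")


@dataclass(frozen=True)
class SimulationScenario:
    """A constant-parameter two-state Markov chain to simulate.

    ``p_01`` is the probability of moving from an unobserved (0) to an
    observed (1) ingestion day; ``p_10`` the reverse.  The expected long-run
    success rate is p_01 / (p_01 + p_10).
    """

    label: str
    p_01: float
    p_10: float
    horizon_days: int = 60
    seed: int = 0
    initial_state_rule: str = "stationary"

    def __post_init__(self) -> None:
        for p in (self.p_01, self.p_10):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transition probability {p} outside [0, 1]")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be positive")
        if self.initial_state_rule not in _INIT_RULES:
            raise ValueError(f"initial_state_rule must be one of {_INIT_RULES}")

    @property
    def expected_success_rate(self) -> float:
        """Long-run adherence p_01 / (p_01 + p_10)."""
        s = self.p_01 + self.p_10
        if s == 0:
            raise ValueError("expected success rate undefined when p_01 + p_10 = 0")
        return self.p_01 / s


def simulate_chain(scenario: SimulationScenario) -> IngestionSequence:
    """Draw one sequence from a constant-parameter chain, reproducibly.

    The initial state is a stationary draw by default (or fixed to 0/1);
    each subsequent day is drawn from the constant transition matrix.
    """
    rng = np.random.default_rng(scenario.seed)
    rule = scenario.initial_state_rule
    if rule == "stationary":
        # raises when p_01 + p_10 == 0 (stationary law not unique)
        state = int(rng.random() < scenario.expected_success_rate)
    else:
        state = 1 if rule == "fixed_1" else 0
    stay = (1.0 - scenario.p_01, 1.0 - scenario.p_10)  # P(stay | state)
    obs = np.empty(scenario.horizon_days, dtype=np.int64)
    obs[0] = state
    u = rng.random(scenario.horizon_days - 1)
    for t in range(1, scenario.horizon_days):
        if u[t - 1] >= stay[state]:
            state = 1 - state
        obs[t] = state
    return IngestionSequence(scenario.label, tuple(int(o) for o in obs))


def preset_scenarios() -> list[SimulationScenario]:
    """The six illustrative 60-day simulation presets.

    Expected long-run success rates for A/B/C-D/E are 0.75, 0.17, 0.38 and
    0.83 by the closed form p_01 / (p_01 + p_10); preset F (p_01=.1,
    p_10=.3) works out to 0.25.
    """
    params = [
        ("presetA", 0.3, 0.1),
        ("presetB", 0.1, 0.5),
        ("presetC", 0.3, 0.5),
        ("presetD", 0.3, 0.5),
        ("presetE", 0.5, 0.1),
        ("presetF", 0.1, 0.3),
    ]
    return [
        SimulationScenario(label, p01, p10, horizon_days=60, seed=301 + i)
        for i, (label, p01, p10) in enumerate(params)
    ]


def synthetic_cohort(
    n_subjects: int,
    scenario_mix: list[tuple[SimulationScenario, float]] | None = None,
    seed: int = 0,
) -> list[IngestionSequence]:
    """A reproducible cohort of simulated subjects.

    ``scenario_mix`` pairs scenarios with selection weights (summing to 1);
    by default the six presets are mixed uniformly.  Each subject gets a
    child seed drawn from ``seed`` and an id ``S0001``, ``S0002``, ...
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    if scenario_mix is None:
        presets = preset_scenarios()
        scenario_mix = [(s, 1.0 / len(presets)) for s in presets]
    if not scenario_mix:
        raise ValueError("scenario_mix must not be empty")
    weights = np.array([w for _, w in scenario_mix], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"scenario weights sum to {weights.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(scenario_mix), size=n_subjects, p=weights)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    cohort = []
    for i, (pick, child) in enumerate(zip(picks, child_seeds), start=1):
        base = scenario_mix[pick][0]
        scen = replace(base, seed=int(child))
        seq = simulate_chain(scen)
        cohort.append(IngestionSequence(f"S{i:04d}", seq.observations))
    return cohort
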