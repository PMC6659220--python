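"""Simulation of examinations with exposed items and pre-knowledge cheaters.

The default scenario mirrors the examination conditions the detector is
calibrated for: 100 multiple-choice items of which 20 are reused (exposed),
200 students, item difficulties and true abilities standard normal, and the
cheaters' effective score gain drawn from a scaled Beta distribution —
``3 * Beta(9, 4)`` for high-effective pre-knowledge and ``3 * Beta(5, 5)``
for low-effective pre-knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ItemBank, ResponseMatrix, StudentCohort, gated_prob

__all__ = [
    "ScenarioConfig",
    "PAPER_SCENARIOS",
    "simulate_items",
    "simulate_cohort",
    "simulate_responses",
    "simulate_exam",
    "replicate_rng",
]

_GAIN_PARAMS = {"high": (9.0, 4.0), "low": (5.0, 5.0)}


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    Parameters
    ----------
    n_students, n_items, n_exposed : int
        Examination size; ``n_exposed`` items are flagged as reused.
    prop_cheaters : float
        True prevalence of item pre-knowledge, in ``[0, 1]``.
    efficacy : {"high", "low", "none"}
        Gain distribution for cheaters; ``"none"`` forces an all-honest
        cohort regardless of ``prop_cheaters``.
    n_replicates : int
        Independent replicates of the scenario.
    seed : int
        Master seed; replicate ``r`` uses the sub-stream ``(seed, r)``.
    """

    prop_cheaters: float
    efficacy: str = "high"
    n_students: int = 200
    n_items: int = 100
    n_exposed: int = 20
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prop_cheaters <= 1:
            raise ValueError("prop_cheaters must be in [0, 1]")
        if not 0 < self.n_exposed < self.n_items:
            raise ValueError("need 0 < n_exposed < n_items")
        if self.efficacy not in ("high", "low", "none"):
            raise ValueError(f"unknown efficacy {self.efficacy!r}")

    @property
    def name(self) -> str:
        pct = round(100 * self.prop_cheaters)
        return f"{pct}-{self.efficacy}"

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


#: The eight scenario presets of the calibration study: true prevalence
#: 5/10/35/70% crossed with high/low cheating efficacy.
PAPER_SCENARIOS: dict[str, ScenarioConfig] = {
    f"{pct}-{eff}": ScenarioConfig(prop_cheaters=pct / 100, efficacy=eff)
    for pct in (5, 10, 35, 70)
    for eff in ("high", "low")
}


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic independent sub-stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


def simulate_items(
    n_items: int, n_exposed: int, rng: np.random.Generator
) -> ItemBank:
    """Draw an item bank: N(0,1) difficulties, ``n_exposed`` exposed flags.

    The exposed items are chosen uniformly without replacement; only their
    count is fixed by the design.
    """
    if not 0 < n_exposed < n_items:
        raise ValueError("need 0 < n_exposed < n_items")
    difficulty = rng.standard_normal(n_items)
    exposed = np.zeros(n_items, dtype=int)
    exposed[rng.choice(n_items, size=n_exposed, replace=False)] = 1
    return ItemBank(difficulty=difficulty, exposed=exposed)


def simulate_cohort(
    n_students: int,
    prop_cheaters: float,
    efficacy: str,
    rng: np.random.Generator,
) -> StudentCohort:
    """Draw a cohort: N(0,1) true abilities plus scaled-Beta gains.

    Exactly ``round(prop_cheaters * n_students)`` students are cheaters,
    chosen uniformly, so the scenario's true prevalence is exact in every
    replicate.  Cheater gains are ``3 * Beta(9, 4)`` (high efficacy) or
    ``3 * Beta(5, 5)`` (low); honest students have gain 0 and
    ``theta_cheat == theta_true``.
    """
    if not 0 <= prop_cheaters <= 1:
        raise ValueError("prop_cheaters must be in [0, 1]")
    if efficacy == "none":
        prop_cheaters = 0.0
    elif efficacy not in _GAIN_PARAMS:
        raise ValueError(f"unknown efficacy {efficacy!r}")
    theta_true = rng.standard_normal(n_students)
    gain = np.zeros(n_students)
    n_cheat = round(prop_cheaters * n_students)
    if n_cheat:
        a, b = _GAIN_PARAMS[efficacy]
        who = rng.choice(n_students, size=n_cheat, replace=False)
        gain[who] = 3.0 * rng.beta(a, b, size=n_cheat)
    theta_cheat = theta_true + gain
    return StudentCohort(
        theta_true=theta_true,
        theta_cheat=theta_cheat,
        gain=gain,
        is_cheater=(gain > 0).astype(int),
    )


def simulate_responses(
    items: ItemBank, cohort: StudentCohort, rng: np.random.Generator
) -> ResponseMatrix:
    """Bernoulli responses under the gated mixture.

    Each entry is an independent draw with success probability
    ``gated_prob(theta_t, theta_c, T, G, b)``.
    """
    p = gated_prob(
        cohort.theta_true[:, None],
        cohort.theta_cheat[:, None],
        cohort.is_cheater[:, None],
        items.exposed[None, :],
        items.difficulty[None, :],
    )
    values = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseMatrix(
        values=values, student_id=cohort.student_id, item_id=items.item_id
    )


def simulate_exam(
    scenario: ScenarioConfig, replicate: int = 0
) -> tuple[ItemBank, StudentCohort, ResponseMatrix]:
    """Simulate one full replicate (items, cohort, responses) of a scenario."""
    rng = replicate_rng(scenario.seed, replicate)
    items = simulate_items(scenario.n_items, scenario.n_exposed, rng)
    cohort = simulate_cohort(
        scenario.n_students, scenario.prop_cheaters, scenario.efficacy, rng
    )
    responses = simulate_responses(items, cohort, rng)
    return items, cohort, responses
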