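"""Synthetic cohorts for the contingency-degradation task.

No agent model is fitted to human data anywhere in this package; the agents
here are a deliberately minimal *generative* model used to produce event
streams with the statistical structure the analysis pipeline assumes:

* delta-rule beliefs about the two conditional outcome probabilities
  P(O|A) and P(O|~A), updated on the branch experienced in each 1-s bin;
* a logistic response policy combining a baseline propensity, the believed
  contingency scaled by an inverse temperature, and a cue-specific habit
  strength that grows with every reinforced response;
* block-level causality ratings read out from the believed ΔP on the
  −100..100 scale, plus a Bernoulli memory-test outcome.

Varying the parameters spans the phenotypes of interest: a *goal-directed*
agent (high inverse temperature, no habit weight) suppresses responding when
the contingency turns negative; a *habitual* agent (contingency-blind policy
driven by accrued habit strength) keeps responding; a *mixed* cohort with
heterogeneous learning rates produces the belief–behaviour correlations the
exploratory analyses look for.

The task environment side is exact: within each 1-s bin at most one response
is possible, and the outcome for the bin is drawn Bernoulli(P1) if the agent
responded and Bernoulli(P2) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .design import (
    VARIANTS,
    BlockSpec,
    ContingencySpec,
    ExperimentDesign,
    build_design,
)

__all__ = [
    "BinRecord",
    "BlockData",
    "AgentParams",
    "AgentState",
    "ParticipantData",
    "step_bin",
    "simulate_block",
    "simulate_participant",
    "simulate_cohort",
    "goal_directed_params",
    "habitual_params",
    "mixed_params",
    "PRESETS",
]


@dataclass(frozen=True)
class BinRecord:
    """One 1-second bin: whether a response occurred and whether an outcome
    was delivered.  The 1-s lockout (at most one response per bin) holds by
    construction."""

    bin_index: int
    responded: bool
    outcome: bool


@dataclass
class BlockData:
    """Simulated (or imported) data for one block.

    Bin-level events are stored as two boolean arrays; the ``bins`` property
    materialises them as :class:`BinRecord` objects when object-level access
    is preferred.
    """

    spec: BlockSpec
    responded: np.ndarray
    outcomes: np.ndarray
    causality_rating: int
    memory_correct: bool

    def __post_init__(self) -> None:
        self.responded = np.asarray(self.responded, dtype=bool)
        self.outcomes = np.asarray(self.outcomes, dtype=bool)
        if self.responded.shape != (self.spec.duration_bins,):
            raise ValueError(
                f"expected {self.spec.duration_bins} bins, got {self.responded.shape}"
            )
        if self.outcomes.shape != self.responded.shape:
            raise ValueError("responded/outcomes length mismatch")
        if not (-100 <= self.causality_rating <= 100):
            raise ValueError("causality_rating outside the -100..100 scale")

    @property
    def bins(self) -> list[BinRecord]:
        return [
            BinRecord(i, bool(r), bool(o))
            for i, (r, o) in enumerate(zip(self.responded, self.outcomes))
        ]

    @property
    def n_responses(self) -> int:
        return int(self.responded.sum())


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic responder.

    learning_rate
        Delta-rule step (0–1) for the conditional-probability beliefs.
    inverse_temperature
        Weight (≥0) of the believed ΔP in the logistic response policy.
    habit_gain
        Habit-strength increment (≥0) per reinforced response.
    habit_weight
        Weight (≥0) of habit strength in the response policy.
    rating_noise_sd
        SD (≥0) of Gaussian noise added to causality ratings, on the
        −100..100 scale.
    memory_error_rate
        Per-block probability (0–1) of failing the cue memory test.
    baseline_logit
        Intercept of the response policy (log-odds of responding when the
        believed contingency is zero and no habit has accrued).
    """

    learning_rate: float = 0.12
    inverse_temperature: float = 5.0
    habit_gain: float = 0.0
    habit_weight: float = 0.0
    rating_noise_sd: float = 15.0
    memory_error_rate: float = 0.01
    baseline_logit: float = -0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in [0, 1]")
        for name in ("inverse_temperature", "habit_gain", "habit_weight", "rating_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.memory_error_rate <= 1.0):
            raise ValueError("memory_error_rate must lie in [0, 1]")


@dataclass(frozen=True)
class AgentState:
    """Per-cue learning state: beliefs about P(O|A) and P(O|~A), and the
    accrued habit strength for that cue.  Habit never transfers between
    cues; beliefs persist across blocks and sessions of the same cue."""

    p1_belief: float = 0.5
    p2_belief: float = 0.5
    habit_strength: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1_belief <= 1.0 and 0.0 <= self.p2_belief <= 1.0):
            raise ValueError("beliefs must lie in [0, 1]")
        if self.habit_strength < 0:
            raise ValueError("habit_strength must be >= 0")


def _logistic(x: float) -> float:
    if x >= 36.0:
        return 1.0
    if x <= -36.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def response_probability(state: AgentState, params: AgentParams) -> float:
    """Per-bin response probability under the logistic policy."""
    return _logistic(
        params.baseline_logit
        + params.inverse_temperature * (state.p1_belief - state.p2_belief)
        + params.habit_weight * state.habit_strength
    )


def step_bin(
    state: AgentState,
    params: AgentParams,
    contingency: ContingencySpec,
    rng: np.random.Generator,
) -> tuple[BinRecord, AgentState]:
    """Advance one 1-second bin: respond, sample the outcome, learn.

    Consumes exactly two uniforms from ``rng`` (response, then outcome), so a
    block of n bins consumed scalar-wise matches ``rng.random((n, 2))``
    consumed row-wise.
    """
    p_resp = response_probability(state, params)
    responded = rng.random() < p_resp
    u_out = rng.random()
    p1 = contingency.p_outcome_given_action
    p2 = contingency.p_outcome_given_no_action
    outcome = u_out < (p1 if responded else p2)
    lr = params.learning_rate
    p1b, p2b, hab = state.p1_belief, state.p2_belief, state.habit_strength
    if responded:
        p1b += lr * ((1.0 if outcome else 0.0) - p1b)
        if outcome:
            hab += params.habit_gain
    else:
        p2b += lr * ((1.0 if outcome else 0.0) - p2b)
    new_state = AgentState(p1b, p2b, hab)
    return BinRecord(0, bool(responded), bool(outcome)), new_state


def _run_block(
    p1b: float,
    p2b: float,
    hab: float,
    params: AgentParams,
    p1: float,
    p2: float,
    u: np.ndarray,
) -> tuple[list[bool], list[bool], float, float, float]:
    # Tight scalar loop; semantically identical to iterating step_bin with the
    # same uniform stream (asserted by a unit test).
    lr = params.learning_rate
    beta = params.inverse_temperature
    hgain = params.habit_gain
    hweight = params.habit_weight
    base = params.baseline_logit
    resp: list[bool] = []
    out: list[bool] = []
    exp = math.exp
    for u_r, u_o in u:
        x = base + beta * (p1b - p2b) + hweight * hab
        if x >= 36.0:
            p = 1.0
        elif x <= -36.0:
            p = 0.0
        else:
            p = 1.0 / (1.0 + exp(-x))
        if u_r < p:
            o = u_o < p1
            if o:
                p1b += lr * (1.0 - p1b)
                hab += hgain
            else:
                p1b -= lr * p1b
            resp.append(True)
        else:
            o = u_o < p2
            if o:
                p2b += lr * (1.0 - p2b)
            else:
                p2b -= lr * p2b
            resp.append(False)
        out.append(o)
    return resp, out, p1b, p2b, hab


def simulate_block(
    state: AgentState,
    params: AgentParams,
    spec: BlockSpec,
    rng: np.random.Generator,
) -> tuple[BlockData, AgentState]:
    """Run one block of ``spec.duration_bins`` bins and read out the
    block-end causality rating and memory-test result.

    The rating is ``round(clip(100·(p1_belief − p2_belief) + noise, −100,
    100))`` with the beliefs *after* the block, emulating a judgment based on
    the just-experienced contingency.
    """
    u = rng.random((spec.duration_bins, 2))
    resp, out, p1b, p2b, hab = _run_block(
        state.p1_belief,
        state.p2_belief,
        state.habit_strength,
        params,
        spec.contingency.p_outcome_given_action,
        spec.contingency.p_outcome_given_no_action,
        u,
    )
    noise = rng.normal(0.0, params.rating_noise_sd)
    rating = int(round(min(100.0, max(-100.0, 100.0 * (p1b - p2b) + noise))))
    memory_correct = bool(rng.random() >= params.memory_error_rate)
    block = BlockData(
        spec=spec,
        responded=np.asarray(resp, dtype=bool),
        outcomes=np.asarray(out, dtype=bool),
        causality_rating=rating,
        memory_correct=memory_correct,
    )
    return block, AgentState(p1b, p2b, hab)


@dataclass
class ParticipantData:
    """All blocks of one participant, in presentation order."""

    participant_id: int
    variant: str
    counterbalance_group: str | None
    blocks: list[BlockData]
    params: AgentParams | None = None
    design: ExperimentDesign | None = None
    final_states: dict[str, AgentState] = field(default_factory=dict)

    def first_test_cue(self) -> str:
        """Cue of the first overtrained/standard habit-test block
        (the participant's between-subject group)."""
        for b in self.blocks:
            if b.spec.phase == "habit_test" and b.spec.cue != "filler":
                return b.spec.cue
        raise ValueError("participant has no overtrained/standard habit test")


def simulate_participant(
    design: ExperimentDesign,
    params: AgentParams,
    rng: np.random.Generator,
) -> ParticipantData:
    """Execute a full design for one agent.

    Learning state is kept per cue and carried across blocks and sessions;
    it is never reset at block boundaries.
    """
    states: dict[str, AgentState] = {}
    blocks: list[BlockData] = []
    for spec in design.blocks():
        state = states.get(spec.cue, AgentState())
        block, state = simulate_block(state, params, spec, rng)
        states[spec.cue] = state
        blocks.append(block)
    return ParticipantData(
        participant_id=design.participant_id,
        variant=design.variant,
        counterbalance_group=design.counterbalance_group,
        blocks=blocks,
        params=params,
        design=design,
        final_states=states,
    )


# --- parameter presets -----------------------------------------------------

def goal_directed_params(rng: np.random.Generator | None = None) -> AgentParams:
    """Contingency-tracking agent: responding follows the believed ΔP.

    Calibrated so that converged training responding sits near 0.9 per bin
    (logistic(−0.8 + 5·0.6) ≈ 0.90), in the band human cohorts show, and
    collapses once the believed contingency turns negative.
    """
    return AgentParams(
        learning_rate=0.12,
        inverse_temperature=5.0,
        habit_gain=0.0,
        habit_weight=0.0,
        rating_noise_sd=15.0,
        memory_error_rate=0.01,
        baseline_logit=-0.8,
    )


def habitual_params(rng: np.random.Generator | None = None) -> AgentParams:
    """Contingency-blind S-R agent: no belief learning; responding is driven
    by a baseline propensity plus habit strength accrued from reinforced
    responses, so test-block responding matches training responding."""
    return AgentParams(
        learning_rate=0.0,
        inverse_temperature=0.0,
        habit_gain=1.0,
        habit_weight=0.0015,
        rating_noise_sd=15.0,
        memory_error_rate=0.01,
        baseline_logit=0.5,
    )


def mixed_params(rng: np.random.Generator) -> AgentParams:
    """Heterogeneous cohort: learning rate and inverse temperature vary
    across participants, so some agents detect the degradation (high rating,
    suppressed responding) and some do not — producing the negative
    ratio-vs-rating correlation in test blocks."""
    return AgentParams(
        learning_rate=float(rng.uniform(0.005, 0.25)),
        inverse_temperature=float(rng.uniform(1.5, 7.0)),
        habit_gain=1.0,
        habit_weight=float(rng.uniform(0.0, 0.001)),
        rating_noise_sd=20.0,
        memory_error_rate=0.02,
        baseline_logit=-0.5,
    )


PRESETS: dict[str, Callable[[np.random.Generator], AgentParams]] = {
    "goal_directed": lambda rng: goal_directed_params(rng),
    "habitual": lambda rng: habitual_params(rng),
    "mixed": mixed_params,
}


def simulate_cohort(
    variant: str,
    n_participants: int,
    preset: str | Callable[[np.random.Generator], AgentParams] = "goal_directed",
    seed: int = 0,
) -> list[ParticipantData]:
    """Simulate a cohort of agents through one experiment variant.

    ``preset`` names a parameter preset (``goal_directed``, ``habitual``,
    ``mixed``) or is a callable drawing :class:`AgentParams` from a
    per-participant generator.  Counterbalance groups (exp2/exp3) alternate
    A/B by participant index; exp1's test order is its per-participant coin
    flip inside :func:`operant.design.build_design`.  Fully reproducible
    from ``seed``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    sampler = PRESETS[preset] if isinstance(preset, str) else preset
    children = np.random.SeedSequence(seed).spawn(n_participants)
    cohort: list[ParticipantData] = []
    for pid in range(n_participants):
        rng = np.random.default_rng(children[pid])
        group = None if variant == "exp1" else ("A" if pid % 2 == 0 else "B")
        design = build_design(variant, pid, seed, group)
        params = sampler(rng)
        cohort.append(simulate_participant(design, params, rng))
    return cohort
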