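"""Block schedules for the free-operant contingency-degradation task.

The task is organised in 120-second blocks of free responding.  During
*training* blocks an outcome is more likely after a response than without one
(positive contingency, ΔP = P(O|A) − P(O|~A) > 0); during *habit-test* blocks
the contingency is degraded below zero, so that withholding the response is
the better policy.  Three cues are trained to different extents:

* ``overtrained`` — 24 positive blocks across three sessions,
* ``standard``   — 6 positive blocks,
* ``filler``     — 2 positive blocks, degraded already in session 1
  (experiment variants 1 and 3 only).

Three experiment variants share the block economy but differ in how the
session-3 test order for the overtrained and standard cues is assigned:
random per participant (``exp1``), or counterbalanced across participants
(``exp2``, which also drops the filler cue, and ``exp3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CUES",
    "PHASES",
    "VARIANTS",
    "ContingencySpec",
    "BlockSpec",
    "ExperimentDesign",
    "POSITIVE",
    "NEGATIVE",
    "make_contingency",
    "pseudorandomize_order",
    "build_design",
    "design_to_frame",
    "write_design_csv",
]

CUES = ("overtrained", "standard", "filler")
PHASES = ("training", "habit_test")
VARIANTS = ("exp1", "exp2", "exp3")


@dataclass(frozen=True)
class ContingencySpec:
    """Programmed outcome probabilities for one block.

    ``p_outcome_given_action`` (P1) applies to 1-s bins containing a
    response, ``p_outcome_given_no_action`` (P2) to bins without one;
    ``delta_p`` = P1 − P2 is the unidirectional contingency index.
    """

    p_outcome_given_action: float
    p_outcome_given_no_action: float

    def __post_init__(self) -> None:
        for name in ("p_outcome_given_action", "p_outcome_given_no_action"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p!r}")

    @property
    def delta_p(self) -> float:
        return self.p_outcome_given_action - self.p_outcome_given_no_action


def make_contingency(p1: float, p2: float) -> ContingencySpec:
    """Build a :class:`ContingencySpec` from P(O|A) and P(O|~A)."""
    return ContingencySpec(float(p1), float(p2))


#: Training contingency: ΔP = +0.6 (P1 = 0.6, P2 = 0).
POSITIVE = make_contingency(0.6, 0.0)
#: Habit-test contingency: ΔP = −0.3 (P1 = 0.6, P2 = 0.9).
NEGATIVE = make_contingency(0.6, 0.9)


@dataclass(frozen=True)
class BlockSpec:
    """One 120-bin block: its place in the schedule and its contingency."""

    session: int
    position: int  # 0-based index within session
    cue: str
    phase: str
    contingency: ContingencySpec
    duration_bins: int = 120

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.duration_bins < 1:
            raise ValueError("duration_bins must be >= 1")
        if self.session < 1:
            raise ValueError("session must be >= 1")
        if self.position < 0:
            raise ValueError("position must be >= 0")
        dp = self.contingency.delta_p
        if self.phase == "training" and dp <= 0:
            raise ValueError("training blocks require delta_p > 0")
        if self.phase == "habit_test" and dp >= 0:
            raise ValueError("habit_test blocks require delta_p < 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Full multi-session schedule for one participant."""

    variant: str
    participant_id: int
    counterbalance_group: str | None
    sessions: tuple[tuple[BlockSpec, ...], ...]
    seed: int

    def blocks(self) -> Iterator[BlockSpec]:
        """Iterate blocks in presentation order."""
        for session in self.sessions:
            yield from session

    @property
    def n_blocks(self) -> int:
        return sum(len(s) for s in self.sessions)

    def count(
        self,
        cue: str | None = None,
        phase: str | None = None,
        session: int | None = None,
    ) -> int:
        """Count blocks matching the given cue / phase / session filters."""
        n = 0
        for b in self.blocks():
            if cue is not None and b.cue != cue:
                continue
            if phase is not None and b.phase != phase:
                continue
            if session is not None and b.session != session:
                continue
            n += 1
        return n

    def first_test_cue(self) -> str:
        """Cue of the first overtrained/standard habit-test block.

        This is the participant's between-subject group: in exp1 it realises
        the per-participant coin flip, in exp2/exp3 the counterbalance group.
        """
        for b in self.blocks():
            if b.phase == "habit_test" and b.cue != "filler":
                return b.cue
        raise ValueError("design contains no overtrained/standard habit test")


def pseudorandomize_order(
    blocks: Sequence[BlockSpec], rng: np.random.Generator | int
) -> list[BlockSpec]:
    """Order blocks so each half of the list holds half of each cue's blocks.

    Within each half the order is uniformly random.  Requires an even number
    of blocks per cue.  ``position`` fields of the input are ignored; callers
    re-assign positions after ordering.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_cue: dict[str, list[BlockSpec]] = {}
    for b in blocks:
        by_cue.setdefault(b.cue, []).append(b)
    first: list[BlockSpec] = []
    second: list[BlockSpec] = []
    for cue, items in by_cue.items():
        if len(items) % 2:
            raise ValueError(f"cue {cue!r} has an odd block count ({len(items)})")
        half = len(items) // 2
        first.extend(items[:half])
        second.extend(items[half:])
    for part in (first, second):
        rng.shuffle(part)
    return first + second


def _training(session: int, cue: str) -> BlockSpec:
    return BlockSpec(session, 0, cue, "training", POSITIVE)


def _test(session: int, cue: str) -> BlockSpec:
    return BlockSpec(session, 0, cue, "habit_test", NEGATIVE)


def _number(session_blocks: Iterable[BlockSpec]) -> tuple[BlockSpec, ...]:
    return tuple(
        replace(b, position=i) for i, b in enumerate(session_blocks)
    )


def _session3(session: int, first: str, second: str) -> list[BlockSpec]:
    # Alternating scheme: 2 training -> 2 test -> 2 training -> 2 test, each
    # pair holding one block per tested cue, ordered by the test order.
    out: list[BlockSpec] = []
    for _cycle in range(2):
        out += [_training(session, first), _training(session, second)]
        out += [_test(session, first), _test(session, second)]
    return out


def build_design(
    variant: str,
    participant_id: int,
    seed: int,
    counterbalance_group: str | None = None,
) -> ExperimentDesign:
    """Construct the per-participant block schedule of one experiment variant.

    Parameters
    ----------
    variant
        ``"exp1"``, ``"exp2"`` or ``"exp3"``.
    participant_id
        Non-negative participant index; combined with ``seed`` it determines
        the pseudorandom training orders (and, for exp1, the coin flip that
        sets the session-3 test order).
    seed
        Cohort-level seed; schedules are reproducible byte-for-byte from
        ``(variant, participant_id, seed, counterbalance_group)``.
    counterbalance_group
        ``"A"`` (overtrained tested first) or ``"B"`` (standard first).
        Required for exp2/exp3, ignored for exp1 where the test order is an
        unconstrained fair coin per participant.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "exp1":
        counterbalance_group = None
    else:
        if counterbalance_group not in ("A", "B"):
            raise ValueError(
                f"{variant} requires counterbalance_group 'A' or 'B', "
                f"got {counterbalance_group!r}"
            )
    rng = np.random.default_rng([seed, participant_id])

    if variant in ("exp1", "exp3"):
        s1_training = [_training(1, c) for c in ("overtrained", "standard", "filler") for _ in range(2)]
        s1 = pseudorandomize_order(s1_training, rng) + [_test(1, "filler")] * 2
        s2_training = [_training(2, "overtrained")] * 20 + [_training(2, "standard")] * 2
        s2 = pseudorandomize_order(s2_training, rng)
    else:  # exp2: no filler cue, no session-1 habit test
        s1_training = [_training(1, c) for c in ("overtrained", "standard") for _ in range(2)]
        s1 = pseudorandomize_order(s1_training, rng)
        s2_training = [_training(2, "overtrained")] * 20 + [_training(2, "standard")] * 2
        s2 = pseudorandomize_order(s2_training, rng)

    if variant == "exp1":
        first = "overtrained" if rng.integers(2) == 0 else "standard"
    else:
        first = "overtrained" if counterbalance_group == "A" else "standard"
    second = "standard" if first == "overtrained" else "overtrained"
    s3 = _session3(3, first, second)

    sessions = tuple(_number(s) for s in (s1, s2, s3))
    return ExperimentDesign(
        variant=variant,
        participant_id=participant_id,
        counterbalance_group=counterbalance_group,
        sessions=sessions,
        seed=seed,
    )


def design_to_frame(designs: ExperimentDesign | Iterable[ExperimentDesign]) -> pd.DataFrame:
    """Tabulate one design or an iterable of designs, one row per block."""
    if isinstance(designs, ExperimentDesign):
        designs = [designs]
    rows = []
    for d in designs:
        for b in d.blocks():
            rows.append(
                {
                    "participant_id": d.participant_id,
                    "variant": d.variant,
                    "group": d.counterbalance_group or "",
                    "session": b.session,
                    "position": b.position,
                    "cue": b.cue,
                    "phase": b.phase,
                    "p1": b.contingency.p_outcome_given_action,
                    "p2": b.contingency.p_outcome_given_no_action,
                }
            )
    return pd.DataFrame(rows)


def write_design_csv(designs, path) -> None:
    """Export block schedules to a plain CSV file."""
    design_to_frame(designs).to_csv(path, index=False)
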