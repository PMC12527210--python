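"""Descriptive measures: experienced contingency, response rates, response
ratios, and the memory-test inclusion filter.

The experienced contingency of a block is the empirical analogue of the
programmed one: ``p1_hat`` is the proportion of outcome bins among response
bins, ``p2_hat`` among non-response bins, and ``delta_p_hat = p1_hat −
p2_hat``.  Either conditional is undefined (NaN) when its denominator is
empty — e.g. ``p2_hat`` in a block where the participant responded in every
bin — and then ``delta_p_hat`` is undefined too.  Undefined values propagate
as NaN and are excluded listwise from downstream analyses.

The response ratio compares baseline (training) to test responding:

    ratio = mean baseline responses / (mean baseline + mean test responses)

where each mean is the mean response count per block.  A ratio near 0.5
means responding carried on unchanged under the degraded contingency
(habitual persistence); values near 1 mean responding was suppressed
(goal-directed adjustment).  The standard within-subject form uses the last
two training blocks of a cue as baseline and both of its test blocks; the
between-subject first-test-block form uses a single baseline block (the last
training block before the first test) and that first test block only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import BlockData, ParticipantData

__all__ = [
    "BlockMeasures",
    "RatioScore",
    "experienced_contingency",
    "response_rate",
    "response_ratio",
    "select_ratio_blocks",
    "participant_ratio",
    "memory_accuracy",
    "apply_inclusion",
    "measures_table",
    "summary_grid",
]


@dataclass(frozen=True)
class BlockMeasures:
    """Per-block descriptives; undefined conditionals are NaN."""

    response_rate: float
    p1_hat: float
    p2_hat: float
    delta_p_hat: float


@dataclass(frozen=True)
class RatioScore:
    """Baseline/(baseline+test) response ratio for one cue."""

    cue: str
    ratio: float
    n_baseline_blocks: int
    n_test_blocks: int


def response_rate(block: BlockData) -> float:
    """Mean responses per 1-second bin (the lockout bounds it by 1)."""
    n = block.spec.duration_bins
    if n < 1:
        raise ValueError("block has no bins")
    return float(block.responded.sum() / n)


def experienced_contingency(block: BlockData) -> BlockMeasures:
    """Empirical P(O|A), P(O|~A) and their difference for one block."""
    if block.spec.duration_bins < 1:
        raise ValueError("block has no bins")
    resp = block.responded
    out = block.outcomes
    n_resp = int(resp.sum())
    n_none = resp.size - n_resp
    p1_hat = float(out[resp].sum() / n_resp) if n_resp else math.nan
    p2_hat = float(out[~resp].sum() / n_none) if n_none else math.nan
    delta = p1_hat - p2_hat  # NaN propagates
    return BlockMeasures(
        response_rate=n_resp / resp.size,
        p1_hat=p1_hat,
        p2_hat=p2_hat,
        delta_p_hat=delta,
    )


def response_ratio(
    baseline_blocks: Sequence[BlockData],
    test_blocks: Sequence[BlockData],
) -> RatioScore:
    """Baseline/(baseline+test) ratio of mean per-block response counts.

    NaN when all blocks contain zero responses (0/0).
    """
    if not baseline_blocks or not test_blocks:
        raise ValueError("baseline_blocks and test_blocks must be non-empty")
    mean_base = float(np.mean([b.n_responses for b in baseline_blocks]))
    mean_test = float(np.mean([b.n_responses for b in test_blocks]))
    total = mean_base + mean_test
    ratio = mean_base / total if total > 0 else math.nan
    cues = {b.spec.cue for b in test_blocks}
    cue = cues.pop() if len(cues) == 1 else "mixed"
    return RatioScore(
        cue=cue,
        ratio=ratio,
        n_baseline_blocks=len(baseline_blocks),
        n_test_blocks=len(test_blocks),
    )


def select_ratio_blocks(
    blocks: Sequence[BlockData],
    cue: str,
    n_baseline: int = 2,
    first_test_only: bool = False,
) -> tuple[list[BlockData], list[BlockData]]:
    """Pick baseline and test blocks for one cue's response ratio.

    Baseline blocks are the last ``n_baseline`` same-cue training blocks
    preceding the cue's *first* habit-test block, in presentation order
    (for session-3 cues this reaches back into session 2 when only one
    session-3 training block precedes the first test).  Test blocks are all
    of the cue's habit-test blocks, or only the first when
    ``first_test_only``.
    """
    cue_training: list[BlockData] = []
    tests: list[BlockData] = []
    first_test_seen = False
    for b in blocks:
        if b.spec.cue != cue:
            continue
        if b.spec.phase == "habit_test":
            tests.append(b)
            first_test_seen = True
        elif not first_test_seen:
            cue_training.append(b)
    if not tests:
        raise ValueError(f"no habit-test blocks for cue {cue!r}")
    baseline = cue_training[-n_baseline:]
    if len(baseline) < n_baseline:
        raise ValueError(
            f"only {len(baseline)} training blocks precede the first "
            f"{cue!r} test; {n_baseline} requested"
        )
    if first_test_only:
        tests = tests[:1]
    return baseline, tests


def participant_ratio(
    participant: ParticipantData,
    cue: str,
    n_baseline: int = 2,
    first_test_only: bool = False,
) -> RatioScore:
    """Response ratio for one participant and cue (see
    :func:`select_ratio_blocks` for the block selection rule)."""
    baseline, tests = select_ratio_blocks(
        participant.blocks, cue, n_baseline=n_baseline, first_test_only=first_test_only
    )
    return response_ratio(baseline, tests)


def memory_accuracy(participant: ParticipantData) -> float:
    """Proportion of blocks with a correct cue-memory response."""
    flags = [b.memory_correct for b in participant.blocks]
    if not flags:
        raise ValueError("participant has no blocks")
    return float(np.mean(flags))


def apply_inclusion(
    cohort: Iterable[ParticipantData],
    memory_threshold: float = 0.9,
) -> tuple[list[ParticipantData], list[int]]:
    """Keep participants whose memory accuracy is at least the threshold
    (0.90 by default; exactly at threshold is included)."""
    included: list[ParticipantData] = []
    excluded: list[int] = []
    for p in cohort:
        if memory_accuracy(p) >= memory_threshold:
            included.append(p)
        else:
            excluded.append(p.participant_id)
    return included, excluded


def measures_table(cohort: Iterable[ParticipantData]) -> pd.DataFrame:
    """Per-block descriptives for a cohort, one row per block."""
    rows = []
    for p in cohort:
        for b in p.blocks:
            m = experienced_contingency(b)
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "variant": p.variant,
                    "group": p.counterbalance_group or "",
                    "session": b.spec.session,
                    "position": b.spec.position,
                    "cue": b.spec.cue,
                    "phase": b.spec.phase,
                    "p1": b.spec.contingency.p_outcome_given_action,
                    "p2": b.spec.contingency.p_outcome_given_no_action,
                    "delta_p": b.spec.contingency.delta_p,
                    "response_rate": m.response_rate,
                    "p1_hat": m.p1_hat,
                    "p2_hat": m.p2_hat,
                    "delta_p_hat": m.delta_p_hat,
                    "causality_rating": b.causality_rating,
                    "memory_correct": int(b.memory_correct),
                }
            )
    return pd.DataFrame(rows)


def summary_grid(
    cohort: Iterable[ParticipantData],
    aggregate: str = "participant",
) -> pd.DataFrame:
    """Cue x phase grid of experienced contingency, response rate and
    causality ratings (mean and SD), in the shape habit studies tabulate.

    ``aggregate="participant"`` averages blocks within participant first and
    reports between-participant means/SDs; ``aggregate="block"`` pools all
    blocks.  Both are offered because tabulated summaries in the literature
    are ambiguous between the two.
    """
    if aggregate not in ("participant", "block"):
        raise ValueError("aggregate must be 'participant' or 'block'")
    table = measures_table(cohort)
    keys = ["cue", "phase", "p1", "p2", "delta_p"]
    values = ["delta_p_hat", "response_rate", "causality_rating"]
    if aggregate == "participant":
        table = (
            table.groupby(keys + ["participant_id"], as_index=False)[values].mean()
        )
    grid = table.groupby(keys, as_index=False)[values].agg(["mean", "std"])
    grid.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in grid.columns
    ]
    return grid.sort_values(["phase", "cue"]).reset_index(drop=True)
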