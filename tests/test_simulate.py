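"""Synthetic agents and the task environment: outcome delivery matches the
programmed conditional probabilities, learning follows the delta rule, and
cohorts are reproducible."""

import math

import numpy as np
import pytest

from operant.design import POSITIVE, BlockSpec, make_contingency
from operant.measures import memory_accuracy, response_rate
from operant.simulate import (
    AgentParams,
    AgentState,
    goal_directed_params,
    simulate_block,
    simulate_cohort,
    simulate_participant,
    step_bin,
)
from operant.design import build_design


def _constant_policy(p_respond, **kwargs):
    """Params whose response probability is a fixed constant."""
    logit = math.log(p_respond / (1 - p_respond))
    defaults = dict(
        learning_rate=0.0,
        inverse_temperature=0.0,
        habit_gain=0.0,
        habit_weight=0.0,
        rating_noise_sd=0.0,
        memory_error_rate=0.0,
        baseline_logit=logit,
    )
    defaults.update(kwargs)
    return AgentParams(**defaults)


class TestStepBin:
    def test_environment_conditionals_match_programmed(self):
        """Over many bins, P(outcome|response) ~ P1 and P(outcome|no resp) ~ P2."""
        rng = np.random.default_rng(42)
        params = _constant_policy(0.5, learning_rate=0.05)
        cont = make_contingency(0.6, 0.9)
        state = AgentState()
        resp, out = [], []
        for _ in range(10_000):
            rec, state = step_bin(state, params, cont, rng)
            resp.append(rec.responded)
            out.append(rec.outcome)
        resp = np.array(resp)
        out = np.array(out)
        n1 = resp.sum()
        p1_hat = out[resp].mean()
        assert abs(p1_hat - 0.6) <= 3 * math.sqrt(0.6 * 0.4 / n1)
        n2 = (~resp).sum()
        p2_hat = out[~resp].mean()
        assert abs(p2_hat - 0.9) <= 3 * math.sqrt(0.9 * 0.1 / n2)

    def test_constant_policy_rate(self):
        """habit_gain = 0 and zero inverse temperature reduce the policy to
        a constant logistic(baseline_logit)."""
        rng = np.random.default_rng(1)
        params = _constant_policy(0.83, learning_rate=0.3)
        state = AgentState()
        probs = set()
        from operant.simulate import response_probability

        for _ in range(500):
            probs.add(round(response_probability(state, params), 12))
            _, state = step_bin(state, params, POSITIVE, rng)
        assert probs == {round(0.83, 12)}

    def test_full_step_delta_rule(self):
        """learning_rate = 1: after a response bin the P(O|A) belief equals
        that bin's outcome indicator."""
        rng = np.random.default_rng(3)
        params = _constant_policy(0.999999, learning_rate=1.0)
        state = AgentState()
        for _ in range(50):
            rec, state = step_bin(state, params, POSITIVE, rng)
            if rec.responded:
                assert state.p1_belief == float(rec.outcome)

    def test_beliefs_follow_delta_rule_recursion(self):
        """Final beliefs equal an independent delta-rule replay of the
        emitted event stream."""
        rng = np.random.default_rng(9)
        params = AgentParams(learning_rate=0.2, inverse_temperature=3.0)
        spec = BlockSpec(1, 0, "standard", "training", POSITIVE)
        block, state = simulate_block(AgentState(), params, spec, rng)
        p1b = p2b = 0.5
        for r, o in zip(block.responded, block.outcomes):
            if r:
                p1b += 0.2 * (float(o) - p1b)
            else:
                p2b += 0.2 * (float(o) - p2b)
        assert state.p1_belief == pytest.approx(p1b, abs=1e-12)
        assert state.p2_belief == pytest.approx(p2b, abs=1e-12)


class TestSimulateBlock:
    def test_matches_scalar_stepping(self):
        """The block-level fast path consumes the same uniform stream as
        scalar step_bin and produces identical events and state."""
        params = AgentParams(learning_rate=0.15, inverse_temperature=4.0,
                             habit_gain=0.5, habit_weight=0.01)
        spec = BlockSpec(1, 0, "standard", "training", POSITIVE, duration_bins=200)
        block, state = simulate_block(AgentState(), params, spec,
                                      np.random.default_rng(123))
        rng = np.random.default_rng(123)
        st = AgentState()
        records = []
        for _ in range(200):
            rec, st = step_bin(st, params, spec.contingency, rng)
            records.append(rec)
        assert [bool(r) for r in block.responded] == [r.responded for r in records]
        assert [bool(o) for o in block.outcomes] == [r.outcome for r in records]
        assert state == st

    def test_rating_formula_without_noise(self):
        """rating = round(100 * believed delta-P) when noise is off."""
        params = _constant_policy(0.9)  # learning_rate 0: beliefs frozen
        spec = BlockSpec(1, 0, "standard", "training", POSITIVE, duration_bins=10)
        block, _ = simulate_block(
            AgentState(p1_belief=0.6, p2_belief=0.0), params, spec,
            np.random.default_rng(0),
        )
        assert block.causality_rating == 60

    def test_pure_habit_agent_rate_unchanged_at_test(self):
        """A contingency-blind agent responds at the same rate under the
        degraded contingency as in training (within 3 binomial SE)."""
        params = _constant_policy(0.9, habit_weight=0.0)
        train_spec = BlockSpec(1, 0, "overtrained", "training", POSITIVE, 2000)
        test_spec = BlockSpec(3, 0, "overtrained", "habit_test",
                              make_contingency(0.6, 0.9), 2000)
        rng = np.random.default_rng(7)
        train, state = simulate_block(AgentState(habit_strength=50.0), params,
                                      train_spec, rng)
        test, _ = simulate_block(state, params, test_spec, rng)
        se = math.sqrt(2 * 0.9 * 0.1 / 2000)
        assert abs(response_rate(train) - response_rate(test)) <= 3 * se

    def test_goal_directed_rating_negative_after_test(self):
        """After enough degraded-contingency bins a contingency-tracking
        agent believes delta-P < 0 and rates causality negative (median
        over seeds)."""
        spec = BlockSpec(3, 0, "standard", "habit_test",
                         make_contingency(0.6, 0.9), duration_bins=360)
        ratings, diffs = [], []
        for seed in range(50):
            params = goal_directed_params()
            block, state = simulate_block(
                AgentState(p1_belief=0.6, p2_belief=0.0), params, spec,
                np.random.default_rng(seed),
            )
            ratings.append(block.causality_rating)
            diffs.append(state.p1_belief - state.p2_belief)
        assert np.median(ratings) < 0
        assert np.median(diffs) < 0


class TestSimulateCohort:
    def test_reproducible_from_seed(self):
        a = simulate_cohort("exp2", 4, "mixed", seed=99)
        b = simulate_cohort("exp2", 4, "mixed", seed=99)
        for p, q in zip(a, b):
            assert p.params == q.params
            for x, y in zip(p.blocks, q.blocks):
                assert np.array_equal(x.responded, y.responded)
                assert np.array_equal(x.outcomes, y.outcomes)
                assert x.causality_rating == y.causality_rating

    def test_goal_directed_training_rate_in_human_band(self, goal_cohort):
        """Mean per-bin training response rate lands in the 0.8-0.95 band
        typical of human cohorts on this task."""
        rates = [
            response_rate(b)
            for p in goal_cohort
            for b in p.blocks
            if b.spec.phase == "training"
        ]
        assert 0.8 <= np.mean(rates) <= 0.95

    def test_habit_strength_nondecreasing(self, goal_cohort):
        cohort = simulate_cohort("exp1", 2, "habitual", seed=5)
        for p in cohort:
            for state in p.final_states.values():
                assert state.habit_strength >= 0

    def test_memory_failures_match_binomial_expectation(self):
        """With a 20% per-block memory error rate, the number of
        participants failing the 90% criterion matches the closed-form
        binomial expectation within 3 SE."""
        from scipy import stats

        error_rate = 0.2
        sampler = lambda rng: AgentParams(memory_error_rate=error_rate)
        cohort = simulate_cohort("exp1", 50, sampler, seed=21)
        n_blocks = len(cohort[0].blocks)
        max_errors = n_blocks - math.ceil(0.9 * n_blocks)  # still included
        p_fail = float(stats.binom.sf(max_errors, n_blocks, error_rate))
        failures = sum(memory_accuracy(p) < 0.9 for p in cohort)
        se = math.sqrt(50 * p_fail * (1 - p_fail))
        assert abs(failures - 50 * p_fail) <= 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_cohort("exp9", 5)
        with pytest.raises(ValueError):
            simulate_cohort("exp1", 0)


class TestAgentParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": 1.5},
            {"inverse_temperature": -1.0},
            {"memory_error_rate": -0.1},
            {"rating_noise_sd": -2.0},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AgentParams(**kwargs)
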