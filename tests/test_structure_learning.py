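"""Failure detection, typing-factor expansion, and analytic Bayesian model
reduction (Dirichlet log-evidence differences)."""

import numpy as np
import pytest

from transcend.exceptions import ModelValidationError
from transcend.generative_model import default_forager_spec, make_agent_model
from transcend.hierarchy import AgentState
from transcend.structure_learning import (
    ModelHistory,
    StructureLearningParams,
    expand_typing_factor,
    failure_detected,
    maybe_expand,
    merge_log_evidence,
    reduce_model,
)


def _history(values, window=10, tick=200, last_expansion=0):
    h = ModelHistory(window=window, last_expansion_tick=last_expansion)
    for i, v in enumerate(values):
        h.push(v, tick - len(values) + i + 1)
    return h


class TestFailureDetected:
    def test_strong_reduction_is_progress(self):
        h = _history(np.linspace(5.0, 1.0, 10))
        assert not failure_detected(h, 0.01, 50)

    def test_plateau_past_cooldown_triggers(self):
        h = _history(np.ones(10))
        assert failure_detected(h, 0.01, 50)

    def test_plateau_within_cooldown_blocked(self):
        h = _history(np.ones(10), last_expansion=190)
        assert not failure_detected(h, 0.01, 50)

    def test_partial_window_never_triggers(self):
        h = _history(np.ones(4), window=10)
        assert not failure_detected(h, 0.01, 0)

    def test_window_must_be_at_least_two(self):
        with pytest.raises(ModelValidationError):
            failure_detected(_history([1.0], window=1), 0.01, 0)


def _v3_agent(seed=0, n_partners=5):
    model = make_agent_model("V3", default_forager_spec(n_partners=n_partners, alpha=0.5))
    return AgentState(model=model)


class TestExpandTypingFactor:
    def test_fresh_statistics_give_near_symmetric_columns(self):
        """With no partner experience the link columns are symmetric
        Dirichlet draws around uniform (default concentration): the maximum
        deviation from 1/3 stays below 0.2 across seeded draws."""
        for seed in range(20):
            agent = _v3_agent()
            expand_typing_factor(agent, 2, np.random.default_rng(seed))
            dev = np.abs(agent.model.levels[1].link - 1 / 3).max()
            assert dev < 0.2

    def test_level1_arrays_bit_identical_before_after(self):
        agent = _v3_agent()
        before_A = [a.copy() for a in agent.model.A]
        before_B = [b.copy() for b in agent.model.B]
        expand_typing_factor(agent, 2, np.random.default_rng(0))
        assert agent.model.n_levels == 2
        for a, b in zip(before_A, agent.model.A):
            assert (a == b).all()
        for a, b in zip(before_B, agent.model.B):
            assert (a == b).all()

    def test_second_expansion_rejected(self):
        agent = _v3_agent()
        expand_typing_factor(agent, 2, np.random.default_rng(0))
        with pytest.raises(ModelValidationError):
            expand_typing_factor(agent, 2, np.random.default_rng(1))

    def test_non_expandable_agent_rejected(self):
        model = make_agent_model("V1", default_forager_spec())
        agent = AgentState(model=model)
        with pytest.raises(ModelValidationError):
            expand_typing_factor(agent, 2, np.random.default_rng(0))

    def test_experience_seeds_types_along_conduct_split(self):
        """Partners with cooperative vs. selfish observation histories end
        up typed apart after an experience-informed expansion."""
        agent = _v3_agent()
        for slot in range(3):  # cooperative histories
            agent.partner_stats[slot] = np.array([12.0, 0.0, 0.0, 2.0])
        for slot in range(3, 5):  # concealing histories
            agent.partner_stats[slot] = np.array([4.0, 1.0, 8.0, 1.0])
        expand_typing_factor(agent, 2, np.random.default_rng(0))
        coop_types = {int(np.argmax(agent.typing[s])) for s in range(3)}
        selfish_types = {int(np.argmax(agent.typing[s])) for s in range(3, 5)}
        assert len(coop_types) == 1 and len(selfish_types) == 1
        assert coop_types != selfish_types


class TestReduceModel:
    def test_identical_priors_give_zero(self):
        post = np.array([[4.0, 2.0], [3.0, 5.0]])
        prior = np.ones((2, 2))
        assert reduce_model(post, prior, prior) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_role_swap(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            data = rng.integers(0, 20, size=(3, 4)).astype(float)
            a = rng.uniform(0.5, 3.0, size=(3, 4))
            a_tilde = rng.uniform(0.5, 3.0, size=(3, 4))
            fwd = reduce_model(a + data, a_tilde, a)
            back = reduce_model(a_tilde + data, a, a_tilde)
            assert fwd == pytest.approx(-back, abs=1e-9)

    def test_shape_congruence_enforced(self):
        with pytest.raises(ModelValidationError):
            reduce_model(np.ones((2, 2)), np.ones((3, 2)))


class TestMergeLogEvidence:
    def test_duplicate_columns_favor_merging(self):
        assert merge_log_evidence([np.array([10.0, 0.0]), np.array([10.0, 0.0])]) > 0

    def test_differentiated_columns_reject_merging(self):
        assert merge_log_evidence([np.array([10.0, 0.0]), np.array([0.0, 10.0])]) < 0

    def test_matches_hand_computed_beta_functions(self):
        # binary outcomes, flat prior: evidence ratio reduces to a ratio of
        # Beta functions computable by hand
        from scipy.special import betaln

        d1 = np.array([3.0, 1.0])
        d2 = np.array([2.0, 2.0])
        expected = (
            (betaln(1 + 5, 1 + 3) - betaln(1, 1))
            - (betaln(4, 2) - betaln(1, 1))
            - (betaln(3, 3) - betaln(1, 1))
        )
        assert merge_log_evidence([d1, d2]) == pytest.approx(expected, abs=1e-12)

    def test_needs_two_columns(self):
        with pytest.raises(ModelValidationError):
            merge_log_evidence([np.array([1.0, 2.0])])


class TestMaybeExpand:
    def _prime(self, agent, stats):
        for slot, s in stats.items():
            agent.partner_stats[slot] = np.asarray(s, float)
        for i in range(agent.sl_params.window):
            agent.history.push(1.0, 150 + i)  # flat F, past cooldown

    def test_heterogeneous_experience_expansion_sticks(self):
        agent = _v3_agent()
        self._prime(agent, {0: [12, 0, 0, 2], 1: [11, 0, 1, 2],
                            2: [3, 1, 9, 1], 3: [4, 0, 8, 2]})
        event = maybe_expand(agent, np.random.default_rng(0))
        assert event is not None and event["kind"] == "expansion"
        assert agent.model.n_levels == 2

    def test_homogeneous_experience_proposal_reverted(self):
        agent = _v3_agent()
        self._prime(agent, {s: [10, 0, 1, 2] for s in range(4)})
        event = maybe_expand(agent, np.random.default_rng(0))
        assert event is not None and event["kind"] == "expansion-reverted"
        assert agent.model.n_levels == 1
        assert agent.model.expandable  # may try again after cooldown

    def test_insufficient_experience_defers(self):
        agent = _v3_agent()
        self._prime(agent, {0: [9, 0, 1, 1]})  # only one informed partner
        assert maybe_expand(agent, np.random.default_rng(0)) is None
        assert agent.model.n_levels == 1
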