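"""Shared fixtures: seeded RNGs and random-model generators for oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

from transcend.generative_model import default_forager_spec, make_agent_model


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_categorical(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(np.ones(n))


def random_single_factor(rng: np.random.Generator):
    """(prior, A, obs) for a one-factor, one-modality model with full support."""
    n_s = int(rng.integers(2, 6))
    n_o = int(rng.integers(2, 6))
    prior = rng.dirichlet(np.full(n_s, 2.0))
    A = rng.dirichlet(np.full(n_o, 2.0), size=n_s).T  # columns over outcomes
    obs = int(rng.integers(n_o))
    return prior, A, obs


def random_two_factor(rng: np.random.Generator):
    """(priors, A, parents, obs) with one joint-parent modality plus one
    single-parent modality, all full support."""
    s1, s2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
    o1, o2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
    priors = [rng.dirichlet(np.full(s1, 2.0)), rng.dirichlet(np.full(s2, 2.0))]
    A_joint = rng.dirichlet(np.full(o1, 2.0), size=s1 * s2).T.reshape(o1, s1, s2)
    A_single = rng.dirichlet(np.full(o2, 2.0), size=s2).T
    A = [A_joint, A_single]
    parents = [(0, 1), (1,)]
    obs = [int(rng.integers(o1)), int(rng.integers(o2))]
    return priors, A, parents, obs


@pytest.fixture
def v1_model():
    return make_agent_model("V1", default_forager_spec(n_partners=3, n_signals=2))


@pytest.fixture
def v2_model():
    return make_agent_model(
        "V2", default_forager_spec(n_partners=3, n_signals=2, alpha=0.5)
    )


@pytest.fixture
def cultural_and_ego_models():
    spec = default_forager_spec(n_partners=3, n_signals=2)
    m_c = make_agent_model("V1", {**spec, "preferences": "cultural"})
    m_e = make_agent_model("V1", {**spec, "preferences": "egocentric"})
    return m_c, m_e
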