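"""Moral typing by Bayesian model comparison.

An observer scores a watched agent's actions under two fully specified
behavioral models that share likelihood and transition arrays and differ
in preferences: the *cultural* model (sharing and yielding preferred) and
the *egocentric* model (own satiety only).  Accumulated log-likelihood
ratios of observed actions (delta_F) plus a prior-odds term from expected
free energy (delta_G) give the log odds that the target operates with
cultural depth; crossing a threshold, with hysteresis, emits a
Declaration -- the speech act that triggers sanctions in the world loop.

Sign convention: model priors follow P(m) proportional to exp(-G(m)), so
delta_G = G(egocentric) - G(cultural); lower expected free energy means
higher prior probability.
"""

from __future__ import annotations

from copy import copy
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ModelValidationError
from .generative_model import AgentModel
from .inference import BeliefState, evaluate_policies, policy_posterior

__all__ = [
    "ModelComparison",
    "TypingBelief",
    "Declaration",
    "Watcher",
    "predictive_likelihood",
    "action_distribution",
    "accumulate_delta_F",
    "delta_G",
    "model_posterior",
    "detect_violation",
]

LIKELIHOOD_FLOOR = 1e-12
LOG_ODDS_CAP = 50.0
THETA_DEVIANT = 0.5
HYSTERESIS = 0.1


@dataclass
class ModelComparison:
    """Running evidence that a watched agent runs the cultural model."""

    target: int | str
    delta_F: float = 0.0
    delta_G: float = 0.0
    log_odds: float = 0.0
    posterior: float = 0.5  # P(m_culture | o)
    evidence_count: int = 0

    def refresh(self) -> "ModelComparison":
        self.log_odds = self.delta_F + self.delta_G
        capped = float(np.clip(self.log_odds, -LOG_ODDS_CAP, LOG_ODDS_CAP))
        self.posterior = 1.0 / (1.0 + np.exp(-capped))
        return self


@dataclass
class TypingBelief:
    """Categorical over type labels; binary {cultural, egocentric} baseline."""

    probs: np.ndarray
    labels: tuple[str, ...] = ("cultural", "egocentric")

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        if self.probs.size != len(self.labels):
            raise ModelValidationError("TypingBelief: probs/labels length mismatch")


@dataclass
class Declaration:
    """Public accusation of a norm violation, with the evidence at emission."""

    declarer: int | str
    target: int | str
    tick: int
    evidence: ModelComparison


# ---------------------------------------------------------------------------
# predictive machinery

def action_distribution(model: AgentModel, context: BeliefState) -> np.ndarray:
    """Marginal first-action probabilities of a behavioral model in context."""
    evals = evaluate_policies(model, context)
    post = policy_posterior(evals, model.E, model.gamma_policy)
    probs = np.zeros(model.n_actions)
    np.add.at(probs, model.policies[:, 0], post)
    return probs


def predictive_likelihood(
    model: AgentModel, observed_action: int, context: BeliefState
) -> float:
    """Probability the behavioral model assigns to the observed action.

    Floored at 1e-12 so log-ratios stay finite.
    """
    probs = action_distribution(model, context)
    if not (0 <= int(observed_action) < probs.size):
        raise ModelValidationError(
            f"observed_action: index {observed_action} outside the legal action set"
        )
    return max(float(probs[int(observed_action)]), LIKELIHOOD_FLOOR)


def accumulate_delta_F(
    cmp: ModelComparison,
    observed_action: int,
    context: BeliefState,
    m_culture: AgentModel,
    m_ego: AgentModel,
) -> ModelComparison:
    """Add one observation's log-likelihood ratio to the running delta_F."""
    p_c = predictive_likelihood(m_culture, observed_action, context)
    p_e = predictive_likelihood(m_ego, observed_action, context)
    cmp.delta_F += float(np.log(p_c) - np.log(p_e))
    cmp.evidence_count += 1
    return cmp.refresh()


def delta_G(m_culture: AgentModel, m_ego: AgentModel, context: BeliefState) -> float:
    """Prior log odds of the cultural model from expected free energy.

    Each model's aggregate G is the softmin of its per-policy expected free
    energies (habit-weighted, at the model's own policy temperature); with
    P(m) proportional to exp(-G(m)) the log odds are
    G(egocentric) - G(cultural).  Shared arrays give exactly 0.
    """

    def aggregate(m: AgentModel) -> float:
        evals = evaluate_policies(m, context)
        ln_e = np.log(np.maximum(m.E, 1e-300))
        z = ln_e - m.gamma_policy * evals.G
        return float(-(np.logaddexp.reduce(z)) / m.gamma_policy)

    return aggregate(m_ego) - aggregate(m_culture)


def model_posterior(cmp: ModelComparison) -> TypingBelief:
    """P(cultural) = logistic(delta_F + delta_G), log odds capped at +/-50."""
    cmp.refresh()
    return TypingBelief(np.array([cmp.posterior, 1.0 - cmp.posterior]))


# ---------------------------------------------------------------------------
# violation detection

@dataclass
class Watcher:
    """One observer's evidence stream about one target, with declaration state.

    The detector arms once P(cultural) has been at least
    ``theta + hysteresis`` and fires (once per crossing) when it falls
    below ``theta``; it cannot fire again until re-armed.
    """

    declarer: int | str
    target: int | str
    theta: float = THETA_DEVIANT
    hysteresis: float = HYSTERESIS
    cmp: ModelComparison = field(default=None)  # type: ignore[assignment]
    armed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ModelValidationError("theta_deviant: must lie in (0, 1)")
        if self.cmp is None:
            self.cmp = ModelComparison(target=self.target)

    def observe(
        self,
        observed_action: int,
        context: BeliefState,
        m_culture: AgentModel,
        m_ego: AgentModel,
        tick: int = 0,
    ) -> Declaration | None:
        accumulate_delta_F(self.cmp, observed_action, context, m_culture, m_ego)
        return detect_violation(self, tick)

    def observe_probs(self, p_culture: float, p_ego: float,
                      tick: int = 0) -> Declaration | None:
        """Accumulate one observation from precomputed predictive probabilities."""
        p_c = max(float(p_culture), LIKELIHOOD_FLOOR)
        p_e = max(float(p_ego), LIKELIHOOD_FLOOR)
        self.cmp.delta_F += float(np.log(p_c) - np.log(p_e))
        self.cmp.evidence_count += 1
        self.cmp.refresh()
        return detect_violation(self, tick)

    def hear_declaration(self, trust: float, weight: float,
                         tick: int = 0) -> Declaration | None:
        """Assimilate an overheard accusation against this watcher's target.

        Testimony counts as negative evidence about the target's cultural
        depth, scaled by the hearer's trust in the declarer (its P(cultural)
        for them) -- the confirmation-biased uptake that lets declarations
        reinforce group boundaries without direct observation.
        """
        self.cmp.delta_F -= float(weight) * float(trust)
        self.cmp.evidence_count += 1
        self.cmp.refresh()
        return detect_violation(self, tick)


def detect_violation(watcher: Watcher, tick: int = 0) -> Declaration | None:
    """Threshold-with-hysteresis crossing detector over P(cultural).

    Emits at most one Declaration per downward crossing of ``theta``; the
    detector re-arms only after the posterior recovers to
    ``theta + hysteresis``.
    """
    p = watcher.cmp.refresh().posterior
    if p >= watcher.theta + watcher.hysteresis:
        watcher.armed = True
        return None
    if watcher.armed and p < watcher.theta:
        watcher.armed = False
        return Declaration(
            declarer=watcher.declarer,
            target=watcher.target,
            tick=tick,
            evidence=copy(watcher.cmp),
        )
    return None
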