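"""Two-level message passing and the full per-tick agent cycle.

Level 1 infers world-facing states from observations.  For two-level
agents the partner-conduct posterior is summarized and passed upward as a
soft observation to a categorical typing factor; the typing posterior is
then mapped down through the link array and blended with the bottom-up
predictive prior under the precision gain ``alpha``:

    prior  proportional to  exp[(1 - alpha) ln base + alpha ln top_down]

alpha = 0 reproduces the bottom-up prior exactly (the agent behaves as a
one-level V1 twin); alpha = 1 imposes the typing prediction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ModelValidationError
from .generative_model import (
    AgentModel,
    F_PARTNER,
    F_PMOVE,
    M_PACT,
    M_SIG,
    dirichlet_expectation,
    validate_categorical,
)
from .inference import (
    BeliefState,
    FreeEnergyReport,
    evaluate_policies,
    free_energy,
    infer_states,
    policy_posterior,
    select_action,
    softmax,
    update_habits,
    update_likelihood,
)
from . import structure_learning as sl

__all__ = ["AscendingMessage", "DescendingPrior", "AgentState", "ascend", "descend", "step_agent"]

_TINY = 1e-300
BLEND_FLOOR = 1e-12


@dataclass
class AscendingMessage:
    """Soft observation over level-2 outcome categories."""

    probs: np.ndarray
    source_tick: int = 0

    def __post_init__(self) -> None:
        self.probs = validate_categorical(np.asarray(self.probs, float), "ascending message")


@dataclass
class DescendingPrior:
    """Alpha-blended empirical prior for one level-1 factor."""

    probs: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.probs = validate_categorical(np.asarray(self.probs, float), "descending prior")
        if not (0.0 <= self.alpha <= 1.0):
            raise ModelValidationError(f"alpha: {self.alpha} outside [0, 1]")


def ascend(level1_posterior: BeliefState | np.ndarray, summary_map: np.ndarray,
           *, factor: int = F_PMOVE, tick: int = 0) -> AscendingMessage:
    """Summarize a level-1 posterior into a level-2 soft observation."""
    q = (np.asarray(level1_posterior.factors[factor], float)
         if isinstance(level1_posterior, BeliefState)
         else np.asarray(level1_posterior, float))
    summary_map = np.asarray(summary_map, float)
    if summary_map.shape[1] != q.size:
        raise ModelValidationError(
            f"summary_map: {summary_map.shape} incompatible with posterior of size {q.size}"
        )
    msg = summary_map @ q
    return AscendingMessage(msg / msg.sum(), tick)


def descend(
    level2_posterior: np.ndarray,
    link: np.ndarray,
    base_prior: np.ndarray,
    alpha: float,
) -> DescendingPrior:
    """Blend the typing prediction into the bottom-up prior with gain alpha.

    The blend is log-linear (geometric); the boundary cases are returned
    exactly, not through the exp/log round trip.  Zero entries in the
    top-down prediction are floored at 1e-12 before the blend.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ModelValidationError(f"alpha: {alpha} outside [0, 1]")
    base = np.asarray(base_prior, float)
    top_down = np.asarray(link, float) @ np.asarray(level2_posterior, float)
    top_down = top_down / top_down.sum()
    if alpha == 0.0:
        return DescendingPrior(base.copy(), 0.0)
    if alpha == 1.0:
        return DescendingPrior(top_down.copy(), 1.0)
    top_down = np.maximum(top_down, BLEND_FLOOR)
    ln_blend = (1.0 - alpha) * np.log(np.maximum(base, BLEND_FLOOR)) + alpha * np.log(top_down)
    return DescendingPrior(softmax(ln_blend), alpha)


# ---------------------------------------------------------------------------
# persistent agent state and the per-tick cycle

@dataclass
class AgentState:
    """Everything an agent carries between ticks.

    ``typing`` maps partner slots to level-2 posteriors; ``partner_stats``
    accumulates observed partner-action outcome counts per slot (the
    experience V3 expansion is initialized from); ``alpha`` is the
    *effective* precision, which consumed declarations may raise above the
    configured baseline.
    """

    model: AgentModel
    belief: BeliefState = None  # type: ignore[assignment]
    last_action: int | None = None
    last_obs_slot: int | None = None
    alpha: float = None  # type: ignore[assignment]
    typing: dict[int, np.ndarray] = field(default_factory=dict)
    partner_stats: dict[int, np.ndarray] = field(default_factory=dict)
    history: "sl.ModelHistory" = None  # type: ignore[assignment]
    sl_params: "sl.StructureLearningParams" = None  # type: ignore[assignment]
    tick: int = 0

    def __post_init__(self) -> None:
        if self.belief is None:
            self.belief = BeliefState(1, [d.copy() for d in self.model.D], 0)
        if self.alpha is None:
            self.alpha = float(self.model.alpha)
        if self.sl_params is None:
            self.sl_params = sl.StructureLearningParams()
        if self.history is None:
            self.history = sl.ModelHistory(window=self.sl_params.window)

    def typing_for(self, slot: int) -> np.ndarray:
        if self.model.n_levels < 2:
            raise ModelValidationError("typing_for: one-level agent has no typing factor")
        if slot not in self.typing:
            self.typing[slot] = self.model.D2.copy()
        return self.typing[slot]

    def raise_alpha(self, increment: float) -> None:
        """A consumed declaration raises the effective precision (capped at 1)."""
        self.alpha = min(1.0, self.alpha + float(increment))


def _base_priors(agent: AgentState, obs_slot: int | None) -> list[np.ndarray]:
    """Bottom-up predictive priors: B-propagated posterior (D on tick 0),
    with the partner-identity factor clamped to the encounter that produced
    the observation.  The partner-move prior resets to D when the partner
    changed, since the carried belief concerned someone else."""
    model = agent.model
    if agent.last_action is None:
        priors = [d.copy() for d in model.D]
    else:
        u = agent.last_action
        priors = [model.B[f][:, :, u] @ agent.belief.factors[f]
                  for f in range(len(model.D))]
        if obs_slot != agent.last_obs_slot:
            priors[F_PMOVE] = model.D[F_PMOVE].copy()
    if obs_slot is not None:
        delta = np.zeros(model.D[F_PARTNER].size)
        delta[obs_slot] = 1.0
        priors[F_PARTNER] = delta
    return priors


def step_agent(
    agent: AgentState,
    obs: Sequence[int | None],
    partner_slot: int | None,
    rng: np.random.Generator,
    *,
    next_partner_slot: int | None = "same",  # type: ignore[assignment]
    mode: str = "sample",
) -> tuple[int, FreeEnergyReport]:
    """One full perception-action cycle; returns (action index, F report).

    ``partner_slot`` identifies the partner whose encounter produced
    ``obs`` (perception and typing updates are credited to it);
    ``next_partner_slot`` is the partner of the upcoming encounter, whose
    typing shapes the planning prior (defaults to the same partner).

    Order: bottom-up priors -> (descend, two-level only) -> level-1 state
    inference -> ascend + level-2 typing update -> free-energy report ->
    expected-free-energy policy evaluation under the alpha-blended
    expectation about the next partner -> action selection -> Dirichlet
    learning -> structure-learning bookkeeping (V3).
    """
    model = agent.model
    two_level = model.n_levels == 2
    if isinstance(next_partner_slot, str):
        next_partner_slot = partner_slot
    priors = _base_priors(agent, partner_slot)

    prior_typing = None
    if two_level and partner_slot is not None:
        prior_typing = agent.typing_for(partner_slot).copy()
        priors[F_PMOVE] = descend(
            prior_typing, model.link, priors[F_PMOVE], agent.alpha
        ).probs

    prior_state = BeliefState(1, priors, agent.tick)
    posterior = infer_states(obs, prior_state, model.A, model.A_parents)

    q2 = None
    if two_level and partner_slot is not None:
        msg = ascend(posterior, model.summary_map, tick=agent.tick)
        log_lik = np.log(np.maximum(model.A2, _TINY)).T @ msg.probs
        q2 = softmax(np.log(np.maximum(prior_typing, _TINY)) + log_lik)
        agent.typing[partner_slot] = q2

    report = free_energy(
        posterior, obs, model.A, model.A_parents, priors,
        q2=q2, prior2=prior_typing,
    )

    # planning belief: who am I facing next, and what do I expect of them?
    plan = [q.copy() for q in posterior.factors]
    if next_partner_slot is not None:
        delta = np.zeros(model.D[F_PARTNER].size)
        delta[next_partner_slot] = 1.0
        plan[F_PARTNER] = delta
    base_plan = (plan[F_PMOVE] if next_partner_slot == partner_slot
                 else model.D[F_PMOVE].copy())
    if two_level and next_partner_slot is not None:
        base_plan = descend(
            agent.typing_for(next_partner_slot), model.link, base_plan, agent.alpha
        ).probs
    plan[F_PMOVE] = base_plan

    evals = evaluate_policies(model, BeliefState(1, plan, agent.tick))
    post = policy_posterior(evals, model.E, model.gamma_policy)
    _, action = select_action(post, model.policies, mode=mode, rng=rng)

    # --- learning ---------------------------------------------------------
    if model.eta_a > 0 and obs[M_SIG] is not None and model.pA[M_SIG] is not None:
        model.pA[M_SIG] = update_likelihood(
            model.pA[M_SIG], [posterior.factors[F_PARTNER]], int(obs[M_SIG]), model.eta_a
        )
        model.A[M_SIG] = dirichlet_expectation(model.pA[M_SIG])
    if model.eta_e > 0 and model.pE is not None:
        model.pE = update_habits(model.pE, post, model.eta_e)
        model.E = model.pE / model.pE.sum()

    if partner_slot is not None and obs[M_PACT] is not None:
        stats = agent.partner_stats.setdefault(
            partner_slot, np.zeros(model.A[M_PACT].shape[0])
        )
        stats[int(obs[M_PACT])] += 1.0

    agent.belief = posterior
    agent.last_action = action
    agent.last_obs_slot = partner_slot
    agent.tick += 1

    if model.expandable:
        agent.history.push(report.total, agent.tick)
        sl.maybe_expand(agent, rng)

    return action, report
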