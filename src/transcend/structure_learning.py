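"""V3 structure learning: grow a typing level, prune it by model reduction.

A V3 agent starts with a single level.  When variational free energy stops
falling over a sliding window despite continued interaction, the agent
proposes a second, categorical typing factor whose arrays are initialized
from its own partner-conditioned outcome statistics (not from any oracle
labels).  The proposal is immediately audited by analytic Bayesian model
reduction: if merging the new types back into one explains the same
experience at least as well, the expansion is reverted.  Unexplainable
heterogeneity among partners is therefore what makes an expansion stick.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.special import gammaln

from .exceptions import ModelValidationError
from .generative_model import (
    LevelSpec,
    PACT_CONCEAL,
    PACT_COOP,
    PACT_DEFECT,
    PACT_NONE,
)

__all__ = [
    "ModelHistory",
    "StructureLearningParams",
    "failure_detected",
    "expand_typing_factor",
    "reduce_model",
    "merge_log_evidence",
    "maybe_expand",
]

# partner-action outcomes folded onto the partner-move factor categories
# (cooperative, selfish, absent)
_PACT_TO_PMOVE = np.zeros((3, 4))
_PACT_TO_PMOVE[0, PACT_COOP] = 1.0
_PACT_TO_PMOVE[1, PACT_DEFECT] = 1.0
_PACT_TO_PMOVE[1, PACT_CONCEAL] = 1.0
_PACT_TO_PMOVE[2, PACT_NONE] = 1.0


@dataclass
class StructureLearningParams:
    """Knobs of the expansion trigger and proposal.

    ``epsilon`` (nats) is the minimal first-half-to-second-half free-energy
    drop still counted as progress over a ``window``-tick buffer;
    ``cooldown`` spaces consecutive proposals; ``concentration`` is the
    symmetric Dirichlet concentration of fresh type columns; partners with
    fewer than ``min_obs`` observed acts do not inform the proposal, and
    per-partner evidence is capped at ``evidence_cap`` pseudo-counts so no
    single partner dominates the initialization.
    """

    epsilon: float = 0.01
    window: int = 50
    cooldown: int = 100
    k_types: int = 2
    concentration: float = 32.0
    min_obs: int = 3
    evidence_cap: float = 10.0


@dataclass
class ModelHistory:
    """Ring buffer of per-tick total free energy plus expansion bookkeeping."""

    window: int = 50
    values: deque = field(default_factory=deque)
    last_expansion_tick: int = 0
    events: list[dict[str, Any]] = field(default_factory=list)

    def push(self, f_value: float, tick: int) -> None:
        self.values.append(float(f_value))
        while len(self.values) > self.window:
            self.values.popleft()
        self.tick = tick

    tick: int = 0


def failure_detected(history: ModelHistory, epsilon: float, cooldown: int) -> bool:
    """True when a full window shows no material free-energy reduction.

    Compares the mean of the first half of the buffer against the second
    half; a drop below ``epsilon`` nats counts as failure, provided at
    least ``cooldown`` ticks have passed since the last expansion proposal.
    """
    if history.window < 2:
        raise ModelValidationError("failure_detected: window must be >= 2")
    if len(history.values) < history.window:
        return False
    if history.tick - history.last_expansion_tick < cooldown:
        return False
    vals = np.asarray(history.values, float)
    half = vals.size // 2
    return float(vals[:half].mean() - vals[half:].mean()) < epsilon


# ---------------------------------------------------------------------------
# analytic model reduction

def _log_beta_columns(counts: np.ndarray) -> float:
    """Sum over columns of ln B(column) for a Dirichlet count array
    (outcomes on axis 0)."""
    c = np.asarray(counts, float).reshape(counts.shape[0], -1)
    return float(np.sum(gammaln(c)) - np.sum(gammaln(c.sum(axis=0))))


def reduce_model(
    full_counts: np.ndarray,
    reduced_prior: np.ndarray,
    full_prior: np.ndarray | None = None,
) -> float:
    """Log-evidence difference of a reduced Dirichlet model vs. the full one.

    ``full_counts`` is the full model's posterior concentration; the same
    data re-scored under ``reduced_prior`` gives the reduced posterior.
    Positive values favor the reduction.  Antisymmetric under exchanging
    the two priors' roles.
    """
    full_counts = np.asarray(full_counts, float)
    reduced_prior = np.asarray(reduced_prior, float)
    if full_prior is None:
        full_prior = np.ones_like(full_counts)
    full_prior = np.asarray(full_prior, float)
    if not (full_counts.shape == reduced_prior.shape == full_prior.shape):
        raise ModelValidationError("reduce_model: count arrays not shape-congruent")
    data = full_counts - full_prior
    if (data < -1e-9).any():
        raise ModelValidationError("reduce_model: posterior counts below prior counts")
    reduced_post = reduced_prior + data
    return (
        _log_beta_columns(reduced_post)
        - _log_beta_columns(reduced_prior)
        - _log_beta_columns(full_counts)
        + _log_beta_columns(full_prior)
    )


def merge_log_evidence(
    data_columns: Sequence[np.ndarray],
    prior_concentration: float = 1.0,
) -> float:
    """Evidence gain of one shared Dirichlet column over per-type columns.

    Given the outcome counts attributed to each type, compares the model in
    which all types share a single outcome distribution against the one
    with a separate distribution per type.  Positive values favor the
    merge (redundant typing); strongly differentiated columns come out
    negative.
    """
    cols = [np.asarray(c, float) for c in data_columns]
    if len(cols) < 2:
        raise ModelValidationError("merge_log_evidence: need at least two columns")
    a0 = np.full_like(cols[0], float(prior_concentration))

    def ln_beta(v: np.ndarray) -> float:
        return float(np.sum(gammaln(v)) - gammaln(np.sum(v)))

    pooled = ln_beta(a0 + np.sum(cols, axis=0)) - ln_beta(a0)
    separate = sum(ln_beta(a0 + c) - ln_beta(a0) for c in cols)
    return pooled - separate


# ---------------------------------------------------------------------------
# expansion proposal

def _partner_profiles(
    partner_stats: dict[int, np.ndarray], params: StructureLearningParams
) -> dict[int, np.ndarray]:
    """Per-partner pmove-category counts, capped, for partners with enough data."""
    out = {}
    for slot, counts in partner_stats.items():
        total = counts.sum()
        if total < params.min_obs:
            continue
        mapped = _PACT_TO_PMOVE @ counts
        if total > params.evidence_cap:
            mapped = mapped * (params.evidence_cap / total)
        out[slot] = mapped
    return out


def _split_partners(profiles: dict[int, np.ndarray], k: int) -> list[list[int]]:
    """Partition partners into k groups by cooperativeness score, splitting
    at the largest gaps in the sorted score sequence."""
    scored = sorted(
        profiles,
        key=lambda s: float(
            (profiles[s][0] - profiles[s][1]) / max(profiles[s].sum(), 1e-12)
        ),
    )
    if len(scored) <= k:
        return [[s] for s in scored] + [[] for _ in range(k - len(scored))]
    scores = [
        float((profiles[s][0] - profiles[s][1]) / max(profiles[s].sum(), 1e-12))
        for s in scored
    ]
    gaps = np.diff(scores)
    cut_idx = np.sort(np.argsort(gaps)[-(k - 1):]) + 1
    groups, start = [], 0
    for c in list(cut_idx) + [len(scored)]:
        groups.append(scored[start:c])
        start = c
    return groups


def expand_typing_factor(
    agent: Any, k: int, rng: np.random.Generator
) -> dict[str, Any]:
    """Grow a K-type level-2 factor on a one-level expandable agent.

    Link and level-2 likelihood columns are symmetric Dirichlet draws
    perturbed by the pooled partner-conditioned outcome statistics of each
    proposed type; level-1 arrays are untouched.  Returns an event record;
    raises if the agent is already two-level.
    """
    model = agent.model
    if not model.expandable:
        raise ModelValidationError("expand_typing_factor: agent is not expandable")
    if model.n_levels != 1:
        raise ModelValidationError("expand_typing_factor: model already has a typing level")
    if k < 2:
        raise ModelValidationError("expand_typing_factor: K must be >= 2")
    params: StructureLearningParams = agent.sl_params

    profiles = _partner_profiles(agent.partner_stats, params)
    groups = _split_partners(profiles, k)

    link = np.zeros((3, k))
    for t in range(k):
        draw = rng.dirichlet(np.full(3, params.concentration))
        pooled = np.sum([profiles[s] for s in groups[t]], axis=0) if groups[t] else 0.0
        col = params.concentration * draw + pooled
        link[:, t] = col / col.sum()

    labels = [f"type-{t}" for t in range(k)]
    model.levels.append(
        LevelSpec(index=2, factor_sizes=[k], modality_sizes=[3],
                  link=link, alpha=model.alpha, labels=labels)
    )
    model.A2 = link.copy()
    model.D2 = np.full(k, 1.0 / k)
    model.summary_map = np.eye(3)
    model.type_labels = labels

    # seed typing beliefs from each partner's own evidence under the new types
    ln_link = np.log(np.maximum(link, 1e-300))
    for slot, prof in profiles.items():
        logits = prof @ ln_link
        q = np.exp(logits - logits.max())
        agent.typing[slot] = q / q.sum()

    type_data = [
        np.sum([profiles[s] for s in groups[t]], axis=0) if groups[t] else np.zeros(3)
        for t in range(k)
    ]
    return {
        "kind": "expansion",
        "tick": agent.tick,
        "k": k,
        "groups": groups,
        "type_data": type_data,
    }


def _revert_expansion(agent: Any) -> None:
    model = agent.model
    model.levels.pop()
    model.A2 = None
    model.D2 = None
    model.summary_map = None
    model.type_labels = []
    agent.typing.clear()


def maybe_expand(agent: Any, rng: np.random.Generator) -> dict[str, Any] | None:
    """Run the expansion trigger and, if it fires, the audited proposal.

    Called every tick on expandable agents.  A proposal whose types are
    better merged (positive merge log-evidence) is reverted; either way the
    cooldown clock restarts.  Event records accumulate on the history.
    """
    params: StructureLearningParams = agent.sl_params
    history: ModelHistory = agent.history
    if agent.model.n_levels != 1 or not agent.model.expandable:
        return None
    if not failure_detected(history, params.epsilon, params.cooldown):
        return None
    history.last_expansion_tick = history.tick

    profiles = _partner_profiles(agent.partner_stats, params)
    if len(profiles) < 2:
        return None  # not enough distinct experience to propose types

    event = expand_typing_factor(agent, params.k_types, rng)
    gain = merge_log_evidence(event["type_data"])
    event["merge_log_evidence"] = gain
    if gain > 0:
        _revert_expansion(agent)
        event["kind"] = "expansion-reverted"
    history.events.append(event)
    return event
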