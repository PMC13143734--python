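"""Single-level active-inference computations.

State posteriors (exact for one factor, damped mean-field for several),
variational free energy with its accuracy / per-level complexity /
transcendental decomposition, expected free energy with the pragmatic
(risk) and epistemic (ambiguity) split, policy posteriors, action
selection, and Dirichlet learning updates.

All quantities are in natural logarithms (nats); the metrics module alone
converts to bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np

from .exceptions import ImpossibleObservationError, ModelValidationError
from .generative_model import AgentModel, validate_categorical

__all__ = [
    "BeliefState",
    "FreeEnergyReport",
    "PolicyEvaluation",
    "softmax",
    "kl_div",
    "entropy",
    "infer_states",
    "free_energy",
    "expected_free_energy",
    "evaluate_policies",
    "policy_posterior",
    "select_action",
    "update_likelihood",
    "update_habits",
    "infer_alpha",
]

_TINY = 1e-300

MF_DAMPING = 0.5
MF_TOL = 1e-8
MF_MAX_ITERS = 64


# ---------------------------------------------------------------------------
# small numerics

def softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = np.exp(x - x.max())
    return z / z.sum()


def kl_div(p: np.ndarray, q: np.ndarray) -> float:
    """KL[p || q] in nats; 0 ln 0 := 0; +inf only if p puts mass where q has none."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(np.maximum(q[mask], _TINY)))))


def entropy(p: np.ndarray) -> float:
    p = np.asarray(p, float)
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])))


# ---------------------------------------------------------------------------
# containers

@dataclass
class BeliefState:
    """Per-factor categorical beliefs at one hierarchical level and tick."""

    level: int
    factors: list[np.ndarray]
    tick: int = 0

    def validate(self) -> "BeliefState":
        for i, q in enumerate(self.factors):
            validate_categorical(q, f"belief factor {i}")
        return self

    def copy(self) -> "BeliefState":
        return BeliefState(self.level, [q.copy() for q in self.factors], self.tick)


@dataclass
class FreeEnergyReport:
    """Variational free energy and its decomposition (nats).

    ``total = -accuracy + sum(complexity) + transcendental``; ``accuracy``
    is the expected log-likelihood of the observations under the posterior,
    ``complexity[n]`` the KL from the level-(n+1) posterior to its prior
    (for level 1, the prior is the descending alpha-blended one when a
    higher level is present), and ``transcendental`` the KL from the
    posterior over the precision alpha to its prior (0 when alpha is fixed).
    """

    total: float
    accuracy: float
    complexity: list[float]
    transcendental: float = 0.0

    def check_identity(self, tol: float = 1e-9) -> None:
        lhs = -self.accuracy + sum(self.complexity) + self.transcendental
        if abs(lhs - self.total) > tol:
            raise AssertionError(f"free-energy identity violated: {lhs} vs {self.total}")


@dataclass
class PolicyEvaluation:
    """Expected free energy per policy, with the risk + ambiguity split."""

    G: np.ndarray
    risk: np.ndarray
    ambiguity: np.ndarray
    posterior: np.ndarray | None = field(default=None)


# ---------------------------------------------------------------------------
# state inference

def _likelihood_slices(
    obs: Sequence[int | None],
    A: Sequence[np.ndarray],
    A_parents: Sequence[tuple[int, ...]],
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """(parents, A[m][o_m]) for each observed modality, with range checks."""
    out = []
    for m, o in enumerate(obs):
        if o is None:
            continue
        if not (0 <= int(o) < A[m].shape[0]):
            raise ModelValidationError(f"obs[{m}]: outcome index {o} out of range")
        out.append((tuple(A_parents[m]), A[m][int(o)]))
    return out


def _expect_over(lik: np.ndarray, parents: tuple[int, ...], qs: Sequence[np.ndarray],
                 keep: int | None) -> np.ndarray | float:
    """Contract a likelihood slice with q over all parents except ``keep``.

    Returns a vector over factor ``keep`` (or a scalar when keep is None).
    """
    out = lik
    # contract from the last axis backwards so axis indices stay valid
    for ax in range(len(parents) - 1, -1, -1):
        f = parents[ax]
        if f == keep:
            continue
        out = np.tensordot(out, qs[f], axes=([ax], [0]))
    if keep is None:
        return float(out)
    return np.asarray(out, float)


def infer_states(
    obs: Sequence[int | None],
    prior: BeliefState,
    A: Sequence[np.ndarray],
    A_parents: Sequence[tuple[int, ...]],
    *,
    damping: float = MF_DAMPING,
    tol: float = MF_TOL,
    max_iters: int = MF_MAX_ITERS,
    f_trace: list[float] | None = None,
) -> BeliefState:
    """Posterior over hidden states given one multi-modality observation.

    A single factor gives the exact posterior ``prior x likelihood``;
    several factors are resolved by damped sequential mean-field updates.
    If ``f_trace`` is a list, the variational free energy after every
    damped sweep is appended to it (diagnostics; the damped sequential
    schedule descends F monotonically).
    Raises :class:`ImpossibleObservationError` when any observed modality
    has zero marginal likelihood under the prior.
    """
    priors = [np.asarray(p, float) for p in prior.factors]
    slices = _likelihood_slices(obs, A, A_parents)

    for parents, lik in slices:
        marg = _expect_over(lik, parents, priors, None)
        if marg <= _TINY:
            raise ImpossibleObservationError(
                "observation has zero marginal likelihood under the prior"
            )

    n_factors = len(priors)
    log_priors = [np.log(np.maximum(p, _TINY)) for p in priors]

    if n_factors == 1 or all(len(p) == 1 for p, _ in slices):
        # one factor, or fully factorized likelihoods: posterior is exact
        posts = [p.copy() for p in priors]
        for parents, lik in slices:
            if n_factors == 1:
                posts[0] = posts[0] * lik
            else:
                posts[parents[0]] = posts[parents[0]] * lik
        return BeliefState(prior.level, [q / q.sum() for q in posts], prior.tick)

    qs = [p.copy() for p in priors]
    log_liks = [(parents, np.log(np.maximum(lik, _TINY))) for parents, lik in slices]
    for _ in range(max_iters):
        delta = 0.0
        for f in range(n_factors):
            ln_msg = log_priors[f].copy()
            for parents, log_lik in log_liks:
                if f not in parents:
                    continue
                # variational message: expected log-likelihood under the
                # other factors' current beliefs
                ln_msg = ln_msg + _expect_over(log_lik, parents, qs, f)
            new = softmax(ln_msg)
            mixed = (1.0 - damping) * qs[f] + damping * new
            delta = max(delta, float(np.abs(mixed - qs[f]).max()))
            qs[f] = mixed
        if f_trace is not None:
            state = BeliefState(prior.level, qs, prior.tick)
            f_trace.append(free_energy(state, obs, A, A_parents, priors).total)
        if delta < tol:
            break
    return BeliefState(prior.level, [q / q.sum() for q in qs], prior.tick)


# ---------------------------------------------------------------------------
# free energy

def free_energy(
    q: BeliefState,
    obs: Sequence[int | None],
    A: Sequence[np.ndarray],
    A_parents: Sequence[tuple[int, ...]],
    priors: Sequence[np.ndarray],
    *,
    q2: np.ndarray | None = None,
    prior2: np.ndarray | None = None,
    q_alpha: np.ndarray | None = None,
    prior_alpha: np.ndarray | None = None,
) -> FreeEnergyReport:
    """Variational free energy of beliefs ``q`` given an observation.

    ``priors`` are the level-1 per-factor priors actually in force (the
    descending alpha-blended prior for a hierarchical agent).  Optional
    level-2 and alpha posteriors/priors contribute the higher-order
    complexity and transcendental terms; for a one-level agent both are 0.
    """
    qs = [np.asarray(x, float) for x in q.factors]
    accuracy = 0.0
    for parents, lik in _likelihood_slices(obs, A, A_parents):
        log_lik = np.log(np.maximum(lik, _TINY))
        accuracy += _expect_over(log_lik, parents, qs, None)
    complexity = [sum(kl_div(qf, pf) for qf, pf in zip(qs, priors))]
    if q2 is not None and prior2 is not None:
        complexity.append(kl_div(q2, prior2))
    transcendental = 0.0
    if q_alpha is not None and prior_alpha is not None:
        transcendental = kl_div(q_alpha, prior_alpha)
    total = -accuracy + sum(complexity) + transcendental
    return FreeEnergyReport(total, accuracy, complexity, transcendental)


# ---------------------------------------------------------------------------
# expected free energy

def _predict_outcome(lik: np.ndarray, parents: tuple[int, ...],
                     qs: Sequence[np.ndarray]) -> np.ndarray:
    """Predicted outcome distribution: contract A[m] with q over its parents."""
    out = lik
    for ax in range(len(parents), 0, -1):  # outcome axis 0 stays
        out = np.tensordot(out, qs[parents[ax - 1]], axes=([ax], [0]))
    return np.asarray(out, float)


def _efe_caches(model: AgentModel) -> dict:
    """Per-model memo of softmax(C) and per-column likelihood entropies.

    Entries are invalidated by identity when an A array is replaced (the
    signal likelihood is re-learned every tick)."""
    cache = getattr(model, "_efe_cache", None)
    if cache is None:
        cache = {"goals": None, "C_ref": None, "colh": {}}
        object.__setattr__(model, "_efe_cache", cache)
    if cache["C_ref"] is not model.C or cache["goals"] is None:
        cache["goals"] = [softmax(c) for c in model.C]
        cache["log_goals"] = [np.log(np.maximum(g, _TINY)) for g in cache["goals"]]
        cache["C_ref"] = model.C
    for m, lik in enumerate(model.A):
        ref_colh = cache["colh"].get(m)
        if ref_colh is None or ref_colh[0] is not lik:
            flat = lik.reshape(lik.shape[0], -1)
            col_h = -np.sum(
                np.where(flat > 0, flat * np.log(np.maximum(flat, _TINY)), 0.0), axis=0
            )
            cache["colh"][m] = (lik, col_h)
    return cache


def _step_cost(model: AgentModel, qs: Sequence[np.ndarray], cache: dict) -> tuple[float, float]:
    """One-step (risk, ambiguity) of the predicted state distribution."""
    risk = 0.0
    amb = 0.0
    for m, (lik, parents) in enumerate(zip(model.A, model.A_parents)):
        pred = _predict_outcome(lik, parents, qs)
        g = cache["goals"][m]
        mask = pred > 0
        risk += float(np.sum(pred[mask] * (np.log(pred[mask]) - cache["log_goals"][m][mask])))
        col_h = cache["colh"][m][1]
        if len(parents) == 1:
            amb += float(col_h @ qs[parents[0]])
        else:
            q_joint = reduce(np.multiply.outer, [qs[f] for f in parents]).reshape(-1)
            amb += float(col_h @ q_joint)
    return risk, amb


def expected_free_energy(
    policy: Sequence[int],
    model: AgentModel,
    belief: BeliefState,
    *,
    priors_override: Sequence[np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """(G, risk, ambiguity) of one open-loop policy from the current belief.

    Per step: risk = KL[predicted outcomes || softmax(C)] summed over
    modalities, ambiguity = expected outcome entropy of A under predicted
    states; G is their sum over the horizon.
    """
    qs = [np.asarray(x, float) for x in
          (priors_override if priors_override is not None else belief.factors)]
    cache = _efe_caches(model)
    risk = 0.0
    ambiguity = 0.0
    for u in policy:
        qs = [model.B[f][:, :, u] @ qs[f] for f in range(len(qs))]
        r, a = _step_cost(model, qs, cache)
        risk += r
        ambiguity += a
    return risk + ambiguity, risk, ambiguity


def evaluate_policies(
    model: AgentModel,
    belief: BeliefState,
    *,
    priors_override: Sequence[np.ndarray] | None = None,
) -> PolicyEvaluation:
    """Expected free energy of every policy, sharing common action prefixes
    (open-loop policies form a tree; each node's step cost is computed once)."""
    qs0 = [np.asarray(x, float) for x in
           (priors_override if priors_override is not None else belief.factors)]
    cache = _efe_caches(model)
    n, horizon = model.policies.shape
    G = np.zeros(n)
    risk = np.zeros(n)
    amb = np.zeros(n)

    def recurse(indices: np.ndarray, qs: list[np.ndarray], depth: int,
                r_acc: float, a_acc: float) -> None:
        if depth == horizon:
            risk[indices] = r_acc
            amb[indices] = a_acc
            G[indices] = r_acc + a_acc
            return
        acts = model.policies[indices, depth]
        for u in np.unique(acts):
            sub = indices[acts == u]
            qs_next = [model.B[f][:, :, u] @ qs[f] for f in range(len(qs))]
            r, a = _step_cost(model, qs_next, cache)
            recurse(sub, qs_next, depth + 1, r_acc + r, a_acc + a)

    recurse(np.arange(n), qs0, 0, 0.0, 0.0)
    return PolicyEvaluation(G=G, risk=risk, ambiguity=amb)


def policy_posterior(evals: PolicyEvaluation, E: np.ndarray, gamma_policy: float) -> np.ndarray:
    """Softmax policy posterior: probs proportional to E * exp(-gamma * G)."""
    if gamma_policy <= 0:
        raise ModelValidationError("gamma_policy: must be > 0")
    E = validate_categorical(np.asarray(E, float), "E")
    post = softmax(np.log(np.maximum(E, _TINY)) - gamma_policy * evals.G)
    evals.posterior = post
    return post


def select_action(
    post: np.ndarray,
    policies: np.ndarray,
    mode: str = "sample",
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Pick a policy from its posterior; return (policy index, first action).

    ``argmax`` is deterministic with lowest-index tie-break; ``sample`` is
    reproducible given the generator state.
    """
    post = validate_categorical(np.asarray(post, float), "policy posterior")
    if mode == "argmax":
        idx = int(np.argmax(post))
    elif mode == "sample":
        if rng is None:
            raise ModelValidationError("select_action: sample mode requires an rng")
        idx = int(rng.choice(post.size, p=post))
    else:
        raise ModelValidationError(f"select_action: unknown mode {mode!r}")
    return idx, int(policies[idx, 0])


# ---------------------------------------------------------------------------
# learning

def update_likelihood(
    counts: np.ndarray,
    q_parents: Sequence[np.ndarray],
    obs: int,
    eta_a: float,
) -> np.ndarray:
    """Dirichlet update of likelihood counts: counts[obs] += eta * outer(q)."""
    if eta_a < 0:
        raise ModelValidationError("eta_a: must be >= 0")
    out = np.array(counts, float, copy=True)
    out[obs] += eta_a * reduce(np.multiply.outer, [np.asarray(q, float) for q in q_parents])
    return out


def update_habits(e_counts: np.ndarray, post: np.ndarray, eta_e: float) -> np.ndarray:
    if eta_e < 0:
        raise ModelValidationError("eta_e: must be >= 0")
    return np.asarray(e_counts, float) + eta_e * np.asarray(post, float)


def infer_alpha(
    grid: Sequence[float],
    per_alpha_F: Sequence[float],
    prior_alpha: np.ndarray,
) -> np.ndarray:
    """Posterior over a discrete grid of precision values: prior x exp(-F)."""
    grid = np.asarray(grid, float)
    F = np.asarray(per_alpha_F, float)
    if grid.shape != F.shape:
        raise ModelValidationError("infer_alpha: grid and F lengths differ")
    prior = validate_categorical(np.asarray(prior_alpha, float), "prior_alpha")
    with np.errstate(divide="ignore"):
        logits = np.log(prior) - F  # -inf on zero-prior support stays excluded
    return softmax(logits)
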