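"""Post-hoc metrics over traces: polarization, signal information, fitness.

This is the only module that reports information in bits; everything
upstream works in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ModelValidationError
from .generative_model import _preference_vectors
from .trace import Trace

__all__ = [
    "PolarizationResult",
    "polarization_index",
    "mean_polarization",
    "signal_mutual_information",
    "fitness_summary",
]


@dataclass
class PolarizationResult:
    rho: list[float]
    n_trials: int
    mean: float


def polarization_index(beliefs: Sequence[float]) -> float:
    """Spread of scalar beliefs across agents: twice the population SD.

    For beliefs in [0, 1] the index is bounded on [0, 1]; consensus gives
    0 and a maximal half-at-0/half-at-1 split gives 1.
    """
    b = np.asarray(beliefs, float)
    if b.size < 2:
        raise ModelValidationError("polarization_index: need at least 2 beliefs")
    return float(2.0 * b.std())


def mean_polarization(trials: Sequence[Sequence[float]]) -> PolarizationResult:
    """Average polarization over simulation trials."""
    if len(trials) < 1:
        raise ModelValidationError("mean_polarization: empty trial list")
    rho = [polarization_index(t) for t in trials]
    return PolarizationResult(rho=rho, n_trials=len(rho), mean=float(np.mean(rho)))


def signal_mutual_information(
    trace: Trace,
    label: str = "sender-group",
    window: tuple[int, int] | None = None,
) -> float:
    """Plug-in mutual information (bits) between signal symbols and a
    sender label over the signal events in a tick window.

    ``label`` is ``sender-group`` (group tag) or ``sender-valence``
    (satiety bin at emission).  Sliding this window over a run exposes
    signal migration from valence toward group meaning.
    """
    key = {"sender-group": "group", "sender-valence": "valence"}.get(label)
    if key is None:
        raise ModelValidationError(f"signal_mutual_information: unknown label {label!r}")
    events = trace.of_kind("signal")
    if window is not None:
        lo, hi = window
        events = [e for e in events if lo <= e["tick"] < hi]
    if not events:
        raise ModelValidationError("signal_mutual_information: no signal events in window")
    pairs = [(e["symbol"], e[key]) for e in events]
    symbols = sorted({s for s, _ in pairs})
    labels = sorted({l for _, l in pairs})
    joint = np.zeros((len(symbols), len(labels)))
    for s, l in pairs:
        joint[symbols.index(s), labels.index(l)] += 1.0
    joint /= joint.sum()
    ps = joint.sum(axis=1, keepdims=True)
    pl = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / (ps @ pl)[mask])))
    return max(mi, 0.0)


def fitness_summary(trace: Trace) -> dict[str, dict]:
    """Cumulative preference score per agent and per group.

    Fitness is the sum over ticks of the log-probability each agent's
    (softmax-normalized) preferences assign to its realized observations;
    deterministic given the trace.
    """
    man = trace.manifest
    n_signals = man["n_signals"]
    n_actions = 3 + n_signals
    prefs = {}
    for i, preset in enumerate(man["agent_preferences"]):
        goals = [np.log(_softmax(c)) for c in
                 _preference_vectors(preset, n_actions, n_signals)]
        prefs[i] = goals
    per_agent: dict[int, float] = {i: 0.0 for i in prefs}
    for rec in trace.of_kind("obs"):
        i = rec["agent"]
        goals = prefs[i]
        for m, o in enumerate(rec["o"]):
            if o is not None:
                per_agent[i] += float(goals[m][int(o)])
    groups = man["agent_groups"]
    per_group: dict[str, float] = {}
    for i, g in enumerate(groups):
        per_group.setdefault(g, []).append(per_agent[i])  # type: ignore[attr-defined]
    per_group = {g: float(np.mean(v)) for g, v in per_group.items()}
    versions = man["agent_versions"]
    per_version: dict[str, float] = {}
    for i, v in enumerate(versions):
        per_version.setdefault(v, []).append(per_agent[i])  # type: ignore[attr-defined]
    per_version = {v: float(np.mean(x)) for v, x in per_version.items()}
    return {"per_agent": per_agent, "per_group": per_group, "per_version": per_version}


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(np.asarray(x, float) - np.max(x))
    return z / z.sum()
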