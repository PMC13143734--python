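"""Closed-loop simulation driver, parameter sweeps, and the prediction
harnesses: moral-typing model recovery, version fitness under stranger
pressure, structure-learning regimes, and attention-bias polarization.

Every harness returns plain numbers computed from runs of the package's
own world loop; nothing is asserted here (tests do that).
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
import pandas as pd

from .generative_model import default_forager_spec, make_agent_model
from .inference import BeliefState
from .metrics import fitness_summary, polarization_index
from .model_selection import LIKELIHOOD_FLOOR, action_distribution, delta_G
from .trace import Trace, make_manifest
from .world import AgentSpec, World, WorldConfig

__all__ = [
    "run_simulation",
    "sweep",
    "model_recovery",
    "version_fitness_experiment",
    "alpha_sweep",
    "polarization_experiment",
    "structure_learning_run",
    "structure_learning_experiment",
]


# ---------------------------------------------------------------------------
# the closed loop

def run_simulation(config: WorldConfig, seed: int | None = None) -> Trace:
    """Run the full world-agents loop for ``config.n_ticks`` and collect a
    schema-stable trace (manifest, events, observations, beliefs, model
    comparisons, structure-learning events, final summary)."""
    cfg = config.model_copy(deep=True)
    if seed is not None:
        cfg.seed = int(seed)
    world = World(cfg)
    trace = Trace()
    trace.add(make_manifest(
        cfg.model_dump(), cfg.seed,
        n_signals=cfg.n_signals,
        agent_names=[a.name for a in cfg.agents],
        agent_versions=[a.version for a in cfg.agents],
        agent_groups=[a.group for a in cfg.agents],
        agent_preferences=[a.preferences for a in cfg.agents],
    ))
    ev_idx = 0
    for _ in range(cfg.n_ticks):
        world.step()
        t = world.tick - 1
        for e in world.events[ev_idx:]:
            trace.add({"kind": e.kind, **e.to_record()})
        ev_idx = len(world.events)
        for i in range(world.n):
            trace.add({"kind": "obs", "tick": t, "agent": i,
                       "o": world._last_obs[i].as_indices()})
            st = world.states[i]
            if st is not None:
                rep = world._last_reports[i]
                trace.add({
                    "kind": "belief", "tick": t, "agent": i, "level": 1,
                    "factors": [f.tolist() for f in st.belief.factors],
                    "F": None if rep is None else rep.total,
                    "alpha": st.alpha, "n_levels": st.model.n_levels,
                })
            j = world._last_pairing.get(i)
            if j is not None and j in world.watchers[i]:
                w = world.watchers[i][j]
                trace.add({"kind": "comparison", "tick": t, "agent": i,
                           "target": j, "delta_F": w.cmp.delta_F,
                           "delta_G": w.cmp.delta_G,
                           "log_odds": w.cmp.log_odds,
                           "posterior": w.cmp.posterior,
                           "evidence_count": w.cmp.evidence_count})
    for i, st in enumerate(world.states):
        if st is not None and st.model.expandable:
            for ev in st.history.events:
                trace.add({"kind": ev["kind"], "tick": ev["tick"], "agent": i,
                           "k": ev["k"],
                           "merge_log_evidence": ev.get("merge_log_evidence")})
    trace.add({
        "kind": "summary", "tick": world.tick,
        "conservation_residual": world.conservation_residual(),
        "final_alpha": [None if s is None else s.alpha for s in world.states],
        "final_n_levels": [None if s is None else s.model.n_levels
                           for s in world.states],
        "n_declarations": len(trace.of_kind("declaration")),
        "n_sanctions": len(trace.of_kind("sanction")),
    })
    return trace


def _set_path(d: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    cur: Any = d
    for p in parts[:-1]:
        cur = cur[int(p)] if isinstance(cur, list) else cur[p]
    last = parts[-1]
    if isinstance(cur, list):
        cur[int(last)] = value
    elif last not in cur:
        raise KeyError(f"sweep: parameter path {path!r} does not resolve")
    else:
        cur[last] = value


def sweep(
    config: WorldConfig,
    param_path: str,
    values: Sequence[Any],
    seeds: Sequence[int],
    out_csv: str | None = None,
) -> pd.DataFrame:
    """Cross-product of values x seeds; one summary row per run."""
    if len(values) == 0:
        raise ValueError("sweep: empty value list")
    rows = []
    for v in values:
        d = config.model_dump()
        _set_path(d, param_path, v)
        cfg = WorldConfig(**d)
        for s in seeds:
            trace = run_simulation(cfg, seed=int(s))
            fit = fitness_summary(trace)
            beliefs = _final_typing_means(trace)
            rho = polarization_index(beliefs) if len(beliefs) >= 2 else float("nan")
            summary = trace.of_kind("summary")[0]
            row = {param_path: v, "seed": int(s),
                   "mean_fitness": float(np.mean(list(fit["per_agent"].values()))),
                   "polarization": rho,
                   "n_declarations": summary["n_declarations"],
                   "n_sanctions": summary["n_sanctions"]}
            rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df


def _final_typing_means(trace: Trace) -> list[float]:
    """Per-agent mean P(cultural) over watched targets at end of run."""
    latest: dict[tuple[int, int], float] = {}
    for r in trace.of_kind("comparison"):
        latest[(r["agent"], r["target"])] = r["posterior"]
    per_agent: dict[int, list[float]] = {}
    for (i, _j), p in latest.items():
        per_agent.setdefault(i, []).append(p)
    n = len(trace.manifest["agent_names"])
    return [float(np.mean(per_agent[i])) if i in per_agent else 0.5
            for i in range(n)]


# ---------------------------------------------------------------------------
# harness: model recovery (moral typing of simulated actors)

def model_recovery(
    n_per_class: int = 200,
    length: int = 20,
    checkpoints: Sequence[int] = (5, 10, 20),
    seed: int = 0,
) -> dict[str, Any]:
    """Generate action sequences from true cultural vs. egocentric actors
    and ask the log-odds accumulator who generated each.

    Contexts are random full-support beliefs; the observer scores each
    action under both behavioral models and accumulates delta_F, adding
    delta_G (recomputed in the final context) once at the end.  Returns
    per-class sign accuracies and the mean P(cultural) for cultural actors
    at each checkpoint length.
    """
    rng = np.random.default_rng(seed)
    spec = default_forager_spec(n_partners=3, n_signals=2)
    m_c = make_agent_model("V1", {**spec, "preferences": "cultural"})
    m_e = make_agent_model("V1", {**spec, "preferences": "egocentric"})
    sizes = m_c.factor_sizes()
    acc = {}
    posterior_by_len = {L: [] for L in checkpoints}
    for cls, actor in (("cultural", m_c), ("egocentric", m_e)):
        correct = 0
        for _ in range(n_per_class):
            dF = 0.0
            ctx = None
            for t in range(1, length + 1):
                ctx = BeliefState(1, [rng.dirichlet(np.ones(sz)) for sz in sizes])
                dist_c = action_distribution(m_c, ctx)
                dist_e = action_distribution(m_e, ctx)
                gen = dist_c if cls == "cultural" else dist_e
                a = int(rng.choice(gen.size, p=gen))
                dF += float(np.log(max(dist_c[a], LIKELIHOOD_FLOOR))
                            - np.log(max(dist_e[a], LIKELIHOOD_FLOOR)))
                if cls == "cultural" and t in posterior_by_len:
                    dG = delta_G(m_c, m_e, ctx)
                    lo = float(np.clip(dF + dG, -50, 50))
                    posterior_by_len[t].append(1.0 / (1.0 + np.exp(-lo)))
            want_positive = cls == "cultural"
            if (dF > 0) == want_positive and dF != 0:
                correct += 1
        acc[cls] = correct / n_per_class
    return {
        "accuracy_cultural": acc["cultural"],
        "accuracy_egocentric": acc["egocentric"],
        "mean_posterior_by_length": {
            L: float(np.mean(v)) for L, v in posterior_by_len.items() if v
        },
        "n_per_class": n_per_class,
    }


# ---------------------------------------------------------------------------
# harness: version fitness under stranger pressure

def _mixed_population(n_v1: int, n_v2: int, alpha: float) -> list[AgentSpec]:
    agents = []
    for k in range(n_v1):
        agents.append(AgentSpec(name=f"v1-{k}", version="V1", group="A",
                                preferences="cultural"))
    for k in range(n_v2):
        agents.append(AgentSpec(name=f"v2-{k}", version="V2", group="A",
                                alpha=alpha, preferences="cultural"))
    agents += [
        AgentSpec(name="coop-0", group="B", share_prob=0.5, conceal_prob=0.0),
        AgentSpec(name="coop-1", group="B", share_prob=0.5, conceal_prob=0.0),
        AgentSpec(name="def-0", group="C", share_prob=0.0, conceal_prob=0.5),
        AgentSpec(name="def-1", group="C", share_prob=0.0, conceal_prob=0.5),
    ]
    return agents


def version_fitness_experiment(
    seeds: Sequence[int] = tuple(range(10)),
    n_ticks: int = 120,
    stranger_rate: float = 0.8,
    alpha: float = 0.5,
    n_permutations: int = 2000,
    perm_seed: int = 0,
) -> dict[str, Any]:
    """Mean fitness of V2 vs. V1 agents in a mixed population with high
    stranger-encounter rates, with a permutation-test p-value for the
    direction (typing capacity should not hurt)."""
    v1_scores, v2_scores = [], []
    for s in seeds:
        cfg = WorldConfig(agents=_mixed_population(2, 2, alpha),
                          stranger_rate=stranger_rate, n_ticks=n_ticks,
                          seed=int(s))
        fit = fitness_summary(run_simulation(cfg))
        for i, spec in enumerate(cfg.agents):
            if spec.version == "V1":
                v1_scores.append(fit["per_agent"][i])
            elif spec.version == "V2":
                v2_scores.append(fit["per_agent"][i])
    v1 = np.asarray(v1_scores)
    v2 = np.asarray(v2_scores)
    observed = float(v2.mean() - v1.mean())
    rng = np.random.default_rng(perm_seed)
    pooled = np.concatenate([v1, v2])
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        if pooled[v1.size:].mean() - pooled[:v1.size].mean() >= observed:
            count += 1
    return {"mean_v1": float(v1.mean()), "mean_v2": float(v2.mean()),
            "difference": observed,
            "p_value": (count + 1) / (n_permutations + 1),
            "n_seeds": len(list(seeds))}


def alpha_sweep(
    alphas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    seeds: Sequence[int] = tuple(range(5)),
    n_ticks: int = 120,
) -> pd.DataFrame:
    """Fitness-vs-alpha curve for V2 agents; unimodality is reported in the
    returned frame, never asserted."""
    rows = []
    for a in alphas:
        scores = []
        for s in seeds:
            cfg = WorldConfig(agents=_mixed_population(0, 2, float(a)),
                              stranger_rate=0.5, n_ticks=n_ticks, seed=int(s))
            fit = fitness_summary(run_simulation(cfg))
            scores.extend(fit["per_agent"][i]
                          for i, sp in enumerate(cfg.agents) if sp.version == "V2")
        rows.append({"alpha": float(a), "mean_fitness": float(np.mean(scores)),
                     "sd": float(np.std(scores))})
    df = pd.DataFrame(rows)
    f = df["mean_fitness"].to_numpy()
    peak = int(np.argmax(f))
    df.attrs["unimodal"] = bool(
        np.all(np.diff(f[: peak + 1]) >= 0) and np.all(np.diff(f[peak:]) <= 0)
    )
    return df


# ---------------------------------------------------------------------------
# harness: polarization vs. attention bias

def polarization_experiment(
    gamma_values: Sequence[float] = (0.0, 2.0, 8.0),
    seeds: Sequence[int] = tuple(range(10)),
    n_agents: int = 8,
    n_ticks: int = 150,
) -> dict[str, Any]:
    """Mean polarization of typing beliefs as a function of the
    confirmation-biased attention gain, under sparse encounters.

    Half the population are cooperators, half concealers; every agent
    watches whoever it meets.  The belief scalar per agent is its mean
    P(cultural) over watched targets.
    """
    out = {"gamma": list(map(float, gamma_values)), "mean_rho": [], "se_rho": []}
    for g in gamma_values:
        rhos = []
        for s in seeds:
            agents = []
            for k in range(n_agents):
                if k < n_agents // 2:
                    agents.append(AgentSpec(name=f"coop-{k}", group="B",
                                            share_prob=0.5, conceal_prob=0.0,
                                            signal_prob=0.1))
                else:
                    agents.append(AgentSpec(name=f"def-{k}", group="C",
                                            share_prob=0.0, conceal_prob=0.5,
                                            signal_prob=0.1))
            cfg = WorldConfig(agents=agents, gamma_att=float(g),
                              stranger_rate=0.05, encounter_rate=0.3,
                              familiarity_min=0,
                              n_ticks=n_ticks, seed=int(s),
                              sanctions={"confiscate": False, "banish_ticks": 0})
            world = World(cfg)
            for _ in range(cfg.n_ticks):
                world.step()
            beliefs = []
            for i in range(world.n):
                ws = world.watchers[i]
                beliefs.append(
                    float(np.mean([w.cmp.posterior for w in ws.values()]))
                    if ws else 0.5
                )
            rhos.append(polarization_index(beliefs))
        out["mean_rho"].append(float(np.mean(rhos)))
        out["se_rho"].append(float(np.std(rhos, ddof=1) / np.sqrt(len(rhos))))
    return out


# ---------------------------------------------------------------------------
# harness: structure-learning regimes

def structure_learning_run(
    heterogeneous: bool,
    seed: int,
    n_ticks: int = 500,
    n_agents: int = 8,
) -> dict[str, Any]:
    """One V3 focal agent among scripted partners; returns whether the
    typing level survived to the end of the run and how well the recovered
    types align with the ground-truth partner groups (best-permutation
    accuracy over typed partners)."""
    agents = [AgentSpec(name="focal", version="V3", group="B", alpha=0.5,
                        preferences="cultural", watcher=False)]
    for k in range(n_agents - 1):
        defector = heterogeneous and k >= (n_agents - 1) // 2
        agents.append(AgentSpec(
            name=("def" if defector else "coop") + f"-{k}",
            group="D" if defector else "B",
            share_prob=0.0 if defector else 0.5,
            conceal_prob=0.6 if defector else 0.0,
            signal_prob=0.1, watcher=False))
    cfg = WorldConfig(agents=agents, stranger_rate=0.3, familiarity_min=0,
                      n_ticks=n_ticks, seed=int(seed),
                      sanctions={"confiscate": False, "banish_ticks": 0})
    world = World(cfg)
    for _ in range(cfg.n_ticks):
        world.step()
    st = world.states[0]
    expanded = st.model.n_levels == 2
    alignment = float("nan")
    if expanded and st.typing:
        slots = sorted(st.typing)
        pred = [int(np.argmax(st.typing[s])) for s in slots]
        truth = [0 if cfg.agents[s + 1].group == "B" else 1 for s in slots]
        k = st.model.D2.size
        best = 0.0
        from itertools import permutations
        for perm in permutations(range(k)):
            hits = sum(1 for p, t in zip(pred, truth) if perm[p] == t)
            best = max(best, hits / len(pred))
        alignment = best
    return {"expanded": expanded, "alignment": alignment,
            "n_proposals": len(st.history.events)}


def structure_learning_experiment(
    n_runs: int = 20,
    n_ticks: int = 500,
    n_agents: int = 8,
    seed0: int = 0,
) -> dict[str, Any]:
    """Expansion rates under heterogeneous vs. homogeneous partners."""
    res: dict[str, Any] = {}
    for name, het in (("heterogeneous", True), ("homogeneous", False)):
        runs = [structure_learning_run(het, seed0 + r, n_ticks, n_agents)
                for r in range(n_runs)]
        rate = float(np.mean([r["expanded"] for r in runs]))
        aligns = [r["alignment"] for r in runs if not np.isnan(r["alignment"])]
        res[name] = {
            "expansion_rate": rate,
            "mean_alignment": float(np.mean(aligns)) if aligns else float("nan"),
            "n_runs": n_runs,
        }
    return res
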