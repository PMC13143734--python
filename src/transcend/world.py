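"""The generative process: a patch-based foraging and signaling world.

Agents are paired into encounters each tick (attention-biased toward
partners they type as culturally faithful), forage patches whose yield
grows with cooperation, share or conceal harvest, emit signals, and --
when a watcher's typing posterior for a partner crosses the deviance
threshold -- declare violations, which verified sanctions answer with
confiscation, banishment, and a rise in every observer's precision alpha.

Resource bookkeeping is exact: patch stocks + private inventories +
cumulative consumption minus cumulative regeneration inflow is invariant.

Tick order: encounters -> actions -> sanctions (previous tick's
declarations) -> regeneration -> observation synthesis (where watchers
update and new declarations are enqueued).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .exceptions import ScenarioError
from .generative_model import (
    ACT_CONCEAL,
    ACT_FORAGE,
    ACT_SHARE,
    ACT_SIGNAL0,
    PACT_CONCEAL,
    PACT_COOP,
    PACT_NONE,
    default_forager_spec,
    make_agent_model,
)
from .hierarchy import AgentState, step_agent
from .inference import BeliefState
from .model_selection import Declaration, Watcher, action_distribution
from .structure_learning import StructureLearningParams

__all__ = [
    "AgentSpec",
    "SanctionRules",
    "WorldConfig",
    "Action",
    "ObservationBundle",
    "Event",
    "World",
    "harvest_yield",
    "regenerate",
    "load_scenario",
    "SCENARIOS",
]


# ---------------------------------------------------------------------------
# configuration (validated on load)

class SanctionRules(BaseModel):
    confiscate: bool = True
    banish_ticks: int = Field(default=20, ge=0)


class AgentSpec(BaseModel):
    """One agent: an inference version or a scripted disposition actor."""

    name: str
    version: Literal["V1", "V2", "V3", "scripted"] = "scripted"
    group: str = "A"
    alpha: float = Field(default=0.5, ge=0.0, le=1.0)
    preferences: str = "cultural"
    # scripted dispositions (ignored for inferring agents)
    share_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    conceal_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    signal_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    signal_symbol: Optional[int] = None
    # observation skill: overrides the world's concealment-detection rate
    p_detect: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    watcher: bool = True  # whether this agent scores partners' model depth


class WorldConfig(BaseModel):
    """World parameters; field ranges enforce the documented invariants."""

    agents: list[AgentSpec]
    n_patches: int = Field(default=2, ge=1)
    patch_capacity: float = Field(default=12.0, gt=0)
    initial_stock: float = Field(default=10.0, ge=0)
    regen_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    coop_coeff: float = Field(default=0.5, ge=0.0)
    base_yield: float = Field(default=1.0, gt=0)
    n_signals: int = Field(default=2, ge=1)
    stranger_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    encounter_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    gamma_att: float = Field(default=0.0, ge=0.0)
    p_detect: float = Field(default=0.5, ge=0.0, le=1.0)
    sanctions: SanctionRules = Field(default_factory=SanctionRules)
    alpha_increment: float = Field(default=0.1, ge=0.0)
    testimony_weight: float = Field(default=2.0, ge=0.0)
    consensus_k: int = Field(default=1, ge=1)
    familiarity_min: int = Field(default=3, ge=0)
    satiety_decay_period: int = Field(default=5, ge=1)
    guilt_lookback: int = Field(default=10, ge=1)
    horizon: int = Field(default=2, ge=1)
    gamma_policy: float = Field(default=1.0, gt=0)
    eta_a: float = Field(default=1.0, ge=0.0)
    eta_e: float = Field(default=0.0, ge=0.0)
    action_mode: Literal["sample", "argmax"] = "sample"
    n_ticks: int = Field(default=100, ge=0)
    seed: int = 0
    # scenario machinery
    fixed_pairings: Optional[list[tuple[int, int]]] = None
    scripted_actions: dict[int, dict[int, list]] = Field(default_factory=dict)
    # structure learning (V3)
    sl_epsilon: float = 0.01
    sl_window: int = Field(default=50, ge=2)
    sl_cooldown: int = Field(default=100, ge=0)
    sl_k_types: int = Field(default=2, ge=2)

    @model_validator(mode="after")
    def _check(self) -> "WorldConfig":
        if len(self.agents) < 2:
            raise ValueError("agents: need at least 2 agents")
        return self


# ---------------------------------------------------------------------------
# runtime containers

@dataclass
class Action:
    kind: str  # forage | share | conceal | signal | declare | move | idle
    symbol: int | None = None
    target: int | None = None
    patch: int | None = None

    def as_policy_index(self) -> int | None:
        """Map a world action onto the agents' policy action set (or None)."""
        return {
            "forage": ACT_FORAGE,
            "share": ACT_SHARE,
            "conceal": ACT_CONCEAL,
        }.get(self.kind, ACT_SIGNAL0 + self.symbol if self.kind == "signal" else None)


@dataclass
class ObservationBundle:
    """Per-agent modality outcomes for one tick (0-based indices)."""

    satiety: int
    patch_yield: int
    partner_action: int
    signal: int
    declaration: int
    own_move: int | None
    partner: int | None = None  # world index of the encountered agent
    partner_slot: int | None = None

    def as_indices(self) -> list[int | None]:
        return [self.satiety, self.patch_yield, self.partner_action,
                self.signal, self.declaration, self.own_move]


@dataclass
class Event:
    tick: int
    kind: str  # action | signal | declaration | sanction | rejected | ...
    actor: int
    target: int | None = None
    payload: dict[str, Any] = field(default_factory=dict)

    def to_record(self) -> dict[str, Any]:
        return {"tick": self.tick, "kind": self.kind, "actor": self.actor,
                "target": self.target, **self.payload}


# ---------------------------------------------------------------------------
# pure resource mechanics

def harvest_yield(n_foragers: int, stock: float, cfg: WorldConfig) -> tuple[float, float]:
    """Per-forager yield and remaining stock under cooperative harvesting.

    yield = min(stock / n, y0 * (1 + c * (n - 1))): cooperation raises the
    per-head take until the patch cannot cover it.
    """
    if n_foragers < 1:
        raise ValueError("harvest_yield: need at least one forager")
    if stock <= 0:
        return 0.0, max(stock, 0.0)
    per = min(stock / n_foragers, cfg.base_yield * (1.0 + cfg.coop_coeff * (n_foragers - 1)))
    return per, stock - per * n_foragers


def regenerate(stock: float, r: float, cap: float) -> float:
    """Logistic-style refill toward capacity: stock + r * (cap - stock)."""
    if not (0.0 <= r <= 1.0):
        raise ValueError("regenerate: rate outside [0, 1]")
    return min(cap, stock + r * (cap - stock))


# ---------------------------------------------------------------------------
# the world

class World:
    """Mutable world state plus the agent population."""

    def __init__(self, cfg: WorldConfig):
        self.cfg = cfg
        self.n = len(cfg.agents)
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(self.n + 1)
        self.rng = np.random.default_rng(children[0])
        self.agent_rngs = [np.random.default_rng(c) for c in children[1:]]

        self.tick = 0
        self.stocks = np.full(cfg.n_patches, float(cfg.initial_stock))
        self.inventory = np.zeros(self.n)
        self.satiety = np.full(self.n, 2.0)
        self.banished_until = np.full(self.n, -1, dtype=int)
        self.patch_of = np.zeros(self.n, dtype=int)
        self.groups = [a.group for a in cfg.agents]
        self.familiarity = np.zeros((self.n, self.n), dtype=int)
        self.last_conceal: dict[int, int] = {}
        self.pending: list[Declaration] = []
        self.events: list[Event] = []
        self.consumed = 0.0
        self.regen_inflow = 0.0
        self.initial_total = float(self.stocks.sum())

        self.states: list[AgentState | None] = []
        self.watchers: list[dict[int, Watcher]] = [dict() for _ in range(self.n)]
        self._last_actions: list[Action | None] = [None] * self.n
        self._last_reports: list[Any] = [None] * self.n
        self._last_obs: list[ObservationBundle] = []
        self._scoring_models = self._build_scoring_models()
        self._default_context = BeliefState(
            1, [d.copy() for d in self._scoring_models[0].D])
        self._static_dists: tuple[np.ndarray, np.ndarray] | None = None
        for i, spec in enumerate(cfg.agents):
            if spec.version == "scripted":
                self.states.append(None)
                continue
            model = make_agent_model(
                spec.version,
                default_forager_spec(
                    n_partners=self.n - 1,
                    n_signals=cfg.n_signals,
                    horizon=cfg.horizon,
                    alpha=spec.alpha,
                    preferences=spec.preferences,
                    gamma_policy=cfg.gamma_policy,
                    eta_a=cfg.eta_a,
                    eta_e=cfg.eta_e,
                ),
            )
            st = AgentState(
                model=model,
                sl_params=StructureLearningParams(
                    epsilon=cfg.sl_epsilon, window=cfg.sl_window,
                    cooldown=cfg.sl_cooldown, k_types=cfg.sl_k_types,
                ),
            )
            self.states.append(st)
        self._last_obs = [self._synthesize_obs(i, None, {}, set())[0]
                          for i in range(self.n)]

    # -- helpers -----------------------------------------------------------
    def _build_scoring_models(self):
        spec = default_forager_spec(n_partners=self.n - 1, n_signals=self.cfg.n_signals,
                                    horizon=self.cfg.horizon,
                                    gamma_policy=self.cfg.gamma_policy)
        m_cult = make_agent_model("V1", {**spec, "preferences": "cultural"})
        m_ego = make_agent_model("V1", {**spec, "preferences": "egocentric"})
        return m_cult, m_ego

    def slot_of(self, observer: int, other: int) -> int:
        """Partner slot in the observer's identity factor (others in index
        order, skipping self; the extra final slot is the stranger)."""
        return other - 1 if other > observer else other

    def active(self, i: int) -> bool:
        return self.banished_until[i] < self.tick

    def active_agents(self) -> list[int]:
        return [i for i in range(self.n) if self.active(i)]

    def satiety_bin(self, i: int) -> int:
        s = self.satiety[i]
        return 0 if s < 1.0 else (1 if s < 3.0 else 2)

    def stock_bin(self, patch: int) -> int:
        frac = self.stocks[patch] / self.cfg.patch_capacity
        return 0 if frac < 1 / 3 else (1 if frac < 2 / 3 else 2)

    def typing_estimate(self, observer: int, other: int) -> float:
        """Observer's current P(cultural) for another agent (0.5 default)."""
        w = self.watchers[observer].get(other)
        return w.cmp.posterior if w is not None else 0.5

    def conservation_residual(self) -> float:
        """Resource identity: stocks + inventories + consumed - regen - initial."""
        return float(self.stocks.sum() + self.inventory.sum()
                     + self.consumed - self.regen_inflow - self.initial_total)

    # -- encounter scheduling ----------------------------------------------
    def schedule_encounters(self) -> dict[int, int | None]:
        """Pair active agents; returns a symmetric partner map (None = alone).

        Each chooser picks a stranger (below-familiarity partner) with
        probability ``stranger_rate``, uniformly; otherwise a familiar
        partner with weight exp(gamma_att * P(cultural)) -- the
        confirmation-biased attention analog.
        """
        cfg = self.cfg
        if cfg.fixed_pairings is not None:
            pairing: dict[int, int | None] = {i: None for i in self.active_agents()}
            for a, b in cfg.fixed_pairings:
                if self.active(a) and self.active(b):
                    pairing[a], pairing[b] = b, a
            return pairing
        order = list(self.active_agents())
        if cfg.encounter_rate < 1.0:  # sparse-encounter regime
            order = [i for i in order if self.rng.random() < cfg.encounter_rate]
        self.rng.shuffle(order)
        pairing = {i: None for i in order}
        unpaired = set(order)
        for i in order:
            if i not in unpaired:
                continue
            unpaired.discard(i)
            candidates = sorted(unpaired)
            if not candidates:
                break
            familiar = [j for j in candidates if self.familiarity[i, j] >= cfg.familiarity_min]
            strangers = [j for j in candidates if j not in familiar]
            pick_stranger = self.rng.random() < cfg.stranger_rate
            pool = strangers if (pick_stranger and strangers) else (familiar or candidates)
            if pool is strangers or not familiar:
                j = int(self.rng.choice(pool))
            else:
                # confirmation-biased attention: weight familiar partners by
                # exp(gamma * P(cultural)); foraging alone is a neutral
                # option at the prior 0.5, so an untrusted pool can be
                # declined rather than sampled
                w = np.exp(cfg.gamma_att * np.array(
                    [self.typing_estimate(i, j) for j in pool] + [0.5]))
                k = int(self.rng.choice(len(pool) + 1, p=w / w.sum()))
                if k == len(pool):
                    continue  # stays alone this tick
                j = pool[k]
            pairing[i], pairing[j] = j, i
            unpaired.discard(j)
        return pairing

    # -- action selection ---------------------------------------------------
    def _scripted_action(self, i: int, rng: np.random.Generator) -> Action:
        spec = self.cfg.agents[i]
        r = rng.random()
        if r < spec.conceal_prob:
            return Action("conceal")
        if r < spec.conceal_prob + spec.share_prob:
            return Action("share")
        if r < spec.conceal_prob + spec.share_prob + spec.signal_prob:
            sym = spec.signal_symbol
            if sym is None:
                sym = sorted(set(self.groups)).index(spec.group) % self.cfg.n_signals
            return Action("signal", symbol=sym)
        return Action("forage")

    def _policy_action_to_world(self, u: int) -> Action:
        if u == ACT_FORAGE:
            return Action("forage")
        if u == ACT_SHARE:
            return Action("share")
        if u == ACT_CONCEAL:
            return Action("conceal")
        return Action("signal", symbol=u - ACT_SIGNAL0)

    def decide_actions(self, pairing: dict[int, int | None]) -> dict[int, Action]:
        actions: dict[int, Action] = {}
        for i in range(self.n):
            if not self.active(i):
                continue
            override = self.cfg.scripted_actions.get(i, {}).get(self.tick)
            if override is not None:
                kind, *rest = override
                actions[i] = Action(kind, **(rest[0] if rest else {}))
                continue
            st = self.states[i]
            if st is None:
                actions[i] = self._scripted_action(i, self.agent_rngs[i])
                continue
            partner = pairing.get(i)
            next_slot = self.slot_of(i, partner) if partner is not None else None
            obs = self._last_obs[i]  # produced by last tick's encounter
            u, report = step_agent(
                st, obs.as_indices(), obs.partner_slot, self.agent_rngs[i],
                next_partner_slot=next_slot, mode=self.cfg.action_mode,
            )
            self._last_reports[i] = report
            actions[i] = self._policy_action_to_world(u)
        return actions

    # -- action application --------------------------------------------------
    def apply_actions(self, pairing: dict[int, int | None],
                      actions: dict[int, Action]) -> None:
        cfg = self.cfg
        # patch assignment: pairs and singletons round-robin over patches
        seen, units = set(), []
        for i in sorted(actions):
            if i in seen:
                continue
            j = pairing.get(i)
            unit = (i,) if j is None else (i, j)
            seen.update(unit)
            units.append(unit)
        for k, unit in enumerate(units):
            for i in unit:
                self.patch_of[i] = k % cfg.n_patches

        colocated: dict[int, list[int]] = {}
        for i in actions:
            colocated.setdefault(int(self.patch_of[i]), []).append(i)

        # legality: banished agents may only move (never reach here); declare
        # by script is legal for active agents
        for patch, members in sorted(colocated.items()):
            harvesters = [i for i in members
                          if actions[i].kind in ("forage", "conceal")]
            if harvesters:
                per, new_stock = harvest_yield(len(harvesters), self.stocks[patch], cfg)
                self.stocks[patch] = new_stock
                communal = 0.0
                for i in harvesters:
                    if actions[i].kind == "forage":
                        communal += per
                    else:
                        self.inventory[i] += per
                        self.last_conceal[i] = self.tick
                if communal > 0:
                    share = communal / len(members)
                    for i in members:
                        self.satiety[i] += share
                    self.consumed += communal
            for i in sorted(members):
                act = actions[i]
                if act.kind == "share":
                    amount = self.inventory[i]
                    self.inventory[i] = 0.0
                    if amount > 0:
                        per = amount / len(members)
                        for j in members:
                            self.satiety[j] += per
                        self.consumed += amount
                self.events.append(Event(self.tick, "action", i,
                                         target=pairing.get(i),
                                         payload={"action": act.kind,
                                                  "symbol": act.symbol,
                                                  "patch": patch,
                                                  "group": self.groups[i]}))
                if act.kind == "signal":
                    self.events.append(Event(
                        self.tick, "signal", i, target=pairing.get(i),
                        payload={"symbol": act.symbol, "group": self.groups[i],
                                 "valence": self.satiety_bin(i)}))
        # private reserves are eaten when hungry
        for i in sorted(actions):
            if self.satiety[i] < 1.0 and self.inventory[i] > 0:
                eat = min(self.inventory[i], 2.0)
                self.inventory[i] -= eat
                self.satiety[i] += eat
                self.consumed += eat

    # -- sanctions -----------------------------------------------------------
    def apply_sanctions(self) -> set[int]:
        """Consume last tick's declarations; punish world-true concealers.

        Returns the set of declared-against targets (heard by everyone in
        this tick's observations, whether or not the sanction was upheld).
        """
        cfg = self.cfg
        declarations, self.pending = self.pending, []
        heard = {int(d.target) for d in declarations}
        by_target: dict[int, list[Declaration]] = {}
        for d in declarations:
            by_target.setdefault(int(d.target), []).append(d)
        for target, decls in sorted(by_target.items()):
            declarers = {d.declarer for d in decls}
            guilty = (target in self.last_conceal
                      and self.tick - self.last_conceal[target] <= cfg.guilt_lookback)
            if not guilty:
                for d in decls:
                    self.events.append(Event(self.tick, "false-declaration",
                                             int(d.declarer), target=target))
                continue
            if len(declarers) < cfg.consensus_k:
                self.events.append(Event(self.tick, "insufficient-consensus",
                                         int(decls[0].declarer), target=target,
                                         payload={"needed": cfg.consensus_k}))
                continue
            confiscated = 0.0
            if cfg.sanctions.confiscate:
                confiscated = float(self.inventory[target])
                self.inventory[target] = 0.0
                self.stocks[self.patch_of[target]] += confiscated
            self.banished_until[target] = self.tick + cfg.sanctions.banish_ticks
            for i in range(self.n):
                if i != target and self.states[i] is not None:
                    self.states[i].raise_alpha(cfg.alpha_increment)
            self.events.append(Event(
                self.tick, "sanction", int(decls[0].declarer), target=target,
                payload={"confiscated": confiscated,
                         "banished_until": int(self.banished_until[target]),
                         "declarers": sorted(int(d.declarer) for d in decls)}))
        return heard

    # -- observation synthesis -----------------------------------------------
    def _synthesize_obs(
        self, i: int, partner: int | None, actions: dict[int, Action],
        declared_targets: set[int],
    ) -> tuple[ObservationBundle, int | None]:
        cfg = self.cfg
        pact, sig = PACT_NONE, 0
        seen_action: int | None = None  # policy-index view for the watcher
        if partner is not None and partner in actions:
            act = actions[partner]
            if act.kind in ("forage", "share"):
                pact = PACT_COOP
                seen_action = act.as_policy_index()
            elif act.kind == "conceal":
                p = cfg.agents[i].p_detect
                p = cfg.p_detect if p is None else p
                if self.rng.random() < p:
                    pact = PACT_CONCEAL
                    seen_action = ACT_CONCEAL
                else:
                    pact = PACT_COOP
                    seen_action = ACT_FORAGE
            elif act.kind == "signal":
                sig = 1 + int(act.symbol)
        own = actions.get(i)
        own_idx = own.as_policy_index() if own is not None else None
        bundle = ObservationBundle(
            satiety=self.satiety_bin(i),
            patch_yield=self.stock_bin(int(self.patch_of[i])) if self.active(i) else 0,
            partner_action=pact,
            signal=sig,
            declaration=1 if (partner in declared_targets) else 0,
            own_move=own_idx,
            partner=partner,
            partner_slot=self.slot_of(i, partner) if partner is not None else None,
        )
        return bundle, seen_action

    def synthesize_observations(self, pairing: dict[int, int | None],
                                actions: dict[int, Action],
                                declared: set[int]) -> None:
        new_obs: list[ObservationBundle] = []
        m_cult, m_ego = self._scoring_models
        for i in range(self.n):
            partner = pairing.get(i) if self.active(i) else None
            bundle, seen = self._synthesize_obs(i, partner, actions, declared)
            new_obs.append(bundle)
            # watchers score the partner's visible act under the two models.
            # The scoring context is the neutral default belief: observers do
            # not know the actor's interoceptive state, so both models are
            # evaluated from the same ignorance (cached, constant per run).
            if (partner is not None and seen is not None
                    and self.cfg.agents[i].watcher):
                w = self.watchers[i].setdefault(partner, Watcher(i, partner))
                if self._static_dists is None:
                    self._static_dists = (
                        action_distribution(m_cult, self._default_context),
                        action_distribution(m_ego, self._default_context),
                    )
                dc, de = self._static_dists
                decl = w.observe_probs(dc[seen], de[seen], tick=self.tick)
                if decl is not None:
                    self.pending.append(decl)
                    self.events.append(Event(
                        self.tick, "declaration", i, target=partner,
                        payload={"delta_F": w.cmp.delta_F,
                                 "log_odds": w.cmp.log_odds,
                                 "posterior": w.cmp.posterior}))
        self._spread_testimony()
        self._last_obs = new_obs

    def _spread_testimony(self) -> None:
        """Co-located bystanders assimilate fresh accusations, weighted by
        their trust in the declarer; uptake can trigger second-hand
        declarations (gossip), which are not re-spread within the tick."""
        if self.cfg.testimony_weight <= 0:
            return
        second_hand: list[Declaration] = []
        for d in self.pending:
            declarer, target = int(d.declarer), int(d.target)
            for h in range(self.n):
                if h in (declarer, target) or not self.active(h):
                    continue
                if self.patch_of[h] != self.patch_of[declarer]:
                    continue
                if not self.cfg.agents[h].watcher:
                    continue
                trust = self.typing_estimate(h, declarer)
                wh = self.watchers[h].setdefault(target, Watcher(h, target))
                decl2 = wh.hear_declaration(
                    trust, self.cfg.testimony_weight, tick=self.tick)
                if decl2 is not None:
                    second_hand.append(decl2)
                    self.events.append(Event(
                        self.tick, "declaration", h, target=target,
                        payload={"second_hand": True,
                                 "posterior": wh.cmp.posterior}))
        self.pending.extend(second_hand)

    # -- one full tick --------------------------------------------------------
    def step(self) -> dict[int, Action]:
        cfg = self.cfg
        pairing = self.schedule_encounters()
        actions = self.decide_actions(pairing)
        self.apply_actions(pairing, actions)
        declared = self.apply_sanctions()
        for p in range(cfg.n_patches):
            before = self.stocks[p]
            self.stocks[p] = regenerate(before, cfg.regen_rate, cfg.patch_capacity)
            self.regen_inflow += self.stocks[p] - before
        if (self.tick + 1) % cfg.satiety_decay_period == 0:
            self.satiety = np.maximum(self.satiety - 1.0, 0.0)
        for i, j in pairing.items():
            if j is not None and i < j:
                self.familiarity[i, j] += 1
                self.familiarity[j, i] += 1
        self.synthesize_observations(pairing, actions, declared)
        self._last_pairing = pairing
        self._last_actions = [actions.get(i) for i in range(self.n)]
        self.tick += 1
        return actions


# ---------------------------------------------------------------------------
# scripted scenarios

def _adam_apple_config(seed: int = 0) -> WorldConfig:
    """The deviant-forager narrative: Adam (a scripted newcomer from another
    band) shares for a few expeditions, then conceals an apple; Pete (a
    perfect observer) detects the concealment and declares; Charles's band
    sanctions.  Pairings are fixed so Pete always forages beside Adam."""
    agents = [
        AgentSpec(name="Adam", version="scripted", group="A",
                  share_prob=0.0, conceal_prob=0.0, signal_prob=0.0),
        AgentSpec(name="Charles", version="V2", group="B", alpha=0.5),
        AgentSpec(name="Pete", version="V2", group="B", alpha=0.5, p_detect=1.0),
        AgentSpec(name="Eve", version="V2", group="B", alpha=0.5),
    ]
    # Adam forages with the group (cooperative), then conceals an apple
    scripted = {0: {t: ["forage"] for t in range(10)}}
    scripted[0][4] = ["conceal"]
    return WorldConfig(
        agents=agents,
        n_patches=2,
        fixed_pairings=[(2, 0), (1, 3)],
        scripted_actions=scripted,
        p_detect=0.5,
        alpha_increment=0.2,
        sanctions=SanctionRules(confiscate=True, banish_ticks=10),
        n_ticks=12,
        seed=seed,
    )


SCENARIOS = {"adam-apple": _adam_apple_config}


def load_scenario(name: str, seed: int = 0) -> WorldConfig:
    """Named narrative fixture; unknown names list the available scenarios."""
    if name not in SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[name](seed)
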