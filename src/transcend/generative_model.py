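"""Discrete generative-model containers for hierarchical active-inference agents.

An agent is a discrete POMDP: likelihood arrays ``A`` (one per observation
modality, each conditioned on a subset of hidden-state factors), transition
arrays ``B`` (one per factor, conditioned on the control/action index),
log-preference vectors ``C``, initial state priors ``D`` and a habit vector
``E`` over the policy set.  V2/V3 agents add a second, categorical "typing"
level whose posterior is fed back down as a precision-weighted (``alpha``)
empirical prior on the first level.

All probability content is stored as plain ``numpy`` arrays; the classes
here validate invariants and provide (de)serialization, they do not wrap
array arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .exceptions import DegenerateDistributionError, ModelValidationError

__all__ = [
    "Categorical",
    "DirichletCounts",
    "LevelSpec",
    "AgentModel",
    "normalize",
    "dirichlet_expectation",
    "validate_categorical",
    "validate_model",
    "make_agent_model",
    "default_forager_spec",
    "CULTURAL_C",
    "EGOCENTRIC_C",
    "ACT_FORAGE",
    "ACT_SHARE",
    "ACT_CONCEAL",
    "ACT_SIGNAL0",
    "M_SAT",
    "M_YIELD",
    "M_PACT",
    "M_SIG",
    "M_DECL",
    "M_OWN",
    "F_SAT",
    "F_STOCK",
    "F_PARTNER",
    "F_PMOVE",
    "F_OWN",
    "PMOVE_COOP",
    "PMOVE_SELFISH",
    "PMOVE_NONE",
    "PACT_COOP",
    "PACT_DEFECT",
    "PACT_CONCEAL",
    "PACT_NONE",
]

TOL = 1e-9
DIRICHLET_FLOOR = 1e-3  # keeps likelihood learning well-defined after sparse evidence

# ---------------------------------------------------------------------------
# index conventions for the default forager model (0-based in code;
# human-readable reports add 1)

# level-1 hidden-state factors
F_SAT, F_STOCK, F_PARTNER, F_PMOVE, F_OWN = 0, 1, 2, 3, 4
# observation modalities
M_SAT, M_YIELD, M_PACT, M_SIG, M_DECL, M_OWN = 0, 1, 2, 3, 4, 5
# partner-move factor states
PMOVE_COOP, PMOVE_SELFISH, PMOVE_NONE = 0, 1, 2
# partner-action modality outcomes
PACT_COOP, PACT_DEFECT, PACT_CONCEAL, PACT_NONE = 0, 1, 2, 3
# policy-selectable actions (signals come after the first three)
ACT_FORAGE, ACT_SHARE, ACT_CONCEAL, ACT_SIGNAL0 = 0, 1, 2, 3


def normalize(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize a non-negative vector to a probability vector.

    Raises :class:`DegenerateDistributionError` on negative entries or an
    all-zero input.
    """
    x = np.asarray(raw, dtype=float)
    if x.size == 0:
        raise DegenerateDistributionError("normalize: empty vector")
    if (x < 0).any():
        raise DegenerateDistributionError("normalize: negative entries")
    s = x.sum()
    if s <= 0:
        raise DegenerateDistributionError("normalize: all-zero vector")
    return x / s


def validate_categorical(p: np.ndarray, name: str = "categorical") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ModelValidationError(f"{name}: must be a non-empty 1-d vector")
    if (p < 0).any():
        raise ModelValidationError(f"{name}: negative probability entries")
    if abs(p.sum() - 1.0) > TOL:
        raise ModelValidationError(f"{name}: entries sum to {p.sum():.12f}, not 1")
    return p


class Categorical:
    """A validated probability vector over a finite support."""

    __slots__ = ("probs",)

    def __init__(self, probs: Sequence[float] | np.ndarray):
        self.probs = validate_categorical(np.asarray(probs, dtype=float))

    def __len__(self) -> int:
        return self.probs.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)

    def __repr__(self) -> str:
        return f"Categorical({np.round(self.probs, 6).tolist()})"


@dataclass
class DirichletCounts:
    """Concentration parameters congruent with a likelihood array or habit vector.

    Entries carry a strictly positive floor so that the implied expected
    distribution never collapses to zero probability after sparse evidence.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts <= 0).any():
            raise ModelValidationError("DirichletCounts: entries must be > 0")


def dirichlet_expectation(counts: np.ndarray | DirichletCounts) -> np.ndarray:
    """Column-wise expected distribution of a Dirichlet count array.

    ``counts`` has outcomes on axis 0; every remaining index selects one
    Dirichlet column.  Raises on any all-zero column.
    """
    c = counts.counts if isinstance(counts, DirichletCounts) else np.asarray(counts, float)
    if (c < 0).any():
        raise DegenerateDistributionError("dirichlet_expectation: negative counts")
    sums = c.sum(axis=0)
    if np.any(sums <= 0):
        raise DegenerateDistributionError("dirichlet_expectation: zero-count column")
    return c / sums


@dataclass
class LevelSpec:
    """Shape metadata for one hierarchical level.

    ``link`` maps this level's states to prior predictions over a designated
    lower-level factor (columns are categoricals over the lower states);
    ``alpha`` is the precision in [0, 1] with which those predictions
    constrain the level below (levels >= 2 only).
    """

    index: int
    factor_sizes: list[int]
    modality_sizes: list[int]
    link: np.ndarray | None = None
    alpha: float | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None and not (0.0 <= self.alpha <= 1.0):
            raise ModelValidationError(f"alpha: {self.alpha} outside [0, 1]")
        if self.link is not None:
            self.link = np.asarray(self.link, dtype=float)
            for k in range(self.link.shape[1]):
                validate_categorical(self.link[:, k], f"link column {k}")


@dataclass
class AgentModel:
    """Full per-agent generative model (one or two levels).

    Level-1 arrays follow the POMDP convention: ``A[m]`` has shape
    ``(n_outcomes[m], *sizes of A_parents[m])``; ``B[f]`` has shape
    ``(n_states, n_states, n_actions)``; ``C[m]`` is an unnormalized
    log-preference vector; ``D[f]`` an initial prior; ``E`` a habit
    categorical over the policy set.
    """

    version: str
    levels: list[LevelSpec]
    A: list[np.ndarray]
    A_parents: list[tuple[int, ...]]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    E: np.ndarray
    policies: np.ndarray  # (n_policies, horizon) action indices
    gamma_policy: float = 1.0
    eta_a: float = 1.0
    eta_e: float = 0.0
    type_labels: list[str] = field(default_factory=list)
    # second level (V2, or V3 after expansion)
    A2: np.ndarray | None = None  # (n_level2_outcomes, n_types)
    D2: np.ndarray | None = None
    summary_map: np.ndarray | None = None  # level-1 posterior -> level-2 outcome cats
    alpha: float = 0.0
    expandable: bool = False
    # learnable Dirichlet counts: per-modality (None = fixed) and habit counts
    pA: list[np.ndarray | None] = field(default_factory=list)
    pE: np.ndarray | None = None

    # -- convenience -------------------------------------------------------
    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_actions(self) -> int:
        return self.B[0].shape[2]

    @property
    def horizon(self) -> int:
        return self.policies.shape[1]

    @property
    def link(self) -> np.ndarray | None:
        return self.levels[1].link if len(self.levels) > 1 else None

    def factor_sizes(self) -> list[int]:
        return list(self.levels[0].factor_sizes)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def arr(a):
            return None if a is None else a.tolist()

        return {
            "version": self.version,
            "index_base": 0,
            "levels": [
                {
                    "index": lv.index,
                    "factor_sizes": lv.factor_sizes,
                    "modality_sizes": lv.modality_sizes,
                    "link": arr(lv.link),
                    "alpha": lv.alpha,
                    "labels": lv.labels,
                }
                for lv in self.levels
            ],
            "A": [a.tolist() for a in self.A],
            "A_parents": [list(p) for p in self.A_parents],
            "B": [b.tolist() for b in self.B],
            "C": [c.tolist() for c in self.C],
            "D": [d.tolist() for d in self.D],
            "E": self.E.tolist(),
            "policies": self.policies.tolist(),
            "gamma_policy": self.gamma_policy,
            "eta_a": self.eta_a,
            "eta_e": self.eta_e,
            "type_labels": list(self.type_labels),
            "A2": arr(self.A2),
            "D2": arr(self.D2),
            "summary_map": arr(self.summary_map),
            "alpha": self.alpha,
            "expandable": self.expandable,
            "pA": [arr(a) for a in self.pA],
            "pE": arr(self.pE),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AgentModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        levels = [
            LevelSpec(
                index=lv["index"],
                factor_sizes=list(lv["factor_sizes"]),
                modality_sizes=list(lv["modality_sizes"]),
                link=arr(lv["link"]),
                alpha=lv["alpha"],
                labels=lv["labels"],
            )
            for lv in d["levels"]
        ]
        model = cls(
            version=d["version"],
            levels=levels,
            A=[np.asarray(a, float) for a in d["A"]],
            A_parents=[tuple(p) for p in d["A_parents"]],
            B=[np.asarray(b, float) for b in d["B"]],
            C=[np.asarray(c, float) for c in d["C"]],
            D=[np.asarray(x, float) for x in d["D"]],
            E=np.asarray(d["E"], float),
            policies=np.asarray(d["policies"], int),
            gamma_policy=d["gamma_policy"],
            eta_a=d["eta_a"],
            eta_e=d["eta_e"],
            type_labels=list(d["type_labels"]),
            A2=arr(d["A2"]),
            D2=arr(d["D2"]),
            summary_map=arr(d["summary_map"]),
            alpha=d["alpha"],
            expandable=d["expandable"],
            pA=[arr(a) for a in d["pA"]],
            pE=arr(d["pE"]),
        )
        validate_model(model)
        return model


def _validate_stochastic_columns(a: np.ndarray, name: str) -> None:
    """Every slice along axis 0 of ``a`` (indexed by the remaining axes)
    must be a categorical over axis 0."""
    flat = a.reshape(a.shape[0], -1)
    if (flat < 0).any():
        raise ModelValidationError(f"{name}: negative entries")
    sums = flat.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > TOL):
        raise ModelValidationError(f"{name}: columns do not sum to 1")


def validate_model(model: AgentModel) -> None:
    """Recursive invariant check over every stochastic array in the model."""
    if model.version not in ("V1", "V2", "V3"):
        raise ModelValidationError(f"version: unknown version {model.version!r}")
    if model.version == "V1" and model.n_levels != 1:
        raise ModelValidationError("levels: V1 must have exactly one level")
    if model.version == "V2" and model.n_levels != 2:
        raise ModelValidationError("levels: V2 must have exactly two levels")
    if not (0.0 <= model.alpha <= 1.0):
        raise ModelValidationError(f"alpha: {model.alpha} outside [0, 1]")
    if model.policies.size == 0:
        raise ModelValidationError("policies: empty policy set")
    if model.gamma_policy <= 0:
        raise ModelValidationError("gamma_policy: must be > 0")
    if model.eta_a < 0 or model.eta_e < 0:
        raise ModelValidationError("learning rates: must be >= 0")
    sizes = model.levels[0].factor_sizes
    for m, (a, parents) in enumerate(zip(model.A, model.A_parents)):
        want = tuple(sizes[f] for f in parents)
        if a.shape[1:] != want:
            raise ModelValidationError(f"A[{m}]: shape {a.shape} vs parents {want}")
        _validate_stochastic_columns(a, f"A[{m}]")
    for f, b in enumerate(model.B):
        if b.shape[0] != b.shape[1] or b.shape[0] != sizes[f]:
            raise ModelValidationError(f"B[{f}]: shape {b.shape} vs factor size {sizes[f]}")
        _validate_stochastic_columns(b, f"B[{f}]")
    for f, d in enumerate(model.D):
        validate_categorical(d, f"D[{f}]")
        if d.size != sizes[f]:
            raise ModelValidationError(f"D[{f}]: wrong length")
    for m, c in enumerate(model.C):
        if not np.all(np.isfinite(c)):
            raise ModelValidationError(f"C[{m}]: non-finite preference entries")
    validate_categorical(model.E, "E")
    if model.E.size != model.policies.shape[0]:
        raise ModelValidationError("E: length does not match policy set")
    if int(model.policies.max()) >= model.n_actions or int(model.policies.min()) < 0:
        raise ModelValidationError("policies: action index out of range")
    for m, pa in enumerate(model.pA):
        if pa is None:
            continue
        if pa.shape != model.A[m].shape:
            raise ModelValidationError(f"pA[{m}]: shape incongruent with A[{m}]")
        if (pa <= 0).any():
            raise ModelValidationError(f"pA[{m}]: entries must be > 0")
    if model.n_levels == 2:
        lv2 = model.levels[1]
        if lv2.link is None or model.A2 is None or model.D2 is None:
            raise ModelValidationError("level 2: link/A2/D2 required for a two-level model")
        k = len(model.type_labels)
        if k < 2:
            raise ModelValidationError("type_labels: need at least 2 labels for level 2")
        if model.A2.shape[1] != k or lv2.link.shape[1] != k or model.D2.size != k:
            raise ModelValidationError("level 2: type cardinality mismatch")
        _validate_stochastic_columns(model.A2, "A2")
        validate_categorical(model.D2, "D2")
        if model.summary_map is not None:
            _validate_stochastic_columns(model.summary_map, "summary_map")


# ---------------------------------------------------------------------------
# default forager model construction

# log-preferences of the *cultural* model: satiation is good, own cooperative
# acts (forage-to-pool, share) are strongly preferred over concealment, seeing
# cooperation and an absence of declarations is mildly preferred.
CULTURAL_C = {
    "satiety": [0.0, 1.5, 2.5],
    "yield": [0.0, 0.4, 0.8],
    "partner_action": [1.0, -1.0, -2.0, 0.0],
    "declaration": [0.5, -1.0],
    "own_forage": 1.0,
    "own_share": 2.0,
    "own_conceal": -4.0,
    "own_signal": 0.0,
}

# the *egocentric* model: own satiety dominates, sharing is a cost and
# concealment a benefit; indifferent to partner conduct and declarations.
EGOCENTRIC_C = {
    "satiety": [-2.0, 1.0, 3.0],
    "yield": [0.0, 0.4, 0.8],
    "partner_action": [0.0, 0.0, 0.0, 0.0],
    "declaration": [0.0, 0.0],
    "own_forage": 1.0,
    "own_share": -1.0,
    "own_conceal": 1.5,
    "own_signal": 0.0,
}


def default_forager_spec(
    n_partners: int = 3,
    n_signals: int = 2,
    horizon: int = 2,
    alpha: float = 0.5,
    type_labels: Sequence[str] = ("in-group", "out-group"),
    preferences: str | Mapping[str, Any] = "cultural",
    gamma_policy: float = 1.0,
    eta_a: float = 1.0,
    eta_e: float = 0.0,
) -> dict[str, Any]:
    """Configuration mapping for the standard foraging/signaling agent."""
    return {
        "n_partners": int(n_partners),
        "n_signals": int(n_signals),
        "horizon": int(horizon),
        "alpha": float(alpha),
        "type_labels": list(type_labels),
        "preferences": preferences,
        "gamma_policy": float(gamma_policy),
        "eta_a": float(eta_a),
        "eta_e": float(eta_e),
    }


def _soft_identity(n: int, p: float = 0.9) -> np.ndarray:
    a = np.full((n, n), (1.0 - p) / (n - 1)) if n > 1 else np.ones((1, 1))
    if n > 1:
        np.fill_diagonal(a, p)
    return a


def _preference_vectors(pref: str | Mapping[str, Any], n_actions: int, n_signals: int):
    if isinstance(pref, str):
        table = {"cultural": CULTURAL_C, "egocentric": EGOCENTRIC_C}
        if pref not in table:
            raise ModelValidationError(f"preferences: unknown preset {pref!r}")
        pref = table[pref]
    own = np.zeros(n_actions)
    own[ACT_FORAGE] = pref["own_forage"]
    own[ACT_SHARE] = pref["own_share"]
    own[ACT_CONCEAL] = pref["own_conceal"]
    own[ACT_SIGNAL0 : ACT_SIGNAL0 + n_signals] = pref["own_signal"]
    return [
        np.asarray(pref["satiety"], float),
        np.asarray(pref["yield"], float),
        np.asarray(pref["partner_action"], float),
        np.zeros(n_signals + 1),  # no intrinsic preference over heard signals
        np.asarray(pref["declaration"], float),
        own,
    ]


def make_agent_model(version: str, spec: Mapping[str, Any]) -> AgentModel:
    """Construct and validate a V1/V2/V3 forager agent from a configuration mapping.

    V1 is single level; V2 carries a fixed typing level with the configured
    labels; V3 starts single level and is flagged expandable (structure
    learning may add the typing level at runtime).
    """
    if version not in ("V1", "V2", "V3"):
        raise ModelValidationError(f"version: unknown version {version!r}")
    required = ("n_partners", "n_signals")
    for key in required:
        if key not in spec:
            raise ModelValidationError(f"{key}: missing from agent spec")
    n_partners = int(spec["n_partners"])
    n_signals = int(spec["n_signals"])
    if n_partners < 1:
        raise ModelValidationError("n_partners: must be >= 1")
    if n_signals < 1:
        raise ModelValidationError("n_signals: must be >= 1")
    horizon = int(spec.get("horizon", 2))
    if horizon < 1:
        raise ModelValidationError("horizon: must be >= 1")
    alpha = float(spec.get("alpha", 0.5))
    if not (0.0 <= alpha <= 1.0):
        raise ModelValidationError(f"alpha: {alpha} outside [0, 1]")
    labels = list(spec.get("type_labels", ["in-group", "out-group"]))
    if version == "V2" and len(labels) < 2:
        raise ModelValidationError("type_labels: V2 requires at least 2 labels")

    n_id = n_partners + 1  # known partners + "stranger" slot
    n_actions = 3 + n_signals
    sizes = [3, 3, n_id, 3, n_actions]
    modality_sizes = [3, 3, 4, n_signals + 1, 2, n_actions]

    # --- likelihoods ------------------------------------------------------
    A_sat = _soft_identity(3, 0.9)
    A_yield = _soft_identity(3, 0.8)
    A_pact = np.array(
        [  # outcome x pmove-state (coop, selfish, none)
            [0.85, 0.10, 0.03],
            [0.02, 0.30, 0.02],
            [0.03, 0.40, 0.02],
            [0.10, 0.20, 0.93],
        ]
    )
    # heard-signal likelihood per partner identity: learnable, near-uniform init
    pA_sig = np.full((n_signals + 1, n_id), 1.0, dtype=float)
    A_sig = dirichlet_expectation(pA_sig)
    A_decl = np.array([[0.97, 0.70, 0.98], [0.03, 0.30, 0.02]])
    A_own = np.eye(n_actions)
    A = [A_sat, A_yield, A_pact, A_sig, A_decl, A_own]
    A_parents = [(F_SAT,), (F_STOCK,), (F_PMOVE,), (F_PARTNER,), (F_PMOVE,), (F_OWN,)]
    pA: list[np.ndarray | None] = [None, None, None, pA_sig, None, None]

    # --- transitions ------------------------------------------------------
    up = np.array([[0.3, 0.0, 0.0], [0.7, 0.3, 0.0], [0.0, 0.7, 1.0]])
    down = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 0.5]])
    drift = np.array([[0.9, 0.2, 0.0], [0.1, 0.7, 0.2], [0.0, 0.1, 0.8]])
    B_sat = np.zeros((3, 3, n_actions))
    for u in range(n_actions):
        if u in (ACT_FORAGE, ACT_CONCEAL):
            B_sat[:, :, u] = up
        elif u == ACT_SHARE:
            B_sat[:, :, u] = down
        else:
            B_sat[:, :, u] = drift
    deplete = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 0.5]])
    hold = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]])
    B_stock = np.zeros((3, 3, n_actions))
    for u in range(n_actions):
        B_stock[:, :, u] = deplete if u in (ACT_FORAGE, ACT_CONCEAL) else hold
    B_id = np.repeat(np.eye(n_id)[:, :, None], n_actions, axis=2)
    # reciprocity expectations: sharing is believed to pull the partner
    # toward cooperativeness, concealing toward selfishness; otherwise the
    # partner's disposition is sticky
    sticky = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    warm = np.array([[0.9, 0.4, 0.3], [0.05, 0.5, 0.1], [0.05, 0.1, 0.6]])
    chill = np.array([[0.6, 0.05, 0.1], [0.3, 0.85, 0.3], [0.1, 0.1, 0.6]])
    B_pmove = np.zeros((3, 3, n_actions))
    for u in range(n_actions):
        if u == ACT_SHARE:
            B_pmove[:, :, u] = warm
        elif u == ACT_CONCEAL:
            B_pmove[:, :, u] = chill
        else:
            B_pmove[:, :, u] = sticky
    B_own = np.zeros((n_actions, n_actions, n_actions))
    for u in range(n_actions):
        B_own[u, :, u] = 1.0  # own next move is the chosen action
    B = [B_sat, B_stock, B_id, B_pmove, B_own]

    C = _preference_vectors(spec.get("preferences", "cultural"), n_actions, n_signals)
    D = [
        np.array([0.1, 0.8, 0.1]),
        np.full(3, 1.0 / 3),
        np.full(n_id, 1.0 / n_id),
        np.array([0.4, 0.2, 0.4]),
        np.full(n_actions, 1.0 / n_actions),
    ]

    policies = np.array(
        [[a for a in p] for p in np.ndindex(*([n_actions] * horizon))], dtype=int
    )
    pE = np.ones(policies.shape[0], dtype=float)
    E = pE / pE.sum()

    levels = [LevelSpec(index=1, factor_sizes=sizes, modality_sizes=modality_sizes)]
    A2 = D2 = summary_map = None
    if version == "V2":
        k = len(labels)
        link, A2 = typing_level_arrays(k)
        D2 = np.full(k, 1.0 / k)
        summary_map = np.eye(3)
        levels.append(
            LevelSpec(
                index=2,
                factor_sizes=[k],
                modality_sizes=[3],
                link=link,
                alpha=alpha,
                labels=labels,
            )
        )

    model = AgentModel(
        version=version,
        levels=levels,
        A=A,
        A_parents=A_parents,
        B=B,
        C=C,
        D=D,
        E=E,
        policies=policies,
        gamma_policy=float(spec.get("gamma_policy", 1.0)),
        eta_a=float(spec.get("eta_a", 1.0)),
        eta_e=float(spec.get("eta_e", 0.0)),
        type_labels=labels if version == "V2" else list(labels),
        A2=A2,
        D2=D2,
        summary_map=summary_map,
        alpha=alpha if version != "V1" else 0.0,
        expandable=(version == "V3"),
        pA=pA,
        pE=pE.copy(),
    )
    validate_model(model)
    return model


def typing_level_arrays(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Default link and level-2 likelihood for a k-type partner-typing factor.

    Type 0 is the most norm-faithful ("in-group"-like: expected to act
    cooperatively), the last type the least; intermediate types interpolate.
    ``link`` columns are priors over the partner-move factor
    (cooperative/selfish/absent); ``A2`` maps types to the ascending summary
    categories (same three-way split).
    """
    if k < 2:
        raise ModelValidationError("type cardinality: must be >= 2")
    coop_ends, self_ends = (0.85, 0.15), (0.05, 0.70)
    link = np.zeros((3, k))
    a2 = np.zeros((3, k))
    for t in range(k):
        w = t / (k - 1)
        coop = coop_ends[0] * (1 - w) + coop_ends[1] * w
        selfish = self_ends[0] * (1 - w) + self_ends[1] * w
        link[:, t] = [coop, selfish, 1.0 - coop - selfish]
        a2[:, t] = [coop, selfish, 1.0 - coop - selfish]
    return link, a2
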