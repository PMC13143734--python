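# Methods

This note documents the generative models, the world, the default
parameters, and the reasoning behind the open design choices.  Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Level-1 generative model

The world-facing model is deliberately the smallest state space that
supports cooperative foraging, signaling, concealment and declarations.

Hidden-state factors (sizes):

| factor | states | role |
|---|---|---|
| satiety | 3 bins | interoceptive drive |
| patch stock | 3 bins | resource context |
| partner identity | one slot per known agent + stranger | who I face |
| partner move | cooperative / selfish / absent | conduct belief |
| own move | one per action | feedback for preferences |

Modalities (outcomes): satiety (3), patch yield (3), partner action
(cooperate / defect / conceal / none), heard signal (alphabet + none),
declaration heard (2), own-move feedback (one per action).  Every modality
depends on a single factor, so level-1 inference is exact; the generic
damped mean-field machinery (`damping 0.5`, `tol 1e-8`, `max 64`
iterations, sequential coordinate updates, which provably never increase
F) is exercised by multi-factor models in the tests.

The own-move factor and its feedback modality are an addition to the
minimal inventory: preferences that distinguish a culturally faithful from
an egocentric actor need an observable consequence of the agent's own act
(sharing preferred vs. concealment preferred).  Without it, preference
differences cannot enter the expected-free-energy comparison at all.

The partner-move transitions are action-dependent ("reciprocity
expectations"): sharing is believed to pull a partner toward
cooperativeness, concealing toward selfishness.  This coupling is what
makes the typing prior behaviorally relevant — with action-independent
conduct dynamics, a typing prior shifts every policy's expected free
energy by the same constant and provably cancels in the policy softmax
(we measured bit-identical fitness across the whole alpha range before
introducing it).

Preference presets (natural-log units): the cultural profile prefers
satiation (0/1.5/2.5), sharing (+2) and foraging (+1) over concealment
(-4), mildly prefers seeing cooperation and hearing no declarations; the
egocentric profile weights own satiety steeply (-2/1/3), treats sharing as
a cost (-1) and concealment as a gain (+1.5), and is indifferent to
partner conduct.  Policy temperature `gamma_policy = 1.0` keeps action
distributions graded (a conceal observation carries about -5 nats of
typing evidence, a share about +5, a forage about +0.3); at the
first-draft value of 4 the distributions were numerically saturated and
single observations decided typing outright.

Dirichlet machinery: the heard-signal likelihood is learnable
(`eta_a = 1`, counts floored at `1e-3` so no outcome is ever locked out);
habits are learnable but off by default (`eta_e = 0`).  Policies are
open-loop action sequences of horizon 2 over {forage, share, conceal,
signal(k)}; declarations are produced by the violation detector rather
than by policy search, since an accusation is modelled as a triggered
speech act, not a planned forage-economy move.

## Hierarchy and the precision gain

Two-level agents summarize the partner-move posterior through an identity
summary map and update a per-partner typing posterior with the geometric
(soft-evidence) rule.  The descending prior is a log-linear blend

    prior ∝ exp[(1 - alpha) ln base + alpha ln top_down]

with the boundary cases returned exactly (no exp/log round trip), because
the alpha = 0 contract is *bit* equality with a V1 twin and the alpha = 1
contract is exact dominance of the typing prediction.  An arithmetic
mixture cannot satisfy the alpha = 1 contract when the base prior has full
support, which is why the geometric blend was chosen.  Zero entries in the
top-down prediction are floored at 1e-12 before the blend.

Perception is credited to the partner who generated the observation (the
encounter of the previous tick); planning uses the typing of the upcoming
partner.  Conflating the two scrambles partner statistics — an early
version did exactly that, and the structure-learning experiments were the
symptom that exposed it.

A consumed, verified declaration raises every observer's effective alpha
by `alpha_increment` (default 0.1; the narrative fixture uses 0.2), capped
at 1.  Alpha can also be inferred over a discrete grid
(`infer_alpha`, posterior ∝ prior × exp(-F)); the KL of that posterior to
its prior is the transcendental term of the free-energy report, which is
zero in the default fixed-alpha runs.

## Moral typing

The two behavioral models share all arrays and differ only in C.  The
prior-odds term uses the convention P(m) ∝ exp(-G(m)) with G aggregated
as the habit-weighted softmin of per-policy expected free energies, so
`dG = G(ego) - G(cultural)` and lower expected free energy means higher
prior probability.  (The other orientation of the prior-odds equality is
one sign flip away; the convention is stated here because the two
equalities in the usual presentation conflict under P(m) ∝ exp(-G).)
Predictive likelihoods are floored at 1e-12, log odds capped at ±50
before the logistic.

Watchers score observed acts in a *neutral default-belief context* rather
than in the observer's own evolving interoceptive state.  The observer
does not know the actor's hunger; when we conditioned on the observer's
own beliefs, an observer who had just eaten judged honest foraging as
mildly egocentric — context leakage, not evidence.  Concealment is the
only covert act: share/forage/signal are scored as seen, an undetected
conceal is scored as forage.

Detection uses threshold `theta = 0.5` with hysteresis 0.1: the detector
arms once P(cultural) has reached 0.6 and fires at most once per downward
crossing of 0.5.

## Structure learning (V3)

Failure detection compares first-half vs. second-half means of a 50-tick
free-energy window (`epsilon = 0.01` nats, cooldown 100 ticks).  A
proposal builds K = 2 type columns from symmetric Dirichlet draws
(concentration 32) perturbed by the pooled, capped (10 pseudo-counts per
partner) partner-conditioned outcome statistics, splitting partners at the
largest gap in their cooperativeness scores.  The proposal is immediately
audited: if one shared Dirichlet column explains the pooled evidence
better than the per-type columns (`merge_log_evidence > 0`), the expansion
is reverted.  Free energy plateaus in *any* stationary world, so the
trigger fires under homogeneous partners too — the audit, not the
trigger, is what makes expansion specific to unexplainable heterogeneity.
Generic congruent-shape Bayesian model reduction (`reduce_model`,
antisymmetric by construction) is provided separately from the merge
score, because a same-shape reduced prior cannot express column pooling.

## The world

Defaults: 2 patches (capacity 12, initial stock 10, regeneration 0.15),
cooperative yield `min(stock/n, 1.0 * (1 + 0.5 (n-1)))`, concealment
detection 0.5 (the fixture's Pete scripts 1.0), satiety decay one unit
per 5 ticks, banishment 20 ticks with confiscation (confiscated goods
return to the patch), familiarity threshold 3 co-located ticks,
`consensus_k = 1`.  Encounter scheduling: with probability
`stranger_rate` a uniform unfamiliar partner; otherwise familiar partners
weighted by `exp(gamma_att * P(cultural))`, with an abstention option at
the neutral prior 0.5 so an untrusted pool can be declined.
`encounter_rate < 1` thins the per-tick pairing pool for sparse-encounter
studies.  Overheard declarations are assimilated by co-located bystanders
as negative evidence weighted by their trust in the declarer
(`testimony_weight = 2`), and can trigger second-hand declarations.
Order within a tick: encounters → actions → sanctions (previous tick's
declarations) → regeneration → observation synthesis.  The conservation
identity (stocks + inventories + cumulative consumption − regeneration
inflow = initial endowment) holds to 1e-9 and is asserted on every tick
of the audit runs.

All indices are 0-based in code and trace files; printed reports are
1-based where they address humans.

## Experiment harnesses and problem sizes

- **Model recovery**: 200 sequences per class, length 20, random
  full-support contexts; sign of dF classifies the generator, and the
  calibration curve reports mean P(cultural) (Eq-style log odds with dG
  recomputed in the checkpoint context, added once) at lengths 5/10/20.
- **Version fitness**: 2 V1 + 2 V2 + 4 scripted agents, stranger rate
  0.8, 120 ticks, 10 seeds, permutation test on the V2-V1 mean difference.
  The direction (V2 ≥ V1) is reported and checked at warn level only.
- **Alpha sweep**: fitness-vs-alpha curve over {0, 0.25, 0.5, 0.75, 1};
  unimodality is reported in the frame attributes, never asserted.
- **Structure-learning regimes**: one V3 focal agent among 7 scripted
  partners (split 4 cooperators / 3 concealers, or homogeneous), 500
  ticks, 20 runs per regime; expansion = typing level alive at run end;
  alignment = best-permutation accuracy of typed partners vs. ground-truth
  groups.
- **Polarization**: 8 scripted agents (half cooperators, half
  concealers), sparse encounters (`encounter_rate 0.3`, stranger rate
  0.05), 150 ticks, 10 seeds per attention gain in {0, 2, 8}.  The
  polarization index is twice the population SD of per-agent mean
  P(cultural) over watched targets (bounded on [0, 1] for [0, 1]-valued
  beliefs: 0 at consensus, 1 at a maximal half/half split).

The synthetic worlds emulate scarce-resource foraging with honest,
disposition-scripted partners; they do not emulate strategic adaptation
by the partners, reproduction, spatial structure, or group-relative norms.
Passing tests therefore show that the inference, typing, enforcement and
structure-learning machinery behaves as specified under controlled
conditions — not that these dynamics quantitatively match any human
population.

## Known limitations

- The attention-bias effect on polarization is weak to absent at these
  scales: across the probed configurations the mean index is essentially
  flat in `gamma_att` (the monotonicity check passes within its one-SE
  tolerance precisely because the curve is flat).  With veridical,
  commonly agreed evidence, biased attention promotes consensus about
  who defects as much as it freezes idiosyncratic beliefs; the
  opinion-dynamics ingredients that drive strong polarization elsewhere
  (social volatility, source-habit formation) are deliberately out of
  scope here, with only the attention-bias analog implemented.
- Two inference levels only; deeper towers (dyadic / shibboleth /
  cultural as separate levels) are collapsed into the typing factor plus
  world-level group tags.
- The posterior factorizes fully across levels (mean-field); structured
  cross-level posteriors are future work.
- B arrays are fixed per configuration (no transition learning), and V3
  expansion can choose cardinality K but cannot invent new modalities.
- The version-fitness direction is seed-noisy at desk scale; it is
  surfaced with a permutation p-value rather than asserted.
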