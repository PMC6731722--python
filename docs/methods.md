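# Methods

## Model and assumptions

The package treats a multilevel population as a multivariate discrete
distribution: one categorical variable per level of the hierarchy
(individuals `I`, collectives `C1`, `C2`, …, lowest level first), with
the joint entry `f(I_i in C1_j in …)` read as `P(I_i, C1_j, …)`. The
key modelling assumption inherited from this encoding is that the
abundance of a collective is measured in terms of the individuals it
contains: marginals at a level are abundance distributions of that
level's types, and conditionals are compositions (member given
collective) or memberships (collective given member).

Selection is deterministic in frequencies. There is no absolute
population size, no drift, no mutation, and no frequency-dependent
fitness: stochasticity enters only through the environment stream
`e(1), e(2), …`, each state of which selects a fixed non-negative
fitness table over configurations. One generation multiplies abundances
by fitness and renormalizes, which is exactly Bayes' rule with the
fitness table as the likelihood of the observed state. A zero
normalizer (zero evidence) is an annihilated population; the update is
undefined there and the package raises a typed `ExtinctionError`
carrying the step index rather than renormalizing silently.

Structural properties are conditional-independence relations, stored as
deleted links `(child, conditioner)` of the chain factorization
`P(e|I,C1,…) P(I|C1,…) … P(C^L)`:

* `(e, V)` — level `V` is *frozen*: its fitness table is constant along
  `V`'s axis. The conserved quantity under update is then the
  composition of `V` given the **full** containing configuration,
  `P(V | all higher levels)`; the conditional given a single higher
  level alone can still move when intermediate levels evolve.
* `(V, W)` with `W` above `V` — the composition at level `V` ignores
  level `W` given the levels in between.

`project_ci` maps an arbitrary distribution onto the constraint set of
a link-deleted structure by rebuilding the chain factorization with
each deleted conditional replaced by its marginalized version. This is
the natural projection for this factorization; where a retained-parent
configuration has zero mass the conditional is undefined and is filled
uniformly over the child axis (the fill only ever multiplies mass that
the projection itself fabricates, and full-support inputs never hit
it). The projection is idempotent and an identity on distributions that
already satisfy the constraints.

## Structure learning

Model evidence equals average fitness, so hierarchy structures are
scored by running each candidate's own replicator trajectory along a
*shared* sampled environment window (common random numbers) and
averaging the log per-step evidence. Scores are comparable only within
a window (same sequence, length and seed); averaging log evidence is
the standard sequential extension of a per-observation evidence and
equals `(1/T) log Π_t w̄_t`, which a brute-force enumeration oracle
reproduces in the tests.

Two transition moves mirror the two ways a new unit of individuality
can appear: `add_top_level` creates a new level whose variable has the
nascent collective plus a distinguished `free` value holding ungrouped
units (a membership-weight map and a mixing parameter ε decide how much
of each existing configuration's mass moves in), and `add_value` adds a
type to an existing level, seeded with a fraction ε of donor mass.
Both conserve total mass exactly and leave untouched entries
bit-for-bit; `merge_value` is the inverse of a single-donor split.
`delete_link`/`restore_link` edit the independence structure; deleting
an environment link also freezes the state's tables along that level so
the state remains consistent with its own structure.

Greedy search accepts the best-scoring candidate only when it beats the
incumbent by more than a margin δ (default 1e-6 in mean-log-evidence
units); ties and sub-margin gains keep the incumbent, and ranking ties
break toward fewer levels, then fewer total types, then lexicographic
structure id. This deterministic simplicity-first rule makes the
automatic Occam's razor explicit: pure-structure moves (no mass, no
fitness change) score *exactly* equal — the normalizer is computed with
correctly-rounded summation (`math.fsum`), so appended zero-mass cells
cannot perturb it — and are therefore never adopted at any δ > 0.
Candidate generation is pluggable; the default proposes one grouping
per unordered pair of top-level types and one split per existing type.
Competing structures are compared counterfactually on shared windows,
not as coexisting subpopulations; ε is a move parameter (default 0.5),
not a learned quantity.

## Synthetic environments

Fitness tables are generated from a multiplicative rule
`w(I_i in C1_j in …; e) = b(I_i; e) · s(C1_j; e) · …` with per-individual
base fitnesses and per-collective synergy factors. `s ≡ 1` makes every
table constant along all collective axes given the individual type —
the exact no-synergy null in which no grouping can change evidence.
Synergy for "these types do better together" is keyed by the frozenset
of member labels and resolved through deterministic group labels
(`g:I1+I2`), which is how grouping moves advertise their members.
Environment streams are i.i.d. or first-order Markov (initialized at
the stationary distribution); all sampling consumes an explicit seed.

The standard study environment (`two_state_synergy_environment`) uses
three individual types and two equiprobable i.i.d. states with base
fitnesses (1.5, 0.8, 1.0) and (0.8, 1.5, 1.0) over (I1, I2, I3) — each
specialist favoured in one state, a neutral bystander — and a
co-membership synergy `s` on {I1, I2} in both states. These values make
the environment informative without being degenerate: with `s = 4` the
grouped structure's per-step evidence dominates the ungrouped one's
under every state, so recovery is driven by the evidence comparison
itself rather than by lucky environment draws. The recovery study runs
50 seeded greedy searches with window T = 24 and at most 3 rounds;
sizes are desk-scale by design (a few hundred cells at most), keeping
every quantity checkable against explicit enumeration.

What the generator does *not* emulate: finite-population sampling noise,
mutation, frequency-dependent payoffs, continuous environments, and any
mechanistic coupling that would give a collective an identity beyond its
type label. Passing tests therefore demonstrate the internal
consistency of the dictionary and the behaviour of evidence-driven
transitions under clean multiplicative synergy — not robustness of
structure recovery under demographic noise or model misspecification.

## Numerical choices

* Distributions validate to unit sum at 1e-9 (accumulated float error
  over long trajectories); pointwise identities are tested at 1e-12.
* Both update codepaths compute the normalizer with `math.fsum`
  (correctly rounded, order-insensitive); the replicator path is numpy
  elementwise, the Bayesian path a pure-Python loop accumulating in
  reversed cell order. Their agreement is checked, not assumed.
* Trajectory evidence accumulates as `Σ log w̄(t)`; the raw product
  underflows after a few hundred steps.
* Zero-mass conditioning raises typed errors (`EmptyCollectiveError`)
  instead of returning NaN; a conditional-independence query whose
  conditioner is absent, or nowhere has two positive-mass values, is
  vacuously satisfied (the measure-theoretic convention).
* Dense lowest-level-first array storage; per-round search seeds derive
  from the run seed and round index via `numpy.random.SeedSequence`.

## Limitations

Transient collectives that re-assort members each generation are not
modelled (only persistent, composition-defined collectives are), and
collective identity beyond a type label — including any parameter
coupling across levels it would induce — is out of scope. Search is
greedy hill-climbing only: no annealing, no structure priors, and no
scores other than evidence. Dense storage limits hierarchies to desk
scale, which is intentional for a reference implementation whose every
number is meant to be reproducible by enumeration.
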