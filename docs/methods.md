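# Methods

## Model representation and restructuring

A `MetabolicModel` is a compounds × reactions stoichiometric matrix with
per-reaction flux bounds (mmol·gDW⁻¹·h⁻¹ scale), exactly one biomass
reaction, and compartment-tagged compounds (`c` cytoplasm, `e`
extracellular, `p` periplasm; `p` only for collections that declare one).
Compound identity within a namespace is the `(base_id, compartment)` pair;
identity *across* compartments — used for transport and for nesting — is by
`base_id` alone.

Raw models express their medium through exchange pseudo-reactions. We
replace each exchange (single `e`-compound, coefficient ±1) by equivalent
bounds on that compound's net production rate `c'_j`: a sink `X[e] →` with
flux range `[l, u]` leaves the rest of the network constrained to
`l ≤ c'_j ≤ u`, so an availability of `m` units appears as
`env_lower = −m ≤ c'_j ≤ env_upper`. Duplicate exchanges for one compound
have their induced intervals summed (logged). Externalization provably
preserves the FBA optimum; the test suite checks this to 1e-8 relative on
50 random models. Internal compounds are held strictly at steady state —
raw right-hand sides encoding internal accumulation are out of scope.

Harmonization re-indexes a set of models of one collection onto the sorted
union of their compounds, so the same row means the same compound
everywhere. It is idempotent and order-independent by construction. Models
from different collections are never mixed (their identifier dialects are
not reconcilable without curation).

## The pair system

The endosymbiont's extracellular compartment is the host's cytoplasm
(never the periplasm). Its matrix is partitioned into `S_E` (its own `c`/`p`
rows, private and balanced to zero) and `S_E→H` (its `e` rows re-mapped to
the host-side `base_id@c` rows). An `e`-compound with no cytoplasmic
counterpart anywhere in the namespace cannot be re-mapped; it is kept on a
flagged *orphan* row with bounds `[0, 0]`, which makes the
"endosymbiont needs direct environment access" failure mode structural
rather than heuristic.

The joint environment is the elementwise sum of the two ancestral
environments; since each summand interval contains zero, each ancestor
remains independently feasible in it. The ancestral environment bounds
apply to the shared external `e` rows only; host cytoplasm rows stay at
steady state while absorbing `S_E→H y`. Host and endosymbiont biomass
fluxes are constrained equal — the pair reproduces as a unit — implemented
as a hard equality (growth-ratio parameters are a non-goal). One
endosymbiont copy per host is assumed (a single `y` block). An infeasible
pair LP is classified exactly like zero growth: nonviable.

## Numerical choices

LPs are solved with HiGHS via scipy (`milp` with no integrality, which
accepts two-sided row constraints directly). Solver feasibility is ~1e-9
and is never conflated with the *biological* viability threshold of 0.001
on the growth rate; growth exactly at 0.0005 is nonviable, 0.0011 viable.
Infeasible LPs count as growth 0 so the survive/not classification is a
total function; unbounded LPs are reported with a diagnostic (columns with
infinite bounds) and solver failures are flagged, never silent. Alternative
optima are accepted silently everywhere except the community computation,
which interrogates them explicitly (below). Reported optima normalize IEEE
negative zero.

## Repair

Candidate transport compounds are those simultaneously (1) available in
the joint environment in nonzero amount, (2) present in both `e` and `c`
compartments somewhere in the union of the two models' compounds, and
(3) touched by at least one endosymbiont reaction. Added transports are
reversible `X[e] ↔ X[c]` columns with symmetric bounds ±1000 (the
collections' conventional "unbounded" magnitude), bypassing any periplasm;
reversibility is the least-committal reading of "enabling" a transport.

Diagnosis runs in fixed order: *transport* (viable after adding all
candidate transports?) then *access* (viable after additionally giving the
endosymbiont a direct conduit from each nonzero environmental compound's
`e` row to the row where its copy of that compound lives — the mapped
cytoplasm row or the orphan row — so supply stays limited by the joint
environment). The flags are not mutually exclusive.

Minimal transport sets are found greedily: start from all candidates,
attempt single removals in a seeded random order, keep a removal whenever
the pair stays viable. The result is always irreducible but only an
*estimate* of the true minimum; the pipeline takes the best of 5 restarts,
and on generated instances with ≤ 12 candidates exhaustive subset
enumeration confirms the minimum cardinality is found in well over 95% of
cases (the suite observed 100%). Single-compound specificity is decided by
an exhaustive singleton scan.

## Competition

A perturbation removes one compound from the medium by zeroing its uptake
bound only — removing a compound cannot forbid excreting it. Robustness is
the proportion of single-compound removals survived; the joint outcome of
(pair, ancestral host, ancestral endosymbiont) falls into 8 classes (2
unanimous, 6 mixed) that provably partition the boolean cube.

Relative fitness of the pair against an ancestor is
`(pair − ancestor)/ancestor`, both grown in the same joint environment
(ancestors are *not* re-run in their private environments; reports state
this). Two growth rates within 1e-6 relative are "equal". The directional
definition is reported for both references, since the reference switches
depending on which party is slower.

The community computation pools the `e`-row consumption of three entities
— ancestral host, ancestral endosymbiont, and the pair with its internal
coupling intact, each with private internal rows — against one shared
environment (the same joint environment used elsewhere, applied once).
Step 1 maximizes the summed biomass fluxes (`z`); step 2 maximizes and
minimizes each entity's biomass with the total fixed at `z`. A partition
is *unique* when every entity's spread satisfies `(max − min)/max ≤ 0.10`
(entities with `max = 0` count as unique); non-unique cases are excluded
from community statistics and counted.

## Evolvability

A mutation relaxes one reaction's bounds to `[−1000·|l|, 1000·u]` and is
beneficial when growth rises by more than 1e-6 relative (guarding against
solver noise; relaxations can never *decrease* an optimum, which the suite
enforces as a hard no-harm law). For the rare `l > 0` reaction the formula
flips the direction constraint; such reactions are flagged in the log and
handled verbatim. Pair scans mutate host-reaction and endosymbiont-reaction
bounds separately, against the pair LP's column bounds, restoring them
after every evaluation (reset integrity is tested bit-for-bit).
Collections where no mutation is ever beneficial (environment-limited
regimes) are tightened — all bounds divided by 100 — and re-scanned, which
moves the binding constraints onto the reactions.

Note an asymmetry worth knowing: even for identical host and endosymbiont
models the two pair contexts are not mirror images, because host transports
serve both organisms. Relaxing a shared transport in the host context can
be beneficial while the same relaxation in the endosymbiont context is
neutral.

Beneficial-count comparisons across pairs use a paired two-sided Wilcoxon
signed-rank test implemented from its definition (average ranks for ties,
exact dynamic-programming null for n ≤ 25, tie-corrected normal
approximation above; validated against scipy). Cross-collection viable
fractions are compared with one-way ANOVA from the between/within
sum-of-squares definitions (degenerate zero-within-variance cases reported
as infinite F with a flag).

## Synthetic data

The generator emulates the *structure* of curated collections at toy
scale, not their content: multi-compartment models with one biomass
reaction, flux bounds, and an environment guaranteeing baseline viability.
Each environmental substrate feeds a transport and a chain of internal
conversions ending in a biomass precursor; biomass consumes one unit of
each precursor by default (heterogeneous coefficients optional), keeping
the expected optimum in closed form:
`min(biomass_cap, min_k min(availability, chain_cap_k)/demand_k)`, exact
for `redundancy = 0` (shortcut reactions, always 1-to-1 and therefore
mass-conserving, can only re-route flux, never create it — LPs stay
bounded by construction). Defaults: availability 10, reaction capacities
drawn per reaction from `[50, 100]` so the environment binds growth (the
regime of the larger curated collections); the `bound_limited` preset
(capacities `[2.5, 5]`) gives the opposite regime in which bound mutations
matter. Capacities are drawn rather than constant because homogeneous
bounds would make every chain reaction bind simultaneously after
tightening, leaving no *single* mutation beneficial. One inert
environmental compound is included by default so knockout screens contain
harmless perturbations. Every model is FBA-verified viable before being
returned, and every engineered defect label (transport-deficient,
access-deficient, both) is confirmed by running the diagnosis LPs on the
emitted pair.

What the generator does **not** emulate: realistic reaction content,
shared pathway cores, cofactor coupling, periplasm-specific transport
chains, or collection-scale namespaces. Passing tests therefore
demonstrate the correctness of the machinery on networks with known
ground truth, not quantitative predictions about real model collections.

## Survey design and problem sizes

Surveys sample unordered model pairs with replacement (never pairing a
model instance with itself) and evaluate both directed configurations;
statistics are reported per batch to expose sampling variation. All
randomness flows from one root seed through named substreams; outputs are
tidy CSV plus a JSON summary and are byte-identical under a fixed seed.
Solver failures are tabulated, never abort a survey.

The shipped test and acceptance runs use deliberately small problem
sizes — collections of 12–60 models with 2–3 substrates and pathway depth
1–4, surveys of 10 batches × 50 pairs, 50–100 random models or pairs per
oracle check — chosen so the full suite plus the acceptance script
completes in about a minute while every check still exercises the same
code paths as a collection-scale run.

## Known limitations

- The greedy minimal-set search estimates, not guarantees, minimum repair
  cardinality (restarts mitigate).
- Community growth is a static two-step LP; no dynamics, dilution, or
  multi-compound knockouts.
- Mutations are single and non-compounding; no reaction gain/loss, no
  stoichiometric mutations, no epistasis.
- The endosymbiosis LP describes a primitive, pre-adaptation pairing: no
  division of labor, regulation, or eukaryote-like compartment structure.
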