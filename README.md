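# endoflux

Flux-balance assessment of metabolic compatibility in putative
host–endosymbiont pairs of prokaryotes.

Endosymbiosis — one cell living and reproducing inside another — is
vanishingly rare among bacteria and archaea, yet one such event produced the
mitochondrion and, with it, eukaryotes. One candidate explanation is
*metabolic compatibility*: can two metabolisms actually grow on the same
resources when one is nested inside the other? `endoflux` makes that
question quantitative with constraint-based metabolic models. It is aimed at
researchers in microbial systems biology and evolution who work with
genome-scale metabolic reconstructions (or want controlled synthetic
stand-ins for them).

## The model

A metabolism is a stoichiometric matrix `S` (compounds × reactions) with
flux bounds `l ≤ x ≤ u` and a biomass reaction whose flux is the growth
proxy. Instead of exchange pseudo-reactions, each model carries an
*externalized environment*: bounds `a_j ≤ c'_j ≤ b_j` on the net production
rate `c'_j = Σ_k S[j,k] x_k` of every extracellular compound (internal
compounds are held at steady state, `c'_j = 0`). Growth in isolation is the
linear program

    max  x_λ    s.t.  a ≤ S x ≤ b,   l ≤ x ≤ u.

For an endosymbiosis, the endosymbiont's extracellular compartment *is* the
host's cytoplasm. Partitioning the endosymbiont's matrix into rows strictly
inside it (`S_E`) and rows re-mapped onto host cytoplasm compounds
(`S_E→H`), the pair is the single LP

    max  x_λH   s.t.  a_H + a_E ≤ S_H x + S_E→H y ≤ b_H + b_E
                      S_E y = 0,   l ≤ x, y ≤ u,   x_λH = y_λE,

solved in the *joint environment* (elementwise sum of the two ancestral
environments, in which each ancestor can still grow alone). On top of this
core the package provides:

- **viability** of both directed configurations of a species pair
  (growth ≥ 0.001);
- **repair** of nonviable pairs: diagnosing whether the block is a missing
  host transport or missing environment access, and finding irreducible
  minimal sets of compounds whose host `[e]↔[c]` transport restores
  viability;
- **competition** against the ancestors: single-compound knockout
  robustness screens, relative growth rates, and a two-step
  shared-environment community LP with a 10% uniqueness filter;
- **evolvability**: ×1000 bound-relaxation mutation scans, reaction by
  reaction, compared between pair and ancestors (sign-rank statistics);
- a **synthetic generator** of viable pathway models and of pairs with
  engineered nonviability causes, with closed-form expected growth rates;
- a batched **survey pipeline** and `endoflux` CLI over harmonized model
  collections (toy TSV, SBML L3+fbc, archive IO).

## Worked example

Host `TOY-A` grows on substrate A; would-be endosymbiont `TOY-B` grows on
substrate N. Inside the host, `TOY-B` starves — the host has no N
transporter — and the repair machinery identifies and fixes exactly that:

```python
import endoflux as ef

host = ef.make_fixture("TOY-A").model
endo = ef.make_fixture("TOY-B").model
host, endo = ef.harmonize_namespace([host, endo])

pair = ef.build_pair(host, endo)
print("joint environment:", pair.joint_env.bounds)
print("pair growth:      ", ef.maximize_pair_growth(pair).growth)

result = ef.diagnose_nonviability(pair)
print("cause = missing transport?", result.cause_transport)
print("minimal transport set:", ef.minimal_transport_set(pair, order_seed=0))

repaired = ef.add_universal_transport(pair, ["N"])
growth = ef.maximize_pair_growth(repaired).growth
print("repaired pair growth:", growth)

host_growth = ef.maximize_growth(host, pair.joint_env).growth
fit = ef.pairwise_relative_fitness(growth, host_growth)
print("host growth:", host_growth, "-> pair is", fit.classification,
      f"(advantage {fit.advantage:+.2f})")

records, scores = ef.survival_screen(repaired, host, endo)
print("robustness:", {k: s.proportion for k, s in scores.items()})
```

prints

```
joint environment: {'A': (-10.0, 0.0), 'N': (-10.0, 0.0)}
pair growth:       0.0
cause = missing transport? True
minimal transport set: {'N'}
repaired pair growth: 10.0
host growth: 10.0 -> pair is equal (advantage +0.00)
robustness: {'pair': 0.0, 'host': 0.5, 'endo': 0.5}
```

The nonviable pair (growth 0, below the 0.001 viability threshold) is fixed
by transporting the single compound N; the repaired pair then grows at 10
(the environment's A supply), no faster than its ancestral host. The
knockout screen shows the cost of coupling: the pair needs *both* A and N,
so it survives neither single-compound removal, while each ancestor
survives the removal of the compound it does not use.

Surveys scale this to collections:

```sh
endoflux generate --n-models 40 --p-defective 0.3 --seed 1 --out coll/
endoflux survey-viability --collection coll/ --batches 10 --batch-size 50 \
    --seed 2 --out results/
```

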