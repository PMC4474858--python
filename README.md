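# mixopt

Optimal approximate designs for mixture experiments.

In a mixture experiment the response depends only on the *proportions*
x₁,…,x_q of the ingredients, so the design region is the simplex
{x ∈ [0,1]^q : Σxᵢ = 1} — possibly cut down by per-component bounds
Lᵢ ≤ xᵢ ≤ Uᵢ or pairwise ratio bounds δ ≤ xᵢ/xⱼ ≤ 1/δ.  An *approximate
design* ξ is a small set of blends x₁,…,x_k with weights p₁,…,p_k (the
fraction of runs at each blend).  For a linear model y = β′f(x) + ε its
information matrix is

    M(ξ) = Σᵢ pᵢ f(xᵢ) f(xᵢ)′,

and the classical criteria minimize −ln det M (D-optimality, precise
coefficient estimates), tr M⁻¹ (A), tr L M⁻¹ (L), or the average prediction
variance over the region (I).  The Kiefer–Wolfowitz equivalence theorem
certifies a candidate: ξ is D-optimal iff f(x)′M⁻¹(ξ)f(x) ≤ d everywhere on
the region, with equality on the support; the same maximum yields the
efficiency lower bound d / sup f′M⁻¹f for any design.

`mixopt` is aimed at statisticians and formulation scientists (pharma, food,
chemical blending) who need optimal or provably near-optimal mixture designs
for models that closed-form theory does not cover.  It provides

- **a projection-based particle swarm optimizer** (`run_projpso`): particles
  live in the hypercube [0,1]^{k(q+1)} encoding k candidate points and k raw
  weights; each evaluation projects the particle onto the simplex (and into
  any box/ratio constraints) by block normalization.  A deterministic polish
  (coordinate-wise point exchange + multiplicative weight optimization)
  sharpens the swarm result to ~10⁻⁶;
- **model families**: Scheffé polynomials of any order, Becker's
  homogeneous models (min / ratio / geometric-mean interactions), Kasatkin
  two-component polynomials, incomplete-cubic submodels, and linear
  log-contrast models, plus custom term lists from YAML;
- **equivalence-theorem verification** (`check_equivalence`): lattice sweep
  plus local refinement of the dispersion function, returning a certificate
  and the efficiency lower bound;
- **an independent oracle** (`multiplicative_d_optimal`): the grid-based
  multiplicative algorithm, sharing no search code with the swarm;
- **closed-form reference designs**, multistage design augmentation
  (`augment_design`), and a library of published benchmark designs.

## Worked example

Find and certify the D-optimal design for Becker's geometric-mean model with
three components (7 parameters):

```python
from mixopt import (PSOConfig, DOptimality, build_named_model,
                    check_equivalence, run_projpso)

model = build_named_model("becker1", 3)
design, trace = run_projpso(
    model, DOptimality(),
    config=PSOConfig(n_particles=256, n_iterations=300, seed=1), k=7,
)
print(design)
print(check_equivalence(design, model))
```

```
MixtureDesign(q=3, k=7)
  0.0000  0.0000  1.0000   w=0.1429
  0.0000  0.5000  0.5000   w=0.1429
  0.0000  1.0000  0.0000   w=0.1429
  0.3333  0.3333  0.3333   w=0.1429
  0.5000  0.0000  0.5000   w=0.1429
  0.5000  0.5000  0.0000   w=0.1429
  1.0000  0.0000  0.0000   w=0.1429
EquivalenceReport(OPTIMAL at tol 0.001; max deviation 2.665e-15 at
[0.5 0.5 0. ]; efficiency lower bound 1.0000)
```

The design spends 1/7 of the runs at each of the three pure blends, the
three 50:50 blends and the equal ternary blend; the dispersion maximum over
the whole simplex equals the number of parameters (deviation ~0), which is
exactly the equivalence-theorem condition for D-optimality, so the design
is certified optimal and its efficiency lower bound is 1.

The same workflow from a shell:

```sh
mixopt find --model becker1 --q 3 --criterion D --k 7 --seed 1 --out design.json
mixopt verify design.json --model becker1 --q 3
mixopt efficiency other.json design.json --model becker1 --q 3
mixopt oracle --model becker1 --q 3 --grid-per-factor 101
```

## Benchmarks

`scripts/acceptance.py` re-derives the package's headline benchmark
quantities from scratch — optimal support coordinates and weights for the
Becker, Kasatkin, incomplete-cubic and log-contrast families (each swarm
result certified by the equivalence theorem before use), the A-optimal
weighted simplex-centroid weights, and relative efficiencies / efficiency
bounds of published designs from the bundled library:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object with a value (and the problem size used) per
benchmark id.  See `docs/methods.md` for the algorithms, tolerances and
known caveats, including one published value the bundled design table
provably cannot reproduce.
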