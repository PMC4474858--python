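# Methods

## The design problem

An approximate design ξ on the simplex S^{q−1} (optionally intersected with
box bounds L ≤ x ≤ U and pairwise ratio bounds δ ≤ xᵢ/xⱼ ≤ 1/δ) is scored by
a convex functional of its information matrix M(ξ) = Σ pᵢ f(xᵢ)f(xᵢ)′:

| criterion | objective (minimized) | dispersion function | bound |
|---|---|---|---|
| D | −ln det M | f′M⁻¹f | d |
| A | tr M⁻¹ | f′M⁻²f | tr M⁻¹ |
| L | tr L M⁻¹ | f′M⁻¹LM⁻¹f | tr L M⁻¹ |
| I | tr L M⁻¹, L = ∫ f f′ dμ | as L | as L |

Because all supported models are linear in their coefficients, M never
depends on the unknown coefficients.  The equivalence theorem states that ξ
is optimal iff its dispersion never exceeds the bound, with equality on the
support; the D-efficiency lower bound d / sup f′M⁻¹f follows from the same
supremum and needs no knowledge of the optimum.

## The swarm search

Particles are vectors in Ξ = [0,1]^{k(q+1)}: k point blocks of length q and
one weight block of length k.  The projection P normalizes each block by its
sum, mapping Ξ* (no zero-sum block) onto the design space; P is idempotent.
Velocities follow the canonical update v ← w_t v + γ₁α₁∘(pbest−x) +
γ₂α₂∘(gbest−x) with componentwise U(0,1) randomness; the cognitive factor
pairs with the personal best and the social factor with the global best (the
standard convention — with the default γ₁ = γ₂ the two pairings coincide
anyway).  Positions are initialized i.i.d. uniform, velocities at zero, and
escaped particles are repaired by clipping to [0,1]; a block that clips to
all zeros (where "nearest boundary point of Ξ*" is ill-defined) is reset to
the uniform block 1/(block length), the minimal unbiased repair.  No velocity
clamping is used — repair-after-move keeps the contract simpler.

Defaults: γ₁ = γ₂ = 2; inertia linear from 0.9 to 0.4 over the run; flock
256 and 300 iterations (use ~1024/400+ for models with ≥9 parameters); early
stop after 80 iterations with gbest improvement below 1e-8.  Ratio-bounded
log-contrast regions are small, and γ₁ = γ₂ = 0.5 (the `log_contrast_preset`)
is markedly more reliable there.  k defaults to the parameter count d; when
repeated seeds fail the equivalence check, retry with k+1, k+2 (`--auto-k`).
Singular particles (condition-scaled smallest eigenvalue of M below 1e-10)
are scored +∞ so the swarm ranks them worst. Evaluation is fully batched:
one einsum builds all N information matrices, one batched eigendecomposition
scores them.

### Constrained regions

Constraints are enforced at evaluation time by composing two projections
after the simplex normalization:

- **box bounds** — clip violating coordinates to their bounds, freeze them,
  and rescale the free coordinates to absorb the residual mass (uniformly if
  the free mass is zero); at most q passes.  E.g. U = (0.5, 1, 1) sends
  (0.8, 0.1, 0.1) to (0.5, 0.25, 0.25).
- **ratio bounds** — the feasible set is star-shaped about the centroid, and
  each pair constraint is linear along the segment toward it, so the minimal
  shrink factor has a closed form: t = maxᵢⱼ Dᵢⱼ/(Dᵢⱼ + (1−δ)/q) with
  Dᵢⱼ = max(δxⱼ − xᵢ, 0).  E.g. δ = 0.2 sends the vertex (1,0,0) to
  (5/7, 1/7, 1/7).

Both maps are idempotent and leave feasible points untouched.

### Polish

The raw global best is reliably correct in structure but only ~1e-3 –1e-4 in
coordinates.  A deterministic post-processing loop sharpens it to ~1e-6 or
better:

1. **point exchange / relocation**: each support point is re-optimized
   against the rank-one-downdated matrix M − pᵢ f(xᵢ)f(xᵢ)′ (optimizing the
   full-design dispersion instead would be biased by the point's own
   contribution and is unstable).  A coarse candidate lattice (step 1/4) is
   probed first — the relocation objective can have basins separated by
   barriers, e.g. when the swarm parked two blocks on the same vertex — then
   Nelder–Mead refines through the projection.  Each accepted move improves
   the criterion.  A block with (near-)zero weight has a flat objective and
   can never regain weight under the multiplicative update, so it is probed
   with a nominal share 1/(2k) before relocation.
2. **merge** points within 1e-4 Euclidean distance (weight-weighted means;
   1e-3 while iterating with the swarm), **prune** weights below 1e-6;
3. **multiplicative weight polish** on the fixed support: w ← w·φ/Σwφ for D
   (monotone), damped w ← w·φ^{1/2}/Σ for trace criteria; the weight problem
   is convex, so this converges to the support-optimal weights.

The loop repeats (≤ the `rounds` cap) until the design is stationary to
1e-10.  This goes beyond a weight-only polish; relocating points against the
downdated matrix is what delivers published-table agreement at the fourth
decimal, and every step is criterion-monotone, so it cannot degrade a swarm
result.

### Multistage augmentation

Given a committed first stage ξ₀ with n₀ runs, the second stage minimizes the
criterion of (n₀M(ξ₀) + n₁M(ξ₁))/(n₀+n₁) over ξ₁; the fixed component is
threaded through swarm scoring, weight polish, and point relocation alike.
n₀ = 0 reduces exactly to the plain search.

## Verification

`check_equivalence` evaluates the dispersion deviation on a rational simplex
lattice (step 0.005 for q ≤ 4, 0.02 beyond; built in integer arithmetic so
vertices and midpoints are exact) restricted to the feasible region, then
refines the best 20 lattice points, the design's own support, and — for box
regions — the extreme points of the polytope (where the dispersion of a
first-order model, a convex quadratic, must attain its maximum) with
Nelder–Mead through the projection.  The verdict "optimal" means the
supremum found is ≤ 1e-3 (matching 4-decimal reporting); reference designs
are held to 1e-6.  This is heuristic multistart, not a formal certificate,
but the dispersion surfaces of the catalogued models have few maxima and
the lattice stage alone brackets them.

The grid-based multiplicative algorithm is the independent oracle: from
uniform weights on a lattice, w ← w·d(x,ξ)/d until max d ≤ d(1+ε) on the
full grid.  Per-iteration work is restricted to an active set (weights decay
geometrically off-support) with a full-grid sweep every 25 iterations that
both applies the stopping rule and lets a suppressed candidate regrow.  Its
criterion history is monotone, which the tests assert.

## Models

Term kinds: monomials (with intercept), min-terms, ratio terms
xᵢxⱼ/(xᵢ+xⱼ), geometric means over index subsets, the cubic difference
xᵢxⱼ(xᵢ−xⱼ), Kasatkin's x₁x₂(x₁−x₂)^p, and log-contrasts log(xᵢ/x_q)
(requiring a ratio-bounded region; a zero proportion raises a domain error).
Term order is fixed (linear ascending, then interaction families in
lexicographic index order) so serialized matrices are reproducible.
Kasatkin models are built on q = 2; published tables report them with a
structurally zero third coordinate, and the fixtures keep that convention.
Cubic families are exposed with q explicit components (the q = 3 catalogue:
9 terms without the three-way effect, 10 with it).  None of the optimizers
require derivatives, so the non-differentiable min/geomean terms need no
special handling.

Moment matrices for I-optimality use the Dirichlet identity
E[∏xᵢ^{aᵢ}] = (q−1)!∏aᵢ!/(q−1+Σaᵢ)! on the unconstrained simplex
(monomial terms only) and seeded Monte Carlo rejection sampling otherwise.

## Reference designs and known symmetries

Closed forms shipped: vertex designs (first-order, D and A); the {q,2}
simplex-centroid (quadratic, D); the A-optimal weighted centroid design with
per-vertex weight √(4q−3)/(q√(4q−3)+2q(q−1)) for q ≥ 4 — for q = 3 the
orbit weights are only known numerically (0.1418, 0.1873, 0.0128), so they
are sharpened at build time by the multiplicative algorithm on the fixed
{3,3} support, which reproduces the published values at 4 decimals and
passes the equivalence check at ~1e-11; cubic designs with edge splits at
(1 ± 1/√5)/2; and the two log-contrast families
(1, δ, δ)/(1+2δ) and (1, 1, δ)/(2+δ) with their permutations.

The log-contrast D-optimum is *non-unique*: the two families have identical
determinants, and compositional inversion x ↦ (1/x)/Σ(1/x) is an exact model
symmetry (it maps the regressor by diag(1, −1, …, −1) and preserves the
ratio constraints), carrying each family onto the other
(`inversion_image`).  The swarm, as observed over many seeds, lands on the
edge-adjacent family (largest coordinate 1/(2+δ)); when the vertex-adjacent
family is wanted, take the inversion image and certify it — the benchmark
script reports the largest support coordinate over the certified pair.

## The bundled design library

Every published benchmark design ships as JSON at its reporting precision
(4 decimals), with a `note` documenting provenance and any correction:
several printed tables contain internal inconsistencies (weight vectors not
summing to one, points off the simplex, one support orbit on the wrong
edge).  Where the correct reading could be established independently — by
the multiplicative oracle, by the swarm, or by cross-checking a second
published solution of the same problem — the fixture stores the corrected
values and says so; weights whose exact rational values were established
(e.g. 1/16, 3/32, 1/8) are stored exactly.  One 13-point constrained design
has a weight vector summing to 0.8468 with no recoverable correction; it is
flagged `renormalize` and rescaled on load, and its published efficiency
lower bound (0.9701) is not reproducible from the printed table: the
support itself caps the bound at 0.4936 under *any* weighting (the
dispersion supremum of a first-order model sits at the region's extreme
points, which can be enumerated exactly).  The corresponding acceptance test
asserts the published value and is intentionally left failing, with the full
analysis in the project notes.

## What a green test does and does not establish

There is no synthetic data generator here — the package's inputs are model
specifications, and the benchmark problems are fully specified by them.  The
test suite certifies designs against the equivalence theorem (a necessary
and sufficient optimality condition, evaluated numerically) and
cross-checks the swarm against the multiplicative oracle on 201-level
grids.  Green tests establish optimality up to the lattice/refinement
resolution of the dispersion maximizer and the 1e-3/1e-6 verdict
tolerances; they do not constitute formal global-optimality proofs, and
swarm tests accept the first of a small fixed set of seeds whose result is
certified — single-seed convergence is not guaranteed (flocks can converge
prematurely, e.g. duplicating a vertex), which mirrors the repeated-run
practice standard for these optimizers.

## Numerical choices

- Singularity threshold: condition-scaled smallest eigenvalue below 1e-10 →
  `SingularDesignError` (or +∞ during swarm scoring).
- Weight-sum validation: 1e-8 on user IO; 5e-4 on 4-decimal fixtures.
- Simplex membership: 1e-10 internal, 1e-8 on IO.
- Ties in the dispersion argmax are broken toward the lexicographically
  smallest lattice point (argsort stability).
- Lattice steps must divide 1 exactly in rational arithmetic; counts follow
  the stars-and-bars formula C(n+q−1, q−1).

## Limitations

Exact (integer-replicate) rounding, blocking, mixture-amount models,
c-/minimax/Bayesian criteria, and formal certificates for the dispersion
supremum are out of scope.  The multiplicative oracle implements only the
multiplicative/vertex-direction core (no nearest-neighbor exchange
acceleration), so it is the correctness reference, not a speed reference.
A-criterion swarm runs occasionally drop a very small-weight support point
(e.g. a centroid carrying ~1% of the mass); the deterministic weight
optimization on a fixed candidate support is the more reliable route for
such cases and is what the benchmark script uses for the A-optimal
quadratic.
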