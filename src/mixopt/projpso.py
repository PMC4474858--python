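"""Projection-based particle swarm optimization for mixture designs.

Each particle is a vector in the hypercube ``Xi = [0,1]^{k(q+1)}`` encoding
``k`` unnormalized support points and ``k`` unnormalized weights.  The swarm
moves with the canonical PSO dynamics (inertia plus cognitive and social
pulls with componentwise uniform random scalings), particles leaving the
hypercube are repaired, and every particle is scored by projecting it onto
the simplex (and, when present, into the constrained design region) and
evaluating the design criterion there.  Working in the hypercube keeps the
dynamics unconstrained; the projection does all the geometry.

After the swarm converges, the raw global best is tidied and polished: each
support point is relocated by coordinate ascent against the rank-one
downdated information matrix (with a coarse exchange probe to jump basin
barriers), nearby points are merged, and the weights are sharpened by the
multiplicative algorithm on the fixed support — every step is
criterion-monotone, so polishing can only improve the swarm result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import (
    DesignSpace,
    MixtureDesign,
    ParticleState,
    merge_support,
    project_points_to_space,
    project_to_space,
    prune_weights,
)
from .criteria import (
    Criterion,
    DOptimality,
    IOptimality,
    SINGULARITY_RTOL,
)
from .models import ModelSpec, regressor

__all__ = ["PSOConfig", "SwarmState", "OptimizationFailure", "run_projpso", "augment_design", "polish_design"]


class OptimizationFailure(RuntimeError):
    """Raised when the swarm never found a nonsingular design."""


@dataclass(frozen=True)
class PSOConfig:
    """Tuning parameters of the swarm.

    The defaults follow standard PSO practice: cognitive and social factors
    ``gamma1 = gamma2 = 2`` and an inertia weight decreasing linearly from
    0.9 to 0.4 over the run.  For log-contrast models on tightly
    ratio-constrained regions, ``gamma1 = gamma2 = 0.5`` searches the small
    feasible region more reliably (see :func:`log_contrast_preset`).
    Only ``n_particles`` and ``n_iterations`` usually need adjusting:
    larger for models with more parameters.
    """

    n_particles: int = 256
    n_iterations: int = 300
    gamma1: float = 2.0
    gamma2: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    k: int | None = None
    seed: int | None = None
    #: stop early when gbest improves by less than this for `patience` iters
    ftol: float = 1e-8
    patience: int = 80

    def __post_init__(self) -> None:
        if self.n_particles < 2 or self.n_iterations < 1:
            raise ValueError("need at least 2 particles and 1 iteration")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("learning factors must be positive")
        if not (0 < self.inertia_end <= self.inertia_start < 1):
            raise ValueError("inertia schedule must satisfy 0 < w_end <= w_start < 1")

    def inertia(self, t: int) -> float:
        """Linear schedule w_t from ``inertia_start`` down to ``inertia_end``."""
        if self.n_iterations == 1:
            return self.inertia_start
        frac = t / (self.n_iterations - 1)
        return self.inertia_start + frac * (self.inertia_end - self.inertia_start)


def log_contrast_preset(**overrides) -> PSOConfig:
    """Swarm settings that work well for ratio-constrained log-contrast
    models: gentle learning factors gamma1 = gamma2 = 0.5."""
    defaults = dict(gamma1=0.5, gamma2=0.5)
    defaults.update(overrides)
    return PSOConfig(**defaults)


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping for the flock."""

    positions: np.ndarray  # (N, m)
    velocities: np.ndarray  # (N, m)
    pbest_pos: np.ndarray  # (N, m)
    pbest_val: np.ndarray  # (N,)
    gbest_pos: np.ndarray  # (m,)
    gbest_val: float
    t: int
    k: int
    q: int

    def gbest_particle(self) -> ParticleState:
        return ParticleState(k=self.k, q=self.q, raw=self.gbest_pos.copy())


def _repair(positions: np.ndarray, k: int, q: int) -> np.ndarray:
    """Bring escaped particles back into the admissible set Xi*.

    Entries are clipped to [0, 1]; any block that collapses to an all-zero
    sum after clipping is reset to the uniform vector 1/(block length) —
    the minimal unbiased repair (a nearest boundary point is ill-defined
    for a zero block).
    """
    x = np.clip(positions, 0.0, 1.0)
    pts = x[:, : k * q].reshape(-1, k, q)
    psums = pts.sum(axis=2)
    dead = psums <= 0.0
    if dead.any():
        pts = np.where(dead[:, :, None], 1.0 / q, pts)
        x[:, : k * q] = pts.reshape(-1, k * q)
    w = x[:, k * q :]
    wdead = w.sum(axis=1) <= 0.0
    if wdead.any():
        x[wdead, k * q :] = 1.0 / k
    return x


class _Evaluator:
    """Batched particle scoring: project all particles, build all information
    matrices with one einsum, score with batched determinants/inverses.
    Singular particles rank worst (+inf)."""

    def __init__(
        self,
        model: ModelSpec,
        criterion: Criterion,
        space: DesignSpace,
        k: int,
        M0: np.ndarray | None = None,
        w0: float = 0.0,
    ):
        self.model = model
        self.criterion = (
            criterion.resolve(model) if isinstance(criterion, IOptimality) else criterion
        )
        self.space = space
        self.k = k
        self.q = model.q
        self.M0 = M0  # fixed first-stage information, already weighted by w0
        self.w0 = w0  # fraction of total runs already committed to stage one

    def designs_from_positions(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized projection: positions (N, m) -> points (N, k, q),
        weights (N, k).  Assumes repaired input (no zero blocks)."""
        N = positions.shape[0]
        pts = positions[:, : self.k * self.q].reshape(N, self.k, self.q)
        pts = pts / pts.sum(axis=2, keepdims=True)
        if not self.space.is_unconstrained:
            flat = project_points_to_space(pts.reshape(-1, self.q), self.space)
            pts = flat.reshape(N, self.k, self.q)
        w = positions[:, self.k * self.q :]
        w = w / w.sum(axis=1, keepdims=True)
        return pts, w

    def info_matrices(self, pts: np.ndarray, w: np.ndarray) -> np.ndarray:
        N = pts.shape[0]
        F = regressor(self.model, pts.reshape(-1, self.q)).reshape(N, self.k, -1)
        M = np.einsum("nkd,nk,nke->nde", F, w, F, optimize=True)
        if self.M0 is not None:
            M = self.w0 * self.M0[None, :, :] + (1.0 - self.w0) * M
        return M

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        pts, w = self.designs_from_positions(positions)
        M = self.info_matrices(pts, w)
        return self.score(M)

    def score(self, M: np.ndarray) -> np.ndarray:
        eigs = np.linalg.eigvalsh(M)
        singular = (eigs[:, 0] <= SINGULARITY_RTOL * np.maximum(eigs[:, -1], 0)) | (
            eigs[:, 0] <= 0
        )
        vals = np.full(M.shape[0], np.inf)
        ok = ~singular
        if ok.any():
            if isinstance(self.criterion, DOptimality):
                vals[ok] = -np.log(eigs[ok]).sum(axis=1)
            else:
                L = self.criterion.L_matrix(self.model)
                Minv = np.linalg.inv(M[ok])
                vals[ok] = np.einsum("de,ned->n", L, Minv)
        return vals

    def design_value(self, design: MixtureDesign) -> float:
        F = regressor(self.model, design.points)
        M = F.T @ (design.weights[:, None] * F)
        if self.M0 is not None:
            M = self.w0 * self.M0 + (1.0 - self.w0) * M
        return float(self.score(M[None])[0])


def pso_step(
    state: SwarmState,
    config: PSOConfig,
    evaluate,
    rng: np.random.Generator,
) -> SwarmState:
    """One synchronous swarm update.

    Velocity: ``v <- w_t v + gamma1 a1 ∘ (pbest - x) + gamma2 a2 ∘ (gbest - x)``
    with fresh uniform(0,1) vectors a1, a2 per particle and component
    (Hadamard products).  Positions move by the velocity, are repaired into
    Xi*, and pbest/gbest are refreshed.  gbest never worsens.
    """
    N, m = state.positions.shape
    w_t = config.inertia(state.t)
    a1 = rng.uniform(size=(N, m))
    a2 = rng.uniform(size=(N, m))
    vel = (
        w_t * state.velocities
        + config.gamma1 * a1 * (state.pbest_pos - state.positions)
        + config.gamma2 * a2 * (state.gbest_pos[None, :] - state.positions)
    )
    pos = _repair(state.positions + vel, state.k, state.q)
    vals = evaluate(pos)
    improved = vals < state.pbest_val
    pbest_pos = np.where(improved[:, None], pos, state.pbest_pos)
    pbest_val = np.where(improved, vals, state.pbest_val)
    ibest = int(np.argmin(pbest_val))
    if pbest_val[ibest] < state.gbest_val:
        gbest_pos = pbest_pos[ibest].copy()
        gbest_val = float(pbest_val[ibest])
    else:
        gbest_pos, gbest_val = state.gbest_pos, state.gbest_val
    return SwarmState(
        positions=pos,
        velocities=vel,
        pbest_pos=pbest_pos,
        pbest_val=pbest_val,
        gbest_pos=gbest_pos,
        gbest_val=gbest_val,
        t=state.t + 1,
        k=state.k,
        q=state.q,
    )


def _init_swarm(
    k: int, q: int, config: PSOConfig, evaluate, rng: np.random.Generator
) -> SwarmState:
    m = k * (q + 1)
    pos = _repair(rng.uniform(size=(config.n_particles, m)), k, q)
    vel = np.zeros_like(pos)
    vals = evaluate(pos)
    ibest = int(np.argmin(vals))
    return SwarmState(
        positions=pos,
        velocities=vel,
        pbest_pos=pos.copy(),
        pbest_val=vals.copy(),
        gbest_pos=pos[ibest].copy(),
        gbest_val=float(vals[ibest]),
        t=0,
        k=k,
        q=q,
    )


def multiplicative_weight_polish(
    model: ModelSpec,
    criterion: Criterion,
    points: np.ndarray,
    space: DesignSpace | None = None,
    weights: np.ndarray | None = None,
    max_iters: int = 20000,
    tol: float = 1e-10,
    M0: np.ndarray | None = None,
    w0: float = 0.0,
) -> np.ndarray:
    """Optimize the weights on a fixed support by multiplicative updates.

    For D the update is ``w_i <- w_i d_i / d`` (d_i the dispersion at the
    i-th point), which is monotone; for trace-type criteria the damped
    update ``w_i ∝ w_i (phi_i / bound)^{1/2}`` is used.  The weight problem
    is convex, so this converges to the optimal weights for the support.
    """
    criterion = (
        criterion.resolve(model) if isinstance(criterion, IOptimality) else criterion
    )
    F = regressor(model, points)
    r, d = F.shape
    w = np.full(r, 1.0 / r) if weights is None else np.asarray(weights, float).copy()
    # exact zeros are absorbing states of the multiplicative update; floor
    # them so a relocated support point can earn weight back
    w = np.maximum(w, 1e-10)
    w = w / w.sum()
    Lmat = None if isinstance(criterion, DOptimality) else criterion.L_matrix(model)
    for _ in range(max_iters):
        M = F.T @ (w[:, None] * F)
        if M0 is not None:
            M = w0 * M0 + (1.0 - w0) * M
        eigs, V = np.linalg.eigh(M)
        if eigs[0] <= SINGULARITY_RTOL * max(eigs[-1], 0):
            # singular support matrix: nothing to polish
            return w
        Minv = (V / eigs) @ V.T
        if Lmat is None:
            phi = np.einsum("rd,de,re->r", F, Minv, F)
            bound = float(d) if M0 is None else float(np.sum((1.0 - w0) * phi * w))
            new = w * phi
        else:
            A = Minv @ Lmat @ Minv
            phi = np.einsum("rd,de,re->r", F, A, F)
            new = w * np.sqrt(np.maximum(phi, 0.0))
        s = new.sum()
        if s <= 0:
            return w
        new = new / s
        if np.max(np.abs(new - w)) < tol:
            w = new
            break
        w = new
    return w


def refine_support(
    model: ModelSpec,
    criterion: Criterion,
    design: MixtureDesign,
    space: DesignSpace,
    M0: np.ndarray | None = None,
    w0: float = 0.0,
) -> MixtureDesign:
    """Sharpen each support point by exact coordinate ascent on the criterion.

    Moving a single point x_i (weight fixed) changes the information matrix
    to ``M_rest + p_i f(x) f(x)'``, so the best relocation of that point
    optimizes the criterion of this rank-one update — a smooth scalar
    objective minimized with Nelder-Mead through the simplex projection.
    Each accepted move improves the criterion, so the sweep is monotone.
    (Optimizing the full-design dispersion instead would be biased by the
    point's own contribution to M.)
    """
    crit = criterion.resolve(model) if isinstance(criterion, IOptimality) else criterion
    Lmat = None if isinstance(crit, DOptimality) else crit.L_matrix(model)

    def value_of(M: np.ndarray) -> float:
        eigs = np.linalg.eigvalsh(M)
        if eigs[0] <= SINGULARITY_RTOL * max(eigs[-1], 0):
            return np.inf
        if Lmat is None:
            return -float(np.log(eigs).sum())
        w_, V = np.linalg.eigh(M)
        return float(np.sum(Lmat * ((V / w_) @ V.T)))

    pts = design.points.copy()
    wts = design.weights
    F = regressor(model, pts)
    M_full = F.T @ (wts[:, None] * F)
    # coarse exchange candidates (vertices, edge splits, centroids): the
    # relocation objective can have basins separated by barriers — e.g. a
    # duplicated support point is locally stuck — so each point also
    # considers a Fedorov-style jump to the best coarse candidate
    from .verify import simplex_lattice

    try:
        cand = simplex_lattice(model.q, 0.25, space if not space.is_unconstrained else None)
    except ValueError:
        cand = pts.copy()
    cand = project_points_to_space(cand, space)
    for i in range(design.k):
        f_i = regressor(model, pts[i])
        M_rest = M_full - wts[i] * np.outer(f_i, f_i)
        # a (nearly) weightless point has a flat relocation objective and can
        # never be revived by the multiplicative weight update; probe it with
        # a nominal share so the exchange step can park it somewhere useful
        w_probe = wts[i] if wts[i] > 1e-4 else 0.5 / design.k

        def objective(u: np.ndarray) -> float:
            u = np.abs(u)
            s = u.sum()
            if s <= 0:
                return np.inf
            x = project_points_to_space((u / s)[None, :], space)[0]
            f = regressor(model, x)
            M = M_rest + w_probe * np.outer(f, f)
            if M0 is not None:
                M = w0 * M0 + (1.0 - w0) * M
            return value_of(M)

        current = objective(pts[i])
        cand_vals = np.array([objective(c) for c in cand])
        start = pts[i]
        if cand_vals.min() < current:
            start = cand[int(cand_vals.argmin())]
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-14, "maxiter": 300 * model.q},
        )
        if np.isfinite(res.fun) and res.fun <= current:
            u = np.abs(res.x)
            new_pt = project_points_to_space((u / u.sum())[None, :], space)[0]
            pts[i] = new_pt
            f_new = regressor(model, new_pt)
            M_full = M_rest + wts[i] * np.outer(f_new, f_new)
    return MixtureDesign(pts, wts)


def polish_design(
    model: ModelSpec,
    criterion: Criterion,
    design: MixtureDesign,
    space: DesignSpace | None = None,
    rounds: int = 3,
    merge_tol: float = 1e-4,
    prune_eps: float = 1e-6,
    M0: np.ndarray | None = None,
    w0: float = 0.0,
) -> MixtureDesign:
    """Deterministic post-processing of a swarm result: alternate support
    refinement (dispersion maxima), support merging, weight pruning and
    multiplicative weight polish until the design is stationary."""
    space = space or DesignSpace(model.q)
    out = design
    for _ in range(rounds):
        prev = out
        out = refine_support(model, criterion, out, space, M0=M0, w0=w0)
        out = merge_support(out, merge_tol)
        w = multiplicative_weight_polish(
            model, criterion, out.points, space, weights=out.weights, M0=M0, w0=w0
        )
        out = MixtureDesign(out.points, w)
        try:
            out = prune_weights(out, prune_eps)
        except ValueError:
            pass
        if (
            out.k == prev.k
            and np.max(np.abs(out.sorted().points - prev.sorted().points)) < 1e-10
            and np.max(np.abs(out.sorted().weights - prev.sorted().weights)) < 1e-10
        ):
            break
    return out.sorted()


def run_projpso(
    model: ModelSpec,
    criterion: Criterion | None = None,
    space: DesignSpace | None = None,
    config: PSOConfig | None = None,
    k: int | None = None,
    polish: bool = True,
    merge_tol: float = 1e-4,
    prune_eps: float = 1e-6,
    _M0: np.ndarray | None = None,
    _w0: float = 0.0,
) -> tuple[MixtureDesign, np.ndarray]:
    """Search for an optimal approximate design with the projected swarm.

    Returns the tidied global-best design and the trace of global-best
    criterion values per iteration (monotone non-increasing).  ``k``
    defaults to the number of model parameters ``d`` (an optimal design
    needs at least ``d`` support points for a nonsingular D-criterion);
    pass a larger ``k`` when repeated runs fail the equivalence check.
    """
    criterion = criterion or DOptimality()
    space = space or DesignSpace(model.q)
    config = config or PSOConfig()
    k = k or config.k or model.d
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(model, criterion, space, k, M0=_M0, w0=_w0)
    state = _init_swarm(k, model.q, config, evaluator, rng)
    trace = [state.gbest_val]
    stall = 0
    for _ in range(config.n_iterations):
        prev = state.gbest_val
        state = pso_step(state, config, evaluator, rng)
        trace.append(state.gbest_val)
        stall = stall + 1 if prev - state.gbest_val < config.ftol else 0
        if stall >= config.patience:
            break
    if not np.isfinite(state.gbest_val):
        raise OptimizationFailure(
            f"no nonsingular design found with k={k} after {state.t} iterations; "
            "increase k or the flock size"
        )
    from .core import project_particle

    design = project_particle(state.gbest_particle())
    design = project_to_space(design, space)
    if polish:
        # merge only after the first refinement sweep: a duplicated support
        # block still carries weight the coordinate ascent can relocate
        design = polish_design(
            model,
            criterion,
            design,
            space,
            merge_tol=merge_tol,
            prune_eps=prune_eps,
            M0=_M0,
            w0=_w0,
        )
    else:
        try:
            design = prune_weights(design, prune_eps)
        except ValueError:
            pass
        design = merge_support(design, merge_tol).sorted()
    return design, np.asarray(trace)


def augment_design(
    initial: MixtureDesign,
    n0: int,
    n1: int,
    model: ModelSpec,
    criterion: Criterion | None = None,
    space: DesignSpace | None = None,
    config: PSOConfig | None = None,
    k: int | None = None,
    polish: bool = True,
) -> tuple[MixtureDesign, np.ndarray]:
    """Second-stage (augmentation) design search.

    Given an already-run first stage ``initial`` with ``n0`` observations,
    find the ``n1``-observation second stage ``xi_1`` minimizing the
    criterion of the combined information
    ``(n0 M(xi_0) + n1 M(xi_1)) / (n0 + n1)``.  With ``n0 = 0`` this is a
    plain design search.
    """
    if n0 < 0 or n1 <= 0:
        raise ValueError("need n0 >= 0 and n1 > 0")
    criterion = criterion or DOptimality()
    if n0 == 0:
        return run_projpso(model, criterion, space, config, k=k, polish=polish)
    from .models import information_matrix

    M0 = information_matrix(model, initial)
    w0 = n0 / (n0 + n1)
    return run_projpso(
        model, criterion, space, config, k=k, polish=polish, _M0=M0, _w0=w0
    )
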