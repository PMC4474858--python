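"""Grid-based multiplicative optimizer and closed-form reference designs.

The multiplicative algorithm optimizes the design weights over a fixed
candidate grid: for D-optimality the update ``w_i <- w_i d(x_i, xi) / d``
is monotone in the criterion and converges to the optimal weights on the
grid.  Combined with a fine simplex lattice it serves as an independent
oracle for the swarm optimizer: the two approaches share no code path
beyond the information matrix itself.

``reference_design`` returns designs whose optimality is known analytically
(or, for the 3-component A-optimal quadratic, established numerically in
the literature): vertex designs for first-order models, simplex-centroid
designs for the quadratic, the cubic designs with edge coordinate
``(1 - 1/sqrt 5)/2``, and the two equally weighted support families of the
ratio-constrained linear log-contrast model.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import DesignSpace, MixtureDesign, merge_support, prune_weights
from .criteria import (
    Criterion,
    DOptimality,
    SINGULARITY_RTOL,
    SingularDesignError,
)
from .models import ModelSpec, regressor, scheffe
from .verify import simplex_lattice

__all__ = ["multiplicative_d_optimal", "reference_design", "grid_from_per_factor"]


def grid_from_per_factor(q: int, points_per_factor: int, space: DesignSpace | None = None) -> np.ndarray:
    """A simplex lattice described the way grid-exchange algorithms do:
    ``points_per_factor`` uniformly spaced levels per component
    (101 levels corresponds to step 0.01)."""
    step = 1.0 / (points_per_factor - 1)
    return simplex_lattice(q, step, space)


def multiplicative_d_optimal(
    model: ModelSpec,
    grid: np.ndarray,
    eps: float = 1e-6,
    max_iters: int = 100_000,
    merge_tol: float = 1e-4,
    prune_eps: float = 1e-6,
    return_history: bool = False,
):
    """D-optimal weights over a candidate grid by multiplicative updates.

    Starts uniform, iterates ``w_i <- w_i d(x_i)/d`` and stops when the
    equivalence-style rule ``max_i d(x_i)/d <= 1 + eps`` holds on the grid.
    Returns the pruned, merged design (and the criterion history when
    requested; the history is non-increasing).
    """
    grid = np.asarray(grid, float)
    F = regressor(model, grid)
    r, d = F.shape
    w = np.full(r, 1.0 / r)
    M = F.T @ (w[:, None] * F)
    eigs = np.linalg.eigvalsh(M)
    if eigs[0] <= SINGULARITY_RTOL * max(eigs[-1], 0):
        raise SingularDesignError(
            "candidate grid does not span the model: uniform-start matrix singular"
        )
    history = []
    # Active-set acceleration: the multiplicative update drives most grid
    # weights to zero geometrically, so per-iteration work is restricted to
    # the currently weighted candidates; every `check_every` iterations the
    # dispersion is swept over the *full* grid — this is the stopping rule
    # and also lets a suppressed candidate with dispersion above d regrow.
    check_every = 25
    active = np.ones(r, dtype=bool)
    for it in range(max_iters):
        idx = np.flatnonzero(active)
        Fa = F[idx]
        wa = w[idx]
        M = Fa.T @ (wa[:, None] * Fa)
        eigs, V = np.linalg.eigh(M)
        if eigs[0] <= SINGULARITY_RTOL * max(eigs[-1], 0):
            raise SingularDesignError("weights collapsed to a singular design")
        if return_history:
            history.append(-float(np.log(eigs).sum()))
        Minv = (V / eigs) @ V.T
        if it % check_every == 0:
            disp_full = np.einsum("rd,de,re->r", F, Minv, F)
            if disp_full.max() / d <= 1.0 + eps:
                break
            w = w * disp_full / d
            w = w / w.sum()
            active = w > 1e-12 / r
        else:
            disp = np.einsum("rd,de,re->r", Fa, Minv, Fa)
            wa = wa * disp / d
            w[:] = 0.0
            w[idx] = wa / wa.sum()
    keep = w > 0
    design = MixtureDesign(grid[keep], w[keep])
    try:
        design = prune_weights(design, prune_eps)
    except ValueError:
        pass
    design = merge_support(design, merge_tol)
    if return_history:
        return design, np.asarray(history)
    return design


# ---------------------------------------------------------------------------
# closed-form reference designs


def _vertices(q: int) -> np.ndarray:
    return np.eye(q)


def _face_centroids(q: int, r: int) -> np.ndarray:
    """Centroids of all (r-1)-dimensional faces: points with r coordinates
    equal to 1/r."""
    pts = []
    for comb in itertools.combinations(range(q), r):
        x = np.zeros(q)
        x[list(comb)] = 1.0 / r
        pts.append(x)
    return np.array(pts)


def simplex_centroid_design(q: int, depth: int) -> MixtureDesign:
    """The equally weighted {q, depth} simplex-centroid design (vertices,
    edge midpoints, ... up to depth-way centroids)."""
    pts = np.vstack([_face_centroids(q, r) for r in range(1, depth + 1)])
    k = pts.shape[0]
    return MixtureDesign(pts, np.full(k, 1.0 / k))


def _a_optimal_quadratic(q: int) -> MixtureDesign:
    if q == 3:
        # numerically established {3,3} weighted centroid design; orbit
        # weights sharpened on the fixed support so the design passes the
        # equivalence check to high precision (printed values: vertex
        # 0.1418, edge midpoint 0.1873, centroid 0.0128)
        from .criteria import AOptimality
        from .projpso import multiplicative_weight_polish

        pts = np.vstack([_face_centroids(3, 1), _face_centroids(3, 2), _face_centroids(3, 3)])
        w0 = np.concatenate([np.full(3, 0.1418), np.full(3, 0.1873), [0.0128]])
        w = multiplicative_weight_polish(
            scheffe(3, 2), AOptimality(), pts, weights=w0 / w0.sum(), tol=1e-14
        )
        return MixtureDesign(pts, w)
    if q < 4:
        raise ValueError("A-optimal quadratic reference needs q = 3 or q >= 4")
    root = np.sqrt(4.0 * q - 3.0)
    r1 = root / (q * root + 2.0 * q * (q - 1.0))  # weight per vertex
    r2 = 4.0 * r1 / root  # weight per edge midpoint
    pts = np.vstack([_face_centroids(q, 1), _face_centroids(q, 2)])
    n_edges = q * (q - 1) // 2
    w = np.concatenate([np.full(q, r1), np.full(n_edges, r2)])
    return MixtureDesign(pts, w / w.sum())


_EDGE_CUBIC = 0.5 * (1.0 - 1.0 / np.sqrt(5.0))  # ~0.2764, the cubic edge split


def _cubic_edge_points(q: int) -> np.ndarray:
    pts = []
    for i, j in itertools.permutations(range(q), 2):
        x = np.zeros(q)
        x[i] = 1.0 - _EDGE_CUBIC
        x[j] = _EDGE_CUBIC
        pts.append(x)
    return np.array(pts)


def _cubic_no3way_design(q: int) -> MixtureDesign:
    pts = np.vstack([_vertices(q), _cubic_edge_points(q)])
    k = pts.shape[0]
    return MixtureDesign(pts, np.full(k, 1.0 / k))


def _cubic_full_design(q: int) -> MixtureDesign:
    pts = np.vstack([_vertices(q), _cubic_edge_points(q), _face_centroids(q, 3)])
    k = pts.shape[0]
    return MixtureDesign(pts, np.full(k, 1.0 / k))


def log_contrast_supports(q: int, delta: float, family: int = 1) -> np.ndarray:
    """The two support families of the D-optimal design for the 3-component
    linear log-contrast model with ratio bound delta.

    Family 1 puts one large coordinate ``1/(1+2 delta)`` against two small
    ones; family 2 puts two large coordinates ``1/(2+delta)`` against one
    small one.  Both are D-optimal with equal determinant.
    """
    if q != 3:
        raise ValueError("closed-form log-contrast designs are known for q = 3")
    if family == 1:
        big, small = 1.0 / (1.0 + 2.0 * delta), delta / (1.0 + 2.0 * delta)
        base = np.array([big, small, small])
    elif family == 2:
        big, small = 1.0 / (2.0 + delta), delta / (2.0 + delta)
        base = np.array([big, big, small])
    else:
        raise ValueError("family must be 1 or 2")
    return np.array([np.roll(base, shift) for shift in range(3)])


def inversion_image(design: MixtureDesign) -> MixtureDesign:
    """The compositional-inversion image of a design: each support point is
    replaced by its normalized coordinatewise reciprocal.

    For the linear log-contrast model this is an exact model symmetry: the
    regressor maps as ``f(y) = R f(x)`` with ``R = diag(1, -1, ..., -1)``,
    so determinants of information matrices are preserved, and the pairwise
    ratio constraints are invariant.  Hence the image of a D-optimal design
    is again D-optimal — this is how the two known optimal support families
    map onto each other.  Requires strictly positive coordinates.
    """
    if np.any(design.points <= 0):
        raise ValueError("inversion requires strictly positive coordinates")
    inv = 1.0 / design.points
    inv = inv / inv.sum(axis=1, keepdims=True)
    return MixtureDesign(inv, design.weights)


def reference_design(
    name: str,
    q: int,
    criterion: str = "D",
    delta: float | None = None,
    family: int = 1,
) -> MixtureDesign:
    """Analytic (or literature-established) optimal designs.

    Catalogue:

    - ``linear``: the q vertices, equal weights (both D- and A-optimal)
    - ``quadratic`` with D: the {q, 2} simplex-centroid, equal weights
    - ``quadratic`` with A: the weighted centroid design with vertex weight
      ``sqrt(4q-3) / (q sqrt(4q-3) + 2q(q-1))`` for q >= 4, numeric orbit
      weights for q = 3
    - ``cubic_no3way`` / ``cubic_full`` with D: vertices, the
      (1 ± 1/sqrt 5)/2 edge splits, and (full model) the face centroids
    - ``logcontrast`` with D: the equally weighted 3-point family (needs
      ``delta``)
    """
    crit = criterion.upper()
    name = name.lower()
    if name == "linear":
        if crit not in ("D", "A"):
            raise ValueError("linear reference designs cover D and A")
        return MixtureDesign(_vertices(q), np.full(q, 1.0 / q))
    if name == "quadratic":
        if crit == "D":
            return simplex_centroid_design(q, 2)
        if crit == "A":
            return _a_optimal_quadratic(q)
        raise ValueError("quadratic reference designs cover D and A")
    if name == "cubic_no3way":
        if crit != "D":
            raise ValueError("cubic reference designs are D-optimal")
        return _cubic_no3way_design(q)
    if name == "cubic_full":
        if crit != "D":
            raise ValueError("cubic reference designs are D-optimal")
        return _cubic_full_design(q)
    if name == "logcontrast":
        if crit != "D":
            raise ValueError("log-contrast reference designs are D-optimal")
        if delta is None:
            raise ValueError("log-contrast reference designs need delta")
        pts = log_contrast_supports(q, delta, family)
        return MixtureDesign(pts, np.full(3, 1.0 / 3.0))
    raise ValueError(f"no closed-form reference design named {name!r}")
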