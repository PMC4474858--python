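"""Design containers, the simplex projection operator, and support housekeeping.

An approximate design for a mixture experiment with ``q`` components is a
probability measure with finite support on the regular simplex
``S^{q-1} = {x in [0,1]^q : sum x_i = 1}``: a set of support points (the
blends to run) and a weight vector (the fraction of the experimental effort
spent at each blend).  The swarm optimizer searches the hypercube
``Xi = [0,1]^{k(q+1)}`` and maps candidate vectors onto designs with the
block-normalization projection implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixtureDesign",
    "DesignSpace",
    "ParticleState",
    "InvalidParticleError",
    "InfeasibleSpaceError",
    "project_particle",
    "project_points_to_space",
    "project_to_space",
    "merge_support",
    "prune_weights",
]

SIMPLEX_ATOL = 1e-10


class InvalidParticleError(ValueError):
    """Raised when a particle vector lies outside the admissible set Xi*."""


class InfeasibleSpaceError(ValueError):
    """Raised when a constrained design region is empty or inconsistent."""


@dataclass(frozen=True)
class MixtureDesign:
    """An approximate design: ``k`` support points on the simplex plus weights.

    Parameters
    ----------
    points
        Array of shape ``(k, q)``; each row is a composition (nonnegative
        proportions summing to one).
    weights
        Length-``k`` probability vector.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        w = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 2:
            raise ValueError("points must be a (k, q) array with k >= 1, q >= 2")
        if w.shape[0] != pts.shape[0]:
            raise ValueError("weights length must match number of points")
        if np.any(pts < -SIMPLEX_ATOL):
            raise ValueError("design points must have nonnegative coordinates")
        if not np.allclose(pts.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each design point must sum to 1")
        if np.any(w < -SIMPLEX_ATOL):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.10f})")
        # snap tiny negatives and renormalize the last digit of rounding noise
        pts = np.clip(pts, 0.0, None)
        pts = pts / pts.sum(axis=1, keepdims=True)
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return self.points.shape[0]

    @property
    def q(self) -> int:
        return self.points.shape[1]

    def sorted(self) -> "MixtureDesign":
        """Return a copy with support points in lexicographic order
        (keys rounded to 12 decimals so numerical dust cannot reorder)."""
        order = np.lexsort(np.round(self.points, 12).T[::-1])
        return MixtureDesign(self.points[order], self.weights[order])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rows = [
            "  " + "  ".join(f"{c:.4f}" for c in p) + f"   w={w:.4f}"
            for p, w in zip(self.points, self.weights)
        ]
        return f"MixtureDesign(q={self.q}, k={self.k})\n" + "\n".join(rows)


@dataclass(frozen=True)
class DesignSpace:
    """The design region: the simplex, optionally cut by box or ratio bounds.

    Box bounds restrict each component to ``L_i <= x_i <= U_i``; the ratio
    bound ``delta`` (used with log-contrast models) requires
    ``delta <= x_i / x_j <= 1/delta`` for every pair of components.
    """

    q: int
    lower: np.ndarray = None  # type: ignore[assignment]
    upper: np.ndarray = None  # type: ignore[assignment]
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.q < 2:
            raise InfeasibleSpaceError("q must be >= 2")
        lo = np.zeros(self.q) if self.lower is None else np.asarray(self.lower, float)
        hi = np.ones(self.q) if self.upper is None else np.asarray(self.upper, float)
        if lo.shape != (self.q,) or hi.shape != (self.q,):
            raise InfeasibleSpaceError("bounds must have length q")
        if np.any(lo < 0) or np.any(hi > 1) or np.any(lo >= hi):
            raise InfeasibleSpaceError("bounds must satisfy 0 <= L_i < U_i <= 1")
        if lo.sum() > 1 + SIMPLEX_ATOL or hi.sum() < 1 - SIMPLEX_ATOL:
            raise InfeasibleSpaceError("box constraints leave no feasible composition")
        if self.delta is not None:
            if not (0.0 < self.delta < 1.0):
                raise InfeasibleSpaceError("delta must lie strictly in (0, 1)")
            centroid = np.full(self.q, 1.0 / self.q)
            if np.any(centroid < lo - SIMPLEX_ATOL) or np.any(centroid > hi + SIMPLEX_ATOL):
                raise InfeasibleSpaceError("centroid infeasible: box and ratio bounds conflict")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def is_unconstrained(self) -> bool:
        return (
            self.delta is None
            and np.all(self.lower == 0.0)
            and np.all(self.upper == 1.0)
        )

    def contains(self, x: np.ndarray, atol: float = 1e-8) -> np.ndarray:
        """Vectorized feasibility check for an ``(n, q)`` array of compositions."""
        x = np.atleast_2d(np.asarray(x, float))
        ok = np.abs(x.sum(axis=1) - 1.0) <= max(atol, 1e-8)
        ok &= np.all(x >= self.lower - atol, axis=1)
        ok &= np.all(x <= self.upper + atol, axis=1)
        if self.delta is not None:
            ok &= x.min(axis=1) >= self.delta * x.max(axis=1) - atol
        return ok


@dataclass
class ParticleState:
    """A raw swarm position: ``k`` unnormalized points plus unnormalized weights.

    The vector has length ``m = k (q + 1)``: the first ``k`` blocks of length
    ``q`` encode candidate points, the trailing block of length ``k`` encodes
    weights.  Membership in the admissible set Xi* requires every block to
    have a positive sum (otherwise normalization is undefined).
    """

    k: int
    q: int
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float).ravel()
        if self.raw.shape[0] != self.m:
            raise ValueError(f"raw vector must have length k(q+1) = {self.m}")

    @property
    def m(self) -> int:
        return self.k * (self.q + 1)

    def point_blocks(self) -> np.ndarray:
        return self.raw[: self.k * self.q].reshape(self.k, self.q)

    def weight_block(self) -> np.ndarray:
        return self.raw[self.k * self.q :]

    def in_admissible_set(self, atol: float = 0.0) -> bool:
        if np.any(self.raw < -atol) or np.any(self.raw > 1 + atol):
            return False
        if np.any(self.point_blocks().sum(axis=1) <= 0):
            return False
        return self.weight_block().sum() > 0


def project_particle(particle: ParticleState) -> MixtureDesign:
    """Map a raw hypercube vector onto a design by per-block normalization.

    Each point block is divided by its sum and the weight block by its sum;
    the map is idempotent (applying it to the flattened result is a no-op).

    Raises
    ------
    InvalidParticleError
        If any block sums to zero (the particle lies outside Xi*); callers
        must repair such particles before projecting.
    """
    pts = particle.point_blocks()
    w = particle.weight_block()
    psums = pts.sum(axis=1)
    wsum = w.sum()
    if np.any(psums <= 0) or wsum <= 0:
        raise InvalidParticleError("particle outside Xi*: a block sums to zero")
    return MixtureDesign(pts / psums[:, None], w / wsum)


def flatten_design(design: MixtureDesign) -> ParticleState:
    """Encode a design as a particle (the right inverse of the projection)."""
    raw = np.concatenate([design.points.ravel(), design.weights])
    return ParticleState(k=design.k, q=design.q, raw=raw)


def _project_box(points: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Clip-and-redistribute points into the box-constrained simplex.

    Violating coordinates are fixed at their bounds; the remaining mass is
    spread over the free coordinates in proportion to their current values
    (uniformly if they are all zero).  At most ``q`` passes are needed since
    each pass fixes at least one coordinate.
    """
    q = points.shape[1]
    x = np.clip(points, lower, upper)
    fixed = np.zeros_like(x, dtype=bool)
    for _ in range(q + 1):
        resid = 1.0 - np.where(fixed, x, 0.0).sum(axis=1)
        free_sum = np.where(~fixed, x, 0.0).sum(axis=1)
        n_free = (~fixed).sum(axis=1)
        scale = np.where(free_sum > 0, resid / np.where(free_sum > 0, free_sum, 1.0), 0.0)
        uniform = np.where(n_free > 0, resid / np.maximum(n_free, 1), 0.0)
        x = np.where(fixed, x, np.where(free_sum[:, None] > 0, x * scale[:, None], uniform[:, None]))
        low_viol = ~fixed & (x < lower - SIMPLEX_ATOL)
        high_viol = ~fixed & (x > upper + SIMPLEX_ATOL)
        if not (low_viol.any() or high_viol.any()):
            break
        x = np.where(low_viol, lower, x)
        x = np.where(high_viol, upper, x)
        fixed |= low_viol | high_viol
    return x


def _project_ratio(points: np.ndarray, delta: float, q: int) -> np.ndarray:
    """Shrink each point toward the centroid just enough to satisfy the
    pairwise ratio bounds ``delta <= x_i/x_j <= 1/delta``.

    The feasible region is star-shaped about the centroid, so along the line
    ``(1-t) x + t c`` every pair constraint is linear in ``t``; the smallest
    feasible ``t`` has a closed form per pair and we take the max over pairs.
    The binding constraints are ``x_i >= delta * x_j``, i.e.
    ``min_i x_i >= delta * max_j x_j``, and it suffices to consider the
    (min, max) coordinate pair jointly with every other pair; the per-pair
    threshold is ``t_ij = (delta x_j - x_i) / (delta x_j - x_i + (1-delta)/q)``
    whenever ``x_i < delta x_j``.
    """
    c = 1.0 / q
    # deficit for ordered pair (i, j): delta*x_j - x_i, need <= 0
    deficit = delta * points[:, None, :] - points[:, :, None]  # (n, i, j)
    deficit = np.maximum(deficit, 0.0)
    t_pair = deficit / (deficit + (1.0 - delta) * c)
    t = t_pair.max(axis=(1, 2))
    return (1.0 - t[:, None]) * points + t[:, None] * c


def project_points_to_space(points: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Project an ``(n, q)`` array of simplex points into the design region."""
    points = np.atleast_2d(np.asarray(points, float))
    if space.is_unconstrained:
        return points
    x = points
    if not (np.all(space.lower == 0.0) and np.all(space.upper == 1.0)):
        x = _project_box(x, space.lower, space.upper)
    if space.delta is not None:
        x = _project_ratio(x, space.delta, space.q)
    return x


def project_to_space(design: MixtureDesign, space: DesignSpace) -> MixtureDesign:
    """Return a design with every support point projected into ``space``.

    Feasible points are left untouched; infeasible ones are moved by the
    clip-and-redistribute rule (box bounds) and/or shrunk toward the centroid
    (ratio bounds).  Weights are unchanged.
    """
    if design.q != space.q:
        raise ValueError("design and space must have the same number of components")
    feas = space.contains(design.points, atol=SIMPLEX_ATOL)
    if feas.all():
        return design
    pts = design.points.copy()
    pts[~feas] = project_points_to_space(pts[~feas], space)
    return MixtureDesign(pts, design.weights)


def merge_support(design: MixtureDesign, tol: float = 1e-4) -> MixtureDesign:
    """Coalesce support points within Euclidean distance ``tol``.

    Clusters are formed by single linkage on the pairwise distances and each
    cluster is replaced by its weight-weighted mean with the summed weight.
    ``tol = 0`` merges exact duplicates only.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    k = design.k
    if k == 1:
        return design
    d = np.linalg.norm(design.points[:, None, :] - design.points[None, :, :], axis=2)
    # union-find single linkage
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] <= tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(k):
        clusters.setdefault(find(i), []).append(i)
    new_pts, new_w = [], []
    for members in clusters.values():
        idx = np.array(members)
        wsum = design.weights[idx].sum()
        if wsum > 0:
            centroid = (design.weights[idx][:, None] * design.points[idx]).sum(axis=0) / wsum
        else:
            centroid = design.points[idx].mean(axis=0)
        new_pts.append(centroid / centroid.sum())
        new_w.append(wsum)
    order = sorted(range(len(new_pts)), key=lambda i: tuple(new_pts[i]))
    pts = np.array(new_pts)[order]
    w = np.array(new_w)[order]
    return MixtureDesign(pts, w / w.sum())


def prune_weights(design: MixtureDesign, eps: float = 1e-6) -> MixtureDesign:
    """Drop support points whose weight is below ``eps`` and renormalize."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    keep = design.weights >= eps if eps > 0 else np.ones(design.k, bool)
    if eps > 0 and not keep.any():
        raise ValueError("all weights fall below the pruning threshold")
    if keep.all():
        return design
    w = design.weights[keep]
    return MixtureDesign(design.points[keep], w / w.sum())
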