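"""Equivalence-theorem verification by global maximization of the dispersion.

A candidate design is certified (numerically) optimal when the dispersion
deviation — the directional derivative of the criterion minus its bound —
is nonpositive over the whole design region.  The supremum is located in two
stages: an exhaustive rational lattice sweep over the feasible region,
followed by derivative-free local refinement (Nelder-Mead through the
simplex projection) around the best lattice points.  This is a heuristic
multistart, not a formal global certificate; for the models here the
dispersion is a smooth (or piecewise smooth) function with few local maxima
and the two-stage search is reliable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize

from .core import DesignSpace, MixtureDesign, project_points_to_space
from .criteria import Criterion, DOptimality, dispersion
from .models import ModelSpec

__all__ = ["EquivalenceReport", "check_equivalence", "simplex_lattice", "default_step"]


@dataclass(frozen=True)
class EquivalenceReport:
    """Outcome of an equivalence check."""

    max_deviation: float
    argmax: np.ndarray
    optimal: bool
    tolerance: float
    efficiency_lower_bound: float
    grid_step: float
    lattice_max: float
    n_lattice: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "OPTIMAL" if self.optimal else "NOT optimal"
        return (
            f"EquivalenceReport({verdict} at tol {self.tolerance:g}; "
            f"max deviation {self.max_deviation:.3e} at "
            f"{np.round(self.argmax, 4)}; "
            f"efficiency lower bound {self.efficiency_lower_bound:.4f})"
        )


def default_step(q: int) -> float:
    """Default lattice step: 0.005 up to 4 components, 0.02 beyond
    (the lattice count grows combinatorially with q)."""
    return 0.005 if q <= 4 else 0.02


def _compositions(n: int, q: int, _memo: dict | None = None) -> np.ndarray:
    """All length-q nonnegative integer vectors summing to n
    (C(n+q-1, q-1) rows), built bottom-up with memoized array stacking."""
    if _memo is None:
        _memo = {}
    key = (n, q)
    if key in _memo:
        return _memo[key]
    if q == 1:
        out = np.array([[n]], dtype=np.int32)
    else:
        blocks = []
        for first in range(n, -1, -1):
            rest = _compositions(n - first, q - 1, _memo)
            blocks.append(
                np.column_stack([np.full(rest.shape[0], first, dtype=np.int32), rest])
            )
        out = np.vstack(blocks)
    _memo[key] = out
    return out


def simplex_lattice(
    q: int, step: float, space: DesignSpace | None = None
) -> np.ndarray:
    """The rational lattice {x : x_i = step * integer, sum x_i = 1} filtered
    by the design-space constraints.  ``1/step`` must be an integer so that
    vertices and edge midpoints are hit exactly (no floating-point drift).
    """
    frac = Fraction(step).limit_denominator(10**9)
    if frac.numerator != 1 or not np.isclose(step, float(frac), atol=1e-12):
        n = round(1.0 / step)
        if not np.isclose(n * step, 1.0, atol=1e-9):
            raise ValueError("step must divide 1 exactly (e.g. 0.01, 0.005)")
    else:
        n = frac.denominator
    pts = _compositions(n, q).astype(float) / n
    if space is not None and not space.is_unconstrained:
        pts = pts[space.contains(pts)]
        if pts.shape[0] == 0:
            raise ValueError("no lattice point is feasible; refine the step")
    return pts


def _space_extreme_candidates(space: DesignSpace) -> np.ndarray:
    """Extra refinement seeds at the extreme points of a box-constrained
    region.  The vertices of {0 <= x <= U, sum x = 1} have every coordinate
    at a bound except at most one; the dispersion of many criteria is
    convex in x on linear models, so its maximum sits at such a vertex."""
    q = space.q
    if space.delta is not None:
        return np.empty((0, q))
    cands = []
    import itertools

    for r in range(q):
        for S in itertools.combinations(range(q), r):
            hi = sum(space.upper[list(S)]) if S else 0.0
            resid = 1.0 - hi
            if resid < -1e-12:
                continue
            for j in range(q):
                if j in S:
                    continue
                x = np.where([i in S for i in range(q)], space.upper, 0.0)
                if space.lower[j] - 1e-12 <= resid <= space.upper[j] + 1e-12:
                    xv = x.copy()
                    xv[j] = resid
                    if abs(xv.sum() - 1.0) < 1e-9 and np.all(xv >= space.lower - 1e-12):
                        cands.append(xv)
    if not cands:
        return np.empty((0, q))
    return np.unique(np.round(np.array(cands), 12), axis=0)


def check_equivalence(
    design: MixtureDesign,
    model: ModelSpec,
    criterion: Criterion | None = None,
    space: DesignSpace | None = None,
    grid_step: float | None = None,
    tol: float = 1e-3,
    n_refine: int = 20,
) -> EquivalenceReport:
    """Check the Kiefer-Wolfowitz condition for a design.

    Evaluates the dispersion deviation on a simplex lattice restricted to
    the feasible region, then polishes the ``n_refine`` best lattice points
    (plus the design's own support and, for box regions, the polytope
    vertices) with Nelder-Mead reparametrized through the projection
    operator.  The verdict is ``optimal`` iff the supremum found is at most
    ``tol``.
    """
    criterion = criterion or DOptimality()
    space = space or DesignSpace(model.q)
    step = grid_step if grid_step is not None else default_step(model.q)
    lattice = simplex_lattice(model.q, step, space)
    dev = dispersion(criterion, model, design, lattice, deviation=True)
    order = np.argsort(dev)[::-1]
    lattice_max = float(dev[order[0]])

    starts = [lattice[i] for i in order[:n_refine]]
    starts.extend(design.points)
    extremes = _space_extreme_candidates(space)
    if extremes.size:
        starts.extend(extremes)

    def neg_dev(u: np.ndarray) -> float:
        u = np.abs(u)
        s = u.sum()
        if s <= 0:
            return np.inf
        x = project_points_to_space((u / s)[None, :], space)
        return -float(dispersion(criterion, model, design, x[0], deviation=True))

    best_val = lattice_max
    best_x = lattice[order[0]]
    for x0 in starts:
        res = minimize(
            neg_dev,
            np.asarray(x0, float),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 2000},
        )
        if -res.fun > best_val:
            u = np.abs(res.x)
            xs = project_points_to_space((u / u.sum())[None, :], space)[0]
            best_val = -res.fun
            best_x = xs
    # refinement can only raise the lattice supremum
    best_val = max(best_val, lattice_max)

    if isinstance(criterion, DOptimality):
        eff_lb = model.d / (model.d + max(best_val, 0.0))
    else:
        from .criteria import dispersion_bound

        b = dispersion_bound(criterion, model, design)
        eff_lb = b / (b + max(best_val, 0.0))
    return EquivalenceReport(
        max_deviation=float(best_val),
        argmax=np.asarray(best_x),
        optimal=bool(best_val <= tol),
        tolerance=tol,
        efficiency_lower_bound=float(eff_lb),
        grid_step=step,
        lattice_max=lattice_max,
        n_lattice=lattice.shape[0],
    )


def plot_dispersion(
    design: MixtureDesign,
    model: ModelSpec,
    criterion: Criterion | None = None,
    space: DesignSpace | None = None,
    step: float = 0.01,
    path: str | None = None,
):  # pragma: no cover - optional plotting
    """Ternary-style scatter of the dispersion deviation for q = 3 models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if model.q != 3:
        raise ValueError("plotting supports q = 3 only")
    criterion = criterion or DOptimality()
    space = space or DesignSpace(3)
    pts = simplex_lattice(3, step, space)
    dev = dispersion(criterion, model, design, pts, deviation=True)
    # barycentric -> planar
    u = pts[:, 1] + 0.5 * pts[:, 2]
    v = (np.sqrt(3) / 2) * pts[:, 2]
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(u, v, c=dev, s=4, cmap="viridis")
    su = design.points[:, 1] + 0.5 * design.points[:, 2]
    sv = (np.sqrt(3) / 2) * design.points[:, 2]
    ax.plot(su, sv, "r^", ms=8, mfc="none", label="support")
    fig.colorbar(sc, label="dispersion deviation")
    ax.set_aspect("equal")
    ax.legend()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
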