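"""Design optimality criteria, dispersion functions, and efficiencies.

All criteria are convex functionals of the information matrix, written so
that smaller is better:

- D: ``-ln det M`` (generalized variance of the coefficient estimates)
- L: ``tr L M^{-1}`` for a user matrix ``L`` (A when ``L = I``; I when ``L``
  is the uniform moment matrix of the design region)

The Kiefer-Wolfowitz equivalence theorem turns optimality into a pointwise
check on the dispersion (directional-derivative) function: for D the design
is optimal iff ``f(x)' M^{-1} f(x) <= d`` everywhere, for L-type iff
``f(x)' M^{-1} L M^{-1} f(x) <= tr L M^{-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DesignSpace, MixtureDesign
from .models import ModelSpec, information_matrix, moment_matrix, regressor

__all__ = [
    "Criterion",
    "DOptimality",
    "AOptimality",
    "LOptimality",
    "IOptimality",
    "SingularDesignError",
    "criterion_value",
    "dispersion",
    "dispersion_bound",
    "d_efficiency",
    "l_efficiency",
    "d_efficiency_lower_bound",
]

#: relative eigenvalue threshold below which M is treated as singular
SINGULARITY_RTOL = 1e-10


class SingularDesignError(np.linalg.LinAlgError):
    """The design's information matrix is singular for the requested criterion."""

    def __init__(self, msg: str, rank: int | None = None):
        super().__init__(msg)
        self.rank = rank


def safe_inverse(M: np.ndarray) -> np.ndarray:
    """Invert a symmetric PSD matrix, raising :class:`SingularDesignError`
    when the condition-scaled smallest eigenvalue falls below threshold."""
    w, V = np.linalg.eigh(M)
    if w[-1] <= 0 or w[0] <= SINGULARITY_RTOL * w[-1]:
        rank = int(np.sum(w > SINGULARITY_RTOL * max(w[-1], 0)))
        raise SingularDesignError(
            f"information matrix numerically singular (rank {rank} of {M.shape[0]})",
            rank=rank,
        )
    return (V / w) @ V.T


@dataclass(frozen=True)
class Criterion:
    """Base class; subclasses fix the scalarization of M."""

    kind: str = "base"

    def value_from_M(self, M: np.ndarray) -> float:
        raise NotImplementedError

    def L_matrix(self, model: ModelSpec) -> np.ndarray | None:
        """The L matrix for trace-type criteria, None for D."""
        return None


@dataclass(frozen=True)
class DOptimality(Criterion):
    kind: str = "D"

    def value_from_M(self, M: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(M)
        w = np.linalg.eigvalsh(M)
        if sign <= 0 or w[0] <= SINGULARITY_RTOL * max(w[-1], 0):
            rank = int(np.sum(w > SINGULARITY_RTOL * max(w[-1], 0)))
            raise SingularDesignError("singular information matrix", rank=rank)
        return -logdet


@dataclass(frozen=True)
class LOptimality(Criterion):
    """``tr L M^{-1}`` with a fixed symmetric PSD matrix L."""

    L: np.ndarray = None  # type: ignore[assignment]
    kind: str = "L"

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("L must be a square matrix")
        if not np.allclose(L, L.T, atol=1e-10):
            raise ValueError("L must be symmetric")
        if np.linalg.eigvalsh(L)[0] < -1e-10:
            raise ValueError("L must be positive semidefinite")
        object.__setattr__(self, "L", 0.5 * (L + L.T))

    def value_from_M(self, M: np.ndarray) -> float:
        return float(np.sum(self.L * safe_inverse(M)))

    def L_matrix(self, model: ModelSpec) -> np.ndarray:
        if self.L.shape[0] != model.d:
            raise ValueError("L dimension does not match the model")
        return self.L


@dataclass(frozen=True)
class AOptimality(Criterion):
    """``tr M^{-1}``: average variance of the coefficient estimates."""

    kind: str = "A"

    def value_from_M(self, M: np.ndarray) -> float:
        return float(np.trace(safe_inverse(M)))

    def L_matrix(self, model: ModelSpec) -> np.ndarray:
        return np.eye(model.d)


@dataclass(frozen=True)
class IOptimality(Criterion):
    """``tr L M^{-1}`` with L the uniform moment matrix of the region
    (average prediction variance over the design space)."""

    space: DesignSpace = None  # type: ignore[assignment]
    method: str = "analytic"
    seed: int = 0
    kind: str = "I"

    def resolve(self, model: ModelSpec) -> LOptimality:
        L = moment_matrix(model, self.space, method=self.method, seed=self.seed)
        return LOptimality(L=L)

    def value_from_M(self, M: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError("resolve() against a model first")

    def L_matrix(self, model: ModelSpec) -> np.ndarray:
        return moment_matrix(model, self.space, method=self.method, seed=self.seed)


def make_criterion(kind: str, **kwargs) -> Criterion:
    kind = kind.upper()
    if kind == "D":
        return DOptimality()
    if kind == "A":
        return AOptimality()
    if kind == "L":
        return LOptimality(L=kwargs["L"])
    if kind == "I":
        return IOptimality(
            space=kwargs.get("space"),
            method=kwargs.get("method", "analytic"),
            seed=kwargs.get("seed", 0),
        )
    raise ValueError(f"unknown criterion {kind!r}")


def _resolved(criterion: Criterion, model: ModelSpec) -> Criterion:
    if isinstance(criterion, IOptimality):
        return criterion.resolve(model)
    return criterion


def criterion_value(
    criterion: Criterion, model: ModelSpec, design: MixtureDesign
) -> float:
    """Evaluate the (to-be-minimized) criterion at a design."""
    crit = _resolved(criterion, model)
    M = information_matrix(model, design)
    return crit.value_from_M(M)


def dispersion(
    criterion: Criterion,
    model: ModelSpec,
    design: MixtureDesign,
    x: np.ndarray,
    deviation: bool = False,
) -> np.ndarray | float:
    """Directional-derivative (dispersion) function of the criterion.

    D: ``f' M^{-1} f``; L-type: ``f' M^{-1} L M^{-1} f``.  With
    ``deviation=True`` the criterion-specific bound (``d`` or
    ``tr L M^{-1}``) is subtracted, so an optimal design has nonpositive
    values everywhere with equality at its support.
    """
    crit = _resolved(criterion, model)
    M = information_matrix(model, design)
    Minv = safe_inverse(M)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    F = regressor(model, np.atleast_2d(x))
    if isinstance(crit, DOptimality):
        vals = np.einsum("nd,de,ne->n", F, Minv, F)
        bound = float(model.d)
    else:
        L = crit.L_matrix(model)
        A = Minv @ L @ Minv
        vals = np.einsum("nd,de,ne->n", F, A, F)
        bound = float(np.sum(L * Minv))
    if deviation:
        vals = vals - bound
    return float(vals[0]) if single else vals


def dispersion_bound(
    criterion: Criterion, model: ModelSpec, design: MixtureDesign
) -> float:
    """The equivalence-theorem bound: ``d`` for D, ``tr L M^{-1}`` otherwise."""
    crit = _resolved(criterion, model)
    if isinstance(crit, DOptimality):
        return float(model.d)
    M = information_matrix(model, design)
    return float(np.sum(crit.L_matrix(model) * safe_inverse(M)))


def d_efficiency(
    model: ModelSpec, design: MixtureDesign, reference: MixtureDesign
) -> float:
    """Relative D-efficiency ``(det M(design) / det M(reference))^{1/d}``.

    Interpretation: a value of 0.5 means the design must be run at twice the
    sample size to estimate the coefficients as precisely as the reference.
    """
    d = model.d
    for xi in (design, reference):
        M = information_matrix(model, xi)
        sign, _ = np.linalg.slogdet(M)
        w = np.linalg.eigvalsh(M)
        if sign <= 0 or w[0] <= SINGULARITY_RTOL * max(w[-1], 0):
            raise SingularDesignError("singular information matrix in efficiency")
    _, ld1 = np.linalg.slogdet(information_matrix(model, design))
    _, ld2 = np.linalg.slogdet(information_matrix(model, reference))
    return float(np.exp((ld1 - ld2) / d))


def l_efficiency(
    model: ModelSpec,
    design: MixtureDesign,
    reference: MixtureDesign,
    L: np.ndarray | None = None,
) -> float:
    """Relative L-efficiency ``tr L M(reference)^{-1} / tr L M(design)^{-1}``
    (A-efficiency when ``L`` is omitted)."""
    Lmat = np.eye(model.d) if L is None else np.asarray(L, float)
    crit = LOptimality(L=Lmat)
    num = crit.value_from_M(information_matrix(model, reference))
    den = crit.value_from_M(information_matrix(model, design))
    return num / den


def d_efficiency_lower_bound(
    model: ModelSpec,
    design: MixtureDesign,
    space: DesignSpace | None = None,
    **maximizer_settings,
) -> float:
    """Atwood-type D-efficiency lower bound ``d / sup_x f' M^{-1} f``.

    Computable from the design alone (no optimum needed); equals 1 exactly
    when the design passes the D equivalence check.  The supremum over the
    design region is delegated to :func:`mixopt.verify.check_equivalence`.
    """
    from .verify import check_equivalence

    space = space or DesignSpace(model.q)
    report = check_equivalence(
        design, model, DOptimality(), space, **maximizer_settings
    )
    sup = report.max_deviation + model.d
    return model.d / sup
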