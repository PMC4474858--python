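"""Mixture-model regression functions and information matrices.

A linear mixture model is ``y = beta' f(x) + eps`` with ``f`` a ``d``-vector
of regressors in the component proportions ``x``.  Because the model is
linear in the coefficients, the (normalized) Fisher information matrix of an
approximate design ``xi`` is ``M(xi) = sum_i p_i f(x_i) f(x_i)'`` and does
not depend on the unknown coefficients; only the term list matters here.

Families covered: Scheffé canonical polynomials of any order, Becker's
homogeneous-of-degree-one models (min, ratio and geometric-mean interaction
terms), Kasatkin's two-component polynomials with ``x1 x2 (x1 - x2)^i``
terms, incomplete cubic submodels, and linear log-contrast models in
``log(x_i / x_q)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import DesignSpace, MixtureDesign

__all__ = [
    "Term",
    "ModelSpec",
    "build_named_model",
    "regressor",
    "information_matrix",
    "moment_matrix",
    "MODEL_CATALOGUE",
]


@dataclass(frozen=True)
class Term:
    """A single regressor.

    kind:
        - ``intercept``: the constant 1
        - ``monomial``: ``prod_i x_i^{a_i}`` with exponent vector ``a``
        - ``min``: ``min_{i in S} x_i`` over an index subset ``S``
        - ``ratio2``: ``x_i x_j / (x_i + x_j)`` (0 when both vanish)
        - ``geomean``: ``(prod_{i in S} x_i)^{1/|S|}``
        - ``cubic_diff``: ``x_i x_j (x_i - x_j)``
        - ``kasatkin``: ``x_1 x_2 (x_1 - x_2)^p``
        - ``logcontrast``: ``log(x_i / x_q)`` (last component as reference)

    ``indices`` are 0-based component indices; ``power`` is the Kasatkin
    exponent ``p >= 0`` or, for ``monomial``, ``indices`` doubles as the
    exponent vector of length q.
    """

    kind: str
    indices: tuple[int, ...] = ()
    power: int = 0

    def label(self) -> str:
        i = self.indices
        if self.kind == "intercept":
            return "1"
        if self.kind == "monomial":
            parts = [
                f"x{j + 1}" + (f"^{a}" if a > 1 else "")
                for j, a in enumerate(i)
                if a > 0
            ]
            return "*".join(parts) if parts else "1"
        if self.kind == "min":
            return "min(" + ",".join(f"x{j + 1}" for j in i) + ")"
        if self.kind == "ratio2":
            return f"x{i[0] + 1}x{i[1] + 1}/(x{i[0] + 1}+x{i[1] + 1})"
        if self.kind == "geomean":
            return "(" + "".join(f"x{j + 1}" for j in i) + f")^(1/{len(i)})"
        if self.kind == "cubic_diff":
            return f"x{i[0] + 1}x{i[1] + 1}(x{i[0] + 1}-x{i[1] + 1})"
        if self.kind == "kasatkin":
            return f"x1x2(x1-x2)^{self.power}"
        if self.kind == "logcontrast":
            return f"log(x{i[0] + 1}/xq)"
        raise ValueError(f"unknown term kind {self.kind!r}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate on an ``(n, q)`` array; returns a length-``n`` vector."""
        if self.kind == "intercept":
            return np.ones(x.shape[0])
        if self.kind == "monomial":
            a = np.asarray(self.indices)
            return np.prod(x ** a, axis=1)
        if self.kind == "min":
            return x[:, list(self.indices)].min(axis=1)
        if self.kind == "ratio2":
            i, j = self.indices
            s = x[:, i] + x[:, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(s > 0, x[:, i] * x[:, j] / np.where(s > 0, s, 1.0), 0.0)
            return v
        if self.kind == "geomean":
            idx = list(self.indices)
            return np.prod(x[:, idx], axis=1) ** (1.0 / len(idx))
        if self.kind == "cubic_diff":
            i, j = self.indices
            return x[:, i] * x[:, j] * (x[:, i] - x[:, j])
        if self.kind == "kasatkin":
            return x[:, 0] * x[:, 1] * (x[:, 0] - x[:, 1]) ** self.power
        if self.kind == "logcontrast":
            (i,) = self.indices
            q = x.shape[1]
            if np.any(x[:, i] <= 0) or np.any(x[:, q - 1] <= 0):
                raise ValueError(
                    "log-contrast term undefined at a zero proportion; "
                    "use a ratio-constrained design space"
                )
            return np.log(x[:, i] / x[:, q - 1])
        raise ValueError(f"unknown term kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """An ordered term list defining ``f(x)`` with ``d = len(terms)``."""

    q: int
    terms: tuple[Term, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if len(self.terms) < 1:
            raise ValueError("a model needs at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("model terms must be distinct")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def d(self) -> int:
        return len(self.terms)

    def labels(self) -> list[str]:
        return [t.label() for t in self.terms]


def regressor(model: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Evaluate ``f`` at one composition (returns shape ``(d,)``) or at an
    ``(n, q)`` array of compositions (returns shape ``(n, d)``)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.q:
        raise ValueError(f"expected {model.q} components, got {X.shape[1]}")
    F = np.column_stack([t.evaluate(X) for t in model.terms])
    return F[0] if single else F


def _monomial(q: int, exps: dict[int, int]) -> Term:
    a = [0] * q
    for i, e in exps.items():
        a[i] = e
    return Term("monomial", tuple(a))


def scheffe(q: int, order: int) -> ModelSpec:
    """Scheffé canonical polynomial of the given order: linear terms plus all
    square-free interaction products of 2..order distinct components.
    ``d = sum_{s=1}^{order} C(q, s)`` (``q(q+1)/2`` for the quadratic)."""
    if not 1 <= order <= q:
        raise ValueError("order must be between 1 and q")
    terms = [_monomial(q, {i: 1}) for i in range(q)]
    for s in range(2, order + 1):
        for comb in itertools.combinations(range(q), s):
            terms.append(_monomial(q, {i: 1 for i in comb}))
    return ModelSpec(q, tuple(terms), name=f"scheffe{order}")


def becker(q: int, variant: int) -> ModelSpec:
    """Becker's homogeneous models: linear terms plus one interaction family
    over every subset of 2..q components.

    variant 1: ``(prod x_i)^{1/|S|}`` geometric means;
    variant 2: ``x_i x_j/(x_i+x_j)`` pairs, ``prod x_i/(sum x_i)^{|S|-1}``
    in general (on the simplex the full-subset term is the plain product);
    variant 3: ``min`` terms.
    """
    if variant not in (1, 2, 3):
        raise ValueError("Becker variant must be 1, 2 or 3")
    terms = [_monomial(q, {i: 1}) for i in range(q)]
    for s in range(2, q + 1):
        for comb in itertools.combinations(range(q), s):
            if variant == 1:
                terms.append(Term("geomean", comb))
            elif variant == 3:
                terms.append(Term("min", comb))
            else:
                if s == 2:
                    terms.append(Term("ratio2", comb))
                else:
                    # prod/(sum)^{s-1}; the component sums to 1 on the full
                    # simplex when |S| = q, leaving the plain product
                    if s == q:
                        terms.append(_monomial(q, {i: 1 for i in comb}))
                    else:
                        raise NotImplementedError(
                            "Becker model 2 with 3 < |S| < q subsets is not catalogued"
                        )
    return ModelSpec(q, tuple(terms), name=f"becker{variant}")


def kasatkin(order: int) -> ModelSpec:
    """Kasatkin's two-component polynomial of the given order:
    ``theta1 x1 + theta2 x2 + sum_{i=0}^{order-2} phi_i x1 x2 (x1-x2)^i``.
    Built on q = 2; optimal designs embed in q = 3 with a zero coordinate.
    """
    if order < 2:
        raise ValueError("Kasatkin order must be >= 2")
    terms = [_monomial(2, {0: 1}), _monomial(2, {1: 1})]
    for p in range(order - 1):
        terms.append(Term("kasatkin", (0, 1), power=p))
    return ModelSpec(2, tuple(terms), name=f"kasatkin{order}")


def cubic_no3way(q: int = 3) -> ModelSpec:
    """Cubic model without the three-way effect: linear + pairwise products +
    ``x_i x_j (x_i - x_j)`` terms.  d = 3q for q = 3 gives 9."""
    terms = [_monomial(q, {i: 1}) for i in range(q)]
    for i, j in itertools.combinations(range(q), 2):
        terms.append(_monomial(q, {i: 1, j: 1}))
    for i, j in itertools.combinations(range(q), 2):
        terms.append(Term("cubic_diff", (i, j)))
    return ModelSpec(q, tuple(terms), name="cubic_no3way")


def cubic_full(q: int = 3) -> ModelSpec:
    """Full cubic model: adds the three-way products to :func:`cubic_no3way`."""
    terms = list(cubic_no3way(q).terms)
    for comb in itertools.combinations(range(q), 3):
        terms.append(_monomial(q, {i: 1 for i in comb}))
    return ModelSpec(q, tuple(terms), name="cubic_full")


def _ic_model(which: str) -> ModelSpec:
    """Incomplete-cubic submodels on q = 3 (pharmaceutical formulation use)."""
    q = 3
    lin = [_monomial(q, {i: 1}) for i in range(q)]
    pair = {(i, j): _monomial(q, {i: 1, j: 1}) for i, j in itertools.combinations(range(3), 2)}
    gam = {(i, j): Term("cubic_diff", (i, j)) for i, j in itertools.combinations(range(3), 2)}
    triple = _monomial(q, {0: 1, 1: 1, 2: 1})
    if which == "A":
        terms = lin + [pair[(0, 2)], pair[(1, 2)]] + list(gam.values()) + [triple]
    elif which == "B":
        terms = lin + [pair[(1, 2)]] + list(gam.values()) + [triple]
    elif which == "C":
        terms = lin + list(pair.values()) + [gam[(0, 2)], gam[(1, 2)]]
    elif which == "D":
        terms = lin + list(pair.values()) + [gam[(0, 2)], gam[(1, 2)], triple]
    else:
        raise ValueError("IC model must be A, B, C or D")
    return ModelSpec(q, tuple(terms), name=f"ic{which}")


def eq15_model() -> ModelSpec:
    """Eight-term incomplete cubic polynomial in (x1, x2) with an intercept,
    used on the 3-simplex: 1, x1, x2, x1^2, x1x2, x2^2, x1^3, x1x2^2."""
    q = 3
    terms = (
        Term("intercept"),
        _monomial(q, {0: 1}),
        _monomial(q, {1: 1}),
        _monomial(q, {0: 2}),
        _monomial(q, {0: 1, 1: 1}),
        _monomial(q, {1: 2}),
        _monomial(q, {0: 3}),
        _monomial(q, {0: 1, 1: 2}),
    )
    return ModelSpec(q, terms, name="eq15")


def logcontrast(q: int) -> ModelSpec:
    """Linear log-contrast model: intercept plus ``log(x_i/x_q)``,
    i = 1..q-1.  Requires a ratio-bounded design space (x > 0)."""
    terms = [Term("intercept")] + [Term("logcontrast", (i,)) for i in range(q - 1)]
    return ModelSpec(q, tuple(terms), name="logcontrast")


MODEL_CATALOGUE: dict[str, str] = {
    "scheffe<n>": "Scheffé polynomial of order n (e.g. scheffe2)",
    "becker1": "Becker: geometric-mean interactions",
    "becker2": "Becker: ratio interactions",
    "becker3": "Becker: min interactions",
    "kasatkin<n>": "Kasatkin polynomial of order n (two components)",
    "cubic_no3way": "cubic without the 3-way effect",
    "cubic_full": "full cubic",
    "icA": "incomplete cubic model A",
    "icB": "incomplete cubic model B",
    "icC": "incomplete cubic model C",
    "icD": "incomplete cubic model D",
    "eq15": "incomplete cubic with intercept in (x1, x2)",
    "logcontrast": "linear log-contrast model",
}


def build_named_model(name: str, q: int | None = None) -> ModelSpec:
    """Construct a model from its catalogue name.

    ``q`` is required for families defined for any number of components and
    ignored (or checked) where the family fixes it.
    """
    name = name.strip().lower()
    if name.startswith("scheffe"):
        order = int(name[len("scheffe") :])
        if q is None:
            raise ValueError("scheffe models need q")
        return scheffe(q, order)
    if name.startswith("becker"):
        variant = int(name[len("becker") :])
        return becker(q or 3, variant)
    if name.startswith("kasatkin"):
        return kasatkin(int(name[len("kasatkin") :]))
    if name == "cubic_no3way":
        return cubic_no3way(q or 3)
    if name == "cubic_full":
        return cubic_full(q or 3)
    if name.startswith("ic") and len(name) == 3:
        return _ic_model(name[2].upper())
    if name == "eq15":
        return eq15_model()
    if name == "logcontrast":
        if q is None:
            raise ValueError("logcontrast models need q")
        return logcontrast(q)
    raise ValueError(f"unknown model name {name!r}")


def information_matrix(model: ModelSpec, design: MixtureDesign) -> np.ndarray:
    """``M(xi) = sum_i p_i f(x_i) f(x_i)'`` — symmetric PSD, d x d."""
    F = regressor(model, design.points)
    M = F.T @ (design.weights[:, None] * F)
    return 0.5 * (M + M.T)


def _uniform_simplex_monomial_mean(q: int, a: np.ndarray) -> float:
    """Mean of ``prod x_i^{a_i}`` under the uniform distribution on the
    simplex (a Dirichlet(1,..,1) moment):
    ``(q-1)! * prod a_i! / (q-1+sum a_i)!``."""
    num = math.factorial(q - 1)
    for ai in a:
        num *= math.factorial(int(ai))
    return num / math.factorial(q - 1 + int(a.sum()))


def moment_matrix(
    model: ModelSpec,
    space: DesignSpace | None = None,
    method: str = "analytic",
    n_draws: int = 200_000,
    seed: int | None = 0,
) -> np.ndarray:
    """The region moment matrix ``L = E_mu[f f']`` with ``mu`` uniform on the
    design region (the I-optimality weighting).

    ``method='analytic'`` uses the Dirichlet moment identity and is exact,
    but only for monomial/intercept terms on the unconstrained simplex;
    ``method='montecarlo'`` averages over uniform draws (rejection-sampled
    into a constrained region) with a fixed seed.
    """
    space = space or DesignSpace(model.q)
    if method == "analytic":
        if not space.is_unconstrained:
            raise ValueError("analytic moments require the unconstrained simplex")
        exps = []
        for t in model.terms:
            if t.kind == "monomial":
                exps.append(np.asarray(t.indices))
            elif t.kind == "intercept":
                exps.append(np.zeros(model.q, dtype=int))
            else:
                raise ValueError(
                    f"analytic moments unavailable for term kind {t.kind!r}"
                )
        d = model.d
        L = np.empty((d, d))
        for i in range(d):
            for j in range(i, d):
                L[i, j] = L[j, i] = _uniform_simplex_monomial_mean(
                    model.q, exps[i] + exps[j]
                )
        return L
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        total = np.zeros((model.d, model.d))
        kept = 0
        while kept < n_draws:
            X = rng.dirichlet(np.ones(model.q), size=max(n_draws - kept, 1000))
            X = X[space.contains(X)]
            if X.shape[0] == 0:
                continue
            X = X[: n_draws - kept]
            F = regressor(model, X)
            total += F.T @ F
            kept += X.shape[0]
        L = total / kept
        return 0.5 * (L + L.T)
    raise ValueError("method must be 'analytic' or 'montecarlo'")
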