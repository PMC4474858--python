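import numpy as np
import pytest

from mixopt import DesignSpace, MixtureDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def vertex_design_q3():
    return MixtureDesign(np.eye(3), np.full(3, 1 / 3))


@pytest.fixture
def ratio_space_q3():
    return DesignSpace(3, delta=0.2)


def random_design(rng, q=3, k=5):
    pts = rng.dirichlet(np.ones(q), size=k)
    w = rng.dirichlet(np.ones(k))
    return MixtureDesign(pts, w)


def assert_designs_match(found, expected, coord_tol=1e-4, weight_tol=1e-4):
    """Compare two designs as weighted point sets (order-free)."""
    assert found.k == expected.k, f"k mismatch: {found.k} vs {expected.k}"
    used = set()
    for p, w in zip(expected.points, expected.weights):
        d = np.linalg.norm(found.points - p, axis=1)
        i = int(np.argmin(d))
        assert d[i] <= coord_tol, f"no match for point {p} (closest at {d[i]:.2e})"
        assert i not in used, "two expected points matched the same found point"
        used.add(i)
        assert abs(found.weights[i] - w) <= weight_tol, (
            f"weight mismatch at {p}: {found.weights[i]:.5f} vs {w:.5f}"
        )
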