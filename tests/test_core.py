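"""Design containers, hypercube projection, and support housekeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixopt import (
    DesignSpace,
    MixtureDesign,
    ParticleState,
    merge_support,
    project_particle,
    project_to_space,
    prune_weights,
)
from mixopt.core import InfeasibleSpaceError, InvalidParticleError, flatten_design
from mixopt.cli_io import load_fixture


class TestMixtureDesign:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MixtureDesign([[0.5, 0.4]], [1.0])  # off simplex
        with pytest.raises(ValueError):
            MixtureDesign([[0.5, 0.5]], [0.5])  # weights not summing to 1
        with pytest.raises(ValueError):
            MixtureDesign([[0.5, 0.5], [1.0, 0.0]], [1.5, -0.5])

    def test_halved_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureDesign(np.eye(3), np.full(3, 1 / 6))


class TestProjectParticle:
    def test_direct_normalization(self):
        raw = ParticleState(k=2, q=2, raw=[0.3, 0.1, 0.5, 0.5, 0.2, 0.6])
        d = project_particle(raw)
        np.testing.assert_allclose(d.points, [[0.75, 0.25], [0.5, 0.5]])
        np.testing.assert_allclose(d.weights, [0.25, 0.75])

    def test_zero_point_block_rejected(self):
        raw = ParticleState(k=2, q=2, raw=[0.0, 0.0, 0.5, 0.5, 0.2, 0.6])
        with pytest.raises(InvalidParticleError):
            project_particle(raw)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_idempotence(self, seed):
        """P(P(xi)) = P(xi): projecting the flattened projection is a no-op."""
        rng = np.random.default_rng(seed)
        k, q = int(rng.integers(1, 6)), int(rng.integers(2, 5))
        raw = rng.uniform(0.05, 1.0, size=k * (q + 1))
        d1 = project_particle(ParticleState(k=k, q=q, raw=raw))
        d2 = project_particle(flatten_design(d1))
        np.testing.assert_allclose(d1.points, d2.points, atol=1e-14)
        np.testing.assert_allclose(d1.weights, d2.weights, atol=1e-14)


class TestDesignSpace:
    def test_infeasible_rejected(self):
        with pytest.raises(InfeasibleSpaceError):
            DesignSpace(3, upper=np.array([0.2, 0.2, 0.2]))  # sum U < 1
        with pytest.raises(InfeasibleSpaceError):
            DesignSpace(3, lower=np.array([0.5, 0.4, 0.3]))  # sum L > 1
        with pytest.raises(InfeasibleSpaceError):
            DesignSpace(3, delta=1.5)

    def test_contains(self):
        sp = DesignSpace(3, delta=0.2)
        assert sp.contains(np.array([[1 / 3, 1 / 3, 1 / 3], [1, 0, 0]])).tolist() == [True, False]


class TestProjectToSpace:
    def test_unconstrained_identity(self, vertex_design_q3):
        sp = DesignSpace(3)
        assert project_to_space(vertex_design_q3, sp) is vertex_design_q3

    def test_ratio_shrink_to_boundary(self, ratio_space_q3):
        # vertex pulled along the segment to the centroid until delta <= xi/xj
        d = MixtureDesign([[1.0, 0.0, 0.0]], [1.0])
        out = project_to_space(d, ratio_space_q3)
        np.testing.assert_allclose(out.points[0], [5 / 7, 1 / 7, 1 / 7], atol=1e-10)
        assert ratio_space_q3.contains(out.points).all()
        # idempotent
        again = project_to_space(out, ratio_space_q3)
        np.testing.assert_allclose(again.points, out.points, atol=1e-12)

    def test_ratio_shrink_is_minimal(self, ratio_space_q3):
        """Brute force over the shrink parameter: no smaller t is feasible."""
        x = np.array([1.0, 0.0, 0.0])
        c = np.full(3, 1 / 3)
        out = project_to_space(MixtureDesign([x], [1.0]), ratio_space_q3).points[0]
        t_used = 1.0 - (out[0] - c[0]) / (x[0] - c[0])
        for t in np.linspace(0, t_used - 1e-4, 400):
            y = (1 - t) * x + t * c
            assert not ratio_space_q3.contains(y[None])[0]

    def test_box_clip_and_redistribute(self):
        sp = DesignSpace(3, upper=np.array([0.5, 1.0, 1.0]))
        d = MixtureDesign([[0.8, 0.1, 0.1]], [1.0])
        out = project_to_space(d, sp)
        np.testing.assert_allclose(out.points[0], [0.5, 0.25, 0.25], atol=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_projection_feasible_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(2, 5))
        upper = rng.uniform(1.0 / q + 0.1, 1.0, size=q)  # keep the centroid feasible
        sp = DesignSpace(q, upper=upper, delta=float(rng.uniform(0.05, 0.3)))
        pts = rng.dirichlet(np.full(q, 0.5), size=4)
        d = MixtureDesign(pts, np.full(4, 0.25))
        out = project_to_space(d, sp)
        assert sp.contains(out.points, atol=1e-9).all()
        out2 = project_to_space(out, sp)
        np.testing.assert_allclose(out.points, out2.points, atol=1e-9)


class TestMergeSupport:
    def test_identical_points_merge(self):
        d = MixtureDesign([[0.5, 0.5], [0.5, 0.5]], [0.3, 0.7])
        out = merge_support(d, 1e-8)
        assert out.k == 1
        np.testing.assert_allclose(out.weights, [1.0])

    def test_tol_zero_keeps_distinct(self):
        d = MixtureDesign([[0.4, 0.6], [0.6, 0.4]], [0.5, 0.5])
        assert merge_support(d, 0.0).k == 2

    def test_cocktail_pair_merges(self):
        """The published 10-point grid design has one mergeable pair."""
        d = load_fixture("sec5_cocktail_eq15")
        merged = merge_support(d, 0.01)
        assert merged.k == 9
        assert abs(merged.weights.sum() - 1.0) < 1e-10

    def test_merge_preserves_criterion_approximately(self):
        from mixopt import DOptimality, build_named_model, criterion_value

        model = build_named_model("eq15")
        d = load_fixture("sec5_cocktail_eq15")
        v0 = criterion_value(DOptimality(), model, d)
        v1 = criterion_value(DOptimality(), model, merge_support(d, 0.01))
        assert abs(v1 - v0) < 1e-2


class TestPruneWeights:
    def test_drop_zero_weight(self):
        d = MixtureDesign(np.eye(3), [0.5, 0.5, 0.0])
        out = prune_weights(d, 1e-6)
        assert out.k == 2
        np.testing.assert_allclose(out.weights, [0.5, 0.5])

    def test_eps_zero_identity(self):
        d = MixtureDesign(np.eye(3), [0.5, 0.5, 0.0])
        assert prune_weights(d, 0.0).k == 3

    def test_constrained_six_factor_design_prunes_to_12(self):
        d = load_fixture("sec45_linear6_constrained")
        assert d.k == 13
        assert prune_weights(d, 0.001).k == 12

    def test_all_below_threshold_errors(self):
        d = MixtureDesign(np.eye(3), np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            prune_weights(d, 0.5)
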