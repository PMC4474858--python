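"""Swarm dynamics, determinism, and recovery of known optima."""

import numpy as np
import pytest

from mixopt import (
    DOptimality,
    MixtureDesign,
    PSOConfig,
    augment_design,
    build_named_model,
    criterion_value,
    run_projpso,
)
from mixopt.core import flatten_design
from mixopt.models import scheffe
from mixopt.projpso import _Evaluator, _init_swarm, pso_step
from mixopt.core import DesignSpace
from conftest import assert_designs_match


def _evaluator(model, k):
    return _Evaluator(model, DOptimality(), DesignSpace(model.q), k)


class TestPsoStep:
    def test_fixed_point_at_optimum(self, vertex_design_q3):
        """Zero velocity, zero learning factors at the optimum: state frozen."""
        m = scheffe(3, 1)
        ev = _evaluator(m, 3)
        raw = flatten_design(vertex_design_q3).raw
        cfg = PSOConfig(n_particles=2, n_iterations=5, gamma1=1e-12, gamma2=1e-12)
        rng = np.random.default_rng(0)
        state = _init_swarm(3, 3, cfg, ev, rng)
        state.positions[:] = raw
        state.velocities[:] = 0.0
        state.pbest_pos[:] = raw
        state.pbest_val[:] = ev(state.positions)
        state.gbest_pos = raw.copy()
        state.gbest_val = float(state.pbest_val[0])
        new = pso_step(state, cfg, ev, rng)
        np.testing.assert_allclose(new.positions, state.positions, atol=1e-9)
        assert np.isclose(new.gbest_val, 3 * np.log(3.0))

    def test_gbest_monotone(self):
        m = scheffe(3, 2)
        ev = _evaluator(m, 6)
        cfg = PSOConfig(n_particles=32, n_iterations=60, seed=11)
        rng = np.random.default_rng(11)
        state = _init_swarm(6, 3, cfg, ev, rng)
        vals = [state.gbest_val]
        for _ in range(60):
            state = pso_step(state, cfg, ev, rng)
            vals.append(state.gbest_val)
        assert np.all(np.diff(vals) <= 0)


class TestRunProjPSO:
    def test_seeded_determinism(self):
        m = scheffe(3, 1)
        cfg = PSOConfig(n_particles=32, n_iterations=50, seed=123)
        d1, t1 = run_projpso(m, config=cfg, k=3)
        d2, t2 = run_projpso(m, config=cfg, k=3)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(d1.points, d2.points)
        np.testing.assert_array_equal(d1.weights, d2.weights)

    def test_linear_q3_recovers_vertices(self, vertex_design_q3):
        d, trace = run_projpso(
            scheffe(3, 1),
            config=PSOConfig(n_particles=64, n_iterations=200, seed=1),
            k=3,
        )
        assert np.all(np.diff(trace) <= 1e-12)
        assert_designs_match(d, vertex_design_q3, coord_tol=1e-6, weight_tol=1e-6)

    def test_quadratic_q3_recovers_simplex_centroid(self):
        from mixopt.baselines import simplex_centroid_design

        d, _ = run_projpso(
            scheffe(3, 2),
            config=PSOConfig(n_particles=128, n_iterations=250, seed=2),
            k=6,
        )
        assert_designs_match(d, simplex_centroid_design(3, 2), coord_tol=1e-6, weight_tol=1e-6)

    def test_kasatkin4_table_design(self):
        """Support (1,0), (0,1), the 0.1727/0.8273 splits and the midpoint."""
        m = build_named_model("kasatkin4")
        d, _ = run_projpso(
            m, config=PSOConfig(n_particles=256, n_iterations=300, seed=4), k=5,
            merge_tol=1e-3,
        )
        expected = MixtureDesign(
            [[1, 0], [0, 1], [0.8273, 0.1727], [0.1727, 0.8273], [0.5, 0.5]],
            np.full(5, 0.2),
        )
        assert_designs_match(d, expected, coord_tol=5e-5, weight_tol=1e-6)


class TestAugmentDesign:
    def test_n0_zero_degenerates_to_plain_search(self, vertex_design_q3):
        m = scheffe(3, 1)
        cfg = PSOConfig(n_particles=64, n_iterations=150, seed=3)
        d, _ = augment_design(vertex_design_q3, 0, 8, m, config=cfg, k=3)
        assert_designs_match(d, vertex_design_q3, coord_tol=1e-6, weight_tol=1e-6)

    def test_optimal_initial_is_fixed_point(self, vertex_design_q3):
        """Augmenting the optimum leaves the combined design optimal."""
        m = scheffe(3, 1)
        cfg = PSOConfig(n_particles=64, n_iterations=150, seed=3)
        d, _ = augment_design(vertex_design_q3, 8, 8, m, config=cfg, k=3)
        from mixopt.models import information_matrix

        M = 0.5 * information_matrix(m, vertex_design_q3) + 0.5 * information_matrix(m, d)
        combined_val = -np.linalg.slogdet(M)[1]
        assert np.isclose(combined_val, 3 * np.log(3.0), atol=1e-8)

    def test_published_becker1_second_stage(self):
        """8-run first stage, 8 more runs: the printed 6-point second stage
        with its 0.1992 maximum weight at a vertex."""
        from mixopt.cli_io import load_fixture

        m = build_named_model("becker1", 3)
        xi0 = load_fixture("sec5_multistage_xi0")
        cfg = PSOConfig(n_particles=512, n_iterations=300, seed=1)
        d, _ = augment_design(xi0, 8, 8, m, config=cfg, k=8)
        expected = load_fixture("sec5_multistage_xi1")
        assert_designs_match(d, expected, coord_tol=2e-3, weight_tol=2e-4)
        imax = int(np.argmax(d.weights))
        assert round(float(d.weights[imax]), 4) == 0.1992
        assert np.isclose(d.points[imax].max(), 1.0, atol=1e-6)  # a vertex
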