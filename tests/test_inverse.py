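"""Surrogate, genetic algorithm and inverse-loop tests.

The full-resolution, full-budget parameter-recovery runs live in the
acceptance suite; here the loop is exercised at coarse resolution and small
budgets where its contracts (determinism, audit consistency, bound
behaviour) are cheap to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from corneafit.inverse import (
    InverseConfig,
    _ga_minimize,
    fit_material,
    surrogate_fit,
)
from corneafit.metrics import DeformationMetrics, compute_metrics
from corneafit.synthetic_data import phantom_params


class TestSurrogate:
    @staticmethod
    def bowl(x, y):
        return (x - 0.3) ** 2 + 2.0 * (y + 0.1) ** 2

    def test_quadratic_bowl_loo_error_below_2pct_of_range(self):
        g = np.linspace(-1, 1, 5)
        samples = [((x, y), self.bowl(x, y)) for x in g for y in g]
        _, loo = surrogate_fit(samples)
        rng_ = max(v for _, v in samples) - min(v for _, v in samples)
        assert loo < 0.02 * rng_

    def test_interpolates_training_points(self):
        g = np.linspace(-1, 1, 5)
        samples = [((x, y), self.bowl(x, y)) for x in g for y in g]
        predict, _ = surrogate_fit(samples)
        pts = np.array([p for p, _ in samples])
        vals = np.array([v for _, v in samples])
        assert np.abs(predict(pts) - vals).max() < 1e-6

    def test_constant_samples_give_constant_predictor(self):
        g = np.linspace(0, 1, 4)
        samples = [((x, y), 0.7) for x in g for y in g]
        predict, _ = surrogate_fit(samples)
        q = np.array([[0.31, 0.62], [0.9, 0.05]])
        assert np.abs(predict(q) - 0.7).max() < 1e-8

    def test_duplicates_collapsed(self):
        samples = [((0.1, 0.2), 1.0)] * 5 + [
            ((x, y), self.bowl(x, y)) for x, y in
            [(0, 0), (0.5, 0.5), (-0.5, 0.3), (0.2, -0.4), (0.8, 0.1)]
        ]
        predict, _ = surrogate_fit(samples)  # 6 distinct points: no error
        assert np.isfinite(predict(np.array([[0.0, 0.0]]))[0])

    def test_too_few_points_rejected(self):
        with pytest.raises(Exception):
            surrogate_fit([((0.0, 0.0), 1.0), ((1.0, 1.0), 2.0)])


class TestGeneticAlgorithm:
    def test_finds_minimum_of_smooth_function(self):
        def f(p):
            return (p[:, 0] - 0.4) ** 2 + (p[:, 1] + 0.7) ** 2

        rng = np.random.default_rng(3)
        x = _ga_minimize(f, np.array([-2.0, -2.0]), np.array([2.0, 2.0]), 40, 50, rng)
        assert np.linalg.norm(x - [0.4, -0.7]) < 0.02

    def test_respects_bounds(self):
        def f(p):
            return -p[:, 0] - p[:, 1]  # optimum at the upper corner

        rng = np.random.default_rng(4)
        x = _ga_minimize(f, np.array([0.0, 0.0]), np.array([1.0, 1.0]), 30, 30, rng)
        assert np.all(x <= 1.0) and np.linalg.norm(x - [1.0, 1.0]) < 1e-6

    def test_deterministic_given_seed(self):
        def f(p):
            return np.sin(3 * p[:, 0]) + p[:, 1] ** 2

        lo, hi = np.array([-1.0, -1.0]), np.array([1.0, 1.0])
        x1 = _ga_minimize(f, lo, hi, 25, 25, np.random.default_rng(11))
        x2 = _ga_minimize(f, lo, hi, 25, 25, np.random.default_rng(11))
        assert np.array_equal(x1, x2)


SMALL = dict(
    n_initial_samples=8, max_fe_evaluations=18, ga_population=25,
    ga_generations=25,
)


@pytest.fixture(scope="module")
def target(coarse_sim):
    return compute_metrics(coarse_sim.metrics_record(phantom_params("S")))


@pytest.fixture(scope="module")
def fit5(coarse_sim, target):
    cfg = InverseConfig(rng_seed=5, **SMALL)
    res = fit_material(
        target, coarse_sim.geom, 15.0, coarse_sim.load, cfg, mesh=coarse_sim.mesh
    )
    return cfg, res


class TestFitMaterial:
    def test_recovers_stiffness_and_is_deterministic(self, coarse_sim, target, fit5):
        cfg, r1 = fit5
        r2 = fit_material(
            target, coarse_sim.geom, 15.0, coarse_sim.load, cfg, mesh=coarse_sim.mesh
        )
        assert r1.params == r2.params
        assert r1.merit == r2.merit
        assert [e["merit"] for e in r1.evaluations] == [
            e["merit"] for e in r2.evaluations
        ]
        truth_e = phantom_params("S").youngs_modulus
        assert r1.params.youngs_modulus == pytest.approx(truth_e, rel=0.05)
        assert r1.converged

    def test_audit_merit_matches_final_fe_run(self, coarse_sim, target, fit5):
        """The reported merit equals a fresh cold-started forward evaluation."""
        from corneafit.metrics import merit as merit_fn

        cfg, res = fit5
        m = compute_metrics(coarse_sim.metrics_record(res.params, warm_start=False))
        assert abs(merit_fn(target, m, cfg.weight_cpr) - res.merit) < 1e-10

    def test_best_verified_merit_nonincreasing(self, fit5):
        _, res = fit5
        merits = [e["merit"] for e in res.evaluations]
        running = np.minimum.accumulate(merits)
        assert np.all(np.diff(running) <= 0.0)

    def test_unreachable_target_flags_nonconvergence(self, coarse_sim):
        """A DA larger than achievable at the softest bound cannot be fitted."""
        impossible = DeformationMetrics(da=5.0, pda=2.5, cpr=2.0, thc_ms=15.0)
        cfg = InverseConfig(
            c10_bounds=(0.05, 0.2), c01_bounds=(0.05, 0.2), rng_seed=7,
            n_initial_samples=6, max_fe_evaluations=10, ga_population=20,
            ga_generations=15,
        )
        res = fit_material(
            impossible, coarse_sim.geom, 15.0, coarse_sim.load, cfg,
            mesh=coarse_sim.mesh,
        )
        assert not res.converged
        # the best effort sits at/near the soft (lower) bound
        assert res.params.c10 < 0.08 and res.params.c01 < 0.08

    def test_nonfinite_measured_metrics_rejected(self, coarse_sim):
        bad = DeformationMetrics(da=np.inf, pda=1.0, cpr=2.0, thc_ms=15.0)
        with pytest.raises(Exception):
            fit_material(bad, coarse_sim.geom, 15.0, coarse_sim.load,
                         InverseConfig(**SMALL), mesh=coarse_sim.mesh)
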