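"""Solver verification: oracles, tangent consistency, physical invariants."""

from __future__ import annotations

import numpy as np
import pytest

from corneafit.errors import NonConvergenceError
from corneafit.fe_engine import FEModel, LoadCase, check_tangent, solve_static
from corneafit.geometry import (
    CorneaGeometry,
    build_cap_mesh,
    build_cylinder_mesh,
    build_mesh,
    build_plate_mesh,
)
from corneafit.materials import MooneyRivlinParams, uniaxial_nominal_stress

MR = MooneyRivlinParams(0.03, 0.015)


def cylinder_model(lam_target: float, nr: int = 2, nz: int = 6):
    """Cylinder stretched by prescribed end displacement (driven problem)."""
    mesh = build_cylinder_mesh(1.0, 3.0, nr=nr, nz=nz)
    top = mesh.node_sets["top"]
    ddofs = top * 2 + 1
    dvals = np.full(len(top), (lam_target - 1.0) * 3.0)
    model = FEModel(mesh, {"cornea": MR}, driven=(ddofs, dvals))
    model.fixed[mesh.node_sets["bottom"] * 2 + 1] = True
    model.free = ~model.fixed
    model.set_load()
    return mesh, model, ddofs


class TestSolveStatic:
    def test_zero_load_gives_zero_displacement(self):
        mesh = build_cap_mesh(8.8, 0.55, 60.0, 2, 24)
        field = solve_static(mesh, MR, None, LoadCase(), n_increments=1)
        assert field.converged
        assert np.abs(field.u).max() == 0.0

    def test_uniaxial_cylinder_matches_closed_form(self):
        lam = 1.2
        mesh, model, ddofs = cylinder_model(lam)
        res = model.march(1.0, n_increments=4, tol=1e-8)
        r, _ = model.residual(res.u.ravel(), 1.0)
        p_fe = r[ddofs].sum() / (np.pi * 1.0**2)
        assert p_fe == pytest.approx(uniaxial_nominal_stress(lam, MR), rel=0.01)

    def test_laplace_membrane_stress_at_apex(self):
        """Thin pressurised cap: apex biaxial Cauchy stress ~ p R / (2 t)."""
        p, rmid, t = 0.002, 8.8, 0.55
        mesh = build_cap_mesh(rmid, t, 60.0, n_tt=4, n_mer=60)
        model = FEModel(mesh, {"cornea": MR})
        model.set_load(ramp=LoadCase(internal_pressure=p))
        res = model.march(1.0, n_increments=5, tol=1e-6)
        sig = model.cauchy_stress(res.u.ravel())
        n_mer = 60
        apex_col = np.arange(0, 4 * n_mer, n_mer)  # elements touching the axis
        hoop = sig[0][apex_col][:, :, 2, 2].mean() + sig[1][apex_col][:, :, 2, 2].mean()
        assert hoop == pytest.approx(p * rmid / (2 * t), rel=0.05)

    def test_nonconvergence_reports_load_fraction(self):
        mesh = build_cap_mesh(8.8, 0.35, 60.0, 2, 30)
        model = FEModel(mesh, {"cornea": MR})
        # absurd pressure: the shell cannot equilibrate the full load
        model.set_load(ramp=LoadCase(internal_pressure=5.0))
        with pytest.raises(NonConvergenceError) as exc:
            model.march(1.0, n_increments=4, tol=1e-6)
        assert 0.0 <= exc.value.last_converged_fraction < 1.0


class TestTangentConsistency:
    def test_identity_state_no_load(self):
        mesh, model, _ = cylinder_model(1.2, nr=2, nz=3)
        u = np.zeros(model.ndof)
        assert check_tangent(model, u, 0.0) < 1e-6

    def test_random_perturbed_state(self, rng):
        mesh, model, _ = cylinder_model(1.2, nr=2, nz=3)
        res = model.march(0.5, n_increments=3, tol=1e-8)
        u = res.u.ravel() + 0.01 * rng.standard_normal(model.ndof)
        u[model.fixed] = res.u.ravel()[model.fixed]
        assert check_tangent(model, u, 0.5) < 1e-4

    def test_follower_pressure_load_stiffness_included(self):
        mesh = build_cap_mesh(8.8, 0.55, 50.0, 2, 20)
        model = FEModel(mesh, {"cornea": MR})
        model.set_load(ramp=LoadCase(internal_pressure=0.002))
        res = model.march(1.0, n_increments=4, tol=1e-6)
        assert check_tangent(model, res.u.ravel(), 1.0) < 1e-4


@pytest.fixture(scope="module")
def inflated():
    mesh = build_mesh(CorneaGeometry(thickness=0.45), 3, 48)
    model = FEModel(mesh, {"cornea": MR, "holder": CorneaGeometry().holder})
    model.set_load(ramp=LoadCase(internal_pressure=15 * 1.33322e-4))
    res = model.march(1.0, n_increments=5, tol=1e-6)
    return mesh, model, res


class TestPhysicalInvariants:
    def test_near_incompressibility(self, inflated):
        """Corneal volume change stays below 0.5% at full load."""
        _, model, res = inflated
        assert model.volume_change(res.u.ravel()) < 0.005

    def test_increment_count_does_not_change_solution(self, inflated):
        """Elastic quasi-statics is path independent: doubling the load
        increments moves the apex by < 0.1%."""
        mesh, model, res = inflated
        res2 = model.march(1.0, n_increments=10, tol=1e-6)
        apex = mesh.node_sets["apex_anterior"][0]
        z1 = res.u[apex, 1]
        z2 = res2.u[apex, 1]
        assert abs(z2 - z1) / abs(z1) < 1e-3

    def test_solution_invariant_under_node_reordering(self):
        mesh = build_cap_mesh(8.8, 0.55, 50.0, 2, 24)
        load = LoadCase(internal_pressure=0.002)
        ref = solve_static(mesh, MR, None, load, n_increments=4, tol=1e-9)

        rng = np.random.default_rng(7)
        perm = rng.permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        from corneafit.geometry import Mesh

        mesh2 = Mesh(
            nodes=mesh.nodes[inv],
            elems=perm[mesh.elems],
            regions=mesh.regions,
            node_sets={k: perm[v] for k, v in mesh.node_sets.items()},
            edge_sets={k: perm[v] for k, v in mesh.edge_sets.items()},
            meta=mesh.meta,
        )
        res2 = solve_static(mesh2, MR, None, load, n_increments=4, tol=1e-9)
        assert np.abs(res2.u[perm] - ref.u).max() <= 1e-8 * np.abs(ref.u).max()

    def test_thin_plate_bending_free_of_volumetric_locking(self):
        """Clamped circular plate deflection vs Kirchhoff theory within 5%.

        With a naive fully integrated near-incompressible element the plate
        would lock and deflect a fraction of the analytic value; the
        selective reduced integration must recover thin-bending behaviour.
        """
        a, t = 5.0, 0.25
        mr = MooneyRivlinParams(0.3, 0.1)
        mu, kappa = mr.shear_modulus, mr.bulk_penalty
        nu = (3 * kappa - 2 * mu) / (2 * (3 * kappa + mu))
        e = 2 * mu * (1 + nu)
        d = e * t**3 / (12 * (1 - nu**2))
        w_target = 0.002  # << t: linear regime
        p = w_target * 64 * d / a**4
        mesh = build_plate_mesh(a, t, n_t=4, n_r=80)
        model = FEModel(mesh, {"cornea": mr})
        model.set_load(
            ramp=LoadCase(external_pressure_field=lambda r: np.full_like(r, p))
        )
        res = model.march(1.0, n_increments=2, tol=1e-7)
        w_c = -res.u[mesh.node_sets["center_bottom"][0], 1]
        assert w_c == pytest.approx(w_target, rel=0.05)
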