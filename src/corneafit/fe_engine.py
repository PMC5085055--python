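"""Quasi-static nonlinear axisymmetric finite-element solver.

Total-Lagrangian kinematics on 4-node bilinear quadrilaterals with an
axisymmetric hoop stretch.  Near-incompressibility of the Mooney-Rivlin
cornea is handled by selective reduced integration: the deviatoric
(isochoric) stress is integrated at the full 2x2 Gauss rule while the
volumetric penalty is integrated at the single element centre, which removes
volumetric locking without extra pressure unknowns.  The stiff holder ring
uses a Saint Venant-Kirchhoff material at the full rule.

Pressure loads (the intraocular pressure on the wetted posterior surface and
the air-puff field on the anterior surface) are *follower* loads: they act
normal to the deformed surface and contribute a load-stiffness term to the
tangent.  Consistent tangents are assembled from exact constitutive
derivatives obtained by complex-step differentiation of the analytic
``S(C)`` stress functions, so Newton converges quadratically.

The solver marches the load with automatic increment halving (at most 5
halvings) and reports equilibrium when ``||R_free|| <= tol * ref`` where
``ref`` is the larger of the external-force and reaction-force norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from corneafit.errors import ConfigurationError, NonConvergenceError
from corneafit.geometry import Mesh
from corneafit.materials import (
    LinearElasticParams,
    MooneyRivlinParams,
    second_pk_isochoric,
    second_pk_svk,
    second_pk_volumetric,
)

__all__ = ["LoadCase", "DisplacementField", "FEModel", "solve_static", "check_tangent"]

_G = 1.0 / np.sqrt(3.0)
_GP_FULL = [(-_G, -_G, 1.0), (_G, -_G, 1.0), (_G, _G, 1.0), (-_G, _G, 1.0)]
_GP_CENTER = [(0.0, 0.0, 4.0)]
_CSTEP = 1e-30


@dataclass(frozen=True)
class LoadCase:
    """Static pressure loading at one instant.

    ``internal_pressure`` (MPa) acts uniformly on the wetted posterior
    surface (the IOP); ``external_pressure_field`` maps the reference lateral
    coordinate r (mm) to an anterior pressure (MPa) -- the air puff frozen at
    one instant.
    """

    internal_pressure: float = 0.0
    external_pressure_field: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.internal_pressure < 0.0:
            raise ConfigurationError("internal_pressure must be >= 0")


@dataclass
class DisplacementField:
    """Converged nodal solution (u_r, u_z) in mm plus solve diagnostics."""

    u: np.ndarray
    converged: bool
    residual_norm: float
    history: list = field(default_factory=list)


def _shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    n = 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )
    dn = 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )
    return n, dn


class _Block:
    """Vectorised element block: one region x one Gauss rule x one S(C)."""

    def __init__(self, nodes: np.ndarray, elems: np.ndarray, gps, sfun) -> None:
        self.sfun = sfun
        ne = elems.shape[0]
        ng = len(gps)
        xe = nodes[elems]  # (E, 4, 2)
        self.dofs = np.empty((ne, 8), dtype=np.intp)
        self.dofs[:, 0::2] = elems * 2
        self.dofs[:, 1::2] = elems * 2 + 1
        self.w = np.empty((ne, ng))
        self.dF = np.zeros((ne, ng, 8, 3, 3))
        for g, (xi, eta, gw) in enumerate(gps):
            n, dn = _shape(xi, eta)
            j0 = np.einsum("eai,aj->eij", xe, dn)
            detj = j0[:, 0, 0] * j0[:, 1, 1] - j0[:, 0, 1] * j0[:, 1, 0]
            if np.any(detj <= 0.0):
                raise ConfigurationError("non-positive element Jacobian")
            inv = np.empty_like(j0)
            inv[:, 0, 0] = j0[:, 1, 1]
            inv[:, 0, 1] = -j0[:, 0, 1]
            inv[:, 1, 0] = -j0[:, 1, 0]
            inv[:, 1, 1] = j0[:, 0, 0]
            inv /= detj[:, None, None]
            dndx = np.einsum("aj,eji->eai", dn, inv)  # (E, 4, 2)
            r = xe[:, :, 0] @ n  # (E,)
            self.w[:, g] = gw * detj * 2.0 * np.pi * r
            for a in range(4):
                self.dF[:, g, 2 * a, 0, 0] = dndx[:, a, 0]
                self.dF[:, g, 2 * a, 0, 1] = dndx[:, a, 1]
                self.dF[:, g, 2 * a, 2, 2] = n[a] / r
                self.dF[:, g, 2 * a + 1, 1, 0] = dndx[:, a, 0]
                self.dF[:, g, 2 * a + 1, 1, 1] = dndx[:, a, 1]
        # geometric-stiffness kernel with weights folded in:
        # Gw[e,g,a,b,i,j] = w[e,g] * sum_k dF[e,g,a,k,i] dF[e,g,b,k,j]
        self.Gw = np.einsum("eg,egaki,egbkj->egabij", self.w, self.dF, self.dF)
        self.rows = np.repeat(self.dofs, 8, axis=1).ravel()
        self.cols = np.tile(self.dofs, (1, 8)).ravel()

    def deformation(self, uflat: np.ndarray):
        ue = uflat[self.dofs]  # (E, 8)
        f = np.einsum("ed,egdij->egij", ue, self.dF)
        f[..., 0, 0] += 1.0
        f[..., 1, 1] += 1.0
        f[..., 2, 2] += 1.0
        c = np.einsum("egki,egkj->egij", f, f)
        return f, c

    def internal_force(self, uflat: np.ndarray, out: np.ndarray) -> None:
        # trial Newton states may carry J <= 0; the resulting NaNs are
        # detected by the solver, so the numpy warnings are suppressed here
        with np.errstate(divide="ignore", invalid="ignore"):
            f, c = self.deformation(uflat)
            s = self.sfun(c)
            dc = np.einsum("egki,egdkj->egdij", f, self.dF)
            dc = dc + dc.swapaxes(-1, -2)
            fe = 0.5 * np.einsum("eg,egij,egdij->ed", self.w, s, dc)
        np.add.at(out, self.dofs, fe)

    def stiffness(self, uflat: np.ndarray) -> np.ndarray:
        """Element stiffness matrices (E, 8, 8): material + geometric parts."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f, c = self.deformation(uflat)
            s = self.sfun(c)
            dc = np.einsum("egki,egdkj->egdij", f, self.dF)
            dc = dc + dc.swapaxes(-1, -2)
            ds = self.sfun(c[:, :, None] + 1j * _CSTEP * dc).imag / _CSTEP
            kmat = 0.5 * np.einsum("eg,egaij,egbij->eab", self.w, dc, ds)
            kgeo = np.einsum("egabij,egij->eab", self.Gw, s)
        return kmat + kgeo

    def volumes(self, uflat: np.ndarray) -> tuple[float, float]:
        """(reference volume, deformed volume) integrated at this block's GPs."""
        f, _ = self.deformation(uflat)
        det = np.linalg.det(f)
        v0 = float(self.w.sum())
        v = float((self.w * det).sum())
        return v0, v


class _PressureSet:
    """Follower pressure on a chain of boundary edges.

    ``sign=+1`` pushes along ``(dz, -dr)`` of the (deformed) edge tangent --
    the convention for the anterior surface with chains ordered from the axis
    outward; ``sign=-1`` is the wetted posterior surface (IOP pushing the
    shell toward the nozzle).
    """

    def __init__(self, nodes: np.ndarray, edges: np.ndarray, pref: np.ndarray, sign: float):
        self.edges = edges
        self.xref = nodes[edges]  # (M, 2, 2)
        self.pref = pref  # (M, 2) magnitude at the 2 edge Gauss points
        self.sign = sign
        self.dofs = np.empty((edges.shape[0], 4), dtype=np.intp)
        self.dofs[:, 0] = edges[:, 0] * 2
        self.dofs[:, 1] = edges[:, 0] * 2 + 1
        self.dofs[:, 2] = edges[:, 1] * 2
        self.dofs[:, 3] = edges[:, 1] * 2 + 1
        self.rows = np.repeat(self.dofs, 4, axis=1).ravel()
        self.cols = np.tile(self.dofs, (1, 4)).ravel()

    def _force(self, x: np.ndarray) -> np.ndarray:
        """Edge force vectors (M, 4) given deformed edge coords (M, 2, 2)."""
        dr = 0.5 * (x[:, 1, 0] - x[:, 0, 0])
        dz = 0.5 * (x[:, 1, 1] - x[:, 0, 1])
        f = np.zeros((x.shape[0], 4), dtype=x.dtype)
        for g, xi in enumerate((-_G, _G)):
            n1, n2 = 0.5 * (1 - xi), 0.5 * (1 + xi)
            r = n1 * x[:, 0, 0] + n2 * x[:, 1, 0]
            coef = self.pref[:, g] * 2.0 * np.pi * r * self.sign
            f[:, 0] += coef * n1 * dz
            f[:, 1] -= coef * n1 * dr
            f[:, 2] += coef * n2 * dz
            f[:, 3] -= coef * n2 * dr
        return f

    def external_force(self, uflat: np.ndarray, scale: float, out: np.ndarray) -> None:
        x = self.xref + uflat[self.dofs].reshape(-1, 2, 2)
        np.add.at(out, self.dofs, scale * self._force(x))

    def stiffness(self, uflat: np.ndarray, scale: float) -> np.ndarray:
        """Load-stiffness d f_ext / d u, (M, 4, 4), by complex step."""
        x0 = self.xref + uflat[self.dofs].reshape(-1, 2, 2)
        k = np.empty((x0.shape[0], 4, 4))
        for d in range(4):
            x = x0.astype(complex)
            x.reshape(-1, 4)[:, d] += 1j * _CSTEP
            k[:, :, d] = scale * self._force(x).imag / _CSTEP
        return k


class FEModel:
    """Assembled axisymmetric model: mesh + materials + constraints + loads."""

    def __init__(
        self,
        mesh: Mesh,
        materials: dict[str, MooneyRivlinParams | LinearElasticParams],
        driven: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        self.mesh = mesh
        self.materials = dict(materials)
        self.ndof = 2 * mesh.n_nodes
        self.blocks: list[_Block] = []
        self._region_blocks: dict[str, list[_Block]] = {}
        for region, eids in mesh.regions.items():
            if len(eids) == 0:
                continue
            mat = materials.get(region)
            if mat is None:
                raise ConfigurationError(f"no material for region '{region}'")
            elems = mesh.elems[eids]
            if isinstance(mat, MooneyRivlinParams):
                blocks = [
                    _Block(mesh.nodes, elems, _GP_FULL, None),
                    _Block(mesh.nodes, elems, _GP_CENTER, None),
                ]
            elif isinstance(mat, LinearElasticParams):
                blocks = [_Block(mesh.nodes, elems, _GP_FULL, None)]
            else:
                raise ConfigurationError(f"unsupported material type for '{region}'")
            self._region_blocks[region] = blocks
            self.blocks.extend(blocks)
            self.set_material(region, mat)

        fixed = np.zeros(self.ndof, dtype=bool)
        self.dirichlet_values = np.zeros(self.ndof)
        if "axis" in mesh.node_sets:
            fixed[mesh.node_sets["axis"] * 2] = True  # u_r = 0 on the axis
        if "fixed" in mesh.node_sets:
            fixed[mesh.node_sets["fixed"] * 2] = True
            fixed[mesh.node_sets["fixed"] * 2 + 1] = True
        if driven is not None:
            ddofs, dvals = driven
            fixed[ddofs] = True
            self.dirichlet_values[ddofs] = dvals  # scaled by the load factor
        self.fixed = fixed
        self.free = ~fixed
        self.base_sets: list[_PressureSet] = []
        self.ramp_sets: list[_PressureSet] = []

    def set_material(
        self, region: str, mat: MooneyRivlinParams | LinearElasticParams
    ) -> None:
        """Swap the material of a region without re-deriving mesh quantities.

        The expensive per-element kinematic precomputations depend only on
        the mesh, so the inverse loop can re-parameterise the cornea cheaply.
        """
        blocks = self._region_blocks[region]
        if isinstance(mat, MooneyRivlinParams):
            if len(blocks) != 2:
                raise ConfigurationError(f"region '{region}' is not hyperelastic")
            blocks[0].sfun = lambda c, m=mat: second_pk_isochoric(c, m.c10, m.c01)
            blocks[1].sfun = lambda c, m=mat: second_pk_volumetric(c, m.bulk_penalty)
        elif isinstance(mat, LinearElasticParams):
            if len(blocks) != 1:
                raise ConfigurationError(f"region '{region}' is not linear elastic")
            lam, mu = mat.lame
            blocks[0].sfun = lambda c, lam=lam, mu=mu: second_pk_svk(c, lam, mu)
        else:
            raise ConfigurationError("unsupported material type")
        self.materials[region] = mat

    # ------------------------------------------------------------------ loads

    def _make_sets(self, load: LoadCase) -> list[_PressureSet]:
        sets = []
        es = self.mesh.edge_sets
        if load.internal_pressure > 0.0 and "posterior_wetted" in es:
            edges = es["posterior_wetted"]
            pref = np.full((edges.shape[0], 2), load.internal_pressure)
            sets.append(_PressureSet(self.mesh.nodes, edges, pref, sign=-1.0))
        if load.external_pressure_field is not None and "anterior" in es:
            edges = es["anterior"]
            x = self.mesh.nodes[edges]
            pref = np.empty((edges.shape[0], 2))
            for g, xi in enumerate((-_G, _G)):
                n1, n2 = 0.5 * (1 - xi), 0.5 * (1 + xi)
                rg = n1 * x[:, 0, 0] + n2 * x[:, 1, 0]
                pref[:, g] = load.external_pressure_field(rg)
            if np.any(pref != 0.0):
                sets.append(_PressureSet(self.mesh.nodes, edges, pref, sign=1.0))
        return sets

    def set_load(self, base: LoadCase | None = None, ramp: LoadCase | None = None) -> None:
        """Configure the load: ``base`` held constant, ``ramp`` scaled by the factor."""
        self.base_sets = self._make_sets(base) if base is not None else []
        self.ramp_sets = self._make_sets(ramp) if ramp is not None else []

    # ------------------------------------------------------------- assembly

    def external_force(self, uflat: np.ndarray, factor: float) -> np.ndarray:
        fext = np.zeros(self.ndof)
        for ps in self.base_sets:
            ps.external_force(uflat, 1.0, fext)
        for ps in self.ramp_sets:
            ps.external_force(uflat, factor, fext)
        return fext

    def internal_force(self, uflat: np.ndarray) -> np.ndarray:
        fint = np.zeros(self.ndof)
        for b in self.blocks:
            b.internal_force(uflat, fint)
        return fint

    def residual(self, uflat: np.ndarray, factor: float) -> tuple[np.ndarray, float]:
        """Out-of-balance force R = f_int - f_ext and the convergence reference."""
        fext = self.external_force(uflat, factor)
        r = self.internal_force(uflat) - fext
        ref = max(
            float(np.linalg.norm(fext[self.free])),
            float(np.linalg.norm(r[self.fixed])),  # reaction magnitude
        )
        return r, ref

    def tangent(self, uflat: np.ndarray, factor: float) -> sp.csr_matrix:
        rows, cols, data = [], [], []
        for b in self.blocks:
            ke = b.stiffness(uflat)
            rows.append(b.rows)
            cols.append(b.cols)
            data.append(ke.ravel())
        for ps, scale in [(p, 1.0) for p in self.base_sets] + [
            (p, factor) for p in self.ramp_sets
        ]:
            ke = -ps.stiffness(uflat, scale)  # K = dR/du = K_int - d f_ext/du
            rows.append(ps.rows)
            cols.append(ps.cols)
            data.append(ke.ravel())
        k = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        )
        return k.tocsr()

    # --------------------------------------------------------------- solving

    def _newton(
        self,
        uflat: np.ndarray,
        factor: float,
        tol: float,
        max_iter: int = 20,
        n_backtrack: int = 6,
    ) -> tuple[np.ndarray, float, bool, int]:
        """Full Newton; backtracks only on non-finite trial states (J <= 0).

        Force-residual norms of thin shells are strongly non-monotone over
        the first iterations, so no sufficient-decrease condition is
        enforced; divergence is detected by persistent growth and handed to
        the increment-halving driver.
        """
        u = uflat.copy()
        u[self.fixed] = factor * self.dirichlet_values[self.fixed]
        free = self.free
        r, ref = self.residual(u, factor)
        rn = float(np.linalg.norm(r[free]))
        if not np.isfinite(rn):
            return u, rn, False, 0
        rn0 = max(rn, 1e-12)
        for it in range(max_iter):
            if rn <= tol * max(ref, 1e-12):
                return u, rn, True, it
            if rn > 1e6 * rn0:
                return u, rn, False, it  # diverging
            k = self.tangent(u, factor)
            kff = k[free][:, free].tocsc()
            try:
                du = splu(kff).solve(-r[free])
            except RuntimeError:
                return u, rn, False, it
            if not np.all(np.isfinite(du)):
                return u, rn, False, it
            alpha = 1.0
            for _ in range(n_backtrack):
                utry = u.copy()
                utry[free] += alpha * du
                rtry, reftry = self.residual(utry, factor)
                rtn = float(np.linalg.norm(rtry[free]))
                if np.isfinite(rtn):
                    u, r, ref, rn = utry, rtry, reftry, rtn
                    break
                alpha *= 0.5
            else:
                return u, rn, False, it
            # roundoff floor: the force residual cancels large element
            # contributions, so accept when the update itself stagnates
            dun = alpha * float(np.linalg.norm(du))
            if dun <= 1e-12 * max(float(np.linalg.norm(u[free])), 1e-12):
                return u, rn, True, it + 1
        return u, rn, rn <= tol * max(ref, 1e-12), max_iter

    def march(
        self,
        target: float = 1.0,
        n_increments: int = 20,
        tol: float = 1e-6,
        u0: np.ndarray | None = None,
        start: float = 0.0,
        max_halvings: int = 5,
    ) -> DisplacementField:
        """Incrementally advance the ramp factor from ``start`` to ``target``."""
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        f = start
        df0 = (target - start) / max(n_increments, 1)
        df = df0
        halvings = 0
        history: list[tuple[float, int]] = []
        rn = 0.0
        while f < target - 1e-12:
            ftry = min(f + df, target)
            unew, rn, ok, nit = self._newton(u, ftry, tol)
            if ok:
                u, f = unew, ftry
                history.append((f, nit))
                df = min(df * 1.5, df0)
                halvings = 0  # the limit applies to consecutive halvings
            else:
                halvings += 1
                if halvings > max_halvings:
                    raise NonConvergenceError(
                        f"Newton diverged at load factor {ftry:.4g} after "
                        f"{max_halvings} halvings",
                        last_converged_fraction=f,
                    )
                df *= 0.5
        if not history:  # zero-length ramp: verify equilibrium at 'start'
            u, rn, ok, nit = self._newton(u, target, tol)
            history.append((target, nit))
            if not ok:
                raise NonConvergenceError(
                    "no equilibrium at initial state", last_converged_fraction=0.0
                )
        return DisplacementField(
            u=u.reshape(-1, 2), converged=True, residual_norm=rn, history=history
        )

    # ------------------------------------------------------------ diagnostics

    def cauchy_stress(self, uflat: np.ndarray) -> list[np.ndarray]:
        """Per-block Cauchy stress at the Gauss points, sigma = F S F^T / J."""
        out = []
        for b in self.blocks:
            f, c = b.deformation(uflat)
            s = b.sfun(c)
            det = np.linalg.det(f)
            sig = np.einsum("egik,egkl,egjl->egij", f, s, f) / det[..., None, None]
            out.append(sig)
        return out

    def volume_change(self, uflat: np.ndarray, region_block: int = 0) -> float:
        """Relative volume change |V - V0| / V0 of a block (default: cornea dev)."""
        v0, v = self.blocks[region_block].volumes(uflat)
        return abs(v - v0) / v0


def solve_static(
    mesh: Mesh,
    material: MooneyRivlinParams,
    holder: LinearElasticParams | None,
    load: LoadCase,
    n_increments: int = 20,
    tol: float = 1e-6,
    u0: np.ndarray | None = None,
) -> DisplacementField:
    """Equilibrate the mesh under ``load`` ramped proportionally from zero.

    Pressure loads are follower loads; equilibrium means
    ``||R|| / max(||f_ext||, ||reactions||) < tol`` at the final increment.
    Raises :class:`NonConvergenceError` (carrying the last converged load
    fraction) if Newton diverges even after 5 increment halvings.
    """
    mats: dict[str, MooneyRivlinParams | LinearElasticParams] = {"cornea": material}
    if "holder" in mesh.regions and len(mesh.regions["holder"]):
        if holder is None:
            raise ConfigurationError("mesh has a holder region but no holder material")
        mats["holder"] = holder
    model = FEModel(mesh, mats)
    model.set_load(ramp=load)
    return model.march(1.0, n_increments, tol, u0=u0.ravel() if u0 is not None else None)


def check_tangent(
    model: FEModel,
    uflat: np.ndarray,
    factor: float = 1.0,
    dofs: np.ndarray | None = None,
    h: float = 1e-7,
) -> float:
    """Verify the assembled stiffness against finite differences of the residual.

    Central-differences columns of the global residual are compared with the
    analytic tangent; returns ``max |K_fd - K| / max |K|`` over the probed
    columns (free dofs only).
    """
    k = model.tangent(uflat, factor).toarray()
    free = np.flatnonzero(model.free)
    probe = free if dofs is None else np.intersect1d(dofs, free)
    scale = np.abs(k[np.ix_(free, free)]).max()
    err = 0.0
    for d in probe:
        up, um = uflat.copy(), uflat.copy()
        up[d] += h
        um[d] -= h
        col = (model.residual(up, factor)[0] - model.residual(um, factor)[0]) / (2 * h)
        err = max(err, float(np.abs(col[free] - k[free, d]).max()) / scale)
    return err
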