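"""Hyperelastic constitutive models for corneal tissue and phantom materials.

The cornea (and the hydrogel phantom materials that stand in for it) is
modelled as a two-parameter Mooney-Rivlin solid,

    W = C10 (I1b - 3) + C01 (I2b - 3) + k/2 (J - 1)^2,

where ``I1b``, ``I2b`` are the *isochoric* invariants of the left (or right)
Cauchy-Green tensor, ``J = det F`` is the volume ratio and ``k`` is a large
volumetric penalty enforcing near-incompressibility.  The deviatoric /
volumetric split keeps a pure-displacement finite-element formulation feasible
while staying within ~1e-3 of the fully incompressible response at the default
penalty (``k = 1000 mu``).  At near-incompressibility the difference between
full and isochoric invariants in the deviatoric term is negligible; the
isochoric form is used because it decouples shape change from the penalty.

Units: lengths in mm, stresses/moduli in MPa, forces in N.

The module also provides the exact incompressible uniaxial solution

    P(lam) = 2 (lam - lam^-2) (C10 + C01 / lam)

(first Piola-Kirchhoff / engineering stress), which serves as the independent
oracle for the finite-element strip model, and a small-strain linear elastic
material used for the rigid-like phantom holder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidStateError",
    "MooneyRivlinParams",
    "LinearElasticParams",
    "DeformationState",
    "strain_energy",
    "constitutive_update",
    "uniaxial_nominal_stress",
    "second_pk_isochoric",
    "second_pk_volumetric",
    "second_pk_mooney_rivlin",
    "second_pk_svk",
]


class InvalidStateError(ValueError):
    """A deformation state is physically inadmissible (e.g. ``J <= 0``)."""


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Mooney-Rivlin material constants.

    Parameters
    ----------
    c10, c01:
        The two deviatoric constants in MPa.  The small-strain shear modulus
        is ``mu = 2 (c10 + c01)`` and the incompressible small-strain Young's
        modulus is ``E = 3 mu = 6 (c10 + c01)``.
    bulk_penalty:
        Volumetric stiffness ``k`` in MPa.  Defaults to ``1000 mu`` which puts
        the effective Poisson ratio at ~0.4995.  Values below ``100 mu`` leave
        the near-incompressible regime and are rejected.
    """

    c10: float
    c01: float
    bulk_penalty: float | None = None

    def __post_init__(self) -> None:
        mu = 2.0 * (self.c10 + self.c01)
        if not mu > 0.0:
            raise ValueError(f"shear modulus 2*(c10+c01) must be > 0, got {mu}")
        if self.bulk_penalty is None:
            object.__setattr__(self, "bulk_penalty", 1000.0 * mu)
        if self.bulk_penalty < 100.0 * mu:
            raise ValueError(
                f"bulk_penalty={self.bulk_penalty} < 100*mu={100 * mu}: "
                "outside the near-incompressible regime"
            )

    @property
    def shear_modulus(self) -> float:
        return 2.0 * (self.c10 + self.c01)

    @property
    def youngs_modulus(self) -> float:
        """Small-strain Young's modulus of the incompressible solid, 6*(c10+c01)."""
        return 6.0 * (self.c10 + self.c01)


@dataclass(frozen=True)
class LinearElasticParams:
    """Isotropic linear elastic constants (used for the lens holder ring)."""

    youngs_modulus: float
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0.0:
            raise ValueError("youngs_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
        mu = e / (2.0 * (1.0 + nu))
        return lam, mu


# ----------------------------------------------------------------------------
# small complex-safe 3x3 tensor algebra (vectorised over leading axes)

_I3 = np.eye(3)


def _det33(a: np.ndarray) -> np.ndarray:
    return (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )


def _inv33(a: np.ndarray) -> np.ndarray:
    """Explicit cofactor inverse; works on complex input (np.linalg.inv does too,
    but the explicit form avoids LAPACK round trips on tiny stacked arrays)."""
    out = np.empty_like(a)
    out[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    out[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    out[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    out[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    out[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    out[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    out[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    out[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    out[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return out / _det33(a)[..., None, None]


def _invariants(c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """I1, I2, det of a stack of (right or left) Cauchy-Green tensors."""
    i1 = np.trace(c, axis1=-2, axis2=-1)
    cc = c @ c
    i2 = 0.5 * (i1 * i1 - np.trace(cc, axis1=-2, axis2=-1))
    return i1, i2, _det33(c)


# ----------------------------------------------------------------------------
# second Piola-Kirchhoff stress functions, S(C).  All are complex-step safe and
# vectorised over leading axes; the FE engine differentiates them by complex
# perturbation to obtain exact consistent tangents.


def second_pk_isochoric(c: np.ndarray, c10: float, c01: float) -> np.ndarray:
    """Deviatoric Mooney-Rivlin 2nd PK stress, S = 2 dW_iso/dC."""
    i1, i2, detc = _invariants(c)
    j23 = detc ** (-1.0 / 3.0)  # J^{-2/3}
    j43 = detc ** (-2.0 / 3.0)  # J^{-4/3}
    cinv = _inv33(c)
    eye = _I3.astype(c.dtype) if c.dtype != np.float64 else _I3
    term1 = j23[..., None, None] * (eye - (i1 / 3.0)[..., None, None] * cinv)
    term2 = j43[..., None, None] * (
        i1[..., None, None] * eye - c - (2.0 * i2 / 3.0)[..., None, None] * cinv
    )
    return 2.0 * (c10 * term1 + c01 * term2)


def second_pk_volumetric(c: np.ndarray, kappa: float) -> np.ndarray:
    """Volumetric penalty 2nd PK stress, S = 2 d/dC [k/2 (J-1)^2] = k (J-1) J C^-1."""
    j = np.sqrt(_det33(c))
    return (kappa * (j - 1.0) * j)[..., None, None] * _inv33(c)


def second_pk_mooney_rivlin(c: np.ndarray, params: MooneyRivlinParams) -> np.ndarray:
    return second_pk_isochoric(c, params.c10, params.c01) + second_pk_volumetric(
        c, params.bulk_penalty
    )


def second_pk_svk(c: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """Saint Venant-Kirchhoff stress S = lam tr(E) I + 2 mu E, E = (C - I)/2."""
    eye = _I3.astype(c.dtype) if c.dtype != np.float64 else _I3
    e = 0.5 * (c - eye)
    tre = np.trace(e, axis1=-2, axis2=-1)
    return lam * tre[..., None, None] * eye + 2.0 * mu * e


# ----------------------------------------------------------------------------
# point-wise API on deformation states


@dataclass(frozen=True)
class DeformationState:
    """Local deformation at a material point.

    Holds the full 3x3 deformation gradient.  In the axisymmetric setting the
    gradient is an in-plane 2x2 block plus the hoop stretch on the (2, 2)
    entry, but nothing here assumes that structure.
    """

    deformation_gradient: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.deformation_gradient, dtype=float)
        if f.shape != (3, 3):
            raise ValueError("deformation_gradient must be 3x3")
        object.__setattr__(self, "deformation_gradient", f)
        if not self.J > 0.0:
            raise InvalidStateError(f"det(F) = {self.J} <= 0")

    @property
    def J(self) -> float:
        return float(_det33(self.deformation_gradient))

    @property
    def left_cauchy_green(self) -> np.ndarray:
        f = self.deformation_gradient
        return f @ f.T

    @property
    def I1(self) -> float:
        return float(np.trace(self.left_cauchy_green))

    @property
    def I2(self) -> float:
        b = self.left_cauchy_green
        return float(0.5 * (np.trace(b) ** 2 - np.trace(b @ b)))


def strain_energy(state: DeformationState, params: MooneyRivlinParams) -> float:
    """Strain-energy density (MPa) of the near-incompressible Mooney-Rivlin solid.

    Evaluates ``c10 (I1b - 3) + c01 (I2b - 3) + k/2 (J - 1)^2`` with the
    isochoric invariants ``I1b = J^(-2/3) I1``, ``I2b = J^(-4/3) I2``.
    """
    j = state.J
    if not j > 0.0:  # pragma: no cover - guarded in DeformationState
        raise InvalidStateError(f"J = {j} <= 0")
    i1b = j ** (-2.0 / 3.0) * state.I1
    i2b = j ** (-4.0 / 3.0) * state.I2
    return float(
        params.c10 * (i1b - 3.0)
        + params.c01 * (i2b - 3.0)
        + 0.5 * params.bulk_penalty * (j - 1.0) ** 2
    )


def constitutive_update(
    state: DeformationState, params: MooneyRivlinParams
) -> tuple[np.ndarray, np.ndarray]:
    """Cauchy stress and spatial tangent modulus at a material point.

    Returns
    -------
    sigma : (3, 3) ndarray
        Cauchy stress ``sigma = F S F^T / J`` in MPa.
    c_spatial : (3, 3, 3, 3) ndarray
        Spatial elasticity tensor, the push-forward
        ``c_ijkl = J^-1 F_iI F_jJ F_kK F_lL C_IJKL`` of the material tangent
        ``C = 2 dS/dC``.  Minor and major symmetric.

    The material tangent is obtained by complex-step differentiation of the
    analytic ``S(C)`` (exact to machine precision).
    """
    f = state.deformation_gradient
    j = state.J
    c = f.T @ f
    s = second_pk_mooney_rivlin(c, params)
    sigma = f @ s @ f.T / j

    # material tangent C_IJKL = directional derivative of S along (E_KL + E_LK)
    h = 1e-30
    c_mat = np.empty((3, 3, 3, 3))
    for k in range(3):
        for l in range(k, 3):
            dc = np.zeros((3, 3))
            dc[k, l] += 1.0
            dc[l, k] += 1.0
            ds = np.imag(second_pk_mooney_rivlin(c + 1j * h * dc, params)) / h
            c_mat[:, :, k, l] = ds
            c_mat[:, :, l, k] = ds
    c_spatial = np.einsum("iI,jJ,kK,lL,IJKL->ijkl", f, f, f, f, c_mat) / j
    return sigma, c_spatial


def uniaxial_nominal_stress(
    stretch: float | np.ndarray, params: MooneyRivlinParams
) -> float | np.ndarray:
    """Exact incompressible uniaxial nominal (engineering) stress.

    ``P(lam) = 2 (lam - lam^-2) (c10 + c01 / lam)`` -- the closed-form first
    Piola-Kirchhoff stress of an incompressible Mooney-Rivlin bar stretched to
    ``lam``; the volumetric penalty plays no role in the exact solution.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be > 0")
    p = 2.0 * (lam - lam**-2.0) * (params.c10 + params.c01 / lam)
    if np.isscalar(stretch) or np.ndim(stretch) == 0:
        return float(p)
    return p
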