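"""Parametric cornea + holder geometry and structured axisymmetric meshing.

The phantom corneas are spherical shells of uniform thickness: anterior and
posterior surfaces are concentric spheres, so ``anterior_radius =
posterior_radius + thickness``.  The shell is clamped at its periphery in a
rigid-like artificial-chamber holder, modelled as a stiff elastic ring bonded
to the posterior face of the corneal overhang.

Coordinates: ``z`` along the symmetry / air-jet axis, positive toward the air
nozzle; ``r >= 0`` is the lateral (radial) coordinate.  The common centre of
curvature sits at the origin, so the apex of the anterior surface is at
``(0, anterior_radius)``.

All meshes are structured mapped grids of 4-node quadrilaterals, which keeps
meshing deterministic and makes convergence studies trivial.  Besides the
cornea+holder mesh, the module provides three verification geometries
(cylinder, circular plate, clamped spherical cap) used by the solver test
battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import asin, pi

import numpy as np

from corneafit.errors import ConfigurationError
from corneafit.materials import LinearElasticParams

__all__ = [
    "CorneaGeometry",
    "Mesh",
    "build_mesh",
    "build_cylinder_mesh",
    "build_plate_mesh",
    "build_cap_mesh",
]

_GAUSS_2 = 1.0 / np.sqrt(3.0)


@dataclass(frozen=True)
class CorneaGeometry:
    """Spherical-shell cornea geometry plus holder configuration.

    Lengths in mm.  ``anterior_radius`` may be omitted, in which case it is
    derived from the concentric-spheres constraint; when given it must satisfy
    ``anterior_radius == posterior_radius + thickness``.
    """

    posterior_radius: float = 8.60
    thickness: float = 0.55
    anterior_radius: float | None = None
    aperture_radius: float = 5.5
    holder: LinearElasticParams = field(
        default_factory=lambda: LinearElasticParams(1500.0, 0.3)
    )
    holder_width: float = 2.0
    holder_depth: float = 2.0

    def __post_init__(self) -> None:
        if self.posterior_radius <= 0 or self.thickness <= 0:
            raise ConfigurationError("radii and thickness must be positive")
        expected = self.posterior_radius + self.thickness
        if self.anterior_radius is None:
            object.__setattr__(self, "anterior_radius", expected)
        elif abs(self.anterior_radius - expected) > 1e-9:
            raise ConfigurationError(
                f"anterior_radius={self.anterior_radius} != posterior_radius + "
                f"thickness = {expected} (concentric spheres / uniform thickness)"
            )
        if not 0.0 < self.aperture_radius < self.anterior_radius:
            raise ConfigurationError("aperture_radius must be in (0, anterior_radius)")
        rim = self.aperture_radius + self.holder_width
        if rim >= self.posterior_radius:
            raise ConfigurationError(
                "aperture_radius + holder_width must be < posterior_radius"
            )


@dataclass
class Mesh:
    """Axisymmetric quadrilateral mesh with named node and edge sets.

    Attributes
    ----------
    nodes : (N, 2) float array of (r, z) coordinates in mm.
    elems : (E, 4) int array, counter-clockwise connectivity in the (r, z)
        half-plane (positive bilinear Jacobian).
    regions : dict mapping region name ('cornea', 'holder', ...) to the array
        of element indices in it.
    node_sets : dict of named node-index arrays ('axis', 'fixed', ...).
    edge_sets : dict of named (M, 2) arrays of boundary edges, ordered as
        chains from the symmetry axis outward.
    """

    nodes: np.ndarray
    elems: np.ndarray
    regions: dict[str, np.ndarray]
    node_sets: dict[str, np.ndarray]
    edge_sets: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_areas(self) -> np.ndarray:
        """Meridian-plane (cross-section) area of each quad (shoelace)."""
        x = self.nodes[self.elems]  # (E, 4, 2)
        x1 = np.roll(x, -1, axis=1)
        return 0.5 * np.abs(
            np.sum(x[:, :, 0] * x1[:, :, 1] - x1[:, :, 0] * x[:, :, 1], axis=1)
        )

    def to_vtk(self, path, point_data: dict[str, np.ndarray] | None = None) -> None:
        """Export as legacy ASCII VTK (quad cells) for visualisation.

        The (r, z) half-plane maps to (x, y); optional per-node arrays (e.g.
        displacement components) are written as point data.
        """
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\naxisymmetric mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {self.n_nodes} double\n")
            for r, z in self.nodes:
                f.write(f"{r:.9g} {z:.9g} 0\n")
            f.write(f"CELLS {self.n_elems} {5 * self.n_elems}\n")
            for e in self.elems:
                f.write("4 " + " ".join(str(int(i)) for i in e) + "\n")
            f.write(f"CELL_TYPES {self.n_elems}\n")
            f.write("9\n" * self.n_elems)
            if point_data:
                f.write(f"POINT_DATA {self.n_nodes}\n")
                for name, arr in point_data.items():
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in np.asarray(arr, dtype=float):
                        f.write(f"{v:.9g}\n")

    def check(self) -> None:
        """Validate basic mesh invariants; raises ConfigurationError."""
        if np.any(self.nodes[:, 0] < -1e-12):
            raise ConfigurationError("nodes with r < 0")
        if np.any(_gauss_jacobians(self.nodes, self.elems) <= 0.0):
            raise ConfigurationError("non-positive element Jacobian")
        for name, edges in self.edge_sets.items():
            if len(edges) and np.any(edges[:-1, 1] != edges[1:, 0]):
                raise ConfigurationError(f"edge set '{name}' is not a chain")


def _gauss_jacobians(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Bilinear Jacobian determinant at the 2x2 Gauss points, (E, 4)."""
    xe = nodes[elems]  # (E, 4, 2)
    dets = np.empty((elems.shape[0], 4))
    gp = [(-_GAUSS_2, -_GAUSS_2), (_GAUSS_2, -_GAUSS_2),
          (_GAUSS_2, _GAUSS_2), (-_GAUSS_2, _GAUSS_2)]
    for k, (xi, eta) in enumerate(gp):
        dn = 0.25 * np.array(
            [
                [-(1 - eta), -(1 - xi)],
                [(1 - eta), -(1 + xi)],
                [(1 + eta), (1 + xi)],
                [-(1 + eta), (1 - xi)],
            ]
        )  # (4, 2) d N / d(xi, eta)
        j = np.einsum("eai,aj->eij", xe, dn)
        dets[:, k] = j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0]
    return dets


def build_mesh(
    geom: CorneaGeometry,
    n_through_thickness: int = 4,
    n_meridian: int = 100,
    n_holder_depth: int = 3,
) -> Mesh:
    """Structured mesh of the cornea shell plus the bonded holder ring.

    The corneal shell spans polar angles from the apex to the outer edge of
    the holder contact; exactly ``n_through_thickness * n_meridian`` corneal
    elements are generated.  A meridian node line is placed exactly at the
    aperture radius, where the wetted (pressurised) posterior region ends and
    the holder contact begins.  Holder nodes on the contact face are shared
    with the corneal posterior nodes (bonded).
    """
    if n_through_thickness < 2:
        raise ConfigurationError("n_through_thickness must be >= 2")
    if n_meridian < 20:
        raise ConfigurationError("n_meridian must be >= 20")

    rp, t = geom.posterior_radius, geom.thickness
    phi_clamp = asin(geom.aperture_radius / rp)
    phi_end = asin((geom.aperture_radius + geom.holder_width) / rp)

    n2 = int(round(n_meridian * (phi_end - phi_clamp) / phi_end))
    n2 = min(max(n2, 3), n_meridian - 10)
    n1 = n_meridian - n2
    phis = np.concatenate(
        [np.linspace(0.0, phi_clamp, n1 + 1), np.linspace(phi_clamp, phi_end, n2 + 1)[1:]]
    )
    rhos = rp + np.linspace(0.0, t, n_through_thickness + 1)

    nmer1 = n_meridian + 1

    def nid(j: int, i: int) -> int:  # layer j (posterior=0), meridian station i
        return j * nmer1 + i

    rr, pp = np.meshgrid(rhos, phis, indexing="ij")
    nodes = np.column_stack([(rr * np.sin(pp)).ravel(), (rr * np.cos(pp)).ravel()])
    nodes[0::nmer1, 0] = 0.0  # snap axis nodes exactly

    elems = []
    for j in range(n_through_thickness):
        for i in range(n_meridian):
            elems.append([nid(j, i), nid(j, i + 1), nid(j + 1, i + 1), nid(j + 1, i)])
    n_cornea = len(elems)

    # holder ring: extrude the posterior contact nodes (i >= n1) downward (-z)
    contact = [nid(0, i) for i in range(n1, n_meridian + 1)]
    n_base = nodes.shape[0]
    layers = [np.asarray(contact)]
    extra = []
    for k in range(1, n_holder_depth + 1):
        dz = k * geom.holder_depth / n_holder_depth
        pts = nodes[contact].copy()
        pts[:, 1] -= dz
        ids = np.arange(n_base + (k - 1) * len(contact), n_base + k * len(contact))
        extra.append(pts)
        layers.append(ids)
    nodes = np.vstack([nodes] + extra)
    for k in range(n_holder_depth):
        top, bot = layers[k], layers[k + 1]
        for i in range(len(contact) - 1):
            elems.append([bot[i], bot[i + 1], top[i + 1], top[i]])
    elems = np.asarray(elems, dtype=np.intp)

    regions = {
        "cornea": np.arange(n_cornea, dtype=np.intp),
        "holder": np.arange(n_cornea, elems.shape[0], dtype=np.intp),
    }
    axis_nodes = np.array(
        [nid(j, 0) for j in range(n_through_thickness + 1)], dtype=np.intp
    )
    fixed = np.unique(
        np.concatenate(
            [layers[-1], [layers[k][-1] for k in range(1, n_holder_depth + 1)]]
        )
    ).astype(np.intp)
    jn = n_through_thickness
    node_sets = {
        "axis": axis_nodes,
        "fixed": fixed,
        "apex_anterior": np.array([nid(jn, 0)], dtype=np.intp),
        "apex_posterior": np.array([nid(0, 0)], dtype=np.intp),
        "anterior_surface": np.array([nid(jn, i) for i in range(nmer1)], dtype=np.intp),
        "posterior_surface": np.array([nid(0, i) for i in range(nmer1)], dtype=np.intp),
        "holder_contact": np.asarray(contact, dtype=np.intp),
    }
    edge_sets = {
        "anterior": np.array(
            [[nid(jn, i), nid(jn, i + 1)] for i in range(n_meridian)], dtype=np.intp
        ),
        "posterior_wetted": np.array(
            [[nid(0, i), nid(0, i + 1)] for i in range(n1)], dtype=np.intp
        ),
    }
    mesh = Mesh(
        nodes=nodes,
        elems=elems,
        regions=regions,
        node_sets=node_sets,
        edge_sets=edge_sets,
        meta={
            "geometry": geom,
            "n_through_thickness": n_through_thickness,
            "n_meridian": n_meridian,
            "phi_clamp": phi_clamp,
            "phi_end": phi_end,
            "i_clamp": n1,
        },
    )
    mesh.check()
    return mesh


# ----------------------------------------------------------------------------
# verification geometries


def _grid_mesh(rs: np.ndarray, zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nr, nz = len(rs) - 1, len(zs) - 1
    rr, zz = np.meshgrid(rs, zs, indexing="ij")  # node (i, j) -> i * (nz+1) + j
    nodes = np.column_stack([rr.ravel(), zz.ravel()])

    def nid(i, j):
        return i * (nz + 1) + j

    elems = np.array(
        [
            [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
            for i in range(nr)
            for j in range(nz)
        ],
        dtype=np.intp,
    )
    return nodes, elems


def build_cylinder_mesh(radius: float, length: float, nr: int = 4, nz: int = 8) -> Mesh:
    """Solid circular cylinder (axis = z), used for uniaxial-tension verification."""
    nodes, elems = _grid_mesh(np.linspace(0, radius, nr + 1), np.linspace(0, length, nz + 1))
    nz1 = nz + 1
    node_sets = {
        "axis": np.arange(nz1, dtype=np.intp),
        "bottom": np.arange(0, nodes.shape[0], nz1, dtype=np.intp),
        "top": np.arange(nz, nodes.shape[0], nz1, dtype=np.intp),
    }
    mesh = Mesh(nodes, elems, {"cornea": np.arange(elems.shape[0], dtype=np.intp)},
                node_sets, {}, {"radius": radius, "length": length})
    mesh.check()
    return mesh


def build_plate_mesh(radius: float, thickness: float, n_t: int = 4, n_r: int = 60) -> Mesh:
    """Clamped circular plate (pressure on the top face), for bending/locking tests."""
    nodes, elems = _grid_mesh(
        np.linspace(0, radius, n_r + 1), np.linspace(0, thickness, n_t + 1)
    )
    nt1 = n_t + 1
    top = np.arange(n_t, nodes.shape[0], nt1, dtype=np.intp)  # z = thickness, r increasing
    node_sets = {
        "axis": np.arange(nt1, dtype=np.intp),
        "fixed": np.arange(n_r * nt1, nodes.shape[0], dtype=np.intp),  # outer column
        "center_bottom": np.array([0], dtype=np.intp),
    }
    edge_sets = {"anterior": np.column_stack([top[:-1], top[1:]])}
    mesh = Mesh(nodes, elems, {"cornea": np.arange(elems.shape[0], dtype=np.intp)},
                node_sets, edge_sets, {"radius": radius, "thickness": thickness})
    mesh.check()
    return mesh


def build_cap_mesh(
    mid_radius: float,
    thickness: float,
    phi_end_deg: float = 60.0,
    n_tt: int = 4,
    n_mer: int = 60,
) -> Mesh:
    """Clamped spherical cap with internal pressure on the full inner surface.

    Used for the Laplace-law membrane-stress verification: at the apex of a
    thin pressurised cap the biaxial Cauchy stress is ~ p R / (2 t).
    """
    rp = mid_radius - 0.5 * thickness
    phi_end = phi_end_deg * pi / 180.0
    phis = np.linspace(0.0, phi_end, n_mer + 1)
    rhos = rp + np.linspace(0.0, thickness, n_tt + 1)
    rr, pp = np.meshgrid(rhos, phis, indexing="ij")
    nodes = np.column_stack([(rr * np.sin(pp)).ravel(), (rr * np.cos(pp)).ravel()])
    nmer1 = n_mer + 1
    nodes[0::nmer1, 0] = 0.0

    def nid(j, i):
        return j * nmer1 + i

    elems = np.array(
        [
            [nid(j, i), nid(j, i + 1), nid(j + 1, i + 1), nid(j + 1, i)]
            for j in range(n_tt)
            for i in range(n_mer)
        ],
        dtype=np.intp,
    )
    node_sets = {
        "axis": np.array([nid(j, 0) for j in range(n_tt + 1)], dtype=np.intp),
        "fixed": np.array([nid(j, n_mer) for j in range(n_tt + 1)], dtype=np.intp),
        "apex_anterior": np.array([nid(n_tt, 0)], dtype=np.intp),
    }
    edge_sets = {
        "posterior_wetted": np.array(
            [[nid(0, i), nid(0, i + 1)] for i in range(n_mer)], dtype=np.intp
        ),
        "anterior": np.array(
            [[nid(n_tt, i), nid(n_tt, i + 1)] for i in range(n_mer)], dtype=np.intp
        ),
    }
    mesh = Mesh(nodes, elems, {"cornea": np.arange(elems.shape[0], dtype=np.intp)},
                node_sets, edge_sets,
                {"mid_radius": mid_radius, "thickness": thickness})
    mesh.check()
    return mesh
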