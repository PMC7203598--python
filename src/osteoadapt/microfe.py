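"""Matrix-free voxel finite-element solver for linear elasticity.

Every bone voxel becomes one linear 8-node hexahedral element; because all
elements are identical cubes a single element stiffness matrix is shared
across the model and the global stiffness action ``K u`` is evaluated
element-by-element (gather / dense multiply / scatter-add) without ever
assembling ``K``.  The preconditioned conjugate-gradient solve with a
Jacobi (diagonal) preconditioner is deterministic for a fixed tolerance.

Boundary conditions follow the physiological tibia compression setup:
all nodes on the proximal (max z) surface are fully constrained, and the
distal (min z) surface nodes are kinematically coupled to a reference
point at the distal area centroid whose rotations are fixed, so every
distal node shares one unknown translation vector and the load enters at
the reference point.  Unit (1 N) loads along the three anatomical axes are
solved once per model and physiological load cases are obtained by linear
superposition of the displacement fields.

Units are SI throughout: metres, newtons, pascals.  Voxel spacing is
converted from micrometres when the model is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, cg

from .image import BoneMask

#: Default tissue elastic modulus for murine cortical bone, Pa.
DEFAULT_E = 14.8e9
#: Default Poisson ratio.
DEFAULT_NU = 0.3

#: Peak physiological walking-load coefficients at the ankle, N per gram of
#: body mass, along (medial-lateral, anterior-posterior, superior-inferior).
LOAD_PER_GRAM = {"ml": 0.0, "ap": 0.00289, "si": 0.01355}

# Local corner ordering: a = dx + 2*dy + 4*dz, matching the global lattice.
_CORNER_OFFSETS = np.array([[a & 1, (a >> 1) & 1, (a >> 2) & 1] for a in range(8)])
_CORNER_SIGNS = 2 * _CORNER_OFFSETS - 1  # xi coordinates of corners
_GP = _CORNER_SIGNS / np.sqrt(3.0)  # 2x2x2 Gauss points, same ordering


class SolverError(RuntimeError):
    pass


def elastic_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at a point xi, shape (8, 3), on the [-1, 1]^3 reference cube."""
    s = _CORNER_SIGNS
    g = np.empty((8, 3))
    for a in range(8):
        fx = 1 + xi[0] * s[a, 0]
        fy = 1 + xi[1] * s[a, 1]
        fz = 1 + xi[2] * s[a, 2]
        g[a] = 0.125 * np.array([s[a, 0] * fy * fz, fx * s[a, 1] * fz, fx * fy * s[a, 2]])
    return g


def _b_matrices(h: float) -> np.ndarray:
    """Strain-displacement matrices at the 8 Gauss points, shape (8, 6, 24).

    DOF ordering is node-major: (n0x, n0y, n0z, n1x, ...).  Shear rows use
    engineering shear strain.
    """
    B = np.zeros((8, 6, 24))
    for g in range(8):
        grad = _shape_gradients(_GP[g]) * (2.0 / h)  # dN/dx
        for a in range(8):
            dx, dy, dz = grad[a]
            c = 3 * a
            B[g, 0, c + 0] = dx
            B[g, 1, c + 1] = dy
            B[g, 2, c + 2] = dz
            B[g, 3, c + 0] = dy
            B[g, 3, c + 1] = dx
            B[g, 4, c + 1] = dz
            B[g, 4, c + 2] = dy
            B[g, 5, c + 0] = dz
            B[g, 5, c + 2] = dx
    return B


def element_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cube element with edge ``h`` (metres)."""
    C = elastic_matrix(E, nu)
    B = _b_matrices(h)
    detJ = (h / 2.0) ** 3
    Ke = np.zeros((24, 24))
    for g in range(8):
        Ke += B[g].T @ C @ B[g] * detJ
    return 0.5 * (Ke + Ke.T)


def _extrapolation_matrix() -> np.ndarray:
    """Gauss-to-corner extrapolation, shape (8 corners, 8 Gauss points).

    Treats the Gauss values as a trilinear field on the sub-cube spanned by
    the Gauss points and evaluates it at the element corners (the standard
    trilinear recovery rule; coefficients fall outside [0, 1])."""
    M = np.empty((8, 8))
    for c in range(8):
        for g in range(8):
            M[c, g] = np.prod(0.5 * (1 + np.sqrt(3.0) * _CORNER_SIGNS[c] * _CORNER_SIGNS[g]))
    return M


@dataclass
class FEModel:
    """Voxel hexahedral FE model with tibia boundary conditions."""

    mask: BoneMask
    h: float  # element edge, metres
    E: float
    nu: float
    voxels: np.ndarray  # (ne, 3) voxel indices
    enodes: np.ndarray  # (ne, 8) compact node ids
    node_coords: np.ndarray  # (nn, 3) lattice coordinates (integers)
    proximal_nodes: np.ndarray = field(default=None)
    distal_nodes: np.ndarray = field(default=None)
    reference_point: np.ndarray = field(default=None)
    bc_applied: bool = False

    def __post_init__(self):
        self.Ke = element_stiffness(self.E, self.nu, self.h)
        self.B = _b_matrices(self.h)
        self.C = elastic_matrix(self.E, self.nu)
        self.M_extrap = _extrapolation_matrix()
        self.edof = (self.enodes[:, :, None] * 3 + np.arange(3)).reshape(-1, 24)

    @property
    def n_elements(self) -> int:
        return len(self.voxels)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def apply_K(self, u: np.ndarray) -> np.ndarray:
        """Global stiffness action on a full DOF vector (3 * n_nodes)."""
        ue = u[self.edof]
        fe = ue @ self.Ke
        return np.bincount(self.edof.ravel(), weights=fe.ravel(), minlength=3 * self.n_nodes)

    def stiffness_diagonal(self) -> np.ndarray:
        d = np.tile(np.diag(self.Ke), self.n_elements)
        return np.bincount(self.edof.ravel(), weights=d, minlength=3 * self.n_nodes)


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement vectors in metres."""

    values: np.ndarray  # (nn, 3)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


class LoadVector(NamedTuple):
    """Force components in newtons along the anatomical axes."""

    f_ml: float
    f_ap: float
    f_si: float


@dataclass(frozen=True)
class StimulusField:
    """Mechanical stimulus at the surface nodes of a model.

    ``kind`` is ``"sed"`` (strain energy density, Pa) or ``"eps_max"``
    (maximum principal strain, microstrain).
    """

    kind: str
    node_coords: np.ndarray  # (ns, 3) lattice coordinates of surface nodes
    values: np.ndarray  # (ns,)


def build_fe_model(
    mask: BoneMask, E: float = DEFAULT_E, nu: float = DEFAULT_NU
) -> FEModel:
    """Convert a bone mask into a hexahedral FE model (one element per voxel).

    The mask must be a single face-connected component; run
    :func:`osteoadapt.image.largest_component` first otherwise.
    """
    if mask.count() == 0:
        raise ValueError("cannot build an FE model from an empty mask")
    if not (-1.0 < nu < 0.5) or not E > 0:
        raise ValueError("require E > 0 and -1 < nu < 0.5")
    structure = ndimage.generate_binary_structure(3, 1)
    _, n_comp = ndimage.label(mask.data, structure=structure)
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} face-connected components; "
            "apply largest_component before building the FE model"
        )
    voxels = np.argwhere(mask.data)
    nx, ny, nz = mask.shape
    corners = voxels[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (ne, 8, 3)
    full_ids = (corners[..., 0] * (ny + 1) + corners[..., 1]) * (nz + 1) + corners[..., 2]
    active = np.unique(full_ids)
    enodes = np.searchsorted(active, full_ids).astype(np.int64)
    node_coords = np.stack(
        np.unravel_index(active, (nx + 1, ny + 1, nz + 1)), axis=1
    ).astype(np.int64)
    h = mask.spacing * 1e-6
    return FEModel(mask=mask, h=h, E=E, nu=nu, voxels=voxels,
                   enodes=enodes, node_coords=node_coords)


def apply_boundary_conditions(model: FEModel) -> FEModel:
    """Identify the proximal fixed set and the distal coupled set.

    Proximal nodes (node plane at the top of the max-z bone layer) are fully
    fixed; distal nodes (node plane at the bottom of the min-z bone layer)
    are tied to a rotation-fixed reference point at the distal area centroid.
    """
    kz = model.node_coords[:, 2]
    vz = model.voxels[:, 2]
    z_top, z_bot = int(vz.max()) + 1, int(vz.min())
    proximal = np.flatnonzero(kz == z_top)
    distal = np.flatnonzero(kz == z_bot)
    if proximal.size == 0 or distal.size == 0:
        raise ValueError("empty proximal or distal constraint set")
    if np.intersect1d(proximal, distal).size:
        raise ValueError("proximal and distal constraint sets overlap")
    model.proximal_nodes = proximal
    model.distal_nodes = distal
    model.reference_point = model.node_coords[distal].mean(axis=0) * model.h
    model.bc_applied = True
    return model


class _ReducedSystem:
    """Master-slave reduction of the constrained stiffness system.

    Unknowns are the free node DOFs followed by the 3 master translations of
    the coupled distal set; proximal DOFs are eliminated (zero)."""

    def __init__(self, model: FEModel):
        if not model.bc_applied:
            raise SolverError("apply_boundary_conditions before solving")
        nn = model.n_nodes
        node_class = np.zeros(nn, dtype=np.int8)
        node_class[model.distal_nodes] = 1
        node_class[model.proximal_nodes] = 2
        self.model = model
        self.free_nodes = np.flatnonzero(node_class == 0)
        self.distal_nodes = model.distal_nodes
        self.free_dofs = (self.free_nodes[:, None] * 3 + np.arange(3)).ravel()
        self.nf = self.free_dofs.size
        self.n = self.nf + 3
        d_full = model.stiffness_diagonal()
        diag = np.empty(self.n)
        diag[: self.nf] = d_full[self.free_dofs]
        diag[self.nf :] = d_full.reshape(nn, 3)[self.distal_nodes].sum(axis=0)
        self.inv_diag = 1.0 / diag

    def expand(self, ur: np.ndarray) -> np.ndarray:
        u = np.zeros(3 * self.model.n_nodes)
        u[self.free_dofs] = ur[: self.nf]
        u.reshape(-1, 3)[self.distal_nodes] = ur[self.nf :]
        return u

    def reduce(self, f: np.ndarray) -> np.ndarray:
        fr = np.empty(self.n)
        fr[: self.nf] = f[self.free_dofs]
        fr[self.nf :] = f.reshape(-1, 3)[self.distal_nodes].sum(axis=0)
        return fr

    def matvec(self, ur: np.ndarray) -> np.ndarray:
        return self.reduce(self.model.apply_K(self.expand(ur)))

    def solve(self, force: np.ndarray, tol: float, maxiter: int) -> np.ndarray:
        rhs = np.zeros(self.n)
        rhs[self.nf :] = force
        op = LinearOperator((self.n, self.n), matvec=self.matvec, dtype=np.float64)
        pre = LinearOperator((self.n, self.n), matvec=lambda r: self.inv_diag * r,
                             dtype=np.float64)
        x, info = cg(op, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=pre)
        if info != 0:
            res = np.linalg.norm(self.matvec(x) - rhs) / np.linalg.norm(rhs)
            raise SolverError(f"CG did not converge (info={info}, rel. residual {res:.2e})")
        return self.expand(x)


def solve_unit_loads(
    model: FEModel, tol: float = 1e-8, maxiter: int = 100_000
) -> tuple[DisplacementField, DisplacementField, DisplacementField]:
    """Displacement fields for 1 N along each anatomical axis (ml, ap, si)."""
    system = _ReducedSystem(model)
    fields = []
    for axis in range(3):
        force = np.zeros(3)
        force[axis] = 1.0
        u = system.solve(force, tol=tol, maxiter=maxiter)
        fields.append(DisplacementField(u.reshape(-1, 3)))
    return tuple(fields)


def physiological_load(body_mass: float) -> LoadVector:
    """Peak walking load at the ankle for a mouse of the given body mass (g).

    The medial-lateral component is zero; only the superior-inferior and
    anterior-posterior components enter the physiological load case.
    """
    if not body_mass > 0:
        raise ValueError("body mass must be positive")
    return LoadVector(
        f_ml=LOAD_PER_GRAM["ml"] * body_mass,
        f_ap=LOAD_PER_GRAM["ap"] * body_mass,
        f_si=LOAD_PER_GRAM["si"] * body_mass,
    )


def superpose(
    unit_fields: tuple[DisplacementField, DisplacementField, DisplacementField],
    load: LoadVector,
) -> DisplacementField:
    """Weight the unit-load displacement fields by the load components.

    Superposition happens on displacements (and hence strains) -- never on
    SED values, which are quadratic in strain; the stimulus is computed
    after the superposed field is formed.
    """
    shapes = {f.values.shape for f in unit_fields}
    if len(shapes) != 1:
        raise ValueError("unit fields come from different models")
    u = (load.f_ml * unit_fields[0].values
         + load.f_ap * unit_fields[1].values
         + load.f_si * unit_fields[2].values)
    return DisplacementField(u)


def surface_nodes(model: FEModel) -> np.ndarray:
    """Compact ids of nodes incident to at least one unshared element face.

    A node is interior exactly when all 8 voxels around it are bone, i.e.
    when it appears as a corner of 8 elements."""
    counts = np.bincount(model.enodes.ravel(), minlength=model.n_nodes)
    return np.flatnonzero(counts < 8)


def compute_stimulus_field(
    model: FEModel, u: DisplacementField, kind: str = "sed"
) -> StimulusField:
    """Nodal mechanical stimulus restricted to the surface nodes.

    Strains are evaluated at the 2x2x2 Gauss points, extrapolated to the
    element corners by the trilinear recovery rule and averaged over all
    elements sharing each node.  For SED the scalar is extrapolated; for the
    maximum principal strain the six tensor components are extrapolated and
    averaged first and the eigenvalue is taken at the node (in microstrain).
    """
    if kind not in ("sed", "eps_max"):
        raise ValueError(f"unknown stimulus kind {kind!r}")
    ue = u.values.reshape(-1)[model.edof]  # (ne, 24)
    eps = np.einsum("gij,nj->ngi", model.B, ue)  # (ne, 8, 6)
    nn = model.n_nodes
    flat = model.enodes.ravel()
    n_shared = np.bincount(flat, minlength=nn).astype(np.float64)
    if kind == "sed":
        sed = 0.5 * np.einsum("ngi,ij,ngj->ng", eps, model.C, eps)
        corner = np.einsum("cg,ng->nc", model.M_extrap, sed)
        nodal = np.bincount(flat, weights=corner.ravel(), minlength=nn) / n_shared
        nodal = np.maximum(nodal, 0.0)  # extrapolation can undershoot zero
    else:
        corner = np.einsum("cg,ngi->nci", model.M_extrap, eps)
        nodal_eps = np.empty((nn, 6))
        for i in range(6):
            nodal_eps[:, i] = np.bincount(
                flat, weights=corner[:, :, i].ravel(), minlength=nn
            ) / n_shared
        T = np.empty((nn, 3, 3))
        T[:, 0, 0] = nodal_eps[:, 0]
        T[:, 1, 1] = nodal_eps[:, 1]
        T[:, 2, 2] = nodal_eps[:, 2]
        T[:, 0, 1] = T[:, 1, 0] = 0.5 * nodal_eps[:, 3]
        T[:, 1, 2] = T[:, 2, 1] = 0.5 * nodal_eps[:, 4]
        T[:, 0, 2] = T[:, 2, 0] = 0.5 * nodal_eps[:, 5]
        nodal = np.linalg.eigvalsh(T)[:, -1] * 1e6
    surf = surface_nodes(model)
    return StimulusField(kind=kind, node_coords=model.node_coords[surf].copy(),
                         values=nodal[surf])


def stimulus_to_volume(field: StimulusField, shape: tuple[int, int, int]) -> np.ndarray:
    """Scatter a surface-node stimulus onto the node lattice of an image grid
    (shape is the voxel grid; the returned array is one larger per axis)."""
    out = np.zeros((shape[0] + 1, shape[1] + 1, shape[2] + 1))
    c = field.node_coords
    out[c[:, 0], c[:, 1], c[:, 2]] = field.values
    return out
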