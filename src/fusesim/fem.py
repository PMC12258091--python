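"""Small-strain linear-elastic FE analysis on 4-node tetrahedra.

Constant-strain tetrahedra (the C3D4 analog), mm-N-MPa unit system.
Compression is applied as a statically equivalent nodal load over the
cranial face; a flexion moment is applied as a linear (area-weighted)
nodal-force distribution with zero net force — a distributed-coupling
surrogate that avoids the artificial stiffening of a rigid tie.

Stimulus conventions: the strain stimulus is the magnitude of the most
compressive (most negative) principal strain in percent; hydrostatic
pressure p = -(s1+s2+s3)/3 is positive in compression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .construct import LabeledMesh, _element_faces, tet_volumes
from .errors import AssemblyError, GeometryError, SolverError


@dataclass(frozen=True)
class LoadSpec:
    """One load case: axial compression plus optional sagittal flexion moment."""

    axial_force: float = 0.0       # N, compressive (acts in -z on the cranial face)
    flexion_moment: float = 0.0    # N*mm about the transverse (x) axis
    duty_fraction: float = 1.0     # share of daily loading time


def element_gradients(mesh: LabeledMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (E,4,3) and volumes (E,) of all tets."""
    p = mesh.node_coords[mesh.tets]
    A = p[:, 1:] - p[:, 0:1]                 # (E,3,3), rows = edge vectors
    vols = np.linalg.det(A) / 6.0
    bad = np.flatnonzero(vols <= 0)
    if bad.size:
        raise AssemblyError(f"inverted or degenerate element(s): {bad[:10].tolist()}")
    Ainv = np.linalg.inv(A)                  # columns of Ainv = grad N_1..3
    grads = np.empty((len(p), 4, 3))
    grads[:, 1:, :] = np.transpose(Ainv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vols


def isotropic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Voigt 6x6 elasticity matrices, order (xx,yy,zz,xy,yz,zx), eng. shear."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] = lam + 2 * mu
        D[..., 3 + i, 3 + i] = mu
    return D


def element_B(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (E,6,12) for CST elements."""
    E = grads.shape[0]
    B = np.zeros((E, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


class FESystem:
    """Assembled global stiffness for a mesh with per-element materials."""

    def __init__(self, mesh: LabeledMesh, element_E, element_nu):
        self.mesh = mesh
        self.element_E = np.broadcast_to(
            np.asarray(element_E, dtype=float), (mesh.n_elements,)
        ).copy()
        self.element_nu = np.broadcast_to(
            np.asarray(element_nu, dtype=float), (mesh.n_elements,)
        ).copy()
        self.K = self._assemble()

    def _assemble(self) -> sp.csr_matrix:
        mesh = self.mesh
        grads, vols = element_gradients(mesh)
        B = element_B(grads)
        D = isotropic_D(self.element_E, self.element_nu)
        ke = np.einsum("e,eji,ejk,ekl->eil", vols, B, D, B, optimize=True)

        dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 12)
        rows = np.repeat(dofs, 12, axis=1).ravel()
        cols = np.tile(dofs, (1, 12)).ravel()
        n = 3 * mesh.n_nodes
        K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        return K

    def factorize(self, fixed_nodes: np.ndarray) -> "ConstrainedSystem":
        return ConstrainedSystem(self, np.asarray(fixed_nodes))


def assemble_system(mesh: LabeledMesh, element_E, element_nu) -> FESystem:
    """Assemble the global linear-elastic system (spec-level entry point)."""
    return FESystem(mesh, element_E, element_nu)


class ConstrainedSystem:
    """Stiffness with Dirichlet constraints applied, factorized once."""

    def __init__(self, system: FESystem, fixed_nodes: np.ndarray):
        if fixed_nodes.size == 0:
            raise SolverError("fixed node set is empty; rigid-body modes remain")
        self.system = system
        n = system.K.shape[0]
        fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
        self.fixed_dofs = fixed_dofs
        free = np.ones(n, dtype=bool)
        free[fixed_dofs] = False
        self.free = np.flatnonzero(free)
        Kff = system.K[self.free][:, self.free].tocsc()
        try:
            # symmetric-mode minimum-degree ordering: K is SPD after
            # constraint elimination, roughly halves factorization time
            self.lu = spla.splu(
                Kff, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
            )
        except RuntimeError as exc:  # exactly singular
            raise SolverError(f"singular constrained system: {exc}") from exc
        udiag = np.abs(self.lu.U.diagonal())
        if udiag.size and udiag.min() <= 1e-12 * max(udiag.max(), 1.0):
            raise SolverError(
                "numerically singular constrained system (disconnected "
                "components or unmerged duplicate nodes?)"
            )
        self.Kff = Kff

    def solve(self, f: np.ndarray, fixed_values: np.ndarray | None = None) -> np.ndarray:
        """Solve for the full displacement field (N,3) given nodal loads (N,3)."""
        n = self.system.K.shape[0]
        f = np.asarray(f, dtype=float).reshape(n)
        u = np.zeros(n)
        rhs = f[self.free]
        if fixed_values is not None:
            uc = np.asarray(fixed_values, dtype=float).reshape(-1)
            u[self.fixed_dofs] = uc
            rhs = rhs - self.system.K[self.free][:, self.fixed_dofs] @ uc
        uf = self.lu.solve(rhs)
        if not np.all(np.isfinite(uf)):
            raise SolverError("non-finite solution; system singular or ill-conditioned")
        resid = np.linalg.norm(self.Kff @ uf - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and resid / scale > 1e-7:
            raise SolverError(f"solver residual too large: {resid / scale:.2e}")
        u[self.free] = uf
        return u.reshape(-1, 3)

    def reactions(self, u: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Reaction forces (N,3): K u - f, nonzero only on constrained DOFs."""
        r = self.system.K @ u.ravel() - np.asarray(f, dtype=float).ravel()
        return r.reshape(-1, 3)


# ---------------------------------------------------------------------------
# loads


def surface_tributary_areas(mesh: LabeledMesh, node_set: np.ndarray) -> np.ndarray:
    """Tributary area per node of ``node_set`` from the boundary triangles
    whose three corners all lie in the set."""
    faces = _element_faces(mesh.tets)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    inset = np.zeros(mesh.n_nodes, dtype=bool)
    inset[node_set] = True
    on = boundary[np.all(inset[boundary], axis=1)]
    if on.size == 0:
        raise GeometryError("node set spans no boundary triangles")
    p = mesh.node_coords[on]
    area = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    trib = np.zeros(mesh.n_nodes)
    np.add.at(trib, on.ravel(), np.repeat(area / 3.0, 3))
    return trib[node_set]


def load_vector(mesh: LabeledMesh, load: LoadSpec) -> np.ndarray:
    """Statically equivalent nodal load vector (N,3) for one load case.

    Compression: uniform traction in -z over the cranial face.  Flexion
    moment M about +x: nodal z-forces proportional to tributary area times
    (y - ybar); net force zero, net moment about the face centroid = M, so
    the anterior side (small y) is pushed down for M > 0.
    """
    nodes = mesh.node_sets["cranial_load"]
    areas = surface_tributary_areas(mesh, nodes)
    f = np.zeros((mesh.n_nodes, 3))
    if load.axial_force:
        f[nodes, 2] -= load.axial_force * areas / areas.sum()
    if load.flexion_moment:
        y = mesh.node_coords[nodes, 1]
        ybar = np.average(y, weights=areas)
        dy = y - ybar
        denom = np.sum(areas * dy * dy)
        f[nodes, 2] += load.flexion_moment * areas * dy / denom
    return f


def solve_static(
    system: FESystem,
    fixed_set: np.ndarray,
    load: LoadSpec,
    *,
    factorized: ConstrainedSystem | None = None,
) -> np.ndarray:
    """Equilibrium displacement field (N,3) under one load case."""
    cs = factorized if factorized is not None else system.factorize(fixed_set)
    return cs.solve(load_vector(system.mesh, load))


# ---------------------------------------------------------------------------
# derived quantities


@dataclass
class StimulusField:
    """Per-element mechanical stimuli driving tissue differentiation."""

    eps_min_pct: np.ndarray  # |most compressive principal strain| in %
    p_hyd: np.ndarray        # hydrostatic pressure, MPa, compression-positive

    def __post_init__(self):
        if not (np.all(np.isfinite(self.eps_min_pct)) and np.all(np.isfinite(self.p_hyd))):
            raise AssemblyError("non-finite stimulus values")


def element_strain_tensors(mesh: LabeledMesh, displacement: np.ndarray) -> np.ndarray:
    """Small-strain tensors (E,3,3) from shape-function gradients."""
    grads, _ = element_gradients(mesh)
    u = displacement[mesh.tets]                    # (E,4,3)
    H = np.einsum("eai,eaj->eij", u, grads)        # du_i/dx_j
    return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def element_stimuli(
    mesh: LabeledMesh,
    displacement: np.ndarray,
    element_E,
    element_nu,
) -> StimulusField:
    """Per-element (eps_min_pct, p_hyd) for a solved displacement field."""
    eps = element_strain_tensors(mesh, displacement)
    principal = np.linalg.eigvalsh(eps)            # ascending
    eps_min_pct = np.maximum(0.0, -principal[:, 0]) * 100.0

    E = np.broadcast_to(np.asarray(element_E, float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(element_nu, float), (mesh.n_elements,))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = np.trace(eps, axis1=1, axis2=2)
    trace_sigma = (3 * lam + 2 * mu) * tr
    p_hyd = -trace_sigma / 3.0
    return StimulusField(eps_min_pct=eps_min_pct, p_hyd=p_hyd)


def rom_flexion_angle(
    mesh: LabeledMesh, displacement: np.ndarray, node_set: np.ndarray | None = None
) -> float:
    """Best-fit rigid rotation of the cranial node set about the transverse
    (x) axis, in degrees (signed; positive = flexion, anterior down)."""
    nodes = node_set if node_set is not None else mesh.node_sets["cranial_load"]
    X = mesh.node_coords[nodes]
    Y = X + displacement[nodes]
    Xc = X - X.mean(axis=0)
    if len(nodes) < 3 or np.linalg.matrix_rank(Xc, tol=1e-9) < 2:
        raise GeometryError("need >= 3 non-collinear nodes for a rigid fit")
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    from scipy.spatial.transform import Rotation

    rotvec = Rotation.from_matrix(R).as_rotvec(degrees=True)
    # flexion (anterior tips down) is a positive rotation about +x in this
    # frame, matching the sign of the applied flexion_moment
    return float(rotvec[0])
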