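"""Small-strain linear-elastic tetrahedral FE solver with growth loading.

The mechanical model mirrors a quasi-static implicit FE setup: linear
isotropic materials, nodal constraints in all degrees of freedom at the
foramen magnum ring and the nasion, isotropic eigenstrain ("thermal
analogy") loading of the intracranial regions, and node-to-surface penalty
contact with regularized Coulomb friction between the ICV outer surface and
the inner calvaria.  Large total growth is accumulated by updated-coordinate
stepping outside this module; each call here solves one small-strain
sub-increment.

Units: mm, MPa, N (1 MPa * mm^2 = 1 N).  Contact pressure = k_n * penetration
with k_n in N/mm per mm^2 of surface, i.e. MPa/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .mesh import BRAIN_LABELS, CSF_LABEL, LabeledMesh

GROWTH_LABELS = BRAIN_LABELS | {CSF_LABEL}


class SolverError(RuntimeError):
    pass


@dataclass
class Material:
    E: float          # elastic modulus, MPa
    nu: float         # Poisson's ratio
    alpha: float = 0.0  # isotropic eigenstrain per increment (growth regions)

    def validate(self, label=""):
        if self.E <= 0:
            raise ValueError(f"E must be > 0 for {label!r}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(f"nu must lie in (-1, 0.5) for {label!r}")


@dataclass
class MaterialCard:
    """Region label -> material map with class-level defaults.

    ``formed_modulus``/``formed_nu`` are applied to elements flagged as
    ossified, overriding their original (suture/craniotomy) material.
    """

    by_label: dict = field(default_factory=dict)
    formed_modulus: float = 3000.0
    formed_nu: float = 0.3
    growth_labels: frozenset = GROWTH_LABELS   # regions carrying eigenstrain

    @classmethod
    def baseline(cls, bone=(3000.0, 0.3), suture=(30.0, 0.3),
                 craniotomy=(30.0, 0.3), brain=(100.0, 0.48), csf=(40.0, 0.48)):
        """The baseline material card: bone 3000 MPa, sutures and craniotomies
        30 MPa (nu 0.3), brain 100 MPa and CSF 40 MPa (nu 0.48)."""
        card = cls()
        card._defaults = {
            "bone": Material(*bone), "suture": Material(*suture),
            "craniotomy": Material(*craniotomy), "brain": Material(*brain),
            "csf": Material(*csf),
        }
        card.formed_modulus = bone[0]
        card.formed_nu = bone[1]
        return card

    def _class_of(self, label: str) -> str:
        from .mesh import is_bone, is_craniotomy
        if label in GROWTH_LABELS:
            return "csf" if label == CSF_LABEL else "brain"
        if is_craniotomy(label):
            return "craniotomy"
        if is_bone(label):
            return "bone"
        return "suture"

    def lookup(self, label: str) -> Material:
        if label in self.by_label:
            return self.by_label[label]
        defaults = getattr(self, "_defaults", None)
        if defaults is None:
            raise KeyError(f"no material defined for region {label!r}")
        return defaults[self._class_of(label)]

    def set(self, label: str, E: float, nu: float):
        self.by_label[label] = Material(E, nu)

    def copy(self) -> "MaterialCard":
        card = MaterialCard(dict(self.by_label), self.formed_modulus,
                            self.formed_nu, self.growth_labels)
        if hasattr(self, "_defaults"):
            card._defaults = dict(self._defaults)
        return card

    def resolve(self, mesh: LabeledMesh, alpha: float = 0.0):
        """Per-element (E, nu, alpha) arrays; ossified elements get the formed
        bone material; only ICV regions carry the growth eigenstrain."""
        n = len(mesh.tets)
        E = np.empty(n)
        nu = np.empty(n)
        al = np.zeros(n)
        for code, label in enumerate(mesh.region_names):
            m = mesh.region_id == code
            if not m.any():
                continue
            mat = self.lookup(label)
            mat.validate(label)
            E[m], nu[m] = mat.E, mat.nu
            if label in self.growth_labels:
                al[m] = alpha
        oss = mesh.ossified
        E[oss], nu[oss] = self.formed_modulus, self.formed_nu
        al[oss] = 0.0
        return E, nu, al


@dataclass
class ContactSpec:
    """Penalty frictional contact parameters (defaults follow the validated
    setup: mu = 0.1, penetration tolerance 0.5, normal stiffness 600 N/mm)."""

    friction_coefficient: float = 0.1
    normal_penalty_stiffness: float = 600.0   # N/mm per mm^2 (MPa/mm)
    penetration_tolerance: float = 0.5        # mm
    tangential_penalty_stiffness: float = None
    pair: str = "icv_skull"

    def __post_init__(self):
        if self.friction_coefficient < 0:
            raise ValueError("friction coefficient must be >= 0")
        if self.normal_penalty_stiffness <= 0:
            raise ValueError("normal penalty stiffness must be > 0")
        if self.penetration_tolerance <= 0:
            raise ValueError("penetration tolerance must be > 0")
        if self.tangential_penalty_stiffness is None:
            # softer stick regularization than the normal penalty: the Coulomb
            # cap still bounds tangential traction, and the gentler springs
            # keep the stick/slip fixed point from limit-cycling
            self.tangential_penalty_stiffness = 0.1 * self.normal_penalty_stiffness


@dataclass
class SimulationState:
    """Solution of one growth sub-increment."""

    u: np.ndarray                      # (n_nodes, 3) mm
    strain: np.ndarray = None          # (n_elem, 6) engineering Voigt
    eps_h: np.ndarray = None           # (n_elem,) hydrostatic strain
    contact_node_pressure: np.ndarray = None   # per slave node, MPa
    contact_node_gap: np.ndarray = None        # per slave node, mm (+ = open)
    slave_nodes: np.ndarray = None
    residual: float = 0.0
    increment: int = 0
    age: float = 0.0


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _iso_D(E, nu):
    """Isotropic elasticity matrices (n, 6, 6), engineering shear strains."""
    n = len(E)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((n, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _linear_grads(points, tets):
    """Shape-function gradients (n, 4, 3) and volumes for 4-node tets."""
    p = points[tets]
    M = np.concatenate([np.ones((len(tets), 4, 1)), p], axis=2)  # (n,4,4)
    det = np.linalg.det(M)
    vol = np.abs(det) / 6.0
    if np.any(vol <= 0):
        raise SolverError("degenerate element (zero volume) in assembly")
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:4, :].transpose(0, 2, 1)  # (n, 4, 3)
    return grads, vol


def _B_from_grads(grads):
    """Strain-displacement matrices (n, 6, 3*k) from gradients (n, k, 3)."""
    n, k, _ = grads.shape
    B = np.zeros((n, 6, 3 * k))
    gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
    c = 3 * np.arange(k)
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


_TET10_GP = np.array(
    [
        [0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
        [0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
    ]
)


def _tet10_dN(xi):
    """d N / d(xi, eta, zeta) for the 10-node tet at one integration point."""
    x, y, z = xi
    L = np.array([1 - x - y - z, x, y, z])
    dL = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    dN = np.zeros((10, 3))
    for a in range(4):
        dN[a] = (4 * L[a] - 1) * dL[a]
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for m, (a, b) in enumerate(edges):
        dN[4 + m] = 4 * (L[a] * dL[b] + L[b] * dL[a])
    return dN


def element_matrices(points, tets, E, nu, alpha):
    """Per-element stiffness and eigenstrain load vectors.

    Returns (Ke, fe) with shapes (n, 3k, 3k), (n, 3k) for k corner/midside
    nodes.  Linear tets integrate exactly; quadratic tets use 4-point Gauss.
    """
    D = _iso_D(np.asarray(E, float), np.asarray(nu, float))
    eps0 = np.zeros((len(tets), 6))
    eps0[:, :3] = np.asarray(alpha, float)[:, None]
    if tets.shape[1] == 4:
        grads, vol = _linear_grads(points, tets)
        B = _B_from_grads(grads)
        DB = np.einsum("nij,njk->nik", D, B)
        Ke = np.einsum("nji,njk,n->nik", B, DB, vol)
        fe = np.einsum("nji,njk,nk,n->ni", B, D, eps0, vol)
        return Ke, fe
    # quadratic: isoparametric on straight-sided tets
    n = len(tets)
    Ke = np.zeros((n, 30, 30))
    fe = np.zeros((n, 30))
    p = points[tets]  # (n, 10, 3)
    for gp in _TET10_GP:
        dN = _tet10_dN(gp)              # (10, 3)
        J = np.einsum("ai,naj->nij", dN, p)  # (n, 3, 3)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise SolverError("inverted quadratic element in assembly")
        Jinv = np.linalg.inv(J)
        grads = np.einsum("ai,nji->naj", dN, Jinv)
        B = _B_from_grads(grads)
        w = detJ / 24.0   # reference tet volume 1/6, 4 equal weights
        DB = np.einsum("nij,njk->nik", D, B)
        Ke += np.einsum("nji,njk,n->nik", B, DB, w)
        fe += np.einsum("nji,njk,nk,n->ni", B, D, eps0, w)
    return Ke, fe


def assemble(mesh: LabeledMesh, materials: MaterialCard, alpha: float = 0.0,
             points: np.ndarray = None):
    """Global stiffness matrix (CSR) and growth load vector.

    ``alpha`` is the isotropic eigenstrain applied to the ICV (brain + CSF)
    regions for this sub-increment.  ``points`` overrides the mesh node
    coordinates (updated-coordinate stepping).
    """
    pts = mesh.points if points is None else points
    E, nu, al = materials.resolve(mesh, alpha)
    Ke, fe = element_matrices(pts, mesh.tets, E, nu, al)
    k = mesh.tets.shape[1]
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(len(mesh.tets), 3 * k)
    rows = np.repeat(dofs, 3 * k, axis=1).ravel()
    cols = np.tile(dofs, (1, 3 * k)).ravel()
    ndof = 3 * len(pts)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    f = np.zeros(ndof)
    np.add.at(f, dofs.ravel(), fe.ravel())
    return K, f


def compute_strains(mesh: LabeledMesh, u: np.ndarray, points: np.ndarray = None):
    """Element strain tensors (Voigt) and hydrostatic strain tr(eps)/3."""
    pts = mesh.points if points is None else points
    uu = u.reshape(-1, 3)
    if mesh.order == 1:
        grads, _ = _linear_grads(pts, mesh.tets)
        ue = uu[mesh.tets]  # (n, 4, 3)
        g = np.einsum("nai,naj->nij", grads, ue)  # grad u^T actually d u_j/d x_i
    else:
        # average of the 4 Gauss points
        p = pts[mesh.tets]
        g = np.zeros((len(mesh.tets), 3, 3))
        for gp in _TET10_GP:
            dN = _tet10_dN(gp)
            J = np.einsum("ai,naj->nij", dN, p)
            grads = np.einsum("ai,nji->naj", dN, np.linalg.inv(J))
            g += 0.25 * np.einsum("nai,naj->nij", grads, uu[mesh.tets])
    eps = 0.5 * (g + g.transpose(0, 2, 1))
    voigt = np.stack(
        [eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
         2 * eps[:, 0, 1], 2 * eps[:, 1, 2], 2 * eps[:, 0, 2]], axis=1
    )
    eps_h = voigt[:, :3].sum(axis=1) / 3.0
    return voigt, eps_h


# ---------------------------------------------------------------------------
# linear solves
# ---------------------------------------------------------------------------

def solve_dirichlet(K, f, fixed_dofs, fixed_vals=None):
    """Direct sparse solve with prescribed displacements eliminated."""
    ndof = K.shape[0]
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    if fixed_dofs.size == 0:
        raise SolverError("no constraints: system is singular (rigid modes)")
    vals = np.zeros(len(fixed_dofs)) if fixed_vals is None else np.asarray(fixed_vals)
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)
    u = np.zeros(ndof)
    u[fixed_dofs] = vals
    rhs = f[free] - K[free][:, fixed_dofs] @ vals
    Kff = K[free][:, free].tocsc()
    try:
        u[free] = spla.spsolve(Kff, rhs)
    except Exception as e:  # pragma: no cover
        raise SolverError(f"singular constrained system: {e}") from e
    if not np.all(np.isfinite(u)):
        raise SolverError("singular constrained system (non-finite solution)")
    return u


def rigid_modes(points):
    """Orthonormal basis of the 6 rigid-body modes (3 translations, 3 rotations)."""
    n = len(points)
    c = points - points.mean(axis=0)
    modes = np.zeros((3 * n, 6))
    for i in range(3):
        modes[i::3, i] = 1.0
    modes[1::3, 3], modes[2::3, 3] = -c[:, 2], c[:, 1]
    modes[0::3, 4], modes[2::3, 4] = c[:, 2], -c[:, 0]
    modes[0::3, 5], modes[1::3, 5] = -c[:, 1], c[:, 0]
    q, _ = np.linalg.qr(modes)
    return q


def solve_free(K, f, points, rtol=1e-10):
    """Solve the unconstrained (free-floating) system by projecting out the
    rigid-body modes; requires a self-equilibrated load (growth eigenstrain)."""
    R = rigid_modes(points)
    proj = lambda v: v - R @ (R.T @ v)
    op = spla.LinearOperator(K.shape, matvec=lambda v: proj(K @ proj(v)))
    d = K.diagonal()
    d[d <= 0] = 1.0
    M = spla.LinearOperator(K.shape, matvec=lambda v: v / d)
    b = proj(f)
    u, info = spla.cg(op, b, rtol=rtol, maxiter=4000, M=M)
    if info != 0:
        raise SolverError(f"free-expansion CG failed to converge (info={info})")
    return proj(u)


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------

def _point_tri_project(p, tri):
    """Closest points on triangles tri (n,3,3) to points p (n,3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom[denom == 0] = 1.0
    v = vb / denom
    w = vc / denom
    v = np.clip(v, 0, 1)
    w = np.clip(w, 0, 1 - v)
    uu = 1 - v - w
    # vertex/edge regions
    m = (d1 <= 0) & (d2 <= 0)
    v[m], w[m] = 0.0, 0.0
    m = (d3 >= 0) & (d4 <= d3)
    v[m], w[m] = 1.0, 0.0
    m = (d6 >= 0) & (d5 <= d6)
    v[m], w[m] = 0.0, 1.0
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(d1 - d3 != 0, d1 / np.maximum(d1 - d3, 1e-300), 0.0)
    v[m], w[m] = np.clip(t[m], 0, 1), 0.0
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.where(d2 - d6 != 0, d2 / np.maximum(d2 - d6, 1e-300), 0.0)
    v[m], w[m] = 0.0, np.clip(t[m], 0, 1)
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    t = (d4 - d3) / np.maximum((d4 - d3) + (d5 - d6), 1e-300)
    v[m], w[m] = 1 - np.clip(t[m], 0, 1), np.clip(t[m], 0, 1)
    uu = 1 - v - w
    bary = np.stack([uu, v, w], axis=1)
    closest = np.einsum("nk,nkj->nj", bary, tri)
    return closest, bary


class ContactPair:
    """Node-to-surface penalty contact between the ICV outer surface (slave
    nodes) and the inner calvarial surface (master triangles)."""

    def __init__(self, mesh: LabeledMesh, spec: ContactSpec):
        reg = mesh.surface_pairs.get(spec.pair)
        if reg is None:
            raise SolverError(f"contact pair {spec.pair!r} not registered on mesh")
        self.spec = spec
        self.slave_faces = reg.slave_faces
        self.master_faces = reg.master_faces
        self.slave_nodes = reg.slave_nodes
        self.center = mesh.points[self.slave_nodes].mean(axis=0)
        # lumped tributary area per slave node (third of adjacent face areas)
        self.area = self._lumped_areas(mesh.points)

    def _lumped_areas(self, pts):
        tri = pts[self.slave_faces]
        a2 = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        area = np.zeros(len(pts))
        for k in range(3):
            np.add.at(area, self.slave_faces[:, k], a2 / 3.0)
        return area[self.slave_nodes]

    def find(self, pts, u):
        """Geometry query at configuration pts + u.

        Returns (gap, normal, face_idx, bary): gap > 0 means the slave node
        has penetrated beyond the master surface (away from the ICV centre).
        """
        y = pts + u.reshape(-1, 3)
        ys = y[self.slave_nodes]
        mtri = y[self.master_faces]
        cent = mtri.mean(axis=1)
        tree = cKDTree(cent)
        k = min(8, len(cent))
        _, cand = tree.query(ys, k=k)
        cand = cand.reshape(len(ys), k)
        best_d = np.full(len(ys), np.inf)
        best_f = np.zeros(len(ys), dtype=np.int64)
        best_c = np.zeros((len(ys), 3))
        best_b = np.zeros((len(ys), 3))
        for j in range(k):
            f = cand[:, j]
            closest, bary = _point_tri_project(ys, mtri[f])
            d = np.linalg.norm(ys - closest, axis=1)
            m = d < best_d
            best_d[m], best_f[m] = d[m], f[m]
            best_c[m], best_b[m] = closest[m], bary[m]
        # smooth (area-weighted nodal) master normals, so the contact force
        # stays continuous when a slave node slides across a facet edge
        fn = np.cross(mtri[:, 1] - mtri[:, 0], mtri[:, 2] - mtri[:, 0])
        out_dir = cent - self.center
        flip = np.einsum("ij,ij->i", fn, out_dir) < 0
        fn[flip] *= -1
        node_n = np.zeros((len(y), 3))
        for kk in range(3):
            np.add.at(node_n, self.master_faces[:, kk], fn)
        n = np.einsum("nk,nkj->nj", best_b, node_n[self.master_faces[best_f]])
        n /= np.maximum(np.linalg.norm(n, axis=1), 1e-300)[:, None]
        gap = np.einsum("ij,ij->i", ys - best_c, n)
        return gap, n, best_f, best_b


@dataclass
class ContactKinematics:
    """Frozen per-sub-increment contact geometry.

    Projections, normals and reference gaps are evaluated once at the start
    of each sub-increment (updated coordinates), making the gap an exactly
    linear function of the displacement.  This keeps every sub-increment a
    well-posed piecewise-linear problem for the active-set iteration, at the
    cost of ignoring within-increment rotation of the contact frame (small,
    since increments carry ~1-2 % strain).
    """

    gap0: np.ndarray
    n: np.ndarray
    fidx: np.ndarray
    bary: np.ndarray


def contact_forces(pair: ContactPair, frz: ContactKinematics, u, ndof):
    """Penalty contact force vector, tangent stiffness and diagnostics.

    gap(u) = gap0 + n . (u_slave - sum_k w_k u_master_k).  Nodes with
    gap >= 0 are active (the surfaces start coincident, "initially in
    contact"); sliding nodes use a secant tangential stiffness so the
    Coulomb cap stays in the Jacobian.
    """
    spec = pair.spec
    kn = spec.normal_penalty_stiffness
    kt = spec.tangential_penalty_stiffness
    mu = spec.friction_coefficient

    uu = u.reshape(-1, 3)
    m_nodes_all = pair.master_faces[frz.fidx]           # (ns, 3)
    rel = uu[pair.slave_nodes] - np.einsum("nk,nkj->nj", frz.bary, uu[m_nodes_all])
    rel_n = np.einsum("ij,ij->i", rel, frz.n)
    gap = frz.gap0 + rel_n
    active = gap >= 0.0
    f = np.zeros(ndof)
    pressure = np.where(active, kn * np.maximum(gap, 0.0), 0.0)
    if not active.any():
        return f, sp.csr_matrix((ndof, ndof)), pressure, gap, active

    s_nodes = pair.slave_nodes[active]
    m_nodes = m_nodes_all[active]
    w = frz.bary[active]
    nn = frz.n[active]
    A = pair.area[active]
    fn_mag = kn * A * gap[active]

    rel_t = rel[active] - rel_n[active, None] * nn
    ft = -kt * A[:, None] * rel_t
    ft_mag = np.linalg.norm(ft, axis=1)
    cap = mu * fn_mag
    sliding = ft_mag > cap
    scale = np.ones(len(ft))
    scale[sliding] = cap[sliding] / np.maximum(ft_mag[sliding], 1e-300)
    ft *= scale[:, None]

    force_s = -fn_mag[:, None] * nn + ft               # on slave nodes
    dofs_s = 3 * s_nodes[:, None] + np.arange(3)
    np.add.at(f, dofs_s.ravel(), force_s.ravel())
    for k in range(3):
        dofs_m = 3 * m_nodes[:, k, None] + np.arange(3)
        np.add.at(f, dofs_m.ravel(), (-w[:, k, None] * force_s).ravel())

    # tangent blocks coupling each slave with its 3 master nodes
    na = len(s_nodes)
    kmat = kn * A[:, None, None] * np.einsum("ni,nj->nij", nn, nn)
    t_proj = np.eye(3)[None] - np.einsum("ni,nj->nij", nn, nn)
    k_tan = np.where(sliding, scale * kt, kt) * A      # secant when sliding
    kmat += k_tan[:, None, None] * t_proj
    wfull = np.concatenate([np.ones((na, 1)), -w], axis=1)  # slave, 3 masters
    nodes4 = np.concatenate([s_nodes[:, None], m_nodes], axis=1)  # (na, 4)
    blocks = np.einsum("na,nb,nij->naibj", wfull, wfull, kmat)    # (na,4,3,4,3)
    dofs4 = (3 * nodes4[:, :, None] + np.arange(3)).reshape(na, 12)
    rows = np.repeat(dofs4, 12, axis=1).ravel()
    cols = np.tile(dofs4, (1, 12)).ravel()
    Kc = sp.coo_matrix(
        (blocks.reshape(na, 12, 12).ravel(), (rows, cols)), shape=(ndof, ndof)
    ).tocsr()
    return f, Kc, pressure, gap, active


def default_constraint_dofs(mesh: LabeledMesh):
    """All-DOF nodal constraints at the foramen magnum ring and the nasion."""
    nodes = []
    for name in ("foramen_magnum_ring", "nasion"):
        ns = mesh.node_sets.get(name)
        if ns is None or len(ns) == 0:
            raise SolverError(f"constraint node set {name!r} missing or empty")
        nodes.append(np.asarray(ns))
    stem = mesh.node_sets.get("icv_foramen")
    if stem is not None and len(stem):
        nodes.append(np.asarray(stem))
    nodes = np.unique(np.concatenate(nodes))
    return (3 * nodes[:, None] + np.arange(3)).ravel()


def solve_increment(
    mesh: LabeledMesh,
    materials: MaterialCard,
    alpha: float,
    contact: ContactSpec = None,
    constraints=None,
    points: np.ndarray = None,
    max_iters: int = 60,
    rtol: float = 1e-8,
    increment: int = 0,
    age: float = 0.0,
    step_cap: float = 10.0,
    accept_tol: float = 1e-4,
) -> SimulationState:
    """Solve one quasi-static growth sub-increment.

    Assembles the constrained linear system with eigenstrain ``alpha`` on the
    ICV regions and iterates the penalty contact state (active set and
    stick/slip) to a fixed point.  Raises :class:`SolverError` on
    non-convergence, reporting the last residual.
    """
    pts = mesh.points if points is None else points
    K, f = assemble(mesh, materials, alpha, points=pts)
    fixed = default_constraint_dofs(mesh) if constraints is None else np.asarray(constraints)
    ndof = K.shape[0]
    u = np.zeros(ndof)
    pair = ContactPair(mesh, contact) if contact is not None else None

    if pair is None:
        u = solve_dirichlet(K, f, fixed)
        state = SimulationState(u=u.reshape(-1, 3), increment=increment, age=age)
    else:
        # weak-spring stabilization: before contact engages, the ICV is a
        # disconnected component; tiny diagonal springs remove the rigid
        # modes without measurably loading the solution.
        k_weak = 1e-9 * np.abs(K.diagonal()).mean()
        Kw = (K + k_weak * sp.eye(ndof)).tocsr()
        gap0, n0, fidx0, bary0 = pair.find(pts, np.zeros(ndof))
        frz = ContactKinematics(gap0, n0, fidx0, bary0)
        prev_sig = None
        load_ref = max(np.linalg.norm(f), 1e-12)
        free = np.setdiff1d(np.arange(ndof), fixed)
        last_res = np.inf
        best_res, best_u = np.inf, u.copy()
        converged = False
        for it in range(max_iters):
            fc, Kc, pressure, gap, active = contact_forces(pair, frz, u, ndof)
            r = f + fc - Kw @ u
            last_res = np.linalg.norm(r[free]) / load_ref
            if last_res < best_res:
                best_res, best_u = last_res, u.copy()
            sig = hash((active.tobytes(),))
            if last_res <= rtol and sig == prev_sig:
                converged = True
                break
            if it >= 30 and best_res <= accept_tol:
                break  # near-equilibrium limit cycle; stop grinding
            prev_sig = sig
            du = solve_dirichlet((Kw + Kc).tocsr(), r, fixed)
            # damp overly large steps: the contact linearization is only
            # trustworthy for motions small against the geometry
            dmax = np.abs(du).max()
            if dmax > step_cap:
                du *= step_cap / dmax
            # Coulomb stick/slip fixed points can limit-cycle; under-relax
            # progressively once the easy progress is made
            omega = 1.0 if it < 15 else (0.5 if it < 35 else 0.25)
            u = u + omega * du
        if not converged:
            # accept a near-equilibrium limit cycle; the residual is recorded
            # on the state for downstream scrutiny
            if best_res > accept_tol:
                raise SolverError(
                    f"contact iteration did not converge in {max_iters} iterations "
                    f"(last residual {last_res:.3e})"
                )
            u, last_res = best_u, best_res
        fc, Kc, pressure, gap, active = contact_forces(pair, frz, u, ndof)
        pen = np.maximum(gap, 0.0)
        if pen.max(initial=0.0) > contact.penetration_tolerance:
            raise SolverError(
                f"max penetration {pen.max():.3f} mm exceeds tolerance "
                f"{contact.penetration_tolerance} mm (stiffen the penalty)"
            )
        state = SimulationState(
            u=u.reshape(-1, 3),
            contact_node_pressure=pressure,
            contact_node_gap=-gap,  # + = open clearance
            slave_nodes=pair.slave_nodes,
            residual=last_res,
            increment=increment,
            age=age,
        )
    state.strain, state.eps_h = compute_strains(mesh, state.u, points=pts)
    return state


def extract_contact_pressure(state: SimulationState, mesh: LabeledMesh,
                             pair_name: str = "icv_skull"):
    """Per-face contact pressure map over the ICV outer surface (MPa).

    Face pressure is the mean of its three node pressures; open faces are 0.
    """
    if state.contact_node_pressure is None:
        raise ValueError("state carries no contact solution")
    reg = mesh.surface_pairs[pair_name]
    node_p = np.zeros(len(mesh.points))
    node_p[state.slave_nodes] = state.contact_node_pressure
    return node_p[reg.slave_faces].mean(axis=1)
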