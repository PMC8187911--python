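"""Parametric synthetic calvaria + intracranial volume generator.

Patient CT geometry is not publicly available, so the pipeline runs on a
parametric stand-in that preserves the topology and label adjacency the
growth algorithms consume: an ellipsoidal calvarial shell (bone plates
separated by suture strips, sagittal suture fused), an optional uniform CSF
layer, a brain partitioned into five lobes, a circular foramen-magnum
opening, craniometric landmarks, and the Renier-"H" craniotomy pattern
(fused sagittal strip removed and reinserted as two squares, parietal cuts,
one lateral wedge per side) with a configurable residual kerf gap.

Axes convention: +x anterior, +y left, +z superior; midsagittal plane y = 0.
All lengths mm.  The mesh is built from a UV-sphere template whose y < 0
half is an exact mirror copy of the y > 0 half, so node positions are
midsagittally symmetric to machine precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    CSF_LABEL,
    LabeledMesh,
    SurfacePair,
    check_conforming,
)


class MeshingError(RuntimeError):
    pass


@dataclass
class CraniotomySpec:
    """Renier "H" craniotomy pattern parameters.

    ``parietal_cut_width`` is the mediolateral extent of the rectangular
    parietal cuts (the 3-4 cm figure); ``kerf_gap`` is the width of the open
    gap the saw leaves everywhere bone was cut, which is what ossification
    must bridge.
    """

    parietal_cut_width: float = 35.0   # mm, must be in [30, 40]
    kerf_gap: float = 10.0             # mm
    n_reinserted_squares: int = 2
    wedge_count_per_side: int = 1

    def validate(self):
        if not (30.0 <= self.parietal_cut_width <= 40.0):
            raise ValueError(
                f"parietal_cut_width={self.parietal_cut_width} mm outside the "
                "3-4 cm surgical range [30, 40]"
            )
        if self.kerf_gap <= 0:
            raise ValueError("kerf_gap must be > 0 (zero-area cuts are degenerate)")
        if self.n_reinserted_squares != 2:
            raise ValueError("the replicated technique reinserts exactly 2 squares")
        if self.wedge_count_per_side != 1:
            raise ValueError("one lateral wedge per side is supported")


_DEFAULT_SUTURE_WIDTH = {
    "metopic": 2.0,
    "coronal": 2.0,
    "lambdoid": 2.0,
    "squamosal": 2.0,
    "sagittal": 20.0,            # width of the fused strip removed at surgery
    "anterior_fontanelle": 12.0,  # radius of the fontanelle disc
}


@dataclass
class SkullParams:
    """Geometry of the synthetic 4-month-old calvaria."""

    icv_target_volume: float = 659.0          # ml, preoperative ICV
    shell_thickness: float = 3.0              # mm calvarial bone
    csf_thickness: float = 2.5                # mm; 0 disables (Model II)
    suture_width: dict = field(default_factory=lambda: dict(_DEFAULT_SUTURE_WIDTH))
    fused_sutures: frozenset = frozenset({"sagittal"})
    craniotomy_spec: CraniotomySpec | None = None
    ellipsoid_semi_axes: tuple = (80.0, 50.0, 42.0)   # AP, ML, vertical proportions
    mesh_size: float = 9.0                    # mm target surface edge length
    foramen_angle_deg: float = 22.0           # half-angle of the foramen opening
    seed: int = 0

    def validate(self):
        if self.icv_target_volume <= 0:
            raise ValueError("icv_target_volume must be > 0")
        if self.shell_thickness <= 0:
            raise ValueError("shell_thickness must be > 0")
        if not (0.0 <= self.csf_thickness <= 3.0):
            raise ValueError("csf_thickness must lie in [0, 3] mm")
        if any(a <= 0 for a in self.ellipsoid_semi_axes):
            raise ValueError("ellipsoid_semi_axes must be > 0")
        if self.mesh_size <= 0:
            raise ValueError("mesh_size must be > 0")
        for k, w in self.suture_width.items():
            if w <= 0:
                raise ValueError(f"suture_width[{k!r}] must be > 0")
        if self.craniotomy_spec is not None:
            self.craniotomy_spec.validate()


# ---------------------------------------------------------------------------
# UV-sphere template with exact midsagittal mirror symmetry
# ---------------------------------------------------------------------------

def _uv_sphere(n_theta: int, n_phi: int):
    """Unit-sphere directions and triangles; poles on the z axis.

    Nodes in the y < 0 half are exact mirror images of the y > 0 half and the
    quad-splitting diagonals are mirrored, so reflection about y = 0 maps the
    node set onto itself exactly.
    """
    assert n_phi % 2 == 0
    thetas = np.linspace(0.0, np.pi, n_theta + 1)
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    n_ring = n_theta - 1
    n_nodes = 2 + n_ring * n_phi
    dirs = np.zeros((n_nodes, 3))
    dirs[0] = (0, 0, 1.0)
    dirs[1] = (0, 0, -1.0)

    def idx(i, j):  # i in 1..n_theta-1, j modulo n_phi
        return 2 + (i - 1) * n_phi + (j % n_phi)

    for i in range(1, n_theta):
        st, ct = np.sin(thetas[i]), np.cos(thetas[i])
        for j in range(n_phi // 2 + 1):
            x, y = st * np.cos(phis[j]), st * np.sin(phis[j])
            if j in (0, n_phi // 2):
                y = 0.0
            dirs[idx(i, j)] = (x, y, ct)
            if 0 < j < n_phi // 2:
                dirs[idx(i, n_phi - j)] = (x, -y, ct)

    tris = []
    for j in range(n_phi):  # caps
        tris.append((0, idx(1, j), idx(1, j + 1)))
        tris.append((1, idx(n_theta - 1, j + 1), idx(n_theta - 1, j)))
    for i in range(1, n_theta - 1):
        for j in range(n_phi):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i + 1, j + 1), idx(i, j + 1)
            if j < n_phi // 2:  # mirrored diagonal choice on the other half
                tris.append((a, b, c))
                tris.append((a, c, d))
            else:
                tris.append((a, b, d))
                tris.append((b, c, d))
    return dirs, np.asarray(tris, dtype=np.int64)


def _split_prisms(bot: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets with globally conforming diagonals.

    Every quad face takes the diagonal through its smallest global node index,
    which both adjacent prisms agree on.
    """
    pr = np.column_stack([bot, top])  # (m, 6): V0 V1 V2 | V3 V4 V5
    m = len(pr)
    # bring the overall smallest vertex to position 0 (flip + rotate)
    flip = pr.argmin(axis=1) >= 3
    pf = pr.copy()
    # upside-down flip preserving prism structure: bottom <- (V3, V5, V4)
    pf[flip] = pr[flip][:, [3, 5, 4, 0, 2, 1]]
    rot = pf[:, :3].argmin(axis=1)
    out = np.empty_like(pf)
    for r, perm in ((0, [0, 1, 2, 3, 4, 5]), (1, [1, 2, 0, 4, 5, 3]), (2, [2, 0, 1, 5, 3, 4])):
        sel = rot == r
        out[sel] = pf[sel][:, perm]
    V = out
    tets = np.empty((m, 3, 4), dtype=np.int64)
    # remaining quad (V1, V2, V5, V4): diagonal through its smallest vertex
    diag15 = np.minimum(V[:, 1], V[:, 5]) < np.minimum(V[:, 2], V[:, 4])
    a = diag15
    tets[a, 0] = V[a][:, [0, 1, 2, 5]]
    tets[a, 1] = V[a][:, [0, 1, 5, 4]]
    tets[a, 2] = V[a][:, [0, 4, 5, 3]]
    b = ~diag15
    tets[b, 0] = V[b][:, [0, 1, 2, 4]]
    tets[b, 1] = V[b][:, [0, 4, 2, 5]]
    tets[b, 2] = V[b][:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def _fix_orientation(points, tets):
    p = points[tets]
    v = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    neg = v < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    zero = np.abs(v) < 1e-12
    if zero.any():
        raise MeshingError(f"{zero.sum()} degenerate (zero-volume) tetrahedra produced")
    return tets


# ---------------------------------------------------------------------------
# region labeling
# ---------------------------------------------------------------------------

def _lobe_labels(cent: np.ndarray, axes) -> np.ndarray:
    """Partition ICV element centroids into 5 brain lobes by anatomical sector."""
    u = cent / np.asarray(axes)
    n = np.linalg.norm(u, axis=1)
    n[n == 0] = 1.0
    u = u / n[:, None]
    lab = np.full(len(cent), "brain_parietal", dtype=object)
    lab[np.abs(u[:, 1]) > 0.55] = "brain_temporal"
    lab[u[:, 0] > 0.30] = "brain_frontal"
    lab[u[:, 0] < -0.45] = "brain_occipital"
    lab[(u[:, 2] < -0.35) & (u[:, 0] < 0.1)] = "cerebellum"
    return lab


def _shell_labels(cent: np.ndarray, axes, widths, fused, mesh_size) -> np.ndarray:
    """Assign bone-plate / suture labels to skull-shell element centroids.

    Suture strips are snapped to at least roughly one element width so that
    every labeled region exists at coarse resolution.
    """
    a, b, c = axes
    x, y, z = cent[:, 0], cent[:, 1], cent[:, 2]
    u = cent / np.asarray(axes)
    un = u / np.maximum(np.linalg.norm(u, axis=1), 1e-12)[:, None]
    uz = un[:, 2]

    x_c, x_l = 0.40 * a, -0.55 * a        # coronal / lambdoid suture planes
    h_eff = lambda w: max(w / 2.0, 0.55 * mesh_size)
    h_cor = h_eff(widths.get("coronal", 2.0))
    h_lam = h_eff(widths.get("lambdoid", 2.0))
    h_met = h_eff(widths.get("metopic", 2.0))
    h_sq = h_eff(widths.get("squamosal", 2.0))
    w_sag = widths.get("sagittal", 20.0)
    r_af = widths.get("anterior_fontanelle", 12.0)
    z_sq = 0.12 * c                        # squamosal suture height
    bregma = np.array([x_c, 0.0, c * np.sqrt(max(0.0, 1 - (x_c / a) ** 2))])

    lab = np.full(len(cent), "", dtype=object)
    todo = lab == ""

    def put(mask, name):
        nonlocal todo
        m = mask & todo
        lab[m] = name
        todo &= ~m

    put(np.linalg.norm(cent - bregma, axis=1) <= r_af, "anterior_fontanelle")
    sag_name = "sagittal_fused" if "sagittal" in fused else "sagittal_suture"
    put((np.abs(y) <= w_sag / 2) & (x > x_l + h_lam) & (x < x_c - h_cor) & (uz > 0.45),
        sag_name)
    put((np.abs(y) <= h_met) & (x > x_c) & (uz > 0.15), "metopic")
    put((np.abs(x - x_c) <= h_cor) & (z > z_sq), "coronal")
    put((np.abs(x - x_l) <= h_lam) & (z > z_sq), "lambdoid")
    put((np.abs(z - z_sq) <= h_sq) & (np.abs(u[:, 1]) > 0.45) & (x > x_l) & (x < x_c),
        "squamosal")
    put(uz < -0.30, "craniofacial")
    put(x < x_l, "occipital")
    put(x > x_c, "frontal")
    lateral = np.abs(u[:, 1]) > 0.45
    put(lateral & (z < z_sq), "temporal_L", )
    # split the two temporal/parietal groups by side
    lab[(lab == "temporal_L") & (y < 0)] = "temporal_R"
    put(y >= 0, "parietal_L")
    put(np.ones(len(cent), dtype=bool), "parietal_R")
    return lab


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _build(params: SkullParams, icv_axes: np.ndarray) -> LabeledMesh:
    a, b, c = icv_axes
    r_typ = float(np.mean(icv_axes))
    n_theta = int(np.clip(round(np.pi * r_typ / params.mesh_size), 8, 80))
    n_phi = 2 * n_theta
    dirs, tris = _uv_sphere(n_theta, n_phi)
    n_surf = len(dirs)

    csf = params.csf_thickness
    brain_outer = icv_axes - csf if csf > 0 else icv_axes
    if np.any(brain_outer <= 0):
        raise MeshingError("csf_thickness leaves no room for the brain")
    layer_axes = [0.55 * brain_outer, brain_outer]
    if csf > 0:
        layer_axes.append(icv_axes)          # CSF outer == ICV surface
    skull_inner = icv_axes                   # duplicated, coincident
    skull_outer = icv_axes + params.shell_thickness

    pts = [np.zeros((1, 3))]
    layer_ids = []
    nid = 1
    for ax in layer_axes + [skull_inner, skull_outer]:
        pts.append(dirs * ax)
        layer_ids.append(np.arange(nid, nid + n_surf))
        nid += n_surf
    points = np.vstack(pts)
    n_icv_layers = len(layer_axes)
    icv_surf_layer = layer_ids[n_icv_layers - 1]
    skull_in_layer = layer_ids[n_icv_layers]
    skull_out_layer = layer_ids[n_icv_layers + 1]

    tet_blocks, lab_blocks = [], []
    # brain core: centre node to innermost layer
    core = np.column_stack(
        [np.zeros(len(tris), dtype=np.int64), layer_ids[0][tris]]
    )
    tet_blocks.append(core)
    lab_blocks.append(np.full(len(tris), "brain", dtype=object))
    # concentric ICV layers
    for k in range(n_icv_layers - 1):
        t = _split_prisms(layer_ids[k][tris], layer_ids[k + 1][tris])
        tet_blocks.append(t)
        name = "csf" if (csf > 0 and k == n_icv_layers - 2) else "brain"
        lab_blocks.append(np.full(len(t), name, dtype=object))
    # skull shell, with the foramen-magnum columns removed
    fm_cos = np.cos(np.pi - np.deg2rad(params.foramen_angle_deg))
    tri_dirs = dirs[tris].mean(axis=1)
    keep = tri_dirs[:, 2] > fm_cos * np.linalg.norm(tri_dirs, axis=1)
    shell = _split_prisms(skull_in_layer[tris[keep]], skull_out_layer[tris[keep]])
    tet_blocks.append(shell)
    lab_blocks.append(np.full(len(shell), "skull", dtype=object))

    tets = np.vstack(tet_blocks)
    coarse = np.concatenate(lab_blocks)
    tets = _fix_orientation(points, tets)

    # final per-element labels
    cent = points[tets].mean(axis=1)
    labels = np.empty(len(tets), dtype=object)
    m_brain = coarse == "brain"
    labels[m_brain] = _lobe_labels(cent[m_brain], brain_outer)
    labels[coarse == "csf"] = CSF_LABEL
    m_sk = coarse == "skull"
    mid_axes = icv_axes + params.shell_thickness / 2.0
    labels[m_sk] = _shell_labels(
        cent[m_sk], mid_axes, params.suture_width, params.fused_sutures, params.mesh_size
    )

    names = sorted(set(labels))
    code = {n: i for i, n in enumerate(names)}
    region_id = np.array([code[l] for l in labels], dtype=np.int32)

    # contact surface pair (coincident, duplicated nodes)
    slave_faces = icv_surf_layer[tris]
    master_faces = skull_in_layer[tris[keep]]

    # node sets
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    d_th = np.pi / n_theta
    fm_ang = np.deg2rad(params.foramen_angle_deg)
    rim = np.abs((np.pi - theta) - fm_ang) <= 0.75 * d_th
    fm_ring = np.concatenate([skull_in_layer[rim], skull_out_layer[rim]])
    mid = np.abs(dirs[:, 1]) < 1e-9
    nas_dir = np.array([np.cos(np.deg2rad(-21.0)), 0.0, np.sin(np.deg2rad(-21.0))])
    nas_score = dirs @ nas_dir
    nas = mid & (nas_score > np.cos(1.4 * d_th)) & (dirs[:, 2] < 0)
    if not nas.any():
        nas = mid & (nas_score == nas_score[mid].max())
    nasion = np.concatenate([skull_in_layer[nas], skull_out_layer[nas]])

    mesh = LabeledMesh(
        points=points,
        tets=tets,
        region_id=region_id,
        region_names=list(names),
        node_sets={
            "foramen_magnum_ring": np.unique(fm_ring),
            "nasion": np.unique(nasion),
            # brainstem: ICV nodes inside the foramen cone, constrained with
            # the ring so the intracranial content is anchored inferiorly
            "icv_foramen": np.unique(
                np.concatenate(
                    [lay[dirs[:, 2] < fm_cos] for lay in layer_ids[: n_icv_layers]]
                )
            ),
            "skull_outer": skull_out_layer.copy(),
            "skull_inner": skull_in_layer.copy(),
            "icv_surface": icv_surf_layer.copy(),
        },
        surface_pairs={"icv_skull": SurfacePair(slave_faces, master_faces)},
        meta={
            "icv_axes": tuple(icv_axes),
            "brain_axes": tuple(brain_outer),
            "shell_thickness": params.shell_thickness,
            "csf_thickness": csf,
            "mesh_size": params.mesh_size,
            "n_theta": n_theta,
            "x_coronal": 0.40 * mid_axes[0],
            "x_lambdoid": -0.55 * mid_axes[0],
            "z_squamosal": 0.12 * mid_axes[2],
            "h_coronal": max(params.suture_width.get("coronal", 2.0) / 2.0,
                             0.55 * params.mesh_size),
            "h_lambdoid": max(params.suture_width.get("lambdoid", 2.0) / 2.0,
                              0.55 * params.mesh_size),
            "sagittal_width": params.suture_width.get("sagittal", 20.0),
            "af_radius": params.suture_width.get("anterior_fontanelle", 12.0),
            "af_center": (
                0.40 * mid_axes[0], 0.0,
                mid_axes[2] * float(np.sqrt(1.0 - 0.40**2)),
            ),
            "seed": params.seed,
        },
    )
    return mesh


def generate_calvaria(params: SkullParams, with_craniotomies: bool = True) -> LabeledMesh:
    """Generate the labeled calvaria + ICV mesh.

    The discretized ICV volume is calibrated to ``icv_target_volume`` by a
    second rescaled build, so the match is exact up to floating point; the
    semi-axes parameter sets the shape (proportions), not absolute size.
    """
    params.validate()
    axes0 = np.asarray(params.ellipsoid_semi_axes, dtype=float)
    target_mm3 = params.icv_target_volume * 1000.0
    s_analytic = (target_mm3 / (4.0 / 3.0 * np.pi * np.prod(axes0))) ** (1.0 / 3.0)
    axes = axes0 * s_analytic
    mesh = _build(params, axes)
    v1 = mesh.icv_volume_ml() * 1000.0
    mesh = _build(params, axes * (target_mm3 / v1) ** (1.0 / 3.0))

    if not check_conforming(mesh):
        raise MeshingError("generated mesh is not conforming (non-watertight surface)")
    expected = {
        "frontal", "parietal_L", "parietal_R", "occipital", "temporal_L",
        "temporal_R", "craniofacial", "metopic", "coronal", "lambdoid",
        "squamosal", "anterior_fontanelle",
    } | ({"csf"} if params.csf_thickness > 0 else set())
    missing = expected - set(mesh.labels_present())
    if missing:
        raise MeshingError(
            f"regions {sorted(missing)} came out empty; mesh_size="
            f"{params.mesh_size} is likely too coarse for the suture widths"
        )
    place_landmarks(mesh)
    if with_craniotomies and params.craniotomy_spec is not None:
        mesh = apply_craniotomies(mesh, params.craniotomy_spec)
    return mesh


def apply_craniotomies(mesh: LabeledMesh, spec: CraniotomySpec) -> LabeledMesh:
    """Relabel the fused sagittal strip and parietal bone with the Renier-"H"
    pattern: two reinserted squares surrounded by kerf gaps, one rectangular
    cut posterior of the coronal and anterior of the lambdoid suture per side,
    and one lateral wedge per side reaching the squamosal.

    Geometry is untouched; only element labels change.
    """
    spec.validate()
    if "sagittal_fused" not in mesh.region_names:
        raise ValueError("mesh has no fused sagittal strip to resect")
    out = mesh.copy()
    g = spec.kerf_gap
    cent = out.centroids()
    labels = out.element_labels()
    x, y, z = cent[:, 0], cent[:, 1], cent[:, 2]
    meta = out.meta
    w_sag = meta["sagittal_width"]
    x_c, x_l = meta["x_coronal"], meta["x_lambdoid"]
    z_sq = meta["z_squamosal"]

    sag = labels == "sagittal_fused"
    if not sag.any():
        raise ValueError("fused sagittal strip is empty")
    x0, x1 = x[sag].min(), x[sag].max()
    span = x1 - x0
    if span <= 2 * g:
        raise ValueError(
            f"kerf_gap={g} mm leaves no room for reinserted squares over the "
            f"{span:.1f} mm sagittal strip"
        )
    # strip partition along x: square | kerf | square.  The squares abut the
    # coronal/lambdoid margins so every kerf gap is flanked by bone on both
    # sides (bilateral formation); the kerf between and beside the squares
    # is what ossification must bridge.
    sq = (span - g) / 2.0
    in_sq = sag & ((x < x0 + sq) | (x > x1 - sq))
    new = labels.copy()
    new[in_sq] = "reinserted_bone"
    new[sag & ~in_sq] = "craniotomy_sagittal"

    # parasagittal kerf taken from the parietal plates
    par = (labels == "parietal_L") | (labels == "parietal_R")
    near_strip = (np.abs(y) > w_sag / 2.0) & (np.abs(y) <= w_sag / 2.0 + g)
    lateral_kerf = par & near_strip & (x > x0) & (x < x1)
    new[lateral_kerf & (y > 0)] = "craniotomy_parasagittal_L"
    new[lateral_kerf & (y < 0)] = "craniotomy_parasagittal_R"

    # rectangular parietal cuts: posterior of coronal / anterior of lambdoid
    avail = np.abs(y[par]).max() - w_sag / 2.0 if par.any() else 0.0
    if spec.parietal_cut_width > avail:
        raise ValueError(
            f"parietal_cut_width={spec.parietal_cut_width} mm exceeds the "
            f"available parietal span; achievable maximum is {avail:.1f} mm"
        )
    reach = (np.abs(y) > w_sag / 2.0) & (
        np.abs(y) <= w_sag / 2.0 + spec.parietal_cut_width
    )
    # cuts sit one kerf-width away from the sutures, leaving the usual
    # surgical bone margin (also the formation front's seed on that side)
    x_ant = x_c - meta["h_coronal"] - 1.5 * g   # posterior of the coronal
    x_post = x_l + meta["h_lambdoid"] + 1.5 * g  # anterior of the lambdoid
    ant = par & reach & (np.abs(x - x_ant) <= g / 2.0)
    post = par & reach & (np.abs(x - x_post) <= g / 2.0)
    for m, nm in ((ant, "craniotomy_parietal_a"), (post, "craniotomy_parietal_p")):
        new[m & (y > 0)] = nm + "_L"
        new[m & (y < 0)] = nm + "_R"

    # lateral wedges from the parietal cut down to the squamosal
    x_w = 0.5 * (x_c + x_l)
    wedge = par & (np.abs(x - x_w) <= g / 2.0) & (z > z_sq) & (
        np.abs(y) > w_sag / 2.0 + spec.parietal_cut_width * 0.4
    )
    new[wedge & (y > 0)] = "craniotomy_wedge_L"
    new[wedge & (y < 0)] = "craniotomy_wedge_R"

    made = {n for n in np.unique(new)} - {n for n in np.unique(labels)}
    if not any(n.startswith("craniotomy") for n in made):
        raise ValueError("craniotomy relabeling produced no craniotomy elements")
    if "reinserted_bone" not in made:
        raise ValueError("no reinserted squares produced; strip too short for kerfs")

    names = sorted(set(new))
    code = {n: i for i, n in enumerate(names)}
    out.region_names = list(names)
    out.region_id = np.array([code[l] for l in new], dtype=np.int32)
    return out


def place_landmarks(mesh: LabeledMesh) -> LabeledMesh:
    """Locate the six craniometric landmarks on the outer skull surface.

    glabella/opisthocranion: extreme anterior/posterior midline outer nodes;
    euryons: extreme lateral outer nodes; bregma: outer midline node at the
    coronal-sagittal junction; basion: anterior foramen-magnum-ring node.
    """
    outer = mesh.node_sets.get("skull_outer")
    if outer is None or len(outer) == 0:
        raise ValueError("mesh has no outer skull surface node set")
    p = mesh.points[outer]
    ytol = 1e-6 * (np.abs(p[:, 1]).max() + 1.0)
    mid = np.abs(p[:, 1]) <= ytol
    if not mid.any():
        raise ValueError("no midline nodes on the outer surface")
    mid_ids = outer[mid]
    mp = mesh.points[mid_ids]
    lm = {}
    lm["glabella"] = int(mid_ids[np.argmax(mp[:, 0])])
    lm["opisthocranion"] = int(mid_ids[np.argmin(mp[:, 0])])
    lm["euryon_L"] = int(outer[np.argmax(p[:, 1])])
    lm["euryon_R"] = int(outer[np.argmin(p[:, 1])])
    meta = mesh.meta
    if "x_coronal" in meta:
        ax = np.asarray(meta["icv_axes"]) + meta["shell_thickness"]
        xc = meta["x_coronal"]
        bz = ax[2] * np.sqrt(max(0.0, 1 - (xc / ax[0]) ** 2))
        target = np.array([xc, 0.0, bz])
    else:
        target = np.array([0.0, 0.0, np.max(p[:, 2])])
    lm["bregma"] = int(mid_ids[np.argmin(np.linalg.norm(mp - target, axis=1))])
    ring = mesh.node_sets.get("foramen_magnum_ring")
    if ring is not None and len(ring):
        rp = mesh.points[ring]
        lm["basion"] = int(ring[np.argmax(rp[:, 0])])
    else:
        lm["basion"] = int(mid_ids[np.argmin(mp[:, 2])])
    mesh.landmarks.update(lm)
    return mesh
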