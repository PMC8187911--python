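"""Benchmark fixture geometries: structured boxes and sphere-in-shell.

These small meshes back the verification suite (patch test, uniaxial bar,
thick-wall sphere with an expanding core, 1D ossification-front slab) and
the mesh-convergence check.  They reuse the same layered-sphere machinery as
the skull generator so they exercise identical code paths.
"""

from __future__ import annotations

import numpy as np

from .mesh import LabeledMesh, SurfacePair
from .synthetic_skull import _fix_orientation, _split_prisms, _uv_sphere

# Kuhn subdivision of the unit cube into 6 tets sharing the main diagonal;
# identical in every cell, hence conforming across cell faces.
_KUHN = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 7, 5],
        [0, 5, 7, 4],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
    ]
)


def box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(2, 2, 2), label="block",
             label_fn=None) -> LabeledMesh:
    """Structured tetrahedral box mesh on [0, L] per axis.

    ``label_fn(centroids) -> array of label strings`` may assign per-element
    regions (e.g. bone | suture | bone slabs).
    """
    nx, ny, nz = divisions
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    cells = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corners = np.array(
                    [
                        nid(i, j, k), nid(i + 1, j, k), nid(i, j + 1, k),
                        nid(i + 1, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                        nid(i, j + 1, k + 1), nid(i + 1, j + 1, k + 1),
                    ]
                )
                cells.append(corners[_KUHN])
    tets = _fix_orientation(points, np.vstack(cells))
    cent = points[tets].mean(axis=1)
    if label_fn is None:
        labels = np.full(len(tets), label, dtype=object)
    else:
        labels = np.asarray(label_fn(cent), dtype=object)
    names = sorted(set(labels))
    code = {n: i for i, n in enumerate(names)}
    return LabeledMesh(
        points=points,
        tets=tets,
        region_id=np.array([code[l] for l in labels], dtype=np.int32),
        region_names=names,
    )


def sphere_in_shell(
    r_core=20.0,
    r_outer=26.0,
    n_theta=14,
    core_label="core",
    shell_label="shell",
    bonded=True,
) -> LabeledMesh:
    """Solid sphere inside a concentric shell.

    ``bonded=True`` shares nodes at the interface (tied assembly, the
    closed-form thick-wall benchmark); ``bonded=False`` duplicates the
    interface nodes and registers a ``core_shell`` contact pair with the
    initially coincident surfaces.
    """
    dirs, tris = _uv_sphere(n_theta, 2 * n_theta)
    n_surf = len(dirs)
    radii_core = [0.55 * r_core, r_core]
    pts = [np.zeros((1, 3))]
    layer_ids = []
    nid = 1
    for r in radii_core:
        pts.append(dirs * r)
        layer_ids.append(np.arange(nid, nid + n_surf))
        nid += n_surf
    if bonded:
        shell_in = layer_ids[-1]
    else:
        pts.append(dirs * r_core)
        shell_in = np.arange(nid, nid + n_surf)
        layer_ids.append(shell_in)
        nid += n_surf
    r_mid = 0.5 * (r_core + r_outer)
    shell_layers = [shell_in]
    for r in (r_mid, r_outer):
        pts.append(dirs * r)
        shell_layers.append(np.arange(nid, nid + n_surf))
        nid += n_surf
    points = np.vstack(pts)

    blocks = [np.column_stack([np.zeros(len(tris), dtype=np.int64), layer_ids[0][tris]])]
    blocks.append(_split_prisms(layer_ids[0][tris], layer_ids[1][tris]))
    for a, b in zip(shell_layers[:-1], shell_layers[1:]):
        blocks.append(_split_prisms(a[tris], b[tris]))
    sizes = [len(b) for b in blocks]
    tets = _fix_orientation(points, np.vstack(blocks))
    labels = np.concatenate(
        [
            np.full(sizes[0] + sizes[1], core_label, dtype=object),
            np.full(sum(sizes[2:]), shell_label, dtype=object),
        ]
    )
    names = sorted(set(labels))
    code = {n: i for i, n in enumerate(names)}
    mesh = LabeledMesh(
        points=points,
        tets=tets,
        region_id=np.array([code[l] for l in labels], dtype=np.int32),
        region_names=names,
        node_sets={"outer": shell_layers[-1].copy()},
    )
    if not bonded:
        mesh.surface_pairs["core_shell"] = SurfacePair(
            layer_ids[1][tris].copy(), shell_in[tris].copy()
        )
    return mesh


def lame_interface_pressure(r_core, r_outer, E_core, nu_core, E_shell, nu_shell,
                            alpha):
    """Closed-form interface pressure for a uniformly expanding elastic sphere
    inside a traction-free concentric shell (thick-wall solution).

    Core displacement u = A r; shell u = C r + D / r^2; continuity of u and
    radial stress at r_core, zero radial stress at r_outer.
    """
    K1 = E_core / (3 * (1 - 2 * nu_core))
    K2 = E_shell / (3 * (1 - 2 * nu_shell))
    G2 = E_shell / (2 * (1 + nu_shell))
    beta = 4 * G2 / (3 * K2 * r_outer**3)
    D = 3 * K1 * alpha / (
        (3 * K1 - 3 * K2) * beta + (3 * K1 + 4 * G2) / r_core**3
    )
    return 4 * G2 * D * (1 / r_core**3 - 1 / r_outer**3)
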