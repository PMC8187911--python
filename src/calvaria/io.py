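"""Mesh and report I/O: ASCII VTU (XML) with embedded label metadata, YAML
configuration blocks, and CSV/JSON reports.

The VTU files are plain VTK XML unstructured grids (readable by ParaView);
region labels go out as the ``region_id`` cell array plus a JSON metadata
comment that this package's own reader uses to restore label names, node
sets and landmarks on round-trip.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

import numpy as np
import yaml

from .mesh import LabeledMesh, SurfacePair

_VTK_TET, _VTK_TET10 = 10, 24


def _arr(parent, name, data, kind="Float64", comps=1):
    el = ET.SubElement(parent, "DataArray", Name=name, type=kind,
                       NumberOfComponents=str(comps), format="ascii")
    flat = np.asarray(data).ravel()
    if kind.startswith("Float"):
        el.text = " ".join(f"{v:.10g}" for v in flat)
    else:
        el.text = " ".join(str(int(v)) for v in flat)
    return el


def save_vtu(mesh: LabeledMesh, path, cell_data=None, point_data=None):
    """Write the mesh (+ optional extra arrays) as an ASCII VTU file."""
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    n_pts, n_cells = len(mesh.points), len(mesh.tets)
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n_pts),
                          NumberOfCells=str(n_cells))
    pts = ET.SubElement(piece, "Points")
    _arr(pts, "Points", mesh.points, comps=3)
    cells = ET.SubElement(piece, "Cells")
    _arr(cells, "connectivity", mesh.tets, kind="Int64")
    _arr(cells, "offsets", np.arange(1, n_cells + 1) * mesh.tets.shape[1], kind="Int64")
    ctype = _VTK_TET if mesh.tets.shape[1] == 4 else _VTK_TET10
    _arr(cells, "types", np.full(n_cells, ctype), kind="UInt8")
    cd = ET.SubElement(piece, "CellData")
    _arr(cd, "region_id", mesh.region_id, kind="Int32")
    _arr(cd, "ossified", mesh.ossified.astype(np.int8), kind="Int8")
    for name, data in (cell_data or {}).items():
        _arr(cd, name, data)
    pd_el = ET.SubElement(piece, "PointData")
    for name, ns in mesh.node_sets.items():
        flag = np.zeros(n_pts, dtype=np.int8)
        flag[np.asarray(ns)] = 1
        _arr(pd_el, f"nodeset_{name}", flag, kind="Int8")
    lm_flag = np.zeros(n_pts, dtype=np.int32)
    for i, (name, nid) in enumerate(sorted(mesh.landmarks.items()), start=1):
        lm_flag[nid] = i
    _arr(pd_el, "landmark_id", lm_flag, kind="Int32")
    for name, data in (point_data or {}).items():
        comps = 3 if np.asarray(data).ndim == 2 else 1
        _arr(pd_el, name, data, comps=comps)

    meta = {
        "region_names": list(mesh.region_names),
        "landmarks": {k: int(v) for k, v in mesh.landmarks.items()},
        "node_sets": {k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()},
        "surface_pairs": {
            k: {"slave_faces": v.slave_faces.tolist(),
                "master_faces": v.master_faces.tolist()}
            for k, v in mesh.surface_pairs.items()
        },
        "meta": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in mesh.meta.items()
                 if isinstance(v, (int, float, str, tuple, list))},
    }
    xml = ET.tostring(root, encoding="unicode")
    comment = "<!--calvaria:" + json.dumps(meta) + "-->\n"
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write(comment)
        fh.write(xml)


def load_vtu(path) -> LabeledMesh:
    """Read a VTU written by :func:`save_vtu`, restoring labels, node sets,
    landmarks and contact surface registries."""
    with open(path) as fh:
        text = fh.read()
    meta = None
    start = text.find("<!--calvaria:")
    if start >= 0:
        end = text.index("-->", start)
        meta = json.loads(text[start + len("<!--calvaria:"):end])
        text = text[:start] + text[end + 3:]
    root = ET.fromstring(text.split("?>", 1)[-1])
    piece = root.find(".//Piece")
    get = lambda parent, name: piece.find(f".//{parent}/DataArray[@Name='{name}']")
    pts = np.fromstring(get("Points", "Points").text, sep=" ").reshape(-1, 3)
    conn = np.fromstring(get("Cells", "connectivity").text, sep=" ", dtype=np.int64)
    offs = np.fromstring(get("Cells", "offsets").text, sep=" ", dtype=np.int64)
    k = offs[0]
    tets = conn.reshape(-1, k)
    region = np.fromstring(get("CellData", "region_id").text, sep=" ", dtype=np.int32)
    oss_el = get("CellData", "ossified")
    ossified = (
        np.fromstring(oss_el.text, sep=" ", dtype=np.int64).astype(bool)
        if oss_el is not None else None
    )
    if meta is None:
        names = [f"region_{i}" for i in range(region.max() + 1)]
        mesh = LabeledMesh(pts, tets, region, names, ossified=ossified)
        return mesh
    mesh = LabeledMesh(
        pts, tets, region, list(meta["region_names"]), ossified=ossified,
        landmarks={k: int(v) for k, v in meta["landmarks"].items()},
        node_sets={k: np.asarray(v, dtype=np.int64)
                   for k, v in meta["node_sets"].items()},
        surface_pairs={
            k: SurfacePair(np.asarray(v["slave_faces"], dtype=np.int64),
                           np.asarray(v["master_faces"], dtype=np.int64))
            for k, v in meta["surface_pairs"].items()
        },
        meta={k: (tuple(v) if isinstance(v, list) else v)
              for k, v in meta["meta"].items()},
    )
    return mesh


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def skull_params_from_config(cfg: dict):
    """Build SkullParams (+ CraniotomySpec) from the ``geometry:`` block."""
    from .synthetic_skull import CraniotomySpec, SkullParams

    g = dict(cfg.get("geometry", {}))
    cspec = g.pop("craniotomy_spec", None)
    if cspec is not None:
        cspec = CraniotomySpec(**cspec)
    if "ellipsoid_semi_axes" in g:
        g["ellipsoid_semi_axes"] = tuple(g["ellipsoid_semi_axes"])
    if "fused_sutures" in g:
        g["fused_sutures"] = frozenset(g["fused_sutures"])
    return SkullParams(craniotomy_spec=cspec, **g)


def contact_from_config(cfg: dict):
    from .fe_core import ContactSpec

    return ContactSpec(**cfg.get("mechanics", {}).get("contact", {}))


def save_report_csv(report, path):
    import pandas as pd

    if hasattr(report, "to_frame"):
        report.to_frame().to_csv(path)
    elif hasattr(report, "to_dict"):
        pd.DataFrame([report.to_dict()]).to_csv(path, index=False)
    else:
        pd.DataFrame(report).to_csv(path, index=False)
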