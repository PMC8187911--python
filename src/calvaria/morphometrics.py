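"""Craniometric measurements, patency timelines, pressures, cross-sections.

Outputs mirror a standard post-operative analysis: skull length (glabella to
opisthocranion), width (euryon to euryon), height (basion to bregma), the
cephalic index CI = width / length x 100, ICV volume, per-region
suture/craniotomy patency versus age, per-lobe contact-pressure statistics
over the ICV surface, and planar cross-section outlines of the outer skull
surface.

Reported dimensions and CI are rounded half-away-from-zero to 2 decimals,
the convention that reproduces published craniometric tables.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fe_core import SimulationState, extract_contact_pressure
from .mesh import LabeledMesh

LOBES = ("frontal", "temporal", "parietal", "occipital", "cerebellum")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the craniometric table convention)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def cephalic_index(width: float, length: float) -> float:
    """CI = width / length x 100, to 2 decimals."""
    if length <= 0 or width <= 0:
        raise ValueError("width and length must be positive")
    return round_half_away(100.0 * width / length, 2)


@dataclass
class MorphometricsReport:
    length: float          # mm
    width: float           # mm
    height: float          # mm
    cephalic_index: float
    icv_volume: float      # ml
    age: float = np.nan    # months

    def to_dict(self):
        return {
            "length_mm": self.length,
            "width_mm": self.width,
            "height_mm": self.height,
            "cephalic_index": self.cephalic_index,
            "icv_volume_ml": self.icv_volume,
            "age_months": self.age,
        }


def measure(mesh: LabeledMesh, age: float = np.nan) -> MorphometricsReport:
    """Landmark-pair distances and cephalic index of a (deformed) skull mesh."""
    needed = {
        "length": ("glabella", "opisthocranion"),
        "width": ("euryon_L", "euryon_R"),
        "height": ("basion", "bregma"),
    }
    dims = {}
    for dim, (a, b) in needed.items():
        for lm in (a, b):
            if lm not in mesh.landmarks:
                raise ValueError(f"landmark {lm!r} missing from mesh")
        pa = mesh.points[mesh.landmarks[a]]
        pb = mesh.points[mesh.landmarks[b]]
        dims[dim] = round_half_away(float(np.linalg.norm(pa - pb)), 2)
    try:
        icv = round_half_away(mesh.icv_volume_ml(), 2)
    except ValueError:
        icv = np.nan
    return MorphometricsReport(
        length=dims["length"],
        width=dims["width"],
        height=dims["height"],
        cephalic_index=cephalic_index(dims["width"], dims["length"]),
        icv_volume=icv,
        age=age,
    )


def icv_volume(mesh: LabeledMesh) -> float:
    """ICV (brain + CSF) volume in ml from signed tetrahedron volumes."""
    return mesh.icv_volume_ml()


# ---------------------------------------------------------------------------
# patency
# ---------------------------------------------------------------------------

@dataclass
class PatencyTimeline:
    """Per-region fraction of originally soft elements still unossified."""

    regions: dict        # label -> (ages, fractions) arrays
    closure_age: dict    # label -> months (inf = still open at end)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab, (ages, fr) in self.regions.items():
            for a, f in zip(ages, fr):
                rows.append({"region": lab, "age_months": a, "fraction_open": f})
        return pd.DataFrame(rows)


def patency(series, labels_of_interest=None) -> PatencyTimeline:
    """Patency timeline from a growth result or a list of (age, mesh) pairs.

    For a :class:`~calvaria.growth_formation.GrowthResult` the per-element
    front-arrival ages give closure ages exactly; a plain mesh series is
    sampled at its snapshot ages.
    """
    from .growth_formation import GrowthResult
    from .mesh import is_gap

    if isinstance(series, GrowthResult):
        mesh = series.mesh
        el = mesh.element_labels()
        gap_labels = sorted({l for l in el if is_gap(l)})
        if labels_of_interest is not None:
            gap_labels = [l for l in gap_labels if l in labels_of_interest]
        ages = series.ages
        oss_age = series.oss_age
        regions, closure = {}, {}
        grid = np.unique(np.concatenate([ages, oss_age[np.isfinite(oss_age)]]))
        for lab in gap_labels:
            sel = el == lab
            fr = np.array([np.mean(oss_age[sel] > a) for a in grid])
            regions[lab] = (grid, fr)
            closure[lab] = float(oss_age[sel].max())
        return PatencyTimeline(regions, closure)

    pairs = list(series)
    if not pairs:
        raise ValueError("empty mesh series")
    n0 = len(pairs[0][1].tets)
    for _, m in pairs:
        if len(m.tets) != n0:
            raise ValueError("inconsistent element counts across the mesh series")
    el = pairs[0][1].element_labels()
    gap_labels = sorted({l for l in el if is_gap(l)})
    regions, closure = {}, {}
    for lab in gap_labels:
        sel = el == lab
        ages = np.array([a for a, _ in pairs])
        fr = np.array([1.0 - m.ossified[sel].mean() for _, m in pairs])
        regions[lab] = (ages, fr)
        closed = ages[fr == 0]
        closure[lab] = float(closed[0]) if len(closed) else np.inf
    return PatencyTimeline(regions, closure)


# ---------------------------------------------------------------------------
# contact pressure per lobe
# ---------------------------------------------------------------------------

@dataclass
class PressureReport:
    per_lobe: dict       # lobe -> dict(min, max, mean) in MPa

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"lobe": k, **v} for k, v in self.per_lobe.items()]
        ).set_index("lobe")

    @property
    def all_lobe_mean(self) -> float:
        return float(np.mean([v["mean"] for v in self.per_lobe.values()]))


def _lobe_of_directions(cent: np.ndarray, axes) -> np.ndarray:
    from .synthetic_skull import _lobe_labels

    return np.array([l.replace("brain_", "") for l in _lobe_labels(cent, axes)])


def pressure_report(state: SimulationState, mesh: LabeledMesh,
                    pair_name: str = "icv_skull") -> PressureReport:
    """Min / max / mean contact pressure per brain lobe over the ICV surface.

    Every ICV surface face of a lobe enters the statistics; faces not in
    contact contribute zero, so minima are typically 0 and means are whole-
    surface averages (the convention matching reported per-lobe tables).
    """
    face_p = extract_contact_pressure(state, mesh, pair_name)
    reg = mesh.surface_pairs[pair_name]
    cent = mesh.points[reg.slave_faces].mean(axis=1)
    center = mesh.points[reg.slave_nodes].mean(axis=0)
    axes = mesh.meta.get("brain_axes") or mesh.meta.get("icv_axes")
    if axes is None:
        axes = np.ptp(mesh.points[reg.slave_nodes], axis=0) / 2.0
    lobes = _lobe_of_directions(cent - center, np.asarray(axes))
    per = {}
    for lobe in LOBES:
        sel = lobes == lobe
        if not sel.any():
            raise ValueError(f"no ICV surface faces assigned to lobe {lobe!r}")
        p = face_p[sel]
        per[lobe] = {
            "min": float(p.min()),
            "max": float(p.max()),
            "mean": float(p.mean()),
        }
    return PressureReport(per)


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------

def _outer_surface_faces(mesh: LabeledMesh) -> np.ndarray:
    outer_nodes = mesh.node_sets.get("skull_outer")
    from .mesh import BONE_LABELS, SUTURE_LABELS, is_craniotomy

    skull = mesh.mask(
        lambda l: l in BONE_LABELS or l in SUTURE_LABELS or is_craniotomy(l)
    )
    faces = mesh.interface_faces_of(skull)
    if outer_nodes is not None and len(outer_nodes):
        on = np.zeros(len(mesh.points), dtype=bool)
        on[outer_nodes] = True
        faces = faces[on[faces].all(axis=1)]
    if len(faces) == 0:
        raise ValueError("no outer skull surface faces found")
    return faces


def cross_section(mesh: LabeledMesh, plane_point, plane_normal):
    """Intersection polylines of the outer skull surface with a plane.

    Returns a list of (m, 3) polyline arrays (closed loops where the surface
    is closed); empty list if the plane misses the mesh.
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(plane_point, dtype=float)
    faces = _outer_surface_faces(mesh)
    tri = mesh.points[faces]
    d = np.einsum("nkj,j->nk", tri - p0, n)
    crossing = ~((d > 0).all(axis=1) | (d < 0).all(axis=1))
    segments = []
    for t, dd in zip(tri[crossing], d[crossing]):
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = dd[a], dd[b]
            if (da > 0) != (db > 0) or da == 0 or db == 0:
                if da == db:
                    continue
                s = da / (da - db)
                if 0.0 <= s <= 1.0:
                    pts.append(t[a] + s * (t[b] - t[a]))
        if len(pts) >= 2:
            segments.append((pts[0], pts[1]))
    if not segments:
        return []
    # chain segments into polylines by matching endpoints
    tol = 1e-6 * max(np.ptp(mesh.points, axis=0).max(), 1.0)
    segs = [(tuple(np.round(a / tol).astype(np.int64)),
             tuple(np.round(b / tol).astype(np.int64)), a, b) for a, b in segments]
    adj = {}
    for i, (ka, kb, _, _) in enumerate(segs):
        adj.setdefault(ka, []).append((i, 0))
        adj.setdefault(kb, []).append((i, 1))
    used = np.zeros(len(segs), dtype=bool)
    polylines = []
    for i0 in range(len(segs)):
        if used[i0]:
            continue
        used[i0] = True
        ka, kb, pa, pb = segs[i0]
        chain = [pa, pb]
        key = kb
        while True:
            nxt = [(j, e) for j, e in adj.get(key, []) if not used[j]]
            if not nxt:
                break
            j, e = nxt[0]
            used[j] = True
            ja, jb, qa, qb = segs[j]
            if e == 0:
                chain.append(qb)
                key = jb
            else:
                chain.append(qa)
                key = ja
        polylines.append(np.asarray(chain))
    return polylines


def polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def plot_patency(timeline: PatencyTimeline, path=None, ax=None):
    """Patency-versus-age curves per suture/craniotomy region (requires
    matplotlib; returns the axes)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for lab, (ages, fr) in sorted(timeline.regions.items()):
        ax.step(ages, fr, where="post", label=lab)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("fraction unossified")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, ncol=2)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
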