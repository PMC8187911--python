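"""Labeled tetrahedral mesh container used throughout the pipeline.

A :class:`LabeledMesh` is the single in-memory representation of the skull
assembly: node coordinates in mm, tetrahedral connectivity (linear 4-node or
quadratic 10-node), one region label per element (bone plates, sutures,
craniotomy gaps, CSF, brain lobes), named node sets (constraints, landmarks)
and the registry of the contact surface pair (intracranial-volume outer
surface against the inner calvarial surface).

Region labels are stored as integer codes into ``region_names`` so that large
meshes stay compact; all public helpers accept and return label strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Label taxonomy.  Bone-class regions resist growth and seed the ossification
# front; suture/craniotomy-class regions are the soft gaps that ossify.
BONE_LABELS = frozenset(
    {
        "frontal",
        "parietal_L",
        "parietal_R",
        "occipital",
        "temporal_L",
        "temporal_R",
        "craniofacial",
        "sagittal_fused",
        "reinserted_bone",
    }
)
SUTURE_LABELS = frozenset(
    {"metopic", "coronal", "lambdoid", "squamosal", "anterior_fontanelle",
     "sagittal_suture"}
)
BRAIN_LABELS = frozenset(
    {"brain_frontal", "brain_temporal", "brain_parietal", "brain_occipital", "cerebellum"}
)
CSF_LABEL = "csf"
ICV_LABELS = BRAIN_LABELS | {CSF_LABEL}
LANDMARK_NAMES = ("glabella", "opisthocranion", "euryon_L", "euryon_R", "basion", "bregma")


def is_craniotomy(label: str) -> bool:
    return label.startswith("craniotomy")


def is_bone(label: str) -> bool:
    return label in BONE_LABELS


def is_gap(label: str) -> bool:
    """Soft tissue that may ossify: sutures and craniotomy kerfs."""
    return label in SUTURE_LABELS or is_craniotomy(label)


@dataclass
class SurfacePair:
    """Contact surface registry: slave = ICV outer surface, master = inner calvaria.

    Faces are (n, 3) arrays of corner-node indices; the two surfaces are
    geometrically coincident at generation time but use duplicated nodes so
    that they can separate or slide.
    """

    slave_faces: np.ndarray
    master_faces: np.ndarray
    slave_nodes: np.ndarray = field(default=None)
    master_nodes: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.slave_nodes is None:
            self.slave_nodes = np.unique(self.slave_faces)
        if self.master_nodes is None:
            self.master_nodes = np.unique(self.master_faces)


@dataclass
class LabeledMesh:
    points: np.ndarray                      # (n_nodes, 3) mm
    tets: np.ndarray                        # (n_elem, 4) or (n_elem, 10)
    region_id: np.ndarray                   # (n_elem,) int codes
    region_names: list                      # code -> label string
    node_sets: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)   # name -> node index
    surface_pairs: dict = field(default_factory=dict)
    ossified: np.ndarray = None             # (n_elem,) bool
    order: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.region_id = np.asarray(self.region_id, dtype=np.int32)
        if self.ossified is None:
            self.ossified = np.zeros(len(self.tets), dtype=bool)
        self.order = 2 if self.tets.shape[1] == 10 else 1

    # -- label helpers -------------------------------------------------
    def code(self, label: str) -> int:
        try:
            return self.region_names.index(label)
        except ValueError:
            raise KeyError(f"region label {label!r} not present in mesh") from None

    def ensure_code(self, label: str) -> int:
        if label not in self.region_names:
            self.region_names.append(label)
        return self.region_names.index(label)

    def labels_present(self):
        return [self.region_names[c] for c in np.unique(self.region_id)]

    def element_labels(self) -> np.ndarray:
        return np.asarray(self.region_names, dtype=object)[self.region_id]

    def elements_with(self, *labels) -> np.ndarray:
        codes = [self.region_names.index(l) for l in labels if l in self.region_names]
        if not codes:
            return np.zeros(0, dtype=np.int64)
        return np.flatnonzero(np.isin(self.region_id, codes))

    def mask(self, predicate) -> np.ndarray:
        """Boolean element mask from a predicate on label strings."""
        per_code = np.array([bool(predicate(n)) for n in self.region_names])
        return per_code[self.region_id]

    def bone_mask(self) -> np.ndarray:
        """Bone-class elements including everything already ossified."""
        return self.mask(is_bone) | self.ossified

    # -- geometry ------------------------------------------------------
    @property
    def corner_tets(self) -> np.ndarray:
        return self.tets[:, :4]

    def tet_volumes(self) -> np.ndarray:
        p = self.points[self.corner_tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    def centroids(self) -> np.ndarray:
        return self.points[self.corner_tets].mean(axis=1)

    def region_volume(self, *labels) -> float:
        """Total volume (mm^3) of the given region labels."""
        idx = self.elements_with(*labels)
        if idx.size == 0:
            return 0.0
        return float(self.tet_volumes()[idx].sum())

    def icv_volume_ml(self) -> float:
        labels = [l for l in self.region_names if l in ICV_LABELS]
        if not labels:
            raise ValueError("mesh has no ICV (brain/CSF) labeled elements")
        return self.region_volume(*labels) / 1000.0

    def boundary_faces(self, element_idx=None) -> np.ndarray:
        """Faces of the given element subset that are not shared within it."""
        if element_idx is None:
            tets = self.corner_tets
        else:
            tets = self.corner_tets[element_idx]
        faces = _tet_faces(tets)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def interface_faces_of(self, mask: np.ndarray) -> np.ndarray:
        """Faces separating masked elements from the rest (or the exterior)."""
        return self.boundary_faces(np.flatnonzero(mask))

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            points=self.points.copy(),
            tets=self.tets.copy(),
            region_id=self.region_id.copy(),
            region_names=list(self.region_names),
            node_sets={k: np.array(v) for k, v in self.node_sets.items()},
            landmarks=dict(self.landmarks),
            surface_pairs={
                k: SurfacePair(v.slave_faces.copy(), v.master_faces.copy())
                for k, v in self.surface_pairs.items()
            },
            ossified=self.ossified.copy(),
            meta=dict(self.meta),
        )


def extract_region(mesh: LabeledMesh, labels) -> LabeledMesh:
    """Submesh of the elements with the given labels (nodes renumbered)."""
    idx = mesh.elements_with(*labels)
    if idx.size == 0:
        raise ValueError(f"no elements with labels {labels}")
    tets = mesh.tets[idx]
    used = np.unique(tets)
    remap = -np.ones(len(mesh.points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = LabeledMesh(
        points=mesh.points[used],
        tets=remap[tets],
        region_id=mesh.region_id[idx],
        region_names=list(mesh.region_names),
        ossified=mesh.ossified[idx],
        meta=dict(mesh.meta),
    )
    for name, ns in mesh.node_sets.items():
        kept = remap[np.asarray(ns)]
        kept = kept[kept >= 0]
        if kept.size:
            sub.node_sets[name] = kept
    for name, nid in mesh.landmarks.items():
        if remap[nid] >= 0:
            sub.landmarks[name] = int(remap[nid])
    return sub


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    """All 4 oriented faces of each tet, outward for positively oriented tets."""
    f = np.concatenate(
        [
            tets[:, [0, 2, 1]],
            tets[:, [0, 1, 3]],
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
        ]
    )
    return f


def check_conforming(mesh: LabeledMesh) -> bool:
    """Every interior face must be shared by exactly two tetrahedra."""
    faces = np.sort(_tet_faces(mesh.corner_tets), axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    return bool(np.all((counts == 1) | (counts == 2)))


def to_quadratic(mesh: LabeledMesh) -> LabeledMesh:
    """Insert midside nodes, turning 4-node tets into 10-node tets.

    Corner node indices are preserved, so node sets, landmarks and contact
    surface corner-face registries remain valid.
    """
    if mesh.order == 2:
        return mesh
    tets = mesh.corner_tets
    edges = np.concatenate(
        [tets[:, e] for e in ([0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3])]
    )
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.points[uniq[:, 0]] + mesh.points[uniq[:, 1]])
    n0 = len(mesh.points)
    mid_ids = (n0 + np.arange(len(uniq)))[inv].reshape(6, -1).T
    tets10 = np.column_stack([tets, mid_ids])
    out = mesh.copy()
    out.points = np.vstack([mesh.points, mid])
    out.tets = tets10
    out.order = 2
    return out
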