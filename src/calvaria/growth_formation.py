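"""Six-interval ICV growth driving and suture/craniotomy bone formation.

The intracranial volume is expanded from the preoperative 659 ml to the
76-month follow-up 1245 ml in six equal-volume-ratio intervals via the
thermal-expansion analogy: each interval applies an isotropic eigenstrain
alpha_i = ratio^(1/3) - 1 to the ICV regions, the quasi-static contact
problem is solved, and node coordinates are updated (updated-coordinate
stepping) so the ~24 % total linear growth accumulates from small steps.
Interval end volumes are mapped to patient age through a monotone ICV-age
curve whose endpoints are pinned at (659 ml, 4 mo) and (1245 ml, 76 mo).

Two bone-formation methods run between solves:

* Scenario I ("gradual"): suture/craniotomy elements whose centroid lies
  within rate x months of the nearest bone element face, and whose
  hydrostatic strain lies inside the 0-50 % window, ossify (get the full
  bone modulus).  The front is re-seeded from newly ossified elements, so
  formation propagates from the bone edges at the prescribed mm/month rate.
* Scenario II ("bulk"): the whole suture/craniotomy regions stiffen along a
  geometric modulus ramp from the soft baseline to the bone modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fe_core import ContactSpec, MaterialCard, SimulationState, SolverError, solve_increment
from .mesh import LabeledMesh, is_gap

# Default ICV (ml) -> age (months) table.  Endpoints are the patient's
# measured volumes; interior knots follow the strongly concave shape of
# normal infant intracranial growth (fast in the first year, slow later).
DEFAULT_VOLUME_AGE_TABLE = (
    (659.0, 4.0),
    (750.0, 7.0),
    (850.0, 11.0),
    (950.0, 16.0),
    (1050.0, 25.0),
    (1150.0, 42.0),
    (1245.0, 76.0),
)


@dataclass
class GrowthSchedule:
    v_pre: float                      # ml
    v_follow: float                   # ml
    n_intervals: int
    alpha: np.ndarray                 # per-interval linear strain
    volumes: np.ndarray               # interval end volumes, ml (n+1 incl. start)
    ages: np.ndarray                  # months at each interval boundary (n+1)

    @property
    def start_age(self):
        return float(self.ages[0])

    @property
    def end_age(self):
        return float(self.ages[-1])

    def validate(self):
        if self.v_follow <= self.v_pre:
            raise ValueError("follow-up volume must exceed preoperative volume")
        total = np.prod((1.0 + self.alpha) ** 3)
        if abs(total - self.v_follow / self.v_pre) > 1e-9 * total:
            raise ValueError("per-interval strains inconsistent with volume ratio")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("volume->age curve must be strictly increasing")


def build_schedule(v_pre: float = 659.0, v_follow: float = 1245.0,
                   n_intervals: int = 6, curve=DEFAULT_VOLUME_AGE_TABLE) -> GrowthSchedule:
    """Equal-volume-ratio growth schedule.

    Each interval multiplies the ICV by (v_follow/v_pre)^(1/n); the linear
    eigenstrain per interval is the cube root of that ratio minus one.
    """
    if v_pre <= 0 or v_follow <= 0:
        raise ValueError("volumes must be positive")
    if v_follow <= v_pre:
        raise ValueError("v_follow must exceed v_pre (growth only)")
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    curve = np.asarray(curve, dtype=float)
    if np.any(np.diff(curve[:, 0]) <= 0) or np.any(np.diff(curve[:, 1]) <= 0):
        raise ValueError("volume->age curve must be strictly increasing")
    ratio = (v_follow / v_pre) ** (1.0 / n_intervals)
    alpha = np.full(n_intervals, ratio ** (1.0 / 3.0) - 1.0)
    volumes = v_pre * ratio ** np.arange(n_intervals + 1)
    ages = np.interp(volumes, curve[:, 0], curve[:, 1])
    sched = GrowthSchedule(v_pre, v_follow, n_intervals, alpha, volumes, ages)
    sched.validate()
    return sched


@dataclass
class FormationRule:
    """Bone-formation scenario and rates.

    Rates are mm of new bone per month of volume growth, applied from every
    bone margin (so a gap of width w bridges in w / (2 rate) months).
    ``closure_deadlines`` forces a region fully closed at a given age, used
    to replicate imposed early metopic/fontanelle closure.
    """

    scenario: str = "gradual"              # "gradual" | "bulk"
    suture_rate: float = 0.1               # mm/month
    craniotomy_rate: float = 0.8           # mm/month
    rate_overrides: dict = field(default_factory=dict)   # label -> mm/month
    strain_window: tuple = (0.0, 0.5)      # hydrostatic strain gate
    formed_modulus: float = 3000.0         # MPa on conversion
    bulk_ramp_start: float = 30.0          # MPa (baseline suture/craniotomy)
    bulk_ramp_end: float = 3000.0          # MPa (bone) at the final interval
    closure_deadlines: dict = field(default_factory=dict)  # label -> age months

    def validate(self):
        if self.scenario not in ("gradual", "bulk"):
            raise ValueError(f"unknown formation scenario {self.scenario!r}")
        if self.suture_rate < 0 or self.craniotomy_rate < 0:
            raise ValueError("formation rates must be >= 0")
        if any(r < 0 for r in self.rate_overrides.values()):
            raise ValueError("formation rates must be >= 0")
        lo, hi = self.strain_window
        if lo > hi:
            raise ValueError("strain window low must be <= high")

    def rate_for(self, label: str) -> float:
        if label in self.rate_overrides:
            return self.rate_overrides[label]
        if label.startswith("craniotomy"):
            return self.craniotomy_rate
        return self.suture_rate

    def bulk_modulus_at(self, interval_index: int, n_intervals: int) -> float:
        """Geometric ramp value: start * (end/start)^(k/n)."""
        if interval_index < 0 or interval_index > n_intervals:
            raise ValueError(
                f"interval index {interval_index} outside the {n_intervals}-interval ramp"
            )
        r = self.bulk_ramp_end / self.bulk_ramp_start
        return float(self.bulk_ramp_start * r ** (interval_index / n_intervals))


def _bone_face_tree(mesh: LabeledMesh):
    """KD-tree over the original bone-margin faces, in current coordinates.

    The ossification front travels at a constant rate from the bone margins,
    so an element ossifies when the cumulative front travel rate x months
    reaches its distance from the *original* margin -- identical to seeding
    the front from newly ossified elements in the continuum limit, but free
    of the element-size quantization that stalls a per-step radius on coarse
    meshes.
    """
    from .mesh import is_bone

    bone = mesh.mask(is_bone)
    if not bone.any():
        return None, None
    faces = mesh.interface_faces_of(bone)
    tri = mesh.points[faces]
    return cKDTree(tri.mean(axis=1)), tri


def _dist_to_bone(mesh: LabeledMesh, query_pts: np.ndarray) -> np.ndarray:
    """Distance from points to the nearest bone-element face (exact point-to-
    triangle on KD-tree candidates)."""
    from .fe_core import _point_tri_project

    tree, tri = _bone_face_tree(mesh)
    if tree is None:
        return np.full(len(query_pts), np.inf)
    k = min(8, len(tri))
    _, cand = tree.query(query_pts, k=k)
    cand = cand.reshape(len(query_pts), k)
    best = np.full(len(query_pts), np.inf)
    for j in range(k):
        closest, _ = _point_tri_project(query_pts, tri[cand[:, j]])
        best = np.minimum(best, np.linalg.norm(query_pts - closest, axis=1))
    return best


def gradual_formation_step(mesh: LabeledMesh, state: SimulationState,
                           rule: FormationRule, months_elapsed: float,
                           age: float = None) -> int:
    """Ossify every suture/craniotomy element reached by the formation front.

    An element converts when its centroid lies within rate x months_elapsed
    (cumulative months of volume growth) of the nearest bone-margin face AND
    the magnitude of its hydrostatic strain lies inside the strain window
    (the 0-50 % gate; the printed convention does not fix the sign, so the
    magnitude is gated).  Mutates ``mesh.ossified`` in place and returns the
    number of newly converted elements; ossified elements never revert.
    """
    if months_elapsed <= 0:
        raise ValueError("months_elapsed must be > 0")
    if state is None or state.eps_h is None:
        raise ValueError("state carries no hydrostatic strain field")
    rule.validate()
    labels = mesh.element_labels()
    cand = mesh.mask(is_gap) & ~mesh.ossified
    deadline_hit = np.zeros(len(labels), dtype=bool)
    if age is not None:
        for lab, dl in rule.closure_deadlines.items():
            if age >= dl:
                deadline_hit |= labels == lab
    if not cand.any():
        return 0
    idx = np.flatnonzero(cand)
    cached = mesh.meta.get("formation_dist")
    if cached is not None:
        # material-frame front: distances frozen at the undeformed geometry,
        # since formed bone is advected with the stretching tissue
        dist = cached[idx]
    else:
        dist = _dist_to_bone(mesh, mesh.centroids()[idx])
    rates = np.array([rule.rate_for(l) for l in labels[idx]])
    radius = rates * months_elapsed
    lo, hi = rule.strain_window
    eh = np.abs(state.eps_h[idx])
    convert = (dist <= radius) & (eh >= lo) & (eh <= hi)
    new = np.zeros(len(labels), dtype=bool)
    new[idx[convert]] = True
    new |= deadline_hit & cand
    mesh.ossified |= new
    # per-element front-arrival ages (exact given the current geometry, not
    # quantized to the solver step grid)
    if "oss_age" in mesh.meta and age is not None:
        oss_age = mesh.meta["oss_age"]
        t0 = age - months_elapsed
        with np.errstate(divide="ignore"):
            arrival = t0 + np.where(rates > 0, dist / np.maximum(rates, 1e-300), np.inf)
        floor = mesh.meta.get("oss_age_floor", t0)
        arr = np.clip(arrival[convert], a_min=floor, a_max=age)
        oss_age[idx[convert]] = np.minimum(oss_age[idx[convert]], arr)
        for lab, dl in rule.closure_deadlines.items():
            sel = new & (labels == lab)
            oss_age[sel] = np.minimum(oss_age[sel], max(dl, t0))
    return int(new.sum())


def bulk_formation_step(materials: MaterialCard, rule: FormationRule,
                        interval_index: int, n_intervals: int = 6,
                        mesh: LabeledMesh = None) -> MaterialCard:
    """Scenario II: stiffen whole suture/craniotomy regions along the ramp.

    Returns an updated material card; at the end of the ramp the regions
    reach the bone modulus and (if a mesh is given) are flagged ossified.
    """
    rule.validate()
    E = rule.bulk_modulus_at(interval_index, n_intervals)
    card = materials.copy()
    labels = mesh.region_names if mesh is not None else None
    target = (
        [l for l in labels if is_gap(l)]
        if labels is not None
        else None
    )
    if target is None:
        raise ValueError("bulk_formation_step requires the mesh for region labels")
    for lab in target:
        prev = materials.lookup(lab)
        card.set(lab, max(E, prev.E), prev.nu)
    if interval_index >= n_intervals and mesh is not None:
        mesh.ossified |= mesh.mask(is_gap)
    return card


@dataclass
class GrowthRecord:
    age: float
    ossified: np.ndarray
    state: SimulationState = None
    icv_volume_ml: float = 0.0


@dataclass
class GrowthResult:
    """Time series of a growth simulation plus the final deformed mesh."""

    mesh: LabeledMesh                 # final (deformed, relabeled) mesh
    records: list                     # GrowthRecord per sub-increment
    schedule: GrowthSchedule
    rule: FormationRule
    materials: MaterialCard

    @property
    def ages(self):
        return np.array([r.age for r in self.records])

    @property
    def oss_age(self):
        """Per-element ossification (front-arrival) age in months; inf = open."""
        return self.mesh.meta.get("oss_age")

    def closure_age(self, prefix: str) -> float:
        """Age at which every element of regions starting with ``prefix`` is
        ossified; inf if any stays open."""
        labels = self.mesh.element_labels()
        sel = np.array([l.startswith(prefix) for l in labels])
        if not sel.any():
            raise ValueError(f"no region labels start with {prefix!r}")
        return float(self.oss_age[sel].max())

    @property
    def final_state(self):
        for r in reversed(self.records):
            if r.state is not None:
                return r.state
        return None


def run_growth(
    mesh: LabeledMesh,
    materials: MaterialCard,
    schedule: GrowthSchedule,
    rule: FormationRule,
    contact: ContactSpec = None,
    n_substeps: int = 3,
    constraints=None,
    free_expansion: bool = False,
    keep_states: bool = True,
    progress=None,
) -> GrowthResult:
    """Run the six-interval growth simulation.

    ``free_expansion=True`` drops skull contact and boundary constraints and
    solves the floating ICV with rigid modes projected out (the cube-law
    verification path).  Formation steps run after every sub-increment with
    the months elapsed since the previous step; under the bulk scenario the
    material ramp advances once per interval.
    """
    schedule.validate()
    rule.validate()
    mesh = mesh.copy()
    materials = materials.copy()
    work = mesh.points.copy()
    mesh.meta["oss_age"] = np.full(len(mesh.tets), np.inf)
    if rule.scenario == "gradual":
        # freeze the formation-front metric in the undeformed (material) frame
        gap_el = mesh.mask(is_gap)
        d0 = np.full(len(mesh.tets), np.inf)
        if gap_el.any():
            d0[gap_el] = _dist_to_bone(mesh, mesh.centroids()[gap_el])
        # the fontanelle is a disc whose nominal rim is the bone margin; use
        # the exact disc geometry so coarse-mesh centroid quantization does
        # not shrink its effective radius (the disc radius, not the element
        # sampling, decides whether it can close)
        if "af_center" in mesh.meta and "anterior_fontanelle" in mesh.region_names:
            af = mesh.element_labels() == "anterior_fontanelle"
            if af.any():
                r_af = mesh.meta["af_radius"]
                c = np.asarray(mesh.meta["af_center"])
                d_rim = r_af - np.linalg.norm(mesh.centroids()[af] - c, axis=1)
                d0[af] = np.clip(d_rim, 0.1, r_af)
        mesh.meta["formation_dist"] = d0
    records = [GrowthRecord(schedule.start_age, mesh.ossified.copy(),
                            icv_volume_ml=mesh.icv_volume_ml())]
    age_prev = schedule.start_age
    for k in range(schedule.n_intervals):
        a_i = schedule.alpha[k]
        a_sub = (1.0 + a_i) ** (1.0 / n_substeps) - 1.0
        if rule.scenario == "bulk":
            # ramp value applied for the whole interval; the final interval
            # is solved at the full bone modulus (the regions close)
            idx = schedule.n_intervals if k == schedule.n_intervals - 1 else k
            materials = bulk_formation_step(
                materials, rule, idx, schedule.n_intervals, mesh=mesh
            )
            if idx == schedule.n_intervals:
                mesh.meta["oss_age"][mesh.ossified] = np.minimum(
                    mesh.meta["oss_age"][mesh.ossified], schedule.end_age
                )
        for s in range(n_substeps):
            frac = (s + 1) / n_substeps
            age = schedule.ages[k] + (schedule.ages[k + 1] - schedule.ages[k]) * frac
            try:
                if free_expansion:
                    from .fe_core import assemble, solve_free

                    K, f = assemble(mesh, materials, a_sub, points=work)
                    u = solve_free(K, f, work)
                    state = SimulationState(u=u.reshape(-1, 3), age=age)
                    from .fe_core import compute_strains

                    state.strain, state.eps_h = compute_strains(mesh, state.u, points=work)
                else:
                    state = solve_increment(
                        mesh, materials, a_sub, contact=contact,
                        constraints=constraints, points=work,
                        increment=k * n_substeps + s, age=age,
                    )
            except SolverError as e:
                raise SolverError(f"interval {k + 1}, sub-increment {s + 1}: {e}") from e
            work = work + state.u
            mesh.points = work.copy()
            if rule.scenario == "gradual":
                mesh.meta["oss_age_floor"] = age_prev
                gradual_formation_step(
                    mesh, state, rule, age - schedule.start_age, age=age
                )
            records.append(
                GrowthRecord(
                    age,
                    mesh.ossified.copy(),
                    state=state if keep_states else None,
                    icv_volume_ml=mesh.icv_volume_ml(),
                )
            )
            age_prev = age
            if progress is not None:
                progress(k, s, age)
    return GrowthResult(mesh, records, schedule, rule, materials)
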