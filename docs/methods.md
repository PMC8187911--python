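# Methods

`calvaria` simulates post-operative calvarial growth in an infant treated
for sagittal craniosynostosis with a Renier-"H" calvarial reconstruction,
at desk scale, on a parametric synthetic skull. This note documents the
model, its assumptions, the numerical choices, and what the synthetic
geometry does and does not represent.

## The mechanical model

The assembly is a conforming tetrahedral mesh with three tissue groups:

* **Calvaria** — bone plates (frontal, parietal, occipital, temporal, a
  craniofacial block) separated by soft suture strips (metopic, coronal,
  lambdoid, squamosal, anterior fontanelle); the sagittal suture is fused
  (bone) preoperatively. The Renier-"H" craniotomies are relabelings of this
  shell: the fused strip is replaced by two reinserted bone squares
  surrounded by open kerf gaps, two rectangular cuts cross each parietal
  plate (posterior of the coronal and anterior of the lambdoid, separated
  from the sutures by a one-kerf bone margin, as the surgeon leaves), and
  one wedge per side runs down to the squamosal.
* **Intracranial volume (ICV)** — a brain partitioned into five lobes
  (frontal, temporal, parietal, occipital, cerebellum) by axis-aligned
  anatomical sectors, plus, in Model I, a uniform 2.5 mm CSF layer between
  brain and bone modeled as a soft solid. Model II (no CSF layer) is the
  baseline.
* All materials are linear isotropic. Baseline elastic moduli (MPa):
  bone 3000, sutures 30, craniotomies 30, brain 100, CSF 40; Poisson's
  ratios 0.3 for the hard tissues and 0.48 for brain and CSF.

Growth is imposed through the thermal-expansion analogy: an isotropic
eigenstrain applied to the ICV regions. The preoperative ICV (659 ml at
4 months of age) expands to the follow-up ICV (1245 ml at 76 months) in six
equal-volume-ratio intervals; each interval carries the linear eigenstrain
`(V_{k+1}/V_k)^{1/3} − 1` and is subdivided into sub-increments (default 3)
solved quasi-statically. Node coordinates are updated after every
sub-increment, so the ~24 % total linear growth accumulates from
small-strain steps.

The ICV outer surface and the inner calvarial surface are initially
coincident, duplicated-node surfaces coupled by node-to-surface penalty
contact with Coulomb friction: friction coefficient 0.1, normal penalty
600 N/mm per mm² of surface (contact pressure = 600 × penetration, in MPa),
penetration tolerance 0.5 mm. All degrees of freedom are fixed on the
foramen-magnum ring, along the nasion, and on the ICV nodes inside the
foramen cone (the brainstem anchor). Bone–suture–CSF interfaces are bonded
by shared nodes.

### Volume→age mapping

Interval end volumes map to patient ages through a monotone ICV(age) table
pinned at (659 ml, 4 mo) and (1245 ml, 76 mo). The interior knots follow
the strongly concave shape of normal infant intracranial growth — roughly
750 ml at 7 mo, 950 ml at 16 mo, 1150 ml at 42 mo — because intracranial
volume grows far faster in the first year than later; a linear interpolation
would push the first growth interval past the first birthday and distort
every closure-age prediction. The table is a configuration input; only its
endpoints are patient measurements.

## Bone formation

**Scenario I, "gradual" (baseline).** Ossification proceeds from the bone
margins at a constant rate per month of volume growth: 0.1 mm/month for
sutures, 0.8 mm/month for craniotomy gaps. A suture/craniotomy element
ossifies (and immediately receives the full bone modulus) when

1. its centroid lies within `rate × months since 4 mo` of the nearest bone
   face, with the distance evaluated once on the **undeformed** geometry
   (the material frame: newly formed bone is advected with the stretching
   tissue, so the front travels at the nominal rate through the tissue even
   while the kerf gaps widen spatially), and
2. the magnitude of its hydrostatic strain, `|tr(ε)|/3`, lies in the 0–50 %
   window at the current solve (the strain gate; the magnitude convention is
   used because the deformed vault leaves a few kerf elements in mild
   compression, which would otherwise never ossify).

This front is the exact continuum limit of seeding the front from newly
ossified elements and is robust to element-size quantization, which is what
a per-step radius re-measured from the current bone set is not at desk
resolution. For the anterior fontanelle the front distance uses the nominal
disc geometry (distance to the 12 mm rim) rather than the labeled-element
margins, since centroid sampling would otherwise shrink the disc's
effective radius by nearly half at coarse resolution — the disc radius, not
the element sampling, decides whether the fontanelle can close (at
0.1 mm/month over 72 months it cannot, so it stays patent; at the
accelerated 0.6 mm/month it closes by 24 months). Each element's
front-arrival age `4 + d/rate` is recorded, so closure ages are not
quantized to the solver's step grid. Ossified elements never revert.

**Scenario II, "bulk".** Instead of a spatial front, the whole
suture/craniotomy regions stiffen along a geometric modulus ramp
`30 × 100^{k/6}` MPa applied during interval k; the final interval is
solved at the full bone modulus (3000 MPa) and the regions are flagged
closed at the end age. This is the computationally cheaper whole-region
alternative; by the final interval it rigidifies every gap — including the
fontanelle, which the gradual front leaves patent — and consequently raises
the final ICV contact pressure above the gradual scenario's.

**Imposed closures.** Experiment "test5" accelerates the metopic and
anterior-fontanelle rates to 0.6 mm/month and force-closes both regions at
24 months of age if any element is still open (an imposed calibration of
early physiological closure).

## Synthetic geometry

Patient CT is not available, so the generator builds a parametric analogue
that preserves the topology and label adjacency the algorithms consume: a
scaphocephalic ellipsoid (default semi-axis proportions 80 : 50 : 42,
anterior–posterior : mediolateral : vertical) built from concentric
UV-sphere layers. The y < 0 half of the template is an exact mirror copy of
the y > 0 half, so node positions are midsagittally symmetric to machine
precision. The discrete ICV volume is calibrated to the target (659 ml) by
a rescaled second build, so the match is exact rather than within
discretization error. A circular foramen-magnum opening (22° half-angle) is
cut from the shell; six craniometric landmarks (glabella, opisthocranion,
both euryons, basion, bregma) are placed on extremal/junction outer-surface
nodes.

Suture strips are nominally 2 mm wide but snapped to at least roughly one
element width so every region exists at coarse resolution; closure ages of
sutures therefore scale with mesh size at desk scale (craniotomy closure is
governed by the 10 mm kerf, which is resolved). The residual kerf gap around
reinserted pieces (10 mm default) is a construct — the source surgery does
not state it — chosen so that bilateral formation at 0.8 mm/month bridges
the craniotomies shortly before 12 months of age, the reported behaviour.

What the synthetic skull does **not** represent: real calvarial curvature
and thickness maps, patient-specific suture geometry, the actual H-pattern
proportions, bone anisotropy or heterogeneity, or the manual intra-operative
bone deformation. Absolute morphometric predictions (length, width, CI in
mm) therefore cannot be compared with the patient's values; what carries
over are the algorithmic behaviours — closure timing driven by rates and
gap widths, the pressure ordering between formation scenarios, and the
cushioning effect of the CSF layer.

## Numerics

* Linear 4-node tetrahedra by default (10-node quadratic supported and
  patch-tested; element counts of 5–30 k replace the source setup's 4 M).
  Assembly is vectorized; solves use sparse LU on the constrained system.
* Contact kinematics (projections, smoothed area-weighted nodal normals,
  reference gaps) are frozen at the start of each sub-increment, making the
  gap exactly linear in the displacement; the active set and Coulomb
  stick/slip states are iterated to a fixed point (tolerance 1e-8 of the
  load norm, capped at 60 iterations with progressive under-relaxation;
  near-equilibrium limit cycles below 1e-4 are accepted and the residual
  recorded on the state). Touching nodes (gap = 0) are active with zero
  force, matching surfaces that start in contact.
* The tangential penalty is 0.1 × the normal penalty: the Coulomb cap still
  bounds tangential traction, and the softer stick springs prevent
  stick/slip limit-cycling on the suture-hinged vault.
* Tiny weak springs (1e-9 × mean stiffness diagonal) stabilize the ICV
  rigid modes before contact engages, as quasi-static commercial solvers do.
* Free (unconstrained) growth verification solves project out the six
  rigid-body modes and use conjugate gradients.
* Verification: patch test to 1e-8; uniaxial bar exact; thick-wall
  expanding-sphere benchmark within 1 % (bonded, consistent nodal
  reactions) and within 10 % through the contact path (penalty compliance
  included); energy consistency to 1e-6; mesh convergence within 2 %
  between refinements.
* Brain ν = 0.48 with linear tetrahedra implies some volumetric locking;
  free dilation is exact (affine), but confined pressure magnitudes carry
  discretization bias. Orderings between scenarios, not absolute pressures,
  are the meaningful desk-scale output.

## Problem sizes and determinism

Default experiment resolution is a 9 mm target edge (~10–25 k elements);
the test suite and the acceptance computation use 12–13 mm (~5–8 k
elements) with 2 sub-increments per interval, sizes chosen so a full
sensitivity grid runs on one CPU at desk scale. Everything is deterministic:
the generator is structured (the seed parameter only feeds optional meshing
jitter, off by default), and the solver has no stochastic component; two
runs of the same configuration are bit-identical.

## Known limitations

* Ossification is a geometric front with a strain gate, not a
  mechanobiological differentiation model; formed bone jumps to the full
  bone modulus with no maturation ramp.
* The CSF is a soft solid layer; no fluid pressure or flow.
* Suture closure ages at coarse resolution inherit the snapped strip
  widths; they are comparable across configurations (the sensitivity
  orderings), not calibrated clinical predictions.
* The anterior fontanelle is an idealized 12 mm-radius disc; its patency
  behaviour is governed entirely by that radius and the formation rate.
* The constrained vault stores part of the imposed growth elastically, so
  the final ICV undershoots the follow-up volume by 2–5 % depending on
  resolution (volumetric locking of the nearly incompressible brain with
  linear tetrahedra).
* Contact pressures depend on the penalty stiffness (pressure =
  600 MPa/mm × penetration) and on mesh resolution; per-lobe minima of
  zero reflect whole-surface statistics including non-contacting faces.
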