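# Methods

`fusesim` simulates bone regeneration in a posteriorly instrumented lumbar
interbody fusion (PLIF) segment with an iterative, mechano-regulated
healing loop coupled to a linear-elastic finite-element model. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic construct does and does not represent.

## The construct

The simulated geometry is an idealized two-vertebra fusion segment built
parametrically rather than from patient imaging: two rectangular vertebral
blocks (default 40 × 30 × 20 mm) with a 1 mm cortical shell around a
trabecular core, a 9 mm disc space filled with healing tissue (the
"callus" or fusion region), two solid interbody cages (9 mm high, 10 mm
wide, 22 mm deep, placed symmetrically about the sagittal midline), and a
posterior fixation bridge of two square-section titanium rods tied to the
posterior cortical faces. All interfaces — implant–bone, callus–bone,
callus–cage — are tied, realized as shared-node conforming meshes.

Meshing is a tensor-product grid whose breakpoints coincide with every
region boundary, subdivided to target edge lengths and split into
tetrahedra by the Kuhn (orthoscheme) triangulation. Consequences worth
knowing:

* region volumes are exact (every region boundary is a grid plane), and
  the mesh is bit-identical for identical parameters — there is no
  randomness anywhere in the pipeline;
* all tetrahedra are non-obtuse orthoschemes, which gives the diffusion
  operator the M-matrix property used below;
* default target edges are 2.5 mm in-plane, 1.8 mm axially in the disc
  space and 3.0 mm axially in the vertebrae, chosen as the coarsest
  discretization that leaves the healing region with enough resolution
  (~10 500 callus tetrahedra, 5 axial element layers across the disc
  space) for front propagation and bridging detection while keeping a
  full 15-week simulation in the minutes range on a single core. Halving
  the edges changes the calibrated diffusion coefficient by < 5 % and
  leaves region volumes within meshing tolerance.

The vertebral blocks are deliberately crude: the healing algorithm needs a
plausible load path (stiff cage pillars in parallel with soft callus,
compliant trabecular cores, stiff cortical walls), not anatomical fidelity,
and reported sensitivity of spinal kinematics to bony material properties
is low. What the idealization does *not* reproduce: curved endplates and
cage–endplate contact mechanics, facet joints and ligaments (resected in
PLIF), segmental lordosis, and any patient-specific variation.

## Finite-element model

Four-node constant-strain tetrahedra (the C3D4 element), small strains,
isotropic linear elasticity, mm–N–MPa units. Healing tissues follow the
long-bone-healing convention: granulation 1 MPa (ν 0.167), fibrous 2 MPa
(0.167), cartilage 10 MPa (0.167), newly formed bone 1000 MPa (0.325);
cortical bone 10 GPa (0.3), trabecular 100 MPa (0.3); cages PEEK 3.5 GPa
or titanium 110 GPa (0.3), fixation titanium.

The caudal face is fixed. Compression (500 N) is applied as a statically
equivalent, tributary-area-weighted nodal load over the cranial face. The
flexion moment is a linear nodal-force distribution over the same face
(zero net force, prescribed net moment about the transverse axis) — a
distributed-coupling surrogate chosen over a rigid tie to avoid artificial
stiffening of the loaded face.

CST elements are known to be stiff in bending; the verification suite
quantifies this with a cantilever oracle (tip rotation within 8 % of
Euler–Bernoulli at 16 elements through the bending depth). In the
construct, bending of the fused segment is resisted almost entirely by the
cage pillars and fixation, so the element-level bending bias has little
leverage on the callus stimuli.

The solver is a sparse direct factorization (SuperLU, symmetric-mode
minimum-degree ordering) reused across load cases of one iteration; a
relative-residual check (1e-7) and a pivot check guard against silently
singular systems.

Per-element stimuli are the magnitude of the most compressive principal
strain, in percent, and the hydrostatic pressure p = −(σ₁+σ₂+σ₃)/3 (MPa,
positive in compression), evaluated from the element strain tensor and
Hooke's law.

## Cell migration

Osteoprogenitor migration into the fusion region is a normalized diffusion
problem, dn/dt = D∇²n, on the callus submesh only (cages and fixation are
impermeable; zero flux on all other boundaries), with the vertebral
endplates as a Dirichlet source n = 1 — the bony endplate interface is the
cell reservoir, and the Dirichlet choice guarantees the stated maximum
density of 1. Cell mitosis and apoptosis are neglected and D is constant.

Time integration is backward Euler with a lumped mass matrix, 0.5-day
sub-steps inside each weekly macro-step. On non-obtuse meshes this scheme
satisfies a discrete maximum principle, so 0 ≤ n ≤ 1 holds at every
sub-step without clipping (asserted in the tests).

D is not a measured quantity: it is calibrated by bisection (1 % relative
bracket) to the smallest value for which the cell front covers the entire
intervertebral space — minimum nodal density ≥ 0.95 — by the end of week
4. The 0.95 threshold operationalizes "entire space" because exact n = 1
everywhere is only reached asymptotically; it is configurable. On the
default construct the calibrated D ≈ 0.99 mm²/day, and first full coverage
occurs at week 4 by construction of the calibration; the steady state is
n = 1 to 1e-6 everywhere.

## Tissue differentiation

Each week, every callus element is classified from its combined stimulus
(ε = strain stimulus in %, p = hydrostatic pressure in MPa):

* **resorption** if ε < 0.1 % and |p| < 0.15 MPa (mechanically idle);
* **bone** (intramembranous route) if ε ≤ 5 % and |p| ≤ 0.15 MPa;
* **cartilage band** (endochondral route) if p > 0.15 MPa and ε ≤ 15 %;
* **fibrous tissue** otherwise.

The resorption limits (0.1 %, 0.15 MPa) are the values established for
this rule family; the bone/cartilage/fibrous boundaries (5 %, 0.15 MPa,
15 %) follow the Claes–Heigele diagram and are configurable. The
resorption condition uses AND: an element is resorbed only when it is idle
in both stimulus components — OR would resorb highly pressurized but
low-strain tissue, contradicting the stress-shielding interpretation.

State update per element:

1. a resorption target reverts the element to granulation (the mesh is
   never modified; "removal" is a material reassignment);
2. differentiation into fibrous/cartilage/bone requires an element-mean
   cell density n̄ ≥ 0.25 (no cells, no tissue);
3. the endochondral band is a bone-forming route, not a terminal state:
   soft tissue there becomes cartilage, existing cartilage matures to
   bone, and existing bone persists. This matters because load-bearing
   bone at 1000 MPa inevitably develops |p| > 0.15 MPa; a literal
   band→state map would perpetually demote functioning bone to cartilage
   and the fusion could never consolidate;
4. ossification front: with the front rule on (default), bone may form
   only in elements face-adjacent to bone that survives the current
   iteration or to the vertebral bone interface, and bone islands that
   lose their face-connected path to an interface revert to granulation.
   The bone set is therefore always reachable from the endplates — bone
   grows from the vertebral surfaces toward the center, as observed
   clinically and in the tests;
5. element stiffness follows a rule of mixtures,
   E_target = n̄·E_phenotype + (1−n̄)·E_granulation, and the modulus
   applied to the FE model is the mean of the last 3 weekly targets
   (granulation-padded at the start). This 3-week material window damps
   the one-week form/resorb limit cycle of instantaneous property
   switching — a newly stiffened element shields itself into the
   resorption band and flips back — and realizes gradual maturation and
   *slow* resorption of shielded bone. Window 1 recovers the undamped
   update and is what the operation-level unit contracts are written
   against. The Poisson ratio switches immediately with phenotype.

Classification itself remains a pure, total function of (ε, p) — verified
exhaustively against an independently coded band evaluator on a
0.01 % × 0.01 MPa grid.

## Loading protocols and moment calibration

Two protocols are compared, mirroring a day of habitual loading:

* **compression**: 500 N axial, duty 1.0;
* **hybrid** (habitual flexion): 63 % of the day 500 N + flexion moment,
  37 % of the day 500 N alone.

Per-case stimuli are combined as the duty-weighted mean (time-averaged
exposure); a "max" envelope mode exists for sensitivity analysis.

The flexion moment is calibrated, not prescribed: the assumption is that
people flex their spine to the same range of motion before and after
surgery. The physiological reference is a whole lumbar spine (L1–L5)
reaching 19.37° of flexion under 7.5 Nm with a 500 N preload. Because the
simulated construct is a single (very stiff) fused segment, the ROM target
cannot be meaningful for the segment alone — matching 19.37° of segmental
rotation would require a ~2000 Nm moment and >40 % callus strains. The
untreated segments are therefore represented by a lumped series
flexibility, default (19.37° × 3/4)/7.5 Nm ≈ 0.0019 °/N·mm (three healthy
segments sharing the physiological ROM equally), and the moment is
increased until construct rotation + adjacent-segment rotation reaches the
target. Linearity makes θ(M) affine, so a secant step from two solves
lands within the 0.05° tolerance. On the default granulation-state
construct this yields ≈ 9.8 N·m — slightly above the physiological
7.5 N·m, as expected when a motion segment is replaced by a stiffer
construct. Setting the adjacent flexibility to zero recovers a pure
single-segment calibration. The moment is calibrated once, at the week-1
granulation state, and held constant (a constant habitual ROM during
healing is assumed); per-iteration recalibration is available as an
option.

## The weekly loop and outputs

Each of the 15 iterations (1 iteration = 1 week, ~105 days total):
diffuse cells for 7 days → assemble/factorize the FE model with current
element properties → solve every load case → combine stimuli by duty →
classify → update tissue → record metrics. The initial state is
all-granulation callus with cells only at the endplate sources.

Recorded per week:

* **bone volume %** — volume fraction of callus elements with bone
  phenotype, normalized by the callus (intervertebral) volume only; the
  solid cages are excluded from numerator and denominator since they
  cannot ossify. An E-weighted variant (`bone_volume_weighted`) counts
  each bone element by its maturity.
* **stiffness without implants** (N/mm) — cages and fixation softened to
  1e-3 MPa (element deletion would change the mesh), 500 N probe load,
  force / mean axial displacement of the cranial face: the load-carrying
  capacity of the biological tissue alone.
* **resorption-zone volume %** — callus volume fraction classified into
  the resorption band by the current combined stimulus (the
  stress-shielding footprint).
* **bridged** — whether a face-connected path of bone elements joins
  elements touching the cranial vertebral interface to elements touching
  the caudal one (the model's definition of arthrodesis).

Runs are deterministic: identical configuration produces byte-identical
`history.csv`.

## What the synthetic conditions can and cannot show

The default construct reproduces the *mechanics* that drive the published
fusion-pattern observations: stiff cages shield the central fusion region
(a persistent resorption zone between the cages from mid-healing on),
bone grows inward from the endplates, habitual flexion loads the anterior
and peripheral callus into the bone-formation band and increases final
bone volume relative to pure compression, titanium cages shield more than
PEEK while barely changing final bone volume. These are ordering and
pattern statements; absolute bone-volume percentages depend on the
idealized geometry and the desk-scale discretization and are not expected
to match a CT-derived subject-specific model. Quantities tied to the
diffusion calibration (coverage by week 4, maximum density 1) are exact
reproductions of the model's stated calibration and are recomputed by
`scripts/acceptance.py`.

## Known limitations

* Linear kinematics and materials; no contact, no cage–endplate
  micromotion (tied interfaces), no follower load (a single fused segment
  makes the axial face load equivalent up to curvature the idealized
  geometry lacks).
* The differentiation thresholds come from long-bone healing; their
  transfer to spinal fusion is the same assumption the underlying
  algorithm family makes.
* One cell population, constant D, no angiogenesis or biochemical
  signaling; no bone graft or BMP effects.
* The adjacent-segment flexibility is a single lumped constant; no
  adjacent-level remodeling.
* Weekly time discretization; the absolute time scale inherits the
  algorithm family's calibration and is not separately validated.
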