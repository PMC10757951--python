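# Methods

`osteovox` simulates bone regeneration in a stabilised femoral osteotomy as a
coupled micro-multiphysics agent-based model: every 10.5 µm voxel of a
micro-CT-resolution lattice carries mineral density, osteoid, at most one
cell, chemical concentrations and a mechanical signal, and four sub-models
exchange state on a fixed schedule.  This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Coupling scheme

One macro-step spans 8 h.  At its start the micro-FE problem is solved once
and the strain-energy density (SED) and effective strain (EFF) fields are
frozen for the rest of the step.  Then 24 cell/vessel updates (20 min each)
interleave with 16 implicit reaction–diffusion–decay (RDD) substeps (30 min
each) following a fixed table that alternates C,R,C,R,C blocks; the ordering
is part of the contract, and a master seed spawns named RNG streams
(initialisation / cells / vessels) so runs are bit-identical for a fixed
seed.  The timestep ratios (24 cell updates per FE solve; 48 RDD iterations
per day) are fixed by the model design; the interleaving table itself is a
reconstruction, chosen so neither field lags the other by more than a
fraction of the macro-step.

## Micro-FE mechanics

Each voxel is an 8-node hexahedral element.  Young's modulus follows the
mineral density: 3 MPa below 395 mg HA/cm³ (soft tissue), linear from 4 GPa
at 395 to 14 GPa at 720 mg HA/cm³, Poisson 0.3 everywhere, linear elasticity
throughout.  Two protocols run per macro-step:

* **Apparent stiffness**: 1 % axial compression with frictionless platens
  (bottom face fixed axially, minimal lateral pinning), k_c = reaction
  force / displacement.  Frictionless platens make the homogeneous-bar
  stiffness exactly E·A/L, which anchors the oracle tests.
* **Ambulatory load**: the proximal face receives an axial displacement
  varying linearly across the section, w(x) = 1 + β(x − x_c)/d, i.e.
  compression plus a bending gradient about the section centroid that
  strengthens as the fixator plane (offset d, default 3 mm) moves closer.
  The linear solution is rescaled so the total axial reaction equals the
  peak ambulatory force F_w = 10.5 N, and the strain fields are multiplied
  by the callus load share k_c/(k_c + k_f) with fixator stiffness
  k_f = 23.8 N/mm.

SED is evaluated from the centroid strain per element; EFF = √(2·SED/E).
Both fields are Gaussian-regularised (σ = 1.0 voxel, kernel truncated at
⌈support/σ⌉ = 1 voxel; the truncation convention follows micro-CT evaluation
practice and is exposed in the config).  The osteogenic thresholds are
SED > 0.008 MPa or EFF > 0.008; resorption is permitted below
SED = 0.015 MPa (the osteolytic window).  Both are used globally for cells
in mineralised and soft tissue.

The linear systems are solved with conjugate gradients preconditioned by a
geometric multigrid hierarchy (trilinear prolongation between 2×-coarsened
node grids, Galerkin coarse operators, Chebyshev smoothing — robust to the
3 MPa / 14 GPa modulus contrast of a freshly bridged callus — and sparse LU
on the coarsest level), converged to a relative residual of 1e-6; systems
below 40 k unknowns go to a sparse direct solve.  The preconditioner is rebuilt
whenever more than 64 voxels change tissue class and at least every 4
macro-steps; CG always iterates on the current matrix, so the lag affects
iteration counts only, never the solution.

## Reaction–diffusion–decay

Seven species diffuse and decay: VEGF, RANKL, OPG, sclerostin (Scl),
TGF-β, the RANKL–OPG complex, and oxygen.  Each obeys
∂c/∂t = ∇·(D∇c) − λc, advanced by an unconditionally stable backward-time
centred-space (BTCS) step with harmonic-mean face diffusivities (exactly
conservative on a closed domain), Dirichlet values on the proximal/distal
faces and reflective lateral faces.  Cytokines share one diffusivity in soft
tissue (100 µm²/s) and are 100× slower through mineralised voxels; oxygen
diffuses equally through both (the compensation for the absent
intra-cortical vasculature).  The per-voxel diffusivity map refreshes every
RDD substep from the mineral field; the factorised operator is refreshed
once more than 512 voxels have flipped class (config
`rdd.rebuild_threshold_voxels`) because an LU refactorisation costs seconds
while a few-voxel coefficient lag over minutes of simulated time is
negligible.  All same-coefficient cytokines share one factorisation and are
solved as a single multi-RHS backsolve.

The reaction step applies receptor–ligand kinetics per cell (receptors
RANK←RANKL, VEGFR←VEGF, TGFBR1←TGF-β, LRP5/6←Scl), advancing the linear
binding ODE dB/dt = k_on·c·(N−B) − k_off·B by its exact exponential
relaxation with the local ligand frozen over the substep; the net bound
amount is removed from (or returned to) the voxel's free pool, capped by
availability, so ligand mass is conserved to rounding.  OPG and RANKL
additionally complex to inert RANKL–OPG by second-order mass action.

**Unpinned rate constants.**  The absolute diffusivities, decay constants,
binding parameters and production rates are not experimentally anchored;
they are calibration knobs chosen once to reproduce the qualitative course
of healing (hypoxia after POD 1, inflammation subsiding within a week,
RANKL-driven remodelling after bridging) and exposed in the config:

| parameter | default | rationale |
|---|---|---|
| D_soft (cytokines) | 100 µm²/s | diffusion length √(D/λ) = 1 mm ≫ gap width |
| λ (cytokines) | 1e-4 /s | hours-scale turnover |
| binding sites N | 100 /cell | lets ~1e-8 mol/m³ ligand reach the 50 % RANK activation gate within voxel-supply limits |
| k_off | 1e-4 /s | K_D = 1e-8 mol/m³ (1e-9 for TGFBR1) |
| O₂ consumption | 3.9e-20 mol/s/cell | ≈ 0.06 mol/m³ per voxel per 30-min step: dense tissue outruns diffusive supply ~170 µm from a source |
| production rates | 0.5–5e-24 mol/s/cell | near-field concentrations of order K_D for physiological cell counts |

A cell is *oxygen-sufficient* when its voxel holds more oxygen than one
iteration consumes; VEGF secretion scales with the complementary oxygen
deficit, 0 when fully saturated.

## Cell agents

Soft-tissue voxels (≤ 395 mg HA/cm³) host SSPC, HSC, immune (M2), OBL, OCL,
lining and vascular cells; mineralised voxels host only pre-osteocytes and
osteocytes.  One cell per voxel, always.

* **Migration** — one face-adjacent step per 20-min update within soft
  tissue (probability 1 ⇒ mean path speed 31.5 µm/h).  Occupied
  destinations swap, except OBL↔OCL which never swap.  OCL bias half their
  steps toward the highest-RANKL neighbour and OBL toward the highest-EFF
  neighbour (the bias probabilities and the softmax sharpness β = 5 of the
  deposition/resorption polarisation are reconstructions, exposed in
  config).
* **Differentiation** — SSPC→OBL needs oxygen sufficiency, an osteogenic
  signal and TGFBR1 engagement (occupancy > 0.25); mineral-lining SSPC/OBL
  in quiescent niches (EFF ≤ 0.008) become lining cells; lining cells
  re-differentiate to OBL when strained unless sclerostin occupies LRP5/6
  (> 0.5); HSC→OCL needs oxygen plus > 50 % RANK occupancy while
  immune→OCL needs only the RANK gate (hypoxia-tolerant); OBL whose voxel
  mineralises embed as pre-osteocytes at rate 0.2/step *only while the
  local osteocyte density of the surrounding mineralised tissue (radius-2
  box) is below the 44,800 cells/mm³ target* — the density gate makes the
  embedded density converge to the calibration target regardless of the
  embedding rate, which then only sets the approach speed; non-embedding
  OBL step aside or are engulfed.  Pre-osteocytes mature to osteocytes
  after 72 h.
* **Population dynamics** — SSPC and HSC divide (0.02/h) into a free
  neighbour when oxygenated and mechanically stimulated; SSPC, HSC, immune,
  OBL and OCL die spontaneously (0.002–0.006/h); osteocytes do neither.
* **Cytokine production** — osteocytes secrete RANKL and Scl maximally at
  zero SED, falling linearly to zero at the 0.015 MPa reference, and OPG
  rising with SED; OBL/lining couple RANKL (falling) and OPG (rising) to
  EFF; immune cells secrete TGF-β constantly; the VEGF producers (SSPC,
  immune, OBL, OCL, pre-OCY, lining) scale v_max by the oxygen deficit.
* **Osteoid** — OBL above EFF_FOR deposit 4 mg HA/cm³-equivalent per
  20-min event into their own voxel plus one strain-polarised neighbour
  (softmax over neighbour EFF), never into vessel voxels, capped so
  mineral + osteoid ≤ 720.
* **Resorption** — only face-adjacent OCL clusters of ≥ 3 with mean RANK
  occupancy > 0.5 resorb, at 0.2 events per cluster per step, removing one
  adjacent mineralised voxel inside the osteolytic window chosen by
  minimal-‖∇SED‖ polarisation; mineral and osteoid go to zero and the
  voxel's banked latent TGF-β is released to the field.

## Mineralisation

Osteoid converts to mineral at 30 mg HA/cm³/day per voxel, capped at 720;
fresh mineral crossing 395 flips the voxel's diffusivity and occupancy class
on the next substep but contains no osteocyte until an OBL embeds — the
deliberate time-delay that postpones mechanosensing in new bone.  1e-26 mol
of latent TGF-β is banked per mg HA/cm³ mineralised (a full voxel stores
~7e-24 mol, a K_D-scale local pulse on resorption).

## Vasculature

Tip cells move at most one voxel per 20-min update (probability 0.5) by a
three-way choice — steepest VEGF ascent (0.5), previous direction (0.3),
random (0.2) — through soft tissue only, with no mechanosensitivity.  The
vacated voxel becomes a permanent stalk; stalks above a VEGF threshold spawn
new tips (rate 1e-3 per stalk per step); a tip touching a foreign vessel
voxel anastomoses (becomes stalk, the segment graph gains an edge, closed
rings increment the loop count).  Growth stops below the sprout-maintenance
VEGF level (2e-9 mol/m³).  Vessel voxels are void of osteoid, block cell
migration, and are held at the normoxic oxygen set-point (0.065 mol/m³)
during RDD substeps — a fixed-concentration source approximation whose small
mass defect is confined to vessel voxels.

## Initial condition

The synthetic phantom is a hollow-cylinder diaphysis: two cortical
fragments at 720 mg HA/cm³ separated by a transverse gap, marrow and gap at
density 0, wrapped in a 52.5-µm (5-voxel) periosteal shell.  Four volumes of
interest are built from the POD-0 geometry: defect centre/periphery (DC/DP)
spanning the gap inside/outside the cortical envelope, fragment
centre/periphery (FC/FP) likewise at fragment levels.  The haematoma is the
DC mask dilated by 210 µm.  Seeding: SSPC on 50 % of free periosteal voxels
and 10 % of the haematoma, immune cells on 10 % of the haematoma, HSC on 5 %
of the marrow, lining cells on 20 % of the bone surface, osteocytes at
44,800/mm³ inside mineralised tissue, and a configured number of endothelial
tip cells on the periosteal+endosteal surfaces of both fragments (200 at
full scale).  VEGF and O₂ start 5× higher inside the haematoma
(normoxic background 0.065 mol/m³); the RDD runs 48 substeps (one day)
before cells are placed with all receptors unbound.  OBL and OCL are absent
at POD 0.  The seeding fractions are configurable defaults, not measured
values.

## Desk-scale study conditions

The full murine problem (~12 M elements) is beyond a single-CPU desk run, so
the packaged study conditions use a geometrically similar thin phantom:
outer cortical radius 63 µm, inner 31.5 µm, fragments 147 µm, on a
26×26×40-voxel domain (~90 k FE unknowns), with the peak force and fixator
stiffness scaled by the cortical-area ratio (×Ct.Ar/0.92 mm²) so
tissue-level stresses and strains match the full femur, and tip-cell seeding
scaled to 20.  The default gap is 84 µm — the same gap-to-diameter ratio
(≈ 0.5) as the 0.85 mm osteotomy in the full-size femur — and the non-union
comparison doubles it.  On these conditions the model reproduces the
qualitative course of healing: an osteoid burst in week 1, hypoxia-driven
vascular invasion, mineralised bridging of the gap early in week 2 with a
two-orders-of-magnitude stiffness rise, and osteoclastic remodelling of the
unloaded cortices thereafter.  What the desk-scale phantom does *not*
emulate: real cortical geometry and density heterogeneity, image noise,
animal-to-animal variation, and the absolute magnitudes of in vivo bone
volume fractions — passing tests demonstrate the mechanisms and their
couplings, not quantitative agreement with any animal.

## Morphometry

Bone volume uses 14 thresholds (395 to 720 by 25 mg HA/cm³); BV/TV is
normalised to the centre VOI of each pair (DC for DC/DP, FC for FC/FP).
BV645/BV395 measures the mineralised fraction.  Formation / quiescence /
resorption masks difference two thresholded timepoints; BFR and BRR are
per-day percentages of the baseline bone volume.  Cortical metrics follow
micro-CT guidelines: slice-wise filled-contour areas (Ct.Ar, Ma.Ar with the
largest cavity as the medulla and remaining internal voids as intracortical
pores, Ct.Po), and Ct.Th by distance-transform sphere fitting.  Gap width
traces rays perpendicular to the least-squares longitudinal axis (every 2°,
every axial row between the fragments); the rows whose ray crosses no bone,
times the voxel height, give a per-direction width, and the median over
directions is reported.  Vascular volume counts 26-connected vessel voxels
(singletons excluded).  Model-vs-reference scoring is the RMSE of BV/TV
differences per VOI per threshold across matched timepoints.

## Numerical and degenerate-input notes

* FE: patch-test exact (trilinear elements, affine fields); all-void meshes
  and unconstrained systems raise; k_c + k_f = 0 raises.
* RDD: closed-domain mass conservation to 1e-10; non-negativity enforced by
  flooring after each implicit step (the M-matrix property makes negative
  values rounding-level only).
* Agents: ties in polarisation broken by the seeded RNG (Gumbel-max
  sampling of the softmax); blocked moves mean staying put; a division with
  no free neighbour is skipped.
* Checkpoints (HDF5) store lattice, agents, fields, vessel graph and RNG
  stream states; restore-and-continue is bit-identical to running straight
  through.

## Known limitations

No chondrocytes or cartilage (gap-healing regime only), no adipocytes, no
interstitial flow or poroelasticity, no vessel maturation/perfusion, no
intra-cortical vasculature (compensated through the oxygen diffusivity
rule), linear elasticity for all tissues, and rate constants calibrated
rather than measured.  Vessels displace resident mobile cells when they
invade an occupied voxel (the resident moves or dies), which slightly
overstates vascular pressure in dense haematomas.
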