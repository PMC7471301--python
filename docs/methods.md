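# Methods

## Coordinate conventions

Volumes are regular 3-D grids with per-axis spacing (mm), an origin (the
world position of the *center* of voxel (0,0,0)) and an orthonormal
direction matrix mapping grid axes to anatomical right/anterior/superior
(RAS) axes.  Anterior is the axis along which proptosis is positive.
Voxel-center (not corner) positions make the junction slab and ray
sampling symmetric around the plane.  NIfTI affines are decomposed into
spacing × direction; sheared (non-orthogonal) headers are rejected rather
than silently resampled.  DICOM series are read slice-by-slice, sorted
along the slice normal, and rejected when the inter-slice steps deviate
from their median by more than 1% (a missing slice must not silently
stretch the geometry); LPS coordinates are converted to RAS.

## Segmentation energy

The eyeball segmenter is an interactive graph cut: seeds on one axial
slice, a global binary labeling over the whole volume.  The energy is the
standard unary + contrast-sensitive pairwise form

    E(L) = Σ_v U_v(L_v) + λ Σ_{(v,w)∈N} B_vw [L_v ≠ L_w],
    U_v(1) = −log P_fg(I_v),  U_v(0) = −log P_bg(I_v),
    B_vw = exp(−(I_v − I_w)² / 2σ_edge²) / dist(v, w),

with `dist` the world distance between voxel centers, so anisotropic
voxels weight their neighbors correctly.  Class likelihoods are seed
histograms: 64 bins over [−1000, 1000] HU, one Laplace pseudo-count per
bin (keeping every unary finite), normalized.  A Gaussian class model is
available as a parameter switch.  Defaults: λ = 2, σ_edge = 50 HU,
6-connectivity (26 available).  λ and σ_edge are scaled to the ~100 HU
eyeball/fat contrast of orbital CT: boundary edges (ΔI ≈ 100 HU) cost
e^−2 ≈ 0.14 per face while same-tissue edges cost ≈ 1, so smoothing
removes speckle without eroding the true boundary.

Seeds are hard constraints, implemented as terminal capacities exceeding
everything else incident to the seed node, so no finite cut can place a
seed on the wrong side.  The minimum cut is computed by max-flow
(`scipy.sparse.csgraph.maximum_flow`).  The solver works on int32
capacities, so energies are scaled to integers adaptively: per-voxel
unaries are first shifted by their minimum (which changes no energy
difference), a feasible labeling (per-voxel argmin with seeds forced)
gives a true upper bound on the min-cut value, and the scale is chosen so
that bound stays below 2^28 capacity units, capped at 2^28 per nat.  On
micro-volumes this makes the arithmetic effectively exact (the test suite
verifies the returned cut attains the exhaustive global minimum to 1e-6);
on full volumes the energy resolution is still ~1e-5 of a unary unit.
Ties between equal-energy cuts are broken deterministically by residual
reachability from the source under the fixed voxel ordering, so identical
inputs always yield identical masks.

Segmentation is run per eye; the post-processing step keeps only the
26-connected component(s) containing a foreground seed, discarding
speckle and any structures (e.g. the contralateral globe) that share the
eyeball's intensity range but not its seeds.

## Plane, junction, ray

The interzygomatic plane passes through three rim reference points: the
normal is the normalized cross product of two edge vectors, sign-flipped
to point anteriorly, and the anchor is the points' centroid — so the
plane (as a point set and oriented normal) is invariant to the order of
the three points.  Collinear points (triangle area ≤ 1e-6 mm²) and an
anterior axis lying in the plane are errors.

The junction is the set of mask voxels whose centers lie within half the
smallest voxel spacing of the plane — the thinnest slab that is still
populated on every grid; its centroid (unweighted mean of voxel centers)
is projected onto the plane, so the measurement ray starts exactly on the
plane.  Surface-intersection or volume weighting of the slab voxels was
considered and rejected: at 1 mm voxels the difference is far below the
digitization error, and the unweighted mean is the simplest deterministic
choice.

The ray marches from the centroid along the plane normal in steps of a
quarter of the smallest spacing, sampling mask occupancy by trilinear
interpolation thresholded at 0.5, and takes the *last* inside→outside
crossing before occupancy stays below 0.5 for the remainder of the grid
— i.e. the anterior pole of the globe, robust to a centroid that sits
marginally outside the digitized mask.  The crossing is refined by
bisection to better than 0.01 mm.  The reported length is the
centroid-to-exit distance in mm (2-decimal reporting; no 0.5 mm rounding,
which applies only to Hertel data entry in the study generator).

The 2-D method is deliberately manual, mirroring clinical practice: the
user supplies the two lateral rim points and the corneal apex from one
axial slice, and the measurement is the perpendicular point-to-line
distance, signed positive anteriorly.  The 3-D method measures to the
segmented eyeball surface while the 2-D convention targets the posterior
cornea; the two therefore need not agree on real anatomy, and no
reconciliation is attempted.

### Accuracy

For a digitized sphere the measurement has a closed-form truth (signed
center-to-plane distance + radius).  Each stage contributes at most a few
tenths of a voxel of digitization error; across randomized phantom sweeps
(radii 10–14 mm, plane offsets 2–10 mm, oblique planes, ≤ 15 HU noise)
the absolute error stays below half the smallest voxel spacing.  One
degenerate alignment is excluded by construction in the examples: a
sphere centered exactly on the voxel lattice with an integer radius
places voxel centers exactly on the mathematical surface, where the
trilinear 0.5-crossing sits exactly half a voxel out.  Random (continuous)
phantom geometry never hits this measure-zero configuration.

## Phantoms

Phantoms emulate exactly the features the pipeline consumes: one filled
sphere per eyeball at 20 HU, orbital fat at −80 HU, 5 mm cubic bone
blocks (700 HU) centered on the rim landmarks, optional 100 HU anterior
"lens cap", additive Gaussian HU noise (default σ = 10), 1 mm isotropic
voxels (matching a 1 mm slice-thickness/increment acquisition), single
seeded RNG.  The HU palette follows the ordering of real orbital tissues;
the ≥ 20 HU eyeball/fat separation invariant guarantees seed histograms
can separate the classes.  Not modeled: extraocular muscles, the optic
nerve, beam hardening, partial-volume blur at tissue interfaces, and
strabismus as geometric rotation.  Passing phantom tests therefore
demonstrates geometric and optimization correctness on idealized
anatomy, not segmentation robustness on pathological orbits.

## Synthetic measurement study

The study generator emulates the *structure* of a clinical
method-comparison cohort — subject × eye × method × repeat × rater — not
any particular patient data.  Each eye draws a latent true proptosis
N(17.78, 3.2²) mm; a reading is truth + method bias + rater effect +
fresh noise; repeats share everything but the noise; Hertel readings are
rounded to the nearest 0.5 mm.  Method biases (0, +1.43, +0.78 mm for
Hertel, single-slice CT, 3-D software) reproduce the reported
between-method mean gaps.  Per-method noise sigmas (1.8, 1.1, 0.2 mm)
were solved from the reported Bland–Altman limits of agreement under the
independent-noise assumption; the system clamps the software sigma near
zero, which is consistent with its near-unity repeat reliability.  Rater
effects are N(0, 1.5²) mm offsets per rater × method; a strabismus
subgroup (fraction 21/126) adds 0.8 mm extra noise (in quadrature) to the
Hertel and CT readings, encoding that eye deviation degrades those two
methods specifically.  Limitation: with a single per-method noise term
(no method × subject interaction), the generator cannot reproduce the
published repeat-reliability coefficients and the limits of agreement
simultaneously; the defaults prioritize the agreement structure.

## Agreement statistics

All implemented from their sums-of-squares definitions (n−1 standard
deviations throughout): repeated-measures one-way ANOVA (condition effect
tested against the subject × condition residual, no sphericity
correction — a Greenhouse–Geisser flag is out of scope since the target
protocol reports plain RM-ANOVA), Bonferroni-corrected pairwise paired
t-tests (multiplier k(k−1)/2, capped at 1), Pearson correlation,
Bland–Altman with a fixed 1.96 multiplier, Cronbach's α for repeats, and
ICC for raters.  "Interclass correlation coefficient", as the term is
used clinically, is read as the intraclass correlation coefficient;
the default form is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — which is the appropriate form when raters
are a random sample and their systematic offsets should count against
agreement; ICC(3,1) (consistency) is selectable.  Degenerate inputs have
defined behavior: zero error variance reports an infinite F (p = 0) with
a degeneracy flag, a zero-variance paired difference yields t = 0, p = 1
when the mean difference is also zero, and α/ICC raise on absent
between-subject variance.  Each eye is an observational unit with its
subject id retained (matching eye-level cohort counts); no mixed model
for eye-within-subject correlation is fitted, as the target protocol does
not use one.

## Problem sizes

Default test and validation problem sizes were chosen to exercise every
code path at full fidelity while keeping the suite quick on a laptop:
64×64×48 phantom grids (the smallest grid holding two 12 mm globes, rim
landmarks and realistic plane offsets at 1 mm), 20-phantom validation
sweeps, 50 micro-volumes (≤ 18 free voxels) for exhaustive optimality
checks, and 500–2000 simulated units for Monte-Carlo parameter recovery
(3σ/√n tolerances).
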