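# Methods

## Measurement model

A five-ball phantom is imaged by the EPID over a full gantry rotation:
balls *a*–*d* are rigidly fixed to the gantry head on a square around the
beam axis (nominally ±60 mm at the isocentre plane, mounted ~550 mm from
the source), ball *e* sits at the nominal isocentre on a couch-mounted rod.
Because *a*–*d* rotate with the head while *e* stays in the room frame,
their projected tracks separate the deformations of the three subsystems:

* displacement of *e*'s shadow = EPID (panel) displacement, after removing
  the set-up-offset signature (below);
* mean displacement of *a*–*d* = EPID displacement + gantry-head
  displacement, so the difference isolates the gantry sag;
* magnification of the *a*–*d* pair separations = SDD change (common mode)
  and panel tilt (differential mode, gun-vs-target pairs for pitch,
  left-vs-right pairs for roll);
* rotation of a pair's separation vector = panel/collimator yaw (skew);
* distance from the *a*–*d* centroid to each 50% field edge = bulk drift
  of the corresponding MLC carriage (left/right banks) or leaf-face
  position (gun/target), which per-leaf encoders cannot detect.

Every series is referenced to the frame nearest gantry zero (required
within 2°, ties broken by acquisition order) and reads exactly zero there:
machine calibrations are defined at gantry zero, and the re-anchoring also
reconciles the sag equations with that convention (as printed, the
equation value at θ = 0 would be −A).  ΔSDD is reported at the detector
(physical) scale; all other lengths at the isocentre plane (detector mm
divided by SDD/SAD, SAD = 1000 mm).

### Set-up offset correction and identifiability

A lateral / vertical offset of ball *e* (or of the lasers used to place
it) appears as A·cos θ / B·sin θ in its projected track.  *A* and *B* are
ordinary least squares against the bases {cos θ − 1} and {sin θ}, which
vanish at the reference so the fit never moves it.  A genuine
first-harmonic component of panel sag is mathematically indistinguishable
from this signature; the fit absorbs it.  Consequently the exact
equation-inversion property holds on the identifiable model subspace
(cross-plane sag with no cosine terms, in-plane sag with no sin θ term),
and the simulator's default curves are built from second harmonics, which
are orthogonal to the fit bases over a uniformly sampled rotation.  The
fit residual is reported, never dropped: with real sag present it is
dominated by the sag itself.

### Pairings

The SDD estimate uses left pair (a, c) vs right pair (b, d); skew uses
(a, b) (checked against (c, d)); pitch uses the gun (a, b) vs target
(c, d) x-separations over the in-plane midpoint distance; roll uses the
left (a, c) vs right (b, d) y-separations over the cross-plane midpoint
distance.  The pairings are a configuration field of `PhantomGeometry`
because the roll formula is the one place where a literal reading of the
source equations pairs markers with zero nominal separation in the
denominator; the default pairing is the geometrically meaningful one.

## Detection

1. **Conservative smoothing**: each pixel is clamped into the [min, max]
   of its 8-neighbourhood — removes isolated noise spikes without blurring
   edges, and is idempotent.  Note that *pairs* of adjacent spikes survive
   it by construction.
2. **2×2 rank-4 filter**: the window maximum (rank 1 = minimum is
   selectable), used in the ball candidate search, where it prevents dark
   single-pixel dropouts from seeding or splitting blobs.  The output grid
   sits at the window centres, so the image origin metadata is shifted by
   half a pixel; symmetric dark blobs then keep their measured positions.
3. **Ball bearings**: matched filtering with a disc kernel of the smallest
   projected ball diameter; candidates are connected regions of match
   score above 15% of the field contrast, eroded away from the penumbra;
   roles a–e are assigned by optimal matching to the translated nominal
   layout and validated (pairwise separations within 25% of nominal, *e*
   inside the quadrilateral).  Sub-pixel centres: an iteratively
   re-centred intensity-weighted centroid (window 1.5 projected radii,
   annulus-estimated background, weights soft-thresholded 2σ above the
   noise floor) followed by a least-squares fit of a soft-edged disc whose
   model integrates the disc coverage over each pixel footprint (2-point
   Gauss quadrature per axis — detector pixels are area integrators) with
   a soft-L1 loss scaled to the local noise.  The robust fit concentrates
   statistical weight at the shadow rim, reaching ~0.5 µm localisation
   noise per head marker at the isocentre scale under the default
   simulation noise, and bounds the influence of surviving spike pairs
   (one such event on the *reference* frame would otherwise offset the
   tilt and SDD series for the whole arc).
4. **Field edges**: 50% of (plateau − baseline) crossings by linear
   interpolation — for a symmetric (e.g. linear) penumbra this is the
   geometric edge regardless of penumbra width.  Left/right bank edges are
   the means of per-leaf-row crossings (5 mm rows between the gun/target
   penumbras); gun/target edges come from the profile averaged over the
   central third of the aperture width.  Ball footprints (2× projected
   radius) are masked out of all profiles.  Edges are measured on the
   conservative-smoothed image: the rank-max filter would dilate the
   bright aperture asymmetrically by half a pixel per side.

The tilt metrics set the precision requirement: they amplify marker-pair
separation noise by SDD⁰/(W·H) ≈ 0.1 rad/mm (W = H = 120 mm pair
separations), so micron-level ball localisation is needed for the ~0.01°
tilt precision that published reproducibility figures imply.

## Synthetic phantom (ground truth)

`MachineModel` drives every deformation as a low-order Fourier series in
the gantry angle (orders ≤ 3, re-zeroed at gantry zero, optional
antisymmetric step across zero emulating gantry backlash).  The projection
is constructed to solve the analysis equations in reverse — marker means
carry sag, pair separations carry ΔSDD and tilt, the pair orientation
carries skew, edges carry carriage offsets plus the common-mode marker
motion — so `metrics(project(model)) == model` to machine precision
(< 1e−12 mm) without imaging.  Defaults mirror the deformation magnitudes
typical of in-service machines: in-plane EPID sag range 1.0 mm (cross
0.2), gantry sag 0.7/0.4 mm, ΔSDD amplitude 1.7 mm, skew 0.15°, tilt
0.1°/0.04°, carriage drifts up to ~1 mm peaking at the lateral gantry
angles where gravity acts along leaf travel (left-bank maximum at −90°),
e-ball offset (0.8, −0.5) mm.

Rendering: open-field plateau 1000, blocked baseline 100, linear penumbra
3 mm (detector scale), ball shadows as 40% attenuation discs rasterised
with 2×2 supersampling and a one-pixel soft edge; Gaussian noise
σ = 3 intensity units (~0.3% of contrast, representative of
flood-field-corrected portal images) and 0.1% salt spikes; aS1000-like
1024 × 768 panel at 0.392 mm pitch by default (aS500-like 512 × 384 at
0.784 mm available and used in most tests for speed).  DICOM RT Image
files carry gantry/collimator angle, SID, pixel spacing and image
position; the reader wraps angles to the IEC interval (−180°, 180°].

### What the simulator does not emulate

Scatter, energy response and detector glare; leaf-by-leaf position errors
and rounded leaf-end penumbra shape; collimator-angle-dependent aperture
rotation (collimator setting is carried as metadata only); cine frame
averaging (each rendered image is final); couch structures.  Passing tests
therefore demonstrate the geometric correctness and noise behaviour of the
algorithm chain, not its robustness to every clinical image artefact.
Aperture edges translate with the carriage offsets but are not
additionally magnified by the SDD variation, matching the equations'
assumption that marker-to-edge distances isolate carriage motion.

## Statistics and tolerances

Range = max − min per series with the extremum angles; reproducibility =
per-angle sample SD across replicates (matched by nearest angle within
2°), summarised by its maximum; condition comparisons = RMSD after linear
interpolation of both series onto the union of their angle grids within
the overlapping range (≥ 270° required).  Verdicts: EPID sag, gantry sag
and ΔSDD against maximum absolute excursion (2 / 1 / 5 mm, non-stereotactic
profile); carriage sag against the per-direction range (1 mm), since a
bulk carriage drift is a systematic leaf-position error (0.3 mm is noted
as the stricter systematic limit); skew and tilt are reported without a
numeric verdict.  The SDD impact helper converts ΔSDD to percent
magnification (ΔSDD/SDD⁰) and first-order inverse-square dose change
(twice that).

## Problem sizes and numerical choices

Cine arcs use 91 images (4° spacing, duplicate 0°/360° endpoint frames
retained, first in acquisition order as reference); integrated arcs 37
images (10°).  The test suite renders mostly aS500-format frames; the
full-pipeline recovery checks use the aS1000 format.  Tolerances asserted
by the tests: < 1e−9 mm equation round trip; < 0.05 mm / 0.02° RMS
full-pipeline recovery and ≤ 0.02 mm misalignment amplitudes; detection
RMS well under 0.1 mm.  Under the default noise the null-machine tilt
series has a max-abs excursion of ~0.008–0.014°: at the Cramér–Rao bound
of the localiser this is the physical noise floor of the tilt metric, and
it slightly exceeds an idealised 0.01° everywhere-bound on some noise
realisations — visible in the acceptance suite, and consistent with tilt
being the least reproducible angle-valued metric in practice.

Degenerate inputs raise typed errors rather than producing numbers:
pair separations below 10 mm (SDD/skew/tilt denominators), missing
gantry-zero frame, < 270° angular coverage for the misalignment fit or
RMSD comparison, clipped apertures, fewer than five candidate blobs,
ambiguous role assignment.
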