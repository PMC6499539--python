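# Methods

## Cell registration

### Model

One larva's in situ dataset is a cloud of segmented nucleus centroids
(micrometres) with per-cell marker label sets over {VGAT, VGLUT, VACHT} and
up to four named landmark cells (left/right antenna cells and ddNs).  The
reference is either the packaged connectome circuit fixture or another
dataset.  Registration assumes the clouds are related by an affine map plus
isotropic per-cell noise — appropriate for inter-larva variation in pose,
scale and mild anisotropic growth, but not for nonlinear tissue distortion
(deformable registration is deliberately out of scope).

The fit is affine coherent point drift: the source cloud is a Gaussian
mixture with equal weights, one isotropic component of variance σ² per
point, and an optional uniform outlier component of weight `w` (default 0);
the reference cloud is treated as observations.  EM alternates posterior
computation (log-domain, for stability at small σ²) with the closed-form
M-step for B, t and σ².  The negative log-likelihood is non-increasing; the
iteration stops when its absolute change drops below `tolerance`
(default 1e-3) or at `max_iterations` (default 1000).  σ² is floored at
1e-12 so the trace stays positive on exact-fit data.

Numerical choices:

* Both clouds are centered and jointly scaled by the reference RMS radius
  before EM, and the transform is composed back to micrometres afterwards.
  This makes the σ² initialization (mean pairwise squared distance) and the
  convergence threshold meaningful regardless of unit choices.
* The reported σ² trace is rescaled to squared micrometres so it is directly
  comparable to residual distances.
* Degenerate sources (fewer than 4 points, or coplanar within rank
  tolerance 1e-9) are rejected rather than silently producing a singular
  M-step.

### Anchor initialization

CPD has a limited basin of attraction, so the source is first rotated using
landmarks.  With one shared anchor the initialization is the minimal
rotation taking the source anchor→cluster-centroid vector onto the
reference's; the roll about that axis is unconstrained by a single landmark
and left at zero.  With two or more shared anchors the rotation is the
orthogonal Procrustes (Kabsch) solution over the anchor points plus the
cluster centroid, which also fixes the roll.  Anchors coincident with the
cluster centroid are a degenerate geometry and rejected.

### Correspondence and label transfer

Each transformed source cell is matched to its Euclidean-nearest reference
cell, independently, so many-to-one matches are allowed (a strict one-to-one
Hungarian assignment is available as an option, off by default).  Exact
distance ties break to the lexicographically smallest reference cell id.
Matched reference cells accumulate the union of their donors' label sets
with a multiplicity record; unmatched reference cells carry no call.

### Consensus

The heat map stores, per reference cell and marker, the exact fraction of
datasets whose transferred set contains the marker, plus a no-call column
(fraction of datasets in which nothing mapped to the cell); every entry is
k/n by construction.  Consensus calls use a majority threshold of 0.6,
chosen in (0.5, 1] so that a clear majority is called, two markers can both
be called on genuinely co-expressing cells, and an even 0.5/0.5 split stays
unresolved.  The confusion matrix counts, over every *ordered* pair of
datasets (A→B and B→A are distinct because registration is asymmetric), how
often A's and B's corresponded cells received the same reference assignment.
The A–B correspondence defaults to a fresh registration of A onto B
(`pairing="direct"`); matching the two clouds after transforming both into
the reference frame (`pairing="via-reference"`) is also provided.  Counts
are stored as exact integers; row normalization is a rendering concern.
Pooling by neuron class sums counts over class membership and conserves
total mass.

## Behavior

### Tracking

The tracker follows the classic assay recipe: the background is the
pixelwise mean of all frames; detections are connected components of the
background-subtracted frame above threshold (Otsu of the difference image by
default, explicitly settable — synthetic scenes use a fixed threshold of 12
intensity units, about 6× the rendered noise SD, so faded detections of
long-resting larvae are kept), with intensity-weighted centroids, minimum
area 5 px, restricted to the ROI.  Linking is greedy per initial-frame
object, nearest detection frame by frame; frames with no detections at all
keep the previous position rather than teleporting to a distant object.

Whole-track rejection rules: implied speed above 6.5 mm/s
(`rejected_speed`), leaving the ROI (`rejected_roi`), or staying within a
2 px radius of a rolling anchor point for a full 60 s window
(`rejected_stationary`).  The 2 px stationarity radius exists because
sub-pixel centroid jitter must not count as movement.  Rejected tracks are
excluded from all downstream metrics in full.  Tracks of larvae that come
within a contact radius of each other are flagged and excluded from the
dimming denominator.

A separate Fiji-style preparation step (subtract the minimum Z-projection,
invert black and white) is provided for externally recorded stacks whose
larvae are dark on a bright field.

### Bouts and endpoints

Speed is the backward difference of position times the frame rate.  Bout
candidates are maximal runs where the 3-frame moving-average speed is at or
above `speed_on` (default 0.5 mm/s); runs closer than 0.2 s are merged and
runs shorter than 0.3 s dropped; run edges are then refined on the *raw*
speed trace so smoothing bridges single-frame dips without inflating
durations.  A bout whose speed samples span k frames has duration k/fps.

* Tortuosity is arc length over start-to-end chord (≥ 1; undefined and
  reported missing when the path closes on itself).
* Sustained swims are bouts strictly longer than 10 s.
* A dimming responder must have mean speed below `speed_on` over the 1 s
  before the dim and an evoked bout (first onset within 5 s after the dim)
  strictly longer than 3 s; larvae moving at the dim, or contact-flagged,
  are excluded from the denominator.
* The distal third for phototaxis is the region whose projection onto the
  light axis exceeds r/3 from the dish center (chords perpendicular to the
  light direction cutting the diameter into equal thirds); boundary
  positions count as distal.
* Per-larva summaries report bout count per minute, duration mean/SD and
  inter-bout-interval SD (end-of-bout to next onset); SDs are only reported
  for larvae with at least 4 bouts.
* Group comparisons are thin wrappers over the Wilcoxon rank-sum test,
  Student's t, and a two-sided variance-ratio F test (written directly from
  the F distribution since SciPy exposes no two-sample variance test).

## Synthetic data

### Centroid clouds

The reference geometry comes from the packaged circuit fixture: the
connectome's class inventory (23 PR-I, 7 PR-II, 6 PR-III photoreceptors; a
30-cell relay cluster of 6 prRN, 8 pr-AMG RN, 10 AntRN, 2 PBRN, 2 PCRN,
2 PNRN; 6 MGIN, 10 MN, 2 ddN, 7 AMG, 3 ACIN, 2 antenna cells, 2 eminens
cells) laid out with the described anatomy — photoreceptor somata in rows
with ≥ 3 µm spacing and slight curvature (so clouds are never coplanar),
PR-II anterior of PR-I, relay classes ordered along the A–P axis with the
AntRNs rearmost, anchors at the antenna-cell and ddN positions.  The
coordinates are synthetic stand-ins: the connectome's own coordinate table
is not published, so registration tests are self-consistent against this
fixture rather than against the real ssEM geometry.  This is the main gap
between passing tests and real data: the tests certify the algorithm under
the stated noise model, not the actual stereotypy of *Ciona* larvae.

The label model encodes the consensus assignments: PR-II all VGAT-positive
with the two anterior-most cells VGAT-only and the other five co-expressing
VGLUT; PR-I all VGLUT-only except the two most ventral cells (one VGAT-only,
one VGAT+VGLUT — the PR-9/PR-10 analogs); relay cluster 16 VGAT + 11 VACHT +
3 unlabeled (one pr-AMG RN left blank as the unresolved-cell analog, plus
the two PNRNs).

Pseudo-larvae apply a sampled affine pose — rotation up to 60° about a
random axis, independent off-diagonal shear entries up to ±0.2, translation
up to ±20 µm — plus isotropic Gaussian centroid jitter (0.5 µm default,
roughly nucleus-segmentation precision against ≥ 3 µm cell spacing) and
optional per-cell dropout emulating the ±1-cell count variation between
larvae.  Anchors transform identically and are jittered but never dropped.
The true transform is returned for oracle checks.

### Swim scenes

Larvae alternate stationary periods and bouts.  Onsets follow an
exponential-interval process at 8 bouts/min (the spontaneous regime) with
bout durations normal (mean 1.5 s, SD 0.5 s, floored at 0.5 s) and at least
1 s between bouts — gaps and flicks below the bout-segmentation resolution
are not part of the emulated regime.  The clock-like mode fixes both the
interval and the duration, reproducing the oscillator phenotype whose
per-larva interval SD collapses to ~0.  During a bout the larva takes
run-and-turn steps: speed ~N(3.0, 0.3) mm/s, heading diffusing with
per-step Gaussian noise (0.25 rad default) that sets tortuosity, walls
reflecting the heading.  An optional dim event triggers an evoked bout
(default 5 s) in larvae that are stationary at the dim, with a configurable
response probability; an optional heading bias emulates taxis.

Scenes are rendered as isotropic Gaussian blobs (σ 1.5 px, amplitude 120)
on a flat background (level 20) with Gaussian pixel noise (SD 2), 8-bit.
Larvae are ~1 mm and unresolved at assay magnification, so blobs trade
realism for analyzable ground truth; tails, occlusions and illumination
gradients are not modelled.  The default calibration is 0.1 mm/px on a
200×200 px field at 8.9 fps (spontaneous assays) or 5 fps (dimming assays).
An optional per-larva confinement cell (a private reflecting box) realizes
the non-colliding condition used by the tracker-recovery studies; free
scenes can and do produce near-contacts.

The ground-truth bout log is quantized to the frame grid: a bout whose
displacements occupy frames a..b is logged with duration (b−a+1)/fps, which
is exactly what an ideal tracker measures, so end-to-end recovery is
compared against what the renderer actually drew rather than against the
continuous-time program (which differs by sub-frame rounding).

## Problem sizes

The test suite and the acceptance script run the registration studies at
20 seeds on 30-cell clouds, the tracker studies on 60 s scenes of 5–10
larvae at 200×200 px, and the end-to-end behavioral recovery over 8–20
rendered minutes of video; these sizes give stable Monte-Carlo estimates
(binomial/normal standard errors well inside the asserted tolerances) while
keeping a full run in the minutes range.

## Known limitations

* The affine model cannot absorb nonlinear deformation; heavily distorted
  larvae would need deformable registration.
* Greedy per-object linking does not preserve identities through real
  occlusions or contacts; contacts are flagged, not resolved.
* The stationarity, threshold and bout-segmentation defaults are documented
  choices, not fitted constants; assays with very different optics or larva
  sizes will need the exposed parameters adjusted.
* The packaged reference coordinates are synthetic; applying the pipeline to
  real connectome coordinates only requires replacing the fixture file.
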