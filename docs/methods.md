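# Methods

## Problem and model

After focal tumor ablation — in particular irreversible electroporation
(IRE), where several parallel needle applicators create treatment zones
that merge into one irregular, often indented body — acute treatment
control asks two geometric questions: how large a spherical tumor could
this zone have treated with a uniform safety margin, and where does that
usable spherical core sit? Both are properties of the **largest inscribed
sphere** of the segmented zone. Its center is the Chebyshev center of the
body; its diameter minus twice the safety margin (default 5 mm, the margin
associated with better local control after thermal ablation of liver
metastases) is the diameter of the largest treatable tumor sphere, which
shares the same center. The distance between the zone's barycenter and the
Chebyshev center (**barycenter offset**) quantifies how eccentric the
usable core is.

The package implements two analysis routes over a binary segmentation:

* **Segmentation-based analysis ("technique A")** — barycenter as the
  unweighted centroid of foreground voxel centers; principal axes as the
  eigenvectors of the voxel-coordinate covariance; long / intermediate /
  short diameters as chords through the barycenter along those axes,
  relabelled by realized length; circularity `short/long` and sphericity
  `long / ((intermediate + short)/2)`; inscribed sphere and barycenter
  offset from the Euclidean distance transform; treatable tumor sphere at
  a configurable margin.
* **Plane-based standard analysis ("technique B")** — an automation of the
  manual caliper workflow: maximal 2D Feret diameter over axial slices,
  the projection width of the same slice perpendicular to it, and the
  global craniocaudal extent; the three values are ordered by size, the
  inscribed-sphere diameter is *defined* as the short diameter, and the
  tumor sphere again subtracts twice the margin. No center or offset is
  produced, by construction.

The **difference ratio** (inscribed diameter of A minus that of B, in mm)
quantifies the disagreement; negative values mean the plane-based reading
overestimates the usable zone, which is exactly what happens on indented
shapes, where calipers span outer extents but no large sphere fits.

## Numerical choices

* **Voxel model.** A voxel is foreground as a whole; voxel `(i,j,k)` has
  world position `origin + index · spacing` (voxel-center convention,
  axis-aligned world frame). The canonical test spacing is
  1 × 1 × 0.5 mm, matching 1 mm axial CT reconstructions with 0.5 mm
  overlap. Rotational header components are ignored; the craniocaudal
  role is assigned to the lattice axis closest to the world
  superior-inferior direction (axis 2 when the header is silent).
* **Distance map.** `scipy.ndimage.distance_transform_edt` with the
  anisotropic spacing as sampling, after padding the volume by one
  background voxel per face so zones touching the grid border are treated
  as bounded rather than extending into virtual tissue.
* **Inscribed sphere.** Candidate centers are restricted to voxel
  centers; the radius is the maximal distance-map value minus half the
  smallest voxel size, approximating distance to the boundary *surface*
  rather than to the nearest background voxel *center* (without the
  correction a digitized radius-r sphere would systematically report
  2r + one voxel). Ties within 1e-9 mm — e.g. the medial ridge of an
  elongated zone — are broken by proximity to the barycenter, then by
  smallest linear voxel index, so results are deterministic and favor the
  centered interpretation. The center is therefore only sub-voxel
  accurate: half a voxel is the stated precision limit, which matches the
  resolution of the input segmentation.
* **Chords.** Lines are sampled at a quarter of the smallest voxel size
  over ± half the grid diagonal; the chord is the distance between the
  projections of the two extreme foreground voxel centers hit. Chords use
  the *outer* extent — interior gaps do not shorten them — because axis
  diameters describe the zone's span while indentations are meant to be
  penalized by the inscribed sphere, not by the calipers.
* **Principal axes.** Eigenvector signs are fixed (largest-magnitude
  component positive); eigenvalue groups with relative gaps below 1e-6
  are ordered lexicographically by coordinates so isotropic shapes give
  reproducible axes. Collinear or planar masks raise an error naming the
  vanishing component. The three chord lengths are re-sorted after
  measurement because eigenvalue order reflects variance, not chord
  length.
* **Coverage.** A tumor (sphere or co-registered mask) is covered at
  margin m iff every tumor voxel center is zone foreground with
  distance-map value ≥ m; the minimum achieved margin and the first
  failing location are reported. Grids must share a lattice — resampling
  is out of scope.
* **Technique B details.** The perpendicular diameter is the projection
  width of the slice foreground perpendicular to the long-diameter
  direction (no anchor point is imposed — a width is the deterministic
  automation of a hand-held caliper), measured on the same slice as the
  long diameter; a flag allows maximizing over all slices instead. Note
  that the exhaustive Feret maximum of a rectangle is its diagonal, so
  for box-like slices the perpendicular width is measured relative to the
  diagonal, not the long side.
* **Shape-ratio variants.** On size-ordered diameters sphericity is ≥ 1
  by construction. Plane-based readings are sometimes evaluated with the
  plane roles kept as measured (axial-long, axial-perpendicular,
  craniocaudal), which can yield sphericity < 1; the technique-B report
  exposes this unordered variant alongside the ordered one rather than
  hard-coding either interpretation as ground truth.
* **Tumor-sphere arithmetic.** The treatable tumor sphere subtracts twice
  the margin from the *inscribed-sphere* diameter (for technique B the
  inscribed diameter equals the short diameter, so both subtractions
  coincide there). Verbal descriptions of the workflow sometimes refer
  the subtraction to the short diameter even for the segmentation route;
  the reported group values are only consistent with the inscribed-sphere
  reading, which is what this package computes. A result of 0 mm signals
  "no tumor treatable at this margin".
* **Group statistics.** Mean ± sample SD (n−1) and range; a single report
  yields SD 0 with n = 1 flagged. Nonparametric significance testing is
  deliberately not reimplemented — reports serialize to tidy JSON/CSV for
  any statistics package. Published group difference ratios are means of
  per-lesion differences; differences of rounded group means can disagree
  with them in the last decimal (−14.8 vs −14.9 for the large-zone
  protocol), which is a rounding artifact, not a computational one.

## Synthetic phantoms

The generators stand in for CT segmentations of in-vivo zones and carry
analytic truth:

* **sphere / ellipsoid** — convex references (closed-form diameters,
  inscribed sphere, shape ratios); an ellipsoid approximates a
  single-needle thermal-ablation zone.
* **notched sphere** — radius R minus a cylinder of radius r: with the
  notch drilled through the center the inscribed diameter is R − r at
  offset (R + r)/2 perpendicular to the notch (the barycenter lands in
  the void, the defined error case for barycenter chords); drilled only
  to the center the inscribed diameter is R at offset R/2 and the full
  technique-A analysis applies.
* **dumbbell** — two lobes and a thin bridge, probing outer-extent chord
  semantics across a waist.
* **multi-applicator** — parallel needles along the craniocaudal axis;
  for each applicator pair (optionally limited to pairs within a
  connection distance) the zone contains all points within the pair's
  lobe radius of the vertical rectangle spanning the two active segments
  (a capsule slab), mirroring how IRE zones expand between applicator
  pairs and merge. No electric-field physics is attempted. A seeded
  per-pair radius jitter (default 0.25, i.e. radii in 0.75–1.0 × the
  9 mm default lobe radius) roughens the merged surface the way real
  zones are indented; jitter 0 gives a smooth body on which the two
  techniques agree.

Protocol presets mirror the three in-vivo electroporation protocols:
three applicators on a 15 mm (protocol 1) or 20 mm (protocol 2) triangle
with 20/25 mm tip exposure, and six applicators as three parallel pairs
(15 mm within a pair, pair centers 22.5 mm apart, 30 mm exposure,
capsules only between applicators up to 23 mm apart) for protocol 3. The
exact six-needle layout is not standardized; this one was chosen so the
generated zone's long diameter (~60–64 mm smooth, ~58–61 mm jittered)
sits at the scale of the reported large-protocol zones (long diameter
74.5 ± 6.1 mm in vivo) while keeping the merged body singly connected
with genuine waists. The 9 mm lobe radius is a realistic half-width for
an electroporation lobe between needles 15–20 mm apart at ~1500 V/cm.

What the phantoms do **not** emulate: CT noise, contrast-enhancement
gradients, partial-volume effects at the zone rim, manual-segmentation
variability, and anatomically constrained zone shapes. Passing the
phantom suites therefore demonstrates correctness of the *geometry* on
voxelized bodies of realistic scale and shape class, not robustness to
segmentation error on clinical images.

## Problem sizes and verification

Unit and property tests run phantoms up to ~120³ voxels; oracle
equivalence (exhaustive nearest-background search via KD-tree, flood-fill
connectivity, per-voxel containment) is asserted on 20 random phantoms of
at most 64³ voxels, where the brute force is exact and fast. The
acceptance script regenerates everything from scratch — worked-example
arithmetic on published group means, ellipsoid parameter recovery at
1 × 1 × 0.5 mm, and a five-seed six-applicator suite — in a few seconds.

## Known limitations

* No sub-voxel optimization of the Chebyshev center; error bounded by
  half a voxel.
* World frames are axis-aligned: oblique acquisitions are treated as if
  their lattice axes were anatomical axes; resampling/registration is out
  of scope.
* One zone per analysis: multi-component masks are reduced to the largest
  component (with a warning) before measurement.
* Spherical tumors and uniform margins only; anisotropic margin models
  and sphere packing are non-goals.
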