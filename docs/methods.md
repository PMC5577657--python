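# Methods

## The measurement model

A CT scan of a seed in a seedbed is a 3-D scalar grid with isotropic
voxels (20 µm in the scans this workflow targets; the voxel size is a
parameter everywhere). Three materials are distinguishable by X-ray
attenuation: air (darkest), organic seed material (intermediate) and
mineral soil (brightest). Water films and micro-pores below the scan
resolution are *not* segmentable and are explicitly outside the model —
"contact" here means voxel-scale adjacency between the seed surface and
soil material, a proxy for (not a measurement of) hydraulic contact.

### Phase segmentation

Two greyscale cut points `t1 < t2` split the histogram into three bands;
band→phase assignment defaults to dark-to-bright air/seed/soil and is
configurable, because pelleting material can overlap soil minerals in
attenuation. When no thresholds are supplied a 3-class multi-Otsu
estimate is used; a volume without three distinguishable modes raises a
degenerate-histogram error rather than guessing.

Partial-volume voxels at soil–air interfaces take intermediate values
that fall into the *seed* band, depositing a voxel-thin seed-labelled
film over soil surfaces. When this film touches the real seed it would
masquerade as seed surface, so seed selection optionally applies a
morphological opening (`film_opening_radius`, default 1 voxel in the
batch pipeline, off in the raw API) that removes sheets up to ~2 voxels
thick while leaving the seed body — two orders of magnitude thicker —
intact.

### Seed closing

A germinating seed opens internal air spaces, and the contact denominator
must be the surface of the *closed* object. Closing is a morphological
closing with a Euclidean ball (default radius 3 voxels, sealing openings
up to ~6 voxels ≈ 120 µm wide) followed by filling every background
component not connected to the grid boundary. Background connectivity for
the fill is 6-connected, the standard dual of the 26-connected
foreground, which prevents diagonal "tunnelling" through one-voxel gaps.
The operation is extensive (never removes voxels), idempotent, and
reports the volume increase and the signed surface change it caused.

### Contact

Soil is dilated by one step of the configured structuring element
(default 26-connectivity, i.e. a 3×3×3 cube, so diagonal grain–seed
adjacency counts as contact at this resolution; 6 and 18 are selectable).
The seed surface is discretised into the exposed faces of its voxels
(6-neighbourhood); a face is a *contact face* iff its owning seed voxel
lies inside the dilated soil. The contact percentage is the face-count
ratio. This makes the headline ratio exactly independent of the
absolute-area estimator: face counting overestimates smooth surfaces by a
systematic ≈1.5× (the mean of |nx|+|ny|+|nz| over the sphere), while the
mesh estimator (marching cubes after a 1-voxel-σ Gaussian anti-aliasing
of the binary grid) is accurate to ≲1% for objects resolved at ≥15 voxels
radius. Absolute mm² values are reported with the configured estimator and
`contact_area = contact% × surface_area` so numerator and denominator
share one discretisation.

### Iceberg rings

The two shells are the sets of non-seed voxels within 5 and 15 voxels of
the closed seed, measured by Chebyshev distance by default so that "5
voxels" means exactly five applications of the same +1-voxel dilation
used for contact (Euclidean is selectable). The long-range shell spans
distances 1–15 and therefore *contains* the short shell's region; the
annulus variant (6–15) is available behind the `inner_voxels`/
`long_range_annulus` flags. Within a shell:

* volume effect = `100 · soil/(soil + air)` voxel counts — a scale-free
  soil density; stray seed-phase voxels from other seeds count as neither
  and are tallied separately;
* surface effect = `100 · contact area / soil surface area in the
  shell`, the soil surface being the boundary-face area of the soil phase
  restricted to shell voxels (the same discretisation as contact; the
  alternative — whole aggregates intersecting the shell — is noted as
  future work);
* change in soil mass = `100 · short effect / long effect`.

In a statistically homogeneous medium the volume effects at both ranges
are equal, so the volume change ratio is 100%. The surface change ratio
is *not* 100% there: by its definition it equals the ratio of soil
surface areas between the two shells, which scales with shell size
(≈300% for uniform media at these widths). A shell with no soil surface
yields an explicit undefined flag, not a division error. Shells clipped
by the grid boundary are computed on the clipped domain with the clipped
fraction reported and a warning above 5%.

## The phantom generator

The generator emulates the study conditions the metrics were designed
for: isotropic 20 µm voxels; a seed of ~4 mm — a sphere (a pelleted and
coated seed) or a 5-lobed star prism of 4 × 3 × 3 mm (a naked sugar-beet
seed); granular soil of spherical grains sieved to < 1 mm diameter,
placed by random sequential addition to a target solid fraction
(default 30–35%, typical of a loosely packed sieved seedbed) with a
configurable overlap tolerance to mimic fused aggregates; per-phase grey
means 10/120/220 with noise SD 8 on an 8-bit-like scale, chosen for clean
three-mode histograms; optional Gaussian blur emulating the
partial-volume effect; an optional internal cavity vented by a crack
(the crack exits through the seed's flank, offset 0.4 r from the pole
axis — a coat split does not pass through a geometric pole, and a
channel through the digitized sphere's extreme pole voxel could never be
resealed exactly by any closing). The seed keeps ≥15 voxels (the
long-range ring) of boundary clearance by construction.

Ground truth is recorded before degradation: the label map, the analytic
contact fraction `(1 − cos θ)/2` for plane-bounded (spherical-cap) soil,
and per-distance soil/air tallies out to 15 voxels for checking ring
compositions.

What the phantoms do *not* emulate — and hence what passing tests do not
show about real scans: real aggregate morphology (grains are spheres),
X-ray physics (beam hardening, scatter, ring artefacts), moisture films,
seed swelling over time, and gravity-settled packings (placement is
random sequential addition, chosen for determinism; the metrics consume
the achieved density, not the placement physics). Validation on phantoms
demonstrates that the *measurement* is correct, not that segmentation of
an arbitrary field scan will be easy.

## Numerical and design choices

* Axis order is (z, y, x) with z the scan axis; voxel size must be
  isotropic — all dilation/ring arithmetic assumes it, and anisotropic
  headers are rejected.
* TIFF spacing metadata is treated as untrustworthy: a JSON sidecar
  written next to the file carries the voxel size, and an explicit
  argument beats either with a logged warning on conflict.
* Chebyshev shells are computed with a chessboard distance transform,
  which is provably identical to iterated 26-dilation differences (and is
  tested against an all-pairs brute force).
* Replicate summaries use the n−1 sample SD over √n (SEM); a single
  replicate yields SEM 0 with an explicit flag.
* Batch analysis isolates per-column failures; only an all-fail batch
  raises. Row order is deterministic.
* Validation problem sizes: cap phantoms use a 500 µm-radius seed
  (25 voxels) in an 84³ grid; oracle equivalence uses 200 random ≤20³
  scenes; the shape-effect comparison runs at 40 µm voxels with
  half-linear-scale seeds in a 140³ grid — the check is directional and
  scale-free, and this keeps a five-packing comparison at desk scale.
* Inferential statistics between treatments are deliberately excluded;
  the package reports per-replicate values and mean ± SEM only.

## Known limitations

* Absolute mm² areas depend on the estimator; only the face-count ratio
  is estimator-independent. Cross-tool comparisons should use the
  contact percentage, not raw areas.
* The contact percentage saturates at dense packings and is
  resolution-dependent by construction (+1 voxel means one voxel at
  whatever the scan resolution is).
* Grain packings above ~40% solid fraction become slow to reach by
  random sequential addition; the generator caps the target at 0.64 and
  returns the achieved fraction.
* Auto-thresholding assumes three separable intensity modes; pellet
  coatings with mineral filler may require explicit thresholds and a
  custom band order.
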