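# Methods

## Scope and model

`arcore` post-processes tractography for a short projection bundle
between two small seed regions — the acoustic radiation (AR) between the
medial geniculate nucleus (MGN) and Heschl's gyrus (HG) is the motivating
case — under a rule system designed for bundles that run close to larger
tracts. The package deliberately does **not** generate streamlines:
probabilistic tracking (e.g. iFOD2 with anatomically constrained
tractography), gray/white-matter cropping and mask creation (FreeSurfer,
bundle segmentations) are upstream. `arcore` consumes candidate
tractograms and masks and produces the accepted subset, the density-
thresholded core mask, its outcome grade, and along-tract statistics.

## Coordinates and voxel membership

All streamlines are held in world RAS millimetres; masks keep their
native voxel grid plus a 4×4 affine whose action places voxel *centres*
at integer indices. A world point belongs to the voxel whose centre is
nearest, with round-half-to-even at exact ties. The TRK dialect's
voxel-scaled corner-origin coordinates are converted at the I/O boundary
only (via nibabel), so TCK and TRK inputs are indistinguishable
downstream. Out-of-grid points are flagged, never clamped.

Mask traversal is tested on a supersampled path: all vertices plus
points interpolated along each segment at spacing at most half the
smallest voxel edge (configurable via `FilterConfig.traversal_step_mm`).
Vertex-only testing would miss thin masks crossed between vertices; the
same supersampled visitation drives the track-density map, so filtering
and mapping are mutually consistent.

## Filter rules

Rules are evaluated in a fixed, documented order — length, endpoints,
endpoint exclusion, hard exclusion (masks in sorted name order), modified
soft exclusion (sorted) — and the first failure is reported, making
per-reason tallies deterministic and the report auditable. The report
satisfies `accepted + Σ rejected = generated` unconditionally.

Defaults (`FilterConfig`): length cap 60 mm; distance threshold 40 mm;
density threshold 10 streamlines; stopping criteria 1,000 accepted or
150 million consumed candidates. Because candidate generation is
upstream, the "generated" counter counts candidates consumed from the
input tractogram.

Two readings of the near-seed corridor rule are possible; the default is
conjunctive — a neighbouring-bundle voxel is removed when it is closer
than 40 mm to the MGN **and** closer than 40 mm to the HG — because for
a bundle only 40–60 mm long the conjunctive corridor is exactly the
territory the bundle itself must occupy, and the stated intent of the
rule is to allow streamlines into the shared near-seed voxels. The
disjunctive (OR) reading is available via
`FilterConfig(corridor_conjunctive=False)` and always removes a superset
of the conjunctive reading. "Closer than" is strict: voxels at exactly
the threshold are kept. Distances are Euclidean in world mm to the
nearest mask voxel (not geodesic, not centroid-based), computed with an
exact Euclidean distance transform honouring anisotropic spacings.

The endpoint-exclusion region (STG role) rejects by *termination* only:
a streamline merely brushing it mid-path is not rejected (the upstream
tracker is assumed to crop at the gray/white interface);
`FilterConfig(reject_midpath_endpoint_exclude=True)` extends the rule to
mid-path traversal. One reporting subtlety: with disjoint masks, a
streamline terminating in the exclusion region necessarily also fails
the seed-connection test. To keep the two report categories meaningful,
an endpoint failure whose stray terminus lies in the exclusion region
(outside any seed) is tallied as `rejected_endpoint_exclude`; all other
endpoint failures are `rejected_endpoints`.

## Density mask and outcome grade

The core mask is `density ≥ k` (default k = 10) computed on the merged
pair of seed-direction tractograms — combine first, threshold second.
Each streamline contributes at most one count per voxel regardless of
re-entries. The output grid defaults to the seed masks' grid.

The uncut / fragmented / failed taxonomy is operationalised as: failed
iff the mask is empty; uncut iff some single connected component
(26-connectivity by default) intersects both seeds after dilating each
seed by a touch tolerance (default 1 voxel); fragmented otherwise.
Components are labelled by decreasing volume with a lexicographic
tie-break, so labelling is deterministic. The original grading of such
reconstructions was visual; connectivity and tolerance are exposed
because no numeric criterion exists to copy.

## Tractometry

Streamlines are oriented so position 0 is the MGN-side terminus
(nearest-seed-voxel distance decides the side; exact ties keep stored
order with a warning-free deterministic outcome), resampled to 100
equal-arc-length points (the along-tract analytics convention), and the
scalar volume is sampled by trilinear interpolation; out-of-volume
samples propagate as NaN and are excluded pairwise. The unit of analysis
is the subject-level mean profile — never individual streamlines, which
would pseudo-replicate — and group summaries are the pointwise mean with
a t-based 95% CI. Group comparison is a pointwise two-sample pooled-
variance t-test with family-wise-error control across the 100 positions:
Bonferroni by default (simple, conservative), or a maxT permutation
scheme (null distribution of the maximum |t| over positions under label
permutation; adapts to the spatial correlation of neighbouring
positions, p-values computed with the add-one convention so the observed
labelling counts as one draw).

## Phantom generator

Scenes are built on a 64³ grid at 1.25 mm isotropic (an 80 mm cube, the
working resolution of high-quality diffusion data) with two spherical
seed blobs of radius 4 mm separated by 45 mm and a quadratic-Bézier
centreline whose control-point offset is solved by bisection to a target
arc length of 48 mm — inside the 40–60 mm range expected for the AR.
Ground-truth streamlines are the centreline plus a per-streamline offset
drawn uniformly from a disc of radius 2.5 mm perpendicular to the chord:
a uniform-density cross-section is the natural phantom for a core
defined by a density threshold, and it keeps every endpoint strictly
inside its seed blob (offset 2.5 mm + half voxel diagonal ≈ 1.1 mm
< 4 mm radius). The ground-truth corridor is the k = 1 density footprint
of the bundle.

Distractor families mirror the rejection taxonomy one-to-one, each with
small clipped Gaussian jitter (sd 0.5 mm, clipped at 1 mm) so labels are
guaranteed by geometric margins, not luck:

- *over-length*: seed-to-seed arcs solved to 70 mm, bulging out of the
  crowded plane;
- *cortical leak*: terminates in a 4.5 mm blob abutting the HG-role seed
  (10 mm from its centre, disjoint from it);
- *stray endpoint*: terminates in free space;
- *hard crosser*: dips through a z-oriented cylinder (radius 4 mm,
  CST role) offset 12 mm from the chord on the far side of the bundle;
- *distal soft toucher*: a seed-to-seed polyline detouring through the
  retained distal blob of the neighbour-bundle mask (59 mm total — under
  the cap, with every blob voxel ≥ 40 mm from the MGN-role seed mask);
- *corridor toucher*: bulges through the neighbour's near-seed blob
  (within 40 mm of both seeds, hence removed from the modified mask) and
  must be **accepted**.

The scalar (FA-like) volume assigns, to every voxel within 6 mm of the
centreline, `profile(t)` of the normalised arc position *t* of its
nearest centreline point, and a constant 0.15 background elsewhere. The
default profile `0.12 + 1.5·t·(1−t)` is low at the thalamic end, peaks
mid-tract and falls towards cortex — the qualitative shape reported for
AR FA profiles. Scenes are fully deterministic for a fixed seed (within
one numpy Generator algorithm version).

What the phantom does *not* emulate: curved sheet-like fasciculi,
partial-volume and noise structure of measured FA, kissing/crossing
geometry at sub-voxel scale, or tracking failures (candidates here are
clean polylines). Passing phantom tests therefore validates the
*rule system and its accounting*, not tracking robustness on real data.

## Verification strategy and problem sizes

Every geometric primitive is checked against an independent brute-force
oracle (plain-loop length sums, exhaustive nearest-voxel distance search,
flood-fill components, per-point mask membership with its own affine
solve and rounding), and the full filter is checked for exact agreement
— accepted set and per-reason counts — against a brute-force
implementation on 20 randomly seeded scenes. Statistical calibration
uses 1,000 Monte-Carlo replicates at 17 subjects per arm over 100
positions: the Bonferroni family-wise error rate under the null, the
coverage of the 95% CI, and the localisation of a large (2.5 σ)
mid-tract group difference. The default test and acceptance runs use
1,000-streamline bundles on 64³ grids, which keeps the suite to well
under a minute for the pipeline stages and a few seconds for the
Monte-Carlo block.

## Known limitations

- No resampling of masks onto a common grid: mismatched grids are an
  error by design (silent resampling corrupts thin masks); resample
  explicitly upstream.
- The 40 mm rule uses Euclidean world-mm distance; if a study computed
  it in voxel units on an anisotropic grid the removed sets would
  differ slightly.
- Density is integer visitation (no partial-volume weighting), matching
  the common track-density convention.
- The maxT permutation enumerates random label permutations, not the
  exact permutation group; p-values carry the usual Monte-Carlo
  granularity of 1/(B+1).
- `FilterConfig.both_seeds_required` is reserved for future relaxation
  of the endpoint rule; the current filter always requires both seeds.
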