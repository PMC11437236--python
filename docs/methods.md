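# Methods

## Problem and pipeline

Two parcellations of the same brain are compared by expressing one (the
"query", delivered as sparse 2D annotation plates) in the voxel space of
the other (the "reference", a 3D integer label volume).  The pipeline has
four stages: (1) anchor each plate in the volume and resample a matching
reference plate; (2) optionally refine the anchoring in-plane with
landmark markers; (3) count, per section, the joint label distribution of
query and reference pixels; (4) aggregate counts into section, segment and
whole-region proportions, and derive qualitative relation records and
metadata documents.

## Geometry and sampling conventions

A plate is placed by an origin `o` (its upper-left corner) and two
full-extent in-plane edge vectors `u`, `v`, all in voxel coordinates — the
convention of the interactive 2D-to-3D registration tool family this
pipeline's inputs come from.  Pixel `(i, j)` of a `w x h` plate samples the
continuous coordinate `o + ((i+0.5)/w)·u + ((j+0.5)/h)·v` (pixel-centre
convention).  Voxel centres sit at integer coordinates; a continuous
coordinate resolves to a voxel by per-axis round-half-up, which makes the
axis-aligned spec with `o = (-0.5, -0.5, k)` reproduce slice `k` exactly.
Labels are always looked up nearest-neighbour, never interpolated, and
coordinates outside the volume yield background 0.  These conventions are
frozen so that fixtures and tests are bit-exact; tie-break choices at
half-integer coordinates are otherwise arbitrary.

Plates are treated as infinitesimal planes.  The 40 µm physical section
thickness enters only the sampling-ratio arithmetic, because the
quantification operates on single plates, not slabs.  Plate arrays are
indexed `[column, row]` = (x, y), matching the volume's axis order; the
PNG reader/writer transposes to row-major image layout.

## Nonlinear refinement model

Interactive refinement tools let an operator drag landmarks; the published
descriptions of such tools do not specify their deformation math.  This
package freezes a documented stand-in: a piecewise-affine map on the
Delaunay triangulation of the marker source points plus the four pinned
plate corners, evaluated with barycentric interpolation.  It is the
identity for an empty marker set, exact at every marker, continuous
everywhere, and the identity on the pinned boundary.  Markers move a
pixel's *sampling position* (forward warp in sampling space), so label
images are never resampled.  The model is isolated behind `PlateWarp` /
`warp_point` so an alternative (e.g. Gaussian RBF) could be swapped in;
no result in this package depends on matching any particular tool's
deformation.  `PlateWarp.inverse()` inverts exactly by reusing the forward
triangulation; simply swapping marker source/target re-triangulates
independently and is only approximately inverse (sub-pixel for small,
well-separated moves — the regime refinement is meant for).

## Counting and proportions

For query region q on one section, `counts[q, r]` is the number of pixels
with annotation q and reference label r; query background pixels are never
objects.  Query pixels falling outside the reference brain are tallied
under reference id 0 and kept in the section total ΣOPs, because section
proportions OP_reg/ΣOPs are normalised by *all* object pixels; the
alternative (dropping reference background) is available via
`include_reference_background=False` since published reports do not state
the choice.  Connected-component ("object splitting") outputs are out of
scope; only aggregate counts are recorded.

Sections containing a region are ordered by decreasing Bregma and split
floor(n/3) / remainder-to-middle / floor(n/3).  Pooling is pixel-weighted
(ratio of summed counts), reading "in the same way as for the section-wise
data" as summing numerators and denominators; an unweighted per-section
mean is available via `method="mean"`.  Fraction maps always sum to 1
within 1e-9 when nonempty.

## Sampling ratios and the published extent tables

`total_sections = round_half_up(extent / 0.04 mm)` and
`ratio = round_half_up(100·n/total)`.  Half-up rounding is the only rule
consistent with the published tables (e.g. a 1.9 mm region gives 47.5 →
48 sections and 12.5 → 13%).  `round_half_up` snaps its argument to nine
decimals first so binary float noise cannot flip an exact half.

`extent_tables` stores both published tables with a per-row audit.  Three
rows of the stereotaxic-v6 table print a Bregma end inconsistent with the
row's own mutually consistent length/total/ratio triple (CPu, IPAC, PN);
the stored canonical ends are the length-consistent values, with the raw
printed end and an explanatory note kept on the row.  The published
ratio range (29–67%) and average (37%) for that table only hold with the
published per-row ratios, which supports treating the stray end values as
misprints.  In the *Brain Maps* v3 table the VTA and STN total-length
cells are swapped while ends, totals and ratios agree; the ends are
canonical there.  That table's published 19% average does not equal the
mean of its own per-row ratios (15.5 → 16); this package only reports
recomputed means.  Percent values are integers to match the tables; raw
fractions stay on the records.

## Relation classification and metadata

The qualitative vocabulary is identical / part_of / includes / overlapping
/ non_overlapping, with non_overlapping reserved for same-term regions with
zero overlap.  `classify_relation(f_ab, f_ba)` is a deliberately simple,
advisory heuristic: both directed fractions ≥ τ_identity (default 0.95) →
identical; one → part_of / includes; anything ≥ τ_floor (default 1e-4) →
overlapping.  Published calls of this kind are made by expert inspection
and no numeric rule exists for them, so τ_identity is a package choice,
the classifier is antisymmetric by construction, and callers are expected
to emit the raw fractions alongside each call.

Directed part_of/includes records are closed under inversion by
`expand_bidirectional` (idempotent; conflicting pre-existing inverses are
an error).  `to_openminds` emits SANDS-style JSON (BrainAtlas,
BrainAtlasVersion, ParcellationTerminologyVersion,
ParcellationEntityVersion with embedded qualitative/quantitative relation
assessments; AtlasAnnotation carries a file link only when the atlas has a
label volume).  Quantitative assessments below 0.01% are dropped.  Field
names follow the cited schema vocabulary; @context and versioned-IRI
minting are out of scope.  Documents validate against the schema shipped
in `src/atlasoverlap/schemas/`, checked by the package's own small
JSON-Schema-subset validator.  Storage is a portable three-CSV directory
(nomenclatures, regions, relations) with foreign keys validated on load;
region comparability scores are stored as opaque optional integers.

## Synthetic scenarios

`make_reference_volume` draws `n_regions` ellipsoids (default 8) fully
inside a 128×64×64 grid at a nominal 39 µm voxel — the real setting scaled
down ~8× per axis — painted in id order so later regions overwrite earlier
ones; a two-group parent hierarchy is attached by centroid position.
Fully-inside placement keeps painted voxel counts within ~2% of the
analytic ellipsoid volume, which is the generator's own oracle.
`make_query_atlas` applies translation / dilation / merge / split plans
and records exact 3D joint counts via `oracle_overlap_3d`, a deliberately
naive per-voxel tally independent of the pipeline's vectorised counter.
`cut_plate_series` cuts coronal plates at `spacing_mm` (default one voxel)
with optional mediolateral/dorsoventral tilts (rotations of `u`, `v` about
the plate centre), keeps an evenly spread `sampled_fraction` of them, and,
when a deformation amplitude is set, cuts each plate through a smooth
jittered-grid piecewise-affine warp while emitting the exact markers that
reproduce it — so refinement restores the undeformed sampling up to a
one-pixel boundary band.  Bregma is affine in z with the zero level at
30% of the rostrocaudal extent.

`recovery_scenario(seed)` freezes the standard study condition: eight
regions, four translated by (1, 0, 2) voxels, one dilated, one pair
merged, one split; one-voxel plate spacing, 4° mediolateral tilt, 30%
sampling — matching the 15–67% sampling range of printed stereotaxic
atlases.  Under these conditions pooled pipeline fractions recover the 3D
truth within ±5 percentage points for every region spanning ≥20 sections
(observed worst ≈2–4 pp over ten seeds), and with 100% sampling, zero tilt
and zero deformation recovery is exact, since the plates then *are* the
volume slices.

What the generator does not emulate: histological appearance, staining or
MRI texture, within-plane anatomical detail beyond smooth blobs, section
damage, or operator judgement in interactive registration.  Passing tests
therefore demonstrate correctness of the geometry, counting and
aggregation machinery under known ground truth — not the fidelity of any
particular real-world registration.

## Numerical and degenerate-input choices

- Degenerate anchoring (`|u×v| = 0`) and degenerate marker triangulations
  raise geometry errors; out-of-range pixels and fractions raise domain
  errors.
- Colour-coded plates decode by exact RGB match only; unknown colours
  (e.g. anti-aliased edges) raise an error listing each RGB value and its
  pixel count.  The plate writer emits exact, unantialiased PNGs.
- A region extent shorter than the plate count implies more sampled than
  estimated sections; the record is flagged (`oversampled`), not rejected,
  since the cause is typically a table misprint upstream.
- Sections with zero pixels of a query region do not enter that region's
  segment partition.
- Chart summaries order rows by descending fraction (ties by region id)
  and collapse fractions below 0.01% into an "other" row (id −1).

## Problem sizes used by the test suite and acceptance script

Oracle-equivalence checks run 100 random 64×64 plate pairs against a
double-loop tally; extraction checks cover every axis-aligned slice of a
24×18×14 volume; the recovery study runs ten seeded 128×64×64 scenarios at
30% sampling plus one full-sampling exactness run.  These sizes exercise
every code path at full fidelity while keeping a complete run in the order
of seconds.
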