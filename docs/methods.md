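# Methods

## Problem

In dental CT/CBCT of the mandible, teeth and the alveolar bone of their
sockets are nearly isointense, and the gradient across the tooth boundary is
weak: no single global threshold separates an individual tooth from the bone
that holds it.  `toothprop` implements a semiautomatic scheme that exploits
two facts instead: (i) on a well-chosen *reference* axial slice a human can
mark each tooth with a seed, and (ii) tooth cross-sections change only
gradually from one axial slice to the next, so a segmentation found on one
slice is a strong prior — both in *shape* and in *threshold* — for its
neighbors.

## Pipeline

The user supplies a reference slice index, one or more seed pixels per tooth
on it, and a 3D bounding box around the dentition.  The reference slice is
denoised (3×3 median), each tooth is grown from its seeds at the initial
T-value (see below) by seeded region growing (SRG), and interior cavities
are filled.  That per-tooth state — a binary mask and the T-value that
produced it — then propagates slice by slice toward +z and −z.  Per slice
and per tooth:

1. **Denoise** the slice with a median filter (kernel 3, reflecting edges).
2. **Seed derivation**: pixels of the previous mask eroded by 1 px whose
   denoised intensity still exceeds the previous T-value.  The erosion
   guards against boundary drift; if the set is empty, the brightest
   previous-mask pixel is used (the mask centroid would land in the dark
   pulp of an annular cross-section).
3. **Threshold search** (below) finds the slice's working T-value,
   warm-started at the previous slice's T.
4. **SRG** grows the tooth from the seeds: a queue-based FIFO expansion that
   admits a neighbor x iff x lies in the bounding box, I(x) ≥ T, and
   |I(x) − mean(A)| < δ.
5. **Hole filling** recovers the dark dentin/pulp interior: the background
   is flood-grown from the bounding-box boundary by pure connectivity
   (inverse SRG) and its complement is taken.
6. **Branch removal** intersects the grown mask with the previous mask
   dilated by 2–5 px (default 3, disk footprint) and keeps only the
   seed-connected component, pruning leaks into sockets or neighboring
   teeth.
7. **Size check**: if the area ratio to the previous slice leaves
   [1 − s, 1 + s] (default s = 0.3), the threshold is nudged by
   ±`retry_t_step` (20 HU) and steps 4–6 rerun, at most `max_retries` (5)
   times; then the attempt with ratio closest to 1 is accepted with a
   warning.

A tooth whose mask empties — past the root apex or crown tip, or at the
user's bounding-box limit — is marked terminated.  Pixels claimed by two
teeth are assigned to the tooth whose previous-slice mask is nearer
(Euclidean distance transform; ties to the smaller id), keeping per-slice
masks disjoint by construction.

Propagation stops at the z-limits of the user's bounding box.  This mirrors
the intended workflow — the box is drawn around the dentition — and matters
below the root apices, where the phantom (like a real mandible) continues as
bone that is isointense with teeth: without the box the tracker can follow a
small bone blob indefinitely.

## Initial T-value

The volume histogram (10 HU bins) shows air, soft tissue and bone as
separate modes.  Peaks are detected with a prominence floor (5% of the
tallest bin); the lowest-intensity peak is discarded as background when
three or more exist; the two most populated remaining peaks are the tissue
and bone modes, and the initial T-value is the center of the minimum-count
bin strictly between them (deepest valley).  Ties are broken to the midpoint
of the longest tied run of bins — with multiple zero-count gaps (one on
each side of the pulp mode) the longest gap is the natural valley.  A
histogram without two such modes raises an error and the user must supply T.

## Per-slice threshold search

Let A(T) be the area of the seed-connected component of the thresholded
slice, *with enclosed cavities counted*: the previous-slice area it is
compared to comes out of hole filling, so the measure must fill too —
otherwise every tooth looks ~20% too small the moment its crown leaves the
socket bone and only the dentin ring clears the threshold.  A(T) is
non-increasing in T, so two integer-HU bisections (each warm-started at the
previous slice's T, which only shrinks the bracket and cannot change the
result) locate:

* `t_high` — the greatest T with A(T) ≥ (1 − τ)·prev, τ = 0.10: keep the
  previous shape and size;
* `t_low` — the least T with A(T) ≤ F·prev, F = 2.0: prevent
  oversegmentation, where "oversegmented" means the component has merged
  into the socket arch, which multiplies its area, while genuine
  slice-to-slice growth of a tooth stays far below the factor.

The returned threshold is the midpoint of [t_low, t_high].  Between the
socket and tooth intensity distributions A(T) plateaus at the true tooth
area, and the midpoint sits inside that plateau, so area tracking is
self-correcting rather than pinned to a constraint edge.  (Taking `t_high`
itself — available as `anchor="greatest"` — is maximally leak-safe but pins
every slice at (1 − τ)·prev, eroding the mask by τ per slice; measured on
the default phantom this costs ~15% false-negative volume.)  When no
non-oversegmenting T exists the keep-size bound wins; when no T keeps the
area, the search fails and the tooth terminates.  On integer-valued CT the
integer bisection is exact, which also makes it independent of the warm
start and equal to an exhaustive linear scan of the bracket.

## Region growing choices

The printed membership rule |I(x) − mean(A)| < δ does not say whether
mean(A) updates as the region grows.  Default is `mean_mode="frozen"`
(mean of the seed intensities): the admission predicate is then static, the
result is independent of seed order and of any partitioning of the seed set,
and growing scattered seed groups separately and merging them reproduces the
full-set result exactly — the property that makes parallel decomposition
safe, which this package states as a contract and tests, without shipping a
threaded implementation.  A running mean is available behind a flag with
FIFO order fixed by lexicographic seed sorting.  Connectivity defaults to
4 in-plane (conservative against leaks through diagonal contacts); δ
defaults to 60 HU — three times the default phantom noise sigma — and must
be retuned for real data (≈3× the local noise level is the intended scale).
Sweep order over x, then y, then z is a cache-efficiency detail in the
original formulation; here only results are contractual, never traversal
order.

## Synthetic phantom

The phantom reproduces the features that make the problem hard, not dental
anatomy.  Defaults (the conditions all headline numbers refer to):
128×128×64 voxels at 0.2 mm; 14 teeth as tubes with elliptical
cross-sections (base radius 4.6 px, radial/tangential axis ratio 1.1) on a
215° arch of radius 46 px; linear radius taper 0.01 per slice toward the
root (area changes ≈2%/slice, "gradual" in the sense the propagation
premise needs); a concentric pulp core at 0.45× the tooth radius wherever a
≥1 px dentin ring remains around it.  Intensities (HU): air −1000, soft
tissue 200, pulp 600, socket bone 1300, tooth = socket + `contrast_gap`
(default 150); additive Gaussian noise, σ = 20 HU, rounded to int16.
Crowns protrude 4 slices above the bone into soft tissue; bone continues 4
slices below the root apices.  Seeds are the reference-slice centroid of
each tooth, displaced outward along the arch radius when it lands in pulp;
the bounding box is the dentition's tight box with a 3 px in-plane and 1
slice z margin.  Generation is a pure function of the config; teeth that
would overlap raise an error rather than silently merging ground truth.

What the phantom does *not* model: beam hardening and metal artifacts
(known failure mode of the approach), partial-volume blur at boundaries,
root branching (multi-rooted molars), the periodontal ligament space, and
anatomical cross-section shapes.  Passing the phantom criteria therefore
shows the propagation machinery is correct under low contrast, interior
holes and gradual drift — not that the method handles artifact-laden
clinical data.

## Error metrics

For automatic mask A and manual/reference mask M (voxel counts):
E_fp = (|A| − |A∩M|)/|M|·100, E_fn = (|M| − |A∩M|)/|M|·100,
E_vol = (|A|/|M| − 1)·100, E_sim = (1 − 2|A∩M|/(|A|+|M|))·100.
E_vol = E_fp − E_fn holds identically; E_sim is the Dice complement in
percent.  E_vol is computed signed per tooth and reported as an absolute
value in tables.  Aggregation is mean ± sample standard deviation across
teeth, then across datasets.

## Numerical details and edge cases

* Thresholding is `I ≥ T` throughout; intensities are treated as integer HU
  and thresholds searched over integers (`bisection_tol` is 1 HU).
* Hole filling uses minimal connectivity (4 in 2D, 6 in 3D) for the
  background flood — the conservative choice that cannot leak through
  diagonal gaps; a mask covering the whole box boundary fills to the entire
  box and logs a warning.
* The optional bone pre-mask (suppress voxels < 1400 HU before any
  per-slice work) reflects the classical mandible extraction threshold; it
  is off by default and not used for phantoms, whose socket bone sits below
  1400 on purpose.
* Degenerate inputs: empty seed lists, seeds below threshold, even median
  kernels, empty previous masks and empty manual masks all raise typed
  errors rather than propagating empty results.

## Problem sizes used in tests

Unit tests run on a 6-tooth 96×96×40 phantom; the accuracy, containment,
degradation and determinism checks run the full default 14-tooth 128×128×64
conditions, three RNG seeds each, and the degradation check repeats them at
contrast gaps {300, 150, 75, 40} HU.  These sizes keep a complete run of
the pipeline to roughly ten seconds per volume while leaving every
mechanism (taper, pulp, termination at both ends, neighbor contention)
active.

## Known limitations

* Below the root apex the tracker can follow socket bone for the 1–2 slices
  the bounding box still allows; with a generous box this grows.
* At contrast gaps at or below the SRG δ (≤ ~60 HU at σ = 20), growth leaks
  into sockets faster than branch removal can prune; errors rise steeply
  (this is the measured degradation trend, and the regime the original
  problem statement calls genuinely hard).
* The retry loop's accept-best fallback can lock onto a plausible-sized
  piece of bone when a root tip thins to a few pixels.
* No DICOM series reading, no resampling, no registration: volumes must
  arrive as NIfTI/NRRD/raw in HU-like units on an isotropic-enough grid.
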