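# Methods

## Problem setting

Two-colour FISH assays for gene rearrangements (e.g. the t(14;18)
BCL2–IGH translocation of follicular lymphoma) are read by counting and
relating sub-micron green (FITC) and red (TRITC) probe signals inside
individual cell nuclei.  In lymphoid tissue the nuclei touch and overlap,
and whole-slide fluorescence scanners therefore acquire short z-stacks
(here 7 focal planes, 0.4 µm apart) rather than single images.  The
package implements the full analysis chain for such stacks — extended
focus projection, adaptive-threshold nuclear segmentation with watershed
separation, cross-plane nucleus registration, within-nucleus spot calling,
break-apart / dual-fusion genotype classification — together with the
statistics used to compare segmentation methods, and a synthetic-data
generator that makes every stage testable against exact ground truth.

## Extended-focus projection

"Selecting high-intensity pixels across focal planes" is implemented as a
per-pixel, per-channel maximum-intensity projection.  This is the simplest
operator satisfying the description; no intensity normalisation across
planes is applied before selection.  The projection is pixelwise ≥ every
source plane and each output value is attained in at least one plane.

## Adaptive-threshold segmentation

A pixel is foreground iff

    gray(p) > m_w(p) + offset

where `m_w` is the Gaussian-weighted mean over a `window_size` square
neighbourhood (weights from a sampled Gaussian of width `gaussian_sigma`,
default `window/6`, normalised to sum 1; reflected boundary padding).  The
kernel is applied separably with an explicit sampled kernel rather than a
library local-threshold routine, so the operator agrees exactly with a
brute-force windowed-mean computation — this is what the oracle tests
check.

Two numerical conventions matter:

* **Strict inequality** — constant images yield empty masks.
* **Offset sign** — a *positive* offset raises the threshold above the
  local mean.  With the opposite convention a blank image becomes
  all-foreground (0 > 0 − offset), which contradicts the intended role of
  the offset as a background suppressor; the package therefore adds the
  offset.  For noisy images a sensible offset is ≈ 2 × the background
  noise sigma (background then binarises at the ~2.3% level and the small
  specks are removed by the area filter).

Cleanup removes components below `min_area_px` (default: the area of a
3 µm disk at 0.25 µm/px — lymphocyte nuclei are 5–8 µm), smooths with
morphological opening+closing (radius 2 px), and fills holes.  Touching
nuclei are split by a watershed on the negated interior distance
transform, seeded at distance maxima separated by ≥ `split_min_distance_px`;
components too small to host such a maximum keep one seed at their
distance maximum so no foreground is dropped.  Flooding is confined to the
foreground, so disjoint components are never merged; ridge-pixel
assignment follows the library watershed's deterministic flood order.
Border-touching nuclei are retained by default (`exclude_border` flips
this).  Externally produced instance masks (from neural-network
segmenters) are adapted by relabelling to consecutive IDs and splitting
disconnected labels.

## Cross-plane nucleus registration

Segmenting each plane independently would count a nucleus once per plane.
The registry accumulates per-plane outer contours (hierarchy level 0;
holes ignored) with centroid and pixel area, processing planes
focal-plane-first and then alternating outward (z0, z0−1, z0+1, …; ties to
the lower index), so the best-focused contour of each nucleus claims its
ID.  A candidate is rejected when it conflicts with a registered nucleus
in **either** direction: a registered centre inside or on the edge of the
new contour, or the new centre inside or on the edge of a registered
contour.  The one-directional rule (registered-centre-in-new-contour
only) cannot guarantee the symmetric non-redundancy invariant — a
shrunken off-focus contour of an already-registered nucleus can fail the
first test while its centre sits inside the registered contour — so the
bidirectional test is used.  Point-in-polygon tests are boundary-inclusive
(`shapely` covers), which conservatively prevents double counting of
edge-touching duplicates.  Registration is idempotent: replaying any
processed plane leaves the registry unchanged.

## Spot detection

Signal planes are grayscaled (RGB pages split, keeping the channel's
colour plane) and Gaussian-blurred (`blur_sigma_px`, default 1).  Seeds
are intensity peaks that (a) lie inside some registered contour (contour
polygons rasterised to an ownership image; overlaps resolve to the lower
nucleus ID), (b) exceed the spot threshold — absolute, or by default the
95th percentile of within-contour intensities per nucleus and plane — and
(c) survive an h-maxima prominence test with h = 10% of the plane's
dynamic range (absolute override available).  Equal-intensity peak ties
resolve to the lexicographically smaller coordinate.  Each seed grows
into the connected super-threshold region containing it, clipped to the
owning contour and to a disk of `max_spot_diameter_um` (default 0.5 µm,
the physical upper bound for probe signals; the clip prevents flooding
through diffuse background).  A grown spot is registered only if its
member-pixel set is disjoint, in (row, col) space across planes, from
every prior spot of the same nucleus and channel — the same
non-redundancy idea as nucleus registration, collapsing re-detections of
one physical spot in adjacent focal planes into a single record kept at
the plane closest to best focus.  Both unique-spot counts and raw
per-plane detection counts are reported.

## Genotype classification

Spot centres are converted to physical 3-D coordinates (pixel pitch in
x/y, plane index × z-step in z; 2-D if plane information is absent).  A
green–red pair is *colocalized* at distance ≤ `colocalization_radius_um`
and *separated* at distance ≥ `separation_factor × spot_diameter_um`
(default 3 × 0.5 µm = 1.5 µm — three spot diameters).  Matching is
nearest-first greedy and one-to-one: colocalized pairs are formed first,
separated pairs among the remaining spots; intermediate-distance pairs
are never formed and surface as `n_unpaired` (an optimal
minimum-distance bipartite assignment is available via
`optimal_matching`).  Break-apart mode calls a nucleus aberrant iff at
least one separated pair exists (the intact locus shows colocalized
pairs); dual-fusion mode iff at least one colocalized pair exists (normal
loci are separated).  Nuclei with fewer than
`min_spots_per_channel_for_call` spots in either channel are ambiguous.
The same distance rule serves both probe modes; the thresholds are
config-exposed.  Sample summaries report nucleus count, total and mean
spots per nucleus per channel, and the label fractions (which sum to 1
exactly).  A sample-level aberrance flag uses a default 0.10 fraction
threshold — a package default, not a clinically validated cut-off.

## Evaluation statistics

Object-level detection has no meaningful true negative, so accuracy is
computed TN-free: recall = TP/(TP+FN), precision = TP/(TP+FP), F = the
harmonic mean (= Dice on these counts), accuracy = TP/(TP+FP+FN)
(= Jaccard), and J = D/(2−D).  The bundled benchmark rows are consistent
with exactly this TN-free form, which is why it was chosen.  Matching of
predicted to true objects is greedy one-to-one, nearest-centroid within a
radius by default or mask-IoU ≥ 0.5 by option.  `VS`/`VP` are the n−1 and
n denominator variances (ratio identically (n−1)/n); Pearson and Cohen's
kappa delegate to scipy/scikit-learn behind the module surface, with
independent hand-formula oracles in the tests.  Printed benchmark values
are independently rounded to 2 d.p., so recomputed identities are
verified to within one last-digit step (±0.011).

## Synthetic data generator

The generator emulates: densely packed, partially overlapping ellipsoidal
nuclei; two-colour sub-resolution spots placed by genotype; Gaussian
defocus falloff around a focal plane; constant background plus Gaussian
noise; 16-bit output.  Defaults (the reference study conditions): 200
nuclei in a 768×768 field at 0.25 µm/px (a ×40 / NA 0.8 scan; the pixel
pitch is a package choice, exposed in config), 7 planes at 0.4 µm, nuclei
5–8 µm in-plane with z semi-axes 1.3–1.8 µm (section-trimmed) and centre
depths within ±0.6 µm of the focal plane, 20% overlap fraction, genotype
mix 40% normal / 30% fusion / 30% break-apart, 0.4 µm spots (FWHM),
DAPI peak 18000 and spot peak 30000 over background 300 with noise σ 150.

* **Layout** — sequential rejection sampling; each nucleus is forced to
  touch an existing one (centre distance 0.65–1.0 × summed radii) while
  the realised overlap fraction (share of nuclei touching ≥ 1 neighbour
  by the circumscribing-circle rule) trails the target, and kept clear
  otherwise; layouts retry until within ±0.05 of the target.
* **Spot geometry** — spots sit on a circle inside 0.8 × the focal-plane
  cross-section, so the registered (best-focus) contour contains them
  with margin.  Normal: G,R,G,R on the circle (four separated green–red
  chords); fusion and break-apart: a fused pair (offset 0.05 µm) at one
  vertex of a triangle with a lone green and lone red at the others.  The
  two aberrant patterns are geometrically identical — they differ only by
  probe context — so recovery of the planted mix is assessed as
  normal-vs-aberrant fractions under dual-fusion reading.  Separations
  are enforced **in the image plane** (planted chords 1.8–2.4 µm, hard
  floor 1.6 µm > 3 × 0.4 µm + margin): measured spot depth is quantised
  to the registration plane, so only in-plane geometry reliably survives
  detection.
* **Rendering** — DAPI planes are ellipsoid cross-sections scaled by
  exp(−(z−z₀)²/2s²) with s = 1.5 µm about the focal plane; spots are
  Gaussian blobs defocused about their *own* depth with the sharper
  s = 0.6 µm of a point emitter.  This gives the observed behaviour that
  nuclear contours/counts and per-plane spot counts peak at the focal
  plane and fall off outward.

What the generator does **not** model: optical PSF beyond the Gaussian
blobs, autofluorescence texture, chromatic shift, photobleaching,
scanner-specific noise.  Passing pipeline-recovery tests therefore shows
the algorithmic chain is correct under the stated imaging model, not that
it is robust to every real-slide artifact.

## Analysis parameters for synthetic runs

`fishstack.pipeline.synthetic_analysis_configs` matches the analysis to
the generator's imaging model: threshold offset 2 × noise σ (300),
watershed seed separation 9 px (≈ a small nuclear radius at 0.25 µm/px,
avoiding over-fragmentation of noisy distance ridges), spot blur 1 px,
and classification with `spot_diameter_um = 0.4` (the simulated probe)
and `colocalization_radius_um = 0.6` — two independently detected peaks
of one physical locus can land ~2 px (0.5 µm) apart on the grid, which a
radius of one spot diameter (1.6 px) does not cover.

## Known limitations and degenerate inputs

* Per-plane count monotonicity is probed on non-overlapping layouts: with
  20% overlap the watershed occasionally merges a touching pair only at
  the focal plane (where cross-sections are largest), perturbing the
  focal count by ±1 for reasons unrelated to defocus.
* Greedy nearest-first matching (object matching and signal pairing) can
  in principle differ from the optimal assignment in adversarial
  geometries; the optimal variant is available by flag.
* A spot lying in the overlap zone of two registered contours is assigned
  to the lower nucleus ID; with moderate overlap this misassignment is
  rare and bounded by the genotype-fraction tolerance.
* Blank images, empty registries, empty masks and single-plane stacks are
  all legal inputs and covered by tests; a 0-plane stack is rejected at
  construction.
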