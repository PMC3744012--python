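# Methods

## The competitive kernel

Every model in this package is one inhibitory pool (or a set of them) of
`N` rate neurons with non-negative, unit-norm weight vectors, updated by a
rank-based competitive Hebbian rule (see the README for the equations).
The design combines four forms of competition: inner-product activation,
a learning scale that decays with activation rank, divisive normalization
by the pool maximum, and subtractive inhibition by the mean of the most
active peers (`κ = 0.3`, peer set of up to ten neurons, generalized to
`min(10, N−1)` for small pools).

Numerical conventions:

* **Ranks** break ties by the lowest neuron index; this makes every run
  fully deterministic.
* **Winner output** equals 1 exactly (the winner's numerator and
  denominator are the same float expression), which the test suite checks
  to 1e-12 throughout training.
* **Initialization** is uniform-positive random with unit-norm rows: the
  sources do not fix it, and this keeps weights on the manifold the model
  assumes (the positive octant of the unit sphere for 3-input pools).
* **Negative outputs** of weakly active neurons are not clipped by default
  (the equations as given); a `clip_negative_y` flag exists for sensitivity
  checks. Weight entries are clamped at zero before renormalization so the
  non-negativity constraint survives occasional anti-Hebbian drift; in all
  shipped configurations the clamp never binds measurably.
* The **rank-zero neuron** (`μ = 0`) is left bitwise untouched.
* **Degenerate updates** (a zero-norm mixed vector) leave the row unchanged
  and emit a warning; an all-zero stimulus is skipped.
* **Seeding**: one root seed fans out via named `SeedSequence` child
  streams (init / shuffle / data / …), so experiments are exactly
  reproducible and component seeds never collide.

The inner loop exists twice with identical arithmetic: a plain-NumPy
reference and a numba-compiled twin used by default (a regression test pins
their agreement below 1e-14). This is what makes steady-state training
(millions of presentations) affordable inside the test suite.

## Rank exponent α

The exponent α controls how sharply learning is confined to the top-ranked
neurons. Model behaviour depends on it qualitatively, and the package uses
different values per experiment, each for a stated reason:

* **Face-space experiments: α = N.** Sharp competition is what lets a large
  pool retain selectivity along a low-variance stimulus dimension. With a
  flat exponent (α = 4 for all pool sizes) the steady state collapses every
  pool onto the major axis — mid-ranked neurons keep being pulled toward
  every stimulus, and the pools become insensitive to the minor dimension
  regardless of N, destroying the holism contrast the sweep is designed to
  show. At N = 4 the two choices coincide.
* **Hierarchy: α = N₁ = 9 in layer 1, α = 1 in layer 2.** Sharp local
  feature competition; broad, slowly differentiating output learning.
* **Cortical sheet: α = 1.** Lateral excitation acts by scaling
  output-dependent learning; with a steep exponent only the top few ranks
  learn at all and the lateral term cannot reorganize the sheet (the
  agreement index is flat in `h`). A flat rank profile distributes
  plasticity so cortical neighbors co-learn and patches can form.

## Epoch counts

Learning runs at `r = 0.001` with no annealing, so "steady state" takes
many epochs. Defaults per experiment (all overridable):

* holism sweep: 2000 epochs × 500 exemplars (past convergence; the
  classifier spread statistics stop changing well before this);
* exposure experiments: 200 epochs × 1100 (or 2000) exemplars — density
  counts are already stable here and identical to 1000-epoch runs in spot
  checks;
* hierarchy: 100 epochs for layer 1, then 300 for layer 2 (phased:
  layer 2 learns on a frozen layer-1 code);
* cortical sheet: 1000 epochs × 260 exemplars (the agreement index is
  unchanged at 3000).

## Synthetic stimuli

**Sphere clouds** are independent normals in the (azimuth, elevation)
chart, rejection-resampled to the positive octant; a population mostly
outside the octant is a configuration error. Empirical spreads match the
nominal ones to a few percent at the shipped sizes.

**Face images** are schematic 256 × 256 grayscale renderings on a mid-gray
(0.5) background, controlled by eight parameters: head width/height, eye
separation and size, nose length, mouth width and vertical position, brow
height. A hair cap (tied to brow height), brows, eyes, a nose wedge, a
mouth bar, cheek highlights and a head outline give the edge-detecting
front end rich, identity-bearing structure. Geometry respects a hard
midline contract: upper-face features live strictly in rows 0–127, the
mouth strictly in rows 128–255, so lower-half manipulations (delete /
exchange / offset) separate feature sets exactly.

Generator choices that matter, and why:

* **Feature variation is several working-pixels large** (s.d. 5–15 px at
  256²). The front end smooths at σ = 5 px and downsamples 4×; sub-pixel
  variation would leave all output-layer weight rows nearly identical, and
  code read-outs would be dominated by rounding noise rather than identity.
* **The between-population shift (4 s.d. on eye separation, brow height,
  head width) is concentrated on upper-face geometry**, as with real
  morphological differences between populations; population identity
  therefore survives lower-half manipulations.
* **Distinct individuals**: faces within a population are
  rejection-sampled to be at least 1.5 normalized s.d. apart in parameter
  space. Real stimulus sets contain distinct people; an unconstrained
  normal cloud occasionally yields near-duplicates whose identical codes
  would be artifacts of the sampler, not the model.
* **The head interior sits at the background level and the jaw outline
  fades below the jaw**, so blanking the lower half introduces no spurious
  strong edge along the cut line — the stated purpose of the mid-gray
  background.

What the generator does **not** emulate: texture, shading and hair
variation of real faces, 3-D pose, expression, illumination. Passing tests
therefore show that the *mechanisms* (exposure-dependent allocation,
competition, lateral coupling) produce the phenomena on stimuli with
controlled statistics — not that the pipeline reaches photographic-face
performance levels.

## Front-end normalization

The image front end is Laplacian-of-Gaussian (σ = 2 px, configurable)
followed by Gaussian smoothing (σ = 5 px), block-averaged to 64 × 64 and
min–max rescaled to [0, 1] per image (a constant image maps to zeros).
Because the signed response is rescaled, edge-free regions sit at a
mid-level pedestal rather than zero. This convention is load-bearing for
the manipulation battery: a blanked half drives its pools with a flat,
face-independent pedestal whose ratio-normalized outputs are near-uniform —
a mild, identity-neutral perturbation — whereas exchanging halves injects
structured evidence for a different identity. A zero-preserving
(edge-energy) normalization was evaluated and rejected: it silences half
the output-layer input under deletion, making deletion the *most*
disruptive manipulation and inverting the delete/exchange ordering the
model family is known for.

## Analyses

* **Win regions** are inner-product argmax assignments (a spherical
  Voronoi tessellation); classifier-to-group assignment is by majority of
  won exemplars, with a nearest-centroid fallback for neurons that win
  nothing.
* **Radial thresholds** walk a straight line in the chart from a group's
  empirical mean, probing at multiples of 0.1 group-s.d. (isotropic: the
  mean of the two per-dimension sample s.d.s) until the winning classifier
  changes, capping at 1 s.d.; probes leaving the octant cap the threshold
  at the last valid distance and set a flag. A 100×-finer brute-force scan
  serves as the oracle in tests.
* **Unique ranked codes** count stimuli whose full descending output
  ranking is shared by no other stimulus; per-population fractions divide
  by population size.
* **Clustering** is Ward linkage on Euclidean distances of output vectors,
  cut at six clusters; **projections** are mean-centered PCA onto the top
  four variance axes.
* **The manipulation battery** samples seven faces per population
  (seeded), manipulates the lower half (exchange partners drawn from the
  same population, never the face itself), and tabulates mean top-n overlap
  (n = 1…5) of the most active output neurons before vs. after.
* **Neighbor agreement** is the fraction of unordered grid-neighbor pairs
  whose neurons prefer the same category (272 pairs on a 9 × 9 sheet).

## Problem sizes

Test-suite experiments run at the configurations above with 10 seeds per
property; the acceptance script averages 3–5 seeds per quantity. These
sizes put every seed-fraction criterion well inside its observed stability
region while keeping a full run in the minutes range on one core.

## Known limitations

* The holism sweep's minor-dimension spread at large N partly reflects
  broadly tuned neurons that were never recruited to the exemplar cloud;
  the recruited subset shows the same ordering with a smaller margin.
* The delete-vs-exchange overlap ordering for the heavily trained
  population is a modest-margin effect (≈ 0.05–0.15 mean overlap
  difference) and depends on the front-end pedestal convention discussed
  above.
* Discrimination profiles are chart-planar: trajectories are straight in
  (azimuth, elevation), not geodesics; at the shipped cloud positions the
  difference is negligible.
* The balanced-exposure equivalence of thresholds holds at the shipped
  200-epoch configuration; with much longer training the two groups'
  threshold means drift apart stochastically even though coverage remains
  statistically symmetric.
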