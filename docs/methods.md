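# Methods

## Filtration and complex construction

An 8-bit grayscale image M of size X × Y is the integer function
f(x, y) ∈ [0, 255]. Its sublevel sets K_i = f⁻¹([0, i]) grow
monotonically with i, giving the filtration K_0 ⊂ K_1 ⊂ … ⊂ K_255.
Each pixel is modeled as a filled unit square carrying its gray value;
edges and vertices take the minimum over incident pixels
(T-construction). Consequences:

* sublevel sets are **8-connected**, their complements 4-connected;
* the Euler characteristic of K_t is χ = V − E + F, where F counts mask
  pixels and V, E count lattice vertices/edges incident to at least one
  mask pixel;
* β₁(K_t) = β₀(K_t) − χ(K_t) for any 2-D image (no enclosed voids).

The T-construction reads stained pixels as filled squares, the natural
interpretation of block-diagram imagery; the fixtures used for exact
tests are additionally built so every intended adjacency is
edge-sharing and every intended separation is ≥ 2 pixels, making their
diagrams identical under either connectivity convention.

## Diagram computation

**PD₀** is computed by union-find over pixels sorted by gray value
(stable sort, row-major tie order). A component is born at the minimum
gray level of its basin; when two components meet, the elder (smaller
birth) survives and the younger dies at the merge level, contributing a
(birth, death) point. Equal-birth ties are resolved toward the
component whose minimum pixel comes first in row-major order — a
deterministic choice that cannot affect the diagram multiset. Merges
with birth = death (plateau artifacts) have zero persistence and are
discarded. The one component that never merges is the **essential
class**, recorded with death = 255.

**PD₁** uses Alexander duality instead of matrix reduction: holes of
the 8-connected sublevel set are bounded 4-connected components of the
strict superlevel set. A second union-find processes pixels in
*decreasing* gray order with a virtual exterior node (border pixels
union with it); when an enclosed region of maximum gray m merges into
an older region or the exterior at level c, the sublevel filtration
gains a hole alive for thresholds t ∈ [c, m−1] — a PD₁ point (c, m).
On full rectangular images every region eventually connects to the
exterior, so PD₁ has no essential class.

Both computations are validated against an independent oracle
(`betti_at_threshold`) that shares no code with them: direct
8-connected labeling for β₀ and the V − E + F Euler count for β₁, plus
a label-containment brute force for persistent Betti numbers β₀^{i,j}.

## Persistent Betti numbers and multiplicities

β_p^{i,j} is the rank of the map H_p(K_i) → H_p(K_j), counted from the
diagram as classes with birth ≤ i and death > j plus essential classes
born by i. Multiplicities follow the inclusion–exclusion formula

    μ_p^{i,j} = β_p^{i,j−1} − β_p^{i−1,j−1} − (β_p^{i,j} − β_p^{i−1,j}),

with β_p^{−1,·} := 0 (K_{−1} is empty).

One convention point deserves care. Survivors are *plotted* at
death = 255, and the worked three-level example counts the three
surviving dark components with multiplicity 3 at (L, H). The
mathematical rank convention (essential classes alive at every j) would
make the formula yield only the non-essential deaths at the top level.
The two contracts cannot share a convention, so the package uses each
where it is correct: `persistent_betti` treats the essential class as
immortal (and therefore matches brute-force label containment at every
(i, j), including i = j = 255), while `multiplicity` takes recorded
deaths literally (and therefore reproduces the stored diagram
multiplicity at every occupied point, including the top level). Both
docstrings state their convention.

## Noise filtering

Points with lifetime |death − birth| < δ are topological noise; the
default δ = 40 gray levels follows the published choice. Filtering is
applied to **both** PD₀ and PD₁ before every downstream metric — the
noise definition immediately precedes the index construction, and
unfiltered short bars would otherwise dominate class counts. δ is
exposed everywhere (δ = 0 disables). Filtering at δ₁ then δ₂ equals
filtering at max(δ₁, δ₂).

## Clustering and indices

PD₀ classes enter 2-means clustering with multiplicity expanded (each
homology class is one observation; the index counts classes, not
distinct coordinates). The implementation is a weighted Lloyd
iteration, deterministic by construction:

* initialization at the minimum-birth and maximum-birth classes (ties:
  lower death, then row order);
* iteration to an exact assignment fixpoint, at most 500 rounds;
  distance ties assign to the first center;
* empty-cluster guard: the point farthest from the surviving center is
  reassigned and iteration continues; a diagram that still cannot
  sustain two clusters is reported as a structured degenerate result;
* the converged lower-birth center is labeled C₁ (positive); on a
  birth tie the lower-death center is C₁. Center_x1 < Center_x2 always
  holds on output.

This fixed initialization targets the birth-axis separation that
stained fields actually exhibit (positive nuclei dark, negative nuclei
mid-gray). It attains the exhaustive-partition optimum on all small
diagrams in the test suite; it is not a global 2-means solver for
arbitrary point clouds, where the optimal split may lie along the death
axis.

PHI is the positive-class fraction. WSS_k sums squared Euclidean
distances of cluster-k classes to C_k; BSS sums cluster size times
squared distance from the overall centroid to each center;
RSS = BSS / (BSS + WSS1 + WSS2), with the all-points-identical 0/0
case defined as 0. Cohort-scale summaries of WSS are reported both raw
and as RMS radii √(WSS_k / n_k) — published per-grade WSS magnitudes
(tens of gray levels) are on the square-root scale, but the divisor is
not stated, so both candidates are exposed and internal tests use only
internally consistent quantities. PD₁ is summarized by its
multiplicity-weighted centroid and WSS about it; an empty PD₁ yields an
explicit n = 0 sentinel with NaN coordinates rather than fake zeros.

For visualization, diagrams are binned on a 32 × 32 grid over
[0, 255]² (cells half-open except the last) and rendered with counts
clipped to 40, matching the published display convention; raw counts
conserve total multiplicity and are the numeric contract.

## Threshold classification

Binary nuclear grade (type A = G1, type B = G2/G3) is regressed on a
scalar score by one-variable logistic regression,
logit P(B) = a + b·score, fitted by Newton/IRLS (tolerance 1e−8, max
100 iterations, via statsmodels). The decision threshold is −a/b, the
score at fitted probability 0.5. Perfectly separated classes make the
maximum-likelihood fit diverge; that case is detected by a direct gap
test and the midpoint of the separating gap is returned, flagged.
Classification predicts type B when score > threshold; a score exactly
at the threshold goes to type A (ties break toward the lower grade;
flag-controlled). Confusion counts, accuracy, sensitivity (type-B
recall) and specificity are reported.

## Synthetic data

The fixture generator reproduces two exactly-solvable three-level
layouts (L = 0, M = 128, H = 255 by default): *components* — three
isolated dark blocks, two dark blocks each joined to a distinct dark
block by a mid-gray bridge, five isolated mid-gray blocks, giving
PD₀ = {(L,M): 2, (L,H): 3, (M,H): 5}; *holes* — two dark rings with
mid-gray interiors and two mid-gray rings with white interiors, giving
PD₁ = {(L,M): 2, (M,H): 2}. Ring walls are 2 pixels thick and all
separations ≥ 3 pixels, so the counts are connectivity-unambiguous.

The IHC-field generator places non-overlapping axis-aligned ellipses by
rejection sampling (at most 10⁴ attempts per nucleus, failure reports
the achieved count): semi-axes Gaussian around `radius_mean` ± sd,
truncated at 2 px; positives filled at gray 30, negatives at 130, on a
background of 220; additive Gaussian noise (sd 5), clipped and rounded.
Defaults — 256 × 256 canvas, 40 nuclei, radius 6 ± 1.5 px, minimum
separation 3 px — emulate the nucleus density of a ×40 high-power
field at a reduced canvas that keeps a full pipeline run well under a
second; clinical scans (1280 × 960 and larger) run through the same
code path, only slower. The generator emulates staining *contrast and
counts*, not real histology: no stain texture, no stroma, no
overlapping or rotated nuclei, no chromatic variation. Passing tests
therefore demonstrate that the pipeline recovers known class fractions
and geometry under the stated contrast model, not that it handles
stain-quality artifacts of real slides.

With noise sd 5 and δ = 40, nuclei produce classes with lifetimes of
roughly 90–190 gray levels while noise bars live only a few levels — a
persistence ≥ 40 noise bar would require an ~8 σ pit, so ground-truth
counts survive filtering exactly in practice.

## Numerical and degenerate-input choices

* 1-pixel-wide images are legal (PD₁ empty by construction); constant
  images yield a single essential class (birth = death = 255 tolerated
  in the one all-white case).
* 16-bit input is rejected unless explicit down-conversion is requested
  (linear rescale, round half up); RGB requires an explicit flag and
  uses Rec. 601 luma.
* RSS and PHI are exact rationals of integer counts where the inputs
  are; float comparisons in tests use 1e−9 tolerances.
* All randomness is confined to the synthetic generator and seeded;
  every pipeline stage is deterministic given its inputs.

## Known limitations

* PD₁ via duality is correct for 2-D images only; no volumetric data,
  no dimension ≥ 2 persistence, no point-cloud (Vietoris–Rips)
  complexes.
* The clustering is the deterministic variant described above, not a
  global 2-means solver.
* No stroma exclusion, nuclear segmentation, or color deconvolution:
  the score operates on raw grayscale intensity, as intended.
* Published per-cohort statistics (correlations with pathologist
  scores, per-grade means) require the original patient images and are
  out of scope; the package reproduces the method, the worked examples,
  and the confusion-count arithmetic.
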