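# Methods

## Filtered cubical complexes of grayscale images

Images are modelled with the T-construction: a pixel at grid position
(r, c) with intensity v is a 2-cube carrying filtration value v, and every
edge and vertex carries the minimum intensity over the squares it bounds.
An H×W image therefore yields H·W squares, H·(W+1) + W·(H+1) edges and
(H+1)·(W+1) vertices, and faces never exceed their cofaces, so the
sublevel sets K_i (cells with value ≤ i) are genuine subcomplexes, nested
in i. The sublevel index set is {0, …, depth−1}: 256 levels for 8-bit
images.

Two consequences of the min rule are worth stating because they fix the
connectivity conventions for everything downstream: dark (foreground)
pixel components are 8-connected (diagonal pixels share a vertex whose
value never exceeds either pixel), and holes/background are 4-connected.
Coordinates are row-major with the origin at the top-left pixel.

Color input is converted with the ITU-R BT.601 luminance weights
(0.299, 0.587, 0.114), rounded to the nearest integer; grayscale input
passes through unchanged.

## Persistent homology

`compute_persistence` returns H₀ and H₁ bars of the sublevel filtration.
Conventions:

* Essential classes (the one component that never dies) are retained with
  death capped at the top level depth−1. No rectangular image has an
  essential H₁ class.
* Zero-persistence pairs (birth = death) are discarded; they carry no
  geometric information and would pollute entropy and point counts. The
  essential H₀ bar is exempt (a constant image at the top level is born
  and capped at the same value).
* Betti-curve membership is half-open, [birth, death), with essential
  bars counting through the top level inclusive. The open-interval
  alternative would undercount a feature at its own birth level and
  contradicts the barcode of the worked 3×3 example, but we flag it as a
  convention choice rather than a forced one.

Two independent algorithms are implemented:

* **union_find** (default). H₀ by Kruskal-style merging of pixels in
  increasing connection value max(a, b) under 8-connectivity with the
  elder rule. H₁ by duality: a hole of K_i is a bounded 4-connected
  component of the strict superlevel set {v > i}, so superlevel
  components are tracked in decreasing threshold with a virtual outside
  node attached to border pixels at their own value; a bounded component
  with maximum pixel m that joins the outside (or an elder component,
  when one hole splits into two in the sublevel direction) at threshold t
  yields the hole bar (t, m). This runs in near-linear time and is what
  the feature pipeline uses.
* **reduction**. Textbook boundary-matrix reduction over GF(2) with
  cells sorted by (filtration value, dimension, anchor) and the
  twist/clearing optimisation. Tie order among equal filtration values is
  fixed for determinism; any valid order yields the same diagram.

The test suite holds the two in exact (bar-for-bar) agreement on random
images and checks both against a brute-force oracle: per-level flood fill
for β₀ and the Euler characteristic χ = V − E + F for β₁ = β₀ − χ (valid
because a 2-D sublevel complex has no 2-cycles). The Betti-curve oracle
alone would not pin down the birth–death pairing, which is why the
dual-algorithm comparison exists.

## Descriptors

All descriptors are computed per homology dimension on the bars described
above (essential deaths already capped, so all lifetimes are finite).
For a diagram {(bᵢ, dᵢ)} with lifetimes lᵢ = dᵢ − bᵢ and L = Σ lᵢ:

* **Persistent entropy**: −Σ (lᵢ/L) ln(lᵢ/L); 0 for an empty or
  single-bar diagram. (Natural log; the standard negative Shannon form,
  guaranteeing PE ≥ 0.)
* **Bottleneck amplitude**: max lᵢ/2 — the L∞ distance from the diagram
  to the empty diagram, each point matched to the diagonal. The
  Wasserstein amplitudes are (Σ (lᵢ/2)ᵖ)^(1/p), p ∈ {1, 2}. Interpreting
  these one-diagram "distances" as amplitudes against the canonical empty
  reference is a design choice: a distance per image per dimension is
  only well-defined against a fixed reference diagram, and the empty
  diagram is the standard one.
* **Landscapes** λ₁, λ₂: k-th largest value over the tent functions
  min(x − b, d − x)₊; zero where fewer than k bars cover x.
* **Betti curves**: bar-count functions under the half-open convention.
* **Heat surfaces**: Σᵢ G_σ(x − bᵢ, y − dᵢ) − G_σ(x − dᵢ, y − bᵢ), a
  positive Gaussian bump per point minus its mirror across the diagonal;
  antisymmetric, and exactly zero for diagonal points. σ ∈ {1.6, 3.2}
  luminescence levels.
* **Point counts**: number of stored (off-diagonal) bars.

Functional descriptors are sampled on a fixed uniform grid of
n_bins = 100 points over [0, depth−1] (100×100 over its square for
surfaces), and L¹/L² norms are rectangle-rule approximations
(Σ |f|ᵖ Δ)^(1/p) with Δ the grid cell measure. The fixed range makes
features comparable across images; per-diagram ranges would not be.
n_bins is configurable.

Numerical caveat: at the default grid over 256 levels the spacing is
≈ 2.58 levels, larger than the σ = 1.6 bandwidth, so the σ = 1.6 heat
norms are under-resolved and shift by ~2–3% when the grid is doubled;
every other functional feature changes by < 2% under refinement. The
σ = 1.6 features remain deterministic and perfectly usable as classifier
inputs (the grid is part of the feature definition), but they should not
be read as converged integrals.

The assembled vector has exactly 30 entries in a fixed order (entropy,
bottleneck, W₁, W₂, landscapes, Betti curves, heat kernels, point counts;
H₀ before H₁ within each family); `FEATURE_NAMES` gives the canonical
column names.

## Classifier and metrics

An L2-penalized logistic regression classifies the feature vectors,
labels encoded good = 0, bad = 1 (the legacy numeric label 2 is accepted
as "bad"). Defaults: C = 150 000, tolerance 10⁻⁸, liblinear, 10 000 max
iterations — the optimum of the tuning grid
{tol: 10⁻⁴/10⁻⁶/10⁻⁸} × {C: 50k/100k/150k} × {lbfgs/saga/liblinear} ×
{max_iter: 10k/50k/100k}. Features are standardized (zero mean, unit
variance, statistics from the training fold only) before fitting; at
C = 150 000 the penalty is so weak that unscaled descriptors spanning
orders of magnitude would dominate the optimisation. Tuning is an
exhaustive grid search by cross-validated accuracy with ties broken
toward smaller C, then larger tolerance (the weaker fit). The solver is
an implementation detail: any convergent penalized-likelihood optimizer
is acceptable, and non-convergence is recorded in the model metadata
rather than raised.

Confusion counts use the 0.5 probability threshold. Accuracy, per-class
precision/recall/F1 and MCC are computed by exact rational arithmetic
from the counts; any 0/0 is reported as 0 with a logged note (this
convention applies only when a marginal actually vanishes — an
all-wrong predictor legitimately scores MCC = −1). ROC points sweep all
score thresholds and AUC is the trapezoidal area, which equals the
tie-averaged rank probability P(s_pos > s_neg); the test suite verifies
that identity against exhaustive pairwise enumeration.

## Synthetic fundus phantoms

Real fundus photographs cannot ship with the package, so the study design
is emulated by a generator whose *good* class renders the gross topology
of a readable image in grayscale: a bright retina disc (≈170, mild radial
shading) on a dark surround (≈12), a dark macula blob (≈55), a bright
optic-disc region (≈235), branching dark vessel walks (≈75), a dozen
small dark spots, and Gaussian pixel noise (σ = 4). This guarantees the
two signatures the method exploits: an H₁ bar spanning ≳ 85% of the depth
(the bright retina enclosed by the dark aperture, filled only when the
optic-disc peak enters) and several persistent dark H₀ components. The
*bad* class passes a good phantom through 1–3 random degradations:
Gaussian blur (σ 1.5–3.5 px), multiplicative illumination gradient
(darkest factor 0.35–0.65), 1–3 opaque occluding discs (near-black or
near-white), and contrast compression toward the mean (factor 0.35–0.6).
Magnitudes were chosen so the classes are separable but overlapping: a
balanced 100+100 study reaches held-out AUC between roughly 0.95 and 1.0
across seeds rather than a degenerate 1.0 everywhere.

What the phantoms do **not** model: color channels and chromatic
artifacts, real vessel trees, pathology, sensor vignetting, JPEG
artefacts, or the label noise of human quality grading. Passing the
synthetic study therefore shows the pipeline is wired correctly end to
end and that the topological features carry the intended degradation
signal — it does not certify clinical performance on real data.

Studies are balanced with a stratified 85/15 train/validation split; the
validation subset takes ⌈0.15·n⌉ images per class, so 50 per class gives
an 84/16 split. All randomness derives from a single seed via spawned
generators; identical seeds reproduce images, split and features
byte-for-byte. The default phantom side is 64 px — large enough for the
anatomy to be resolvable, small enough that a 200-image study featurizes
in well under a minute on one core (the persistence step is the
union-find path).

The 3×3 worked-example fixture is a *reconstruction*: the minimal matrix
over four luminescence levels consistent with one component appearing at
level 1 and surviving to the end and one hole born at 2 and filled at 4.
It is stored with 0-based depth 5 so the level value 4 is representable.

## Degenerate inputs and edge cases

Empty diagrams score 0 on every descriptor. A constant image yields a
single essential H₀ bar and no H₁ bars, so all H₁-derived features are 0.
1×N images have no holes. Longest-bar ties break toward the smaller
birth, then smaller death. Single-class label vectors, fewer than 2
samples per class, non-finite features, out-of-range thresholds and
malformed feature tables raise validation/schema errors rather than
propagating.

## Known limitations

* Homology is computed in dimensions 0 and 1 only; 3-D (voxel) stacks
  and the V-construction are out of scope.
* The σ = 1.6 heat norms are under-resolved at the default grid (above).
* The phantom study is a scaled stand-in (hundreds of images, 64 px)
  for a real curated dataset of thousands of full-resolution
  photographs; absolute metric values on real data will differ.
* Barcode/diagram plotting is deliberately minimal (CSV export is the
  supported interchange format).
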