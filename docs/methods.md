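# Methods

## Model

A single muscle fibre segment is idealized as a circular cylinder of constant
radius R and length L. Peripheral myonuclei are treated as points on the
cylinder surface, described by unrolled coordinates (z, θ) with z ∈ [0, L]
along the axis and θ ∈ [0, 2π) around it. Distances between nuclei are, by
default, geodesics on the unrolled rectangle,

    d = sqrt(Δz² + (R·Δθ_w)²),   Δθ_w = min(|Δθ|, 2π − |Δθ|),

i.e. the surface wraps in θ but the segment ends are hard boundaries in z.
A `metric: chord` switch replaces the arc R·Δθ_w by the 3D chord
2R·sin(Δθ_w/2) for sensitivity analysis; all pipeline stages honour it.

For a fibre with n nuclei the orderness score is

    g = (ME − MR) / (MO − MR)

with ME the observed mean nearest-neighbour distance on the surface, MR the
expected mean NN distance of n points placed uniformly at random on the same
cylinder (z ~ U(0, L), θ ~ U(0, 2π)), and MO the mean NN distance of a
maximally spread arrangement of n points. g is reported unclipped: negative
values flag clustering beyond random; values slightly above 1 can occur
because MO is a heuristic lower bound on the true optimum (see below). A
`clip_g` option restricts reports to [0, 1].

## Cylinder estimation

The fit must be accurate enough that a truly random fibre scores 0 on
average; two standard estimators fail that bar at realistic n, so both were
replaced by small-sample-corrected versions. These are the package's own
design choices:

* **Axis.** Initialized as the principal axis of the nucleus cloud (SVD of
  the centred coordinates), then refined by a least-squares constant-radius
  cylinder fit: damped Gauss–Newton on the residuals r_i − mean(r), where r_i
  is the perpendicular distance to the candidate axis, over the four
  identifiable parameters (transverse offset and tilt in the principal-axis
  frame — parametrizing this way removes the two gauge freedoms of a line in
  space and makes the solve deterministic). Rationale: the raw principal axis
  passes through the noisy transverse centroid (error ~ R·√π/(2√n), ≈ 1.8 µm
  at n = 100, R = 20 µm) and its wobble distorts projected azimuths
  asymmetrically, inflating the null score by ≈ 0.7 percentage points; the
  cylinder criterion is instead conditioned by the radial scatter of nuclei
  about the surface (≈ 0.5 µm), ~30× smaller. The refinement needs n ≥ 7 and
  non-degenerate transverse spread; otherwise the principal axis is kept.
  The refinement uses a fixed 30-iteration budget with scale-equivariant
  finite-difference steps, so fits are pure functions of the input bits
  (byte-identical reruns) and scale exactly with the coordinates.
* **Radius.** Mean perpendicular distance of the nuclei to the axis — nuclei
  are peripheral, so they trace the surface; a fibre-boundary radius is not
  recoverable from coordinates alone.
* **Length.** The axial span s = max − min of the projections underestimates
  the segment: for n uniform positions E[s] = L·(n−1)/(n+1). The reported
  length applies the uniform-support correction L̂ = s·(n+1)/(n−1) (the
  minimum-variance unbiased estimator of a uniform support), with the origin
  placed s/(n−1) below the minimal projection. Besides restoring unbiased
  length recovery, this removes an O(1/n) score bias: with L̂ = s the two
  extreme nuclei sit exactly on the segment boundaries, where edge effects
  inflate their NN distances relative to the uniform reference (whose extremes
  fall ~L/n inside); after the correction the observed extremes sit exactly at
  the expected position of uniform extremes. Measured on 800 random fibres at
  n = 100, the naive fit gives ME − MR = +0.19 ± 0.02 µm (≈ +1.5 points of g);
  the corrected fit gives −0.03 ± 0.02 µm, statistically zero. The price is
  that L̂ intentionally exceeds the observed span — e.g. 8 nuclei spanning
  exactly 10 µm axially report L̂ = 90/7 ≈ 12.86 µm.
* **θ origin.** The coordinate axis most orthogonal to the fitted axis fixes
  θ = 0; only θ differences enter any statistic, so results are independent
  of the convention (tested via rigid-motion invariance).
* Projections are clamped into [0, L] within a relative tolerance of 1e−6;
  nuclei on the axis (undefined azimuth) and fitted radii below a 0.5 µm
  floor (near-collinear input) are errors, not silent results.

## Random reference (MR)

Monte Carlo: `mr_reps` independent draws of n uniform points on the fitted
cylinder; MR is the mean over repetitions of the mean NN distance, with its
standard error. Default `mr_reps = 1000` puts the Monte-Carlo SE of MR near
0.02 µm at the default geometry — an order of magnitude below the per-fibre
sampling noise of ME. The SE is propagated to a first-order uncertainty on g
(`g_se`), kept in the machine-readable output only.

## Optimal reference (MO)

No closed-form optimal packing exists on a bounded cylinder, so MO is
operationalized as the best of:

1. a **wrapped triangular lattice**: rows at z = (i+½)·L/m, points equally
   spaced around the circumference with alternate rows offset by half a
   spacing. Candidate row counts (divisors of n, plus integers around the
   equilateral optimum m* = sqrt(2nL/(√3·2πR))) are constructed explicitly
   and the layout with the largest minimum pairwise distance wins; uneven row
   occupancy is flagged;
2. `mo_restarts` runs of **maximin refinement** (first from the lattice, the
   rest from uniform-random starts): at each of `mo_iterations` steps one
   point of the current closest pair is perturbed by a Gaussian step whose
   scale decays geometrically from one hexagonal spacing a_hex =
   sqrt(2·2πRL/(√3 n)) to 10⁻³·a_hex, and the move is kept only if the global
   minimum pairwise distance strictly increases.

MO is the best configuration's **mean** NN distance and is never below the
raw lattice's. Because the refinement is heuristic, MO is a lower bound on
the true optimum, so near-perfect fibres can score slightly above 100%
(flagged, not clipped). Defaults `mo_restarts = 8`, `mo_iterations = 2000`.
Validation: for n = 2 the optimizer reaches the analytic optimum
sqrt(L² + (πR)²) (opposite ends, opposite sides) within 0.01%; for n = 200
at the default geometry MO lies within 15% of the hexagonal estimate a_hex.

## Seeds and determinism

One master seed governs a run. Per-fibre sub-seeds are derived by SHA-256
from (master seed, fibre id, component tag) — independent streams for the
Monte-Carlo null and the optimizer that do not depend on batch order or
composition. All stochastic results are pure functions of (inputs, seed);
re-running a pipeline reproduces every output file byte for byte.

## Group comparison

Fibres are the replicates (animal-level nesting is not modelled). Groups are
summarized as mean ± SE of g in percent and compared with a one-way ANOVA;
pairwise follow-ups are t tests on the pooled within-group mean square with
Bonferroni multiplication, p_adj = min(1, p_raw · n_comparisons). Degenerate
inputs raise (single group → summary only; zero within-group variance
everywhere → undefined F).

## Synthetic fibres

The generator emulates spot-detection output: surface points lifted to 3D at
radius R with Gaussian radial jitter (default sd 0.5 µm, the scale of
segmentation noise), an arbitrary rigid pose and no preferred frame. The
order parameter is **best-candidate sampling**: each nucleus is the best of
k uniform candidates, maximizing the surface distance to the nuclei already
placed. k = 1 reduces exactly (same seed, same stream) to uniform random
placement; increasing k yields blue-noise-like patterns approaching the
lattice. Chosen over lattice-plus-jitter because a single integer spans the
whole continuum with an exact random end point and no wrap artefacts.

Defaults — n = 100 nuclei, R = 20 µm, L = 500 µm — are conventions at the
scale of a mouse EDL fibre segment (tens of µm across, hundreds of µm of
imaged length, ~100 peripheral nuclei), not reproductions of any particular
dataset. What the generator does **not** emulate: nuclear shape and size
(points only), central (non-peripheral) nuclei, fibre curvature and taper,
segmentation errors other than isotropic radial jitter (no missed or merged
nuclei), and anisotropic z-resolution of confocal stacks. Passing tests
therefore certify the estimators and references on ideal cylindrical
geometry with realistic sampling noise — not robustness to curved fibres or
imperfect segmentation, which should be judged on real data.

## Numerical choices and edge cases

* Duplicate surface coordinates are allowed (NN distance 0) but warned about
  and flagged; an optional `min_separation` filter (off by default) greedily
  collapses points closer than a threshold.
* The score denominator MO − MR must exceed 10⁻⁶·max(MR, 1) µm; otherwise
  the normalization is meaningless (tiny n, degenerate geometry) and the
  fibre errors out — errors are reported per fibre, never silently dropped;
  a run fails only if every fibre fails.
* Tables print 4 significant figures; the JSON sidecar keeps full precision
  and is what `compare` consumes, so the two-stage CLI path is bit-identical
  to the one-shot path.
* Problem sizes used by the shipped end-to-end checks (200 fibres at
  `mr_reps = 400`, `mo_restarts = 4`; 50 fibres per order level) were chosen
  so the whole validation runs in minutes on one core while keeping the
  Monte-Carlo resolution of the cohort mean near 0.4 percentage points.

## Known limitations

* MO is a lower bound; g has a small positive ceiling bias for near-optimal
  patterns (scores slightly above 100% are possible and flagged).
* The cylinder model assumes straight, constant-radius fibres; strongly
  curved or tapered segments should be cut into shorter pieces upstream.
* The residual null-calibration bias after the estimator corrections is
  below ~0.1 µm in ME − MR (≲ 0.5 points of g at the default geometry) but
  not exactly zero; it shrinks with n.
* Group inference treats fibres as independent replicates; with few animals
  per group a hierarchical model would be more conservative.
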