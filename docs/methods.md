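# Methods

This note documents the models, estimators, conventions and design choices
behind `afpq`, in the spirit of a statistics package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement plane and its containers

All analysis happens on the circular mouth-exit cross-section, treated as a
closed disk of diameter `D` (default 20 mm — a plausible mouthpiece bore;
the physical diameter of real sampling planes varies and is configurable).
Coordinates are physical millimetres, origin at the disk centre, x
rightward, y upward; angles are degrees counterclockwise from +x. Raster
grids cover the disk's bounding square at `resolution^2` pixels (default
512, giving seven dyadic box scales); row 0 is the image top, pixel bins
are half-open, and points exactly on the disk boundary are kept (closed
disk) and folded into the outermost in-mask pixel so that every particle is
counted.

Three grids derive from a particle cloud:

* **occupancy** — pixel is 1 iff at least one particle centre falls in it;
  input to fractal dimension and lacunarity;
* **relative concentration** — per-pixel count divided by the mean in-mask
  count, so the in-mask mean is exactly 1 (grayscale maps persist as 32-bit
  float TIFF: integer quantization would visibly violate that invariant on
  round trip);
* **disparity** — the signed elementwise difference against a baseline
  concentration map; identical inputs give an identically zero map.

## Box-counting dimension

`D_B` is the magnitude of the slope of an unweighted natural-log
least-squares regression of occupied-box counts on box size. Conventions,
declared rather than inherited (the desktop tools usually used for this
analysis do not publish their settings):

* scale series: dyadic `eps = 2, 4, ..., min(H, W)//4`, extended to
  `min//2` (and, for small tiles, down to `eps = 1`) whenever fewer than
  five scales would result; five scales are the minimum for a fit;
* per scale, the count is minimized over the four corner-anchored grid
  offsets, reducing grid-placement bias; counts are exact — they match a
  brute-force scanning loop on small images, and aligned scales on the
  Sierpinski carpet reproduce the construction recursion `N(3^k) =
  8^(levels-k)` exactly;
* `R^2` is always reported; a constant count series (single filled pixel)
  raises a degenerate-series error rather than returning a number.

ROI variants crop first and analyze the crop as a full image (ROI side ≥ 32
px). The local grid tiles the image (default 6×6), reports per-tile fits,
marks tiles with fewer than two filled pixels as *undefined* — never zero,
which would corrupt ratio maps — and forms `beta = FD_case / FD_baseline`
where both tiles are defined.

## Lacunarity

Gliding-box lacunarity per size is `lambda(eps) = (sigma/mu)^2`, the
squared coefficient of variation of filled-pixel counts over all window
positions (population SD, stride 1 by default; larger strides subsample
positions and slightly bias `sigma` for non-stationary patterns). The
aggregate `Lambda` is the unweighted mean over the box-size series, which
defaults to the same dyadic series the fractal module uses so the two
measures are comparable. The `(sigma/mu)^2` convention is fixed here; the
alternative `1 + (sigma/mu)^2` differs by a monotone shift, so every
comparative statement is convention-invariant. For disk-masked images the
windows are restricted to the square inscribed in the mask — gliding over
the empty corners would report the mask itself as heterogeneity.

Limits used as self-checks: translation-invariant patterns at the window
scale (all-filled images, a checkerboard sampled at its period) give
exactly zero; concentrating a fixed pixel budget raises `Lambda` sharply.

## Multifractal spectra

The estimator is the direct (normalized-measure) method rather than a
Legendre transform of `tau(q)`: numerically stable and free of concavity
artefacts. At each dyadic box size the box masses `P_i` are renormalized to
sum 1; empty boxes are dropped and their logarithms never evaluated. For
each exponent `q` (default grid −5…+5, step 0.25):

* `mu_i(q) = P_i^q / sum_j P_j^q`, accumulated in the log domain
  (`logsumexp`) so extreme `q` cannot overflow;
* `alpha(q)`, `f(q)` and `tau(q)` are slopes of `sum mu ln P`,
  `sum mu ln mu` and `ln sum P^q` against `ln eps`; `D_q = tau/(q-1)`,
  with the information-dimension limit (slope of `sum P ln P`) used inside
  a `|q-1| < 1e-9` window;
* per-`q` `R^2` of the scaling fit is reported, and values below 0.9 emit
  a warning — poor scaling means the spectrum should not be interpreted —
  but never an error.

Validation anchors: a uniform map returns `D_q = alpha = f = 2` for every
`q` to rounding; a depth-8 deterministic 2×2 cascade with weights `w`
reproduces `D_q = log2(sum w^q)/(1-q)` and
`alpha(q) = -sum w^q log2 w / sum w^q` to machine precision, because dyadic
boxes align with the construction. The tangency relations (`max f = D_0` at
`q=0`, `f = alpha = D_1` at `q=1`) hold by construction of the estimator.

Exact monotonicity of `D_q` in `q` is a property of the underlying measure;
on noisy finite-sample inputs the finite-scale regression can wobble by a
few 10⁻³, which the tests allow for. A degenerate measure (all mass in one
box at every scale) is reported as a point spectrum with dimension 0 and an
*undefined* (None) asymmetry.

On point-sampled concentration maps the finest-scale box masses are
dominated by Poisson counting noise, which reads as spurious
multifractality. The pipeline therefore applies a mild Gaussian
regularization (default sigma = 4 px at 512² resolution, i.e. ≈ 0.16 mm —
well below the millimetre scale of any planted structure) to concentration
maps before spectrum estimation. The estimator itself is validated on
exact, unsmoothed measures; the smoothing parameter is configurable and can
be set to 0.

## Directional profiles

Profiles scan the cloud in four coordinates — `x/X`, `y/Y` (bounding square
mapped to [0,1], y-up), `r/R`, and `theta` — with 50 equal-width bins by
default (36 sectors for the rose plot). Densities are
`(count/total × 100%) / bin area` in %/mm², with bin areas computed
analytically (circular-segment differences for strips, annuli, equal
sectors), so density × area sums to exactly 100% in every direction.
Near-degenerate edge strips (area below 1% of the mean bin area, possible
only at high bin counts) are merged inward before normalization. Spike
calls are local maxima of the 3-bin-smoothed density (circular smoothing
for the rose scan) exceeding a prominence multiple (default 2×) of the
global mean density `100%/disk area`. A planted hot spot is recovered in
all four directions within one bin, which triangulates its position from
two orthogonal scans.

## Replicate statistics and features

Metrics are aggregated over replicates (default five per model, mirroring
repeated breath tests with independently seeded inlet profiles) as mean ±
sample SD (n−1). Models are compared per metric with the Kruskal–Wallis
rank test, average ranks and the standard tie-correction divisor. Because
4 models × 5 replicates sits near the edge of the chi-squared
approximation's validity, an exact permutation p-value (full enumeration of
group assignments) is computed automatically for pooled N ≤ 12 and is then
preferred; the recursion carries only running rank sums, keeping the
N = 12, 4-group case (369 600 assignments) under a second. Stars follow
`* p<0.05`, `** p<0.01`. No multiple-testing correction is applied across
metrics; the output says so explicitly.

Feature vectors have a fixed 26-slot schema (whole-image and ROI `D_B` and
`Lambda`, spectrum widths/asymmetry and `D0/D1/D2`, per-direction profile
moments and spike calls); absent metrics occupy explicit null slots so the
schema never changes shape, which downstream classifiers require.

## The synthetic generator

The generator emulates the qualitative anatomy of real exhaled patterns —
a counter-rotating vortex pair (truncated Gaussians with a radially
decaying swirl displacement), a vertical central stripe, a uniform
asymmetric background, optional accumulation hot spots — as a seeded
mixture on the closed disk. Sampling is a pure function of the parameter
set and seed; replicate k uses seed base+k.

Disease perturbations are planted by construction:

* a **crescent void** is an annular sector in which sampled candidates are
  rejection-thinned with probability `d` (the depletion). Sampling
  continues until the requested count is reached, so the void holds the
  fraction `(1-d)·m/(1-d·m)` of particles in expectation (`m` = base
  mixture mass of the void); full depletion empties it exactly.
* the **severity series D0–D3** maps two constriction fractions per level
  to (i) void depletion and angular extent and (ii) two physical
  consequences of a choked branch: the hot spot it feeds fades
  (excess weight × (1−d)), and part of the bolus is trapped by impaction
  (exhaled count × (1 − 0.3·d)). These mechanisms were fixed at design
  time, validated over several independent seed bases, and give the
  expected clinical directions: whole-image and ROI fractal dimension fall,
  and the ROI spectrum narrows, monotonically with severity.

What the generator does **not** emulate: any actual fluid dynamics,
airway geometry, particle inertia or deposition physics; correlations
between pattern features that a real bronchial tree would induce; realistic
absolute metric values. Passing tests therefore demonstrate that the
*estimators* recover known structure and orderings planted in their input —
not that real diseased lungs produce these exact numbers.

Analytic fixtures complete the test bed: the Sierpinski carpet (box
dimension log 8/log 3 ≈ 1.8928, recovered within 0.05 by the default dyadic
scale policy and exactly on its aligned 3^k scales) and deterministic
multiplicative cascades with closed-form spectra.

## Problem sizes and defaults

Default study conditions: 512² rasters on a 20 mm disk, 10⁵ particles per
fingerprint (2×10⁵ for the severity series, which probes subtler
contrasts), 5 replicates per model, 50 bins per scan, q ∈ [−5, 5] step
0.25, upper-left ROI of ≈ 4×4 mm placed over the planted hot-spot region
and clear of the crescent's radial band. These sizes make every analysis
stage exact or sampling-noise-limited at the few-per-mil level while the
full cohort runs in seconds on a laptop.

## Known limitations

* Box counts and lacunarity use pixelized occupancy; at very low particle
  counts the occupancy grid undersamples the pattern and both measures
  drift toward their sparse-limit values.
* Lacunarity windows restricted to the inscribed square ignore the disk's
  outer ring; patterns whose heterogeneity lives mostly at the rim are
  under-characterized.
* The multifractal regression assumes power-law scaling across the dyadic
  range; the R² diagnostics flag, but cannot repair, inputs that do not
  scale.
* The exact permutation test enumerates only up to N = 12; beyond that the
  chi-squared approximation is used without a Monte-Carlo fallback.
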