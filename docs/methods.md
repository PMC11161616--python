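# Methods

## Scope and model

`fibrintda` quantifies the architecture of fibrin networks in fluorescence
micrographs by topological data analysis. A 2D grayscale image with
intensities in [0, 1] is treated as a filtration function on a cubical
complex and its sublevel-set persistent homology is computed in dimensions 0
(connected components) and 1 (holes). Each feature is a point (birth, death)
in the persistence diagram; its persistence `death − birth` measures how
distinct the feature is. Diagrams are summarized by count-calibrated noise
thresholds, Wasserstein distances, weighted silhouettes, and — on the
segmented image — the box-counting fractal dimension; paired experimental
conditions are compared metric-by-metric with two-sided paired t-tests at
the 5% level.

## Cubical persistence

**Construction.** V-construction: one vertex per pixel carrying its
intensity; edges join 4-neighbours; unit squares span 2×2 blocks; every cell
enters the filtration at the maximum of its vertices. The alternative
T-construction (pixels as top cells) is not used; the V-construction makes
the sublevel binary image at level *t* exactly the set of vertices with
value ≤ *t*, so diagram-derived Betti numbers can be cross-checked by flood
fill, which the test suite does.

**Algorithms.** Dimension 0 is a union-find sweep over vertices in
ascending value order with the elder rule. Dimension 1 uses duality: a hole
of the sublevel complex is a bounded component of its complement, so H1
pairs are obtained from superlevel 0-dimensional persistence on the dual
face graph (squares as nodes plus one outer node at +∞; primal edges as
dual edges weighted by their filtration value). A merge at edge weight *w*
killing a dual component born at square value *s* is a primal hole with
birth *w* and death *s*. Both kernels are numba-compiled. The test suite
verifies exact agreement with a naive full boundary-matrix reduction on
hundreds of random images including tied values.

**Conventions.** Zero-persistence pairs are diagonal points and never
reported; the diagram is then independent of tie-breaking among
equal-valued pixels. The full grid is connected, so there is exactly one
essential 0-class; its death is capped at 1.0 (the top of the normalized
intensity range) so it contributes finitely to Wasserstein functionals; a
flag drops it instead. There are no essential 1-classes in 2D. For
fluorescence images the pipeline default is `sublevel_inverted` (filter
1 − intensity) so that bright fibers are the early, component-forming
structures; the orientation is recorded in every report.

## Preprocessing

Z-stacks are averaged along z and min–max rescaled (a constant stack maps
to zeros). Enhancement applies, in fixed order: box (mean) filter,
order-statistic filter (median by default), global histogram equalization
(256 bins), and a self-guided guided filter (radius 4 px, eps 10⁻⁴) for
edge-preserving smoothing. The guided filter is the standard box-filter
formulation, written here because no installed dependency provides one.
Every knob is an explicit `EnhanceConfig` field; identity settings return
the input unchanged. Segmentation is global Otsu; feature counting uses
8-connected foreground and 4-connected background (the standard
complementary pair), and a background region touching the border is never a
hole. Exact parameters of the original acquisition environment are not
published; the defaults above are declared, not inferred.

## Noise threshold

Fine image resolution makes most diagram points noise. For each image the
segmented feature count *c* (components for dim 0, holes for dim 1) places
a cutoff midway between the *c*-th and (*c*+1)-th largest persistence, so
keeping points with persistence ≥ cutoff retains exactly *c* features;
boundary cases: *c* = diagram size keeps everything (half the smallest
persistence), *c* = 0 sits just above the maximum, *c* beyond the diagram
size contributes 0 with a warning. The group threshold is the arithmetic
mean over all images of a study (both arms jointly, `grouped` mode) and is
applied unchanged to every image; `per_image` and `off` modes are
available and recorded in the report.

## Distances and summaries

The p-th Wasserstein distance between diagrams uses the infinity-norm
ground cost with the diagonal available as a matching partner (cost
persistence/2); it is solved exactly as a square assignment problem via the
Hungarian algorithm on the augmented cost matrix (diagonal–diagonal pairs
cost 0). Default p = 1, configurable; p is not fixed by the method itself.
The distance from the diagonal-only diagram has the closed form
(Σ (persistence/2)^p)^(1/p) and is cross-checked against the assignment
route in tests. By default the thresholded (distinct-point) diagrams feed
the Wasserstein computations; raw mode is available and logged. Weighted
silhouettes are weighted averages of triangle functions peaking at each
point's midlife, with weights persistence^power (default power 1), sampled
on a uniform 512-point grid over [0, 1].

## Fractal dimension

Box counting over dyadic box sizes ε ∈ {2, 4, …, ≤ min(h, w)/2}; the
dimension is the least-squares slope of log N(ε) versus log(1/ε). Two
scales are deliberately excluded: the full-image box (N = 1 always, a pure
leverage point) and the single-pixel box ε = 1. At the pixel scale any
rasterized set looks locally 2-dimensional and finite-depth fractals
flatten; including ε = 1 biases the depth-5 Sierpinski carpet estimate to
1.84 (true value log 8/log 3 ≈ 1.8928), while the chosen schedule gives
1.869 at 243² and calibrates the filled square (2.000) and a line segment
(0.95) correctly. Note the fit is exact for plane-filling frames only when
the image side is divisible by the box sizes (powers of two in practice).

## Synthetic fibrin fields

The generator emulates what the pipeline consumes: bright curvilinear
fibers on dark background, meshed into a connected network with enclosed
voids, plus isolated bright fragments.

* Fibers are cubic Bézier curves with endpoints on the image border
  (chord ≥ 0.4 × side), perpendicular control-point jitter scaled by
  `waviness`, rasterized at a per-fiber width drawn from
  N(`fiber_thickness`, `thickness_spread`) and floored at 1 px.
  Border-to-border fibers intersect, which is what creates holes — no
  polymerization kinetics are modelled.
* Isolated blobs (disks) model disconnected fragments and carry most of the
  component count; they are placed clear of the fiber mesh (clearance
  covers fibers rendered up to twice their nominal width) and of each
  other, falling back to a random spot on crowded canvases.
* The clean binary scene is shaded background/fiber level, blurred with a
  Gaussian PSF (`psf_sigma`), and corrupted with additive Gaussian noise
  clipped to [0, 1]. The noiseless mask is returned alongside the image, so
  ground-truth component/hole counts are available to every test.

Paired cohorts draw each subject's layout once from a subject-level RNG
stream shared by both arms; the treatment only rescales how many
fibers/blobs are rendered (`component_factor`) and how wide
(`thickness_factor`), and per-arm noise comes from separate streams. A null
effect therefore differs between arms only by noise — exactly the paired
design the t-test assumes. Condition archetypes: `dilution_like`
(component_factor 0.5), `inhibition_like` (component_factor 0.7, thickness
factor 1.8), `baseline` (unit factors).

**Scales.** Default parameters describe a 256 px field (60 fibers, 40
fragments, width 2.5 px); `FiberFieldParams.scaled_to(size)` rescales
fiber/fragment counts linearly with the side and width with resolution.
Replicate-level simulations (power and type-I error, 200 and 1000
replicates of 11-pair studies) use the fixed `SMALL_STUDY` conditions: a
64 px field with 8 fibers, 16 fragments, width 1.5 px, noise σ = 0.04, PSF
σ = 0.8 — dense enough to mesh with holes while fragments carry the
component signal, and matching segmented-fibrin feature densities per unit
area at desk scale. Replicate studies use the lightweight path (raw
generated image → diagram → count-calibrated threshold from the
ground-truth mask → dim-0 distance from diagonal); the full
enhancement/segmentation path is exercised by the pipeline and CLI tests.

**What the generator does not emulate.** Real micrographs have spatially
varying background, anisotropic PSFs, fiber branching (rather than
crossing), intensity variation along fibers, depth attenuation in z, and
correlated (photon) noise. Passing tests therefore show the pipeline's
internal correctness and its sensitivity to controlled architectural
contrasts, not segmentation robustness on real microscopy data. In
particular, Otsu segmentation of background-dominated noisy images yields
spurious small fragments, so segmented component counts can move opposite
to the ground truth even while the diagram-based metrics track it — one
motivation for the count-calibrated threshold operating on the grayscale
diagram rather than on segmentation alone.

## Statistics

Two-sided paired t-tests with t-based 95% CIs throughout; no
multiple-testing correction across metric families (noted in report
footers). Sign convention: `mean_difference = mean(treated) −
mean(baseline)`, so component-depleting interventions give negative
estimates for diagram mass. Zero-variance differences are flagged
degenerate with undefined p. Group summaries are means with t-based CIs.

## Determinism and numerics

Identical parameters and seeds give bit-identical images (RNG streams are
spawned from `numpy.random.SeedSequence`), and CLI reports carry no
timestamps and use fixed float formatting, so reruns are byte-identical.
Cell-order ties in the filtration are broken by lexicographic pixel index;
the reported diagram is provably independent of that choice. Wasserstein
assignment is exact (no approximation); costs are formed in double
precision. Thresholding uses `persistence ≥ cutoff`, and the calibrated
cutoff reproduces the target count exactly whenever persistences are
distinct (tested).

## Known limitations

* 2D only: z-stacks are averaged, no 3D cubical homology.
* No bottleneck distance, landscapes, or kernel summaries.
* Box-counting estimates carry finite-size bias for sets that misalign
  with dyadic grids; the reported values are slopes over the stated
  schedule, not asymptotic dimensions.
* Segmented feature counts inherit Otsu's sensitivity to background noise
  (see above); on real data a cleaning step may be warranted before
  counting, which this package deliberately does not impose.
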