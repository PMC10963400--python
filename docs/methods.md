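# Methods

This note records the model, the numerical choices and the open design
decisions behind `eeguq`, and what its synthetic head model does and
does not establish about real heads.

## Volume conductor and forward solution

The head is a concentric five-shell sphere — white matter, gray matter,
CSF, skull, skin, with default outer radii 67 / 78 / 80 / 86 / 92 mm —
and piecewise-constant isotropic conductivity per shell. The radii are
package defaults (config-overridable), chosen so that gray-matter
sources span depths of roughly 2.5–13 mm below the inner skull surface
(radius 80 mm) and deep sources reach 45 mm, which gives depth profiles
a comparable axis to realistic cortical models where gyral crowns sit a
few mm and the insula or the longitudinal fissure several cm below the
inner skull.

The quasi-static potential of a current dipole separates in spherical
harmonics after rotating the source onto the polar axis and splitting
the moment into a radial part (zonal harmonics, P_n) and a tangential
part (order-one harmonics, sinθ·P_n′·cosφ). Within each shell the
degree-n radial factor is A·rⁿ + B·r^−(n+1); the dipole enters through
the known infinite-medium expansion in its own shell, and the
coefficients solve a linear system per degree: continuity of potential
and of radial current σ∂V/∂r at each interface, regularity at the
origin, zero current through the scalp. Numerically:

* basis functions are scaled per layer to (r/R_l)ⁿ and (R_l/r)^(n+1)
  so every matrix entry stays within a few orders of magnitude of unity
  up to degree 200 (unscaled monomials under/overflow near degree 40);
* all degrees are assembled and solved in batched 9×9 systems;
* the series is truncated at the model's `series_truncation` (default
  200) with early stopping once a 20-degree chunk contributes less than
  `truncation_tol` (default 1e-8) of the running maximum. The default
  is set by the *shallowest* default sources: at depth 2.5 mm the term
  ratio is b/R ≈ 0.84, so degree 80 would leave a ~1e-6 tail while 200
  reaches ~1e-9. Non-convergence raises a warning carrying the tail
  estimate, never a silent result.

Every emitted potential vector is average-referenced. No reference
electrode is singled out anywhere; RDM, MAG and GoF are all computed on
average-referenced vectors (they are reference-dependent quantities, so
one convention is fixed package-wide).

Correctness anchors: the equal-conductivity limit reproduces an
independently implemented closed-form homogeneous-sphere dipole
potential to better than 1e-6 relative (measured ~2e-10); a five-shell
model with tissues sharing conductivities equals the equivalent
two-shell model to machine precision; potentials are linear in the
moment, scale as 1/σ under global conductivity scaling, and are
invariant under joint rotation of source, moment and electrodes.

One physical caveat: the potential-norm-vs-depth decay is strictly
monotone in a homogeneous sphere and within each layer, but *not*
across the GM→WM interface at standard conductivities — the local drop
from 330 to 140 mS/m boosts the dipole's potential. This is physics,
not a solver artifact, and the tests assert decay accordingly.

## Priors and units

Uniform priors per tissue, in mS/m: skin (280, 870, standard 430),
skull (1.6, 33, 10), GM (220, 670, 330), WM (90, 290, 140); CSF is
fixed at 1790 (its inter-individual variation is negligible). Configs
state conductivities in mS/m; the solver converts to S/m internally.
Positions are mm throughout. RDM, MAG and GoF are unit-invariant, so
only consistency matters.

## Montage and source grids

Electrodes are a deterministic Fibonacci lattice restricted to a polar
cap (default 80 electrodes, 110° half-angle), a synthetic stand-in for
an extended 10-10 layout. Source grids are Fibonacci lattices on
spheres of radius (inner skull − depth), one per requested depth, with
radial, tangential (seed-deterministic direction in the tangent plane)
or alternating orientations.

The **dual grid** used by all inverse scans is the primary lattice
pushed `dual_offset` (default 1 mm) deeper and rotated about z by
`dual_offset/radius`, so each dual point sits 1–1.4 mm from its primary
partner and no point coincides. This emulates the statistical structure
of scanning on the dual mesh of a triangulated cortex, where dual
vertices sit a fraction of a millimetre from primary ones: data are
never inverted on their own discretization, and the mean primary→dual
nearest-neighbour distance (~1.3 mm for the defaults, recorded on the
returned grids together with the per-point distances and their max) is
the unavoidable localization floor. A full lattice rotation was
rejected: at desk-scale point counts it places dual points tens of mm
from primary ones, which resembles no cortical dual mesh and makes the
discretization floor meaningless. With the chosen construction,
noise-free matched-conductivity scans select the nearest dual point for
every tested source, so the worst-case error equals the grid's reported
max nearest-neighbour spacing.

## Polynomial-chaos surrogate

Each leadfield entry (electrode × moment axis × source) is expanded in
a total-degree Legendre basis over the four uncertain conductivities,
each mapped affinely from its prior interval onto [−1, 1] (Legendre
polynomials are the orthogonal family for uniform priors). The fit is
plain least squares on a scrambled-Halton sample of the prior box with
2× oversampling of the basis size; the design's condition number is
checked (rejection above 1e8 with advice), and per-source relative
residuals are stored as diagnostics. RDM and MAG are always computed
*after* evaluating the surrogate — the error measures are nonlinear in
σ and are never expanded directly.

**Order.** The default total degree is 8 (495 basis terms, 990 fit
solves). This is dictated by the skull prior: its interval spans a
factor of ~20 and the leadfield is strongly nonlinear in σ_skull, so
measured held-out errors fall from RDM ≈ 0.15/0.055/0.011 at orders
2/4/6 to ≈ 0.002 at order 8 — the first order comfortably below the 1%
RDM and MAG accuracy the surrogate must have to stand in for the
forward solver in the Sobol and sweep analyses. (A log-transformed
skull coordinate was tried and bought nothing at order 4.) Polynomial
targets of degree ≤ order are reproduced to machine precision, and
held-out error decreases monotonically with order on the sphere map.

Surrogates persist to a single compressed `.npz` container with the fit
configuration echoed as metadata.

## Sobol indices

Two independent N×4 prior-sample matrices A and B are drawn; for a
subset u of tissues, the swapped matrix A_B^(u) takes the u columns
row-wise from B. The outputs y = f(B) and y_u = f(A_B^(u)) share
exactly the inputs in u, and the Janon estimator of the closed index of
u is

    Ŝ = [ mean(y·y_u) − m² ] / [ mean((y²+y_u²)/2) − m² ],
    m = mean((y+y_u)/2),

which has optimal asymptotic variance among pick-freeze estimators.
First-order indices are closed singletons; the pure skin–skull
interaction is Ŝ_{ij}^closed − Ŝᵢ − Ŝⱼ (other pairs on request);
the total effect is 1 − Ŝ^closed of the complement. The per-source
output is the RDM (or MAG) of the surrogate-evaluated potentials of the
source's oriented dipole against the standard-conductivity reference
computed with the analytic solver.

Monte-Carlo uncertainty is a paired bootstrap over rows (default 200
resamples). Raw estimates may fall slightly outside [0, 1]; raw and
clamped values are both reported (transparency over cosmetics), with a
degeneracy flag for constant outputs. Defaults: 50,000 samples per
parameter for full runs; the test and acceptance suites use 4,096
(desk-scale; estimator correctness is checked separately against
analytic decompositions of the additive, centered-product and Ishigami
functions, where errors scale as N^(−1/2)).

## Goal-function scan and conductivity sweep

GoF = 1 − (‖u − LᵢLᵢ⁺u‖/‖u‖)² with the pseudoinverse truncated at a
relative singular-value tolerance of 1e-10; free orientation only.
Ties at the argmax break to the lowest grid index (determinism). The
sweep draws K (default 1,000) conductivity sets uniformly from the
priors, simulates the source's measurement per draw (surrogate by
default; a direct analytic path is available and tested to pick
identical winners), scans against the standard-conductivity dual-grid
leadfield, and records reconstruction, localization error, depth
change, depth-change ratio (|Δdepth|/error, defined 0 at exact hits
below 1e-9 mm; in the sphere it always lies in [0, 1]), per-draw RDM
and winning GoF. No sensor noise is added — the sweep isolates the
conductivity effect. Scan grids for sweeps should span a depth ladder
(default 2.5–45 mm in 2.5 mm steps) so depth shifts are resolvable.

## Correlation and depth-profile analyses

Per source: (i) Pearson correlation (Spearman behind a flag) of
|σᵢ − center| with the distance of each reconstruction from its cloud
centroid — the absolute deviation because scatter is sign-blind;
(ii) correlation of σᵢ with reconstructed depth; (iii) correlation of
per-draw RDM with localization error. The deviation center defaults to
the prior mean (σ_min + σ_max)/2, with (σ_max − σ_min)/2 selectable as
an alternative centering that appears in the literature. Zero-variance
inputs yield r = 0 with an explicit `undefined` flag.

Depth profiles report per-bin count, median and quartiles (linear
interpolation between order statistics — the numpy default rule), with
2.5 mm bins over 0–45 mm by default and empty bins emitted with count
0 and missing statistics.

## Pipeline, determinism and problem sizes

One global seed is split via `numpy.random.SeedSequence` into per-stage
substreams; every artifact is a TSV with a provenance header (package
version, stage, config hash, seed), and identical (config, seed) runs
are bitwise identical. The CLI (`eeguq model|surrogate|sobol|sweep|
analyze|all`) is a thin wrapper over the library; stages consume each
other's artifacts by path and refuse to run with a named hint when an
upstream product is missing.

The test and acceptance suites run the full machinery at desk scale as
the package's own study sizes: 80 electrodes; a 20-source grid spanning
depths 2.5–45 mm for forward-oracle and surrogate accuracy; 3 depths ×
16 sources for the matched-localization check; 8 tangential sources at
25 mm, N = 4,096 Sobol samples and K = 500 sweep draws (seeds 1 and 2)
for the qualitative findings. At these sizes the skull's median
first-order RDM Sobol index is ≈ 0.57–0.59 with total ≈ 0.9, the
skull-conductivity-vs-depth correlation is ≈ −0.9 and skin ≈ +0.3, and
the skull deviation-vs-scatter correlation ≈ 0.65–0.70.

## What the synthetic model does and does not show

The sphere reproduces the *mechanisms* — shell-wise current shunting,
the skull bottleneck, the skin–skull interaction, depth-directed
mislocalization — and its analytic solution makes every number
independently checkable. It has no gyri or sulci, no anisotropic white
matter, no skull compacta/spongiosa distinction, no realistic electrode
layout, and orientation classes (radial/tangential) are idealized
rather than anatomy-driven. Passing tests therefore establish the
correctness of the estimators and the qualitative direction and rough
magnitude of conductivity effects in layered conductors; they do not
calibrate absolute localization errors for any real head. Extended
sources, other inverse methods (MNE, beamformers, LORETA) and
conductivity calibration are out of scope.
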