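# Methods

## The model of developmental noise

Both simulators treat developmental noise as randomness in the *initial*
morphogen concentrations only: the dynamics, boundary conditions and stopping
rule are deterministic. This is a deliberately high-level noise model — it
stands in for the many microscopic sources (intrinsic transcriptional noise,
cell-to-cell signaling noise) that a Gillespie or SDE treatment would resolve,
none of which are modeled here. A (parameter set, seed) pair therefore
reproduces a pattern bit-for-bit, and a *phenotype cloud* — the set of
phenotypes produced by one parameter set across seeds — is a well-defined,
reproducible Monte-Carlo object.

Both models are stopped at a fixed point in time rather than run to a steady
state: the patterns of interest are intermediate-time patterns whose pigmented
regions are discrete but not yet fully circular.

## Linear Turing model

    du/dt = f_u u − f_v v + D ∇²u
    dv/dt = g_u u − g_v v +   ∇²v

on an N×N lattice (default N = 200, spacing dx = 1) with periodic boundaries,
initial u, v ~ Uniform(0, 1) i.i.d. per cell, forward-Euler updates with the
5-point Laplacian, dt = 0.05 (a factor ≈2.5 below the explicit stability bound
dx²/(4·max(D, 1))), stopped after n_steps = 200 000 updates. Construction
validates the diffusion-driven-instability conditions

    f_u − g_v < 0,   f_v g_u − f_u g_v > 0,   f_u − D g_v > 0,
    (f_u − D g_v)² > 4 D (f_v g_u − f_u g_v).

**Fixed kinetic constants.** Only f_u (and the binarization threshold) are
varied in scans; the remaining constants default to f_v = g_u = g_v = 1 and
D = 0.25, chosen so the Turing conditions hold over the whole scanned range
f_u ∈ [0.80, 0.84]. All are configurable. With these defaults the fastest
growing wavenumber gives a pattern wavelength of ≈6.5 lattice cells,
confirmed against the measured Fourier wavelength of simulated fields
(agreement within ±25% is a tested invariant).

**Exact spectral propagation.** Because the scheme is linear with constant
coefficients, each periodic Fourier mode evolves independently under a 2×2
one-step matrix A(k) = I + dt·J(k). The default integration path computes
A(k)^n_steps by binary exponentiation (vectorized over all modes, with global
rescaling against overflow) and applies it in Fourier space — the *identical*
linear map as n_steps literal Euler updates, at O(N² log n_steps) cost. A
literal Euler path (`method="euler"`) is retained; the two agree to ≤1e−10,
and single-mode runs agree with an independent scalar 2×2 iteration of the
same mode to the same tolerance (relative to the mode's largest amplitude —
for modes that decay by many orders of magnitude the final amplitude is below
the roundoff floor of the initial one, so normalizing by it would overstate
the error). The speedup is what makes 1000-member clouds and grid scans cheap.

**Unbounded growth and rescaling.** A linear model has no saturating
nonlinearity, so unstable modes grow without bound; over 200 000 steps the
amplitude overflows float64. Fields are rescaled by a common positive factor
(its log recorded in `MorphogenField.log_amplitude`). Every downstream
statistic is invariant under positive rescaling, including binarization.

## FitzHugh-Nagumo model

    du/dt = −(u − R)(u² − 1) − ρ(v − u) + D ∇²u
    dv/dt = −(v − u) + ∇²v

with R = 0.047 (the reference activator concentration), D = 0.0194, on a
no-flux square of side L = 20 discretized 200×200 (dx = 0.1), integrated over
t ∈ [0, 20] from the homogeneous steady state u = v = −1 perturbed by i.i.d.
Uniform(−0.25, +0.25) noise at every grid point. The perturbation is applied
to both fields by default (`perturb_target="u"` gives the activator-only
variant). The kinetics have three homogeneous steady states u = v ∈
{−1, R, +1}; the quadratic term (absent when R = 0) is what stabilizes spots
over stripes, and the package's stochastic test confirms that R = 0 runs have
higher mean spot eccentricity than R = 0.047 runs at matched ρ.

**Integrator.** Method of lines with the 5-point no-flux Laplacian, advanced
by Strang splitting: the linear diffusion terms are applied exactly in the
DCT-II basis (cosines diagonalize the mirrored-ghost-cell Laplacian), and the
pointwise reaction terms by Heun's method, dt = 0.02. An adaptive RK45
method-of-lines integrator at these grids is stability-limited by the
inhibitor diffusion (thousands of steps regardless of accuracy) and orders of
magnitude slower; the splitting integrator is cross-validated against an RK45
reference on a small grid (max deviation < 0.02 on O(1) fields) and keeps the
homogeneous steady states exact fixed points, which the fixed-point tests
exercise at t_end = 20. Splitting error is O(dt²) per step and immaterial at
the scale of the pattern statistics.

## Binarization

A pixel is pigmented iff s ≥ T̂·mean(s), where T̂ is the threshold relative to
the mean of a positively shifted activator s:

- **FHN:** s = u + 1, anchoring the background steady state −1 at zero.
- **Linear model:** s = u − min(u). The linear kinetics damp the uniform
  (k = 0) mode at rate |f_u − g_v|/2 while patterned modes grow, so at the
  measurement time the raw field oscillates about zero and its mean carries no
  information; a mean-relative threshold on the raw field would degenerate to
  FA ≈ 0.5 for every T̂. Anchoring at the field minimum restores the intended
  semantics: T̂ ∈ [1.1, 1.7] selects the upper morphogen range and yields
  minority-pigmented spot patterns (measured FA ≈ 0.38 → 0.01 across that
  range at the defaults).

Both shifts, and the unshifted rule, are selectable (`shift=` argument).
Since high-level excursion sets of a smooth random field are isolated blobs,
raising T̂ moves patterns from labyrinthine toward discrete, rounder spots.

## Photographic pipeline

Photographs are contrast-enhanced by tile-based adaptive histogram
equalization (CLAHE, default 8×8 tiles, clip limit 0.01), then thresholded at
T = μ − σ computed over the region of interest (spots are dark: pigmented
means intensity ≤ T). Cleanup fills interior holes first (4-connected
background), then removes 8-connected components smaller than 10 pixels
(strictly smaller by default; the comparator is configurable since the
boundary case is conventionally ambiguous). Cleanup is idempotent.
Threshold-sensitivity envelopes re-run the pipeline at μ − σ ± δσ for
δ ∈ {0.25, 0.1} by default and report per-statistic (min, max) intervals.

Region selection takes the largest disk centered at the silhouette centroid
(radius = Euclidean distance transform at the centroid). For comparing
simulated to observed patterns, `cut_scaled_disk` first fixes the physical
pixel size so the simulated mean spot diameter matches the observed one, then
cuts a disk of the observed radius at a seeded random position — matching
both the statistics and the *number of spots sampled*, which controls how
broad the resulting clouds are.

**Simulated patterns are not hole-filled** when measured into clouds: only
stray components < 10 px are removed. Ring-shaped (annular) spots are a
genuine output of the FHN model near tuned thresholds, not threshold noise,
and hole-filling would erase them.

## Phenotype-space machinery

Phenotypes are [FA, EE] with unweighted Euclidean distance (both coordinates
dimensionless in [0, 1]; configurable weights are provided but not default).
The r% cloud takes k = floor(r·n/100) members closest to the componentwise
mean center, ties broken by simulation index; containment uses ≤ the k-th
distance. floor-plus-≤ guarantees the exact cardinality |r% cloud| =
floor(r·n/100) (a tested invariant), at the cost of treating boundary ties as
inside. Nesting in r holds by construction when clouds are shared.

Cloud generation derives child seeds from the master seed by a counter-based
`SeedSequence` spawn (recorded in run manifests), excludes spotless runs with
a logged count, and aborts if more than 10% of runs are spotless (the
parameter set is outside the patterning regime). Neutral-region scans,
grid-phenotype maps and relatedness scoring share clouds through a cache
keyed by (LALI-type, n, domain spec, master seed), so one grid's simulations
serve all phenotypes. The representative LALI-type of a neutral region is the
member grid point whose cloud center is nearest the phenotype.

The relatedness score between phenotypes i and j counts containment outcomes
{i ∈ 95% cloud of j's type, j ∈ 95% cloud of i's type} × {linear, FHN}: an
integer 0–4, symmetric by construction.

## Problem sizes

Full-scale defaults follow the reference configuration (200×200 grids, 200K
steps / t ∈ [0, 20], 1000-member showcase clouds). The test suite and the
bundled examples run reduced configurations chosen so that patterns still
contain dozens of spots: the linear model at 64×64 with 20K steps (same
kinetics, same wavelength of ≈6.5 cells, hence ≈100 spots) and the FHN model
at 96×96 with L = 9.6 (keeping the reference resolution dx = 0.1 so spot size
in pixels is unchanged) or smaller. Monte-Carlo checks state their n
explicitly; the 1000-member cardinality check runs the linear model, where
the spectral propagator makes the cloud a few seconds' work.

## Synthetic fixtures: what they do and do not show

Fixture images (hard-edged ellipses on jittered hexagonal lattices, binary
stripes, linear illumination ramps, Gaussian pixel noise, convex silhouettes)
carry exact ground truth, so they bound measurement error tightly: FA is
exact by pixel counting, EE within 0.02 of the axis-ratio formula, both
wavelength estimators within 10% of the construction period. They do not
reproduce the photographic nuisances of real specimens — vignetting,
specularity, pigment gradation, irregular spot contours — so passing these
tests validates the measurement code, not robustness to arbitrary field
photographs. Anti-aliasing is off by default precisely so the counting
oracles are exact; soft-edged variants exist for robustness tests.

## Known limitations

- The linear model's fixed kinetic constants are package defaults, not
  empirical values; parameter coordinates of published example patterns are
  therefore comparable only qualitatively.
- The FHN threshold's published absolute form is ambiguous; the package uses
  the relative-to-mean convention uniformly across both models.
- Silhouette delineation of real specimens is out of scope (masks are taken
  as input); so are color/hue analysis and 3-D domains.
- Neutral regions are scanned over 2-D parameter slices; the data model
  stores higher-dimensional fixed records but scans do not exercise them.
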