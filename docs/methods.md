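# Methods

## The experiment being modeled

A live-cell PAINT acquisition images transient binding of a fluorescent
imager peptide to a tagged protein of interest under TIRF illumination.
Each binding event produces a diffraction-limited spot lasting one to a few
50 ms frames; localizing every spot and accumulating positions over
100–200 s yields a super-resolution reconstruction. Two target geometries
are emulated: nuclear histone clusters ("clutches" — tight, roughly
isotropic patches of binding sites ~50 nm in radius) and motile
mitochondria-like tubes that translate on the tens-of-seconds timescale.

## Simulation model

**Scenes.** Clutch scenes place cluster centers uniformly over the field of
view (inset by a 4σ margin) and scatter `sites_per_cluster` sites as an
isotropic Gaussian of sd `cluster_sigma` around each center; stragglers are
clipped to the boundary. Tube scenes draw a natural cubic spline through
4–8 uniform control points per tube and scatter sites along it with
isotropic transverse sd `tube_sigma`. Motion is rigid per-structure: each
tube receives a constant-velocity displacement of magnitude `drift_speed`
in a random direction; there is no fission/fusion or shape change. All
randomness derives from `numpy.random.default_rng(seed)`.

**Kinetics.** Per site, binding events arrive as a homogeneous Poisson
process of rate `site_on_rate` over the acquisition, with i.i.d.
exponential bound durations of mean `mean_residence`. The defaults
(`site_on_rate` = 0.02 s⁻¹, `mean_residence` = 0.1 s, 50 ms exposure,
duration up to 200 s = 4000 frames) are plausible values for a reversible
coiled-coil imager pair, chosen once so that a nucleus-scale scene of a few
thousand sites produces a localization rate in the low hundreds per second;
they are not measured constants.

**Direct mode.** Each event contributes one localization per frame whose
exposure it overlaps by at least 50% (configurable), at the
motion-displaced site position plus isotropic Gaussian error with sd drawn
from the precision model (default: constant 20 nm, consistent with a
< 30 nm-filtered acquisition). With this rounding-to-nearest counting the
expected retained frames per event of duration d ≥ e/2 is exactly d/e
(e = exposure), so the expected localization rate for exponential durations
is `n_sites · rate · (τ + e/2) · exp(−e/(2τ)) / e`; with no overlap
threshold it is the familiar `n_sites · rate · (τ/e + 1)`. Both formulas
are exposed and simulation-verified.

**Image mode.** Bound emitters deposit `photon_rate × bound-time` expected
photons as a pixel-integrated (erf) Gaussian of sd `psf_sigma` (default
150 nm on 100 nm pixels), plus a uniform background (default
10 photons/px/frame); every pixel is Poisson-sampled into a uint16 frame.
No photobleaching, fluorophore blinking, diffusing-imager background, or
3D PSF is modeled.

## Localization

Detection band-passes each frame with a difference of Gaussians (1.0 and
2.5 px) and takes strict local maxima above `5 × robust sd` (median
absolute deviation of the filtered image). Fitting is least-squares on a
7×7 window with the sampled symmetric Gaussian `b + A·exp(−r²/2s²)`; fits
are rejected on non-convergence, vanishing amplitude, or fitted width
outside [0.5, 3]× the PSF prior. Photon count is N = 2πAs² (pixel units);
the background sd entering the precision formula is the fit-residual sd.
Coordinates follow the ThunderSTORM convention: origin at the outer corner
of pixel (0,0), pixel centers at (index + 0.5)·pixel_size, frames 1-based.
Duplicate fits within one fitted sigma in a frame keep the brighter.
Monte-Carlo validation shows the per-axis position RMSE agrees with the
Thompson estimate to better than 10% at 1000 photons over 10 background.
The precision filter is strict (<), default 30 nm.

## Merging and residence times

Greedy frame-ordered linking: within each frame, records join the nearest
open chain whose running-mean position lies within the link radius
(default 20 nm) and whose last member is at most `max_off_frames + 1`
frames back (default 1 off-frame, read literally as one fully dark frame);
ties go to the earlier-created chain, each chain absorbs at most one record
per frame, and every record joins exactly one chain.

Chain length in frames for an exponential duration at random frame phase is
`floor(r) + Bernoulli(frac(r))` with r = duration/exposure, so the
chain-length distribution decays exactly geometrically with ratio
`exp(−e/τ)` for chains of ≥ 2 frames. The mean-residence estimator
therefore censors single-frame chains (contaminated by sub-exposure events
and split chains) and applies the shifted-geometric MLE; it recovers a
100 ms simulated mean within a few percent at ~2000 chains. Note that
merging requires per-frame positional scatter comfortably below the link
radius: at 20 nm precision a 20 nm radius splits chains, so kinetic
analyses use bright, well-localized sites (5 nm precision condition).

## Rendering

Histogram rendering bins positions at 10 nm/px (≥5× finer than the
expected resolution); mass equals the rendered record count exactly. Time
windows are half-open [t0, t1), so non-overlapping windows partition the
acquisition. Gaussian rendering deposits per-record unit-mass kernels of
sd = uncertainty, normalized by the untruncated kernel so edge clipping
loses mass (≤1% interior). The moving-window stack defaults to a 25 s
window advanced in 0.5 s steps.

## Fourier ring correlation

Records are randomly split into equal halves; each half is rendered on the
common grid, zero-padded to a square power of two, and correlated per
integer-radius Fourier ring (radii rounded to nearest integer cover every
pixel up to Nyquist exactly once). The curve is smoothed with a 3-ring
moving average before the fixed-threshold (1/7) crossing is found by linear
interpolation; no crossing yields an undefined resolution rather than an
error. Integration-time analysis samples frame subsets without replacement
(scattered, not contiguous — both interpretations exist; scattered is the
default) with n = 3 replicates per time. A caveat: two *independent* point
sets rendered on a grid that is then zero-padded share the padding box
edge, which produces genuine low-frequency correlation; decorrelation
checks therefore use fields of view that fill the padded grid.

## Clustering and density

DBSCAN is delegated to scikit-learn with labels relabeled in order of first
appearance; defaults eps = 0.3 and min_pts = 5 (self included). The eps
value is interpreted in µm: pipeline coordinates are nm and are divided by
1000 before clustering, making eps 300 nm — the only unit reading
compatible with ~50 nm clusters (0.3 nm would cluster nothing, 0.3 px is
render-scale dependent). Per-cluster morphology: convex-hull area
(assumption-free, oracle-testable), axis lengths 4√(covariance
eigenvalues), and eccentricity reported primarily as the minor/major axis
ratio in [0, 1] (a printed eccentricity of ~0.66 cannot be a major/minor
ratio, which is ≥ 1); the standard √(1 − ratio²) form is also emitted.
Clusters with < 3 members or a degenerate covariance get area 0 and NaN
eccentricity. NN analysis computes exact nearest-neighbor distances
(k-d tree, contract-identical to brute force), a per-cluster mean NN
distance D_c, per-member neighbor counts within `radius_scale × D_c` (self
excluded, noise points undefined), and a highlight mask at
NN ≤ 5 × D_c.

## Problem sizes and what the tests show

The validation suite runs on synthetic acquisitions of 10⁴–10⁵
localizations (nucleus-scale morphology: 1000 clusters × 6 sites over a
200 µm field, 100 s; kinetics: 500 isolated sites, 100 s; resolution: 300
clusters × 20 sites over 10 µm, 200 s, ~1.2 × 10⁵ localizations). These
sizes make every stage's statistical checks well-powered while keeping the
full suite under a minute of compute for most modules. Because the
generator omits drift, bleaching, unbound-imager background and structured
autofluorescence, passing tests demonstrate correctness of the analysis
chain under the stated model — not robustness to those real-data artifacts.

## Known limitations

* Single-emitter fitting only; overlapping emitters in one diffraction
  spot produce rejected or biased fits.
* No drift correction; simulated scenes are drift-free except the explicit
  tube motion model.
* The merge step's running-mean anchor and one-per-frame absorption are a
  declared convention; other linkers (intensity-weighted, motion-aware)
  would differ on ambiguous gaps.
* FRC on histogram renders slightly depends on the render bin; 10 nm/px
  keeps the threshold crossing far from Nyquist in the regimes tested.
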