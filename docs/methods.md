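# Methods

## Imaging model

A fluorescent volume `g(x, z) ≥ 0` is imaged by a microscope (numerical
aperture `NA`, magnification `M`, emission wavelength `λ`) with a microlens
array (pitch `d`, F-number matched to the image-side NA) at the native image
plane and the sensor at the lenslets' back focal plane.  Realigning the raw
sensor image by lenslet position `x` and intra-lenslet offset `u` yields
phase-space views `Y(x, u) = L(x + u)`, one sample per lenslet per view.
Because the phase-space PSF is spatially invariant per angle under
lenslet-pitch sampling, the acquisition is a set of depth-summed 2D
convolutions

    Y(x, u) = Σ_z g(·, z) * H(·, z, u),     Ŷ(x, u) ~ Pois(Y(x, u)),

with shot noise the only noise source modelled.  Background is assumed
removed; camera read noise, sCMOS fixed-pattern noise and scattering are out
of scope.

## Phase-space PSF

`H` is generated by simulating the sensor image of an on-axis point source at
each depth and realigning it — algebraically equivalent to the band-integral
definition of the phase-space PSF, and it reuses the tested realignment code.

**Focal field.**  The complex field at the native image plane is the scalar
Debye integral of an aplanatic circular-pupil objective,

    U(r, z) = ∫₀^α √(cos θ) sin θ · J₀(k n r sin θ) · e^{i k n z cos θ} dθ,

with `k = 2π/λ`, `α = asin(NA/n)` and object-space coordinates (image
coordinates divided by `M`).  The `√cos θ` apodization is the aplanatic
(sine-condition) choice; at NA 0.5 the scalar approximation is adequate and
vectorial corrections are omitted.  The depth-dependent constant phase is
dropped — it cancels in the squared modulus.  Gauss–Legendre quadrature over
the aperture angle with the node count scaled to the radial and axial
oscillation budget (64 + 8 per oscillation cycle, capped at 4000) keeps the
integral accurate at every depth requested.

**Discrete sensor model.**  The image plane carries exactly `n_u` field
samples per lenslet (7.69 µm for the default 100 µm pitch, 13 pixels).  Each
lenslet windows its block of `n_u × n_u` samples (the square aperture) and
optically Fourier-transforms it to the sensor; the sub-image is the squared
modulus of the orthonormal 2D DFT of the block with DC shifted to the
central pixel, so `u = (0,0)` is the lenslet centre.  This makes realignment
exact, conserves energy per lenslet (Parseval), and fixes the
pixel-to-frequency-band mapping that a continuous-band formulation leaves
open.  The sampling is valid whenever the sample pitch is below the
image-side Nyquist pitch `λ/(2·NA/M)` (≈ 12 µm for the defaults); the Debye
field is band-limited to the pupil, so defocus never widens the band, and a
`SamplingError` is raised when the criterion fails.  The physically distinct
sensor pixel size (`ds = 6.5 µm`, `n_u·ds = 84.5 µm < 100 µm`) is absorbed
into the relay magnification of the camera optics; configuration validation
requires the implied relay factor to lie in [0.5, 2].

**Weights.**  `ω_u = Σ_z ‖H_{z,u}‖₁ / Σ_u Σ_z ‖H_{z,u}‖₁` compensates the
per-angle shot-noise variance.  All `n_u²` angles are kept, including the
corner angles outside the NA circle, whose weights are naturally ≈ 0 (4.6e-6
versus 3.8e-2 for the central angle at the defaults); an optional threshold
can zero them explicitly.

## Reconstruction

The volume estimate maximises the Poisson likelihood by multiplicative
iterations using a ratio of backprojections,

    X ← X · [Σ_u ω_u BP(Ŷ_u)] / [Σ_u ω_u BP(FP(X))]           (all-angle)
    X ← X · BP(Ŷ_u')/BP(FP(X))  with Ŷ_u' = Ŷ_u1 + Ŷ_u2,
                                     H_u' = H_u1 + H_u2       (subset pair)

Subset groups are drawn per epoch as a fresh seeded permutation of all
angles chunked into pairs (one singleton when the count is odd: 169 angles →
84 pairs + 1 singleton).  Subset updates are unweighted, matching the merged
two-view update; the group size generalises beyond 2 for ablations.  The
single-angle mode (groups of one, random order) is the ptychographic
baseline.

**Fourier evaluation.**  `FP` multiplies the per-slice 2D spectra of the
volume with the PSF spectra and sums over depth; `BP` embeds the 2D image as
the central slice of a 3D stack — whose 3D spectrum is the replication of
its 2D spectrum across depth — and multiplies with the conjugate (laterally
flipped) PSF spectra.  Both use identical zero-padding: measurement size
plus PSF half-extent, rounded up to FFT-friendly lengths.  With identical
padding, `BP` is the exact adjoint of `FP` on the padded grid (verified to
1e-8 in randomized inner-product tests), and both match brute-force spatial
convolution/backprojection to better than 1e-5 relative on all tested
instances.

**Numerical choices.**
- Denominator floor: `den ← max(den, ε·max(den))` with `ε = 1e-10`; avoids
  ratio blow-ups without perturbing well-scaled voxels.
- Initialisation: uniform volume scaled so the total forward-projected
  intensity equals the total measured intensity.
- Stopping: fixed epoch count (default 5); no convergence threshold.
- Zeros are absorbing: multiplicative updates keep exact zeros at zero.
  At extremely sparse photon budgets this makes the subset modes collapse
  toward empty volumes — a property of the update, reported as-is.
- The all-angle weighted update is an ISRA-like ratio of backprojections,
  not the classical RL ratio-inside-backprojection; its Poisson
  log-likelihood descent is an empirical observation (asserted on the
  noise-free fixture), not a theorem.
- `upsample > 1` (sub-lenslet reconstruction grids) is scaffolded in the
  configuration but unimplemented: it requires PSFs at sub-lenslet offsets,
  which the spatially-invariant PSF model deliberately does not provide.

**Total variation.**  `TV(X) = Σ √(D₁² + D₂² + D₃² + δ²)` with forward
differences, replicate boundary and smoothing `δ = 1e-8` (the gradient is
validated against central finite differences of the same functional).  Each
application takes `K` steps `X ← X − α·v/‖v‖₂` followed by clipping at zero;
defaults `α = 3.0`, `K = 1`, applied once per epoch after the data updates
(a per-subset option exists, default off).  Note that `α` is an *absolute
intensity* step — the gradient is normalised, the data are not — so its
effect depends on the photon scale of the measurement and on the volume
size.  Fixtures therefore carry photon-scale amplitudes (an impulse of
1000 photons, measurements of 1–100 photons/pixel); with order-unity data
the default step would dominate a desk-scale volume.

## Synthetic data

Phantoms are seeded and reproducible: `beads` (isotropic Gaussian blobs,
count set so the above-half-maximum voxel fraction tracks the requested
density), `rods` (random 3D segments with Gaussian cross-section), `layers`
(axially separated smoothed textures).  They emulate sparse labelled
structures at a controllable density but none of the background
fluorescence, scattering, aberrations or spectral structure of real tissue,
so passing benchmarks demonstrate correct algorithmic behaviour under the
stated model — not performance on experimental recordings.

Shot noise: the clean measurement is rescaled to a photon budget — either
the maximum pixel (default; the quoted level bounds per-pixel counts) or the
mean pixel — and each pixel replaced by a seeded Poisson draw.  The mean
convention matches the usual reading of "photons per pixel" for a scene
that fills the field of view.

## Evaluation

SSIM uses the standard Gaussian-window formulation (11×11 window, σ = 1.5,
K₁ = 0.01, K₂ = 0.03), computed per z-slice against the reference's global
dynamic range and averaged over slices; volumetric-vs-slice-wise averaging
is a convention, and the slice-wise mean is used throughout.  Because
reconstructions live on the photon scale of their measurement, both volumes
are scaled to unit maximum before comparison.  Depth-coded projections tint
each slice with an evenly spaced hue (HSV, endpoint excluded so the first
and last planes differ) and average along z.

The noise-robustness benchmark simulates a 64×64×16 bead phantom (density
0.05 — a dense scene; at much sparser settings SSIM degenerates, scoring an
empty volume above any structured reconstruction, and cannot rank methods),
corrupts it at mean photon budgets {1, 3.1, 10, 100} per pixel, reconstructs
with 5 epochs of each method variant, and scores against the phantom.  Five
replicates share their noisy measurement and schedule seed across methods,
so method contrasts are paired; orderings are asserted with the exact
one-sided Wilcoxon signed-rank test at α = 0.05 (five skewed paired
differences: a t-test's normality assumption does not hold).  Noise-free
rows are evaluated at the intensity scale of the largest finite budget so
the scale-bearing TV step sees comparable data.  Only orderings and trends
across methods and levels are meaningful at this scale; absolute SSIM values
depend on the scene.

## Complexity accounting

The Fourier projector accumulates an operation-count proxy from the
transforms it actually executes (`N log₂ N` per 2D FFT at the padded size,
plus pointwise spectral work); the spatial reference cost is modelled as the
direct-convolution burden `N² · N_psf²` per depth and angle.  Doubling tests
at lateral sizes 32→64→128 confirm the ≈ `N² log N` growth of the Fourier
path against the PSF-footprint-laden spatial model.  No wall-clock claims
are made: timings are hardware- and implementation-dependent.

## Problem sizes

Default verification sizes, chosen to exercise every code path at desk
scale: oracle checks on ≤ 32×32 lateral grids with ≤ 8 depth planes and
≤ 5×5 angles; point-source recovery on 32×32×8 with the full 13×13 angle
set; the noise benchmark on 64×64×16 with 13×13 angles and five replicates.

## Known limitations

- Rectified inputs are assumed: microlens-grid rotation/registration of
  experimental camera frames is not provided, nor hexagonal layouts.
- Spatially invariant PSF per angle; aberrations, vectorial high-NA effects
  and defocused-MLA geometries are not modelled.
- Iterative only: no deterministic Fourier-interpolation reconstruction.
- The axial missing-cone problem of light-field tomography is inherited:
  axial resolution is markedly worse than lateral, visible in xz views.
- CPU only; the FFT backend is scipy.fft.
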