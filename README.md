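# lfdeconv — Fourier-domain phase-space deconvolution for light-field microscopy

Light-field microscopy (LFM) captures a 3D fluorescent sample in a single
camera exposure: a microlens array at the native image plane splits the light
so that the sensor records both where a ray arrived (which lenslet, spatial
coordinate `x`) and in which direction it was travelling (offset under the
lenslet, angular coordinate `u`).  Realigning the raw image `L` into
phase-space views `Y(x, u) = L(x + u)` turns the recording into a set of
`n_u × n_u` low-resolution projections of the volume, one per angle — a
tomographic problem with diffraction: each view is the depth-summed
convolution of the volume with a wave-optics phase-space PSF,

    Y(x, u) = Σ_z  g(·, z) * H(·, z, u),        Ŷ = Pois(Y),

with `H(x, z, u)` computed from the scalar Debye model of the objective and a
discrete Fourier model of each lenslet.  `lfdeconv` recovers `g` by
Richardson–Lucy-type multiplicative iterations evaluated in the Fourier
domain,

    X ← X · [Σ_u ω_u BP(Ŷ_u)] / [Σ_u ω_u BP(FP(X))],

where `FP`/`BP` are the forward/backward projections (`BP` is the exact
adjoint of `FP`), and `ω_u ∝ Σ_z ‖H_{z,u}‖₁` weights each angle by its PSF
energy to compensate shot-noise variance.  Two accelerated variants are
provided: a random-subset mode that merges two random views per sub-iteration
(`Y' = Y_u1 + Y_u2`, `H' = H_u1 + H_u2`) to combine single-angle convergence
speed with multi-view noise averaging, and a single-angle baseline.  An
isotropic 3D total-variation step `X ← X − α·∇TV/‖∇TV‖₂` (defaults α = 3.0,
K = 1) exploits the sparsity of fluorescent structures between epochs.

The package is aimed at microscopists and algorithm developers who want a
tested, self-contained reference implementation: wave-optics PSF generation,
realignment, a Poisson forward simulator with synthetic phantoms, the
Fourier-domain reconstructor with a brute-force spatial-domain oracle, SSIM
evaluation, depth-coded rendering, and a CLI — no external data needed.

## Worked example

```python
import numpy as np
import lfdeconv as lf

# full-scale system: NA 0.5, 23x, 13x13 pixels behind each 100 um lenslet
cfg = lf.OpticalConfig(n_u=13, n_x_psf=9, z_planes=np.linspace(-14, 14, 8))
psf = lf.phase_space_psf(cfg)

phantom = lf.make_phantom("beads", (32, 32, 8), density=0.05, seed=7,
                          z_planes=cfg.z_planes)
clean = lf.forward_project(phantom, psf)
noisy = lf.add_shot_noise(clean, lf.NoiseSpec(photons_per_pixel=100, seed=1,
                                              normalization="mean"))

model = lf.PhaseSpaceDeconvolution(noisy, psf)
res = model.fit(n_iter=5, mode="subset_pairs", alpha=3.0, k_tv=1, seed=1,
                reference=phantom)
print(res.summary())
```

prints

```
Fourier Phase-Space Deconvolution Results
=============================================
mode:            subset_pairs
epochs:          5
TV alpha / K:    3 / 1
seed:            1
volume:          32x32x8 voxels
final NLL:       -8.74443e+07
final residual:  0.477763
final SSIM:      0.5128

 iteration           nll  rel_residual     ssim
         1 -8.776325e+07      0.457406 0.472092
         2 -7.324591e+07      1.225307 0.178049
         3 -8.857859e+07      0.241256 0.631255
         4 -8.754383e+07      0.475364 0.447770
         5 -8.744430e+07      0.477763 0.512845
```

`nll` is the Poisson negative log-likelihood of the current volume against
all 169 views, `rel_residual` the relative L2 data misfit (the floor is set
by the shot noise, here ≈ 1/√100 per pixel), and `ssim` the slice-averaged
structural similarity against the ground-truth phantom after both are scaled
to unit maximum.  Subset iterations trade monotonicity for speed, so
epoch-to-epoch oscillation on noisy data is expected; the `mle_all_angles`
mode descends smoothly but converges more slowly per unit work.

The same pipeline is available from the shell:

```bash
lfdeconv psf --out psf.tif                     # PSF stack + JSON sidecar
lfdeconv simulate --volume vol.tif --psf psf.tif --photons 100 --seed 1 --out meas.tif
lfdeconv reconstruct --measurement meas.tif --psf psf.tif --iters 5 --seed 1 \
    --out rec.tif --metrics metrics.csv --log run.log
lfdeconv benchmark --psf psf.tif --levels 1,3.1,10,100 --seeds 5 --out report.csv
```

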