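"""Synthetic volumes and forward simulation of light-field acquisition.

The imaging model is, per angular component u,

    Y(x, u) = sum_z g(., z) * H(., z, u),

a depth-summed 2D convolution of the volume with the phase-space PSF,
followed by Poisson shot noise, the dominant noise source in fluorescence
light-field imaging.  This module keeps the spatial-domain form as the
reference implementation; the Fourier path in :mod:`lfdeconv.deconv` must
agree with it.

Phantoms (beads, rods, layers) stand in for real fluorescence volumes: they
emulate sparse labelled structures at controllable density but none of the
optical background, scattering or autofluorescence texture of tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .optics import PhaseSpacePSF
from .phasespace import PhaseSpaceMeasurement

__all__ = [
    "Volume",
    "NoiseSpec",
    "forward_project",
    "add_shot_noise",
    "make_phantom",
]


@dataclass
class Volume:
    """Nonnegative 3D intensity grid ``g[x1, x2, z]``.

    Lateral sampling is in lenslet units (one voxel per microlens);
    ``z_planes`` gives the axial positions in um, matching the PSF grid.
    """

    g: np.ndarray
    z_planes: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.z_planes = np.asarray(self.z_planes, dtype=float)
        if self.g.ndim != 3:
            raise ValueError("volume must be 3D [x1, x2, z]")
        if self.g.shape[2] != len(self.z_planes):
            raise ValueError(
                f"volume has {self.g.shape[2]} slices but {len(self.z_planes)} "
                "z_planes"
            )
        if not np.all(np.isfinite(self.g)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.g < 0):
            raise ValueError("volume contains negative values")

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.g.shape[0], self.g.shape[1]

    @property
    def n_z(self) -> int:
        return self.g.shape[2]


@dataclass
class NoiseSpec:
    """Shot-noise level specification.

    ``photons_per_pixel`` sets the photon count of the brightest measurement
    pixel after rescaling (``normalization="max"``, default) or the mean count
    over all pixels (``"mean"``); ``math.inf`` means noise-free.  The exact
    intensity normalisation behind a quoted "photons per pixel" level is a
    convention, so both are provided.
    """

    photons_per_pixel: float
    seed: int = 0
    normalization: str = "max"

    def __post_init__(self) -> None:
        if not (self.photons_per_pixel > 0):
            raise ValueError("photons_per_pixel must be > 0 (or inf)")
        if self.normalization not in ("max", "mean"):
            raise ValueError("normalization must be 'max' or 'mean'")


def _check_z_match(g: Volume, psf: PhaseSpacePSF) -> None:
    if g.n_z != psf.n_z or not np.allclose(g.z_planes, psf.z_planes):
        raise ValueError(
            "volume and PSF z-grids differ: "
            f"{g.z_planes.tolist()} vs {psf.z_planes.tolist()}"
        )


def forward_project(g: Volume, psf: PhaseSpacePSF) -> PhaseSpaceMeasurement:
    """Clean phase-space measurement of a volume (spatial-domain reference).

    Per angle, sums zero-padded linear 2D convolutions over depth, cropped to
    the volume's lateral grid (one measurement sample per lenslet).  Linear in
    ``g`` and nonnegative by construction.
    """
    _check_z_match(g, psf)
    nu = psf.n_u
    n1, n2 = g.lateral_shape
    y = np.zeros((nu, nu, n1, n2))
    for iu1 in range(nu):
        for iu2 in range(nu):
            acc = np.zeros((n1, n2))
            for iz in range(g.n_z):
                acc += fftconvolve(g.g[:, :, iz], psf.h[iu1, iu2, :, :, iz], mode="same")
            y[iu1, iu2] = acc
    np.clip(y, 0.0, None, out=y)  # fftconvolve roundoff can dip below zero
    return PhaseSpaceMeasurement(y=y, pitch_px=nu)


def add_shot_noise(y: PhaseSpaceMeasurement, spec: NoiseSpec) -> PhaseSpaceMeasurement:
    """Rescale a clean measurement to a photon budget and apply Poisson noise.

    The measurement is scaled so its maximum (or mean) pixel value equals
    ``spec.photons_per_pixel``; each pixel is then replaced by an independent
    Poisson draw with that mean.  Noise-free mode (infinite photon level)
    returns the input unchanged, without rescaling.
    """
    if math.isinf(spec.photons_per_pixel):
        return PhaseSpaceMeasurement(y=y.y.copy(), pitch_px=y.pitch_px)
    ref = y.y.max() if spec.normalization == "max" else y.y.mean()
    if ref <= 0:
        raise ValueError("measurement has no signal to scale to a photon level")
    scaled = y.y * (spec.photons_per_pixel / ref)
    rng = np.random.default_rng(spec.seed)
    noisy = rng.poisson(scaled).astype(float)
    return PhaseSpaceMeasurement(y=noisy, pitch_px=y.pitch_px)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def make_phantom(
    kind: str,
    shape: tuple[int, int, int],
    density: float = 0.01,
    seed: int = 0,
    z_planes: np.ndarray | None = None,
) -> Volume:
    """Seeded sparse phantom volume.

    kind
        ``"beads"``: scattered isotropic Gaussian blobs (sigma ~1.2 voxels),
        count chosen so the fraction of voxels above half maximum is close to
        ``density``.  ``"rods"``: random 3D line segments with a Gaussian
        cross-section, emulating filamentous structures.  ``"layers"``:
        axially separated textured planes (smoothed random texture on a few
        z-slices).
    shape
        ``(n_x1, n_x2, n_z)`` voxel grid.
    density
        Target sparsity in (0, 1].
    z_planes
        Axial positions to attach; defaults to a unit-spaced centred grid.
    """
    if kind not in ("beads", "rods", "layers"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"degenerate shape {shape}")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    n1, n2, nz = shape
    if z_planes is None:
        z_planes = np.arange(nz, dtype=float) - (nz - 1) / 2.0
    rng = np.random.default_rng(seed)
    g = np.zeros(shape)

    if kind == "beads":
        sigma = 1.2
        # voxels above half max per bead ~ sphere of radius sigma*sqrt(2 ln 2)
        r_half = sigma * math.sqrt(2.0 * math.log(2.0))
        vox_per_bead = max(1.0, 4.0 / 3.0 * math.pi * r_half**3)
        n_beads = max(1, round(density * n1 * n2 * nz / vox_per_bead))
        for _ in range(n_beads):
            c = rng.uniform([1, 1, 0.5], [n1 - 1, n2 - 1, nz - 0.5])
            amp = rng.uniform(0.6, 1.0)
            _splat_gaussian(g, c, sigma, amp)
    elif kind == "rods":
        sigma = 0.9
        vox_per_unit_len = max(1.0, math.pi * (sigma * 1.18) ** 2)
        mean_len = 0.5 * min(n1, n2)
        n_rods = max(1, round(density * n1 * n2 * nz / (vox_per_unit_len * mean_len)))
        for _ in range(n_rods):
            a = rng.uniform([0, 0, 0], [n1 - 1, n2 - 1, nz - 1])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            length = rng.uniform(0.5, 1.5) * mean_len
            amp = rng.uniform(0.6, 1.0)
            n_pts = max(2, int(length * 3))
            for t in np.linspace(0.0, 1.0, n_pts):
                _splat_gaussian(g, a + t * length * direction, sigma, amp / 3.0)
    else:  # layers
        n_layers = max(1, min(nz, round(density * nz * 4)))
        zs = rng.choice(nz, size=n_layers, replace=False)
        for iz in zs:
            tex = rng.random((n1, n2))
            tex = gaussian_filter(tex, sigma=2.0, mode="wrap")
            tex -= np.quantile(tex, 1.0 - min(1.0, density * 10))
            g[:, :, iz] += np.clip(tex, 0.0, None)
        if g.max() > 0:
            g /= g.max()
    return Volume(g=g, z_planes=z_planes)


def _splat_gaussian(g: np.ndarray, center: np.ndarray, sigma: float, amp: float) -> None:
    """Add a small truncated Gaussian blob in place (4-sigma support)."""
    n1, n2, nz = g.shape
    r = int(math.ceil(4 * sigma))
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1, [n1, n2, nz])
    if np.any(lo >= hi):
        return
    xx = np.arange(lo[0], hi[0])[:, None, None] - center[0]
    yy = np.arange(lo[1], hi[1])[None, :, None] - center[1]
    zz = np.arange(lo[2], hi[2])[None, None, :] - center[2]
    blob = amp * np.exp(-(xx**2 + yy**2 + zz**2) / (2.0 * sigma**2))
    g[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += blob
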