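"""Wave-optics phase-space PSF model for light-field microscopy.

The microlens array sits at the native image plane and the sensor at the
lenslets' back focal plane.  A point source at object depth ``z`` produces a
complex field ``U_z`` at the image plane, modelled with the scalar Debye
integral of an aplanatic circular-pupil objective.  Each lenslet windows the
field with its square aperture and optically Fourier-transforms it onto the
sensor, where intensity is recorded; realigning the simulated sensor image
yields one spatially-invariant 3D intensity PSF ``H(x, z, u)`` per angular
component ``u``, sampled at the lenslet pitch.

Discretisation: the image plane carries exactly ``n_u`` field samples per
lenslet, so each lenslet's sensor sub-image is the squared modulus of the
orthonormal 2D DFT of its ``n_u x n_u`` windowed field samples, with the DC
bin shifted to the central pixel (u = 0).  This keeps realignment exact and
conserves energy per lenslet (Parseval).  The sampling is valid whenever the
sample pitch is below the image-side Nyquist pitch lambda / (2 NA / M); the
Debye field is band-limited to the pupil, so defocus never widens the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

from .phasespace import RawLFImage, realign

__all__ = [
    "SamplingError",
    "OpticalConfig",
    "ComplexField",
    "PhaseSpacePSF",
    "AngleWeights",
    "debye_field",
    "point_source_sensor_image",
    "phase_space_psf",
    "angle_weights",
]


class SamplingError(ValueError):
    """Raised when the requested grid undersamples the optical field."""


def _default_z_planes() -> np.ndarray:
    return np.linspace(-20.0, 20.0, 11)


@dataclass
class OpticalConfig:
    """Physical and sampling parameters of the light-field microscope.

    Defaults mirror a 0.5 NA / 23x system with a 100 um pitch, F/23 microlens
    array and 13x13 sensor pixels of 6.5 um behind each lenslet.

    Parameters
    ----------
    na : float
        Numerical aperture of the objective.
    magnification : float
        Total lateral magnification from object to native image plane.
    wavelength : float
        Emission wavelength in nm.
    n_medium : float
        Refractive index of the immersion/sample medium.
    lens_pitch : float
        Microlens pitch in um at the native image plane.
    ds : float
        Sensor pixel size behind each microlens, um.
    n_u : int
        Pixels per microlens per dimension (odd).
    z_planes : array
        Axial sample positions in um, object space, strictly increasing;
        z = 0 is the native object plane.
    n_x_psf : int
        Lateral PSF extent in lenslet units (odd).
    mla_fnumber : float
        Microlens F-number.
    """

    na: float = 0.5
    magnification: float = 23.0
    wavelength: float = 525.0
    n_medium: float = 1.0
    lens_pitch: float = 100.0
    ds: float = 6.5
    n_u: int = 13
    z_planes: np.ndarray = field(default_factory=_default_z_planes)
    n_x_psf: int = 9
    mla_fnumber: float = 23.0

    def __post_init__(self) -> None:
        self.z_planes = np.asarray(self.z_planes, dtype=float)
        if not (0.0 < self.na < self.n_medium):
            raise ValueError("na must satisfy 0 < na < n_medium")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")
        if self.lens_pitch <= 0:
            raise ValueError("lens_pitch must be > 0")
        if self.ds <= 0:
            raise ValueError("ds must be > 0")
        if self.n_u < 1 or self.n_u % 2 == 0:
            raise ValueError("n_u must be an odd integer >= 1")
        if self.n_x_psf < 1 or self.n_x_psf % 2 == 0:
            raise ValueError("n_x_psf must be an odd integer >= 1")
        if self.z_planes.ndim != 1 or len(self.z_planes) < 1:
            raise ValueError("z_planes must be a 1D array")
        if len(self.z_planes) > 1 and not np.all(np.diff(self.z_planes) > 0):
            raise ValueError("z_planes must be strictly increasing")
        # The sensor span n_u*ds maps onto one lenslet pitch through the relay
        # optics; require the implied relay magnification to be sane.
        relay = self.lens_pitch / (self.n_u * self.ds)
        if not (0.5 <= relay <= 2.0):
            raise ValueError(
                f"n_u*ds = {self.n_u * self.ds:g} um inconsistent with "
                f"lens_pitch = {self.lens_pitch:g} um (relay magnification "
                f"{relay:.2f} outside [0.5, 2])"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def wavelength_um(self) -> float:
        return self.wavelength * 1e-3

    @property
    def na_image(self) -> float:
        """Image-side numerical aperture NA / M."""
        return self.na / self.magnification

    @property
    def sample_pitch(self) -> float:
        """Image-plane field sampling pitch, um (n_u samples per lenslet)."""
        return self.lens_pitch / self.n_u

    @property
    def nyquist_pitch(self) -> float:
        """Maximum image-plane pitch that still Nyquist-samples the pupil band."""
        return self.wavelength_um / (2.0 * self.na_image)

    @property
    def n_z(self) -> int:
        return len(self.z_planes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["z_planes"] = [float(z) for z in self.z_planes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


@dataclass
class ComplexField:
    """Sampled complex amplitude at the native image plane."""

    values: np.ndarray
    pitch: float
    z: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def energy(self) -> float:
        """Integrated intensity, sum |U|^2 * pitch^2."""
        return float(np.sum(np.abs(self.values) ** 2) * self.pitch**2)


@dataclass
class PhaseSpacePSF:
    """Phase-space PSF stack ``h[u1, u2, x1, x2, z]`` (intensity, a.u.)."""

    h: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 5:
            raise ValueError("PSF must be 5D [u1, u2, x1, x2, z]")
        nu = self.config.n_u
        nx = self.config.n_x_psf
        nz = self.config.n_z
        if self.h.shape != (nu, nu, nx, nx, nz):
            raise ValueError(
                f"PSF shape {self.h.shape} does not match config "
                f"({nu}, {nu}, {nx}, {nx}, {nz})"
            )
        if not np.all(np.isfinite(self.h)):
            raise ValueError("PSF contains non-finite values")
        if np.any(self.h < 0):
            raise ValueError("PSF contains negative values")

    @property
    def n_u(self) -> int:
        return self.h.shape[0]

    @property
    def n_angles(self) -> int:
        return self.n_u * self.n_u

    @property
    def n_x(self) -> int:
        return self.h.shape[2]

    @property
    def n_z(self) -> int:
        return self.h.shape[4]

    @property
    def z_planes(self) -> np.ndarray:
        return self.config.z_planes

    def angle(self, iu1: int, iu2: int) -> np.ndarray:
        """3D PSF ``H(x, z)`` for one angular index pair (array indices)."""
        return self.h[iu1, iu2]


@dataclass
class AngleWeights:
    """Per-angle noise-compensation weights, normalised to sum to one."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("weights must be 2D over (u1, u2)")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")

    def flat(self) -> np.ndarray:
        return self.w.ravel()


# ---------------------------------------------------------------------------
# Debye focal field
# ---------------------------------------------------------------------------

def debye_field(config: OpticalConfig, z: float, oversample: int = 1) -> ComplexField:
    """Complex field at the native image plane from an on-axis point at depth z.

    Scalar Debye integral of an aplanatic objective with a circular pupil:

        U(r, z) = int_0^alpha sqrt(cos t) sin t J0(k n r sin t)
                  exp(i k n z cos t) dt,

    with ``k = 2 pi / lambda``, ``alpha = asin(NA / n)`` and ``r`` the radial
    coordinate in object space.  The image-plane field is the object-space
    field with coordinates scaled by the magnification (constant factors and
    the depth-dependent unit-magnitude phase are dropped; only ``|U|^2``
    matters downstream).  Gauss-Legendre quadrature over the aperture angle,
    with the node count scaled to the radial and axial oscillation rates.

    Parameters
    ----------
    config : OpticalConfig
    z : float
        Object-space depth in um.
    oversample : int
        Lateral super-sampling factor relative to the standard n_u samples
        per lenslet (used for fine-grained field inspection; the PSF pipeline
        always uses ``oversample=1``).

    Raises
    ------
    SamplingError
        If the grid pitch exceeds the image-side Nyquist pitch, i.e. the
        pupil band (and with it the defocus phase) would alias.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    pitch = config.sample_pitch / oversample
    if pitch > config.nyquist_pitch:
        raise SamplingError(
            f"image-plane pitch {pitch:.3g} um exceeds the Nyquist pitch "
            f"{config.nyquist_pitch:.3g} um for NA/M = {config.na_image:.4g}; "
            "the defocus phase would alias on this grid"
        )
    n_side = config.n_x_psf * config.n_u * oversample
    c = (n_side - 1) // 2
    idx = np.arange(n_side) - c
    # squared integer radii -> unique radius table (exact for a centred grid)
    q = idx[:, None] ** 2 + idx[None, :] ** 2
    q_unique, inverse = np.unique(q, return_inverse=True)
    pitch_obj = pitch / config.magnification
    r = np.sqrt(q_unique.astype(float)) * pitch_obj

    k = 2.0 * np.pi / config.wavelength_um
    n = config.n_medium
    alpha = np.arcsin(config.na / n)
    # oscillation budget: radial J0 cycles + axial defocus cycles
    r_max = float(r[-1]) if r.size else 0.0
    radial_cycles = r_max * config.na / config.wavelength_um
    axial_cycles = abs(z) * n * (1.0 - np.cos(alpha)) / config.wavelength_um
    n_nodes = int(64 + 8 * (radial_cycles + axial_cycles))
    x_gl, w_gl = leggauss(min(n_nodes, 4000))
    theta = 0.5 * alpha * (x_gl + 1.0)
    w = 0.5 * alpha * w_gl
    amp = w * np.sqrt(np.cos(theta)) * np.sin(theta)
    phase = np.exp(1j * k * n * z * np.cos(theta))
    bessel = j0(k * n * np.outer(r, np.sin(theta)))
    u_r = bessel @ (amp * phase)
    values = u_r[inverse].reshape(n_side, n_side)
    return ComplexField(values=values, pitch=pitch, z=float(z))


# ---------------------------------------------------------------------------
# Sensor-image simulation and PSF assembly
# ---------------------------------------------------------------------------

def point_source_sensor_image(config: OpticalConfig, z: float) -> np.ndarray:
    """Simulated raw sensor image of an on-axis point source at depth z.

    The field from :func:`debye_field` is windowed by each lenslet's square
    aperture (the block of ``n_u x n_u`` samples under that lenslet) and
    optically Fourier-transformed onto the sensor; pixel ``u`` records the
    energy of frequency bin ``u``, with DC at the central pixel.
    """
    u_field = debye_field(config, z).values
    nx, nu = config.n_x_psf, config.n_u
    blocks = u_field.reshape(nx, nu, nx, nu).transpose(0, 2, 1, 3)
    spect = np.fft.fft2(blocks, axes=(-2, -1), norm="ortho")
    spect = np.fft.fftshift(spect, axes=(-2, -1))
    inten = np.abs(spect) ** 2
    return inten.transpose(0, 2, 1, 3).reshape(nx * nu, nx * nu)


def phase_space_psf(config: OpticalConfig) -> PhaseSpacePSF:
    """Phase-space PSF stack H(x, z, u): one 3D PSF per angular component.

    For each depth the raw sensor image of a point source centred on the
    central lenslet is simulated and realigned, exploiting the per-angle
    spatial invariance of the phase-space PSF under lenslet-pitch sampling.
    """
    nu, nx, nz = config.n_u, config.n_x_psf, config.n_z
    h = np.empty((nu, nu, nx, nx, nz))
    for iz, z in enumerate(config.z_planes):
        raw = point_source_sensor_image(config, z)
        meas = realign(RawLFImage(pixels=raw, pitch_px=nu))
        h[:, :, :, :, iz] = meas.y
    return PhaseSpacePSF(h=h, config=config)


def angle_weights(psf: PhaseSpacePSF, threshold: float = 0.0) -> AngleWeights:
    """Per-angle weights from the PSF energy distribution.

    ``w_u = sum_z ||H_{z,u}||_1 / sum_u sum_z ||H_{z,u}||_1`` — angles that
    collect more PSF energy see proportionally less relative shot noise and
    are weighted up.  Corner angles outside the NA circle carry near-zero
    energy and are naturally suppressed; ``threshold`` (fraction of the
    maximum weight) optionally masks them to exactly zero before
    renormalisation, default off.
    """
    e = psf.h.sum(axis=(2, 3, 4))
    total = e.sum()
    if total <= 0:
        raise ValueError("PSF has zero total energy; weights undefined")
    w = e / total
    if threshold > 0.0:
        w = np.where(w >= threshold * w.max(), w, 0.0)
        w = w / w.sum()
    return AngleWeights(w=w)
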