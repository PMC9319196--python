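"""Realignment between raw light-field sensor images and phase-space views.

A light-field microscope places a microlens array at the native image plane;
each lenslet forms a small sub-image on the sensor.  Realignment regroups the
raw sensor pixels ``L(x')`` into per-angle views ``Y(x, u) = L(x + u)``: the
spatial coordinate ``x`` indexes the lenslet, the angular coordinate ``u`` the
pixel offset from the lenslet centre.  Each view then has exactly one sample
per lenslet and the collection of views is the phase-space measurement the
deconvolver consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RawLFImage",
    "PhaseSpaceMeasurement",
    "realign",
    "derealign",
    "crop_to_pitch",
]


@dataclass
class RawLFImage:
    """A rectified raw sensor image.

    Parameters
    ----------
    pixels : 2D array
        Nonnegative intensities; both dimensions must be integer multiples of
        ``pitch_px``.
    pitch_px : int
        Pixels per microlens per dimension.
    """

    pixels: np.ndarray
    pitch_px: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("raw image must be 2D")
        if self.pitch_px < 1:
            raise ValueError("pitch_px must be >= 1")
        h, w = self.pixels.shape
        if h % self.pitch_px or w % self.pitch_px:
            raise ValueError(
                f"image dimensions {self.pixels.shape} are not multiples of "
                f"the lenslet pitch {self.pitch_px}; use crop_to_pitch first"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("raw image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("raw image contains negative values")


@dataclass
class PhaseSpaceMeasurement:
    """Per-angle views ``Y(x, u)`` stored as a 4D array ``y[u1, u2, x1, x2]``.

    The angular index ``iu`` maps to the signed offset ``iu - (pitch_px-1)//2``
    from the lenslet centre, so with odd pitch the central index is u = (0, 0).
    """

    y: np.ndarray
    pitch_px: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 4:
            raise ValueError("measurement must be a 4D array [u1, u2, x1, x2]")
        if self.y.shape[0] != self.pitch_px or self.y.shape[1] != self.pitch_px:
            raise ValueError(
                f"angular extent {self.y.shape[:2]} does not match "
                f"pitch_px={self.pitch_px}"
            )
        if not np.all(np.isfinite(self.y)):
            raise ValueError("measurement contains non-finite values")
        if np.any(self.y < 0):
            raise ValueError("measurement contains negative values")

    @property
    def n_views(self) -> int:
        return self.pitch_px * self.pitch_px

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.y.shape[2], self.y.shape[3]

    def u_offsets(self) -> np.ndarray:
        """Signed angular offsets corresponding to the angular indices."""
        c = (self.pitch_px - 1) // 2
        return np.arange(self.pitch_px) - c

    def view(self, u1: int, u2: int) -> np.ndarray:
        """Return the view at signed angular offset (u1, u2)."""
        c = (self.pitch_px - 1) // 2
        return self.y[u1 + c, u2 + c]


def realign(image: RawLFImage) -> PhaseSpaceMeasurement:
    """Regroup raw sensor pixels into per-angle views, ``Y(x, u) = L(x + u)``.

    Pure index bookkeeping: view ``(u1, u2)`` collects, from every lenslet, the
    sensor pixel at relative offset ``(u1, u2)`` from the lenslet centre.  The
    total photon count is conserved exactly.
    """
    p = image.pitch_px
    h, w = image.pixels.shape
    nx1, nx2 = h // p, w // p
    blocks = image.pixels.reshape(nx1, p, nx2, p)
    y = blocks.transpose(1, 3, 0, 2).copy()
    return PhaseSpaceMeasurement(y=y, pitch_px=p)


def derealign(meas: PhaseSpaceMeasurement) -> RawLFImage:
    """Exact inverse of :func:`realign`."""
    p = meas.pitch_px
    _, _, nx1, nx2 = meas.y.shape
    pixels = meas.y.transpose(2, 0, 3, 1).reshape(nx1 * p, nx2 * p).copy()
    return RawLFImage(pixels=pixels, pitch_px=p)


def crop_to_pitch(pixels: np.ndarray, pitch_px: int) -> np.ndarray:
    """Centre-crop an image so both dimensions are multiples of ``pitch_px``.

    Provided as an explicit utility: :class:`RawLFImage` deliberately rejects
    mis-sized inputs rather than cropping silently, because a silent crop can
    hide lenslet-registration errors.
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    nh, nw = (h // pitch_px) * pitch_px, (w // pitch_px) * pitch_px
    if nh == 0 or nw == 0:
        raise ValueError("image smaller than one lenslet")
    top, left = (h - nh) // 2, (w - nw) // 2
    return pixels[top : top + nh, left : left + nw]
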