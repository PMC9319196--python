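"""TIFF / JSON / YAML serialisation shared by the CLI and library.

Conventions
-----------
* Raw sensor images: single-page TIFF.
* Phase-space measurements: multi-page TIFF, one view per page, row-major
  over the angular indices (u1, u2); a JSON sidecar records the pitch.
* Volumes: multi-page TIFF, one page per z-slice; sidecar records z_planes.
* PSF stacks: multi-page TIFF, one page per (z, u) slice, z-major then
  row-major over angles; the sidecar records the optical configuration, the
  page ordering and the per-angle weights, so a stack round-trips bit-exactly
  and stays inspectable in standard viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import AngleWeights, OpticalConfig, PhaseSpacePSF, angle_weights
from .phasespace import PhaseSpaceMeasurement, RawLFImage
from .simulate import Volume

__all__ = [
    "save_raw",
    "load_raw",
    "save_measurement",
    "load_measurement",
    "save_volume",
    "load_volume",
    "save_psf",
    "load_psf",
    "save_optical_config",
    "load_optical_config",
]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def save_raw(path, image: RawLFImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"pitch_px": image.pitch_px}))


def load_raw(path, pitch_px: int | None = None) -> RawLFImage:
    pixels = tifffile.imread(str(path)).astype(float)
    if pitch_px is None:
        meta = json.loads(_sidecar(path).read_text())
        pitch_px = int(meta["pitch_px"])
    return RawLFImage(pixels=pixels, pitch_px=pitch_px)


def save_measurement(path, meas: PhaseSpaceMeasurement) -> None:
    p = meas.pitch_px
    pages = meas.y.reshape(p * p, *meas.y.shape[2:]).astype(np.float32)
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"pitch_px": p, "page_order": "row-major over (u1, u2)"})
    )


def load_measurement(path) -> PhaseSpaceMeasurement:
    pages = tifffile.imread(str(path)).astype(float)
    side = _sidecar(path)
    if side.exists():
        p = int(json.loads(side.read_text())["pitch_px"])
    else:
        p = int(round(np.sqrt(pages.shape[0])))
    y = pages.reshape(p, p, *pages.shape[1:])
    return PhaseSpaceMeasurement(y=y, pitch_px=p)


def save_volume(path, vol: Volume) -> None:
    pages = np.ascontiguousarray(vol.g.transpose(2, 0, 1)).astype(np.float32)
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"z_planes": [float(z) for z in vol.z_planes], "page_order": "z"})
    )


def load_volume(path, z_planes=None) -> Volume:
    pages = tifffile.imread(str(path)).astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    if z_planes is None:
        side = _sidecar(path)
        if side.exists():
            z_planes = json.loads(side.read_text())["z_planes"]
        else:
            z_planes = np.arange(pages.shape[0], dtype=float)
    return Volume(g=pages.transpose(1, 2, 0), z_planes=np.asarray(z_planes, float))


def save_psf(path, psf: PhaseSpacePSF, weights: AngleWeights | None = None) -> None:
    nu, _, nx, _, nz = psf.h.shape
    # pages: for each z, all angles row-major over (u1, u2)
    pages = np.ascontiguousarray(psf.h.transpose(4, 0, 1, 2, 3)).reshape(
        nz * nu * nu, nx, nx
    )
    tifffile.imwrite(str(path), pages.astype(np.float32), photometric="minisblack")
    if weights is None:
        weights = angle_weights(psf)
    meta = {
        "config": psf.config.to_dict(),
        "page_order": "z-major, then row-major over (u1, u2)",
        "weights": weights.w.tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_psf(path) -> tuple[PhaseSpacePSF, AngleWeights]:
    meta = json.loads(_sidecar(path).read_text())
    config = OpticalConfig.from_dict(meta["config"])
    pages = tifffile.imread(str(path)).astype(float)
    nu, nx, nz = config.n_u, config.n_x_psf, config.n_z
    h = pages.reshape(nz, nu, nu, nx, nx).transpose(1, 2, 3, 4, 0)
    psf = PhaseSpacePSF(h=np.ascontiguousarray(h), config=config)
    return psf, AngleWeights(w=np.asarray(meta["weights"]))


def save_optical_config(path, config: OpticalConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_optical_config(path) -> OpticalConfig:
    return OpticalConfig.from_dict(yaml.safe_load(Path(path).read_text()))
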