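"""Fourier-domain phase-space Richardson-Lucy deconvolution.

The volume estimate is the maximum-likelihood fit of the Poisson imaging
model ``Y_u ~ Pois(sum_z g * H_{z,u})`` to the realigned light-field views.
The multiplicative update is a ratio of backprojections,

    X <- X * [sum_u w_u BP(Y_u)] / [sum_u w_u BP(FP(X))],

with per-angle weights ``w_u`` proportional to PSF energy; the random-subset
variant merges two random views per sub-iteration, ``Y' = Y_u1 + Y_u2`` and
``H' = H_u1 + H_u2``, trading per-step information for convergence speed
while averaging shot noise.  Forward and backward projection are evaluated in
the Fourier domain: FP multiplies the per-slice spectra of the volume with
the PSF spectra and sums over depth; BP replicates the 2D spectrum of the
residual image across depth and multiplies with the conjugate (laterally
flipped) PSF spectra.  Both use identical zero-padding to FFT-friendly
lengths, so BP is the exact adjoint of FP on the padded grid.  An isotropic
3D total-variation step, applied as a normalised gradient-descent move once
per epoch, regularises the sparse fluorescence volume.

All operators here must agree with the spatial-domain reference
(:func:`lfdeconv.simulate.forward_project` and brute-force backprojection)
to floating-point tolerance; the test-suite enforces this on small instances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft2, next_fast_len, rfft2

from .optics import AngleWeights, PhaseSpacePSF, angle_weights
from .phasespace import PhaseSpaceMeasurement, RawLFImage, realign
from .simulate import Volume

__all__ = [
    "DeconvConfig",
    "SubsetSchedule",
    "ReconstructionResult",
    "FourierProjector",
    "fp_fourier",
    "bp_fourier",
    "rl_update_full",
    "rl_update_subset",
    "make_subset_schedule",
    "tv_gradient",
    "tv_step",
    "reconstruct",
    "PhaseSpaceDeconvolution",
    "poisson_nll",
    "direct_conv_op_count",
]

MODES = ("mle_all_angles", "subset_pairs", "single_angle")


@dataclass
class DeconvConfig:
    """Reconstruction parameters.

    n_iter
        Epoch count; one epoch visits every angle once (default 5).
    mode
        ``"mle_all_angles"`` (weighted all-angle update), ``"subset_pairs"``
        (random pairs per sub-iteration) or ``"single_angle"`` (random order,
        one angle per sub-iteration; the ablation baseline).
    alpha, k_tv
        TV step size and inner repetitions per application (defaults 3.0, 1;
        ``alpha = 0`` or ``k_tv = 0`` disables TV).
    epsilon
        Relative floor applied to the update denominator.
    seed
        Master seed for the subset schedule.
    upsample
        Lateral super-sampling factor of the reconstruction grid (scaffolded;
        only 1 is implemented).
    subset_size
        Angles merged per group in subset mode (default 2; larger values
        reproduce the many-angle-subset ablation).
    tv_per_subset
        Apply the TV step after every angle group instead of once per epoch.
    """

    n_iter: int = 5
    mode: str = "subset_pairs"
    alpha: float = 3.0
    k_tv: int = 1
    epsilon: float = 1e-10
    seed: int = 0
    upsample: int = 1
    subset_size: int = 2
    tv_per_subset: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k_tv < 0:
            raise ValueError("k_tv must be >= 0")
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be > 0")
        if self.upsample < 1:
            raise ValueError("upsample must be >= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


@dataclass
class SubsetSchedule:
    """Seeded ordering of random angle groups, one list per epoch.

    Every epoch is a fresh random permutation of all angles chunked into
    groups of ``subset_size`` (the final group may be smaller when the angle
    count is not a multiple).
    """

    epochs: list
    seed: int
    n_angles: int

    def __post_init__(self) -> None:
        for groups in self.epochs:
            seen = sorted(a for grp in groups for a in grp)
            if seen != list(range(self.n_angles)):
                raise ValueError("each epoch must cover every angle exactly once")


def make_subset_schedule(
    n_angles: int, n_iter: int, seed: int, group_size: int = 2
) -> SubsetSchedule:
    """Random angle-group schedule: ``n_iter`` epochs of chunked permutations."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    epochs = []
    for _ in range(n_iter):
        perm = rng.permutation(n_angles)
        groups = [
            tuple(int(a) for a in perm[i : i + group_size])
            for i in range(0, n_angles, group_size)
        ]
        epochs.append(groups)
    return SubsetSchedule(epochs=epochs, seed=seed, n_angles=n_angles)


# ---------------------------------------------------------------------------
# Fourier-domain projector
# ---------------------------------------------------------------------------

def _fft_cost(p1: int, p2: int) -> float:
    n = p1 * p2
    return n * max(np.log2(n), 1.0)


class FourierProjector:
    """Cached Fourier-domain forward/backward projector for one PSF.

    Pads measurement and PSF to a common FFT-friendly lateral grid
    (measurement size + PSF half-extent on each side) and caches the per-angle
    PSF spectra.  ``op_count`` accumulates a floating-point operation proxy
    (``N log2 N`` per 2D transform plus pointwise spectral work) for
    complexity measurements; no wall-clock claims are attached to it.
    """

    def __init__(self, psf: PhaseSpacePSF, meas_shape: tuple[int, int]):
        self.psf = psf
        self.n1, self.n2 = int(meas_shape[0]), int(meas_shape[1])
        nh = psf.n_x
        self.p1 = next_fast_len(self.n1 + nh - 1)
        self.p2 = next_fast_len(self.n2 + nh - 1)
        self.off = ((nh - 1) // 2, (nh - 1) // 2)
        self.n_z = psf.n_z
        self._hhat: dict[int, np.ndarray] = {}
        self.op_count = 0.0

    # -- angle handling ----------------------------------------------------
    def flat_angle(self, u) -> int:
        nu = self.psf.n_u
        if np.isscalar(u):
            u = int(u)
            if not 0 <= u < nu * nu:
                raise ValueError(f"angle index {u} out of range")
            return u
        iu1, iu2 = (int(v) for v in u)
        if not (0 <= iu1 < nu and 0 <= iu2 < nu):
            raise ValueError(f"angle index {(iu1, iu2)} out of range")
        return iu1 * nu + iu2

    def hhat(self, u) -> np.ndarray:
        """Cached rfft2 spectra of one angle's PSF, shape (n_z, p1, p2//2+1)."""
        a = self.flat_angle(u)
        if a not in self._hhat:
            nu = self.psf.n_u
            h = self.psf.h[a // nu, a % nu]  # (nx, nx, nz)
            spec = rfft2(np.ascontiguousarray(h.transpose(2, 0, 1)), s=(self.p1, self.p2))
            self._hhat[a] = spec
            self.op_count += self.n_z * _fft_cost(self.p1, self.p2)
        return self._hhat[a]

    def hhat_group(self, group) -> np.ndarray:
        """Spectrum of a merged PSF ``H' = sum_{u in group} H_u``."""
        spec = self.hhat(group[0]).copy()
        for u in group[1:]:
            spec += self.hhat(u)
        return spec

    # -- transforms --------------------------------------------------------
    def ghat(self, g: np.ndarray) -> np.ndarray:
        """Per-slice spectra of a volume array ``g[x1, x2, z]``."""
        spec = rfft2(np.ascontiguousarray(g.transpose(2, 0, 1)), s=(self.p1, self.p2))
        self.op_count += g.shape[2] * _fft_cost(self.p1, self.p2)
        return spec

    def fp_from_ghat(self, ghat: np.ndarray, hhat: np.ndarray) -> np.ndarray:
        """Forward projection from precomputed volume spectra (one angle)."""
        s = np.einsum("zij,zij->ij", ghat, hhat)
        self.op_count += self.n_z * self.p1 * (self.p2 // 2 + 1)
        full = irfft2(s, s=(self.p1, self.p2))
        self.op_count += _fft_cost(self.p1, self.p2)
        o1, o2 = self.off
        return full[o1 : o1 + self.n1, o2 : o2 + self.n2]

    def fp(self, g: np.ndarray, hhat: np.ndarray) -> np.ndarray:
        """Depth-summed convolution of a volume with one angle's PSF."""
        return self.fp_from_ghat(self.ghat(g), hhat)

    def bp(self, a: np.ndarray, hhat: np.ndarray) -> np.ndarray:
        """Backprojection of a 2D image through one angle's PSF (FP adjoint).

        The image is embedded as the central slice, its 2D spectrum replicated
        across depth and multiplied with the conjugate of the laterally
        transposed PSF spectrum.
        """
        o1, o2 = self.off
        pad = np.zeros((self.p1, self.p2))
        pad[o1 : o1 + self.n1, o2 : o2 + self.n2] = a
        ahat = rfft2(pad)
        self.op_count += _fft_cost(self.p1, self.p2)
        full = irfft2(ahat[None, :, :] * np.conj(hhat), s=(self.p1, self.p2))
        self.op_count += self.n_z * (self.p1 * (self.p2 // 2 + 1) + _fft_cost(self.p1, self.p2))
        return np.ascontiguousarray(full[:, : self.n1, : self.n2].transpose(1, 2, 0))


def direct_conv_op_count(
    meas_shape: tuple[int, int], n_x_psf: int, n_z: int, n_angles: int
) -> float:
    """Operation-count model of one spatial-domain FP+BP pass by direct 2D
    convolution (the pre-Fourier reference path): every output sample touches
    the full PSF footprint, per depth and per angle."""
    n1, n2 = meas_shape
    per_conv = n1 * n2 * n_x_psf * n_x_psf
    return 2.0 * n_angles * n_z * per_conv


# ---------------------------------------------------------------------------
# Public per-angle operators
# ---------------------------------------------------------------------------

def fp_fourier(
    g: Volume, psf: PhaseSpacePSF, u, projector: FourierProjector | None = None
) -> np.ndarray:
    """Fourier-domain forward projection of a volume for one angle.

    Equals the spatial per-angle forward projection (depth-summed zero-padded
    2D convolution cropped to the volume grid) to floating-point tolerance.
    """
    if g.n_z != psf.n_z:
        raise ValueError("volume and PSF z-grids differ")
    proj = projector or FourierProjector(psf, g.lateral_shape)
    return proj.fp(g.g, proj.hhat(u))


def bp_fourier(
    a: np.ndarray,
    psf: PhaseSpacePSF,
    u,
    projector: FourierProjector | None = None,
) -> Volume:
    """Fourier-domain backprojection of a 2D image for one angle (FP adjoint).

    Expects a nonnegative image (a view or a forward projection); floating
    point roundoff below zero is clipped before the volume is assembled.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError("backprojection input must be a 2D image")
    proj = projector or FourierProjector(psf, a.shape)
    if a.shape != (proj.n1, proj.n2):
        raise ValueError(f"image shape {a.shape} does not match projector")
    vol = proj.bp(a, proj.hhat(u))
    return Volume(g=np.clip(vol, 0.0, None), z_planes=psf.z_planes)


# ---------------------------------------------------------------------------
# Richardson-Lucy updates
# ---------------------------------------------------------------------------

def _floor_div(num: np.ndarray, den: np.ndarray, epsilon: float) -> np.ndarray:
    m = den.max()
    if m <= 0:
        return np.zeros_like(num)
    return num / np.maximum(den, epsilon * m)


def _rl_full_arrays(
    x: np.ndarray,
    proj: FourierProjector,
    w_flat: np.ndarray,
    num: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Weighted all-angle update with a precomputed weighted numerator."""
    ghat = proj.ghat(x)
    den = np.zeros_like(x)
    for a, wa in enumerate(w_flat):
        if wa == 0.0:
            continue
        hh = proj.hhat(a)
        fp = proj.fp_from_ghat(ghat, hh)
        den += wa * proj.bp(fp, hh)
    return np.clip(x * _floor_div(num, den, epsilon), 0.0, None)


def _weighted_bp_of_data(
    proj: FourierProjector, y: np.ndarray, w_flat: np.ndarray
) -> np.ndarray:
    nu = int(np.sqrt(w_flat.size))
    num = np.zeros((proj.n1, proj.n2, proj.n_z))
    for a, wa in enumerate(w_flat):
        if wa == 0.0:
            continue
        num += wa * proj.bp(y[a // nu, a % nu], proj.hhat(a))
    return num


def rl_update_full(
    x: Volume,
    y: PhaseSpaceMeasurement,
    psf: PhaseSpacePSF,
    w: AngleWeights | None = None,
    epsilon: float = 1e-10,
    projector: FourierProjector | None = None,
) -> Volume:
    """One weighted all-angle MLE update (multiplicative; zero voxels stay zero)."""
    if x.g.max() <= 0:
        raise ValueError("all-zero volume cannot be updated multiplicatively")
    if w is None:
        w = angle_weights(psf)
    proj = projector or FourierProjector(psf, x.lateral_shape)
    w_flat = w.flat()
    num = _weighted_bp_of_data(proj, y.y, w_flat)
    out = _rl_full_arrays(x.g, proj, w_flat, num, epsilon)
    return Volume(g=out, z_planes=x.z_planes)


def _rl_group_arrays(
    x: np.ndarray,
    proj: FourierProjector,
    y: np.ndarray,
    group,
    epsilon: float,
    yhat_cache: dict | None = None,
) -> np.ndarray:
    """Unweighted update on a merged angle group: Y' = sum Y_u, H' = sum H_u."""
    nu = proj.psf.n_u
    hh = proj.hhat_group(group)
    merged = y[group[0] // nu, group[0] % nu].astype(float, copy=True)
    for a in group[1:]:
        merged += y[a // nu, a % nu]
    num = proj.bp(merged, hh)
    fp = proj.fp(x, hh)
    den = proj.bp(fp, hh)
    return np.clip(x * _floor_div(num, den, epsilon), 0.0, None)


def rl_update_subset(
    x: Volume,
    y: PhaseSpaceMeasurement,
    psf: PhaseSpacePSF,
    group,
    epsilon: float = 1e-10,
    projector: FourierProjector | None = None,
) -> Volume:
    """One subset update on a group of angles (pair, or singleton, or larger).

    The group's views and PSFs are merged by plain summation before a single
    unweighted ratio-of-backprojections update; a singleton group reduces to
    the single-angle update.
    """
    group = tuple(group) if not np.isscalar(group) else (group,)
    if len(group) == 0:
        raise ValueError("angle group must be nonempty")
    if x.g.max() <= 0:
        raise ValueError("all-zero volume cannot be updated multiplicatively")
    proj = projector or FourierProjector(psf, x.lateral_shape)
    group = tuple(proj.flat_angle(a) for a in group)
    out = _rl_group_arrays(x.g, proj, y.y, group, epsilon)
    return Volume(g=out, z_planes=x.z_planes)


# ---------------------------------------------------------------------------
# Total variation
# ---------------------------------------------------------------------------

def tv_gradient(x: np.ndarray, delta: float = 1e-8) -> np.ndarray:
    """Gradient of the smoothed isotropic 3D TV functional.

    ``TV(x) = sum sqrt(D1^2 + D2^2 + D3^2 + delta^2)`` with forward
    differences and replicate boundary (last difference zero along each axis);
    ``delta`` smooths the kink at flat voxels.
    """
    d1 = np.zeros_like(x)
    d2 = np.zeros_like(x)
    d3 = np.zeros_like(x)
    d1[:-1, :, :] = x[1:, :, :] - x[:-1, :, :]
    d2[:, :-1, :] = x[:, 1:, :] - x[:, :-1, :]
    d3[:, :, :-1] = x[:, :, 1:] - x[:, :, :-1]
    mag = np.sqrt(d1 * d1 + d2 * d2 + d3 * d3 + delta * delta)
    p1, p2, p3 = d1 / mag, d2 / mag, d3 / mag
    v = -(p1 + p2 + p3)
    v[1:, :, :] += p1[:-1, :, :]
    v[:, 1:, :] += p2[:, :-1, :]
    v[:, :, 1:] += p3[:, :, :-1]
    return v


def tv_step(x, alpha: float, k_tv: int, delta: float = 1e-8):
    """``k_tv`` normalised TV gradient-descent steps, clipped to nonnegative.

    Each step moves ``x`` by ``-alpha * v / ||v||_2`` along the TV gradient
    ``v``; a zero gradient (e.g. a constant volume) skips the step.  Accepts a
    raw 3D array or a :class:`~lfdeconv.simulate.Volume` and preserves type.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    is_volume = isinstance(x, Volume)
    arr = x.g.copy() if is_volume else np.array(x, dtype=float)
    if alpha > 0:
        for _ in range(k_tv):
            v = tv_gradient(arr, delta)
            norm = np.linalg.norm(v)
            if norm == 0.0:
                break
            arr -= alpha * v / norm
            np.clip(arr, 0.0, None, out=arr)
    return Volume(g=arr, z_planes=x.z_planes) if is_volume else arr


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def poisson_nll(
    y: np.ndarray, proj: FourierProjector, x: np.ndarray
) -> tuple[float, float]:
    """Poisson negative log-likelihood (up to the y! constant) and relative
    L2 data residual of a volume array against all measured views."""
    nu = proj.psf.n_u
    ghat = proj.ghat(x)
    nll = 0.0
    sq = 0.0
    ysq = 0.0
    for a in range(nu * nu):
        fp = proj.fp_from_ghat(ghat, proj.hhat(a))
        fp = np.clip(fp, 0.0, None)
        ya = y[a // nu, a % nu]
        nll += float(fp.sum() - np.sum(ya * np.log(np.maximum(fp, 1e-300)), where=ya > 0))
        sq += float(np.sum((fp - ya) ** 2))
        ysq += float(np.sum(ya**2))
    rel = np.sqrt(sq / ysq) if ysq > 0 else np.sqrt(sq)
    return nll, rel


# ---------------------------------------------------------------------------
# Full reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    """Fitted volume plus per-epoch diagnostics.

    per_iteration_metrics
        One row per epoch: ``iteration`` (1-based), ``nll`` (Poisson negative
        log-likelihood of the data fit), ``rel_residual`` (relative L2 misfit)
        and ``ssim`` (against the reference volume, NaN when none was given).
    """

    volume: Volume
    per_iteration_metrics: pd.DataFrame
    config_echo: DeconvConfig
    schedule: SubsetSchedule | None = None
    weights: AngleWeights | None = None

    def __post_init__(self) -> None:
        if np.any(self.volume.g < 0):
            raise ValueError("reconstructed volume must be nonnegative")
        if len(self.per_iteration_metrics) != self.config_echo.n_iter:
            raise ValueError("metrics must have one row per epoch")

    def summary(self) -> str:
        cfg = self.config_echo
        m = self.per_iteration_metrics
        lines = [
            "Fourier Phase-Space Deconvolution Results",
            "=" * 45,
            f"mode:            {cfg.mode}",
            f"epochs:          {cfg.n_iter}",
            f"TV alpha / K:    {cfg.alpha:g} / {cfg.k_tv}",
            f"seed:            {cfg.seed}",
            f"volume:          {self.volume.g.shape[0]}x{self.volume.g.shape[1]}"
            f"x{self.volume.n_z} voxels",
            f"final NLL:       {m['nll'].iloc[-1]:.6g}",
            f"final residual:  {m['rel_residual'].iloc[-1]:.6g}",
        ]
        if np.isfinite(m["ssim"].iloc[-1]):
            lines.append(f"final SSIM:      {m['ssim'].iloc[-1]:.4f}")
        lines.append("")
        lines.append(m.to_string(index=False))
        return "\n".join(lines)


def reconstruct(
    y: PhaseSpaceMeasurement,
    psf: PhaseSpacePSF,
    cfg: DeconvConfig | None = None,
    reference: Volume | None = None,
) -> ReconstructionResult:
    """Run the full iterative reconstruction.

    Initialisation is a uniform volume scaled so the total forward-projected
    intensity matches the total measured intensity.  Each epoch applies the
    configured data updates (all-angle weighted MLE, random subset pairs, or
    random single angles), then one TV application; Poisson NLL and the
    relative residual are recorded after every epoch, plus SSIM against
    ``reference`` when given.  Deterministic for a fixed config.
    """
    from .metrics import ssim_volume  # local import: metrics depends on simulate

    cfg = cfg or DeconvConfig()
    if cfg.upsample != 1:
        raise NotImplementedError(
            "sub-lenslet reconstruction grids (upsample > 1) require PSFs at "
            "sub-lenslet offsets, which the spatially-invariant PSF model "
            "does not provide"
        )
    if y.pitch_px != psf.n_u:
        raise ValueError(
            f"measurement has {y.pitch_px}x{y.pitch_px} views but PSF has "
            f"{psf.n_u}x{psf.n_u} angles"
        )
    n1, n2 = y.lateral_shape
    if reference is not None and reference.g.shape != (n1, n2, psf.n_z):
        raise ValueError("reference volume shape does not match reconstruction grid")
    proj = FourierProjector(psf, (n1, n2))
    n_angles = psf.n_angles

    # uniform init scaled to the measured photon budget
    x = np.ones((n1, n2, psf.n_z))
    ghat = proj.ghat(x)
    total_fp = sum(
        float(proj.fp_from_ghat(ghat, proj.hhat(a)).sum()) for a in range(n_angles)
    )
    y_total = float(y.y.sum())
    if total_fp <= 0:
        raise ValueError("PSF projects to zero; cannot initialise")
    x *= max(y_total, 1e-30) / total_fp

    schedule = None
    w = None
    num_full = None
    if cfg.mode == "mle_all_angles":
        w = angle_weights(psf)
        num_full = _weighted_bp_of_data(proj, y.y, w.flat())
    else:
        group_size = cfg.subset_size if cfg.mode == "subset_pairs" else 1
        schedule = make_subset_schedule(n_angles, cfg.n_iter, cfg.seed, group_size)

    rows = []
    for it in range(cfg.n_iter):
        if cfg.mode == "mle_all_angles":
            x = _rl_full_arrays(x, proj, w.flat(), num_full, cfg.epsilon)
            if cfg.alpha > 0 and cfg.k_tv > 0:
                x = tv_step(x, cfg.alpha, cfg.k_tv)
        else:
            for group in schedule.epochs[it]:
                x = _rl_group_arrays(x, proj, y.y, group, cfg.epsilon)
                if cfg.tv_per_subset and cfg.alpha > 0 and cfg.k_tv > 0:
                    x = tv_step(x, cfg.alpha, cfg.k_tv)
            if not cfg.tv_per_subset and cfg.alpha > 0 and cfg.k_tv > 0:
                x = tv_step(x, cfg.alpha, cfg.k_tv)
        nll, rel = poisson_nll(y.y, proj, x)
        ssim = np.nan
        if reference is not None:
            # compare on unit-max scales: the iterate lives on the photon
            # scale of the measurement, the reference on its own units
            xm = x.max()
            rm = reference.g.max()
            ssim = ssim_volume(
                Volume(g=x / xm if xm > 0 else x, z_planes=psf.z_planes),
                Volume(g=reference.g / rm if rm > 0 else reference.g,
                       z_planes=reference.z_planes),
            )
        rows.append({"iteration": it + 1, "nll": nll, "rel_residual": rel, "ssim": ssim})

    volume = Volume(g=x, z_planes=psf.z_planes)
    metrics = pd.DataFrame(rows, columns=["iteration", "nll", "rel_residual", "ssim"])
    return ReconstructionResult(
        volume=volume,
        per_iteration_metrics=metrics,
        config_echo=cfg,
        schedule=schedule,
        weights=w,
    )


class PhaseSpaceDeconvolution:
    """Model object binding a phase-space measurement to a PSF.

    Statsmodels-style entry point: construct from data, then :meth:`fit`
    returns a :class:`ReconstructionResult` carrying the volume estimate and
    per-epoch diagnostics.

    Examples
    --------
    >>> model = PhaseSpaceDeconvolution(measurement, psf)   # doctest: +SKIP
    >>> res = model.fit(n_iter=5, mode="subset_pairs", seed=1)  # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(self, measurement: PhaseSpaceMeasurement, psf: PhaseSpacePSF):
        if measurement.pitch_px != psf.n_u:
            raise ValueError(
                f"measurement has {measurement.pitch_px}x{measurement.pitch_px} "
                f"views but PSF has {psf.n_u}x{psf.n_u} angles"
            )
        self.measurement = measurement
        self.psf = psf

    @classmethod
    def from_raw(cls, raw: RawLFImage, psf: PhaseSpacePSF) -> "PhaseSpaceDeconvolution":
        """Build the model directly from a rectified raw sensor image."""
        return cls(realign(raw), psf)

    def fit(
        self,
        config: DeconvConfig | None = None,
        reference: Volume | None = None,
        **overrides,
    ) -> ReconstructionResult:
        cfg = config or DeconvConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        return reconstruct(self.measurement, self.psf, cfg, reference=reference)
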