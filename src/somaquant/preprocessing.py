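"""Channel restoration and normalization.

Order of operations is fixed: maximum-likelihood deconvolution (optional) →
background subtraction by grayscale opening → static per-channel thresholding
that zeroes sub-threshold voxels.  The deconvolver is a Richardson–Lucy
iteration with a parametric Gaussian PSF; the signal-to-noise ratio enters
only through an optional early-stopping heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from skimage.filters import threshold_otsu
from skimage.morphology import ball, disk
from skimage.morphology import opening as _grey_opening

from .geometry import VoxelGrid
from .imaging import MultiChannelStack

__all__ = [
    "DeconvolutionParams",
    "BackgroundParams",
    "ChannelThresholds",
    "gaussian_psf",
    "richardson_lucy",
    "deconvolve",
    "subtract_background",
    "binarize",
    "suggest_thresholds",
]


@dataclass(frozen=True)
class DeconvolutionParams:
    """Richardson–Lucy restoration settings.

    iterations : maximum RL iterations (typical 15–20).
    snr : expected signal-to-noise ratio; used only for the optional
        early-stopping rule (stop once the mean relative update falls below
        1/snr²).  Set ``stop_on_snr=False`` to always run all iterations.
    psf_sigma_xy, psf_sigma_z : Gaussian PSF standard deviations in µm.
    """

    iterations: int = 18
    snr: float = 25.0
    psf_sigma_xy: float = 0.3
    psf_sigma_z: float = 0.6
    stop_on_snr: bool = False
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.psf_sigma_xy < 0 or self.psf_sigma_z < 0:
            raise ValueError("PSF sigmas must be non-negative")


@dataclass(frozen=True)
class BackgroundParams:
    """Grayscale-opening background estimation.

    opening_radius_px : radius of the structuring element in pixels
        (default 19).  Applied slice-wise in XY by default because the axial
        extent of a stack is small relative to the element; a 3D ball is
        selectable.
    footprint : "disk-sequence" (fast sequence-decomposed approximation of the
        disk), "disk" (exact disk) or "ball" (3D).
    """

    opening_radius_px: int = 19
    footprint: str = "disk-sequence"

    def __post_init__(self) -> None:
        if self.opening_radius_px < 1:
            raise ValueError("opening radius must be >= 1")
        if self.footprint not in ("disk-sequence", "disk", "ball"):
            raise ValueError(f"unknown footprint {self.footprint!r}")


@dataclass(frozen=True)
class ChannelThresholds:
    """Static per-channel intensity thresholds (one scalar per channel)."""

    neurotrace: float
    neun: float
    pcjun: float
    draq5: float

    def __post_init__(self) -> None:
        for name in ("neurotrace", "neun", "pcjun", "draq5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold for {name!r} must be positive")

    def __getitem__(self, name: str) -> float:
        return float(getattr(self, name))

    def as_dict(self) -> dict[str, float]:
        return {n: self[n] for n in ("neurotrace", "neun", "pcjun", "draq5")}


def gaussian_psf(
    grid: VoxelGrid, sigma_xy_um: float, sigma_z_um: float
) -> np.ndarray:
    """Normalized 3D Gaussian PSF sampled on the grid's voxel spacing.

    Sigmas at or below a tenth of a voxel are treated as a delta kernel
    (identity PSF).
    """
    sz = sigma_z_um / grid.dz
    sy = sigma_xy_um / grid.dy
    sx = sigma_xy_um / grid.dx
    if max(sz, sy, sx) <= 0.1:
        return np.ones((1, 1, 1))
    half = [max(1, int(np.ceil(4 * s))) for s in (sz, sy, sx)]
    zz, yy, xx = np.meshgrid(
        *(np.arange(-h, h + 1, dtype=float) for h in half), indexing="ij"
    )
    expo = np.zeros_like(zz)
    for coord, s in ((zz, sz), (yy, sy), (xx, sx)):
        if s > 0:
            expo += (coord / s) ** 2
    psf = np.exp(-0.5 * expo)
    return psf / psf.sum()


def richardson_lucy(
    image: np.ndarray,
    psf: np.ndarray,
    iterations: int,
    snr: float | None = None,
) -> np.ndarray:
    """Richardson–Lucy maximum-likelihood restoration.

    The multiplicative update ``u ← u · (d / (u ⊗ psf)) ⊗ psf*`` maximizes the
    Poisson likelihood and preserves non-negativity.  When ``snr`` is given,
    iteration stops early once the mean relative update drops below
    ``1/snr²``.  Convolutions replicate the border (nearest boundary mode)
    so flat signal is an exact fixed point at the stack edges.
    """
    if not np.all(np.isfinite(image)):
        raise ValueError("deconvolution input contains non-finite intensities")
    image = np.asarray(image, dtype=np.float64)
    if psf.size == 1:
        return image.copy()
    psf_mirror = psf[::-1, ::-1, ::-1]
    eps = np.finfo(float).eps
    estimate = np.full_like(image, max(image.mean(), eps))
    for _ in range(iterations):
        blurred = ndi.convolve(estimate, psf, mode="nearest")
        ratio = image / np.maximum(blurred, eps)
        update = ndi.convolve(ratio, psf_mirror, mode="nearest")
        estimate_new = estimate * np.clip(update, 0, None)
        if snr is not None:
            rel = np.abs(estimate_new - estimate).mean() / max(
                estimate.mean(), eps
            )
            estimate = estimate_new
            if rel < 1.0 / snr**2:
                break
        else:
            estimate = estimate_new
    return np.clip(estimate, 0, None)


def deconvolve(
    stack: MultiChannelStack, params: DeconvolutionParams
) -> MultiChannelStack:
    """Deconvolve every channel with the parametric Gaussian PSF.

    Skippable: with ``params.enabled=False`` the stack passes through
    unchanged (synthetic inputs generated without optical blur need no
    restoration).
    """
    if not params.enabled:
        return stack
    psf = gaussian_psf(stack.grid, params.psf_sigma_xy, params.psf_sigma_z)
    snr = params.snr if params.stop_on_snr else None
    channels = {
        name: richardson_lucy(arr, psf, params.iterations, snr=snr)
        for name, arr in stack.channels.items()
    }
    return stack.replace_channels(channels)


def _opening_footprint(params: BackgroundParams):
    r = params.opening_radius_px
    if params.footprint == "disk":
        return disk(r)
    if params.footprint == "disk-sequence":
        return disk(r, decomposition="sequence")
    return ball(r)


def subtract_background(
    channel: np.ndarray, params: BackgroundParams
) -> np.ndarray:
    """White top-hat: subtract the grayscale-opening background estimate.

    Structures smaller than the element survive at full height; flat
    background (and any pedestal wider than the element) is removed.  The
    output is non-negative by construction and the operation is idempotent.
    """
    channel = np.asarray(channel)
    if channel.dtype != np.float32:
        channel = channel.astype(np.float64)
    fp = _opening_footprint(params)
    if params.footprint == "ball":
        background = ndi.grey_opening(channel, footprint=fp)
    else:
        background = np.empty_like(channel)
        for z in range(channel.shape[0]):
            background[z] = _grey_opening(channel[z], fp)
    return np.clip(channel - background, 0, None)


def binarize(
    channel: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Static threshold: mask of voxels ≥ threshold, sub-threshold zeroed.

    Returns ``(mask, retained)`` where ``retained`` equals the input on the
    mask and 0 elsewhere.  The boundary convention is inclusive: a voxel
    exactly at the threshold is positive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    channel = np.asarray(channel)
    mask = channel >= threshold
    retained = np.where(mask, channel, 0)
    return mask, retained


def suggest_thresholds(
    stack: MultiChannelStack, method: str = "otsu"
) -> ChannelThresholds:
    """Data-driven per-channel threshold suggestions (Otsu bimodal split).

    Suggestions never override explicit configuration; they exist to seed the
    manual threshold choice that the protocol leaves to expert observers.
    """
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    values = {}
    for name, arr in stack.channels.items():
        if np.ptp(arr) == 0:
            raise ValueError(
                f"channel {name!r} is constant; cannot suggest a threshold"
            )
        values[name] = float(threshold_otsu(np.asarray(arr).ravel()))
    return ChannelThresholds(**values)
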