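"""PSF estimation from bead stacks and Richardson-Lucy deconvolution.

The deconvolution is the standard multiplicative maximum-likelihood update
for a Poisson noise model, run with reflective boundary padding of one PSF
support so fibre-cropped volumes do not ring at the edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .types import VoxelVolume

__all__ = ["PointSpreadFunction", "gaussian_psf", "identity_psf", "estimate_psf", "richardson_lucy"]

log = logging.getLogger(__name__)


@dataclass
class PointSpreadFunction:
    """A unit-sum, non-negative 3D blur kernel with physical voxel spacing.

    ``kernel`` is indexed (z, y, x) and centred on its peak; ``voxel_size``
    is (dx, dy, dz) in nm.  ``provenance`` records whether the kernel was
    estimated from bead images or synthesised.
    """

    kernel: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if np.any(self.kernel < 0):
            raise ValueError("PSF kernel must be non-negative")
        s = self.kernel.sum()
        if s <= 0:
            raise ValueError("PSF kernel must have positive mass")
        if not np.isclose(s, 1.0, rtol=1e-6, atol=1e-9):
            warnings.warn("PSF kernel not normalized; normalizing to unit sum")
            self.kernel = self.kernel / s
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.kernel.shape  # type: ignore[return-value]

    def resampled_to(self, voxel_size: tuple[float, float, float]) -> "PointSpreadFunction":
        """Resample the kernel onto a different voxel grid (data untouched)."""
        if tuple(voxel_size) == self.voxel_size:
            return self
        # zoom factor per axis: kernel axes are (z, y, x), voxel_size is (dx, dy, dz)
        src = (self.voxel_size[2], self.voxel_size[1], self.voxel_size[0])
        dst = (voxel_size[2], voxel_size[1], voxel_size[0])
        factors = [s / d for s, d in zip(src, dst)]
        k = ndimage.zoom(self.kernel, factors, order=1, mode="nearest")
        k = np.clip(k, 0, None)
        k /= k.sum()
        return PointSpreadFunction(kernel=k, voxel_size=tuple(voxel_size),
                                   provenance=self.provenance,
                                   meta={**self.meta, "resampled": True})


def gaussian_psf(sigma_nm: tuple[float, float, float],
                 voxel_size: tuple[float, float, float],
                 truncate: float = 3.0) -> PointSpreadFunction:
    """Synthetic separable Gaussian PSF; ``sigma_nm`` is (sx, sy, sz)."""
    dx, dy, dz = voxel_size
    sx, sy, sz = (sigma_nm[0] / dx, sigma_nm[1] / dy, sigma_nm[2] / dz)
    half = [max(1, int(np.ceil(truncate * s))) for s in (sz, sy, sx)]
    zz, yy, xx = np.meshgrid(*(np.arange(-h, h + 1, dtype=float) for h in half), indexing="ij")
    k = np.exp(-0.5 * ((zz / sz) ** 2 + (yy / sy) ** 2 + (xx / sx) ** 2))
    k /= k.sum()
    return PointSpreadFunction(kernel=k, voxel_size=tuple(voxel_size), provenance="synthetic",
                               meta={"sigma_nm": list(sigma_nm)})


def identity_psf(voxel_size: tuple[float, float, float]) -> PointSpreadFunction:
    k = np.zeros((1, 1, 1))
    k[0, 0, 0] = 1.0
    return PointSpreadFunction(kernel=k, voxel_size=tuple(voxel_size), provenance="synthetic")


# ---------------------------------------------------------------------------
# PSF estimation from bead stacks


def _detect_beads(data: np.ndarray, window: tuple[int, int, int]) -> list[np.ndarray]:
    """Local maxima above mean + 5 sd, refined to subvoxel centroids."""
    thr = data.mean() + 5.0 * data.std()
    footprint = np.ones((3, 3, 3), bool)
    maxed = ndimage.maximum_filter(data, footprint=footprint, mode="constant")
    peaks = np.argwhere((data == maxed) & (data > thr))
    centres = []
    half = [w // 2 for w in window]
    for p in peaks:
        lo = [max(0, c - h) for c, h in zip(p, half)]
        hi = [min(n, c + h + 1) for c, h, n in zip(p, half, data.shape)]
        patch = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
        patch = np.clip(patch - patch.min(), 0, None)
        if patch.sum() <= 0:
            continue
        com = ndimage.center_of_mass(patch)
        centres.append(np.array(lo, dtype=float) + np.asarray(com))
    return centres


def estimate_psf(bead_stacks: list[VoxelVolume], bead_diameter: float,
                 window: tuple[int, int, int] | None = None) -> PointSpreadFunction:
    """Average aligned bead images into a PSF estimate.

    Bead centres are detected as bright local maxima, refined to subvoxel
    centroids, aligned by interpolation shift, averaged, background
    subtracted, clipped at zero and normalized to unit sum.  Beads whose
    extraction windows overlap are excluded with a warning.
    """
    if not bead_stacks:
        raise ValueError("need at least one bead stack")
    voxel_size = bead_stacks[0].voxel_size
    if window is None:
        # generous default: ~1.2 um xy, ~1.8 um z support
        dx, dy, dz = voxel_size
        window = (int(2 * round(900 / dz)) + 1,
                  int(2 * round(600 / dy)) + 1,
                  int(2 * round(600 / dx)) + 1)
    window = tuple(int(w) | 1 for w in window)  # force odd
    half = np.array([w // 2 for w in window])

    accum = np.zeros(window, dtype=np.float64)
    n_used = 0
    for stack in bead_stacks:
        data = np.asarray(stack.data, dtype=np.float64)
        centres = _detect_beads(data, window)
        # drop overlapping windows
        kept = []
        for i, c in enumerate(centres):
            ok = True
            for j, d in enumerate(centres):
                if i != j and np.all(np.abs(c - d) < 2 * half + 1):
                    ok = False
            if ok:
                kept.append(c)
        if len(kept) < len(centres):
            warnings.warn(f"excluded {len(centres) - len(kept)} beads with overlapping windows")
        for c in kept:
            ci = np.rint(c).astype(int)
            lo = ci - half
            hi = ci + half + 1
            if np.any(lo < 0) or np.any(hi > np.array(data.shape)):
                continue
            patch = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            frac = c - ci
            if np.any(np.abs(frac) > 1e-6):
                patch = ndimage.shift(patch, -frac, order=1, mode="nearest")
            accum += patch
            n_used += 1
    if n_used == 0:
        raise ValueError("no beads detected above background (mean + 5 sd)")
    psf = accum / n_used
    # background: median over the window faces
    border = np.concatenate([psf[0].ravel(), psf[-1].ravel(),
                             psf[:, 0].ravel(), psf[:, -1].ravel(),
                             psf[:, :, 0].ravel(), psf[:, :, -1].ravel()])
    psf = np.clip(psf - np.median(border), 0, None)
    if psf.sum() <= 0:
        raise ValueError("PSF estimate has no mass after background subtraction")
    # centre on the peak
    peak = np.unravel_index(np.argmax(psf), psf.shape)
    psf = np.roll(psf, [h - p for h, p in zip(half, peak)], axis=(0, 1, 2))
    psf /= psf.sum()
    log.info("estimated PSF from %d beads", n_used)
    return PointSpreadFunction(kernel=psf, voxel_size=voxel_size, provenance="estimated",
                               meta={"n_beads": n_used, "bead_diameter_nm": bead_diameter})


# ---------------------------------------------------------------------------
# Richardson-Lucy


def _otf(kernel: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Kernel embedded at the origin of ``shape`` and transformed."""
    k = np.zeros(shape, dtype=np.float64)
    ks = kernel.shape
    k[tuple(slice(0, s) for s in ks)] = kernel
    k = np.roll(k, [-(s // 2) for s in ks], axis=(0, 1, 2))
    return sfft.rfftn(k)


def richardson_lucy(volume: VoxelVolume, psf: PointSpreadFunction,
                    iterations: int = 25, stop_tol: float | None = None) -> VoxelVolume:
    """Richardson-Lucy maximum-likelihood deconvolution.

    Multiplicative update with reflective padding by one PSF support.
    Output is non-negative; an identity PSF returns the input unchanged
    (to float tolerance) for any iteration count.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains NaN/inf values")
    psf = psf.resampled_to(volume.voxel_size)
    kernel = psf.kernel
    if any(k > d for k, d in zip(kernel.shape, data.shape)):
        raise ValueError("PSF support exceeds volume size")

    offset = min(0.0, data.min())
    data = data - offset  # RL requires non-negative observations
    pad = [(s // 2, s // 2) for s in kernel.shape]
    padded = np.pad(data, pad, mode="reflect")
    shape = padded.shape
    otf = _otf(kernel, shape)
    otf_conj = np.conj(otf)

    eps = 1e-12
    est = padded.copy()
    prev = None
    for _ in range(iterations):
        conv = sfft.irfftn(sfft.rfftn(est) * otf, shape)
        np.clip(conv, eps, None, out=conv)
        ratio = padded / conv
        corr = sfft.irfftn(sfft.rfftn(ratio) * otf_conj, shape)
        est *= corr
        np.clip(est, 0.0, None, out=est)
        if stop_tol is not None:
            denom = np.abs(est).sum() + eps
            if prev is not None and np.abs(est - prev).sum() / denom < stop_tol:
                break
            prev = est.copy()

    crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pad, data.shape))
    out = est[crop] + offset
    return volume.with_data(out, restored={"method": "richardson_lucy",
                                           "iterations": iterations,
                                           "psf_provenance": psf.provenance})
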