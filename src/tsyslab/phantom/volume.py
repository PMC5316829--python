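"""Renderers for synthetic fibre volumes and bead stacks.

The fibre is a straight cylinder along y.  Transverse tubules are rendered
as perforated planes — a grid of thin tubules at a configurable pitch,
two planes per sarcomere at the quarter positions (the A-I junctions).
Longitudinal tubules are y-aligned columns placed with a peripheral radial
bias and added until the tubule volume fraction meets the target; vacuoles
are ellipsoids laid out in longitudinal series.  Intensities compose by
maximum (structures sit on top of any uniform in-fibre glow), so masks are
recoverable exactly by voxel counting.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy.signal import fftconvolve

from ..restoration import PointSpreadFunction
from ..types import VoxelVolume
from .spec import NoiseModel, PhantomSpec, PhantomTruth

__all__ = ["generate_tsys_volume", "generate_bead_stack", "simulate_imaging"]

log = logging.getLogger(__name__)


def _axes_nm(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    return z, y, x


def _fibre_cross_section(spec: PhantomSpec):
    """Boolean (nz, nx) disc mask and the centre (cz, cx) in nm."""
    z, _, x = _axes_nm(spec)
    cz, cx = z.mean(), x.mean()
    r_nm = spec.fibre_radius * 1000.0
    zz, xx = np.meshgrid(z, x, indexing="ij")
    disc = (zz - cz) ** 2 + (xx - cx) ** 2 <= r_nm ** 2
    return disc, (cz, cx)


def _transverse_plane_y_nm(spec: PhantomSpec) -> list[float]:
    """Two tubule planes per sarcomere, at the quarter positions."""
    L = spec.sarcomere_length * 1000.0
    n_sarc = int(math.floor(spec.fibre_length * 1000.0 / L + 1e-9))
    ys = []
    y_max = min(spec.fibre_length, spec.grid_shape[1] * spec.voxel_size[1] / 1000.0) * 1000.0
    for i in range(n_sarc):
        for frac in (0.25, 0.75):
            y = (i + frac) * L
            if y < y_max:
                ys.append(y)
    return ys


def _render_transverse(spec: PhantomSpec, pitch_um: float):
    """Rasterize one perforated transverse plane pattern and its truth lines.

    Returns (pattern2d (nz, nx) bool, list of 2D polylines [(z, x) nm arrays]).
    """
    dx, dy, dz = spec.voxel_size
    z, _, x = _axes_nm(spec)
    disc, (cz, cx) = _fibre_cross_section(spec)
    r_nm = spec.fibre_radius * 1000.0
    pitch = pitch_um * 1000.0
    wx = max(1, int(round(spec.tubule_width / dx)))
    wz = max(1, int(round(spec.tubule_width / dz)))

    nz, nx = disc.shape
    pattern = np.zeros((nz, nx), dtype=bool)
    lines = []

    m_max = int(r_nm // pitch)
    # lines along x at fixed z offsets
    for m in range(-m_max, m_max + 1):
        z0 = cz + m * pitch
        half = r_nm ** 2 - (z0 - cz) ** 2
        if half <= 0:
            continue
        half = math.sqrt(half)
        iz = int(np.argmin(np.abs(z - z0)))
        zlo, zhi = max(0, iz - (wz - 1) // 2), min(nz, iz + wz // 2 + 1)
        xs = np.flatnonzero(np.abs(x - cx) <= half)
        if xs.size == 0:
            continue
        pattern[zlo:zhi, xs[0]:xs[-1] + 1] = True
        pts = np.stack([np.full(xs.size, z[iz]), x[xs]], axis=1)  # (z, x) nm
        lines.append(pts)
    # lines along z at fixed x offsets
    m_max_x = int(r_nm // pitch)
    for m in range(-m_max_x, m_max_x + 1):
        x0 = cx + m * pitch
        half = r_nm ** 2 - (x0 - cx) ** 2
        if half <= 0:
            continue
        half = math.sqrt(half)
        ix = int(np.argmin(np.abs(x - x0)))
        xlo, xhi = max(0, ix - (wx - 1) // 2), min(nx, ix + wx // 2 + 1)
        zs = np.flatnonzero(np.abs(z - cz) <= half)
        if zs.size == 0:
            continue
        pattern[zs[0]:zs[-1] + 1, xlo:xhi] = True
        pts = np.stack([z[zs], np.full(zs.size, x[ix])], axis=1)
        lines.append(pts)
    pattern &= disc
    return pattern, lines


def _sample_radial(rng: np.random.Generator, r_max_nm: float, exponent: float,
                   centre: tuple[float, float]) -> tuple[float, float]:
    """Sample (z, x) nm with areal density ~ (r/R)^exponent."""
    u = rng.random()
    r = r_max_nm * u ** (1.0 / (exponent + 2.0))
    phi = rng.random() * 2 * np.pi
    cz, cx = centre
    return cz + r * math.sin(phi), cx + r * math.cos(phi)


def generate_tsys_volume(spec: PhantomSpec, transverse_budget_fraction: float = 0.8,
                         ) -> tuple[VoxelVolume, PhantomTruth]:
    """Render the synthetic t-system and its exact ground truth.

    The transverse lattice pitch is coarsened automatically (with a log
    message) until the lattice consumes at most ``transverse_budget_fraction``
    of the target tubule volume; longitudinal tubules then fill the
    remainder, sampled with the peripheral radial bias.
    """
    dx, dy, dz = spec.voxel_size
    if spec.tubule_width < min(dx, dy, dz):
        log.warning("tubule width %.0f nm below voxel size; rendering 1 voxel wide",
                    spec.tubule_width)
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.grid_shape
    z_nm, y_nm, x_nm = _axes_nm(spec)

    disc, centre = _fibre_cross_section(spec)
    y_extent = spec.fibre_length * 1000.0
    y_in = y_nm <= y_extent
    fibre = np.zeros(spec.grid_shape, dtype=bool)
    fibre[:, y_in, :] = disc[:, None, :]
    n_fibre = int(fibre.sum())
    if n_fibre == 0:
        raise ValueError("fibre does not intersect the voxel grid")
    target_vox = spec.target_tsys_volume_fraction / 100.0 * n_fibre

    # transverse lattice, auto-coarsening the pitch to leave longitudinal budget
    pitch = spec.transverse_pitch
    plane_ys = _transverse_plane_y_nm(spec)
    wy = max(1, int(round(spec.tubule_width / dy)))
    for _ in range(12):
        pattern, lines2d = _render_transverse(spec, pitch)
        per_plane = int(pattern.sum()) * wy
        if per_plane * len(plane_ys) <= transverse_budget_fraction * target_vox or pattern.sum() == 0:
            break
        pitch *= 1.25
    if pitch != spec.transverse_pitch:
        log.info("transverse pitch coarsened %.2f -> %.2f um to meet the volume target",
                 spec.transverse_pitch, pitch)

    tubule = np.zeros(spec.grid_shape, dtype=bool)
    segments: list[tuple[np.ndarray, str]] = []
    for y0 in plane_ys:
        iy = int(np.argmin(np.abs(y_nm - y0)))
        ylo, yhi = max(0, iy - (wy - 1) // 2), min(ny, iy + wy // 2 + 1)
        tubule[:, ylo:yhi, :] |= pattern[:, None, :]
        for pts2d in lines2d:
            pts = np.stack([pts2d[:, 0], np.full(len(pts2d), y_nm[iy]), pts2d[:, 1]], axis=1)
            segments.append((pts, "transverse"))

    # longitudinal tubules fill the remaining budget
    r_nm = spec.fibre_radius * 1000.0
    wx = max(1, int(round(spec.tubule_width / dx)))
    wz = max(1, int(round(spec.tubule_width / dz)))
    plane_idx = [int(np.argmin(np.abs(y_nm - y0))) for y0 in plane_ys]
    count = int(tubule[fibre].sum())
    typical = None
    for _ in range(50000):
        if not plane_idx or len(plane_idx) < 2:
            break
        deficit = target_vox - count
        if typical is not None and deficit < typical / 2:
            break
        if deficit <= 0:
            break
        zc, xc = _sample_radial(rng, 0.92 * r_nm, spec.longitudinal_radial_exponent, centre)
        iz = int(np.argmin(np.abs(z_nm - zc)))
        ix = int(np.argmin(np.abs(x_nm - xc)))
        p0 = int(rng.integers(0, len(plane_idx) - 1))
        span = int(rng.integers(1, min(4, len(plane_idx) - p0 - 1) + 1))
        iy0, iy1 = plane_idx[p0], plane_idx[p0 + span]
        zlo, zhi = max(0, iz - (wz - 1) // 2), min(nz, iz + wz // 2 + 1)
        xlo, xhi = max(0, ix - (wx - 1) // 2), min(nx, ix + wx // 2 + 1)
        before = int(tubule[zlo:zhi, iy0:iy1 + 1, xlo:xhi].sum())
        tubule[zlo:zhi, iy0:iy1 + 1, xlo:xhi] = True
        added = int(tubule[zlo:zhi, iy0:iy1 + 1, xlo:xhi].sum()) - before
        count += added
        if added > 0:
            pts = np.stack([np.full(iy1 - iy0 + 1, z_nm[iz]), y_nm[iy0:iy1 + 1],
                            np.full(iy1 - iy0 + 1, x_nm[ix])], axis=1)
            segments.append((pts, "longitudinal"))
        if typical is None:
            typical = max(added, 1)
    tubule &= fibre

    # vacuoles in longitudinal series
    vac = np.zeros(spec.grid_shape, dtype=bool)
    n_vac = 0
    if spec.vacuole_count > 0:
        ax_nm = np.array(spec.vacuole_axes) * 500.0  # semi-axes (x, y, z) nm
        L = spec.sarcomere_length * 1000.0
        n_sarc = max(1, int(y_extent // L))
        placed_centres: list[np.ndarray] = []
        n_series = math.ceil(spec.vacuole_count / spec.vacuole_series_length)
        zz3, yy3, xx3 = np.meshgrid(z_nm, y_nm, x_nm, indexing="ij")
        for s in range(n_series):
            remaining = spec.vacuole_count - n_vac
            in_series = min(spec.vacuole_series_length, remaining)
            for _try in range(200):
                r_cap = max(r_nm - max(ax_nm[0], ax_nm[2]) - 2 * max(dx, dz), 0.2 * r_nm)
                zc, xc = _sample_radial(rng, r_cap, spec.longitudinal_radial_exponent, centre)
                s0 = int(rng.integers(0, max(1, n_sarc - in_series + 1)))
                ycs = [(s0 + j + 0.5) * L for j in range(in_series)]
                cand = [np.array([zc, yc, xc]) for yc in ycs]
                min_sep = 2.2 * max(ax_nm)
                ok = all(np.linalg.norm(c - p) > min_sep
                         for c in cand for p in placed_centres)
                if ok:
                    break
            for c in cand:
                e = (((xx3 - c[2]) / ax_nm[0]) ** 2 + ((yy3 - c[1]) / ax_nm[1]) ** 2
                     + ((zz3 - c[0]) / ax_nm[2]) ** 2) <= 1.0
                vac |= e
                placed_centres.append(c)
                n_vac += 1
    vac &= fibre
    tubule &= ~vac  # disjoint label sets

    data = np.zeros(spec.grid_shape, dtype=np.float64)
    if spec.fibre_glow > 0:
        data[fibre] = spec.fibre_glow
    np.maximum(data, np.where(tubule, spec.tubule_intensity, 0.0), out=data)
    np.maximum(data, np.where(vac, spec.vacuole_intensity, 0.0), out=data)

    tub_frac = 100.0 * int(tubule[fibre].sum()) / n_fibre
    vac_frac = 100.0 * int(vac[fibre].sum()) / n_fibre
    volume = VoxelVolume(data=data, voxel_size=spec.voxel_size, fibre_mask=fibre,
                         meta={"generator": "tsys_phantom", "seed": spec.rng_seed,
                               "transverse_pitch_um": pitch})
    truth = PhantomTruth(centreline_segments=segments, tsys_mask=tubule | vac,
                         vacuole_mask=vac, fibre_mask=fibre,
                         tubule_volume_fraction=tub_frac,
                         vacuole_volume_fraction=vac_frac, vacuole_count=n_vac)
    return volume, truth


def generate_bead_stack(n_beads: int, bead_diameter: float,
                        psf_truth: PointSpreadFunction, spec: PhantomSpec,
                        bead_intensity: float = 1000.0,
                        snap_to_voxel: bool = False) -> VoxelVolume:
    """Sub-voxel point beads convolved with a known PSF, plus optional noise.

    Beads are separated by at least two PSF supports; placement failure in
    a too-small volume raises.  Bead centres (voxel coordinates, z/y/x) are
    recorded in ``meta['bead_centres_vox']``.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid_shape
    ks = np.array(psf_truth.kernel.shape)
    margin = ks // 2 + 1
    min_sep = 2.0 * ks.astype(float)  # two PSF supports, per axis
    lo, hi = margin, np.array(shape) - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the PSF support")
    centres: list[np.ndarray] = []
    for _ in range(2000 * n_beads):
        c = lo + rng.random(3) * (hi - lo)
        if snap_to_voxel:
            c = np.rint(c)
        if all(np.any(np.abs(c - p) >= min_sep) for p in centres) or not centres:
            centres.append(c)
        if len(centres) == n_beads:
            break
    if len(centres) < n_beads:
        raise ValueError(f"could not place {n_beads} beads with >= 2 PSF-width separation")

    field = np.zeros(shape, dtype=np.float64)
    for c in centres:
        base = np.floor(c).astype(int)
        frac = c - base
        for dzi in (0, 1):
            for dyi in (0, 1):
                for dxi in (0, 1):
                    w = ((frac[0] if dzi else 1 - frac[0])
                         * (frac[1] if dyi else 1 - frac[1])
                         * (frac[2] if dxi else 1 - frac[2]))
                    if w > 0:
                        field[base[0] + dzi, base[1] + dyi, base[2] + dxi] += bead_intensity * w
    if psf_truth.kernel.size == 1:
        data = field * float(psf_truth.kernel.ravel()[0])
    else:
        data = fftconvolve(field, psf_truth.kernel, mode="same")
        np.clip(data, 0, None, out=data)
    data = spec.noise_model.apply(data, rng)
    return VoxelVolume(data=data, voxel_size=spec.voxel_size,
                       meta={"generator": "bead_stack", "seed": spec.rng_seed,
                             "bead_diameter_nm": bead_diameter,
                             "bead_centres_vox": [c.tolist() for c in centres]})


def simulate_imaging(volume: VoxelVolume, psf: PointSpreadFunction,
                     noise_model: NoiseModel | None = None,
                     rng_seed: int | None = None) -> VoxelVolume:
    """Forward imaging model: blur by the PSF, then apply the noise model.

    Convolution is circular (FFT), which conserves total intensity exactly
    for a unit-sum kernel; intensities are kept in float internally and
    clipped to 16 bits only on export.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    kernel = psf.resampled_to(volume.voxel_size).kernel
    if any(k > d for k, d in zip(kernel.shape, data.shape)):
        raise ValueError("PSF support exceeds volume size")
    if kernel.size == 1:
        blurred = data * float(kernel.ravel()[0])
    else:
        from scipy import fft as sfft
        shape = data.shape
        k = np.zeros(shape)
        k[tuple(slice(0, s) for s in kernel.shape)] = kernel
        k = np.roll(k, [-(s // 2) for s in kernel.shape], axis=(0, 1, 2))
        blurred = sfft.irfftn(sfft.rfftn(data) * sfft.rfftn(k), shape)
    if noise_model is None or noise_model.is_off():
        out = blurred
    else:
        rng = np.random.default_rng(rng_seed)
        out = noise_model.apply(blurred, rng)
    return volume.with_data(out, imaged={"psf": psf.provenance,
                                         "noise": None if noise_model is None
                                         else [noise_model.photon_scale,
                                               noise_model.read_noise_sd]})
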