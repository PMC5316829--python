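"""Vacuole segmentation by intensity-percentile threshold and morphometrics.

The threshold is a percentile of the intensity histogram restricted to the
fibre mask (so extrafibre background cannot shift it); the mask is voxels
strictly brighter than the percentile value.  Connected components
(26-connectivity) below a minimum size are discarded.  Roundness is the
per-z-plane inverse aspect ratio of a second-moment ellipse fit,
aggregated per vacuole as an area-weighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label

from .types import VoxelVolume

__all__ = ["VacuoleSegmentation", "VacuoleTable", "default_min_voxels",
           "segment_vacuoles", "vacuole_roundness", "vacuole_summary"]


@dataclass
class VacuoleSegmentation:
    """Labelled vacuole grid plus the thresholding provenance."""

    labels: np.ndarray
    threshold: float
    percentile: float
    min_voxels: int

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


@dataclass
class VacuoleTable:
    """Per-vacuole morphometrics and fibre-level summaries."""

    per_vacuole: pd.DataFrame  # id, voxel_count, volume_um3, centroid_z/y/x_nm, roundness
    vacuole_count: int
    volume_fraction_percent: float
    count_density_per_1000_um3: float
    fibre_volume_um3: float
    threshold_percentile: float

    def summary_dict(self) -> dict:
        return {
            "vacuole_count": self.vacuole_count,
            "volume_fraction_percent": self.volume_fraction_percent,
            "count_density_per_1000_um3": self.count_density_per_1000_um3,
            "fibre_volume_um3": self.fibre_volume_um3,
            "threshold_percentile": self.threshold_percentile,
            "mean_roundness": (float(self.per_vacuole["roundness"].mean())
                               if len(self.per_vacuole) else float("nan")),
        }


def default_min_voxels(voxel_size: tuple[float, float, float],
                       min_diameter_um: float = 0.4) -> int:
    """Voxel count of a sphere of ``min_diameter_um`` (noise-speck rejection)."""
    dx, dy, dz = voxel_size
    sphere_um3 = math.pi / 6.0 * min_diameter_um ** 3
    voxel_um3 = dx * dy * dz * 1e-9
    return max(1, int(round(sphere_um3 / voxel_um3)))


def segment_vacuoles(volume: VoxelVolume, percentile: float = 55.0,
                     min_voxels: int | None = None,
                     fibre_mask: np.ndarray | None = None) -> VacuoleSegmentation:
    """Label vacuole candidate components above the percentile threshold.

    A constant volume yields an empty labelling (the threshold equals every
    value and the strict inequality admits nothing).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    data = np.asarray(volume.data, dtype=np.float64)
    if fibre_mask is None:
        fibre_mask = volume.fibre_mask
    region = data[fibre_mask] if fibre_mask is not None else data.ravel()
    thr = float(np.percentile(region, percentile))
    mask = data > thr
    if fibre_mask is not None:
        mask &= fibre_mask
    if min_voxels is None:
        min_voxels = default_min_voxels(volume.voxel_size)
    labels = cc_label(mask, connectivity=3)
    if labels.max() > 0 and min_voxels > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        keep = np.ones(counts.size, dtype=bool)
        keep[small] = False
        keep[0] = False
        labels = cc_label(keep[labels], connectivity=3)
    return VacuoleSegmentation(labels=labels, threshold=thr,
                               percentile=percentile, min_voxels=int(min_voxels))


def _plane_roundness(coords_yx: np.ndarray) -> float:
    """Inverse aspect ratio of a second-moment ellipse fit to one z-slice."""
    if len(coords_yx) == 1:
        return 1.0  # single-voxel slice: round by convention
    c = coords_yx - coords_yx.mean(axis=0)
    # second central moments with the 1/12 pixel self-variance term, as in
    # ellipse fits to rasterized regions
    cov = c.T @ c / len(c) + np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    if evals[1] <= 0:
        return 1.0
    return float(math.sqrt(max(evals[0], 0.0) / evals[1]))


def vacuole_roundness(labels: np.ndarray | VacuoleSegmentation) -> dict[int, float]:
    """Area-weighted mean per-plane roundness of each labelled component."""
    if isinstance(labels, VacuoleSegmentation):
        labels = labels.labels
    out: dict[int, float] = {}
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        num = den = 0.0
        for z in range(sub.shape[0]):
            coords = np.argwhere(sub[z])
            if coords.size == 0:
                continue
            area = len(coords)
            num += area * _plane_roundness(coords.astype(float))
            den += area
        out[lab] = num / den if den else 1.0
    return out


def vacuole_summary(seg: VacuoleSegmentation, fibre_mask: np.ndarray,
                    voxel_size: tuple[float, float, float]) -> VacuoleTable:
    """Fibre-level vacuole metrics: count, % volume, count density, roundness."""
    fibre_mask = np.asarray(fibre_mask, dtype=bool)
    n_fibre = int(fibre_mask.sum())
    if n_fibre == 0:
        raise ValueError("empty fibre mask")
    dx, dy, dz = voxel_size
    voxel_um3 = dx * dy * dz * 1e-9
    fibre_um3 = n_fibre * voxel_um3

    labels = seg.labels
    rows = []
    roundness = vacuole_roundness(labels)
    counts = np.bincount(labels.ravel())
    for lab in range(1, labels.max() + 1):
        n_vox = int(counts[lab]) if lab < counts.size else 0
        if n_vox == 0:
            continue
        cz, cy, cx = ndimage.center_of_mass(labels == lab)
        rows.append({"id": lab, "voxel_count": n_vox,
                     "volume_um3": n_vox * voxel_um3,
                     "centroid_z_nm": (cz + 0.5) * dz,
                     "centroid_y_nm": (cy + 0.5) * dy,
                     "centroid_x_nm": (cx + 0.5) * dx,
                     "roundness": roundness.get(lab, 1.0)})
    df = pd.DataFrame(rows, columns=["id", "voxel_count", "volume_um3",
                                     "centroid_z_nm", "centroid_y_nm",
                                     "centroid_x_nm", "roundness"])
    n_vac_vox = int((labels > 0).sum())
    return VacuoleTable(
        per_vacuole=df,
        vacuole_count=len(df),
        volume_fraction_percent=100.0 * n_vac_vox / n_fibre,
        count_density_per_1000_um3=len(df) / fibre_um3 * 1000.0,
        fibre_volume_um3=fibre_um3,
        threshold_percentile=seg.percentile,
    )
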