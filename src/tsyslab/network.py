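"""Tubular-network centreline extraction and orientation analysis.

A binarized tubule mask is thinned to a 1-voxel medial axis, converted to
a graph of branch/end nodes joined by polyline segments, and each segment
is labelled transverse or longitudinal from the angle of its end-to-end
chord to the fibre's transverse plane.  A structure-tensor directionality
histogram reproduces the local-orientation analysis applied to single
longitudinal planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from skimage import filters
from skimage import morphology
from skimage.feature import structure_tensor

from .types import VoxelVolume

__all__ = [
    "Skeleton", "SkeletonSegment", "DirectionalityHistogram",
    "binarize_tubules", "skeletonize", "classify_segments",
    "directionality_histogram", "longitudinal_radial_profile",
    "score_segment_recovery",
]

#: fibre axis in (z, y, x) component order — the long image axis
DEFAULT_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass
class SkeletonSegment:
    """A centreline polyline between two branch/end nodes.

    ``points_nm`` is (N, 3) in (z, y, x) physical coordinates.  ``theta_deg``
    is the chord angle to the transverse plane in [0, 90]; ``label`` is
    'transverse' or 'longitudinal' once classified.
    """

    points_nm: np.ndarray
    theta_deg: Optional[float] = None
    label: Optional[str] = None

    @property
    def chord_nm(self) -> np.ndarray:
        return self.points_nm[-1] - self.points_nm[0]

    @property
    def length_nm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_nm, axis=0), axis=1).sum())


@dataclass
class Skeleton:
    """Centreline graph of the tubular network (physical nm coordinates)."""

    segments: list[SkeletonSegment]
    nodes_nm: np.ndarray                  # (M, 3) branch/end node positions
    voxel_size: tuple[float, float, float]
    voxels: Optional[np.ndarray] = None   # (K, 3) integer skeleton voxel coords
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "voxel_size_nm": list(self.voxel_size),
            "nodes_nm": self.nodes_nm.tolist(),
            "segments": [{"points_nm": s.points_nm.tolist(),
                          "theta_deg": s.theta_deg, "label": s.label}
                         for s in self.segments],
            "provenance": self.provenance,
        }


@dataclass
class DirectionalityHistogram:
    """Percentage histogram of local orientation vs the transverse plane."""

    bin_edges_deg: np.ndarray
    percent: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.percent.sum(), 100.0, atol=1e-6):
            raise ValueError("histogram percentages must sum to 100")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bin_start_deg": self.bin_edges_deg[:-1],
                             "bin_end_deg": self.bin_edges_deg[1:],
                             "percent": self.percent})


# ---------------------------------------------------------------------------


def binarize_tubules(volume: VoxelVolume, method: str = "otsu") -> np.ndarray:
    """Threshold a volume into a tubule foreground mask.

    ``method`` is 'otsu' or 'triangle' (thresholds computed within the
    fibre mask when present; triangle is more robust when a few very
    bright vacuoles dominate the histogram tail), 'percentile:P', or
    'value:V'.  A contrast-free (constant) volume raises.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume intensities must be finite")
    region = data[volume.fibre_mask] if volume.fibre_mask is not None else data.ravel()
    if region.max() == region.min():
        raise ValueError("constant volume: nothing to binarize")
    if method == "otsu":
        thr = filters.threshold_otsu(region)
    elif method == "triangle":
        thr = filters.threshold_triangle(region)
    elif method.startswith("percentile:"):
        thr = np.percentile(region, float(method.split(":", 1)[1]))
    elif method.startswith("value:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = data > thr
    if volume.fibre_mask is not None:
        mask &= volume.fibre_mask
    if not mask.any():
        raise ValueError("binarization produced an empty mask")
    return mask


_NEIGHBOURS = np.array([(dz, dy, dx)
                        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                        if (dz, dy, dx) != (0, 0, 0)])


def skeletonize(mask: np.ndarray, voxel_size: tuple[float, float, float],
                min_segment_voxels: int = 3) -> Skeleton:
    """Medial-axis thinning followed by graph tracing.

    End/branch voxels (26-neighbour degree != 2) become nodes; paths of
    degree-2 voxels between them become polyline segments.  Spur segments
    shorter than ``min_segment_voxels`` are suppressed as thinning
    artifacts.  Masks touching the border are processed with padding and
    flagged in provenance.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to skeletonize")
    touches_border = bool(
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any())
    padded = np.pad(mask, 1)
    skel = morphology.skeletonize(padded)
    skel = skel[1:-1, 1:-1, 1:-1]
    # thinning of a padded mask can only move voxels inward; enforce containment
    skel &= mask

    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _NEIGHBOURS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                nbrs[i].append(j)
    degree = np.array([len(n) for n in nbrs])
    node_ids = set(np.flatnonzero(degree != 2).tolist())

    dx, dy, dz = voxel_size
    scale = np.array([dz, dy, dx])

    def to_nm(idx_list):
        return (coords[idx_list] + 0.5) * scale

    segments: list[SkeletonSegment] = []
    visited_edges = set()

    def walk(start: int, first: int) -> list[int]:
        path = [start, first]
        prev, cur = start, first
        while cur not in node_ids:
            nxt = [n for n in nbrs[cur] if n != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
            if cur == start:  # closed loop
                break
        return path

    for n in sorted(node_ids):
        for first in nbrs[n]:
            edge = (min(n, first), max(n, first))
            if edge in visited_edges:
                continue
            path = walk(n, first)
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add((min(a, b), max(a, b)))
            is_spur = degree[path[0]] <= 1 or degree[path[-1]] <= 1
            if is_spur and len(path) < min_segment_voxels:
                continue
            segments.append(SkeletonSegment(points_nm=to_nm(path)))
    # cycles with no branch voxels at all (isolated rings)
    seen = set()
    for a, b in visited_edges:
        seen.add(a)
        seen.add(b)
    for i in range(len(coords)):
        if degree[i] == 2 and i not in seen and i not in node_ids:
            path = walk(i, nbrs[i][0])
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add((min(a, b), max(a, b)))
                seen.add(a)
                seen.add(b)
            if len(path) >= min_segment_voxels:
                segments.append(SkeletonSegment(points_nm=to_nm(path)))
    if not segments and len(coords) > 0:
        # single isolated voxels / tiny clusters: keep them as degenerate segments
        segments = [SkeletonSegment(points_nm=to_nm(list(range(len(coords)))))]

    nodes_nm = to_nm(sorted(node_ids)) if node_ids else np.empty((0, 3))
    return Skeleton(segments=segments, nodes_nm=np.asarray(nodes_nm),
                    voxel_size=tuple(voxel_size), voxels=coords,
                    provenance={"touches_border": touches_border,
                                "n_skeleton_voxels": int(len(coords))})


def chord_angle_deg(chord: np.ndarray, fibre_axis: np.ndarray = DEFAULT_AXIS) -> float:
    """Angle of a chord to the transverse plane (0 = in-plane, 90 = axial)."""
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("zero-length chord")
    axis = fibre_axis / np.linalg.norm(fibre_axis)
    s = abs(float(np.dot(chord, axis))) / norm
    return float(np.degrees(np.arcsin(min(1.0, s))))


def classify_segments(skeleton: Skeleton, angle_threshold: float = 45.0,
                      fibre_axis: np.ndarray = DEFAULT_AXIS) -> Skeleton:
    """Label each segment transverse (theta < threshold) or longitudinal.

    Theta is measured from the end-to-end chord; zero-length (closed-loop)
    segments are dropped with a warning.
    """
    kept = []
    for seg in skeleton.segments:
        if len(seg.points_nm) < 2 or np.allclose(seg.chord_nm, 0):
            warnings.warn("dropping zero-length segment during classification")
            continue
        theta = chord_angle_deg(seg.chord_nm, fibre_axis)
        seg.theta_deg = theta
        seg.label = "transverse" if theta < angle_threshold else "longitudinal"
        kept.append(seg)
    skeleton.segments = kept
    skeleton.provenance["angle_threshold_deg"] = angle_threshold
    return skeleton


def directionality_histogram(plane: np.ndarray, n_bins: int = 18,
                             sigma: float = 2.0, signed: bool = False,
                             border: int | None = None) -> DirectionalityHistogram:
    """Structure-tensor orientation histogram of a longitudinal (y, x) plane.

    Per-pixel orientation is taken from the eigenvector of the local
    structure tensor; each pixel contributes its anisotropic gradient
    energy (difference of tensor eigenvalues) to the orientation bin.
    Angles are measured from the transverse (x) direction: 0 deg =
    structures running across the fibre, 90 deg = along the fibre axis
    (rows = y = fibre axis, columns = x).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("expected a single 2D plane")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if plane.max() == plane.min():
        raise ValueError("constant image: no orientation energy")
    ayy, axy, axx = structure_tensor(plane, sigma=sigma, order="rc")
    # orientation of the structure (minor eigenvector of the tensor),
    # measured from the x (transverse) axis toward y (fibre axis)
    theta = 0.5 * np.arctan2(2 * axy, axx - ayy) + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2  # wrap to (-90, 90]
    lam = np.sqrt(((axx - ayy) / 2) ** 2 + axy ** 2)  # (l1 - l2)/2
    weight = 2 * lam
    if border is None:
        border = max(2, int(np.ceil(3 * sigma)))
    if plane.shape[0] > 2 * border and plane.shape[1] > 2 * border:
        w = np.zeros_like(weight)
        w[border:-border, border:-border] = weight[border:-border, border:-border]
        weight = w
    total = weight.sum()
    if total <= 0:
        raise ValueError("no orientation energy in the plane")
    deg = np.degrees(theta)
    if signed:
        edges = np.linspace(-90.0, 90.0, n_bins + 1)
    else:
        deg = np.abs(deg)
        edges = np.linspace(0.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(deg.ravel(), bins=edges, weights=weight.ravel())
    percent = 100.0 * hist / hist.sum()
    # exact renormalization to guard against float drift
    percent *= 100.0 / percent.sum()
    return DirectionalityHistogram(bin_edges_deg=edges, percent=percent)


def longitudinal_radial_profile(skeleton: Skeleton,
                                fibre_centre_nm: tuple[float, float],
                                fibre_radius_nm: float,
                                n_shells: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal-tubule length density per radial shell.

    ``fibre_centre_nm`` is (cz, cx).  Returns (shell_edges_normalized,
    density) where density is segment length per unit shell volume,
    normalized so shells are comparable; all-zero when no longitudinal
    segments exist.
    """
    edges = np.linspace(0.0, 1.0, n_shells + 1)
    length = np.zeros(n_shells)
    cz, cx = fibre_centre_nm
    for seg in skeleton.segments:
        if seg.label != "longitudinal":
            continue
        pts = seg.points_nm
        mids = 0.5 * (pts[1:] + pts[:-1])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        r = np.sqrt((mids[:, 0] - cz) ** 2 + (mids[:, 2] - cx) ** 2) / fibre_radius_nm
        idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_shells - 1)
        np.add.at(length, idx, steps)
    shell_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * fibre_radius_nm ** 2
    density = length / shell_area  # per unit cross-section area (per unit volume x length)
    return edges, density


def score_segment_recovery(truth_segments: list, skeleton: Skeleton,
                           tolerance_nm: float | None = None,
                           match_fraction: float = 0.5) -> dict:
    """Fraction of ground-truth segments recovered with the correct label.

    A truth segment counts as recovered when at least ``match_fraction`` of
    its sampled points lie within ``tolerance_nm`` of a skeleton voxel, and
    the majority label among the nearest skeleton segments matches the
    truth label.
    """
    if tolerance_nm is None:
        tolerance_nm = 3.0 * max(skeleton.voxel_size)
    pts = []
    labels = []
    for si, seg in enumerate(skeleton.segments):
        if seg.label is None:
            raise ValueError("skeleton must be classified before scoring")
        pts.append(seg.points_nm)
        labels.extend([seg.label] * len(seg.points_nm))
    if not pts:
        return {"recovered_fraction": 0.0, "n_truth": len(truth_segments),
                "n_correct": 0, "n_detected": 0}
    tree = cKDTree(np.concatenate(pts))
    labels = np.array(labels)

    n_correct = n_detected = 0
    for t_pts, t_label in truth_segments:
        t_pts = np.asarray(t_pts)
        dist, idx = tree.query(t_pts)
        hit = dist <= tolerance_nm
        if hit.mean() >= match_fraction:
            n_detected += 1
            hit_labels = labels[idx[hit]]
            majority = "transverse" if (hit_labels == "transverse").sum() * 2 >= len(hit_labels) \
                else "longitudinal"
            if majority == t_label:
                n_correct += 1
    n_truth = max(1, len(truth_segments))
    return {"recovered_fraction": n_correct / n_truth,
            "n_truth": len(truth_segments), "n_correct": n_correct,
            "n_detected": n_detected}
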