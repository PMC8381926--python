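"""Threshold segmentation and extraction of registration primitives.

Produces the three inputs the registration stage consumes: sub-voxel bead
centroids (connected metal components within a size window), the implant
metal mask (cup body with thread), and bone-surface point clouds.

Connectivity conventions: 26-neighbour for connected components,
6-neighbour (face adjacency) for surface extraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import CTVolume

__all__ = [
    "BeadSet",
    "PointCloud",
    "SegmentationError",
    "BeadExtractionError",
    "EmptyMaskError",
    "threshold_segment",
    "extract_beads",
    "extract_surface_points",
    "split_bone_and_implant",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


class SegmentationError(RuntimeError):
    pass


class BeadExtractionError(SegmentationError):
    pass


class EmptyMaskError(SegmentationError):
    pass


@dataclass(frozen=True)
class PointCloud:
    """Unlabelled 3-D points in world mm."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        p.setflags(write=False)
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class BeadSet:
    """Labelled fiducial centroids in world mm, with per-bead volumes.

    Labels are unique integers; beads are ordered by centroid (x, y, z) at
    extraction time, which makes labelling deterministic.
    """

    points: np.ndarray
    labels: np.ndarray
    volumes_mm3: np.ndarray = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        lab = np.asarray(self.labels, dtype=int).reshape(-1)
        if lab.shape[0] != p.shape[0]:
            raise ValueError("labels and points length mismatch")
        if len(set(lab.tolist())) != lab.shape[0]:
            raise ValueError("bead labels must be unique")
        vols = self.volumes_mm3
        vols = np.zeros(p.shape[0]) if vols is None else np.asarray(vols, dtype=float).reshape(-1)
        if vols.shape[0] != p.shape[0]:
            raise ValueError("volumes and points length mismatch")
        for arr in (p, lab, vols):
            arr.setflags(write=False)
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "volumes_mm3", vols)

    def __len__(self) -> int:
        return self.points.shape[0]

    def require_well_posed(self, min_points: int = 3) -> None:
        """Raise unless the set supports a rigid fit (>= 3 non-collinear)."""
        if len(self) < min_points:
            raise BeadExtractionError(f"need >= {min_points} beads, found {len(self)}")
        c = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-300):
            raise BeadExtractionError("bead configuration is collinear")

    def subset(self, indices) -> "BeadSet":
        idx = np.asarray(indices, dtype=int)
        return BeadSet(self.points[idx], self.labels[idx], self.volumes_mm3[idx])

    # CSV schema shared with the phantom ground-truth export
    def to_csv(self, path, exam: int = 1, structure: str = "bead") -> None:
        pd.DataFrame({
            "exam": exam,
            "structure": structure,
            "label": self.labels,
            "x_mm": self.points[:, 0],
            "y_mm": self.points[:, 1],
            "z_mm": self.points[:, 2],
        }).to_csv(path, index=False, float_format="%.6f")

    @staticmethod
    def from_csv(path, exam: int | None = None, structure: str | None = None) -> "BeadSet":
        df = pd.read_csv(path)
        if exam is not None:
            df = df[df["exam"] == exam]
        if structure is not None:
            df = df[df["structure"] == structure]
        if df.empty:
            raise ValueError(f"{path}: no beads match exam={exam}, structure={structure}")
        return BeadSet(df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                       df["label"].to_numpy())


def threshold_segment(volume: CTVolume, threshold_hu: float) -> np.ndarray:
    """Binary mask of voxels with intensity >= ``threshold_hu``.

    Keeps the grid geometry of the input; an all-false result is allowed
    (downstream stages decide whether that is an error).
    """
    return np.asarray(volume.data) >= float(threshold_hu)


def extract_beads(
    volume: CTVolume,
    threshold_hu: float = 2200.0,
    min_volume_mm3: float = 0.1,
    max_volume_mm3: float = 2.0,
) -> BeadSet:
    """Detect fiducial beads as small connected metal components.

    Components of the thresholded mask (26-connectivity) whose voxel volume
    falls in ``[min_volume_mm3, max_volume_mm3]`` are kept — the window
    excludes both noise specks and large implant structures. Centroids are
    intensity-weighted means of component voxel world positions, with
    weights ``max(HU - threshold, 0)`` so partial-volume edge voxels pull
    the centroid sub-voxel. Beads are sorted by centroid (x, y, z) and
    labelled 0..n-1.
    """
    mask = threshold_segment(volume, threshold_hu)
    labelled, n_comp = ndimage.label(mask, structure=_CONN26)
    if n_comp == 0:
        raise BeadExtractionError(
            "fewer than 3 beads found (no voxels above threshold "
            f"{threshold_hu} HU); review threshold and size window"
        )
    voxvol = volume.voxel_volume_mm3
    counts = np.bincount(labelled.ravel())[1:]  # component 1..n
    keep = np.where(
        (counts * voxvol >= min_volume_mm3) & (counts * voxvol <= max_volume_mm3)
    )[0] + 1
    data = np.asarray(volume.data, dtype=float)
    weights_vol = np.clip(data - threshold_hu, 0.0, None)
    centroids = []
    volumes = []
    for comp in keep:
        idx = np.argwhere(labelled == comp).astype(float)
        w = weights_vol[labelled == comp]
        if w.sum() <= 0:
            w = np.ones(idx.shape[0])
        frac_index = (idx * w[:, None]).sum(axis=0) / w.sum()
        centroids.append(volume.index_to_world(frac_index))
        volumes.append(idx.shape[0] * voxvol)
    if len(centroids) < 3:
        raise BeadExtractionError(
            f"fewer than 3 beads found ({len(centroids)}); review threshold "
            "and bead size window"
        )
    pts = np.asarray(centroids)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    vols = np.asarray(volumes)[order]
    return BeadSet(pts, np.arange(len(pts)), vols)


def extract_surface_points(
    mask: np.ndarray,
    volume: CTVolume,
    subsample_fraction: float = 1.0,
    seed: int = 0,
) -> PointCloud:
    """World coordinates of mask boundary voxels.

    A boundary voxel has at least one face-adjacent (6-neighbour) background
    neighbour; voxels on the array edge count as boundary. Optional uniform
    subsampling keeps a seeded random fraction in deterministic order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract a surface from an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_CONN6, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if subsample_fraction < 1.0:
        n_keep = max(1, int(round(subsample_fraction * idx.shape[0])))
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(idx.shape[0], size=n_keep, replace=False))
        idx = idx[sel]
    return PointCloud(volume.index_to_world(idx.astype(float)))


def extract_isosurface_points(
    volume: CTVolume,
    level_hu: float,
    region_mask: np.ndarray | None = None,
    fill_hu: float | None = None,
    supersample: int = 1,
) -> PointCloud:
    """Sub-voxel isosurface vertices of the HU field at ``level_hu``.

    Marching cubes on the (anti-aliased) intensity field localises the
    surface well below voxel size, which boundary-voxel clouds cannot; this
    is what the surface-registration route uses. ``region_mask`` restricts
    the extraction: intensities outside the (dilated) mask are clamped to
    ``fill_hu`` (default: level - 1000) so only the structure of interest
    contributes vertices.

    ``supersample > 1`` resamples the (cropped) field on a finer grid with
    cubic splines before isosurfacing. Marching cubes interpolates linearly
    between samples, which biases vertices on strongly curved structures by
    up to ~0.1 mm at 0.6-mm voxels; supersampling removes most of that.
    """
    from skimage import measure

    data = np.asarray(volume.data, dtype=float)
    if region_mask is not None:
        region = ndimage.binary_dilation(np.asarray(region_mask, dtype=bool),
                                         structure=_CONN6, iterations=2)
        fill = level_hu - 1000.0 if fill_hu is None else fill_hu
        data = np.where(region, data, fill)
    if not ((data > level_hu).any() and (data < level_hu).any()):
        raise EmptyMaskError(f"no isosurface at {level_hu} HU")
    offset = np.zeros(3)
    scale = 1.0
    if supersample > 1:
        above = np.argwhere(data > level_hu)
        lo = np.maximum(above.min(axis=0) - 3, 0)
        hi = np.minimum(above.max(axis=0) + 4, data.shape)
        crop = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        data = ndimage.zoom(crop, supersample, order=3, grid_mode=True,
                            mode="nearest")
        offset = lo.astype(float)
        scale = float(supersample)
    verts, _, _, _ = measure.marching_cubes(data, level=level_hu)
    if scale != 1.0:
        verts = (verts + 0.5) / scale - 0.5 + offset
    return PointCloud(volume.index_to_world(verts))


def split_bone_and_implant(
    beads: BeadSet,
    implant_mask: np.ndarray,
    volume: CTVolume,
    clearance_mm: float = 3.4,
    min_bone: int = 3,
    min_implant: int = 3,
) -> tuple[BeadSet, BeadSet]:
    """Assign beads to the implant or the bone by proximity to the cup.

    The cup is the largest connected component of the metal mask; beads whose
    centroid lies within ``clearance_mm`` of any cup voxel centre are implant
    beads, the rest are bone beads. Both sets retain their labels. Either
    side ending with fewer than 3 beads is an error.
    """
    from scipy.spatial import cKDTree

    implant_mask = np.asarray(implant_mask, dtype=bool)
    if not implant_mask.any():
        raise EmptyMaskError("implant mask is empty")
    labelled, n_comp = ndimage.label(implant_mask, structure=_CONN26)
    counts = np.bincount(labelled.ravel())[1:]
    cup_label = int(np.argmax(counts)) + 1
    cup_idx = np.argwhere(labelled == cup_label).astype(float)
    tree = cKDTree(volume.index_to_world(cup_idx))
    dist, _ = tree.query(beads.points)
    is_implant = dist <= clearance_mm
    bone_idx = np.where(~is_implant)[0]
    implant_idx = np.where(is_implant)[0]
    if bone_idx.shape[0] < min_bone:
        raise BeadExtractionError(
            f"only {bone_idx.shape[0]} bone beads after split (need >= "
            f"{min_bone}); clearance {clearance_mm} mm may be too large"
        )
    if implant_idx.shape[0] < min_implant:
        raise BeadExtractionError(
            f"only {implant_idx.shape[0]} implant beads after split (need >= "
            f"{min_implant}); clearance {clearance_mm} mm may be too small"
        )
    return beads.subset(bone_idx), beads.subset(implant_idx)
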