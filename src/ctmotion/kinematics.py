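"""Implant-vs-bone motion: composition, 6-DOF decomposition, reorientation,
and the end-to-end two-volume analysis pipeline.

Conventions (documented because commercial tools leave them unstated):

* the relative motion is ``bone⁻¹ ∘ implant`` — the implant transform
  expressed in the bone-anchored frame, identity when both bodies moved
  together;
* translations are reported as the displacement of the implant centre of
  mass; rotations are fixed-frame Cardan angles about x, then y, then z
  (configurable), with the centre of mass as the rotation origin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from . import segmentation as seg
from .registration import (
    DegenerateConfigurationError,
    MatchingError,
    RigidTransform,
    coarse_align,
    icp_register,
    kabsch_fit,
    match_beads,
    quality_gate,
)
from .volume_io import ANATOMICAL_BASIS_RSA, AnalysisConfig, CTVolume

__all__ = [
    "MigrationResult",
    "PipelineError",
    "relative_motion",
    "decompose_6dof",
    "recompose",
    "center_of_mass",
    "reorient",
    "run_ctma",
]

log = logging.getLogger(__name__)

#: flag gimbal lock when |ry| is within this many degrees of 90
_GIMBAL_MARGIN_DEG = 0.1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass(frozen=True)
class MigrationResult:
    """Six-degree-of-freedom implant-vs-bone motion with quality metrics."""

    translations_mm: np.ndarray
    rotations_deg: np.ndarray
    center_of_mass_mm: np.ndarray
    frame: str  # dicom | anatomical
    mode: str = "beads"  # beads | surface
    quality: dict = field(default_factory=dict)
    motion: Optional[RigidTransform] = None
    euler_order: str = "xyz"
    gimbal_warning: bool = False
    alt_rotations_deg: Optional[np.ndarray] = None
    alt_euler_order: Optional[str] = None
    gates: dict = field(default_factory=dict)
    pair_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.translations_mm, dtype=float).reshape(3)
        r = np.asarray(self.rotations_deg, dtype=float).reshape(3)
        c = np.asarray(self.center_of_mass_mm, dtype=float).reshape(3)
        if np.any(r <= -180.0) or np.any(r > 180.0):
            raise ValueError(f"rotations must lie in (-180, 180] deg, got {r}")
        if self.frame not in ("dicom", "anatomical"):
            raise ValueError(f"frame must be 'dicom' or 'anatomical', got {self.frame!r}")
        object.__setattr__(self, "translations_mm", t)
        object.__setattr__(self, "rotations_deg", r)
        object.__setattr__(self, "center_of_mass_mm", c)

    @property
    def dof(self) -> np.ndarray:
        """The six values as (tx, ty, tz, rx, ry, rz)."""
        return np.concatenate([self.translations_mm, self.rotations_deg])

    def to_dict(self) -> dict:
        d = {
            "pair_id": self.pair_id,
            "mode": self.mode,
            "frame": self.frame,
            "translations_mm": [float(v) for v in self.translations_mm],
            "rotations_deg": [float(v) for v in self.rotations_deg],
            "center_of_mass_mm": [float(v) for v in self.center_of_mass_mm],
            "euler_order": self.euler_order,
            "gimbal_warning": bool(self.gimbal_warning),
            "quality": {k: q.to_dict() for k, q in self.quality.items()},
            "gates": {k: {"passed": g.passed, "reasons": list(g.reasons)}
                      for k, g in self.gates.items()},
        }
        if self.motion is not None:
            d["motion"] = self.motion.to_dict()
        return d


def relative_motion(bone: RigidTransform, implant: RigidTransform) -> RigidTransform:
    """Implant motion in the bone-anchored frame: ``bone⁻¹ ∘ implant``.

    Both inputs map exam-1 world coordinates to exam-2 world coordinates for
    their respective body; the result is identity when the bodies moved
    together (pure patient repositioning).
    """
    return bone.inverse() @ implant


def decompose_6dof(
    motion: RigidTransform,
    com,
    order: str = "xyz",
    frame: str = "dicom",
    **result_kwargs,
) -> MigrationResult:
    """Decompose a rigid motion into 6 DOF about a centre of mass.

    Translation is the displacement of ``com`` under the motion; rotation is
    reported as fixed-frame Cardan angles (lowercase scipy convention:
    ``xyz`` rotates about world x first, then y, then z). Near gimbal lock
    (|middle angle| within 0.1° of 90°) the result is flagged and an
    alternate-sequence decomposition is attached.
    """
    com = np.asarray(com, dtype=float).reshape(3)
    if not np.all(np.isfinite(com)):
        raise ValueError("centre of mass must be finite")
    t = motion.apply(com) - com
    rot = Rotation.from_matrix(motion.rotation)
    angles = rot.as_euler(order, degrees=True)
    gimbal = bool(abs(abs(angles[1]) - 90.0) <= _GIMBAL_MARGIN_DEG)
    alt_order = None
    alt_angles = None
    if gimbal:
        alt_order = {"xyz": "zxy", "zyx": "yzx"}.get(order, "zxy")
        alt_angles = rot.as_euler(alt_order, degrees=True)
    return MigrationResult(
        translations_mm=t,
        rotations_deg=angles,
        center_of_mass_mm=com,
        frame=frame,
        motion=motion,
        euler_order=order,
        gimbal_warning=gimbal,
        alt_rotations_deg=alt_angles,
        alt_euler_order=alt_order,
        **result_kwargs,
    )


def recompose(result: MigrationResult) -> RigidTransform:
    """Inverse of :func:`decompose_6dof` (exact round trip)."""
    rot = Rotation.from_euler(result.euler_order, result.rotations_deg, degrees=True)
    r = rot.as_matrix()
    com = result.center_of_mass_mm
    t = com + result.translations_mm - r @ com
    return RigidTransform(r, t)


def center_of_mass(implant_mask: np.ndarray, volume: CTVolume) -> np.ndarray:
    """Unweighted mean world position of the mask voxels."""
    mask = np.asarray(implant_mask, dtype=bool)
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise seg.EmptyMaskError("cannot compute centre of mass of an empty mask")
    return volume.index_to_world(idx.astype(float).mean(axis=0))


def reorient(
    result: MigrationResult,
    basis,
    sign_convention=(1, 1, 1),
) -> MigrationResult:
    """Re-express a migration result in a new orthonormal frame.

    ``basis`` rows are the new axes in the current frame (a proper rotation:
    ``p_new = basis @ p_old``). The underlying motion is conjugated into the
    new frame and re-decomposed about the transformed centre of mass, then
    per-axis rotation signs are flipped according to ``sign_convention``.
    With the identity basis and all-positive signs this is the identity
    operation (apart from relabelling the frame as ``anatomical``).
    """
    b = np.asarray(basis, dtype=float).reshape(3, 3)
    if np.abs(b.T @ b - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(b) - 1) > 1e-9:
        raise ValueError("basis must be orthonormal with det = +1")
    signs = np.asarray(sign_convention, dtype=float).reshape(3)
    if not np.all(np.isin(signs, (-1.0, 1.0))):
        raise ValueError("sign_convention entries must be +1 or -1")
    if result.motion is None:
        raise ValueError("result carries no motion transform; cannot reorient")
    g = RigidTransform(b, np.zeros(3))
    motion_new = g @ result.motion @ g.inverse()
    com_new = b @ result.center_of_mass_mm
    out = decompose_6dof(
        motion_new, com_new, order=result.euler_order, frame="anatomical",
        mode=result.mode, quality=result.quality, gates=result.gates,
        pair_id=result.pair_id,
    )
    return replace(out, rotations_deg=out.rotations_deg * signs)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _stage(name):
    """Wrap stage failures with the stage name for diagnosability."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _bone_surface_cloud(
    volume: CTVolume, bone_thr: float, metal_thr: float
) -> seg.PointCloud:
    """Sub-voxel bone isosurface: metal clamped out, largest component kept.

    Metal voxels are clamped to soft tissue before isosurfacing so only
    bone/soft transitions cross the level; the holes this leaves around
    in-bone beads move rigidly with the bone and help the registration.
    """
    data = np.asarray(volume.data, dtype=float)
    clamped = np.where(data >= metal_thr, bone_thr - 1000.0, data)
    mask = clamped >= bone_thr
    if not mask.any():
        raise seg.EmptyMaskError(f"no voxels in [{bone_thr}, {metal_thr}) HU")
    bone_mask = _largest_component(mask)
    work = CTVolume(clamped, volume.spacing, volume.origin, volume.orientation)
    return seg.extract_isosurface_points(work, bone_thr, region_mask=bone_mask)


def _implant_surface_cloud(
    volume: CTVolume, metal_thr: float, clearance_mm: float
) -> seg.PointCloud:
    """Sub-voxel isosurface of the implant metal: cup, thread AND cup beads.

    The cup-with-thread surface alone is nearly invariant under a screw
    motion (rotate about the cup axis while sliding one thread pitch), so
    the liner beads must be part of the cloud to pin that degree of freedom.
    Implant beads are the metal voxels within ``clearance_mm`` of the cup
    component (the same ownership rule as the bead split).
    """
    from scipy import ndimage

    metal = np.asarray(volume.data) >= metal_thr
    cup = _largest_component(metal)
    dist = ndimage.distance_transform_edt(~cup, sampling=volume.spacing)
    region = cup | (metal & (dist <= clearance_mm))
    return seg.extract_isosurface_points(volume, metal_thr, region_mask=region,
                                         supersample=2)


def _sweep_init(
    source: seg.PointCloud, target: seg.PointCloud, seed: int, n_azimuth: int = 24
) -> RigidTransform:
    """Coarse alignment robust to near-symmetric clouds.

    PCA coarse alignment leaves the rotation about an approximate symmetry
    axis poorly determined; sweep azimuth offsets about the target's most
    distinct principal axis and keep the candidate with the lowest
    nearest-neighbour RMS on a seeded probe subsample.
    """
    from scipy.spatial.transform import Rotation as _R

    from .registration import _subsample, coarse_align_candidates

    bases = coarse_align_candidates(source, target)
    tgt = np.asarray(target.points)
    src = np.asarray(source.points)
    ct = tgt.mean(axis=0)
    _, _, vt = np.linalg.svd(tgt - ct, full_matrices=False)
    axis = vt[2]  # smallest-variance direction ~ symmetry axis of a shell
    candidates = []
    for base in bases:
        for k in range(n_azimuth):
            ang = 2.0 * np.pi * k / n_azimuth
            rot = _R.from_rotvec(axis * ang).as_matrix()
            spin = RigidTransform(rot, ct - rot @ ct)  # rotate about target centroid
            candidates.append(spin @ base)
    # deduplicate (flip candidates often coincide with azimuth spins of
    # each other on a near-symmetric cloud)
    unique: list = []
    for cand in candidates:
        if not any((cand.inverse() @ u).rotation_angle_deg < 5.0 for u in unique):
            unique.append(cand)
    # the raw NN score is almost flat in azimuth (the shell dominates, the
    # asymmetric features are few) — rank candidates by where a short
    # point-metric ICP takes them instead
    probe = seg.PointCloud(_subsample(src, 2000, seed + 2))
    best, best_rms = None, np.inf
    for cand in unique:
        refined, q = icp_register(
            probe, target, cand, metric="point",
            max_iter=12, tol_mm=1e-3, max_target_points=20000, seed=seed + 4)
        if q.mean_error_mm < best_rms - 1e-12:
            best_rms = q.mean_error_mm
            best = refined
    return best


def run_ctma(
    exam1: CTVolume,
    exam2: CTVolume,
    config: AnalysisConfig | None = None,
    pair_id: str = "",
) -> MigrationResult:
    """Full migration analysis of one examination pair.

    Stages: metal segmentation and bead extraction on both exams; bead
    ownership split (cup vs bone); bone registration (matched beads or bone
    surface ICP per ``config.registration_mode``); implant registration
    (matched cup beads, with an ICP fallback on the thread+bead surface when
    fewer than 3 bead pairs survive); relative motion; 6-DOF decomposition
    about the implant centre of mass; optional reorientation into the
    anatomical frame. Quality-gate failures are recorded on the result but
    do not abort the analysis.
    """
    if config is None:
        config = AnalysisConfig()

    with _stage("segmentation"):
        metal1 = seg.threshold_segment(exam1, config.metal_threshold_hu)
        metal2 = seg.threshold_segment(exam2, config.metal_threshold_hu)
        beads1 = seg.extract_beads(
            exam1, config.metal_threshold_hu,
            config.bead_min_volume_mm3, config.bead_max_volume_mm3)
        beads2 = seg.extract_beads(
            exam2, config.metal_threshold_hu,
            config.bead_min_volume_mm3, config.bead_max_volume_mm3)
        bone_beads1, impl_beads1 = seg.split_bone_and_implant(
            beads1, metal1, exam1, config.bead_clearance_mm)
        bone_beads2, impl_beads2 = seg.split_bone_and_implant(
            beads2, metal2, exam2, config.bead_clearance_mm)

    with _stage("bone_registration"):
        if config.registration_mode == "beads":
            bone_beads1.require_well_posed()
            bone_beads2.require_well_posed()
            init = coarse_align(bone_beads1.points, bone_beads2.points, seed=config.seed)
            corr = match_beads(bone_beads1, bone_beads2, init,
                               max_distance_mm=config.match_max_distance_mm)
            bone_t, bone_q = kabsch_fit(
                bone_beads1.points[corr.index_a], bone_beads2.points[corr.index_b])
        else:
            cloud1 = _bone_surface_cloud(
                exam1, config.bone_threshold_for_exam(1), config.metal_threshold_hu)
            cloud2 = _bone_surface_cloud(
                exam2, config.bone_threshold_for_exam(2), config.metal_threshold_hu)
            init = _sweep_init(cloud1, cloud2, seed=config.seed)
            # point-metric capture first, then point-to-plane refinement
            # (plane metric removes the tangential sampling-noise floor)
            capture, _ = icp_register(
                cloud1, cloud2, init, metric="point",
                max_iter=config.icp_max_iter, tol_mm=1e-3,
                max_target_points=config.max_surface_points, seed=config.seed)
            bone_t, bone_q = icp_register(
                cloud1, cloud2, capture, metric="plane",
                max_iter=config.icp_max_iter, tol_mm=config.icp_tol_mm,
                max_target_points=config.max_surface_points, seed=config.seed)

    with _stage("implant_registration"):
        # the implant registers on "thread and beads": a matched-bead fit
        # seeds an ICP refinement on the cup metal isosurface, whose thread
        # supplies the rotational stability the small bead cluster lacks
        anchors = {}
        try:
            impl_beads1.require_well_posed()
            impl_beads2.require_well_posed()
            corr_i = match_beads(impl_beads1, impl_beads2, bone_t,
                                 max_distance_mm=config.match_max_distance_mm)
            impl_init, _ = kabsch_fit(
                impl_beads1.points[corr_i.index_a], impl_beads2.points[corr_i.index_b])
            # bead centroids are far more accurate than thread isosurface
            # vertices: anchor the ICP's screw-slide direction with them
            anchors = dict(
                anchor_source=impl_beads1.points[corr_i.index_a],
                anchor_target=impl_beads2.points[corr_i.index_b],
            )
        except (seg.SegmentationError, MatchingError, DegenerateConfigurationError) as exc:
            log.warning("implant bead fit unavailable (%s); initialising the "
                        "thread+bead ICP from the bone transform", exc)
            impl_init = bone_t
        surf1 = _implant_surface_cloud(exam1, config.metal_threshold_hu,
                                       config.bead_clearance_mm)
        surf2 = _implant_surface_cloud(exam2, config.metal_threshold_hu,
                                       config.bead_clearance_mm)
        icp_kwargs = dict(
            metric="plane", max_iter=config.icp_max_iter,
            max_target_points=config.max_surface_points, seed=config.seed)
        if anchors:
            # annealed anchors: strong to enter the right basin from the
            # bead fit, weak so the surface sets the final pose
            capture_i, _ = icp_register(
                surf1, surf2, impl_init, tol_mm=config.icp_tol_mm,
                anchor_weight=200.0, **anchors, **icp_kwargs)
            impl_t, impl_q = icp_register(
                surf1, surf2, capture_i, tol_mm=config.icp_tol_mm / 10.0,
                anchor_weight=5.0, **anchors, **icp_kwargs)
        else:
            impl_t, impl_q = icp_register(
                surf1, surf2, impl_init, tol_mm=config.icp_tol_mm, **icp_kwargs)

    with _stage("kinematics"):
        motion = relative_motion(bone_t, impl_t)
        com = center_of_mass(_largest_component(metal1), exam1)
        quality = {"bone": bone_q, "implant": impl_q}
        gates = {k: quality_gate(q, config.cn_max, config.me_max_mm)
                 for k, q in quality.items()}
        result = decompose_6dof(
            motion, com, order=config.euler_order, frame="dicom",
            mode=config.registration_mode, quality=quality, gates=gates,
            pair_id=pair_id,
        )
        for body, gate in gates.items():
            if not gate.passed:
                log.warning("quality gate failed for %s: %s", body, "; ".join(gate.reasons))

    if config.target_frame == "anatomical":
        with _stage("reorient"):
            basis = config.anatomical_basis
            if np.allclose(basis, np.eye(3)):
                basis = ANATOMICAL_BASIS_RSA
            result = reorient(result, basis, config.rotation_signs)
    return result


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    labelled, n = ndimage.label(np.asarray(mask, dtype=bool),
                                structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise seg.EmptyMaskError("metal mask is empty")
    counts = np.bincount(labelled.ravel())[1:]
    return labelled == (int(np.argmax(counts)) + 1)
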