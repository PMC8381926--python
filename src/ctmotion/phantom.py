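"""Digital hip phantom: paired CT volumes with known implant migration.

The scene is a pelvis stand-in — a hollow hemispherical bone shell with
irregular surface bosses — holding a threaded metal cup. Tantalum-like
beads sit in the bone shell and inside the cup liner. Exam 1 renders the
scene as placed; exam 2 re-renders it analytically after applying a
whole-scene repositioning transform, with the implant additionally moved
by the migration transform relative to the bone. Because both exams are
rendered from the same continuous scene description (anti-aliased signed
distance fields), the ground truth is exact and no resampling blur is
introduced.

All randomness (bead jitter, boss placement, noise, streaks) flows from a
single integer seed, so identical inputs give bit-identical volumes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registration import RigidTransform
from .volume_io import CTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomBoundsError",
    "generate_phantom_pair",
    "sample_repositioning",
    "DEFAULT_REPOSITIONING_BOUNDS",
]

#: (max translation mm, max rotation deg) suggested for patient repositioning
#: between double examinations; not reported in clinical protocols, so keep
#: it configurable. Desk-scale phantoms need smaller bounds to stay in FOV.
DEFAULT_REPOSITIONING_BOUNDS = (20.0, 10.0)


class PhantomBoundsError(ValueError):
    """Requested motion pushes scene structures outside the field of view."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic scene.

    Defaults give a ~57 mm cube at isotropic 0.6 mm voxels with HU classes
    chosen so the standard thresholds separate them by construction:
    metal (3000) > 2200 > bone (900) >= 600 > soft tissue (40).
    """

    volume_shape: tuple = (96, 96, 96)
    voxel_spacing_mm: tuple = (0.6, 0.6, 0.6)
    bone_hu: float = 900.0
    soft_tissue_hu: float = 40.0
    metal_hu: float = 3000.0
    #: tantalum is much denser than the cup alloy; a high bead intensity is
    #: required for 1-mm beads to stay above the metal threshold under
    #: partial-volume averaging at 0.6-mm voxels (as real beads do); 6000
    #: keeps the thresholded blob within the 0.1-2.0 mm3 size window
    bead_hu: float = 6000.0
    bead_diameter_mm: float = 1.0
    n_bone_beads: int = 6
    n_implant_beads: int = 4
    cup_outer_radius_mm: float = 9.0
    cup_thread_pitch_mm: float = 3.0
    cup_thickness_mm: float = 2.0
    thread_height_mm: float = 1.0
    #: rim lugs break the thread's screw near-symmetry (rotate-and-slide
    #: leaves a pure helical shell almost unchanged); real cups carry such
    #: azimuth-asymmetric features (screw holes, fins, wire markers)
    n_cup_lugs: int = 3
    lug_radius_mm: float = 1.5
    bone_outer_radius_mm: float = 16.0
    bone_thickness_mm: float = 3.5
    n_surface_bosses: int = 10
    boss_radius_mm: float = 2.2
    noise_sd_hu: float = 0.0
    streak_amplitude_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.volume_shape)
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(shape) != 3 or any(s < 8 for s in shape):
            raise ValueError(f"volume_shape must be 3 axes of >= 8 voxels, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel_spacing_mm must be positive, got {spacing}")
        object.__setattr__(self, "volume_shape", shape)
        object.__setattr__(self, "voxel_spacing_mm", spacing)
        if not (self.bead_hu >= self.metal_hu > 2200.0):
            raise ValueError("need bead_hu >= metal_hu > 2200 HU")
        if not (self.bone_hu >= 600.0 > self.soft_tissue_hu):
            raise ValueError("need bone_hu >= 600 HU > soft_tissue_hu")
        if self.n_bone_beads < 3 or self.n_implant_beads < 3:
            raise ValueError("need at least 3 beads per structure")
        if self.noise_sd_hu < 0 or self.streak_amplitude_hu < 0:
            raise ValueError("noise/streak amplitudes must be >= 0")
        if self.bead_diameter_mm <= 0:
            raise ValueError("bead_diameter_mm must be positive")
        if self.cup_outer_radius_mm + self.thread_height_mm >= (
            self.bone_outer_radius_mm - self.bone_thickness_mm
        ):
            raise ValueError("cup (incl. thread) must fit inside the bone shell cavity")

    def with_overrides(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Exact scene bookkeeping for one phantom pair.

    ``migration`` is the implant motion relative to bone (exam-1 world
    frame); ``repositioning`` maps the exam-1 scene into exam 2. By
    construction ``implant exam-2 coords = repositioning ∘ migration``
    applied to exam-1 coords.
    """

    migration: RigidTransform
    repositioning: RigidTransform
    bone_bead_coords_exam1: np.ndarray
    bone_bead_coords_exam2: np.ndarray
    implant_bead_coords_exam1: np.ndarray
    implant_bead_coords_exam2: np.ndarray
    implant_center_mm: np.ndarray
    metal_voxel_counts: tuple = (0, 0)
    bone_or_metal_voxel_counts: tuple = (0, 0)
    seed: int = 0

    def max_consistency_error_mm(self) -> float:
        """Residual of the rigid-consistency invariant (should be ~0)."""
        expected = (self.repositioning @ self.migration).apply(self.implant_bead_coords_exam1)
        e_impl = np.abs(expected - self.implant_bead_coords_exam2).max()
        expected_bone = self.repositioning.apply(self.bone_bead_coords_exam1)
        e_bone = np.abs(expected_bone - self.bone_bead_coords_exam2).max()
        return float(max(e_impl, e_bone))

    def to_json(self, path) -> None:
        payload = {
            "migration": self.migration.to_dict(),
            "repositioning": self.repositioning.to_dict(),
            "implant_center_mm": [float(v) for v in self.implant_center_mm],
            "metal_voxel_counts": list(self.metal_voxel_counts),
            "bone_or_metal_voxel_counts": list(self.bone_or_metal_voxel_counts),
            "seed": int(self.seed),
            "bone_bead_coords_exam1": self.bone_bead_coords_exam1.tolist(),
            "bone_bead_coords_exam2": self.bone_bead_coords_exam2.tolist(),
            "implant_bead_coords_exam1": self.implant_bead_coords_exam1.tolist(),
            "implant_bead_coords_exam2": self.implant_bead_coords_exam2.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def from_json(path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return GroundTruth(
            migration=RigidTransform.from_dict(d["migration"]),
            repositioning=RigidTransform.from_dict(d["repositioning"]),
            bone_bead_coords_exam1=np.asarray(d["bone_bead_coords_exam1"]),
            bone_bead_coords_exam2=np.asarray(d["bone_bead_coords_exam2"]),
            implant_bead_coords_exam1=np.asarray(d["implant_bead_coords_exam1"]),
            implant_bead_coords_exam2=np.asarray(d["implant_bead_coords_exam2"]),
            implant_center_mm=np.asarray(d["implant_center_mm"]),
            metal_voxel_counts=tuple(d["metal_voxel_counts"]),
            bone_or_metal_voxel_counts=tuple(d["bone_or_metal_voxel_counts"]),
            seed=int(d["seed"]),
        )

    def beads_to_csv(self, path) -> None:
        rows = []
        for exam, bone, impl in (
            (1, self.bone_bead_coords_exam1, self.implant_bead_coords_exam1),
            (2, self.bone_bead_coords_exam2, self.implant_bead_coords_exam2),
        ):
            for label, p in enumerate(bone):
                rows.append((exam, "bone", label, *p))
            for label, p in enumerate(impl):
                rows.append((exam, "implant", label, *p))
        pd.DataFrame(rows, columns=["exam", "structure", "label", "x_mm", "y_mm", "z_mm"]) \
            .to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# scene construction


def _spherical_dirs(rng, n, theta_lo, theta_hi, phi_offset_deg, jitter_deg):
    """Deterministic well-spread directions on the upper hemisphere."""
    thetas = np.where(np.arange(n) % 2 == 0, theta_lo, theta_hi).astype(float)
    phis = phi_offset_deg + np.arange(n) * 360.0 / n
    thetas = thetas + rng.uniform(-jitter_deg, jitter_deg, size=n)
    phis = phis + rng.uniform(-jitter_deg, jitter_deg, size=n)
    th = np.deg2rad(thetas)
    ph = np.deg2rad(phis)
    return np.column_stack([
        np.sin(th) * np.cos(ph),
        np.sin(th) * np.sin(ph),
        np.cos(th),
    ])


@dataclass(frozen=True)
class _Scene:
    center: np.ndarray
    bone_bead_coords: np.ndarray
    implant_bead_coords: np.ndarray
    boss_centers: np.ndarray
    lug_centers: np.ndarray
    streak_phase: float


def _build_scene(spec: PhantomSpec, center: np.ndarray) -> _Scene:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC7]))
    bead_r = spec.bead_diameter_mm / 2.0
    bone_mid_r = spec.bone_outer_radius_mm - spec.bone_thickness_mm / 2.0
    for _ in range(20):
        dirs = _spherical_dirs(rng, spec.n_bone_beads, 40.0, 62.0, 0.0, 6.0)
        bone_beads = center + dirs * bone_mid_r
        c = bone_beads - bone_beads.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] > 1e-3 * s[0]:
            break
    else:  # pragma: no cover - placements above are always non-collinear
        raise RuntimeError("failed to place non-collinear bone beads")
    # keep a clear gap between bead edge and the cup's partial-volume tail
    # (both anti-aliased over ~1 voxel) or bead centroids bias outward
    cup_inner = spec.cup_outer_radius_mm - spec.cup_thickness_mm
    impl_r = max(cup_inner - 1.8 - bead_r, bead_r + 0.5)
    dirs_i = _spherical_dirs(rng, spec.n_implant_beads, 25.0, 50.0, 30.0, 5.0)
    implant_beads = center + dirs_i * impl_r
    boss_dirs = _spherical_dirs(rng, spec.n_surface_bosses, 20.0, 70.0, 12.0, 14.0)
    bosses = center + boss_dirs * spec.bone_outer_radius_mm
    if spec.n_cup_lugs > 0:
        lug_dirs = _spherical_dirs(rng, spec.n_cup_lugs, 72.0, 78.0, 55.0, 4.0)
        lugs = center + lug_dirs * (spec.cup_outer_radius_mm + 0.2)
    else:
        lugs = np.empty((0, 3))
    streak_phase = float(rng.uniform(0, 2 * np.pi))
    return _Scene(center, bone_beads, implant_beads, bosses, lugs, streak_phase)


def _aa(d: np.ndarray, w: float) -> np.ndarray:
    """Anti-aliased occupancy from a signed inside-distance (d > 0 inside).

    Smoothstep edge profile (C1): a piecewise-linear ramp has kinks that
    make trilinearly-sampled isosurface positions depend on grid alignment
    to first order, which would put a spurious ~0.1 mm floor under every
    surface registration.
    """
    t = np.clip(0.5 + d / (2.0 * w), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _sphere_occ(q: np.ndarray, centers: np.ndarray, radius: float, w: float) -> np.ndarray:
    occ = np.zeros(q.shape[0])
    for c in np.atleast_2d(centers):
        d = radius - np.sqrt(np.sum((q - c) ** 2, axis=1))
        np.maximum(occ, _aa(d, w), out=occ)
    return occ


def _bone_occupancy(spec: PhantomSpec, scene: _Scene, q: np.ndarray, w: float) -> np.ndarray:
    rel = q - scene.center
    r = np.sqrt(np.sum(rel**2, axis=1))
    inner = spec.bone_outer_radius_mm - spec.bone_thickness_mm
    shell = (
        _aa(spec.bone_outer_radius_mm - r, w)
        * _aa(r - inner, w)
        * _aa(rel[:, 2] + 0.6, w)  # hemisphere opening towards -z
    )
    bosses = _sphere_occ(q, scene.boss_centers, spec.boss_radius_mm, w)
    return np.maximum(shell, bosses)


def _implant_metal_occupancy(spec: PhantomSpec, scene: _Scene, q: np.ndarray, w: float) -> np.ndarray:
    rel = q - scene.center
    r = np.sqrt(np.sum(rel**2, axis=1))
    inner = spec.cup_outer_radius_mm - spec.cup_thickness_mm
    upper = _aa(rel[:, 2] + 0.6, w)
    # helical thread as a smooth sinusoidal modulation of the outer radius:
    # sharp ridge profiles alias badly at 0.6-mm voxels (a real scanner's
    # reconstruction kernel blurs them anyway), a smooth modulation keeps
    # the isosurface consistent between the two differently-posed rasters
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    phase = 2.0 * np.pi * rel[:, 2] / spec.cup_thread_pitch_mm - phi
    outer = spec.cup_outer_radius_mm + spec.thread_height_mm * 0.5 * (
        1.0 + np.cos(phase)
    )
    occ = _aa(outer - r, w) * _aa(r - inner, w) * upper
    if scene.lug_centers.shape[0]:
        occ = np.maximum(occ, _sphere_occ(q, scene.lug_centers, spec.lug_radius_mm, w))
    return occ


def _render(
    spec: PhantomSpec,
    scene: _Scene,
    grid_points: np.ndarray,
    bone_transform: RigidTransform,
    implant_transform: RigidTransform,
) -> tuple[np.ndarray, int, int]:
    """Noiseless HU field plus metal / bone-or-metal voxel counts."""
    w = max(spec.voxel_spacing_mm)
    bead_r = spec.bead_diameter_mm / 2.0
    qb = bone_transform.inverse().apply(grid_points)
    qi = implant_transform.inverse().apply(grid_points)
    occ_bone = _bone_occupancy(spec, scene, qb, w)
    occ_cup = _implant_metal_occupancy(spec, scene, qi, w)
    occ_beads = np.maximum(
        _sphere_occ(qb, scene.bone_bead_coords, bead_r, w),
        _sphere_occ(qi, scene.implant_bead_coords, bead_r, w),
    )
    hu = np.full(grid_points.shape[0], spec.soft_tissue_hu)
    hu = hu * (1.0 - occ_bone) + spec.bone_hu * occ_bone
    hu = hu * (1.0 - occ_cup) + spec.metal_hu * occ_cup
    hu = hu * (1.0 - occ_beads) + spec.bead_hu * occ_beads
    n_metal = int(np.count_nonzero(hu >= 2200.0))
    n_bone_or_metal = int(np.count_nonzero(hu >= 600.0))
    return hu, n_metal, n_bone_or_metal


def _fov_probe_points(spec: PhantomSpec, scene: _Scene) -> dict:
    """Deterministic sample points on the outer extents of each body."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(200)
    z = np.linspace(0.02, 0.98, 200)  # upper hemisphere only
    rho = np.sqrt(1 - z**2)
    dirs = np.column_stack([rho * np.cos(golden * k), rho * np.sin(golden * k), z])
    bone_pts = np.vstack([
        scene.center + dirs * (spec.bone_outer_radius_mm + 0.2),
        scene.boss_centers + spec.boss_radius_mm * np.array([0.0, 0.0, 1.0]),
        scene.bone_bead_coords,
    ])
    cup_pts = np.vstack([
        scene.center + dirs * (spec.cup_outer_radius_mm + spec.thread_height_mm + 0.2),
        scene.implant_bead_coords,
    ])
    if scene.lug_centers.shape[0]:
        cup_pts = np.vstack([
            cup_pts,
            scene.lug_centers + spec.lug_radius_mm * np.array([0.0, 0.0, 1.0]),
        ])
    return {"bone": bone_pts, "implant": cup_pts}


def _check_fov(volume_lo, volume_hi, margin, probes: dict, transforms: dict) -> None:
    for body, pts in probes.items():
        moved = transforms[body].apply(pts)
        lo_violation = (volume_lo + margin) - moved.min(axis=0)
        hi_violation = moved.max(axis=0) - (volume_hi - margin)
        worst = np.maximum(lo_violation, hi_violation)
        if np.any(worst > 0):
            axis = "xyz"[int(np.argmax(worst))]
            raise PhantomBoundsError(
                f"{body} structures leave the field of view along {axis} by "
                f"{worst.max():.2f} mm (margin {margin:.2f} mm); reduce the "
                "migration/repositioning magnitude or enlarge the volume"
            )


def _grid_world_points(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.volume_shape
    sp = np.asarray(spec.voxel_spacing_mm)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    return idx * sp


def _add_artefacts(
    spec: PhantomSpec, scene: _Scene, hu_flat: np.ndarray, grid_points: np.ndarray,
    exam_index: int,
) -> np.ndarray:
    out = hu_flat
    if spec.streak_amplitude_hu > 0:
        rel = grid_points - scene.center
        r_cyl = np.sqrt(rel[:, 0] ** 2 + rel[:, 1] ** 2)
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        streak = (
            spec.streak_amplitude_hu
            * np.cos(12.0 * phi + scene.streak_phase + exam_index)
            * np.exp(-r_cyl / 15.0)
        )
        out = out + streak
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x0E, exam_index]))
        out = out + rng.normal(0.0, spec.noise_sd_hu, size=out.shape[0])
    return out


def generate_phantom_pair(
    spec: PhantomSpec,
    migration: RigidTransform | None = None,
    repositioning: RigidTransform | None = None,
) -> tuple[CTVolume, CTVolume, GroundTruth]:
    """Render the double-examination pair for a given ground-truth motion.

    Exam 1 renders the scene in place. Exam 2 renders the bone under
    ``repositioning`` and the implant under ``repositioning ∘ migration``.
    Raises :class:`PhantomBoundsError` when the requested motion pushes any
    structure outside the field of view.
    """
    if migration is None:
        migration = RigidTransform.identity()
    if repositioning is None:
        repositioning = RigidTransform.identity()
    sp = np.asarray(spec.voxel_spacing_mm)
    shape = np.asarray(spec.volume_shape)
    center = (shape - 1) / 2.0 * sp
    scene = _build_scene(spec, center)
    grid_points = _grid_world_points(spec)
    lo = np.zeros(3)
    hi = (shape - 1) * sp
    probes = _fov_probe_points(spec, scene)
    identity = RigidTransform.identity()
    implant2 = repositioning @ migration
    _check_fov(lo, hi, max(sp), probes, {"bone": identity, "implant": identity})
    _check_fov(lo, hi, max(sp), probes, {"bone": repositioning, "implant": implant2})

    hu1, m1, bm1 = _render(spec, scene, grid_points, identity, identity)
    hu2, m2, bm2 = _render(spec, scene, grid_points, repositioning, implant2)
    hu1 = _add_artefacts(spec, scene, hu1, grid_points, 1)
    hu2 = _add_artefacts(spec, scene, hu2, grid_points, 2)

    vol1 = CTVolume(hu1.reshape(spec.volume_shape).astype(np.float32), sp)
    vol2 = CTVolume(hu2.reshape(spec.volume_shape).astype(np.float32), sp)
    gt = GroundTruth(
        migration=migration,
        repositioning=repositioning,
        bone_bead_coords_exam1=scene.bone_bead_coords,
        bone_bead_coords_exam2=repositioning.apply(scene.bone_bead_coords),
        implant_bead_coords_exam1=scene.implant_bead_coords,
        implant_bead_coords_exam2=implant2.apply(scene.implant_bead_coords),
        implant_center_mm=scene.center.copy(),
        metal_voxel_counts=(m1, m2),
        bone_or_metal_voxel_counts=(bm1, bm2),
        seed=spec.seed,
    )
    return vol1, vol2, gt


def sample_repositioning(
    max_translation_mm: float, max_rotation_deg: float, seed: int
) -> RigidTransform:
    """Uniform random rigid transform within the given bounds (seeded).

    Rotation: uniform axis, angle uniform on [0, max]. Translation: uniform
    direction, radius distributed as a uniform ball. Zero bounds give the
    exact identity.
    """
    if max_translation_mm < 0 or max_rotation_deg < 0:
        raise ValueError("repositioning bounds must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rotation_deg)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    tmag = max_translation_mm * rng.uniform() ** (1.0 / 3.0)
    return RigidTransform.from_axis_angle(axis, angle, tdir * tmag)
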