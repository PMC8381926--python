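"""Volume and table I/O plus analysis configuration.

The internal world frame is the scanner/DICOM patient frame (LPS), with
world coordinates in millimetres everywhere. Voxel ``(i, j, k)`` (0-based)
maps to ``origin + orientation @ (spacing * (i, j, k))``; this mapping is
shared by every reader so that the same physical structure yields the same
world coordinates regardless of storage format. NIfTI files (RAS) are
converted on read/write.
"""
from __future__ import annotations

import os
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import _dicom
from ._dicom import DicomError, MixedSeriesError, NonUniformSpacingError

__all__ = [
    "CTVolume",
    "AnalysisConfig",
    "VolumeReadError",
    "DicomError",
    "MixedSeriesError",
    "NonUniformSpacingError",
    "read_volume",
    "write_volume",
    "write_migration_table",
    "read_migration_table",
    "MIGRATION_TABLE_COLUMNS",
]

#: LPS <-> RAS conversion (negate x and y)
_LPS_FROM_RAS = np.diag([-1.0, -1.0, 1.0])


class VolumeReadError(IOError):
    """File exists but cannot be interpreted as a CT volume."""


@dataclass(frozen=True)
class CTVolume:
    """A 3-D HU-calibrated scalar grid with world geometry (mm, LPS).

    ``data`` is indexed ``[i, j, k]`` along the x/y/z index axes;
    ``orientation`` columns are the world directions of those index axes.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {d.shape}")
        sp = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(sp <= 0):
            raise ValueError(f"spacing must be strictly positive, got {sp}")
        o = np.asarray(self.origin, dtype=float).reshape(3)
        m = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.abs(m.T @ m - np.eye(3)).max() > 1e-6 or abs(abs(np.linalg.det(m)) - 1) > 1e-6:
            raise ValueError("orientation must be orthonormal with |det| = 1")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "orientation", m)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, indices) -> np.ndarray:
        """Map (fractional) voxel indices to world mm. Accepts (3,) or (n, 3)."""
        idx = np.asarray(indices, dtype=float)
        single = idx.ndim == 1
        idx = np.atleast_2d(idx)
        world = idx * self.spacing @ self.orientation.T + self.origin
        return world[0] if single else world

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centres."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)], dtype=float)
        w = self.index_to_world(corners)
        return w.min(axis=0), w.max(axis=0)

    def world_center(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape, dtype=float) - 1) / 2.0)


# ---------------------------------------------------------------------------
# configuration

#: DICOM-LPS -> RSA-like anatomical frame: x transverse, y longitudinal
#: (superior), z sagittal (anterior); proper rotation (det = +1).
ANATOMICAL_BASIS_RSA = np.array(
    [[1.0, 0.0, 0.0],
     [0.0, 0.0, 1.0],
     [0.0, -1.0, 0.0]]
)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the migration pipeline, with study defaults.

    ``bone_threshold_hu_exam1/2`` override the global bone threshold per
    exam (needed when the two acquisitions were reconstructed differently).
    """

    bone_threshold_hu: float = 600.0
    metal_threshold_hu: float = 2200.0
    registration_mode: str = "beads"  # beads | surface
    euler_order: str = "xyz"
    anatomical_basis: np.ndarray = field(default_factory=lambda: np.eye(3))
    rotation_signs: tuple = (1, 1, 1)
    target_frame: str = "dicom"  # dicom | anatomical
    bone_threshold_hu_exam1: float | None = None
    bone_threshold_hu_exam2: float | None = None
    bead_min_volume_mm3: float = 0.1
    bead_max_volume_mm3: float = 2.0
    bead_clearance_mm: float = 3.4
    match_max_distance_mm: float = 5.0
    icp_max_iter: int = 100
    icp_tol_mm: float = 1e-4
    max_surface_points: int = 50000
    cn_max: float = 100.0
    me_max_mm: float = 0.30
    dose_conversion_factor: float = 0.0129
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.metal_threshold_hu > self.bone_threshold_hu > -1000.0):
            raise ValueError(
                "thresholds must satisfy metal > bone > air (-1000 HU); got "
                f"metal={self.metal_threshold_hu}, bone={self.bone_threshold_hu}"
            )
        if self.registration_mode not in ("beads", "surface"):
            raise ValueError(f"unknown registration_mode {self.registration_mode!r}")
        if self.target_frame not in ("dicom", "anatomical"):
            raise ValueError(f"unknown target_frame {self.target_frame!r}")
        b = np.asarray(self.anatomical_basis, dtype=float).reshape(3, 3)
        if np.abs(b.T @ b - np.eye(3)).max() > 1e-6 or abs(np.linalg.det(b) - 1) > 1e-6:
            raise ValueError("anatomical_basis must be orthonormal with det = +1")
        object.__setattr__(self, "anatomical_basis", b)
        object.__setattr__(self, "rotation_signs", tuple(int(s) for s in self.rotation_signs))
        if any(s not in (-1, 1) for s in self.rotation_signs):
            raise ValueError("rotation_signs entries must be +1 or -1")

    def bone_threshold_for_exam(self, exam: int) -> float:
        override = {1: self.bone_threshold_hu_exam1, 2: self.bone_threshold_hu_exam2}[exam]
        return self.bone_threshold_hu if override is None else float(override)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    # -- (de)serialisation as a flat YAML mapping ------------------------
    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if isinstance(v, np.ndarray):
                v = [[float(x) for x in row] for row in v]
            elif isinstance(v, tuple):
                v = list(v)
            d[name] = v
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @staticmethod
    def from_dict(d: dict) -> "AnalysisConfig":
        known = set(AnalysisConfig.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return AnalysisConfig(**d)

    @staticmethod
    def from_yaml(path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return AnalysisConfig.from_dict(d)


# ---------------------------------------------------------------------------
# volume readers/writers


def read_volume(path) -> CTVolume:
    """Read a CT volume from a DICOM series directory, NIfTI, or MetaImage.

    DICOM rescale slope/intercept are applied so intensities are HU; NIfTI
    RAS geometry is converted to the internal LPS frame.
    """
    path = str(path)
    if os.path.isdir(path):
        data, spacing, origin, direction = _dicom.read_series(path)
        return CTVolume(data, spacing, origin, direction)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if lower.endswith((".mha", ".mhd")):
        return _read_metaimage(path)
    raise VolumeReadError(f"{path}: unrecognised volume format")


def write_volume(volume: CTVolume, path) -> None:
    """Write as NIfTI (.nii/.nii.gz), MetaImage (.mha), or a DICOM series
    (any other path is treated as a series directory)."""
    path = str(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        _write_nifti(volume, path)
    elif lower.endswith(".mha"):
        _write_metaimage(volume, path)
    else:
        _dicom.write_series(path, np.asarray(volume.data, dtype=np.float64),
                            volume.spacing, volume.origin, volume.orientation)


def _lps_affine(volume: CTVolume) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = volume.orientation * volume.spacing
    a[:3, 3] = volume.origin
    return a


def _write_nifti(volume: CTVolume, path: str) -> None:
    import nibabel as nib

    affine = _lps_affine(volume).copy()
    affine[:3, :] = _LPS_FROM_RAS @ affine[:3, :]  # store as RAS
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)


def _read_nifti(path: str) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error paths vary
        raise VolumeReadError(f"{path}: {exc}") from exc
    affine = np.asarray(img.affine, dtype=float)
    affine_lps = affine.copy()
    affine_lps[:3, :] = _LPS_FROM_RAS @ affine[:3, :]
    m = affine_lps[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise VolumeReadError(f"{path}: degenerate affine")
    direction = m / spacing
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise VolumeReadError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return CTVolume(data, spacing, affine_lps[:3, 3], direction)


_MET_DTYPES = {
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
    "MET_UCHAR": np.uint8,
}


def _write_metaimage(volume: CTVolume, path: str) -> None:
    data = np.asarray(volume.data, dtype=np.float32)
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = " + " ".join(f"{v:.17g}" for v in volume.orientation.flatten(order="F")),
        "Offset = " + " ".join(f"{v:.17g}" for v in volume.origin),
        "ElementSpacing = " + " ".join(f"{v:.17g}" for v in volume.spacing),
        "DimSize = " + " ".join(str(s) for s in data.shape),
        "ElementType = MET_FLOAT",
        "ElementDataFile = LOCAL",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        # raw stream is x-fastest: transpose so index i varies fastest
        fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def _read_metaimage(path: str) -> CTVolume:
    with open(path, "rb") as fh:
        raw = fh.read()
    fields: dict[str, str] = {}
    pos = 0
    while True:
        eol = raw.find(b"\n", pos)
        if eol < 0:
            raise VolumeReadError(f"{path}: header not terminated")
        line = raw[pos:eol].decode("ascii", errors="replace").strip()
        pos = eol + 1
        if "=" not in line:
            raise VolumeReadError(f"{path}: malformed header line {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        fields[key] = value
        if key == "ElementDataFile":
            break
    try:
        dims = [int(v) for v in fields["DimSize"].split()]
        spacing = np.array([float(v) for v in fields["ElementSpacing"].split()])
        dtype = _MET_DTYPES[fields["ElementType"]]
    except (KeyError, ValueError) as exc:
        raise VolumeReadError(f"{path}: incomplete MetaImage header ({exc})") from exc
    if len(dims) != 3:
        raise VolumeReadError(f"{path}: expected NDims 3")
    origin = np.array([float(v) for v in fields.get("Offset", "0 0 0").split()])
    tm = fields.get("TransformMatrix", "1 0 0 0 1 0 0 0 1")
    direction = np.array([float(v) for v in tm.split()]).reshape(3, 3, order="F")
    if fields["ElementDataFile"] != "LOCAL":
        raise VolumeReadError(f"{path}: only ElementDataFile = LOCAL is supported")
    buf = raw[pos:]
    if fields.get("CompressedData", "False").lower() == "true":
        buf = zlib.decompress(buf)
    n = dims[0] * dims[1] * dims[2]
    arr = np.frombuffer(buf, dtype=dtype, count=n)
    data = arr.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return CTVolume(data.astype(np.float32), spacing, origin, direction)


# ---------------------------------------------------------------------------
# migration result tables

MIGRATION_TABLE_COLUMNS = [
    "pair_id", "mode", "frame",
    "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg",
    "com_x_mm", "com_y_mm", "com_z_mm",
    "bone_mean_error_mm", "bone_condition_number", "bone_n_points",
    "bone_converged", "bone_iterations",
    "implant_mean_error_mm", "implant_condition_number", "implant_n_points",
    "implant_converged", "implant_iterations",
    "gimbal_warning",
]


def write_migration_table(results, path) -> None:
    """Write migration results as a fixed-header CSV (one row per exam pair).

    Floats are written at 6 decimals; mixing coordinate frames in one table
    is rejected. An empty list produces a header-only file with a warning.
    """
    if not results:
        warnings.warn("writing header-only migration table (no results)", stacklevel=2)
        pd.DataFrame(columns=MIGRATION_TABLE_COLUMNS).to_csv(path, index=False)
        return
    frames = {r.frame for r in results}
    if len(frames) > 1:
        raise ValueError(
            f"cannot mix coordinate frames in one table: {sorted(frames)}"
        )
    rows = []
    for r in results:
        qb = r.quality["bone"]
        qi = r.quality["implant"]
        rows.append({
            "pair_id": r.pair_id,
            "mode": r.mode,
            "frame": r.frame,
            "tx_mm": r.translations_mm[0], "ty_mm": r.translations_mm[1],
            "tz_mm": r.translations_mm[2],
            "rx_deg": r.rotations_deg[0], "ry_deg": r.rotations_deg[1],
            "rz_deg": r.rotations_deg[2],
            "com_x_mm": r.center_of_mass_mm[0], "com_y_mm": r.center_of_mass_mm[1],
            "com_z_mm": r.center_of_mass_mm[2],
            "bone_mean_error_mm": qb.mean_error_mm,
            "bone_condition_number": qb.condition_number,
            "bone_n_points": qb.n_points,
            "bone_converged": qb.converged,
            "bone_iterations": qb.iterations,
            "implant_mean_error_mm": qi.mean_error_mm,
            "implant_condition_number": qi.condition_number,
            "implant_n_points": qi.n_points,
            "implant_converged": qi.converged,
            "implant_iterations": qi.iterations,
            "gimbal_warning": r.gimbal_warning,
        })
    df = pd.DataFrame(rows, columns=MIGRATION_TABLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_migration_table(path) -> list:
    """Read a migration CSV back into :class:`~ctmotion.kinematics.MigrationResult`s."""
    from .kinematics import MigrationResult  # lazy: avoids an import cycle
    from .registration import RegistrationQuality

    df = pd.read_csv(path)
    missing = [c for c in MIGRATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing migration-table columns {missing}")
    out = []
    for _, row in df.iterrows():
        quality = {
            body: RegistrationQuality(
                mean_error_mm=float(row[f"{body}_mean_error_mm"]),
                condition_number=float(row[f"{body}_condition_number"]),
                n_points=int(row[f"{body}_n_points"]),
                converged=bool(row[f"{body}_converged"]),
                iterations=int(row[f"{body}_iterations"]),
            )
            for body in ("bone", "implant")
        }
        out.append(MigrationResult(
            translations_mm=np.array([row["tx_mm"], row["ty_mm"], row["tz_mm"]]),
            rotations_deg=np.array([row["rx_deg"], row["ry_deg"], row["rz_deg"]]),
            center_of_mass_mm=np.array([row["com_x_mm"], row["com_y_mm"], row["com_z_mm"]]),
            frame=str(row["frame"]),
            mode=str(row["mode"]),
            quality=quality,
            pair_id=str(row["pair_id"]),
            gimbal_warning=bool(row["gimbal_warning"]),
        ))
    return out
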