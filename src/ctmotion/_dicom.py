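"""Minimal DICOM series codec (explicit VR little endian, CT slices).

Only the subset needed to exchange HU-calibrated axial slice stacks is
implemented: uncompressed 16-bit monochrome pixel data with rescale
slope/intercept and full patient-space geometry. This is deliberately not a
general DICOM implementation; unknown elements are skipped on read.
"""
from __future__ import annotations

import os
import struct
import uuid
from dataclasses import dataclass, field

import numpy as np

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_CLASS_CT = "1.2.840.10008.5.1.4.1.1.2"

# VRs that use the 4-byte length form (with 2 reserved bytes) in explicit VR
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

_UNDEFINED_LENGTH = 0xFFFFFFFF


class DicomError(IOError):
    """Unreadable or unsupported DICOM input."""


class MixedSeriesError(DicomError):
    """Directory contains more than one SeriesInstanceUID."""


class NonUniformSpacingError(DicomError):
    """Slice positions are not uniformly spaced along the stack normal."""


def new_uid() -> str:
    return "2.25." + str(uuid.uuid4().int)


def _encode_element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    if len(value) > 0xFFFF:
        raise DicomError(f"value too long for short-form VR {vr!r}")
    return head + struct.pack("<H", len(value)) + value


def _txt(s) -> bytes:
    return str(s).encode("ascii")


def _ds(values) -> bytes:
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    return "\\".join(f"{v:.10g}" for v in vals).encode("ascii")


def write_slice(
    path: str,
    pixels: np.ndarray,
    *,
    series_uid: str,
    study_uid: str,
    instance_number: int,
    position: np.ndarray,
    orientation_rows: np.ndarray,
    orientation_cols: np.ndarray,
    pixel_spacing_row_col: np.ndarray,
    slice_thickness: float,
    rescale_slope: float = 1.0,
    rescale_intercept: float = -1024.0,
) -> None:
    """Write one uint16 slice (rows x cols) as an explicit-VR-LE CT file."""
    if pixels.dtype != np.uint16 or pixels.ndim != 2:
        raise ValueError("pixels must be a 2-D uint16 array")
    sop_uid = new_uid()
    rows, cols = pixels.shape

    meta_elems = (
        _encode_element(0x0002, 0x0002, b"UI", _txt(SOP_CLASS_CT))
        + _encode_element(0x0002, 0x0003, b"UI", _txt(sop_uid))
        + _encode_element(0x0002, 0x0010, b"UI", _txt(TRANSFER_SYNTAX_EXPLICIT_LE))
    )
    meta = _encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_elems))) + meta_elems

    iop = np.concatenate([orientation_rows, orientation_cols])
    body = b"".join(
        [
            _encode_element(0x0008, 0x0016, b"UI", _txt(SOP_CLASS_CT)),
            _encode_element(0x0008, 0x0018, b"UI", _txt(sop_uid)),
            _encode_element(0x0008, 0x0060, b"CS", b"CT"),
            _encode_element(0x0018, 0x0050, b"DS", _ds([slice_thickness])),
            _encode_element(0x0020, 0x000D, b"UI", _txt(study_uid)),
            _encode_element(0x0020, 0x000E, b"UI", _txt(series_uid)),
            _encode_element(0x0020, 0x0013, b"IS", _txt(instance_number)),
            _encode_element(0x0020, 0x0032, b"DS", _ds(position)),
            _encode_element(0x0020, 0x0037, b"DS", _ds(iop)),
            _encode_element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            _encode_element(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
            _encode_element(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
            _encode_element(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
            _encode_element(0x0028, 0x0030, b"DS", _ds(pixel_spacing_row_col)),
            _encode_element(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
            _encode_element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
            _encode_element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
            _encode_element(0x0028, 0x0103, b"US", struct.pack("<H", 0)),
            _encode_element(0x0028, 0x1052, b"DS", _ds([rescale_intercept])),
            _encode_element(0x0028, 0x1053, b"DS", _ds([rescale_slope])),
            _encode_element(0x7FE0, 0x0010, b"OW", pixels.astype("<u2").tobytes()),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(meta)
        fh.write(body)


@dataclass
class SliceInfo:
    path: str
    series_uid: str
    instance_number: int
    position: np.ndarray
    orientation: np.ndarray  # 6-vector: row direction then column direction
    pixel_spacing: np.ndarray  # (row spacing, col spacing)
    rescale_slope: float
    rescale_intercept: float
    rows: int
    cols: int
    pixels: np.ndarray = field(repr=False, default=None)


def _read_elements(buf: bytes, start: int):
    """Yield (group, elem, vr, value_bytes) from an explicit-VR-LE stream."""
    pos = start
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            data_start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            data_start = pos + 8
        if length == _UNDEFINED_LENGTH:
            raise DicomError(
                f"undefined-length element ({group:04x},{elem:04x}) not supported"
            )
        value = buf[data_start : data_start + length]
        yield group, elem, vr, value
        pos = data_start + length


def read_slice(path: str) -> SliceInfo:
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError(f"{path}: missing DICM magic; not a DICOM part-10 file")
    tags: dict[tuple[int, int], bytes] = {}
    pixels_raw = None
    for group, elem, vr, value in _read_elements(buf, 132):
        if group == 0x0002:
            if (group, elem) == (0x0002, 0x0010):
                ts = value.rstrip(b"\x00 ").decode("ascii")
                if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
                    raise DicomError(
                        f"{path}: unsupported transfer syntax {ts} "
                        f"(only explicit VR little endian is supported)"
                    )
            continue
        if (group, elem) == (0x7FE0, 0x0010):
            pixels_raw = value
        else:
            tags[(group, elem)] = value

    def text(tag, default=None):
        if tag not in tags:
            if default is None:
                raise DicomError(f"{path}: missing required tag {tag}")
            return default
        return tags[tag].rstrip(b"\x00 ").decode("ascii")

    def us(tag):
        return struct.unpack("<H", tags[tag][:2])[0]

    if pixels_raw is None:
        raise DicomError(f"{path}: no PixelData")
    bits = us((0x0028, 0x0100))
    signed = us((0x0028, 0x0103)) == 1
    if bits != 16:
        raise DicomError(f"{path}: only 16-bit pixel data supported (got {bits})")
    rows, cols = us((0x0028, 0x0010)), us((0x0028, 0x0011))
    dtype = "<i2" if signed else "<u2"
    pixels = np.frombuffer(pixels_raw[: rows * cols * 2], dtype=dtype).reshape(rows, cols)
    return SliceInfo(
        path=path,
        series_uid=text((0x0020, 0x000E)),
        instance_number=int(text((0x0020, 0x0013), "0")),
        position=np.array([float(v) for v in text((0x0020, 0x0032)).split("\\")]),
        orientation=np.array([float(v) for v in text((0x0020, 0x0037)).split("\\")]),
        pixel_spacing=np.array([float(v) for v in text((0x0028, 0x0030)).split("\\")]),
        rescale_slope=float(text((0x0028, 0x1053), "1")),
        rescale_intercept=float(text((0x0028, 0x1052), "0")),
        rows=rows,
        cols=cols,
        pixels=pixels,
    )


def read_series(directory: str, spacing_rtol: float = 1e-3):
    """Read a single-series slice stack from ``directory``.

    Returns ``(data_xyz, spacing, origin, direction)`` where ``data_xyz`` is
    indexed ``[i, j, k]`` = (column, row, slice), spacing is mm per axis,
    and direction columns are the world directions of the three index axes.
    """
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".") and os.path.isfile(os.path.join(directory, f))
    )
    slices = []
    for p in paths:
        try:
            slices.append(read_slice(p))
        except DicomError as exc:
            if "missing DICM magic" in str(exc):
                continue  # tolerate stray non-DICOM files
            raise
    if not slices:
        raise DicomError(f"{directory}: no readable DICOM slices found")
    uids = sorted({s.series_uid for s in slices})
    if len(uids) > 1:
        raise MixedSeriesError(
            f"{directory}: multiple series present: " + ", ".join(uids)
        )
    ref = slices[0]
    row_dir = ref.orientation[:3]
    col_dir = ref.orientation[3:]
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda s: float(np.dot(s.position, normal)))
    zpos = np.array([float(np.dot(s.position, normal)) for s in slices])
    if len(slices) < 2:
        dz = ref.pixel_spacing[0]
    else:
        steps = np.diff(zpos)
        dz = float(np.mean(steps))
        if dz <= 0 or np.any(np.abs(steps - dz) > spacing_rtol * max(abs(dz), 1e-9)):
            raise NonUniformSpacingError(
                f"{directory}: non-uniform slice spacing (steps "
                f"{steps.min():.6f}..{steps.max():.6f} mm)"
            )
    rows, cols = ref.rows, ref.cols
    data = np.empty((cols, rows, len(slices)), dtype=np.float32)
    for k, s in enumerate(slices):
        if (s.rows, s.cols) != (rows, cols):
            raise DicomError(f"{directory}: inconsistent slice dimensions")
        hu = s.pixels.astype(np.float64) * s.rescale_slope + s.rescale_intercept
        data[:, :, k] = hu.T  # (rows, cols) -> (cols, rows)
    spacing = np.array([ref.pixel_spacing[1], ref.pixel_spacing[0], dz])
    direction = np.column_stack([row_dir, col_dir, normal])
    origin = slices[0].position.astype(float)
    return data, spacing, origin, direction


def write_series(
    directory: str,
    data_xyz: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    direction: np.ndarray,
    *,
    rescale_intercept: float = -1024.0,
) -> str:
    """Write a volume as an axial slice stack; returns the SeriesInstanceUID."""
    os.makedirs(directory, exist_ok=True)
    series_uid = new_uid()
    study_uid = new_uid()
    nx, ny, nz = data_xyz.shape
    row_dir = direction[:, 0]
    col_dir = direction[:, 1]
    normal = direction[:, 2]
    stored = np.clip(np.round(data_xyz - rescale_intercept), 0, 65535).astype(np.uint16)
    for k in range(nz):
        pos = origin + normal * spacing[2] * k
        write_slice(
            os.path.join(directory, f"slice_{k:04d}.dcm"),
            stored[:, :, k].T.copy(),  # (cols, rows) -> (rows, cols)
            series_uid=series_uid,
            study_uid=study_uid,
            instance_number=k + 1,
            position=pos,
            orientation_rows=row_dir,
            orientation_cols=col_dir,
            pixel_spacing_row_col=np.array([spacing[1], spacing[0]]),
            slice_thickness=spacing[2],
            rescale_intercept=rescale_intercept,
        )
    return series_uid
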