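"""Rigid-body registration primitives.

This module provides the matched-point least-squares solver (Kabsch/SVD),
marker-configuration quality metrics with pass/fail gates, deterministic
mutual-nearest-neighbour bead matching, iterative-closest-point alignment
for surface point clouds, and a PCA-based coarse aligner used to
initialise both registration routes.

All coordinates are world millimetres; all transforms are proper rigid
motions (rotation + translation, no scaling or reflection).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import BeadSet

__all__ = [
    "RigidTransform",
    "RegistrationQuality",
    "GateResult",
    "Correspondence",
    "DegenerateConfigurationError",
    "MatchingError",
    "kabsch_fit",
    "condition_number",
    "quality_gate",
    "match_beads",
    "icp_register",
    "coarse_align",
]

#: tolerance for accepting a user-supplied rotation matrix as orthonormal
_ROT_INPUT_TOL = 1e-6


class DegenerateConfigurationError(ValueError):
    """Point configuration is rank-deficient (e.g. collinear markers)."""


class MatchingError(RuntimeError):
    """Bead correspondence could not be established."""


def _as_points(x, name: str = "points") -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"{name}: expected an (n, 3) array, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name}: contains non-finite coordinates")
    return p


def _project_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to ``m`` (Frobenius norm), via SVD."""
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> rotation @ p + translation`` (mm).

    The rotation is validated on construction: it must be orthonormal with
    determinant +1 within ``1e-6``; small numerical drift is projected back
    onto SO(3) so that composed transforms keep the invariant to ~1e-12.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.array(self.rotation, dtype=float)
        t = np.array(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {r.shape}")
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(t)):
            raise ValueError("transform contains non-finite values")
        err = np.abs(r.T @ r - np.eye(3)).max()
        det = np.linalg.det(r)
        if err > _ROT_INPUT_TOL or abs(det - 1.0) > _ROT_INPUT_TOL:
            raise ValueError(
                f"rotation is not a proper rotation (orthonormality error "
                f"{err:.3g}, det {det:.6f})"
            )
        if err > 1e-12:
            r = _project_rotation(r)
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    # -- constructors ----------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_euler(
        angles_deg: Sequence[float],
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        order: str = "xyz",
    ) -> "RigidTransform":
        """Build from fixed-frame Cardan angles in degrees (order ``xyz`` =
        rotate about x first, then y, then z, all about the world axes)."""
        rot = Rotation.from_euler(order, np.asarray(angles_deg, dtype=float), degrees=True)
        return RigidTransform(rot.as_matrix(), np.asarray(translation, dtype=float))

    @staticmethod
    def from_axis_angle(
        axis: Sequence[float], angle_deg: float, translation: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be non-zero")
        rot = Rotation.from_rotvec(a / n * np.deg2rad(angle_deg))
        return RigidTransform(rot.as_matrix(), np.asarray(translation, dtype=float))

    # -- algebra ---------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other`` — apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation angle (axis-angle magnitude) in degrees.

        Uses atan2 of the axial (skew) part rather than arccos of the
        trace, which loses half the floating-point digits near 0° and 180°.
        """
        r = self.rotation
        axial = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
        s = np.linalg.norm(axial) / 2.0
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.rad2deg(np.arctan2(s, c)))

    def isclose(self, other: "RigidTransform", atol_mm: float = 1e-9, atol_deg: float = 1e-9) -> bool:
        delta = self.inverse().compose(other)
        return (
            float(np.linalg.norm(delta.translation)) <= atol_mm
            and delta.rotation_angle_deg <= atol_deg
        )

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [[float(v) for v in row] for row in self.rotation],
            "translation_mm": [float(v) for v in self.translation],
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["rotation"], dtype=float),
                              np.asarray(d["translation_mm"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_json(path) -> "RigidTransform":
        with open(path) as fh:
            return RigidTransform.from_dict(json.load(fh))


@dataclass(frozen=True)
class RegistrationQuality:
    """Quality metrics of a single rigid registration.

    ``mean_error_mm`` is the RMS residual after the fit; ``condition_number``
    is the spread metric of the marker/point configuration (sigma_max /
    sigma_min of the centred coordinate matrix, ``inf`` for degenerate sets).
    """

    mean_error_mm: float
    condition_number: float
    n_points: int
    converged: bool = True
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.mean_error_mm < 0:
            raise ValueError("mean_error_mm must be >= 0")
        if np.isfinite(self.condition_number) and self.condition_number < 1.0 - 1e-9:
            raise ValueError("condition_number must be >= 1 (or inf for degenerate sets)")

    def to_dict(self) -> dict:
        return {
            "mean_error_mm": float(self.mean_error_mm),
            "condition_number": float(self.condition_number),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }


@dataclass(frozen=True)
class GateResult:
    passed: bool
    reasons: tuple = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def condition_number(points) -> float:
    """Spread metric of a marker configuration.

    Ratio of largest to smallest singular value of the centred coordinate
    matrix (rows = points - centroid). Returns ``inf`` for rank-deficient
    (collinear or coincident) configurations. Invariant to rigid motion and
    to uniform scaling of the configuration.
    """
    p = _as_points(points)
    if p.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 points for a condition number, got {p.shape[0]}"
        )
    c = p - p.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[-1] <= s[0] * 1e-12 or s[0] == 0.0:
        return float("inf")
    return float(s[0] / s[-1])


def quality_gate(
    q: RegistrationQuality, cn_max: float = 100.0, me_max_mm: float = 0.30
) -> GateResult:
    """Pass/fail gate on registration quality.

    Fails iff ``condition_number >= cn_max`` or ``mean_error_mm >= me_max_mm``
    (the conventional acceptance limits are CN < 100 and ME < 0.30 mm);
    every violated limit is listed in ``reasons``.
    """
    reasons = []
    if not (q.condition_number < cn_max):
        reasons.append(
            f"condition number {q.condition_number:.3g} >= limit {cn_max:g}"
        )
    if not (q.mean_error_mm < me_max_mm):
        reasons.append(
            f"mean error {q.mean_error_mm:.4g} mm >= limit {me_max_mm:g} mm"
        )
    return GateResult(passed=not reasons, reasons=tuple(reasons))


def kabsch_fit(source, target) -> tuple[RigidTransform, RegistrationQuality]:
    """Least-squares optimal proper rigid transform mapping source -> target.

    Points are matched 1:1 by index. SVD-based with reflection correction;
    raises :class:`DegenerateConfigurationError` for configurations whose
    centred coordinate matrix has rank < 2 (collinear points), for which the
    rotation is not identifiable.
    """
    src = _as_points(source, "source")
    tgt = _as_points(target, "target")
    if src.shape != tgt.shape:
        raise ValueError(f"source/target length mismatch: {src.shape[0]} vs {tgt.shape[0]}")
    n = src.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(f"need >= 3 matched points, got {n}")
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    a = src - cs
    b = tgt - ct
    s = np.linalg.svd(a, compute_uv=False)
    rank = int(np.sum(s > s[0] * 1e-9)) if s[0] > 0 else 0
    if rank < 2:
        raise DegenerateConfigurationError(
            f"source configuration has rank {rank} (< 2): rotation not identifiable"
        )
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - rot @ cs
    transform = RigidTransform(rot, t)
    resid = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    quality = RegistrationQuality(
        mean_error_mm=rms,
        condition_number=condition_number(src),
        n_points=n,
        converged=True,
        iterations=1,
    )
    return transform, quality


@dataclass(frozen=True)
class Correspondence:
    """Mutual-nearest-neighbour bead pairing between two labelled sets."""

    pairs: tuple  # ((label_a, label_b), ...)
    index_a: np.ndarray
    index_b: np.ndarray
    unmatched_a: tuple = ()
    unmatched_b: tuple = ()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _mutual_nn_pairs(pa: np.ndarray, pb: np.ndarray, max_distance: float):
    tree_b = cKDTree(pb)
    tree_a = cKDTree(pa)
    d_ab, nn_ab = tree_b.query(pa)  # for each a: nearest b
    _, nn_ba = tree_a.query(pb)  # for each b: nearest a
    idx_a, idx_b = [], []
    for ia in range(pa.shape[0]):
        ib = int(nn_ab[ia])
        if int(nn_ba[ib]) == ia and d_ab[ia] <= max_distance:
            idx_a.append(ia)
            idx_b.append(ib)
    return np.asarray(idx_a, dtype=int), np.asarray(idx_b, dtype=int)


def _distance_consistent_match(
    pa: np.ndarray, pb: np.ndarray, tol_mm: float = 0.35
):
    """Init-free correspondence search by interpoint-distance consistency.

    Pairs of triplets with matching (sorted) triangle sides seed 3-point
    rigid fits; the candidate aligning the most beads one-to-one within
    ``tol_mm`` wins (ties: lowest RMS). Deterministic; O(n^3 choose
    buckets), fine for marker-scale sets.
    """
    from itertools import combinations, permutations

    na, nb = pa.shape[0], pb.shape[0]
    tris_a = list(combinations(range(na), 3))
    tris_b = list(combinations(range(nb), 3))
    tree_b = cKDTree(pb)
    best = None  # (n_inliers, -rms, idx_a, idx_b)
    for ta in tris_a:
        qa = pa[list(ta)]
        da = np.array([np.linalg.norm(qa[0] - qa[1]),
                       np.linalg.norm(qa[0] - qa[2]),
                       np.linalg.norm(qa[1] - qa[2])])
        for tb in tris_b:
            for perm in permutations(tb):
                qb = pb[list(perm)]
                db = np.array([np.linalg.norm(qb[0] - qb[1]),
                               np.linalg.norm(qb[0] - qb[2]),
                               np.linalg.norm(qb[1] - qb[2])])
                if np.abs(da - db).max() > tol_mm:
                    continue
                try:
                    cand, _ = kabsch_fit(qa, qb)
                except DegenerateConfigurationError:
                    continue
                moved = cand.apply(pa)
                dist, nn = tree_b.query(moved)
                # greedy one-to-one inliers, closest first
                order = np.argsort(dist, kind="stable")
                used_b: set = set()
                ia_list, ib_list = [], []
                for ia in order:
                    ib = int(nn[ia])
                    if dist[ia] <= tol_mm and ib not in used_b:
                        used_b.add(ib)
                        ia_list.append(int(ia))
                        ib_list.append(ib)
                if len(ia_list) < 3:
                    continue
                resid = cand.apply(pa[ia_list]) - pb[ib_list]
                rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
                key = (len(ia_list), -rms)
                if best is None or key > (best[0], best[1]):
                    srt = np.argsort(ia_list, kind="stable")
                    best = (len(ia_list), -rms,
                            np.asarray(ia_list)[srt], np.asarray(ib_list)[srt])
    if best is None:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return best[2], best[3]


def match_beads(
    set_a: "BeadSet",
    set_b: "BeadSet",
    init: RigidTransform | None = None,
    max_distance_mm: float = np.inf,
    verify_rms_mm: float = 0.35,
) -> Correspondence:
    """Automatic bead correspondence between two labelled sets.

    Mutual nearest neighbours after applying ``init`` to ``set_a``; if that
    yields fewer than 3 pairs, or a 3-point-plus rigid fit over the pairs
    leaves an RMS above ``verify_rms_mm`` (a symptom of aliased matches
    when the true motion is large relative to bead spacing), an init-free
    interpoint-distance consistency search takes over. Bead dropout on
    either side is tolerated and reported as long as at least 3 pairs
    remain; ties are resolved deterministically by the smallest label index
    (bead sets are sorted by centroid on extraction).
    """
    if init is None:
        init = RigidTransform.identity()
    pa_raw = np.asarray(set_a.points, dtype=float)
    pb = np.asarray(set_b.points, dtype=float)
    if pa_raw.shape[0] < 3 or pb.shape[0] < 3:
        raise MatchingError(
            f"need >= 3 beads on both sides, got {pa_raw.shape[0]} and {pb.shape[0]}"
        )
    idx_a, idx_b = _mutual_nn_pairs(init.apply(pa_raw), pb, max_distance_mm)
    ok = idx_a.shape[0] >= 3
    if ok:
        try:
            _, q = kabsch_fit(pa_raw[idx_a], pb[idx_b])
            ok = q.mean_error_mm <= verify_rms_mm
        except DegenerateConfigurationError:
            ok = False
    if not ok:
        idx_a, idx_b = _distance_consistent_match(pa_raw, pb)
    if idx_a.shape[0] < 3:
        raise MatchingError(
            f"only {idx_a.shape[0]} consistent bead pairs found (need >= 3); "
            "check bead extraction or increase the matching tolerance"
        )
    labels_a = list(set_a.labels)
    labels_b = list(set_b.labels)
    matched_a = set(idx_a.tolist())
    matched_b = set(idx_b.tolist())
    return Correspondence(
        pairs=tuple((labels_a[i], labels_b[j]) for i, j in zip(idx_a, idx_b)),
        index_a=idx_a,
        index_b=idx_b,
        unmatched_a=tuple(labels_a[i] for i in range(pa_raw.shape[0]) if i not in matched_a),
        unmatched_b=tuple(labels_b[j] for j in range(pb.shape[0]) if j not in matched_b),
    )


def _subsample(points: np.ndarray, n_max: int, seed: int) -> np.ndarray:
    if points.shape[0] <= n_max:
        return points
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(points.shape[0], size=n_max, replace=False))
    return points[keep]


def estimate_normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """Unit surface normals by local PCA over the k nearest neighbours.

    Normal orientation (sign) is arbitrary; point-to-plane residuals below
    use squared projections, so the sign never matters.
    """
    pts = _as_points(points)
    k = min(k, pts.shape[0])
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    nbrs = pts[idx]  # (n, k, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred)
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, :, 0]  # eigenvector of the smallest eigenvalue


_PLANE_MAX_ROT_RAD = 0.05
_PLANE_MAX_TRANS_MM = 1.0


def _solve_point_to_plane(src, tgt, normals, centre, anchors=None) -> RigidTransform:
    """One linearised point-to-plane step (small-angle least squares).

    The rotation is parameterised about ``centre`` (the source centroid) to
    decorrelate it from translation. Near-symmetric surfaces make the 6x6
    system ill-conditioned along the symmetry twist, so small eigenvalues
    are truncated and the step is clamped; without this the solve slides
    arbitrarily far along the symmetry valley.
    """
    p = src - centre
    r = np.einsum("ni,ni->n", tgt - src, normals)  # signed plane distances
    jac = np.hstack([np.cross(p, normals), normals])  # (n, 6): rot, trans
    h = jac.T @ jac
    g = jac.T @ r
    if anchors is not None:
        a_src, a_tgt, weight = anchors
        pa = a_src - centre
        ra = (a_tgt - a_src).ravel()  # 3 point-to-point residuals per anchor
        eye = np.tile(np.eye(3), (pa.shape[0], 1))
        cross = np.zeros((3 * pa.shape[0], 3))
        for k, e in enumerate(np.eye(3)):
            cross[k::3] = np.cross(pa, e)  # (omega x p) . e_k = omega . (p x e_k)
        ja = np.hstack([cross, eye])
        h = h + weight * (ja.T @ ja)
        g = g + weight * (ja.T @ ra)
    vals, vecs = np.linalg.eigh(h)
    good = vals > max(vals.max(), 1e-300) * 1e-8
    x = vecs[:, good] @ ((vecs[:, good].T @ g) / vals[good])
    rot_step = np.linalg.norm(x[:3])
    if rot_step > _PLANE_MAX_ROT_RAD:
        x *= _PLANE_MAX_ROT_RAD / rot_step
    trans_step = np.linalg.norm(x[3:])
    if trans_step > _PLANE_MAX_TRANS_MM:
        x *= _PLANE_MAX_TRANS_MM / trans_step
    rot = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(rot, x[3:] + centre - rot @ centre)


def icp_register(
    source,
    target,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol_mm: float = 1e-4,
    metric: str = "point",
    max_source_points: int = 20000,
    max_target_points: int = 50000,
    seed: int = 0,
    anchor_source=None,
    anchor_target=None,
    anchor_weight: float = 25.0,
) -> tuple[RigidTransform, RegistrationQuality]:
    """Iterative closest point rigid alignment.

    ``metric='point'`` alternates nearest-neighbour correspondence with a
    Kabsch refit; ``metric='plane'`` minimises point-to-plane distances
    against PCA-estimated target normals, which removes the tangential
    sampling-noise floor and is the recommended metric for voxelised or
    resampled surfaces. Iteration stops when the RMS change falls below
    ``tol_mm`` or ``max_iter`` is reached. Clouds beyond the stated caps
    are subsampled with a fixed seed, so results are deterministic; if the
    RMS never improves, the best iterate is returned with
    ``converged = False``.

    ``anchor_source``/``anchor_target`` (plane metric only) are matched 1:1
    landmark pairs added to the solve as point-to-point terms with weight
    ``anchor_weight`` per coordinate. Surfaces with a near-symmetry (e.g. a
    threaded shell, symmetric under rotate-and-slide) leave one twist
    direction unconstrained; a few accurately-known landmarks pin it.
    """
    if metric not in ("point", "plane"):
        raise ValueError(f"unknown ICP metric {metric!r}")
    src_full = _as_points(getattr(source, "points", source), "source")
    tgt_full = _as_points(getattr(target, "points", target), "target")
    if init is None:
        init = RigidTransform.identity()
    src = _subsample(src_full, max_source_points, seed)
    tgt = _subsample(tgt_full, max_target_points, seed + 1)
    tree = cKDTree(tgt)
    cn = condition_number(src) if src.shape[0] >= 3 else float("inf")
    normals = estimate_normals(tgt) if metric == "plane" else None
    a_src = a_tgt = None
    if anchor_source is not None:
        if metric != "plane":
            raise ValueError("landmark anchors require metric='plane'")
        a_src = _as_points(anchor_source, "anchor_source")
        a_tgt = _as_points(anchor_target, "anchor_target")
        if a_src.shape != a_tgt.shape:
            raise ValueError("anchor source/target length mismatch")

    transform = init
    best_cost = np.inf
    best_rms = np.inf
    best_transform = transform
    prev_cost = np.inf
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        moved = transform.apply(src)
        dist, idx = tree.query(moved)
        anchors = None
        if metric == "plane":
            resid = np.einsum("ni,ni->n", moved - tgt[idx], normals[idx])
            rms = float(np.sqrt(np.mean(resid**2)))
            cost = rms
            if a_src is not None:
                a_moved = transform.apply(a_src)
                anchors = (a_moved, a_tgt, anchor_weight)
                sq = np.sum(resid**2) + anchor_weight * np.sum((a_tgt - a_moved) ** 2)
                denom = resid.shape[0] + anchor_weight * 3 * a_src.shape[0]
                cost = float(np.sqrt(sq / denom))
        else:
            rms = float(np.sqrt(np.mean(dist**2)))
            cost = rms
        if cost < best_cost:
            best_cost = cost
            best_rms = rms
            best_transform = transform
        if cost <= tol_mm or abs(prev_cost - cost) < tol_mm:
            converged = True
            break
        prev_cost = cost
        if metric == "plane":
            step = _solve_point_to_plane(moved, tgt[idx], normals[idx],
                                         moved.mean(axis=0), anchors)
            transform = step @ transform
        else:
            transform, _ = kabsch_fit(src, tgt[idx])
    quality = RegistrationQuality(
        mean_error_mm=best_rms if np.isfinite(best_rms) else 0.0,
        condition_number=cn,
        n_points=src.shape[0],
        converged=converged,
        iterations=iterations,
    )
    return best_transform, quality


def coarse_align_candidates(source, target) -> list:
    """The four proper principal-axis pairings (plus centroid shift).

    Principal axes are sign-ambiguous, so aligning two PCA frames leaves a
    four-fold rotation ambiguity (180° flips about the axes, restricted to
    det = +1). All four candidates are returned so a caller with better
    information (e.g. a symmetry-aware sweep) can score them itself.
    Degenerate or near-isotropic clouds yield the single centroid-only
    candidate, with a warning.
    """
    src = _as_points(getattr(source, "points", source), "source")
    tgt = _as_points(getattr(target, "points", target), "target")
    if src.shape[0] == 0 or tgt.shape[0] == 0:
        raise ValueError("coarse alignment requires non-empty clouds")
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    if src.shape[0] < 3 or tgt.shape[0] < 3:
        return [RigidTransform(np.eye(3), ct - cs)]

    _, s_s, vt_s = np.linalg.svd(src - cs, full_matrices=False)
    _, s_t, vt_t = np.linalg.svd(tgt - ct, full_matrices=False)
    if s_s[-1] <= 1e-12 * s_s[0] or s_s[0] == 0 or (s_s[0] / max(s_s[-1], 1e-300)) < 1.05:
        warnings.warn(
            "near-isotropic or degenerate principal axes; falling back to "
            "centroid-only coarse alignment",
            stacklevel=2,
        )
        return [RigidTransform(np.eye(3), ct - cs)]

    # canonicalise both axis frames to proper rotations before pairing
    if np.linalg.det(vt_s) < 0:
        vt_s = vt_s * np.array([[1.0], [1.0], [-1.0]])
    if np.linalg.det(vt_t) < 0:
        vt_t = vt_t * np.array([[1.0], [1.0], [-1.0]])
    out = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        signs = np.array([sx, sy, sx * sy], dtype=float)  # keeps det = +1
        rot = vt_t.T @ np.diag(signs) @ vt_s
        out.append(RigidTransform(rot, ct - rot @ cs))
    return out


def coarse_align(source, target, seed: int = 0) -> RigidTransform:
    """Deterministic coarse alignment: centroid shift + principal axes.

    The rotation candidates are the four proper sign assignments of the
    principal-axis frames; the candidate with the smallest nearest-neighbour
    RMS (on a seeded subsample) wins. Clouds with near-isotropic principal
    moments fall back to centroid-only alignment with a warning.
    """
    src = _as_points(getattr(source, "points", source), "source")
    tgt = _as_points(getattr(target, "points", target), "target")
    candidates = coarse_align_candidates(src, tgt)
    if len(candidates) == 1:
        return candidates[0]
    src_probe = _subsample(src, 2000, seed)
    tree = cKDTree(_subsample(tgt, 20000, seed + 1))
    best = candidates[0]
    best_score = np.inf
    for cand in candidates:
        d, _ = tree.query(cand.apply(src_probe))
        score = float(np.sqrt(np.mean(d**2)))
        if score < best_score - 1e-12:
            best_score = score
            best = cand
    return best
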