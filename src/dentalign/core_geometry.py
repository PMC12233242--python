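"""Rigid-body mathematics shared by every stage of the pipeline.

Conventions
-----------
* Points are row vectors in an ``(N, 3)`` array, coordinates in mm.
* A :class:`RigidTransform` acts as ``x -> R @ x + t``.
* Quaternions are ``(w, x, y, z)`` with unit norm and canonical sign
  ``w >= 0`` (removes the double-cover ambiguity from serialized output).
* Serialized 4x4 matrices are written in column-major element order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "kabsch_align",
    "rodrigues_rotation",
    "quat_slerp",
    "quat_multiply",
    "quat_conjugate",
    "rotmat_to_quat",
    "quat_to_rotmat",
    "transform_points",
    "write_transform_text",
    "read_transform_text",
]

_ORTHO_TOL = 1e-6


def _check_rotation(matrix: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {matrix.shape}")
    if not np.allclose(matrix.T @ matrix, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal within tolerance")
    if np.linalg.det(matrix) < 0:
        raise ValueError("matrix is a reflection (det < 0), not a rotation")
    return matrix


def canonical_quat(q: np.ndarray) -> np.ndarray:
    """Normalize a quaternion and fix the sign so that w >= 0."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n < 1e-12:
        raise ValueError("zero-norm quaternion")
    q = q / n
    if q[0] < 0 or (q[0] == 0 and (q[np.argmax(np.abs(q))] < 0)):
        q = -q
    return q


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform (rotation + translation) in 3-D.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Orthonormal, det = +1.
    translation : (3,) ndarray
        Displacement in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite translation")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("bottom row of a rigid transform must be (0,0,0,1)")
        return cls(matrix[:3, :3], matrix[:3, 3])

    @classmethod
    def from_quat_trans(cls, quat: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(quat_to_rotmat(quat), translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @property
    def quaternion(self) -> np.ndarray:
        return rotmat_to_quat(self.rotation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return transform_points(points, self)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other, i.e. the transform applying ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle of this transform, degrees in [0, 180]."""
        w = np.clip(np.abs(self.quaternion[0]), -1.0, 1.0)
        return float(np.degrees(2.0 * np.arccos(w)))

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


def kabsch_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source_points`` onto ``target_points``.

    SVD-based alignment of two corresponded point sets: centroids are
    removed, the covariance ``S = X_cᵀ Y_c`` is decomposed as
    ``U Σ Vᵀ``, and the rotation is ``R = V M Uᵀ`` with
    ``M = diag(1, 1, det(V Uᵀ))`` correcting a possible reflection so
    that ``det(R) = +1``. The translation is ``t = ȳ − R x̄``.

    Raises
    ------
    ValueError
        If point counts differ, fewer than 3 points are given, or the
        geometry is degenerate (collinear points / rank-deficient
        covariance).
    """
    x = np.asarray(source_points, dtype=float)
    y = np.asarray(target_points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or y.ndim != 2 or y.shape[1] != 3:
        raise ValueError("point sets must be (N, 3) arrays")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"correspondence error: {x.shape[0]} source vs {y.shape[0]} target points"
        )
    if x.shape[0] < 3:
        raise ValueError("degenerate geometry: need at least 3 corresponded points")

    xbar = x.mean(axis=0)
    ybar = y.mean(axis=0)
    s = (x - xbar).T @ (y - ybar)
    u, sing, vt = np.linalg.svd(s)
    # Two near-zero singular values => points essentially collinear; the
    # in-plane rotation about that line is then unconstrained.
    if sing[1] <= sing[0] * 1e-9:
        raise ValueError("degenerate geometry: source points are (near-)collinear")
    v = vt.T
    m = np.diag([1.0, 1.0, np.sign(np.linalg.det(v @ u.T))])
    r = v @ m @ u.T
    t = ybar - r @ xbar
    return RigidTransform(r, t)


def rodrigues_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix from an axis-angle pair.

    ``R = I cosθ + (1 − cosθ) n nᵀ + sinθ [n]×`` with ``[n]×`` the
    skew-symmetric matrix of the unit axis ``n``.
    """
    n = np.asarray(axis, dtype=float).reshape(3)
    nn = np.linalg.norm(n)
    if abs(nn - 1.0) > 1e-8:
        if nn < 1e-12:
            raise ValueError("invalid axis: zero length")
        raise ValueError(f"invalid axis: norm {nn} is not 1 within 1e-8")
    c, s = np.cos(angle), np.sin(angle)
    skew = np.array([[0.0, -n[2], n[1]], [n[2], 0.0, -n[0]], [-n[1], n[0], 0.0]])
    return c * np.eye(3) + (1.0 - c) * np.outer(n, n) + s * skew


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {n} is not 1 within 1e-6")
    w, x, y, z = q / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotmat_to_quat(matrix: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z), canonical sign w >= 0, of a rotation matrix.

    Shepperd's method: pick the largest of the four squared components to
    avoid catastrophic cancellation near 180° rotations.
    """
    m = _check_rotation(matrix)
    tr = np.trace(m)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    elif m[0, 0] >= m[1, 1] and m[0, 0] >= m[2, 2]:
        s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2.0
        q = np.array(
            [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        )
    elif m[1, 1] >= m[2, 2]:
        s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2.0
        q = np.array(
            [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        )
    else:
        s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2.0
        q = np.array(
            [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
        )
    return canonical_quat(q)


def quat_slerp(q0: np.ndarray, q1: np.ndarray, u: float) -> np.ndarray:
    """Spherical linear interpolation between two unit quaternions.

    Interpolates along the shortest great-circle arc (``q1`` is negated
    if the quaternion dot product is negative, absorbing the double
    cover). ``u`` must lie in [0, 1]; the result is unit-norm.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"interpolation fraction {u} outside [0, 1]")
    q0 = canonical_quat(q0)
    q1 = np.asarray(q1, dtype=float) / np.linalg.norm(q1)
    dot = float(np.dot(q0, q1))
    if dot < 0.0:
        q1, dot = -q1, -dot
    dot = min(dot, 1.0)
    theta = np.arccos(dot)
    if theta < 1e-10:
        out = (1.0 - u) * q0 + u * q1  # nearly parallel: lerp is exact enough
    else:
        out = (np.sin((1.0 - u) * theta) * q0 + np.sin(u * theta) * q1) / np.sin(theta)
    return canonical_quat(out)


def transform_points(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to an (N, 3) cloud: ``R @ p + t`` per point."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must have 3 coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in input points")
    out = pts @ transform.rotation.T + transform.translation
    return out[0] if squeeze else out


def write_transform_text(path, transforms: dict[int, RigidTransform] | list[RigidTransform]) -> None:
    """Write per-tooth 4x4 transforms as plain text, column-major element order.

    Each block is ``# tooth <index>`` followed by the 16 elements of the
    homogeneous matrix read down the columns, one per line.
    """
    if isinstance(transforms, list):
        transforms = dict(enumerate(transforms))
    lines: list[str] = []
    for idx in sorted(transforms):
        lines.append(f"# tooth {idx}")
        for val in transforms[idx].matrix.flatten(order="F"):
            lines.append(f"{val:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_transform_text(path) -> dict[int, RigidTransform]:
    transforms: dict[int, RigidTransform] = {}
    idx = None
    buf: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if idx is not None and buf:
                    raise ValueError(f"incomplete matrix for tooth {idx} in {path}")
                idx = int(line.split()[-1])
                buf = []
            else:
                buf.append(float(line))
                if len(buf) == 16:
                    mat = np.array(buf).reshape(4, 4, order="F")
                    transforms[idx] = RigidTransform.from_matrix(mat)
                    idx, buf = None, []
    if buf:
        raise ValueError(f"trailing incomplete matrix in {path}")
    return transforms
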