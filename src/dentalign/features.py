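"""Hierarchical geometric feature extraction for single teeth.

Five feature families feed the pose-regression network: a farthest-point
subsample of the crown cloud (shape), per-type anatomical landmarks
(Mesial/Distal/... as on clinical annotation sheets), the tooth's local
frame expressed as a quaternion, an oriented-bounding-box descriptor,
and a one-hot tooth-type code.

Landmark counts differ by tooth type (2 for incisors and cuspids, 4 for
premolars, 6 for molars); they are packed into a fixed-width masked
vector so every tooth yields the same feature shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import rotmat_to_quat

__all__ = [
    "TOOTH_TYPES",
    "MAX_LANDMARKS",
    "ToothFeatures",
    "fps_sample",
    "landmark_schema",
    "extract_landmarks",
    "compute_obb",
    "frame_to_quaternion",
    "build_feature_tensor",
]

TOOTH_TYPES = ("incisor", "cuspid", "premolar", "molar")
MAX_LANDMARKS = 6

# "DistantLip" is kept as the serialized molar landmark name (faithful to
# the annotation sheets this mirrors); "DistalLip" is accepted as an alias.
_SCHEMAS: dict[str, tuple[str, ...]] = {
    "incisor": ("Mesial", "Distal"),
    "cuspid": ("Mesial", "Distal"),
    "premolar": ("Mesial", "Distal", "Lip", "Tongue"),
    "molar": ("Mesial", "Distal", "MesialLip", "DistantLip", "MesialTongue", "DistalTongue"),
}
LANDMARK_ALIASES = {"DistalLip": "DistantLip"}


def landmark_schema(tooth_type: str) -> tuple[str, ...]:
    """Ordered landmark names for a tooth type."""
    try:
        return _SCHEMAS[tooth_type]
    except KeyError:
        raise ValueError(
            f"unknown tooth type {tooth_type!r}; expected one of {TOOTH_TYPES}"
        ) from None


def type_onehot(tooth_type: str) -> np.ndarray:
    if tooth_type not in TOOTH_TYPES:
        raise ValueError(f"unknown tooth type {tooth_type!r}")
    return (np.array(TOOTH_TYPES) == tooth_type).astype(float)


def fps_sample(points: np.ndarray, m: int, rng_seed: int | None = None) -> np.ndarray:
    """Farthest-point subsample of an ``(N, 3)`` cloud down to ``m`` points.

    The first point is the one nearest the centroid and each subsequent
    point maximizes its distance to the already-selected set, ties broken
    by lowest index — the selection is therefore fully deterministic and
    invariant to the row order of the input (``rng_seed`` is accepted for
    interface symmetry with the other samplers but is not consumed).
    With ``m == N`` the cloud is returned unchanged, so resampling a pair
    of corresponded clouds to their current size preserves correspondence.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if m > n:
        raise ValueError(f"undersampled: requested {m} points from a cloud of {n}")
    if m == n:
        return pts.copy()
    centroid = pts.mean(axis=0)
    selected = np.empty(m, dtype=int)
    selected[0] = int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))
    dist = np.linalg.norm(pts - pts[selected[0]], axis=1)
    for i in range(1, m):
        selected[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(pts - pts[selected[i]], axis=1))
    return pts[selected]


def extract_landmarks(tooth) -> tuple[np.ndarray, bool]:
    """Fixed-width masked landmark vector for one tooth.

    Landmarks are snapped to the nearest vertex of the tooth's cloud and
    packed in schema order into the first slots of a 6-landmark vector:
    18 coordinates followed by 6 presence bits. Returns the vector and a
    flag telling whether annotated landmarks were available (``False``
    means the analytic fallback — extreme points along the tooth frame
    axes — was used).
    """
    schema = landmark_schema(tooth.tooth_type)
    pts = np.asarray(tooth.points, dtype=float)
    coords = np.zeros((MAX_LANDMARKS, 3))
    mask = np.zeros(MAX_LANDMARKS)
    annotated = bool(tooth.landmarks)
    for slot, name in enumerate(schema):
        if annotated:
            key = name if name in tooth.landmarks else LANDMARK_ALIASES.get(name, name)
            target = np.asarray(tooth.landmarks[key], dtype=float)
        else:
            # fallback: extreme point along the mesiodistal / buccolingual axes
            axis = np.asarray(tooth.frame)[slot % 2] * (1 if slot < 2 else -1)
            target = pts[np.argmax(pts @ axis)]
        coords[slot] = pts[np.argmin(np.linalg.norm(pts - target, axis=1))]
        mask[slot] = 1.0
    return np.concatenate([coords.ravel(), mask]), annotated


def compute_obb(points: np.ndarray) -> np.ndarray:
    """PCA oriented-bounding-box descriptor: center 3, extents 3, axis quat 4.

    Axes are the principal components sorted by decreasing variance with a
    deterministic sign policy (each of the first two axes is oriented
    toward positive dot with +x, falling back to +y then +z when nearly
    perpendicular); the third axis is their cross product, so the frame is
    always right-handed. Extents are half-ranges of the projections.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("OBB needs at least 4 points of shape (N, 3)")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= max(evals[-1] * 1e-10, 1e-18):
        raise ValueError("degenerate geometry: points are (near-)coplanar")
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T.copy()
    for i in range(2):
        for ref in np.eye(3):
            d = float(axes[i] @ ref)
            if abs(d) > 1e-8:
                if d < 0:
                    axes[i] = -axes[i]
                break
    axes[2] = np.cross(axes[0], axes[1])
    proj = centered @ axes.T
    extents = (proj.max(axis=0) - proj.min(axis=0)) / 2.0
    quat = rotmat_to_quat(axes.T)  # columns = axes: world frame -> box frame
    return np.concatenate([center, extents, quat])


def frame_to_quaternion(axes: np.ndarray) -> np.ndarray:
    """Quaternion of the rotation taking the world frame onto a tooth frame.

    The three axis vectors are re-orthonormalized by Gram–Schmidt and the
    third axis replaced by the cross product of the first two, enforcing
    right-handedness; the quaternion is returned with canonical sign.
    """
    a = np.asarray(axes, dtype=float).reshape(3, 3).copy()
    n0 = np.linalg.norm(a[0])
    if n0 < 1e-8:
        raise ValueError("invalid frame: first axis has zero length")
    a[0] /= n0
    a[1] -= (a[1] @ a[0]) * a[0]
    n1 = np.linalg.norm(a[1])
    if n1 < 1e-8:
        raise ValueError("invalid frame: axes are rank-deficient")
    a[1] /= n1
    a[2] = np.cross(a[0], a[1])
    return rotmat_to_quat(a.T)


@dataclass
class ToothFeatures:
    """Fixed-shape feature block of one tooth."""

    sampled_points: np.ndarray  # (m, 3) mm
    landmark_vector: np.ndarray  # (24,) = 18 coords + 6 mask bits
    frame_quaternion: np.ndarray  # (4,)
    obb_descriptor: np.ndarray  # (10,)
    type_onehot: np.ndarray  # (4,)

    @property
    def vector(self) -> np.ndarray:
        """All features concatenated into one flat vector."""
        return np.concatenate(
            [
                self.sampled_points.ravel(),
                self.landmark_vector,
                self.frame_quaternion,
                self.obb_descriptor,
                self.type_onehot,
            ]
        )

    @property
    def landmark_coords(self) -> np.ndarray:
        return self.landmark_vector[: 3 * MAX_LANDMARKS].reshape(MAX_LANDMARKS, 3)


def build_feature_tensor(case, m: int = 32) -> list[ToothFeatures]:
    """Feature blocks for every tooth of a case (constant width across types)."""
    feats = []
    for tooth in case.teeth:
        lm, _ = extract_landmarks(tooth)
        feats.append(
            ToothFeatures(
                sampled_points=fps_sample(tooth.points, m),
                landmark_vector=lm,
                frame_quaternion=frame_to_quaternion(tooth.frame),
                obb_descriptor=compute_obb(tooth.points),
                type_onehot=type_onehot(tooth.tooth_type),
            )
        )
    return feats
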