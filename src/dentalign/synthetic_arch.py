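"""Synthetic single-arch dental cases with known ground-truth corrections.

Clinical malocclusion datasets are private; this module generates
stand-in cases with the same structure: an ordered arch of per-tooth
point clouds (the malocclusion state), per-tooth rigid transforms to the
corrected state, per-type anatomical landmarks, and local tooth frames.

Geometry
--------
Crowns are superellipsoids with type-specific semi-axes and exponents —
crude but analytically convenient: landmarks and frames come for free as
extreme points / principal axes. Teeth sit on a parabolic arch curve
(occlusal direction +z, arch opening toward −y, units mm) in the ideal
configuration; the malocclusion state is produced by applying the
*inverse* of a bounded random rigid perturbation per tooth, so the
stored target transform restores the ideal arch exactly by construction.

Default perturbation severity is 5 mm / 5° per axis (rotations about the
tooth centroid composed per axis), half the 10 mm / 10° physiological
movement limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_geometry import RigidTransform, rodrigues_rotation, transform_points
from .features import compute_obb, landmark_schema

__all__ = [
    "Tooth",
    "DentalCase",
    "generate_tooth",
    "generate_arch_case",
    "split_cases",
    "transform_tooth",
    "DEFAULT_SEVERITY",
    "TOOTH_SHAPE_PARAMS",
]

DEFAULT_SEVERITY = (5.0, 5.0)  # (max |translation| mm per axis, max rotation deg per axis)

# semi-axes (mesiodistal, buccolingual, occlusal) in mm and superellipsoid
# exponents (vertical, equatorial) per tooth type
TOOTH_SHAPE_PARAMS: dict[str, dict] = {
    "incisor": {"size": (3.8, 2.0, 5.5), "e1": 0.9, "e2": 0.8},
    "cuspid": {"size": (3.6, 2.8, 6.0), "e1": 1.2, "e2": 0.9},
    "premolar": {"size": (3.4, 3.0, 4.5), "e1": 0.9, "e2": 0.9},
    "molar": {"size": (5.0, 4.3, 4.0), "e1": 0.7, "e2": 0.6},
}

DEFAULT_ARCH_PARAMS = {"apex_y": 25.0, "coeff": 0.055, "gap": 0.5}


@dataclass
class Tooth:
    """One tooth: crown point cloud plus its annotations.

    ``frame`` rows are the (mesiodistal, buccolingual, occlusal) axes;
    the first axis follows the arch tangent left→right, the second points
    outward (lip side), the third toward the occlusal surface.
    """

    points: np.ndarray
    tooth_type: str
    arch_index: int
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape[0] < 50:
            raise ValueError("a tooth cloud needs at least 50 points")
        self.frame = np.asarray(self.frame, dtype=float)
        expected = set(landmark_schema(self.tooth_type))
        if self.landmarks and set(self.landmarks) != expected:
            raise ValueError(
                f"landmark names {sorted(self.landmarks)} do not match the "
                f"{self.tooth_type} schema {sorted(expected)}"
            )

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def obb(self) -> np.ndarray:
        return compute_obb(self.points)


def transform_tooth(tooth: Tooth, transform: RigidTransform) -> Tooth:
    """A new tooth with points, landmarks and frame rigidly transformed."""
    return Tooth(
        points=transform.apply(tooth.points),
        tooth_type=tooth.tooth_type,
        arch_index=tooth.arch_index,
        landmarks={k: transform.apply(v) for k, v in tooth.landmarks.items()},
        frame=tooth.frame @ transform.rotation.T,
    )


@dataclass
class DentalCase:
    """An ordered arch of teeth (malocclusion state) plus ground truth."""

    teeth: list[Tooth]
    target_transforms: list[RigidTransform]
    case_id: str = "case"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 12 <= len(self.teeth) <= 16:
            raise ValueError(f"a case needs 12–16 teeth, got {len(self.teeth)}")
        if len(self.target_transforms) != len(self.teeth):
            raise ValueError("every tooth needs a target transform")

    @property
    def n_teeth(self) -> int:
        return len(self.teeth)

    def end_tooth(self, i: int) -> Tooth:
        """Tooth ``i`` in the corrected state."""
        return transform_tooth(self.teeth[i], self.target_transforms[i])

    def end_case(self) -> "DentalCase":
        """The fully corrected arch (identity target transforms)."""
        return DentalCase(
            teeth=[self.end_tooth(i) for i in range(self.n_teeth)],
            target_transforms=[RigidTransform.identity()] * self.n_teeth,
            case_id=self.case_id + "_end",
            rng_seed=self.rng_seed,
        )


def _signed_pow(x: np.ndarray, e: float) -> np.ndarray:
    return np.sign(x) * np.abs(x) ** e


def generate_tooth(
    tooth_type: str,
    size_mm=None,
    n_points: int = 400,
    rng_seed: int = 0,
) -> Tooth:
    """Superellipsoid crown cloud in the tooth's own frame.

    Local axes: +x mesiodistal, +y lip side, +z occlusal. Landmarks sit at
    the analytic extreme points of the surface (equator for Mesial/Distal
    and Lip/Tongue, 45° meridians for the molar corner landmarks); the
    mesial side is labelled at +x and relabelled at arch-placement time
    for teeth on the right half of the arch (the shape is x-symmetric).
    """
    params = TOOTH_SHAPE_PARAMS.get(tooth_type)
    if params is None:
        raise ValueError(f"unknown tooth type {tooth_type!r}")
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    a, b, c = size_mm if size_mm is not None else params["size"]
    if min(a, b, c) <= 0:
        raise ValueError("tooth semi-axes must be positive")
    e1, e2 = params["e1"], params["e2"]
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform(-np.pi / 2, np.pi / 2, n_points)
    v = rng.uniform(-np.pi, np.pi, n_points)
    cu, su = _signed_pow(np.cos(u), e1), _signed_pow(np.sin(u), e1)
    cv, sv = _signed_pow(np.cos(v), e2), _signed_pow(np.sin(v), e2)
    pts = np.column_stack([a * cu * cv, b * cu * sv, c * su])

    k = (np.sqrt(0.5)) ** e2  # 45° meridian factor
    full = {
        "Mesial": np.array([a, 0.0, 0.0]),
        "Distal": np.array([-a, 0.0, 0.0]),
        "Lip": np.array([0.0, b, 0.0]),
        "Tongue": np.array([0.0, -b, 0.0]),
        "MesialLip": np.array([a * k, b * k, 0.0]),
        "DistantLip": np.array([-a * k, b * k, 0.0]),
        "MesialTongue": np.array([a * k, -b * k, 0.0]),
        "DistalTongue": np.array([-a * k, -b * k, 0.0]),
    }
    landmarks = {name: full[name] for name in landmark_schema(tooth_type)}
    return Tooth(points=pts, tooth_type=tooth_type, arch_index=-1, landmarks=landmarks)


_MIRROR = {
    "Mesial": "Distal",
    "Distal": "Mesial",
    "MesialLip": "DistantLip",
    "DistantLip": "MesialLip",
    "MesialTongue": "DistalTongue",
    "DistalTongue": "MesialTongue",
    "Lip": "Lip",
    "Tongue": "Tongue",
}


def _type_sequence(n_teeth: int) -> list[str]:
    if not 12 <= n_teeth <= 16 or n_teeth % 2:
        raise ValueError(f"n_teeth must be an even number in [12, 16], got {n_teeth}")
    n_molar = n_teeth // 2 - 5
    half = ["molar"] * n_molar + ["premolar", "premolar", "cuspid", "incisor", "incisor"]
    return half + half[::-1]


def sample_perturbation(max_trans: float, max_rot_deg: float, rng: np.random.Generator):
    """Per-axis bounded perturbation: (3x3 rotation, 3-vector displacement).

    Rotation composes three axis rotations Rz·Ry·Rx with each angle drawn
    from U(−max_rot, max_rot); translation components from U(−max_trans,
    max_trans). Bounds hold per axis by construction.
    """
    t = rng.uniform(-max_trans, max_trans, 3)
    angles = np.radians(rng.uniform(-max_rot_deg, max_rot_deg, 3))
    r = np.eye(3)
    for axis_idx in range(3):
        axis = np.zeros(3)
        axis[axis_idx] = 1.0
        r = rodrigues_rotation(axis, angles[axis_idx]) @ r
    return r, t


def generate_arch_case(
    n_teeth: int = 14,
    arch_params: dict | None = None,
    malocclusion_severity: tuple[float, float] = DEFAULT_SEVERITY,
    rng_seed: int = 0,
    n_points: int = 400,
    case_id: str | None = None,
) -> DentalCase:
    """A synthetic dental case with exact ground-truth correction transforms.

    Teeth are laid out along the parabola ``y = apex_y − coeff·x²`` in the
    ideal configuration (standard mirrored type sequence, adjacent crowns
    separated by ``gap`` mm of arc); each tooth is then displaced by the
    inverse of a random perturbation bounded by ``malocclusion_severity``
    and that perturbation is stored as its target transform, so
    ``target_transforms[i]`` maps the malocclusion tooth exactly onto its
    ideal position.
    """
    params = dict(DEFAULT_ARCH_PARAMS, **(arch_params or {}))
    max_trans, max_rot = malocclusion_severity
    if max_trans < 0 or max_rot < 0:
        raise ValueError("severity bounds must be non-negative")
    types = _type_sequence(n_teeth)
    rng = np.random.default_rng(rng_seed)

    widths = [2 * TOOTH_SHAPE_PARAMS[t]["size"][0] + params["gap"] for t in types]
    total = sum(widths)
    arc_centers = np.cumsum([0] + widths[:-1]) + np.array(widths) / 2 - total / 2

    # arc length -> x lookup along the parabola
    coeff = params["coeff"]
    xs = np.linspace(-0.75 * total, 0.75 * total, 4001)
    ds = np.sqrt(1.0 + (2 * coeff * xs) ** 2)
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(xs))])
    s -= s[len(s) // 2]

    teeth: list[Tooth] = []
    transforms: list[RigidTransform] = []
    for i, (ttype, s_i) in enumerate(zip(types, arc_centers)):
        x_i = float(np.interp(s_i, s, xs))
        center = np.array([x_i, params["apex_y"] - coeff * x_i**2, 0.0])
        slope = -2 * coeff * x_i
        tangent = np.array([1.0, slope, 0.0])
        tangent /= np.linalg.norm(tangent)
        outward = np.array([-slope, 1.0, 0.0])
        outward /= np.linalg.norm(outward)
        rot_place = np.column_stack([tangent, outward, [0.0, 0.0, 1.0]])

        local = generate_tooth(ttype, n_points=n_points, rng_seed=int(rng.integers(2**31)))
        if s_i > 0:  # right half: mesial side faces −x locally
            local.landmarks = {_MIRROR[k]: v for k, v in local.landmarks.items()}
        placement = RigidTransform(rot_place, center)
        ideal = Tooth(
            points=placement.apply(local.points),
            tooth_type=ttype,
            arch_index=i,
            landmarks={k: placement.apply(v) for k, v in local.landmarks.items()},
            frame=rot_place.T,
        )

        r, t = sample_perturbation(max_trans, max_rot, rng)
        c = ideal.centroid
        correction = RigidTransform(r, c - r @ c + t)  # rotate about the centroid, then shift
        teeth.append(transform_tooth(ideal, correction.inverse()))
        transforms.append(correction)

    return DentalCase(
        teeth=teeth,
        target_transforms=transforms,
        case_id=case_id or f"synthetic_{rng_seed}",
        rng_seed=rng_seed,
    )


def split_cases(cases: list, train_fraction: float, rng_seed: int = 0):
    """Deterministic shuffled split into (train, test)."""
    if not cases:
        raise ValueError("empty case list")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    order = np.random.default_rng(rng_seed).permutation(len(cases))
    n_train = int(np.floor(train_fraction * len(cases)))
    train = [cases[i] for i in order[:n_train]]
    test = [cases[i] for i in order[n_train:]]
    return train, test
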