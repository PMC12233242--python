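"""Geometric adaptive augmentation (GAOS): interpolated intermediate states.

Given matched malocclusion / corrected pairs, this stage fits each
tooth's rigid correction by SVD alignment, expresses its rotation as a
quaternion, and synthesizes intermediate physiological states by SLERP
on the rotation and linear interpolation of the displacement. Pairs
whose per-tooth point counts disagree are first standardized by seeded
farthest-point sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_geometry import (
    RigidTransform,
    kabsch_align,
    quat_slerp,
    quat_to_rotmat,
    transform_points,
    write_transform_text,
)
from .features import fps_sample

__all__ = [
    "PairRegistry",
    "validate_pairs",
    "standardize_pair",
    "fit_pair_transform",
    "generate_intermediates",
    "run_gaos",
]

log = logging.getLogger(__name__)


@dataclass
class PairRegistry:
    """Classification of start/end case pairs into conforming and not."""

    list_p: list = field(default_factory=list)  # conforming pair ids
    list_u: list = field(default_factory=list)  # non-conforming pair ids


def _tooth_points(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "points", obj), dtype=float)


def validate_pairs(start_cases: list, end_cases: list) -> PairRegistry:
    """Classify each start/end pair by structural conformity.

    A pair is conforming when both cases carry the same teeth (count and
    type sequence) and every tooth has matching point counts; anything
    else lands in ``list_u`` for standardization. Pairs are identified by
    index into the input lists.
    """
    if len(start_cases) != len(end_cases):
        raise ValueError(
            f"pairing error: {len(start_cases)} start vs {len(end_cases)} end cases"
        )
    registry = PairRegistry()
    for idx, (cs, ce) in enumerate(zip(start_cases, end_cases)):
        ok = len(cs.teeth) == len(ce.teeth) and all(
            ts.tooth_type == te.tooth_type and ts.points.shape[0] == te.points.shape[0]
            for ts, te in zip(cs.teeth, ce.teeth)
        )
        (registry.list_p if ok else registry.list_u).append(idx)
    return registry


def standardize_pair(
    start_tooth_points: np.ndarray,
    end_tooth_points: np.ndarray,
    n_target: int,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample both clouds of a tooth pair to exactly ``n_target`` points.

    Farthest-point sampling keeps shape extremes; both sides are sampled
    independently but deterministically.
    """
    start = _tooth_points(start_tooth_points)
    end = _tooth_points(end_tooth_points)
    for name, cloud in (("start", start), ("end", end)):
        if cloud.shape[0] < n_target:
            raise ValueError(
                f"undersampled: {name} cloud has {cloud.shape[0]} < {n_target} points"
            )
    return fps_sample(start, n_target, rng_seed), fps_sample(end, n_target, rng_seed)


def fit_pair_transform(start_tooth, end_tooth) -> RigidTransform:
    """Per-tooth local correction transform by corresponded SVD alignment.

    Expects a standardized pair (row-wise correspondence); the result is
    a proper rigid transform, available in quaternion + translation form
    through :class:`RigidTransform`.
    """
    return kabsch_align(_tooth_points(start_tooth), _tooth_points(end_tooth))


def generate_intermediates(start_tooth, transform: RigidTransform, K: int) -> list[np.ndarray]:
    """K intermediate clouds strictly between the start and corrected states.

    For k = 1..K the interpolation fraction is u = k/(K+1) (endpoints
    excluded: both already exist as cases); the rotation follows the
    SLERP geodesic from identity to the pair transform's quaternion and
    the displacement scales linearly, so the intermediate state at u has
    rotation angle u·θ and translation u·‖t‖ exactly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    start = _tooth_points(start_tooth)
    q1 = transform.quaternion
    identity = np.array([1.0, 0.0, 0.0, 0.0])
    out = []
    for k in range(1, K + 1):
        u = k / (K + 1)
        q_u = quat_slerp(identity, q1, u)
        t_u = u * transform.translation
        out.append(transform_points(start, RigidTransform(quat_to_rotmat(q_u), t_u)))
    return out


def interpolated_transform(transform: RigidTransform, u: float) -> RigidTransform:
    """The rigid transform at interpolation fraction ``u`` along the geodesic."""
    q_u = quat_slerp(np.array([1.0, 0.0, 0.0, 0.0]), transform.quaternion, u)
    return RigidTransform(quat_to_rotmat(q_u), u * transform.translation)


def run_gaos(
    start_dir,
    end_dir,
    out_dir,
    K: int = 3,
    n_target: int = 400,
    rng_seed: int = 0,
) -> dict:
    """Directory-level GAOS: augment every start/end case pair on disk.

    Reads paired case directories (matched by name) from ``start_dir``
    and ``end_dir``, standardizes any non-conforming pair, and writes K
    intermediate cases per pair. Every emitted case carries target
    transforms to the corrected state (so it is directly trainable) plus
    a ``*_transform.txt`` sidecar with the start→intermediate transforms
    in column-major text form. Returns a summary dict of counts.
    """
    from pathlib import Path

    from .case_io import list_case_dirs, read_case, write_case
    from .synthetic_arch import DentalCase, Tooth

    start_dir, end_dir, out_dir = Path(start_dir), Path(end_dir), Path(out_dir)
    start_ids = [p.name for p in list_case_dirs(start_dir)]
    end_ids = {p.name for p in list_case_dirs(end_dir)}
    common = [cid for cid in start_ids if cid in end_ids]
    if not common:
        raise ValueError(f"no paired case directories between {start_dir} and {end_dir}")
    start_cases = [read_case(start_dir / cid) for cid in common]
    end_cases = [read_case(end_dir / cid) for cid in common]
    registry = validate_pairs(start_cases, end_cases)
    log.info("gaos: %d conforming pairs, %d standardized", len(registry.list_p), len(registry.list_u))

    out_dir.mkdir(parents=True, exist_ok=True)
    n_written = 0
    for idx in registry.list_p + registry.list_u:
        cs, ce = start_cases[idx], end_cases[idx]
        clouds = [
            standardize_pair(ts, te, n_target, rng_seed)
            for ts, te in zip(cs.teeth, ce.teeth)
        ]
        totals = [fit_pair_transform(a, b) for a, b in clouds]
        for k in range(1, K + 1):
            u = k / (K + 1)
            partials = [interpolated_transform(t, u) for t in totals]
            teeth = [
                Tooth(
                    points=partial.apply(a),
                    tooth_type=tooth.tooth_type,
                    arch_index=tooth.arch_index,
                    landmarks={n: partial.apply(tooth.landmarks[n]) for n in tooth.landmarks},
                    frame=tooth.frame @ partial.rotation.T,
                )
                for (a, _), partial, tooth in zip(clouds, partials, cs.teeth)
            ]
            remaining = [tot.compose(p.inverse()) for tot, p in zip(totals, partials)]
            mid_id = f"{common[idx]}_gaos{k}"
            case = DentalCase(teeth=teeth, target_transforms=remaining,
                              case_id=mid_id, rng_seed=rng_seed)
            write_case(case, out_dir / mid_id)
            write_transform_text(out_dir / mid_id / f"{mid_id}_transform.txt", partials)
            n_written += 1
    return {
        "pairs": len(common),
        "conforming": len(registry.list_p),
        "standardized": len(registry.list_u),
        "intermediates_written": n_written,
    }
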