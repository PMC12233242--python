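"""Physiologically bounded random rigid augmentation (PARS).

Generates clinically plausible variants of a case by perturbing teeth
with rigid transforms sampled inside hard physiological limits: every
translation component uniform in [−10, 10] mm and the rotation angle
uniform in [−10°, 10°] about one of the coordinate axes, both bounds
configurable. Because sampling happens inside the box, the bounds hold
with probability 1 — no clamping.

Rotations are applied about the tooth (or arch) centroid so the bound on
the translation sample is exactly the bound on the tooth displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import RigidTransform, rodrigues_rotation
from .synthetic_arch import DentalCase, Tooth, transform_tooth

__all__ = ["PhysioBounds", "sample_constrained_transform", "augment_case"]


@dataclass(frozen=True)
class PhysioBounds:
    """Hard limits on tooth movement: mm per axis and degrees per rotation."""

    max_abs_translation: float = 10.0
    max_abs_angle: float = 10.0

    def __post_init__(self) -> None:
        if self.max_abs_translation < 0 or self.max_abs_angle < 0:
            raise ValueError("physiological bounds must be non-negative")


def sample_constrained_transform(
    bounds: PhysioBounds,
    rng: np.random.Generator,
    per_axis: bool = False,
) -> RigidTransform:
    """One random rigid transform inside the physiological box.

    Translation components are U(−max_t, max_t). By default the rotation
    is about a single uniformly chosen coordinate axis with angle
    U(−max_θ, max_θ), which keeps the stated angle bound exact; with
    ``per_axis=True`` three bounded axis rotations are composed instead
    (the composed angle may then exceed the per-axis bound).
    """
    t = rng.uniform(-bounds.max_abs_translation, bounds.max_abs_translation, 3)
    max_rad = np.radians(bounds.max_abs_angle)
    if per_axis:
        r = np.eye(3)
        for i in range(3):
            axis = np.zeros(3)
            axis[i] = 1.0
            r = rodrigues_rotation(axis, rng.uniform(-max_rad, max_rad)) @ r
    else:
        axis = np.zeros(3)
        axis[rng.integers(3)] = 1.0
        r = rodrigues_rotation(axis, rng.uniform(-max_rad, max_rad))
    return RigidTransform(r, t)


def _about(center: np.ndarray, s: RigidTransform) -> RigidTransform:
    """Re-express a transform so its rotation pivots about ``center``."""
    return RigidTransform(s.rotation, center - s.rotation @ center + s.translation)


def augment_case(
    case: DentalCase,
    bounds: PhysioBounds,
    rng: np.random.Generator,
    mode: str = "per_tooth",
) -> DentalCase:
    """A new case with bounded random perturbations applied on top.

    Each tooth's points go through its sampled transform (pivoting about
    the tooth centroid in ``per_tooth`` mode, about the arch centroid in
    ``whole_arch`` mode) and the stored target transforms are composed
    with the inverse perturbation, so the ground truth stays exact. The
    input case is untouched.
    """
    if mode not in ("per_tooth", "whole_arch"):
        raise ValueError(f"unknown mode {mode!r}")
    new_teeth: list[Tooth] = []
    new_targets: list[RigidTransform] = []
    if mode == "whole_arch":
        arch_centroid = np.mean([t.centroid for t in case.teeth], axis=0)
        shared = _about(arch_centroid, sample_constrained_transform(bounds, rng))
    for tooth, target in zip(case.teeth, case.target_transforms):
        if mode == "per_tooth":
            s = _about(tooth.centroid, sample_constrained_transform(bounds, rng))
        else:
            s = shared
        new_teeth.append(transform_tooth(tooth, s))
        new_targets.append(target.compose(s.inverse()))
    return DentalCase(
        teeth=new_teeth,
        target_transforms=new_targets,
        case_id=case.case_id + "_pars",
        rng_seed=case.rng_seed,
    )
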