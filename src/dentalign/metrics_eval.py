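"""Evaluation metrics: per-tooth pose errors and case-level reporting.

``ME_r`` is the geodesic rotation error in degrees, ``ME_t`` the
Euclidean translation error in mm — both well-defined and used for all
quantitative comparisons. ``CSA`` (case similarity, higher is better,
in [0, 1]) has no published closed form; the default here is an
*interpretation* — mean over teeth of quaternion alignment damped by an
exponential of the translation error — and is pluggable via the
``csa_fn`` argument of :func:`evaluate`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic_arch import DentalCase

__all__ = [
    "rotation_error",
    "translation_error",
    "case_similarity_score",
    "evaluate",
    "identity_baseline",
    "EvalReport",
]


def _check_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise ValueError("non-unit quaternion")
    return q


def rotation_error(pred_quat: np.ndarray, true_quat: np.ndarray) -> float:
    """Geodesic angle between two rotations, degrees in [0, 180].

    ``2·arccos(|⟨p, g⟩|)`` — invariant to quaternion sign, symmetric.
    """
    p, g = _check_unit(pred_quat), _check_unit(true_quat)
    return float(np.degrees(2.0 * np.arccos(np.clip(abs(float(p @ g)), 0.0, 1.0))))


def translation_error(pred_t: np.ndarray, true_t: np.ndarray) -> float:
    """Euclidean distance between predicted and true translations, mm."""
    return float(np.linalg.norm(np.asarray(pred_t, float) - np.asarray(true_t, float)))


def case_similarity_score(
    pred_quats: np.ndarray,
    pred_trans: np.ndarray,
    true_quats: np.ndarray,
    true_trans: np.ndarray,
    tau: float = 10.0,
) -> float:
    """Default CSA interpretation in [0, 1]; 1 iff the prediction is exact.

    Mean over teeth of ``|⟨p_r, g_r⟩| · exp(−‖p_t − g_t‖/τ)`` with
    τ = 10 mm. Monotone decreasing in both rotation and translation
    error. This is a documented interpretation, not a published formula.
    """
    scores = [
        abs(float(_check_unit(pq) @ _check_unit(gq))) * np.exp(
            -translation_error(pt, gt) / tau
        )
        for pq, pt, gq, gt in zip(pred_quats, pred_trans, true_quats, true_trans)
    ]
    return float(np.mean(scores))


@dataclass
class EvalReport:
    """Mean/Min/Max CSA plus mean rotation (deg) and translation (mm) errors."""

    csa_mean: float
    csa_min: float
    csa_max: float
    me_r: float
    me_t: float
    per_case: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "csa_mean": self.csa_mean, "csa_min": self.csa_min, "csa_max": self.csa_max,
            "me_r": self.me_r, "me_t": self.me_t, "per_case": self.per_case,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "csa", "me_r_deg", "me_t_mm"])
            for rec in self.per_case:
                writer.writerow([rec["case_id"], rec["csa"], rec["me_r"], rec["me_t"]])
            writer.writerow(["MEAN", self.csa_mean, self.me_r, self.me_t])
            writer.writerow(["MIN_CSA", self.csa_min, "", ""])
            writer.writerow(["MAX_CSA", self.csa_max, "", ""])


def _case_record(case: DentalCase, quats, trans, csa_fn) -> dict:
    gq = np.stack([t.quaternion for t in case.target_transforms])
    gt = np.stack([t.translation for t in case.target_transforms])
    return {
        "case_id": case.case_id,
        "csa": csa_fn(quats, trans, gq, gt),
        "me_r": float(np.mean([rotation_error(p, g) for p, g in zip(quats, gq)])),
        "me_t": float(np.mean([translation_error(p, g) for p, g in zip(trans, gt)])),
    }


def _aggregate(records: list[dict]) -> EvalReport:
    records = sorted(records, key=lambda r: r["case_id"])
    csas = [r["csa"] for r in records]
    return EvalReport(
        csa_mean=float(np.mean(csas)),
        csa_min=float(np.min(csas)),
        csa_max=float(np.max(csas)),
        me_r=float(np.mean([r["me_r"] for r in records])),
        me_t=float(np.mean([r["me_t"] for r in records])),
        per_case=records,
    )


def evaluate(model, test_cases: list[DentalCase], csa_fn=case_similarity_score) -> EvalReport:
    """Run the model over a test set and aggregate per-case scores.

    CSA is aggregated over cases to mean/min/max; ME_r / ME_t are
    averaged over teeth within a case, then over cases. The report is
    invariant to the order of ``test_cases``.
    """
    from .fvamp import predict

    records = []
    for case in test_cases:
        pose = predict(model, case)
        records.append(_case_record(case, pose.quaternions, pose.translations, csa_fn))
    return _aggregate(records)


def identity_baseline(cases: list[DentalCase], csa_fn=case_similarity_score) -> EvalReport:
    """Evaluation of the do-nothing predictor (identity pose for every tooth).

    Its ME_t / ME_r equal the mean magnitudes of the stored correction
    transforms — the floor any trained model must beat.
    """
    identity_q = np.array([1.0, 0.0, 0.0, 0.0])
    records = []
    for case in cases:
        quats = np.tile(identity_q, (case.n_teeth, 1))
        trans = np.zeros((case.n_teeth, 3))
        records.append(_case_record(case, quats, trans, csa_fn))
    return _aggregate(records)
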