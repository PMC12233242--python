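"""Case readers/writers and configuration handling.

On-disk case layout (one directory per case)::

    case_0001/
      manifest.json        # case id, units, per-tooth entries
      tooth_00.ply         # ascii point cloud (or any trimesh-readable mesh)
      ...
      transforms.txt       # per-tooth 4x4 target transforms, column-major text

Units are millimetres throughout; the manifest must declare them and the
reader rejects anything else. Meshes with faces (OBJ/STL/PLY) are
surface-sampled uniformly by area to the configured point count with a
fixed seed; vertex-only PLY files are taken as point clouds verbatim.
All writers emit deterministic plain text (17 significant digits, no
timestamps), so identical inputs give byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core_geometry import RigidTransform, read_transform_text, write_transform_text
from .synthetic_arch import DentalCase, Tooth

__all__ = [
    "read_case",
    "write_case",
    "list_case_dirs",
    "load_config",
    "write_config_snapshot",
]

MESH_EXTENSIONS = {".ply", ".obj", ".stl"}


def _write_ply_points(path: Path, points: np.ndarray) -> None:
    pts = np.asarray(points, dtype=float)
    header = (
        "ply\nformat ascii 1.0\n"
        f"element vertex {len(pts)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in pts)
    path.write_text(header + body + "\n")


def write_case(case: DentalCase, out_dir: str | Path) -> None:
    """Serialize a case: one ascii PLY per tooth + JSON manifest + transforms."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tooth in enumerate(case.teeth):
        fname = f"tooth_{i:02d}.ply"
        _write_ply_points(out_dir / fname, tooth.points)
        entries.append({
            "file": fname,
            "tooth_type": tooth.tooth_type,
            "arch_index": tooth.arch_index,
            "landmarks": {k: list(v) for k, v in sorted(tooth.landmarks.items())},
            "frame": tooth.frame.tolist(),
        })
    write_transform_text(out_dir / "transforms.txt", case.target_transforms)
    manifest = {
        "case_id": case.case_id,
        "rng_seed": case.rng_seed,
        "units": "mm",
        "transforms": "transforms.txt",
        "teeth": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _load_points(path: Path, n_points: int | None, rng_seed: int) -> np.ndarray:
    import trimesh

    if path.suffix.lower() not in MESH_EXTENSIONS:
        raise ValueError(f"format error: unknown extension {path.suffix!r} for {path}")
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise ValueError(f"corrupt or unreadable mesh file {path}: {exc}") from exc
    if isinstance(obj, trimesh.Trimesh) and len(obj.faces) > 0:
        count = n_points or 400
        samples, _ = trimesh.sample.sample_surface(obj, count, seed=rng_seed)
        return np.asarray(samples, dtype=float)
    verts = np.asarray(getattr(obj, "vertices", np.empty((0, 3))), dtype=float)
    if verts.size == 0:
        raise ValueError(f"corrupt mesh file {path}: no vertices")
    return verts


def read_case(case_dir: str | Path, n_points: int | None = None, rng_seed: int = 0) -> DentalCase:
    """Load a case directory; round-trips :func:`write_case` losslessly.

    ``n_points`` controls area-uniform surface sampling when a tooth file
    is a triangle mesh (point clouds are used verbatim). Missing target
    transforms default to the identity for every tooth.
    """
    case_dir = Path(case_dir)
    manifest_path = case_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"schema error: no manifest.json in {case_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("units", "mm") != "mm":
        raise ValueError(
            f"schema error: units {manifest.get('units')!r} in {manifest_path}; expected mm"
        )
    teeth = []
    for entry in manifest["teeth"]:
        pts = _load_points(case_dir / entry["file"], n_points, rng_seed)
        teeth.append(Tooth(
            points=pts,
            tooth_type=entry["tooth_type"],
            arch_index=entry["arch_index"],
            landmarks={k: np.asarray(v, float) for k, v in entry.get("landmarks", {}).items()},
            frame=np.asarray(entry.get("frame", np.eye(3)), dtype=float),
        ))
    tpath = manifest.get("transforms")
    if tpath and (case_dir / tpath).exists():
        tdict = read_transform_text(case_dir / tpath)
        transforms = [tdict[i] for i in range(len(teeth))]
    else:
        transforms = [RigidTransform.identity() for _ in teeth]
    return DentalCase(
        teeth=teeth,
        target_transforms=transforms,
        case_id=manifest.get("case_id", case_dir.name),
        rng_seed=manifest.get("rng_seed", 0),
    )


def list_case_dirs(root: str | Path) -> list[Path]:
    """Sorted list of case directories (those containing a manifest) under root."""
    root = Path(root)
    return sorted(p for p in root.iterdir() if (p / "manifest.json").exists())


def load_config(path: str | Path | None, defaults: dict) -> dict:
    """Merge a YAML config file (possibly nested) over a defaults dict."""
    merged = json.loads(json.dumps(defaults))  # deep copy via JSON
    if path is None:
        return merged
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}

    def merge(dst: dict, src: dict) -> dict:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v
        return dst

    return merge(merged, user)


def write_config_snapshot(config: dict, out_dir: str | Path, stage: str) -> None:
    """Record the fully resolved configuration next to a stage's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{stage}_config.json", "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
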