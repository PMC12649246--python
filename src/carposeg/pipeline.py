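"""End-to-end analysis: phantom generation, two-workflow segmentation,
mesh comparison and paired statistics, with a hashed artifact manifest.

The full run mirrors the study design on synthetic data:

1. *pairs* — replicate two-condition scans of one phantom, tight
   segmentation of every scan, paired volume statistics;
2. *shape* — tight vs smooth segmentation of one thin-shelled phantom,
   rigid registration, signed surface-deviation map and summary table;
3. *jst* — a two-body phantom, tight segmentation of both bodies,
   joint-space thickness over the facing region.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .meshmetrics import distance_report, joint_space_thickness, mesh_volume, register_meshes, signed_distance_map
from .phantom import (
    ConditionPairs,
    PhantomSpec,
    SecondBody,
    cortical_seed,
    generate_condition_pair,
    generate_phantom,
    second_body_seed,
)
from .segmentation import SMOOTH_PARAMS, TIGHT_PARAMS, SegmentationParams, smooth_segment, tight_segment
from .stats import ComparisonReport, VolumePairTable, run_comparison


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _build_spec(overrides: dict, base: PhantomSpec) -> PhantomSpec:
    if not overrides:
        return base
    valid = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(overrides) - valid
    if unknown:
        raise PipelineError("config", f"unknown phantom keys: {sorted(unknown)}")
    kw = dict(overrides)
    for key in ("semi_axes", "lobe2_semi_axes", "lobe2_offset", "rotation_deg",
                "translation_mm", "spacing", "grid_shape"):
        if kw.get(key) is not None:
            kw[key] = tuple(kw[key])
    if isinstance(kw.get("second_body"), dict):
        sb = dict(kw["second_body"])
        if "semi_axes" in sb:
            sb["semi_axes"] = tuple(sb["semi_axes"])
        kw["second_body"] = SecondBody(**sb)
    return dataclasses.replace(base, **kw)


_PAIR_BASE = PhantomSpec(semi_axes=(4.0, 4.0, 4.0), shell_thickness_mm=1.0)
_SHAPE_BASE = PhantomSpec(
    shape="two_lobe",
    semi_axes=(6.0, 4.5, 4.0),
    lobe2_semi_axes=(5.0, 4.0, 3.5),
    lobe2_offset=(4.0, 1.0, 0.5),
    shell_thickness_mm=0.8,
)
_JST_BASE = PhantomSpec(
    semi_axes=(5.0, 5.0, 5.0),
    shell_thickness_mm=1.0,
    second_body=SecondBody(semi_axes=(5.0, 5.0, 5.0), gap_mm=1.3),
)


@dataclass
class RunConfig:
    """Configuration of :func:`run_full_analysis`.

    ``table`` switches to statistics-only mode on an existing volume-pair
    CSV.  The three phantom blocks override :class:`PhantomSpec` fields of
    the corresponding stage; unknown keys are rejected.
    """

    seed: int = 1
    output_dir: str = "carposeg_out"
    replicates: int = 10
    volume_perturbation: float = 0.0
    pair_phantom: dict = field(default_factory=dict)
    shape_phantom: dict = field(default_factory=dict)
    jst_phantom: dict = field(default_factory=dict)
    table: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_volume_table(path) -> VolumePairTable:
    """Read a volume-pair CSV (columns scan_id + frozen/thawed or a/b)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for a_name, b_name, la, lb in (
        ("frozen_mm3", "thawed_mm3", "frozen", "thawed"),
        ("volume_a_mm3", "volume_b_mm3", "A", "B"),
    ):
        if a_name in cols and b_name in cols:
            return VolumePairTable.from_volumes(
                df[cols.get("scan_id", df.columns[0])],
                df[cols[a_name]],
                df[cols[b_name]],
                label_a=la,
                label_b=lb,
            )
    raise PipelineError("config", f"no volume-pair columns found in {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: dict, path: Path) -> Path:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def segment_condition_pairs(cond: ConditionPairs) -> VolumePairTable:
    """Tight-segment every replicate pair and tabulate mesh volumes."""
    va, vb = [], []
    for vol_a, vol_b in cond.pairs:
        mesh_a = tight_segment(vol_a, cortical_seed(cond.spec_a, vol_a))
        mesh_b = tight_segment(vol_b, cortical_seed(cond.spec_b, vol_b))
        va.append(mesh_volume(mesh_a))
        vb.append(mesh_volume(mesh_b))
    ids = list(range(1, len(va) + 1))
    return VolumePairTable.from_volumes(ids, va, vb, label_a="A", label_b="B")


def simulate_rejection_rate(
    spec: PhantomSpec,
    volume_perturbation: float,
    n_pairs: int = 10,
    n_repetitions: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of seeded repetitions in which the paired t-test rejects.

    Each repetition draws ``n_pairs`` fresh two-condition scan pairs of the
    phantom, tight-segments all of them and tests the volume pairing at
    level ``alpha``.  With ``volume_perturbation = 0`` this estimates the
    test's size (false-rejection rate); with a nonzero perturbation, its
    power.
    """
    rejections = 0
    for rep in range(n_repetitions):
        cond = generate_condition_pair(spec, volume_perturbation, n_pairs, seed=seed + rep)
        report = run_comparison(table=segment_condition_pairs(cond))
        rejections += report.test.p_value < alpha
    return rejections / n_repetitions


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written
    to ``manifest.json``).  A stage failure aborts with a stage-tagged
    error; artifacts of completed stages are retained."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def finish(stage: str, payload: dict):
        manifest["stages"][stage] = payload

    try:
        if config.table is not None:
            report = run_comparison(table=load_volume_table(config.table))
            files.append(_write_json(report.to_dict(), out / "stats.json"))
            table_path = out / "volumes.csv"
            report.table.to_csv(table_path, index=False, float_format="%.6f")
            files.append(table_path)
            finish("stats", {"n_pairs": int(report.test.n)})
        else:
            _run_pair_stage(config, out, files, finish)
            _run_shape_stage(config, out, files, finish)
            _run_jst_stage(config, out, files, finish)
    finally:
        manifest["files"] = {p.name: _sha256(p) for p in files}
        _write_json(manifest, out / "manifest.json")
    return manifest


def _run_pair_stage(config, out, files, finish):
    try:
        spec = _build_spec(config.pair_phantom, _PAIR_BASE)
        cond = generate_condition_pair(
            spec, config.volume_perturbation, config.replicates, config.seed
        )
        table = segment_condition_pairs(cond)
        report = run_comparison(table=table)
        path = out / "volumes.csv"
        report.table.to_csv(path, index=False, float_format="%.6f")
        files.append(path)
        files.append(_write_json(report.to_dict(), out / "stats.json"))
        finish(
            "pairs",
            {
                "n_pairs": int(report.test.n),
                "truth_volume_a_mm3": cond.truth_a.outer_volume_mm3,
                "truth_volume_b_mm3": cond.truth_b.outer_volume_mm3,
            },
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("pairs", str(exc)) from exc


def _run_shape_stage(config, out, files, finish):
    try:
        spec = _build_spec(config.shape_phantom, _SHAPE_BASE)
        spec = dataclasses.replace(spec, seed=config.seed)
        volume, _ = generate_phantom(spec, compute_truth=False)
        seed_vox = cortical_seed(spec, volume)
        tight = tight_segment(volume, seed_vox)
        smooth = smooth_segment(volume, seed_vox)
        transform = register_meshes(smooth, tight)
        aligned = smooth.copy()
        aligned.vertices = transform.apply(aligned.vertices)
        dmap = signed_distance_map(tight, aligned)
        report = distance_report(dmap)
        per_point = report.pop("per_point_mm")
        files.append(_write_json(report, out / "distance_stats.json"))
        df = pd.DataFrame(
            {
                "x_mm": dmap.points[:, 0],
                "y_mm": dmap.points[:, 1],
                "z_mm": dmap.points[:, 2],
                "signed_distance_mm": per_point,
            }
        )
        path = out / "distance_map.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        files.append(path)
        files.append(cio.write_mesh(tight, out / "tight.stl"))
        files.append(
            cio.write_mesh(
                tight, out / "tight_distance.ply", vertex_scalars={"signed_distance": dmap.signed_mm}
            )
        )
        files.append(cio.write_mesh(smooth, out / "smooth.stl"))
        finish(
            "shape",
            {
                "tight_volume_mm3": mesh_volume(tight),
                "smooth_volume_mm3": mesh_volume(smooth),
                "registration_rms_mm": transform.rms_history[-1] if transform.rms_history else None,
                "included_count": report["included_count"],
            },
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("shape", str(exc)) from exc


def _run_jst_stage(config, out, files, finish):
    try:
        spec = _build_spec(config.jst_phantom, _JST_BASE)
        spec = dataclasses.replace(spec, seed=config.seed + 1)
        volume, truth = generate_phantom(spec)
        bone_a = tight_segment(volume, cortical_seed(spec, volume))
        bone_b = tight_segment(volume, second_body_seed(spec, volume))
        result = joint_space_thickness(bone_a, bone_b)
        payload = {
            "has_facing_surface": bool(result.has_facing_surface),
            "minimum_mm": result.minimum_mm,
            "n_articular_vertices": int(len(result.vertex_indices)),
            "true_gap_mm": truth.gap_mm,
        }
        files.append(_write_json(payload, out / "jst.json"))
        finish("jst", payload)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("jst", str(exc)) from exc
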