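"""End-to-end orchestration: detect -> label -> extract -> grade.

A study is a set of sagittal scans of one subject, keyed by MR sequence.
Detection runs on the sequence with the most slices; levels are assigned
once and shared across sequences; disc volumes are extracted per sequence
and graded jointly by CAST.  Reports are deterministic JSON (floats rounded,
keys sorted) so a fixed seed reproduces a byte-identical file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, cast, levels, vfr, vfr_net, volumes
from .scan_io import SagittalScan, normalise_intensity

SCHEMA_VERSION = 1

REPORT_SCHEMA = {
    "type": "object",
    "required": ["schema_version", "tool_version", "config_hash", "seed",
                 "studies"],
    "properties": {
        "schema_version": {"type": "number"},
        "tool_version": {"type": "string"},
        "config_hash": {"type": "string"},
        "seed": {"type": "number"},
        "studies": {"type": "array", "items": {
            "type": "object",
            "required": ["study_id", "instances", "discs", "timings_s",
                         "warnings"],
            "properties": {
                "study_id": {"type": "string"},
                "instances": {"type": "array", "items": {
                    "type": "object",
                    "required": ["level", "centroid_mm", "confidence"],
                    "properties": {
                        "level": {"type": "string"},
                        "centroid_mm": {"type": "array",
                                        "items": {"type": "number"}},
                        "confidence": {"type": "number"},
                        "skip_before": {"type": "boolean"},
                        "transitional": {"type": "boolean"},
                    },
                }},
                "discs": {"type": "array", "items": {
                    "type": "object",
                    "required": ["level", "tasks"],
                    "properties": {"level": {"type": "string"},
                                   "tasks": {"type": "object"}},
                }},
                "timings_s": {"type": "object"},
                "warnings": {"type": "array", "items": {"type": "string"}},
            },
        }},
    },
}


def validate_report(report: dict, schema: dict | None = None,
                    path: str = "report") -> None:
    """Validate a report against the (subset) JSON schema used by this tool.

    Raises ValueError naming the offending path on the first violation.
    """
    schema = schema or REPORT_SCHEMA
    stype = schema.get("type")
    if stype == "object":
        if not isinstance(report, dict):
            raise ValueError(f"{path}: expected object")
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
    elif stype == "array":
        if not isinstance(report, list):
            raise ValueError(f"{path}: expected array")
        for i, item in enumerate(report):
            validate_report(item, schema.get("items", {}), f"{path}[{i}]")
    elif stype == "string":
        if not isinstance(report, str):
            raise ValueError(f"{path}: expected string")
    elif stype == "number":
        if isinstance(report, bool) or not isinstance(report, (int, float)):
            raise ValueError(f"{path}: expected number")
    elif stype == "boolean":
        if not isinstance(report, bool):
            raise ValueError(f"{path}: expected boolean")


@dataclass
class ModelBundle:
    """The three trained stages plus their task list."""

    detector: vfr_net.VFRNet
    appearance: levels.AppearanceNet
    context: levels.ContextNet | None
    grader: cast.CastModel

    def save(self, directory: Path | str) -> None:
        from . import nn
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nn.save_params(directory / "detector.npz", self.detector,
                       {"stage": "detector", "patch_px": self.detector.cfg.patch_px,
                        "c_peak": self.detector.cfg.c_peak})
        nn.save_params(directory / "appearance.npz", self.appearance,
                       {"stage": "appearance", "in_px": self.appearance.in_px})
        if self.context is not None:
            nn.save_params(directory / "context.npz", self.context,
                           {"stage": "context"})
        nn.save_params(directory / "grader.npz", self.grader,
                       {"stage": "grader",
                        "tasks": [[t.name, t.n_classes, t.unit]
                                  for t in self.grader.tasks]})

    @staticmethod
    def load(directory: Path | str, seed: int = 0) -> "ModelBundle":
        from . import nn
        directory = Path(directory)
        for stage in ("detector", "appearance", "grader"):
            if not (directory / f"{stage}.npz").exists():
                raise FileNotFoundError(
                    f"missing checkpoint for the {stage} stage: "
                    f"{directory / (stage + '.npz')}")
        rng = np.random.default_rng(seed)
        bundle = default_bundle(rng)
        nn.load_params(directory / "detector.npz", bundle.detector)
        nn.load_params(directory / "appearance.npz", bundle.appearance)
        if (directory / "context.npz").exists():
            nn.load_params(directory / "context.npz", bundle.context)
        else:
            bundle.context = None
        nn.load_params(directory / "grader.npz", bundle.grader)
        return bundle


DEMO_TASKS = [cast.GradingTaskSpec("degeneration", 2),
              cast.GradingTaskSpec("neighbour", 2)]


def default_bundle(rng: np.random.Generator) -> ModelBundle:
    """Seed-initialised tiny-profile bundle (untrained)."""
    return ModelBundle(
        detector=vfr_net.VFRNet(rng),
        appearance=levels.AppearanceNet(rng),
        context=levels.ContextNet(rng),
        grader=cast.CastModel(DEMO_TASKS, rng, cast.CastConfig.tiny()),
    )


@dataclass
class PipelineConfig:
    patch_edge_cm: float = 50.0
    patch_overlap: float = 0.4
    stack_iou: float = 0.5
    appearance_volume: tuple[int, int, int] = (64, 64, 4)
    disc_out_shape: tuple[int, int] = (28, 56)
    beam_width: int = 50
    lambda_skip: float = float(np.log(0.2))
    lambda_var: float = float(np.log(0.1))
    normalise: bool = True
    float_decimals: int = 6

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def detect_scan(scan: SagittalScan, detector: vfr_net.VFRNet,
                config: PipelineConfig) -> list[vfr.VertebraInstance]:
    """Patch-split every slice, detect and merge landmarks, group into quads
    and stack across slices."""
    quads_by_slice: dict[int, list[vfr.QuadDetection]] = {}
    for s in range(scan.n_slices):
        patches = vfr.split_into_patches(scan, s, edge_cm=config.patch_edge_cm,
                                         overlap=config.patch_overlap,
                                         out_px=detector.cfg.patch_px)
        per_patch, affines = [], []
        for pixels, affine in patches:
            image = np.clip(pixels, 0.0, 1.0)
            per_patch.append(vfr_net.detect_slice_landmarks(detector, image))
            affines.append(affine)
        merged = vfr.merge_patch_landmarks(per_patch, affines,
                                           scan.pixel_spacing_mm)
        quads_by_slice[s] = vfr.group_landmarks(merged, slice_index=s)
    return vfr.stack_slices(quads_by_slice, iou_threshold=config.stack_iou)


def _round_floats(obj, decimals: int):
    if isinstance(obj, float):
        return round(obj, decimals)
    if isinstance(obj, dict):
        return {k: _round_floats(v, decimals) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, decimals) for v in obj]
    return obj


def run_pipeline(studies: list[dict[str, SagittalScan]],
                 bundle: ModelBundle, seed: int = 0,
                 config: PipelineConfig | None = None,
                 study_ids: list[str] | None = None) -> dict:
    """Run detect -> label -> extract -> grade over studies.

    Each study is a mapping {sequence name: SagittalScan}.  A failure in one
    study is recorded in its warnings and does not abort the batch.
    """
    config = config or PipelineConfig()
    report = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "config_hash": config.hash(),
        "seed": int(seed),
        "studies": [],
    }
    for i, study in enumerate(studies):
        sid = study_ids[i] if study_ids else f"study-{i}"
        entry = {"study_id": sid, "instances": [], "discs": [],
                 "timings_s": {}, "warnings": []}
        try:
            _run_study(study, bundle, config, entry)
        except Exception as exc:   # noqa: BLE001 - batch robustness contract
            entry["warnings"].append(f"study failed: {exc}")
        report["studies"].append(entry)
    report = _round_floats(report, config.float_decimals)
    validate_report(report)
    return report


def _run_study(study: dict[str, SagittalScan], bundle: ModelBundle,
               config: PipelineConfig, entry: dict) -> None:
    t0 = time.perf_counter()
    scans = {seq: (normalise_intensity(s) if config.normalise else s)
             for seq, s in study.items()}
    ref_seq = max(scans, key=lambda k: scans[k].n_slices)
    ref_scan = scans[ref_seq]
    instances = detect_scan(ref_scan, bundle.detector, config)
    entry["timings_s"]["detect"] = time.perf_counter() - t0
    if not instances:
        entry["warnings"].append("no vertebrae detected")
        return

    t1 = time.perf_counter()
    seq = levels.label_instances(ref_scan, instances, bundle.appearance,
                                 bundle.context,
                                 volume_shape=config.appearance_volume,
                                 beam_width=config.beam_width,
                                 lambda_skip=config.lambda_skip,
                                 lambda_var=config.lambda_var)
    entry["timings_s"]["label"] = time.perf_counter() - t1
    for inst, label, skip in zip(instances, seq.labels, seq.skip_flags):
        entry["instances"].append({
            "level": label,
            "centroid_mm": [float(v) for v in inst.centroid_mm(ref_scan)],
            "confidence": inst.confidence(),
            "skip_before": bool(skip),
            "transitional": bool(seq.transitional and label == levels.VIRTUAL_LEVEL),
        })

    t2 = time.perf_counter()
    volumes_in = []
    for j in range(len(instances) - 1):
        upper, lower = instances[j], instances[j + 1]
        if upper.level not in levels.LEVEL_INDEX or \
                lower.level not in levels.LEVEL_INDEX:
            continue
        if levels.LEVEL_INDEX[lower.level] - levels.LEVEL_INDEX[upper.level] != 1:
            continue
        for seq_name, scan in scans.items():
            disc = volumes.extract_disc_volume(scan, upper, lower,
                                               out_shape=config.disc_out_shape)
            volumes_in.append((levels.LEVEL_INDEX[upper.level], seq_name,
                               disc.voxels))
    entry["timings_s"]["extract"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    probs, attention = bundle.grader.forward_study(volumes_in, rng=None)
    idx_to_name = {levels.LEVEL_INDEX[lv]: f"{lv}/{levels.LADDER[i + 1]}"
                   for i, lv in enumerate(levels.LADDER[:-1])}
    by_level: dict[int, dict] = {}
    for task, per_unit in probs.items():
        for idx, p in per_unit.items():
            by_level.setdefault(idx, {})[task] = [float(v) for v in p.data]
    for idx in sorted(by_level):
        entry["discs"].append({"level": idx_to_name.get(idx, str(idx)),
                               "tasks": by_level[idx]})
    entry["timings_s"]["grade"] = time.perf_counter() - t3


def strip_timings(report: dict) -> dict:
    """Timing-free copy of a report."""
    out = json.loads(json.dumps(report))
    for study in out["studies"]:
        study["timings_s"] = {}
    return out


def report_to_json(report: dict, include_timings: bool = False) -> str:
    """Serialise a report deterministically (sorted keys, rounded floats).

    Wall-clock timings are volatile, so the canonical serialisation excludes
    them by default: two runs with the same inputs, models and seed then
    produce byte-identical files.  Timings remain available on the in-memory
    report and in the logs.
    """
    if not include_timings:
        report = strip_timings(report)
    return json.dumps(report, sort_keys=True, indent=2)
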