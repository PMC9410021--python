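"""Configuration and end-to-end orchestration.

Ties together phantom generation, detection training, weak masks,
2-way identification training and evaluation.  The end-to-end demo is a
deliberately scaled-down experiment on phantom data: it compares the three
training setups (supervised source-only baseline, + unsupervised sanity
loss on the target stream, + a few labeled target scans) and reports their
target-domain metrics.  At this scale only the *ordering* of the setups is
meaningful, not the magnitudes reachable with real CT and long training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .detection import (
    DetectionPatchSpec,
    DetectionTrainConfig,
    extract_detection_patches,
    postprocess_largest_component,
    predict_detection,
    train_detector,
)
from .dsl_loss import DSLConfig
from .evaluation import (
    distance_stats,
    id_rate,
    pixel_classification_rate,
    segmentation_metrics,
)
from .identification import (
    IdentificationPatchSpec,
    TwoWayTrainConfig,
    extract_identification_patches,
    predict_identification,
    train_two_way,
)
from .labels import dense_to_sparse
from .phantom import PhantomConfig, generate_phantom

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemoConfig:
    n_source_scans: int = 4
    n_target_scans: int = 4
    n_test_scans: int = 3

    def __post_init__(self):
        if min(self.n_source_scans, self.n_target_scans, self.n_test_scans) < 1:
            raise ValueError("demo scan counts must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = PhantomConfig()
    detection_patches: DetectionPatchSpec = DetectionPatchSpec()
    detection_train: DetectionTrainConfig = DetectionTrainConfig()
    identification_patches: IdentificationPatchSpec = IdentificationPatchSpec()
    identification_train: TwoWayTrainConfig = TwoWayTrainConfig()
    dsl: DSLConfig = DSLConfig(mode="surrogate")
    demo: DemoConfig = DemoConfig()
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"


_SECTIONS = {
    "phantom": PhantomConfig,
    "detection_patches": DetectionPatchSpec,
    "detection_train": DetectionTrainConfig,
    "identification_patches": IdentificationPatchSpec,
    "identification_train": TwoWayTrainConfig,
    "dsl": DSLConfig,
    "demo": DemoConfig,
}
_SCALARS = {"seed", "out_dir", "log_level"}


def _build_section(cls, raw: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - set(fields))
    if unknown:
        raise ValueError(f"unknown key(s) {unknown} in config section '{section}'")
    kwargs = {}
    for key, val in raw.items():
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML; omitted keys take the method's
    published defaults (c1=20, lr=5e-4, n_shift=30, ...)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    unknown = sorted(set(raw) - set(_SECTIONS) - _SCALARS)
    if unknown:
        raise ValueError(f"{path}: unknown top-level config key(s) {unknown}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        block = raw.get(section)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ValueError(f"{path}: section '{section}' must be a mapping")
        kwargs[section] = _build_section(cls, block, section)
    if "dsl" not in kwargs:
        kwargs["dsl"] = DSLConfig(mode="surrogate")
    for key in _SCALARS:
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def demo_config(seed: int = 0) -> PipelineConfig:
    """The scaled-down phantom experiment: small grids, a tiny network and a
    35-epoch cap so the three-arm comparison runs on one CPU in minutes."""
    return PipelineConfig(
        phantom=PhantomConfig(
            n_vertebrae=6,
            first_vertebra_id=10,  # T3..T8
            grid_shape=(33, 64, 224),
            seed=seed,
        ),
        detection_patches=DetectionPatchSpec(patch_shape=(16, 16, 24)),
        detection_train=DetectionTrainConfig(
            learning_rate=2e-2, batch_size=16, epochs=40, seed=seed
        ),
        identification_patches=IdentificationPatchSpec(
            patch_shape=(8, 32, 160), patches_per_scan_train=40
        ),
        identification_train=TwoWayTrainConfig(
            learning_rate=5e-3,
            target_learning_rate=2e-3,
            batch_size=16,
            epochs=35,
            n_labeled_target_scans=2,
            seed=seed,
        ),
        dsl=DSLConfig(mode="surrogate"),
        demo=DemoConfig(),
        seed=seed,
    )


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31))


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _mean(values):
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def run_e2e_demo(cfg: PipelineConfig | None = None, seed: int | None = None,
                 out_dir=None) -> dict:
    """Run the full phantom experiment once and return the report dict.

    Trains detection on source phantoms, then the identification model in
    three arms — without UDA, with the sanity loss on the unlabeled target
    stream, and with ``n_labeled_target_scans`` labeled target scans joining
    the source stream — and evaluates all arms on held-out target phantoms.
    """
    if cfg is None:
        cfg = demo_config(seed if seed is not None else 0)
    if seed is None:
        seed = cfg.seed

    source = [
        generate_phantom(replace(cfg.phantom, domain="source",
                                 seed=_derived_seed(seed, i)))
        for i in range(cfg.demo.n_source_scans)
    ]
    target = [
        generate_phantom(replace(cfg.phantom, domain="target",
                                 seed=_derived_seed(seed, 100 + i)))
        for i in range(cfg.demo.n_target_scans)
    ]
    test = [
        generate_phantom(replace(cfg.phantom, domain="target",
                                 seed=_derived_seed(seed, 200 + i)))
        for i in range(cfg.demo.n_test_scans)
    ]

    # --- stage 1: detection, trained on the labeled source domain only
    det_samples = []
    for i, s in enumerate(source):
        det_samples += extract_detection_patches(
            s.volume, s.dense, cfg.detection_patches, "train",
            seed=_derived_seed(seed, 300 + i),
        )
    det_cfg = replace(cfg.detection_train, seed=_derived_seed(seed, 7))
    detector = train_detector(det_samples, det_cfg)

    det_raw = [predict_detection(detector, s.volume, cfg.detection_patches,
                                 postprocess=False) for s in test]
    det_post = [postprocess_largest_component(m) for m in det_raw]
    seg_pre = [segmentation_metrics(m, s.spine_mask) for m, s in zip(det_raw, test)]
    seg_post = [segmentation_metrics(m, s.spine_mask) for m, s in zip(det_post, test)]
    detection_report = {
        "iou_vertebrae_without_postprocessing": _mean(
            [m["vertebrae"].iou for m in seg_pre]
        ),
        "iou_vertebrae_with_postprocessing": _mean(
            [m["vertebrae"].iou for m in seg_post]
        ),
        "dice_vertebrae_with_postprocessing": _mean(
            [m["vertebrae"].dice for m in seg_post]
        ),
        "accuracy_overall_with_postprocessing": _mean(
            [m["overall"].accuracy for m in seg_post]
        ),
    }

    # --- stage 2 streams
    source_stream = []
    for i, s in enumerate(source):
        source_stream += extract_identification_patches(
            s.volume, s.dense, None, cfg.identification_patches, "train",
            seed=_derived_seed(seed, 400 + i),
        )
    target_stream = []
    for i, s in enumerate(target):
        det_mask = predict_detection(detector, s.volume, cfg.detection_patches)
        target_stream += extract_identification_patches(
            s.volume, None, det_mask, cfg.identification_patches, "train",
            seed=_derived_seed(seed, 500 + i),
        )

    id_cfg = replace(cfg.identification_train, seed=_derived_seed(seed, 9))
    rd, _ = cfg.phantom.tables()

    arms = {
        "without_uda": (source_stream, []),
        "with_uda": (source_stream, target_stream),
    }
    k = cfg.identification_train.n_labeled_target_scans
    if k > 0:
        rng = np.random.default_rng(_derived_seed(seed, 11))
        chosen = rng.choice(len(target), size=min(k, len(target)), replace=False)
        labeled_extra = []
        for i in sorted(int(c) for c in chosen):
            labeled_extra += extract_identification_patches(
                target[i].volume, target[i].dense, None,
                cfg.identification_patches, "train",
                seed=_derived_seed(seed, 600 + i),
            )
        arms[f"with_{k}_target_labels"] = (
            source_stream + labeled_extra, target_stream
        )

    report: dict = {"seed": seed, "detection": detection_report, "arms": {}}
    test_dets = [predict_detection(detector, s.volume, cfg.detection_patches)
                 for s in test]
    for name, (src, tgt) in arms.items():
        model = train_two_way(src, tgt, id_cfg, cfg.dsl, rd)
        pix, ids, means, stds = [], [], [], []
        for s, det_mask in zip(test, test_dets):
            _, pred_dense = predict_identification(
                model, s.volume, det_mask, cfg.identification_patches
            )
            pix.append(pixel_classification_rate(pred_dense, s.dense))
            pred_cents = dense_to_sparse(pred_dense)
            rate, _ = id_rate(pred_cents, s.centroids)
            ids.append(rate)
            try:
                m, sd = distance_stats(pred_cents, s.centroids)
                means.append(m)
                stds.append(sd)
            except ValueError:
                pass
        report["arms"][name] = {
            "pixel_rate": _mean(pix),
            "id_rate": _mean(ids),
            "mean_dist_mm": _mean(means),
            "std_dist_mm": _mean(stds),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "demo_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest = {
            "config_hash": _config_hash(cfg),
            "seed": seed,
            "package_version": _package_version(),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("spine-uda")
    except Exception:
        return "unknown"


def run_demo_suite(seeds, cfg_factory=demo_config, out_dir=None) -> dict:
    """Run the demo across several seeds and aggregate the arm metrics."""
    runs = [run_e2e_demo(cfg_factory(s), seed=s) for s in seeds]
    arm_names = runs[0]["arms"].keys()
    summary = {
        "seeds": list(seeds),
        "runs": runs,
        "detection": {
            key: _mean([r["detection"][key] for r in runs])
            for key in runs[0]["detection"]
        },
        "arms": {
            name: {
                metric: _mean([r["arms"][name][metric] for r in runs])
                for metric in ("pixel_rate", "id_rate", "mean_dist_mm", "std_dist_mm")
            }
            for name in arm_names
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "demo_suite.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
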