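"""Stage 2 — vertebra identification with 2-way domain-adaptive training.

A per-pixel regressor predicts a continuous vertebra value (1 = C1 ... 26 =
S2) on the sagittal plane.  Training alternates strictly between labeled
source mini-batches (supervised L1) and unlabeled target mini-batches
(surrogate Domain Sanity Loss on the detection-masked prediction, with a
weak vertebra mask built per patch).  With an empty target stream the
procedure degenerates bit-exactly to the supervised baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import BinaryMask, Volume
from .detection import _pad_to, _tile_origins
from .dsl_loss import (
    DSLConfig,
    MaskedPrediction,
    mask_background,
    round_half_up,
    surrogate_s1_grad,
    surrogate_s2_grad,
    term_s3,
    term_s4,
)
from .labels import DenseLabels, ReferenceDistances
from .models import Adam, IdentificationNet
from .weakmask import WeakMask, build_weak_mask, clean_weak_mask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentificationPatchSpec:
    patch_shape: tuple[int, int, int] = (8, 80, 320)
    patches_per_scan_train: int = 300

    def __post_init__(self):
        if any(p < 1 for p in self.patch_shape):
            raise ValueError("patch_shape entries must be >= 1")
        if self.patches_per_scan_train < 1:
            raise ValueError("patches_per_scan_train must be >= 1")


@dataclass(frozen=True)
class TwoWayTrainConfig:
    learning_rate: float = 5e-4
    target_learning_rate: float | None = None  # None -> same as learning_rate
    batch_size: int = 32
    epochs: int = 100
    n_labeled_target_scans: int = 0
    alternation: str = "strict_alternate"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.target_learning_rate is not None and self.target_learning_rate <= 0:
            raise ValueError("target_learning_rate must be positive")
        if self.n_labeled_target_scans < 0:
            raise ValueError("n_labeled_target_scans must be >= 0")
        if self.alternation != "strict_alternate":
            raise ValueError("only strict_alternate alternation is supported")


@dataclass
class PatchRecord:
    """One training/test patch: HU data plus whatever annotation it has."""

    patch: np.ndarray
    labels: np.ndarray | None  # 3D integer dense labels
    det: np.ndarray | None  # 3D {0,1} detection mask
    origin: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def extract_identification_patches(
    vol: Volume,
    dense: DenseLabels | None = None,
    det_mask: BinaryMask | None = None,
    spec: IdentificationPatchSpec = IdentificationPatchSpec(),
    mode: str = "train",
    seed: int = 0,
    pad_value: float = 0.0,
) -> list[PatchRecord]:
    """Cut identification patches from a scan.

    Labeled training scans guarantee every patch contains at least one
    vertebra voxel; unlabeled scans sample patches from the detected spine
    region instead (and carry the detection mask for loss masking).  Test
    mode tiles the whole scan.
    """
    patch = spec.patch_shape
    data = _pad_to(vol.data, patch, pad_value)
    lab = det = None
    if dense is not None:
        lab = _pad_to(dense.data, patch, 0)
    if det_mask is not None:
        det = _pad_to(det_mask.data, patch, 0)

    def cut(arr, origin):
        return arr[tuple(slice(o, o + p) for o, p in zip(origin, patch))]

    def record(origin):
        origin = tuple(int(o) for o in origin)
        return PatchRecord(
            patch=cut(data, origin),
            labels=None if lab is None else cut(lab, origin),
            det=None if det is None else cut(det, origin),
            origin=origin,
            spacing=vol.spacing,
        )

    if mode == "test":
        out = []
        for origin in _tile_origins(data.shape, patch):
            end = [min(o + p, data.shape[a]) for a, (o, p) in enumerate(zip(origin, patch))]
            sl = tuple(slice(o, e) for o, e in zip(origin, end))
            rec = PatchRecord(
                patch=_pad_to(data[sl], patch, pad_value),
                labels=None if lab is None else _pad_to(lab[sl], patch, 0),
                det=None if det is None else _pad_to(det[sl], patch, 0),
                origin=tuple(origin),
                spacing=vol.spacing,
            )
            out.append(rec)
        return out

    if mode != "train":
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    if lab is not None:
        anchor = np.argwhere(lab > 0)
    else:
        if det is None or not det.any():
            raise ValueError(
                "unlabeled scans need a nonempty detection mask to locate the "
                "spine: run the detection stage first"
            )
        anchor = np.argwhere(det > 0)
    rng = np.random.default_rng(seed)
    max_origin = np.array(data.shape) - np.array(patch)
    out = []
    for _ in range(spec.patches_per_scan_train):
        center = anchor[rng.integers(len(anchor))]
        jitter = rng.integers(-np.array(patch) // 4, np.array(patch) // 4 + 1)
        origin = np.clip(center - np.array(patch) // 2 + jitter, 0, max_origin)
        out.append(record(origin))
    return out


def l1_source_loss(pred: np.ndarray, dense_labels: np.ndarray) -> float:
    """Mean absolute difference between continuous predictions and integer
    labels over all pixels (background target 0) — the supervised loss whose
    magnitude respects vertebra order."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(dense_labels, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs labels {target.shape}")
    return float(np.mean(np.abs(pred - target)))


def _project_labels(labels3d: np.ndarray) -> np.ndarray:
    return np.asarray(labels3d).max(axis=0).astype(np.float64)


def _project_det(det3d: np.ndarray) -> np.ndarray:
    return (np.asarray(det3d).max(axis=0) > 0).astype(np.float64)


def _prep_source(model, rec: PatchRecord):
    X, shape = model.features(rec.patch, rec.origin, rec.spacing)
    return X, _project_labels(rec.labels).ravel(), shape


def _prep_target(model, rec: PatchRecord, dsl_cfg: DSLConfig):
    X, shape = model.features(rec.patch, rec.origin, rec.spacing)
    det2d = _project_det(rec.det)
    # mean projection for the weak mask: noise-robust while staying on the
    # HU scale the 180 threshold assumes
    img2d = np.asarray(rec.patch, dtype=np.float64).mean(axis=0)
    wm = clean_weak_mask(build_weak_mask(img2d, det2d))
    return X, det2d, wm, shape


def train_two_way(
    source_patches,
    target_patches,
    cfg: TwoWayTrainConfig = TwoWayTrainConfig(),
    dsl_cfg: DSLConfig = DSLConfig(mode="surrogate"),
    rd: ReferenceDistances | None = None,
    model: IdentificationNet | None = None,
) -> IdentificationNet:
    """Alternating source/target training of the identification model.

    Source steps minimize the supervised L1; target steps minimize the
    surrogate Domain Sanity Loss of the detection-masked prediction (s1/s2
    provide subgradients; s3/s4 are evaluated exactly for monitoring).  When
    one stream runs out within an epoch the other finishes it.  Labeled
    target scans, if any, are composed into the source stream by the caller.
    An empty target stream reproduces the supervised baseline bit-exactly.

    Each stream keeps its own Adam state (optionally its own learning rate):
    the two loss families have very different gradient statistics, and a
    shared second-moment estimate lets either stream stall the other.
    """
    from .labels import load_reference_distances

    source_patches = list(source_patches)
    target_patches = list(target_patches)
    if not source_patches and not target_patches:
        raise ValueError("both training streams are empty")
    if not source_patches:
        raise ValueError("the labeled source stream must not be empty")
    if rd is None:
        rd = load_reference_distances()
    if model is None:
        model = IdentificationNet(seed=cfg.seed, learning_rate=cfg.learning_rate)

    src = [_prep_source(model, r) for r in source_patches]
    tgt = [_prep_target(model, r, dsl_cfg) for r in target_patches]
    rng_src = np.random.default_rng(cfg.seed + 101)
    rng_tgt = np.random.default_rng(cfg.seed + 202)
    source_opt = model.optimizer
    target_opt = Adam(cfg.target_learning_rate or cfg.learning_rate)

    step = 0
    for epoch in range(cfg.epochs):
        src_order = list(rng_src.permutation(len(src)))
        tgt_order = list(rng_tgt.permutation(len(tgt))) if tgt else []
        src_batches = [
            src_order[i : i + cfg.batch_size]
            for i in range(0, len(src_order), cfg.batch_size)
        ]
        tgt_batches = [
            tgt_order[i : i + cfg.batch_size]
            for i in range(0, len(tgt_order), cfg.batch_size)
        ]
        n_steps = max(len(src_batches), len(tgt_batches)) * 2
        si = ti = 0
        for k in range(n_steps):
            take_source = (k % 2 == 0 and si < len(src_batches)) or ti >= len(tgt_batches)
            if take_source and si < len(src_batches):
                idx = src_batches[si]
                si += 1
                X = np.concatenate([src[i][0] for i in idx])
                t = np.concatenate([src[i][1] for i in idx])
                y, cache = model.forward_features(X)
                loss = float(np.mean(np.abs(y - t)))
                dy = np.sign(y - t) / len(t)
                source_opt.step(model.mlp.params, model.backward(cache, dy))
                model.history.append((epoch, "source", loss))
                step += 1
            elif ti < len(tgt_batches):
                idx = tgt_batches[ti]
                ti += 1
                grads_sum = None
                losses = []
                for i in idx:
                    X, det2d, wm, shape = tgt[i]
                    y, cache = model.forward_features(X)
                    yhat = mask_background(
                        y.reshape(shape),
                        det2d,
                        spacing=(target_patches[i].spacing[1],
                                 target_patches[i].spacing[2]),
                    )
                    if not yhat.spine().any():
                        continue
                    s1, g1 = surrogate_s1_grad(yhat, dsl_cfg)
                    s2, g2 = surrogate_s2_grad(yhat, dsl_cfg)
                    s3 = term_s3(yhat, rd)
                    s4 = term_s4(wm, yhat)
                    losses.append(
                        dsl_cfg.c1 * s1 + dsl_cfg.c2 * s2 + dsl_cfg.c3 * s3
                        + dsl_cfg.c4 * s4
                    )
                    dyhat = (dsl_cfg.c1 * g1 + dsl_cfg.c2 * g2) * det2d
                    g = model.backward(cache, dyhat.ravel() / len(idx))
                    if grads_sum is None:
                        grads_sum = g
                    else:
                        for key in grads_sum:
                            grads_sum[key] += g[key]
                if grads_sum is not None:
                    target_opt.step(model.mlp.params, grads_sum)
                    model.history.append((epoch, "target", float(np.mean(losses))))
                    step += 1
        if model.history:
            log.info("identification epoch %d/%d: last loss %.4f",
                     epoch + 1, cfg.epochs, model.history[-1][2])
    return model


def train_supervised(
    source_patches,
    cfg: TwoWayTrainConfig = TwoWayTrainConfig(),
    model: IdentificationNet | None = None,
) -> IdentificationNet:
    """The no-UDA baseline: 2-way training with an empty target stream."""
    return train_two_way(source_patches, [], cfg=cfg, model=model)


def predict_identification(
    model: IdentificationNet,
    vol: Volume,
    det_mask: BinaryMask,
    spec: IdentificationPatchSpec = IdentificationPatchSpec(),
    floor_spine_to_one: bool = True,
) -> tuple[MaskedPrediction, DenseLabels]:
    """Tile a scan, predict continuous vertebra values, mask the background
    with the detection output and round half-up to integer labels.

    Values above 26 are clipped to 26; on-mask values rounding to 0 are
    floored to 1 (a spine pixel cannot be background).  Returns the masked
    continuous sagittal-plane prediction and the 3D dense labels.
    """
    if det_mask is None:
        raise ValueError("prediction needs the detection mask; run detection first")
    if det_mask.shape != vol.shape:
        raise ValueError("volume and detection mask must share a shape")
    records = extract_identification_patches(vol, None, None, spec, mode="test")
    patch = spec.patch_shape
    canvas_shape = tuple(int(np.ceil(s / p)) * p for s, p in zip(vol.shape, patch))
    cont = np.zeros(canvas_shape)
    for rec in records:
        plane = model.predict_plane(rec.patch, rec.origin, rec.spacing)
        sl = tuple(slice(o, o + p) for o, p in zip(rec.origin, patch))
        cont[sl] = plane[None, :, :]
    cont = cont[tuple(slice(0, s) for s in vol.shape)]
    det = det_mask.data.astype(np.float64)
    masked = cont * det
    rounded = round_half_up(masked)
    rounded = np.clip(rounded, 0, 26)
    if floor_spine_to_one:
        rounded = np.where((det > 0) & (rounded < 1), 1, rounded)
    rounded = (rounded * det).astype(np.int16)
    mp = MaskedPrediction(masked.max(axis=0), (vol.spacing[1], vol.spacing[2]))
    return mp, DenseLabels(rounded, vol.spacing)
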