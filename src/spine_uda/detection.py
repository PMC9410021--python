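"""Stage 1 — spine detection.

Patches are cut from the 3D volume, a binary segmenter is trained with a
class-weighted BCE (spine weighted 1.0, background 0.1 so the spine is
confidently detected as one large component), and predictions are
post-processed by 3D connected-component analysis that keeps only the
largest component — discarding bed rails and other compact artefacts.
Detection trains on labeled source data only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, Volume
from .labels import DenseLabels
from .models import DetectionNet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionPatchSpec:
    patch_shape: tuple[int, int, int] = (80, 80, 96)
    patches_per_scan_train: int = 10
    min_spine_patches: int = 8

    def __post_init__(self):
        if any(p < 1 for p in self.patch_shape):
            raise ValueError("patch_shape entries must be >= 1")
        if not 0 <= self.min_spine_patches <= self.patches_per_scan_train:
            raise ValueError("min_spine_patches must be <= patches_per_scan_train")


@dataclass(frozen=True)
class DetectionTrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 70
    loss_weight_spine: float = 1.0
    loss_weight_background: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.loss_weight_spine <= 0 or self.loss_weight_background <= 0:
            raise ValueError("BCE class weights must be positive")


def _pad_to(arr: np.ndarray, target, value=0.0) -> np.ndarray:
    pad = [(0, max(t - s, 0)) for s, t in zip(arr.shape, target)]
    if not any(p[1] for p in pad):
        return arr
    return np.pad(arr, pad, constant_values=value)


def _tile_origins(shape, patch) -> list[tuple[int, int, int]]:
    counts = [int(np.ceil(s / p)) for s, p in zip(shape, patch)]
    return [
        (i * patch[0], j * patch[1], k * patch[2])
        for i, j, k in product(*(range(c) for c in counts))
    ]


def extract_detection_patches(
    vol: Volume,
    dense: DenseLabels | None,
    spec: DetectionPatchSpec = DetectionPatchSpec(),
    mode: str = "train",
    seed: int = 0,
    pad_value: float = 0.0,
):
    """Cut (patch, binary-labels, origin) triples from a scan.

    ``train``: ``patches_per_scan_train`` random patches of which at least
    ``min_spine_patches`` contain spine voxels (requires dense labels —
    detection is trained on the labeled source domain only).
    ``test``: a non-overlapping tiling of the padded scan; origins allow
    exact reassembly.
    """
    patch = spec.patch_shape
    data = _pad_to(vol.data, patch, pad_value)
    labels = None
    if dense is not None:
        if dense.shape != vol.shape:
            raise ValueError("volume and dense labels must share a shape")
        labels = _pad_to((dense.data > 0).astype(np.uint8), patch, 0)

    def cut(arr, origin):
        return arr[tuple(slice(o, o + p) for o, p in zip(origin, patch))]

    if mode == "test":
        out = []
        for origin in _tile_origins(data.shape, patch):
            end = [min(o + p, data.shape[a]) for a, (o, p) in enumerate(zip(origin, patch))]
            # clip the last tile via padding so every tile is full-sized
            full = _pad_to(data[tuple(slice(o, e) for o, e in zip(origin, end))],
                           patch, pad_value)
            lab = None
            if labels is not None:
                lab = _pad_to(labels[tuple(slice(o, e) for o, e in zip(origin, end))],
                              patch, 0)
            out.append((full, lab, tuple(origin)))
        return out

    if mode != "train":
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    if labels is None:
        raise ValueError(
            "train mode needs dense labels: the detection stage is trained on "
            "the labeled source domain only"
        )
    rng = np.random.default_rng(seed)
    spine_vox = np.argwhere(labels > 0)
    if len(spine_vox) == 0:
        raise ValueError("scan contains no spine voxels")
    max_origin = np.array(data.shape) - np.array(patch)
    out = []
    for i in range(spec.patches_per_scan_train):
        if i < spec.min_spine_patches:
            center = spine_vox[rng.integers(len(spine_vox))]
            jitter = rng.integers(-np.array(patch) // 4, np.array(patch) // 4 + 1)
            origin = np.clip(center - np.array(patch) // 2 + jitter, 0, max_origin)
        else:
            origin = np.array([rng.integers(0, m + 1) for m in max_origin])
        origin = tuple(int(o) for o in origin)
        out.append((cut(data, origin), cut(labels, origin), origin))
    return out


def weighted_bce(
    pred: np.ndarray,
    target: np.ndarray,
    w_spine: float = 1.0,
    w_bg: float = 0.1,
    eps: float = 1e-7,
) -> float:
    """Mean class-weighted binary cross-entropy over all voxels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if np.any(pred <= 0) or np.any(pred >= 1):
        log.debug("clamping predictions outside (0, 1) at eps=%g", eps)
    p = np.clip(pred, eps, 1 - eps)
    w = np.where(target > 0, w_spine, w_bg)
    return float(np.mean(w * (-target * np.log(p) - (1 - target) * np.log(1 - p))))


def train_detector(
    samples,
    cfg: DetectionTrainConfig = DetectionTrainConfig(),
    model: DetectionNet | None = None,
) -> DetectionNet:
    """Train a binary spine segmenter on (patch, labels, origin) samples with
    Adam on the weighted BCE.  Seeded and bit-reproducible; the per-epoch
    mean loss is logged and kept in ``model.history``."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample set")
    if model is None:
        model = DetectionNet(seed=cfg.seed, learning_rate=cfg.learning_rate)
    feats = [model.features(p) for p, _, _ in samples]
    targs = [np.asarray(t, dtype=np.float64).ravel() for _, t, _ in samples]
    rng = np.random.default_rng(cfg.seed + 1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            X = np.concatenate([feats[i] for i in idx])
            t = np.concatenate([targs[i] for i in idx])
            p, cache = model.forward_features(X)
            losses.append(
                weighted_bce(p, t, cfg.loss_weight_spine, cfg.loss_weight_background)
            )
            w = np.where(t > 0, cfg.loss_weight_spine, cfg.loss_weight_background)
            dz = w * (np.clip(p, 1e-7, 1 - 1e-7) - t) / len(t)
            model.apply_gradients(model.backward_logits(cache, dz))
        epoch_loss = float(np.mean(losses))
        model.history.append(epoch_loss)
        log.info("detection epoch %d/%d: loss %.5f", epoch + 1, cfg.epochs, epoch_loss)
    return model


def assemble_prediction(
    patch_predictions,
    full_shape,
    spacing=(1.0, 1.0, 1.0),
    threshold: float = 0.5,
) -> BinaryMask:
    """Reassemble per-patch probability tiles into a full-grid binary mask.

    Probabilities >= threshold (ties labeled spine) become 1; regions padded
    past the original grid are cropped away.
    """
    tiles = list(patch_predictions)
    if not tiles:
        raise ValueError("no tiles given")
    patch = tiles[0][0].shape
    canvas_shape = tuple(
        int(np.ceil(s / p)) * p for s, p in zip(full_shape, patch)
    )
    expected = set(_tile_origins(canvas_shape, patch))
    canvas = np.zeros(canvas_shape)
    seen = set()
    for prob, origin in tiles:
        origin = tuple(int(o) for o in origin)
        if prob.shape != patch:
            raise ValueError(f"tile at {origin} has shape {prob.shape}, expected {patch}")
        canvas[tuple(slice(o, o + p) for o, p in zip(origin, patch))] = prob
        seen.add(origin)
    missing = expected - seen
    if missing:
        raise ValueError(f"missing tile at origin {sorted(missing)[0]}")
    cropped = canvas[tuple(slice(0, s) for s in full_shape)]
    return BinaryMask((cropped >= threshold).astype(np.uint8), spacing)


def postprocess_largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest 3D connected component of a binary mask.

    Smaller components are discarded as artefacts; ties are broken toward
    the component whose first voxel comes earliest in scan order (smallest
    lexicographic origin).  An empty mask passes through with a warning.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=int)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labeled, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        warnings.warn("post-processing an empty detection mask", stacklevel=2)
        return BinaryMask(np.zeros_like(mask.data), mask.spacing)
    sizes = np.bincount(labeled.ravel())[1:]
    best = sizes.max()
    candidates = [c + 1 for c in np.flatnonzero(sizes == best)]
    if len(candidates) > 1:
        flat = labeled.ravel()
        candidates.sort(key=lambda c: int(np.flatnonzero(flat == c)[0]))
    keep = candidates[0]
    return BinaryMask((labeled == keep).astype(np.uint8), mask.spacing)


def predict_detection(
    model: DetectionNet,
    vol: Volume,
    spec: DetectionPatchSpec = DetectionPatchSpec(),
    postprocess: bool = True,
    threshold: float = 0.5,
) -> BinaryMask:
    """Tile a scan, predict every tile, reassemble, optionally post-process."""
    tiles = extract_detection_patches(vol, None, spec, mode="test")
    preds = [(model.predict_proba(patch), origin) for patch, _, origin in tiles]
    mask = assemble_prediction(preds, vol.shape, vol.spacing, threshold)
    if postprocess:
        mask = postprocess_largest_component(mask)
    return mask
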