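"""The Domain Sanity Loss: four anatomical sanity checks on a sagittal
per-pixel vertebra-value prediction.

The checks penalize predictions that are anatomically impossible and hence
need no labels:

* ``s1`` — vertebra values must ascend craniocaudally: every pixel compared
  with the same prediction shifted right by ``s = 1..n_shift`` columns.
* ``s2`` — pixels orthogonal to the spine (one image column) must share one
  label, taken as the column median.
* ``s3`` — distances between consecutive predicted vertebra centroids must
  match literature reference distances (L1 deviation, normalized by the 25
  adjacent pairs of a full spine).
* ``s4`` — each connected component of an unsupervised weak vertebra mask
  must carry a single predicted label (counts excess unique labels).

Each term exists in an *exact* counting form (evaluation, tests) and, for
``s1``/``s2``, a *surrogate* form (hinge / absolute deviation from a
detached median) whose subgradients drive training; the surrogate is zero
exactly when the exact count is zero.  The weighted total is
``c1*s1 + c2*s2 + c3*s3 + c4*s4``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .labels import N_VERT_PAIRS, ReferenceDistances
from .weakmask import WeakMask

__all__ = [
    "MaskedPrediction",
    "DSLConfig",
    "LossBreakdown",
    "mask_background",
    "term_s1",
    "term_s2",
    "term_s3",
    "term_s4",
    "dsl_total",
    "surrogate_s1_grad",
    "surrogate_s2_grad",
    "round_half_up",
]


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer with halves rounded up (0.5 -> 1)."""
    return np.floor(np.asarray(x) + 0.5)


@dataclass(frozen=True)
class MaskedPrediction:
    """Continuous per-pixel vertebra values over the sagittal plane, with the
    background already forced to exactly zero (spine pixels are nonzero)."""

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)  # mm per pixel along (row, col)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError(f"prediction must be 2D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("prediction contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 2 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", sp)

    @property
    def n_row(self) -> int:
        return self.data.shape[0]

    @property
    def n_col(self) -> int:
        return self.data.shape[1]

    @property
    def n_pix(self) -> int:
        return self.data.size

    def spine(self) -> np.ndarray:
        """Boolean mask of spine pixels: those whose prediction rounds to a
        vertebra (>= 0.5).  For integer label grids this coincides with
        "nonzero"; for continuous model outputs it excludes pixels the model
        itself calls background (values near 0 inside an imprecise detection
        mask), which would otherwise create spurious order violations."""
        return self.data >= 0.5


@dataclass(frozen=True)
class DSLConfig:
    c1: float = 20.0
    c2: float = 1.0
    c3: float = 1.0 / 40.0
    c4: float = 1.0 / 100.0
    n_shift: int = 30
    strict_margin: float = 0.0
    spine_only_comparisons: bool = True
    strict_inequality: bool = True  # False restores the printed ">= 0" form
    normalize_by_spine: bool = False  # divide by spine pixels instead of n_pix
    mode: str = "exact"

    def __post_init__(self):
        if not (self.c1 > 0 and self.c2 > 0 and self.c3 > 0 and self.c4 > 0):
            raise ValueError("the four weights c1..c4 must all be positive")
        if self.n_shift < 1:
            raise ValueError("n_shift must be >= 1")
        if self.strict_margin < 0:
            raise ValueError("strict_margin must be >= 0")
        if self.mode not in ("exact", "surrogate"):
            raise ValueError(f"mode must be 'exact' or 'surrogate', got {self.mode!r}")


@dataclass(frozen=True)
class LossBreakdown:
    s1: float
    s2: float
    s3: float
    s4: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"s1": self.s1, "s2": self.s2, "s3": self.s3, "s4": self.s4,
                "total": self.total}


def mask_background(raw_prediction: np.ndarray, det_mask: np.ndarray,
                    spacing=(1.0, 1.0)) -> MaskedPrediction:
    """Zero out non-spine pixels by multiplying with the detection mask."""
    raw = np.asarray(raw_prediction, dtype=np.float64)
    det = np.asarray(det_mask)
    if raw.shape != det.shape:
        raise ValueError(f"shape mismatch: prediction {raw.shape} vs mask {det.shape}")
    return MaskedPrediction(raw * det, spacing)


def _normalizer(yhat: MaskedPrediction, cfg: DSLConfig) -> float:
    if cfg.normalize_by_spine:
        n = int(yhat.spine().sum())
        return float(max(n, 1))
    return float(yhat.n_pix)


def _violates(diff: np.ndarray, cfg: DSLConfig) -> np.ndarray:
    if cfg.strict_inequality:
        return diff > cfg.strict_margin
    return diff >= cfg.strict_margin


def _s1_pairs(yhat: MaskedPrediction, cfg: DSLConfig):
    """Yield (diff, pair_mask, s) over shifts; diff = y[:, j] - y[:, j+s]."""
    y = yhat.data
    nz = yhat.spine()
    if yhat.n_col <= cfg.n_shift:
        raise ValueError(
            f"n_col={yhat.n_col} must exceed n_shift={cfg.n_shift}; "
            "use a smaller n_shift for this grid"
        )
    for s in range(1, cfg.n_shift + 1):
        diff = y[:, :-s] - y[:, s:]
        if cfg.spine_only_comparisons:
            pair = nz[:, :-s] & nz[:, s:]
        else:
            pair = np.ones_like(diff, dtype=bool)
        yield diff, pair, s


def term_s1(yhat: MaskedPrediction, cfg: DSLConfig = DSLConfig()) -> float:
    """Ordering check: fraction of pixel pairs violating the craniocaudal
    ascending order (exact), or the mean positive violation (surrogate)."""
    total = 0.0
    for diff, pair, _ in _s1_pairs(yhat, cfg):
        if cfg.mode == "surrogate":
            total += float(np.sum(np.maximum(diff, 0.0) * pair))
        else:
            total += float(np.sum(_violates(diff, cfg) & pair))
    return total / _normalizer(yhat, cfg)


def _column_medians(yhat: MaskedPrediction, cfg: DSLConfig) -> np.ndarray:
    """Per-column median label; over spine pixels only when configured.
    Columns with no counted pixel get NaN."""
    y = yhat.data
    if cfg.spine_only_comparisons:
        masked = np.where(yhat.spine(), y, np.nan)
        with warnings.catch_warnings():
            # all-background columns legitimately yield NaN medians
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmedian(masked, axis=0)
    return np.median(y, axis=0)


def term_s2(yhat: MaskedPrediction, cfg: DSLConfig = DSLConfig()) -> float:
    """Column-consistency check against the per-column median label."""
    y = yhat.data
    med = _column_medians(yhat, cfg)
    counted = yhat.spine() if cfg.spine_only_comparisons else np.ones_like(y, bool)
    counted = counted & ~np.isnan(med)[None, :]
    dev = np.abs(y - np.where(np.isnan(med), 0.0, med)[None, :])
    if cfg.mode == "surrogate":
        total = float(np.sum(dev * counted))
    else:
        total = float(np.sum((dev > cfg.strict_margin) & counted))
    return total / _normalizer(yhat, cfg)


def prediction_centroids(yhat: MaskedPrediction) -> dict[int, np.ndarray]:
    """Centroids (mm, per-axis median of pixel coordinates) of the rounded
    nonzero prediction — the same dense->sparse rule used for evaluation."""
    labels = round_half_up(yhat.data)
    labels[~yhat.spine()] = 0
    out: dict[int, np.ndarray] = {}
    sp = np.asarray(yhat.spacing)
    for k in np.unique(labels):
        if k <= 0:
            continue
        coords = np.argwhere(labels == k)
        out[int(k)] = np.median(coords, axis=0) * sp
    return out


def term_s3(yhat: MaskedPrediction, rd: ReferenceDistances) -> float:
    """Centroid-distance check against the literature reference table."""
    cents = prediction_centroids(yhat)
    total = 0.0
    for k in sorted(cents):
        if k + 1 in cents and 1 <= k <= N_VERT_PAIRS:
            delta = float(np.linalg.norm(cents[k + 1] - cents[k]))
            total += abs(delta - rd[(k, k + 1)])
    return total / N_VERT_PAIRS


def term_s4(wm: WeakMask, yhat: MaskedPrediction) -> float:
    """Weak-mask consistency: excess unique labels per connected component."""
    if wm.n_components == 0:
        return 0.0
    if wm.data.shape != yhat.data.shape:
        raise ValueError(
            f"weak mask shape {wm.data.shape} != prediction shape {yhat.data.shape}"
        )
    labels = round_half_up(yhat.data)
    total = 0.0
    for coords in wm.components.values():
        vals = labels[coords[:, 0], coords[:, 1]]
        uniq = np.unique(vals[vals > 0])
        total += max(len(uniq) - 1, 0)
    return total / wm.n_components


def dsl_total(
    yhat: MaskedPrediction,
    wm: WeakMask,
    rd: ReferenceDistances,
    cfg: DSLConfig = DSLConfig(),
) -> LossBreakdown:
    """All four sanity-check terms plus the weighted total."""
    s1 = term_s1(yhat, cfg)
    s2 = term_s2(yhat, cfg)
    s3 = term_s3(yhat, rd)
    s4 = term_s4(wm, yhat)
    total = cfg.c1 * s1 + cfg.c2 * s2 + cfg.c3 * s3 + cfg.c4 * s4
    return LossBreakdown(s1, s2, s3, s4, total)


# ---------------------------------------------------------------------------
# Surrogate subgradients (w.r.t. the masked prediction grid)
# ---------------------------------------------------------------------------


def surrogate_s1_grad(yhat: MaskedPrediction, cfg: DSLConfig):
    """Surrogate s1 value and its subgradient w.r.t. the prediction grid."""
    grad = np.zeros_like(yhat.data)
    norm = _normalizer(yhat, cfg)
    total = 0.0
    for diff, pair, s in _s1_pairs(yhat, cfg):
        pos = (diff > 0) & pair
        total += float(np.sum(diff[pos]))
        grad[:, :-s] += pos / norm
        grad[:, s:] -= pos / norm
    return total / norm, grad


def surrogate_s2_grad(yhat: MaskedPrediction, cfg: DSLConfig):
    """Surrogate s2 value and subgradient; the column median is detached."""
    med = _column_medians(yhat, cfg)
    counted = yhat.spine() if cfg.spine_only_comparisons else np.ones_like(yhat.data, bool)
    counted = counted & ~np.isnan(med)[None, :]
    dev = (yhat.data - np.where(np.isnan(med), 0.0, med)[None, :]) * counted
    norm = _normalizer(yhat, cfg)
    return float(np.sum(np.abs(dev))) / norm, np.sign(dev) / norm
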