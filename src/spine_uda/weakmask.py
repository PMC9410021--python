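"""Unsupervised weak vertebra-segmentation masks on the sagittal plane.

The weak mask is built from the scan itself (never from labels): the image
is restricted to the detected spine, thresholded at 180 HU to emphasize the
bright vertebral bodies, and segmented with the graph-based
Felzenszwalb-Huttenlocher algorithm.  Components are then cleaned with
cheap shape heuristics.  The result is deliberately imprecise — it is used
only as a consistency reference by the fourth sanity-check term, never as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.segmentation import felzenszwalb

DEFAULT_HU_THRESHOLD = 180.0


@dataclass(frozen=True)
class FelzParams:
    """Felzenszwalb-Huttenlocher parameters, tuned on phantom slices.

    ``min_size`` sits below the smallest plausible vertebra face (~300 px at
    1 mm) but high enough to absorb the thin boundary-gradient fragments the
    internal Gaussian smoothing produces around strong edges.
    """

    scale: float = 100.0
    sigma: float = 0.8
    min_size: int = 150


@dataclass
class WeakMask:
    """2D integer grid (0 = no component, k >= 1 = component id) plus the
    coordinate set of every component."""

    data: np.ndarray
    components: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int32)
        if self.data.ndim != 2:
            raise ValueError(f"weak mask must be 2D, got shape {self.data.shape}")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @classmethod
    def empty(cls, shape) -> "WeakMask":
        return cls(np.zeros(shape, dtype=np.int32), {})

    @classmethod
    def from_label_grid(cls, grid: np.ndarray) -> "WeakMask":
        comps = {}
        out = np.zeros_like(grid, dtype=np.int32)
        next_id = 1
        for k in np.unique(grid):
            if k == 0:
                continue
            coords = np.argwhere(grid == k)
            comps[next_id] = coords
            out[coords[:, 0], coords[:, 1]] = next_id
            next_id += 1
        return cls(out, comps)


def _renumber(shape, comps_list) -> WeakMask:
    """Deterministically renumber components by their first pixel in scan order."""
    comps_list = sorted(comps_list, key=lambda c: (int(c[:, 0].min()), int(c[c[:, 0] == c[:, 0].min(), 1].min())))
    out = np.zeros(shape, dtype=np.int32)
    comps = {}
    for i, coords in enumerate(comps_list, start=1):
        comps[i] = coords
        out[coords[:, 0], coords[:, 1]] = i
    return WeakMask(out, comps)


def build_weak_mask(
    scan_patch: np.ndarray,
    detection_patch: np.ndarray,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    felz: FelzParams = FelzParams(),
) -> WeakMask:
    """Weak mask = Felzenszwalb segmentation of the thresholded, detection-
    masked sagittal image; the background segment is dropped."""
    scan = np.asarray(scan_patch, dtype=np.float64)
    det = np.asarray(detection_patch)
    if scan.shape != det.shape:
        raise ValueError(f"shape mismatch: scan {scan.shape} vs detection {det.shape}")
    img = scan * det
    img[img < hu_threshold] = 0.0
    if not np.any(img > 0):
        return WeakMask.empty(scan.shape)
    seg = felzenszwalb(
        img, scale=felz.scale, sigma=felz.sigma, min_size=felz.min_size, channel_axis=None
    )
    comps: list[np.ndarray] = []
    for sid in np.unique(seg):
        region = seg == sid
        # a segment dominated by zero-intensity pixels is background
        if np.mean(img[region] == 0) >= 0.5:
            continue
        # guarantee connectivity: split segments into connected pieces
        pieces = cc_label(region, connectivity=2)
        for pid in range(1, pieces.max() + 1):
            comps.append(np.argwhere(pieces == pid))
    return _renumber(scan.shape, comps)


def _bbox(coords: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int(coords[:, 0].min()),
        int(coords[:, 0].max()),
        int(coords[:, 1].min()),
        int(coords[:, 1].max()),
    )


def filter_components(
    wm: WeakMask,
    min_area: int = 25,
    max_area: int = 5000,
    max_aspect_ratio: float = 3.0,
) -> WeakMask:
    """Drop components whose area or bounding-box aspect ratio cannot belong
    to a vertebra; survivors are renumbered contiguously."""
    kept = []
    for coords in wm.components.values():
        area = len(coords)
        if not min_area <= area <= max_area:
            continue
        r0, r1, c0, c1 = _bbox(coords)
        h, w = r1 - r0 + 1, c1 - c0 + 1
        if max(h, w) / min(h, w) > max_aspect_ratio:
            continue
        kept.append(coords)
    return _renumber(wm.data.shape, kept)


def merge_enclosed(wm: WeakMask) -> WeakMask:
    """Merge components whose bounding box lies entirely inside another's,
    repeating until a fixpoint is reached."""
    comps = [c for c in wm.components.values()]
    changed = True
    while changed:
        changed = False
        boxes = [_bbox(c) for c in comps]
        for i in range(len(comps)):
            for j in range(len(comps)):
                if i == j:
                    continue
                ri0, ri1, ci0, ci1 = boxes[i]
                rj0, rj1, cj0, cj1 = boxes[j]
                if ri0 >= rj0 and ri1 <= rj1 and ci0 >= cj0 and ci1 <= cj1:
                    comps[j] = np.vstack([comps[j], comps[i]])
                    del comps[i]
                    changed = True
                    break
            if changed:
                break
    return _renumber(wm.data.shape, comps)


def clean_weak_mask(wm: WeakMask, **filter_kwargs) -> WeakMask:
    """The standard post-processing pair: shape filtering, then merging of
    enclosed components (idempotent)."""
    return merge_enclosed(filter_components(wm, **filter_kwargs))
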