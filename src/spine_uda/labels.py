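"""Dense/sparse label conversion and the vertebra reference tables.

Vertebra numbering follows the ascending convention 1 = C1 ... 26 = S2.
Sparse annotations are vertebra centroids in mm; dense annotations are
integer grids where 0 is background and k marks vertebra k.  The conversion
back from dense to sparse takes the per-axis *median* voxel coordinate of
each label, which makes the recovered centroid robust to outlying pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core_io import (
    N_VERTEBRAE,
    NAME_TO_ID,
    ID_TO_NAME,
    CentroidSet,
    _check_spacing,
)

N_VERT_PAIRS = N_VERTEBRAE - 1  # the Eq.-style normalizer n_vert = 25


@dataclass(frozen=True)
class DenseLabels:
    """Integer grid: 0 = background, k in 1..26 = vertebra k."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"dense labels must be 3D, got shape {data.shape}")
        if data.min(initial=0) < 0 or data.max(initial=0) > N_VERTEBRAE:
            raise ValueError(
                f"dense label values must lie in 0..{N_VERTEBRAE}, "
                f"got range [{data.min()}, {data.max()}]"
            )
        object.__setattr__(self, "data", data.astype(np.int16))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def present_ids(self) -> list[int]:
        vals = np.unique(self.data)
        return [int(v) for v in vals if v > 0]


@dataclass(frozen=True)
class ReferenceDistances:
    """Mean adjacent inter-centroid distances (mm): (k, k+1) -> mm, k=1..25."""

    dbar: dict[tuple[int, int], float]

    def __post_init__(self):
        clean = {}
        for (a, b), v in self.dbar.items():
            a, b, v = int(a), int(b), float(v)
            if b != a + 1 or not 1 <= a <= N_VERT_PAIRS:
                raise ValueError(f"invalid adjacent pair ({a}, {b})")
            if not v > 0:
                raise ValueError(f"reference distance for pair ({a},{b}) must be > 0")
            clean[(a, b)] = v
        missing = [k for k in range(1, N_VERT_PAIRS + 1) if (k, k + 1) not in clean]
        if missing:
            raise ValueError(f"missing adjacent pairs starting at ids {missing}")
        object.__setattr__(self, "dbar", clean)

    def __getitem__(self, pair: tuple[int, int]) -> float:
        return self.dbar[(int(pair[0]), int(pair[1]))]


@dataclass(frozen=True)
class VertebraSizeTable:
    """Average dense-label box extent (mm) per vertebra id, as (sag, row, col)."""

    size: dict[int, tuple[float, float, float]]

    def __post_init__(self):
        clean = {}
        for vid, ext in self.size.items():
            vid = int(vid)
            if not 1 <= vid <= N_VERTEBRAE:
                raise ValueError(f"vertebra id {vid} outside 1..{N_VERTEBRAE}")
            ext = tuple(float(e) for e in ext)
            if len(ext) != 3 or any(e <= 0 for e in ext):
                raise ValueError(f"extent for vertebra {vid} must be 3 positives")
            clean[vid] = ext
        missing = [k for k in range(1, N_VERTEBRAE + 1) if k not in clean]
        if missing:
            raise ValueError(f"size table missing vertebra ids {missing}")
        object.__setattr__(self, "size", clean)

    def __getitem__(self, vid: int) -> tuple[float, float, float]:
        return self.size[int(vid)]


def _resource_yaml(name: str) -> dict:
    with resources.files("spine_uda.resources").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_reference_distances(path=None) -> ReferenceDistances:
    """Load the adjacency-spacing table (default: the packaged YAML)."""
    if path is None:
        raw = _resource_yaml("reference_distances.yaml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    dbar = {}
    for key, val in raw.items():
        a_name, b_name = str(key).split("-")
        dbar[(NAME_TO_ID[a_name], NAME_TO_ID[b_name])] = float(val)
    return ReferenceDistances(dbar)


def load_vertebra_sizes(path=None) -> VertebraSizeTable:
    if path is None:
        raw = _resource_yaml("vertebra_sizes.yaml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return VertebraSizeTable({NAME_TO_ID[str(k)]: tuple(v) for k, v in raw.items()})


def adjacent_reference(rd: ReferenceDistances, k: int) -> float:
    """Mean distance (mm) between vertebra k and k+1 from the reference table."""
    k = int(k)
    if not 1 <= k <= N_VERT_PAIRS:
        raise ValueError(f"adjacent pair index k={k} outside 1..{N_VERT_PAIRS}")
    return rd[(k, k + 1)]


def sparse_to_dense(
    cs: CentroidSet,
    shape: tuple[int, int, int],
    spacing=(1.0, 1.0, 1.0),
    sizes: VertebraSizeTable | None = None,
) -> DenseLabels:
    """Convert sparse centroid annotations to dense per-voxel labels.

    Each vertebra k becomes an axis-aligned box of label k centred on its
    centroid with the extent from the size table.  Where boxes overlap the
    contested voxel is assigned to the nearer centroid (ties to the lower id).
    """
    spacing = _check_spacing(spacing)
    if sizes is None:
        sizes = load_vertebra_sizes()
    shape = tuple(int(s) for s in shape)
    out = np.zeros(shape, dtype=np.int16)
    best = np.full(shape, np.inf)
    sp = np.asarray(spacing)
    for vid, pos_mm in cs.items():
        pos_vox = pos_mm / sp
        if np.any(pos_vox < 0) or np.any(pos_vox > np.asarray(shape) - 1):
            raise ValueError(
                f"centroid of vertebra {vid} ({ID_TO_NAME[vid]}) at {pos_mm} mm "
                f"lies outside the grid of shape {shape}"
            )
        half = np.asarray(sizes[vid]) / 2.0 / sp
        lo = np.maximum(np.ceil(pos_vox - half), 0).astype(int)
        hi = np.minimum(np.floor(pos_vox + half), np.asarray(shape) - 1).astype(int)
        sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
        grids = np.meshgrid(
            *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
        )
        d2 = sum(((g - p) * s) ** 2 for g, p, s in zip(grids, pos_vox, sp))
        closer = d2 < best[sl]  # strict: ties keep the earlier (lower) id
        out[sl] = np.where(closer, vid, out[sl])
        best[sl] = np.where(closer, d2, best[sl])
    return DenseLabels(out, spacing)


def dense_to_sparse(dense: DenseLabels) -> CentroidSet:
    """Recover centroids as the per-axis median voxel coordinate, in mm.

    Ids absent from the grid are absent from the output; an all-zero grid
    yields an empty set.
    """
    entries: dict[int, np.ndarray] = {}
    sp = np.asarray(dense.spacing)
    for vid in dense.present_ids():
        coords = np.argwhere(dense.data == vid)
        entries[vid] = np.median(coords, axis=0) * sp
    return CentroidSet(entries)
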