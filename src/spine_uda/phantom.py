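"""Synthetic spine-phantom CT volumes with ground-truth annotations.

The phantom emulates a spine-focused CT scan: a craniocaudal chain of bright
cuboid "vertebrae" whose centroid spacing follows the packaged reference
distance table, embedded in soft-tissue background noise, optionally with a
bed-like cuboid artefact.  Consecutive cuboids are bridged by a thin rod at
sub-threshold intensity (emulating discs/posterior elements) so the whole
spine forms a single connected component while the 180 HU weak-mask
threshold still separates individual vertebrae.

Two domains are generated: ``source`` (clean) and ``target``, which differs
in noise level, global intensity scaling and random column cropping —
the kinds of distribution shift a scanner/protocol change induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import BinaryMask, CentroidSet, Volume
from .dsl_loss import MaskedPrediction
from .labels import (
    DenseLabels,
    ReferenceDistances,
    VertebraSizeTable,
    adjacent_reference,
    load_reference_distances,
    load_vertebra_sizes,
    sparse_to_dense,
)

HU_THRESHOLD = 180.0  # weak-mask intensity threshold the phantom must straddle


@dataclass(frozen=True)
class PhantomConfig:
    n_vertebrae: int = 10
    first_vertebra_id: int = 8  # T1
    grid_shape: tuple[int, int, int] = (64, 96, 352)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_spine_hu: float = 700.0
    intensity_disc_hu: float = 165.0
    intensity_background_hu: float = 40.0
    intensity_bed_hu: float = 400.0
    noise_sd_hu: float = 15.0
    include_bed_artefact: bool = True
    gap_fraction: float = 0.2
    centroid_jitter: int = 6
    domain: str = "source"
    target_noise_sd_hu: float = 60.0
    target_intensity_scale: float = 0.9
    target_crop_cols: int = 8
    seed: int = 0
    reference_distances: ReferenceDistances | None = None
    vertebra_sizes: VertebraSizeTable | None = None

    def __post_init__(self):
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if not 1 <= self.first_vertebra_id <= 26:
            raise ValueError("first_vertebra_id must lie in 1..26")
        if self.first_vertebra_id + self.n_vertebrae - 1 > 26:
            raise ValueError(
                "first_vertebra_id + n_vertebrae - 1 must not exceed 26 "
                f"(got {self.first_vertebra_id} + {self.n_vertebrae} - 1)"
            )
        if not self.intensity_spine_hu > HU_THRESHOLD > self.intensity_background_hu:
            raise ValueError(
                f"need intensity_spine_hu > {HU_THRESHOLD} > intensity_background_hu"
            )
        if not self.intensity_disc_hu < HU_THRESHOLD:
            raise ValueError("intensity_disc_hu must stay below the 180 HU threshold")
        if (
            self.domain == "target"
            and self.target_intensity_scale * self.intensity_spine_hu <= HU_THRESHOLD
        ):
            raise ValueError("target intensity scaling pushes the spine below 180 HU")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must lie in [0, 1)")

    def tables(self) -> tuple[ReferenceDistances, VertebraSizeTable]:
        rd = self.reference_distances or load_reference_distances()
        sizes = self.vertebra_sizes or load_vertebra_sizes()
        return rd, sizes


@dataclass
class PhantomSample:
    volume: Volume
    centroids: CentroidSet
    dense: DenseLabels
    spine_mask: BinaryMask
    bed_mask: BinaryMask | None
    disc_mask: np.ndarray  # boolean, the sub-threshold bridging rod
    config: PhantomConfig


def _centroid_columns(cfg: PhantomConfig, rd: ReferenceDistances, rng) -> np.ndarray:
    ids = range(cfg.first_vertebra_id, cfg.first_vertebra_id + cfg.n_vertebrae)
    gaps = [adjacent_reference(rd, k) for k in list(ids)[:-1]]
    span = float(sum(gaps))
    ncol_mm = cfg.grid_shape[2] * cfg.spacing[2]
    _, sizes = cfg.tables()
    max_half = max(sizes[k][2] for k in ids) / 2.0
    margin = max_half + cfg.target_crop_cols * cfg.spacing[2] + 2.0
    start0 = (ncol_mm - span) / 2.0
    lo, hi = margin, ncol_mm - 1 - span - margin
    if hi < lo:
        raise ValueError(
            f"grid with {cfg.grid_shape[2]} columns cannot hold {cfg.n_vertebrae} "
            f"vertebrae spanning {span:.0f} mm plus margins"
        )
    jit = rng.integers(-cfg.centroid_jitter, cfg.centroid_jitter + 1)
    start = float(np.clip(start0 + jit, lo, hi))
    # snap to the voxel grid so odd box extents stay symmetric around centroids
    start = round(start / cfg.spacing[2]) * cfg.spacing[2]
    return start + np.concatenate([[0.0], np.cumsum(gaps)])


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """Render one seeded phantom sample (deterministic given the config)."""
    rng = np.random.default_rng(cfg.seed)
    rd, sizes = cfg.tables()
    nsag, nrow, ncol = cfg.grid_shape
    sp = np.asarray(cfg.spacing)

    ids = list(range(cfg.first_vertebra_id, cfg.first_vertebra_id + cfg.n_vertebrae))
    for a, b in zip(ids[:-1], ids[1:]):
        d = adjacent_reference(rd, a)
        if (sizes[a][2] + sizes[b][2]) / 2.0 > (1.0 - cfg.gap_fraction) * d:
            raise ValueError(
                f"boxes of vertebrae {a},{b} leave less than a "
                f"{cfg.gap_fraction:.0%} inter-vertebral gap"
            )

    cols_mm = _centroid_columns(cfg, rd, rng)
    center_mm = np.array([(nsag // 2) * sp[0], (nrow // 2) * sp[1], 0.0])
    centroids = CentroidSet(
        {
            vid: np.array([center_mm[0], center_mm[1], c])
            for vid, c in zip(ids, cols_mm)
        }
    )
    dense = sparse_to_dense(centroids, cfg.grid_shape, cfg.spacing, sizes)
    cuboid = dense.data > 0

    # a continuous sub-threshold "posterior element" bar running laterally
    # behind the vertebral bodies bridges consecutive cuboids, so the spine
    # forms one connected component.  It is row-symmetric and its ends
    # overhang the first/last centroid by exactly half the adjacent reference
    # distance, keeping the per-label medians in sagittal projections exactly
    # on the centroids.
    disc = np.zeros(cfg.grid_shape, dtype=bool)
    label_grid = dense.data.copy()
    sag_c, row_c = nsag // 2, nrow // 2
    bar_sl = (
        slice(min(sag_c + 6, nsag - 1), min(sag_c + 19, nsag)),
        slice(max(row_c - 6, 0), min(row_c + 7, nrow)),
    )
    col_idx_mm = np.arange(ncol) * sp[2]
    nearest = np.array(
        [ids[int(np.argmin(np.abs(cols_mm - c)))] for c in col_idx_mm], dtype=np.int16
    )
    lead = adjacent_reference(rd, ids[0]) / 2 if len(ids) > 1 else 10.0
    trail = adjacent_reference(rd, ids[-2]) / 2 if len(ids) > 1 else 10.0
    in_bar = (col_idx_mm >= cols_mm[0] - lead) & (col_idx_mm <= cols_mm[-1] + trail)
    for j in np.nonzero(in_bar)[0]:
        block = label_grid[bar_sl + (j,)]
        free = block == 0
        block[free] = nearest[j]
        disc[bar_sl + (j,)] |= free
    dense = DenseLabels(label_grid, cfg.spacing)
    spine = dense.data > 0

    noiseless = np.full(cfg.grid_shape, cfg.intensity_background_hu)
    noiseless[cuboid] = cfg.intensity_spine_hu
    noiseless[disc] = cfg.intensity_disc_hu

    bed = None
    if cfg.include_bed_artefact:
        bed = np.zeros(cfg.grid_shape, dtype=np.uint8)
        bed[:, nrow - 6 : nrow - 3, :] = 1
        noiseless[bed.astype(bool)] = cfg.intensity_bed_hu

    noise_sd = cfg.noise_sd_hu
    if cfg.domain == "target":
        noiseless = noiseless * cfg.target_intensity_scale
        noise_sd = cfg.target_noise_sd_hu
    data = noiseless + rng.normal(0.0, noise_sd, size=cfg.grid_shape)

    if cfg.domain == "target" and cfg.target_crop_cols > 0:
        c0 = int(rng.integers(0, cfg.target_crop_cols + 1))
        c1 = ncol - (cfg.target_crop_cols - c0)
        data = data[:, :, c0:c1]
        label_grid = dense.data[:, :, c0:c1]
        spine = spine[:, :, c0:c1]
        disc = disc[:, :, c0:c1]
        if bed is not None:
            bed = bed[:, :, c0:c1]
        shift = c0 * sp[2]
        centroids = CentroidSet(
            {vid: pos - np.array([0.0, 0.0, shift]) for vid, pos in centroids.items()}
        )
        dense = DenseLabels(label_grid, cfg.spacing)

    return PhantomSample(
        volume=Volume(data, cfg.spacing),
        centroids=centroids,
        dense=dense,
        spine_mask=BinaryMask(spine.astype(np.uint8), cfg.spacing),
        bed_mask=None if bed is None else BinaryMask(bed, cfg.spacing),
        disc_mask=disc,
        config=cfg,
    )


def generate_pair(cfg: PhantomConfig) -> tuple[PhantomSample, PhantomSample]:
    """Source/target siblings sharing geometry statistics but not intensity."""
    return (
        generate_phantom(replace(cfg, domain="source")),
        generate_phantom(replace(cfg, domain="target")),
    )


CORRUPT_MODES = ("shift_columns", "swap_adjacent", "jitter_pixels")


def corrupt_labels(dense: DenseLabels, mode: str, magnitude, seed: int = 0) -> DenseLabels:
    """Return a corrupted copy of a dense label grid (test driver for the
    failure cases the sanity checks are designed to catch)."""
    rng = np.random.default_rng(seed)
    data = dense.data.copy()
    if mode == "shift_columns":
        m = int(magnitude)
        out = np.zeros_like(data)
        if m == 0:
            out = data
        elif m > 0:
            out[:, :, m:] = data[:, :, :-m]
        else:
            out[:, :, :m] = data[:, :, -m:]
        return DenseLabels(out, dense.spacing)
    if mode == "swap_adjacent":
        n_swaps = int(magnitude)
        present = set(int(v) for v in np.unique(data) if v > 0)
        pairs = [(k, k + 1) for k in sorted(present) if k + 1 in present]
        if n_swaps > 0 and not pairs:
            raise ValueError("no adjacent vertebra pair present to swap")
        for idx in rng.choice(len(pairs), size=min(n_swaps, len(pairs)), replace=False) if n_swaps else []:
            a, b = pairs[int(idx)]
            ma, mb = data == a, data == b
            data[ma], data[mb] = b, a
        return DenseLabels(data, dense.spacing)
    if mode == "jitter_pixels":
        frac = float(magnitude)
        coords = np.argwhere(data > 0)
        n = int(round(frac * len(coords)))
        if n > 0:
            pick = coords[rng.choice(len(coords), size=n, replace=False)]
            signs = rng.choice([-1, 1], size=n)
            for (s, i, j), sg in zip(pick, signs):
                data[s, i, j] = np.clip(data[s, i, j] + sg, 1, 26)
        return DenseLabels(data, dense.spacing)
    raise ValueError(f"unknown corruption mode {mode!r}; choose from {CORRUPT_MODES}")


def sagittal_projection(arr: np.ndarray) -> np.ndarray:
    """Collapse the sagittal-slab axis by maximum intensity -> (row, col)."""
    return np.asarray(arr).max(axis=0)


def sagittal_mean_projection(arr: np.ndarray) -> np.ndarray:
    """Collapse the sagittal-slab axis by mean intensity -> (row, col).

    The preferred input for weak-mask construction: the mean suppresses
    noise while keeping the HU scale meaningful for thresholding, whereas a
    maximum projection lets noise peaks pierce the 180 HU threshold and
    bridge neighbouring vertebrae."""
    return np.asarray(arr, dtype=np.float64).mean(axis=0)


def ideal_band_prediction(sample: PhantomSample) -> MaskedPrediction:
    """The gap-free ideal sagittal prediction for a phantom.

    Every column in the spine's range carries the id of the nearest centroid,
    over the row band the spine occupies — the contiguous label bands a
    perfectly adapted regressor would produce after rounding.  All four
    sanity-check terms are zero on this prediction.
    """
    nrow, ncol = sample.dense.shape[1], sample.dense.shape[2]
    sp = sample.dense.spacing
    ids = sample.centroids.ids()
    cols_mm = np.array([sample.centroids[v][2] for v in ids])
    rd, _ = sample.config.tables()

    # symmetric label bands: column j belongs to vertebra k iff it is closer
    # to c_k than half the smaller adjacent spacing; symmetry keeps the band
    # median exactly on the centroid, so the distance check is exactly zero
    halves = []
    for pos, vid in enumerate(ids):
        dists = []
        if pos > 0:
            dists.append(adjacent_reference(rd, ids[pos - 1]))
        if pos < len(ids) - 1:
            dists.append(adjacent_reference(rd, vid))
        halves.append(min(dists) / 2.0 if dists else 10.0)

    proj = sagittal_projection(sample.spine_mask.data)
    rows = np.nonzero(proj.any(axis=1))[0]
    col_mm = np.arange(ncol) * sp[2]
    band = np.zeros(ncol)
    for vid, c, h in zip(ids, cols_mm, halves):
        band[np.abs(col_mm - c) < h] = vid
    data = np.zeros((nrow, ncol))
    data[rows[0] : rows[-1] + 1, :] = band[None, :]
    return MaskedPrediction(data, (sp[1], sp[2]))
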