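"""Readers, writers and shared grid conventions.

Arrays are indexed ``(sagittal slab, row, column)``; the column axis runs
craniocaudally, so vertebra numbers increase with the column index.  A voxel
index ``v`` maps to the mm position ``v * spacing`` with the grid origin at
voxel ``(0, 0, 0)``.  Centroid files store mm coordinates so that the 20 mm
evaluation threshold is independent of voxel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

N_VERTEBRAE = 26

VERTEBRA_NAMES: tuple[str, ...] = tuple(
    [f"C{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["S1", "S2"]
)

#: vertebra id (1..26) -> anatomical name ("C1".."S2")
ID_TO_NAME: dict[int, str] = {i + 1: n for i, n in enumerate(VERTEBRA_NAMES)}
NAME_TO_ID: dict[str, int] = {n: i for i, n in ID_TO_NAME.items()}

CENTROID_COLUMNS = ("id", "x_mm", "y_mm", "z_mm")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries, got {spacing}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass(frozen=True)
class Volume:
    """A 3D CT grid of Hounsfield-unit intensities with mm voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume data contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 3D {0,1} grid sharing shape and spacing with its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {data.shape}")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "data", data.astype(np.uint8))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CentroidSet:
    """Sparse labels: vertebra id (1=C1 .. 26=S2) -> 3D position in mm."""

    entries: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[int, np.ndarray] = {}
        for vid, pos in self.entries.items():
            vid = int(vid)
            if not 1 <= vid <= N_VERTEBRAE:
                raise ValueError(
                    f"vertebra id {vid} outside valid range 1..{N_VERTEBRAE}"
                )
            if vid in clean:
                raise ValueError(f"duplicate vertebra id {vid}")
            pos = np.asarray(pos, dtype=np.float64)
            if pos.shape != (3,):
                raise ValueError(f"position of vertebra {vid} must be 3D, got {pos}")
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite position for vertebra {vid}: {pos}")
            clean[vid] = pos
        self.entries = dict(sorted(clean.items()))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, vid: int) -> bool:
        return int(vid) in self.entries

    def __getitem__(self, vid: int) -> np.ndarray:
        return self.entries[int(vid)]

    def ids(self) -> list[int]:
        return list(self.entries)

    def items(self):
        return self.entries.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, CentroidSet):
            return NotImplemented
        return self.ids() == other.ids() and all(
            np.array_equal(self.entries[k], other.entries[k]) for k in self.entries
        )


# ---------------------------------------------------------------------------
# NIfTI volumes / masks / dense label grids
# ---------------------------------------------------------------------------


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: header field 'pixdim' does not provide a positive per-axis "
            f"voxel spacing (got {zooms})"
        )
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D grid, got shape {data.shape}")
    return data, tuple(float(z) for z in zooms)


def read_volume(path) -> Volume:
    """Read a NIfTI volume; intensities are interpreted as HU."""
    data, spacing = _load_nifti(path)
    return Volume(data, spacing)


def write_volume(vol: Volume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data, _affine(vol.spacing)), str(path))
    return path


def read_mask(path) -> BinaryMask:
    data, spacing = _load_nifti(path)
    return BinaryMask(np.rint(data).astype(np.uint8), spacing)


def write_mask(mask: BinaryMask, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing)), str(path))
    return path


def read_dense(path):
    """Read an integer dense-label grid (0=background, k=vertebra k)."""
    from .labels import DenseLabels  # local import to avoid a cycle

    data, spacing = _load_nifti(path)
    return DenseLabels(np.rint(data).astype(np.int16), spacing)


def write_dense(dense, path) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(dense.data.astype(np.int16), _affine(dense.spacing)), str(path)
    )
    return path


# ---------------------------------------------------------------------------
# Centroid annotations (CSV with header id,x_mm,y_mm,z_mm; JSON equivalent)
# ---------------------------------------------------------------------------


def _centroids_from_records(records, source: str) -> CentroidSet:
    entries: dict[int, np.ndarray] = {}
    for rec in records:
        try:
            vid = int(rec["id"])
            pos = np.array(
                [float(rec["x_mm"]), float(rec["y_mm"]), float(rec["z_mm"])]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"{source}: each centroid needs fields {CENTROID_COLUMNS}: {exc}"
            ) from exc
        if vid in entries:
            raise ValueError(f"{source}: duplicate vertebra id {vid}")
        entries[vid] = pos
    return CentroidSet(entries)


def read_centroids(path) -> CentroidSet:
    """Read centroid annotations from CSV or JSON (mm coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        records = payload["centroids"] if isinstance(payload, dict) else payload
        return _centroids_from_records(records, str(path))
    frame = pd.read_csv(path)
    missing = [c for c in CENTROID_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing centroid columns {missing}")
    return _centroids_from_records(frame.to_dict("records"), str(path))


def write_centroids(cs: CentroidSet, path) -> Path:
    """Write a CentroidSet; format chosen by suffix (.csv default, .json)."""
    path = Path(path)
    records = [
        {"id": vid, "x_mm": pos[0], "y_mm": pos[1], "z_mm": pos[2]}
        for vid, pos in cs.items()
    ]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"centroids": records}, fh, indent=2)
    else:
        frame = pd.DataFrame(records, columns=list(CENTROID_COLUMNS))
        frame.to_csv(path, index=False)
    return path


def mm_to_voxel(pos_mm, spacing) -> np.ndarray:
    """Continuous voxel index of an mm position (origin at voxel (0,0,0))."""
    return np.asarray(pos_mm, dtype=np.float64) / np.asarray(spacing, dtype=np.float64)


def voxel_to_mm(index, spacing) -> np.ndarray:
    return np.asarray(index, dtype=np.float64) * np.asarray(spacing, dtype=np.float64)
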