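"""Volumetric and tabular I/O plus the flat-feature <-> volume mapping.

Every beta map is stored as a full-grid flat vector in Fortran (x-fastest)
order; voxels outside the brain mask are exactly zero.  The Fortran order is
fixed so that signature maps are comparable across runs and serialized
artifacts.  Volumes are written float32, in-memory computation is float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BetaSample",
    "VolumeStack",
    "Cohort",
    "ParcellationVolume",
    "read_dataset",
    "write_dataset",
    "write_map",
    "read_map",
    "load_parcellation",
]

METADATA_COLUMNS = ("subject_id", "block_index", "cue_type", "rating")

CUE_NEUTRAL = 0
CUE_DRUG = 1

RATING_MIN = 1
RATING_MAX = 4


@dataclass(frozen=True)
class BetaSample:
    """One cue block: a flat voxel beta vector plus its metadata.

    ``betas`` spans the full grid (Fortran flat order); out-of-mask voxels
    are exactly zero.  This is the unit of prediction throughout.
    """

    subject_id: str
    block_index: int
    cue_type: int
    rating: int
    betas: np.ndarray

    def __post_init__(self) -> None:
        if self.cue_type not in (CUE_NEUTRAL, CUE_DRUG):
            raise ValueError(f"cue_type must be 0 or 1, got {self.cue_type}")
        if not (RATING_MIN <= self.rating <= RATING_MAX):
            raise ValueError(f"rating must be in [1, 4], got {self.rating}")


@dataclass(frozen=True)
class VolumeStack:
    """Spatial bookkeeping: grid shape, affine, mask and the voxel index map.

    ``in_mask_flat`` lists the Fortran-order flat indices of in-mask voxels in
    ascending order; it is the bijection between in-mask 3D coordinates and
    feature columns restricted to the mask.
    """

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray  # 3D bool

    in_mask_flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.grid_shape):
            raise ValueError("mask shape does not match grid_shape")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        flat = np.flatnonzero(mask.reshape(-1, order="F"))
        object.__setattr__(self, "in_mask_flat", flat)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_in_mask(self) -> int:
        return int(self.in_mask_flat.size)

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """3D volume -> full-grid flat vector (Fortran order)."""
        volume = np.asarray(volume)
        if volume.shape != tuple(self.grid_shape):
            raise ValueError("volume shape does not match grid_shape")
        return volume.reshape(-1, order="F")

    def unflatten(self, vec: np.ndarray) -> np.ndarray:
        """Full-grid flat vector -> 3D volume (Fortran order)."""
        vec = np.asarray(vec)
        if vec.size != self.n_voxels:
            raise ValueError("vector length does not match grid size")
        return vec.reshape(self.grid_shape, order="F")

    def scatter(self, in_mask_values: np.ndarray) -> np.ndarray:
        """In-mask-length vector -> full-grid flat vector, zeros off mask."""
        in_mask_values = np.asarray(in_mask_values)
        if in_mask_values.size != self.n_in_mask:
            raise ValueError(
                f"expected {self.n_in_mask} in-mask values, got {in_mask_values.size}"
            )
        full = np.zeros(self.n_voxels, dtype=float)
        full[self.in_mask_flat] = in_mask_values
        return full

    def restrict(self, full_vec: np.ndarray) -> np.ndarray:
        """Full-grid flat vector -> in-mask-length vector."""
        full_vec = np.asarray(full_vec)
        if full_vec.size != self.n_voxels:
            raise ValueError("vector length does not match grid size")
        return full_vec[self.in_mask_flat]


class Cohort:
    """A stack of beta samples: feature matrix + metadata + spatial info.

    ``X`` has one row per cue block and one column per grid voxel (Fortran
    flat order, zeros off mask).  ``meta`` holds subject_id, block_index,
    cue_type, rating.  Behaves as a sequence of :class:`BetaSample`.
    """

    def __init__(self, X: np.ndarray, meta: pd.DataFrame, stack: VolumeStack):
        X = np.asarray(X, dtype=float)
        meta = meta.reset_index(drop=True)
        if X.ndim != 2:
            raise ValueError("X must be 2D (samples x voxels)")
        if len(meta) != X.shape[0]:
            raise ValueError(
                f"metadata rows ({len(meta)}) != sample count ({X.shape[0]})"
            )
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if X.shape[1] != stack.n_voxels:
            raise ValueError("X column count does not match grid size")
        ratings = meta["rating"].to_numpy()
        if not np.isin(ratings, np.arange(RATING_MIN, RATING_MAX + 1)).all():
            raise ValueError("ratings outside the 1-4 scale")
        cues = meta["cue_type"].to_numpy()
        if not np.isin(cues, [CUE_NEUTRAL, CUE_DRUG]).all():
            raise ValueError("unknown cue codes (expected 0=neutral, 1=drug)")
        self.X = X
        self.meta = meta
        self.stack = stack

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.X.shape[0]

    def __getitem__(self, i: int) -> BetaSample:
        row = self.meta.iloc[i]
        return BetaSample(
            subject_id=str(row["subject_id"]),
            block_index=int(row["block_index"]),
            cue_type=int(row["cue_type"]),
            rating=int(row["rating"]),
            betas=self.X[i],
        )

    def __iter__(self) -> Iterator[BetaSample]:
        for i in range(len(self)):
            yield self[i]

    # -- convenience -------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in first-appearance order."""
        return list(dict.fromkeys(self.meta["subject_id"].astype(str)))

    @property
    def ratings(self) -> np.ndarray:
        return self.meta["rating"].to_numpy(dtype=float)

    @property
    def cue_types(self) -> np.ndarray:
        return self.meta["cue_type"].to_numpy(dtype=int)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].astype(str).to_numpy()

    def select(self, index: np.ndarray) -> "Cohort":
        """Row-subset (bool mask or integer indices) as a new cohort."""
        index = np.asarray(index)
        return Cohort(self.X[index], self.meta.iloc[index], self.stack)

    def select_subjects(self, subjects: Sequence[str]) -> "Cohort":
        keep = set(map(str, subjects))
        mask = self.meta["subject_id"].astype(str).isin(keep).to_numpy()
        return self.select(mask)

    def mean_beta_map(self) -> np.ndarray:
        """Average beta vector over samples (full-grid flat layout)."""
        return self.X.mean(axis=0)


@dataclass(frozen=True)
class ParcellationVolume:
    """Integer-labeled atlas volume; label 0 is background."""

    labels: np.ndarray  # 3D int
    region_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("parcellation labels must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = np.rint(labels).astype(int)
        object.__setattr__(self, "labels", labels)

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]


# ---------------------------------------------------------------------------
# NIfTI / TSV round trips
# ---------------------------------------------------------------------------

def write_dataset(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as 4D NIfTI + TSV metadata + mask NIfTI.

    Returns the paths written, keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = cohort.stack
    vol4d = np.stack(
        [stack.unflatten(row) for row in cohort.X], axis=-1
    ).astype(np.float32)
    paths = {
        "betas": out / "betas.nii.gz",
        "metadata": out / "metadata.tsv",
        "mask": out / "mask.nii.gz",
    }
    nib.save(nib.Nifti1Image(vol4d, stack.affine), paths["betas"])
    nib.save(
        nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine), paths["mask"]
    )
    cohort.meta[list(METADATA_COLUMNS)].to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def read_dataset(
    volume_path: str | Path,
    metadata_path: str | Path,
    mask_path: str | Path | None = None,
) -> Cohort:
    """Load a 4D beta stack + metadata table into a :class:`Cohort`.

    If no mask is given, the mask is the set of voxels nonzero in at least
    one sample.  Voxels outside the mask are zeroed in the feature matrix.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    meta = pd.read_csv(metadata_path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if data.shape[3] != len(meta):
        raise ValueError(
            f"4th-axis length ({data.shape[3]}) != metadata rows ({len(meta)})"
        )
    grid_shape = data.shape[:3]
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != grid_shape:
            raise ValueError("mask shape does not match data grid")
    else:
        mask = np.any(data != 0, axis=3)
    stack = VolumeStack(grid_shape=grid_shape, affine=img.affine, mask=mask)
    X = data.reshape(-1, data.shape[3], order="F").T.copy()
    off_mask = ~stack.mask.reshape(-1, order="F")
    X[:, off_mask] = 0.0
    return Cohort(X, meta, stack)


def write_map(
    weights: np.ndarray, stack: VolumeStack, path: str | Path
) -> Path:
    """Write a voxel weight vector as a 3D NIfTI map.

    ``weights`` may be in-mask length (scattered to the grid) or already
    full-grid length.  Out-of-mask voxels are written as zero.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == stack.n_in_mask:
        full = stack.scatter(weights)
    elif weights.size == stack.n_voxels:
        full = np.where(stack.mask.reshape(-1, order="F"), weights, 0.0)
    else:
        raise ValueError(
            f"weight length {weights.size} matches neither in-mask "
            f"({stack.n_in_mask}) nor grid ({stack.n_voxels}) size"
        )
    vol = stack.unflatten(full).astype(np.float32)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol, stack.affine), path)
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D map; returns (volume float64, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def load_parcellation(
    path: str | Path, names_path: str | Path | None = None
) -> ParcellationVolume:
    """Load an integer-labeled parcellation, optionally with a names TSV.

    The names table needs columns ``region_id`` and ``region_name``.
    """
    labels = np.rint(np.asarray(nib.load(str(path)).dataobj)).astype(int)
    names = None
    if names_path is not None:
        tbl = pd.read_csv(names_path, sep="\t")
        names = dict(
            zip(tbl["region_id"].astype(int), tbl["region_name"].astype(str))
        )
    return ParcellationVolume(labels=labels, region_names=names)
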