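"""Binary ROI mask I/O, validation, fusion, and the volumetry baseline.

Masks are NIfTI volumes (``.nii``/``.nii.gz``) carrying a voxel-to-world
affine. Downstream geometry is computed in world millimetres, so the affine
is preserved verbatim through every operation. Region fusion is the voxelwise
union of two co-registered masks ("Hippo-Amygdala" ROI): the two structures
are merged into a single ROI before surface extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

VALID_REGION_TAGS = ("hippocampus", "amygdala", "fused")

MANIFEST_COLUMNS = ("subject_id", "label", "path_hippocampus", "path_amygdala")


class MaskFormatError(ValueError):
    """File could not be read as a NIfTI volume."""


class EmptyMaskError(ValueError):
    """Mask has no foreground voxels."""


class GridMismatchError(ValueError):
    """Masks to be fused do not share a voxel grid / affine."""


@dataclass
class VoxelMask:
    """Binary occupancy grid with voxel-to-world affine (mm).

    Attributes
    ----------
    grid : (I, J, K) uint8 array of {0, 1}
    affine : (4, 4) float array, voxel index -> world mm
    subject_id : opaque subject identifier
    region_tag : one of {hippocampus, amygdala, fused}
    """

    grid: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    region_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got ndim={self.grid.ndim}")
        vals = np.unique(self.grid)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask grid must contain only 0 and 1")
        self.grid = self.grid.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        sp = self.spacing
        if not (np.isfinite(sp).all() and (sp > 0).all()):
            raise ValueError(f"voxel spacing must be positive and finite, got {sp}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge lengths (mm), column norms of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


def load_mask(
    path: str | Path,
    threshold: float = 0.5,
    label: int | None = None,
    keep_largest: bool = False,
    subject_id: str = "",
    region_tag: str = "",
) -> VoxelMask:
    """Load a NIfTI volume and binarize it.

    Parameters
    ----------
    threshold : binarization cut in (0, 1]; foreground is ``value >= threshold``.
        Segmentation tools may emit probabilistic maps; 0.5 is the conventional
        mid-level cut.
    label : if given, select voxels equal to this integer label first (for
        label-map inputs with one integer per structure), then binarize.
    keep_largest : restrict to the largest connected component. Segmentation
        specks can corrupt curvature statistics; off by default, with a logged
        warning when more than one component is present.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise MaskFormatError(f"cannot read {path} as a NIfTI volume: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if label is not None:
        grid = (data == label).astype(np.uint8)
    else:
        grid = (data >= threshold).astype(np.uint8)
    if grid.sum() == 0:
        raise EmptyMaskError(
            f"mask has no foreground voxels (subject={subject_id!r}, "
            f"region={region_tag!r}, file={path})"
        )
    ncomp = _component_count(grid)
    if ncomp > 1:
        if keep_largest:
            grid = _largest_component(grid)
        else:
            logger.warning(
                "mask %s (subject=%s region=%s) has %d connected components",
                path, subject_id, region_tag, ncomp,
            )
    return VoxelMask(grid=grid, affine=img.affine, subject_id=subject_id,
                     region_tag=region_tag)


def save_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as NIfTI; round-trips grid and affine bit-exactly."""
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def _component_count(grid: np.ndarray) -> int:
    _, n = ndimage.label(grid)
    return n


def _largest_component(grid: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(grid)
    if n <= 1:
        return grid
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


def fuse_regions(a: VoxelMask, b: VoxelMask, affine_atol: float = 1e-4) -> VoxelMask:
    """Voxelwise union of two masks in the same space ("region-level fusion").

    The two ROIs are added voxelwise and re-binarized, forming a single fused
    ROI that downstream surface extraction treats as one structure. Requires
    both masks to live on the same grid (registration is upstream of this
    tool), enforced via shape equality and affine agreement within
    ``affine_atol``.
    """
    if a.grid.shape != b.grid.shape:
        raise GridMismatchError(
            f"grid shapes differ: {a.grid.shape} vs {b.grid.shape}"
        )
    if not np.allclose(a.affine, b.affine, atol=affine_atol):
        raise GridMismatchError("affines differ beyond tolerance; masks must be "
                                "co-registered in the same space")
    fused = ((a.grid.astype(np.int16) + b.grid.astype(np.int16)) >= 1).astype(np.uint8)
    return VoxelMask(grid=fused, affine=a.affine, subject_id=a.subject_id,
                     region_tag="fused")


def mask_volume(m: VoxelMask) -> float:
    """Foreground volume in mm^3: voxel count x product of spacings."""
    return float(m.n_foreground * np.prod(m.spacing))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Columns: subject_id, label (NC/MCI/AD), path_hippocampus, path_amygdala.
    Relative mask paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    bad = set(df["label"]) - {"NC", "MCI", "AD"}
    if bad:
        raise ValueError(f"manifest has unknown labels: {sorted(bad)}")
    base = path.parent
    for col in ("path_hippocampus", "path_amygdala"):
        df[col] = [str(p) if Path(p).is_absolute() else str(base / p)
                   for p in df[col]]
    return df
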