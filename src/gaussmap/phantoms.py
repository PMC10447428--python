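"""Synthetic voxel phantoms: a desk-scale stand-in for segmented ROI masks.

Each subject carries two closed genus-0 shapes on a shared voxel grid: a
larger hippocampus-like ellipsoid and a smaller amygdala-like one, offset in
space. Disease class enters as a localized atrophy-like indentation - a
smooth spherical-cap dent whose depth grows NC (none) -> MCI (moderate) ->
AD (deep) - emulating the premise that focal curvature change, not global
volume, is the discriminative signal. A C2-smooth bump profile is used so
curvature stays well-defined at the dent rim (a hard boolean cut would
create curvature singularities that test the estimator unfairly, not the
science).

Per-subject nuisance variation: a random rigid orientation, a global scale
jitter (so volume alone separates classes only weakly), and low-amplitude
smooth radial noise. All randomness flows from the spec seed through
numpy's SeedSequence, so cohorts are bit-reproducible.

Default geometry (semi-axes, depths, jitter) is a frozen calibration of the
stated world: hippocampus-scale structures at 1 mm isotropic voxels, dent
depths chosen so the end-to-end pipeline separates classes through curvature
while the volume-only baseline stays mediocre.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mask_io import VoxelMask, save_mask

#: dent depth (mm) per diagnostic class, hippocampus-like region
CLASS_DEPTHS = {"NC": 0.0, "MCI": 2.6, "AD": 4.0}
#: the amygdala-like region dents proportionally less (smaller structure)
AMYGDALA_DEPTH_FACTOR = 0.6

HIPPO_SEMI_AXES = (14.0, 9.0, 7.0)
AMYG_SEMI_AXES = (8.0, 6.0, 5.0)
AMYG_OFFSET = (24.0, 0.0, 0.0)  # world-mm offset of the amygdala centre


@dataclass
class PhantomSpec:
    """Stated generative parameters for one phantom shape."""

    class_label: str = "NC"
    semi_axes: tuple = HIPPO_SEMI_AXES
    indent_depth: float | None = None  # None -> CLASS_DEPTHS[class_label]
    indent_width: float = 0.9          # angular half-width of the dent (rad)
    scale_jitter_sd: float = 0.012     # SD of log global scale
    noise_sd: float = 0.15             # radial surface noise SD (mm)
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_DEPTHS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.indent_depth is None:
            self.indent_depth = CLASS_DEPTHS[self.class_label]
        if min(self.semi_axes) <= 2 * max(self.spacing):
            raise ValueError("semi-axes must exceed twice the voxel spacing")
        if self.indent_depth >= min(self.semi_axes):
            raise ValueError("indentation depth must be smaller than the "
                             "smallest semi-axis")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _radial_noise_field(rng: np.random.Generator, n_modes: int = 5,
                        angular_freq: float = 3.0):
    """Smooth random function on the unit sphere, roughly unit variance."""
    dirs = rng.normal(size=(n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    amps = rng.normal(size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)

    def field(unit_dirs: np.ndarray) -> np.ndarray:
        proj = unit_dirs @ dirs.T  # (n, n_modes)
        return (amps * np.cos(angular_freq * proj + phases)).sum(axis=1) \
            / np.sqrt(n_modes)

    return field


def _render(spec: PhantomSpec, rng: np.random.Generator, grid_shape,
            affine, center_world) -> np.ndarray:
    """Rasterize one indented, jittered ellipsoid onto a voxel grid."""
    R = _random_rotation(rng)
    scale = float(np.exp(rng.normal(0.0, spec.scale_jitter_sd)))
    A = R @ np.diag(np.asarray(spec.semi_axes) * scale)
    Ainv = np.linalg.inv(A)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    noise = _radial_noise_field(rng)

    idx = np.indices(grid_shape).reshape(3, -1).T
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    w = (world - center_world) @ Ainv.T
    r = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        what = np.where(r[:, None] > 1e-12, w / np.maximum(r, 1e-12)[:, None], 0.0)
    # mm per unit of normalized radius along each direction
    dir_mm = np.linalg.norm(what @ A.T, axis=1)
    dir_mm = np.maximum(dir_mm, 1e-9)
    rho = np.ones(len(w))
    if spec.indent_depth > 0:
        ang = np.arccos(np.clip(what @ u, -1.0, 1.0))
        t = ang / spec.indent_width
        inside = t < 1.0
        bump = np.zeros(len(w))
        bump[inside] = (1.0 - t[inside] ** 2) ** 3  # C2-smooth cap profile
        rho -= (spec.indent_depth / dir_mm) * bump
    if spec.noise_sd > 0:
        rho += (spec.noise_sd / dir_mm) * noise(what)
    occ = (r <= rho).reshape(grid_shape)
    return occ.astype(np.uint8)


def make_phantom(spec: PhantomSpec, subject_id: str = "",
                 region_tag: str = "hippocampus") -> VoxelMask:
    """Voxelize one phantom on its own tight grid. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = max(spec.semi_axes) * 1.35 + 3 * spacing.max()
    shape = tuple(int(np.ceil(2 * extent / s)) | 1 for s in spacing)
    affine = np.diag([*spacing, 1.0])
    center = affine[:3, :3] @ ((np.array(shape) - 1) / 2.0)
    grid = _render(spec, rng, shape, affine, center)
    if grid.sum() == 0:
        raise ValueError("phantom spec produced no foreground at this "
                         "resolution; coarsen spacing or enlarge the shape")
    return VoxelMask(grid=grid, affine=affine, subject_id=subject_id,
                     region_tag=region_tag)


def make_subject_masks(class_label: str, seed: int,
                       spacing=(1.0, 1.0, 1.0),
                       scale_jitter_sd: float = 0.012,
                       noise_sd: float = 0.15,
                       subject_id: str = "") -> tuple[VoxelMask, VoxelMask]:
    """Hippocampus-like and amygdala-like phantoms on a shared grid.

    A common grid (and identical affine) is what region-level fusion
    requires; the two structures are spatially offset and disjoint.
    """
    spacing = np.asarray(spacing, dtype=float)
    depth = CLASS_DEPTHS[class_label]
    hip = PhantomSpec(class_label=class_label, semi_axes=HIPPO_SEMI_AXES,
                      indent_depth=depth, scale_jitter_sd=scale_jitter_sd,
                      noise_sd=noise_sd, spacing=tuple(spacing), seed=seed)
    amy = PhantomSpec(class_label=class_label, semi_axes=AMYG_SEMI_AXES,
                      indent_depth=depth * AMYGDALA_DEPTH_FACTOR,
                      scale_jitter_sd=scale_jitter_sd, noise_sd=noise_sd,
                      spacing=tuple(spacing), seed=seed)
    margin = 4.0
    lo = -(max(HIPPO_SEMI_AXES) * 1.3 + margin)
    hi = AMYG_OFFSET[0] + max(AMYG_SEMI_AXES) * 1.3 + margin
    half_yz = max(HIPPO_SEMI_AXES) * 1.3 + margin
    mins = np.array([lo, -half_yz, -half_yz])
    maxs = np.array([hi, half_yz, half_yz])
    shape = tuple(int(np.ceil((maxs[i] - mins[i]) / spacing[i])) + 1
                  for i in range(3))
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = mins
    rng_h = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng_a = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    grid_h = _render(hip, rng_h, shape, affine, np.zeros(3))
    grid_a = _render(amy, rng_a, shape, affine, np.asarray(AMYG_OFFSET))
    if grid_h.sum() == 0 or grid_a.sum() == 0:
        raise ValueError("phantom rendering produced an empty region")
    mh = VoxelMask(grid=grid_h, affine=affine, subject_id=subject_id,
                   region_tag="hippocampus")
    ma = VoxelMask(grid=grid_a, affine=affine, subject_id=subject_id,
                   region_tag="amygdala")
    return mh, ma


def make_cohort(outdir: str | Path, n_per_class: int = 20, seed: int = 0,
                spacing=(1.0, 1.0, 1.0), scale_jitter_sd: float = 0.012,
                noise_sd: float = 0.15) -> Path:
    """Write a full synthetic cohort (masks + manifest); returns manifest path.

    Produces ``n_per_class`` subjects for each of NC, MCI and AD, two NIfTI
    masks per subject, and a manifest CSV with relative paths - the exact
    format the real-data path consumes. Byte-reproducible for a fixed seed.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 subjects per class")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(3 * n_per_class) % (2 ** 31)
    rows = []
    i = 0
    for label in ("NC", "MCI", "AD"):
        for j in range(n_per_class):
            sid = f"{label}{j:03d}"
            mh, ma = make_subject_masks(
                label, int(subject_seeds[i]), spacing=spacing,
                scale_jitter_sd=scale_jitter_sd, noise_sd=noise_sd,
                subject_id=sid)
            ph = f"{sid}_hippocampus.nii.gz"
            pa = f"{sid}_amygdala.nii.gz"
            save_mask(mh, outdir / ph)
            save_mask(ma, outdir / pa)
            rows.append({"subject_id": sid, "label": label,
                         "path_hippocampus": ph, "path_amygdala": pa})
            i += 1
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
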