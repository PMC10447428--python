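"""Triangle surface extraction from voxel masks, smoothing, and mesh utilities.

The Gauss map sends each surface point p to its unit normal n(p) on the
sphere; everything downstream (the shape operator and its curvature
invariants) differentiates that map, so the mesh must be a clean, closed,
consistently outward-oriented triangulation in world millimetres.

Extraction is marching cubes on a lightly Gaussian-filtered occupancy grid:
curvature is a second-derivative quantity and raw marching cubes on binary
data produces +/-45 degree staircase facets that dominate the estimate.
Default smoothing is Taubin's lambda/mu flow, which (unlike plain Laplacian
averaging) does not shrink the shape appreciably - important because the
descriptors are curvature magnitudes with units 1/mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from skimage import measure


class DegenerateSurfaceError(ValueError):
    """Foreground too small / too thin to enclose an isosurface."""


@dataclass
class TriangleMesh:
    """Closed oriented triangle surface in world (mm) coordinates.

    vertices : (n, 3) float array
    faces : (m, 3) int array, consistent outward (counter-clockwise) winding
    vertex_normals : (n, 3) unit outward normals, the Gauss-map image points
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


# ---------------------------------------------------------------------------
# extraction

def extract_surface(mask, level: float = 0.5, presmooth_sigma: float = 1.0,
                    smooth_iterations: int = 20,
                    smooth_method: str = "taubin") -> TriangleMesh:
    """Extract a closed outward-oriented isosurface from a VoxelMask.

    The occupancy grid is zero-padded (so the isosurface closes), filtered
    with a Gaussian of ``presmooth_sigma`` voxels, and triangulated by
    marching cubes at ``level``. Vertices are mapped to world mm by the
    mask affine; winding is fixed so the enclosed signed volume is positive
    (normals point away from the foreground). Smoothing is applied unless
    ``smooth_method='none'`` or ``smooth_iterations=0``.
    """
    if not 0 < level < 1:
        raise ValueError(f"isosurface level must be in (0,1), got {level}")
    if mask.n_foreground < 1:
        raise DegenerateSurfaceError("mask has no foreground voxels")
    pad = max(2, int(np.ceil(3 * presmooth_sigma)))
    grid = np.pad(mask.grid.astype(float), pad)
    if presmooth_sigma > 0:
        grid = ndimage.gaussian_filter(grid, presmooth_sigma)
    if grid.max() <= level:
        raise DegenerateSurfaceError(
            f"foreground too small: filtered occupancy peaks at {grid.max():.3f}"
            f" <= level {level} (subject={mask.subject_id!r},"
            f" region={mask.region_tag!r})"
        )
    verts, faces, _, _ = measure.marching_cubes(grid, level=level)
    verts = verts - pad  # back to unpadded voxel index coordinates
    verts = verts @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    mesh = TriangleMesh(vertices=verts, faces=faces)
    if mesh_volume(mesh) < 0:  # affine may be mirror-image (det < 0)
        mesh.faces = mesh.faces[:, ::-1]
    if smooth_method != "none" and smooth_iterations > 0:
        mesh = smooth_mesh(mesh, iterations=smooth_iterations, method=smooth_method)
    compute_vertex_normals(mesh)
    return mesh


# ---------------------------------------------------------------------------
# smoothing

def _uniform_laplacian(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Umbrella operator L with L @ V = mean(neighbours) - vertex."""
    n = mesh.n_vertices
    f = mesh.faces
    e0 = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    e1 = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    A = sparse.csr_matrix((np.ones_like(e0, dtype=float), (e0, e1)), shape=(n, n))
    A.data[:] = 1.0  # collapse duplicate edge entries
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    D = sparse.diags(1.0 / deg)
    return (D @ A - sparse.identity(n)).tocsr()


def smooth_mesh(mesh: TriangleMesh, iterations: int = 20,
                method: str = "taubin", lam: float = 0.5,
                mu: float = -0.53) -> TriangleMesh:
    """Smooth vertex positions; topology (V, E, F) is untouched.

    ``taubin`` alternates a shrink step (lambda) with an inflate step (mu),
    keeping enclosed volume nearly constant; ``laplacian`` uses the shrink
    step only; ``none`` returns a copy.
    """
    if method not in ("taubin", "laplacian", "none"):
        raise ValueError(f"unknown smoothing method {method!r}")
    V = mesh.vertices.copy()
    if method != "none" and iterations > 0:
        L = _uniform_laplacian(mesh)
        for _ in range(iterations):
            V = V + lam * (L @ V)
            if method == "taubin":
                V = V + mu * (L @ V)
    out = TriangleMesh(vertices=V, faces=mesh.faces.copy())
    compute_vertex_normals(out)
    return out


# ---------------------------------------------------------------------------
# normals and elementary integrals

def face_normals_areas(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    v = mesh.vertices
    f = mesh.faces
    cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    a2 = np.linalg.norm(cr, axis=1)
    areas = 0.5 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cr / a2[:, None]
    normals[a2 == 0] = 0.0
    return normals, areas


def compute_vertex_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Area-weighted average of incident face normals, unit length, in place."""
    fn, fa = face_normals_areas(mesh)
    acc = np.zeros_like(mesh.vertices)
    w = fn * fa[:, None]
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], w)
    norms = np.linalg.norm(acc, axis=1)
    if (norms == 0).any():
        bad = int((norms == 0).sum())
        raise DegenerateSurfaceError(
            f"{bad} vertices have only zero-area incident faces")
    mesh.vertex_normals = acc / norms[:, None]
    return mesh


def mesh_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume by the divergence theorem (positive = outward)."""
    v = mesh.vertices
    f = mesh.faces
    return float(np.einsum("ij,ij->i", v[f[:, 0]],
                           np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


def mesh_area(mesh: TriangleMesh) -> float:
    return float(face_normals_areas(mesh)[1].sum())


# ---------------------------------------------------------------------------
# topology checks

def _edges(mesh: TriangleMesh) -> np.ndarray:
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    return np.sort(e, axis=1)


def euler_characteristic(mesh: TriangleMesh) -> int:
    """V - E + F; 2 per genus-0 closed component, 0 for a torus."""
    e = np.unique(_edges(mesh), axis=0)
    return mesh.n_vertices - len(e) + mesh.n_faces


def is_watertight(mesh: TriangleMesh) -> bool:
    """True when every edge is shared by exactly two faces."""
    _, counts = np.unique(_edges(mesh), axis=0, return_counts=True)
    return bool((counts == 2).all())


# ---------------------------------------------------------------------------
# PLY / OBJ I/O (ASCII) for inspection in external viewers

def save_ply(mesh: TriangleMesh, path: str | Path,
             vertex_scalars: dict[str, np.ndarray] | None = None) -> None:
    """Write ASCII PLY, optionally with named per-vertex scalar properties."""
    scalars = vertex_scalars or {}
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        for name in scalars:
            fh.write(f"property float {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        cols = [mesh.vertices] + [np.asarray(s, dtype=float)[:, None]
                                  for s in scalars.values()]
        for row in np.hstack(cols):
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        for tri in mesh.faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def load_ply(path: str | Path) -> TriangleMesh:
    """Read ASCII PLY written by :func:`save_ply` (xyz + faces only)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    nv = nf = 0
    header_end = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            nv = int(ln.split()[-1])
        elif ln.startswith("element face"):
            nf = int(ln.split()[-1])
        elif ln == "end_header":
            header_end = i + 1
            break
    verts = np.array([[float(x) for x in ln.split()[:3]]
                      for ln in lines[header_end:header_end + nv]])
    faces = np.array([[int(x) for x in ln.split()[1:4]]
                      for ln in lines[header_end + nv:header_end + nv + nf]])
    mesh = TriangleMesh(vertices=verts, faces=faces)
    compute_vertex_normals(mesh)
    return mesh


def save_obj(mesh: TriangleMesh, path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for tri in mesh.faces + 1:  # OBJ is 1-indexed
            fh.write(f"f {tri[0]} {tri[1]} {tri[2]}\n")
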