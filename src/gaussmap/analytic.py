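"""Analytic triangulated surfaces with known curvature.

These are the ground-truth fixtures for the curvature stack: a sphere has
kappa1 = kappa2 = 1/r everywhere, a cylinder's lateral wall has {1/r, 0},
a plane is flat, a torus integrates Gaussian curvature to zero, and an
ellipsoid exercises anisotropy while Gauss-Bonnet still demands 4*pi.
"""

from __future__ import annotations

import numpy as np

from .surface import TriangleMesh, compute_vertex_normals, mesh_volume


def _dedup(verts: np.ndarray, faces: np.ndarray, decimals: int = 9):
    key = np.round(verts, decimals)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return verts[idx], inv[faces]


def icosphere(radius: float = 1.0, subdivisions: int = 3,
              center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Subdivided icosahedron projected to the sphere of given radius."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    for _ in range(subdivisions):
        a, b, c = f[:, 0], f[:, 1], f[:, 2]
        mab = v[a] + v[b]
        mbc = v[b] + v[c]
        mca = v[c] + v[a]
        new = np.vstack([mab, mbc, mca])
        new /= np.linalg.norm(new, axis=1)[:, None]
        base = len(v)
        iab = base + np.arange(len(f))
        ibc = iab + len(f)
        ica = ibc + len(f)
        v = np.vstack([v, new])
        f = np.vstack([
            np.column_stack([a, iab, ica]),
            np.column_stack([iab, b, ibc]),
            np.column_stack([ica, ibc, c]),
            np.column_stack([iab, ibc, ica]),
        ])
        v, f = _dedup(v, f)
    verts = v * radius + np.asarray(center, dtype=float)
    mesh = TriangleMesh(vertices=verts, faces=f)
    if mesh_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    compute_vertex_normals(mesh)
    return mesh


def ellipsoid(semi_axes=(20.0, 15.0, 10.0), subdivisions: int = 4,
              center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned ellipsoid as a scaled icosphere."""
    sph = icosphere(1.0, subdivisions)
    verts = sph.vertices * np.asarray(semi_axes, dtype=float) + np.asarray(center)
    mesh = TriangleMesh(vertices=verts, faces=sph.faces)
    compute_vertex_normals(mesh)
    return mesh


def cylinder(radius: float = 2.0, height: float = 10.0, n_theta: int = 64,
             n_z: int = 32) -> TriangleMesh:
    """Closed (capped) cylinder about the z axis, centred at the origin.

    Lateral-wall vertices (away from the rims) have principal curvatures
    1/radius and 0.
    """
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2, height / 2, n_z + 1)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    lateral = np.column_stack([
        radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()])
    faces = []
    def lid(i, j):  # lateral index
        return i * (n_z + 1) + j
    for i in range(n_theta):
        i2 = (i + 1) % n_theta
        for j in range(n_z):
            faces.append([lid(i, j), lid(i2, j), lid(i2, j + 1)])
            faces.append([lid(i, j), lid(i2, j + 1), lid(i, j + 1)])
    verts = [lateral]
    top = len(lateral)
    bot = top + 1
    verts.append(np.array([[0, 0, height / 2], [0, 0, -height / 2]]))
    for i in range(n_theta):
        i2 = (i + 1) % n_theta
        faces.append([lid(i, n_z), lid(i2, n_z), top])
        faces.append([lid(i2, 0), lid(i, 0), bot])
    mesh = TriangleMesh(vertices=np.vstack(verts), faces=np.array(faces))
    if mesh_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    compute_vertex_normals(mesh)
    return mesh


def torus(major_radius: float = 10.0, minor_radius: float = 3.0,
          n_major: int = 64, n_minor: int = 32) -> TriangleMesh:
    """Ring torus; genus 1, so total Gaussian curvature is zero."""
    u = np.linspace(0, 2 * np.pi, n_major, endpoint=False)
    v = np.linspace(0, 2 * np.pi, n_minor, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (major_radius + minor_radius * np.cos(vv)) * np.cos(uu)
    y = (major_radius + minor_radius * np.cos(vv)) * np.sin(uu)
    z = minor_radius * np.sin(vv)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    faces = []
    for i in range(n_major):
        i2 = (i + 1) % n_major
        for j in range(n_minor):
            j2 = (j + 1) % n_minor
            a = i * n_minor + j
            b = i2 * n_minor + j
            c = i2 * n_minor + j2
            d = i * n_minor + j2
            faces.append([a, b, c])
            faces.append([a, c, d])
    mesh = TriangleMesh(vertices=verts, faces=np.array(faces))
    if mesh_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    compute_vertex_normals(mesh)
    return mesh


def plane_patch(n: int = 15, spacing: float = 1.0) -> TriangleMesh:
    """Flat triangulated square in z=0, normals +z; open (boundary) mesh."""
    g = np.arange(n) * spacing
    xx, yy = np.meshgrid(g, g, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            c = (i + 1) * n + j + 1
            d = i * n + j + 1
            faces.append([a, b, c])
            faces.append([a, c, d])
    mesh = TriangleMesh(vertices=verts, faces=np.array(faces))
    compute_vertex_normals(mesh)
    return mesh


def interior_vertex_mask(mesh: TriangleMesh) -> np.ndarray:
    """Vertices not touching a boundary edge (edge with < 2 incident faces)."""
    f = mesh.faces
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    boundary_verts = np.unique(uniq[counts != 2])
    mask = np.ones(mesh.n_vertices, dtype=bool)
    mask[boundary_verts] = False
    return mask
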