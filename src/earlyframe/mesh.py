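"""Triangulated meshes with per-vertex geometry and named patches.

The cohort mesh is a pair of icospheres (one per hemisphere) carved into
latitude/longitude parcels, with dedicated patches for reference regions,
a disease-vulnerable zone and a medial wall that is excluded from all
vertex statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "Mesh",
    "icosphere",
    "triangle_grid",
    "build_cohort_mesh",
    "erode_patch",
]


@dataclass
class Mesh:
    """Shared triangulated surface carrying all per-vertex geometry.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Triangle indices into ``vertices``.
    normals : (n, 3) float array
        Unit outward normal per vertex.
    thickness : (n,) float array
        Cortical thickness in mm per vertex.
    patches : dict of str -> (n,) bool array
        Named vertex patches (parcels, reference regions, ``vulnerable``,
        ``medial_wall``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    thickness: np.ndarray
    patches: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise ValueError("negative triangle index")
        self._areas: np.ndarray | None = None
        self._adjacency: csr_matrix | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (mm²); each triangle contributes one
        third of its area to each of its corners."""
        if self._areas is None:
            tri = self.vertices[self.faces]
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            tri_area = 0.5 * np.linalg.norm(cross, axis=1)
            areas = np.zeros(self.n_vertices)
            np.add.at(areas, self.faces.ravel(), np.repeat(tri_area / 3.0, 3))
            self._areas = areas
        return self._areas

    @property
    def total_area(self) -> float:
        return float(self.vertex_areas.sum())

    @property
    def adjacency(self) -> csr_matrix:
        """Sparse symmetric vertex adjacency from the triangle edges."""
        if self._adjacency is None:
            f = self.faces
            i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
            j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
            n = self.n_vertices
            a = coo_matrix(
                (np.ones(2 * len(i)), (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(n, n),
            ).tocsr()
            a.data[:] = 1.0
            self._adjacency = a
        return self._adjacency

    def edge_lengths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique undirected edges (i, j, length)."""
        a = self.adjacency.tocoo()
        keep = a.row < a.col
        i, j = a.row[keep], a.col[keep]
        d = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
        return i, j, d

    def patch_mask(self, name: str) -> np.ndarray:
        if name not in self.patches:
            raise KeyError(f"unknown patch {name!r}; have {sorted(self.patches)}")
        return self.patches[name]

    @property
    def included(self) -> np.ndarray:
        """Vertices entering any statistic: everything outside the medial wall."""
        mask = np.ones(self.n_vertices, dtype=bool)
        if "medial_wall" in self.patches:
            mask &= ~self.patches["medial_wall"]
        return mask

    def parcel_names(self) -> list[str]:
        return sorted(p for p in self.patches if "parcel_" in p)

    def validate(self) -> None:
        areas = self.vertex_areas
        if np.any(areas <= 0):
            raise ValueError("vertex areas must be strictly positive")
        for name, mask in self.patches.items():
            if mask.shape != (self.n_vertices,):
                raise ValueError(f"patch {name!r} has wrong shape")


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.intp,
    )
    return v, f


def icosphere(subdivisions: int = 4, radius: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere scaled to ``radius``; subdivision 4 has 2562 vertices."""
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m /= np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.intp)
    return verts * radius, faces


def triangle_grid(nx: int, ny: int, spacing: float = 1.0) -> Mesh:
    """Flat regular triangular lattice, used to validate smoothing kernels."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing * np.sqrt(3) / 2
    xv, yv = np.meshgrid(xs, ys)
    xv = xv + (np.arange(ny)[:, None] % 2) * spacing / 2
    verts = np.column_stack([xv.ravel(), yv.ravel(), np.zeros(nx * ny)])
    faces = []
    for r in range(ny - 1):
        for c in range(nx - 1):
            a = r * nx + c
            b = a + 1
            cc = a + nx
            d = cc + 1
            if r % 2 == 0:
                faces += [[a, b, cc], [b, d, cc]]
            else:
                faces += [[a, b, d], [a, d, cc]]
    faces = np.array(faces, dtype=np.intp)
    normals = np.tile([0.0, 0.0, 1.0], (len(verts), 1))
    thickness = np.full(len(verts), 2.5)
    return Mesh(verts, faces, normals, thickness, {})


def _latlon_parcels(unit_xyz: np.ndarray, prefix: str) -> dict[str, np.ndarray]:
    """34 parcels per hemisphere: 2 polar caps + 4 latitude rows x 8 sectors."""
    z = np.clip(unit_xyz[:, 2], -1.0, 1.0)
    lat = np.arccos(z)  # 0 at north pole .. pi at south
    lon = np.mod(np.arctan2(unit_xyz[:, 1], unit_xyz[:, 0]), 2 * np.pi)
    # 6 latitude rows with equal angular height
    row = np.minimum((lat / np.pi * 6).astype(int), 5)
    sector = np.minimum((lon / (2 * np.pi) * 8).astype(int), 7)
    parcels: dict[str, np.ndarray] = {}
    idx = 0
    parcels[f"{prefix}parcel_{idx:02d}"] = row == 0
    idx += 1
    for r in range(1, 5):
        for s in range(8):
            parcels[f"{prefix}parcel_{idx:02d}"] = (row == r) & (sector == s)
            idx += 1
    parcels[f"{prefix}parcel_{idx:02d}"] = row == 5
    return parcels


def build_cohort_mesh(subdivisions: int = 4, radius: float = 50.0,
                      hemisphere_gap: float = 4.0) -> Mesh:
    """Two-hemisphere icosphere mesh with parcels and analysis patches.

    Patches:

    - ``lh_parcel_00`` .. ``rh_parcel_33``: 68 parcels (34 per hemisphere).
    - ``medial_wall``: the cap of each sphere facing the midline; excluded
      from all vertex statistics.
    - ``vulnerable``: temporo-parietal stand-in where disease effects live.
    - ``pons``, ``cerebellum``, ``cerebellar_GM``, ``cerebral_WM``: small
      inferior patches standing in for reference regions.
    """
    v1, f1 = icosphere(subdivisions, radius)
    nv = len(v1)
    offset = np.array([radius + hemisphere_gap / 2.0, 0.0, 0.0])
    verts = np.vstack([v1 - offset, v1 + offset])
    faces = np.vstack([f1, f1 + nv])
    unit = np.vstack([v1 / radius, v1 / radius])
    normals = np.vstack([v1 / radius, v1 / radius])
    # mild sinusoidal thickness variation around 2.5 mm
    thickness = 2.5 + 0.3 * np.sin(3 * unit[:, 2]) * np.cos(2 * unit[:, 1])

    patches: dict[str, np.ndarray] = {}
    lh = _latlon_parcels(unit[:nv], "lh_")
    rh = _latlon_parcels(unit[nv:], "rh_")
    for name, m in lh.items():
        patches[name] = np.concatenate([m, np.zeros(nv, bool)])
    for name, m in rh.items():
        patches[name] = np.concatenate([np.zeros(nv, bool), m])

    # medial wall: cap facing the other hemisphere (lh faces +x, rh faces -x)
    med = np.zeros(2 * nv, bool)
    med[:nv] = unit[:nv, 0] > 0.93
    med[nv:] = unit[nv:, 0] < -0.93
    patches["medial_wall"] = med

    # vulnerable: mid-latitude posterior band on both hemispheres
    z, y = unit[:, 2], unit[:, 1]
    vuln = (np.abs(z) < 0.6) & (y < 0.45) & ~med
    patches["vulnerable"] = vuln

    # reference-region stand-ins near the south pole, disjoint by longitude;
    # pons gets the largest patch (stablest reference mean), cerebral WM the
    # smallest (noisiest)
    lon = np.mod(np.arctan2(unit[:, 1], unit[:, 0]), 2 * np.pi)
    south = (z < -0.78) & ~med
    patches["pons"] = south & (lon < np.pi)
    patches["cerebellum"] = south & (lon >= np.pi) & (lon < 1.75 * np.pi)
    # cerebellar GM = inner (deeper) part of the cerebellum patch
    patches["cerebellar_GM"] = patches["cerebellum"] & (z < -0.85)
    patches["cerebral_WM"] = south & (lon >= 1.75 * np.pi)

    mesh = Mesh(verts, faces, normals, thickness, patches)
    mesh.validate()
    return mesh


def erode_patch(mesh: Mesh, mask: np.ndarray, radius_mm: float) -> np.ndarray:
    """Geodesic erosion: drop patch vertices within ``radius_mm`` of any
    vertex outside the patch, measured along mesh edges."""
    if radius_mm <= 0:
        return mask.copy()
    mask = np.asarray(mask, bool)
    outside = np.flatnonzero(~mask)
    if outside.size == 0 or mask.sum() == 0:
        return mask.copy()
    i, j, d = mesh.edge_lengths()
    n = mesh.n_vertices
    w = coo_matrix(
        (np.concatenate([d, d]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    dist = dijkstra(w, directed=False, indices=outside, min_only=True,
                    limit=radius_mm * 1.001)
    eroded = mask & ~(dist <= radius_mm)
    return eroded
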