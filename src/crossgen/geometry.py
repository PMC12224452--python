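"""Source-space geometry.

Builds the icosahedral source meshes that stand in for a per-hemisphere
cortical source space, assigns named regions, derives the left-lateralized
"language mask" used by the decoding analyses, computes searchlight
neighborhoods (k nearest sources, center included), and constructs the
spatiotemporal adjacency graph over (source, timepoint) nodes that cluster
inference runs on.

A level-k icosphere has ``10 * 4**k + 2`` vertices; level 4 gives the 2562
sources-per-hemisphere convention of standard MEG source spaces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "SourceMesh",
    "LanguageMask",
    "Neighborhoods",
    "ConfigurationError",
    "build_icosphere",
    "assign_regions",
    "default_region_spec",
    "make_language_mask",
    "searchlight_neighborhoods",
    "spatiotemporal_adjacency",
    "mesh_to_json",
    "mesh_from_json",
    "DEFAULT_REGIONS",
]

#: Region names used by the default six-cap partition, after the regions of
#: the left-hemisphere language mask: anterior temporal lobe, middle temporal
#: gyrus, inferior frontal gyrus, ventromedial prefrontal cortex, angular
#: gyrus, supramarginal gyrus.
DEFAULT_REGIONS = ("LATL", "LMTG", "LIFG", "LvmPFC", "LAG", "LSMG")

OUTSIDE_MASK = "outside_mask"


class ConfigurationError(ValueError):
    """Raised for inconsistent region / mask / effect configuration."""


@dataclass(frozen=True)
class SourceMesh:
    """Triangulated unit-sphere mesh of source points.

    Parameters
    ----------
    coords : (V, 3) float array of unit vectors.
    edges : (E, 2) int array, each row ``(i, j)`` with ``i < j``, sorted
        lexicographically; the undirected edge relation.
    level : subdivision level the mesh was built at.
    region_labels : per-vertex region tag; ``"outside_mask"`` when unset.
    hemisphere : per-vertex hemisphere tag (a single synthetic hemisphere
        by default).
    """

    coords: np.ndarray
    edges: np.ndarray
    level: int
    region_labels: tuple[str, ...] = ()
    hemisphere: tuple[str, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        edges = np.asarray(self.edges, dtype=np.int64)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "edges", edges)
        if not self.region_labels:
            object.__setattr__(
                self, "region_labels", (OUTSIDE_MASK,) * len(coords)
            )
        if not self.hemisphere:
            object.__setattr__(self, "hemisphere", ("lh",) * len(coords))

    @property
    def n_vertices(self) -> int:
        return len(self.coords)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency as a CSR matrix."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i), dtype=bool)
        mat = sp.coo_matrix(
            (data, (np.r_[i, j], np.r_[j, i])),
            shape=(self.n_vertices, self.n_vertices),
        )
        return mat.tocsr()

    def neighbors(self, vertex: int) -> np.ndarray:
        """Sorted array of vertices sharing an edge with ``vertex``."""
        adj = self.adjacency()
        return adj.indices[adj.indptr[vertex] : adj.indptr[vertex + 1]]

    def region_vertices(self, name: str) -> np.ndarray:
        labels = np.asarray(self.region_labels)
        return np.flatnonzero(labels == name)


@dataclass(frozen=True)
class LanguageMask:
    """Ordered (ascending) vertex indices included in the analysis mask."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.int64)
        if v.size == 0:
            raise ConfigurationError("language mask is empty")
        if not np.all(np.diff(v) > 0):
            raise ConfigurationError("mask vertices must be strictly ascending")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class Neighborhoods:
    """Searchlight membership: for each masked vertex, its k member vertices.

    ``members[c]`` lists mesh vertex indices, the center first, then by
    ascending chord distance with ties broken by ascending vertex index.
    """

    centers: np.ndarray
    members: np.ndarray
    k: int
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.centers)


# ---------------------------------------------------------------------------
# icosphere construction


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def build_icosphere(level: int) -> SourceMesh:
    """Icosphere by recursive edge-midpoint subdivision of an icosahedron.

    Each subdivision splits every triangle into four by the midpoints of its
    edges, projected to the unit sphere. Midpoints are deduplicated by first
    occurrence, which fixes a deterministic vertex ordering.

    Parameters
    ----------
    level : subdivision level; ``10 * 4**level + 2`` vertices. Must be in
        ``[0, 6]`` (the cap guards against runaway memory use).
    """
    if level < 0:
        raise ValueError(f"subdivision level must be >= 0, got {level}")
    if level > 6:
        raise ValueError(f"subdivision level must be <= 6, got {level}")
    verts, faces = _icosahedron()
    verts = list(verts)
    for _ in range(level):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = midpoint.get(key)
            if idx is None:
                p = verts[a] + verts[b]
                p = p / np.linalg.norm(p)
                verts.append(p)
                idx = len(verts) - 1
                midpoint[key] = idx
            return idx

        new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
        for f, (a, b, c) in enumerate(faces):
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces[4 * f : 4 * f + 4] = [
                [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
            ]
        faces = new_faces
    edge_set = set()
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (c, a)):
            edge_set.add((u, v) if u < v else (v, u))
    edges = np.array(sorted(edge_set), dtype=np.int64)
    return SourceMesh(coords=np.asarray(verts), edges=edges, level=level)


# ---------------------------------------------------------------------------
# regions and masks


def assign_regions(mesh: SourceMesh, region_spec: dict) -> SourceMesh:
    """Label mesh vertices by region.

    ``region_spec`` maps region name to either an explicit index sequence or
    a predicate ``f(coords) -> bool array``. Regions must be disjoint;
    uncovered vertices are labeled ``"outside_mask"``.
    """
    labels = np.array([OUTSIDE_MASK] * mesh.n_vertices, dtype=object)
    claimed = np.zeros(mesh.n_vertices, dtype=bool)
    for name, spec_item in region_spec.items():
        if callable(spec_item):
            sel = np.asarray(spec_item(mesh.coords), dtype=bool)
            idx = np.flatnonzero(sel)
        else:
            idx = np.asarray(list(spec_item), dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_vertices):
                raise ConfigurationError(
                    f"region {name!r} lists vertices outside the mesh"
                )
        if np.any(claimed[idx]):
            overlap = np.flatnonzero(claimed[idx])
            raise ConfigurationError(
                f"region {name!r} overlaps an earlier region at "
                f"{idx[overlap][:5].tolist()}"
            )
        claimed[idx] = True
        labels[idx] = name
    return replace(mesh, region_labels=tuple(labels))


def default_region_spec(mesh: SourceMesh, names: tuple[str, ...] = DEFAULT_REGIONS) -> dict:
    """Partition the mesh into contiguous spherical caps, one per name.

    Seeds are chosen by deterministic farthest-point sampling from vertex 0;
    every vertex joins the cap of its nearest seed (ties to the lower seed
    index), giving a full disjoint cover to play the role of anatomical
    labels.
    """
    coords = mesh.coords
    seeds = [0]
    d = np.linalg.norm(coords - coords[0], axis=1)
    for _ in range(len(names) - 1):
        seeds.append(int(np.argmax(d)))
        d = np.minimum(d, np.linalg.norm(coords - coords[seeds[-1]], axis=1))
    seed_coords = coords[seeds]
    dist = cdist(coords, seed_coords)
    owner = np.argmin(dist, axis=1)
    return {name: np.flatnonzero(owner == i) for i, name in enumerate(names)}


def make_language_mask(mesh: SourceMesh, region_names: list[str]) -> LanguageMask:
    """Union of the named regions' vertices, in ascending index order."""
    labels = set(mesh.region_labels)
    sel: set[int] = set()
    for name in region_names:
        if name not in labels:
            raise ConfigurationError(
                f"unknown region {name!r}; mesh has {sorted(labels)}"
            )
        sel.update(mesh.region_vertices(name).tolist())
    if not sel:
        raise ConfigurationError(f"regions {region_names} cover no vertices")
    return LanguageMask(vertices=np.array(sorted(sel), dtype=np.int64))


# ---------------------------------------------------------------------------
# searchlights and adjacency


def searchlight_neighborhoods(
    mesh: SourceMesh, mask: LanguageMask, k: int = 20
) -> Neighborhoods:
    """k-nearest-source searchlights within the mask.

    "Radius of 20 sources" is read as a 20-member set: the center plus its
    19 nearest masked neighbors by Euclidean chord distance on the sphere
    (chord distance is monotone in geodesic distance, so the ordering is the
    same). Ties break by ascending vertex index.
    """
    if k < 1:
        raise ValueError(f"searchlight size k must be >= 1, got {k}")
    warn_records: list[str] = []
    n = len(mask)
    if k > n:
        warn_records.append(
            f"k={k} exceeds mask size {n}; neighborhoods truncated to {n}"
        )
        k = n
    pts = mesh.coords[mask.vertices]
    dist = cdist(pts, pts)
    members = np.empty((n, k), dtype=np.int64)
    for c in range(n):
        order = np.lexsort((mask.vertices, dist[c]))
        members[c] = mask.vertices[order[:k]]
    return Neighborhoods(
        centers=mask.vertices.copy(),
        members=members,
        k=k,
        warnings=tuple(warn_records),
    )


def spatiotemporal_adjacency(
    mesh: SourceMesh, mask: LanguageMask, n_times: int
) -> sp.csr_matrix:
    """Adjacency over (masked source, timepoint) nodes for cluster inference.

    Node ``(v, t)`` is adjacent to ``(w, t)`` when ``{v, w}`` is a mesh edge
    inside the mask, and to ``(v, t-1)`` / ``(v, t+1)``. Node index is
    ``source_position * n_times + t`` with source positions in mask order.
    """
    if n_times < 1:
        raise ValueError(f"n_times must be >= 1, got {n_times}")
    pos = {int(v): i for i, v in enumerate(mask.vertices)}
    n_src = len(mask)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    in_mask = np.isin(mesh.edges, mask.vertices).all(axis=1)
    masked_edges = mesh.edges[in_mask]
    if len(masked_edges):
        ei = np.array([pos[int(a)] for a in masked_edges[:, 0]])
        ej = np.array([pos[int(b)] for b in masked_edges[:, 1]])
        for t in range(n_times):
            rows.append(ei * n_times + t)
            cols.append(ej * n_times + t)
    if n_times > 1:
        src = np.arange(n_src)
        for t in range(n_times - 1):
            rows.append(src * n_times + t)
            cols.append(src * n_times + t + 1)
    n_nodes = n_src * n_times
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    data = np.ones(2 * len(r), dtype=bool)
    mat = sp.coo_matrix((data, (np.r_[r, c], np.r_[c, r])), shape=(n_nodes, n_nodes))
    return mat.tocsr()


# ---------------------------------------------------------------------------
# serialization


def mesh_to_json(mesh: SourceMesh) -> str:
    regions: dict[str, list[int]] = {}
    labels = np.asarray(mesh.region_labels)
    for name in sorted(set(mesh.region_labels)):
        regions[name] = np.flatnonzero(labels == name).tolist()
    return json.dumps(
        {
            "level": mesh.level,
            "coords": np.round(mesh.coords, 12).tolist(),
            "edges": mesh.edges.tolist(),
            "regions": regions,
        }
    )


def mesh_from_json(text: str) -> SourceMesh:
    obj = json.loads(text)
    coords = np.asarray(obj["coords"], dtype=float)
    labels = np.array([OUTSIDE_MASK] * len(coords), dtype=object)
    for name, idx in obj["regions"].items():
        labels[np.asarray(idx, dtype=int)] = name
    return SourceMesh(
        coords=coords,
        edges=np.asarray(obj["edges"], dtype=np.int64),
        level=int(obj["level"]),
        region_labels=tuple(labels),
    )
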