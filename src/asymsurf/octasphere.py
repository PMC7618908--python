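"""Octasphere construction: recursively subdivided octahedron meshes.

The octahedron is invariant under x -> -x, and midpoint subdivision followed
by projection to the sphere commutes with that reflection bitwise, so every
subdivision level carries an *exact* mirror vertex permutation.  Vertex
ordering is nested: the vertices of level l are the first 4*4^l + 2 vertices
of level l+1, which the coarse-to-fine registration relies on.
"""

from __future__ import annotations

import numpy as np

from asymsurf.mesh_core import SphericalMesh

__all__ = [
    "make_octasphere",
    "octasphere_vertex_count",
    "octasphere_level",
    "octasphere_parents",
    "MAX_LEVEL",
]

MAX_LEVEL = 7

_OCTA_VERTS = np.array(
    [
        [1.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.0, -1.0],
    ]
)

# outward winding (counter-clockwise seen from outside)
_OCTA_TRIS = np.array(
    [
        [0, 2, 4],
        [2, 1, 4],
        [1, 3, 4],
        [3, 0, 4],
        [2, 0, 5],
        [1, 2, 5],
        [3, 1, 5],
        [0, 3, 5],
    ]
)


def octasphere_vertex_count(level: int) -> int:
    return 4 * 4**level + 2


def make_octasphere(level: int) -> SphericalMesh:
    """Build the level-``level`` octasphere with its mirror permutation.

    V = 4*4^level + 2; level 0 is the octahedron itself.
    """
    if level < 0:
        raise ValueError("level must be nonnegative")
    if level > MAX_LEVEL:
        raise ValueError(f"level {level} exceeds the size guard ({MAX_LEVEL})")

    verts = [v for v in _OCTA_VERTS]
    tris = _OCTA_TRIS.copy()
    for _ in range(level):
        tris = _subdivide(verts, tris)
    vertices = np.asarray(verts, dtype=np.float64)
    mesh = SphericalMesh(vertices, np.asarray(tris, dtype=np.int64))
    mesh.mirror_perm = _mirror_perm(vertices)
    mesh.validate()
    return mesh


def _subdivide(verts: list[np.ndarray], tris: np.ndarray) -> np.ndarray:
    midpoint: dict[tuple[int, int], int] = {}

    def mid(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        k = midpoint.get(key)
        if k is None:
            m = verts[i] + verts[j]
            m = m / np.sqrt(m @ m)
            k = len(verts)
            verts.append(m)
            midpoint[key] = k
        return k

    out = np.empty((4 * len(tris), 3), dtype=np.int64)
    for f, (a, b, c) in enumerate(tris):
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        out[4 * f + 0] = (a, ab, ca)
        out[4 * f + 1] = (b, bc, ab)
        out[4 * f + 2] = (c, ca, bc)
        out[4 * f + 3] = (ab, bc, ca)
    return out


def octasphere_level(n_vertices: int) -> int | None:
    """Octasphere subdivision level for a vertex count, or None."""
    for level in range(MAX_LEVEL + 1):
        if octasphere_vertex_count(level) == n_vertices:
            return level
    return None


def octasphere_parents(level: int) -> np.ndarray:
    """Edge parents of the vertices added when refining level-1 -> level.

    Returns an (V_level - V_{level-1}, 2) array: row k holds the two
    coarse-mesh vertex indices whose midpoint created vertex
    V_{level-1} + k.  Used to upsample deformation fields level by level.
    """
    if level < 1 or level > MAX_LEVEL:
        raise ValueError("level must be in 1..MAX_LEVEL")
    verts = [v for v in _OCTA_VERTS]
    tris = _OCTA_TRIS.copy()
    for _ in range(level - 1):
        tris = _subdivide(verts, tris)
    n_coarse = len(verts)
    _subdivide(verts, tris)
    # midpoints were appended in creation order; recover their parents
    parents = np.empty((len(verts) - n_coarse, 2), dtype=np.int64)
    midpoint: dict[tuple[int, int], int] = {}
    idx = n_coarse
    for a, b, c in tris:
        for i, j in ((a, b), (b, c), (c, a)):
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                midpoint[key] = idx
                parents[idx - n_coarse] = key
                idx += 1
    return parents


def _mirror_perm(vertices: np.ndarray) -> np.ndarray:
    """Exact x -> -x permutation via coordinate lookup (bitwise match)."""
    lookup = {
        (v[0], v[1], v[2]): i for i, v in enumerate(np.round(vertices, 12))
    }
    rounded = np.round(vertices, 12)
    perm = np.empty(len(vertices), dtype=np.int64)
    for i, v in enumerate(rounded):
        perm[i] = lookup[(-v[0], v[1], v[2])]
    return perm
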