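"""Spherical point location and barycentric interpolation.

Location uses central (gnomonic) barycentric coordinates: a point p lies in
spherical triangle (A, B, C) iff the solution b of [A B C] b = p has all
components nonnegative; normalising b to sum 1 gives interpolation weights
that reproduce linear-in-coordinates fields exactly at the mapped points.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from asymsurf.mesh_core import SphericalMesh

__all__ = ["SphereInterpolator"]

_INSIDE_TOL = -1e-10


class SphereInterpolator:
    """Reusable point-location + barycentric-weight engine for one mesh."""

    def __init__(self, mesh: SphericalMesh):
        self.mesh = mesh
        self._tree = cKDTree(mesh.vertices)
        # triangle corner matrices M = [A B C] (columns) and their inverses
        tri_pts = mesh.vertices[mesh.triangles]  # (F, 3 corners, 3 xyz)
        m = np.transpose(tri_pts, (0, 2, 1))  # (F, 3 xyz, 3 corners)
        self._minv = np.linalg.inv(m)
        # padded vertex -> incident triangles table
        vt = mesh.vertex_triangles()
        self._max_deg = max(len(t) for t in vt)
        pad = np.full((mesh.n_vertices, self._max_deg), -1, dtype=np.int64)
        for i, t in enumerate(vt):
            pad[i, : len(t)] = t
        self._vtx_tris = pad

    # -- location -----------------------------------------------------------

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Locate unit-sphere points.

        Returns (triangle index, barycentric weights (N, 3), fallback flag).
        Weights are nonnegative and sum to 1.  Points that no candidate
        triangle contains are assigned the best (clamped) candidate and
        flagged.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(pts)
        tri_idx = np.full(n, -1, dtype=np.int64)
        bary = np.zeros((n, 3))
        flagged = np.zeros(n, dtype=bool)

        todo = np.arange(n)
        for k in (1, 6, 20):
            if len(todo) == 0:
                break
            cand = self._candidates(pts[todo], k)
            best_tri, best_bary, ok = self._best_candidate(pts[todo], cand)
            tri_idx[todo] = best_tri
            bary[todo] = best_bary
            todo = todo[~ok]
        if len(todo):
            flagged[todo] = True
            # clamp to the best candidate found in the widest search
            b = np.clip(bary[todo], 0.0, None)
            s = b.sum(axis=1, keepdims=True)
            s[s == 0.0] = 1.0
            bary[todo] = b / s
        # snap points sitting on a mesh vertex to exact one-hot weights
        corner = np.argmax(bary, axis=1)
        hit = bary[np.arange(n), corner] >= 1.0 - 1e-12
        if hit.any():
            bary[hit] = 0.0
            bary[hit, corner[hit]] = 1.0
        return tri_idx, bary, flagged

    def _candidates(self, pts: np.ndarray, k: int) -> np.ndarray:
        kq = min(k, self.mesh.n_vertices)
        _, vidx = self._tree.query(pts, k=kq)
        if kq == 1:
            vidx = vidx[:, None]
        cand = self._vtx_tris[vidx]  # (N, kq, max_deg)
        return cand.reshape(len(pts), -1)

    def _best_candidate(
        self, pts: np.ndarray, cand: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        safe = np.where(cand < 0, 0, cand)
        b = np.einsum("ncij,nj->nci", self._minv[safe], pts)
        ssum = b.sum(axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            bn = b / ssum
        score = bn.min(axis=2)
        score[(cand < 0) | ~np.isfinite(score) | (ssum[:, :, 0] <= 0)] = -np.inf
        pick = np.argmax(score, axis=1)
        rows = np.arange(len(pts))
        best_tri = cand[rows, pick]
        best_bary = bn[rows, pick]
        ok = score[rows, pick] >= _INSIDE_TOL
        return best_tri, best_bary, ok

    # -- interpolation ------------------------------------------------------

    def weights(self, points: np.ndarray) -> sparse.csr_matrix:
        """Sparse (N x V) barycentric weight matrix for the given points."""
        tri_idx, bary, _ = self.locate(points)
        n = len(tri_idx)
        cols = self.mesh.triangles[tri_idx].ravel()
        rows = np.repeat(np.arange(n), 3)
        return sparse.csr_matrix(
            (bary.ravel(), (rows, cols)), shape=(n, self.mesh.n_vertices)
        )

    def interpolate(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Interpolate per-vertex values (V,) or (V, k) at the given points."""
        tri_idx, bary, _ = self.locate(points)
        corners = self.mesh.triangles[tri_idx]  # (N, 3)
        vals = np.asarray(values, dtype=np.float64)
        if vals.ndim == 1:
            return np.einsum("nc,nc->n", vals[corners], bary)
        return np.einsum("ncj,nc->nj", vals[corners], bary)
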