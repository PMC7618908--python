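"""Mesh and metric primitives.

Geometry lives on a shared triangulated topology: a :class:`SphericalMesh`
(unit sphere, optionally with an exact mirror vertex permutation) paired with
one or more :class:`AnatomicalSurface` coordinate sets (white / pial /
midthickness, in mm).  Per-vertex scalar fields are :class:`MetricMap`
objects.  This module provides the per-vertex feature computations
(thickness, vertex area, mean curvature), curvature-bias regression,
surface-constrained Gaussian smoothing via heat diffusion, and file I/O in
the GIFTI dialect plus TSV covariate tables.

Conventions: 0-based indexing, mm coordinates on RAS-like axes, mirror plane
x = 0.  Missing vertices are represented by a boolean ``valid`` mask with a
finite sentinel value (0.0), never by NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from asymsurf.errors import StructuralError, ValidationError

__all__ = [
    "SphericalMesh",
    "AnatomicalSurface",
    "MetricMap",
    "surface_from_mesh",
    "cortical_thickness",
    "vertex_areas",
    "mean_curvature",
    "regress_out_curvature",
    "smooth_metric",
    "diffuse_on_surface",
    "read_surface",
    "write_surface",
    "read_metric",
    "write_metric",
    "read_covariates",
    "write_covariates",
]

COVARIATE_COLUMNS = [
    "subject_id",
    "ga_weeks",
    "pma_weeks",
    "sex",
    "bwz",
    "tbv_cm3",
    "hemi_vol_asym_cm3",
]

_UNIT_TOL = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SphericalMesh:
    """Closed triangulated topology on the unit sphere.

    Parameters
    ----------
    vertices : (V, 3) float array
        Unit-norm coordinates (dimensionless).
    triangles : (F, 3) int array
        0-based vertex index triples with consistent outward winding.
    mirror_perm : (V,) int array, optional
        Involutive vertex permutation realising ``x -> -x`` exactly.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    mirror_perm: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.mirror_perm is not None:
            self.mirror_perm = np.asarray(self.mirror_perm, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    # -- topology helpers ---------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:,0] < e[:,1]."""
        if "edges" not in self._cache:
            t = self.triangles
            e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
            e.sort(axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean vertex adjacency (CSR)."""
        if "adjacency" not in self._cache:
            e = self.edges()
            n = self.n_vertices
            data = np.ones(len(e), dtype=np.int8)
            a = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
            self._cache["adjacency"] = (a + a.T).tocsr()
        return self._cache["adjacency"]

    def vertex_triangles(self) -> list[np.ndarray]:
        """Triangle indices incident to each vertex."""
        if "vertex_triangles" not in self._cache:
            incidence: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for f, tri in enumerate(self.triangles):
                for v in tri:
                    incidence[v].append(f)
            self._cache["vertex_triangles"] = [
                np.asarray(x, dtype=np.int64) for x in incidence
            ]
        return self._cache["vertex_triangles"]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`StructuralError`."""
        norms = np.linalg.norm(self.vertices, axis=1)
        if not np.all(np.abs(norms - 1.0) <= _UNIT_TOL):
            raise StructuralError(
                f"vertex norms deviate from 1 by up to {np.abs(norms - 1).max():.3g}"
            )
        v, f = self.n_vertices, self.n_triangles
        e = len(self.edges())
        if v - e + f != 2:
            raise StructuralError(
                f"Euler characteristic V-E+F = {v - e + f}, expected 2"
            )
        _check_winding(self.vertices, self.triangles)
        if self.mirror_perm is not None:
            p = self.mirror_perm
            if not np.array_equal(p[p], np.arange(v)):
                raise StructuralError("mirror_perm is not an involution")
            mirrored = self.vertices.copy()
            mirrored[:, 0] *= -1.0
            if np.abs(self.vertices[p] - mirrored).max() > _UNIT_TOL:
                raise StructuralError("mirror_perm does not realise x -> -x")

    def require_mirror(self) -> np.ndarray:
        if self.mirror_perm is None:
            raise StructuralError(
                "mesh has no mirror permutation; use a mirror-symmetric mesh "
                "(e.g. an octasphere)"
            )
        return self.mirror_perm


@dataclass
class AnatomicalSurface:
    """3D surface coordinates (mm) on the same topology as a SphericalMesh.

    ``role`` tags the surface as white / pial / midthickness / sphere.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    role: str = "midthickness"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def validate(self, mesh: SphericalMesh | None = None) -> None:
        if mesh is not None and self.n_vertices != mesh.n_vertices:
            raise StructuralError(
                f"surface has {self.n_vertices} vertices but the paired mesh "
                f"has {mesh.n_vertices}"
            )
        if np.any(self.triangle_areas() == 0.0):
            raise StructuralError("surface contains degenerate (zero-area) triangles")


def surface_from_mesh(mesh: SphericalMesh, radius: float = 1.0,
                      role: str = "sphere") -> AnatomicalSurface:
    """View a spherical mesh as an anatomical surface of the given radius."""
    return AnatomicalSurface(mesh.vertices * radius, mesh.triangles, role=role)


@dataclass
class MetricMap:
    """Per-vertex scalar field tagged with hemisphere and feature name.

    ``valid`` marks vertices carrying data; invalid vertices hold the finite
    sentinel 0.0.  ``valid=None`` means all vertices are valid.
    """

    values: np.ndarray
    hemisphere: str = "left"  # left | right | symmetric
    feature: str = "metric"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.n_vertices, dtype=bool)
        return self.valid

    def validate(self, mesh: SphericalMesh | AnatomicalSurface | None = None) -> None:
        if mesh is not None and self.n_vertices != mesh.n_vertices:
            raise StructuralError(
                f"metric has {self.n_vertices} values but the mesh has "
                f"{mesh.n_vertices} vertices"
            )
        if not np.all(np.isfinite(self.values[self.valid_mask()])):
            raise ValidationError(
                f"metric '{self.feature}' contains non-finite values at valid vertices"
            )

    def with_values(self, values: np.ndarray, feature: str | None = None) -> "MetricMap":
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       feature=self.feature if feature is None else feature)


def _check_winding(vertices: np.ndarray, triangles: np.ndarray) -> None:
    """Consistent orientation: each undirected edge is traversed once per
    direction, and the total signed volume is positive (outward normals)."""
    directed = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    # a consistently wound closed surface never repeats a directed edge
    keys = directed[:, 0].astype(np.int64) * len(vertices) + directed[:, 1]
    if len(np.unique(keys)) != len(keys):
        raise StructuralError("inconsistent triangle winding (repeated directed edge)")
    p = vertices[triangles]
    vol6 = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum()
    if vol6 <= 0:
        raise StructuralError("triangle winding gives non-positive signed volume")


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------


def cortical_thickness(white: AnatomicalSurface, pial: AnatomicalSurface) -> MetricMap:
    """Per-vertex Euclidean distance between white and pial surfaces (mm)."""
    if white.n_vertices != pial.n_vertices or not np.array_equal(
        white.triangles, pial.triangles
    ):
        raise StructuralError("white and pial surfaces differ in topology")
    d = np.linalg.norm(pial.vertices - white.vertices, axis=1)
    return MetricMap(d, feature="thickness")


def vertex_areas(surface: AnatomicalSurface) -> MetricMap:
    """One third of the area of each incident triangle, summed per vertex (mm^2).

    The per-vertex values sum exactly to the total mesh area.
    """
    tri_areas = surface.triangle_areas()
    n_degenerate = int(np.count_nonzero(tri_areas == 0.0))
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} degenerate triangles contribute zero area",
            RuntimeWarning,
            stacklevel=2,
        )
    va = np.zeros(surface.n_vertices)
    third = tri_areas / 3.0
    for k in range(3):
        np.add.at(va, surface.triangles[:, k], third)
    return MetricMap(va, feature="vertex_area")


def _cotangent_weights(surface: AnatomicalSurface) -> sparse.csr_matrix:
    """Symmetric cotangent edge-weight matrix (zero diagonal)."""
    tris = surface.triangles
    pts = surface.vertices
    n = surface.n_vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = tris[:, k]
        j = tris[:, (k + 1) % 3]
        o = tris[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        u = pts[i] - pts[o]
        v = pts[j] - pts[o]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cross = np.where(cross == 0.0, np.finfo(float).tiny, cross)
        cot = np.einsum("ij,ij->i", u, v) / cross
        rows.append(i)
        cols.append(j)
        vals.append(0.5 * cot)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    w = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return (w + w.T).tocsr()


def mean_curvature(surface: AnatomicalSurface) -> MetricMap:
    """Discrete mean curvature (1/mm) from the cotangent Laplacian.

    Half the norm of the area-normalised Laplacian of the coordinates,
    signed positive where the surface bends away from the outward normal
    (a sphere of radius r gives +1/r everywhere).  Vertices whose mixed
    area is non-positive fall back to uniform weights and are flagged.
    """
    w = _cotangent_weights(surface)
    areas = vertex_areas(surface).values
    deg = np.asarray(w.sum(axis=1)).ravel()
    lap = w @ surface.vertices - deg[:, None] * surface.vertices  # = -2 A H n

    bad = areas <= 0
    if np.any(bad):
        adj = sparse.csr_matrix(
            (np.ones(w.nnz), w.indices, w.indptr), shape=w.shape
        )
        nn = np.asarray(adj.sum(axis=1)).ravel()
        nn = np.where(nn == 0, 1.0, nn)
        uni = adj @ surface.vertices / nn[:, None] - surface.vertices
        lap[bad] = uni[bad]
        areas = np.where(bad, 1.0, areas)

    hvec = lap / areas[:, None]  # norm 2H on a smooth surface
    mag = 0.5 * np.linalg.norm(hvec, axis=1)

    normals = _vertex_normals(surface)
    sign = -np.sign(np.einsum("ij,ij->i", hvec, normals))
    sign[sign == 0] = 1.0
    out = MetricMap(mag * sign, feature="mean_curvature")
    if np.any(bad):
        out.valid = ~bad
        out.values[bad] = 0.0
    return out


def _vertex_normals(surface: AnatomicalSurface) -> np.ndarray:
    p = surface.vertices[surface.triangles]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # area-weighted
    vn = np.zeros_like(surface.vertices)
    for k in range(3):
        np.add.at(vn, surface.triangles[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    return vn / norms[:, None]


def regress_out_curvature(metric: MetricMap, curvature: MetricMap) -> MetricMap:
    """Remove folding bias: residualise a metric on [1, curvature].

    The output keeps the input's global mean, so absolute levels (and hence
    asymmetry indices) are preserved.  Idempotent; output is uncorrelated
    with curvature to numerical precision.
    """
    if metric.n_vertices != curvature.n_vertices:
        raise StructuralError("metric and curvature live on different meshes")
    if metric.hemisphere != curvature.hemisphere:
        raise StructuralError(
            f"hemisphere mismatch: {metric.hemisphere} vs {curvature.hemisphere}"
        )
    ok = metric.valid_mask() & curvature.valid_mask()
    y = metric.values[ok]
    c = curvature.values[ok]
    if np.ptp(c) == 0.0:
        warnings.warn(
            "curvature map is constant; regression skipped", RuntimeWarning,
            stacklevel=2,
        )
        return metric.with_values(metric.values.copy())
    x = np.column_stack([np.ones(len(c)), c])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = np.array(metric.values, copy=True)
    resid[ok] = y - x @ beta + y.mean()
    out = metric.with_values(resid)
    out.valid = None if metric.valid is None and curvature.valid is None else ok
    return out


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_metric(
    metric: MetricMap,
    surface: AnatomicalSurface,
    sigma_mm: float,
    max_steps: int = 20000,
) -> MetricMap:
    """Approximate geodesic Gaussian smoothing by explicit heat diffusion.

    Runs the heat equation for time t = sigma^2 / 2 using explicit Euler
    steps of the area-normalised cotangent Laplacian, with the step size
    held below the stability limit (Gershgorin bound).  Constant maps are
    invariant and the area-weighted global mean is conserved.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be nonnegative")
    if metric.n_vertices != surface.n_vertices:
        raise StructuralError("metric and surface differ in vertex count")
    if sigma_mm == 0.0:
        return metric.with_values(metric.values.copy())

    u = diffuse_on_surface(metric.values, surface, sigma_mm, max_steps)
    return metric.with_values(u)


def diffuse_on_surface(
    values: np.ndarray,
    surface: AnatomicalSurface,
    sigma_mm: float,
    max_steps: int = 20000,
) -> np.ndarray:
    """Heat-diffuse per-vertex data (V,) or (V, k) for time sigma^2/2.

    Shared engine behind :func:`smooth_metric`; applying it to a (V, k)
    block is column-for-column identical to k single-column calls.
    """
    values = np.asarray(values, dtype=np.float64)
    if sigma_mm == 0.0:
        return values.copy()
    t_total = 0.5 * sigma_mm**2
    key = ("diffusion", id(surface))
    if key not in surface._cache:
        w = _cotangent_weights(surface)
        areas = vertex_areas(surface).values
        areas = np.where(areas <= 0, np.finfo(float).tiny, areas)
        deg = np.asarray(w.sum(axis=1)).ravel()
        absrow = np.asarray(abs(w).sum(axis=1)).ravel()
        surface._cache[key] = (w, areas, deg, absrow)
    w, areas, deg, absrow = surface._cache[key]
    # explicit-Euler stability: dt < 2 / lambda_max; Gershgorin gives
    # lambda_max <= max_i (|deg_i| + sum_j |w_ij|) / a_i
    lam = np.max((np.abs(deg) + absrow) / areas)
    dt_max = 0.9 * 2.0 / lam
    n_steps = max(1, int(np.ceil(t_total / dt_max)))
    if n_steps > max_steps:
        raise ValueError(
            f"smoothing sigma={sigma_mm} needs {n_steps} diffusion steps "
            f"(> {max_steps}); increase max_steps or reduce sigma"
        )
    dt = t_total / n_steps
    u = values.copy()
    inv_a = 1.0 / areas
    col = (slice(None), None) if u.ndim == 2 else slice(None)
    for _ in range(n_steps):
        u = u + dt * inv_a[col] * (w @ u - deg[col] * u)
    return u


# ---------------------------------------------------------------------------
# I/O (GIFTI dialect + TSV covariates)
# ---------------------------------------------------------------------------


def _gifti():
    import nibabel as nib
    from nibabel import gifti

    return nib, gifti


def write_surface(
    path: str | Path,
    surface: AnatomicalSurface | SphericalMesh,
    hemisphere: str = "left",
    age_weeks: int | None = None,
) -> None:
    """Write surface geometry as a GIFTI .surf.gii file."""
    nib, gifti = _gifti()
    verts = np.asarray(surface.vertices, dtype=np.float32)
    tris = np.asarray(surface.triangles, dtype=np.int32)
    meta = {"hemisphere": hemisphere}
    if isinstance(surface, AnatomicalSurface):
        meta["role"] = surface.role
    if age_weeks is not None:
        meta["age_weeks"] = str(age_weeks)
    img = gifti.GiftiImage()
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            verts, intent="NIFTI_INTENT_POINTSET",
            meta=gifti.GiftiMetaData(**meta),
        )
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(tris, intent="NIFTI_INTENT_TRIANGLE")
    )
    nib.save(img, str(path))


def read_surface(path: str | Path, spherical: bool = False,
                 validate: bool = True):
    """Read a GIFTI surface; returns AnatomicalSurface or SphericalMesh.

    Surfaces with inconsistent winding are rejected on load.
    """
    nib, _ = _gifti()
    img = nib.load(str(path))
    pointsets = [d for d in img.darrays if d.intent == 1008]  # POINTSET
    tris = [d for d in img.darrays if d.intent == 1009]  # TRIANGLE
    if not pointsets or not tris:
        raise ValidationError(f"{path}: not a surface GIFTI file")
    verts = np.asarray(pointsets[0].data, dtype=np.float64)
    faces = np.asarray(tris[0].data, dtype=np.int64)
    if faces.max() >= len(verts):
        raise ValidationError(
            f"{path}: triangle index {faces.max()} out of range for "
            f"{len(verts)} vertices"
        )
    if validate:
        _check_winding(verts, faces)
    meta = dict(pointsets[0].meta)
    if spherical:
        norms = np.linalg.norm(verts, axis=1)
        verts = verts / norms[:, None]
        mesh = SphericalMesh(verts, faces)
        mesh.mirror_perm = _find_mirror_perm(verts)
        return mesh
    return AnatomicalSurface(verts, faces, role=meta.get("role", "midthickness"))


def _find_mirror_perm(verts: np.ndarray, tol: float = 1e-9) -> np.ndarray | None:
    """Recover the x -> -x permutation by coordinate lookup, if it exists."""
    from scipy.spatial import cKDTree

    mirrored = verts.copy()
    mirrored[:, 0] *= -1.0
    dist, idx = cKDTree(verts).query(mirrored)
    if dist.max() > tol:
        return None
    perm = np.asarray(idx, dtype=np.int64)
    if not np.array_equal(perm[perm], np.arange(len(verts))):
        return None
    return perm


def write_metric(
    path: str | Path,
    metric: MetricMap,
    age_weeks: int | None = None,
) -> None:
    """Write a per-vertex metric as a GIFTI .func.gii file."""
    nib, gifti = _gifti()
    meta = {"hemisphere": metric.hemisphere, "feature": metric.feature}
    if age_weeks is not None:
        meta["age_weeks"] = str(age_weeks)
    img = gifti.GiftiImage()
    # float64 keeps the round trip within 1e-7 for O(1)-magnitude metrics
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            np.asarray(metric.values, dtype=np.float64),
            intent="NIFTI_INTENT_NONE",
            datatype="NIFTI_TYPE_FLOAT64",
            meta=gifti.GiftiMetaData(**meta),
        )
    )
    if metric.valid is not None:
        img.add_gifti_data_array(
            gifti.GiftiDataArray(
                metric.valid.astype(np.float32),
                intent="NIFTI_INTENT_NONE",
                meta=gifti.GiftiMetaData(feature="valid_mask"),
            )
        )
    # 'force' keeps the float64 datatype (strict mode insists on float32)
    Path(path).write_bytes(img.to_xml(mode="force"))


def read_metric(path: str | Path, mesh=None) -> MetricMap:
    """Read a per-vertex metric GIFTI file; check vertex count if mesh given."""
    nib, _ = _gifti()
    img = nib.load(str(path))
    if not img.darrays:
        raise ValidationError(f"{path}: empty metric file")
    meta = dict(img.darrays[0].meta)
    values = np.asarray(img.darrays[0].data, dtype=np.float64)
    valid = None
    for d in img.darrays[1:]:
        if dict(d.meta).get("feature") == "valid_mask":
            valid = np.asarray(d.data) > 0.5
    if mesh is not None and len(values) != mesh.n_vertices:
        raise StructuralError(
            f"{path}: metric has {len(values)} values but the mesh has "
            f"{mesh.n_vertices} vertices"
        )
    return MetricMap(
        values,
        hemisphere=meta.get("hemisphere", "left"),
        feature=meta.get("feature", "metric"),
        valid=valid,
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate table (TSV); validate required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: covariate table missing required columns: {missing}"
        )
    return df


def write_covariates(path: str | Path, df: pd.DataFrame) -> None:
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"covariate table missing required columns: {missing}")
    df.to_csv(path, sep="\t", index=False)
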