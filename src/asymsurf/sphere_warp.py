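"""Deformation-field algebra on the sphere and sulcal-depth-driven registration.

A :class:`DeformationField` stores, for each vertex of its source space,
the unit-sphere position it maps to in its target space.  All spaces in
this package share one triangulated topology, so fields can be composed,
inverted, averaged, and used to resample metrics by barycentric
interpolation.  :func:`register` is a lightweight coarse-to-fine SSD +
Dirichlet-penalty optimiser standing in for heavyweight spherical
registration tools behind the same interface: it is deterministic, its
objective is non-increasing across accepted steps, and it never emits a
field with folded triangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from asymsurf._interp import SphereInterpolator
from asymsurf.errors import ConvergenceError, StructuralError
from asymsurf.mesh_core import (
    MetricMap,
    SphericalMesh,
    smooth_metric,
    surface_from_mesh,
    vertex_areas,
)
from asymsurf.octasphere import (
    make_octasphere,
    octasphere_level,
    octasphere_parents,
    octasphere_vertex_count,
)

__all__ = [
    "evaluate_field",
    "DeformationField",
    "RegistrationParams",
    "identity_field",
    "resample_metric",
    "compose",
    "invert",
    "average_deformations",
    "register",
    "mirror_map",
    "mirror_metric",
    "folded_triangles",
    "geodesic_distance",
    "deformation_to_metric_values",
    "deformation_from_metric_values",
]


def _normalize(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance (radians) between unit vectors, elementwise.

    Computed from the chord length (2 asin(|a-b|/2)), which stays accurate
    near zero where arccos of the dot product loses half the precision.
    """
    chord = np.linalg.norm(a - b, axis=-1)
    return 2.0 * np.arcsin(np.clip(0.5 * chord, 0.0, 1.0))


@dataclass
class DeformationField:
    """Per-vertex spherical warp: source vertex i maps to ``targets[i]``.

    ``mesh`` is the shared topology of the source space; ``source_space``
    and ``target_space`` are opaque labels used for compatibility checks.
    """

    targets: np.ndarray
    mesh: SphericalMesh
    source_space: str = "source"
    target_space: str = "target"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.targets = np.ascontiguousarray(self.targets, dtype=np.float64)

    @property
    def n_vertices(self) -> int:
        return self.targets.shape[0]

    def validate(self) -> None:
        norms = np.linalg.norm(self.targets, axis=1)
        if np.abs(norms - 1.0).max() > 1e-12:
            raise StructuralError("deformation targets are not unit-norm")
        n_folds = int(folded_triangles(self.targets, self.mesh).sum())
        if n_folds:
            raise StructuralError(f"deformation folds {n_folds} triangles")

    def displacement(self) -> np.ndarray:
        """Geodesic displacement (radians) of every vertex."""
        return geodesic_distance(self.mesh.vertices, self.targets)


def identity_field(mesh: SphericalMesh, space: str = "space") -> DeformationField:
    return DeformationField(
        mesh.vertices.copy(), mesh, source_space=space, target_space=space
    )


def folded_triangles(targets: np.ndarray, mesh: SphericalMesh) -> np.ndarray:
    """Boolean per-triangle flag: mapped orientation flips vs the source.

    Source octaspheres are wound outward (positive triple product), so a
    fold is a mapped triangle with non-positive triple product.
    """
    p = targets[mesh.triangles]
    det = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2]))
    return det <= 0.0


def _interpolator(mesh: SphericalMesh) -> SphereInterpolator:
    if "interp" not in mesh._cache:
        mesh._cache["interp"] = SphereInterpolator(mesh)
    return mesh._cache["interp"]


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------


def resample_metric(
    metric: MetricMap,
    deformation: DeformationField,
    target_mesh: SphericalMesh | None = None,
) -> MetricMap:
    """Pull a metric living on the deformation's target space back onto its
    source mesh by barycentric interpolation at the mapped positions."""
    mesh = target_mesh if target_mesh is not None else deformation.mesh
    if metric.n_vertices != mesh.n_vertices:
        raise StructuralError(
            f"metric has {metric.n_vertices} values but the deformation's "
            f"target mesh has {mesh.n_vertices} vertices"
        )
    interp = _interpolator(mesh)
    tri_idx, bary, flagged = interp.locate(deformation.targets)
    corners = mesh.triangles[tri_idx]
    values = np.einsum("nc,nc->n", metric.values[corners], bary)
    out = metric.with_values(values)
    if metric.valid is not None:
        frac = np.einsum("nc,nc->n", metric.valid[corners].astype(float), bary)
        out.valid = frac > 1.0 - 1e-9
        out.values[~out.valid] = 0.0
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} mapped points used nearest-triangle fallback",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def evaluate_field(d: DeformationField, points: np.ndarray) -> np.ndarray:
    """Evaluate a deformation at arbitrary unit-sphere points.

    Barycentric interpolation of the target positions followed by
    projection to the sphere; exact for linear fields (rotations), O(h^2)
    representation error for general smooth warps.
    """
    interp = _interpolator(d.mesh)
    return _normalize(interp.interpolate(d.targets, points))


def compose(d1: DeformationField, d2: DeformationField) -> DeformationField:
    """Concatenate warps: the result maps v to d2(d1(v))."""
    if d1.target_space != d2.source_space:
        raise StructuralError(
            f"cannot compose: d1 targets '{d1.target_space}' but d2 starts "
            f"from '{d2.source_space}'"
        )
    return DeformationField(
        evaluate_field(d2, d1.targets),
        d1.mesh,
        source_space=d1.source_space,
        target_space=d2.target_space,
    )


def invert(
    d: DeformationField,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> DeformationField:
    """Fixed-point inverse: find p with d(p) = v for every vertex v.

    The defining contract is that composing with the inverse stays within
    1e-3 radians of the identity; non-convergence raises with the residual.
    """
    if folded_triangles(d.targets, d.mesh).any():
        raise StructuralError("cannot invert a deformation with folded triangles")
    v = d.mesh.vertices

    # exact piecewise-linear inverse: locate each vertex in the image mesh
    # (mapped targets, same triangles) and pull its barycentric weights
    # back to the source triangle
    image = SphericalMesh(d.targets, d.mesh.triangles)
    tri_idx, bary, _ = SphereInterpolator(image).locate(v)
    p = _normalize(
        np.einsum("nc,ncj->nj", bary, v[d.mesh.triangles[tri_idx]])
    )

    def residuals(q: np.ndarray) -> np.ndarray:
        return evaluate_field(d, q) - v

    err = residuals(p)
    res = np.linalg.norm(err, axis=1)
    alpha = 1.0
    for _ in range(max_iter):
        if res.max() < tol:
            break
        trial = _normalize(p - alpha * err)
        trial_err = residuals(trial)
        trial_res = np.linalg.norm(trial_err, axis=1)
        improved = trial_res < res
        if improved.any():
            p[improved] = trial[improved]
            err[improved] = trial_err[improved]
            res[improved] = trial_res[improved]
            alpha = min(1.0, alpha * 1.2)
        else:
            alpha *= 0.5
            if alpha < 1e-8:
                break
    resid = float(res.max())
    if resid > 1e-3:
        raise ConvergenceError(
            f"deformation inverse did not converge: residual {resid:.3g} rad"
        )
    return DeformationField(
        p, d.mesh, source_space=d.target_space, target_space=d.source_space
    )


def average_deformations(
    fields: list[DeformationField],
    weights: np.ndarray | None = None,
) -> DeformationField:
    """Weighted Euclidean mean of targets, projected back to the sphere."""
    if not fields:
        raise ValueError("no fields to average")
    spaces = {(f.source_space, f.target_space) for f in fields}
    if len(spaces) > 1:
        raise StructuralError(f"fields span inconsistent spaces: {spaces}")
    if weights is None:
        weights = np.full(len(fields), 1.0 / len(fields))
    else:
        weights = np.asarray(weights, dtype=np.float64)
        weights = weights / weights.sum()
    one_hot = np.nonzero(weights == 1.0)[0]
    if len(one_hot) == 1:
        f = fields[int(one_hot[0])]
        return DeformationField(
            f.targets.copy(), f.mesh,
            source_space=f.source_space, target_space=f.target_space,
        )
    mean = np.zeros_like(fields[0].targets)
    for f, w in zip(fields, weights):
        mean += w * f.targets
    norms = np.linalg.norm(mean, axis=1)
    if norms.min() < 0.5:
        raise StructuralError(
            "near-antipodal deformation average (|mean| < 0.5); "
            "displacements too large to average in ambient coordinates"
        )
    return DeformationField(
        mean / norms[:, None],
        fields[0].mesh,
        source_space=fields[0].source_space,
        target_space=fields[0].target_space,
    )


def scale_deformation(d: DeformationField, factor: float,
                      target_space: str | None = None) -> DeformationField:
    """Geodesically scale every vertex displacement by ``factor`` (slerp)."""
    v = d.mesh.vertices
    t = d.targets
    ang = geodesic_distance(v, t)
    # slerp between v and t at parameter `factor`
    small = ang < 1e-12
    sin_ang = np.where(small, 1.0, np.sin(ang))
    w0 = np.where(small, 1.0 - factor, np.sin((1.0 - factor) * ang) / sin_ang)
    w1 = np.where(small, factor, np.sin(factor * ang) / sin_ang)
    out = _normalize(w0[:, None] * v + w1[:, None] * t)
    return DeformationField(
        out, d.mesh, source_space=d.source_space,
        target_space=target_space or d.target_space,
    )


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------


def mirror_map(mesh: SphericalMesh) -> np.ndarray:
    """The exact x -> -x vertex permutation of a symmetric mesh."""
    return mesh.require_mirror()


def mirror_metric(metric: MetricMap, mesh: SphericalMesh) -> MetricMap:
    """Reindex a metric through the mirror permutation (involutive)."""
    perm = mirror_map(mesh)
    flip = {"left": "right", "right": "left"}
    out = replace(
        metric,
        values=metric.values[perm],
        hemisphere=flip.get(metric.hemisphere, metric.hemisphere),
    )
    if metric.valid is not None:
        out.valid = metric.valid[perm]
    return out


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationParams:
    """Coarse-to-fine SSD registration settings.

    ``levels`` are octasphere control-grid levels per stage (clipped to the
    data mesh's own level; a repeated level re-optimises with the next
    smoothing width).  ``sigmas`` are per-stage metric smoothing widths in
    mesh units (radians on the unit sphere); ``lambdas`` weight the
    Dirichlet penalty per stage, annealed high to low so coarse stages stay
    near-rigid while fine stages track local detail.
    """

    levels: tuple[int, ...] = (2, 3, 3, 4, 4)
    iters_per_level: int = 100
    lambdas: tuple[float, ...] = (1.0, 0.3, 0.1, 0.03, 0.01)
    sigmas: tuple[float, ...] = (0.3, 0.15, 0.08, 0.05, 0.03)
    step_init: float = 0.05
    min_step: float = 1e-7
    fd_eps: float = 1e-4

    def stage(self, i: int) -> tuple[float, float]:
        lam = self.lambdas[min(i, len(self.lambdas) - 1)]
        sig = self.sigmas[min(i, len(self.sigmas) - 1)]
        return lam, sig


def register(
    source: MetricMap,
    target: MetricMap,
    mesh: SphericalMesh,
    params: RegistrationParams | None = None,
    source_space: str = "source",
    target_space: str = "target",
) -> DeformationField:
    """Find a warp d with target(d(v)) ~ source(v), coarse to fine.

    Minimises area-weighted SSD of metric values plus a Dirichlet
    (graph-Laplacian) penalty on displacements, by projected gradient
    descent with backtracking.  Steps that fold a triangle or increase the
    objective are rejected and halved; the accepted-objective sequence is
    non-increasing and the returned field has no folded triangles.
    """
    params = params or RegistrationParams()
    if source.n_vertices != mesh.n_vertices or target.n_vertices != mesh.n_vertices:
        raise StructuralError("metrics and mesh differ in vertex count")

    data_level = octasphere_level(mesh.n_vertices)
    if data_level is None:
        levels = [None]  # single stage on the mesh itself
    else:
        levels = [min(lv, data_level) for lv in params.levels]
        # keep stage order but never go back down a level
        levels = [lv for i, lv in enumerate(levels)
                  if i == 0 or lv >= levels[i - 1]]

    sphere = surface_from_mesh(mesh)
    full_interp = _interpolator(mesh)

    targets = None  # control-grid state
    prev_level = None
    for stage, lv in enumerate(levels):
        lam, sigma = params.stage(stage)
        s_sm = smooth_metric(source, sphere, sigma).values
        t_sm = smooth_metric(target, sphere, sigma).values
        scale = max(np.std(s_sm), 1e-12)
        s_sm, t_sm = s_sm / scale, t_sm / scale

        if lv is None or lv == data_level:
            control = mesh
            n_ctrl = mesh.n_vertices
        else:
            control = make_octasphere(lv)
            n_ctrl = control.n_vertices

        if targets is None:
            targets = control.vertices.copy()
        elif prev_level is not None and lv is not None and lv > prev_level:
            targets = _upsample_targets(targets, prev_level, lv)
        prev_level = lv

        targets = _optimise_level(
            targets,
            control,
            s_sm[:n_ctrl],
            t_sm,
            full_interp,
            params,
            lam,
        )

    if data_level is not None and prev_level is not None and prev_level != data_level:
        targets = _upsample_targets(targets, prev_level, data_level)
    targets = _unfold(targets, mesh)

    return DeformationField(
        targets, mesh, source_space=source_space, target_space=target_space
    )


def _upsample_targets(targets: np.ndarray, from_level: int, to_level: int | None,
                      ) -> np.ndarray:
    lv = from_level
    while to_level is not None and lv < to_level:
        parents = octasphere_parents(lv + 1)
        new = _normalize(targets[parents[:, 0]] + targets[parents[:, 1]])
        targets = np.vstack([targets, new])
        lv += 1
    return targets


def _optimise_level(
    targets: np.ndarray,
    control: SphericalMesh,
    source_vals: np.ndarray,
    target_vals_full: np.ndarray,
    full_interp: SphereInterpolator,
    params: RegistrationParams,
    lam: float,
) -> np.ndarray:
    areas = vertex_areas(surface_from_mesh(control)).values
    edges = control.edges()
    base = control.vertices

    def objective(t: np.ndarray) -> float:
        r = full_interp.interpolate(target_vals_full, t) - source_vals
        e_data = float(np.sum(areas * r * r))
        u = t - base
        du = u[edges[:, 0]] - u[edges[:, 1]]
        return e_data + lam * float(np.sum(du * du))

    def gradient(t: np.ndarray) -> np.ndarray:
        r = full_interp.interpolate(target_vals_full, t) - source_vals
        e1, e2 = _tangent_basis(t)
        h = params.fd_eps
        g1 = (
            full_interp.interpolate(target_vals_full, _normalize(t + h * e1))
            - full_interp.interpolate(target_vals_full, _normalize(t - h * e1))
        ) / (2 * h)
        g2 = (
            full_interp.interpolate(target_vals_full, _normalize(t + h * e2))
            - full_interp.interpolate(target_vals_full, _normalize(t - h * e2))
        ) / (2 * h)
        g = 2.0 * (areas * r)[:, None] * (g1[:, None] * e1 + g2[:, None] * e2)
        # Dirichlet term gradient: 2 lambda * graph-Laplacian of displacement
        u = t - base
        lap = np.zeros_like(u)
        du = u[edges[:, 0]] - u[edges[:, 1]]
        np.add.at(lap, edges[:, 0], du)
        np.add.at(lap, edges[:, 1], -du)
        g = g + 2.0 * lam * lap
        # project to the sphere's tangent space
        g -= np.einsum("ij,ij->i", g, t)[:, None] * t
        return g

    e_cur = objective(targets)
    step = params.step_init
    for _ in range(params.iters_per_level):
        g = gradient(targets)
        gmax = np.abs(g).max()
        if gmax < 1e-14:
            break
        accepted = False
        while step >= params.min_step:
            trial = _normalize(targets - step * g)
            if folded_triangles(trial, control).any():
                step *= 0.5
                continue
            e_trial = objective(trial)
            if e_trial < e_cur:
                targets, e_cur = trial, e_trial
                step = min(step * 1.3, 1.0)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return targets


def _tangent_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.zeros_like(t)
    smallest = np.argmin(np.abs(t), axis=1)
    ref[np.arange(len(t)), smallest] = 1.0
    e1 = np.cross(t, ref)
    e1 = _normalize(e1)
    e2 = np.cross(t, e1)
    return e1, e2


def _unfold(targets: np.ndarray, mesh: SphericalMesh, max_iter: int = 50,
            ) -> np.ndarray:
    """Relax folded triangles (rare, post-upsampling) by local averaging."""
    adj = mesh.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel().astype(float)
    for _ in range(max_iter):
        folds = folded_triangles(targets, mesh)
        if not folds.any():
            return targets
        bad = np.unique(mesh.triangles[folds])
        nbr_mean = (adj @ targets) / deg[:, None]
        targets = targets.copy()
        targets[bad] = _normalize(0.5 * targets[bad] + 0.5 * nbr_mean[bad])
    raise ConvergenceError("could not remove folded triangles from deformation")


# ---------------------------------------------------------------------------
# Serialisation (per-vertex xyz triples)
# ---------------------------------------------------------------------------


def deformation_to_metric_values(d: DeformationField) -> np.ndarray:
    """(V, 3) target coordinates, the on-disk representation of a field."""
    return d.targets.copy()


def deformation_from_metric_values(
    values: np.ndarray,
    mesh: SphericalMesh,
    source_space: str = "source",
    target_space: str = "target",
) -> DeformationField:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mesh.n_vertices, 3):
        raise StructuralError(
            f"deformation values have shape {values.shape}, expected "
            f"({mesh.n_vertices}, 3)"
        )
    return DeformationField(
        _normalize(values), mesh,
        source_space=source_space, target_space=target_space,
    )
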