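"""Per-subject asymmetry-index maps on the symmetric template.

The asymmetry index is AI = (L - R) / ((L + R) / 2), positive for leftward
asymmetry, computed vertex-wise once the right hemisphere has been mirrored
onto the left topology.  Structural AI maps are smoothed on the subject's
symmetric midthickness surface (mean of left and flipped-right anatomy) so
that smoothing is not biased by either hemisphere; functional AI maps are
masked by the group component masks and left unsmoothed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from asymsurf.errors import StructuralError
from asymsurf.mesh_core import (
    AnatomicalSurface,
    MetricMap,
    SphericalMesh,
    smooth_metric,
)

__all__ = [
    "AsymmetryMap",
    "asymmetry_index",
    "symmetric_midthickness",
    "smooth_asymmetry",
    "functional_mask",
    "apply_mask",
    "roi_summary",
]

#: features that are nonnegative by nature; negative inputs there make the
#: normalised index unbounded and trigger a warning
NONNEGATIVE_FEATURES = {"thickness", "vertex_area", "area", "myelin"}


@dataclass
class AsymmetryMap:
    """Per-vertex asymmetry index (dimensionless) for one subject/feature."""

    values: np.ndarray
    feature: str = "metric"
    subject_id: str = ""
    mask: np.ndarray | None = None  # True = analysed vertex

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def mask_array(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.n_vertices, dtype=bool)
        return self.mask

    def as_metric(self) -> MetricMap:
        return MetricMap(
            self.values.copy(),
            hemisphere="symmetric",
            feature=f"AI_{self.feature}",
            valid=None if self.mask is None else self.mask.copy(),
        )


def asymmetry_index(
    left: MetricMap,
    right: MetricMap,
    eps: float = 1e-8,
    subject_id: str = "",
) -> AsymmetryMap:
    """AI = (L - R) / ((L + R) / 2), leftward positive.

    ``right`` must already be mirrored onto the left topology (vertex-wise
    correspondence).  Where the denominator magnitude falls below ``eps``
    the index is set to 0 and the vertex is excluded from the mask.
    """
    if left.n_vertices != right.n_vertices:
        raise StructuralError("hemisphere maps differ in vertex count")
    l_vals = left.values
    r_vals = right.values
    if left.feature in NONNEGATIVE_FEATURES and (
        (l_vals < 0).any() or (r_vals < 0).any()
    ):
        warnings.warn(
            f"negative values in nonnegative feature '{left.feature}'; "
            "the asymmetry index is unbounded there",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = 0.5 * (l_vals + r_vals)
    ok = np.abs(denom) >= eps
    ai = np.zeros(left.n_vertices)
    ai[ok] = (l_vals[ok] - r_vals[ok]) / denom[ok]
    mask = ok & left.valid_mask() & right.valid_mask()
    ai[~mask] = 0.0
    return AsymmetryMap(
        ai,
        feature=left.feature,
        subject_id=subject_id,
        mask=None if mask.all() else mask,
    )


def symmetric_midthickness(
    left: AnatomicalSurface,
    right: AnatomicalSurface,
    mesh: SphericalMesh,
    iterations: int = 10,
    strength: float = 0.75,
) -> AnatomicalSurface:
    """Hemispherically unbiased smoothing surface.

    Vertex i of the right surface is homologous to vertex i of the left
    (same-index correspondence), so flipping the right surface along the
    YZ plane overlays it on the left; the coordinates are then averaged
    and smoothed iteratively: v <- (1-s) v + s (neighbour mean).
    Exchanging the hemisphere inputs reflects the output through the YZ
    plane (an isometry, so smoothing behaviour is hemisphere-unbiased).
    """
    mesh.require_mirror()
    if left.n_vertices != right.n_vertices or left.n_vertices != mesh.n_vertices:
        raise StructuralError("surfaces and mesh differ in vertex count")

    flipped = right.vertices.copy()
    flipped[:, 0] *= -1.0
    coords = 0.5 * (left.vertices + flipped)

    adj = mesh.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel().astype(float)
    for _ in range(iterations):
        nbr_mean = (adj @ coords) / deg[:, None]
        coords = (1.0 - strength) * coords + strength * nbr_mean
    return AnatomicalSurface(coords, mesh.triangles, role="midthickness")


def smooth_asymmetry(
    ai: AsymmetryMap,
    sym_mid: AnatomicalSurface,
    sigma_mm: float = 2.0,
) -> AsymmetryMap:
    """Smooth an AI map on the symmetric midthickness geometry."""
    sm = smooth_metric(ai.as_metric(), sym_mid, sigma_mm)
    out = AsymmetryMap(sm.values, feature=ai.feature, subject_id=ai.subject_id,
                       mask=None if ai.mask is None else ai.mask.copy())
    if out.mask is not None:
        out.values[~out.mask] = 0.0
    return out


def functional_mask(
    group_map_z: MetricMap,
    mesh: SphericalMesh | None = None,
    z_thresh: float = 5.1,
    component: str = "",
) -> np.ndarray:
    """Supra-threshold mask {Z > z_thresh} of a symmetric group component.

    The same mask is applied to every subject's AI map for the component so
    all maps share one spatial extent; an empty mask is an error.
    """
    mask = group_map_z.values > z_thresh
    if mesh is not None and mesh.mirror_perm is not None:
        # group maps are symmetric up to numerics; intersecting with the
        # mirrored mask makes the shared spatial extent exactly mirror-even
        mask = mask & mask[mesh.mirror_perm]
    if not mask.any():
        raise StructuralError(
            f"component '{component or group_map_z.feature}' has no vertex "
            f"above Z={z_thresh}"
        )
    return mask


def apply_mask(ai: AsymmetryMap, mask: np.ndarray) -> AsymmetryMap:
    """Restrict an AI map to a component mask (values outside set to 0)."""
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != ai.n_vertices:
        raise StructuralError("mask and AI map differ in vertex count")
    combined = mask & ai.mask_array()
    values = np.where(combined, ai.values, 0.0)
    return AsymmetryMap(values, feature=ai.feature, subject_id=ai.subject_id,
                        mask=combined)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    cutoff = 0.5 * w.sum()
    return float(v[np.searchsorted(cw, cutoff)])


def roi_summary(
    ai: AsymmetryMap,
    labels: np.ndarray,
    areas: MetricMap,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-ROI area-weighted mean and median AI.

    Conservation: sum over ROIs of (ROI area x ROI mean) equals the global
    area-weighted AI total over analysed vertices.
    """
    labels = np.asarray(labels)
    if len(labels) != ai.n_vertices or areas.n_vertices != ai.n_vertices:
        raise StructuralError("labels/areas do not match the AI map's mesh")
    analysed = ai.mask_array()
    rows = []
    for lab in np.unique(labels[analysed]):
        sel = analysed & (labels == lab)
        w = areas.values[sel]
        v = ai.values[sel]
        total_area = float(w.sum())
        rows.append(
            {
                "roi": int(lab),
                "name": (label_names or {}).get(int(lab), str(int(lab))),
                "n_vertices": int(sel.sum()),
                "area": total_area,
                "mean_ai": float(np.sum(w * v) / total_area),
                "median_ai": _weighted_median(v, w),
            }
        )
    return pd.DataFrame(rows)
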