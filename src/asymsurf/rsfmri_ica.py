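"""Functional stream: smoothing, incremental group PCA, mirror-symmetrised
group ICA, and dual regression.

The defining property of this stream is hemispheric bias removal: the
reduced data fed to group ICA stacks the left-hemisphere block on top of
the mirrored right-hemisphere block, so the group spatial maps are
mirror-symmetric by construction and any left-right difference seen in a
dual-regressed single-subject map reflects that subject's own data, not
the group template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from asymsurf.errors import StructuralError
from asymsurf.mesh_core import AnatomicalSurface, diffuse_on_surface

__all__ = [
    "TimeseriesMatrix",
    "ICADecomposition",
    "smooth_timeseries",
    "migp",
    "mirror_concatenate",
    "group_ica",
    "dual_regression",
]


@dataclass
class TimeseriesMatrix:
    """frames x vertices timeseries, demeaned per vertex on construction."""

    data: np.ndarray
    hemisphere: str = "left"
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.data = data - data.mean(axis=0, keepdims=True)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class ICADecomposition:
    """Group ICA result: Z-scored spatial maps (components x vertices)."""

    spatial_maps: np.ndarray
    mixing: np.ndarray | None = None
    dimensionality: int = 0
    seed: int | None = None
    keep: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.spatial_maps = np.atleast_2d(
            np.asarray(self.spatial_maps, dtype=np.float64)
        )
        if self.dimensionality == 0:
            self.dimensionality = self.spatial_maps.shape[0]

    def kept_maps(self) -> np.ndarray:
        if self.keep is None:
            return self.spatial_maps
        return self.spatial_maps[self.keep]


def smooth_timeseries(
    ts: TimeseriesMatrix,
    surface: AnatomicalSurface,
    sigma_mm: float = 4.0,
) -> TimeseriesMatrix:
    """Frame-by-frame surface smoothing (shared diffusion engine, so each
    frame equals a single-frame smooth_metric call to float round-off)."""
    if ts.n_vertices != surface.n_vertices:
        raise StructuralError("timeseries and surface differ in vertex count")
    smoothed = diffuse_on_surface(ts.data.T, surface, sigma_mm).T
    return TimeseriesMatrix(smoothed, hemisphere=ts.hemisphere,
                            subject_id=ts.subject_id)


def migp(
    subjects: list[TimeseriesMatrix],
    d_internal: int,
    seed: int = 0,
) -> np.ndarray:
    """MELODIC-style incremental group PCA.

    Streams subjects in a seeded random order, concatenating each subject's
    frames onto the running low-rank representation and truncating back to
    ``d_internal`` rows by SVD.  The returned (d_internal x vertices) block's
    row space approximates the top eigenspace of the full concatenation.
    """
    if not subjects:
        raise ValueError("no subjects")
    total = sum(s.n_frames for s in subjects)
    if d_internal > total:
        raise StructuralError(
            f"d_internal={d_internal} exceeds total frame count {total}"
        )
    n_vertices = subjects[0].n_vertices
    for s in subjects:
        if s.n_vertices != n_vertices:
            raise StructuralError("subjects differ in vertex count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    w: np.ndarray | None = None
    for idx in order:
        block = subjects[idx].data
        w = block if w is None else np.vstack([w, block])
        if w.shape[0] > d_internal:
            u, s_vals, vt = np.linalg.svd(w, full_matrices=False)
            w = s_vals[:d_internal, None] * vt[:d_internal]
    return w


def mirror_concatenate(
    left_block: np.ndarray,
    right_block: np.ndarray,
    mirror_perm: np.ndarray | None,
) -> np.ndarray:
    """Stack the left block on top of the mirrored right block.

    Exchanging the hemisphere inputs permutes rows only (same multiset),
    so downstream ICA sees a hemispherically unbiased data matrix.
    """
    if mirror_perm is None:
        raise StructuralError(
            "mirror permutation required; use a mirror-symmetric mesh"
        )
    left_block = np.atleast_2d(left_block)
    right_block = np.atleast_2d(right_block)
    if left_block.shape[1] != right_block.shape[1]:
        raise StructuralError("hemisphere blocks differ in vertex count")
    if left_block.shape[1] != len(mirror_perm):
        raise StructuralError("mirror permutation length mismatch")
    return np.vstack([left_block, right_block[:, mirror_perm]])


def group_ica(
    reduced: np.ndarray,
    d: int = 8,
    seed: int = 0,
    max_restarts: int = 5,
    max_iter: int = 1000,
) -> ICADecomposition:
    """Spatial group ICA of the reduced matrix (rows x vertices).

    Fixed-point ICA (logcosh contrast, deflation) with vertices as samples.
    Deterministic under a fixed seed; component sign is fixed so spatial
    skewness is nonnegative, and maps are Z-scored.  Non-convergent runs
    are retried with consecutive seeds before failing.
    """
    reduced = np.atleast_2d(np.asarray(reduced, dtype=np.float64))
    if d > reduced.shape[0]:
        raise StructuralError(
            f"ICA dimensionality {d} exceeds the {reduced.shape[0]} rows of "
            "the reduced matrix"
        )
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        ica = FastICA(
            n_components=d,
            algorithm="deflation",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                sources = ica.fit_transform(reduced.T)  # (V, d)
            except Exception as err:  # numerical failure: retry
                last_err = err
                continue
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            last_err = RuntimeError(f"ICA did not converge with seed {seed + attempt}")
            continue
        maps = sources.T
        # deterministic orientation: nonnegative spatial skewness
        centred = maps - maps.mean(axis=1, keepdims=True)
        skew = (centred**3).mean(axis=1)
        flip = np.where(skew < 0, -1.0, 1.0)
        maps = maps * flip[:, None]
        std = maps.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        maps = (maps - maps.mean(axis=1, keepdims=True)) / std
        mixing = ica.mixing_ * flip[None, :]
        return ICADecomposition(
            spatial_maps=maps, mixing=mixing, dimensionality=d, seed=seed + attempt
        )
    raise RuntimeError(
        f"group ICA failed after {max_restarts} seeded restarts: {last_err}"
    )


def dual_regression(
    group_maps: np.ndarray,
    subject_ts: TimeseriesMatrix,
    normalise_timecourses: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage dual regression.

    Stage 1 regresses every frame on the group spatial maps, giving one
    timecourse per component; stage 2 regresses every vertex's timeseries
    on the (variance-normalised) timecourses, giving subject spatial maps.
    Identically-zero group maps yield zero timecourses and zero maps;
    collinear nonzero maps are an error.
    """
    maps = np.atleast_2d(np.asarray(group_maps, dtype=np.float64))
    d, n_vertices = maps.shape
    y = subject_ts.data
    if y.shape[1] != n_vertices:
        raise StructuralError(
            f"timeseries has {y.shape[1]} vertices, group maps have {n_vertices}"
        )
    nonzero = np.any(maps != 0.0, axis=1)
    act = maps[nonzero]
    if act.shape[0]:
        rank = np.linalg.matrix_rank(act)
        if rank < act.shape[0]:
            gram = np.corrcoef(act)
            pairs = [
                (int(i), int(j))
                for i in range(len(gram))
                for j in range(i + 1, len(gram))
                if abs(gram[i, j]) > 0.999
            ]
            idx = np.nonzero(nonzero)[0]
            named = [(int(idx[i]), int(idx[j])) for i, j in pairs]
            raise StructuralError(
                f"group maps are rank deficient; collinear component pairs: {named}"
            )
    timecourses = np.zeros((y.shape[0], d))
    if act.shape[0]:
        tc_act = np.linalg.lstsq(act.T, y.T, rcond=None)[0].T  # (T, d_act)
        timecourses[:, nonzero] = tc_act
    subject_maps = np.zeros((d, n_vertices))
    if act.shape[0]:
        a = timecourses[:, nonzero]
        if normalise_timecourses:
            sd = a.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            a = a / sd
        betas = np.linalg.lstsq(a, y, rcond=None)[0]  # (d_act, V)
        subject_maps[nonzero] = betas
    return timecourses, subject_maps
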