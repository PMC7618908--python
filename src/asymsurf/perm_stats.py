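"""Vertex-wise GLM, mesh TFCE, and permutation FWE inference.

The inference chain: ordinary-least-squares t maps per contrast
(:func:`fit_glm`), threshold-free cluster enhancement on the mesh vertex
graph (:func:`tfce`), and a max-statistic permutation test
(:func:`permutation_test`) correcting family-wise error jointly across
vertices, image features, and design contrasts.  One-sample analyses use
sign flipping of nuisance-residualised data; general designs use
Freedman-Lane shuffling.  :func:`cohort_stats` provides the cohort-level
demographic tests (one- and two-sample t, chi-squared independence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from asymsurf._tfce import tfce_kernel
from asymsurf.errors import StructuralError
from asymsurf.mesh_core import MetricMap, SphericalMesh

__all__ = [
    "DesignMatrix",
    "Contrast",
    "TFCEParams",
    "StatResult",
    "fit_glm",
    "tfce",
    "permutation_test",
    "significance_mask",
    "cohort_stats",
    "SIGNIFICANCE_NEGLOG10P",
]

#: significance convention: -log10(p_fwe) must exceed this (alpha = 0.05)
SIGNIFICANCE_NEGLOG10P = 1.3

_T_SENTINEL = 1e6

STANDARD_COVARIATE_COLUMNS = [
    "ga_weeks",
    "pma_weeks",
    "sex",
    "bwz",
    "tbv_cm3",
    "hemi_vol_asym_cm3",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with named columns."""

    matrix: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[1] != len(self.columns):
            raise StructuralError(
                f"design has {self.matrix.shape[1]} columns but "
                f"{len(self.columns)} names"
            )
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise StructuralError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_covariates(
        cls,
        covariates: pd.DataFrame,
        columns: list[str] | None = None,
        demean: bool = True,
    ) -> "DesignMatrix":
        """Intercept plus (optionally demeaned) covariate columns.

        Demeaning makes the intercept contrast estimate the cohort mean at
        average covariate values, the conventional one-sample setup.
        """
        cols = columns if columns is not None else STANDARD_COVARIATE_COLUMNS
        missing = [c for c in cols if c not in covariates.columns]
        if missing:
            raise StructuralError(f"covariate table missing columns: {missing}")
        x = covariates[cols].to_numpy(dtype=np.float64)
        if demean:
            x = x - x.mean(axis=0)
        mat = np.column_stack([np.ones(len(x)), x])
        return cls(mat, ["intercept", *cols])


@dataclass
class Contrast:
    """One-sided contrast over design columns."""

    weights: np.ndarray
    label: str = "C1"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not np.any(self.weights != 0.0):
            raise StructuralError(f"contrast {self.label} has no nonzero weight")

    @classmethod
    def on_column(cls, design: DesignMatrix, column: str, sign: float = 1.0,
                  label: str | None = None) -> "Contrast":
        w = np.zeros(len(design.columns))
        w[design.columns.index(column)] = sign
        return cls(w, label=label or f"{'+' if sign > 0 else '-'}{column}")


@dataclass
class TFCEParams:
    """TFCE settings: height exponent H, extent exponent E, threshold step
    dh (None: max(stat)/100, held fixed across permutations), and the
    group-average vertex areas (mm^2) feeding cluster extent."""

    areas: np.ndarray
    height_exp: float = 2.0
    extent_exp: float = 0.6
    dh: float | None = None
    n_steps: int = 100

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=np.float64)
        if self.height_exp <= 0 or self.extent_exp <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")


@dataclass
class StatResult:
    """Per-vertex t, TFCE, and FWE-corrected -log10 p for one feature x contrast."""

    t: np.ndarray
    tfce: np.ndarray
    neglog10p: np.ndarray
    feature: str
    contrast: str
    n_permutations: int
    seed: int | None = None
    zero_variance: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def _glm_machinery(x: np.ndarray, c: np.ndarray):
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    cgc = float(c @ xtx_inv @ c)
    return pinv, cgc, n - p


def _t_from_data(y: np.ndarray, x: np.ndarray, c: np.ndarray,
                 pinv: np.ndarray, cgc: float, dof: int):
    beta = pinv @ y
    resid = y - x @ beta
    ss = np.einsum("ij,ij->j", resid, resid)
    eff = c @ beta
    denom2 = ss / dof * cgc
    zero = denom2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(denom2)
    if np.any(zero):
        t[zero] = np.sign(eff[zero]) * _T_SENTINEL
        t[zero & (eff == 0.0)] = 0.0
    np.clip(t, -_T_SENTINEL, _T_SENTINEL, out=t)
    return t, zero


def fit_glm(y: np.ndarray, design: DesignMatrix, contrast: Contrast) -> StatResult:
    """OLS t-statistic map for one contrast.

    ``y`` is subjects x vertices.  Vertices with zero residual variance get
    a capped sentinel t (sign of the effect, magnitude 1e6) and are flagged.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise StructuralError(
            f"data has {y.shape[0]} subjects but design has {x.shape[0]} rows"
        )
    if x.shape[0] <= x.shape[1]:
        raise StructuralError("need more subjects than design columns")
    if len(contrast.weights) != x.shape[1]:
        raise StructuralError("contrast length does not match design columns")
    pinv, cgc, dof = _glm_machinery(x, contrast.weights)
    t, zero = _t_from_data(y, x, contrast.weights, pinv, cgc, dof)
    return StatResult(
        t=t, tfce=np.array([]), neglog10p=np.array([]),
        feature="", contrast=contrast.label, n_permutations=0,
        zero_variance=zero if zero.any() else None,
    )


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


def _mesh_csr(mesh: SphericalMesh):
    adj = mesh.adjacency()
    return adj.indptr.astype(np.int64), adj.indices.astype(np.int64)


def tfce(
    stat: np.ndarray | MetricMap,
    mesh: SphericalMesh,
    params: TFCEParams,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    Sweeps thresholds h = dh, 2dh, ... <= max(stat); every vertex in a
    suprathreshold component of total vertex-area e accumulates
    e^E * h^H * dh.  Output is zero wherever stat <= 0; raising any input
    value never lowers any output value.
    """
    values = stat.values if isinstance(stat, MetricMap) else np.asarray(stat)
    values = np.ascontiguousarray(values, dtype=np.float64)
    if len(values) != mesh.n_vertices:
        raise StructuralError("stat map and mesh differ in vertex count")
    if len(params.areas) != mesh.n_vertices:
        raise StructuralError("TFCE areas and mesh differ in vertex count")
    step = dh if dh is not None else params.dh
    if step is None:
        smax = float(values.max(initial=0.0))
        if smax <= 0.0:
            return np.zeros_like(values)
        step = smax / params.n_steps
    if step <= 0:
        raise ValueError("dh must be positive")
    indptr, indices = _mesh_csr(mesh)
    return tfce_kernel(
        values, indptr, indices, params.areas, float(step),
        float(params.height_exp), float(params.extent_exp),
    )


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


def _intercept_only_contrast(design: DesignMatrix, contrast: Contrast) -> None:
    try:
        icol = design.columns.index("intercept")
    except ValueError as err:
        raise StructuralError("sign-flip scheme needs an intercept column") from err
    nz = np.nonzero(contrast.weights)[0]
    if list(nz) != [icol]:
        raise StructuralError(
            f"sign-flip scheme requires an intercept-only contrast; "
            f"'{contrast.label}' weights other columns"
        )


def permutation_test(
    data: dict[str, np.ndarray],
    design: DesignMatrix,
    contrasts: list[Contrast],
    mesh: SphericalMesh,
    params: TFCEParams,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "sign_flip",
    families: dict[str, str] | None = None,
) -> dict[tuple[str, str], StatResult]:
    """Max-TFCE permutation test across features and contrasts.

    ``data`` maps feature name -> (subjects x vertices) array.  One shared
    permutation schedule drives every feature and contrast; the null is the
    maximum TFCE over vertices, features, and contrasts (or within the
    family named per feature when ``families`` is given).  p-values use the
    (1 + count) / (1 + n_perm) convention, so they are never below
    1/(n_perm + 1).
    """
    if scheme not in ("sign_flip", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme '{scheme}'")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very low; p-value resolution is "
            f"{1.0 / (n_perm + 1):.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    x = design.matrix
    n = x.shape[0]
    rng = np.random.default_rng(seed)

    if scheme == "sign_flip":
        for c in contrasts:
            _intercept_only_contrast(design, c)

    # per-contrast machinery, with data residualised per Freedman-Lane
    machinery = []
    for c in contrasts:
        pinv, cgc, dof = _glm_machinery(x, c.weights)
        nuis = x[:, c.weights == 0.0]
        if nuis.shape[1]:
            hz = nuis @ np.linalg.pinv(nuis)
            rz = np.eye(n) - hz
        else:
            hz = np.zeros((n, n))
            rz = np.eye(n)
        machinery.append((pinv, cgc, dof, hz, rz))

    feats = list(data.keys())
    for f in feats:
        if data[f].shape != (n, mesh.n_vertices):
            raise StructuralError(
                f"feature '{f}' has shape {data[f].shape}, expected "
                f"({n}, {mesh.n_vertices})"
            )

    fam_of = {f: (families or {}).get(f, "all") for f in feats}
    fam_names = sorted(set(fam_of.values()))

    # observed statistics and the fixed dh per feature x contrast
    observed: dict[tuple[str, str], dict] = {}
    for f in feats:
        for ci, c in enumerate(contrasts):
            pinv, cgc, dof, hz, rz = machinery[ci]
            t, zero = _t_from_data(data[f], x, c.weights, pinv, cgc, dof)
            smax = float(np.maximum(t, 0.0).max())
            step = params.dh if params.dh is not None else (
                smax / params.n_steps if smax > 0 else 1.0
            )
            tf = tfce(t, mesh, params, dh=step)
            observed[(f, c.label)] = {
                "t": t, "tfce": tf, "dh": step, "zero": zero,
                "count": np.zeros(mesh.n_vertices), "family": fam_of[f],
            }

    resid = {
        (f, ci): machinery[ci][4] @ data[f]
        for f in feats
        for ci in range(len(contrasts))
    }
    fitted = {
        (f, ci): machinery[ci][3] @ data[f]
        for f in feats
        for ci in range(len(contrasts))
    }

    for _ in range(n_perm):
        if scheme == "sign_flip":
            flips = rng.choice([-1.0, 1.0], size=n)
        else:
            order = rng.permutation(n)
        fam_max = {fam: 0.0 for fam in fam_names}
        perm_tfce: dict[tuple[str, str], np.ndarray] = {}
        for f in feats:
            for ci, c in enumerate(contrasts):
                pinv, cgc, dof, hz, rz = machinery[ci]
                if scheme == "sign_flip":
                    ystar = fitted[(f, ci)] + flips[:, None] * resid[(f, ci)]
                else:
                    ystar = fitted[(f, ci)] + resid[(f, ci)][order]
                t, _ = _t_from_data(ystar, x, c.weights, pinv, cgc, dof)
                obs = observed[(f, c.label)]
                tf = tfce(t, mesh, params, dh=obs["dh"])
                perm_tfce[(f, c.label)] = tf
                fam = obs["family"]
                fam_max[fam] = max(fam_max[fam], float(tf.max(initial=0.0)))
        for key, obs in observed.items():
            obs["count"] += fam_max[obs["family"]] >= obs["tfce"]

    results: dict[tuple[str, str], StatResult] = {}
    for (f, lbl), obs in observed.items():
        p = (1.0 + obs["count"]) / (1.0 + n_perm)
        results[(f, lbl)] = StatResult(
            t=obs["t"],
            tfce=obs["tfce"],
            neglog10p=-np.log10(p),
            feature=f,
            contrast=lbl,
            n_permutations=n_perm,
            seed=seed,
            zero_variance=obs["zero"] if obs["zero"].any() else None,
        )
    return results


def significance_mask(result: StatResult, alpha: float = 0.05) -> np.ndarray:
    """Strict threshold: -log10(p_fwe) > -log10(alpha) (1.301 at 0.05)."""
    return result.neglog10p > -np.log10(alpha)


# ---------------------------------------------------------------------------
# Cohort demographics
# ---------------------------------------------------------------------------


def cohort_stats(
    covariates: pd.DataFrame,
    group_col: str = "group",
    continuous: tuple[str, ...] = ("ga_weeks", "pma_weeks", "bwz", "tbv_cm3"),
    asym_col: str = "hemi_vol_asym_cm3",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Demographic test table: per-group one-sample t on hemispheric volume
    asymmetry, between-group two-sample t on continuous covariates, and a
    chi-squared independence test on sex x group; medians and IQRs included.
    """
    if group_col in covariates.columns:
        groups = {g: d for g, d in covariates.groupby(group_col)}
    else:
        groups = {"all": covariates}
    for g, d in groups.items():
        if len(d) < 2:
            raise StructuralError(f"group '{g}' has n={len(d)} < 2")
    rows = []
    for g, d in groups.items():
        vals = d[asym_col].to_numpy(dtype=float)
        if np.allclose(vals, vals[0]) and vals[0] == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_1samp(vals, 0.0)
        rows.append(
            {
                "test": "one_sample_t",
                "variable": asym_col,
                "group": g,
                "n": len(d),
                "statistic": float(t),
                "p": float(p),
                "median": float(np.median(vals)),
                "iqr_low": float(np.percentile(vals, 25)),
                "iqr_high": float(np.percentile(vals, 75)),
            }
        )
    if len(groups) == 2:
        (g1, d1), (g2, d2) = groups.items()
        for col in continuous:
            a = d1[col].to_numpy(dtype=float)
            b = d2[col].to_numpy(dtype=float)
            if np.array_equal(np.sort(a), np.sort(b)):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(a, b)
            rows.append(
                {
                    "test": "two_sample_t",
                    "variable": col,
                    "group": f"{g1} vs {g2}",
                    "n": len(a) + len(b),
                    "statistic": float(t),
                    "p": float(p),
                    "median": float(np.median(np.concatenate([a, b]))),
                    "iqr_low": float(np.percentile(np.concatenate([a, b]), 25)),
                    "iqr_high": float(np.percentile(np.concatenate([a, b]), 75)),
                }
            )
        table = pd.crosstab(covariates[group_col], covariates[sex_col])
        if table.to_numpy().min() >= 0 and table.shape == (2, 2) and \
                len(np.unique(table.to_numpy())) == 1:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = sps.chi2_contingency(table)
        rows.append(
            {
                "test": "chi2_independence",
                "variable": sex_col,
                "group": f"{g1} vs {g2}",
                "n": len(covariates),
                "statistic": float(chi2),
                "p": float(p),
                "median": np.nan,
                "iqr_low": np.nan,
                "iqr_high": np.nan,
            }
        )
    return pd.DataFrame(rows)
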