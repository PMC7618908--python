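import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from asymsurf.errors import StructuralError
from asymsurf.mesh_core import surface_from_mesh, vertex_areas
from asymsurf.perm_stats import (
    SIGNIFICANCE_NEGLOG10P,
    Contrast,
    DesignMatrix,
    StatResult,
    TFCEParams,
    cohort_stats,
    fit_glm,
    permutation_test,
    significance_mask,
    tfce,
)


def tfce_oracle(stat, mesh, areas, dh, h_exp=2.0, e_exp=0.6):
    """Brute-force per-threshold connected-component sweep (pure Python)."""
    n = len(stat)
    adj = [[] for _ in range(n)]
    for a, b in mesh.edges():
        adj[a].append(int(b))
        adj[b].append(int(a))
    out = np.zeros(n)
    smax = max(0.0, float(np.max(stat)))
    k = 1
    h = dh
    while h <= smax:
        labels = [-1] * n
        n_comp = 0
        for v in range(n):
            if stat[v] >= h and labels[v] < 0:
                labels[v] = n_comp
                stack = [v]
                while stack:
                    u = stack.pop()
                    for w in adj[u]:
                        if stat[w] >= h and labels[w] < 0:
                            labels[w] = n_comp
                            stack.append(w)
                n_comp += 1
        comp_area = [0.0] * n_comp
        for v in range(n):
            if stat[v] >= h:
                comp_area[labels[v]] += areas[v]
        for v in range(n):
            if stat[v] >= h:
                out[v] += comp_area[labels[v]] ** e_exp * h**h_exp * dh
        k += 1
        h = dh * k
    return out


@pytest.fixture(scope="module")
def areas_lv2(mesh_lv2):
    return vertex_areas(surface_from_mesh(mesh_lv2, radius=50.0)).values


@pytest.fixture(scope="module")
def areas_lv3(mesh_lv3):
    return vertex_areas(surface_from_mesh(mesh_lv3, radius=50.0)).values


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


class TestFitGLM:
    def test_one_sample_closed_form(self, rng):
        y = rng.normal(0.3, 1.0, size=(25, 40))
        design = DesignMatrix(np.ones((25, 1)), ["intercept"])
        res = fit_glm(y, design, Contrast([1.0], "C1"))
        expected = y.mean(axis=0) / (y.std(axis=0, ddof=1) / np.sqrt(25))
        assert np.abs(res.t - expected).max() <= 1e-10

    def test_two_sample_pooled_closed_form(self, rng):
        # textbook pooled-variance two-sample t oracle
        n1, n2 = 12, 15
        y = np.vstack(
            [rng.normal(0, 1, (n1, 30)), rng.normal(0.5, 1, (n2, 30))]
        )
        group = np.r_[np.ones(n1), np.zeros(n2)]
        design = DesignMatrix(
            np.column_stack([np.ones(n1 + n2), group]), ["intercept", "group"]
        )
        res = fit_glm(y, design, Contrast([0.0, 1.0], "grp"))
        a, b = y[:n1], y[n1:]
        sp2 = (
            (n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)
        ) / (n1 + n2 - 2)
        expected = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(
            sp2 * (1 / n1 + 1 / n2)
        )
        assert np.abs(res.t - expected).max() <= 1e-10

    def test_orthogonal_nuisance_only_rescales_dof(self, rng):
        # an orthogonal nuisance that explains nothing leaves the contrast
        # estimate and residuals unchanged; the t statistic changes only by
        # the exact residual-dof factor sqrt((n-2)/(n-1))
        n = 30
        nuis = rng.normal(size=n)
        nuis -= nuis.mean()  # orthogonal to the intercept
        y = rng.normal(size=(n, 20))
        y -= np.outer(nuis, nuis @ y) / (nuis @ nuis)  # orthogonal to nuisance
        design1 = DesignMatrix(np.ones((n, 1)), ["intercept"])
        t1 = fit_glm(y, design1, Contrast([1.0], "C1")).t
        design2 = DesignMatrix(
            np.column_stack([np.ones(n), nuis]), ["intercept", "z"]
        )
        t2 = fit_glm(y, design2, Contrast([1.0, 0.0], "C1")).t
        assert np.abs(t2 - t1 * np.sqrt((n - 2) / (n - 1))).max() <= 1e-8

    def test_zero_variance_sentinel(self):
        y = np.tile([[1.0, 0.0]], (10, 1))
        design = DesignMatrix(np.ones((10, 1)), ["intercept"])
        res = fit_glm(y, design, Contrast([1.0], "C1"))
        assert res.t[0] == 1e6
        assert res.t[1] == 0.0
        assert res.zero_variance is not None and res.zero_variance.all()

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(StructuralError, match="rank"):
            DesignMatrix(x, ["a", "b"])


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


class TestTFCE:
    def test_all_zero_map(self, mesh_lv2, areas_lv2):
        params = TFCEParams(areas=areas_lv2)
        out = tfce(np.zeros(mesh_lv2.n_vertices), mesh_lv2, params)
        assert np.all(out == 0.0)

    def test_negative_values_give_zero(self, mesh_lv2, areas_lv2, rng):
        stat = -np.abs(rng.normal(size=mesh_lv2.n_vertices))
        params = TFCEParams(areas=areas_lv2)
        out = tfce(stat, mesh_lv2, params, dh=0.05)
        assert np.all(out == 0.0)

    def test_isolated_vertex_analytic_sum(self, mesh_lv2, areas_lv2):
        # single suprathreshold vertex: output = sum_k a^0.6 (k dh)^2 dh
        stat = np.zeros(mesh_lv2.n_vertices)
        vtx, s, dh = 7, 1.37, 0.05
        stat[vtx] = s
        params = TFCEParams(areas=areas_lv2)
        out = tfce(stat, mesh_lv2, params, dh=dh)
        a = areas_lv2[vtx]
        expected = 0.0
        k = 1
        while dh * k <= s:
            expected += a**0.6 * (dh * k) ** 2.0 * dh
            k += 1
        assert out[vtx] == pytest.approx(expected, rel=1e-12)
        assert np.all(out[np.arange(len(out)) != vtx] == 0.0)

    def test_bitwise_equals_bruteforce_50_maps(self, mesh_lv2, areas_lv2):
        rng = np.random.default_rng(7)
        params = TFCEParams(areas=areas_lv2)
        for _ in range(50):
            stat = rng.normal(size=mesh_lv2.n_vertices)
            smax = max(float(stat.max()), 0.0)
            if smax == 0.0:
                continue
            dh = smax / 100.0
            fast = tfce(stat, mesh_lv2, params, dh=dh)
            slow = tfce_oracle(stat, mesh_lv2, areas_lv2, dh)
            assert np.array_equal(fast, slow)

    def test_monotone_in_input(self, mesh_lv2, areas_lv2, rng):
        params = TFCEParams(areas=areas_lv2)
        stat = np.abs(rng.normal(size=mesh_lv2.n_vertices))
        dh = float(stat.max()) / 100.0
        base = tfce(stat, mesh_lv2, params, dh=dh)
        bumped = stat.copy()
        bumped[5] += 0.5
        out = tfce(bumped, mesh_lv2, params, dh=dh)
        assert np.all(out >= base - 1e-15)

    def test_splitting_component_never_raises_values(self, mesh_lv2, areas_lv2):
        # cut-vertex oracle: recompute both configurations directly
        rng = np.random.default_rng(3)
        stat = np.abs(rng.normal(size=mesh_lv2.n_vertices)) + 0.5
        dh = float(stat.max()) / 80.0
        params = TFCEParams(areas=areas_lv2)
        base = tfce(stat, mesh_lv2, params, dh=dh)
        cut = stat.copy()
        cut[10] = 0.0
        out = tfce(cut, mesh_lv2, params, dh=dh)
        keep = np.arange(mesh_lv2.n_vertices) != 10
        assert np.all(out[keep] <= base[keep] + 1e-12)

    def test_nonpositive_dh_rejected(self, mesh_lv2, areas_lv2, rng):
        params = TFCEParams(areas=areas_lv2)
        with pytest.raises(ValueError, match="dh"):
            tfce(np.ones(mesh_lv2.n_vertices), mesh_lv2, params, dh=0.0)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


class TestPermutationTest:
    def _setup(self, mesh, areas, n):
        design = DesignMatrix(np.ones((n, 1)), ["intercept"])
        contrasts = [Contrast([1.0], "C1"), Contrast([-1.0], "C2")]
        params = TFCEParams(areas=areas)
        return design, contrasts, params

    def test_strong_effect_saturates_p(self, mesh_lv3, areas_lv3):
        rng = np.random.default_rng(0)
        n, n_perm = 30, 500
        y = rng.normal(0, 0.1, size=(n, mesh_lv3.n_vertices))
        patch = mesh_lv3.vertices[:, 2] > 0.9
        y[:, patch] += 1.0  # 10x the noise sd
        design, contrasts, params = self._setup(mesh_lv3, areas_lv3, n)
        res = permutation_test(
            {"ai": y}, design, contrasts, mesh_lv3, params,
            n_perm=n_perm, seed=1,
        )
        p_min = 10 ** (-res[("ai", "C1")].neglog10p[patch].max())
        assert p_min == pytest.approx(1.0 / (n_perm + 1), rel=1e-9)

    def test_p_never_below_permutation_bound(self, mesh_lv2, areas_lv2):
        rng = np.random.default_rng(5)
        n, n_perm = 12, 200
        y = rng.normal(size=(n, mesh_lv2.n_vertices))
        design, contrasts, params = self._setup(mesh_lv2, areas_lv2, n)
        res = permutation_test(
            {"ai": y}, design, contrasts, mesh_lv2, params,
            n_perm=n_perm, seed=2,
        )
        for r in res.values():
            p = 10 ** (-r.neglog10p)
            assert np.all(p >= 1.0 / (n_perm + 1) - 1e-12)
            assert np.all(p <= 1.0 + 1e-12)

    def test_low_n_perm_warns(self, mesh_lv2, areas_lv2, rng):
        y = rng.normal(size=(8, mesh_lv2.n_vertices))
        design, contrasts, params = self._setup(mesh_lv2, areas_lv2, 8)
        with pytest.warns(RuntimeWarning, match="n_perm"):
            permutation_test(
                {"ai": y}, design, contrasts, mesh_lv2, params,
                n_perm=50, seed=3,
            )

    def test_sign_flip_with_covariate_contrast_rejected(self, mesh_lv2,
                                                        areas_lv2, rng):
        n = 10
        y = rng.normal(size=(n, mesh_lv2.n_vertices))
        design = DesignMatrix(
            np.column_stack([np.ones(n), rng.normal(size=n)]),
            ["intercept", "pma"],
        )
        params = TFCEParams(areas=areas_lv2)
        with pytest.raises(StructuralError, match="intercept-only"):
            permutation_test(
                {"ai": y}, design, [Contrast([0.0, 1.0], "C3")],
                mesh_lv2, params, n_perm=100, seed=0,
            )

    def test_freedman_lane_covariate_contrast_runs(self, mesh_lv2, areas_lv2,
                                                   rng):
        n = 20
        y = rng.normal(size=(n, mesh_lv2.n_vertices))
        design = DesignMatrix(
            np.column_stack([np.ones(n), rng.normal(size=n)]),
            ["intercept", "pma"],
        )
        params = TFCEParams(areas=areas_lv2)
        res = permutation_test(
            {"ai": y}, design, [Contrast([0.0, 1.0], "C3")],
            mesh_lv2, params, n_perm=100, seed=0, scheme="freedman_lane",
        )
        assert ("ai", "C3") in res

    def test_joint_fwe_monotone_in_family_size(self, mesh_lv2, areas_lv2):
        # correcting across more features never decreases any p-value
        rng = np.random.default_rng(11)
        n, n_perm = 15, 300
        y1 = rng.normal(size=(n, mesh_lv2.n_vertices))
        y2 = rng.normal(size=(n, mesh_lv2.n_vertices))
        design, contrasts, params = self._setup(mesh_lv2, areas_lv2, n)
        solo = permutation_test(
            {"a": y1}, design, contrasts, mesh_lv2, params,
            n_perm=n_perm, seed=4,
        )
        joint = permutation_test(
            {"a": y1, "b": y2}, design, contrasts, mesh_lv2, params,
            n_perm=n_perm, seed=4,
        )
        for lbl in ("C1", "C2"):
            assert np.all(
                joint[("a", lbl)].neglog10p <= solo[("a", lbl)].neglog10p + 1e-12
            )

    def test_determinism(self, mesh_lv2, areas_lv2, rng):
        y = rng.normal(size=(10, mesh_lv2.n_vertices))
        design, contrasts, params = self._setup(mesh_lv2, areas_lv2, 10)
        a = permutation_test({"ai": y}, design, contrasts, mesh_lv2, params,
                             n_perm=150, seed=9)
        b = permutation_test({"ai": y}, design, contrasts, mesh_lv2, params,
                             n_perm=150, seed=9)
        for key in a:
            assert np.array_equal(a[key].neglog10p, b[key].neglog10p)

    def test_fixed_vertex_p_super_uniform(self, mesh_lv2, areas_lv2):
        # under the null the FWE p at a fixed vertex is super-uniform:
        # empirical CDF at 0.05 stays below 0.07
        rng = np.random.default_rng(21)
        design, contrasts, params = self._setup(mesh_lv2, areas_lv2, 12)
        n_rep = 120
        hits = 0
        for _ in range(n_rep):
            y = rng.normal(size=(12, mesh_lv2.n_vertices))
            res = permutation_test(
                {"ai": y}, design, contrasts[:1], mesh_lv2, params,
                n_perm=150, seed=int(rng.integers(1 << 30)),
            )
            p0 = 10 ** (-res[("ai", "C1")].neglog10p[0])
            hits += p0 <= 0.05
        assert hits / n_rep <= 0.07


class TestSignificanceMask:
    def _result(self, p):
        return StatResult(
            t=np.zeros_like(p), tfce=np.zeros_like(p),
            neglog10p=-np.log10(p), feature="f", contrast="C1",
            n_permutations=1000,
        )

    def test_p_exactly_alpha_excluded(self):
        res = self._result(np.array([0.05]))
        assert not significance_mask(res, alpha=0.05).any()

    def test_p_just_below_alpha_included(self):
        res = self._result(np.array([0.049]))
        assert significance_mask(res, alpha=0.05).all()

    def test_threshold_convention_matches_1p3(self):
        # -log10(0.05) = 1.30103 > the conventional 1.3 cut-off
        assert -np.log10(0.05) == pytest.approx(1.30103, abs=1e-5)
        assert -np.log10(0.05) > SIGNIFICANCE_NEGLOG10P


class TestCohortStats:
    def _cov(self, rng, n1=20, n2=15, asym_shift=-1.8):
        rows = []
        for i in range(n1 + n2):
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "group": "term" if i < n1 else "preterm",
                    "ga_weeks": rng.uniform(37, 42),
                    "pma_weeks": rng.uniform(38, 44),
                    "sex": int(rng.integers(0, 2)),
                    "bwz": rng.normal(),
                    "tbv_cm3": rng.normal(340, 30),
                    "hemi_vol_asym_cm3": rng.normal(asym_shift, 1.5),
                }
            )
        return pd.DataFrame(rows)

    def test_zero_asymmetry_gives_t0_p1(self, rng):
        df = self._cov(rng)
        df["hemi_vol_asym_cm3"] = 0.0
        table = cohort_stats(df)
        one = table[table.test == "one_sample_t"]
        assert np.allclose(one.statistic, 0.0)
        assert np.allclose(one.p, 1.0)

    def test_identical_groups_two_sample_t0(self, rng):
        df = self._cov(rng, n1=10, n2=10)
        df.loc[df.group == "preterm", "ga_weeks"] = df.loc[
            df.group == "term", "ga_weeks"
        ].to_numpy()
        table = cohort_stats(df)
        row = table[(table.test == "two_sample_t") & (table.variable == "ga_weeks")]
        assert np.isclose(float(row.statistic.iloc[0]), 0.0)

    def test_balanced_sex_chi2_zero(self, rng):
        df = self._cov(rng, n1=20, n2=20)
        df["sex"] = ([0] * 10 + [1] * 10) * 2  # perfect independence
        table = cohort_stats(df)
        row = table[table.test == "chi2_independence"]
        assert float(row.statistic.iloc[0]) == pytest.approx(0.0)
        assert float(row.p.iloc[0]) == pytest.approx(1.0)

    def test_one_sample_matches_scipy(self, rng):
        df = self._cov(rng)
        table = cohort_stats(df)
        for grp in ("term", "preterm"):
            vals = df[df.group == grp]["hemi_vol_asym_cm3"]
            t, p = sps.ttest_1samp(vals, 0.0)
            row = table[(table.test == "one_sample_t") & (table.group == grp)]
            assert float(row.statistic.iloc[0]) == pytest.approx(float(t))
            assert float(row.p.iloc[0]) == pytest.approx(float(p))

    def test_tiny_group_rejected(self, rng):
        df = self._cov(rng, n1=1, n2=10)
        with pytest.raises(StructuralError, match="n=1"):
            cohort_stats(df)
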