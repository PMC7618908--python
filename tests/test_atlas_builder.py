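import numpy as np
import pytest

from asymsurf.atlas_builder import (
    SpatioTemporalAtlas,
    Template,
    adaptive_kernel_weights,
    build_template_chain,
    build_weekly_template,
    dedrift,
    refine_atlas,
    resample_subject,
    subject_to_template,
    symmetrize_template,
)
from asymsurf.errors import StructuralError
from asymsurf.mesh_core import MetricMap
from asymsurf.records import SubjectRecord
from asymsurf.sphere_warp import (
    DeformationField,
    average_deformations,
    geodesic_distance,
    identity_field,
    invert,
    resample_metric,
)

from conftest import band_limited_field, rotation_matrix, smooth_random_warp


def even_field(mesh, seed):
    """Mirror-even band-limited field (a valid symmetric template map)."""
    f = band_limited_field(mesh, seed)
    return 0.5 * (f + f[mesh.mirror_perm])


def make_subject(sid, age, mesh, sulc, thickness=None):
    metrics = {
        "sulc": {
            "left": MetricMap(sulc, "left", "sulc"),
            "right": MetricMap(sulc.copy(), "right", "sulc"),
        }
    }
    if thickness is not None:
        metrics["thickness"] = {
            "left": MetricMap(thickness, "left", "thickness"),
            "right": MetricMap(thickness.copy(), "right", "thickness"),
        }
    return SubjectRecord(
        subject_id=sid, age_weeks=age, covariates={}, metrics=metrics
    )


# ---------------------------------------------------------------------------
# adaptive kernel weights
# ---------------------------------------------------------------------------


class TestKernelWeights:
    def test_all_at_target_uniform(self):
        w = adaptive_kernel_weights(np.full(12, 40.0), 40, min_effective_n=8)
        assert np.allclose(w, 1.0 / 12.0)

    def test_weights_sum_to_one(self, rng):
        ages = rng.uniform(37, 44, size=30)
        w = adaptive_kernel_weights(ages, 40, min_effective_n=8)
        assert abs(w.sum() - 1.0) <= 1e-12

    def test_effective_n_reached(self, rng):
        # derived oracle: recompute (sum w)^2 / sum w^2 directly
        ages = rng.uniform(28, 44, size=40)
        for week in (30, 36, 40, 44):
            w = adaptive_kernel_weights(ages, week, min_effective_n=8)
            ess = w.sum() ** 2 / np.sum(w * w)
            assert ess >= 8 - 1e-6

    def test_small_cohort_rejected(self):
        with pytest.raises(StructuralError, match="minimum effective"):
            adaptive_kernel_weights(np.array([40.0, 41.0]), 40,
                                    min_effective_n=8)


# ---------------------------------------------------------------------------
# weekly template
# ---------------------------------------------------------------------------


class TestWeeklyTemplate:
    def test_identical_subjects(self, mesh_lv2, rng):
        sulc = rng.normal(size=mesh_lv2.n_vertices)
        subs = [make_subject(f"s{i}", 40.0, mesh_lv2, sulc) for i in range(4)]
        tmpl = build_weekly_template(
            subs, {}, 40, np.full(4, 0.25), mesh_lv2
        )
        assert np.abs(tmpl.metric("sulc", "left").values - sulc).max() <= 1e-10

    def test_two_subject_mean(self, mesh_lv2, rng):
        a = rng.normal(size=mesh_lv2.n_vertices)
        b = rng.normal(size=mesh_lv2.n_vertices)
        subs = [
            make_subject("a", 40.0, mesh_lv2, a),
            make_subject("b", 40.0, mesh_lv2, b),
        ]
        tmpl = build_weekly_template(subs, {}, 40, np.array([0.5, 0.5]), mesh_lv2)
        assert np.allclose(
            tmpl.metric("sulc", "left").values, 0.5 * (a + b)
        )

    def test_reordered_summation_oracle(self, mesh_lv2, rng):
        fields = [rng.normal(size=mesh_lv2.n_vertices) for _ in range(6)]
        weights = rng.random(6)
        weights /= weights.sum()
        subs = [
            make_subject(f"s{i}", 40.0, mesh_lv2, f)
            for i, f in enumerate(fields)
        ]
        tmpl = build_weekly_template(subs, {}, 40, weights, mesh_lv2)
        # oracle: accumulate per-vertex in reversed subject order
        expected = np.zeros(mesh_lv2.n_vertices)
        for f, w in reversed(list(zip(fields, weights))):
            expected += w * f
        assert np.abs(
            tmpl.metric("sulc", "left").values - expected
        ).max() <= 1e-12


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


class TestRefineAtlas:
    def _initial_atlas(self, mesh, subjects, weeks):
        ages = np.asarray([s.age_weeks for s in subjects])
        templates = {}
        for w in weeks:
            wts = adaptive_kernel_weights(ages, w, min_effective_n=4)
            templates[w] = build_weekly_template(subjects, {}, w, wts, mesh)
        return SpatioTemporalAtlas(templates=templates)

    def test_zero_noise_identity_cohort_converges_fast(self, mesh_lv3):
        sulc = band_limited_field(mesh_lv3, 5)
        subs = [make_subject(f"s{i}", 40.0, mesh_lv3, sulc) for i in range(5)]
        atlas = self._initial_atlas(mesh_lv3, subs, [40])
        refined, defs, trace = refine_atlas(
            subs, atlas, mesh_lv3, max_iter=3, min_effective_n=4
        )
        assert len(trace) <= 3  # converged in one refinement iteration
        assert trace[0] <= 1e-10

    def test_planted_warps_reduce_variance(self, mesh_lv3):
        base = band_limited_field(mesh_lv3, 17)
        from asymsurf._interp import SphereInterpolator

        interp = SphereInterpolator(mesh_lv3)
        subs = []
        for i in range(6):
            w = smooth_random_warp(mesh_lv3, 50 + i, np.deg2rad(7))
            subs.append(
                make_subject(
                    f"s{i}", 40.0, mesh_lv3,
                    interp.interpolate(base, w.targets),
                )
            )
        atlas = self._initial_atlas(mesh_lv3, subs, [40])
        refined, defs, trace = refine_atlas(
            subs, atlas, mesh_lv3, max_iter=2, min_effective_n=4, tol=1e-6
        )
        assert trace[-1] <= 0.5 * trace[0]

    def test_terminates_within_max_iter(self, mesh_lv2, rng):
        subs = [
            make_subject(
                f"s{i}", 40.0, mesh_lv2, band_limited_field(mesh_lv2, 80 + i)
            )
            for i in range(5)
        ]
        atlas = self._initial_atlas(mesh_lv2, subs, [40])
        _, _, trace = refine_atlas(
            subs, atlas, mesh_lv2, max_iter=2, min_effective_n=4, tol=1e-9
        )
        assert len(trace) <= 3


# ---------------------------------------------------------------------------
# dedrift
# ---------------------------------------------------------------------------


class TestDedrift:
    def test_identity_inputs(self, mesh_lv3):
        fields = [identity_field(mesh_lv3, "native") for _ in range(4)]
        for f in fields:
            f.target_space = "template"
        out = dedrift(fields)
        for f in out:
            assert f.displacement().max() <= 1e-8

    def test_common_rotation_removed(self, mesh_lv3):
        r = rotation_matrix([0, 0, 1], 0.2)
        originals = [
            smooth_random_warp(mesh_lv3, seed, 0.04) for seed in range(4)
        ]
        drifted = [
            DeformationField(o.targets @ r.T, mesh_lv3, "native", "template")
            for o in originals
        ]
        out = dedrift(drifted)
        for o, f in zip(originals, out):
            assert geodesic_distance(o.targets, f.targets).mean() <= 0.05

    def test_output_mean_near_identity(self, mesh_lv3):
        fields = [
            DeformationField(
                smooth_random_warp(mesh_lv3, s, 0.08).targets,
                mesh_lv3, "native", "template",
            )
            for s in range(5)
        ]
        out = dedrift(fields)
        avg = average_deformations(out)
        assert avg.displacement().max() <= 1e-3


# ---------------------------------------------------------------------------
# symmetrisation
# ---------------------------------------------------------------------------


class TestSymmetrize:
    def test_output_equals_its_mirror_exactly(self, mesh_lv3):
        perm = mesh_lv3.mirror_perm
        left = band_limited_field(mesh_lv3, 31)
        right = 0.8 * left + 0.4 * band_limited_field(mesh_lv3, 32)
        tmpl = Template(
            age_weeks=40, mesh=mesh_lv3,
            metrics={
                "sulc": {
                    "left": MetricMap(left, "left", "sulc"),
                    "right": MetricMap(right, "right", "sulc"),
                }
            },
        )
        sym, d_l, d_r = symmetrize_template(tmpl)
        values = sym.metric("sulc").values
        assert np.abs(values - values[perm]).max() <= 1e-10
        assert sym.symmetric

    def test_symmetric_input_is_fixed_point(self, mesh_lv3):
        f = even_field(mesh_lv3, 33)
        tmpl = Template(
            age_weeks=40, mesh=mesh_lv3,
            metrics={
                "sulc": {
                    "left": MetricMap(f, "left", "sulc"),
                    "right": MetricMap(f.copy(), "right", "sulc"),
                }
            },
        )
        sym, d_l, d_r = symmetrize_template(tmpl)
        assert d_l.displacement().max() <= 1e-3
        assert np.abs(sym.metric("sulc").values - f).max() <= 0.05

    def test_idempotent_within_interpolation_tolerance(self, mesh_lv3):
        left = band_limited_field(mesh_lv3, 34)
        right = 0.9 * left + 0.2 * band_limited_field(mesh_lv3, 35)
        tmpl = Template(
            age_weeks=40, mesh=mesh_lv3,
            metrics={
                "sulc": {
                    "left": MetricMap(left, "left", "sulc"),
                    "right": MetricMap(right, "right", "sulc"),
                }
            },
        )
        once, _, _ = symmetrize_template(tmpl)
        again_in = Template(
            age_weeks=40, mesh=mesh_lv3,
            metrics={
                "sulc": {
                    "left": once.metric("sulc"),
                    "right": once.metric("sulc"),
                }
            },
        )
        twice, _, _ = symmetrize_template(again_in)
        assert np.abs(
            twice.metric("sulc").values - once.metric("sulc").values
        ).max() <= 0.05

    def test_missing_hemisphere_raises(self, mesh_lv3):
        tmpl = Template(
            age_weeks=40, mesh=mesh_lv3,
            metrics={"sulc": {"left": MetricMap(
                band_limited_field(mesh_lv3, 1), "left", "sulc")}},
        )
        with pytest.raises(StructuralError, match="left and right"):
            symmetrize_template(tmpl)


# ---------------------------------------------------------------------------
# chain + subject mapping
# ---------------------------------------------------------------------------


def symmetric_atlas(mesh, weeks, seed=60):
    templates = {}
    for i, w in enumerate(weeks):
        f = even_field(mesh, seed + i)
        templates[w] = Template(
            age_weeks=w, mesh=mesh, symmetric=True,
            metrics={"sulc": {"symmetric": MetricMap(f, "symmetric", "sulc")}},
        )
    return SpatioTemporalAtlas(templates=templates)


class TestChain:
    def test_identical_templates_identity_chain(self, mesh_lv3):
        f = even_field(mesh_lv3, 61)
        templates = {
            w: Template(
                age_weeks=w, mesh=mesh_lv3, symmetric=True,
                metrics={
                    "sulc": {"symmetric": MetricMap(f.copy(), "symmetric", "sulc")}
                },
            )
            for w in (39, 40, 41)
        }
        atlas = build_template_chain(
            SpatioTemporalAtlas(templates=templates)
        )
        for w in (39, 41):
            assert atlas.to40[w].displacement().max() <= 1e-3

    def test_reference_week_is_identity(self, mesh_lv3):
        atlas = build_template_chain(symmetric_atlas(mesh_lv3, [39, 40, 41]))
        assert np.array_equal(atlas.to40[40].targets, mesh_lv3.vertices)

    def test_missing_week_raises(self, mesh_lv3):
        with pytest.raises(StructuralError, match="gap"):
            build_template_chain(symmetric_atlas(mesh_lv3, [38, 40]))

    def test_missing_reference_raises(self, mesh_lv3):
        with pytest.raises(StructuralError, match="reference"):
            build_template_chain(symmetric_atlas(mesh_lv3, [38, 39]))

    def test_planted_warp_subject_recovery(self, mesh_lv4):
        # subject = known warp of the 40-week template; after registration
        # and single-step resampling its sulc must match the template
        from asymsurf._interp import SphereInterpolator

        atlas = build_template_chain(symmetric_atlas(mesh_lv4, [40]))
        tmpl_vals = atlas.templates[40].metric("sulc").values
        w = smooth_random_warp(mesh_lv4, 71, np.deg2rad(6))
        interp = SphereInterpolator(mesh_lv4)
        subj_vals = interp.interpolate(tmpl_vals, w.targets)
        subj = make_subject("sub", 40.0, mesh_lv4, subj_vals)
        d = subject_to_template(subj, atlas)
        resampled = resample_subject(
            subj.metric("sulc", "left"), d, mesh_lv4
        )
        corr = np.corrcoef(resampled.values, tmpl_vals)[0, 1]
        assert corr >= 0.98


class TestSingleInterpolationRule:
    def test_single_step_beats_double_interpolation(self, mesh_lv4):
        # ground truth: subject field sampled from a known template warp;
        # the single-step resampling must be closer to the truth than a
        # deliberately double-interpolated version
        from asymsurf._interp import SphereInterpolator

        interp = SphereInterpolator(mesh_lv4)
        truth = band_limited_field(mesh_lv4, 81)
        w1 = smooth_random_warp(mesh_lv4, 82, np.deg2rad(5))
        w2 = smooth_random_warp(mesh_lv4, 83, np.deg2rad(5))
        w1 = DeformationField(w1.targets, mesh_lv4, "40wk", "local")
        w2 = DeformationField(w2.targets, mesh_lv4, "local", "native")
        from asymsurf.sphere_warp import compose

        native = MetricMap(
            interp.interpolate(truth, compose(w1, w2).targets)
        )
        # single interpolation through the composed warp
        single = resample_metric(native, invert(compose(w1, w2)))
        # double interpolation: native -> local -> 40wk
        local = resample_metric(native, invert(w2))
        double = resample_metric(local, invert(w1))
        err_single = np.abs(single.values - truth).mean()
        err_double = np.abs(double.values - truth).mean()
        assert err_single < err_double
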