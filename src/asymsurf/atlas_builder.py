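"""Left-right symmetric spatiotemporal template construction.

Weekly templates are adaptive-kernel-weighted averages of registered
subject maps, iteratively refined by re-registration until within-template
variance converges.  Symmetrisation registers the left and right sulcal
depth templates in both directions, averages the forward with the inverted
backward warp to reach a halfway space, resamples both hemispheres there,
and replaces the sulcal depth by the left/mirrored-right mean — after which
every template metric equals its own mirror exactly.  Week-to-week
registrations are chained into direct to-40-week deformations so subject
data reaches the final space through a single interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from asymsurf.errors import ConvergenceError, StructuralError
from asymsurf.mesh_core import MetricMap, SphericalMesh
from asymsurf.records import SubjectRecord
from asymsurf.sphere_warp import (
    DeformationField,
    RegistrationParams,
    average_deformations,
    compose,
    identity_field,
    invert,
    mirror_metric,
    register,
    resample_metric,
    scale_deformation,
)

__all__ = [
    "Template",
    "SpatioTemporalAtlas",
    "adaptive_kernel_weights",
    "build_weekly_template",
    "refine_atlas",
    "dedrift",
    "symmetrize_template",
    "build_template_chain",
    "subject_to_template",
    "resample_subject",
]

REFERENCE_WEEK = 40


@dataclass
class Template:
    """Weekly template: named metrics per hemisphere on a shared mesh.

    ``metrics`` maps feature -> hemisphere ('left'/'right'/'symmetric') ->
    MetricMap.  When ``symmetric`` is set, every metric carries the
    'symmetric' key and equals its own mirror.
    """

    age_weeks: int
    mesh: SphericalMesh
    metrics: dict[str, dict[str, MetricMap]] = field(default_factory=dict)
    symmetric: bool = False

    def metric(self, feature: str, hemisphere: str | None = None) -> MetricMap:
        maps = self.metrics[feature]
        if hemisphere is None:
            hemisphere = "symmetric" if "symmetric" in maps else "left"
        return maps[hemisphere]

    def check_symmetry(self, tol: float = 1e-10) -> None:
        perm = self.mesh.require_mirror()
        for feature, maps in self.metrics.items():
            m = maps.get("symmetric")
            if m is None:
                raise StructuralError(f"feature '{feature}' has no symmetric map")
            if np.abs(m.values - m.values[perm]).max() > tol:
                raise StructuralError(
                    f"symmetric template metric '{feature}' differs from its mirror"
                )


@dataclass
class SpatioTemporalAtlas:
    """Weekly templates plus week-to-week and direct-to-40-week warps."""

    templates: dict[int, Template]
    chain: dict[tuple[int, int], DeformationField] = field(default_factory=dict)
    to40: dict[int, DeformationField] = field(default_factory=dict)

    @property
    def weeks(self) -> list[int]:
        return sorted(self.templates)

    def nearest_week(self, age_weeks: float) -> int:
        weeks = np.asarray(self.weeks)
        return int(weeks[np.argmin(np.abs(weeks - age_weeks))])


# ---------------------------------------------------------------------------
# Weekly averaging
# ---------------------------------------------------------------------------


def adaptive_kernel_weights(
    subject_ages: np.ndarray,
    target_week: float,
    min_effective_n: int = 8,
    initial_width: float = 0.5,
    growth: float = 1.1,
) -> np.ndarray:
    """Gaussian age-kernel weights with adaptively grown width.

    The width grows geometrically until the effective sample size
    (sum w)^2 / sum w^2 reaches ``min_effective_n``; weights sum to 1.
    """
    ages = np.asarray(subject_ages, dtype=np.float64)
    if len(ages) < min_effective_n:
        raise StructuralError(
            f"cohort of {len(ages)} subjects is below the minimum effective "
            f"sample size {min_effective_n}"
        )
    width = initial_width
    for _ in range(1000):
        w = np.exp(-0.5 * ((ages - target_week) / width) ** 2)
        total = w.sum()
        if total > 0:
            ess = total**2 / np.sum(w * w)
            if ess >= min_effective_n - 1e-9:
                return w / total
        width *= growth
    raise ConvergenceError("adaptive kernel width failed to reach target ESS")


def build_weekly_template(
    subjects: list[SubjectRecord],
    deformations: dict[str, DeformationField],
    week: int,
    weights: np.ndarray,
    mesh: SphericalMesh,
    features: tuple[str, ...] = ("sulc",),
    hemispheres: tuple[str, ...] = ("left", "right"),
) -> Template:
    """Weighted per-vertex mean of subject metrics resampled to the common
    space via each subject's template-to-native deformation."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(subjects):
        raise StructuralError("one weight per subject required")
    metrics: dict[str, dict[str, MetricMap]] = {}
    for feature in features:
        metrics[feature] = {}
        for hemi in hemispheres:
            acc = np.zeros(mesh.n_vertices)
            for subj, w in zip(subjects, weights):
                m = subj.metric(feature, hemi)
                d = deformations.get(subj.subject_id)
                if d is not None:
                    m = resample_metric(m, d, mesh)
                acc += w * m.values
            metrics[feature][hemi] = MetricMap(acc, hemi, feature)
    return Template(age_weeks=week, mesh=mesh, metrics=metrics)


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------


def _within_template_variance(
    subjects, deformations, weeks_of, templates, mesh, feature="sulc"
) -> float:
    total, count = 0.0, 0
    for subj in subjects:
        tmpl = templates[weeks_of[subj.subject_id]]
        for hemi in ("left", "right"):
            m = subj.metric(feature, hemi)
            d = deformations.get(subj.subject_id)
            if d is not None:
                m = resample_metric(m, d, mesh)
            diff = m.values - tmpl.metric(feature, hemi).values
            total += float(np.mean(diff * diff))
            count += 1
    return total / max(count, 1)


def refine_atlas(
    subjects: list[SubjectRecord],
    initial_atlas: SpatioTemporalAtlas,
    mesh: SphericalMesh,
    max_iter: int = 10,
    tol: float = 1e-3,
    feature: str = "sulc",
    features: tuple[str, ...] = ("sulc",),
    reg_params: RegistrationParams | None = None,
    min_effective_n: int = 8,
) -> tuple[SpatioTemporalAtlas, dict[str, DeformationField], list[float]]:
    """Alternate subject-to-template registration and template rebuilding.

    Stops when the relative change in mean within-template variance drops
    below ``tol`` or ``max_iter`` is reached; two consecutive variance
    increases beyond tolerance raise with the iteration trace.  Returns the
    refined atlas, the template-to-native deformations used for averaging,
    and the variance trace.
    """
    weeks_of = {
        s.subject_id: initial_atlas.nearest_week(s.age_weeks) for s in subjects
    }
    ages = np.asarray([s.age_weeks for s in subjects])
    templates = dict(initial_atlas.templates)
    deformations: dict[str, DeformationField] = {}
    trace = [
        _within_template_variance(
            subjects, deformations, weeks_of, templates, mesh, feature
        )
    ]
    n_increases = 0
    for _ in range(max_iter):
        for subj in subjects:
            tmpl = templates[weeks_of[subj.subject_id]]
            d_fwd = register(
                subj.metric(feature, "left"),
                tmpl.metric(feature, "left"),
                mesh,
                reg_params,
                source_space="native",
                target_space=f"week-{tmpl.age_weeks}",
            )
            # averaging pulls subject data onto template vertices
            deformations[subj.subject_id] = invert(d_fwd)
        new_templates = {}
        for week in initial_atlas.weeks:
            w = adaptive_kernel_weights(ages, week, min_effective_n)
            new_templates[week] = build_weekly_template(
                subjects, deformations, week, w, mesh, features=features
            )
        templates = new_templates
        var = _within_template_variance(
            subjects, deformations, weeks_of, templates, mesh, feature
        )
        trace.append(var)
        if var > trace[-2] + 1e-6:
            n_increases += 1
            if n_increases >= 2:
                raise ConvergenceError(
                    f"template variance diverging; trace: {trace}"
                )
        else:
            n_increases = 0
        if abs(trace[-2] - var) <= tol * max(trace[-2], 1e-12):
            break
    return (
        SpatioTemporalAtlas(templates=templates),
        deformations,
        trace,
    )


def dedrift(
    deformations: list[DeformationField],
    tol: float = 1e-3,
    max_iter: int = 5,
) -> list[DeformationField]:
    """Remove the ensemble-mean warp so the template space is unbiased.

    Each field is composed with the inverse of the average field, repeated
    (composition and averaging do not commute exactly) until the average of
    the outputs is within ``tol`` radians of the identity.
    """
    fields = list(deformations)
    space = deformations[0].target_space
    for _ in range(max_iter):
        mean = average_deformations(fields)
        if float(mean.displacement().max()) <= tol:
            return fields
        mean_inv = invert(mean)
        mean_inv = DeformationField(
            mean_inv.targets, mean_inv.mesh,
            source_space=space, target_space=space,
        )
        fields = [compose(d, mean_inv) for d in fields]
    mean = average_deformations(fields)
    resid = float(mean.displacement().max())
    if resid > tol:
        raise ConvergenceError(
            f"dedrift residual mean displacement {resid:.3g} rad exceeds {tol}"
        )
    return fields


# ---------------------------------------------------------------------------
# Symmetrisation
# ---------------------------------------------------------------------------


def symmetrize_template(
    template: Template,
    feature: str = "sulc",
    reg_params: RegistrationParams | None = None,
) -> tuple[Template, DeformationField, DeformationField]:
    """Make a weekly template left-right symmetric.

    Registers L->R and R->L on the driving feature, averages the forward
    warp with the inverted backward warp, halves it to define the halfway
    space, resamples both hemispheres' metrics there, and replaces every
    metric by the mean of the resampled left map and the mirrored resampled
    right map (projected onto the mirror-even subspace, so the symmetric
    invariant holds exactly).  Returns the symmetric template and the
    left- and right-hemisphere warps into the halfway space.
    """
    mesh = template.mesh
    perm = mesh.require_mirror()
    maps = template.metrics.get(feature, {})
    if "left" not in maps or "right" not in maps:
        raise StructuralError(
            f"symmetrisation needs left and right '{feature}' maps"
        )
    week = template.age_weeks
    d_lr = register(maps["left"], maps["right"], mesh, reg_params,
                    source_space="L", target_space="R")
    d_rl = register(maps["right"], maps["left"], mesh, reg_params,
                    source_space="R", target_space="L")
    d_rl_inv = invert(d_rl)
    d_full = average_deformations(
        [d_lr, DeformationField(d_rl_inv.targets, mesh, "L", "R")]
    )
    d_half_l = scale_deformation(d_full, 0.5, target_space="halfway")
    d_full_back = average_deformations(
        [d_rl, DeformationField(invert(d_lr).targets, mesh, "R", "L")]
    )
    d_half_r = scale_deformation(d_full_back, 0.5, target_space="halfway")

    # pulling data onto the halfway-space vertices needs the inverse warps
    pull_l = invert(d_half_l)
    pull_r = invert(d_half_r)

    out_metrics: dict[str, dict[str, MetricMap]] = {}
    for feat, hemi_maps in template.metrics.items():
        if "left" not in hemi_maps or "right" not in hemi_maps:
            continue
        left_half = resample_metric(hemi_maps["left"], pull_l, mesh)
        right_half = resample_metric(hemi_maps["right"], pull_r, mesh)
        mean_map = 0.5 * (left_half.values + mirror_metric(
            MetricMap(right_half.values, "right", feat), mesh
        ).values)
        # exact mirror-even projection (addition is commutative: bitwise even)
        sym_vals = 0.5 * (mean_map + mean_map[perm])
        out_metrics[feat] = {
            "symmetric": MetricMap(sym_vals, "symmetric", feat)
        }
    out = Template(
        age_weeks=week, mesh=mesh, metrics=out_metrics, symmetric=True
    )
    out.check_symmetry()
    return out, d_half_l, d_half_r


# ---------------------------------------------------------------------------
# Week chain and subject mapping
# ---------------------------------------------------------------------------


def build_template_chain(
    atlas: SpatioTemporalAtlas,
    feature: str = "sulc",
    reg_params: RegistrationParams | None = None,
    reference_week: int = REFERENCE_WEEK,
) -> SpatioTemporalAtlas:
    """Register consecutive weekly templates and compose direct-to-reference
    deformations; to40 at the reference week is the identity."""
    weeks = atlas.weeks
    if reference_week not in weeks:
        raise StructuralError(
            f"reference week {reference_week} missing from atlas weeks {weeks}"
        )
    for a, b in zip(weeks, weeks[1:]):
        if b - a != 1:
            raise StructuralError(
                f"week chain has a gap between {a} and {b}; consecutive "
                "weekly templates are required"
            )
    mesh = atlas.templates[weeks[0]].mesh
    chain: dict[tuple[int, int], DeformationField] = {}
    for a, b in zip(weeks, weeks[1:]):
        up = register(
            atlas.templates[a].metric(feature),
            atlas.templates[b].metric(feature),
            mesh,
            reg_params,
            source_space=f"week-{a}",
            target_space=f"week-{b}",
        )
        chain[(a, b)] = up
        down = invert(up)
        chain[(b, a)] = down

    to40: dict[int, DeformationField] = {
        reference_week: identity_field(mesh, f"week-{reference_week}")
    }
    for w in sorted([w for w in weeks if w < reference_week], reverse=True):
        nxt = chain[(w, w + 1)]
        to40[w] = compose(nxt, to40[w + 1]) if w + 1 != reference_week else nxt
    for w in sorted([w for w in weeks if w > reference_week]):
        prv = chain[(w, w - 1)]
        to40[w] = compose(prv, to40[w - 1]) if w - 1 != reference_week else prv
    return SpatioTemporalAtlas(templates=atlas.templates, chain=chain, to40=to40)


def subject_to_template(
    subject: SubjectRecord,
    atlas: SpatioTemporalAtlas,
    feature: str = "sulc",
    hemisphere: str = "left",
    reg_params: RegistrationParams | None = None,
) -> DeformationField:
    """Single native-to-reference-week deformation for one subject:
    native -> local weekly template composed with the template chain."""
    week = atlas.nearest_week(subject.age_weeks)
    if week not in atlas.to40:
        raise StructuralError(
            f"atlas has no to-reference deformation for week {week}; "
            "run build_template_chain first"
        )
    mesh = atlas.templates[week].mesh
    d_local = register(
        subject.metric(feature, hemisphere),
        atlas.templates[week].metric(feature),
        mesh,
        reg_params,
        source_space="native",
        target_space=f"week-{week}",
    )
    return compose(d_local, atlas.to40[week])


def resample_subject(
    metric: MetricMap,
    native_to_ref: DeformationField,
    mesh: SphericalMesh,
) -> MetricMap:
    """Bring a native-space subject metric onto the reference mesh with a
    single interpolation of the data (the deformation inversion interpolates
    only warp coordinates, never the metric)."""
    pull = invert(native_to_ref)
    return resample_metric(metric, pull, mesh)
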