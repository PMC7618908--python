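"""Synthetic cohorts on mirror-symmetric spherical cortices.

Generates everything the pipeline consumes: octasphere meshes with exact
mirror permutations, band-limited sulcal-depth-like template fields with a
linear age trajectory, subject-specific smooth spherical warps, planted
lateralised effects of configurable size and region, covariate effects,
Gaussian metric noise, and network-structured timeseries with lateralised
amplitude.  Every generator is driven by an explicit seed and returns
machine-readable ground truth sufficient to score recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from asymsurf.errors import StructuralError
from asymsurf.mesh_core import (
    AnatomicalSurface,
    MetricMap,
    SphericalMesh,
    vertex_areas,
    surface_from_mesh,
)
from asymsurf.octasphere import (  # noqa: F401  (re-exported API)
    MAX_LEVEL,
    make_octasphere,
    octasphere_level,
    octasphere_vertex_count,
)
from asymsurf.records import SubjectRecord
from asymsurf.rsfmri_ica import TimeseriesMatrix
from asymsurf.sphere_warp import DeformationField, _interpolator

__all__ = [
    "make_octasphere",
    "CohortSpec",
    "PlantedEffect",
    "TimeseriesSpec",
    "GroundTruth",
    "generate_template_pattern",
    "random_smooth_warp",
    "cap_region",
    "generate_structural_cohort",
    "generate_functional_cohort",
]


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffect:
    """A lateralised effect: asymmetry index ``delta`` inside a spherical cap
    covering ``area_frac`` of the sphere, centred at ``center`` (unit vec)."""

    feature: str = "thickness"
    delta: float = 0.2
    center: tuple[float, float, float] = (0.0, 0.0, 1.0)
    area_frac: float = 0.05


@dataclass
class TimeseriesSpec:
    n_networks: int = 4
    n_frames: int = 200
    lateralisation: float = 0.0  # left amplitude = (1 + delta_f) * right
    noise_sd: float = 0.1
    network_width: float = 0.25  # gaussian bump width (radians)
    lateralised: str | list[int] = "all"


@dataclass
class CohortSpec:
    n_subjects: int = 20
    seed: int = 0
    mesh_level: int = 3
    age_range: tuple[float, float] = (37.0, 44.0)
    effects: list[PlantedEffect] = field(default_factory=list)
    sex_effect: float = 0.0  # added to AI for sex == 1
    age_slope: float = 0.0  # AI change per week of PMA, inside effect regions
    warp_magnitude: float = 0.0  # mean vertex displacement, radians
    noise_sd: float = 0.05
    base_thickness: float = 2.5
    thickness_amplitude: float = 0.3
    timeseries: TimeseriesSpec | None = None

    def __post_init__(self) -> None:
        for name in ("sex_effect", "age_slope", "warp_magnitude", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Machine-readable truth for a generated cohort."""

    spec: CohortSpec
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    true_ai: dict[str, np.ndarray] = field(default_factory=dict)  # subject -> field
    warps: dict[str, np.ndarray] = field(default_factory=dict)  # subject -> targets
    covariates: dict[str, dict] = field(default_factory=dict)
    network_maps: np.ndarray | None = None
    network_amplitudes: dict[str, np.ndarray] | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        payload = {
            "spec": json.loads(json.dumps(asdict(self.spec), default=str)),
            "region_masks": conv(self.region_masks),
            "true_ai": conv(self.true_ai),
            "warps": conv(self.warps),
            "covariates": conv(self.covariates),
            "network_maps": conv(self.network_maps),
            "network_amplitudes": conv(self.network_amplitudes),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Field and warp generators
# ---------------------------------------------------------------------------


def _sphere_angles(mesh: SphericalMesh) -> tuple[np.ndarray, np.ndarray]:
    v = mesh.vertices
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return theta, phi


_pattern_cache: dict = {}


def generate_template_pattern(
    mesh: SphericalMesh,
    seed: int,
    band: tuple[int, int] = (3, 8),
) -> MetricMap:
    """Band-limited random smooth field (real spherical harmonics).

    Gaussian coefficients over degrees band[0]..band[1]; the result is
    standardised to zero area-weighted mean and unit area-weighted variance.
    An empty band gives the zero field.  Results are memoised per
    (geometry, seed, band) — repeated cohort generation is harmonic-free.
    """
    from scipy.special import sph_harm_y

    key = (hash(mesh.vertices.tobytes()), seed, band)
    if key in _pattern_cache:
        return MetricMap(_pattern_cache[key].copy(), hemisphere="symmetric",
                         feature="pattern")

    lmin, lmax = band
    rng = np.random.default_rng(seed)
    theta, phi = _sphere_angles(mesh)
    f = np.zeros(mesh.n_vertices)
    if lmin > lmax:
        return MetricMap(f, hemisphere="symmetric", feature="pattern")
    for ell in range(lmin, lmax + 1):
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            f += rng.normal() * np.real(y)
            if m > 0:
                f += rng.normal() * np.imag(y)
    w = vertex_areas(surface_from_mesh(mesh)).values
    w = w / w.sum()
    f = f - np.sum(w * f)
    var = np.sum(w * f * f)
    if var > 0:
        f = f / np.sqrt(var)
    if len(_pattern_cache) < 4096:
        _pattern_cache[key] = f.copy()
    return MetricMap(f, hemisphere="symmetric", feature="pattern")


def random_smooth_warp(
    mesh: SphericalMesh,
    rng: np.random.Generator,
    mean_displacement: float,
    band: tuple[int, int] = (1, 2),
) -> DeformationField:
    """Smooth tangent-vector warp with the requested mean displacement."""
    if mean_displacement == 0.0:
        return DeformationField(mesh.vertices.copy(), mesh,
                                source_space="native", target_space="template")
    comps = np.stack(
        [
            generate_template_pattern(
                mesh, int(rng.integers(0, 2**31)), band
            ).values
            for _ in range(3)
        ],
        axis=1,
    )
    v = mesh.vertices
    tang = comps - np.einsum("ij,ij->i", comps, v)[:, None] * v
    scale = np.linalg.norm(tang, axis=1).mean()
    if scale > 0:
        tang *= mean_displacement / scale
    t = v + tang
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return DeformationField(t, mesh, source_space="native",
                            target_space="template")


def cap_region(mesh: SphericalMesh, center: np.ndarray, area_frac: float,
               ) -> np.ndarray:
    """Boolean mask of the spherical cap of the given fractional area."""
    center = np.asarray(center, dtype=np.float64)
    center = center / np.linalg.norm(center)
    cos_theta = 1.0 - 2.0 * area_frac  # cap area fraction = (1 - cos) / 2
    mask = mesh.vertices @ center >= cos_theta
    if not mask.any():
        raise StructuralError("effect region contains no vertices on this mesh")
    return mask


# ---------------------------------------------------------------------------
# Structural cohort
# ---------------------------------------------------------------------------


def _age_template(mesh: SphericalMesh, seed: int, age: float,
                  age_range: tuple[float, float] = (28.0, 44.0)) -> np.ndarray:
    """Linear interpolation between two band-limited endpoint fields."""
    young = generate_template_pattern(mesh, seed).values
    old = generate_template_pattern(mesh, seed + 1).values
    lo, hi = age_range
    t = np.clip((age - lo) / (hi - lo), 0.0, 1.0)
    return (1.0 - t) * young + t * old


def generate_structural_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate subjects with planted structural asymmetries.

    Per subject, the left sulcal-depth map is the age-evolved template
    pulled through a seeded smooth warp plus Gaussian noise; thickness-like
    maps carry the planted asymmetry: L = base * (1 + AI/2) and
    R = base * (1 - AI/2), so the true asymmetry index equals the planted
    field exactly before noise.  Right maps are stored mirrored onto the
    left topology.  Anatomical surfaces are built by radial displacement
    (white) plus a thickness offset (pial).
    """
    mesh = make_octasphere(spec.mesh_level)
    perm = mesh.require_mirror()
    rng = np.random.default_rng(spec.seed)
    interp = _interpolator(mesh)
    truth = GroundTruth(spec=spec)

    for eff in spec.effects:
        truth.region_masks[eff.feature] = cap_region(
            mesh, np.asarray(eff.center), eff.area_frac
        )

    subjects: list[SubjectRecord] = []
    for i in range(spec.n_subjects):
        sid = f"sub-{i:03d}"
        age = float(rng.uniform(*spec.age_range))
        sex = int(rng.integers(0, 2))
        cov = {
            "subject_id": sid,
            "ga_weeks": float(rng.uniform(*spec.age_range)),
            "pma_weeks": age,
            "sex": sex,
            "bwz": float(rng.normal()),
            "tbv_cm3": float(rng.normal(340.0, 30.0)),
            "hemi_vol_asym_cm3": float(rng.normal(-1.8, 1.5)),
        }
        warp = random_smooth_warp(mesh, rng, spec.warp_magnitude)
        truth.warps[sid] = warp.targets

        sulc_tmpl = _age_template(mesh, spec.seed + 7777, age)
        pull = (
            interp.interpolate(sulc_tmpl, warp.targets)
            if spec.warp_magnitude > 0
            else sulc_tmpl
        )
        sulc_l = pull + rng.normal(0.0, spec.noise_sd, mesh.n_vertices)
        sulc_r = pull + rng.normal(0.0, spec.noise_sd, mesh.n_vertices)

        base = spec.base_thickness + spec.thickness_amplitude * sulc_tmpl
        ai_field = np.zeros(mesh.n_vertices)
        for eff in spec.effects:
            region = truth.region_masks[eff.feature]
            amount = (
                eff.delta
                + spec.sex_effect * sex
                + spec.age_slope * (age - 0.5 * sum(spec.age_range))
            )
            ai_field = ai_field + amount * region
        truth.true_ai[sid] = ai_field
        base_l = base * (1.0 + 0.5 * ai_field)
        base_r = base * (1.0 - 0.5 * ai_field)
        if spec.warp_magnitude > 0:
            base_l = interp.interpolate(base_l, warp.targets)
            base_r = interp.interpolate(base_r, warp.targets)
        thick_l = base_l + rng.normal(0.0, spec.noise_sd, mesh.n_vertices)
        thick_r = base_r + rng.normal(0.0, spec.noise_sd, mesh.n_vertices)

        surfaces = _build_surfaces(mesh, perm, sulc_l, sulc_r, thick_l, thick_r)
        truth.covariates[sid] = cov
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age_weeks=age,
                covariates=cov,
                metrics={
                    "sulc": {
                        "left": MetricMap(sulc_l, "left", "sulc"),
                        "right": MetricMap(sulc_r, "right", "sulc"),
                    },
                    "thickness": {
                        "left": MetricMap(thick_l, "left", "thickness"),
                        "right": MetricMap(thick_r, "right", "thickness"),
                    },
                },
                surfaces=surfaces,
            )
        )
    return subjects, truth


def _build_surfaces(mesh, perm, sulc_l, sulc_r, thick_l, thick_r,
                    radius: float = 50.0, sulc_amp: float = 2.0):
    """White from radial displacement, pial by thickness offset, mid halfway.

    Same-index homologous convention: right-surface vertex i sits at the
    YZ-plane reflection of the left frame, and the (pre-mirrored) right
    maps index it directly.
    """
    out = {}
    for hemi, sulc, thick in (("left", sulc_l, thick_l), ("right", sulc_r, thick_r)):
        r_white = radius + sulc_amp * sulc
        verts = mesh.vertices.copy()
        if hemi == "right":
            verts[:, 0] *= -1.0
        white = verts * r_white[:, None]
        pial = verts * (r_white + thick)[:, None]
        mid = 0.5 * (white + pial)
        tris = mesh.triangles
        if hemi == "right":
            tris = tris[:, ::-1]  # keep outward winding after reflection
        out[hemi] = {
            "white": AnatomicalSurface(white, tris, role="white"),
            "pial": AnatomicalSurface(pial, tris, role="pial"),
            "midthickness": AnatomicalSurface(mid, tris, role="midthickness"),
        }
    return out


# ---------------------------------------------------------------------------
# Functional cohort
# ---------------------------------------------------------------------------


def _network_maps(mesh: SphericalMesh, rng: np.random.Generator,
                  n_networks: int, width: float) -> np.ndarray:
    """Mirror-symmetric Gaussian-bump network maps (components x vertices).

    Bump centres (and their mirror images) are rejection-sampled to stay
    well separated across components, keeping the planted networks close to
    spatially orthogonal so recovery scores are meaningful.
    """
    maps = np.empty((n_networks, mesh.n_vertices))
    v = mesh.vertices
    min_sep = 3.0 * width
    placed: list[np.ndarray] = []
    for k in range(n_networks):
        for _ in range(500):
            c = rng.normal(size=3)
            c /= np.linalg.norm(c)
            cm = c * np.array([-1.0, 1.0, 1.0])
            ok = all(
                min(np.arccos(np.clip(p @ c, -1, 1)),
                    np.arccos(np.clip(p @ cm, -1, 1))) >= min_sep
                for p in placed
            )
            if ok:
                break
        else:
            raise StructuralError(
                f"could not place {n_networks} separated networks of width "
                f"{width}; reduce n_networks or width"
            )
        placed.extend([c, cm])
        d1 = np.arccos(np.clip(v @ c, -1, 1))
        d2 = np.arccos(np.clip(v @ cm, -1, 1))
        maps[k] = np.exp(-0.5 * (d1 / width) ** 2) + np.exp(
            -0.5 * (d2 / width) ** 2
        )
    return maps


def generate_functional_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate per-hemisphere timeseries with lateralised network amplitude.

    Y_hemi = sum_k a_k^hemi s_k(t) m_k(v) + noise, with shared timecourses
    s_k across hemispheres, mirror-symmetric maps m_k, and
    a^L = (1 + delta_f) a^R for lateralised networks.  Both hemisphere
    blocks are expressed on the left topology (right pre-mirrored), exactly
    like the structural metrics.
    """
    ts_spec = spec.timeseries
    if ts_spec is None:
        raise ValueError("CohortSpec.timeseries must be set")
    if ts_spec.n_networks > ts_spec.n_frames / 4:
        raise StructuralError(
            f"{ts_spec.n_networks} networks need at least "
            f"{4 * ts_spec.n_networks} frames for identifiability "
            f"(got {ts_spec.n_frames})"
        )
    mesh = make_octasphere(spec.mesh_level)
    rng = np.random.default_rng(spec.seed)
    maps = _network_maps(mesh, rng, ts_spec.n_networks, ts_spec.network_width)

    if ts_spec.lateralised == "all":
        lat_idx = np.arange(ts_spec.n_networks)
    else:
        lat_idx = np.asarray(ts_spec.lateralised, dtype=int)

    truth = GroundTruth(spec=spec, network_maps=maps, network_amplitudes={})
    subjects: list[SubjectRecord] = []
    for i in range(spec.n_subjects):
        sid = f"sub-{i:03d}"
        amp_r = rng.uniform(0.8, 1.2, size=ts_spec.n_networks)
        amp_l = amp_r.copy()
        amp_l[lat_idx] *= 1.0 + ts_spec.lateralisation
        s = rng.normal(size=(ts_spec.n_frames, ts_spec.n_networks))
        noise_l = rng.normal(0.0, ts_spec.noise_sd,
                             (ts_spec.n_frames, mesh.n_vertices))
        noise_r = rng.normal(0.0, ts_spec.noise_sd,
                             (ts_spec.n_frames, mesh.n_vertices))
        y_l = (s * amp_l) @ maps + (noise_l if ts_spec.noise_sd > 0 else 0.0)
        y_r = (s * amp_r) @ maps + (noise_r if ts_spec.noise_sd > 0 else 0.0)
        truth.network_amplitudes[sid] = np.stack([amp_l, amp_r])
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age_weeks=float(rng.uniform(*spec.age_range)),
                covariates={"subject_id": sid},
                timeseries={
                    "left": TimeseriesMatrix(y_l, "left", sid),
                    "right": TimeseriesMatrix(y_r, "right", sid),
                },
            )
        )
    return subjects, truth
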