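# asymsurf

Left–right cortical surface asymmetry analysis on spherical meshes, exercised
end to end on synthetic spherical cortices with planted asymmetries.

The package implements the full processing chain for mapping structural and
functional hemispheric asymmetry of a cortical hemisphere pair:

- **`mesh_core`** — mesh/metric primitives: cortical thickness, vertex areas,
  discrete mean curvature, curvature-bias regression, surface-constrained
  Gaussian smoothing (heat diffusion), GIFTI-dialect and TSV I/O.
- **`sphere_warp`** — deformation-field algebra on the sphere (resample,
  compose, invert, average, mirror) and a lightweight coarse-to-fine
  SSD + Dirichlet-penalty spherical registration driven by sulcal depth.
- **`atlas_builder`** — left–right symmetric spatiotemporal templates:
  adaptive-kernel weekly averaging, iterative refinement, dedrifting,
  cross-hemispheric symmetrisation, and week-to-week deformation chains
  giving single-interpolation subject-to-reference resampling.
- **`asym_maps`** — asymmetry-index maps AI = (L−R)/((L+R)/2) (leftward
  positive), subject-specific symmetric midthickness smoothing surfaces,
  functional component masks, ROI summaries.
- **`rsfmri_ica`** — the functional stream: timeseries smoothing, incremental
  group PCA (MIGP), mirror-concatenated group ICA (hemispherically unbiased
  group maps), and dual regression.
- **`perm_stats`** — vertex-wise GLM, threshold-free cluster enhancement
  (TFCE, H=2.0, E=0.6) on the mesh graph, sign-flip / Freedman–Lane
  max-statistic permutation inference with FWE control across vertices,
  features and contrasts, and cohort demographic tests.
- **`synth_cohort`** — octasphere meshes with exact mirror permutations,
  band-limited sulcal-depth-like template fields, smooth random warps,
  cohorts with planted lateralised effects, and network-structured
  timeseries with lateralised amplitude, all seeded with machine-readable
  ground truth.
- **`cli`** — `asymsurf` command-line pipeline.

Right-hemisphere data use the same-index homologous convention: maps are
stored pre-mirrored onto the left topology (vertex i of either hemisphere is
the same anatomical location), and right surfaces are the YZ-plane
reflection of the left frame.

## CLI

Every stage reads a YAML config (a root `seed` is mandatory) and writes its
artifacts plus a manifest into `--out`:

```bash
asymsurf simulate --config config.yaml --out run/   # synthetic cohort
asymsurf atlas    --config config.yaml --out run/   # symmetric templates
asymsurf asym     --config config.yaml --out run/   # subject AI maps
asymsurf ica      --config config.yaml --out run/   # functional stream
asymsurf stats    --config config.yaml --out run/   # permutation TFCE
asymsurf full     --config config.yaml --out run/   # the whole chain
```

Minimal config:

```yaml
seed: 17
n_subjects: 10
mesh_level: 3
weeks: [39, 40, 41]
n_perm: 500
effects:
  - {feature: thickness, delta: 0.2, center: [0, 0, 1], area_frac: 0.05}
```

Re-running an identical config reproduces identical outputs; all randomness
flows from the root seed through named per-stage substreams.

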