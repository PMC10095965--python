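# gravirod

Growing elastic-rod analysis of shoot gravitropism.

A plant shoot placed horizontally bends upward over ~140 minutes. `gravirod`
models the shoot centerline as a discrete elastic rod (stretching, bending
and gravitational forces, quasi-static equilibration with a clamped base and
a free tip) whose growing apical zone elongates and updates its intrinsic
curvature by a gravi-proprioceptive law

```
dκ0/dt = β σ cos θ − γ κ
```

(β: gravitropic sensitivity, γ: proprioceptive sensitivity, θ: tangent angle
from horizontal, κ: realized curvature). The package provides:

- `gravirod.mechanics` — discrete rod geometry, energies, analytic forces,
  and overdamped equilibration that records, per force component, the exact
  displacement it contributed (stretch / bend / gravity decomposition).
- `gravirod.growth` — growth-zone elongation, the curvature update, the
  simulation loop, and the dimensionless groups
  S = Lgz·β/γ (growth sensitivity) and G̃ = (B/ρg)^(1/3)/Lgz
  (growth-elasto-gravity).
- `gravirod.centerline` — cubic-spline fitting of sampled centerlines
  (chord-length parameterization, arc-length reparameterization), signed
  curvature profiles, curvature kymographs, morphospace coordinates
  (extension ratio, maximum final curvature) and Welch group comparisons.
- `gravirod.fitting` — exhaustive (S, G̃) grid search minimizing the
  relative-squared morphospace deviation between model and data, with
  node caching, cohort-average fits, and an optional noise-calibrated
  model-side estimator.
- `gravirod.decomposition` — per-step displacement decomposition maps,
  force-maximum comparisons between runs, flank elongation rates and
  differential-cell-growth (DCG) maps with the inner-flank-shrinkage check.
- `gravirod.synthetic` — ground-truth-known synthetic cohorts (default 16
  wild-type-like vs 15 mutant-like individuals differing only in β) with
  deterministic seeding, for end-to-end testing without any external data.

Units: mm, minutes; gravity acts along −y; arc length is zero at the base;
curvature is positive counter-clockwise (upward bending for a rod pointing
+x).

## CLI

```bash
gravirod synth    --config cfg.yaml --out data/         # synthetic cohorts
gravirod simulate --config cfg.yaml --out traj/         # one trajectory
gravirod analyze  --config cfg.yaml --series data/series.csv --out analysis/
gravirod fit      --config cfg.yaml --series data/series.csv --out fit/
gravirod decompose --config cfg.yaml --out maps/        # force/DCG maps
gravirod compare  --morphospace analysis/morphospace.csv --out report.json
```

The config is a YAML file mirroring the parameter dataclasses (blocks:
`mechanical`, `growth`, `analysis`, `fit`, `synth_wt`, `synth_mut`, plus
`seed` and `log_level`); unknown keys are rejected. Omitting `--config`
uses the defaults. Every run logs its seed and a config hash.

## Typical API session

```python
import gravirod as gr

mp, gp = gr.MechanicalParams(), gr.GrowthParams()
traj = gr.simulate(gr.straight_rod(40.0, 41), mp, gp)   # 140-min bending run

maps = gr.decompose(traj)                 # stretch/bend/gravity displacement maps
dcg = gr.flank_rates(traj, radius=0.75)   # flank elongation rates and DCG

series = gr.sample_series(traj, gr.CohortSpec(noise_sigma=0.0), None)
point = gr.morphospace_point(series)      # (extension ratio, max curvature)
```

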