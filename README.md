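# gardenbias

Spatially explicit, individual-based simulation of neighborhood crowding
in common-garden and transplant-garden experiments, with a bias-analysis
pipeline that quantifies how planting density distorts between-group
ANOVA outcomes and recommends a minimum planting distance.

## The problem

Common gardens grow plants from many source populations in one shared
environment so that performance differences can be attributed to
genetics rather than plasticity. The standard analysis — a one-way ANOVA
of growth on taxonomic group — assumes the plants are independent
replicates. But plants compete with their neighbors, and competitive
tolerance itself varies among the groups under test. At high planting
density the crowding signal leaks into the between-group contrast,
inflating apparent genetic differences and even reordering group
rankings. This package simulates that mechanism for a sagebrush-like
garden (five *Artemisia tridentata* subspecies-cytotypes plus
*A. arbuscula*, 470 plants from 56 source populations on a grid) and
measures the resulting inferential bias as a function of planting
distance.

## The model

Growth of plant *i* in group *s* over one census interval is predicted
with and without the crowding term:

```
full:  mu_F_i = alpha_s + beta_s * Size_i + gamma_s * phi_i + eps_i
base:  mu_B_i = alpha_s + beta_s * Size_i + eps_i,   eps ~ N(0, sigma^2)

phi_i = sum_{j != i} c_{s_j} * Size_j * exp(b * D_ij^2)
```

`alpha` is the intrinsic growth rate, `beta` the initial-size slope,
`gamma` the crowding response (more negative = less neighbor-tolerant),
and `phi` the crowding index: neighbor crown volumes weighted by a
Gaussian-in-distance kernel with per-group scale `c >= 0` and shared
decay `b < 0`. The default decay makes neighbor effects near negligible
beyond 2.5 m.

The sweep rescales one fixed garden to 15 planting distances (0.5–4 m),
propagates parameter uncertainty through 2000 posterior-style draws
(30,000 simulations), and summarizes two bias statistics per distance:

* **relativized F** — `F(mu_F - mu_B) / mean F(mu_B)`, the spurious
  between-group signal injected by crowding, on the scale of the
  genuine group differences;
* **Pearson r** between `mu_F` and `mu_B` (computed with `sigma = 0`),
  whose lower percentile-band edge crossing *r* > .99 defines the
  recommended minimum planting distance.

## Worked example

```python
import gardenbias as gb

layout = gb.make_grid_layout(seed=1)                      # 470 positions, 22 gaps
sizes = gb.make_initial_sizes(layout, seed=2)             # first-census stand-in
draws = gb.make_posterior_draws(n_draws=200, seed=3)      # synthetic posterior
f_sw = gb.run_sweep(layout, sizes, draws, noise_mode="independent", seed=4)
r_sw = gb.run_sweep(layout, sizes, draws, noise_mode="none", seed=4)
summary, groups, rec = gb.summarize_sweep(f_sw, r_sw, group_names=layout.group_names)
print(summary[["distance", "rel_f_mean", "r_mean", "r_lo68"]].round(3).to_string(index=False))
print("recommended minimum planting distance:", rec, "m")
```

```
 distance  rel_f_mean  r_mean  r_lo68
     0.50       0.260   0.455   0.223
     0.75       0.071   0.895   0.840
     1.00       0.024   0.974   0.960
     1.25       0.011   0.992   0.988
     1.50       0.006   0.997   0.996
     ...
     4.00       0.004   1.000   1.000
recommended minimum planting distance: 1.5 m
```

At 0.5 m spacing the crowding term alone generates a between-group F
about a quarter the size of the true group signal, and the full/base
predictions correlate at only r ≈ 0.46; by 4 m the spurious F has
collapsed by a factor of ~60 and r ≈ 1. The smallest distance whose 68%
band of r clears .99 — here 1.5 m — is the recommended minimum spacing.
Group summaries at 0.5 m vs 4 m show crowding reordering the ranking:
the neighbor-tolerant tetraploid `tridentata-4x` overtakes the
intrinsically faster but competition-sensitive diploid `tridentata-2x`
under dense planting.

The parameters here are synthetic (see `docs/methods.md`): they encode
the qualitative structure of the sagebrush study — diploid growth-rate
advantage, tetraploid neighbor tolerance, 2.5 m kernel reach — not the
empirical posterior.

## Command line

```sh
gardenbias all --seed 1 --n-draws 200 --out-dir out/   # full pipeline
gardenbias layout --out layout.csv                     # or stage by stage
gardenbias params --n-draws 200 --out params.json
gardenbias simulate --layout-file layout.csv --params-file params.json --out results.csv
gardenbias recommend --summary out/bias_summary.csv
```

Configuration is a flat YAML file (`--config run.yaml`); flags override
file values.

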