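# myxomorph

Quantitative morphometrics and social-fitness statistics for
myxobacterial fruiting-body development.

When *Myxococcus xanthus* starves, cells aggregate into multicellular
fruiting bodies. Experimental-evolution studies track how this
cooperative developmental phenotype changes when populations repeatedly
co-develop with different partners (benign cooperators, cheaters,
antagonists). `myxomorph` implements the full analysis chain such a
study needs:

- **Image analysis** (`myxomorph.imaging`): plate photographs are
  converted to 8-bit, dust is masked, analysis is restricted to the
  spotted-population ROI, fruiting bodies are segmented by Triangle
  (Zack) histogram thresholding plus connected-component labelling with
  a strict < 20 px² size exclusion, and four traits are measured — the
  per-plate fruiting-body count and, per body, area (px²), density
  (mean grey value) and density heterogeneity (grey-value SD), each
  summarised by its per-plate median.
- **Morphospace** (`myxomorph.morphospace`): traits are z-scored and
  embedded by PCA; each group (ancestor subclones or one treatment's
  populations) is summarised by its centroid over the three biological
  replicate assays with a Hotelling-type 95 % confidence ellipse;
  treatments are clustered hierarchically (Euclidean distance, Ward
  linkage) and within-treatment morphological diversification is the
  mean pairwise Euclidean distance among replicate-population trait
  vectors in standardized space (per assay; cross-assay mean ± s.e.m.).
- **Social statistics** (`myxomorph.social_stats`): one-way and
  total-group mixing effects from spore counts,

  C_i(j) = log₁₀[(s_mix,i / f_i) / s_pure,i],
  B_ij = log₁₀[(s_mix,i + s_mix,j) / (f_i·s_pure,i + f_j·s_pure,j)],

  with one-sample *t*-tests against 0 (0 ⇒ mixing had no effect);
  survival-curve construction from an extinction ledger with Fisher's
  exact test of extinction vs partner category; evolved-vs-ancestor
  *t*-tests and one-way ANOVA + Tukey HSD contrasts.
- **Synthetic data** (`myxomorph.synthetic_data`): ground-truthed
  generators for plate images (dark blobs on a bright spot, optional
  dust), evolution trait trajectories (deterministic treatment effects +
  population random walk + assay noise + extinction hazards) and
  spore-count assays with log-normal noise — every stage of the pipeline
  can be scored against known truth.
- **CLI** (`myxomorph.cli`): `myxomorph simulate-plate | segment |
  morphospace | diversify | mix-effects | extinction | contrasts`, with
  deterministic re-runs from a single seed.

## Worked example

Render a synthetic plate with 40 fruiting-body-like blobs, segment it
and measure the four traits:

```python
from myxomorph.imaging import segment_plate, measure_plate
from myxomorph.synthetic_data import PlateSpec, render_plate

spec = PlateSpec(shape=(512, 512), roi_radius=220.0, n_bodies=40,
                 interior_mean=120.0, background=200.0, noise_sd=2.0)
res = render_plate(spec, seed=42)
regions = segment_plate(res["plate"])
record = measure_plate(regions, {"treatment": "demo", "cycle": 10})
print(f"fruiting bodies: {record.fb_count}")
print(f"median area:     {record.fb_area_med:.1f} px^2")
print(f"median density:  {record.fb_density_med:.1f} grey units")
print(f"median heterog.: {record.fb_hetero_med:.2f} grey units")
```

prints

```
fruiting bodies: 40
median area:     146.0 px^2
median density:  132.5 grey units
median heterog.: 23.19 grey units
```

All 40 planted bodies are recovered. The median density (132.5) sits
close to the planted interior intensity (120 grey units) — with dark
objects a *lower* grey value means a denser body — and the median area
reflects the planted radius distribution (mean 6 px plus the detectable
edge). The heterogeneity median pools the interior texture with the
body's edge gradient.

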