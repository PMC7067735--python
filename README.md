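# habfish

From water-clarity scenarios to coastal predatory-fish biomass maps and
recreational-fishery value.

Eutrophication clouds coastal waters; water clarity (summer Secchi
depth) is the indicator that Baltic Sea policy targets are written in.
Two coastal predators respond in opposite directions: perch
(*Perca fluviatilis*) recruits better in clear water, pikeperch
(*Sander lucioperca*) in turbid water. `habfish` implements the
inference chain that turns per-scenario recruitment-habitat maps into
biomass maps and an economic statement about recreational fishing, for
analysts evaluating eutrophication-mitigation scenarios:

1. **Habitat availability** — for every water cell, the proportion *x*
   of water area within the species' migration distance (10 km perch,
   15 km pikeperch) that is recruitment habitat, by circular focal
   statistics. Land and out-of-grid cells are excluded from both
   numerator and denominator; results are exact integer-count ratios.
2. **Habitat productivity functions** — empirical log-linear relations
   from availability to adult catch-per-unit-effort in standardized
   gill nets: CPUE = 2.03 · ln(*x*) + 9.39 for perch (> 20 cm) and
   CPUE = 0.05 · ln(*x* + 0.02) + 0.21 for pikeperch (> 30 cm),
   clamped at zero. CPUE converts linearly to biomass density
   (kg ha⁻¹); perch maps are limited to 0–10 m depth.
3. **Technique ensemble and scenarios** — each (species, scenario) has
   three distribution-modelling-technique maps (GAM / Maxent / random
   forest labels); cellwise mean ± 1 SE, study-area summaries, and
   percent change against the 0% Secchi baseline across seven scenario
   levels (−10 … +48%).
4. **Validation** — OLS of observed monitoring CPUE on predicted CPUE
   (slope, intercept, r², F, p).
5. **Economics** — willingness-to-pay per kg·h⁻¹ of recreational catch
   from a travel-cost site-choice model (EUR 8.29 perch, EUR 18.0
   pikeperch), applied to ΔWPUE = baseline WPUE × relative biomass
   change, and combined across species with the revealed effort
   preference ratio (505 000 / 83 000 gear days ≈ 6.1) into a net
   benefit index.

The original habitat rasters are not distributable, so the package
ships a first-class synthetic generator: spatially autocorrelated
binary habitat on a generated coastal landscape, with prevalence
responding to the Secchi scenario with the correct sign per species,
three correlated technique variants, and noisy monitoring observations.

## Worked example

```python
from habfish import PipelineConfig, run_pipeline
import pandas as pd, json

cfg = PipelineConfig({"output_dir": "demo", "seed": 42})
manifest = run_pipeline(cfg)
print(f"{manifest['n_files']} artifacts written")

summary = pd.read_csv("demo/scenario_summary.csv")
print(summary[["species", "scenario", "mean_kg_ha", "se_kg_ha", "rel_change_pct"]]
      .round(3).to_string(index=False))
```

prints (206 artifacts: 42 habitat, 42 availability, 42 CPUE and 42
biomass maps, ensembles, reports):

```
  species  scenario  mean_kg_ha  se_kg_ha  rel_change_pct
    perch       -10      11.663     0.044          -4.186
    perch         0      12.172     0.038           0.000
    perch        11      12.714     0.036           4.455
    perch        20      13.123     0.031           7.812
    perch        30      13.542     0.021          11.251
    perch        40      13.925     0.014          14.404
    perch        48      14.216     0.008          16.791
pikeperch       -10       0.536     0.001           9.206
pikeperch         0       0.491     0.001           0.000
pikeperch        11       0.440     0.001         -10.336
pikeperch        20       0.399     0.001         -18.738
pikeperch        30       0.355     0.000         -27.739
pikeperch        40       0.312     0.000         -36.465
pikeperch        48       0.280     0.000         -42.997
```

Mean perch biomass rises and pikeperch biomass falls monotonically as
water clarity improves — the qualitative fingerprint of the method —
with 1-SE spread across the three technique variants. The valuation
report for the +11% target scenario
(`demo/valuation_report.json`) then reads:

```json
{
  "scenario": 11,
  "delta_wpue_kg_per_h": {"perch": 0.04, "pikeperch": -0.03},
  "value_change_eur_per_h": {"perch": 0.3, "pikeperch": -0.5},
  "effort_ratio": 6.0843373493975905,
  "net_index_eur_per_h": 1.3253012048192772,
  "net_sign": 1
}
```

i.e. on this synthetic landscape the +11% clarity target gains anglers
EUR 0.3 per fishing hour on perch, loses EUR 0.5 on pikeperch, and —
because perch is targeted ~6.1× more often — nets positive.

The same stages are available as CLI verbs over TIFF/CSV/YAML files:

```sh
habfish simulate --out maps/
habfish availability --habitat H.tif --water W.tif --radius-m 10000 --out X.tif
habfish run-all --config my_config.yaml
```

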