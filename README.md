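# idhscape

Regional diversity–disturbance analysis for rainforest landscapes.

Tropical-forest inventories at the landscape scale record thousands of
stems under vernacular (forester) names, each corresponding to one or
several botanical species.  `idhscape` is for community ecologists who want
to test the intermediate disturbance hypothesis (IDH) — the prediction that
local species diversity peaks at intermediate disturbance — on such data:
it estimates per-site Fisher's alpha while propagating naming uncertainty
by Monte Carlo, builds a disturbance indicator from the stem frequency of
short-lived Urticaceae pioneers (*Cecropia*, *Pourouma*), validates that
indicator against canopy-gap fractions from LiDAR-like height models,
derives a soil-diversity habitat proxy from field profile descriptions, and
fits hump-shaped diversity–disturbance models.  Because landscape-scale
field campaigns are rarely redistributable, the package ships a
synthetic-landscape generator with the same statistical structure, so the
entire pipeline is testable end-to-end.

## The model

Diversity is summarized by Fisher's alpha, defined implicitly by
`S = α·ln(1 + N/α)` for `S` species among `N` stems, and modelled as

    AlphaDiv_i ~ N(θ0 + θ1·U_i + θ2·U_i^θ3 + θ4·Rain_i + θ5·Alt_i, σ²)

with `U` the Urticaceae stem frequency (%), `Rain` annual rainfall (mm/yr)
and `Alt` elevation (m).  `θ3 = 2` gives the classical IDH hump with its
peak at `U* = −θ1/(2θ2)`; leaving `θ3` free (inferred by a collapsed-Gibbs
MCMC with the composition-draw uncertainty of alpha propagated into the
posterior) tests the robustness of the unimodal shape.  Predictor screening
uses BIC-weighted Bayesian model averaging (posterior inclusion
probabilities) and bidirectional stepwise AIC; residual spatial structure
is checked with an empirical variogram.  See `docs/methods.md` for the full
account.

## Worked example

```python
from idhscape import synth, community
from idhscape.community import fisher_alpha

fisher_alpha(100, 5000)            # 17.71: alpha for 100 species / 5,000 stems

pool = synth.gen_species_pool(1581, alpha_regional=180.0, seed=0)
sites = synth.gen_site_table(synth.GeneratorConfig(n_sites=4, seed=0))
site = sites.iloc[0]
mapping = synth.gen_vernacular_mapping(pool, ambiguity=0.6, seed=0)
stems, _ = synth.gen_inventory(site, pool, 5000, 0.6, seed=0, mapping=mapping)

est = community.estimate_diversity(stems, mapping, n_draws=500, seed=0)
draws = community.composition_draws(stems, mapping, 100, seed=1)
ind = community.compute_indicators(draws, pool, site_id=site.site_id)
```

prints, with the numbers the code produces under these seeds:

```
true alpha 205.8
estimated alpha 203.0 +- 3.1 (95% CI 197.1-209.6)
urti 3.52% (true 3.23%), pioneers 7.14%, WSG 0.632 g/cm3
```

The 5,000-stem inventory recovers the site's true alpha within log-series
sampling error; the ±3.1 spread is identification uncertainty from the
ambiguous vernacular names; the indicator block recovers the injected
disturbance level (3.52% vs 3.23% true, a binomial-sampling gap) and the
stem-weighted community wood density.

## Command line

The full pipeline — simulate → diversity → canopy → soils → fit → report —
runs as one deterministic command:

```sh
idhscape all --outdir out --seed 7
```

or stage by stage (`idhscape simulate|diversity|canopy|soils|fit|report`)
with every config key overridable by a flag (`--fix-power`, `--chains`,
`--threshold`, `--buffer-radius`, ...).  `out/report.md` collects the site
diversity table, indicator–gap correlations, inclusion probabilities, both
model fits, the diversity-peak posterior and the residual variogram;
identically seeded runs are byte-identical.

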