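# revisit

Foraging-site revisitation analysis for GPS tracking data.

Large herbivores return to particular foraging sites again and again, and
*which* sites they return to — and how often — carries different
information than ordinary habitat selection.  `revisit` implements the full
analysis chain for asking both questions of hourly GPS trajectories:

1. **Detection.**  A circle of radius *r* (default 250 m) is centred on
   every trajectory fix and the number of separate visits of the animal's
   own path to that circle is counted; a return only counts as a new visit
   after at least 12 h outside the circle.  Entry/exit times are refined by
   segment–circle intersection under constant velocity.  The radius is
   chosen where the across-site variance of visit counts peaks.
2. **Selection (used vs available).**  Sites near permanent water are
   excluded (500 m buffer); availability is modelled as uniform random
   points in the pooled local-convex-hull home range (isopleth 1).  Because
   both groups are huge, the two-sample Kolmogorov test
   ``D = sup|F̂_used − F̂_avail|`` is repeated 10,000× on balanced 100+100
   subsamples and reported as mean ± SD.
3. **Rate modelling.**  Counts are rescaled to the *revisitation rate* —
   visits per wet/dry seasonal period (seasons segmented from standardised
   NDVI) — and log rate is modelled per sex × season stratum with a linear
   mixed model: scaled covariates (√distance-to-water, EVI, phosphorus,
   temperature, log-slope) with quadratic terms, a random intercept per
   individual, backward AIC elimination with the most-parsimonious-within-
   2-ΔAIC rule, allow-listed interactions, and marginal/conditional
   R² = σ²_f/(σ²_f+σ²_α+σ²_ε), (σ²_f+σ²_α)/(σ²_f+σ²_α+σ²_ε) averaged over
   stratified resamples of the covariate gradients.

A synthetic-study generator (`revisit.synthetic`) produces complete input
bundles — covariate rasters, water features, NDVI seasons, and hotspot-
attraction trajectories whose planted covariate effects are known — so the
entire pipeline can be exercised and validated end to end without any
animal data.

## Worked example

```python
from revisit import (RecursionConfig, StudyConfig, gen_study,
                     revisitation_table, select_radius)

bundle = gen_study(StudyConfig(n_bulls=1, n_cows=1, duration_days=120, seed=42))
sites = revisitation_table(bundle.trajset, RecursionConfig(radius=250.0),
                           centre_stride=4)
top = max(sites, key=lambda s: s.n_visits)
print(len(sites), top.n_visits)
```

prints

```
1440 50
```

— 1,440 candidate sites (one per sampled fix of two 120-day hourly tracks)
of which the most-revisited circle was entered on 50 occasions separated by
at least 12 h.  Running `select_radius` on the same bundle
(`examples/02_radius_selection.py`) prints `selected radius: 200 m` — inside
the 200–300 m band around the generator's 250 m patch scale, which the
variance-peak rule recovers from the trajectories alone.  The
`examples/` directory has one short script per capability (detection,
radius selection, used-vs-available testing, rate modelling, the full
pipeline), each printing the numbers it computes and what they mean.

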