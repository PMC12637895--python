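# dielact

Observer-bias-corrected **diel activity** metrics from time-stamped,
georeferenced species occurrence records, with phylogenetic mixed models
and phylogenetic-signal tests for their trait and climate drivers.

Citizen-science platforms record *when* people photograph an animal, not
when the animal is active: raw hourly observation counts confound true
activity with observer effort, which peaks in the mid-to-late afternoon and
varies by season and region. `dielact` implements a pipeline that

1. converts timestamps to **solar time** (sun zenith at 12:00), bins them
   to the nearest solar hour inside an 8:00–20:00 window, and assigns
   91-day seasons centered on the winter solstice;
2. groups records into **SSCY** units (species × season × 250 km
   equal-area grid cell × year, minimum 30 observations);
3. estimates hourly **observer effort** per season-cell from all-taxon
   counts with a penalized Poisson spline (GAM), and
4. computes bias-corrected activity metrics by bootstrap: each of B = 50
   resamples draws n observations with replacement with probability
   ∝ 1/effort(h); **onset, median and offset** are the means over
   bootstraps of the empirical 10th, 50th and 90th percentile hours, and
   duration = offset − onset;
5. joins seasonal cell temperature, daylength at the cell center on the
   season center date, and species wingspan, z-scales the predictors, and
   fits **phylogenetic linear mixed models**

   y = Xβ + u_species + u_cell + ε,  u_species ~ N(0, σ²ₛ C), u_cell ~ N(0, σ²_c I),

   with C the Brownian-motion covariance of the species phylogeny,
   estimated by REML; candidate models (temperature spline, temperature ×
   wingspan interaction, observation-count term) are compared by exact
   leave-one-out predictive density with an SE-overlap decision rule;
6. quantifies phylogenetic conservatism of the metrics and of the model
   residuals with **Blomberg's K** (tip-permutation test) and **Pagel's λ**
   (ML with a boundary-corrected likelihood-ratio test).

A first-class synthetic-data generator produces a complete study —
phylogeny, Brownian wingspans, covariates, true activity curves (split
normals with known onset/median/offset), an afternoon-peaked effort
process that thins observations, and occurrence CSVs whose timestamps
invert the solar-time conversion — so every stage is verifiable by
parameter recovery against known truth.

## Worked example

```python
import numpy as np
from dielact.synthetic import SyntheticConfig, generate_study, effort_function
from dielact.effort import EffortSurface, HOURS, inverse_effort_weights, uniform_weights
from dielact.activity import bootstrap_metrics, correction_summary

cfg = SyntheticConfig(n_species=20, n_cells=6, seed=42)
truth, tree, grid, occurrences, samples = generate_study(cfg)
print(f"{len(samples)} SSCY samples, {len(occurrences)} records")

corrected, raw = [], []
for s in samples:
    e = effort_function(cfg, s.season)
    surface = EffortSurface(s.season, s.cell_id,
                            tuple(float(v) for v in e(np.array(HOURS, float))),
                            0, False, 0.5)
    corrected.append(bootstrap_metrics(s, inverse_effort_weights(s, surface), B=50, seed=0))
    raw.append(bootstrap_metrics(s, uniform_weights(s), B=50, seed=1))

m = corrected[0]
print(f"{m.species} {m.season} cell={m.cell_id}: onset={m.onset:.2f} "
      f"median={m.median:.2f} offset={m.offset:.2f} duration={m.duration:.2f} h")
s = correction_summary(corrected, raw)
print(f"onset shift {s.onset_shift:+.2f} h, offset shift {s.offset_shift:+.2f} h, "
      f"duration change {s.duration_change:+.2f} h ({s.duration_change_pct:+.1f}%)")
```

prints

```
80 SSCY samples, 7931 records
Species_001 winter cell=(4, 5): onset=12.68 median=13.98 offset=16.12 duration=3.44 h
onset shift -1.42 h, offset shift -0.09 h, duration change +1.33 h (+29.1%)
```

The corrected estimates shift onsets earlier and lengthen durations
relative to the uniform-weight (raw) estimates: exactly the signature of
removing an afternoon-peaked observer bias. The winter onset here sits
late because winter observer effort is concentrated in the warm afternoon,
leaving few early observations to upweight.

The same analysis runs from the shell as a stage pipeline with on-disk
artifacts and a run manifest:

```sh
dielact all --workdir run1 --seed 0          # simulate → ingest → effort →
                                             # metrics → covariates → model → physig
dielact metrics --config pipeline.yaml       # or any single stage
```

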