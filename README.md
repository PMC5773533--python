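# actistate

Active State / Inactive State analysis of home-cage monitoring (HCM) event
streams, for behavioral phenotyping of mice.

Continuous home-cage monitoring records each animal's day as a stream of
events: position fixes emitted whenever the center of mass moves more than
1 cm, and feeding/drinking bouts recorded as time intervals at the feeder
and lickometer. `actistate` organises that stream into two mutually
exclusive behavioral states and runs a statistical battery over the
result:

1. **Home Base** — the cage is discretised into a 2 × 4 grid; the cell(s)
   where the animal spends its longest inactive periods are designated by
   three ordered occupancy rules (niche-preference, single-cell majority,
   best contiguous pair).
2. **State designation** — the union of movement, feeding, and drinking
   events outside the Home Base is scanned for temporal gaps; gaps longer
   than the Inactive State Threshold (IST, default 20 min) become
   Inactive States (IS), and everything between them is bridged into
   Active States (AS). The two state sets exactly partition the 22 h
   observation window (a daily 2 h maintenance period, Zeitgeber time
   6–8, is excluded).
3. **Circadian features** — nine feature classes per mouse-day over 11
   two-hour bins: food (F), water (W), distance (D), AS probability
   (ASP), AS numbers (ASN), AS durations (ASD), and AS intensities for
   feeding, drinking, and movement (ASI_F, ASI_W, ASI_D).
4. **Statistics** — broad-sense heritability of any feature by balanced
   one-way ANOVA variance components,
   H² = V_g / (V_g + V_e) with
   V_g = (MS_between − MS_within)/n, bootstrapped over random halves of
   each animal's days; total and AS time budgets with dark/light
   Kullback–Leibler divergence; onset/offset-aligned feeding and drinking
   probability profiles (180 five-second bins) tested against a
   movement-anchored null with Welch's t; pairwise K-means (K = 2)
   clustering scored by S = (S_in + S_out)/2; cross-validated one-vs-rest
   logistic-regression strain classification at mouse-day and mouse
   level; and 3-D PCA strain ellipsoids with Monte Carlo overlap numbers.

A synthetic-cohort generator (`actistate.synthetic`) produces event
streams from an alternating renewal process with strain-specific
circadian profiles and known ground truth (true states, true nest cell),
so every stage of the pipeline can be validated end to end without
access to recording hardware.

## Worked example

```python
import numpy as np
import actistate as a

library = a.default_strain_library(3, seed=42)
cfg = a.SimulationConfig(strains=library, mice_per_strain=4, days_per_mouse=6, seed=42)
cohort, truth = a.simulate_cohort(cfg)
print(f"cohort: {len(cohort)} mouse-days, strains: {cohort.strains}")

rec = cohort.records[0]
hb = a.designate_home_base(rec)
part = a.designate_states(rec, hb, ist_s=1200.0)
print(f"{rec.mouse_id} day {rec.day_index}: home base cells {hb.cells} ({hb.basis}), "
      f"{part.n_active} active states, {part.total_active_s/3600:.1f} h active")

feats = a.compute_day_features(rec, part, a.assign_event_amounts(rec))
print("ASP per 2 h bin:", np.round(feats.ASP, 2))

table = a.cohort_features(
    a.compute_day_features(r, a.designate_states(r, a.designate_home_base(r)),
                           a.assign_event_amounts(r))
    for r in cohort
)
h2 = a.bootstrap_heritability(table, "ASP", trials=20, n_per_strain=4, seed=0)
print(f"ASP daily heritability: {h2.loc['daily','mean']:.2f} (sd {h2.loc['daily','sd']:.2f})")

from actistate.features import feature_matrix, FEATURE_CLASSES
X, strains, mice = feature_matrix(table, list(FEATURE_CLASSES))
res = a.strain_classifier(X, strains, mice, trials=20, seed=0)
print(f"strain classification: {res.md_mean:.1%} per mouse-day, {res.mouse_mean:.1%} per mouse")
```

Output:

```
cohort: 72 mouse-days, strains: ['S00', 'S01', 'S02']
S00_m00 day 0: home base cells (7,) (niche-max), 13 active states, 6.3 h active
ASP per 2 h bin: [0.   0.24 0.64 0.59 0.57 0.25 0.44 0.   0.08 0.2  0.16]
ASP daily heritability: 0.55 (sd 0.11)
strain classification: 99.9% per mouse-day, 100.0% per mouse
```

The first line confirms the cohort shape. The example animal nests in the
niche cell of the coarse grid (cell 7) and spends 6.3 of its 22 observed
hours in 13 Active States, concentrated in the dark-cycle bins (indices
2–7 of the ASP vector). Daily-average AS probability is substantially
heritable in this three-strain cohort, and the concatenated 99-dimension
feature vectors separate the three strains essentially perfectly under
cross-validation — the strains were constructed with distinct circadian
profiles, so this is the expected parameter-recovery outcome.

## Command line

`actistate` installs a CLI mirroring the library stages:

```bash
actistate simulate --strains 16 --mice 9 --days 12 --seed 7 --out cohort/
actistate homebase cohort/ --out homebases.csv
actistate states cohort/ --ist-min 20 --out states.csv
actistate features cohort/ --out features.csv
actistate heritability features.csv --feature ASP --out h2.csv
actistate run --config analysis.yaml     # full pipeline
```

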