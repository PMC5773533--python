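# Methods

This note records the scientific and numerical choices behind
`actistate`: the state model, the conventions adopted where the method
leaves room, what the synthetic cohorts do and do not emulate, and the
problem sizes the test suite runs at.

## Time, space, and data contract

Time is seconds from Zeitgeber time 0 (lights-on). A mouse-day runs from
the end of the daily maintenance period (ZT8) to the start of the next
one (ZT6 + 24 h), a 22 h window; all intervals are half-open
`[start, end)` so that state partitions are unambiguous. The cage floor
is 24 cm × 45 cm with the origin at the corner nearest the water spout;
the 10 × 10 cm housing niche sits in the far corner. The coarse
home-base grid is 4 cells along the length × 2 across the width
(11.25 × 12 cm), with exactly one cell containing the whole niche; the
fine occupancy grid is 24 × 12 (288 cells of 1.875 × 2 cm). Positions on
an interior gridline belong to the higher-index cell.

Raw data arrive as per-mouse-day event streams: movement fixes
`(t, x, y)` emitted on >1 cm displacement, feeding/drinking bouts as
time intervals, and daily consumption totals. No public file format
exists for such recordings, so the package defines a two-file CSV
dialect (`events.csv` + `totals.csv`); reading uses exact
(`round_trip`) float parsing so that write→read is lossless. Quality
control is validate-and-reject: records with unsorted events,
out-of-cage positions, overlapping same-kind bouts, or out-of-window
times are refused rather than repaired (platform drift correction is a
hardware-specific step outside this package's scope).

## Position and Home Base

Position between movement events is interpolated by sample-and-hold:
the animal occupies its last fix until the next one, which is the only
assumption consistent with fixes being emitted on threshold
displacement. Time before a record's first fix is uncounted. Home Base
designation applies three ordered rules to full-day coarse-grid
occupancy: (1) if the top cell is the niche cell, it is the Home Base;
(2) otherwise a top cell holding more than half of counted time stands
alone; (3) otherwise the edge-adjacent pair with the largest summed
occupancy is chosen, ties broken by the lexicographically smallest cell
pair. Whether full-day or IS-only occupancy should drive the rules is
ambiguous in principle; full-day occupancy is used, and on synthetic
cohorts (where the animal rests in a known nest cell) the two choices
agree.

## State designation

Activity events are all ingestion bouts plus movement fixes outside the
Home Base cells; ingestion is never position-filtered because the
feeder and lickometer are themselves sites of active behavior (this
matters for animals nesting adjacent to the devices). Events are merged
whenever the gap between them is at most the Inactive State Threshold
(IST, default 1200 s); each merged run becomes an Active State spanning
first event start to last event end, and the complement of the positive
ASs within the window forms the Inactive States. Two boundary
conventions are fixed here: a gap exactly equal to the IST is bridged
(only gaps *exceeding* the threshold split), and an isolated event with
long gaps on both sides yields a degenerate zero-length AS that marks
the event but carries no time. Partitions are validated on
construction: exhaustive coverage, disjointness, and all internal gaps
greater than the IST.

A brute-force oracle (`states_oracle`) re-derives the partition by
labeling every tick of a 1 s grid from first principles and is compared
against the sweep-line implementation in tests; the two agree exactly
on simulated cohorts. AS counts are provably non-increasing in the IST
(a larger threshold can only bridge more gaps), which the sweep test
asserts from 5 to 60 min.

## Features

Per-event consumption is not measured by the hardware; each event
receives its time-proportional share of the daily total of its kind.
Nine feature classes are computed over 11 two-hour bins. Conventions
where the definitions need sharpening: an AS spanning a bin boundary is
counted once, in its onset bin, for ASN/ASD, but contributes time to
every overlapped bin for ASP and the intensities (keeping ASN a count
and ASP a fraction); distance steps go to the bin of the later fix;
ingestion amounts are prorated by fractional time overlap when an event
straddles a bin edge; ASD and the intensities of a bin with no AS time
are reported as 0, not missing. Conservation (per-bin food summing to
the daily total) and bin-refinement invariance of distance are tested
exactly.

Daily-pattern correlations (Pearson and Spearman, through
`scipy.stats`) operate on mean 11-bin vectors at mouse or strain level.
Constant vectors make a correlation undefined; such pairs are returned
flagged rather than as NaN. One caveat the test suite documents: a
per-day intensity of 0 in state-free bins induces a spurious
presence/absence correlation with consumption when intensities are
averaged naively; intensity comparisons should use AS-time-weighted
(ratio-of-sums) pooling, which the relevant test does.

## Heritability

Broad-sense heritability uses balanced one-way ANOVA mean squares on
per-mouse feature means (s strains × n mice):
MS_b = n/(s−1)·Σ(μ−μ_i)², MS_w = Σ(μ_ij−μ_i)²/(N−s),
V_g = (MS_b − MS_w)/n clipped at zero, V_e = MS_w, H² = V_g/(V_g+V_e)
(defined 0 when both components vanish). The estimator is affine
invariant and bounded in [0, 1]; it agrees to 1e-10 with a two-pass
naive evaluation and with the F-statistic identity
H² = (F−1)/(F−1+n). Bootstrap robustness: each of 20 trials resamples
half of each mouse's days (floor, minimum 1), subsamples a balanced
n per strain (default 9) from strains with more animals, and
re-evaluates H² per bin and for the across-bin daily mean. Because a
single 16-strain draw carries roughly ±0.09 of realized intraclass
noise, recovery of an analytic target is asserted on means over
independent cohorts, not on one draw.

## Time budgets

Budgets allocate time among IS, feeding, drinking, locomotion, and
"other" (unresolvable non-locomotor movement) for the full day, the
dark cycle (ZT12–24), or the light cycle (ZT0–12; 10 h of it fall in
the window). The event stream does not define "locomotion time"
directly, so it is operationalised as movement episodes — maximal runs
of fixes with inter-fix gaps at most `locomotion_gap_s` (default 1 s) —
intersected with AS time; the parameter is exposed in the configuration
and flagged as a modeling choice. Categories are made disjoint by the
priority feeding > drinking > locomotion so budgets are probability
vectors; the AS-scope budget equals the total-scope within-AS
proportions renormalised by (1 − IS share), which is tested. KL
divergence is computed in nats as D(DC‖LC) after adding a 1e-6
pseudocount to every category and renormalising, making it finite,
nonnegative, and zero exactly on equal budgets. Strain-level bootstrap
budgets pool raw category seconds over sampled days (pooled-time
rather than per-mouse averaging; both are defensible, pooling is the
package default).

## Within-AS structure

For each AS, the 15 min after onset (or before offset) is divided into
180 five-second bins; a bin is 1 if an event of the behavior overlaps
it. Bins beyond a short AS's extent score 0, and scoring is masked to
the aligned AS so neighboring states are never double-attributed.
Offset indexing places bin 179 immediately before the offset. Day
profiles average over the day's ASs; mouse profiles average day
profiles. The null model anchors the same windows (unmasked) at
movement fixes sampled without replacement, as many per day as the
round of the animal's mean daily AS count, and peaks are compared
across mice with Welch's unequal-variance t-test (zero-variance equal
groups return p = 1 by convention). Note that the null is a baseline,
not a distributional twin of the aligned estimate: extent masking makes
real profiles decay with bin index, and null windows run over state
tails; structureless feeding is therefore verified as "the detector
stays silent", not as numerical equality of the two profiles.

## Discrimination

The two-group clustering accuracy score averages within-group purity
and between-group discriminability, S = (S_in + S_out)/2; it is
symmetric under simultaneous relabeling, bounded in [0, 1], equals 1 on
identical labelings, and its mean under uniformly random labels
approaches 0.5 from above (≈0.506 at t = 10,000, inside the ±0.01
acceptance band). Empty predicted groups contribute 0. Pairwise strain
separability runs K-means (K = 2, 10 restarts, seeded) on standardised
train vectors from per-mouse half splits and assigns all days to the
nearest centroid. The full classifier is one-vs-rest L2 logistic
regression (inverse strength C = 1.0, a default the source method
leaves unspecified) on train-standardised features; mouse-level
classification labels each animal's held-out mean vector. Because the
split design places every animal on both sides, permuting mouse→strain
labels does *not* reduce accuracy to chance (the model can exploit an
animal's true-strain cluster); the 6.25% 16-class chance level is
verified on association-free features instead.

PCA on mouse-average vectors uses the population-normalised covariance
C = (1/n)MᵀM of the column-centered matrix and projects onto
variance-normalised components N = MVD^(−1/2), so every projected
column has unit variance; zero-variance features are dropped with a
warning and fewer than three positive eigenvalues is an error. Strain
ellipsoids are axis-aligned (projected mean center, per-component sd
semi-axes, singleton or degenerate strains rejected). Overlap numbers
sample 10,000 points uniformly in the smaller ellipsoid's bounding box
(volume ties broken lexicographically by label) and report the
fraction of in-smaller points also inside the larger; the estimate is
validated against the closed-form sphere–sphere lens volume.

## Synthetic cohorts

The generator drives an alternating IS/AS renewal process. State
durations use piecewise-exponential hazards whose rate follows the
circadian bin active at the *current* time, so expected AS time
fractions track the target 11-bin profile within each bin instead of
lagging across bin boundaries; IS durations add a hard floor (default
21 min, above the 20 min IST) and AS durations a 2 min floor. Within an
AS the animal random-walks outside its nest cell (reflecting walls,
waypoints every ~15 s expanded into 1 s-spaced micro-bursts so
locomotor episodes carry duration), feeds on 5 s slots with probability
`feed_p_base + feed_p0·exp(−decay·t_from_onset)` (random per-AS slot
phase, so event edges are not locked to the profile grid), and drinks
at a baseline rate with a bump in the final minute; during ISs it sits
in its nest cell emitting only within-nest jitter. Event amounts accrue
at constant per-kind rates, so proportional reallocation reproduces
them exactly.

The construction yields three oracle guarantees used throughout the
tests: gap-bridging designation at a 20 min IST recovers the true AS
intervals *exactly* (between-state gaps ≥ 21 min, within-state gaps
≤ 15 s); IS-restricted occupancy argmax is the true nest cell; and the
default 16-strain library (distinct Gaussian-bump nocturnal profiles
with a pairwise L2 floor of 0.05, strain-specific speeds, rates, state
durations, and nest cells alternating between the niche and its
neighbor) is separable enough for ≥95% mouse-level classification.

What the simulator does **not** emulate: event counts are roughly two
orders of magnitude below a real acquisition system (hundreds to a few
thousand events per day rather than tens of thousands; `movement_dt_s`
scales this), there are no persistent individual differences within a
strain, no drift or device malfunction, no correlation between
position and ingestion timing, and gap durations are bimodal by design
rather than empirical. Passing tests therefore demonstrate
correctness of the algorithms and recoverability of planted structure,
not that real mice satisfy the separation assumptions — on real data
the IST sweep and the null-model comparisons are the tools for judging
that.

## Problem sizes and determinism

The default simulated study is 16 strains × 9 mice × 12 days
(1728 mouse-days), matching the balanced heritability design
(s = 16, n = 9, N = 144); smaller cohorts (2–3 strains, 2–6 mice, 2–6
days) serve the per-module tests. All randomness flows from explicit
integer seeds; cohort simulation derives one seed sequence per
mouse-day from the root seed, and the pipeline derives named substreams
per analysis stage, so a fixed configuration reproduces every number
bit for bit. Brute-force state checking runs at 1 s resolution over
100 mouse-days in the acceptance suite.

## Known limitations

* Heritability assumes a balanced design; unbalanced cohorts must be
  subsampled (the bootstrap does this) rather than analysed directly.
* The locomotion category depends on an operational gap parameter with
  no counterpart in the source method's text.
* KL divergence direction is fixed as D(dark‖light); the reverse is
  similar in magnitude for the budgets seen here but not identical.
* Zero-length Active States carry no time and are invisible to every
  time-weighted statistic; they exist only to keep the event algebra
  faithful.
* The Monte Carlo overlap number inherits ~0.005 sd at 10,000 points
  for mid-range overlaps; increase `n_points` for tighter estimates.
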