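# Methods

## The statistic

The pipeline quantifies anticipation of a Zeitgeber transition — the
clock-driven rise of locomotor activity that precedes lights-off in LD,
or the warm→cold step during temperature-cycle entrainment — and how
uniformly a population expresses it.

Per-minute beam-crossing counts are summed into 30-minute bins and each
fly is normalized to its own maximum bin, giving activity in percent of
max on [0, 100]. Bins are labelled by their start minute: the value at
ZT 690 covers minutes 690–719 of the Zeitgeber day. The population
profile is the per-bin **median** across flies (more robust to single
hyperactive individuals than the mean, and the quantity the landmarks
are defined on).

Two landmarks are read off the median profile inside a search window
that ends at the transition:

* **ZT_min** — the *last* bin attaining the window minimum;
* **ZT_max** — the *first* bin after ZT_min attaining the maximum of the
  remaining pre-transition bins.

The bin starting at the transition is never a candidate: the acute
startle burst at the transition is a direct environmental response, not
anticipation, and must not become the peak. Landmarks may also be set
manually; the result records whether they were detected or supplied.

With shared landmarks, each fly's slope is
`(Act(ZT_max) − Act(ZT_min)) / (t_max − t_min)` in percent of max per
minute. **Slo_the** applies the same formula to the median profile;
**Slo_exp** is the median of the individual slopes. Their ratio indexes
population synchronization (≈ 1 for a coherent population), and a fly is
classified *anticipating* when its slope exceeds ½ · Slo_the. The
downhill variant (the activity decline after the morning peak, used on
the second day of constant darkness after temperature cycles, where
control populations are most coherent while *decreasing* activity)
mirrors every rule: first peak bin, then last minimum bin, negative
slopes, and "anticipating" means declining steeper than ½ · Slo_the.

Statistics are computed at full minute/float precision; rounding to
half-hour ZT values and two decimals is display-only.

## Protocol model

Schedules are ordered, contiguous segments with at most one cyclic
modality each: light cycles in LD; temperature (thermophase 25 °C,
cryophase 16 °C) cycles in LLTC/DDTC with light constant. ZT0 is
lights-on under cyclic light and thermophase onset under cyclic
temperature. The standard protocol is LD → constant (LL or DD) →
temperature cycles, with the thermophase onset delayed by a configurable
number of hours (default 5) relative to the old lights-on time. The
partial handover day between the constant segment and the first full
thermophase is excluded from day indexing: "TC day k" counts full days
from the first thermophase onset. A constant segment appended after the
cycles carries the projected subjective-day grid for DD analyses. Only
square-wave transitions are modeled (no ramps or twilight).

Choices the recordings themselves cannot decide, fixed here as package
conventions: invalid monitor readings (status ≠ 1) and gaps stay on the
time grid as masked rows rather than being dropped; a bin with more than
half of its minutes invalid is missing; per-fly normalization uses the
fly's whole recording (a per-day window is available as an option) so
that days remain mutually comparable; flies with zero maximum or zero
total counts in the analysis window are excluded and reported, never
silently dropped.

## Synthetic populations

The generator produces labeled ground-truth data so that every stage is
testable without recordings. Counts are Poisson at the monitor's 1-min
resolution (optionally gamma-overdispersed); the rate of a clock-intact
fly is

    λ(t) = [baseline + evening ramp(φ) + morning ramp(φ)] · siesta(φ) + startle(t)

where φ is the fly's internal phase: equal to ZT in cyclic segments,
free-running at a configurable period (default 24 h) in constant ones.
Ramps are piecewise linear — zero at onset, amplitude at the peak, held
until the transition they anticipate (or an explicit end phase, e.g.
activity persisting into the early thermophase for the dark
temperature-cycle preset), then zero — so the analyzed statistic has an
exact analytic expectation (`expected_rate`, `expected_day_profile`).
The startle is an exponentially decaying burst starting *at* each
transition (default half-life 10 min), which a correct peak search must
exclude. The siesta is a multiplicative midday trough (ZT4–ZT8).

Defaults describe a typical control experiment: 60 flies, baseline
0.2 counts/min, evening ramp 2.0 counts/min rising ZT8.5→ZT11.5 (so the
peak bin holds ≈ 66 counts, a realistic evening maximum), morning ramp
0.8 counts/min before lights-on, startle 3.0 counts/min, siesta depth
0.3.

Three labeled classes compose a population: `synchronized` flies carry
the template phase (plus any population-wide delay); `desynchronized`
flies have the whole ramp program shifted by a uniform random phase
(clock running but not entrained); `flat` flies are clock-disrupted —
no ramps and no siesta, since both are clock outputs — leaving a
constant rate plus the startle, which is pure masking and survives clock
loss. Class sizes are deterministic (rounded fractions) so ground-truth
fractions are exact; membership order is shuffled.

### The clock-disrupted preset

A half-disrupted population whose disrupted members are simply *silent*
between the landmarks does **not** reproduce the mutant signature
(ratio ≈ 0.5): when exactly half the population is low at both
landmarks, the per-bin median and the median of per-fly slopes are
pinned to the same cluster boundary, so Slo_the and Slo_exp attenuate
identically and the ratio stays ≈ 1 (we verified this across mixture
splits, noise levels, and phase-jitter widths). The signature the real
mutants show requires the disrupted flies to be constitutively *active*:
elevated around the clock, they hold the population median up at the
evening peak while contributing no individual slope, and the intact half
keeps the trough median low. Clock mutants are indeed typically
hyperactive off-peak (elevated cryophase activity) and lose the siesta.
The `cycDN_like` preset therefore sets 45% of flies flat with a
constitutive rate of 5 counts/min plus 5% uniformly re-phased
(p_flat + p_desync = 0.5), which yields a 20-seed median
Slo_exp/Slo_the of ≈ 0.55 and ≈ 50% of flies classified anticipating —
the clock-disrupted phenotype. The flat rate and split were calibrated
against that target ratio; they are preset parameters, not generator
defaults.

### What the generator does not emulate

Real recordings add bout structure (bursts and pauses rather than
homogeneous Poisson counts), gradual re-entrainment over the first cycle
days (the generator snaps to the new Zeitgeber instantly), temperature
ramps inside incubators, activity–rest feedback, aging and death. Tests
passing on synthetic data therefore certify the *statistics and
plumbing* — binning, normalization, landmark rules, slope/ratio
arithmetic, classifier behavior on known mixtures — not the biology of
any particular genotype.

## Ground-truth experiments

Two designs in the test suite fix a subtlety of the ½ · Slo_the
classifier. When the anticipating fraction f of a population falls below
one half, the population median lies entirely within the
non-anticipating cluster, Slo_the collapses to noise level, and the
threshold with it — the classifier's false-positive rate then approaches
50% and its estimate of f tends to f + (1−f)/2 no matter how small the
noise. Recovering a known f is therefore done against the **archetype
threshold**: ½ × the theoretical slope of the synchronized template,
computed from the generator's noise-free expected rate through the same
binning/normalization path, with the template's true landmarks
(ZT 510/690). Against that anchor the classifier recovers
f ∈ {0.2, 0.5, 0.8} within ±10 percentage points in ≥ 90% of seeds at
n = 60, and both the anticipating fraction and the Slo_exp ratio degrade
monotonically with the desynchronized fraction. Population-level
analyses (the control and disrupted benchmarks, and the acceptance
script) use the fully self-referential procedure — landmarks and
Slo_the re-estimated from the population under analysis — exactly as one
would on real data.

## Numerical and design notes

* Landmark ties: last bin for the minimum, first for the maximum, per
  the definitions above; a window whose minimum falls on the final
  pre-transition bin is rejected with a request for a narrower window.
* A flat median in the window (min = max) raises "no anticipation
  structure"; the ratio is undefined when Slo_the ≤ 0 (uphill) and an
  error is raised rather than returning a sign-flipped value.
* Landmarks are population-level and shared by all flies; per-group
  analyses should compute landmarks per group.
* Kruskal–Wallis uses the tie-corrected H with the χ² approximation; a
  seeded label-permutation p-value is available for very small groups.
  Pairwise effect sizes are percentile-bootstrap mean differences
  (default 5000 seeded resamples).
* Box plots: quartiles, mean (cross), Tukey 1.5 × IQR whiskers; points
  beyond the fences are outliers.
* Actograms display per-bin population means of normalized activity
  (averaging is conventional for actograms), while daily profiles
  display medians.
* Simulation sizes in the test suite (n = 60 flies, 11-day protocols, 20
  seeds per condition) match the scale of a typical monitor experiment
  and keep every expected contrast several standard errors wide.
* The DAM2 dialect accepted is the 42-field layout with `d mmm yy`
  English month abbreviations (case-insensitive); one dialect, strictly
  validated. Only status code 1 is a valid reading. Monitors are merged
  on exact timestamp intersection; disjoint recordings are an error.

## Known limitations

* The ratio and classifier are only informative when the population
  median retains anticipation structure; for heavily desynchronized
  populations (f < ½) the self-referential threshold is unreliable by
  construction (see above), and the landmark rise amplitude is the
  better degradation signature.
* Re-entrainment dynamics are not modeled; analyses of early cycle days
  on synthetic data are optimistic.
* Period estimation, rhythmicity statistics (χ² / Lomb–Scargle
  periodograms) and sleep-bout analysis are out of scope.
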