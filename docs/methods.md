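# Methods

## The composite score

Each of six domains is rescaled per animal and day as a percent of maximum
possible effect, `%MPE = (test − baseline)/(anchor − baseline) × 100`,
where the baseline is the animal's own pre-operative value and the anchor a
fixed worst-case value calibrated in a gut ischemia–reperfusion cohort
(food 0 g, transit 720 min, sucrose 5 %, von Frey 0.04 g, distance 100 m,
social exploration 20 s). The formula is direction-agnostic: it behaves
identically whether the anchor lies below the baseline (food, distance,
von Frey, social, sucrose) or above it (transit). Raw %MPE is clamped to
[0, 100]: values below 0 mean better-than-baseline performance, values
above 100 exceed the calibrated maximum deficit; clamping keeps every
domain score in {0..3} and makes scoring idempotent.

Bins are contiguous half-open intervals [0, 25), [25, 50), [50, 75),
[75, 100], mapped to scores 3, 2, 1, 0 so that *no deficit scores 3* and
the six-domain sum runs from 0 (gross impairment) to 18 (no impairment).
The opposite ("literal") orientation, under which 75–100 %MPE scores 3, is
retained behind `RunConfig(bin_orientation="literal")` for auditability; it
is not the default because it would score a healthy animal 0/18, which
contradicts the meaning of the composite. Boundary values fall in the
upper bin (e.g. exactly 75% scores 0).

Sucrose preference is a documented caveat: the protocol this score derives
from exempts sucrose from %MPE scaling without stating an alternative yet
still defines a 5% anchor. This package applies the same %MPE formula with
that anchor; since healthy preference sits near 90% and the anchor at 5%,
the domain behaves sensibly under the common formula, but users comparing
against other implementations should be aware of the ambiguity.

Weight gain (% change from baseline) and water intake are computed and
reported but are not composite components. Missing domains invalidate an
animal-day (no imputation or rescaling).

Baselines: food and water use the mean of the three pre-operative days;
every other domain uses the single pre-operative test closest to surgery.
Raw files encode pre-operative replicates as negative days; they are
collapsed to day 0 on read, and a file carrying both day-0 and negative-day
rows for the same animal-domain is rejected.

## Von Frey up-down estimator

The 50% withdrawal threshold is estimated with Dixon's up-down formula on
the log₁₀-force scale: `threshold = 10^(x_f + k·δ)`, with `x_f` the last
filament presented, `δ` the mean log-spacing of the filament set (0.234 for
the default set) and `k` a factor indexed by the terminal response pattern
(up to the last 6 trials, extended backwards until the window contains a
reversal). The shipped k table (`data/dixon_k.json`, 114 patterns) is
generated from the construction that defines these factors: the
maximum-likelihood location of a probit response curve whose spread equals
one log-step, evaluated on the staircase-implied stimulus levels of the
pattern; `generate_k_table` regenerates it and a test pins the file to the
computation. Alternating terminal patterns give k = ∓0.5 (the midpoint
between the two visited filaments), and mirror-image patterns have k of
opposite sign.

Design choices where the protocol is silent: the default filament set is
the standard rat series 0.04–15 g (the lower end matching the allodynia
anchor); testing starts at the set member nearest the geometric mean of
the range (1.0 g); the staircase stops 4 trials after the first response
reversal (the common convention for this method), at a configurable trial
cap, or when a bound is hit twice consecutively — such sessions are
*censored* and clamped to the bound. Estimates are always clamped to the
filament range. Validation is by simulation: against a logistic
psychometric responder the median estimate over 1000 staircases lands
within half a log-step of the true threshold, and estimates rank-correlate
> 0.9 with a brute-force logistic maximum-likelihood fit of the same
trials.

## Synthetic cohorts

The generator emulates the group-level structure the analysis assumes, not
physiology. Each group g and domain carries a latent deficit fraction
`d(t) = m_g · exp(−r_g (t − 1))` for post-operative day t ≥ 1 (0 at
baseline): a day-1 trough followed by exponential recovery. The observed
expectation interpolates between the animal's healthy level and the
domain's anchor by `d(t)`; noise is truncated-normal, or log-normal (on
log₁₀) for the strictly positive transit and von Frey domains, with the
deficit acting on the log scale there. Animals get a between-animal level
(60% of the domain SD) and an animal-specific deficit fraction
(SD 0.08, clipped to [0, 1]).

Calibration (fixed defaults): healthy centers food 17.25 g, sucrose 92%,
distance 240 m, von Frey 1.2 g, transit 72.5 min, social 50 s; laparotomy
day-1 deficit fractions are back-computed from the reported day-1 group
medians on the modelling scale (food 0.609, distance 0.722, and on log₁₀
von Frey 0.428, transit 0.933, reproducing day-1 medians of ~6.75 g,
~139 m, ~0.28 g and ~617 min), with sucrose 0.15 and social 0.30 chosen so
the expected day-1 laparotomy composite sits at the reported median of
6–7/18. Recovery rate defaults to 0.6/day. Treatments scale the
laparotomy kinetics multiplicatively — aspirin m×0.8, r×0.7 (early
benefit, slowed late recovery); aspirin+EPA m×0.55, r×1.3 (larger, faster
recovery) — and sham is a small fast perturbation (m×0.15, r×2) of naive.
Weight follows its own kinetics: +0.8%/day healthy growth minus up to 5%
surgical loss scaled by the latent deficit. Group medians and their
ordering (naive ≈ sham > treated > untreated laparotomy on early days;
near-convergence by day 6) reproduce the reported pattern qualitatively;
exact day-2/day-3 medians are not targeted.

What the generator does **not** emulate: within-animal correlation across
domains beyond the shared latent deficit, cytokine-driven mechanisms,
mortality, estimator noise in the von Frey domain (thresholds are drawn
directly, staircases are simulated separately), or day-to-day
autocorrelation of noise. Passing tests therefore demonstrate the
analysis machinery and its operating characteristics under the assumed
structure, not properties of real animal data.

One reported inconsistency is resolved in the generator's favor of the
narrative: the reported day-1 locomotion medians appear transposed
(the operated group printed *higher* than naive while described as
reduced), so healthy distance is centered at the self-consistent 240 m
naive value and surgery reduces it.

## Statistics

- **Trajectory AUC**: trapezoidal rule over observed days 0–6, no
  extrapolation; a constant score c over a span T gives exactly c·T
  (constant 17 over days 0–6 → 102 score·days, matching the reported naive
  value). Trajectories missing an explicit day-0 point are prepended with
  the baseline composite of 18 (at baseline every %MPE is 0 by
  construction).
- **Kruskal–Wallis**: tie-corrected H with the chi-square (k−1 df)
  p-value; identical pooled values give H = 0, p = 1. For total n ≤ 10 the
  exact permutation distribution is fully enumerated and two summaries are
  reported: the conservative exact p (whole observed atom counted — the
  validity-preserving convention, identical to scipy's exact Mann–Whitney
  p for two groups) and the mid-p (half the atom), the appropriate
  comparator for continuous approximations. At n = 5+5 the chi-square
  approximation tracks the mid-p within 0.02, while the conservative p
  sits above it by up to one atom-mass (~0.09) by construction.
- **Dunn post-hoc**: z-statistics vs a reference group from pooled mean
  ranks with tie-corrected pooled variance; Holm adjustment by default
  (the protocol names Dunn's test without an adjustment method;
  Bonferroni/Šidák/none are configurable).
- **Power**: `required_sample_size` iterates n upward, computing two-sided
  two-sample t-test power from the noncentral t. For the composite design
  assumption (mean 17, SD 4, 50% reduction, 80% power, α = 0.05) it
  returns n = 5/group — one below the commonly used 6 — and a Monte-Carlo
  oracle in the tests confirms the achieved power at that n.
- **Parametric delegates**: RM-ANOVA via statsmodels `AnovaRM`, Dunnett
  via `scipy.stats.dunnett`, one-way ANOVA on AUCs via `f_oneway`; the
  bespoke content of this package is the score, the staircase estimator,
  AUC and the rank-based tests.

## Operating characteristics (computed by the test suite)

On calibrated synthetic cohorts at the study size of n = 6/group: the
day-1 composite Kruskal–Wallis across five zero-deficit groups rejects at
α = 0.05 in ≈4.5% of 1000 replicates (within the 5% ± 2% calibration
band), and laparotomy-vs-naive day-1 comparisons reject in ≥80% (observed
100%) of 500 replicates. Monte-Carlo problem sizes elsewhere: 600 animals
for median-calibration checks, 1000 staircases for estimator recovery,
500 sessions for the ML-agreement check.

## Numerical conventions

Percentiles use linear interpolation (numpy default). Bit-exact
reproducibility: a cohort is a pure function of its seed; measurement CSVs
are written with `%.17g` and parsed with correctly rounded `float()`, so
write–read round-trips are exact; pipeline outputs carry no timestamps and
identical input + configuration produce byte-identical files, recorded in
a manifest with a config digest and seed.
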