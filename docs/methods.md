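# Methods

This note documents the statistical models behind `pufftopo`, the
defaults and why they were chosen, and what the synthetic cohort does
and does not establish about real device data.

## Data model

A **puff record** is one timestamped event with a duration in
(0, 10] s, a discrete power setting (low 7–9 W, medium 9–11 W, high
11–13 W), and an optional self-reported e-liquid nicotine concentration
in mg/mL. The 10-s upper bound is a hard device constraint (automatic
power shutoff); records above it are rejected at load time with a
per-row reason, never silently dropped, because real device logs are
dirty and curation must be auditable. A missing concentration is a
first-class state distinct from 0 mg/mL: zero-nicotine e-liquid is a
deliberate user choice, an absent value is a reporting failure, and the
two enter different denominators downstream.

Concentration bins partition [0, ∞) as zero = {0}, low = (0, 6],
medium = (6, 14), high = [14, ∞). The printed bin labels ("≤6 mg/mL",
"6–14", "≥14") overlap at the boundaries; this package honours the "≤6"
and "≥14" labels literally and assigns the open interval between them
to the medium bin, which keeps the bins disjoint and exhaustive.
Each power band is represented by its midpoint wattage (8, 10, 12 W)
wherever a single number is needed; only the ranges are published.

Timestamps are ISO 8601 and a puff's calendar day is its local date; no
timezone arithmetic is applied (single-country cohort, and the source
data state no timezone handling).

## Emission model

Per-puff nicotine emission is anchored to one laboratory point: under
the Coresta machine-puffing regime (55 mL / 3 s / 30 s) with 12 mg/mL
e-liquid at high power, the device emits **E_ref = 0.0952 mg/puff**.
The default model is separable,

    e(c, d, P) = E_ref · (c / 12 mg/mL) · (d / 3 s) · (w_rep(P) / 12 W),

linear in concentration, duration and representative wattage. This uses
exactly the four inputs the device records, reproduces the anchor
identically, and has clean invariants (homogeneity in c, additivity of
daily totals, a closed-form upper bound for bounded inputs) that the
test suite exploits. It is deliberately minimal: there is no
puff-volume or flow-rate term (the device records duration only — the
55-mL Coresta volume enters solely through E_ref), no duty-cycle or
PG/VG correction, and no saturation at long durations. Because the true
device physics may be nonlinear in wattage, the model is injected as a
replaceable strategy (`model=` argument), so a laboratory-derived
formula can be swapped in without touching any caller.

Puffs with a missing concentration are **not estimable** and are
excluded from every emission aggregate, with exclusion counts reported;
imputation is never attempted. Daily nicotine consumption is the plain
sum of estimable per-puff emissions in a user-day.

## Effect sizes and variability

Because the puff sample is enormous, the package computes no p-values.
The "R²" of a categorical factor is one-way **eta-squared**,
SS_between / SS_total — the standard variance-explained construction
for a categorical predictor. **Cohen d** uses the pooled (n−1) SD
without small-sample correction (a Hedges-style correction is available
as an option, off by default); the reporting layer flags |d| ≥ 0.5 and
prints smaller pairs as "N/A", the convention of such summary tables.
Both statistics are validated against brute-force sum-of-squares
oracles to 1e-10 relative on thousands of random instances.

The unit of analysis is the puff. Puffs within a user are dependent, so
puff-level effect sizes describe the recorded puff population, not a
user-level population; callers can pass per-user aggregates to the same
functions for a sensitivity analysis.

Intra-individual variability is the **CV%** (100 · sample SD / mean) of
each user's daily puff count, daily mean duration and daily nicotine
total over their own active days. A CV is undefined — flagged with a
reason, never zeroed — below two active days or at a non-positive mean.

Printed-style percentages are rounded **half-up** at printed precision
(2 decimals in tables). One published share (the high-power 46.43%)
is a truncation of 46.4356 rather than a half-up rounding; the package
reports the half-up value (46.44).

## Relative-day time course

Each user's first calendar day with at least one puff is their relative
day 1; inactive days are gaps, not zeros. Cohort curves average over
the users *active* on each relative day, one value per user per day —
daily duration is therefore a two-stage (user-then-day) mean, not a
puff-weighted pool — with SE = cross-user sample SD / √n_active and no
autocorrelation correction. A zero-filled sensitivity mode counts
inactive days inside a user's own span as zero puffs/nicotine, because
the choice materially changes the curves for sporadic users.

Adaptation metrics: day-1 mean; plateau mean over relative days 8–21 by
default (use stabilises after about a week); ramp length = the first
relative day whose mean is within a fractional tolerance of the plateau
mean; and the OLS slope over the plateau window, which should be
consistent with zero once use has stabilised. Use-duration subgroups
assign each user ⌈span/7⌉ weeks, span = last − first active day + 1;
the binning is an interpretation (the source does not define one) and
is checked only for partition consistency.

## Synthetic cohort generator

The generator emulates the study conditions so that every pipeline
stage has a testable ground truth. Defaults, with rationale:

* **Cohort**: 58 puff-recording users + 3 survey-only profiles, 60-day
  window starting 2022-02-22; demographic marginals equal to the
  published participant table. Default runs produce ~2×10⁵ puffs, the
  observed scale.
* **Durations**: lognormal clipped at 10 s. Parameters are derived from
  the target mean 3.44 s / SD 1.65 s of the unclipped law (<1% of mass
  is clipped, producing the observed small spike at exactly 10 s). A
  per-user-day jitter of the log-mean (SD 0.08) makes daily mean
  durations wobble a few percent, giving realistic nonzero duration
  CVs. Closed-form clipped-lognormal moments (including the jitter) are
  exported as the oracle for recovery tests.
* **Usage mixture**: the published 12-cell power × concentration-bin
  joint distribution, with bins split over discrete concentration
  values (0, 1, 3, 6, 10, 11, 14, 18 mg/mL) in proportion to published
  per-value counts. Each user draws a sparse personal preference vector
  from Dirichlet(α·π) with α = 6 over the population mixture π, so
  individuals favour a few combinations while E[weights] = π exactly;
  the marginal-fidelity test accounts for the Dirichlet between-user
  variance component p(1−p)/(1+α)/n_users on top of multinomial noise.
  41% of puffs lose their concentration record (the observed
  missingness).
* **Intensity**: per-user baseline rate λ_u ~ lognormal(log 192.5,
  0.95) clipped to [5, 600] puffs/day — heavy-tailed, spanning ~5 to
  several hundred with population mean 250, the observed plateau.
  Daily counts are negative binomial with per-user dispersion
  k_u ~ lognormal(log 3, 1), producing the wide observed spread of
  count CVs; `count_model="poisson"` removes overdispersion for oracle
  tests. Counts are floored at 1 (an active day has ≥1 puff by
  definition); the induced upward bias is negligible except for the
  smallest, most overdispersed users.
* **Adaptation**: the first active day is deflated by δ = 120/250 and
  counts ramp linearly back over 2 days (plateau from relative day 3);
  daily median durations start at 0.8 of plateau and ramp over 6 days
  (plateau from day 7). These are the observed day-1 values and
  stabilisation times.
* **Spans and skipping**: each user is active for a whole-week span
  (1–8 weeks, mean ~3.5, matching the observed mix of short- and
  long-duration users) placed uniformly in the window, and skips
  individual days with probability 0.35, reproducing sporadic use.
* **Timestamps** within a day are uniform; within-day microstructure
  (inter-puff intervals) is *unvalidated structure* — the source
  reports no interval statistics — and must not be analysed as if real.
* **Determinism**: one RNG stream per user, keyed by (seed, user
  index), so identical configurations regenerate byte-identical files
  and enlarging the cohort never perturbs existing users.

What passing tests show: the pipeline's algebra (conservation,
alignment, aggregation order) is correct, and its estimators recover
the generator's known parameters within Monte-Carlo error at study
scale. What they do not show: that real puffing behaviour follows
lognormal/negative-binomial laws, that real users' preferences are
Dirichlet-sparse, or that the separable emission model matches device
physics — those are modelling assumptions, stated above, not findings.
The generated daily nicotine plateau (~9 mg/day) is accordingly an
output of these assumptions (missing-concentration puffs contribute no
nicotine), not a calibrated target.

## Numerical and testing choices

Problem sizes in the test suite: distribution-shape and invariant
checks run on one full-size default cohort; parameter recovery uses 100
seeded replicates of 58-user, 21-day cohorts, comparing each estimator
to ground truth via 3 Monte-Carlo SEs of the replicate errors; ramp
recovery uses tolerance 0.2, under which the true ramp day is 3, and
checks the replicate mean within ±1 day. Effect-size recovery uses 200
replicates of a known standardized shift. Stochastic tests are seeded
(hypothesis runs derandomised), so the suite is fully reproducible.

Known limitations: no inter-puff-interval modelling; no pharmacokinetic
or aerosol-chemistry layer (emission is a theoretical proxy anchored to
one laboratory point); survey covariates are independent of usage in
the generator (real cohorts show association between nicotine history
and intensity), so demographic effect sizes on synthetic data are null
by construction; and the active-user averaging convention, while the
field's standard, makes cohort curves sensitive to who remains active —
the zero-filled mode quantifies that sensitivity.
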