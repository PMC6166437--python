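# Methods

## The paired-mode design

Each woman contributes two measurements of the same construct: an
event-level pregnancy history taken by an interviewer (FTF), with an
outcome code and end date (century-month, months since January 1900)
per pregnancy, and a per-outcome count from a private self-interview
(ACASI) over a stated reference period. The analysis is within-subject:
for each harmonized outcome category — `birth` (live birth, either
delivery mode), `loss` (miscarriage, stillbirth, ectopic pregnancy,
pooled because the self-interview asks about the three in one item) and
`abortion` — we count women reporting at least one event in each mode
over matched windows and take the quotient (ACASI reporters / FTF
reporters). Counting women rather than events makes the statistic
insensitive to multi-event recall depth; an event-count ratio exists as
a clearly-labelled secondary statistic. Estimation is unweighted: the
question is internal reporting consistency of the sample, not
population prevalence.

### Recall windows

All window membership is closed-interval on whole calendar months.

* **standard** — January(Y−5) through December(Y−1) for an interview in
  year Y: the five whole calendar years the five-year self-interview
  item names. Used on both sides for the 2006+ rounds.
* **lifetime** — open start through the interview month. The 2002
  instrument asks lifetime counts, so 2002 comparisons are
  lifetime-vs-lifetime.
* **expanded** — January(Y−6) through the interview month, FTF side
  only. "One extra year" has no canonical endpoint, so the window end is
  configurable (`expanded_end: interview | dec_prior_year`; default
  `interview`). Because the expanded window contains the standard one,
  the expanded ratio can never exceed the standard ratio — a structural
  invariant the tests exercise.

Ongoing pregnancies never enter any outcome count. Respondents missing
or refusing the self-interview module are excluded and logged; the
loader reports every exclusion row-by-row. Multiple births are one
pregnancy.

## Synthetic cohorts and the truth ledger

The generator exists so the whole pipeline can be validated against
known ground truth; it simulates the mechanisms hypothesized to drive
mode differences:

1. **True histories.** Demographics drawn independently per axis from
   configurable shares (defaults follow the unweighted composition of a
   recent survey round of US women 15–44). Per category, event counts
   are Poisson with configurable mean over a reproductive span
   (default 30 years) ending at the interview month; event months
   uniform over that span. `event_placement` can restrict events to the
   standard window or strictly before it for calibration studies, and
   `fixed_event_count` replaces the Poisson draw for closed-form
   designs.
2. **FTF reporting.** Each event is disclosed independently with
   probability `p_ftf[category]` (times optional subgroup multipliers,
   clamped to [0,1]). Event-level independence is the base model; a
   woman-level "never discloses" random effect
   (`p_never_discloser_ftf`) is available because aggregate ratios
   cannot distinguish the two. Disclosed events get a recorded month =
   true month + a symmetric two-sided geometric integer error
   parameterized by its standard deviation (`misdate_sd_months`,
   default 6; discrete, heavier-tailed than a rounded normal, single
   parameter), clamped at the interview month. Only FTF dates are
   misdated — the self-interview has no dates; its recall analogue is
   telescoping.
3. **ACASI reporting.** One disclosure draw per event with
   `p_acasi[category]`; the base windowed count is the number of
   in-window events passing that draw; each out-of-window event is
   telescoped into the count with probability `telescope_in_prob`
   (default 0.02). With probability `confusion_prob` (default 0.03) a
   woman answers with her lifetime disclosed count instead (the same
   per-event draws, ignoring the window). For the 2002 round the item
   is lifetime, so telescoping and confusion are no-ops.

Every stochastic outcome — disclosure flags, recorded months, window
membership, telescoping, the final counted-in-ACASI flag, the per-woman
confusion flag — is written to the `TruthLedger`, and a test recounts
the emitted cohort from the ledger exactly. A single seed drives all
draws; identical config + seed is byte-identical output.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| event rates (birth/loss/abortion) | 1.3 / 0.45 / 0.55 per 30-year span | plausible lifetime magnitudes for US women 15–44 |
| `p_ftf` | 0.97 / 0.60 / 0.50 | births nearly fully disclosed to interviewers; losses and abortions strongly suppressed |
| `p_acasi` | 0.99 / 0.78 / 0.58 | private mode discloses more in every category, most for stigmatized outcomes |
| `misdate_sd_months` | 6 | substantial but sub-year date recall error |
| `telescope_in_prob` | 0.02 | occasional forward-telescoping of old events |
| `confusion_prob` | 0.03 | a small minority answer five-year items with lifetime counts |

No disclosure probability is observable directly; the abortion pair was
calibrated once so the default synthetic five-year round lands in the
magnitude regime documented for real paired-mode data (abortion and
loss ratios ≈ 1.5, birth ≈ 1.2, expanded ratios attenuated toward
parity, roughly a quarter of discordant abortion reporters and over
half of discordant birth reporters matching their lifetime count). The
generator emulates the *reporting mechanisms*, not the population:
there is no age structure in event timing, no correlation between
demographics and event rates unless multipliers are set, no panel
attrition, and no cross-category misreporting (abortions recorded as
miscarriages are a stub fixed at 0 because aggregate ratios cannot
identify it). Passing tests therefore show the statistics are computed
correctly and calibrated under these mechanisms — not that real
surveys satisfy the mechanisms.

## Bootstrap design

* Resampling unit: the respondent (preserves the mode pairing). The
  per-woman reporter indicators are sufficient statistics, so
  replicates are computed by vectorized index resampling.
* B = 5,000 by default; percentile intervals at 2.5/97.5 with linear
  interpolation between closest order statistics (the numpy `linear`
  quantile rule), stated so results are bit-reproducible.
* Replicates with a zero denominator are excluded from percentiles; more
  than 1% of them raises a degenerate-bootstrap error — rare sparse
  replicates should not crash an analysis, frequent ones mean the
  category is too sparse to analyze.
* Round contrasts difference replicate b of one cohort with replicate b
  of the other (valid under independence, reproducible). Subgroup
  contrasts resample the full cohort jointly and recompute both stratum
  ratios per replicate, respecting that strata share one sample.
  Between-category contrasts on the same women use CI non-overlap — a
  conservative device, since a difference distribution is not available
  without modelling the within-woman dependence.
* No multiple-testing correction is applied anywhere.

## Confusion screen

Discordant reporters: ACASI count ≥ 1 and zero events of the category
in the standard FTF window (2006+ rounds only). The lifetime match
requires *exact* equality of the ACASI count with the count of all
completed pregnancies of the category in the history, any date; ≥
would also catch partial lifetime reporting but is not the claim being
tested. Discordance alone does not identify confusion — FTF
nondisclosure and telescoping produce it too — which is exactly what
the generator's ledger quantifies (the `n_truly_confused_in_set` column
of the sensitivity table). Losses are screened alongside births and
abortions but flagged as extra output, since the screen is conventional
only for births and abortions.

## Validation studies and problem sizes

`reportratio.studies` packages the Monte-Carlo designs the acceptance
script and tests drive:

* faithful-limit identity at n = 2,000 (all ratios exactly 1);
* closed-form recovery at n = 50,000 (one in-window event per woman,
  p_acasi = 0.92, p_ftf = 0.80; true ratio 1.15, delta-method SE
  R·sqrt((1−p_a)/(n·p_a) + (1−p_f)/(n·p_f)) ≈ 0.003, checked at 3σ);
* window monotonicity over 100 random configurations at n = 500;
* percentile-CI coverage over 200 cohorts (n = 5,000, B = 500) against
  a 95% ± 4 point band;
* type-I error of the joint subgroup test over 100 equal-disclosure
  cohorts (n = 2,000, B = 500), tolerated at 1–12% for that replication
  count;
* exact agreement with an independent double-loop recount on cohorts of
  50 women;
* ledger recovery of the lifetime-match proportion at n = 20,000 with
  confusion probability 0.3: in a design with all events pre-window and
  full ACASI disclosure, a discordant woman matches iff all k of her
  events were FTF-disclosed, so the expectation is the ledger average
  of p_ftf^k, checked at 3σ.

These sizes make the whole validation run in a few minutes on one CPU
while keeping Monte-Carlo error well inside each tolerance.

## Running on public-use survey extracts

`read_cohort` consumes CSV respondent + pregnancy tables under a
configurable column/value schema; `reportratio.io.nsfg_schema()` maps
CSV exports of the NCHS public-use female respondent and pregnancy
files (original variable names, numeric outcome codes 1–6 recoded onto
the harmonized vocabulary). The public-use files are distributed by
NCHS and cannot be bundled here; to run the external reproduction test,
export per-round CSVs and place them as
`data/nsfg/<round>/respondents.csv` + `pregnancies.csv` in either the
default schema or the NCHS variable names. Education is accepted in
input schemas but has no default recode (no conventional category set
for this analysis); refusals/don't-knows in self-interview counts
exclude the respondent, a package decision documented in the loader.

## Known limitations

* The expanded-window correction can overshoot for near-parity
  categories (expanded birth ratios slightly below 1) because the
  six-year denominator absorbs both misdated and genuinely older
  events; it bounds misdating effects rather than estimating them.
* Aggregate ratios support only bivariate demographic contrasts; the
  statistic cannot enter multivariate models.
* Women who disclose in neither mode are invisible to every quantity
  here; the ratios measure relative, not absolute, completeness.
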