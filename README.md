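# reportratio

Paired survey-mode **reporting ratios** for pregnancy outcomes, with
percentile-bootstrap inference and a ground-truth synthetic-cohort
simulator.

## The problem

Surveys of reproductive health collect pregnancy outcomes twice from the
same woman: once in an interviewer-administered face-to-face (FTF)
pregnancy history — one dated record per pregnancy — and once in a
private audio computer-assisted self-interview (ACASI) that asks for a
single count per outcome over a stated recall period. Stigmatized
outcomes, abortion above all, are underreported to interviewers, so the
two modes disagree; quantifying that disagreement, and separating
privacy effects from recall artifacts (misdated events, lifetime counts
given in answer to a five-year question), is the measurement problem
this package addresses. Its audience is survey methodologists and
demographers working with paired-mode microdata such as the US National
Survey of Family Growth public-use files.

## The statistic

For an outcome category *c* (birth, pregnancy loss, abortion) over
matched recall windows, the within-subject reporting ratio is

```
R_c = #{ i : ACASI count_i(c) >= 1 } / #{ i : FTF window count_i(c) >= 1 }
```

counted over the same n women. R = 1.00 is parity; R > 1 means more
women disclose the outcome privately than to the interviewer. Recall
windows are closed month intervals on century-month codes (months since
January 1900): the *standard* five-year window spans January(Y−5) to
December(Y−1) for an interview in year Y, matching the self-interview
item; the *expanded* variant widens only the FTF denominator to
January(Y−6) through the interview month, so attenuation of R under
expansion measures date misdating rather than disclosure. Inference is
a percentile bootstrap (default B = 5,000) resampling respondents with
replacement — the respondent is the resampling unit, preserving the
mode pairing — with 2.5th/97.5th-percentile intervals, replicate-wise
difference tests between independent cohorts, joint-resampling
difference tests between demographic strata, and a conservative CI
non-overlap check between outcome categories. A sensitivity screen
flags *discordant reporters* (ACASI window report, empty FTF window)
whose ACASI count equals their lifetime FTF count — the signature of
answering a five-year question with a lifetime number.

The synthetic-cohort generator simulates the hypothesized mechanisms —
per-event mode-specific disclosure, two-sided geometric date error,
telescoping into the window, lifetime-for-window confusion — and emits
a truth ledger recording every stochastic decision, so every statistic
can be validated against known ground truth.

## Worked example

```python
from reportratio import GeneratorConfig, generate_cohort, bootstrap_ratio
from reportratio.sensitivity import lifetime_match_proportion

cohort, truth = generate_cohort(GeneratorConfig(n=11_297, seed=20250931))
res = bootstrap_ratio(cohort, "abortion", B=1000, seed=20250929)
print(f"abortion ratio {res.point.ratio:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})")
s = lifetime_match_proportion(cohort, "abortion")
print(f"{s.n_lifetime_match}/{s.n_discordant} discordant reporters "
      f"({100*s.proportion:.0f}%) match their lifetime count")
```

prints

```
abortion ratio 1.53 (1.41-1.67)
124/456 discordant reporters (27%) match their lifetime count
```

i.e. ~53% more women disclose a recent abortion in the self-interview
than to the interviewer in this simulated round, and about a quarter of
the women with a self-reported abortion missing from the matching
history window reported exactly their lifetime abortion count —
consistent with lifetime-for-window confusion rather than extra
disclosure.

The numbered scripts under `analysis/` run the full study on synthetic
rounds: `01_simulate_cohorts.py` (one cohort per survey round, sizes
7,643 / 12,272 / 11,297), `02_reporting_ratios.py` (round × outcome and
stratified ratios), `03_bootstrap_inference.py` (CIs, round contrasts,
category non-overlap), `04_misdating_sensitivity.py` (confusion
screen). Tables land in `results/tables/`. The same machinery runs on
real public-use extracts through `reportratio.io.read_cohort` and the
`reportratio` CLI (`simulate`, `ratios`, `bootstrap`, `sensitivity`,
`report` subcommands); see `docs/methods.md` for the file schema.

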