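#!/usr/bin/env python
"""Simulate one synthetic cohort per survey round.

The three rounds share one behavioral model (disclosure, misdating,
telescoping, lifetime confusion at the package defaults); what changes
across rounds is the instrument: the 2002 self-interview asks lifetime
counts, the later rounds ask five-year counts. Cohort sizes match the
published unweighted sample sizes. Cohort files + truth ledgers go to
scratch/cohorts/<round>/ (regenerable; seed-determined), the sample
composition table to results/tables/.
"""

from pathlib import Path

from reportratio.io import cohort_summary, write_cohort
from reportratio.model import cm_from_date
from reportratio.simulate import GeneratorConfig, generate_cohort

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
TABLES = ROOT / "results" / "tables"

SEED = 20250929

ROUND_SETTINGS = {
    "2002": dict(n=7_643, interview_month=(cm_from_date(2002, 1), cm_from_date(2002, 12))),
    "2006-2010": dict(n=12_272, interview_month=(cm_from_date(2006, 6), cm_from_date(2010, 12))),
    "2011-2015": dict(n=11_297, interview_month=(cm_from_date(2011, 6), cm_from_date(2015, 6))),
}


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    summaries = []
    for offset, (round_code, kw) in enumerate(ROUND_SETTINGS.items()):
        cfg = GeneratorConfig(round=round_code, seed=SEED + offset, **kw)
        cohort, truth = generate_cohort(cfg)
        out = SCRATCH / round_code
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "respondents.csv", out / "pregnancies.csv")
        truth.events.to_csv(out / "truth_events.csv", index=False)
        truth.respondents.to_csv(out / "truth_respondents.csv", index=False)
        summary = cohort_summary(cohort)
        summary.insert(0, "round", round_code)
        summaries.append(summary)
        n_events = len(truth.events)
        print(f"{round_code}: n={len(cohort)}, {n_events} true events "
              f"-> {out}")
    import pandas as pd

    pd.concat(summaries).to_csv(TABLES / "sample_composition.csv", index=False)
    print(f"composition table -> {TABLES / 'sample_composition.csv'}")


if __name__ == "__main__":
    main()
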