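#!/usr/bin/env python
"""Lifetime-for-window confusion screen on the five-year rounds.

For each five-year round: how many women report an outcome in the
self-interview window that is absent from the same window of their
interviewer history, and what fraction of them reported exactly their
lifetime history count — the signature of answering the five-year item
with a lifetime number. The truth ledger says how many discordant
women really were confusion cases, which the detector cannot know from
the survey data alone (discordance also arises from interviewer-mode
nondisclosure and telescoping).
"""

from pathlib import Path

import pandas as pd

from reportratio.errors import UndefinedProportionError
from reportratio.io import read_cohort
from reportratio.model import CATEGORIES, ROUND_2002
from reportratio.sensitivity import discordant_reporters, lifetime_match_proportion

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in sorted(SCRATCH.iterdir()):
        if not d.is_dir() or d.name == ROUND_2002:
            continue
        cohort, _ = read_cohort(d / "respondents.csv", d / "pregnancies.csv")
        truth_resp = pd.read_csv(d / "truth_respondents.csv")
        confused_ids = set(
            truth_resp.loc[truth_resp["confusion_applied"], "respondent_id"]
        )
        for cat in CATEGORIES:
            try:
                s = lifetime_match_proportion(cohort, cat)
            except UndefinedProportionError:
                continue
            ids = discordant_reporters(cohort, cat)
            n_truly_confused = len(ids & confused_ids)
            rows.append({
                "round": d.name, "category": cat,
                "n_discordant": s.n_discordant,
                "n_lifetime_match": s.n_lifetime_match,
                "proportion": s.proportion,
                "n_truly_confused_in_set": n_truly_confused,
                "extra_output": cat == "loss",
            })
            print(f"{d.name} {cat}: {s.n_lifetime_match}/{s.n_discordant} "
                  f"({100 * s.proportion:.0f}%) match lifetime counts; "
                  f"{n_truly_confused} of the discordant set are true "
                  f"confusion cases per the ledger")
    pd.DataFrame(rows).to_csv(TABLES / "sensitivity.csv", index=False)
    print(f"wrote {TABLES / 'sensitivity.csv'}")


if __name__ == "__main__":
    main()
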