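#!/usr/bin/env python
"""Bootstrap CIs, round contrasts, and category non-overlap checks.

Percentile intervals (B=1,000 here; the analysis-grade default is
5,000) for each round x outcome ratio; replicate-wise difference tests
between consecutive rounds; and the conservative CI non-overlap check
between outcome categories within each round.
"""

from pathlib import Path

import pandas as pd

from reportratio.bootstrap import (
    bootstrap_ratio,
    ci_nonoverlap,
    difference_test_independent,
)
from reportratio.io import read_cohort
from reportratio.model import CATEGORIES

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
TABLES = ROOT / "results" / "tables"

B = 1_000
SEED = 20250929


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    rounds = sorted(p.name for p in SCRATCH.iterdir() if p.is_dir())
    boots: dict[tuple[str, str], object] = {}
    rows = []
    for round_code in rounds:
        d = SCRATCH / round_code
        cohort, _ = read_cohort(d / "respondents.csv", d / "pregnancies.csv")
        for cat in CATEGORIES:
            res = bootstrap_ratio(cohort, cat, B=B, seed=SEED)
            boots[(round_code, cat)] = res
            rows.append({"round": round_code, "category": cat,
                         "ratio": res.point.ratio, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "B": res.B, "seed": res.seed})
            print(f"{round_code} {cat}: {res.point.ratio:.2f} "
                  f"({res.ci_low:.2f}-{res.ci_high:.2f})")
    pd.DataFrame(rows).to_csv(TABLES / "bootstrap_cis.csv", index=False)

    drows = []
    for cat in CATEGORIES:
        for earlier, later in zip(rounds, rounds[1:]):
            t = difference_test_independent(boots[(later, cat)],
                                            boots[(earlier, cat)])
            drows.append({"category": cat, "contrast": f"{later} vs {earlier}",
                          "pct_low": t.pct_low, "pct_high": t.pct_high,
                          "significant": t.significant})
            mark = "*" if t.significant else " "
            print(f"{cat} {later} vs {earlier}: diff 95% "
                  f"({t.pct_low:+.3f}, {t.pct_high:+.3f}){mark}")
    pd.DataFrame(drows).to_csv(TABLES / "round_contrasts.csv", index=False)

    orows = []
    for round_code in rounds:
        for a in CATEGORIES:
            for b in CATEGORIES:
                if a >= b:
                    continue
                ra, rb = boots[(round_code, a)], boots[(round_code, b)]
                disjoint = ci_nonoverlap((ra.ci_low, ra.ci_high),
                                         (rb.ci_low, rb.ci_high))
                orows.append({"round": round_code, "pair": f"{a} vs {b}",
                              "nonoverlapping": disjoint})
    pd.DataFrame(orows).to_csv(TABLES / "category_nonoverlap.csv", index=False)
    print(f"wrote contrasts and non-overlap tables to {TABLES}")


if __name__ == "__main__":
    main()
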