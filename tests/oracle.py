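"""Independent brute-force recounts used as test oracles.

Everything here is deliberately written from first principles —
year/month tuple arithmetic and explicit double loops over women and
events — and must stay independent of the package's implementation
(no imports from reportratio internals beyond the plain data objects).
"""

from __future__ import annotations

# raw outcome -> comparable category, restated independently
RAW_TO_CATEGORY = {
    "live_birth_cesarean": "birth",
    "live_birth_vaginal": "birth",
    "stillbirth": "loss",
    "miscarriage": "loss",
    "ectopic": "loss",
    "abortion": "abortion",
}


def ym(cm: int) -> tuple[int, int]:
    """Century-month -> (year, month) by explicit counting."""
    year, month = 1900, 1
    for _ in range(cm - 1):
        month += 1
        if month == 13:
            month, year = 1, year + 1
    return year, month


def window_bounds(round_code: str, interview_cm: int, label: str):
    """(start_cm or None, end_cm) recomputed via calendar tuples."""
    iy, _ = ym(interview_cm)
    if label == "lifetime":
        return None, interview_cm

    def to_cm(y: int, m: int) -> int:
        # count months forward from Jan 1900 (= 1)
        return (y - 1900) * 12 + m

    if label == "standard":
        return to_cm(iy - 5, 1), to_cm(iy - 1, 12)
    if label == "expanded":
        return to_cm(iy - 6, 1), interview_cm
    raise ValueError(label)


def ftf_count(respondent, category: str, label: str) -> int:
    """Events of the category inside the window, by explicit loop."""
    start, end = window_bounds(respondent.round, respondent.interview_month, label)
    n = 0
    for p in respondent.pregnancies:
        if p.is_current:
            continue
        if RAW_TO_CATEGORY[p.outcome_raw] != category:
            continue
        if start is not None and p.end_month < start:
            continue
        if p.end_month > end:
            continue
        n += 1
    return n


def acasi_reported(respondent, category: str) -> int:
    return {
        "birth": respondent.acasi.count_birth,
        "loss": respondent.acasi.count_loss,
        "abortion": respondent.acasi.count_abortion,
    }[category]


def reporting_ratio(cohort, category: str, label: str) -> tuple[int, int, float]:
    """(n_acasi, n_ftf, ratio) by double loop over women and events."""
    n_acasi = n_ftf = 0
    for r in cohort:
        if acasi_reported(r, category) >= 1:
            n_acasi += 1
        if ftf_count(r, category, label) >= 1:
            n_ftf += 1
    return n_acasi, n_ftf, n_acasi / n_ftf


def discordant_ids(cohort, category: str) -> set[str]:
    out = set()
    for r in cohort:
        if acasi_reported(r, category) >= 1 and ftf_count(r, category, "standard") == 0:
            out.add(r.id)
    return out


def lifetime_match(cohort, category: str) -> tuple[int, int]:
    """(n_discordant, n_match) where match = ACASI count equals the
    lifetime FTF count of the category."""
    ids = discordant_ids(cohort, category)
    n_match = 0
    for r in cohort:
        if r.id not in ids:
            continue
        lifetime = sum(
            1
            for p in r.pregnancies
            if not p.is_current and RAW_TO_CATEGORY[p.outcome_raw] == category
        )
        if acasi_reported(r, category) == lifetime:
            n_match += 1
    return len(ids), n_match
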