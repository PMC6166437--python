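"""Lifetime-for-window confusion screen.

A *discordant reporter* is a woman who reports an outcome in the
five-year self-interview window but has no event of that outcome in the
same window of her interviewer-recorded pregnancy history. If her
self-reported count equals her *lifetime* count of that outcome in the
history, the natural reading is that she answered the five-year
question with her lifetime number — a comprehension failure rather
than extra disclosure. This module detects discordant reporters and
measures the fraction consistent with that reading.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedProportionError, UnsupportedRoundError
from .model import (
    Cohort,
    ROUND_2002,
    acasi_count,
    build_window,
    ftf_lifetime_count,
    ftf_window_count,
)


@dataclass(frozen=True)
class DiscordanceSummary:
    """Counts behind the lifetime-match proportion for one category."""

    category: str
    n_discordant: int
    n_lifetime_match: int
    proportion: float


def _require_five_year(cohort: Cohort) -> None:
    if cohort.round == ROUND_2002:
        raise UnsupportedRoundError(
            "discordance screen needs a five-year self-interview window "
            "and dated history (2006+ rounds)"
        )


def discordant_reporters(cohort: Cohort, category: str) -> set[str]:
    """Ids of women with an ACASI report but an empty FTF window.

    Membership: self-interview count >= 1 and zero events of the
    category ending inside the standard window of the history.
    """
    _require_five_year(cohort)
    out: set[str] = set()
    for r in cohort:
        if acasi_count(r, category) < 1:
            continue
        window = build_window(r.round, r.interview_month, "standard")
        if ftf_window_count(r, category, window) == 0:
            out.add(r.id)
    return out


def lifetime_match_proportion(cohort: Cohort, category: str) -> DiscordanceSummary:
    """Fraction of discordant reporters whose ACASI count equals their
    lifetime FTF count of the category.

    Lifetime means every completed pregnancy of the category in the
    history regardless of date; the match requires exact count equality.
    Raises :class:`UndefinedProportionError` when no woman is discordant.
    """
    _require_five_year(cohort)
    ids = discordant_reporters(cohort, category)
    if not ids:
        raise UndefinedProportionError(
            f"no discordant reporters of {category}; proportion undefined"
        )
    n_match = 0
    for r in cohort:
        if r.id in ids and acasi_count(r, category) == ftf_lifetime_count(r, category):
            n_match += 1
    return DiscordanceSummary(
        category=category,
        n_discordant=len(ids),
        n_lifetime_match=n_match,
        proportion=n_match / len(ids),
    )
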