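"""Domain types for paired-mode pregnancy reporting.

The two interview modes of interest are an interviewer-administered
face-to-face (FTF) pregnancy history — one dated record per pregnancy —
and an audio computer-assisted self-interview (ACASI) that asks for a
single count of pregnancies per outcome over a stated recall period
(lifetime in the 2002 round, the previous five calendar years in the
2006-2010 and 2011-2015 rounds).

Dates are century-month codes: months elapsed since January 1900, with
January 1900 = 1 (the NSFG convention for event and interview dates).
All window membership is closed-interval on whole months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import CodingError, CohortError, MissingModeError, UnsupportedWindowError

# ---------------------------------------------------------------------------
# Category sets
# ---------------------------------------------------------------------------

ROUND_2002 = "2002"
ROUND_2006_2010 = "2006-2010"
ROUND_2011_2015 = "2011-2015"
ROUNDS = (ROUND_2002, ROUND_2006_2010, ROUND_2011_2015)

#: Raw outcome codes as recorded on the FTF show-card.
RAW_OUTCOMES = (
    "live_birth_cesarean",
    "live_birth_vaginal",
    "stillbirth",
    "miscarriage",
    "ectopic",
    "abortion",
)

#: Harmonized categories comparable across modes.
CATEGORIES = ("birth", "loss", "abortion")

_HARMONIZE = {
    "live_birth_cesarean": "birth",
    "live_birth_vaginal": "birth",
    "stillbirth": "loss",
    "miscarriage": "loss",
    "ectopic": "loss",
    "abortion": "abortion",
}

DEMOGRAPHIC_AXES = {
    "age_group": ("15-24", "25-34", "35-44"),
    "race_ethnicity": ("white_nl", "black_nl", "other_nl", "latina"),
    "poverty": ("0-99", "100-299", "300+"),
    "marital": ("currently_married", "previously_married", "never_married"),
    "religiosity": ("lt_monthly", "monthly_plus"),
}

#: Reference level per axis for stratified tables (the level other levels
#: are tested against).
REFERENCE_LEVELS = {
    "age_group": "25-34",
    "race_ethnicity": "white_nl",
    "poverty": "300+",
    "marital": "currently_married",
    "religiosity": "lt_monthly",
}

WINDOW_LABELS = ("standard", "expanded", "lifetime")


# ---------------------------------------------------------------------------
# Century-month helpers
# ---------------------------------------------------------------------------

def cm_from_date(year: int, month: int) -> int:
    """Century-month code for a calendar month (January 1900 -> 1)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return (year - 1900) * 12 + month


def cm_year(cm: int) -> int:
    """Calendar year of a century-month code."""
    return 1900 + (cm - 1) // 12


def cm_month(cm: int) -> int:
    """Calendar month (1..12) of a century-month code."""
    return (cm - 1) % 12 + 1


def harmonize_outcome(outcome_raw: str) -> str:
    """Map a raw FTF outcome code to the harmonized ACASI-comparable category.

    Live births (either delivery mode) map to ``birth``; miscarriage,
    stillbirth and ectopic/tubal pregnancy are pooled into ``loss``,
    mirroring the single self-interview item that asks about all three;
    ``abortion`` maps to itself.
    """
    try:
        return _HARMONIZE[outcome_raw]
    except KeyError:
        raise CodingError(f"unknown outcome code: {outcome_raw!r}") from None


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PregnancyRecord:
    """One pregnancy from the FTF history.

    ``end_month`` is the century-month the pregnancy ended; it is absent
    exactly when the pregnancy is ongoing at interview. A multiple birth
    is a single record.
    """

    outcome_raw: str
    end_month: Optional[int] = None
    is_current: bool = False

    def __post_init__(self) -> None:
        if self.outcome_raw not in RAW_OUTCOMES:
            raise CodingError(f"unknown outcome code: {self.outcome_raw!r}")
        if self.is_current and self.end_month is not None:
            raise ValueError("ongoing pregnancy cannot have an end month")
        if not self.is_current and self.end_month is None:
            raise ValueError("completed pregnancy requires an end month")

    @property
    def category(self) -> str:
        return harmonize_outcome(self.outcome_raw)


@dataclass(frozen=True)
class AcasiResponse:
    """Per-outcome counts from the self-administered module.

    ``period_kind`` is ``lifetime`` for the 2002 instrument and
    ``five_year`` for later rounds. ``lifetime_total`` and
    ``currently_pregnant`` exist only on the 2002 instrument. A count of
    ``None`` is a refused / not-ascertained item.
    """

    period_kind: str
    count_birth: Optional[int]
    count_loss: Optional[int]
    count_abortion: Optional[int]
    lifetime_total: Optional[int] = None
    currently_pregnant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.period_kind not in ("lifetime", "five_year"):
            raise CodingError(f"unknown period kind: {self.period_kind!r}")
        for name in ("count_birth", "count_loss", "count_abortion", "lifetime_total"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    def count(self, category: str) -> int:
        """The reported count for a harmonized category.

        Raises :class:`MissingModeError` on a refused item so that the
        respondent is excluded rather than silently counted as zero.
        """
        if category not in CATEGORIES:
            raise CodingError(f"unknown category: {category!r}")
        v = getattr(self, f"count_{category}")
        if v is None:
            raise MissingModeError(f"ACASI count for {category} not ascertained")
        return v

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, f"count_{c}") is not None for c in CATEGORIES
        )


@dataclass(frozen=True)
class Respondent:
    """One woman's paired responses plus recoded demographics."""

    id: str
    round: str
    interview_month: int
    age_group: str
    race_ethnicity: str
    poverty: str
    marital: str
    religiosity: str
    pregnancies: tuple[PregnancyRecord, ...] = ()
    acasi: Optional[AcasiResponse] = None

    def __post_init__(self) -> None:
        if self.round not in ROUNDS:
            raise CodingError(f"unknown round: {self.round!r}")
        for axis, levels in DEMOGRAPHIC_AXES.items():
            v = getattr(self, axis)
            if v not in levels:
                raise CodingError(f"{axis}={v!r} not in {levels}")
        object.__setattr__(self, "pregnancies", tuple(self.pregnancies))
        for p in self.pregnancies:
            if p.end_month is not None and p.end_month > self.interview_month:
                raise ValueError(
                    f"respondent {self.id}: pregnancy ends after interview"
                )


@dataclass(frozen=True)
class ReportingWindow:
    """A closed calendar-month recall interval.

    ``start_month`` is ``None`` for the open-start lifetime window.
    """

    end_month: int
    start_month: Optional[int] = None
    label: str = "standard"

    def __post_init__(self) -> None:
        if self.label not in WINDOW_LABELS:
            raise CodingError(f"unknown window label: {self.label!r}")
        if self.start_month is not None and self.start_month > self.end_month:
            raise ValueError("window start after end")

    def contains(self, cm: int) -> bool:
        if self.start_month is not None and cm < self.start_month:
            return False
        return cm <= self.end_month


def build_window(
    round: str,
    interview_month: int,
    label: str,
    expanded_end: str = "interview",
) -> ReportingWindow:
    """Construct the recall window the instruments imply for a round.

    standard
        January of (interview year - 5) through December of
        (interview year - 1): the five whole calendar years preceding
        the interview year, matching the five-year ACASI item. Only the
        2006+ rounds carry this item.
    expanded
        January of (interview year - 6) through the interview month —
        one extra calendar year on the FTF side, probing date misdating.
        ``expanded_end="dec_prior_year"`` instead closes the window at
        December of (interview year - 1).
    lifetime
        Open start through the interview month (the 2002 instrument).
    """
    if label not in WINDOW_LABELS:
        raise CodingError(f"unknown window label: {label!r}")
    year = cm_year(interview_month)
    if label == "lifetime":
        return ReportingWindow(end_month=interview_month, label="lifetime")
    if round == ROUND_2002:
        raise UnsupportedWindowError(
            f"{label} window unavailable for the 2002 round (lifetime items only)"
        )
    if label == "standard":
        return ReportingWindow(
            start_month=cm_from_date(year - 5, 1),
            end_month=cm_from_date(year - 1, 12),
            label="standard",
        )
    # expanded
    if expanded_end == "interview":
        end = interview_month
    elif expanded_end == "dec_prior_year":
        end = cm_from_date(year - 1, 12)
    else:
        raise CodingError(f"unknown expanded_end: {expanded_end!r}")
    return ReportingWindow(
        start_month=cm_from_date(year - 6, 1), end_month=end, label="expanded"
    )


def ftf_window_count(
    respondent: Respondent, category: str, window: ReportingWindow
) -> int:
    """Number of completed FTF pregnancies of a category ending in the window.

    Ongoing pregnancies never contribute. Both window endpoints are
    included.
    """
    if category not in CATEGORIES:
        raise CodingError(f"unknown category: {category!r}")
    n = 0
    for p in respondent.pregnancies:
        if p.is_current:
            continue
        if p.category == category and window.contains(p.end_month):
            n += 1
    return n


def ftf_lifetime_count(respondent: Respondent, category: str) -> int:
    """Count of all completed FTF pregnancies of a category, any date."""
    window = ReportingWindow(end_month=respondent.interview_month, label="lifetime")
    return ftf_window_count(respondent, category, window)


def acasi_count(respondent: Respondent, category: str) -> int:
    """The self-interview count for a category; errors if the module is missing."""
    if respondent.acasi is None:
        raise MissingModeError(f"respondent {respondent.id} has no ACASI module")
    return respondent.acasi.count(category)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """All analyzable respondents of one survey round."""

    round: str
    respondents: list[Respondent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.round not in ROUNDS:
            raise CodingError(f"unknown round: {self.round!r}")
        for r in self.respondents:
            if r.round != self.round:
                raise CohortError(
                    f"respondent {r.id} round {r.round} != cohort round {self.round}"
                )

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self) -> Iterable[Respondent]:
        return iter(self.respondents)

    @property
    def default_window_label(self) -> str:
        """The window the round's own instruments compare: lifetime for
        2002, the five-calendar-year standard window for later rounds."""
        return "lifetime" if self.round == ROUND_2002 else "standard"
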