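"""The reporting-ratio statistic.

For one outcome category the reporting ratio is

    R = #{women reporting >= 1 event in the self-interview (ACASI)}
        ------------------------------------------------------------
        #{women reporting >= 1 event in the interviewer (FTF) history}

over matched recall windows, computed on the same women (a
within-subject design). R = 1 means the two modes elicit the outcome
from the same number of women; R > 1 means the private mode elicits it
from more women. The *expanded* variant keeps the five-year ACASI
numerator but widens the FTF window by one calendar year, probing how
much of the gap is date misdating rather than disclosure.

The statistic counts women, not events: a woman with three abortions
contributes once to each side. An event-count ratio is offered as a
clearly-labelled secondary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import model
from .errors import UndefinedRatioError, UnsupportedWindowError
from .model import Cohort, ROUND_2002, acasi_count, build_window, ftf_window_count


@dataclass(frozen=True)
class RatioEstimate:
    """One reporting ratio: reporter counts, the ratio, and its context."""

    category: str
    n_acasi: int
    n_ftf: int
    ratio: float
    acasi_window_label: str
    ftf_window_label: str
    stratum: Optional[tuple[str, str]] = None  # (axis, level)
    n_total: int = 0


@dataclass
class StratifiedResult:
    """Per-level estimates for one demographic axis, reference flagged."""

    axis: str
    reference_level: str
    estimates: list[RatioEstimate] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)  # level -> reason


def _check_window_label(cohort: Cohort, label: str) -> None:
    if cohort.round == ROUND_2002:
        if label != "lifetime":
            raise UnsupportedWindowError(
                f"{label} window unavailable for the 2002 round"
            )
    elif label == "lifetime":
        raise UnsupportedWindowError(
            "lifetime comparison undefined for five-year ACASI rounds"
        )


def mode_indicators(
    cohort: Cohort,
    category: str,
    ftf_window_label: Optional[str] = None,
    expanded_end: str = "interview",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-woman reporter indicators (ACASI >= 1, FTF-in-window >= 1).

    The ACASI side always uses the instrument's own reference period
    (lifetime in 2002, five calendar years in later rounds); the FTF
    side uses the requested window. These boolean arrays are the
    sufficient statistics for every ratio and bootstrap in the package.
    """
    label = cohort.default_window_label if ftf_window_label is None else ftf_window_label
    if label != "expanded":
        _check_window_label(cohort, label)
    elif cohort.round == ROUND_2002:
        raise UnsupportedWindowError("expanded window unavailable for the 2002 round")
    n = len(cohort)
    acasi = np.zeros(n, dtype=bool)
    ftf = np.zeros(n, dtype=bool)
    for i, r in enumerate(cohort):
        acasi[i] = acasi_count(r, category) >= 1
        window = build_window(r.round, r.interview_month, label, expanded_end)
        ftf[i] = ftf_window_count(r, category, window) >= 1
    return acasi, ftf


def _estimate(
    acasi: np.ndarray,
    ftf: np.ndarray,
    category: str,
    acasi_label: str,
    ftf_label: str,
    stratum=None,
) -> RatioEstimate:
    n_acasi = int(acasi.sum())
    n_ftf = int(ftf.sum())
    if n_ftf == 0:
        where = f" in stratum {stratum}" if stratum else ""
        raise UndefinedRatioError(
            f"no FTF reporters of {category}{where}: ratio undefined"
        )
    return RatioEstimate(
        category=category,
        n_acasi=n_acasi,
        n_ftf=n_ftf,
        ratio=n_acasi / n_ftf,
        acasi_window_label=acasi_label,
        ftf_window_label=ftf_label,
        stratum=stratum,
        n_total=len(acasi),
    )


def reporting_ratio(
    cohort: Cohort, category: str, ftf_window_label: Optional[str] = None
) -> RatioEstimate:
    """The headline within-subject reporting ratio for one category.

    The FTF window mirrors the ACASI reference period: lifetime for the
    2002 round, the standard five-calendar-year window for 2006+.
    """
    label = cohort.default_window_label if ftf_window_label is None else ftf_window_label
    _check_window_label(cohort, label)
    acasi, ftf = mode_indicators(cohort, category, label)
    acasi_label = "lifetime" if cohort.round == ROUND_2002 else "standard"
    return _estimate(acasi, ftf, category, acasi_label, label)


def expanded_reporting_ratio(
    cohort: Cohort, category: str, expanded_end: str = "interview"
) -> RatioEstimate:
    """Five-year ACASI numerator over a six-year FTF denominator."""
    if cohort.round == ROUND_2002:
        raise UnsupportedWindowError("expanded ratio needs dated five-year rounds")
    acasi, ftf = mode_indicators(cohort, category, "expanded", expanded_end)
    return _estimate(acasi, ftf, category, "standard", "expanded")


def stratified_ratios(
    cohort: Cohort, category: str, axis: str, ftf_window_label: Optional[str] = None
) -> StratifiedResult:
    """Reporting ratios per level of one recoded demographic axis.

    A level with no FTF reporters is recorded as a failure; the other
    levels are still estimated. The reference level is the conventional
    comparison level for the axis.
    """
    if axis not in model.DEMOGRAPHIC_AXES:
        raise KeyError(f"unknown demographic axis: {axis!r}")
    label = cohort.default_window_label if ftf_window_label is None else ftf_window_label
    acasi, ftf = mode_indicators(cohort, category, label)
    levels = np.array([getattr(r, axis) for r in cohort], dtype=object)
    acasi_label = "lifetime" if cohort.round == ROUND_2002 else "standard"
    out = StratifiedResult(axis=axis, reference_level=model.REFERENCE_LEVELS[axis])
    for level in model.DEMOGRAPHIC_AXES[axis]:
        mask = levels == level
        try:
            est = _estimate(
                acasi[mask], ftf[mask], category, acasi_label, label, (axis, level)
            )
        except UndefinedRatioError as exc:
            out.failures[level] = str(exc)
            continue
        out.estimates.append(est)
    return out


def event_count_ratio(
    cohort: Cohort, category: str, ftf_window_label: Optional[str] = None
) -> float:
    """Secondary statistic: total reported events ACASI / FTF.

    Not the headline quantity — the headline ratio counts *women*
    reporting at least one event, not events.
    """
    label = cohort.default_window_label if ftf_window_label is None else ftf_window_label
    _check_window_label(cohort, label)
    num = den = 0
    for r in cohort:
        num += acasi_count(r, category)
        window = build_window(r.round, r.interview_month, label)
        den += ftf_window_count(r, category, window)
    if den == 0:
        raise UndefinedRatioError(f"no FTF events of {category}")
    return num / den
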