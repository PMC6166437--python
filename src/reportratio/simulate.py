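"""Synthetic paired-mode cohorts with ground truth.

The generator emulates the reporting processes hypothesized to drive
mode differences in pregnancy reporting:

* **true histories** — per woman, per outcome category, a Poisson number
  of events placed uniformly over a reproductive span ending at the
  interview month, with demographics drawn independently;
* **interviewer-mode (FTF) reporting** — each true event is disclosed
  independently with a category-specific probability; disclosed events
  receive a misdated recorded month (symmetric two-sided geometric error
  on whole months, clamped at the interview month);
* **self-interview (ACASI) reporting** — each true event is counted
  with a category-specific probability; out-of-window events can be
  *telescoped* into the reference window; with some probability a woman
  answers the five-year item with her lifetime count (*lifetime
  confusion*).

Every stochastic decision is written to a :class:`TruthLedger`, so
downstream statistics can be checked event-by-event against ground
truth. All randomness flows from a single seed: identical config +
seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import model
from .errors import ConfigError
from .model import (
    AcasiResponse,
    Cohort,
    PregnancyRecord,
    Respondent,
    ROUND_2002,
    cm_from_date,
)

# Raw-outcome subtypes per harmonized category, with realistic mix.
_RAW_SPLIT = {
    "birth": (("live_birth_vaginal", 0.68), ("live_birth_cesarean", 0.32)),
    "loss": (("miscarriage", 0.82), ("stillbirth", 0.06), ("ectopic", 0.12)),
    "abortion": (("abortion", 1.0),),
}

#: Sample composition of a recent survey round (unweighted shares).
DEFAULT_DEMOGRAPHIC_PROBS = {
    "age_group": {"15-24": 0.35, "25-34": 0.37, "35-44": 0.28},
    "race_ethnicity": {"white_nl": 0.47, "black_nl": 0.21, "other_nl": 0.07, "latina": 0.25},
    "poverty": {"0-99": 0.35, "100-299": 0.37, "300+": 0.28},
    "marital": {"currently_married": 0.30, "previously_married": 0.13, "never_married": 0.57},
    "religiosity": {"lt_monthly": 0.50, "monthly_plus": 0.50},
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic disclosure/misdating model.

    Disclosure probabilities and event rates are per harmonized category
    (``birth`` / ``loss`` / ``abortion``). Multiplier dicts have the form
    ``{axis: {level: m}}``; the effective probability is clamped to
    [0, 1]. ``event_placement`` restricts where true events fall:
    ``span`` (uniform over the whole simulated history), ``in_window``
    (inside the standard five-year window) or ``pre_window`` (strictly
    before it) — the latter two support calibration studies.
    """

    n: int = 1000
    round: str = model.ROUND_2011_2015
    seed: int = 0
    interview_month: tuple[int, int] | int = (cm_from_date(2011, 6), cm_from_date(2015, 6))
    demographic_probs: dict = field(
        default_factory=lambda: {a: dict(p) for a, p in DEFAULT_DEMOGRAPHIC_PROBS.items()}
    )
    event_rate: dict = field(
        default_factory=lambda: {"birth": 1.3, "loss": 0.45, "abortion": 0.55}
    )
    span_years: float = 30.0
    p_ftf: dict = field(
        default_factory=lambda: {"birth": 0.97, "loss": 0.60, "abortion": 0.50}
    )
    p_acasi: dict = field(
        default_factory=lambda: {"birth": 0.99, "loss": 0.78, "abortion": 0.58}
    )
    misdate_sd_months: float = 6.0
    telescope_in_prob: float = 0.02
    confusion_prob: float = 0.03
    event_rate_multipliers: dict = field(default_factory=dict)
    p_ftf_multipliers: dict = field(default_factory=dict)
    p_acasi_multipliers: dict = field(default_factory=dict)
    #: probability a woman discloses nothing in the FTF history
    #: (woman-level random effect; 0 = pure event-level model)
    p_never_discloser_ftf: float = 0.0
    #: stub for abortion-as-miscarriage misreporting; must stay 0 for now
    cross_category_misclass_prob: float = 0.0
    fixed_event_count: Optional[dict] = None
    event_placement: str = "span"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for name in ("telescope_in_prob", "confusion_prob", "p_never_discloser_ftf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for pname in ("p_ftf", "p_acasi"):
            for cat, v in getattr(self, pname).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{pname}[{cat}] must be in [0, 1], got {v}")
        for cat, v in self.event_rate.items():
            if v < 0:
                raise ConfigError(f"event_rate[{cat}] must be >= 0, got {v}")
        if self.round not in model.ROUNDS:
            raise ConfigError(f"unknown round: {self.round!r}")
        if self.event_placement not in ("span", "in_window", "pre_window"):
            raise ConfigError(f"unknown event_placement: {self.event_placement!r}")
        if self.round == ROUND_2002 and self.event_placement != "span":
            raise ConfigError("window-restricted placement needs a five-year round")
        if self.cross_category_misclass_prob != 0.0:
            raise ConfigError("cross-category misclassification is not implemented")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class TruthLedger:
    """Ground truth and per-event reporting decisions.

    ``events`` has one row per true event:

    ===================  =====================================================
    respondent_id        cohort id the event belongs to
    category             harmonized category
    true_month           century-month the pregnancy actually ended
    outcome_raw          raw outcome code assigned to the event
    disclosed_ftf        event appears in the FTF history
    recorded_ftf_month   recorded (possibly misdated) month; <NA> if hidden
    in_window            true month inside the round's reference window
    acasi_kept           event counted under the mode's disclosure draw
    telescoped_in        out-of-window event pulled into the window count
    counted_in_acasi     event contributes to the final reported count
    ===================  =====================================================

    ``respondents`` has one row per woman with her demographics and the
    ``confusion_applied`` flag.
    """

    events: pd.DataFrame
    respondents: pd.DataFrame

    def true_count(self, respondent_id: str, category: str) -> int:
        ev = self.events
        return int(
            ((ev["respondent_id"] == respondent_id) & (ev["category"] == category)).sum()
        )


def _multiplier_vector(multipliers: dict, demo: dict[str, np.ndarray], n: int) -> np.ndarray:
    mult = np.ones(n)
    for axis, levels in multipliers.items():
        for level, m in levels.items():
            mult[demo[axis] == level] *= m
    return mult


def _geometric_p_for_sd(sd: float) -> float:
    """Success probability of the two-sided geometric month error.

    The error is S*G with S = ±1 equiprobable and G >= 0 geometric
    (number of failures). Its standard deviation is
    sqrt((1-p)(2-p))/p; solve for p by bisection.
    """
    target = sd * sd
    lo, hi = 1e-9, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = (1.0 - mid) * (2.0 - mid) / (mid * mid)
        if val > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _window_bounds(config: GeneratorConfig, interview: np.ndarray):
    """Per-respondent standard-window bounds (None, None for lifetime)."""
    if config.round == ROUND_2002:
        return None, None
    year = 1900 + (interview - 1) // 12
    start = (year - 5 - 1900) * 12 + 1          # January of year-5
    end = (year - 1 - 1900) * 12 + 12           # December of year-1
    return start, end


def generate_true_histories(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> TruthLedger:
    """Draw demographics, interview months, and true event histories.

    Event counts per woman and category are Poisson with the configured
    mean (times any subgroup rate multiplier); event months are uniform
    integers over the placement support ending at the interview month.
    Reporting columns are initialized but not yet filled.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n

    demo: dict[str, np.ndarray] = {}
    for axis, probs in config.demographic_probs.items():
        levels = list(model.DEMOGRAPHIC_AXES[axis])
        p = np.array([probs[lv] for lv in levels], dtype=float)
        p = p / p.sum()
        demo[axis] = rng.choice(np.array(levels, dtype=object), size=n, p=p)

    if isinstance(config.interview_month, int):
        interview = np.full(n, config.interview_month, dtype=np.int64)
    else:
        lo, hi = config.interview_month
        interview = rng.integers(lo, hi + 1, size=n)

    span_months = max(1, int(round(config.span_years * 12)))
    wstart, wend = _window_bounds(config, interview)

    rate_mult = _multiplier_vector(config.event_rate_multipliers, demo, n)

    frames = []
    for cat in model.CATEGORIES:
        if config.fixed_event_count is not None:
            k = np.full(n, int(config.fixed_event_count.get(cat, 0)))
        else:
            lam = config.event_rate.get(cat, 0.0) * rate_mult
            k = rng.poisson(lam)
        idx = np.repeat(np.arange(n), k)
        m = len(idx)
        if m == 0:
            continue
        iv = interview[idx]
        if config.event_placement == "span":
            lo = iv - span_months + 1
            months = rng.integers(lo, iv + 1)
        elif config.event_placement == "in_window":
            months = rng.integers(wstart[idx], wend[idx] + 1)
        else:  # pre_window
            lo = iv - span_months + 1
            hi = wstart[idx] - 1
            if np.any(lo > hi):
                raise ConfigError("span too short to place events before the window")
            months = rng.integers(lo, hi + 1)
        subtypes, weights = zip(*_RAW_SPLIT[cat])
        raw = rng.choice(np.array(subtypes, dtype=object), size=m,
                         p=np.array(weights) / sum(weights))
        frames.append(
            pd.DataFrame(
                {
                    "respondent_idx": idx,
                    "category": cat,
                    "true_month": months,
                    "outcome_raw": raw,
                }
            )
        )

    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = events.sort_values(
            ["respondent_idx", "true_month"], kind="stable"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(
            columns=["respondent_idx", "category", "true_month", "outcome_raw"]
        )

    ids = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    events.insert(0, "respondent_id", ids[events["respondent_idx"].to_numpy(dtype=int)]
                  if len(events) else np.array([], dtype=object))

    resp = pd.DataFrame({"respondent_id": ids, "interview_month": interview})
    for axis in model.DEMOGRAPHIC_AXES:
        resp[axis] = demo[axis]
    resp["confusion_applied"] = False

    for col in ("disclosed_ftf", "in_window", "acasi_kept",
                "telescoped_in", "counted_in_acasi"):
        events[col] = pd.Series([False] * len(events), dtype=bool)
    events["recorded_ftf_month"] = pd.Series([pd.NA] * len(events), dtype="Int64")
    return TruthLedger(events=events, respondents=resp)


def apply_ftf_reporting(
    truth: TruthLedger, config: GeneratorConfig, rng: np.random.Generator
) -> None:
    """Fill the interviewer-mode columns of the ledger in place.

    Each event is disclosed independently with the category's FTF
    probability (times subgroup multiplier, clamped to [0, 1]); a
    woman-level never-discloser effect can zero a woman's entire
    history. Disclosed events get a recorded month equal to the true
    month plus a symmetric two-sided geometric error, clamped to the
    interview month.
    """
    ev = truth.events
    n_ev = len(ev)
    if n_ev == 0:
        return
    resp = truth.respondents
    demo = {axis: resp[axis].to_numpy() for axis in model.DEMOGRAPHIC_AXES}
    mult = _multiplier_vector(config.p_ftf_multipliers, demo, len(resp))
    ridx = ev["respondent_idx"].to_numpy(dtype=int)

    p_cat = np.array([config.p_ftf.get(c, 0.0) for c in ev["category"]])
    p = np.clip(p_cat * mult[ridx], 0.0, 1.0)
    disclosed = rng.random(n_ev) < p

    if config.p_never_discloser_ftf > 0:
        never = rng.random(len(resp)) < config.p_never_discloser_ftf
        disclosed &= ~never[ridx]

    true_month = ev["true_month"].to_numpy(dtype=np.int64)
    if config.misdate_sd_months > 0:
        pgeo = _geometric_p_for_sd(config.misdate_sd_months)
        mag = rng.geometric(pgeo, size=n_ev) - 1
        sign = rng.integers(0, 2, size=n_ev) * 2 - 1
        err = sign * mag
    else:
        err = np.zeros(n_ev, dtype=np.int64)
    interview = resp["interview_month"].to_numpy()[ridx]
    recorded = np.minimum(true_month + err, interview)
    recorded = np.maximum(recorded, 1)

    ev["disclosed_ftf"] = disclosed
    rec = pd.array(recorded, dtype="Int64")
    rec[~disclosed] = pd.NA
    ev["recorded_ftf_month"] = rec


def apply_acasi_reporting(
    truth: TruthLedger, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill self-interview columns and return per-woman reported counts.

    For five-year rounds the base reported count per category is the
    number of in-window true events passing an independent disclosure
    draw, plus out-of-window events telescoped in. With probability
    ``confusion_prob`` a woman's counts are replaced by her lifetime
    disclosed counts (the same per-event disclosure draws, ignoring the
    window). For the 2002 round the item is itself lifetime, so the
    window covers the whole history and telescoping/confusion are
    no-ops.

    Returns a DataFrame indexed like ``truth.respondents`` with one
    column per category.
    """
    ev = truth.events
    resp = truth.respondents
    n = len(resp)
    n_ev = len(ev)

    counts = pd.DataFrame(
        0, index=np.arange(n), columns=list(model.CATEGORIES), dtype=np.int64
    )
    confusion = rng.random(n) < config.confusion_prob
    resp["confusion_applied"] = confusion
    if n_ev == 0:
        return counts

    demo = {axis: resp[axis].to_numpy() for axis in model.DEMOGRAPHIC_AXES}
    mult = _multiplier_vector(config.p_acasi_multipliers, demo, n)
    ridx = ev["respondent_idx"].to_numpy(dtype=int)

    p_cat = np.array([config.p_acasi.get(c, 0.0) for c in ev["category"]])
    p = np.clip(p_cat * mult[ridx], 0.0, 1.0)
    kept = rng.random(n_ev) < p

    true_month = ev["true_month"].to_numpy(dtype=np.int64)
    interview = resp["interview_month"].to_numpy()
    wstart, wend = _window_bounds(config, interview)
    if wstart is None:
        in_window = np.ones(n_ev, dtype=bool)
    else:
        in_window = (true_month >= wstart[ridx]) & (true_month <= wend[ridx])

    telescoped = (~in_window) & (rng.random(n_ev) < config.telescope_in_prob)
    counted_windowed = (kept & in_window) | telescoped
    counted_final = np.where(confusion[ridx], kept, counted_windowed)

    ev["acasi_kept"] = kept
    ev["in_window"] = in_window
    ev["telescoped_in"] = telescoped
    ev["counted_in_acasi"] = counted_final

    contrib = ev.loc[counted_final, ["respondent_idx", "category"]]
    tab = contrib.groupby(["respondent_idx", "category"], observed=True).size()
    for (i, cat), k in tab.items():
        counts.at[i, cat] = k
    return counts


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, TruthLedger]:
    """Run the full generator pipeline and assemble a validated cohort."""
    rng = np.random.default_rng(config.seed)
    truth = generate_true_histories(config, rng)
    apply_ftf_reporting(truth, config, rng)
    counts = apply_acasi_reporting(truth, config, rng)

    ev = truth.events
    resp = truth.respondents
    disclosed = ev[ev["disclosed_ftf"]]
    preg_by_resp: dict[int, list[PregnancyRecord]] = {}
    for i, outcome_raw, month in zip(
        disclosed["respondent_idx"].to_numpy(dtype=int),
        disclosed["outcome_raw"],
        disclosed["recorded_ftf_month"],
    ):
        preg_by_resp.setdefault(i, []).append(
            PregnancyRecord(outcome_raw=outcome_raw, end_month=int(month))
        )

    period_kind = "lifetime" if config.round == ROUND_2002 else "five_year"
    respondents = []
    arr = {c: counts[c].to_numpy() for c in model.CATEGORIES}
    for i in range(config.n):
        acasi = AcasiResponse(
            period_kind=period_kind,
            count_birth=int(arr["birth"][i]),
            count_loss=int(arr["loss"][i]),
            count_abortion=int(arr["abortion"][i]),
        )
        respondents.append(
            Respondent(
                id=resp.at[i, "respondent_id"],
                round=config.round,
                interview_month=int(resp.at[i, "interview_month"]),
                age_group=resp.at[i, "age_group"],
                race_ethnicity=resp.at[i, "race_ethnicity"],
                poverty=resp.at[i, "poverty"],
                marital=resp.at[i, "marital"],
                religiosity=resp.at[i, "religiosity"],
                pregnancies=tuple(preg_by_resp.get(i, ())),
                acasi=acasi,
            )
        )
    return Cohort(round=config.round, respondents=respondents), truth
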