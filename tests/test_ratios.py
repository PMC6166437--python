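"""Reporting-ratio statistic: examples, oracle equivalence, invariants."""

import numpy as np
import pytest

from reportratio.errors import UndefinedRatioError, UnsupportedWindowError
from reportratio.model import CATEGORIES, Cohort, ROUND_2002, ROUND_2011_2015
from reportratio.ratios import (
    event_count_ratio,
    expanded_reporting_ratio,
    reporting_ratio,
    stratified_ratios,
)
from reportratio.simulate import GeneratorConfig, generate_cohort

import oracle
from conftest import make_respondent, preg


def test_hand_cohort_ratio_two(hand_cohort):
    """4 ACASI abortion reporters over 2 FTF reporters -> 2.0."""
    est = reporting_ratio(hand_cohort, "abortion")
    assert (est.n_acasi, est.n_ftf) == (4, 2)
    assert est.ratio == 2.0
    assert est.n_total == 6


def test_identical_indicators_give_unity(faithful_config):
    cohort, _ = generate_cohort(faithful_config)
    for cat in CATEGORIES:
        assert reporting_ratio(cohort, cat).ratio == 1.0


def test_expanded_denominator_widening(hand_cohort):
    """Widening the FTF window adds a reporter to the denominator only:
    numerator unchanged, ratio shrinks accordingly."""
    # w3's 2006-07 abortion stays outside even the expanded window of a
    # June-2013 interview (starts Jan 2007); add a woman aborted in 2007,
    # who reports in the expanded window but not the standard one.
    extra = make_respondent("w7", [preg("abortion", 2007, 8)], acasi_abortion=0)
    cohort = Cohort(round=ROUND_2011_2015,
                    respondents=list(hand_cohort.respondents) + [extra])
    std = reporting_ratio(cohort, "abortion")
    exp = expanded_reporting_ratio(cohort, "abortion")
    assert std.n_ftf == 2 and exp.n_ftf == 3
    assert exp.n_acasi == std.n_acasi == 4
    assert exp.ratio == pytest.approx(4 / 3)


def test_expanded_equals_standard_when_all_events_inside():
    cfg = GeneratorConfig(n=500, seed=17, event_placement="in_window",
                          misdate_sd_months=0.0, telescope_in_prob=0.0,
                          confusion_prob=0.0)
    cohort, _ = generate_cohort(cfg)
    for cat in CATEGORIES:
        assert expanded_reporting_ratio(cohort, cat).ratio == \
            reporting_ratio(cohort, cat).ratio


def test_expanded_never_exceeds_standard():
    """Numerator fixed, denominator nondecreasing under widening."""
    for seed in range(5):
        cohort, _ = generate_cohort(GeneratorConfig(n=800, seed=seed))
        for cat in CATEGORIES:
            assert expanded_reporting_ratio(cohort, cat).ratio <= \
                reporting_ratio(cohort, cat).ratio


@pytest.mark.parametrize("seed", range(6))
def test_brute_force_oracle_equivalence_small_cohorts(seed):
    """On cohorts of <= 50 women the ratio must equal an independent
    double-loop recount exactly."""
    cfg = GeneratorConfig(n=50, seed=seed,
                          event_rate={"birth": 2.0, "loss": 1.2, "abortion": 1.2})
    cohort, _ = generate_cohort(cfg)
    for cat in CATEGORIES:
        n_acasi, n_ftf, ratio = oracle.reporting_ratio(cohort, cat, "standard")
        if n_ftf == 0:
            with pytest.raises(UndefinedRatioError):
                reporting_ratio(cohort, cat)
            continue
        est = reporting_ratio(cohort, cat)
        assert (est.n_acasi, est.n_ftf) == (n_acasi, n_ftf)
        assert est.ratio == ratio
        n_acasi, n_ftf, ratio = oracle.reporting_ratio(cohort, cat, "expanded")
        if n_ftf > 0:
            assert expanded_reporting_ratio(cohort, cat).ratio == ratio


def test_lifetime_round_uses_lifetime_both_sides():
    cfg = GeneratorConfig(n=400, seed=8, round=ROUND_2002,
                          interview_month=(1225, 1236))  # during 2002
    cohort, _ = generate_cohort(cfg)
    for cat in CATEGORIES:
        got = reporting_ratio(cohort, cat)
        n_acasi, n_ftf, ratio = oracle.reporting_ratio(cohort, cat, "lifetime")
        assert got.ratio == ratio
        assert got.acasi_window_label == got.ftf_window_label == "lifetime"
    with pytest.raises(UnsupportedWindowError):
        reporting_ratio(cohort, "abortion", "standard")
    with pytest.raises(UnsupportedWindowError):
        expanded_reporting_ratio(cohort, "abortion")


def test_stratified_recombination():
    """Stratum numerators/denominators over a partition sum to the
    overall counts, for every axis."""
    cohort, _ = generate_cohort(GeneratorConfig(n=3000, seed=4))
    overall = reporting_ratio(cohort, "abortion")
    for axis in ("age_group", "race_ethnicity", "poverty", "marital", "religiosity"):
        strat = stratified_ratios(cohort, "abortion", axis)
        assert not strat.failures
        assert sum(s.n_acasi for s in strat.estimates) == overall.n_acasi
        assert sum(s.n_ftf for s in strat.estimates) == overall.n_ftf
        assert strat.reference_level in {s.stratum[1] for s in strat.estimates}


def test_subgroup_disclosure_multiplier_raises_subgroup_ratio():
    """p_acasi multiplier 1.2 for one level: that level's ratio exceeds
    the reference's (closed form p_acasi*m/p_ftf vs p_acasi/p_ftf)."""
    cfg = GeneratorConfig(
        n=20_000, seed=15,
        fixed_event_count={"abortion": 1},
        event_placement="in_window",
        p_acasi={"birth": 0, "loss": 0, "abortion": 0.6},
        p_ftf={"birth": 0, "loss": 0, "abortion": 0.8},
        misdate_sd_months=0.0, telescope_in_prob=0.0, confusion_prob=0.0,
        p_acasi_multipliers={"religiosity": {"monthly_plus": 1.2}},
    )
    cohort, _ = generate_cohort(cfg)
    strat = stratified_ratios(cohort, "abortion", "religiosity")
    by_level = {s.stratum[1]: s.ratio for s in strat.estimates}
    assert by_level["monthly_plus"] > by_level["lt_monthly"]
    assert by_level["monthly_plus"] == pytest.approx(0.6 * 1.2 / 0.8, abs=0.05)
    assert by_level["lt_monthly"] == pytest.approx(0.6 / 0.8, abs=0.05)


def test_undefined_ratio_names_category(hand_cohort):
    """No FTF loss reporters in the hand cohort -> undefined ratio."""
    with pytest.raises(UndefinedRatioError, match="loss"):
        reporting_ratio(hand_cohort, "loss")


def test_event_count_ratio_secondary(hand_cohort):
    """Events, not women: 5 ACASI abortions vs 2 in-window FTF events."""
    assert event_count_ratio(hand_cohort, "abortion") == pytest.approx(5 / 2)
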