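"""Generator: calibration, determinism, faithful limit, ledger fidelity."""

import numpy as np
import pandas as pd
import pytest

from reportratio.errors import ConfigError
from reportratio.model import CATEGORIES, build_window, ftf_window_count
from reportratio.simulate import (
    GeneratorConfig,
    _geometric_p_for_sd,
    generate_cohort,
    generate_true_histories,
)

from oracle import acasi_reported, ftf_count


def test_zero_rates_give_empty_histories():
    cfg = GeneratorConfig(n=50, seed=1, event_rate={c: 0.0 for c in CATEGORIES})
    cohort, truth = generate_cohort(cfg)
    assert len(truth.events) == 0
    assert all(len(r.pregnancies) == 0 for r in cohort)
    assert all(r.acasi.count_abortion == 0 for r in cohort)


def test_poisson_event_rate_calibration():
    """Mean abortions/woman ~ 0.3 within 3*sqrt(0.3/n) at n=10,000."""
    n, rate = 10_000, 0.3
    cfg = GeneratorConfig(
        n=n, seed=11,
        event_rate={"birth": 0.0, "loss": 0.0, "abortion": rate},
    )
    truth = generate_true_histories(cfg)
    mean = len(truth.events) / n
    assert abs(mean - rate) <= 3 * np.sqrt(rate / n)


def test_fixed_seed_reproduces_ledger_and_cohort():
    cfg = GeneratorConfig(n=300, seed=42)
    c1, t1 = generate_cohort(cfg)
    c2, t2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(t1.events, t2.events)
    pd.testing.assert_frame_equal(t1.respondents, t2.respondents)
    assert c1.respondents == c2.respondents


def test_different_seeds_differ():
    _, t1 = generate_cohort(GeneratorConfig(n=300, seed=1))
    _, t2 = generate_cohort(GeneratorConfig(n=300, seed=2))
    assert not t1.events.equals(t2.events)


def test_faithful_limit_modes_agree_exactly(faithful_config):
    """All probabilities 1 and no noise: ACASI counts equal FTF
    windowed counts woman by woman."""
    cohort, _ = generate_cohort(faithful_config)
    for r in cohort:
        window = build_window(r.round, r.interview_month, "standard")
        for cat in CATEGORIES:
            assert r.acasi.count(cat) == ftf_window_count(r, cat, window)


def test_ftf_disclosure_fraction_binomial_bound():
    """One event per woman, p_ftf = 0.8: disclosed fraction within
    3*sqrt(p(1-p)/n) at n=10,000."""
    p, n = 0.8, 10_000
    cfg = GeneratorConfig(
        n=n, seed=5,
        fixed_event_count={"abortion": 1},
        p_ftf={"birth": 0, "loss": 0, "abortion": p},
        misdate_sd_months=0.0,
    )
    cohort, _ = generate_cohort(cfg)
    frac = sum(1 for r in cohort if len(r.pregnancies) >= 1) / n
    assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


def test_acasi_reporter_fraction_binomial_bound():
    """One in-window event per woman, p_acasi = 0.92: reporter fraction
    within the Monte-Carlo bound."""
    p, n = 0.92, 10_000
    cfg = GeneratorConfig(
        n=n, seed=6,
        fixed_event_count={"abortion": 1},
        event_placement="in_window",
        p_acasi={"birth": 0, "loss": 0, "abortion": p},
        telescope_in_prob=0.0,
        confusion_prob=0.0,
    )
    cohort, _ = generate_cohort(cfg)
    frac = sum(1 for r in cohort if r.acasi.count_abortion >= 1) / n
    assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


def test_confusion_builds_discordant_case():
    """All events pre-window + certain confusion + full ACASI disclosure:
    ACASI reports the lifetime count while the FTF window is empty."""
    cfg = GeneratorConfig(
        n=200, seed=9,
        fixed_event_count={"abortion": 2},
        event_placement="pre_window",
        p_acasi={"birth": 1, "loss": 1, "abortion": 1},
        p_ftf={"birth": 1, "loss": 1, "abortion": 1},
        misdate_sd_months=0.0,
        telescope_in_prob=0.0,
        confusion_prob=1.0,
    )
    cohort, truth = generate_cohort(cfg)
    assert truth.respondents["confusion_applied"].all()
    for r in cohort:
        assert r.acasi.count_abortion == 2
        assert ftf_count(r, "abortion", "standard") == 0
        assert ftf_count(r, "abortion", "lifetime") == 2


def test_ledger_matches_emitted_cohort():
    """The ledger's per-event flags recount exactly to the cohort's
    records and reported counts."""
    cfg = GeneratorConfig(n=400, seed=13, confusion_prob=0.2,
                          telescope_in_prob=0.05)
    cohort, truth = generate_cohort(cfg)
    ev = truth.events
    for r in cohort:
        mine = ev[ev["respondent_id"] == r.id]
        assert len(r.pregnancies) == int(mine["disclosed_ftf"].sum())
        for cat in CATEGORIES:
            ledger_count = int(
                ((mine["category"] == cat) & mine["counted_in_acasi"]).sum()
            )
            assert acasi_reported(r, cat) == ledger_count


def test_recorded_dates_clamped_to_interview():
    cfg = GeneratorConfig(n=300, seed=3, misdate_sd_months=24.0)
    cohort, truth = generate_cohort(cfg)
    for r in cohort:
        for p in r.pregnancies:
            assert p.end_month <= r.interview_month
    ev = truth.events
    disclosed = ev[ev["disclosed_ftf"]]
    assert (disclosed["recorded_ftf_month"].notna()).all()
    assert ev.loc[~ev["disclosed_ftf"], "recorded_ftf_month"].isna().all()


def test_misdate_error_law_sd():
    """The two-sided geometric month error hits the requested spread."""
    for sd in (1.0, 4.0, 12.0):
        p = _geometric_p_for_sd(sd)
        var = (1 - p) * (2 - p) / (p * p)
        assert var == pytest.approx(sd * sd, rel=1e-6)


def test_never_discloser_effect_zeroes_whole_histories():
    cfg = GeneratorConfig(
        n=2000, seed=21,
        fixed_event_count={"abortion": 3},
        p_ftf={"birth": 1, "loss": 1, "abortion": 1},
        p_never_discloser_ftf=0.5,
        misdate_sd_months=0.0,
    )
    cohort, _ = generate_cohort(cfg)
    sizes = {len(r.pregnancies) for r in cohort}
    assert sizes == {0, 3}  # all-or-nothing disclosure
    frac = sum(1 for r in cohort if len(r.pregnancies) == 0) / len(cohort)
    assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 2000)


def test_config_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(n=0)
    with pytest.raises(ConfigError):
        GeneratorConfig(confusion_prob=1.5)
    with pytest.raises(ConfigError):
        GeneratorConfig(p_ftf={"abortion": -0.1})
    with pytest.raises(ConfigError):
        GeneratorConfig(round="2002", event_placement="in_window")
    with pytest.raises(ConfigError):
        GeneratorConfig(cross_category_misclass_prob=0.1)
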