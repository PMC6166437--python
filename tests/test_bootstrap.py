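"""Percentile bootstrap: quantile rule, determinism, difference tests."""

import numpy as np
import pytest

from reportratio.bootstrap import (
    bootstrap_ratio,
    ci_nonoverlap,
    difference_test_independent,
    difference_test_joint,
    percentile_interval,
)
from reportratio.errors import (
    DegenerateBootstrapError,
    IncompatibleBootstrapError,
    NoReplicatesError,
)
from reportratio.model import Cohort, ROUND_2011_2015
from reportratio.simulate import GeneratorConfig, generate_cohort

from conftest import make_respondent, preg


def _one_event_config(p_acasi, p_ftf, n, seed):
    return GeneratorConfig(
        n=n, seed=seed,
        fixed_event_count={"abortion": 1},
        event_placement="in_window",
        p_acasi={"birth": 0, "loss": 0, "abortion": p_acasi},
        p_ftf={"birth": 0, "loss": 0, "abortion": p_ftf},
        misdate_sd_months=0.0, telescope_in_prob=0.0, confusion_prob=0.0,
    )


class TestPercentileInterval:
    def test_linear_interpolation_on_1_to_100(self):
        lo, hi = percentile_interval(np.arange(1, 101), alpha=0.05)
        assert (lo, hi) == pytest.approx((3.475, 97.525))

    def test_constant_sequence(self):
        assert percentile_interval([2.5] * 10) == (2.5, 2.5)

    def test_single_value(self):
        assert percentile_interval([7.0]) == (7.0, 7.0)

    def test_empty_raises(self):
        with pytest.raises(NoReplicatesError):
            percentile_interval([])

    def test_median_inside_interval(self):
        rng = np.random.default_rng(0)
        reps = rng.normal(size=501)
        lo, hi = percentile_interval(reps)
        assert lo <= np.median(reps) <= hi


def test_zero_variance_cohort_gives_point_interval():
    """Every woman reports in both modes: all replicates exactly 1.0."""
    women = [
        make_respondent(f"w{i}", [preg("abortion", 2010, 3)], acasi_abortion=1)
        for i in range(30)
    ]
    cohort = Cohort(round=ROUND_2011_2015, respondents=women)
    res = bootstrap_ratio(cohort, "abortion", B=100, seed=1)
    assert res.point.ratio == 1.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)
    assert np.all(res.replicates == 1.0)


def test_fixed_seed_reproducible():
    cohort, _ = generate_cohort(GeneratorConfig(n=500, seed=2))
    a = bootstrap_ratio(cohort, "abortion", B=100, seed=9)
    b = bootstrap_ratio(cohort, "abortion", B=100, seed=9)
    assert np.array_equal(a.replicates, b.replicates, equal_nan=True)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    c = bootstrap_ratio(cohort, "abortion", B=100, seed=10)
    assert not np.array_equal(a.replicates, c.replicates, equal_nan=True)


def test_point_ratio_within_ci_on_realistic_cohort():
    cohort, _ = generate_cohort(GeneratorConfig(n=4000, seed=3))
    res = bootstrap_ratio(cohort, "abortion", B=400, seed=5)
    assert res.ci_low <= res.point.ratio <= res.ci_high
    assert res.n_undefined == 0


def test_sparse_category_degenerates():
    """A single FTF reporter: ~37% of replicates lose the denominator."""
    women = [make_respondent("w0", [preg("abortion", 2010, 1)], acasi_abortion=1)]
    women += [make_respondent(f"w{i}", [], acasi_abortion=1) for i in range(1, 60)]
    cohort = Cohort(round=ROUND_2011_2015, respondents=women)
    with pytest.raises(DegenerateBootstrapError):
        bootstrap_ratio(cohort, "abortion", B=200, seed=4)


class TestDifferenceIndependent:
    def test_identical_bootstraps_not_significant(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=800, seed=6))
        a = bootstrap_ratio(cohort, "abortion", B=200, seed=7)
        b = bootstrap_ratio(cohort, "abortion", B=200, seed=7)
        t = difference_test_independent(a, b)
        assert np.all(t.diff_replicates == 0.0)
        assert not t.significant

    def test_unequal_B_raises(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=800, seed=6))
        a = bootstrap_ratio(cohort, "abortion", B=100, seed=7)
        b = bootstrap_ratio(cohort, "abortion", B=150, seed=8)
        with pytest.raises(IncompatibleBootstrapError):
            difference_test_independent(a, b)

    def test_separated_rounds_significant(self):
        """True ratios 1.15 vs 1.45 at n=10,000: separation far beyond
        the bootstrap SE, so the difference interval excludes zero."""
        cohortA, _ = generate_cohort(_one_event_config(0.92, 0.80, 10_000, 31))
        cohortB, _ = generate_cohort(_one_event_config(0.87, 0.60, 10_000, 32))
        a = bootstrap_ratio(cohortA, "abortion", B=500, seed=33)
        b = bootstrap_ratio(cohortB, "abortion", B=500, seed=34)
        t = difference_test_independent(a, b)
        assert t.significant
        assert t.pct_high < 0  # A's ratio is the smaller one


class TestDifferenceJoint:
    def test_same_level_all_zero(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=1000, seed=12))
        t = difference_test_joint(
            cohort, "abortion", "religiosity", "monthly_plus", "monthly_plus",
            B=100, seed=13,
        )
        assert np.all(t.diff_replicates[np.isfinite(t.diff_replicates)] == 0.0)
        assert not t.significant

    def test_separated_subgroups_significant(self):
        cfg = _one_event_config(0.5, 0.8, 20_000, 14).with_(
            p_acasi_multipliers={"religiosity": {"monthly_plus": 1.5}}
        )
        cohort, _ = generate_cohort(cfg)
        t = difference_test_joint(
            cohort, "abortion", "religiosity", "monthly_plus", "lt_monthly",
            B=300, seed=15,
        )
        assert t.significant
        assert t.pct_low > 0


class TestCiNonoverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # abortion vs birth CIs, recent five-year round: disjoint
            ((1.36, 1.56), (1.11, 1.15), True),
            # abortion vs miscarriage CIs, earlier round: they touch
            ((1.26, 1.39), (1.37, 1.45), False),
            ((1.0, 2.0), (1.0, 2.0), False),
        ],
    )
    def test_examples(self, a, b, expected):
        assert ci_nonoverlap(a, b) is expected
        assert ci_nonoverlap(b, a) is expected

    def test_unordered_interval_rejected(self):
        with pytest.raises(ValueError):
            ci_nonoverlap((2.0, 1.0), (0.0, 1.0))
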