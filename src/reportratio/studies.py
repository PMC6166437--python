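"""Design-validation simulation studies.

Monte-Carlo checks of the whole pipeline against known ground truth:
the faithful-limit identity, recovery of the closed-form ratio
p_acasi / p_ftf in the one-event-per-woman design, structural window
monotonicity over random configurations, percentile-CI coverage,
the type-I error of the joint subgroup difference test, and recovery
of the lifetime-confusion match proportion from the truth ledger.

These studies exist so the package can quantify its own calibration;
they are driven by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model
from .bootstrap import bootstrap_ratio, difference_test_joint
from .errors import UndefinedRatioError
from .ratios import expanded_reporting_ratio, reporting_ratio
from .sensitivity import discordant_reporters, lifetime_match_proportion
from .simulate import GeneratorConfig, generate_cohort


def one_event_config(
    p_acasi: float, p_ftf: float, n: int, seed: int, **kw
) -> GeneratorConfig:
    """One in-window abortion per woman; no misdating, telescoping or
    confusion. Under this design the reporter indicators are Bernoulli
    (p_acasi) and (p_ftf), so the true reporting ratio is their quotient."""
    return GeneratorConfig(
        n=n, seed=seed,
        fixed_event_count={"abortion": 1},
        event_placement="in_window",
        p_acasi={"birth": 0.0, "loss": 0.0, "abortion": p_acasi},
        p_ftf={"birth": 0.0, "loss": 0.0, "abortion": p_ftf},
        misdate_sd_months=0.0, telescope_in_prob=0.0, confusion_prob=0.0,
        **kw,
    )


def faithful_limit_ratios(n: int, seed: int) -> dict[str, float]:
    """All disclosure probabilities 1, no noise: every ratio must be 1."""
    cfg = GeneratorConfig(
        n=n, seed=seed,
        p_ftf={c: 1.0 for c in model.CATEGORIES},
        p_acasi={c: 1.0 for c in model.CATEGORIES},
        misdate_sd_months=0.0, telescope_in_prob=0.0, confusion_prob=0.0,
    )
    cohort, _ = generate_cohort(cfg)
    return {c: reporting_ratio(cohort, c).ratio for c in model.CATEGORIES}


@dataclass(frozen=True)
class ClosedFormResult:
    ratio: float
    true_ratio: float
    se_delta: float  # delta-method standard error of the estimator

    @property
    def abs_error(self) -> float:
        return abs(self.ratio - self.true_ratio)


def closed_form_recovery(
    p_acasi: float = 0.92, p_ftf: float = 0.80, n: int = 50_000, seed: int = 0
) -> ClosedFormResult:
    """Estimate the ratio in the one-event design and report the
    delta-method SE: R * sqrt((1-pa)/(n*pa) + (1-pf)/(n*pf))."""
    cohort, _ = generate_cohort(one_event_config(p_acasi, p_ftf, n, seed))
    est = reporting_ratio(cohort, "abortion")
    true_ratio = p_acasi / p_ftf
    se = true_ratio * np.sqrt(
        (1 - p_acasi) / (n * p_acasi) + (1 - p_ftf) / (n * p_ftf)
    )
    return ClosedFormResult(ratio=est.ratio, true_ratio=true_ratio, se_delta=se)


def monotonicity_sweep(
    n_configs: int = 100, n: int = 500, seed: int = 0
) -> tuple[int, int]:
    """Random generator configs: count (comparisons, violations) of
    expanded_ratio <= standard_ratio across categories."""
    rng = np.random.default_rng(seed)
    comparisons = violations = 0
    for i in range(n_configs):
        cfg = GeneratorConfig(
            n=n,
            seed=int(rng.integers(0, 2**31 - 1)),
            event_rate={c: float(rng.uniform(0.3, 1.5)) for c in model.CATEGORIES},
            p_ftf={c: float(rng.uniform(0.3, 1.0)) for c in model.CATEGORIES},
            p_acasi={c: float(rng.uniform(0.3, 1.0)) for c in model.CATEGORIES},
            misdate_sd_months=float(rng.uniform(0.0, 12.0)),
            telescope_in_prob=float(rng.uniform(0.0, 0.2)),
            confusion_prob=float(rng.uniform(0.0, 0.3)),
            span_years=float(rng.uniform(10.0, 30.0)),
        )
        cohort, _ = generate_cohort(cfg)
        for cat in model.CATEGORIES:
            try:
                std = reporting_ratio(cohort, cat).ratio
                exp = expanded_reporting_ratio(cohort, cat).ratio
            except UndefinedRatioError:
                continue
            comparisons += 1
            if exp > std:
                violations += 1
    return comparisons, violations


def coverage_study(
    n_cohorts: int = 200,
    n: int = 5_000,
    B: int = 500,
    p_acasi: float = 0.92,
    p_ftf: float = 0.80,
    seed: int = 0,
) -> float:
    """Fraction of independent cohorts whose 95% percentile CI covers
    the closed-form true ratio."""
    rng = np.random.default_rng(seed)
    true_ratio = p_acasi / p_ftf
    covered = 0
    for _ in range(n_cohorts):
        s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
        cohort, _ = generate_cohort(one_event_config(p_acasi, p_ftf, n, s1))
        res = bootstrap_ratio(cohort, "abortion", B=B, seed=s2)
        if res.ci_low <= true_ratio <= res.ci_high:
            covered += 1
    return covered / n_cohorts


def type1_error_study(
    n_cohorts: int = 100,
    n: int = 2_000,
    B: int = 500,
    seed: int = 0,
    axis: str = "religiosity",
) -> float:
    """Rejection rate of the joint subgroup difference test when both
    levels share identical disclosure (nominal level 5%)."""
    rng = np.random.default_rng(seed)
    levelA, levelB = model.DEMOGRAPHIC_AXES[axis][:2]
    rejections = 0
    for _ in range(n_cohorts):
        s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
        cohort, _ = generate_cohort(one_event_config(0.6, 0.8, n, s1))
        t = difference_test_joint(cohort, "abortion", axis, levelA, levelB,
                                  B=B, seed=s2)
        if t.significant:
            rejections += 1
    return rejections / n_cohorts


@dataclass(frozen=True)
class SensitivityRecovery:
    proportion: float          # pipeline output
    expectation: float         # ledger-derived expectation
    sigma: float               # its Monte-Carlo standard deviation
    n_discordant: int

    @property
    def abs_error(self) -> float:
        return abs(self.proportion - self.expectation)


def sensitivity_recovery(
    n: int = 20_000,
    confusion_prob: float = 0.3,
    p_ftf: float = 0.8,
    seed: int = 0,
) -> SensitivityRecovery:
    """Lifetime-match proportion versus its ledger expectation.

    Design: all abortion events strictly before the window, full ACASI
    disclosure, partial FTF disclosure, no telescoping. A woman is
    discordant iff confusion replaced her (zero) windowed count with her
    lifetime count k >= 1; her ACASI count is then k exactly, and it
    matches her FTF lifetime count iff all k events were disclosed —
    probability p_ftf**k, computable per woman from the ledger.
    """
    cfg = GeneratorConfig(
        n=n, seed=seed,
        event_rate={"birth": 0.0, "loss": 0.0, "abortion": 1.0},
        event_placement="pre_window",
        p_acasi={c: 1.0 for c in model.CATEGORIES},
        p_ftf={"birth": 1.0, "loss": 1.0, "abortion": p_ftf},
        misdate_sd_months=0.0, telescope_in_prob=0.0,
        confusion_prob=confusion_prob,
    )
    cohort, truth = generate_cohort(cfg)
    s = lifetime_match_proportion(cohort, "abortion")
    ids = discordant_reporters(cohort, "abortion")
    ev = truth.events
    k = ev[ev["respondent_id"].isin(ids)].groupby("respondent_id").size()
    probs = p_ftf ** k.to_numpy(dtype=float)
    expectation = float(probs.mean())
    sigma = float(np.sqrt((probs * (1 - probs)).sum()) / len(probs))
    return SensitivityRecovery(
        proportion=s.proportion, expectation=expectation, sigma=sigma,
        n_discordant=s.n_discordant,
    )
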