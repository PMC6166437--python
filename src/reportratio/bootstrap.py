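"""Percentile-bootstrap inference for reporting ratios.

The resampling unit is the respondent: each replicate draws n women
with replacement and recomputes the ratio from their paired indicator
pair, preserving the within-subject coupling of the two modes. The
default replication count is 5,000 and intervals are the empirical
2.5th/97.5th percentiles with linear interpolation between order
statistics.

Two significance devices are provided: a replicate-wise difference
distribution whose 95% percentile interval is checked against zero
(for contrasts between independent cohorts, e.g. survey rounds, and —
via joint resampling of the full cohort — between demographic strata of
one sample), and a conservative non-overlap check on two confidence
intervals (for contrasts the difference distribution cannot serve,
e.g. between outcome categories of the same women).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import model
from .errors import (
    DegenerateBootstrapError,
    IncompatibleBootstrapError,
    NoReplicatesError,
)
from .model import Cohort
from .ratios import RatioEstimate, expanded_reporting_ratio, mode_indicators, reporting_ratio

#: fraction of zero-denominator replicates beyond which the cohort is
#: declared too sparse for the category
MAX_UNDEFINED_FRACTION = 0.01

_CHUNK = 256  # replicates per vectorized block; bounds peak memory


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate, replicate ratios and percentile interval."""

    point: RatioEstimate
    replicates: np.ndarray  # length B; NaN where the replicate was undefined
    ci_low: float
    ci_high: float
    n_undefined: int
    seed: int
    alpha: float = 0.05

    @property
    def B(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class DifferenceTest:
    """Replicate-wise difference distribution and its zero-exclusion test."""

    diff_replicates: np.ndarray
    pct_low: float
    pct_high: float
    significant: bool


def percentile_interval(
    replicates: Sequence[float], alpha: float = 0.05
) -> tuple[float, float]:
    """Empirical (alpha/2, 1-alpha/2) quantiles, linear interpolation."""
    arr = np.asarray(replicates, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise NoReplicatesError("no defined replicates to take percentiles of")
    lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _resampled_ratios(
    acasi: np.ndarray,
    ftf: np.ndarray,
    B: int,
    rng: np.random.Generator,
    members: Optional[list[np.ndarray]] = None,
) -> np.ndarray | list[np.ndarray]:
    """Replicate ratios from index resampling of paired indicators.

    With ``members`` given (boolean stratum masks), returns one ratio
    array per stratum, all computed from the same resampled indices
    (joint resampling). Undefined replicates are NaN.
    """
    n = len(acasi)
    acasi_f = acasi.astype(np.float64)
    ftf_f = ftf.astype(np.float64)
    single = members is None
    masks = [np.ones(n, dtype=bool)] if single else members
    out = [np.empty(B) for _ in masks]
    done = 0
    while done < B:
        b = min(_CHUNK, B - done)
        idx = rng.integers(0, n, size=(b, n))
        for j, mask in enumerate(masks):
            if single:
                num = acasi_f[idx].sum(axis=1)
                den = ftf_f[idx].sum(axis=1)
            else:
                m = mask.astype(np.float64)
                num = (acasi_f * m)[idx].sum(axis=1)
                den = (ftf_f * m)[idx].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[j][done:done + b] = np.where(den > 0, num / den, np.nan)
        done += b
    return out[0] if single else out


def bootstrap_ratio(
    cohort: Cohort,
    category: str,
    ftf_window_label: Optional[str] = None,
    B: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    expanded_end: str = "interview",
) -> BootstrapResult:
    """Percentile-bootstrap CI for one reporting ratio.

    ``ftf_window_label`` may be ``standard``/``lifetime`` (headline
    ratio, per round) or ``expanded``. Replicates with an empty FTF
    denominator are dropped from the percentiles; more than 1% of them
    raises :class:`DegenerateBootstrapError`.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    label = cohort.default_window_label if ftf_window_label is None else ftf_window_label
    if label == "expanded":
        point = expanded_reporting_ratio(cohort, category, expanded_end)
    else:
        point = reporting_ratio(cohort, category, label)
    acasi, ftf = mode_indicators(cohort, category, label, expanded_end)
    rng = np.random.default_rng(seed)
    reps = _resampled_ratios(acasi, ftf, B, rng)
    n_undef = int(np.isnan(reps).sum())
    if n_undef > MAX_UNDEFINED_FRACTION * B:
        raise DegenerateBootstrapError(
            f"{n_undef}/{B} replicates had no FTF reporters of {category}"
        )
    lo, hi = percentile_interval(reps, alpha)
    return BootstrapResult(
        point=point, replicates=reps, ci_low=lo, ci_high=hi,
        n_undefined=n_undef, seed=seed, alpha=alpha,
    )


def _zero_excluded(lo: float, hi: float) -> bool:
    return lo > 0 or hi < 0


def difference_test_independent(
    bootA: BootstrapResult, bootB: BootstrapResult, alpha: float = 0.05
) -> DifferenceTest:
    """Contrast two ratios bootstrapped from disjoint cohorts.

    Replicate b of A is paired with replicate b of B (any pairing is
    valid under independence; a fixed one keeps results reproducible).
    Significance = the 95% percentile interval of differences excludes
    zero.
    """
    if bootA.B != bootB.B:
        raise IncompatibleBootstrapError(
            f"replicate counts differ: {bootA.B} vs {bootB.B}"
        )
    diff = bootA.replicates - bootB.replicates
    lo, hi = percentile_interval(diff, alpha)
    return DifferenceTest(
        diff_replicates=diff, pct_low=lo, pct_high=hi,
        significant=_zero_excluded(lo, hi),
    )


def difference_test_joint(
    cohort: Cohort,
    category: str,
    axis: str,
    levelA: str,
    levelB: str,
    B: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    ftf_window_label: Optional[str] = None,
) -> DifferenceTest:
    """Contrast two strata of one cohort by joint full-cohort resampling.

    Each replicate resamples the whole cohort with replacement and
    recomputes both stratum ratios on it, so the dependence induced by
    shared sampling is preserved. Replicates where either stratum has
    no FTF reporters are dropped (capped at 1%).
    """
    if axis not in model.DEMOGRAPHIC_AXES:
        raise KeyError(f"unknown demographic axis: {axis!r}")
    for level in (levelA, levelB):
        if level not in model.DEMOGRAPHIC_AXES[axis]:
            raise KeyError(f"unknown level {level!r} for axis {axis!r}")
    label = cohort.default_window_label if ftf_window_label is None else ftf_window_label
    acasi, ftf = mode_indicators(cohort, category, label)
    levels = np.array([getattr(r, axis) for r in cohort], dtype=object)
    maskA = levels == levelA
    maskB = levels == levelB
    rng = np.random.default_rng(seed)
    repsA, repsB = _resampled_ratios(acasi, ftf, B, rng, members=[maskA, maskB])
    diff = repsA - repsB
    n_undef = int(np.isnan(diff).sum())
    if n_undef > MAX_UNDEFINED_FRACTION * B:
        raise DegenerateBootstrapError(
            f"{n_undef}/{B} replicates had an empty stratum denominator"
        )
    lo, hi = percentile_interval(diff, alpha)
    return DifferenceTest(
        diff_replicates=diff, pct_low=lo, pct_high=hi,
        significant=_zero_excluded(lo, hi),
    )


def ci_nonoverlap(
    intervalA: tuple[float, float], intervalB: tuple[float, float]
) -> bool:
    """True iff the two (low, high) intervals are disjoint.

    A conservative significance device for contrasts where a difference
    distribution is unavailable (e.g. between outcome categories
    reported by the same women).
    """
    loA, hiA = intervalA
    loB, hiB = intervalB
    if loA > hiA or loB > hiB:
        raise ValueError("intervals must be ordered (low, high)")
    return hiA < loB or hiB < loA
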