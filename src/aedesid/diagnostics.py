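"""Diagnostic statistics: sensitivity/specificity with Wald CIs, pooled
Ct summaries, and Welch's two-sample t-test from summary statistics.

Sensitivity is TP / (TP + FN) and specificity TN / (TN + FP); either is
undefined (returned as None) when its denominator is zero — a group with
no true positives, such as the eDNA No Detection class, has no
sensitivity. Confidence intervals use the simple asymptotic (Wald) method
without continuity correction, p +/- z * sqrt(p (1 - p) / n) with
z = 1.96 for 95% confidence; upper bounds above 1 are capped at 1 and
lower bounds below 0 clamped at 0, with the raw bounds retained.

Ct values are reported as mean +/- SD per subgroup and consolidated with
the exact recombination rule for combining subgroup means and standard
deviations, so pooling subgroups reproduces the statistics of the pooled
raw values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .classify import ConfusionCounts, confusion_for_edna, confusion_for_group
from .qpcr_io import Dataset

logger = logging.getLogger(__name__)

DEFAULT_Z = 1.96


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ProportionCI:
    """Wald interval for a proportion, clamped to [0, 1]."""

    p: float
    n: int
    z: float
    lower: float
    upper: float
    lower_raw: float
    upper_raw: float


@dataclass(frozen=True)
class PooledSummary:
    n_total: int
    mean: float
    sd: float | None


@dataclass(frozen=True)
class WelchResult:
    mean_diff: float
    se_diff: float
    df: float
    t_stat: float
    p_two_tailed: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class DiagnosticResult:
    group_label: str
    counts: ConfusionCounts
    sensitivity: ProportionCI | None
    specificity: ProportionCI | None


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when the group has no positive-truth units."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


def specificity(counts: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when the group has no negative-truth units."""
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else None


def asymptotic_ci(p: float, n: int, z: float = DEFAULT_Z) -> ProportionCI:
    """Simple asymptotic (Wald) CI without continuity correction."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must lie in [0, 1]")
    half = z * math.sqrt(p * (1.0 - p) / n)
    lower_raw, upper_raw = p - half, p + half
    return ProportionCI(
        p=p,
        n=n,
        z=z,
        lower=max(0.0, lower_raw),
        upper=min(1.0, upper_raw),
        lower_raw=lower_raw,
        upper_raw=upper_raw,
    )


def pool_summaries(groups: Sequence[tuple[int, float, float]]) -> PooledSummary:
    """Combine per-subgroup (n, mean, sd) into one exact pooled summary.

    The pooled mean is the size-weighted mean; the pooled sum of squares
    adds each subgroup's internal spread (n_i - 1) sd_i^2 and its
    between-group displacement n_i (mean_i - pooled mean)^2, divided by
    (N - 1). Applied pairwise this rule is associative, and pooling the
    subgroups of a split sample reproduces the whole-sample mean and SD.
    """
    if not groups:
        raise ParameterError("no groups to pool")
    for n_i, _, sd_i in groups:
        if n_i < 1:
            raise ParameterError("every subgroup must have n >= 1")
        if sd_i < 0:
            raise ParameterError("subgroup sd must be >= 0")
    n_total = sum(n_i for n_i, _, _ in groups)
    mean = sum(n_i * m_i for n_i, m_i, _ in groups) / n_total
    if n_total < 2:
        return PooledSummary(n_total=n_total, mean=mean, sd=None)
    ss = sum(
        (n_i - 1) * sd_i**2 + n_i * (m_i - mean) ** 2 for n_i, m_i, sd_i in groups
    )
    return PooledSummary(n_total=n_total, mean=mean, sd=math.sqrt(ss / (n_total - 1)))


def welch_test(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> WelchResult:
    """Unpaired two-tailed t-test with Welch's correction, from summaries.

    ``mean_diff`` is mean2 - mean1. Degrees of freedom follow
    Welch-Satterthwaite; with equal n and equal sd this reduces exactly to
    the pooled two-sample test with n1 + n2 - 2 df.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ParameterError("at least one group must have positive sd")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (
        (v1**2 / (n1 - 1) if v1 else 0.0) + (v2**2 / (n2 - 1) if v2 else 0.0)
    )
    mean_diff = mean2 - mean1
    t_stat = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    t_crit = float(stats.t.ppf(0.975, df))
    return WelchResult(
        mean_diff=mean_diff,
        se_diff=se,
        df=df,
        t_stat=t_stat,
        p_two_tailed=float(p),
        ci_lower=mean_diff - t_crit * se,
        ci_upper=mean_diff + t_crit * se,
    )


def _result_from_counts(
    label: str, counts: ConfusionCounts, z: float
) -> DiagnosticResult:
    se = sensitivity(counts)
    sp = specificity(counts)
    return DiagnosticResult(
        group_label=label,
        counts=counts,
        sensitivity=asymptotic_ci(se, counts.tp + counts.fn, z) if se is not None else None,
        specificity=asymptotic_ci(sp, counts.tn + counts.fp, z) if sp is not None else None,
    )


def evaluate_groups(
    dataset: Dataset,
    truth_source: str = "verified",
    proxy_truth: Mapping[str, str] | None = None,
    z: float = DEFAULT_Z,
) -> list[DiagnosticResult]:
    """Per-group sensitivity and specificity with Wald CIs.

    ``truth_source='verified'`` evaluates tissue records grouped by
    life stage x source x species against morphological verification;
    ``truth_source='lca_proxy'`` evaluates eDNA records per extraction
    replicate against the supplied latent-class proxy truth, one result
    per designated class. CI denominators are the corresponding count
    denominators (tp + fn, tn + fp).
    """
    if truth_source == "verified":
        groups: dict[str, list] = {}
        for rec in dataset.tissue_records():
            groups.setdefault(rec.group_label, []).append(rec)
        results = []
        for label in sorted(groups):
            recs = groups[label]
            if not recs:
                logger.warning("group %s is empty; omitted", label)
                continue
            results.append(_result_from_counts(label, confusion_for_group(recs), z))
        return results
    if truth_source == "lca_proxy":
        if proxy_truth is None:
            raise ParameterError("truth_source='lca_proxy' requires proxy_truth")
        per_class = confusion_for_edna(dataset.edna_records(), proxy_truth)
        results = []
        for label, counts in per_class.items():
            if counts.tp + counts.fn + counts.fp + counts.tn == 0:
                logger.warning("class %s has no samples; omitted", label)
                continue
            results.append(_result_from_counts(label, counts, z))
        return results
    raise ParameterError(f"unknown truth_source {truth_source!r}")
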