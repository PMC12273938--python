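"""Descriptive statistics, normality tests and one-way ANOVA.

Covers the cohort-level analysis: per-variable descriptives, Shapiro–Wilk
and Lilliefors-corrected Kolmogorov–Smirnov normality tests, and one-way
fixed-effects ANOVA across the three original nuclear grades — both from
raw per-case values and from published group summaries (n, mean, SD), which
lets reported group tables be re-analysed without the raw data.  Post hoc
pairwise comparisons are two-sided t-tests on the pooled within-group mean
square with Bonferroni correction.

Sample SDs use the n−1 denominator throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateStatisticsError, InputError


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one group: n, mean, sample SD."""

    label: int | str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise InputError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[int | str, int | str]
    mean_difference: float
    t_stat: float
    raw_p: float
    bonferroni_p: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_summaries: tuple[GroupSummary, ...]
    pairwise: tuple[PairwiseComparison, ...] = ()

    @property
    def grand_mean(self) -> float:
        return grand_mean(self.group_summaries)


def describe(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(min, max, mean, sample SD).  A single value has SD 0 (with warning)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("describe() needs at least one value")
    if arr.size == 1:
        warnings.warn("sample SD undefined for n = 1; reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return float(arr.min()), float(arr.max()), float(arr.mean()), sd


def summarize(label: int | str, values: Sequence[float]) -> GroupSummary:
    """Reduce raw values to a :class:`GroupSummary`."""
    arr = np.asarray(values, dtype=float)
    _, _, mean, sd = describe(arr)
    return GroupSummary(label=label, n=arr.size, mean=mean, sd=sd)


def grand_mean(summaries: Sequence[GroupSummary]) -> float:
    """Size-weighted overall mean reconstructed from group summaries."""
    total = sum(s.n for s in summaries)
    if total == 0:
        raise InputError("no observations")
    return sum(s.n * s.mean for s in summaries) / total


def anova_oneway_summary(
    summaries: Sequence[GroupSummary],
) -> tuple[float, int, int, float]:
    """One-way ANOVA from group (n, mean, SD) summaries.

    SSB = Σ nᵢ(meanᵢ − grand mean)², SSW = Σ (nᵢ−1)·sdᵢ²,
    F = (SSB/(k−1)) / (SSW/(N−k)); p from the F(k−1, N−k) distribution.
    """
    if len(summaries) < 2:
        raise InputError("need at least 2 groups")
    for s in summaries:
        if s.n < 2:
            raise InputError(f"group {s.label!r}: ANOVA needs n >= 2 per group")
    k = len(summaries)
    big_n = sum(s.n for s in summaries)
    gm = grand_mean(summaries)
    ssb = sum(s.n * (s.mean - gm) ** 2 for s in summaries)
    ssw = sum((s.n - 1) * s.sd**2 for s in summaries)
    df_between = k - 1
    df_within = big_n - k
    if ssw == 0:
        raise DegenerateStatisticsError("zero within-group variance; F undefined")
    f = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), df_between, df_within, p


def anova_oneway_raw(
    groups: Sequence[Sequence[float]],
    labels: Sequence[int | str] | None = None,
) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw groups, with Bonferroni post hoc.

    Pairwise comparisons are two-sided t-tests using the pooled
    within-group mean square on N−k degrees of freedom; Bonferroni
    p-values are min(1, raw_p × k(k−1)/2).
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise InputError(f"group {i}: ANOVA needs n >= 2 per group")
    if labels is None:
        labels = list(range(1, len(groups) + 1))
    summaries = tuple(summarize(lab, g) for lab, g in zip(labels, groups))
    f, df_b, df_w, p = anova_oneway_summary(summaries)

    msw = sum((s.n - 1) * s.sd**2 for s in summaries) / df_w
    n_pairs = len(summaries) * (len(summaries) - 1) // 2
    pairwise = []
    for a, b in itertools.combinations(summaries, 2):
        se = np.sqrt(msw * (1 / a.n + 1 / b.n))
        t = (a.mean - b.mean) / se
        raw_p = float(2 * sps.t.sf(abs(t), df_w))
        pairwise.append(
            PairwiseComparison(
                pair=(a.label, b.label),
                mean_difference=float(a.mean - b.mean),
                t_stat=float(t),
                raw_p=raw_p,
                bonferroni_p=min(1.0, raw_p * n_pairs),
            )
        )
    return AnovaResult(
        f_stat=f,
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_summaries=summaries,
        pairwise=tuple(pairwise),
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, two-sided p), for 3 ≤ n ≤ 5000."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise InputError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise DegenerateStatisticsError("constant input; normality test undefined")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def _lilliefors_d(arr: np.ndarray) -> float:
    """KS sup-distance to the normal with sample-estimated mean and SD."""
    mean = arr.mean()
    sd = arr.std(ddof=1)
    return float(sps.kstest(arr, "norm", args=(mean, sd)).statistic)


def ks_lilliefors(
    values: Sequence[float], mc_reps: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality test with Lilliefors correction.

    D is the sup-distance between the empirical CDF and the normal CDF with
    mean and SD estimated from the sample.  Because the parameters are
    estimated, the classic KS null distribution does not apply; the p-value
    is computed by Monte-Carlo under the composite null: ``mc_reps``
    standard-normal samples of the same n, each reduced to its own D, with
    p = (1 + #{D* ≥ D}) / (mc_reps + 1).  Fixed seed ⇒ identical (D, p).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise InputError(f"Lilliefors test needs n >= 4, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise DegenerateStatisticsError("constant input; normality test undefined")
    if mc_reps < 1:
        raise InputError("mc_reps must be >= 1")
    d_obs = _lilliefors_d(arr)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((mc_reps, arr.size))
    means = sims.mean(axis=1, keepdims=True)
    sds = sims.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((sims - means) / sds, axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, arr.size + 1)
    d_plus = (i / arr.size - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / arr.size).max(axis=1)
    d_sim = np.maximum(d_plus, d_minus)
    p = (1 + int((d_sim >= d_obs - 1e-15).sum())) / (mc_reps + 1)
    return d_obs, float(p)
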