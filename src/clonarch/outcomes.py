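"""Response-rate and progression-free-survival analysis for biomarker groups.

Objective response rate (ORR) is the number of responders (best objective
response of CR or PR) over the group size, with an exact two-sided
Clopper-Pearson 95% interval (the interval that inverts the equal-tailed
binomial tests; it reproduces e.g. an upper bound of 1 - 0.025^(1/5) = 52%
for 0 of 5 responders). Group ORRs are compared with an exact conditional
test: unstratified this is the two-sided Fisher exact test; stratified,
the null distribution of the total responder count in one group is the
exact convolution of per-stratum central hypergeometrics conditional on
per-stratum margins.

Survival uses the Kaplan-Meier product-limit estimator; group contrasts
report the log-rank p-value and the hazard ratio from a single-covariate
Cox proportional-hazards fit with Efron tie handling and Wald 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "OrrResult",
    "KMCurve",
    "SurvivalComparison",
    "orr_with_exact_ci",
    "compare_orr",
    "km_curve",
    "compare_survival",
]


def _two_sig_figs_percent(x: float) -> str:
    """Format a proportion as a percentage with two significant figures."""
    pct = x * 100.0
    if pct == 0:
        return "0.0"
    return f"{float(f'{pct:.2g}'):g}"


@dataclass(frozen=True)
class OrrResult:
    """ORR with an exact (Clopper-Pearson) two-sided confidence interval.

    ``orr``, ``ci_low`` and ``ci_high`` are proportions in [0, 1]; use
    :meth:`display` for the percentage rendering at two significant figures.
    """

    responders: int
    total: int
    orr: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def display(self) -> str:
        return (
            f"{_two_sig_figs_percent(self.orr)}% "
            f"(95% CI, {_two_sig_figs_percent(self.ci_low)}-"
            f"{_two_sig_figs_percent(self.ci_high)})"
        )


def orr_with_exact_ci(responders: int, total: int, level: float = 0.95) -> OrrResult:
    """Exact binomial (Clopper-Pearson) interval for a response rate.

    The equal-tailed interval endpoints are beta quantiles:
    lower = Beta(alpha/2; r, n-r+1), upper = Beta(1-alpha/2; r+1, n-r),
    with lower = 0 at r = 0 and upper = 1 at r = n.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= responders <= total):
        raise ValueError(f"responders {responders} outside [0, {total}]")
    alpha = 1.0 - level
    lo = 0.0 if responders == 0 else float(
        stats.beta.ppf(alpha / 2, responders, total - responders + 1)
    )
    hi = 1.0 if responders == total else float(
        stats.beta.ppf(1 - alpha / 2, responders + 1, total - responders)
    )
    return OrrResult(
        responders=responders,
        total=total,
        orr=responders / total,
        ci_low=lo,
        ci_high=hi,
        level=level,
    )


def _stratified_exact_p(
    resp_a: np.ndarray,
    resp_b: np.ndarray,
    strata_a: np.ndarray,
    strata_b: np.ndarray,
) -> float:
    """Exact conditional two-sided p for a stratified 2x2xK responder table.

    Conditions on per-stratum responder totals and group sizes; the test
    statistic is the total responder count in group A, whose null pmf is
    the convolution of per-stratum hypergeometric pmfs. Two-sided p sums
    outcome probabilities not exceeding the observed one (matching the
    Fisher point-probability convention, to which this reduces at K = 1).
    """
    levels = sorted(set(strata_a) | set(strata_b))
    pmf = np.array([1.0])  # distribution of total responders in A
    offset = 0  # support starts at `offset`
    observed = 0
    for lev in levels:
        a = resp_a[strata_a == lev]
        b = resp_b[strata_b == lev]
        if len(a) == 0 or len(b) == 0:
            warnings.warn(
                f"stratum {lev!r} absent in one group; dropped", stacklevel=3
            )
            continue
        n_a, k = len(a), int(a.sum() + b.sum())
        total = len(a) + len(b)
        observed += int(a.sum())
        lo = max(0, k - (total - n_a))
        hi = min(k, n_a)
        support = np.arange(lo, hi + 1)
        stratum_pmf = stats.hypergeom.pmf(support, total, k, n_a)
        pmf = np.convolve(pmf, stratum_pmf)
        offset += lo
    p_obs = pmf[observed - offset]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def compare_orr(
    group_a: Sequence[bool],
    group_b: Sequence[bool],
    strata_a: Sequence[str] | None = None,
    strata_b: Sequence[str] | None = None,
) -> float:
    """Two-sided exact p-value for an ORR difference between two groups.

    ``group_a``/``group_b`` are per-patient responder flags; optional
    parallel ``strata_a``/``strata_b`` give each patient's stratification
    level. Without strata (or with a single level) this is exactly the
    two-sided Fisher test on the pooled 2x2 table.
    """
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if strata_a is None or strata_b is None:
        levels: set[str] = set()
    else:
        strata_a = np.asarray(strata_a)
        strata_b = np.asarray(strata_b)
        if len(strata_a) != len(a) or len(strata_b) != len(b):
            raise ValueError("strata must parallel the responder flags")
        levels = set(strata_a) | set(strata_b)
    if len(levels) <= 1:
        from .pathway_coalteration import fisher_exact_2x2

        table = [
            [int(a.sum()), int(len(a) - a.sum())],
            [int(b.sum()), int(len(b) - b.sum())],
        ]
        return fisher_exact_2x2(table)
    return _stratified_exact_p(a, b, strata_a, strata_b)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function with its median survival time."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.timeline, "survival": self.survival})


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit survival estimate.

    The median is the smallest time at which the estimate drops to 0.5 or
    below, absent (None) when the curve never crosses 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("empty input")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    return KMCurve(
        timeline=timeline,
        survival=surv,
        median=None if np.isinf(med) else med,
    )


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group survival contrast: medians, Cox HR (A vs B), log-rank p."""

    label_a: str
    label_b: str
    median_a: float | None
    median_b: float | None
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    logrank_p: float


def compare_survival(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
    *,
    label_a: str = "A",
    label_b: str = "B",
) -> SurvivalComparison:
    """Log-rank test plus Cox PH hazard ratio of group A relative to group B.

    Ties are handled with Efron's method; the HR confidence interval is the
    Wald 95% interval from the single-covariate fit. Requires at least one
    observed event overall.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events observed in either group")
    lr = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    df = pd.DataFrame(
        {
            "time": np.concatenate([ta, tb]),
            "event": np.concatenate([ea, eb]).astype(int),
            "group_a": np.concatenate([np.ones(len(ta)), np.zeros(len(tb))]),
        }
    )
    if ea.sum() == 0 or eb.sum() == 0 or df["group_a"].nunique() < 2:
        raise ValueError("each group needs at least one event for the Cox fit")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["group_a"])
    se = float(cph.standard_errors_["group_a"])
    z = stats.norm.ppf(0.975)
    return SurvivalComparison(
        label_a=label_a,
        label_b=label_b,
        median_a=km_curve(ta, ea).median,
        median_b=km_curve(tb, eb).median,
        hazard_ratio=float(np.exp(coef)),
        hr_ci_low=float(np.exp(coef - z * se)),
        hr_ci_high=float(np.exp(coef + z * se)),
        logrank_p=float(lr.p_value),
    )
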