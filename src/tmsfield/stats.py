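"""Effect-size statistics: dispersion ANOVA, LSD post-hoc, d, r, eta-squared.

The layer mirrors the statistical toolkit of the clinical analysis it
models: one-way ANOVA with eta-squared, Fisher's LSD pairwise post-hoc
tests, two-sample t-tests (paired and independent), Cohen's d from group
summaries, the d -> r effect-size conversion, and the ratio / percent
arithmetic used for orientation comparisons and motor-threshold scaling.

Cohen's d from summaries uses the n-agnostic two-sd pooled form
``|m_a - m_b| / sqrt((sd_a^2 + sd_b^2) / 2)``; the sample-size-weighted
pooled form is also provided.  Reported t statistics from paired designs
are generally not recoverable from group summaries (the pairing
covariance is unknown), so only d, r, eta-squared, ratios and percentages
are treated as exactly reproducible quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatResult",
    "cohens_d_pooled",
    "cohens_d_weighted",
    "d_to_r",
    "eta_squared_from_f",
    "one_way_anova",
    "lsd_posthoc",
    "t_test",
    "percent_change",
    "ratio",
    "percent_mt_from_ratio",
]


@dataclass
class GroupSummary:
    """Label, size, mean and standard deviation of one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_data(cls, label: str, x) -> "GroupSummary":
        x = np.asarray(x, float)
        return cls(label, len(x), float(x.mean()), float(x.std(ddof=1)))


@dataclass
class StatResult:
    """A named statistic with optional degrees of freedom and p-value."""

    statistic_name: str
    value: float
    df: tuple | None = None
    p: float | None = None
    label: str = ""


def cohens_d_pooled(a: GroupSummary, b: GroupSummary) -> float:
    """Two-sd pooled Cohen's d: |m_a - m_b| / sqrt((sd_a^2 + sd_b^2)/2)."""
    denom = np.sqrt((a.sd**2 + b.sd**2) / 2.0)
    if denom == 0:
        raise ValueError("both group sds are zero")
    return float(abs(a.mean - b.mean) / denom)


def cohens_d_weighted(a: GroupSummary, b: GroupSummary) -> float:
    """Sample-size-weighted pooled Cohen's d."""
    pooled = np.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2)
                     / (a.n + b.n - 2))
    if pooled == 0:
        raise ValueError("both group sds are zero")
    return float(abs(a.mean - b.mean) / pooled)


def d_to_r(d: float) -> float:
    """Effect-size correlation r = d / sqrt(d^2 + 4) (equal-n conversion)."""
    if d < 0:
        raise ValueError("d must be non-negative")
    return float(d / np.sqrt(d * d + 4.0))


def eta_squared_from_f(f_value: float, k_groups: int, n_total: int) -> float:
    """eta^2 = (k-1)F / ((k-1)F + (N-k)) for a one-way design."""
    if f_value < 0:
        raise ValueError("F must be non-negative")
    if not n_total > k_groups >= 2:
        raise ValueError("need N > k >= 2")
    df_b, df_w = k_groups - 1, n_total - k_groups
    return float(df_b * f_value / (df_b * f_value + df_w))


def one_way_anova(groups: list[np.ndarray], labels: list[str] | None = None
                  ) -> StatResult:
    """Classical one-way ANOVA from raw data, with eta^2 from sums of squares.

    Returns a StatResult named 'F' whose ``df`` is (df_between, df_within);
    the eta^2 computed from sums of squares (stored on the result as
    ``eta2``) coincides with :func:`eta_squared_from_f` applied to the same
    F by algebraic identity.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    f_value = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f_value, df_b, df_w))
    res = StatResult("F", float(f_value), df=(df_b, df_w), p=p,
                     label="|".join(labels) if labels else "")
    res.eta2 = float(ss_between / (ss_between + ss_within))
    return res


def lsd_posthoc(groups: list[np.ndarray], labels: list[str] | None = None
                ) -> list[StatResult]:
    """Fisher's LSD pairwise t-tests with the pooled within-group MSE.

    Each pairwise t uses ``sqrt(MSE (1/n_i + 1/n_j))`` as its standard
    error and the ANOVA within-group degrees of freedom; no further
    multiplicity correction is applied (that is the LSD procedure).
    """
    groups = [np.asarray(g, float) for g in groups]
    labels = labels or [f"g{i}" for i in range(len(groups))]
    n_total = sum(len(g) for g in groups)
    df_w = n_total - len(groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(mse * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            t = (groups[i].mean() - groups[j].mean()) / se
            p = float(2.0 * sps.t.sf(abs(t), df_w))
            out.append(StatResult("t", float(t), df=(df_w,), p=p,
                                  label=f"{labels[i]}|{labels[j]}"))
    return out


def t_test(a: np.ndarray, b: np.ndarray, paired: bool = False) -> StatResult:
    """Two-sample t-test (independent by default, or paired)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if paired:
        res = sps.ttest_rel(a, b)
        df = (len(a) - 1,)
    else:
        res = sps.ttest_ind(a, b)
        df = (len(a) + len(b) - 2,)
    return StatResult("t", float(res.statistic), df=df, p=float(res.pvalue))


def percent_change(reference: float, value: float) -> float:
    """100 * (value - reference) / reference."""
    if reference == 0:
        raise ValueError("zero reference")
    return float(100.0 * (value - reference) / reference)


def ratio(numer: float, denom: float) -> float:
    if denom == 0:
        raise ValueError("zero denominator")
    return float(numer / denom)


def percent_mt_from_ratio(r: float) -> float:
    """Motor-threshold percentage delivered to the suppressed target.

    With the functional target held at 100% of its intended intensity, a
    functional/anatomical field ratio r leaves the anatomical target at
    100/r percent of motor threshold.
    """
    if r <= 0:
        raise ValueError("ratio must be positive")
    return float(100.0 / r)
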