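"""Group-comparison statistics: Hedge's g, Pearson r with CI, CoV.

Group differences are summarised by the unbiased standardised mean
difference (Hedge's g) with a normal-approximation analytic 95% CI; a
difference is called significant when the CI excludes zero.  Effect sizes
are classed on |g| as small (<= 0.2), medium (<= 0.8) or large (> 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, pearsonr

from .core import DegenerateDataError, ValidationError

__all__ = [
    "GroupSummary",
    "EffectSize",
    "hedges_g",
    "hedges_g_from_summary",
    "pearson_ci",
    "cov_percent",
    "summarize",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    @property
    def cov_percent(self) -> float:
        return cov_percent(self.mean, self.sd)


@dataclass(frozen=True)
class EffectSize:
    g: float
    ci_low: float
    ci_high: float
    klass: str
    significant: bool
    se: float


def _classify(g: float) -> str:
    a = abs(g)
    if a <= 0.2:
        return "small"
    if a <= 0.8:
        return "medium"
    return "large"


def _correction_j(df: int, exact: bool = False) -> float:
    if exact:
        return float(np.exp(gammaln(df / 2.0) - gammaln((df - 1) / 2.0)) / np.sqrt(df / 2.0))
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g_from_summary(
    n_a: int, mean_a: float, sd_a: float,
    n_b: int, mean_b: float, sd_b: float,
    alpha: float = 0.05, exact_correction: bool = False,
) -> EffectSize:
    """Hedge's g between groups A and B from their summary statistics.

    d = (mean_a − mean_b)/s_pooled, g = J·d with the small-sample
    correction J = 1 − 3/(4·df − 1) (df = n_a + n_b − 2; an exact
    gamma-function J is available by flag), and the analytic CI
    g ± z_{1−α/2}·SE with SE² = (n_a+n_b)/(n_a·n_b) + g²/(2·df).
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be >= 0")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 == 0.0:
        if mean_a == mean_b:
            d = 0.0
        else:
            raise DegenerateDataError("zero pooled variance with unequal means")
    else:
        d = (mean_a - mean_b) / np.sqrt(sp2)
    g = _correction_j(df, exact_correction) * d
    se = float(np.sqrt((n_a + n_b) / (n_a * n_b) + g**2 / (2.0 * df)))
    z = float(norm.ppf(1.0 - alpha / 2.0))
    lo, hi = g - z * se, g + z * se
    return EffectSize(float(g), float(lo), float(hi), _classify(g),
                      significant=not (lo <= 0.0 <= hi), se=se)


def hedges_g(sample_a, sample_b, alpha: float = 0.05, exact_correction: bool = False) -> EffectSize:
    """Hedge's g between two samples (see :func:`hedges_g_from_summary`)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    return hedges_g_from_summary(
        a.size, float(a.mean()), float(a.std(ddof=1)),
        b.size, float(b.mean()), float(b.std(ddof=1)),
        alpha=alpha, exact_correction=exact_correction,
    )


def pearson_ci(x, y, alpha: float = 0.05):
    """Pearson correlation with a Fisher-z analytic CI.

    Returns ``(r, (lo, hi))``; requires n >= 4 and non-constant inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    r = float(pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zc = float(norm.ppf(1.0 - alpha / 2.0))
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return r, (float(lo), float(hi))


def cov_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100·σ/μ (undefined at μ = 0)."""
    if mean == 0:
        raise DegenerateDataError("CoV undefined for zero mean")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    return 100.0 * sd / mean


def summarize(values) -> GroupSummary:
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValidationError("summary needs n >= 2")
    return GroupSummary(int(v.size), float(v.mean()), float(v.std(ddof=1)))
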