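"""Statistical battery over decoding-score tables.

Thin, contract-checked wrappers around scipy's implementations of the
D'Agostino–Pearson K² normality test, one-sided one-sample t test and paired
t test, plus normal QQ data and the per-neuron score-ratio summaries used to
compare representations (aligned/original, warp/original).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[float]
    hypothesis: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def dagostino_k2(sample: Sequence[float]) -> TestResult:
    """D'Agostino & Pearson K² omnibus normality test (skewness + kurtosis).

    Requires n ≥ 20; K² is referred to a χ² distribution with 2 df.
    """
    x = np.asarray(sample, float)
    if x.size < 20:
        raise ValueError(f"normality test needs n ≥ 20, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    k2, p = sps.normaltest(x)
    return TestResult(float(k2), float(p), 2.0, "H0: sample is normally distributed")


def one_sample_t(
    sample: Sequence[float], mu0: float, alternative: str = "greater"
) -> TestResult:
    """One-sample t test of H0: μ = mu0 (one-sided 'greater' by default)."""
    x = np.asarray(sample, float)
    if x.size < 2:
        raise ValueError("need n ≥ 2")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    res = sps.ttest_1samp(x, popmean=mu0, alternative=alternative)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        float(x.size - 1),
        f"H0: mu = {mu0}, HA: mu {alternative}",
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided paired t test on the differences a − b; df = n − 1."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need n ≥ 2 pairs")
    if np.ptp(a - b) == 0:
        raise ValueError("differences have zero variance")
    res = sps.ttest_rel(a, b)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        float(a.size - 1),
        "H0: mean difference = 0 (two-sided)",
    )


def qq_points(sample: Sequence[float]):
    """Normal QQ data: theoretical N(0,1) quantiles at plotting positions
    (i − 0.5)/n against the empirical order statistics."""
    x = np.sort(np.asarray(sample, float))
    if x.size < 2:
        raise ValueError("need n ≥ 2")
    p = (np.arange(1, x.size + 1) - 0.5) / x.size
    return sps.norm.ppf(p), x


@dataclass(frozen=True)
class RatioSummary:
    ratios: np.ndarray
    mean_ratio: float


def ratio_summary(
    scores_original: Sequence[float], scores_variant: Sequence[float]
) -> RatioSummary:
    """Per-neuron variant/original score ratios and their mean.

    The mean of per-neuron ratios (not the ratio of mean scores) is reported,
    matching the paired neuron-by-neuron design of the comparisons.
    """
    orig = np.asarray(scores_original, float)
    var = np.asarray(scores_variant, float)
    if orig.shape != var.shape:
        raise ValueError("matched neuron lists required")
    if np.any(orig <= 0):
        raise ValueError("original scores must be positive to form ratios")
    r = var / orig
    return RatioSummary(ratios=r, mean_ratio=float(r.mean()))
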