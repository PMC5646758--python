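"""Inferential statistics: t tests with Cohen's d, Pearson correlation,
Steiger's Z for dependent correlations, and Cousineau within-subject SEs.

All p-values are two-tailed.  Cohen's d for one-sample/paired tests uses
the sample standard deviation (n-1 denominator), i.e. d = (mean - mu0)/SD,
so d can be reconstructed directly from printed means and SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DependentCorrComparison",
    "one_sample_t",
    "paired_t",
    "pearson_r",
    "steiger_z",
    "cousineau_se",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_two_tailed: float
    n: int
    effect_size_d: float | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class DependentCorrComparison:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z_statistic: float
    p_two_tailed: float


def _two_tailed_p(t: float, df: int) -> float:
    if math.isinf(t):
        return 0.0
    return float(2.0 * sps.t.sf(abs(t), df))


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """One-sample t test of mean(values) against mu0.

    t = (mean - mu0) / (sd / sqrt(n)) with sd the sample SD (ddof=1);
    d = (mean - mu0) / sd.  A zero-variance sample off mu0 reports an
    infinite statistic (overflow condition) with p = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    n = len(v)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == mu0:
            return TestResult(0.0, df, 1.0, n, effect_size_d=0.0, mean=mean, sd=sd)
        t = math.inf if mean > mu0 else -math.inf
        return TestResult(t, df, 0.0, n,
                          effect_size_d=math.copysign(math.inf, t), mean=mean, sd=sd)
    t = (mean - mu0) / (sd / math.sqrt(n))
    d = (mean - mu0) / sd
    return TestResult(t, df, _two_tailed_p(t, df), n, effect_size_d=d, mean=mean, sd=sd)


def paired_t(values_a, values_b) -> TestResult:
    """Paired-samples t test: one_sample_t on the differences a - b."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with its t test (df = n - 2)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx = np.std(xv, ddof=1)
    sy = np.std(yv, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant input")
    r = float(np.cov(xv, yv, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return TestResult(math.copysign(math.inf, r), df, 0.0, n, mean=r)
    t = r * math.sqrt(df / (1.0 - r * r))
    return TestResult(t, df, _two_tailed_p(t, df), n, mean=r)


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> DependentCorrComparison:
    """Steiger's Z for two dependent correlations sharing variable j.

    Uses the pooled-correlation form: with z1 = atanh(r_jk), z2 = atanh(r_jh)
    and rbar = (r_jk + r_jh)/2,

        psi  = r_kh (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_kh^2) / 2
        cov  = psi / (1 - rbar^2)^2
        Z    = (z1 - z2) sqrt((n - 3) / (2 - 2 cov))

    compared against the standard normal, two-tailed.
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(r_jk) == 1.0 or abs(r_jh) == 1.0:
        raise ValueError("Fisher transform diverges at |r| = 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z1 = math.atanh(r_jk)
    z2 = math.atanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    rbar2 = rbar * rbar
    psi = r_kh * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_kh * r_kh)
    cov = psi / (1.0 - rbar2) ** 2
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DependentCorrComparison(r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n,
                                   z_statistic=z, p_two_tailed=p)


def cousineau_se(matrix) -> np.ndarray:
    """Within-subject standard errors (Cousineau normalization).

    Each cell of the participants x conditions matrix is re-centered as
    value - participant_mean + grand_mean, removing between-participant
    offsets; the per-condition SE of the normalized values is returned.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 participants and >=2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (no missing cells)")
    normalized = m - m.mean(axis=1, keepdims=True) + m.mean()
    return normalized.std(axis=0, ddof=1) / math.sqrt(m.shape[0])
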