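"""Conventional fit indices (CFI, RMSEA, SRMR) and the chi-square-based BIC.

The BIC used for posterior model probabilities is computed from the model
chi-square, ``BIC = chisq + q ln(n)`` with ``q`` the free-parameter count.
It differs from a full-likelihood BIC only by a dataset-dependent additive
constant, which cancels in BIC *differences*, so posterior probabilities
are identical under either convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    rmsea: float
    srmr: float
    bic: float
    baseline_chisq: float
    baseline_df: int


def cfi(chisq: float, df: int, baseline_chisq: float, baseline_df: int) -> float:
    """Comparative fit index: proportionate reduction in (chisq - df)
    relative to the baseline model, clamped to [0, 1]."""
    num = max(chisq - df, 0.0)
    den = max(baseline_chisq - baseline_df, chisq - df, 0.0)
    if den == 0.0:
        return 1.0
    return min(max(1.0 - num / den, 0.0), 1.0)


def rmsea(chisq: float, df: int, n: int) -> float:
    """Root mean square error of approximation, ``sqrt(max(chisq-df,0)/(df(n-1)))``.

    A saturated model (df = 0) is assigned 0 by convention.
    """
    if df == 0:
        return 0.0
    if df < 0 or n <= 1:
        raise ValueError("df must be >= 0 and n > 1")
    return math.sqrt(max(chisq - df, 0.0) / (df * (n - 1)))


def srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Standardized root mean square residual over the unique covariance
    elements, standardized by the sample standard deviations."""
    s = np.asarray(sample_cov, dtype=float)
    sig = np.asarray(implied_cov, dtype=float)
    if s.shape != sig.shape or s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    d = np.sqrt(np.diag(s))
    if np.any(d <= 0):
        raise ValueError("sample variances must be positive")
    resid = (s - sig) / np.outer(d, d)
    iu = np.triu_indices(s.shape[0])
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def bic_from_chisq(chisq: float, df: int, n: int, p: int) -> float:
    """Chi-square-based BIC: ``chisq + q ln(n)`` with ``q = p(p+1)/2 - df``."""
    q = p * (p + 1) // 2 - df
    if q < 0:
        raise ValueError("df exceeds the number of unique moments")
    return chisq + q * math.log(n)


def bic_loglik(sample_cov: np.ndarray, implied_cov: np.ndarray, n: int, q: int) -> float:
    """Full-likelihood BIC (``-2 ln L + q ln n``), for cross-software
    comparison.  Uses the multivariate-normal likelihood at the ML solution
    with the ML (divisor ``n``) sample covariance.  Only differences between
    models on the same data are meaningful."""
    s = np.asarray(sample_cov, dtype=float)
    sig = np.asarray(implied_cov, dtype=float)
    p = s.shape[0]
    sign, logdet = np.linalg.slogdet(sig)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    minus2ll = n * (logdet + float(np.trace(np.linalg.solve(sig, s))) + p * math.log(2 * math.pi))
    return minus2ll + q * math.log(n)


def compute_indices(
    chisq: float,
    df: int,
    n: int,
    p: int,
    baseline_chisq: float,
    baseline_df: int,
    sample_cov: np.ndarray | None = None,
    implied_cov: np.ndarray | None = None,
) -> FitIndices:
    """Bundle CFI, RMSEA, SRMR and BIC for one fitted model."""
    srmr_val = math.nan
    if sample_cov is not None and implied_cov is not None:
        srmr_val = srmr(sample_cov, implied_cov)
    return FitIndices(
        cfi=cfi(chisq, df, baseline_chisq, baseline_df),
        rmsea=rmsea(chisq, df, n),
        srmr=srmr_val,
        bic=bic_from_chisq(chisq, df, n, p),
        baseline_chisq=baseline_chisq,
        baseline_df=baseline_df,
    )
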