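"""Heterogeneity statistics across per-SNP causal estimates.

Cochran's Q tests whether the single-SNP Wald ratios are consistent with
one common causal effect; I² = 100·(Q − df)/Q expresses the share of the
variation beyond chance. Excess heterogeneity is the usual signature of
pleiotropy or invalid instruments in summary-data MR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import EstimationError
from .summary_data import HarmonizedSet


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_value: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float

    def to_dict(self) -> dict:
        return {
            "Q": self.q,
            "df": self.df,
            "p_value": self.p_value,
            "I2_percent": self.i2,
            "I2_ci_low": self.i2_ci_low,
            "I2_ci_high": self.i2_ci_high,
        }


def _h_to_i2(h: float) -> float:
    """I² (%) from Higgins' H, truncated to [0, 100]."""
    h = max(1.0, h)
    return float(np.clip(100.0 * (h * h - 1.0) / (h * h), 0.0, 100.0))


def cochran_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios with IVW weights.

    With ratio_j = by_j/bx_j and w_j = (bx_j/se_y_j)²,
    Q = Σ w_j (ratio_j − β_IVW)² on n−1 df; the p-value is the chi-square
    upper tail and I² = max(0, 100·(Q − df)/Q). The I² confidence interval
    uses the test-based (Higgins–Thompson) closed form on log H = ½ log(Q/df).
    """
    n = len(hset)
    if n < 2:
        raise EstimationError(f"cochran_q requires >= 2 instruments, got {n}")
    bx, by, se_y = hset.bx, hset.by, hset.se_y
    if np.any(bx == 0):
        raise EstimationError("cochran_q: zero SNP-exposure coefficient present")
    ratios = by / bx
    w = (bx / se_y) ** 2
    beta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = n - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0

    # test-based CI for ln H (Higgins & Thompson 2002), truncated at H = 1
    if q > df:
        se_ln_h = 0.5 * (np.log(q) - np.log(df)) / (np.sqrt(2 * q) - np.sqrt(2 * df - 1))
    elif df > 1:
        se_ln_h = np.sqrt(1.0 / (2 * (df - 1)) * (1.0 - 1.0 / (3 * (df - 1) ** 2)))
    else:
        se_ln_h = np.inf  # df = 1 with Q <= df: interval is uninformative
    ln_h = np.log(max(1.0, np.sqrt(q / df))) if q > 0 else 0.0
    if np.isfinite(se_ln_h):
        lo = _h_to_i2(float(np.exp(ln_h - 1.96 * se_ln_h)))
        hi = _h_to_i2(float(np.exp(ln_h + 1.96 * se_ln_h)))
    else:
        lo, hi = 0.0, 100.0
    return HeterogeneityResult(q=q, df=df, p_value=p, i2=i2, i2_ci_low=lo, i2_ci_high=hi)
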