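"""Scale conversion and power for binary-trait MR estimates.

A causal estimate for a binary exposure is naturally "per 1-unit increase in
the log odds of the exposure", which is hard to read; multiplying the log
effect by ln 2 re-expresses it per *doubling of the odds* of the exposure.
The conventional rounded constant 0.693 is the default so published figures
reproduce digit-for-digit; exact ln 2 is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import stats

from .estimators import PER_DOUBLING, PER_UNIT, MREstimate

#: rounded doubling constant used in published analyses
DOUBLING_FACTOR = 0.693


class ScaleError(ValueError):
    """Invalid scale conversion request."""


def per_doubling(est: MREstimate, exact_ln2: bool = False) -> MREstimate:
    """Rescale an estimate from per-unit-log-odds to per-doubling-of-odds.

    beta, se and both CI endpoints are multiplied by 0.693 (or ln 2 when
    ``exact_ln2``); the p-value is untouched because the z-statistic is
    scale-invariant. On the OR scale this is OR_new = OR_old**0.693.
    """
    if est.scale == PER_DOUBLING:
        raise ScaleError("estimate is already on the per-doubling scale")
    c = float(np.log(2)) if exact_ln2 else DOUBLING_FACTOR
    return replace(
        est,
        beta=est.beta * c,
        se=est.se * c,
        ci_low=est.ci_low * c,
        ci_high=est.ci_high * c,
        scale=PER_DOUBLING,
    )


class ORResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def or_with_ci(est: MREstimate) -> ORResult:
    """Exponentiate an estimate and its CI onto the odds-ratio scale."""
    return ORResult(
        odds_ratio=float(np.exp(est.beta)),
        ci_low=float(np.exp(est.ci_low)),
        ci_high=float(np.exp(est.ci_high)),
        p_value=est.p_value,
    )


@dataclass(frozen=True)
class PowerInput:
    """Inputs for binary-outcome MR power.

    ``r2_exposure`` is the fraction (not percent) of exposure variance
    explained by the instruments; ``case_fraction`` is the outcome study's
    case proportion; ``or_alternative`` the effect size to detect.
    """

    n_outcome: int
    case_fraction: float
    r2_exposure: float
    or_alternative: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome < 1:
            raise ValueError("n_outcome must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 < self.r2_exposure < 1:
            raise ValueError("r2_exposure must be in (0, 1)")
        if not self.or_alternative > 0:
            raise ValueError("or_alternative must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_binary_outcome(inp: PowerInput) -> float:
    """Approximate power of summary-data MR with a binary outcome.

    Standard normal-approximation: the noncentrality is
    z = |ln OR| · sqrt(n · R² · k · (1 − k)) with k the case fraction, and
    power = Φ(z − z_{1−α/2}). Monotone increasing in n, R² and |ln OR|.
    """
    z = abs(np.log(inp.or_alternative)) * np.sqrt(
        inp.n_outcome * inp.r2_exposure * inp.case_fraction * (1 - inp.case_fraction)
    )
    return float(stats.norm.cdf(z - stats.norm.ppf(1 - inp.alpha / 2)))
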