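"""Causal-effect estimators for two-sample summary-data MR.

All estimators consume a :class:`~mrkit.summary_data.HarmonizedSet` whose
per-SNP coefficients are (bx_j, se_x_j) on the exposure and (by_j, se_y_j)
on the outcome, and return the causal effect of the exposure on the outcome
on the log-odds (or trait-unit) scale:

* ``wald_ratio`` — single-SNP ratio by/bx;
* ``ivw_fixed`` — fixed-effects inverse-variance-weighted mean of ratios,
  identical to the zero-intercept weighted regression of by on bx with
  weights 1/se_y²;
* ``ivw_random`` — DerSimonian–Laird additive random-effects version;
* ``ivw_correlated`` — generalized least squares with outcome covariance
  Ω_jk = se_y_j·se_y_k·r_jk for correlated instruments;
* ``ml_correlated`` — bivariate maximum likelihood treating the true
  SNP-exposure effects ξ_j as nuisance parameters (profile likelihood),
  also accepting a correlation matrix;
* ``mr_egger`` — weighted regression with a free intercept; the intercept
  estimates the average directional pleiotropic effect and tests the
  no-pleiotropy assumption, the slope is a pleiotropy-adjusted estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .instruments import LDMatrix
from .summary_data import HarmonizedInstrument, HarmonizedSet

Z95 = 1.96  # conventional normal multiplier for 95% intervals

PER_UNIT = "per_unit_log_odds"
PER_DOUBLING = "per_doubling"


class EstimationError(ValueError):
    """Estimator preconditions violated or numerical failure."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log scale with its uncertainty."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n_snps: int
    scale: str = PER_UNIT

    def __post_init__(self) -> None:
        if self.se < 0:
            raise EstimationError(f"negative se {self.se}")
        if not self.ci_low <= self.beta <= self.ci_high:
            raise EstimationError("CI does not bracket the point estimate")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "scale": self.scale,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": float(np.exp(self.ci_low)),
            "or_ci_high": float(np.exp(self.ci_high)),
        }


class EggerResult(NamedTuple):
    slope: MREstimate
    intercept: MREstimate


def _two_sided_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2 * stats.norm.sf(abs(beta) / se))


def _estimate(beta: float, se: float, method: str, n_snps: int, use_t_df: int | None = None) -> MREstimate:
    if use_t_df is not None:
        mult = float(stats.t.ppf(0.975, use_t_df))
        p = 1.0 if se == 0 and beta == 0 else (
            0.0 if se == 0 else float(2 * stats.t.sf(abs(beta) / se, use_t_df))
        )
    else:
        mult = Z95
        p = _two_sided_p(beta, se)
    return MREstimate(
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - mult * se),
        ci_high=float(beta + mult * se),
        p_value=p,
        method=method,
        n_snps=n_snps,
    )


def wald_ratio(inst: HarmonizedInstrument, se_method: str = "first_order") -> MREstimate:
    """Single-SNP causal estimate by/bx.

    ``first_order`` propagates outcome noise only (se_y/|bx|), matching the
    IVW weight construction; ``second_order`` adds the exposure-noise term
    by²·se_x²/bx⁴ under the delta method.
    """
    if inst.bx == 0:
        raise EstimationError(f"{inst.snp_id}: undefined ratio, bx = 0")
    beta = inst.by / inst.bx
    if se_method == "first_order":
        se = inst.se_y / abs(inst.bx)
    elif se_method == "second_order":
        se = np.sqrt(
            inst.se_y**2 / inst.bx**2 + inst.by**2 * inst.se_x**2 / inst.bx**4
        )
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return _estimate(beta, se, "wald", 1)


def _check_nonempty(hset: HarmonizedSet, n_min: int, method: str) -> None:
    if len(hset) < n_min:
        raise EstimationError(f"{method} requires >= {n_min} instruments, got {len(hset)}")
    if np.any(hset.bx == 0):
        raise EstimationError(f"{method}: zero SNP-exposure coefficient present")


def ivw_fixed(hset: HarmonizedSet) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate.

    beta = Σ bx_j by_j / se_y_j² over Σ bx_j² / se_y_j²; equal to the slope
    of the zero-intercept regression of by on bx with weights 1/se_y².
    """
    _check_nonempty(hset, 1, "ivw_fixed")
    bx, by, se_y = hset.bx, hset.by, hset.se_y
    info = np.sum(bx**2 / se_y**2)
    beta = np.sum(bx * by / se_y**2) / info
    se = 1.0 / np.sqrt(info)
    return _estimate(beta, se, "ivw_fixed", len(hset))


def ivw_random(hset: HarmonizedSet) -> MREstimate:
    """DerSimonian–Laird additive random-effects IVW over per-SNP ratios.

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) from the fixed-effects Q; when
    the ratios are homogeneous (τ² = 0) this equals :func:`ivw_fixed`.
    """
    _check_nonempty(hset, 2, "ivw_random")
    bx, by, se_y = hset.bx, hset.by, hset.se_y
    ratios = by / bx
    w = (bx / se_y) ** 2
    beta_fixed = np.sum(w * ratios) / np.sum(w)
    q = np.sum(w * (ratios - beta_fixed) ** 2)
    df = len(hset) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se_y**2 / bx**2 + tau2)
    beta = np.sum(w_star * ratios) / np.sum(w_star)
    se = 1.0 / np.sqrt(np.sum(w_star))
    return _estimate(beta, se, "ivw_random", len(hset))


def _outcome_covariance(hset: HarmonizedSet, ld: LDMatrix) -> np.ndarray:
    sub = ld.submatrix(hset.snp_ids)
    off = sub.r[~np.eye(len(hset), dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 0.999:
        raise EstimationError(
            "near-singular instrument correlation (|r| >= 0.999); prune the "
            "instrument set before correlated estimation"
        )
    se_y = hset.se_y
    return np.outer(se_y, se_y) * sub.r


def ivw_correlated(hset: HarmonizedSet, ld: LDMatrix) -> MREstimate:
    """Generalized least squares IVW for correlated instruments.

    With outcome covariance Ω_jk = se_y_j se_y_k r_jk,
    beta = (bxᵀΩ⁻¹bx)⁻¹ bxᵀΩ⁻¹by and se = sqrt((bxᵀΩ⁻¹bx)⁻¹). Reduces to
    :func:`ivw_fixed` for an identity correlation matrix.
    """
    _check_nonempty(hset, 1, "ivw_correlated")
    omega = _outcome_covariance(hset, ld)
    bx, by = hset.bx, hset.by
    oinv_bx = np.linalg.solve(omega, bx)
    info = bx @ oinv_bx
    beta = (oinv_bx @ by) / info
    se = 1.0 / np.sqrt(info)
    return _estimate(beta, se, "ivw_correlated", len(hset))


def _profile_loglik(beta: float, hset: HarmonizedSet, omega_inv: np.ndarray) -> float:
    """Log-likelihood profiled over the true SNP-exposure effects ξ.

    Model: bx ~ N(ξ, diag(se_x²)), by ~ N(β·ξ, Ω). For fixed β the
    maximizing ξ solves the linear system (Σx⁻¹ + β²Ω⁻¹)ξ = Σx⁻¹bx + βΩ⁻¹by.
    """
    bx, by, se_x = hset.bx, hset.by, hset.se_x
    sx_inv = 1.0 / se_x**2
    a = np.diag(sx_inv) + beta**2 * omega_inv
    rhs = sx_inv * bx + beta * (omega_inv @ by)
    xi = np.linalg.solve(a, rhs)
    rx = bx - xi
    ry = by - beta * xi
    return float(-0.5 * np.sum(rx**2 * sx_inv) - 0.5 * ry @ omega_inv @ ry)


def ml_correlated(hset: HarmonizedSet, ld: LDMatrix | None = None) -> MREstimate:
    """Maximum-likelihood causal estimate allowing correlated instruments.

    Exposure and outcome coefficients are modelled jointly: bx_j is a noisy
    measurement of the true effect ξ_j, and by_j has mean β·ξ_j with
    covariance Ω from the instrument correlation matrix. β is found by
    maximizing the likelihood profiled over ξ; its standard error comes from
    the curvature of the profile log-likelihood at the maximum (equal to the
    observed information for β). As se_x → 0 this converges to
    :func:`ivw_correlated`.
    """
    _check_nonempty(hset, 1, "ml_correlated")
    if ld is None:
        ld = LDMatrix.identity(hset.snp_ids)
    omega = _outcome_covariance(hset, ld)
    omega_inv = np.linalg.inv(omega)

    start = ivw_correlated(hset, ld).beta
    neg = lambda b: -_profile_loglik(b, hset, omega_inv)
    try:
        res = optimize.minimize_scalar(
            neg, bracket=(start - 1.0, start + 1.0), method="brent",
            options={"xtol": 1e-10, "maxiter": 500},
        )
    except (RuntimeError, ValueError):
        res = optimize.minimize_scalar(
            neg, bounds=(start - 50.0, start + 50.0), method="bounded",
            options={"xatol": 1e-10},
        )
    if not res.success or not np.isfinite(res.x):
        raise EstimationError(f"ml_correlated failed to converge: {res}")
    beta_hat = float(res.x)

    h = max(1e-5, 1e-4 * abs(beta_hat))
    curv = (neg(beta_hat + h) + neg(beta_hat - h) - 2 * neg(beta_hat)) / h**2
    if curv <= 0:
        raise EstimationError(
            f"ml_correlated: non-positive observed information ({curv:.3g}) at optimum"
        )
    se = 1.0 / np.sqrt(curv)
    return _estimate(beta_hat, se, "ml_correlated", len(hset))


def _orient(hset: HarmonizedSet) -> HarmonizedSet:
    """Flip instruments so every SNP-exposure coefficient is non-negative."""
    flipped = [
        replace(i, bx=-i.bx, by=-i.by) if i.bx < 0 else i for i in hset.instruments
    ]
    return HarmonizedSet(flipped, hset.exposure_label, hset.outcome_label)


def mr_egger(hset: HarmonizedSet, use_t: bool = False) -> EggerResult:
    """MR-Egger regression: weighted fit of by = α + β·bx with weights 1/se_y².

    Instruments are first oriented so all bx ≥ 0 (negating both coefficients
    where needed), making the fit invariant to arbitrary pre-flips. The
    intercept α estimates the average directional pleiotropic effect — its
    p-value is the pleiotropy test — and the slope is a causal estimate
    robust to directional pleiotropy under the InSIDE assumption. Standard
    errors use the estimated residual scale (multiplicative overdispersion);
    ``use_t`` switches the reference distribution from normal to t(n−2).
    """
    if len(hset) < 3:
        raise EstimationError(f"mr_egger requires >= 3 instruments, got {len(hset)}")
    oriented = _orient(hset)
    bx, by, se_y = oriented.bx, oriented.by, oriented.se_y
    if np.ptp(bx) == 0:
        raise EstimationError("mr_egger: all SNP-exposure coefficients equal (collinear)")

    w = 1.0 / se_y**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    n = len(hset)
    sigma2 = float(np.sum(w * resid**2) / (n - 2))
    cov = sigma2 * np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov))
    df = n - 2 if use_t else None
    slope = _estimate(coef[1], se_slope, "egger_slope", n, use_t_df=df)
    intercept = _estimate(coef[0], se_int, "egger_intercept", n, use_t_df=df)
    return EggerResult(slope=slope, intercept=intercept)
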