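"""Synthetic two-sample summary statistics with known ground truth.

The generator draws per-SNP true exposure effects ξ_j, optional pleiotropic
effects α_j, and observed coefficients

    bx_j = ξ_j + εx_j,   by_j = β·ξ_j + α_j + εy_j,

with independent exposure-side and outcome-side Gaussian noise at the
configured standard errors (the two-sample assumption) and, when an LD
matrix is supplied, noise drawn jointly with covariance
Ω_jk = se_j·se_k·r_jk. Pleiotropy is drawn independently of ξ by default, so
the InSIDE condition holds by construction; ``inside_violation`` correlates
α with ξ to stress-test MR-Egger's failure mode.

Defaults emulate an analysis built on strongly associated, genome-wide
significant instruments: |ξ| ≈ 0.1 on the log-odds scale with exposure
standard errors of 0.003 (per-SNP F ≈ 10³) and outcome standard errors of
0.013 as in a large case-control GWAS. See docs/methods.md for what these
choices do and do not emulate.

``table1_fixture`` provides the package's worked four-SNP example: the BDNF
region instruments for smoking initiation with their schizophrenia outcome
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .summary_data import AssociationRecord, HarmonizedInstrument, HarmonizedSet

_SE_FLOOR = 1e-12  # reported SE when a noise sd of exactly 0 is requested
_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"))

PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-sample dataset."""

    n_snps: int = 50
    true_beta: float = 0.0
    #: (mean, sd) of the true SNP-exposure effects ξ_j
    bx_distribution: tuple[float, float] = (0.1, 0.03)
    se_x: float | Sequence[float] = 0.003
    se_y: float | Sequence[float] = 0.013
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.005
    pleiotropy_mean: float = 0.01
    #: correlation between α_j and ξ_j; nonzero breaks InSIDE
    inside_violation: float = 0.0
    ld: LDMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if self.bx_distribution[1] < 0 or self.pleiotropy_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1 <= self.inside_violation <= 1:
            raise ValueError("inside_violation must be a correlation in [-1, 1]")
        for name in ("se_x", "se_y"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            if v.size not in (1, self.n_snps):
                raise ValueError(f"{name} must be scalar or length n_snps")
        if self.ld is not None and len(self.ld) != self.n_snps:
            raise ValueError(
                f"LD matrix dimension {len(self.ld)} does not match n_snps {self.n_snps}"
            )


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    true_beta: float
    xi: np.ndarray
    alpha: np.ndarray
    seed: int


def _per_snp(value, n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    return np.full(n, arr[0]) if arr.size == 1 else arr.copy()


def _correlated_noise(rng: np.random.Generator, se: np.ndarray, ld: LDMatrix | None) -> np.ndarray:
    z = rng.standard_normal(se.size)
    if ld is None:
        return se * z
    r = ld.r + 1e-10 * np.eye(len(ld))  # jitter guards exact singularity
    return se * (np.linalg.cholesky(r) @ z)


def _draw(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_snps
    mu, sd = cfg.bx_distribution
    xi = rng.normal(mu, sd, n)

    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(n)
    else:
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        z_ind = rng.standard_normal(n)
        if cfg.inside_violation != 0.0 and sd > 0:
            z_xi = (xi - mu) / sd
            rho = cfg.inside_violation
            z = rho * z_xi + np.sqrt(1 - rho**2) * z_ind
        else:
            z = z_ind
        alpha = mean + cfg.pleiotropy_sd * z

    se_x = _per_snp(cfg.se_x, n)
    se_y = _per_snp(cfg.se_y, n)
    bx = xi + _correlated_noise(rng, se_x, cfg.ld)
    by = cfg.true_beta * xi + alpha + _correlated_noise(rng, se_y, cfg.ld)
    return xi, alpha, bx, by, np.maximum(se_x, _SE_FLOOR), np.maximum(se_y, _SE_FLOOR)


def _snp_ids(cfg: SimulationConfig) -> list[str]:
    if cfg.ld is not None:
        return list(cfg.ld.snp_ids)
    return [f"rs{1000000 + i}" for i in range(cfg.n_snps)]


def simulate_harmonized(cfg: SimulationConfig) -> tuple[HarmonizedSet, SimulationTruth]:
    """Simulate directly into a harmonized instrument set (fast path)."""
    rng = np.random.default_rng(cfg.seed)
    xi, alpha, bx, by, se_x, se_y = _draw(cfg, rng)
    ids = _snp_ids(cfg)
    instruments = [
        HarmonizedInstrument(
            snp_id=ids[j],
            effect_allele=_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0],
            bx=float(bx[j]),
            se_x=float(se_x[j]),
            by=float(by[j]),
            se_y=float(se_y[j]),
        )
        for j in range(cfg.n_snps)
    ]
    hset = HarmonizedSet(instruments, "simulated_exposure", "simulated_outcome")
    return hset, SimulationTruth(cfg.true_beta, xi, alpha, cfg.seed)


def _p_from(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, 1e-300)


def simulate_two_sample(
    cfg: SimulationConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], SimulationTruth]:
    """Simulate paired exposure/outcome summary-statistic records.

    Allele labels are assigned arbitrarily but consistently across the two
    studies (non-palindromic pairs, so harmonization is exact); identical
    configs produce bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    xi, alpha, bx, by, se_x, se_y = _draw(cfg, rng)
    eaf = rng.uniform(0.1, 0.9, cfg.n_snps)
    ids = _snp_ids(cfg)
    px = _p_from(bx, se_x)
    py = _p_from(by, se_y)

    exposure, outcome = [], []
    for j in range(cfg.n_snps):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        common = dict(
            snp_id=ids[j],
            chromosome="1",
            position=1000 * (j + 1),
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eaf[j]),
        )
        exposure.append(
            AssociationRecord(
                beta=float(bx[j]), se=float(se_x[j]), p_value=float(px[j]),
                trait_label="simulated_exposure", **common,
            )
        )
        outcome.append(
            AssociationRecord(
                beta=float(by[j]), se=float(se_y[j]), p_value=float(py[j]),
                trait_label="simulated_outcome", **common,
            )
        )
    return exposure, outcome, SimulationTruth(cfg.true_beta, xi, alpha, cfg.seed)


# --- worked four-SNP example (BDNF region instruments) ---------------------

_TABLE1 = (
    # snp, chrom, pos, effect allele, eaf, bx, se_x, p_x, by, se_y, p_y
    ("rs6265", "11", 27636492, "T", 0.21, -0.061, 0.011, 1.8e-8, -0.052, 0.013, 8e-5),
    ("rs4923460", "11", 27613365, "T", 0.23, -0.058, 0.011, 4.1e-8, -0.045, 0.013, 4.2e-4),
    ("rs1304100", "11", 27528179, "A", 0.74, 0.055, 0.01, 4.4e-8, 0.038, 0.013, 2.7e-3),
    ("rs6484320", "11", 27659764, "A", 0.76, 0.057, 0.01, 4.9e-8, 0.043, 0.013, 7.5e-4),
)
_OTHER_ALLELE = {"T": "C", "A": "G"}


def table1_fixture() -> HarmonizedSet:
    """The four smoking-initiation instruments with schizophrenia outcomes."""
    instruments = [
        HarmonizedInstrument(
            snp_id=snp, effect_allele=ea, bx=bx, se_x=se_x, by=by, se_y=se_y,
        )
        for snp, _c, _p, ea, _f, bx, se_x, _px, by, se_y, _py in _TABLE1
    ]
    return HarmonizedSet(instruments, "smoking_initiation", "schizophrenia")


def table1_records() -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """The same four SNPs as raw exposure/outcome association records."""
    exposure, outcome = [], []
    for snp, chrom, pos, ea, eaf, bx, se_x, px, by, se_y, py in _TABLE1:
        common = dict(
            snp_id=snp, chromosome=chrom, position=pos,
            effect_allele=ea, other_allele=_OTHER_ALLELE[ea], eaf=eaf,
        )
        exposure.append(
            AssociationRecord(beta=bx, se=se_x, p_value=px,
                              trait_label="smoking_initiation", **common)
        )
        outcome.append(
            AssociationRecord(beta=by, se=se_y, p_value=py,
                              trait_label="schizophrenia", **common)
        )
    return exposure, outcome
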