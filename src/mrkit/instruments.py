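"""LD-aware instrument selection: correlation matrices, pruning, proxies.

Instruments for summary-data MR are ideally independent; variants in strong
linkage disequilibrium carry almost no extra information and destabilize the
estimation. This module prunes pairs correlated beyond an r² threshold
(keeping a random member of each pair, stepwise) and substitutes high-LD
proxies for instruments missing from the outcome study. LD comes from a
locally supplied signed correlation matrix — signed r is required downstream
by the correlated-instrument estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-8


class LDError(ValueError):
    """Invalid LD matrix or missing SNP coverage."""


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r) among a set of SNPs.

    Symmetric, unit diagonal, positive semidefinite within ``1e-8``.
    """

    snp_ids: tuple[str, ...]
    r: np.ndarray

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        self.snp_ids = tuple(str(s) for s in snp_ids)
        self.r = np.asarray(r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise LDError(f"matrix shape {self.r.shape} does not match {n} SNP ids")
        if len(set(self.snp_ids)) != n:
            raise LDError("duplicate SNP ids in LD matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise LDError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise LDError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise LDError("correlations must lie in [-1, 1]")
        if n and np.linalg.eigvalsh(self.r).min() < -_PSD_TOL:
            raise LDError("correlation matrix not positive semidefinite")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    # -- construction -----------------------------------------------------
    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(snp_ids, np.eye(len(snp_ids)))

    @classmethod
    def exchangeable(cls, snp_ids: Sequence[str], rho: float) -> "LDMatrix":
        n = len(snp_ids)
        r = np.full((n, n), float(rho))
        np.fill_diagonal(r, 1.0)
        return cls(snp_ids, r)

    @classmethod
    def from_r2(cls, snp_ids: Sequence[str], r2: np.ndarray) -> "LDMatrix":
        """Build from unsigned r²; signs are assumed positive (warned)."""
        logger.warning("LD supplied as r2 only; assuming all correlations positive")
        return cls(snp_ids, np.sqrt(np.clip(np.asarray(r2, dtype=float), 0, 1)))

    @classmethod
    def read(cls, path, sep: str | None = None) -> "LDMatrix":
        """Read a square matrix file whose header row holds the rsIDs."""
        df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write(self, path, sep: str = "\t") -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep=sep)

    # -- access -----------------------------------------------------------
    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __len__(self) -> int:
        return len(self.snp_ids)

    def pair_r(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def pair_r2(self, a: str, b: str) -> float:
        return self.pair_r(a, b) ** 2

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        """Sub-correlation matrix in the given SNP order."""
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise LDError(f"SNP(s) absent from LD matrix: {missing}")
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(snp_ids, self.r[np.ix_(idx, idx)])


def prune_ld(
    snps: Iterable[str],
    ld: LDMatrix,
    r2_threshold: float = 0.9,
    seed: int = 0,
) -> list[str]:
    """Stepwise prune SNP pairs correlated at r² >= ``r2_threshold``.

    Repeatedly finds the first offending pair (scanning pairs in
    lexicographic rsID order), keeps one member chosen uniformly at random
    with the seeded generator, and drops the other, until no pair remains
    above the threshold. Deterministic given ``seed``; the result is
    returned sorted lexicographically and is invariant to input order.
    """
    snps = list(snps)
    if not 0 < r2_threshold <= 1:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    missing = [s for s in snps if s not in ld]
    if missing:
        raise LDError(f"SNP(s) absent from LD matrix: {missing}")

    rng = np.random.default_rng(seed)
    retained = sorted(set(snps))
    while True:
        offending = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                if ld.pair_r2(retained[i], retained[j]) >= r2_threshold:
                    offending = (retained[i], retained[j])
                    break
            if offending:
                break
        if offending is None:
            return retained
        drop = offending[int(rng.integers(2))]
        retained.remove(drop)


def find_proxies(
    wanted: Iterable[str],
    available: Iterable[str],
    ld: LDMatrix,
    r2_min: float = 0.9,
) -> dict[str, str | None]:
    """Map each wanted SNP to itself or its best available proxy.

    A wanted SNP already in ``available`` maps to itself. Otherwise it maps
    to the available SNP with maximal r², provided r² strictly exceeds
    ``r2_min`` (ties broken by the lexicographically smallest rsID); SNPs
    with no qualifying proxy map to ``None``.
    """
    wanted = list(wanted)
    avail = sorted(set(available))
    missing = [s for s in [*wanted, *avail] if s not in ld]
    if missing:
        raise LDError(f"SNP(s) absent from LD matrix: {sorted(set(missing))}")

    mapping: dict[str, str | None] = {}
    avail_set = set(avail)
    for snp in wanted:
        if snp in avail_set:
            mapping[snp] = snp
            continue
        best: str | None = None
        best_r2 = r2_min
        for cand in avail:  # sorted: ties resolve to smallest rsID
            r2 = ld.pair_r2(snp, cand)
            if r2 > best_r2:
                best, best_r2 = cand, r2
        mapping[snp] = best
    return mapping
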