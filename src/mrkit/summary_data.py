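"""GWAS summary-statistics data model, I/O and allele harmonization.

Two-sample Mendelian randomization combines per-SNP association estimates
from an exposure study and an outcome study. Before any estimation the two
sets of coefficients must be expressed on a *common effect allele*: the
outcome beta is sign-flipped whenever its study reported the effect for the
opposite allele (directly or on the opposite strand), and palindromic
(A/T, G/C) variants — where strand cannot be resolved from allele labels —
are oriented by allele frequency or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names for :func:`read_summary_stats`
DEFAULT_COLUMNS = {
    "snp_id": "snp",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p_value": "p",
}

_REQUIRED_FIELDS = (
    "snp_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p_value",
)


class SummaryDataError(ValueError):
    """Invalid summary-statistics input (configuration or row level)."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's estimated association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait —
    a log odds ratio for binary traits, trait units otherwise. ``eaf`` is
    the effect-allele frequency, used only to orient palindromic variants.
    """

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p_value: float
    eaf: float | None = None
    trait_label: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise SummaryDataError(
                f"{self.snp_id}: alleles must be single nucleotides, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise SummaryDataError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not 0 < self.p_value <= 1:
            raise SummaryDataError(f"{self.snp_id}: p-value {self.p_value} outside (0, 1]")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise SummaryDataError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")

    @property
    def palindromic(self) -> bool:
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP's exposure and outcome effects on a common effect allele."""

    snp_id: str
    effect_allele: str
    bx: float
    se_x: float
    by: float
    se_y: float
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise SummaryDataError(
                f"{self.snp_id}: standard errors must be positive "
                f"(se_x={self.se_x}, se_y={self.se_y})"
            )


@dataclass
class HarmonizedSet:
    """Ordered collection of harmonized instruments for one analysis direction."""

    instruments: list[HarmonizedInstrument]
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    #: per-SNP harmonization log with columns (snp, action, reason)
    report: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [i.snp_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise SummaryDataError("duplicate snp_ids in harmonized set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    @property
    def bx(self) -> np.ndarray:
        return np.array([i.bx for i in self.instruments], dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return np.array([i.se_x for i in self.instruments], dtype=float)

    @property
    def by(self) -> np.ndarray:
        return np.array([i.by for i in self.instruments], dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return np.array([i.se_y for i in self.instruments], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        snp_ids: Sequence[str],
        bx: Sequence[float],
        se_x: Sequence[float],
        by: Sequence[float],
        se_y: Sequence[float],
        effect_alleles: Sequence[str] | None = None,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ) -> "HarmonizedSet":
        if effect_alleles is None:
            effect_alleles = ["A"] * len(snp_ids)
        instruments = [
            HarmonizedInstrument(s, a, float(x), float(sx), float(y), float(sy))
            for s, a, x, sx, y, sy in zip(snp_ids, effect_alleles, bx, se_x, by, se_y)
        ]
        return cls(instruments, exposure_label, outcome_label)

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        keep = set(snp_ids)
        return HarmonizedSet(
            [i for i in self.instruments if i.snp_id in keep],
            self.exposure_label,
            self.outcome_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "effect_allele": [i.effect_allele for i in self.instruments],
                "bx": self.bx,
                "se_x": self.se_x,
                "by": self.by,
                "se_y": self.se_y,
                "flipped": [i.flipped for i in self.instruments],
                "palindromic": [i.palindromic for i in self.instruments],
            }
        )


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    trait_label: str = "",
) -> list[AssociationRecord]:
    """Read a delimited summary-statistics table into association records.

    ``column_map`` maps record fields (``snp_id``, ``beta``, ``se`` ...) to
    the file's column names; unspecified fields fall back to
    :data:`DEFAULT_COLUMNS`. Rows whose beta or SE cannot be parsed, or whose
    SE is non-positive, are rejected and counted in a single warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", dtype=str)
    missing = [cols[f] for f in _REQUIRED_FIELDS if cols[f] not in df.columns]
    if missing:
        raise SummaryDataError(f"{path}: missing required column(s) {missing}")
    has_eaf = cols["eaf"] in df.columns

    records: list[AssociationRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        r = dict(zip(df.columns, row))
        try:
            beta = float(r[cols["beta"]])
            se = float(r[cols["se"]])
            if not np.isfinite(beta) or not np.isfinite(se):
                raise ValueError("non-finite beta/se")
            eaf_raw = r.get(cols["eaf"]) if has_eaf else None
            eaf = None
            if eaf_raw is not None and str(eaf_raw).upper() not in ("", "NA", "NAN", "."):
                eaf = float(eaf_raw)
            records.append(
                AssociationRecord(
                    snp_id=str(r[cols["snp_id"]]),
                    chromosome=str(r[cols["chromosome"]]),
                    position=int(float(r[cols["position"]])),
                    effect_allele=str(r[cols["effect_allele"]]).upper(),
                    other_allele=str(r[cols["other_allele"]]).upper(),
                    beta=beta,
                    se=se,
                    p_value=float(r[cols["p_value"]]),
                    eaf=eaf,
                    trait_label=trait_label,
                )
            )
        except (ValueError, SummaryDataError) as exc:
            n_rejected += 1
            logger.debug("rejected row %r: %s", r.get(cols["snp_id"]), exc)
    if n_rejected:
        logger.warning("%s: rejected %d row(s) with invalid beta/SE", path, n_rejected)
    return records


def write_summary_stats(records: Iterable[AssociationRecord], path, sep: str = "\t") -> None:
    """Write records in the same delimited layout :func:`read_summary_stats` reads."""
    df = pd.DataFrame(
        {
            "snp": [r.snp_id for r in records],
            "chr": [r.chromosome for r in records],
            "pos": [r.position for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.p_value for r in records],
        }
    )
    # NA (not empty) for missing values: empty fields are ambiguous under a
    # whitespace separator
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def _ambiguous_freq(eaf: float | None, tol: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= tol


def harmonize(
    exposure: Iterable[AssociationRecord],
    outcome: Iterable[AssociationRecord],
    drop_ambiguous_palindromes: bool = True,
    eaf_tolerance: float = 0.08,
    exposure_label: str | None = None,
    outcome_label: str | None = None,
) -> HarmonizedSet:
    """Align outcome effects onto each exposure record's effect allele.

    For every SNP present in both studies the outcome beta is copied when the
    effect alleles agree, negated when the outcome study reported the opposite
    allele (matched directly or via strand complement), and otherwise the SNP
    is dropped as an allele mismatch. Palindromic variants are oriented by
    comparing effect-allele frequencies to 0.5 when both are available and
    both fall outside ``0.5 ± eaf_tolerance``; unresolvable palindromes are
    dropped when ``drop_ambiguous_palindromes`` is set, else kept as labeled.

    The returned set's ``report`` lists every shared SNP with the action
    taken (``kept``/``dropped``) and a reason.
    """
    exp_by_id = {r.snp_id: r for r in exposure}
    out_by_id = {r.snp_id: r for r in outcome}
    shared = [s for s in exp_by_id if s in out_by_id]

    instruments: list[HarmonizedInstrument] = []
    log_rows: list[tuple[str, str, str]] = []
    for snp in shared:
        ex, ou = exp_by_id[snp], out_by_id[snp]
        exp_alleles = (ex.effect_allele, ex.other_allele)
        out_alleles = (ou.effect_allele, ou.other_allele)
        comp_out = (_COMPLEMENT[ou.effect_allele], _COMPLEMENT[ou.other_allele])

        if out_alleles == exp_alleles or comp_out == exp_alleles:
            flipped = False
        elif out_alleles == exp_alleles[::-1] or comp_out == exp_alleles[::-1]:
            flipped = True
        else:
            log_rows.append((snp, "dropped", "allele mismatch"))
            continue

        by = -ou.beta if flipped else ou.beta
        out_eaf = ou.eaf
        if out_eaf is not None and flipped:
            out_eaf = 1.0 - out_eaf
        reason = "alleles aligned"

        if ex.palindromic:
            # allele labels cannot fix strand; orient by frequency
            if _ambiguous_freq(ex.eaf, eaf_tolerance) or _ambiguous_freq(out_eaf, eaf_tolerance):
                if drop_ambiguous_palindromes:
                    log_rows.append((snp, "dropped", "ambiguous palindromic SNP"))
                    continue
                reason = "palindromic, frequency ambiguous, kept as labeled"
            elif (ex.eaf < 0.5) != (out_eaf < 0.5):
                by = -by
                flipped = not flipped
                reason = "palindromic, oriented by allele frequency"
            else:
                reason = "palindromic, frequencies concordant"

        instruments.append(
            HarmonizedInstrument(
                snp_id=snp,
                effect_allele=ex.effect_allele,
                bx=ex.beta,
                se_x=ex.se,
                by=by,
                se_y=ou.se,
                flipped=flipped,
                palindromic=ex.palindromic,
            )
        )
        log_rows.append((snp, "kept", reason))

    report = pd.DataFrame(log_rows, columns=["snp", "action", "reason"])

    def first_label(records: dict, fallback: str) -> str:
        for r in records.values():
            if r.trait_label:
                return r.trait_label
        return fallback

    exp_label = exposure_label or first_label(exp_by_id, "exposure")
    out_label = outcome_label or first_label(out_by_id, "outcome")
    return HarmonizedSet(instruments, exp_label, out_label, report=report)
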