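"""End-to-end analysis pipeline driven by a YAML config.

Orchestrates one direction of a bidirectional two-sample MR analysis:
read summary statistics → filter instruments by exposure p-value →
LD-prune → harmonize → estimate (primary + sensitivity) → convert scales →
write a report (delimited tables + machine-readable JSON) including a
per-SNP forest table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import EstimationError, MREstimate, wald_ratio
from .heterogeneity import HeterogeneityResult
from .instruments import LDMatrix, prune_ld
from .interpret import or_with_ci, per_doubling
from .model import MRModel
from .summary_data import HarmonizedSet, harmonize, read_summary_stats

logger = logging.getLogger(__name__)

_DEFAULT_ESTIMATORS = ("ivw_fixed", "ivw_random", "egger")


class PipelineError(RuntimeError):
    """Unrecoverable pipeline failure (bad config, no instruments ...)."""


@dataclass
class AnalysisConfig:
    """One analysis direction: files, thresholds and estimator choices."""

    exposure_file: str
    outcome_file: str
    direction: str = "exposure->outcome"
    ld_file: str | None = None
    p_threshold: float = 5e-8
    r2_prune: float = 0.9
    estimators: tuple[str, ...] = ()
    seed: int = 0
    output_dir: str = "mr_output"
    drop_ambiguous_palindromes: bool = True
    eaf_tolerance: float = 0.08
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_threshold", "r2_prune"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise PipelineError(f"{name} must be in (0, 1], got {v}")
        for name in ("exposure_file", "outcome_file", "ld_file"):
            v = getattr(self, name)
            if v is not None and not Path(v).exists():
                raise PipelineError(f"{name} does not exist: {v}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "estimators" in raw:
            raw["estimators"] = tuple(raw["estimators"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Everything one pipeline run produced."""

    direction: str
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    per_snp: pd.DataFrame
    harmonization: pd.DataFrame
    counts: dict
    skipped: dict
    seed: int
    version: str = __version__

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.estimates])

    def to_json_dict(self) -> dict:
        return {
            "direction": self.direction,
            "version": self.version,
            "seed": self.seed,
            "counts": self.counts,
            "skipped": self.skipped,
            "estimates": [e.to_dict() for e in self.estimates],
            "heterogeneity": self.heterogeneity.to_dict() if self.heterogeneity else None,
            "per_snp": self.per_snp.to_dict(orient="records"),
        }


def per_snp_estimates(hset: HarmonizedSet) -> pd.DataFrame:
    """Forest-table rows: one Wald-ratio estimate per SNP on the OR scale.

    SNPs with a zero exposure coefficient are flagged in the ``note``
    column rather than dropped.
    """
    if len(hset) == 0:
        raise PipelineError("per_snp_estimates: empty instrument set")
    rows = []
    for inst in hset:
        row = {
            "snp": inst.snp_id,
            "bx": inst.bx, "se_x": inst.se_x,
            "by": inst.by, "se_y": inst.se_y,
            "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p_value": np.nan, "note": "",
        }
        try:
            o = or_with_ci(wald_ratio(inst))
            row.update(
                odds_ratio=o.odds_ratio, ci_low=o.ci_low,
                ci_high=o.ci_high, p_value=o.p_value,
            )
        except EstimationError:
            row["note"] = "undefined ratio (bx = 0)"
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(cfg: AnalysisConfig, write: bool = True) -> AnalysisReport:
    """Run one analysis direction; deterministic given config and seed."""
    exposure = read_summary_stats(cfg.exposure_file, column_map=cfg.exposure_columns)
    outcome = read_summary_stats(cfg.outcome_file, column_map=cfg.outcome_columns)
    counts = {"exposure_read": len(exposure), "outcome_read": len(outcome)}

    selected = [r for r in exposure if r.p_value < cfg.p_threshold]
    counts["p_filtered"] = len(selected)
    logger.info("%d/%d exposure SNPs pass p < %g", len(selected), len(exposure), cfg.p_threshold)
    if not selected:
        raise PipelineError(
            f"no exposure SNP passes p < {cfg.p_threshold}; "
            "relax p_threshold or check the exposure file"
        )

    ld = LDMatrix.read(cfg.ld_file) if cfg.ld_file else None
    if ld is not None:
        kept = set(prune_ld([r.snp_id for r in selected], ld, cfg.r2_prune, cfg.seed))
        selected = [r for r in selected if r.snp_id in kept]
    counts["after_prune"] = len(selected)

    hset = harmonize(
        selected, outcome,
        drop_ambiguous_palindromes=cfg.drop_ambiguous_palindromes,
        eaf_tolerance=cfg.eaf_tolerance,
    )
    counts["harmonized"] = len(hset)
    if len(hset) == 0:
        raise PipelineError("no instruments survive harmonization")

    requested = list(cfg.estimators) or list(_DEFAULT_ESTIMATORS) + (
        ["ivw_correlated", "ml_correlated"] if ld is not None else []
    )
    model = MRModel(hset, ld=ld.submatrix(hset.snp_ids) if ld is not None else None)
    results = model.fit(requested, skip_failures=True)
    for name, reason in results.skipped.items():
        logger.info("estimator %s skipped: %s", name, reason)

    estimates = list(results.estimates.values())
    estimates += [
        per_doubling(e) for e in results.estimates.values()
        if e.method != "egger_intercept"
    ]
    counts["analyzed"] = len(hset)

    report = AnalysisReport(
        direction=cfg.direction,
        estimates=estimates,
        heterogeneity=results.heterogeneity,
        per_snp=per_snp_estimates(hset),
        harmonization=hset.report if hset.report is not None else pd.DataFrame(),
        counts=counts,
        skipped=results.skipped,
        seed=cfg.seed,
    )
    if write:
        _write_report(report, Path(cfg.output_dir))
    return report


def _write_report(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.estimates_frame().to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    report.per_snp.to_csv(out_dir / "per_snp.tsv", sep="\t", index=False)
    report.harmonization.to_csv(out_dir / "harmonization.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    logger.info("report written to %s", out_dir)
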