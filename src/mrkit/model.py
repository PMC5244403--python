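"""Model/Results facade over the estimator modules.

:class:`MRModel` is built from a harmonized instrument set (optionally with
an LD matrix); ``fit`` runs one or several estimators and returns an
:class:`MRResults` carrying the estimates, heterogeneity diagnostics, the
per-SNP Wald table and a formatted summary. Example::

    >>> from mrkit import MRModel, synthetic
    >>> res = MRModel(synthetic.table1_fixture()).fit("all")
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import EstimationError, MREstimate
from .heterogeneity import HeterogeneityResult, cochran_q
from .instruments import LDMatrix
from .interpret import or_with_ci, per_doubling
from .summary_data import AssociationRecord, HarmonizedSet, harmonize

#: estimators runnable without an LD matrix / with one
_UNCORRELATED = ("ivw_fixed", "ivw_random", "egger")
_CORRELATED = ("ivw_correlated", "ml_correlated")


class MRModel:
    """Two-sample summary-data Mendelian randomization model.

    Parameters
    ----------
    data
        Harmonized instrument set (exposure and outcome coefficients on a
        common effect allele).
    ld
        Optional signed SNP correlation matrix covering the instruments;
        enables the correlated-instrument estimators.
    """

    def __init__(self, data: HarmonizedSet, ld: LDMatrix | None = None):
        if len(data) == 0:
            raise EstimationError("empty instrument set")
        self.data = data
        self.ld = ld

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        snp: str = "snp",
        bx: str = "bx",
        se_x: str = "se_x",
        by: str = "by",
        se_y: str = "se_y",
        ld: LDMatrix | None = None,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ) -> "MRModel":
        hset = HarmonizedSet.from_arrays(
            df[snp].astype(str).tolist(),
            df[bx], df[se_x], df[by], df[se_y],
            exposure_label=exposure_label, outcome_label=outcome_label,
        )
        return cls(hset, ld=ld)

    @classmethod
    def from_records(
        cls,
        exposure: Iterable[AssociationRecord],
        outcome: Iterable[AssociationRecord],
        ld: LDMatrix | None = None,
        **harmonize_kwargs,
    ) -> "MRModel":
        """Harmonize raw exposure/outcome records and build the model."""
        return cls(harmonize(exposure, outcome, **harmonize_kwargs), ld=ld)

    # -- fitting ----------------------------------------------------------
    def _run(self, method: str, **kwargs) -> dict[str, MREstimate]:
        if method == "ivw_fixed":
            return {"ivw_fixed": est.ivw_fixed(self.data)}
        if method == "ivw_random":
            return {"ivw_random": est.ivw_random(self.data)}
        if method == "egger":
            egger = est.mr_egger(self.data, **kwargs)
            return {"egger_slope": egger.slope, "egger_intercept": egger.intercept}
        if method in _CORRELATED:
            if self.ld is None:
                raise EstimationError(f"{method} requires an LD matrix")
            fn = est.ivw_correlated if method == "ivw_correlated" else est.ml_correlated
            return {method: fn(self.data, self.ld)}
        raise ValueError(f"unknown method {method!r}")

    def fit(
        self,
        method: str | Iterable[str] = "ivw_fixed",
        skip_failures: bool = False,
        **kwargs,
    ) -> "MRResults":
        """Fit one or more estimators.

        ``method`` may be a single name, a list of names, or ``"all"``
        (every estimator the data and LD matrix permit). With
        ``skip_failures`` an estimator whose preconditions fail (e.g. Egger
        with fewer than three instruments) is skipped and recorded instead
        of raising.
        """
        if method == "all":
            methods = list(_UNCORRELATED) + (list(_CORRELATED) if self.ld is not None else [])
            skip_failures = True
        elif isinstance(method, str):
            methods = [method]
        else:
            methods = list(method)

        estimates: dict[str, MREstimate] = {}
        skipped: dict[str, str] = {}
        for m in methods:
            try:
                estimates.update(self._run(m, **kwargs))
            except EstimationError as exc:
                if not skip_failures:
                    raise
                skipped[m] = str(exc)
        heterogeneity = None
        if len(self.data) >= 2:
            try:
                heterogeneity = cochran_q(self.data)
            except EstimationError as exc:
                skipped["cochran_q"] = str(exc)
        return MRResults(self, estimates, heterogeneity, skipped)


class MRResults:
    """Fitted causal-effect estimates with diagnostics."""

    def __init__(
        self,
        model: MRModel,
        estimates: Mapping[str, MREstimate],
        heterogeneity: HeterogeneityResult | None = None,
        skipped: Mapping[str, str] | None = None,
    ):
        self.model = model
        self.estimates = dict(estimates)
        self.heterogeneity = heterogeneity
        self.skipped = dict(skipped or {})

    def __getitem__(self, method: str) -> MREstimate:
        return self.estimates[method]

    @property
    def estimate(self) -> MREstimate:
        """The primary (first-fitted) estimate."""
        return next(iter(self.estimates.values()))

    def per_doubling(self, exact_ln2: bool = False) -> dict[str, MREstimate]:
        """Every slope-type estimate rescaled to per-doubling-of-odds."""
        return {
            k: per_doubling(v, exact_ln2=exact_ln2) for k, v in self.estimates.items()
        }

    def per_snp(self) -> pd.DataFrame:
        """Forest-table rows: one Wald-ratio estimate per SNP, OR scale."""
        from .pipeline import per_snp_estimates

        return per_snp_estimates(self.model.data)

    def to_frame(self, include_per_doubling: bool = True) -> pd.DataFrame:
        rows = [e.to_dict() for e in self.estimates.values()]
        if include_per_doubling:
            rows += [e.to_dict() for e in self.per_doubling().values()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table of all fitted estimators."""
        d = self.model.data
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 70,
            f"Exposure: {d.exposure_label}    Outcome: {d.outcome_label}",
            f"Instruments: {len(d)}"
            + ("    (LD matrix supplied)" if self.model.ld is not None else ""),
            "-" * 70,
            f"{'method':<24}{'beta':>8}{'se':>8}{'OR':>7}{'95% CI':>15}{'p':>11}",
        ]
        for name, e in self.estimates.items():
            o = or_with_ci(e)
            lines.append(
                f"{name:<24}{e.beta:>8.3f}{e.se:>8.3f}{o.odds_ratio:>7.2f}"
                f"{f'({o.ci_low:.2f}, {o.ci_high:.2f})':>15}{e.p_value:>11.3g}"
            )
        for name, e in self.per_doubling().items():
            if name == "egger_intercept":
                continue  # intercepts are per-SNP effects, not rescalable slopes
            o = or_with_ci(e)
            lines.append(
                f"{name + ' (x0.693)':<24}{e.beta:>8.3f}{e.se:>8.3f}{o.odds_ratio:>7.2f}"
                f"{f'({o.ci_low:.2f}, {o.ci_high:.2f})':>15}{e.p_value:>11.3g}"
            )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines += [
                "-" * 70,
                f"Cochran Q = {h.q:.3f} on {h.df} df (p = {h.p_value:.3g}); "
                f"I2 = {h.i2:.1f}% (95% CI {h.i2_ci_low:.0f}-{h.i2_ci_high:.0f}%)",
            ]
        for name, reason in self.skipped.items():
            lines.append(f"[skipped] {name}: {reason}")
        lines.append("=" * 70)
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Forest plot: per-SNP Wald ORs with the overall estimate below."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(self.model.data) + 1.5))
        tab = self.per_snp()
        tab = tab[tab["odds_ratio"].notna()]
        y = np.arange(len(tab))[::-1] + 1.0
        ax.errorbar(
            tab["odds_ratio"], y,
            xerr=[tab["odds_ratio"] - tab["ci_low"], tab["ci_high"] - tab["odds_ratio"]],
            fmt="s", color="black", capsize=2,
        )
        labels = list(tab["snp"])
        positions = list(y)
        overall = self.estimates.get("ivw_fixed") or self.estimate
        o = or_with_ci(overall)
        ax.errorbar(
            [o.odds_ratio], [0.0],
            xerr=[[o.odds_ratio - o.ci_low], [o.ci_high - o.odds_ratio]],
            fmt="D", color="firebrick", capsize=2,
        )
        labels.append(f"overall ({overall.method})")
        positions.append(0.0)
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(positions)
        ax.set_yticklabels(labels)
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (95% CI)")
        return ax
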