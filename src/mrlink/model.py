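"""Model/Results interface over the MR estimators.

``MRModel`` is built from harmonized summary data (or directly from two
sumstats tables); ``fit`` returns an ``MRResults`` carrying the estimate,
its uncertainty, heterogeneity diagnostics and a text ``summary()``.
``MediationModel`` does the same for the two-step mediation analysis.
"""

from __future__ import annotations

import pandas as pd

from .sumstats import SumstatsTable, HarmonizedSet, harmonize_pair
from .estimators import (MREstimate, HeterogeneityStats, EggerResult,
                         ivw, mr_egger, wald_ratio, leave_one_out)
from .presso import PressoConfig, PressoResult, presso
from .mediation import MediationResult, two_step_mediation, mediation_effect

RESULT_COLUMNS = ["method", "exposure", "outcome", "n_snp", "beta", "se",
                  "ci_low", "ci_high", "pval", "Q", "Q_df", "Q_pval",
                  "egger_intercept", "egger_intercept_pval"]


class MRResults:
    """Results of one two-sample MR fit."""

    def __init__(self, model: "MRModel", estimate: MREstimate,
                 heterogeneity: HeterogeneityStats | None = None,
                 egger: EggerResult | None = None):
        self.model = model
        self.estimate = estimate
        self.heterogeneity = heterogeneity
        self.egger = egger

    beta = property(lambda self: self.estimate.beta)
    se = property(lambda self: self.estimate.se)
    pval = property(lambda self: self.estimate.pval)
    n_snp = property(lambda self: self.estimate.n_snp)
    method = property(lambda self: self.estimate.method)

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci_low, self.estimate.ci_high

    def to_row(self) -> dict:
        h = self.heterogeneity
        return {
            "method": self.method,
            "exposure": self.model.data.exposure_label,
            "outcome": self.model.data.outcome_label,
            "n_snp": self.n_snp, "beta": self.beta, "se": self.se,
            "ci_low": self.estimate.ci_low, "ci_high": self.estimate.ci_high,
            "pval": self.pval,
            "Q": h.Q if h else None, "Q_df": h.df if h else None,
            "Q_pval": h.pval if h else None,
            "egger_intercept": self.egger.intercept if self.egger else None,
            "egger_intercept_pval": self.egger.intercept_pval if self.egger else None,
        }

    def summary(self) -> str:
        d = self.model.data
        lo, hi = self.conf_int()
        lines = [
            f"Two-sample MR: {d.exposure_label} -> {d.outcome_label}",
            f"  method: {self.method}   instruments: {self.n_snp}",
            f"  beta = {self.beta: .4f}  (SE {self.se:.4f})"
            f"  [95% CI: {lo:.4f}, {hi:.4f}]  p = {self.pval:.3g}",
        ]
        if self.heterogeneity and self.heterogeneity.df > 0:
            h = self.heterogeneity
            lines.append(f"  heterogeneity: Q = {h.Q:.3f} on {h.df} df"
                         f"  (p = {h.pval:.3g})")
        if self.egger:
            lines.append(f"  Egger intercept = {self.egger.intercept: .5f}"
                         f"  (SE {self.egger.intercept_se:.5f},"
                         f" p = {self.egger.intercept_pval:.3g})")
        return "\n".join(lines)


class MRModel:
    """Two-sample MR model over one harmonized exposure/outcome pair."""

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_snp < 1:
            raise ValueError("harmonized set is empty")
        self.data = harmonized

    @classmethod
    def from_sumstats(cls, exposure: SumstatsTable, outcome: SumstatsTable,
                      **harmonize_kwargs) -> "MRModel":
        return cls(harmonize_pair(exposure, outcome, **harmonize_kwargs))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure_label: str = "exposure",
                       outcome_label: str = "outcome") -> "MRModel":
        """Build from a frame with columns gamma, se_gamma, Gamma, se_Gamma
        (and optionally variant_id)."""
        d = df.copy()
        if "variant_id" not in d:
            d["variant_id"] = [f"snp{i + 1}" for i in range(len(d))]
        for col, default in (("eaf", float("nan")), ("flipped", False),
                             ("palindromic", False)):
            if col not in d:
                d[col] = default
        cols = ["variant_id", "gamma", "se_gamma", "Gamma", "se_Gamma",
                "eaf", "flipped", "palindromic"]
        d = d[cols].sort_values("variant_id", kind="mergesort").reset_index(drop=True)
        return cls(HarmonizedSet(exposure_label, outcome_label, d))

    def fit(self, method: str = "ivw", mode: str = "random") -> MRResults:
        if method == "ivw":
            est, het = ivw(self.data, mode=mode)
            return MRResults(self, est, het)
        if method == "egger":
            egger, het = mr_egger(self.data)
            return MRResults(self, egger.slope, het, egger=egger)
        if method == "wald":
            if self.data.n_snp != 1:
                raise ValueError("Wald ratio requires exactly one instrument")
            g = self.data
            est = wald_ratio(g.gamma[0], g.se_gamma[0], g.Gamma[0], g.se_Gamma[0])
            return MRResults(self, est)
        raise ValueError(f"unknown method: {method}")

    def fit_all(self) -> list[MRResults]:
        """IVW (fixed and random) plus Egger when enough instruments."""
        out = [self.fit("ivw", mode="fixed"), self.fit("ivw", mode="random")]
        if self.data.n_snp >= 3:
            out.append(self.fit("egger"))
        return out

    def leave_one_out(self, mode: str = "random"):
        return leave_one_out(self.data, mode=mode)

    def run_presso(self, cfg: PressoConfig | None = None,
                   mode: str = "random") -> PressoResult:
        return presso(self.data, cfg, mode=mode)


def results_table(results: list[MRResults]) -> pd.DataFrame:
    """Delimited-export-ready table, one row per fitted method."""
    return pd.DataFrame([r.to_row() for r in results])[RESULT_COLUMNS]


class MediationResults:
    """Results of a two-step mediation fit (wraps a MediationResult)."""

    def __init__(self, result: MediationResult):
        self.result = result

    proportion = property(lambda self: self.result.proportion)
    proportion_pct = property(lambda self: self.result.proportion_pct)
    indirect = property(lambda self: self.result.indirect)

    def conf_int(self) -> tuple[float, float]:
        return self.result.proportion_ci_low, self.result.proportion_ci_high

    def summary(self) -> str:
        return self.result.summary()


class MediationModel:
    """Two-step mediation MR over exposure, mediator and outcome sumstats."""

    def __init__(self, exposure: SumstatsTable, mediator: SumstatsTable,
                 outcome: SumstatsTable, exposure_instruments,
                 mediator_instruments, mode: str = "random",
                 denominator_mode: str = "fixed", **harmonize_kwargs):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.exposure_instruments = exposure_instruments
        self.mediator_instruments = mediator_instruments
        self.mode = mode
        self.denominator_mode = denominator_mode
        self.harmonize_kwargs = harmonize_kwargs

    def fit(self) -> MediationResults:
        res = two_step_mediation(
            self.exposure, self.mediator, self.outcome,
            self.exposure_instruments, self.mediator_instruments,
            mode=self.mode, denominator_mode=self.denominator_mode,
            **self.harmonize_kwargs)
        return MediationResults(res)

    @staticmethod
    def from_estimates(beta_xm: MREstimate, beta_my: MREstimate,
                       beta_total: MREstimate,
                       denominator_mode: str = "fixed") -> MediationResults:
        """Mediation arithmetic from pre-fitted stage estimates."""
        return MediationResults(mediation_effect(
            beta_xm, beta_my, beta_total, denominator_mode=denominator_mode))
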