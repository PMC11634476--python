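"""Two-step mediation MR: product-of-coefficients indirect effects,
delta-method mediation proportions, and multi-candidate mediator screening.

The indirect effect of an exposure on an outcome through a mediator is
beta1 * beta2, with beta1 the MR estimate exposure -> mediator and beta2 the
MR estimate mediator -> outcome (instrumented by the mediator's own
instruments, excluding the exposure's).  The mediation proportion is the
indirect effect divided by the total effect, with a first-order delta-method
standard error.  Two-sample independence means all covariances are taken as
zero.

``denominator_mode`` controls the proportion SE: ``fixed`` treats the total
effect as a known constant (SE_indirect / |beta_total|); ``propagated``
additionally carries the total-effect variance through the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumstatsTable, HarmonizedSet, harmonize_pair, Z_975
from .estimators import MREstimate, HeterogeneityStats, ivw


@dataclass
class ScreenConfig:
    alpha_screen: float = 0.05
    multiplicity: str = "none"            # none | bh_fdr | bonferroni
    require_direction_consistency: bool = True
    estimator: str = "random"             # IVW mode for every stage
    denominator_mode: str = "fixed"

    def __post_init__(self):
        if not 0 < self.alpha_screen < 1:
            raise ValueError("alpha_screen must be in (0, 1)")
        if self.multiplicity not in ("none", "bh_fdr", "bonferroni"):
            raise ValueError(f"unknown multiplicity rule: {self.multiplicity}")
        if self.estimator not in ("fixed", "random"):
            raise ValueError(f"unknown estimator mode: {self.estimator}")
        if self.denominator_mode not in ("fixed", "propagated"):
            raise ValueError(f"unknown denominator_mode: {self.denominator_mode}")


@dataclass(frozen=True)
class MediationResult:
    """Indirect effect, total effect, and delta-method mediation proportion."""

    beta_total: MREstimate
    beta_xm: MREstimate
    beta_my: MREstimate
    indirect: float
    indirect_se: float
    proportion: float
    proportion_se: float
    proportion_ci_low: float
    proportion_ci_high: float
    denominator_mode: str

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_dict(self) -> dict:
        return {
            "beta_total": self.beta_total.to_dict(),
            "beta_xm": self.beta_xm.to_dict(),
            "beta_my": self.beta_my.to_dict(),
            "indirect": self.indirect, "indirect_se": self.indirect_se,
            "proportion": self.proportion, "proportion_se": self.proportion_se,
            "proportion_ci_low": self.proportion_ci_low,
            "proportion_ci_high": self.proportion_ci_high,
            "denominator_mode": self.denominator_mode,
        }

    def summary(self) -> str:
        lines = [
            "Two-step mediation MR",
            f"  total effect     beta = {self.beta_total.beta: .4f}"
            f"  (SE {self.beta_total.se:.4f})",
            f"  exposure->mediator beta1 = {self.beta_xm.beta: .4f}"
            f"  (SE {self.beta_xm.se:.4f})",
            f"  mediator->outcome  beta2 = {self.beta_my.beta: .4f}"
            f"  (SE {self.beta_my.se:.4f})",
            f"  indirect effect  beta1*beta2 = {self.indirect: .4f}"
            f"  (SE {self.indirect_se:.4f})",
            f"  mediation proportion = {self.proportion_pct:.2f}%"
            f"  [95% CI: {100 * self.proportion_ci_low:.2f}%,"
            f" {100 * self.proportion_ci_high:.2f}%]"
            f"  ({self.denominator_mode} denominator)",
        ]
        return "\n".join(lines)


def mediation_effect(beta_xm: MREstimate, beta_my: MREstimate,
                     beta_total: MREstimate,
                     denominator_mode: str = "fixed") -> MediationResult:
    """Delta-method mediation proportion from three MR estimates.

    indirect = beta1*beta2 with SE sqrt(beta2^2 s1^2 + beta1^2 s2^2);
    proportion = indirect / beta_total.  ``fixed`` mode divides the indirect
    SE by |beta_total|; ``propagated`` mode adds the relative variance of the
    total effect (zero covariances in both cases).
    """
    if denominator_mode not in ("fixed", "propagated"):
        raise ValueError(f"unknown denominator_mode: {denominator_mode}")
    b1, s1 = beta_xm.beta, beta_xm.se
    b2, s2 = beta_my.beta, beta_my.se
    bt, st = beta_total.beta, beta_total.se
    if bt == 0:
        raise ValueError("undefined proportion: total effect is zero")

    indirect = b1 * b2
    indirect_se = float(np.sqrt(b2 ** 2 * s1 ** 2 + b1 ** 2 * s2 ** 2))
    proportion = indirect / bt
    if denominator_mode == "fixed":
        proportion_se = indirect_se / abs(bt)
    else:
        if indirect == 0:
            proportion_se = indirect_se / abs(bt)
        else:
            rel = indirect_se ** 2 / indirect ** 2 + st ** 2 / bt ** 2
            proportion_se = abs(proportion) * float(np.sqrt(rel))
    if not 0 <= proportion <= 1:
        warnings.warn(
            f"mediation proportion {proportion:.3f} outside [0, 1]",
            stacklevel=2)
    return MediationResult(
        beta_total=beta_total, beta_xm=beta_xm, beta_my=beta_my,
        indirect=float(indirect), indirect_se=indirect_se,
        proportion=float(proportion), proportion_se=float(proportion_se),
        proportion_ci_low=float(proportion - Z_975 * proportion_se),
        proportion_ci_high=float(proportion + Z_975 * proportion_se),
        denominator_mode=denominator_mode)


def _as_id_list(instruments) -> list[str]:
    if isinstance(instruments, SumstatsTable):
        return instruments.variant_ids
    return list(instruments)


def _stage_mr(instrument_ids, from_table: SumstatsTable, to_table: SumstatsTable,
              stage: str, mode: str, **harmonize_kwargs) -> tuple[MREstimate, HeterogeneityStats]:
    sub = from_table.subset(instrument_ids)
    if len(sub) == 0:
        raise ValueError(f"no instruments available for stage {stage!r}")
    try:
        h = harmonize_pair(sub, to_table, **harmonize_kwargs)
    except ValueError as err:
        raise ValueError(f"stage {stage!r}: {err}") from err
    return ivw(h, mode=mode)


def two_step_mediation(exposure: SumstatsTable, mediator: SumstatsTable,
                       outcome: SumstatsTable, exposure_instruments,
                       mediator_instruments, mode: str = "random",
                       denominator_mode: str = "fixed",
                       **harmonize_kwargs) -> MediationResult:
    """Run the three MR stages and combine them into a mediation proportion.

    Mediator instruments overlapping the exposure's instrument set are
    excluded (with a warning) so the mediator -> outcome stage is not driven
    by the exposure's own variants.
    """
    exp_ids = _as_id_list(exposure_instruments)
    med_ids = _as_id_list(mediator_instruments)
    overlap = set(exp_ids) & set(med_ids)
    if overlap:
        warnings.warn(f"excluding {len(overlap)} exposure instrument(s) from "
                      "the mediator instrument set", stacklevel=2)
        med_ids = [v for v in med_ids if v not in overlap]

    beta_xm, _ = _stage_mr(exp_ids, exposure, mediator, "exposure->mediator",
                           mode, **harmonize_kwargs)
    beta_my, _ = _stage_mr(med_ids, mediator, outcome, "mediator->outcome",
                           mode, **harmonize_kwargs)
    beta_total, _ = _stage_mr(exp_ids, exposure, outcome, "exposure->outcome",
                              mode, **harmonize_kwargs)
    return mediation_effect(beta_xm, beta_my, beta_total,
                            denominator_mode=denominator_mode)


def _adjust_pvalues(pvals: np.ndarray, rule: str) -> np.ndarray:
    if rule == "none" or len(pvals) == 0:
        return pvals.copy()
    if rule == "bonferroni":
        return np.minimum(1.0, pvals * len(pvals))
    return stats.false_discovery_control(pvals, method="bh")


@dataclass
class ScreenTable:
    """Per-candidate screening results plus stage-A association counts."""

    df: pd.DataFrame
    beta_total: MREstimate
    n_positive: int
    n_negative: int
    results: dict = field(default_factory=dict)   # label -> MediationResult

    @property
    def qualifiers(self) -> list[str]:
        return self.df.loc[self.df["qualifies"], "mediator"].tolist()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA",
                       float_format="%.8g")

    def volcano_frame(self) -> pd.DataFrame:
        """beta2 and -log10 p per candidate, for volcano-style plotting."""
        d = self.df.dropna(subset=["beta_my", "p_my"])
        return pd.DataFrame({
            "mediator": d["mediator"],
            "beta_my": d["beta_my"],
            "neg_log10_p": -np.log10(d["p_my"]),
        })


def screen_mediators(exposure: SumstatsTable, outcome: SumstatsTable,
                     candidates, exposure_instruments,
                     cfg: ScreenConfig | None = None,
                     **harmonize_kwargs) -> ScreenTable:
    """Screen candidate mediators of the exposure -> outcome effect.

    ``candidates`` is an iterable of (label, mediator SumstatsTable,
    mediator instruments).  Stage A runs MR mediator -> outcome for every
    candidate and keeps those passing ``alpha_screen`` after the configured
    multiplicity adjustment; stage B runs MR exposure -> mediator for the
    survivors.  Qualifiers pass both stages and (optionally) have
    sign(beta1*beta2) matching the total effect; each gets a full
    :class:`MediationResult`.
    """
    cfg = cfg or ScreenConfig()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    exp_ids = _as_id_list(exposure_instruments)
    exp_id_set = set(exp_ids)
    mode = cfg.estimator

    beta_total, _ = _stage_mr(exp_ids, exposure, outcome, "exposure->outcome",
                              mode, **harmonize_kwargs)

    rows = []
    stage_a: dict[str, MREstimate] = {}
    for label, med_table, med_instr in candidates:
        med_ids = [v for v in _as_id_list(med_instr) if v not in exp_id_set]
        row = {"mediator": label, "beta_my": np.nan, "se_my": np.nan,
               "p_my": np.nan, "p_my_adj": np.nan, "beta_xm": np.nan,
               "se_xm": np.nan, "p_xm": np.nan, "qualifies": False,
               "proportion_pct": np.nan, "proportion_ci_low_pct": np.nan,
               "proportion_ci_high_pct": np.nan, "note": ""}
        try:
            est, _ = _stage_mr(med_ids, med_table, outcome, f"{label}->outcome",
                               mode, **harmonize_kwargs)
        except ValueError as err:
            warnings.warn(f"candidate {label!r} skipped: {err}", stacklevel=2)
            row["note"] = "no usable instruments"
            rows.append(row)
            continue
        stage_a[label] = est
        row.update(beta_my=est.beta, se_my=est.se, p_my=est.pval)
        rows.append(row)

    tested = [r for r in rows if r["note"] == ""]
    padj = _adjust_pvalues(np.array([r["p_my"] for r in tested]), cfg.multiplicity)
    for r, p in zip(tested, padj):
        r["p_my_adj"] = float(p)

    n_pos = sum(1 for r in tested
                if r["p_my_adj"] < cfg.alpha_screen and r["beta_my"] > 0)
    n_neg = sum(1 for r in tested
                if r["p_my_adj"] < cfg.alpha_screen and r["beta_my"] < 0)

    med_tables = {label: t for label, t, _ in candidates}
    results: dict[str, MediationResult] = {}
    for r in tested:
        if r["p_my_adj"] >= cfg.alpha_screen:
            continue
        label = r["mediator"]
        try:
            beta_xm, _ = _stage_mr(exp_ids, exposure, med_tables[label],
                                   f"exposure->{label}", mode, **harmonize_kwargs)
        except ValueError as err:
            warnings.warn(f"candidate {label!r} stage B failed: {err}",
                          stacklevel=2)
            r["note"] = "stage B failed"
            continue
        r.update(beta_xm=beta_xm.beta, se_xm=beta_xm.se, p_xm=beta_xm.pval)
        if beta_xm.pval >= cfg.alpha_screen:
            continue
        indirect = beta_xm.beta * stage_a[label].beta
        if cfg.require_direction_consistency and np.sign(indirect) != np.sign(beta_total.beta):
            r["note"] = "direction-inconsistent"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            med = mediation_effect(beta_xm, stage_a[label], beta_total,
                                   denominator_mode=cfg.denominator_mode)
        r["qualifies"] = True
        r["proportion_pct"] = med.proportion_pct
        r["proportion_ci_low_pct"] = 100 * med.proportion_ci_low
        r["proportion_ci_high_pct"] = 100 * med.proportion_ci_high
        results[label] = med

    df = pd.DataFrame(rows)
    return ScreenTable(df=df, beta_total=beta_total, n_positive=n_pos,
                       n_negative=n_neg, results=results)
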