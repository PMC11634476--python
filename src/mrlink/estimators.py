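"""Closed-form two-sample MR estimators and heterogeneity statistics.

All estimators operate on harmonized summary data: per-instrument
SNP-exposure effects gamma_j (SE sigma_gamma_j) and SNP-outcome effects
Gamma_j (SE sigma_Gamma_j), weighted by the inverse outcome variance
w_j = 1 / sigma_Gamma_j^2.

Conventions (documented, not configurable):

- normal (z) quantiles for every CI and p-value;
- first-order Wald SE, sigma_Gamma / |gamma| (no exposure-side
  measurement-error correction);
- random-effects IVW applies a multiplicative overdispersion factor
  max(1, sqrt(Q/df)) to the fixed-effect SE and never shrinks below it;
- MR-Egger orients instruments so gamma_j >= 0 before fitting the intercept
  model, and scales both coefficient SEs by max(1, sqrt(Q_egger/df)).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet, Z_975

_P_FLOOR = 1e-300


def _norm_pval(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))


@dataclass(frozen=True)
class MREstimate:
    """One causal estimate with its normal-theory 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float,
                     n_snp: int) -> "MREstimate":
        beta, se = float(beta), float(se)
        if se <= 0:
            raise ValueError("standard error must be positive")
        return cls(method=method, beta=beta, se=se,
                   ci_low=beta - Z_975 * se, ci_high=beta + Z_975 * se,
                   pval=_norm_pval(beta / se), n_snp=int(n_snp))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MREstimate":
        return cls(**d)


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its chi-square reference."""

    Q: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float

    def to_dict(self) -> dict:
        return {"slope": self.slope.to_dict(), "intercept": self.intercept,
                "intercept_se": self.intercept_se,
                "intercept_pval": self.intercept_pval}


def _chi2_sf(Q: float, df: int) -> float:
    if df <= 0:
        return 1.0
    return float(np.clip(stats.chi2.sf(Q, df), _P_FLOOR, 1.0))


def wald_ratio(gamma: float, se_gamma: float, Gamma: float,
               se_Gamma: float) -> MREstimate:
    """Single-instrument causal estimate Gamma/gamma with first-order SE."""
    if gamma == 0:
        raise ValueError("undefined ratio: gamma is zero")
    if se_gamma <= 0 or se_Gamma <= 0:
        raise ValueError("standard errors must be positive")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    return MREstimate.from_beta_se("wald", beta, se, 1)


def _ivw_arrays(g, sg, G, sG, mode):
    w = 1.0 / sG ** 2
    s_wg2 = float(np.sum(w * g ** 2))
    if s_wg2 == 0:
        raise ValueError("all SNP-exposure effects are zero")
    beta = float(np.sum(w * g * G)) / s_wg2
    se_fixed = s_wg2 ** -0.5
    Q = float(np.sum(w * (G - beta * g) ** 2))
    df = len(g) - 1
    se = se_fixed
    if mode == "random" and df > 0:
        se = se_fixed * max(1.0, np.sqrt(Q / df))
    return beta, se, Q, df


def ivw(h: HarmonizedSet, mode: str = "random") -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance weighted estimate (weighted regression of Gamma on
    gamma through the origin) with Cochran's Q.

    ``mode="random"`` multiplies the fixed-effect SE by max(1, sqrt(Q/df)).
    A single instrument delegates to the Wald ratio.
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown IVW mode: {mode}")
    if h.n_snp < 1:
        raise ValueError("empty instrument set")
    if h.n_snp == 1:
        est = wald_ratio(h.gamma[0], h.se_gamma[0], h.Gamma[0], h.se_Gamma[0])
        return est, HeterogeneityStats(Q=0.0, df=0, pval=1.0)
    beta, se, Q, df = _ivw_arrays(h.gamma, h.se_gamma, h.Gamma, h.se_Gamma, mode)
    method = "ivw_fixed" if mode == "fixed" else "ivw_random"
    est = MREstimate.from_beta_se(method, beta, se, h.n_snp)
    return est, HeterogeneityStats(Q=Q, df=df, pval=_chi2_sf(Q, df))


def mr_egger(h: HarmonizedSet) -> tuple[EggerResult, HeterogeneityStats]:
    """MR-Egger weighted regression Gamma = b0 + b1 * gamma.

    Instruments are oriented so gamma_j >= 0; weights are 1/sigma_Gamma_j^2;
    coefficient SEs carry the multiplicative overdispersion factor
    max(1, sqrt(Q/df)) with df = J - 2.
    """
    J = h.n_snp
    if J < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    g = sign * h.gamma
    G = sign * h.Gamma
    w = 1.0 / h.se_Gamma ** 2

    X = np.column_stack([np.ones(J), g])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * G)
    coef = np.linalg.solve(A, b)
    resid = G - X @ coef
    Q = float(np.sum(w * resid ** 2))
    df = J - 2
    scale = max(1.0, Q / df)
    cov = np.linalg.inv(A) * scale
    se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    slope = MREstimate.from_beta_se("egger_slope", coef[1], se1, J)
    egger = EggerResult(slope=slope, intercept=float(coef[0]), intercept_se=se0,
                        intercept_pval=_norm_pval(coef[0] / se0))
    return egger, HeterogeneityStats(Q=Q, df=df, pval=_chi2_sf(Q, df))


def cochran_q(h: HarmonizedSet, beta: float, model: str = "ivw",
              intercept: float = 0.0) -> HeterogeneityStats:
    """Weighted residual heterogeneity Q = sum w_j (Gamma_j - b0 - beta*gamma_j)^2.

    ``model="egger"`` orients instruments to gamma_j >= 0 (matching
    :func:`mr_egger`) and uses df = J - 2; ``model="ivw"`` uses df = J - 1.
    """
    if model not in ("ivw", "egger"):
        raise ValueError(f"unknown model: {model}")
    g, G = h.gamma, h.Gamma
    if model == "egger":
        sign = np.where(g < 0, -1.0, 1.0)
        g, G = sign * g, sign * G
    df = h.n_snp - (1 if model == "ivw" else 2)
    if df <= 0:
        raise ValueError("non-positive degrees of freedom for Q")
    w = 1.0 / h.se_Gamma ** 2
    Q = float(np.sum(w * (G - intercept - beta * g) ** 2))
    return HeterogeneityStats(Q=Q, df=df, pval=_chi2_sf(Q, df))


def leave_one_out(h: HarmonizedSet, mode: str = "random") -> list[tuple[str, MREstimate]]:
    """IVW estimate excluding each instrument in turn."""
    if h.n_snp < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    out = []
    ids = h.variant_ids
    for vid in ids:
        sub = h.drop([vid])
        est, _ = ivw(sub, mode=mode)
        out.append((vid, est))
    return out


def loo_fixed_slopes(g: np.ndarray, sG: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out fixed-effect IVW slopes (one per instrument)."""
    w = 1.0 / sG ** 2
    s_wgG = np.sum(w * g * G)
    s_wg2 = np.sum(w * g ** 2)
    denom = s_wg2 - w * g ** 2
    if np.any(denom <= 0):
        raise ValueError("degenerate leave-one-out weights")
    return (s_wgG - w * g * G) / denom
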