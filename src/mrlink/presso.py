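"""MR-PRESSO: resampling-based global heterogeneity test, per-instrument
outlier detection, and distortion assessment.

The observed statistic is the weighted leave-one-out residual sum of squares

    RSS_obs = sum_j w_j (Gamma_j - beta_{-j} gamma_j)^2,   w_j = 1/sigma_Gamma_j^2,

with beta_{-j} the fixed-effect IVW slope excluding instrument j.  Its null
distribution comes from a parametric bootstrap: for each of K draws,
gamma*_j ~ N(gamma_j, sigma_gamma_j^2) and
Gamma*_j ~ N(beta_{-j} gamma_j, sigma_Gamma_j^2), and the same weighted LOO
RSS is recomputed on the simulated set.  Monte-Carlo p-values are floored at
1/(K+1).  Outliers are instruments whose per-SNP residual p-value falls
below a Bonferroni-adjusted level alpha/J.  The distortion test compares the
raw-vs-corrected shift of the IVW estimate against removing random
same-size instrument subsets.

The draw order is fixed (all gamma* first, then all Gamma*, instrument-major)
so results are bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sumstats import HarmonizedSet
from .estimators import MREstimate, ivw, loo_fixed_slopes


@dataclass
class PressoConfig:
    n_sim: int = 2000
    outlier_alpha: float = 0.05
    n_boot_distortion: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if not 0 < self.outlier_alpha < 1:
            raise ValueError("outlier_alpha must be in (0, 1)")
        if self.n_boot_distortion < 1:
            raise ValueError("n_boot_distortion must be positive")


@dataclass
class PressoDraws:
    """Observed and bootstrap residuals shared by the global and outlier tests."""

    variant_ids: list
    rss_obs: float
    resid_obs: np.ndarray        # (J,)
    rss_sim: np.ndarray          # (K,)
    resid_sim: np.ndarray        # (J, K)
    seed: int


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    per_snp_pval: dict
    outliers: list
    beta_raw: MREstimate
    beta_corrected: MREstimate | None = None
    distortion_pct: float | None = None
    distortion_pval: float | None = None

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "per_snp_pval": dict(self.per_snp_pval),
            "outliers": list(self.outliers),
            "beta_raw": self.beta_raw.to_dict(),
            "beta_corrected": (self.beta_corrected.to_dict()
                               if self.beta_corrected is not None else None),
            "distortion_pct": self.distortion_pct,
            "distortion_pval": self.distortion_pval,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PressoResult":
        return cls(
            rss_obs=d["rss_obs"], global_pval=d["global_pval"],
            per_snp_pval=dict(d["per_snp_pval"]), outliers=list(d["outliers"]),
            beta_raw=MREstimate.from_dict(d["beta_raw"]),
            beta_corrected=(MREstimate.from_dict(d["beta_corrected"])
                            if d.get("beta_corrected") else None),
            distortion_pct=d.get("distortion_pct"),
            distortion_pval=d.get("distortion_pval"),
        )

    @classmethod
    def from_json(cls, s: str) -> "PressoResult":
        return cls.from_dict(json.loads(s))


def _loo_rss(g, sG, G):
    w = 1.0 / sG ** 2
    beta_loo = loo_fixed_slopes(g, sG, G)
    resid = w * (G - beta_loo * g) ** 2
    return resid, float(np.sum(resid))


def presso_global(h: HarmonizedSet, cfg: PressoConfig) -> tuple[float, float, PressoDraws]:
    """Global pleiotropy test; returns (rss_obs, global_pval, draws)."""
    J = h.n_snp
    if J < 4:
        raise ValueError("too few instruments for MR-PRESSO (need >= 4)")
    g, sg, G, sG = h.gamma, h.se_gamma, h.Gamma, h.se_Gamma
    w = 1.0 / sG ** 2
    beta_loo = loo_fixed_slopes(g, sG, G)
    resid_obs = w * (G - beta_loo * g) ** 2
    rss_obs = float(np.sum(resid_obs))

    K = cfg.n_sim
    rng = np.random.default_rng(cfg.seed)
    # instrument-major draw order: all gamma*, then all Gamma*
    g_star = rng.normal(loc=g[:, None], scale=sg[:, None], size=(J, K))
    G_star = rng.normal(loc=(beta_loo * g)[:, None], scale=sG[:, None], size=(J, K))

    s_wgG = np.sum(w[:, None] * g_star * G_star, axis=0)        # (K,)
    s_wg2 = np.sum(w[:, None] * g_star ** 2, axis=0)            # (K,)
    denom = s_wg2[None, :] - w[:, None] * g_star ** 2
    beta_loo_star = (s_wgG[None, :] - w[:, None] * g_star * G_star) / denom
    resid_sim = w[:, None] * (G_star - beta_loo_star * g_star) ** 2   # (J, K)
    rss_sim = resid_sim.sum(axis=0)

    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (K + 1)
    draws = PressoDraws(variant_ids=h.variant_ids, rss_obs=rss_obs,
                        resid_obs=resid_obs, rss_sim=rss_sim,
                        resid_sim=resid_sim, seed=cfg.seed)
    return rss_obs, global_pval, draws


def presso_outliers(h: HarmonizedSet, cfg: PressoConfig,
                    draws: PressoDraws) -> tuple[dict, list]:
    """Per-instrument residual p-values and the Bonferroni outlier set."""
    if draws.variant_ids != h.variant_ids or draws.seed != cfg.seed:
        raise ValueError("draws do not match this data/seed")
    K = draws.resid_sim.shape[1]
    counts = np.sum(draws.resid_sim >= draws.resid_obs[:, None], axis=1)
    pvals = (1 + counts) / (K + 1)
    per_snp = {vid: float(p) for vid, p in zip(h.variant_ids, pvals)}
    cutoff = cfg.outlier_alpha / h.n_snp
    outliers = [vid for vid, p in per_snp.items() if p < cutoff]
    return per_snp, outliers


def presso_distortion(h: HarmonizedSet, outliers: list, cfg: PressoConfig,
                      mode: str = "random"):
    """Distortion of the IVW estimate attributable to the detected outliers.

    Compares 100*(beta_raw - beta_corrected)/|beta_corrected| with the same
    quantity after removing random same-size instrument subsets (sampled with
    replacement from the non-outliers).
    """
    if not outliers:
        raise ValueError("distortion test requires a non-empty outlier set")
    clean = [v for v in h.variant_ids if v not in set(outliers)]
    if len(clean) < 2:
        raise ValueError("outlier removal leaves fewer than 2 instruments")
    beta_raw, _ = ivw(h, mode=mode)
    beta_corr, _ = ivw(h.subset(clean), mode=mode)
    if beta_corr.beta == 0:
        raise ValueError("corrected estimate is zero; distortion undefined")
    distortion_pct = 100.0 * (beta_raw.beta - beta_corr.beta) / abs(beta_corr.beta)

    rng = np.random.default_rng((cfg.seed, 1))   # distinct stream from the bootstrap
    k = len(outliers)
    # vectorized over bootstrap draws via the IVW sufficient sums
    idx = {v: i for i, v in enumerate(h.variant_ids)}
    clean_pos = np.array([idx[v] for v in clean])
    w = 1.0 / h.se_Gamma ** 2
    wgG = w * h.gamma * h.Gamma
    wg2 = w * h.gamma ** 2
    s_wgG, s_wg2 = np.sum(wgG), np.sum(wg2)
    d_null = np.empty(cfg.n_boot_distortion)
    for b in range(cfg.n_boot_distortion):
        picked = np.unique(rng.choice(clean_pos, size=k, replace=True))
        beta_b = (s_wgG - wgG[picked].sum()) / (s_wg2 - wg2[picked].sum())
        d_null[b] = 100.0 * (beta_raw.beta - beta_b) / abs(beta_b)
    distortion_pval = float(np.mean(np.abs(d_null) >= abs(distortion_pct)))
    return beta_raw, beta_corr, float(distortion_pct), distortion_pval


def presso(h: HarmonizedSet, cfg: PressoConfig | None = None,
           mode: str = "random") -> PressoResult:
    """Full MR-PRESSO: global test, outlier localization, and (when outliers
    are found) the outlier-corrected estimate with its distortion test."""
    cfg = cfg or PressoConfig()
    rss_obs, global_pval, draws = presso_global(h, cfg)
    per_snp, outliers = presso_outliers(h, cfg, draws)
    beta_raw, _ = ivw(h, mode=mode)
    result = PressoResult(rss_obs=rss_obs, global_pval=global_pval,
                          per_snp_pval=per_snp, outliers=outliers,
                          beta_raw=beta_raw)
    if outliers and h.n_snp - len(outliers) >= 2:
        beta_raw, beta_corr, d_pct, d_p = presso_distortion(h, outliers, cfg, mode)
        result.beta_raw = beta_raw
        result.beta_corrected = beta_corr
        result.distortion_pct = d_pct
        result.distortion_pval = d_p
    return result
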