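"""Replication-scale simulation studies of estimator behaviour.

Each study repeatedly draws synthetic GWAS chains from :mod:`mrlink.simulate`
and measures a property of the estimators: recovery of the true causal and
mediated effects, calibration of the heterogeneity and pleiotropy tests
under the homogeneous null, and power/localization of MR-PRESSO against
planted pleiotropic outliers.  Problem sizes default to 30 instruments and
200 000 samples per GWAS; replicate counts are chosen so Monte-Carlo error
is small relative to the effects being measured.
"""

from __future__ import annotations

import numpy as np

from .sumstats import harmonize_pair
from .estimators import ivw, mr_egger
from .presso import PressoConfig, presso, presso_global
from .mediation import two_step_mediation
from .simulate import SimConfig, simulate_chain, plant_outliers


def _mc(values) -> tuple[float, float]:
    v = np.asarray(values, float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def recovery_study(n_reps: int = 200, seed: int = 1000,
                   cfg: SimConfig | None = None) -> dict:
    """Mean IVW total effect and two-step mediation proportion over clean
    (pleiotropy-free) replicates, with Monte-Carlo standard errors."""
    base = cfg or SimConfig()
    betas, props = [], []
    for i in range(n_reps):
        c = SimConfig(**{**base.__dict__, "seed": seed + i})
        exposure, mediator, outcome, _, truth = simulate_chain(c)
        res = two_step_mediation(exposure, mediator, outcome,
                                 truth.exposure_instrument_ids,
                                 truth.mediator_instrument_ids)
        betas.append(res.beta_total.beta)
        props.append(res.proportion)
    beta_mean, beta_mc_se = _mc(betas)
    prop_mean, prop_mc_se = _mc(props)
    truth_cfg = SimConfig(**{**base.__dict__, "seed": seed})
    t = simulate_chain(truth_cfg)[4]
    return {
        "n_reps": n_reps,
        "beta_mean": beta_mean, "beta_mc_se": beta_mc_se,
        "beta_true": t.total_effect,
        "proportion_mean": prop_mean, "proportion_mc_se": prop_mc_se,
        "proportion_true": t.mediation_proportion,
    }


def null_calibration_study(n_reps: int = 500, seed: int = 3000,
                           alpha_level: float = 0.05) -> dict:
    """Cochran's Q moments and IVW / Egger-intercept test sizes under the
    homogeneous null (no causal effect, no pleiotropy)."""
    qs, ivw_reject, egger_reject = [], [], []
    for i in range(n_reps):
        cfg = SimConfig(alpha=0.0, theta=0.0, delta=0.0, n_snp_med=0,
                        seed=seed + i)
        exposure, _, outcome, _, truth = simulate_chain(cfg)
        h = harmonize_pair(exposure.subset(truth.exposure_instrument_ids),
                           outcome)
        est, het = ivw(h, mode="random")
        egger, _ = mr_egger(h)
        qs.append(het.Q)
        ivw_reject.append(est.pval < alpha_level)
        egger_reject.append(egger.intercept_pval < alpha_level)
    q_mean, q_mc_se = _mc(qs)
    return {
        "n_reps": n_reps, "n_snp": SimConfig().n_snp,
        "q_mean": q_mean, "q_mc_se": q_mc_se,
        "q_expected": SimConfig().n_snp - 1,
        "ivw_size": float(np.mean(ivw_reject)),
        "egger_intercept_size": float(np.mean(egger_reject)),
    }


def presso_null_study(n_reps: int = 200, n_sim: int = 500,
                      seed: int = 5000, alpha_level: float = 0.05) -> dict:
    """Rejection rate of the MR-PRESSO global test under the homogeneous null."""
    reject = []
    for i in range(n_reps):
        cfg = SimConfig(alpha=0.0, theta=0.0, delta=0.0, n_snp_med=0,
                        seed=seed + i)
        exposure, _, outcome, _, truth = simulate_chain(cfg)
        h = harmonize_pair(exposure.subset(truth.exposure_instrument_ids),
                           outcome)
        _, pval, _ = presso_global(h, PressoConfig(n_sim=n_sim, seed=seed + i))
        reject.append(pval < alpha_level)
    return {"n_reps": n_reps, "n_sim": n_sim,
            "rejection_rate": float(np.mean(reject))}


def outlier_study(n_reps: int = 100, n_sim: int = 2000, k: int = 2,
                  offset_in_se: float = 8.0, seed: int = 7000) -> dict:
    """MR-PRESSO against planted directional pleiotropic outliers.

    Measures global-test power, per-SNP outlier recall and false-positive
    rate, and how often the outlier-corrected IVW estimate lands closer to
    the true total effect than the raw one (among detecting replicates)."""
    glob, recalls, fps, closer, detecting = [], [], [], 0, 0
    for i in range(n_reps):
        cfg = SimConfig(n_snp_med=0, seed=seed + i)
        exposure, _, outcome, _, truth = simulate_chain(cfg)
        outcome, truth = plant_outliers(outcome, truth, k=k,
                                        offset_in_se=offset_in_se,
                                        seed=seed + 50_000 + i)
        h = harmonize_pair(exposure.subset(truth.exposure_instrument_ids),
                           outcome)
        res = presso(h, PressoConfig(n_sim=n_sim, seed=seed + 90_000 + i))
        glob.append(res.global_pval < 0.05)
        planted = set(truth.outlier_ids)
        found = set(res.outliers)
        recalls.append(len(found & planted) / len(planted))
        clean = set(h.variant_ids) - planted
        fps.append(len(found - planted) / len(clean))
        if found:
            detecting += 1
            raw_err = abs(res.beta_raw.beta - truth.total_effect)
            corr_err = abs(res.beta_corrected.beta - truth.total_effect)
            if corr_err < raw_err:
                closer += 1
    return {
        "n_reps": n_reps, "n_sim": n_sim,
        "global_power": float(np.mean(glob)),
        "recall_mean": float(np.mean(recalls)),
        "false_positive_rate": float(np.mean(fps)),
        "n_detecting": detecting,
        "corrected_closer_frac": closer / detecting if detecting else float("nan"),
    }
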