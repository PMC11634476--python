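"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the statistical structure of a drug-target mediation
MR study without any individual-level data: an exposure instrumented by
strong molecular-QTL-like variants, a candidate mediator on the causal path,
and an outcome receiving both a direct and a mediated effect,

    exposure  --alpha-->  mediator  --theta-->  outcome
        \\____________________delta____________________/

Per-SNP truth: exposure effects gamma_j ~ N(0, gamma_sd^2); mediator truth
alpha*gamma_j (plus the mediator's own instruments eta_k ~ N(0, gamma_sd^2));
outcome truth (delta + alpha*theta)*gamma_j + pleiotropy_j, with horizontal
pleiotropy offsets ~ N(pleio_mean, pleio_sd^2) on a pleio_frac subset of the
exposure instruments.  Each trait's sampling SE uses the standardized-trait
approximation SE_j = 1/sqrt(2 f_j (1-f_j) n), observed betas are truth plus
independent normal noise per trait (two-sample independence), and p-values
are two-sided normal tails of beta/SE.  LD is block-diagonal: blocks of
``ld_block_size`` consecutive SNPs share pairwise r^2 = ``ld_r2``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumstatsTable
from .instruments import LDMatrix

# ordered non-palindromic, non-identical allele pairs
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass
class SimConfig:
    """Generative parameters for one synthetic exposure/mediator/outcome trio.

    Defaults emulate a biobank-scale two-sample design: 30 strong instruments
    per trait (mean F on the order of 10^3, as for cis molecular-QTL
    instruments), 200 000 samples per GWAS, and a chain with true total
    effect delta + alpha*theta = -0.30 of which 20% is mediated.
    """

    n_snp: int = 30
    n_snp_med: int = 30
    maf_range: tuple = (0.05, 0.5)
    gamma_sd: float = 0.15
    n_exposure: int = 200_000
    n_mediator: int = 200_000
    n_outcome: int = 200_000
    alpha: float = -0.2
    theta: float = 0.3
    delta: float = -0.24
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    flip_frac: float = 0.0
    palindrome_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.n_snp_med < 0:
            raise ValueError("n_snp_med must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 <= self.pleio_frac < 1:
            raise ValueError("pleio_frac must be in [0, 1)")
        if self.pleio_sd < 0:
            raise ValueError("pleio_sd must be non-negative")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0 <= self.ld_r2 < 1:
            raise ValueError("ld_r2 must be in [0, 1)")
        for name in ("flip_frac", "palindrome_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for recovery tests, consistent with its SimConfig."""

    gamma: pd.Series                # true SNP-exposure effects
    eta: pd.Series                  # true SNP-mediator effects (mediator instruments)
    pleiotropy: pd.Series           # outcome-side offsets, all SNPs
    alpha: float
    theta: float
    delta: float
    pleio_ids: list = field(default_factory=list)
    outlier_ids: list = field(default_factory=list)
    exposure_instrument_ids: list = field(default_factory=list)
    mediator_instrument_ids: list = field(default_factory=list)

    @property
    def total_effect(self) -> float:
        return self.delta + self.alpha * self.theta

    @property
    def mediation_proportion(self) -> float:
        total = self.total_effect
        if total == 0:
            return float("nan")
        return self.alpha * self.theta / total

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.gamma.index)
        return pd.DataFrame({
            "variant_id": ids,
            "gamma_true": self.gamma.to_numpy(),
            "eta_true": self.eta.reindex(ids, fill_value=0.0).to_numpy(),
            "pleiotropy": self.pleiotropy.reindex(ids, fill_value=0.0).to_numpy(),
            "is_exposure_instrument": [v in set(self.exposure_instrument_ids) for v in ids],
            "is_mediator_instrument": [v in set(self.mediator_instrument_ids) for v in ids],
            "is_outlier": [v in set(self.outlier_ids) for v in ids],
        })


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)


def _make_table(label, ids, chrom, pos, ea, oa, eaf, truth, se, n, rng) -> SumstatsTable:
    beta = truth + rng.normal(0.0, se)
    df = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pd.array(pos, dtype="Int64"),
        "effect_allele": ea, "other_allele": oa, "eaf": eaf, "beta": beta,
        "se": se, "pval": _two_sided_p(beta, se),
        "n": pd.array([n] * len(ids), dtype="Int64"),
    })
    return SumstatsTable(label, df)


def simulate_chain(cfg: SimConfig):
    """Generate (exposure, mediator, outcome, ld, truth) for one replicate."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_snp + cfg.n_snp_med
    ids = [f"rs{i + 1:05d}" for i in range(n_total)]
    exp_ids, med_ids = ids[:cfg.n_snp], ids[cfg.n_snp:]

    # genomic layout: LD blocks of consecutive SNPs, blocks far apart
    n_blocks = -(-n_total // cfg.ld_block_size)
    chrom, pos = [], []
    for i in range(n_total):
        block, within = divmod(i, cfg.ld_block_size)
        chrom.append(str(1 + block % 22))
        pos.append(1_000_000 + (block // 22) * 10_000_000 + within * 10_000)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    maf = rng.uniform(*cfg.maf_range, size=n_total)

    gamma = np.zeros(n_total)
    gamma[:cfg.n_snp] = rng.normal(0.0, cfg.gamma_sd, size=cfg.n_snp)
    eta = np.zeros(n_total)
    eta[cfg.n_snp:] = rng.normal(0.0, cfg.gamma_sd, size=cfg.n_snp_med)

    pleio = np.zeros(n_total)
    n_pleio = int(round(cfg.pleio_frac * cfg.n_snp))
    pleio_pos = rng.choice(cfg.n_snp, size=n_pleio, replace=False) if n_pleio else []
    if n_pleio:
        pleio[pleio_pos] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n_pleio)

    truth_exposure = gamma
    truth_mediator = cfg.alpha * gamma + eta
    truth_outcome = (cfg.delta + cfg.alpha * cfg.theta) * gamma \
        + cfg.theta * eta + pleio

    var_term = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_term * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(var_term * cfg.n_mediator)
    se_y = 1.0 / np.sqrt(var_term * cfg.n_outcome)

    exposure = _make_table("exposure", ids, chrom, pos, ea, oa, maf,
                           truth_exposure, se_x, cfg.n_exposure, rng)
    mediator = _make_table("mediator", ids, chrom, pos, ea, oa, maf,
                           truth_mediator, se_m, cfg.n_mediator, rng)
    outcome = _make_table("outcome", ids, chrom, pos, ea, oa, maf,
                          truth_outcome, se_y, cfg.n_outcome, rng)

    r2 = np.eye(n_total)
    if cfg.ld_block_size > 1 and cfg.ld_r2 > 0:
        for b in range(n_blocks):
            lo = b * cfg.ld_block_size
            hi = min(lo + cfg.ld_block_size, n_total)
            r2[lo:hi, lo:hi] = cfg.ld_r2
            np.fill_diagonal(r2[lo:hi, lo:hi], 1.0)
    ld = LDMatrix(ids, r2, {v: (c, p) for v, c, p in zip(ids, chrom, pos)})

    truth = SimTruth(
        gamma=pd.Series(gamma, index=ids),
        eta=pd.Series(eta[cfg.n_snp:], index=med_ids),
        pleiotropy=pd.Series(pleio, index=ids),
        alpha=cfg.alpha, theta=cfg.theta, delta=cfg.delta,
        pleio_ids=[ids[i] for i in pleio_pos],
        exposure_instrument_ids=exp_ids,
        mediator_instrument_ids=med_ids,
    )
    return exposure, mediator, outcome, ld, truth


def perturb_allele_coding(table: SumstatsTable, flip_frac: float,
                          palindrome_frac: float, seed: int) -> SumstatsTable:
    """Stress-test harmonization by re-orienting and palindromizing rows.

    A ``flip_frac`` subset has effect/other alleles swapped with beta negated
    and eaf complemented (an equivalent re-coding of the same association);
    a ``palindrome_frac`` subset has its allele pair rewritten to A/T or C/G.
    Affected ids are recorded in ``meta["flipped_ids"]`` /
    ``meta["palindromized_ids"]``.
    """
    for name, frac in (("flip_frac", flip_frac), ("palindrome_frac", palindrome_frac)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    n = len(df)
    flip = rng.random(n) < flip_frac
    pal = rng.random(n) < palindrome_frac

    if pal.any():
        choice = rng.random(n) < 0.5
        new_ea = np.where(choice, "A", "C")
        new_oa = np.where(choice, "T", "G")
        df.loc[pal, "effect_allele"] = new_ea[pal]
        df.loc[pal, "other_allele"] = new_oa[pal]
    if flip.any():
        ea = df.loc[flip, "effect_allele"].copy()
        df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"].to_numpy()
        df.loc[flip, "other_allele"] = ea.to_numpy()
        df.loc[flip, "beta"] = -df.loc[flip, "beta"]
        df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]

    ids = df["variant_id"].to_numpy()
    out = SumstatsTable(table.trait_label, df.reset_index(drop=True))
    out.meta["flipped_ids"] = ids[flip].tolist()
    out.meta["palindromized_ids"] = ids[pal].tolist()
    return out


def plant_outliers(outcome: SumstatsTable, truth: SimTruth, k: int,
                   offset_in_se: float, seed: int,
                   orient: str = "exposure_increasing"):
    """Add a pleiotropic offset of ``offset_in_se`` outcome SEs to ``k``
    randomly chosen exposure instruments; records the ids in the truth.

    With ``orient="exposure_increasing"`` (default) the offset is applied on
    each instrument's exposure-increasing orientation (multiplied by
    sign(gamma_true)), i.e. directional horizontal pleiotropy — the scenario
    outlier-correction is meant to repair.  ``orient="coded"`` applies the
    offset in the table's allele coding as-is, which (coding being arbitrary)
    amounts to balanced pleiotropy.
    """
    if orient not in ("exposure_increasing", "coded"):
        raise ValueError(f"unknown orient: {orient}")
    n_instr = len(truth.exposure_instrument_ids)
    if k >= n_instr:
        raise ValueError("k must be smaller than the number of instruments")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(truth.exposure_instrument_ids, size=k,
                               replace=False).tolist())
    df = outcome.df.copy()
    mask = df["variant_id"].isin(chosen)
    direction = 1.0
    if orient == "exposure_increasing":
        direction = np.sign(truth.gamma.loc[
            df.loc[mask, "variant_id"]].to_numpy())
        direction[direction == 0] = 1.0
    df.loc[mask, "beta"] = (df.loc[mask, "beta"]
                            + direction * offset_in_se * df.loc[mask, "se"])
    df.loc[mask, "pval"] = _two_sided_p(df.loc[mask, "beta"].to_numpy(float),
                                        df.loc[mask, "se"].to_numpy(float))
    new_truth = dataclasses.replace(truth, outlier_ids=chosen)
    return SumstatsTable(outcome.trait_label, df), new_truth
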