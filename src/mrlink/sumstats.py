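"""GWAS summary-statistics tables: reading, writing, validation and allele
harmonization.

The canonical on-disk dialect is tab-delimited with header
``variant_id chrom pos effect_allele other_allele eaf beta se pval n`` and
``NA`` for missing values.  ``read_sumstats`` additionally accepts common
header spellings (GWAS-SSF-like) through a built-in alias table, and any
other dialect through an explicit ``column_map``.

Harmonization aligns the SNP-outcome associations of a shared instrument set
to the effect allele of the exposure study, producing the
(gamma_j, se_gamma_j, Gamma_j, se_Gamma_j) quadruples every two-sample MR
estimator consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

MANDATORY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

#: accepted lower-cased header spellings, canonical name first
COLUMN_ALIASES: dict[str, list[str]] = {
    "variant_id": ["variant_id", "rsid", "rs_id", "snp", "id", "markername", "variant"],
    "chrom": ["chrom", "chromosome", "chr"],
    "pos": ["pos", "base_pair_location", "bp", "position"],
    "effect_allele": ["effect_allele", "ea", "a1", "allele1", "alt"],
    "other_allele": ["other_allele", "oa", "a2", "allele2", "non_effect_allele", "ref"],
    "eaf": ["eaf", "effect_allele_frequency", "freq", "af", "frq", "maf"],
    "beta": ["beta", "b", "effect", "beta_hat"],
    "se": ["se", "standard_error", "stderr", "sebeta"],
    "pval": ["pval", "p_value", "p", "pvalue"],
    "n": ["n", "sample_size", "n_total"],
}

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: two-sided 97.5% normal quantile, used for every 95% interval in the package
Z_975 = float(stats.norm.ppf(0.975))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise ValueError(f"non-ACGT allele pair: {effect_allele}/{other_allele}")
    return _COMPLEMENT[ea] == oa


@dataclass
class SumstatsTable:
    """Per-variant association summaries for one trait.

    ``df`` holds the canonical columns; ``variant_id`` values are unique and
    row order is stable under a write -> read round trip.
    """

    trait_label: str
    df: pd.DataFrame
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def subset(self, variant_ids) -> "SumstatsTable":
        """Rows whose id is in ``variant_ids``, original order preserved."""
        wanted = set(variant_ids)
        out = self.df[self.df["variant_id"].isin(wanted)].reset_index(drop=True)
        return SumstatsTable(self.trait_label, out)

    def copy(self) -> "SumstatsTable":
        return SumstatsTable(self.trait_label, self.df.copy(), self.n_dropped,
                             dict(self.meta))


@dataclass
class HarmonizedSet:
    """Instruments with exposure and outcome effects on a shared effect allele.

    Columns: variant_id, gamma, se_gamma, Gamma, se_Gamma, eaf, flipped,
    palindromic; sorted by variant_id.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.df["se_gamma"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.df["Gamma"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.df["se_Gamma"].to_numpy(float)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def subset(self, variant_ids) -> "HarmonizedSet":
        wanted = set(variant_ids)
        out = self.df[self.df["variant_id"].isin(wanted)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_label, self.outcome_label, out)

    def drop(self, variant_ids) -> "HarmonizedSet":
        unwanted = set(variant_ids)
        out = self.df[~self.df["variant_id"].isin(unwanted)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_label, self.outcome_label, out)


def _resolve_columns(header: list[str], column_map: dict | None) -> dict[str, str]:
    """Map canonical field names to actual file headers."""
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon in CANONICAL_COLUMNS:
        if canon in column_map:
            if column_map[canon] not in header:
                raise ValueError(
                    f"column_map names column {column_map[canon]!r} for "
                    f"{canon!r} but the file has no such header")
            resolved[canon] = column_map[canon]
            continue
        for alias in COLUMN_ALIASES[canon]:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    return resolved


def read_sumstats(path, column_map: dict | None = None,
                  trait_label: str | None = None) -> SumstatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Rows failing validation (unparseable beta/se, non-positive se, p outside
    (0,1], invalid alleles, out-of-range eaf) are dropped and counted in
    ``table.n_dropped``.  Duplicated variant_id keeps the lowest-p row.
    A missing p-value column is reconstructed from the two-sided normal tail
    of beta/se.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      na_values=["", "NA", "NaN", "nan", "na"],
                      float_precision="round_trip")
    resolved = _resolve_columns(list(raw.columns), column_map)

    df = pd.DataFrame(index=raw.index)
    df["variant_id"] = raw[resolved["variant_id"]].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = raw[resolved[col]].astype(str).str.strip().str.upper()
    def _to_float(series: pd.Series) -> pd.Series:
        # float() is correctly rounded, keeping write->read bit-exact
        def parse(x):
            if x is None or (isinstance(x, float) and np.isnan(x)):
                return np.nan
            try:
                return float(x)
            except (TypeError, ValueError):
                return np.nan
        return series.map(parse).astype(float)

    for col in ("eaf", "beta", "se", "pval"):
        df[col] = _to_float(raw[resolved[col]]) if col in resolved else np.nan
    for col in ("chrom",):
        df[col] = raw[resolved[col]].astype(str).str.strip() if col in resolved else pd.NA
    for col in ("pos", "n"):
        if col in resolved:
            df[col] = pd.to_numeric(raw[resolved[col]], errors="coerce").round().astype("Int64")
        else:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")

    if "pval" not in resolved:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(df["beta"] / df["se"])
        df["pval"] = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)

    allele_ok = (
        df["effect_allele"].isin(list(VALID_ALLELES))
        & df["other_allele"].isin(list(VALID_ALLELES))
        & (df["effect_allele"] != df["other_allele"])
    )
    eaf_ok = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    n_ok = df["n"].isna() | (df["n"] > 0)
    valid = (
        df["variant_id"].ne("")
        & df["beta"].notna()
        & df["se"].notna() & (df["se"] > 0)
        & df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
        & allele_ok & eaf_ok & n_ok
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} invalid row(s)", stacklevel=2)
    df = df[valid]

    n_dup = int(df["variant_id"].duplicated().sum())
    if n_dup:
        warnings.warn(
            f"{path}: {n_dup} duplicated variant_id row(s); keeping lowest p-value",
            stacklevel=2)
        keep = df.groupby("variant_id", sort=False)["pval"].idxmin()
        df = df.loc[sorted(keep)]

    df = df[CANONICAL_COLUMNS].reset_index(drop=True)
    label = trait_label if trait_label is not None else str(path)
    table = SumstatsTable(label, df, n_dropped=n_dropped,
                          meta={"n_duplicates": n_dup})
    return table


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write the canonical tab-delimited dialect at full double precision."""
    out = table.df[CANONICAL_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def harmonize_pair(exposure: SumstatsTable, outcome: SumstatsTable,
                   palindrome_policy: str = "drop_ambiguous",
                   eaf_ambiguity_band: float = 0.08) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect alleles.

    For each shared variant: identical allele pairs are kept as-is; swapped
    pairs (effect <-> other) have the outcome beta negated and eaf
    complemented; non-palindromic pairs are also matched across strands via
    base complement.  Palindromic variants are handled per
    ``palindrome_policy``:

    - ``drop_all``: exclude every palindromic variant;
    - ``keep``: align by allele letters only (strand assumed shared);
    - ``drop_ambiguous`` (default): exclude those with missing eaf or minor
      allele frequency within ``eaf_ambiguity_band`` of 0.5 in either study,
      and align the remainder so minor/major orientation agrees.

    Incompatible allele pairs are dropped.  Rows are sorted by variant_id.
    """
    if palindrome_policy not in ("drop_all", "drop_ambiguous", "keep"):
        raise ValueError(f"unknown palindrome_policy: {palindrome_policy}")
    m = exposure.df.merge(outcome.df, on="variant_id", suffixes=("_x", "_y"))
    if m.empty:
        raise ValueError("no shared instruments between exposure and outcome")

    ea_x, oa_x = m["effect_allele_x"], m["other_allele_x"]
    ea_y, oa_y = m["effect_allele_y"], m["other_allele_y"]
    cea_y, coa_y = ea_y.map(_COMPLEMENT), oa_y.map(_COMPLEMENT)

    pal = (ea_x.map(_COMPLEMENT) == oa_x).to_numpy()
    same = ((ea_y == ea_x) & (oa_y == oa_x)).to_numpy()
    swap = ((ea_y == oa_x) & (oa_y == ea_x)).to_numpy()
    csame = ((cea_y == ea_x) & (coa_y == oa_x)).to_numpy()
    cswap = ((cea_y == oa_x) & (coa_y == ea_x)).to_numpy()

    flip = np.zeros(len(m), dtype=bool)
    drop = np.zeros(len(m), dtype=bool)

    nonpal = ~pal
    keep_asis = nonpal & (same | csame)
    keep_flip = nonpal & (swap | cswap) & ~keep_asis
    flip |= keep_flip
    drop |= nonpal & ~(keep_asis | keep_flip)

    # for palindromic pairs the complement matches coincide with the direct
    # ones, so only same/swap discriminate
    compat = pal & (same | swap)
    drop |= pal & ~compat
    if palindrome_policy == "drop_all":
        drop |= pal
    else:
        flip |= compat & swap
        if palindrome_policy == "drop_ambiguous":
            eaf_x = m["eaf_x"].to_numpy(float)
            eaf_y = m["eaf_y"].to_numpy(float)
            with np.errstate(invalid="ignore"):
                band = eaf_ambiguity_band + 1e-12   # closed band, fp-safe
                ambiguous = (
                    np.isnan(eaf_x) | np.isnan(eaf_y)
                    | (np.abs(eaf_x - 0.5) <= band)
                    | (np.abs(eaf_y - 0.5) <= band)
                )
            drop |= compat & ambiguous
            check = compat & ~ambiguous
            eaf_y_adj = np.where(flip, 1.0 - eaf_y, eaf_y)
            with np.errstate(invalid="ignore"):
                mismatch = (eaf_x < 0.5) != (eaf_y_adj < 0.5)
            flip = flip ^ (check & mismatch)

    keep = ~drop
    if not keep.any():
        raise ValueError("all shared variants dropped during harmonization")

    Gamma = np.where(flip, -m["beta_y"].to_numpy(float), m["beta_y"].to_numpy(float))
    out = pd.DataFrame({
        "variant_id": m["variant_id"],
        "gamma": m["beta_x"].to_numpy(float),
        "se_gamma": m["se_x"].to_numpy(float),
        "Gamma": Gamma,
        "se_Gamma": m["se_y"].to_numpy(float),
        "eaf": m["eaf_x"].to_numpy(float),
        "flipped": flip,
        "palindromic": pal,
    })[keep]
    out = out.sort_values("variant_id", kind="mergesort").reset_index(drop=True)
    return HarmonizedSet(exposure.trait_label, outcome.trait_label, out)
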