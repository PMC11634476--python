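"""Instrument selection: association threshold, greedy LD clumping, and
F-statistic screening of weak instruments.

Defaults follow common drug-target MR practice for molecular instruments:
p < 1e-4, removal of neighbours with r^2 > 0.8 within 250 kb, and F > 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SumstatsTable


@dataclass
class SelectionConfig:
    p_threshold: float = 1e-4
    r2_max: float = 0.8
    window_kb: float = 250.0
    f_min: float = 10.0

    def __post_init__(self):
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")


@dataclass
class InstrumentStrength:
    """Per-variant and aggregate instrument strength, F_j = (beta_j/se_j)^2."""

    f: pd.Series            # indexed by variant_id
    mean_f: float
    n_weak: int


class LDMatrix:
    """Symmetric r^2 matrix over named variants with genomic positions.

    On disk: a tab-delimited square matrix whose header row and first column
    are variant ids, plus a positions sidecar (variant_id, chrom, pos).
    """

    def __init__(self, variant_ids, r2, positions):
        self.variant_ids = list(variant_ids)
        self.r2 = np.asarray(r2, dtype=float)
        self.positions = dict(positions)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        self._validate()

    def _validate(self, tol: float = 1e-8) -> None:
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix dimensions do not match variant_ids")
        if len(self._index) != n:
            raise ValueError("duplicate variant_id in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=tol):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=tol):
            raise ValueError("LD matrix diagonal must be 1")
        if np.nanmin(self.r2) < -tol or np.nanmax(self.r2) > 1 + tol:
            raise ValueError("r2 values must lie in [0, 1]")
        missing = [v for v in self.variant_ids if v not in self.positions]
        if missing:
            raise ValueError(f"positions missing for {len(missing)} variant(s)")

    def __contains__(self, variant_id) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def save(self, matrix_path, positions_path) -> None:
        mat = pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)
        mat.to_csv(matrix_path, sep="\t", index_label="variant_id",
                   float_format="%.17g")
        pos = pd.DataFrame(
            [(v, *self.positions[v]) for v in self.variant_ids],
            columns=["variant_id", "chrom", "pos"])
        pos.to_csv(positions_path, sep="\t", index=False)

    @classmethod
    def load(cls, matrix_path, positions_path) -> "LDMatrix":
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        pos = pd.read_csv(positions_path, sep="\t", dtype={"chrom": str})
        positions = {r.variant_id: (str(r.chrom), int(r.pos))
                     for r in pos.itertuples()}
        return cls(list(mat.columns), mat.to_numpy(float), positions)


def select_by_pvalue(table: SumstatsTable, p_threshold: float) -> SumstatsTable:
    """Rows with p strictly below the threshold, original order preserved.

    A threshold of 1 keeps everything (p-values live in (0, 1], so the
    strict inequality would otherwise drop p exactly 1).
    """
    if p_threshold >= 1.0:
        return SumstatsTable(table.trait_label, table.df.reset_index(drop=True))
    out = table.df[table.df["pval"] < p_threshold].reset_index(drop=True)
    return SumstatsTable(table.trait_label, out)


def clump(table: SumstatsTable, ld: LDMatrix, r2_max: float = 0.8,
          window_kb: float = 250.0) -> SumstatsTable:
    """Greedy best-p-first LD clumping.

    Candidates are ordered by ascending p (ties by variant_id); the best
    remaining variant is retained as index and every other remaining variant
    on the same chromosome within ``window_kb`` and with r^2 > ``r2_max``
    against it is removed.  Variants absent from the LD matrix pass through
    untouched with a warning.  Output keeps original table order.
    """
    df = table.df
    present = df["variant_id"].isin(ld.variant_ids).to_numpy()
    n_absent = int((~present).sum())
    if n_absent:
        warnings.warn(f"{n_absent} variant(s) absent from LD matrix pass "
                      "through clumping untouched", stacklevel=2)

    cand = df[present][["variant_id", "pval"]]
    order = cand.sort_values(["pval", "variant_id"],
                             kind="mergesort")["variant_id"].tolist()
    window_bp = window_kb * 1000.0
    remaining = set(order)
    retained: set[str] = set()
    for vid in order:
        if vid not in remaining:
            continue
        retained.add(vid)
        remaining.discard(vid)
        chrom_i, pos_i = ld.positions[vid]
        for other in list(remaining):
            chrom_o, pos_o = ld.positions[other]
            if (chrom_o == chrom_i and abs(pos_o - pos_i) <= window_bp
                    and ld.r2_between(vid, other) > r2_max):
                remaining.discard(other)

    keep = df["variant_id"].isin(retained).to_numpy() | ~present
    out = df[keep].reset_index(drop=True)
    return SumstatsTable(table.trait_label, out)


def f_statistics(table: SumstatsTable, f_min: float = 10.0) -> InstrumentStrength:
    """Per-variant F = (beta/se)^2, their mean, and the weak-instrument count."""
    beta = table.df["beta"].to_numpy(float)
    se = table.df["se"].to_numpy(float)
    f = (beta / se) ** 2
    series = pd.Series(f, index=table.df["variant_id"].tolist(), name="F")
    return InstrumentStrength(f=series, mean_f=float(np.mean(f)) if len(f) else float("nan"),
                              n_weak=int(np.sum(f < f_min)))


def filter_weak(table: SumstatsTable, f_min: float = 10.0) -> SumstatsTable:
    """Retain instruments with F strictly above ``f_min``."""
    beta = table.df["beta"].to_numpy(float)
    se = table.df["se"].to_numpy(float)
    keep = (beta / se) ** 2 > f_min
    if not keep.any():
        raise ValueError("no instruments survive F filter")
    out = table.df[keep].reset_index(drop=True)
    return SumstatsTable(table.trait_label, out)
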