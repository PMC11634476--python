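"""Reading, writing and harmonizing GWAS summary statistics."""

import numpy as np
import pandas as pd
import pytest

from mrlink import (read_sumstats, write_sumstats, is_palindromic,
                    harmonize_pair, ivw, simulate_chain, SimConfig)
from mrlink.simulate import perturb_allele_coding

from conftest import make_sumstats


def _row(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-5, **kw):
    return dict(variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=beta, se=se, pval=pval, **kw)


class TestReadWrite:
    def test_round_trip_is_identity(self, chain, tmp_path):
        exposure = chain[0]
        path = tmp_path / "exp.tsv"
        write_sumstats(exposure, path)
        back = read_sumstats(path, trait_label=exposure.trait_label)
        pd.testing.assert_frame_equal(back.df, exposure.df, check_exact=True)
        # second round trip re-serializes identically
        path2 = tmp_path / "exp2.tsv"
        write_sumstats(back, path2)
        assert path.read_text() == path2.read_text()

    def test_full_precision_survives(self, tmp_path):
        t = make_sumstats([_row(beta=-0.290), _row(vid="rs2", beta=1 / 3)])
        write_sumstats(t, tmp_path / "t.tsv")
        back = read_sumstats(tmp_path / "t.tsv")
        assert back.df["beta"].iloc[0] == -0.290
        assert back.df["beta"].iloc[1] == 1 / 3

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "variant_id\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-5\n"
            "rs2\tA\tG\t0.1\tNA\t1e-5\n"       # missing se
            "rs3\tA\tG\t0.1\t-0.01\t1e-5\n"    # negative se
            "rs4\tA\tN\t0.1\t0.01\t1e-5\n"     # bad allele
            "rs5\tA\tG\t0.1\t0.01\t0\n")       # p outside (0,1]
        with pytest.warns(UserWarning, match="dropped 4"):
            t = read_sumstats(path)
        assert len(t) == 1 and t.n_dropped == 4
        assert t.variant_ids == ["rs1"]

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        path = tmp_path / "nobeta.tsv"
        path.write_text("variant_id\teffect_allele\tother_allele\tse\tpval\n"
                        "rs1\tA\tG\t0.01\t1e-5\n")
        with pytest.raises(ValueError, match="beta"):
            read_sumstats(path)

    def test_alias_headers_and_column_map(self, tmp_path):
        path = tmp_path / "gwas.csv"
        path.write_text("SNP,CHR,BP,A1,A2,FRQ,BETA,SE,P,N\n"
                        "rs1,2,500,a,g,0.25,0.1,0.01,1e-5,5000\n")
        t = read_sumstats(path)
        assert t.df["effect_allele"].iloc[0] == "A"   # upper-cased
        assert t.df["pos"].iloc[0] == 500
        t2 = read_sumstats(path, column_map={"beta": "BETA", "se": "SE"})
        assert t2.df["beta"].iloc[0] == 0.1

    def test_missing_pval_column_reconstructed(self, tmp_path):
        path = tmp_path / "nop.tsv"
        path.write_text("variant_id\teffect_allele\tother_allele\tbeta\tse\n"
                        "rs1\tA\tG\t0.02\t0.01\n")
        t = read_sumstats(path)
        from scipy import stats
        assert t.df["pval"].iloc[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_duplicate_id_keeps_lowest_p(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("variant_id\teffect_allele\tother_allele\tbeta\tse\tpval\n"
                        "rs1\tA\tG\t0.1\t0.01\t1e-3\n"
                        "rs1\tA\tG\t0.2\t0.01\t1e-8\n")
        with pytest.warns(UserWarning, match="duplicated"):
            t = read_sumstats(path)
        assert len(t) == 1 and t.df["beta"].iloc[0] == 0.2

    def test_empty_table_writes_header_only(self, tmp_path):
        t = make_sumstats([_row()]).subset([])
        write_sumstats(t, tmp_path / "empty.tsv")
        lines = (tmp_path / "empty.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("variant_id\t")


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
])
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(ValueError):
        is_palindromic("A", "N")


class TestHarmonize:
    def test_swapped_alleles_negate_outcome(self):
        exp = make_sumstats([_row()])
        out = make_sumstats([_row(ea="G", oa="A", beta=0.10)], label="out")
        h = harmonize_pair(exp, out)
        assert h.Gamma[0] == -0.10
        assert bool(h.df["flipped"].iloc[0])

    def test_strand_complement_match(self):
        exp = make_sumstats([_row(ea="A", oa="G")])
        # T/C is the complement of A/G on the other strand: same orientation
        out = make_sumstats([_row(ea="T", oa="C", beta=0.10)], label="out")
        h = harmonize_pair(exp, out)
        assert h.Gamma[0] == 0.10 and not h.df["flipped"].iloc[0]
        # C/T is complement-swapped: flip
        out2 = make_sumstats([_row(ea="C", oa="T", beta=0.10)], label="out")
        h2 = harmonize_pair(exp, out2)
        assert h2.Gamma[0] == -0.10 and bool(h2.df["flipped"].iloc[0])

    def test_incompatible_pairs_dropped(self):
        exp = make_sumstats([_row(), _row(vid="rs2")])
        out = make_sumstats([_row(), _row(vid="rs2", ea="A", oa="C")], label="o")
        h = harmonize_pair(exp, out)
        assert h.variant_ids == ["rs1"]

    def test_ambiguous_palindrome_dropped(self):
        exp = make_sumstats([_row(ea="A", oa="T", eaf=0.50), _row(vid="rs2")])
        out = make_sumstats([_row(ea="A", oa="T", eaf=0.50), _row(vid="rs2")],
                            label="o")
        h = harmonize_pair(exp, out, palindrome_policy="drop_ambiguous")
        assert h.variant_ids == ["rs2"]
        # band boundary: eaf 0.42 still dropped, 0.41 kept
        for eaf, kept in [(0.42, False), (0.41, True)]:
            e = make_sumstats([_row(ea="A", oa="T", eaf=eaf), _row(vid="rs2")])
            o = make_sumstats([_row(ea="A", oa="T", eaf=eaf), _row(vid="rs2")],
                              label="o")
            assert ("rs1" in harmonize_pair(e, o).variant_ids) is kept

    def test_palindrome_eaf_orientation(self):
        # same letters but opposite minor-allele orientation: needs a flip
        exp = make_sumstats([_row(ea="A", oa="T", eaf=0.10)])
        out = make_sumstats([_row(ea="A", oa="T", eaf=0.90, beta=0.2)], label="o")
        h = harmonize_pair(exp, out)
        assert h.Gamma[0] == -0.2 and bool(h.df["flipped"].iloc[0])

    def test_drop_all_policy(self):
        exp = make_sumstats([_row(ea="C", oa="G", eaf=0.2), _row(vid="rs2")])
        out = make_sumstats([_row(ea="C", oa="G", eaf=0.2), _row(vid="rs2")],
                            label="o")
        h = harmonize_pair(exp, out, palindrome_policy="drop_all")
        assert h.variant_ids == ["rs2"]

    def test_no_shared_instruments_raises(self):
        exp = make_sumstats([_row()])
        out = make_sumstats([_row(vid="rsX")], label="o")
        with pytest.raises(ValueError, match="no shared instruments"):
            harmonize_pair(exp, out)

    def test_idempotent_on_aligned_pair(self, chain):
        exposure, _, outcome, _, truth = chain
        h = harmonize_pair(exposure, outcome)
        assert not h.df["flipped"].any()
        # gamma column is exactly the exposure betas, outcome untouched
        merged = exposure.df.set_index("variant_id").loc[h.variant_ids]
        np.testing.assert_array_equal(h.gamma, merged["beta"].to_numpy())

    def test_orientation_invariance(self, chain):
        """Arbitrary allele re-coding of the outcome leaves harmonized
        effects (and downstream IVW) unchanged."""
        exposure, _, outcome, _, truth = chain
        base = harmonize_pair(exposure, outcome)
        beta0 = ivw(base)[0].beta
        for seed in (1, 2, 3):
            flipped = perturb_allele_coding(outcome, flip_frac=0.5,
                                            palindrome_frac=0.0, seed=seed)
            h = harmonize_pair(exposure, flipped)
            assert h.variant_ids == base.variant_ids
            np.testing.assert_allclose(h.Gamma, base.Gamma, rtol=0, atol=0)
            assert ivw(h)[0].beta == pytest.approx(beta0, abs=1e-12)
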