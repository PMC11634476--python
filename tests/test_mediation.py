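"""Delta-method mediation proportions, two-step MR, and mediator screening."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mrlink import (MREstimate, mediation_effect, two_step_mediation,
                    screen_mediators, ScreenConfig, ivw, harmonize_pair,
                    SimConfig, simulate_chain, Z_975, SumstatsTable)

from conftest import make_sumstats


def est(beta, se=0.05):
    return MREstimate.from_beta_se("test", beta, se, 10)


# reference insulin-resistance chain, stage SEs back-derived from its
# 95% CIs (half-width / (2 * z_0.975))
B1 = est(-0.207, 0.164 / 3.9199)
B2 = est(0.274, 0.223 / 3.9199)
BT = est(-0.290, 0.109 / 1.9599)


class TestMediationEffect:
    def test_worked_example_proportion(self):
        res = mediation_effect(B1, B2, BT)
        assert round(res.proportion_pct, 2) == 19.56
        assert res.indirect == pytest.approx((-0.207) * 0.274, rel=1e-14)

    def test_null_first_stage(self):
        res = mediation_effect(est(0.0), B2, BT)
        assert res.indirect == 0.0 and res.proportion == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="undefined proportion"):
            mediation_effect(B1, B2, est(0.0))

    def test_warns_outside_unit_interval(self):
        with pytest.warns(UserWarning, match="outside"):
            mediation_effect(est(0.5), est(0.9), est(0.1))

    def test_symbolic_delta_oracle(self):
        """Fixed-denominator CI endpoints match an independent symbolic
        delta-method computation."""
        import sympy as sp
        b1, b2, bt, s1, s2 = sp.symbols("b1 b2 bt s1 s2", positive=False)
        prop = b1 * b2 / bt
        var = (sp.diff(prop, b1) * s1) ** 2 + (sp.diff(prop, b2) * s2) ** 2
        subs = {b1: B1.beta, b2: B2.beta, bt: BT.beta, s1: B1.se, s2: B2.se}
        p0 = float(prop.subs(subs))
        se0 = float(sp.sqrt(var).subs(subs))
        res = mediation_effect(B1, B2, BT, denominator_mode="fixed")
        assert res.proportion == pytest.approx(p0, abs=1e-12)
        assert res.proportion_se == pytest.approx(se0, abs=1e-12)
        assert res.proportion_ci_low == pytest.approx(p0 - Z_975 * se0, abs=1e-10)
        assert res.proportion_ci_high == pytest.approx(p0 + Z_975 * se0, abs=1e-10)

    def test_propagated_mode_adds_denominator_variance(self):
        fixed = mediation_effect(B1, B2, BT, denominator_mode="fixed")
        prop = mediation_effect(B1, B2, BT, denominator_mode="propagated")
        assert prop.proportion == fixed.proportion
        assert prop.proportion_se > fixed.proportion_se
        rel = (fixed.indirect_se ** 2 / fixed.indirect ** 2
               + BT.se ** 2 / BT.beta ** 2)
        expected = abs(fixed.proportion) * np.sqrt(rel)
        assert prop.proportion_se == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_in_mediator_units(self):
        """Rescaling the mediator trait leaves indirect effect, proportion
        and fixed-mode SE unchanged."""
        c = 3.7
        scaled = mediation_effect(est(B1.beta * c, B1.se * c),
                                  est(B2.beta / c, B2.se / c), BT)
        base = mediation_effect(B1, B2, BT)
        assert scaled.indirect == pytest.approx(base.indirect, abs=1e-10)
        assert scaled.proportion == pytest.approx(base.proportion, abs=1e-10)
        assert scaled.proportion_se == pytest.approx(base.proportion_se, abs=1e-10)


class TestTwoStepMediation:
    def test_stages_match_manual_ivw(self, chain):
        exposure, mediator, outcome, _, truth = chain
        exp_ids = truth.exposure_instrument_ids
        med_ids = truth.mediator_instrument_ids
        res = two_step_mediation(exposure, mediator, outcome, exp_ids, med_ids)
        xm, _ = ivw(harmonize_pair(exposure.subset(exp_ids), mediator))
        my, _ = ivw(harmonize_pair(mediator.subset(med_ids), outcome))
        tot, _ = ivw(harmonize_pair(exposure.subset(exp_ids), outcome))
        assert res.beta_xm.beta == xm.beta
        assert res.beta_my.beta == my.beta
        assert res.beta_total.beta == tot.beta
        ref = mediation_effect(xm, my, tot)
        assert res.proportion == ref.proportion

    def test_recovers_true_proportion_roughly(self, chain):
        _, _, _, _, truth = chain
        exposure, mediator, outcome, _, t = chain
        res = two_step_mediation(exposure, mediator, outcome,
                                 t.exposure_instrument_ids,
                                 t.mediator_instrument_ids)
        assert res.proportion == pytest.approx(t.mediation_proportion, abs=0.1)

    def test_overlapping_instruments_excluded(self, chain):
        exposure, mediator, outcome, _, truth = chain
        med_ids = truth.mediator_instrument_ids + truth.exposure_instrument_ids[:2]
        with pytest.warns(UserWarning, match="excluding 2"):
            res = two_step_mediation(exposure, mediator, outcome,
                                     truth.exposure_instrument_ids, med_ids)
        clean = two_step_mediation(exposure, mediator, outcome,
                                   truth.exposure_instrument_ids,
                                   truth.mediator_instrument_ids)
        assert res.beta_my.beta == clean.beta_my.beta

    def test_null_mediator_path(self):
        cfg = SimConfig(seed=31, alpha=0.0, delta=-0.3)
        exposure, mediator, outcome, _, truth = simulate_chain(cfg)
        assert truth.mediation_proportion == 0.0
        res = two_step_mediation(exposure, mediator, outcome,
                                 truth.exposure_instrument_ids,
                                 truth.mediator_instrument_ids)
        assert abs(res.indirect) < 0.05

    def test_missing_stage_instruments_named(self, chain):
        exposure, mediator, outcome, _, truth = chain
        with pytest.raises(ValueError, match="mediator->outcome"):
            two_step_mediation(exposure, mediator, outcome,
                               truth.exposure_instrument_ids, [])


def simulate_candidates(n_true, n_null, seed, n=200_000):
    """Multi-mediator chain: shared exposure and outcome, each candidate with
    its own instruments; true candidates sit on the causal path."""
    rng = np.random.default_rng(seed)
    n_exp, n_per = 30, 10
    labels = [f"M{i}" for i in range(n_true + n_null)]
    n_total = n_exp + n_per * len(labels)
    ids = [f"rs{i + 1:05d}" for i in range(n_total)]
    maf = rng.uniform(0.05, 0.5, n_total)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    gamma = np.zeros(n_total)
    gamma[:n_exp] = rng.normal(0, 0.15, n_exp)

    alpha = {lab: (-0.25 - 0.05 * i if i < n_true else 0.0)
             for i, lab in enumerate(labels)}
    theta = {lab: (0.25 + 0.05 * i if i < n_true else 0.0)
             for i, lab in enumerate(labels)}
    delta = -0.1

    def table(label, truth_vec):
        beta = truth_vec + rng.normal(0, se)
        from scipy import stats as st
        return SumstatsTable(label, pd.DataFrame({
            "variant_id": ids, "chrom": "1",
            "pos": pd.array(np.arange(n_total) * 10 ** 6 + 1, dtype="Int64"),
            "effect_allele": "A", "other_allele": "G", "eaf": maf,
            "beta": beta, "se": se,
            "pval": np.clip(2 * st.norm.sf(np.abs(beta / se)), 1e-300, 1),
            "n": pd.array([n] * n_total, dtype="Int64")}))

    candidates = []
    out_truth = delta * gamma
    for j, lab in enumerate(labels):
        eta = np.zeros(n_total)
        sl = slice(n_exp + j * n_per, n_exp + (j + 1) * n_per)
        eta[sl] = rng.normal(0, 0.15, n_per)
        med_truth = alpha[lab] * gamma + eta
        out_truth = out_truth + theta[lab] * (alpha[lab] * gamma + eta)
        med = table(lab, med_truth)
        candidates.append((lab, med, ids[sl]))
    exposure = table("exposure", gamma)
    outcome = table("outcome", out_truth)
    true_labels = labels[:n_true]
    return exposure, outcome, candidates, ids[:n_exp], true_labels


class TestScreen:
    def test_recovers_true_mediators(self):
        exposure, outcome, candidates, exp_ids, true_labels = \
            simulate_candidates(n_true=3, n_null=5, seed=71)
        screen = screen_mediators(exposure, outcome, candidates, exp_ids)
        got = set(screen.qualifiers)
        assert set(true_labels) <= got
        assert len(got - set(true_labels)) <= 1
        assert screen.n_positive + screen.n_negative >= 3

    def test_single_candidate_reduces_to_two_step(self):
        exposure, outcome, candidates, exp_ids, _ = \
            simulate_candidates(n_true=1, n_null=0, seed=72)
        label, med, med_ids = candidates[0]
        screen = screen_mediators(exposure, outcome, candidates, exp_ids)
        ref = two_step_mediation(exposure, med, outcome, exp_ids, med_ids)
        assert screen.qualifiers == [label]
        assert screen.results[label].proportion == pytest.approx(ref.proportion,
                                                                 rel=1e-12)

    def test_all_null_with_bonferroni(self):
        exposure, outcome, candidates, exp_ids, _ = \
            simulate_candidates(n_true=0, n_null=6, seed=73)
        cfg = ScreenConfig(multiplicity="bonferroni")
        screen = screen_mediators(exposure, outcome, candidates, exp_ids,
                                  cfg=cfg)
        assert screen.qualifiers == []

    def test_unusable_candidate_recorded(self):
        exposure, outcome, candidates, exp_ids, _ = \
            simulate_candidates(n_true=1, n_null=1, seed=74)
        label, med, _ = candidates[1]
        broken = [candidates[0], (label, med, [])]
        with pytest.warns(UserWarning, match="skipped"):
            screen = screen_mediators(exposure, outcome, broken, exp_ids)
        row = screen.df[screen.df["mediator"] == label].iloc[0]
        assert row["note"] == "no usable instruments"
        assert not row["qualifies"]

    def test_empty_candidates_raise(self):
        exposure, outcome, _, exp_ids, _ = simulate_candidates(1, 0, seed=75)
        with pytest.raises(ValueError, match="empty candidate"):
            screen_mediators(exposure, outcome, [], exp_ids)

    def test_export_and_volcano(self, tmp_path):
        exposure, outcome, candidates, exp_ids, _ = \
            simulate_candidates(n_true=2, n_null=2, seed=76)
        screen = screen_mediators(exposure, outcome, candidates, exp_ids)
        screen.to_tsv(tmp_path / "screen.tsv")
        assert (tmp_path / "screen.tsv").exists()
        v = screen.volcano_frame()
        assert {"mediator", "beta_my", "neg_log10_p"} <= set(v.columns)
        assert len(v) == 4
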