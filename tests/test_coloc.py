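"""Signal detection, Wakefield ABFs, and five-hypothesis colocalization."""

import numpy as np
import pytest

from pqtlx.coloc import (
    Signal,
    coloc_pair,
    colocalize_locus,
    detect_signals,
    summarize_concordance,
    wakefield_log_abf,
)
from pqtlx.experiments import run_one_locus
from pqtlx.ld import compute_ld
from pqtlx.simulate import LocusScenario, simulate_locus
from pqtlx.sumstats import apply_qc, harmonize_pair

from conftest import make_locus
from oracles import bruteforce_single_causal_pp


class TestWakefieldABF:
    def test_hand_computed_value(self):
        assert wakefield_log_abf(0.5, 0.1, 0.0225) == pytest.approx(8.0645, abs=1e-3)

    def test_null_effect_pays_occam_factor(self):
        V, W = 0.04, 0.0225
        got = wakefield_log_abf(0.0, 0.2, W)
        assert got == pytest.approx(0.5 * np.log(V / (V + W)))
        assert got <= 0

    def test_vanishing_prior_gives_zero_evidence(self):
        assert wakefield_log_abf(0.7, 0.1, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            wakefield_log_abf(np.inf, 0.1)
        with pytest.raises(ValueError):
            wakefield_log_abf(0.1, 0.0)


def _signal(beta, se, trait="a", lead=0):
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    return Signal(trait, None, lead, 1, beta, se)


class TestColocPair:
    def test_single_variant_locus_forces_pp3_zero(self):
        pair = coloc_pair(_signal([0.5], [0.05]), _signal([0.4], [0.05], "b"))
        assert pair.pp[3] == 0.0
        assert pair.pp[4] > 0.9

    def test_identical_strong_stats_favour_shared_over_distinct(self):
        beta, se = [0.5, 0.02], [0.05, 0.05]
        pair = coloc_pair(_signal(beta, se), _signal(beta, se, "b"))
        assert pair.pp[4] > pair.pp[3]

    def test_matches_bruteforce_enumeration_on_random_loci(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 12))
            ba, bb = rng.normal(0, 0.2, m), rng.normal(0, 0.2, m)
            sa, sb = rng.uniform(0.02, 0.1, m), rng.uniform(0.02, 0.1, m)
            pair = coloc_pair(_signal(ba, sa), _signal(bb, sb, "b"))
            want = bruteforce_single_causal_pp(list(ba), list(sa), list(bb), list(sb))
            np.testing.assert_allclose(pair.pp, want, atol=1e-12)

    def test_pp_and_pip_normalize(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 30))
            pair = coloc_pair(
                _signal(rng.normal(0, 0.3, m), rng.uniform(0.01, 0.2, m)),
                _signal(rng.normal(0, 0.3, m), rng.uniform(0.01, 0.2, m), "b"),
            )
            assert np.sum(pair.pp) == pytest.approx(1.0, abs=1e-9)
            assert np.sum(pair.pip) == pytest.approx(1.0, abs=1e-9)
            assert len(pair.credible_set) >= 1

    def test_pp4_monotone_in_shared_prior(self, rng):
        ba = rng.normal(0, 0.2, 8)
        sa = rng.uniform(0.02, 0.1, 8)
        bb = rng.normal(0, 0.2, 8)
        sb = rng.uniform(0.02, 0.1, 8)
        pp4 = [
            coloc_pair(_signal(ba, sa), _signal(bb, sb, "b"), priors=(1e-4, 1e-4, p12)).pp[4]
            for p12 in (1e-6, 1e-5, 1e-4, 1e-3)
        ]
        assert np.all(np.diff(pp4) >= 0)

    def test_label_symmetry_swaps_pp1_pp2(self, rng):
        ba, sa = rng.normal(0, 0.2, 6), rng.uniform(0.02, 0.1, 6)
        bb, sb = rng.normal(0, 0.2, 6), rng.uniform(0.02, 0.1, 6)
        fwd = coloc_pair(_signal(ba, sa), _signal(bb, sb, "b"))
        rev = coloc_pair(_signal(bb, sb, "b"), _signal(ba, sa))
        assert rev.pp[1] == pytest.approx(fwd.pp[2], abs=1e-12)
        assert rev.pp[2] == pytest.approx(fwd.pp[1], abs=1e-12)
        assert rev.pp[4] == pytest.approx(fwd.pp[4], abs=1e-12)


def _sim_harmonized(scenario):
    stats_a, stats_b, panel, truth = simulate_locus(scenario)
    a, b = harmonize_pair(apply_qc(stats_a), apply_qc(stats_b))
    ld = compute_ld(panel, a.keys())
    return a, b, ld, truth


class TestDetectSignals:
    def test_subthreshold_locus_yields_no_signals(self):
        sc = LocusScenario(label="NULL", m_variants=40, n_blocks=2, n_a=2_000,
                           n_b=500, n_panel=500, seed=21)
        a, b, ld, _ = _sim_harmonized(sc)
        assert detect_signals(a, ld) == []

    def test_single_causal_matches_exhaustive_scan_and_k_invariance(self):
        sc = LocusScenario(m_variants=50, n_blocks=5, n_a=8_000, n_b=2_000,
                          n_panel=2_000, seed=22)
        a, b, ld, truth = _sim_harmonized(sc)
        k1 = detect_signals(a, ld, K=1)
        k10 = detect_signals(a, ld, K=10)
        assert len(k1) == 1
        # oracle: with one signal the lead is the top marginal |z| variant
        z = np.abs(a.df["beta"] / a.df["se"]).to_numpy()
        assert k1[0].lead_idx == int(np.argmax(z))
        assert [s.lead_idx for s in k1] == [k10[0].lead_idx]
        # leave-one-out conditioning with one signal reduces to marginal stats
        n = a.df["n"].to_numpy(dtype=float)
        b_marginal = (a.df["beta"] / a.df["se"]).to_numpy() / np.sqrt(n)
        np.testing.assert_allclose(k1[0].cond_beta, b_marginal, atol=1e-15)

    def test_two_distant_causals_recovered(self):
        sc = LocusScenario(label="SHARED_CONCORDANT", n_shared=2, distinct_r2_max=0.01,
                           m_variants=100, n_blocks=5, h2_signal=0.01,
                           n_a=10_000, n_b=500, n_panel=2_000, seed=23)
        a, b, ld, truth = _sim_harmonized(sc)
        sigs = detect_signals(a, ld)
        assert len(sigs) == 2
        pos_to_idx = {k.pos: i for i, k in enumerate(ld.keys)}
        causal_idx = [pos_to_idx[truth["layout"].positions[c]] for c in truth["causal_a"]]
        for s in sigs:
            assert any(ld.r[s.lead_idx, c] ** 2 > 0.8 for c in causal_idx)


class TestColocalizeLocus:
    def test_shared_locus_colocalizes_and_lead_tags_truth(self):
        sc = LocusScenario(seed=31, n_a=8_000, n_b=2_000, n_panel=2_000)
        a, b, ld, truth = _sim_harmonized(sc)
        res = colocalize_locus(a, b, ld)
        assert res.colocalized and res.coloc_prob > 0.8
        assert res.discordant is False
        pos_to_idx = {k.pos: i for i, k in enumerate(ld.keys)}
        causal = pos_to_idx[truth["layout"].positions[truth["causal_a"][0]]]
        assert ld.r[res.best_pair.lead_idx, causal] ** 2 > 0.8

    def test_zero_signal_trait_yields_null_result(self):
        sc = LocusScenario(label="A_ONLY", seed=32, n_a=8_000, n_b=1_000, n_panel=2_000)
        a, b, ld, _ = _sim_harmonized(sc)
        res = colocalize_locus(a, b, ld)
        assert res.coloc_prob == 0.0 and not res.colocalized
        assert res.discordant is None

    def test_negating_trait_b_flips_discordance_only(self):
        sc = LocusScenario(seed=33, n_a=8_000, n_b=2_000, n_panel=2_000)
        a, b, ld, _ = _sim_harmonized(sc)
        res = colocalize_locus(a, b, ld)
        b_neg = b.with_df(b.df.assign(beta=-b.df["beta"]))
        res_neg = colocalize_locus(a, b_neg, ld)
        assert res.colocalized and res_neg.colocalized
        assert res_neg.coloc_prob == pytest.approx(res.coloc_prob, abs=1e-12)
        assert res_neg.discordant is (not res.discordant)
        assert res_neg.best_pair.lead_idx == res.best_pair.lead_idx


class TestSummarize:
    def _results(self, betas_a, betas_b):
        import pandas as pd

        results, sa, sb = [], {}, {}
        for i, (ba, bb) in enumerate(zip(betas_a, betas_b)):
            pid = f"p{i}"
            a = make_locus([100], [ba], [0.05], protein_id=pid)
            b = make_locus([100], [bb], [0.05], protein_id=pid)
            pair = coloc_pair(
                _signal([ba], [0.05]), _signal([bb], [0.05], "b"),
                marginal_beta_a=np.array([ba]), marginal_beta_b=np.array([bb]),
            )
            from pqtlx.coloc import LocusColocResult

            res = LocusColocResult(pid, 1, 1, float(pair.pp[4]), True, pair, [pair],
                                   discordant=not pair.concordant)
            results.append(res)
            sa[pid], sb[pid] = a, b
        return results, sa, sb

    def test_perfect_rank_agreement(self):
        res, sa, sb = self._results([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert summarize_concordance(res, sa, sb)["spearman_rho"] == pytest.approx(1.0)

    def test_sign_flip_reverses_rho(self):
        res, sa, sb = self._results([0.1, 0.2, 0.3], [-0.1, -0.2, -0.3])
        assert summarize_concordance(res, sa, sb)["spearman_rho"] == pytest.approx(-1.0)

    def test_five_pair_toy_rank_correlation(self):
        # scipy.spearmanr oracle on (1,2),(2,1),(3,4),(4,3),(5,5): d² = 4,
        # rho = 1 - 6*4/(5*24) = 0.8
        res, sa, sb = self._results([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert summarize_concordance(res, sa, sb)["spearman_rho"] == pytest.approx(0.8)

    def test_fewer_than_two_colocalized_gives_no_rho(self):
        res, sa, sb = self._results([0.1], [0.2])
        assert summarize_concordance(res, sa, sb)["spearman_rho"] is None
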