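"""Per-site exact test, BH-FDR, pooled calling, and the replicate rank test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hmucall import caller, simdata
from hmucall.caller import (
    bh_fdr,
    call_sites,
    fold_change,
    replicate_rank_test,
    site_test,
    site_test_vec,
)

from _oracles import fisher_greater_oracle, ranksum_oracle


class TestSiteTest:
    def test_symmetric_table_gives_large_p(self):
        p = site_test((5, 5), (5, 5))
        assert p == pytest.approx(fisher_greater_oracle(5, 5, 5, 5))
        assert p > 0.5

    def test_no_c_anywhere(self):
        assert site_test((0, 100), (0, 100)) == 1.0

    def test_all_zero_table_convention(self):
        assert site_test((0, 0), (0, 0)) == 1.0

    def test_strong_enrichment_matches_enumeration(self):
        p = site_test((50, 50), (0, 100))
        assert p == pytest.approx(fisher_greater_oracle(50, 50, 0, 100), rel=1e-9)
        assert p < 1e-10

    def test_matches_scipy_fisher_exact(self):
        """Cross-check the hypergeometric-tail implementation against the
        reference Fisher routine over a grid of tables."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 60, size=4)
            expected = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert site_test((a, b), (c, d)) == pytest.approx(expected, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            site_test((-1, 5), (0, 5))

    def test_null_pvalues_conservative_or_uniform(self, site1_model):
        """Under treated==control generatively, P(p <= x) <= x (+ MC slack)."""
        rng = np.random.default_rng(3)
        n = 10_000
        depth = 300
        p_c = site1_model.p_bg_c
        tc = rng.binomial(depth, p_c, size=n)
        cc = rng.binomial(depth, p_c, size=n)
        p = site_test_vec(tc, depth - tc, cc, depth - cc)
        for x in [0.001, 0.01, 0.05, 0.1, 0.25, 0.5]:
            emp = np.mean(p <= x)
            assert emp <= x + 3 * np.sqrt(x * (1 - x) / n)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        # q_i = min over j>=i of p_(j) * m / j: here every q collapses to 0.04
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=100)
    def test_min_q_bounds_and_permutation_invariance(self, ps):
        q = bh_fdr(ps)
        assert np.all((q >= 0) & (q <= 1))
        assert q.min() >= min(ps) - 1e-12
        q_perm = bh_fdr(list(reversed(ps)))
        assert np.allclose(sorted(q), sorted(q_perm))


class TestCallSites:
    def test_null_run_no_significant_sites(self, odn1_experiment):
        calls = call_sites(odn1_experiment.treated, odn1_experiment.treated, fdr=0.1)
        assert len(calls) > 0
        assert not calls.significant.any()
        # identical arms: observed count sits at the null center, p >= 1/2
        assert (calls.p_value > 0.5).all()
        assert (calls.fold_change == 1.0).all()

    def test_recovers_true_sites_in_simulated_genome(self, site1_model):
        records, profile = simdata.make_genome(length=8000, n_sites=10, seed=5)
        exp = simdata.simulate_experiment(records, profile, site1_model, 100, 3, seed=5)
        calls = call_sites(exp.treated, exp.control, fdr=0.1, min_depth=100)
        truth = {e.pos0 for e in profile}
        sig = calls[calls.significant]
        assert truth <= set(sig.pos0)
        # false discoveries stay near the nominal FDR
        assert (~sig.pos0.isin(truth)).sum() <= max(2, 0.2 * len(sig))

    def test_lowering_fdr_nests_significant_sets(self, odn1_experiment):
        t, c = odn1_experiment.treated, odn1_experiment.control
        loose = call_sites(t, c, fdr=0.1)
        strict = call_sites(t, c, fdr=0.01)
        loose_set = set(loose[loose.significant].pos0)
        strict_set = set(strict[strict.significant].pos0)
        assert strict_set <= loose_set

    def test_min_depth_excludes_sites(self, odn1_experiment):
        calls = call_sites(
            odn1_experiment.treated, odn1_experiment.control, min_depth=10**7
        )
        assert calls.empty

    def test_output_sorted_by_position(self, odn1_experiment):
        calls = call_sites(odn1_experiment.treated, odn1_experiment.control)
        assert list(calls.pos0) == sorted(calls.pos0)


class TestReplicateRankTest:
    def test_complete_separation_3v7_exact(self):
        """All three modified-site signals above the seven background values:
        one-sided p = 1/C(10,3) = 1/120, two-sided doubles it."""
        high = [0.39, 0.40, 0.41]
        low = [0.010, 0.012, 0.014, 0.013, 0.011, 0.015, 0.016]
        assert replicate_rank_test(high, low, "greater") == pytest.approx(1 / 120)
        assert replicate_rank_test(high, low) == pytest.approx(2 / 120)

    def test_equal_multisets_give_p_1(self):
        assert replicate_rank_test([0.1, 0.2, 0.3], [0.3, 0.1, 0.2]) == pytest.approx(
            1.0
        )
        assert replicate_rank_test([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_exact_enumeration_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            for alt in ("two-sided", "greater", "less"):
                assert replicate_rank_test(x, y, alt) == pytest.approx(
                    ranksum_oracle(x, y, alt), rel=1e-9
                )

    def test_group_size_validated(self):
        with pytest.raises(ValueError):
            replicate_rank_test([0.1], [0.2, 0.3])

    def test_modified_vs_background_on_odn1(self, odn1_experiment):
        """Replicate %C at a fully modified site separates from proximal Ts."""
        from hmucall import pileup

        sig = pileup.signals_table(odn1_experiment.treated)
        truth = {e.pos0 for e in odn1_experiment.profile}
        mod = sig[sig.pos0 == min(truth)].pct_C.tolist()
        bg = sig[~sig.pos0.isin(truth)].pct_C.tolist()
        assert replicate_rank_test(mod, bg, "greater") < 0.01


class TestFoldChange:
    def test_identical_counts_unity(self):
        assert fold_change((10, 90), (10, 90)) == 1.0

    def test_amplicon_vs_control_ratio(self):
        # ((394+.5)/(898+1)) / ((22+.5)/(995+1)) = 19.42...
        fc = fold_change((394, 504), (22, 973))
        assert fc == pytest.approx(
            (394.5 / 899) / (22.5 / 996), rel=1e-12
        )
        assert fc == pytest.approx(19.4, abs=0.05)

    def test_finite_with_zero_counts(self):
        assert np.isfinite(fold_change((0, 100), (0, 100)))

    @given(st.integers(0, 500))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_treated_c(self, n_c):
        assert fold_change((n_c + 1, 100), (5, 100)) > fold_change((n_c, 100), (5, 100))
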