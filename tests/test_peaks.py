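import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cckit.ccio import InsertionSet, TTAAIndex
from cckit.peaks import (
    CallerConfig,
    Peak,
    adjust_pvalues,
    bayesian_blocks_events,
    blocks_score,
    call_blockify,
    call_cccaller,
    call_maccs,
    call_peaks,
    default_ncp_prior,
    expected_count,
    greedy_blocks,
    poisson_upper_tail,
)
from cckit.simdata import SimConfig, score_caller, simulate_genome, simulate_insertions

from conftest import make_insertions


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def poisson_tail_series(x: int, lam: float) -> float:
    """P(X >= x) by direct series summation of the lower tail."""
    if x == 0:
        return 1.0
    term = math.exp(-lam)
    acc = term
    for k in range(1, x):
        term *= lam / k
        acc += term
    return 1.0 - acc


def brute_force_blocks(positions, ncp_prior):
    """Best segmentation by exhaustive search over all 2^(m-1) splits."""
    uniq = sorted(set(float(p) for p in positions))
    m = len(uniq)
    best_score, best_blocks = -math.inf, None
    for r in range(m):
        for cuts in combinations(range(1, m), r):
            bounds = [0, *cuts, m]
            blocks = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
            s = blocks_score(np.asarray(positions, dtype=float), blocks, ncp_prior)
            if s > best_score + 1e-12:
                best_score, best_blocks = s, blocks
    return best_score, best_blocks


class TestPoissonUpperTail:
    def test_x_zero(self):
        assert poisson_upper_tail(0, 5) == 1.0

    def test_series_example(self):
        # oracle: 1 - e^{-1}(1 + 1 + 1/2)
        expected = 1 - math.exp(-1) * 2.5
        assert poisson_upper_tail(3, 1) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_null(self):
        assert poisson_upper_tail(1, 0) == 0.0
        assert poisson_upper_tail(0, 0) == 1.0

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1)
        with pytest.raises(ValueError):
            poisson_upper_tail(1, -1)

    def test_matches_series_oracle_grid(self):
        for lam in (0.1, 0.5, 1.0, 3.0, 10.0, 30.0):
            for x in range(0, 51):
                assert poisson_upper_tail(x, lam) == pytest.approx(
                    poisson_tail_series(x, lam), abs=1e-12
                )

    @given(st.integers(1, 50), st.floats(0.01, 30.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_x(self, x, lam):
        assert poisson_upper_tail(x, lam) <= poisson_upper_tail(x - 1, lam) + 1e-15

    @given(st.integers(1, 30), st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_lam(self, x, lam1, dlam):
        assert poisson_upper_tail(x, lam1 + dlam) >= poisson_upper_tail(x, lam1) - 1e-15


class TestAdjustPvalues:
    def test_single(self):
        assert adjust_pvalues([0.01]) == pytest.approx([0.01])

    def test_hand_vector(self):
        # p*m/rank then cumulative min from the largest: all become 0.04
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_hand_vector_mixed(self):
        # ranks for sorted [0.005, 0.04, 0.04, 0.5]: 0.02, 0.08, 0.0533->0.08? no:
        # adjusted sorted = cummin from right of [0.02, 0.08, 0.05333, 0.5]
        #                 = [0.02, 0.05333, 0.05333, 0.5]
        out = adjust_pvalues([0.04, 0.005, 0.5, 0.04])
        assert out == pytest.approx([0.0533333333, 0.02, 0.5, 0.0533333333], abs=1e-9)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, ps):
        q = adjust_pvalues(ps)
        assert np.all((q >= 0) & (q <= 1))
        assert np.all(q >= np.asarray(ps) - 1e-15)  # BH never decreases a p-value
        # monotone after sorting by p
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestExpectedCount:
    CFG = CallerConfig(mode="with_background", pseudocount=0.5)

    def test_all_ratios_one(self):
        assert expected_count(10, 7, 7, 1000, 1000, self.CFG) == pytest.approx(10.0)

    def test_pseudocount_floor(self):
        assert expected_count(0, 7, 7, 1000, 1000, self.CFG) == pytest.approx(0.5)

    def test_library_scaling(self):
        assert expected_count(10, 7, 7, 2000, 1000, self.CFG) == pytest.approx(20.0)

    def test_ttaa_ratio(self):
        assert expected_count(10, 5, 50, 1000, 1000, self.CFG) == pytest.approx(1.0)

    def test_zero_background_total_errors(self):
        with pytest.raises(ValueError, match="background-free"):
            expected_count(10, 7, 7, 1000, 0, self.CFG)

    def test_background_free_hand_arithmetic(self, uniform_ttaa):
        # peak with 20 insertions, 10 kb window holding 30 total, ttaa ratio
        # 1:99 -> lam = (30-20) * 1/99 ~ 0.10101
        from cckit.peaks import _lambda_background_free

        peak_lo, peak_hi = 500_000, 500_100  # exactly 1 TTAA (at 500000)
        # 10 flanking insertions inside the 10 kb lambda window, outside the peak
        flanking = [495_100 + 1000 * k for k in range(5)] + [
            500_600 + 1000 * k for k in range(5)
        ]
        exp = make_insertions([500_000] * 20 + flanking)
        cfg = CallerConfig(lambda_windows=(5000,), pseudocount=0.0)
        lam = _lambda_background_free("chr1", peak_lo, peak_hi, exp, uniform_ttaa, cfg)
        # window = [495050, 505050): 100 TTAAs, 30 insertions
        assert lam == pytest.approx((30 - 20) * 1 / (100 - 1), abs=1e-12)


class TestGreedyBlocks:
    def test_gap_rule(self):
        blocks = greedy_blocks(np.array([100, 200, 5000]), maxbetween=1000)
        assert blocks == [(0, 2), (2, 3)]

    def test_single_block(self):
        assert greedy_blocks(np.array([100, 200, 5000]), maxbetween=5000) == [(0, 3)]

    def test_empty(self):
        assert greedy_blocks(np.array([], dtype=int), 1000) == []

    @given(st.lists(st.integers(0, 100_000), min_size=1, max_size=200),
           st.integers(1, 5000))
    @settings(max_examples=200, deadline=None)
    def test_partition_property(self, positions, maxbetween):
        pos = np.array(sorted(positions))
        blocks = greedy_blocks(pos, maxbetween)
        # every insertion in exactly one block; counts conserved
        assert sum(j - i for i, j in blocks) == len(pos)
        assert blocks[0][0] == 0 and blocks[-1][1] == len(pos)
        for (i1, j1), (i2, j2) in zip(blocks, blocks[1:]):
            assert j1 == i2
            assert pos[i2] - pos[i2 - 1] > maxbetween  # split justified
        for i, j in blocks:
            if j - i > 1:
                assert np.all(np.diff(pos[i:j]) <= maxbetween)


class TestCCcaller:
    def test_empty_exp_errors(self, uniform_ttaa):
        with pytest.raises(ValueError):
            call_cccaller(InsertionSet(), None, uniform_ttaa, CallerConfig())

    def test_empty_background_falls_back(self, uniform_ttaa, caplog):
        exp = make_insertions([100] * 10)
        with caplog.at_level("WARNING"):
            ps = call_cccaller(exp, InsertionSet(), uniform_ttaa, CallerConfig())
        assert "background-free" in caplog.text
        assert all(p.n_bkg == 0 for p in ps)

    def test_single_planted_site_recovered(self):
        cfg = SimConfig(seed=3, n_true_peaks=1, enrichment=200.0, n_background=1000)
        ttaa = simulate_genome(cfg)
        exp, bkg, truth = simulate_insertions(cfg, ttaa)
        ps = call_cccaller(exp, bkg, ttaa, CallerConfig())
        sc = score_caller(ps, truth, exp)
        assert sc.recall == 1.0 and sc.precision == 1.0

    def test_chromosome_missing_from_index_dropped(self, caplog):
        ttaa = TTAAIndex({"chr1": list(range(0, 10_000, 100))})
        exp = InsertionSet.concat([
            make_insertions([1000] * 10, chrom="chr1"),
            make_insertions([1000] * 10, chrom="chrUn"),
        ])
        with caplog.at_level("WARNING"):
            ps = call_cccaller(exp, None, ttaa, CallerConfig())
        assert all(p.chrom == "chr1" for p in ps)
        assert "chrUn" in caplog.text

    def test_min_insertions_filter(self, uniform_ttaa):
        exp = make_insertions([100, 100, 100, 50_000 , 50_000])
        cfg = CallerConfig(min_insertions=3, pvalue_cutoff=1.0)
        ps = call_cccaller(exp, None, uniform_ttaa, cfg, keep_all=True)
        assert [p.n_exp for p in ps] == [3]

    def test_extend_margin(self, uniform_ttaa):
        exp = make_insertions([1000] * 10)
        ps0 = call_cccaller(exp, None, uniform_ttaa, CallerConfig(extend=0))
        ps1 = call_cccaller(exp, None, uniform_ttaa, CallerConfig(extend=100))
        assert ps1[0].start == ps0[0].start - 100
        assert ps1[0].end == ps0[0].end + 100

    def test_determinism_byte_identical(self, planted_dataset, tmp_path):
        from cckit.ccio import write_bed

        _, ttaa, exp, bkg, _ = planted_dataset
        out1, out2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(call_cccaller(exp, bkg, ttaa, CallerConfig()), out1)
        write_bed(call_cccaller(exp, bkg, ttaa, CallerConfig()), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_scaling_invariance_direction(self, uniform_ttaa):
        # replicating every insertion k times must not flip enrichment direction
        exp = make_insertions([1000] * 12 + list(range(10_000, 900_000, 3000)))
        bkg = make_insertions(list(range(0, 900_000, 1500)))
        def ratio(k):
            e = InsertionSet.concat([exp] * k)
            b = InsertionSet.concat([bkg] * k)
            ps = call_cccaller(e, b, uniform_ttaa, CallerConfig(pvalue_cutoff=1.0),
                               keep_all=True)
            pk = next(p for p in ps if p.start <= 1000 < p.end)
            return pk.n_exp / pk.lam
        r1, r3 = ratio(1), ratio(3)
        assert (r1 > 1) == (r3 > 1)


class TestMACCs:
    def test_no_insertions_no_peaks(self, uniform_ttaa):
        exp = make_insertions([1000] * 10, chrom="chr1")
        ps = call_maccs(exp, None, uniform_ttaa, CallerConfig())
        assert all(p.chrom == "chr1" for p in ps)

    def test_empty_exp_errors(self, uniform_ttaa):
        with pytest.raises(ValueError):
            call_maccs(InsertionSet(), None, uniform_ttaa, CallerConfig())

    def test_two_sites_50kb_apart_two_candidates(self):
        cfg = SimConfig(seed=5, n_true_peaks=0, enrichment=0, n_background=500)
        ttaa = simulate_genome(cfg)
        pos_a = [ttaa.nearest("chrS1", 200_000 + d) for d in range(0, 300, 10)]
        pos_b = [ttaa.nearest("chrS1", 250_000 + d) for d in range(0, 300, 10)]
        exp, bkg, truth = simulate_insertions(cfg, ttaa)
        exp = InsertionSet.concat([exp, make_insertions(pos_a + pos_b, chrom="chrS1")])
        ps = call_maccs(exp, bkg, ttaa, CallerConfig(window=1000, pvalue_cutoff=1e-4))
        hits_a = [p for p in ps if p.start < 201_000 and p.end > 199_500]
        hits_b = [p for p in ps if p.start < 251_000 and p.end > 249_500]
        assert len(hits_a) == 1 and len(hits_b) == 1
        assert hits_a[0] is not hits_b[0]

    def test_concordant_with_cccaller_on_planted_data(self, planted_dataset):
        _, ttaa, exp, bkg, truth = planted_dataset
        cfg = CallerConfig(maxbetween=1100, pvalue_cutoff=1e-4)
        ps_cc = call_cccaller(exp, bkg, ttaa, cfg)
        ps_ma = call_maccs(exp, bkg, ttaa, cfg)
        for sc in (score_caller(ps_cc, truth, exp), score_caller(ps_ma, truth, exp)):
            assert sc.recall == 1.0 and sc.precision >= 0.9
        # reciprocal overlap
        def frac_overlapping(a, b):
            return sum(any(p.overlaps(q) for q in b) for p in a) / len(a)
        assert frac_overlapping(ps_cc, ps_ma) >= 0.9
        assert frac_overlapping(ps_ma, ps_cc) >= 0.9

    def test_peaks_non_overlapping(self, planted_dataset):
        _, ttaa, exp, bkg, _ = planted_dataset
        ps = call_maccs(exp, bkg, ttaa, CallerConfig())
        for a, b in zip(ps, list(ps)[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start


class TestBayesianBlocks:
    def test_single_event(self):
        assert bayesian_blocks_events(np.array([5.0])) == [(0, 1)]

    def test_uniform_events_one_block(self):
        rng = np.random.default_rng(42)
        pos = np.sort(rng.uniform(0, 10_000, size=12))
        blocks = bayesian_blocks_events(pos, ncp_prior=default_ncp_prior(12))
        assert len(blocks) == 1

    def test_two_clusters_change_point(self):
        # 6 tight events, a 9 kb gap, 6 tight events
        pos = np.array([3 * i for i in range(6)] + [9000 + 3 * i for i in range(6)],
                       dtype=float)
        blocks = bayesian_blocks_events(pos, ncp_prior=default_ncp_prior(12))
        assert len(blocks) >= 2
        # a change point falls at or next to the gap (a low-density bridge
        # block over the gap is a legitimate optimum)
        boundaries = {j for j, _ in blocks if j > 0}
        assert boundaries & {5, 6, 7}

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        if seed % 2:
            pos = np.sort(rng.uniform(0, 1000, size=n))
        else:  # clustered
            pos = np.sort(np.concatenate([
                rng.uniform(0, 50, size=n // 2),
                rng.uniform(900, 1000, size=n - n // 2),
            ]))
        ncp = default_ncp_prior(n)
        blocks = bayesian_blocks_events(pos, ncp_prior=ncp)
        dp_score = blocks_score(pos, blocks, ncp)
        bf_score, _ = brute_force_blocks(pos, ncp)
        assert dp_score == pytest.approx(bf_score, abs=1e-9)

    def test_single_insertion_chromosome_block(self, uniform_ttaa):
        exp = make_insertions([1000])
        ps = call_blockify(exp, None, uniform_ttaa,
                           CallerConfig(min_insertions=1, pvalue_cutoff=1.0),
                           keep_all=True)
        assert len(ps) == 1
        assert (ps[0].start, ps[0].end) == (1000, 1004)

    def test_blockify_planted_recovery(self, planted_dataset):
        _, ttaa, exp, bkg, truth = planted_dataset
        ps = call_blockify(exp, bkg, ttaa, CallerConfig())
        sc = score_caller(ps, truth, exp)
        assert sc.recall >= 0.9 and sc.precision >= 0.9


class TestDispatch:
    def test_unknown_method(self, uniform_ttaa):
        with pytest.raises(ValueError, match="unknown method"):
            call_peaks("macs2", make_insertions([1]), None, uniform_ttaa)


class TestCallerConfig:
    def test_step_greater_than_window(self):
        with pytest.raises(ValueError):
            CallerConfig(window=100, step=200)

    def test_bad_maxbetween(self):
        with pytest.raises(ValueError):
            CallerConfig(maxbetween=0)

    def test_empty_lambda_windows(self):
        with pytest.raises(ValueError):
            CallerConfig(lambda_windows=())

    def test_mode_dependent_cutoff(self):
        assert CallerConfig(mode="with_background").cutoff() == 0.01
        assert CallerConfig(mode="background_free").cutoff() == 1e-4
        assert CallerConfig(pvalue_cutoff=0.2).cutoff() == 0.2
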