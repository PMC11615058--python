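"""Promoter windows, domain-aware background, PEI calling and statistics."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from hicstage import pei, synthetic as syn
from hicstage.genome import BinnedGenome
from hicstage.matrix import ContactMatrix
from hicstage.normalization import kr_normalize
from hicstage.tads import TADSet

from conftest import as_contact_matrix


def empty_tadset(genome):
    cols = ["chrom", "start", "end", "start_bin", "end_bin", "class",
            "dscore", "compartment"]
    return TADSet(genome, pd.DataFrame(columns=cols))


def domain_tadset(genome, domains):
    rows = []
    for a, b in domains:
        chrom, start, _ = genome.bin_location(a)
        _, _, end = genome.bin_location(b - 1)
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "start_bin": a, "end_bin": b, "class": "domain",
                     "dscore": np.nan, "compartment": ""})
    return TADSet(genome, pd.DataFrame(rows))


def genes_at_bins(genome, bins, strand="+"):
    rows = []
    for k, b in enumerate(bins):
        chrom, start, end = genome.bin_location(b)
        tss = (start + end) // 2
        rows.append({"chrom": chrom, "start": tss, "end": tss + 1000,
                     "gene": f"g{k}", "score": 0, "strand": strand,
                     "tss": tss})
    return pd.DataFrame(rows)


class TestPromoters:
    def test_window_is_2500_bp_strand_relative(self):
        g = BinnedGenome({"chr1": 1_000_000}, 20_000)
        genes = pd.DataFrame([
            {"chrom": "chr1", "start": 500_000, "end": 510_000,
             "gene": "plus", "score": 0, "strand": "+", "tss": 500_000},
            {"chrom": "chr1", "start": 590_000, "end": 600_000,
             "gene": "minus", "score": 0, "strand": "-", "tss": 600_000},
        ])
        prom = pei.make_promoters(genes, g)
        plus = prom[prom["gene"] == "plus"].iloc[0]
        minus = prom[prom["gene"] == "minus"].iloc[0]
        assert (plus["win_start"], plus["win_end"]) == (498_000, 500_500)
        assert (minus["win_start"], minus["win_end"]) == (599_500, 602_000)

    def test_window_clipped_at_chromosome_start(self):
        g = BinnedGenome({"chr1": 1_000_000}, 20_000)
        genes = genes_at_bins(g, [0])
        genes.loc[0, "tss"] = 500
        prom = pei.make_promoters(genes, g)
        assert prom.iloc[0]["win_start"] == 0


class TestDomainBackground:
    def test_recovers_decay_exponent(self):
        truth = syn.make_truth(n_bins=300, n_tads=0, n_peis=0,
                               plaid_strength=1.0, seed=1)
        m = syn.simulate_matrix(truth, 2)
        bg = pei.fit_domain_background(
            ContactMatrix.from_dense(truth.genome,
                                     m.toarray().astype(float), raw=False),
            empty_tadset(truth.genome),
        )
        assert abs(bg.chrom_fits["chr1"][1] - truth.decay_exponent) < 0.1

    def test_enriched_domain_has_higher_intercept(self):
        truth = syn.make_truth(n_bins=200, n_tads=0, n_peis=0,
                               plaid_strength=1.0, bias_sd=0.0, seed=3)
        truth = replace(truth, tads=[(50, 100, 2.0)])
        m = syn.simulate_matrix(truth, 4)
        ts = domain_tadset(truth.genome, [(50, 100)])
        bg = pei.fit_domain_background(
            ContactMatrix.from_dense(truth.genome,
                                     m.toarray().astype(float), raw=False), ts
        )
        dom_intercept = bg.domain_fits[0][2]
        assert dom_intercept > bg.chrom_fits["chr1"][0]

    def test_constant_matrix_flat_exponent(self):
        dense = np.full((50, 50), 6.0)
        np.fill_diagonal(dense, 0.0)
        m = as_contact_matrix(dense)
        bg = pei.fit_domain_background(m, empty_tadset(m.genome))
        assert abs(bg.chrom_fits["chr1"][1]) < 1e-9

    def test_vector_matches_pointwise(self):
        truth = syn.make_truth(n_bins=100, n_tads=0, n_peis=0, seed=5)
        truth = replace(truth, tads=[(20, 60, 2.0)])
        m = syn.simulate_matrix(truth, 6)
        ts = domain_tadset(truth.genome, [(20, 60)])
        bg = pei.fit_domain_background(
            ContactMatrix.from_dense(truth.genome,
                                     m.toarray().astype(float), raw=False), ts
        )
        js = np.array([1, 15, 25, 59, 80])
        vec = bg.expected_vector(30, js)
        for j, v in zip(js, vec):
            assert v == pytest.approx(bg.expected(30, j))


class TestCallPeis:
    @pytest.fixture()
    def called(self):
        truth = syn.make_truth(n_bins=300, n_tads=0, n_peis=0,
                               plaid_strength=1.0, seed=7)
        peis = [(40, 45, 3.0), (120, 130, 3.0), (200, 215, 3.0)]
        truth = replace(truth, peis=peis)
        m = syn.simulate_matrix(truth, 8)
        b, _ = kr_normalize(m)
        b = pei.scale_to_depth(b, m.total())
        genes = genes_at_bins(truth.genome, [p for p, _, _ in peis])
        promoters = pei.make_promoters(genes, truth.genome)
        bg = pei.fit_domain_background(b, empty_tadset(truth.genome))
        return b, promoters, bg, peis

    def test_planted_peaks_called(self, called):
        b, promoters, bg, planted = called
        ps = pei.call_peis(b, promoters, bg)
        pairs = set(zip(ps.table["promoter_bin"], ps.table["enhancer_bin"]))
        assert all((p, q) in pairs for p, q, _ in planted)

    def test_called_set_satisfies_all_filters(self, called):
        b, promoters, bg, _ = called
        ps = pei.call_peis(b, promoters, bg)
        t = ps.table
        assert (t["q"] < 0.01).all()
        assert (t["distance"] >= 15_000).all()
        assert (t["observed"] > t["expected"]).all()

    def test_fdr_threshold_monotonicity(self, called):
        b, promoters, bg, _ = called
        loose = pei.call_peis(b, promoters, bg, fdr_threshold=0.01)
        strict = pei.call_peis(b, promoters, bg, fdr_threshold=0.001)
        loose_pairs = set(zip(loose.table["promoter_bin"],
                              loose.table["enhancer_bin"]))
        strict_pairs = set(zip(strict.table["promoter_bin"],
                               strict.table["enhancer_bin"]))
        assert strict_pairs <= loose_pairs

    def test_invariant_to_chunking(self, called):
        b, promoters, bg, _ = called
        default = pei.call_peis(b, promoters, bg)
        chunked = pei.call_peis(b, promoters, bg,
                                chunk_bp=2_000_000, step_bp=1_000_000)
        pd.testing.assert_frame_equal(default.table, chunked.table)

    def test_short_distance_peak_never_called(self):
        # 10 kb bins: a peak at 1-bin distance (10 kb) fails the 15 kb filter
        truth = syn.make_truth(n_bins=200, bin_size=10_000, n_tads=0,
                               n_peis=0, plaid_strength=1.0, seed=9)
        truth = replace(truth, peis=[(100, 101, 5.0)])
        m = syn.simulate_matrix(truth, 10)
        b, _ = kr_normalize(m)
        b = pei.scale_to_depth(b, m.total())
        genes = genes_at_bins(truth.genome, [100])
        promoters = pei.make_promoters(genes, truth.genome)
        bg = pei.fit_domain_background(b, empty_tadset(truth.genome))
        ps = pei.call_peis(b, promoters, bg)
        assert not ((ps.table["promoter_bin"] == 100)
                    & (ps.table["enhancer_bin"] == 101)).any()


class TestBenjaminiHochberg:
    def test_matches_brute_force_on_small_sets(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 100)

        def brute_force_bh(pvals):
            n = len(pvals)
            order = np.argsort(pvals)
            q = np.empty(n)
            prev = 1.0
            for rank_from_top in range(n, 0, -1):
                idx = order[rank_from_top - 1]
                q_val = min(prev, pvals[idx] * n / rank_from_top)
                q[idx] = q_val
                prev = q_val
            return q

        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q_sm, brute_force_bh(p), atol=1e-12)


class TestPeiStats:
    def make_peiset(self, genome, rows):
        t = pd.DataFrame(rows, columns=["gene", "promoter_bin", "enhancer_bin",
                                        "distance", "observed", "expected",
                                        "p", "q"])
        return pei.PEISet(genome, t, n_tests=max(len(t), 1),
                          fdr_threshold=0.01, min_distance=15_000)

    def test_single_pei_inside_tad(self):
        g = BinnedGenome({"chr1": 4_000_000}, 20_000)
        ps = self.make_peiset(g, [("g0", 10, 14, 80_000, 30, 5, 1e-9, 1e-6)])
        ts = domain_tadset(g, [(5, 20)])
        promoters = pei.make_promoters(genes_at_bins(g, [10]), g)
        st = pei.pei_stats(ps, ts, promoters)
        assert st.frac_within_tad == 1.0
        assert st.frac_short_range == 1.0

    def test_nearest_promoter_partner_not_skipping(self):
        g = BinnedGenome({"chr1": 4_000_000}, 20_000)
        ps = self.make_peiset(g, [("g0", 10, 14, 80_000, 30, 5, 1e-9, 1e-6)])
        ts = domain_tadset(g, [(5, 20)])
        promoters = pei.make_promoters(genes_at_bins(g, [10, 100]), g)
        st = pei.pei_stats(ps, ts, promoters)
        assert st.frac_skipping == 0.0

    def test_bookkeeping_matches_hand_computation(self):
        g = BinnedGenome({"chr1": 10_000_000}, 20_000)
        rows = [
            ("g0", 10, 14, 80_000, 30, 5, 1e-9, 1e-6),    # in TAD, short
            ("g0", 10, 40, 600_000, 25, 4, 1e-9, 1e-6),   # outside TAD, long
            ("g1", 100, 90, 200_000, 22, 6, 1e-9, 1e-6),  # skipping g0? no, g1 nearest
        ]
        ps = self.make_peiset(g, rows)
        ts = domain_tadset(g, [(5, 20)])
        promoters = pei.make_promoters(genes_at_bins(g, [10, 100]), g)
        st = pei.pei_stats(ps, ts, promoters)
        assert st.total == 3
        assert st.genes_with_pei == 2
        assert st.frac_within_tad == pytest.approx(1 / 3)
        assert st.frac_short_range == pytest.approx(1 / 3)
        assert st.per_gene_counts["g0"] == 2

    def test_empty_set_rejected(self):
        g = BinnedGenome({"chr1": 1_000_000}, 20_000)
        ps = self.make_peiset(g, [])
        with pytest.raises(ValueError):
            pei.pei_stats(ps, empty_tadset(g), pd.DataFrame())


class TestComparePeiSets:
    def make(self, genome, gene_counts):
        rows = []
        for gene, n in gene_counts.items():
            for k in range(n):
                rows.append((gene, 10, 20 + k, 200_000, 30, 5, 1e-9, 1e-6))
        t = pd.DataFrame(rows, columns=["gene", "promoter_bin", "enhancer_bin",
                                        "distance", "observed", "expected",
                                        "p", "q"])
        return pei.PEISet(genome, t, n_tests=100, fdr_threshold=0.01,
                          min_distance=15_000)

    def test_identical_sets_zero_delta(self):
        g = BinnedGenome({"chr1": 10_000_000}, 20_000)
        s = self.make(g, {"a": 3, "b": 1})
        delta, _, _ = pei.compare_pei_sets(s, s)
        assert (delta["delta"] == 0).all()

    def test_forced_delta(self):
        g = BinnedGenome({"chr1": 10_000_000}, 20_000)
        s1 = self.make(g, {"a": 5})
        s2 = self.make(g, {"a": 2})
        delta, losers, gainers = pei.compare_pei_sets(s1, s2)
        assert delta.loc[delta["gene"] == "a", "delta"].iloc[0] == -3

    def test_planted_movers_occupy_top_list(self):
        g = BinnedGenome({"chr1": 10_000_000}, 20_000)
        counts1 = {f"loser{i}": 5 for i in range(10)}
        counts1.update({f"flat{i}": 2 for i in range(20)})
        counts2 = {f"loser{i}": 1 for i in range(10)}
        counts2.update({f"flat{i}": 2 for i in range(20)})
        delta, losers, _ = pei.compare_pei_sets(self.make(g, counts1),
                                                self.make(g, counts2))
        assert set(losers["gene"]) == {f"loser{i}" for i in range(10)}
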