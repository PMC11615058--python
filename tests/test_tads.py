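"""DI, HMM segmentation, insulation score, TAD calling and comparison."""

import numpy as np
import pandas as pd
import pytest

from hicstage import synthetic as syn, tads as tad
from hicstage.compartments import CompartmentProfile
from hicstage.genome import BinnedGenome
from hicstage.matrix import ContactMatrix
from hicstage.normalization import kr_normalize

from conftest import as_contact_matrix


def empty_tadset(genome):
    cols = ["chrom", "start", "end", "start_bin", "end_bin", "class",
            "dscore", "compartment"]
    return tad.TADSet(genome, pd.DataFrame(columns=cols))


class TestDirectionalityIndex:
    def test_symmetric_windows_zero(self):
        dense = np.zeros((7, 7))
        dense[2, 1] = dense[1, 2] = 10.0
        dense[2, 3] = dense[3, 2] = 10.0
        di = tad.directionality_index(as_contact_matrix(dense, 10_000),
                                      window_bp=20_000)
        assert di.values[2] == 0.0

    def test_forced_arithmetic_plus_twenty(self):
        # bin 0: upstream sum A=0, downstream B=20 -> E=10, DI=+20
        dense = np.zeros((6, 6))
        dense[0, 1] = dense[1, 0] = 12.0
        dense[0, 2] = dense[2, 0] = 8.0
        di = tad.directionality_index(as_contact_matrix(dense, 10_000),
                                      window_bp=20_000)
        assert di.values[0] == pytest.approx(20.0)

    def test_antisymmetric_under_mirroring(self, balanced_matrix):
        di = tad.directionality_index(balanced_matrix)
        g = balanced_matrix.genome
        mirrored = ContactMatrix.from_dense(
            g, balanced_matrix.toarray()[::-1, ::-1], raw=False
        )
        di_m = tad.directionality_index(mirrored)
        np.testing.assert_allclose(di_m.values, -di.values[::-1], atol=1e-9)

    def test_two_tad_map_edge_signs(self):
        truth = syn.make_truth(n_bins=100, n_tads=2, n_peis=0,
                               plaid_strength=1.0, bias_sd=0.0, seed=1)
        m = syn.simulate_matrix(truth, 2)
        b, _ = kr_normalize(m)
        di = tad.directionality_index(b, window_bp=500_000)
        for a, e, _ in truth.tads:
            assert di.values[a] > 0
            assert di.values[e - 1] < 0
            mid = (a + e) // 2
            assert abs(di.values[mid]) < di.values[a]

    def test_window_larger_than_chromosome_rejected(self):
        dense = np.ones((4, 4))
        np.fill_diagonal(dense, 0.0)
        with pytest.raises(ValueError, match="larger than chromosome"):
            tad.directionality_index(as_contact_matrix(dense, 10_000),
                                     window_bp=400_000)


class TestHMM:
    def make_di(self, values, bin_size=20_000):
        values = np.asarray(values, dtype=float)
        g = BinnedGenome({"chr1": len(values) * bin_size}, bin_size)
        return tad.DITrack(g, values, 500_000)

    def test_separable_blocks_segment_at_transitions(self):
        v = ([0.0] * 5 + [20.0] * 6 + [0.0] * 4 + [-20.0] * 6 + [0.0] * 5) * 2
        hmm = tad.fit_hmm(self.make_di(v))
        assert hmm.domains == [(5, 21), (31, 47)]

    def test_zero_di_no_domains(self):
        hmm = tad.fit_hmm(self.make_di([0.0] * 40))
        assert hmm.domains == []
        assert (hmm.states == tad.NONE).all()

    def test_state_ordering_stable_across_seeds(self):
        v = [0.0] * 5 + [20.0] * 6 + [-20.0] * 6 + [0.0] * 5
        runs = [tad.fit_hmm(self.make_di(v), seed=s).domains for s in range(3)]
        assert runs[0] == runs[1] == runs[2]


class TestInsulationScore:
    def test_uniform_matrix_zero_everywhere(self):
        dense = np.full((40, 40), 4.0)
        np.fill_diagonal(dense, 0.0)
        ist = tad.insulation_score(as_contact_matrix(dense), 200_000)
        finite = np.isfinite(ist.values)
        assert np.allclose(ist.values[finite], 0.0, atol=1e-9)
        assert len(ist.boundaries) == 0

    def test_scale_invariance(self, balanced_matrix):
        ist1 = tad.insulation_score(balanced_matrix)
        doubled = ContactMatrix.from_dense(
            balanced_matrix.genome, balanced_matrix.toarray() * 2, raw=False
        )
        ist2 = tad.insulation_score(doubled)
        np.testing.assert_allclose(ist1.values, ist2.values, equal_nan=True)
        assert np.array_equal(ist1.boundaries, ist2.boundaries)

    def test_planted_boundary_is_local_minimum(self):
        truth = syn.make_truth(n_bins=120, n_tads=2, n_peis=0,
                               plaid_strength=1.0, bias_sd=0.0, seed=4)
        m = syn.simulate_matrix(truth, 5)
        b, _ = kr_normalize(m)
        ist = tad.insulation_score(b, 300_000)
        # the gap between the two planted domains contains an IS minimum
        (a1, e1, _), (a2, e2, _) = truth.tads
        assert any(e1 - 1 <= m_ <= a2 + 1 for m_ in ist.boundaries)


class TestCallTads:
    def test_output_never_overlaps_and_sorted(self, balanced_matrix):
        di = tad.directionality_index(balanced_matrix)
        hmm = tad.fit_hmm(di)
        ist = tad.insulation_score(balanced_matrix)
        ts = tad.call_tads(hmm, ist)
        t = ts.table
        assert (t["start_bin"].to_numpy()[1:] >= t["end_bin"].to_numpy()[:-1]).all()

    def test_zero_contact_chromosome_unorganized(self):
        g = BinnedGenome({"chr1": 400_000}, 10_000)
        m = ContactMatrix.from_dense(g, np.zeros((40, 40)), raw=False)
        di = tad.directionality_index(m, 100_000)
        hmm = tad.fit_hmm(di)
        ist = tad.insulation_score(m, 100_000)
        ts = tad.call_tads(hmm, ist)
        assert set(ts.table["class"]) == {"unorganized"}


class TestDomainScore:
    def test_forced_eighty_twenty(self):
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 80.0
        dense[1, 2] = dense[2, 1] = 20.0
        m = as_contact_matrix(dense)
        ts = tad.TADSet(m.genome, pd.DataFrame([{
            "chrom": "chr1", "start": 0, "end": 40_000,
            "start_bin": 0, "end_bin": 2, "class": "domain",
            "dscore": np.nan, "compartment": "",
        }]))
        scores = tad.domain_score(m, ts)
        assert scores.iloc[0] == pytest.approx(0.8)

    def test_isolated_chromosome_scores_one(self):
        g = BinnedGenome({"chr1": 60_000, "chr2": 60_000}, 20_000)
        dense = np.zeros((6, 6))
        dense[0, 1] = dense[1, 0] = 5.0
        dense[1, 2] = dense[2, 1] = 3.0
        m = ContactMatrix.from_dense(g, dense, raw=False)
        ts = tad.TADSet(g, pd.DataFrame([{
            "chrom": "chr1", "start": 0, "end": 60_000,
            "start_bin": 0, "end_bin": 3, "class": "domain",
            "dscore": np.nan, "compartment": "",
        }]))
        assert tad.domain_score(m, ts).iloc[0] == 1.0

    def test_strong_domains_outscore_weak(self):
        wins = 0
        for seed in range(20):
            truth = syn.make_truth(n_bins=120, n_tads=0, n_peis=0,
                                   plaid_strength=1.0, seed=seed)
            from dataclasses import replace
            truth = replace(truth, tads=[(10, 40, 2.5), (70, 100, 1.2)])
            m = syn.simulate_matrix(truth, seed + 500)
            ts = tad.TADSet(truth.genome, pd.DataFrame([
                {"chrom": "chr1", "start": 200_000, "end": 800_000,
                 "start_bin": 10, "end_bin": 40, "class": "domain",
                 "dscore": np.nan, "compartment": ""},
                {"chrom": "chr1", "start": 1_400_000, "end": 2_000_000,
                 "start_bin": 70, "end_bin": 100, "class": "domain",
                 "dscore": np.nan, "compartment": ""},
            ]))
            s = tad.domain_score(m, ts)
            wins += s.iloc[0] > s.iloc[1]
        assert wins >= 19


class TestCompartmentLabel:
    @pytest.mark.parametrize("n_a,expected", [(8, "A"), (7, "mixed"), (0, "B")])
    def test_seventy_percent_rule(self, n_a, expected):
        g = BinnedGenome({"chr1": 200_000}, 20_000)
        labels = np.array(["A"] * n_a + ["B"] * (10 - n_a), dtype="U8")
        prof = CompartmentProfile(g, np.ones(10), labels, oriented=True)
        ts = tad.TADSet(g, pd.DataFrame([{
            "chrom": "chr1", "start": 0, "end": 200_000,
            "start_bin": 0, "end_bin": 10, "class": "domain",
            "dscore": np.nan, "compartment": "",
        }]))
        assert tad.tad_compartment_label(ts, prof).iloc[0] == expected


class TestCompareTads:
    def call(self, matrix, seed=0):
        di = tad.directionality_index(matrix)
        hmm = tad.fit_hmm(di, seed=seed)
        ist = tad.insulation_score(matrix)
        return tad.call_tads(hmm, ist), di, ist

    def test_identical_sets_jaccard_one_no_differentials(self, balanced_matrix):
        ts, di, ist = self.call(balanced_matrix)
        cmp = tad.compare_tads(ts, ts, di, di, ist, ist)
        assert cmp.jaccard == 1.0
        assert len(cmp.differential_boundaries) == 0
        assert cmp.spearman_di == pytest.approx(1.0)

    def test_disjoint_boundaries_jaccard_zero(self, balanced_matrix):
        _, di, ist = self.call(balanced_matrix)
        g = balanced_matrix.genome

        def tadset(domains):
            rows = []
            for a, b in domains:
                rows.append({
                    "chrom": "chr1", "start": a * g.bin_size,
                    "end": b * g.bin_size, "start_bin": a, "end_bin": b,
                    "class": "domain", "dscore": np.nan, "compartment": "",
                })
            return tad.TADSet(g, pd.DataFrame(rows))

        ts1 = tadset([(5, 15), (20, 30)])
        ts2 = tadset([(40, 50), (60, 70)])
        cmp = tad.compare_tads(ts1, ts2, di, di, ist, ist, match_tol_bins=1)
        assert cmp.jaccard == 0.0

    def test_empty_side_rejected(self, balanced_matrix):
        ts, di, ist = self.call(balanced_matrix)
        empty = empty_tadset(balanced_matrix.genome)
        with pytest.raises(ValueError, match="no TAD boundaries"):
            tad.compare_tads(ts, empty, di, di, ist, ist)

    def test_moved_boundaries_flagged_differential(self):
        truth = syn.make_truth(n_bins=1000, n_tads=20, n_peis=0,
                               plaid_strength=1.0, seed=8)
        moved_truth, moved_bins = syn.shift_tad_boundaries(
            truth, frac=0.1, min_shift_bins=3, seed=9
        )
        m1 = syn.simulate_matrix(truth, 10)
        m2 = syn.simulate_matrix(moved_truth, 11)
        b1, _ = kr_normalize(m1)
        b2, _ = kr_normalize(m2)
        ts1, di1, ist1 = self.call(b1)
        ts2, di2, ist2 = self.call(b2)
        cmp = tad.compare_tads(ts1, ts2, di1, di2, ist1, ist2)
        moved = np.asarray(moved_bins)
        flagged = cmp.differential_boundaries
        if len(flagged):
            sens = np.mean([np.min(np.abs(flagged - b)) <= 2 for b in moved])
        else:
            sens = 0.0
        stable = np.array(
            [b for b in cmp.consensus_boundaries
             if len(moved) == 0 or np.min(np.abs(moved - b)) > 3]
        )
        false_flags = (
            np.mean([np.min(np.abs(flagged - b)) <= 1 for b in stable])
            if len(flagged) and len(stable) else 0.0
        )
        assert sens >= 0.8
        assert false_flags <= 0.1


class TestBoundaryGeneEnrichment:
    def test_uniform_genes_null(self):
        g = BinnedGenome({"chr1": 20_000_000}, 20_000)
        rng = np.random.default_rng(0)
        genes = pd.DataFrame({
            "chrom": "chr1",
            "tss": rng.integers(0, 20_000_000, 300),
            "gene": [f"g{i}" for i in range(300)],
        })
        boundaries = np.arange(50, 1000, 100)
        ratio, p = tad.boundary_gene_enrichment(boundaries, genes, g,
                                                n_perm=200, seed=1)
        assert 0.8 < ratio < 1.2
        assert p > 0.05

    def test_genes_planted_at_boundaries_enriched(self):
        # four chromosomes shifted independently under the null, so a joint
        # re-alignment of all planted genes is essentially impossible
        g = BinnedGenome({f"chr{k}": 10_000_000 for k in range(1, 5)}, 20_000)
        rng = np.random.default_rng(3)
        rows = []
        all_bounds = []
        for k in range(1, 5):
            local = np.unique(rng.integers(20, 480, 8))
            all_bounds.append(local + g.offset_of(f"chr{k}"))
            for b in local:
                for rep in range(3):
                    rows.append({"chrom": f"chr{k}",
                                 "tss": b * 20_000 + 10_000,
                                 "gene": f"g{k}_{b}_{rep}"})
        genes = pd.DataFrame(rows)
        ratio, p = tad.boundary_gene_enrichment(
            np.concatenate(all_bounds), genes, g, flank_bp=100_000,
            n_perm=999, seed=2
        )
        assert ratio > 2.0
        assert p <= 0.001

    def test_too_few_boundaries_rejected(self):
        g = BinnedGenome({"chr1": 1_000_000}, 20_000)
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [1], "gene": ["g"]})
        with pytest.raises(ValueError, match="boundaries"):
            tad.boundary_gene_enrichment(np.array([5]), genes, g)

    def test_zero_genes_rejected(self):
        g = BinnedGenome({"chr1": 1_000_000}, 20_000)
        with pytest.raises(ValueError, match="gene"):
            tad.boundary_gene_enrichment(
                np.array([5, 20]), pd.DataFrame(columns=["chrom", "tss", "gene"]), g
            )
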