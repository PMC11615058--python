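"""Expected models, O/E correlation, PC1 calling, A-B index, switches."""

import numpy as np
import pytest
from sklearn.decomposition import PCA

from hicstage import compartments as comp, synthetic as syn
from hicstage.matrix import ContactMatrix

from conftest import as_contact_matrix


class TestExpectedMarginal:
    def test_formula_forced_example(self):
        # marginals 60/40 of a total of 100 -> E_01 = 0.6 * 0.4 * 100 = 24
        dense = np.array([[20.0, 40.0], [40.0, 0.0]])
        e = comp.expected_marginal(as_contact_matrix(dense))
        assert e[0, 1] == pytest.approx(24.0)

    def test_uniform_marginals_give_equal_expected(self):
        dense = np.full((6, 6), 2.0)
        np.fill_diagonal(dense, 0.0)
        e = comp.expected_marginal(as_contact_matrix(dense))
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(e[off], e[off].flat[0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        dense = rng.uniform(0, 5, (5, 5))
        dense = np.triu(dense) + np.triu(dense, 1).T
        m = as_contact_matrix(dense)
        e = comp.expected_marginal(m)
        total = dense.sum()
        for i in range(5):
            for j in range(5):
                fi = dense[i].sum() / total
                fj = dense[j].sum() / total
                assert e[i, j] == pytest.approx(fi * fj * total)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            comp.expected_marginal(as_contact_matrix(np.zeros((4, 4))))


class TestExpectedDistance:
    def test_constant_per_distance_gives_unit_oe(self):
        n = 10
        dense = np.zeros((n, n))
        for d in range(1, n):
            dense += np.eye(n, k=d) * (10.0 / d) + np.eye(n, k=-d) * (10.0 / d)
        m = as_contact_matrix(dense)
        exp = comp.expected_distance(m)["chr1"]
        for d in range(1, n):
            np.testing.assert_allclose(
                np.diagonal(dense, offset=d) / exp[d], 1.0
            )

    def test_recovers_decay_exponent(self):
        truth = syn.make_truth(n_bins=400, n_tads=0, n_peis=0,
                               plaid_strength=1.0, seed=2)
        m = syn.simulate_matrix(truth, seed=3)
        exp = comp.expected_distance(m)["chr1"]
        d = np.arange(2, 100)
        slope = np.polyfit(np.log(d), np.log(exp[2:100]), 1)[0]
        assert abs(slope - truth.decay_exponent) < 0.1

    def test_single_occupied_distance(self):
        dense = np.zeros((5, 5))
        dense[0, 3] = dense[3, 0] = 7.0
        exp = comp.expected_distance(as_contact_matrix(dense))["chr1"]
        assert exp[3] == pytest.approx(7.0 / 2)  # two pairs at d=3, one occupied


class TestOECorrelation:
    def test_two_block_plaid_rank_one_pattern(self):
        # a perfect two-block O/E pattern (already distance-free): feed a
        # unit expected vector so the input passes through unchanged
        n = 20
        labels = np.array(["A"] * 10 + ["B"] * 10)
        dense = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    dense[i, j] = 3.0 if labels[i] == labels[j] else 1.0 / 3
        include = np.ones(n, dtype=bool)
        exp = np.ones(n)
        _, corr, kept = comp.oe_and_correlation(dense, exp, include)
        same = labels[kept][:, None] == labels[kept][None, :]
        assert (corr[same] > 0).all()
        assert (corr[~same] < 0).all()
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_matches_textbook_pearson(self, balanced_matrix):
        g = balanced_matrix.genome
        dense = balanced_matrix.toarray()
        exp = comp.expected_distance(balanced_matrix)["chr1"]
        include = dense.sum(axis=1) > 0
        oe, corr, kept = comp.oe_and_correlation(dense, exp, include)
        sub = oe[np.ix_(kept, kept)].copy()
        k = sub.shape[0]
        off_mean = (sub.sum(axis=1) - np.diag(sub)) / (k - 1)
        sub[np.arange(k), np.arange(k)] = off_mean
        x, y = sub[3], sub[17]
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert corr[3, 17] == pytest.approx(r, abs=1e-10)


class TestPC1:
    def test_matches_sklearn_pca_up_to_sign(self, balanced_matrix):
        dense = balanced_matrix.toarray()
        exp = comp.expected_distance(balanced_matrix)["chr1"]
        include = dense.sum(axis=1) > 0
        _, corr, _ = comp.oe_and_correlation(dense, exp, include)
        v = comp.pc1_of_correlation(corr)
        ref = PCA(n_components=1).fit(corr).components_[0]
        agree = min(np.abs(v - ref).max(), np.abs(v + ref).max())
        assert agree < 1e-8

    def test_noise_free_checkerboard_recovered(self):
        truth = syn.make_truth(n_bins=200, n_tads=0, n_peis=0, bias_sd=0.0,
                               seed=7)
        e = syn.build_expected_map(truth)
        m = ContactMatrix.from_dense(truth.genome, e, raw=False)
        gc = syn.simulate_gc(truth, seed=8)
        prof = comp.call_compartments(m, gc=gc)
        inc = prof.included()
        acc = np.mean(prof.labels[inc] == truth.compartment_labels[inc])
        assert max(acc, 1 - acc) >= 0.99

    def test_sign_orientation_invariance(self, balanced_matrix):
        dense = balanced_matrix.toarray()
        exp = comp.expected_distance(balanced_matrix)["chr1"]
        include = dense.sum(axis=1) > 0
        _, corr, _ = comp.oe_and_correlation(dense, exp, include)
        v = comp.pc1_of_correlation(corr)
        gc = np.where(v > 0, 0.46, 0.38)

        def orient(vec):
            return vec if np.corrcoef(vec, gc)[0, 1] >= 0 else -vec

        # the eigenvector's arbitrary sign never changes the oriented labels
        lab1 = np.where(orient(v) > 0, "A", "B")
        lab2 = np.where(orient(-v) > 0, "A", "B")
        assert np.array_equal(lab1, lab2)

    def test_degenerate_partition_warns(self):
        truth = syn.make_truth(n_bins=60, n_tads=0, n_peis=0, bias_sd=0.0,
                               seed=1)
        truth.compartment_labels[:] = "A"
        e = syn.build_expected_map(truth)
        m = ContactMatrix.from_dense(truth.genome, e, raw=False)
        with pytest.warns(UserWarning, match="degenerate"):
            comp.call_compartments(m, gc=syn.simulate_gc(truth, 2))


class TestABIndex:
    def make_profile(self, genome, labels):
        pc1 = np.where(labels == "A", 1.0, -1.0)
        return comp.CompartmentProfile(genome, pc1, labels, oriented=True)

    def test_pure_a_contact_bin(self):
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 5.0  # bin 0 touches only bin 1 (A)
        dense[2, 3] = dense[3, 2] = 1.0
        m = as_contact_matrix(dense)
        labels = np.array(["B", "A", "B", "B"], dtype="U8")
        idx = comp.ab_index(m, self.make_profile(m.genome, labels))
        assert idx[0] == 1.0

    def test_balanced_contacts_zero(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = dense[1, 0] = 2.0
        dense[0, 2] = dense[2, 0] = 2.0
        m = as_contact_matrix(dense)
        labels = np.array(["B", "A", "B"], dtype="U8")
        idx = comp.ab_index(m, self.make_profile(m.genome, labels))
        assert idx[0] == 0.0

    def test_matches_loop_oracle(self, small_matrix, small_truth):
        labels = small_truth.compartment_labels.astype("U8")
        prof = self.make_profile(small_matrix.genome, labels)
        idx = comp.ab_index(small_matrix, prof)
        dense = small_matrix.toarray()
        for i in (0, 10, 150, 299):
            a = sum(dense[i, j] for j in range(300) if labels[j] == "A")
            b = sum(dense[i, j] for j in range(300) if labels[j] == "B")
            assert idx[i] == pytest.approx((a - b) / (a + b))


class TestSwitches:
    def make_profiles(self, n=100, flip=()):
        g = syn.make_truth(n_bins=n, seed=0).genome
        pc1 = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        pc2 = pc1.copy()
        for i in flip:
            pc2[i] = -pc2[i]
        mk = lambda v: comp.CompartmentProfile(
            g, v, np.where(v > 0, "A", "B").astype("U8"), oriented=True
        )
        return mk(pc1), mk(pc2)

    def test_identical_profiles_fully_stable(self):
        p1, p2 = self.make_profiles()
        table = comp.detect_switches(p1, p2, min_abs_delta=0.5)
        assert table.fractions["AB"] == 0.0
        assert table.fractions["BA"] == 0.0
        assert sum(table.fractions.values()) == pytest.approx(1.0)

    def test_infinite_delta_suppresses_all_switches(self):
        p1, p2 = self.make_profiles(flip=(0, 2, 4))
        table = comp.detect_switches(p1, p2, min_abs_delta=np.inf)
        assert table.fractions["AB"] == 0.0
        assert table.fractions["BA"] == 0.0

    def test_flipped_bins_classified(self):
        p1, p2 = self.make_profiles(flip=(0, 1))
        table = comp.detect_switches(p1, p2, min_abs_delta=0.5)
        assert table.classes[0] == "AB"  # was +, now -
        assert table.classes[1] == "BA"
        assert (table.classes[2:] != "AB").all()

    def test_unoriented_profile_rejected(self):
        p1, p2 = self.make_profiles()
        p1.oriented = False
        with pytest.raises(ValueError, match="oriented"):
            comp.detect_switches(p1, p2)

    def test_regions_are_maximal_runs(self):
        p1, p2 = self.make_profiles(n=10)
        table = comp.detect_switches(p1, p2, min_abs_delta=0.5)
        # alternating A/B -> 10 single-bin regions
        assert len(table.regions) == 10
        assert (table.regions["end"] - table.regions["start"] == 20_000).all()
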