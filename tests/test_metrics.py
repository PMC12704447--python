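import numpy as np
import pytest

from chromvqa import engine, lattice, metrics
from chromvqa.likelihood import ContactMap


def ens(n, counts):
    return engine.EnsembleSample(N=n, counts=counts)


class TestCoverage:
    # phi over the 8 three-bead states; top half = indices 4..7
    PHI = np.arange(1.0, 9.0)

    def test_full_top_set_sampled(self):
        e = ens(3, {4: 1, 5: 1, 6: 1, 7: 1})
        cov, emp = metrics.coverage_and_empirical_probability(e, self.PHI, 0.5)
        assert cov == 1.0 and emp == 1.0

    def test_disjoint_sample(self):
        e = ens(3, {0: 10, 1: 5})
        cov, emp = metrics.coverage_and_empirical_probability(e, self.PHI, 0.5)
        assert cov == 0.0 and emp == 0.0

    def test_half_top_set_all_shots_inside(self):
        e = ens(3, {6: 30, 7: 10})
        cov, emp = metrics.coverage_and_empirical_probability(e, self.PHI, 0.5)
        assert cov == 0.5 and emp == 1.0

    def test_empirical_probability_non_increasing_in_q(self):
        # coverage itself is a ratio of two shrinking sets and need not be
        # monotone; the shot mass at/above the threshold always is
        rng = np.random.default_rng(5)
        phi = rng.uniform(size=64)
        e = ens(4, {int(k): int(c) for k, c in zip(rng.integers(0, 64, 30), rng.integers(1, 9, 30))})
        emps = [
            metrics.coverage_and_empirical_probability(e, phi, q)[1]
            for q in (0.0, 0.3, 0.6, 0.9)
        ]
        assert emps == sorted(emps, reverse=True)


class TestEntropy:
    def test_point_mass_is_zero(self):
        assert metrics.empirical_entropy(ens(3, {2: 50})) == 0.0

    def test_two_equal_counts_one_bit(self):
        assert metrics.empirical_entropy(ens(3, {0: 1, 7: 1})) == pytest.approx(1.0)

    def test_uniform_support_log2_of_size(self):
        e = ens(6, {k: 1 for k in range(4096)})
        assert metrics.empirical_entropy(e) == pytest.approx(12.0)


class TestLikelihoodRatioByLevel:
    PHI = np.arange(1.0, 9.0)  # state 7 has lowest energy

    def test_uniform_sample_gives_unit_ratios(self):
        e = ens(3, {k: 10 for k in range(8)})
        np.testing.assert_allclose(
            metrics.likelihood_ratio_by_level(e, self.PHI, bins=4), 1.0
        )

    def test_all_shots_in_lowest_energy_bin(self):
        e = ens(3, {7: 5, 6: 5})
        ratios = metrics.likelihood_ratio_by_level(e, self.PHI, bins=4)
        np.testing.assert_allclose(ratios, [4.0, 0.0, 0.0, 0.0])

    def test_ratios_conserve_unit_mean(self):
        rng = np.random.default_rng(2)
        e = ens(3, {int(k): int(c) for k, c in enumerate(rng.integers(1, 20, 8))})
        ratios = metrics.likelihood_ratio_by_level(e, self.PHI, bins=4)
        assert np.all(ratios >= 0)
        assert ratios.mean() == pytest.approx(1.0)  # equal-occupancy bins


class TestContactRecovery:
    def test_perfect_separation(self):
        pc = ContactMap.from_pairs(4, [(0, 2)])
        inferred = np.zeros((4, 4))
        inferred[0, 2] = inferred[2, 0] = 0.9
        scores = metrics.contact_recovery_scores(pc, inferred)
        assert scores["auc"] == 1.0 and scores["ap"] == 1.0

    def test_constant_scores_are_chance_level(self):
        pc = ContactMap.from_pairs(4, [(0, 2)])
        scores = metrics.contact_recovery_scores(pc, np.full((4, 4), 0.5))
        assert scores["auc"] == pytest.approx(0.5)

    def test_hand_enumerated_rank_statistics(self):
        """2 positives (0.9, 0.4) vs 4 negatives (0.5, 0.1, 0.05, 0.01):
        7 of 8 pos>neg pairs concordant -> AUC 0.875; precision 1 at recall
        0.5 and 2/3 at recall 1 -> AP 5/6."""
        pc = ContactMap.from_pairs(5, [(0, 2), (0, 4)])
        inferred = np.zeros((5, 5))
        vals = {(0, 2): 0.9, (0, 4): 0.4, (0, 3): 0.5, (1, 3): 0.1, (1, 4): 0.05, (2, 4): 0.01}
        for (i, j), v in vals.items():
            inferred[i, j] = inferred[j, i] = v
        scores = metrics.contact_recovery_scores(pc, inferred)
        assert scores["auc"] == pytest.approx(0.875)
        assert scores["ap"] == pytest.approx(5 / 6)
        assert scores["mean_pos"] == pytest.approx(0.65)
        assert scores["max_pos"] == pytest.approx(0.9)

    def test_single_class_auc_undefined(self):
        pc = ContactMap(np.zeros((4, 4), int))
        scores = metrics.contact_recovery_scores(pc, np.full((4, 4), 0.3))
        assert np.isnan(scores["auc"])


class TestDSI:
    def test_exact_binary_recovery(self):
        pc = ContactMap.from_pairs(4, [(0, 2), (1, 3)])
        out = metrics.dsi(pc, pc.entries.astype(float))
        assert out == {"dsi_w": 1.0, "dsi_m": 1.0}

    def test_zero_inferred_with_positives(self):
        pc = ContactMap.from_pairs(4, [(0, 2)])
        out = metrics.dsi(pc, np.zeros((4, 4)))
        assert out["dsi_w"] == 0.0 and out["dsi_m"] == 0.0

    def test_half_confidence_tie(self):
        """One positive and one negative both inferred at 0.5."""
        pc = ContactMap.from_pairs(4, [(0, 2)])
        inferred = np.zeros((4, 4))
        inferred[0, 2] = inferred[2, 0] = 0.5
        inferred[0, 3] = inferred[3, 0] = 0.5
        out = metrics.dsi(pc, inferred)
        assert out["dsi_w"] == pytest.approx(0.5)
        assert out["dsi_m"] == pytest.approx(2 / 3)  # threshold t=0 wins

    def test_empty_target_and_inferred_by_convention(self):
        pc = ContactMap(np.zeros((4, 4), int))
        out = metrics.dsi(pc, np.zeros((4, 4)))
        assert out == {"dsi_w": 1.0, "dsi_m": 1.0}


class TestConsensus:
    def test_identity(self):
        d2 = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
        out = metrics.consensus_scores(d2, np.sqrt(d2))
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-12)
        assert out["spearman"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        d2 = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
        out = metrics.consensus_scores(d2, 2.0 * np.sqrt(d2))
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-12)
        assert out["scale"] == pytest.approx(2.0)

    def test_closed_form_toy(self):
        """D = (1, 1, 2), Dt = (2, 2, 5): s* = 7/3 and RMSD = 1/3."""
        d = np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0]], dtype=float)
        dt = np.array([[0, 2, 2], [2, 0, 5], [2, 5, 0]], dtype=float)
        out = metrics.consensus_scores(d**2, dt)
        assert out["scale"] == pytest.approx(7 / 3)
        assert out["rmsd"] == pytest.approx(1 / 3)

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            metrics.consensus_scores(np.zeros((3, 3)), np.ones((3, 3)))


class TestEnsembleJS:
    def test_identical_ensembles(self):
        a = ens(4, {0: 5, 63: 5})
        assert metrics.ensemble_js_divergence(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_contact_supports(self):
        straight = lattice.SpinString.from_iterable(4, [1] * 6).to_bits()
        hairpin = lattice.SpinString.from_iterable(4, [1, 1, -1, -1, -1, -1]).to_bits()
        js = metrics.ensemble_js_divergence(ens(4, {straight: 4}), ens(4, {hairpin: 4}))
        assert js == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_overlap(self):
        """Uniform on {s1,s2} vs point mass on s1: JS ~ 0.3113 bits."""
        def raw_key(e):
            return dict(e.counts)

        a = ens(4, {0: 1, 1: 1})
        b = ens(4, {0: 2})
        js = metrics.ensemble_js_divergence(a, b, state_key=raw_key)
        expected = 0.5 * (0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)) + 0.5 * np.log2(1 / 0.75)
        assert js == pytest.approx(expected, rel=1e-9)
        assert js == pytest.approx(0.3113, abs=1e-4)

    def test_bead_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bead"):
            metrics.ensemble_js_divergence(ens(4, {0: 1}), ens(5, {0: 1}))


class TestPairedF1:
    def test_identical_singletons(self):
        m = ContactMap.from_pairs(5, [(0, 2), (1, 4)])
        out = metrics.paired_f1([m], [m])
        np.testing.assert_allclose(out["scores"], [1.0])

    def test_contact_disjoint_singletons(self):
        a = ContactMap.from_pairs(5, [(0, 2)])
        b = ContactMap.from_pairs(5, [(1, 4)])
        out = metrics.paired_f1([a], [b])
        np.testing.assert_allclose(out["scores"], [0.0])

    def test_assignment_prefers_diagonal(self):
        """F1 matrix [[1, 0], [0, 0.5]] -> diagonal matching (1, 0.5)."""
        a1 = ContactMap.from_pairs(5, [(0, 2)])
        a2 = ContactMap.from_pairs(5, [(0, 3), (1, 3)])
        b2 = ContactMap.from_pairs(5, [(0, 3), (2, 4)])
        out = metrics.paired_f1([a1, a2], [a1, b2])
        assert sorted(out["scores"].tolist()) == pytest.approx([0.5, 1.0])
        assert out["fraction_at_or_above"][0.5] == 1.0
        assert out["fraction_at_or_above"][0.7] == 0.5

    def test_duplicates_in_first_set_removed(self):
        m = ContactMap.from_pairs(5, [(0, 2)])
        out = metrics.paired_f1([m, m, m], [m, m])
        assert len(out["scores"]) == 1


class TestLandscapeMIC:
    def test_constant_objective(self):
        h = metrics.landscape_mic(
            lambda th: 3.0, p=1, seed=0,
            samples_per_param=8, num_walks=4, walk_len_per_param=16,
        )
        assert h == 0.0

    def test_monotone_walks_carry_no_information(self):
        counter = {"v": 0.0}

        def rising(th):
            counter["v"] += 1.0
            return counter["v"]

        h = metrics.landscape_mic(
            rising, p=1, seed=0, samples_per_param=8, num_walks=4, walk_len_per_param=16
        )
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_alternating_differences_reach_log6_two(self):
        counter = {"k": 0}

        def alternating(th):
            counter["k"] += 1
            return float(counter["k"] % 2)

        h = metrics.landscape_mic(
            alternating, p=1, seed=0,
            samples_per_param=8, num_walks=4, walk_len_per_param=16,
        )
        # 16 alternating differences -> 15 unequal symbol pairs split (8, 7);
        # the infinite-walk limit of this entropy is log6(2) ~ 0.3869
        expected = -(8 / 15) * np.log(8 / 15) / np.log(6) - (7 / 15) * np.log(
            7 / 15
        ) / np.log(6)
        assert h == pytest.approx(expected, rel=1e-9)

    def test_invalid_parameter_count(self):
        with pytest.raises(ValueError, match="parameter"):
            metrics.landscape_mic(lambda th: 0.0, p=0, seed=0)
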