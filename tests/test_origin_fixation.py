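"""Origin-fixation jump chain: matrix, navigability, path entropy, steady states."""

import numpy as np
import pytest
from scipy import linalg

import tfscape as t
from conftest import entropy_by_enumeration, enumerate_paths, random_dag_landscape


class TestMatrix:
    def test_hand_worked_fork_probabilities(self, fork):
        # improving neighbors: transition with f = 0.1, transversion with
        # f = 0.3; at alpha = 0.5 the jump splits 0.05/0.20 vs 0.15/0.20
        M = t.build_matrix(fork, alpha=0.5)
        i = fork.index["AAAAAAAA"]
        j = fork.index["GAAAAAAA"]   # transition, f = 0.1
        k = fork.index["AAAAAAAC"]   # transversion, f = 0.3
        P = M.P.toarray()
        assert P[i, j] == pytest.approx(0.25)
        assert P[i, k] == pytest.approx(0.75)

    def test_extreme_transition_bias_concentrates_on_transition_edge(self, fork):
        M = t.build_matrix(fork, alpha=0.999)
        i, j = fork.index["AAAAAAAA"], fork.index["GAAAAAAA"]
        assert M.P.toarray()[i, j] > 0.99

    def test_peak_row_is_absorbing(self, fork):
        M = t.build_matrix(fork, alpha=0.5)
        p = fork.peak_index
        assert M.absorbing[p]
        assert M.P.toarray()[p, p] == 1.0

    @pytest.mark.parametrize("alpha", [0.05, 0.5, 0.95])
    def test_rows_sum_to_one(self, alpha):
        L = t.synthesize(t.SynthConfig(target_bound_size=100, seed=11))
        M = t.build_matrix(L, alpha=alpha)
        np.testing.assert_allclose(np.asarray(M.P.sum(axis=1)).ravel(), 1.0,
                                   atol=1e-12)

    def test_no_bias_symmetric_under_class_relabeling(self, fork):
        # at alpha = 0.5 transition and transversion edges get equal phi, so
        # relabeling every edge class leaves the matrix unchanged
        M = t.build_matrix(fork, alpha=0.5)
        flipped = t.Landscape(
            tf_name="flip", genotypes=fork.genotypes, scores=fork.scores,
            edges=tuple((i, j, t.TRANSITION if c == t.TRANSVERSION else t.TRANSVERSION)
                        for i, j, c in fork.edges),
            delta=fork.delta)
        Mf = t.build_matrix(flipped, alpha=0.5)
        np.testing.assert_allclose(M.P.toarray(), Mf.P.toarray(), atol=1e-15)

    def test_delta_thresholding_removes_small_gains(self):
        scores = {"AAAAAAAA": 0.36, "AAAAAAAC": 0.40, "AAAAAACC": 0.47}
        L = t.build_landscape(t.ScoreTable(tf_name="chain", scores=scores),
                              min_component=3)
        L.delta = 0.05
        M = t.build_matrix(L, alpha=0.5, use_delta=True)
        assert M.absorbing[L.index["AAAAAAAA"]]  # 0.04 gain is below delta
        M2 = t.build_matrix(L, alpha=0.5, use_delta=False)
        assert not M2.absorbing[L.index["AAAAAAAA"]]


class TestPPeak:
    def test_two_state_chain_reaches_one(self):
        scores = {"AAAAAAAA": 0.36, "AAAAAAAC": 0.45}
        L = t.build_landscape(t.ScoreTable(tf_name="pair", scores=scores),
                              min_component=2)
        L.delta = 0.0
        M = t.build_matrix(L, alpha=0.3)
        assert t.p_peak(M, [L.index["AAAAAAAA"]], t=1) == pytest.approx(1.0)

    def test_absorbing_non_peak_start_scores_zero(self, two_peaks):
        M = t.build_matrix(two_peaks, alpha=0.5)
        local = two_peaks.index["GAAAAAAA"]
        assert M.absorbing[local]
        assert t.p_peak(M, [local], t=100) == 0.0

    def test_fork_hand_value(self, fork):
        M = t.build_matrix(fork, alpha=0.5)
        s = fork.index["AAAAAAAA"]
        for steps in (1, 10, 1000):
            assert t.p_peak(M, [s], t=steps) == pytest.approx(0.75)

    def test_nondecreasing_in_t(self):
        L = t.synthesize(t.SynthConfig(target_bound_size=100, seed=5))
        M = t.build_matrix(L, alpha=0.3)
        starts = L.bottom_fraction()
        vals = [t.p_peak(M, starts, t=steps) for steps in (1, 3, 10, 50, 200)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        # converged once t exceeds the longest accessible path (< n states)
        assert t.p_peak(M, starts, t=L.n) == pytest.approx(
            t.p_peak(M, starts, t=2 * L.n), abs=1e-12)

    def test_two_peaks_never_certain(self, two_peaks):
        for a in (0.05, 0.5, 0.95):
            M = t.build_matrix(two_peaks, alpha=a)
            s = two_peaks.index["AAAAAAAA"]
            assert 0 < t.p_peak(M, [s], t=500) < 1


class TestPathEntropy:
    def test_single_path_has_zero_entropy(self, single_path):
        M = t.build_matrix(single_path, alpha=0.5)
        s = [single_path.index["AAAAAAAA"]]
        assert t.path_entropy(M, s) == pytest.approx(0.0, abs=1e-12)

    def test_two_equiprobable_paths_give_one_bit(self):
        # symmetric diamond: two all-transversion routes with equal scores
        scores = {"AAAAAAAA": 0.36, "AAAAAACA": 0.44, "AAAAAAAC": 0.44,
                  "AAAAAACC": 0.48}
        table = t.ScoreTable(tf_name="twobit", scores=scores)
        L = t.build_landscape(table, min_component=4)
        L.delta = 0.0
        M = t.build_matrix(L, alpha=0.5)
        s = [L.index["AAAAAAAA"]]
        assert t.path_entropy(M, s) == pytest.approx(1.0, abs=1e-9)

    def test_conditioned_path_probabilities_sum_to_one(self, three_paths):
        M = t.build_matrix(three_paths, alpha=0.4)
        s = [three_paths.index["AAAAAAAA"]]
        paths = enumerate_paths(M, s)
        peak_paths = [p for p in paths if p[0][-1] == three_paths.peak_index]
        z = sum(pr for _, pr in peak_paths)
        assert sum(pr / z for _, pr in peak_paths) == pytest.approx(1.0)

    def test_matches_enumeration_on_toys(self, three_paths, two_peaks):
        for L in (three_paths, two_peaks):
            for a in (0.1, 0.5, 0.9):
                M = t.build_matrix(L, alpha=a)
                starts = L.bottom_fraction(0.3)
                exact = t.path_entropy(M, starts)
                brute = entropy_by_enumeration(M, starts, L.peak_index)
                assert exact == pytest.approx(brute, abs=1e-10)

    def test_matches_enumeration_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            L = random_dag_landscape(rng, n_nodes=int(rng.integers(5, 13)))
            M = t.build_matrix(L, alpha=float(rng.uniform(0.1, 0.9)))
            starts = L.bottom_fraction(0.25)
            try:
                exact = t.path_entropy(M, starts)
            except ValueError:
                continue  # peak unreachable: oracle would fail identically
            brute = entropy_by_enumeration(M, starts, L.peak_index)
            assert exact == pytest.approx(brute, abs=1e-9)


class TestSweep:
    def test_grid_shape_and_contents(self, fork):
        res = t.alpha_sweep(fork, t=50)
        assert len(res.table) == 19
        assert res.table.alpha.iloc[0] == pytest.approx(0.05)
        assert res.table.alpha.iloc[-1] == pytest.approx(0.95)
        assert 0.5 in set(np.round(res.table.alpha, 10))

    def test_single_move_chain_is_alpha_independent(self, single_path):
        res = t.alpha_sweep(single_path, t=50)
        np.testing.assert_allclose(res.table.p_peak, 1.0, atol=1e-12)

    def test_three_paths_entropy_minimized_at_transversion_extreme(self, three_paths):
        res = t.alpha_sweep(three_paths, t=50)
        assert res.alpha_min_entropy == pytest.approx(0.05)
        assert res.entropy_reduction > 1.0

    def test_fork_ppeak_maximized_at_transversion_extreme(self, fork):
        # the global peak is reached by a transversion: more transversion
        # supply means more absorption at the peak
        res = t.alpha_sweep(fork, t=50, compute_entropy=False)
        assert res.alpha_max_ppeak == pytest.approx(0.05)
        p = res.table.p_peak.to_numpy()
        assert np.all(np.diff(p) < 0)  # strictly decreasing in alpha


class TestStationary:
    def test_single_absorber_gives_peak_indicator(self, single_path):
        M = t.build_matrix(single_path, alpha=0.5)
        v = t.stationary_distribution(M.P)
        expected = np.zeros(single_path.n)
        expected[single_path.peak_index] = 1.0
        np.testing.assert_allclose(v, expected, atol=1e-10)

    def test_doubly_stochastic_two_state(self):
        v = t.stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        np.testing.assert_allclose(v, [0.5, 0.5], atol=1e-12)

    def test_matches_dense_eigensolver_on_random_chains(self):
        rng = np.random.default_rng(7)
        for n in (5, 9, 20):
            P = rng.uniform(0.05, 1.0, size=(n, n))
            P /= P.sum(axis=1, keepdims=True)
            v = t.stationary_distribution(P)
            w, vl = linalg.eig(P.T)
            lead = np.argmax(w.real)
            ref = np.abs(vl[:, lead].real)
            ref /= ref.sum()
            np.testing.assert_allclose(v, ref, atol=1e-9)

    def test_distance(self):
        assert t.steady_state_distance([1, 0], [0, 1]) == pytest.approx(np.sqrt(2))
        assert t.steady_state_distance([0.5, 0.5, 0], [0, 0.5, 0.5]) == (
            pytest.approx(np.sqrt(0.5)))
        assert t.steady_state_distance([0.2, 0.8], [0.2, 0.8]) == 0.0
        with pytest.raises(ValueError):
            t.steady_state_distance([1, 0], [1, 0, 0])
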