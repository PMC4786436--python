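"""Leave-two-out encoding: folds, selection, regression, pruning, decoding."""

import dataclasses

import numpy as np
import pytest

import handsyn as hs
from handsyn.encoding import (
    cluster_prune,
    fit_encoding_regression,
    select_voxels_stage1,
)


class TestFolds:
    def test_twenty_stimuli_give_190_folds(self):
        folds = hs.enumerate_folds(20)
        assert len(folds) == 190
        assert len(hs.enumerate_folds(3)) == 3

    def test_each_stimulus_in_n_minus_1_pairs(self):
        folds = hs.enumerate_folds(20)
        counts = np.zeros(20, dtype=int)
        for train, pair in folds:
            counts[list(pair)] += 1
            assert len(train) == 18 and not set(train) & set(pair)
        assert np.all(counts == 19)

    def test_too_few_stimuli_rejected(self):
        with pytest.raises(ValueError):
            hs.enumerate_folds(2)


class TestStage1Selection:
    def test_tie_break_by_index(self):
        vp = hs.VoxelPatternSet(
            np.ones((10, 4)), np.c_[np.arange(10), np.zeros(10), np.zeros(10)]
        )
        np.testing.assert_array_equal(
            select_voxels_stage1(vp, [0, 1], 3), [0, 1, 2]
        )

    def test_dominant_voxel_always_kept(self):
        rng = np.random.default_rng(0)
        resp = rng.normal(size=(50, 6))
        resp[17] += 100.0
        vp = hs.VoxelPatternSet(
            resp, np.c_[np.arange(50), np.zeros(50), np.zeros(50)]
        )
        assert 17 in select_voxels_stage1(vp, [0, 2, 4], 5)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        resp = rng.normal(size=(40, 8))
        vp = hs.VoxelPatternSet(
            resp, np.c_[np.arange(40), np.zeros(40), np.zeros(40)]
        )
        train = [0, 3, 5, 7]
        got = select_voxels_stage1(vp, train, 10)
        want = np.sort(np.argsort(-resp[:, train].mean(axis=1))[:10])
        np.testing.assert_array_equal(got, want)


class TestRegression:
    def test_noiseless_linear_r2_one(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(18, 5))
        coef = rng.normal(size=(5, 30))
        patterns = w @ coef
        _, r2 = fit_encoding_regression(w, patterns, include_intercept=True)
        np.testing.assert_allclose(r2, 1.0, atol=1e-10)

    def test_simple_regression_closed_form(self):
        """Single predictor, three stimuli: matches the textbook formulas."""
        x = np.array([[1.0], [2.0], [4.0]])
        y = np.array([[2.0], [3.0], [8.0]])
        coef, r2 = fit_encoding_regression(x, y, include_intercept=True)
        sxy = np.sum((x[:, 0] - x.mean()) * (y[:, 0] - y.mean()))
        sxx = np.sum((x[:, 0] - x.mean()) ** 2)
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        assert abs(coef[0, 0] - slope) < 1e-12
        assert abs(coef[1, 0] - intercept) < 1e-12
        assert abs(r2[0] - sxy**2 / (sxx * np.sum((y - y.mean()) ** 2))) < 1e-12

    def test_null_r2_matches_ols_overfit_expectation(self):
        """Independent patterns: mean training R^2 ~ k/(n-1) by chance."""
        rng = np.random.default_rng(3)
        w = rng.normal(size=(18, 5))
        patterns = rng.normal(size=(18, 4000))
        _, r2 = fit_encoding_regression(w, patterns, include_intercept=True)
        assert abs(np.mean(r2) - 5.0 / 17.0) < 0.02

    def test_collinear_design_rejected(self):
        w = np.random.default_rng(4).normal(size=(18, 4))
        w = np.column_stack([w, w[:, 0]])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_encoding_regression(w, np.zeros((18, 3)))


class TestClusterPrune:
    @staticmethod
    def _grid(mask3d):
        return np.argwhere(np.ones(mask3d.shape, dtype=bool)), mask3d.ravel()

    def test_threshold_definition(self):
        vol = np.zeros((12, 5, 5), dtype=bool)
        vol[:3, :4, :5] = True  # 60-voxel blob
        vol[8:10, 0, :5] = True  # 10-voxel blob
        coords, flat = self._grid(vol)
        selected = np.flatnonzero(flat)
        kept = cluster_prune(coords, selected, min_size=50)
        assert len(kept) == 60

    def test_isolated_voxels_all_pruned(self):
        coords = np.array([[0, 0, 0], [5, 5, 5], [9, 0, 9]])
        kept = cluster_prune(coords, np.arange(3), min_size=2)
        assert len(kept) == 0

    def test_connectivity_modes_differ_on_diagonal(self):
        coords = np.array([[0, 0, 0], [1, 1, 1]])
        assert len(cluster_prune(coords, np.arange(2), 2, "face")) == 0
        assert len(cluster_prune(coords, np.arange(2), 2, "vertex")) == 2

    def test_matches_floodfill_oracle(self):
        """Random masks agree with a brute-force BFS flood fill."""
        rng = np.random.default_rng(5)
        shape = (8, 8, 8)
        coords = np.argwhere(np.ones(shape, dtype=bool))
        for trial in range(5):
            selected = np.flatnonzero(rng.random(512) < 0.3)
            kept = set(cluster_prune(coords, selected, min_size=4).tolist())
            # BFS oracle under face adjacency
            sel_set = set(map(tuple, coords[selected]))
            seen, keep_oracle = set(), set()
            for start in sel_set:
                if start in seen:
                    continue
                comp, queue = [], [start]
                seen.add(start)
                while queue:
                    v = queue.pop()
                    comp.append(v)
                    for ax in range(3):
                        for dd in (-1, 1):
                            nb = list(v)
                            nb[ax] += dd
                            nb = tuple(nb)
                            if nb in sel_set and nb not in seen:
                                seen.add(nb)
                                queue.append(nb)
                if len(comp) >= 4:
                    keep_oracle.update(comp)
            got = set(map(tuple, coords[sorted(kept)]))
            assert got == keep_oracle


class TestPairwiseDecode:
    def test_exact_predictions_score_two(self):
        obs = np.random.default_rng(6).normal(size=(2, 50))
        assert hs.pairwise_decode(obs, obs) == 2

    def test_swapped_predictions_score_zero(self):
        obs = np.random.default_rng(7).normal(size=(2, 50))
        assert hs.pairwise_decode(obs[::-1], obs) == 0

    def test_random_predictions_are_chance(self):
        rng = np.random.default_rng(8)
        total = sum(
            hs.pairwise_decode(rng.normal(size=(2, 40)), rng.normal(size=(2, 40)))
            for _ in range(2000)
        )
        assert abs(total / 4000.0 - 0.5) < 0.03

    def test_zero_variance_pattern_maximal_distance(self):
        obs = np.vstack([np.zeros(20), np.random.default_rng(9).normal(size=20)])
        pred = np.random.default_rng(10).normal(size=(2, 20))
        assert hs.pairwise_decode(pred, obs) in (0, 1, 2)


class TestRunEncoding:
    def test_noiseless_linear_data_is_perfect(self, synergy_model):
        cfg = hs.SynthConfig(
            seed=31, grid_shape=(10, 10, 10), voxel_noise_sd=0.0,
            zero_coef_fraction=0.0, smoothness_fwhm=3.0,
        )
        vp = hs.generate_voxel_patterns(synergy_model.weights, cfg)
        res = hs.run_encoding(
            vp, synergy_model.weights,
            hs.EncodingConfig(600, 200, 10, seed=1),
        )
        assert res.overall_accuracy == 100.0
        assert res.recruitment.max() <= 2 * 190

    def test_recruitment_and_pair_outcome_invariants(
        self, voxel_patterns, synergy_model, small_encoding_cfg
    ):
        res = hs.run_encoding(voxel_patterns, synergy_model.weights, small_encoding_cfg)
        assert 0 <= res.overall_accuracy <= 100
        assert np.all(res.recruitment >= 0) and res.recruitment.max() <= 380
        po = res.pair_outcomes
        assert np.all(np.isnan(np.diag(po)))
        np.testing.assert_allclose(po, po.T, equal_nan=True)

    def test_matches_bruteforce_single_fold(self):
        """Full pipeline agrees with an explicit re-implementation of one
        fold on a 30-voxel instance (no pruning ambiguity: min_size=1)."""
        rng = np.random.default_rng(12)
        w = rng.normal(size=(8, 3))
        resp = rng.normal(size=(30, 8))
        coords = np.argwhere(np.ones((5, 3, 2), dtype=bool))
        vp = hs.VoxelPatternSet(resp, coords)
        cfg = hs.EncodingConfig(20, 8, 1, seed=0)
        res = hs.run_encoding(vp, w, cfg)
        # brute force fold (train on stimuli != {0,1})
        train = [2, 3, 4, 5, 6, 7]
        mean_resp = resp[:, train].mean(axis=1)
        stage1 = np.sort(np.argsort(-mean_resp, kind="stable")[:20])
        x = np.column_stack([w[train], np.ones(len(train))])
        correct = 0
        r2s, coefs = [], []
        for v in stage1:
            y = resp[v, train]
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            fitted = x @ beta
            r2s.append(1 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2))
            coefs.append(beta)
        keep = np.sort(np.argsort(-np.asarray(r2s), kind="stable")[:8])
        final = stage1[keep]
        pred = np.array(
            [
                [np.r_[w[s], 1.0] @ coefs[i] for i in keep]
                for s in (0, 1)
            ]
        )
        obs = resp[final][:, [0, 1]].T
        for i in range(2):
            d_same = 1 - np.corrcoef(pred[i], obs[i])[0, 1]
            d_other = 1 - np.corrcoef(pred[i], obs[1 - i])[0, 1]
            correct += d_same < d_other
        fold0 = next(f for f in res.per_fold if f["pair"] == (0, 1))
        assert fold0["correct"] == correct

    def test_accuracy_monotone_in_snr(self, synergy_model):
        accs = []
        for noise in (4.0, 1.0, 0.25):
            cfg = hs.SynthConfig(
                seed=33, grid_shape=(10, 10, 10), voxel_noise_sd=noise,
                smoothness_fwhm=3.0,
            )
            vp = hs.generate_voxel_patterns(synergy_model.weights, cfg)
            res = hs.run_encoding(
                vp, synergy_model.weights, hs.EncodingConfig(600, 200, 10)
            )
            accs.append(res.overall_accuracy)
        assert accs[0] <= accs[1] <= accs[2]

    def test_stage_counts_clamped_on_small_grids(self, voxel_patterns, synergy_model):
        res = hs.run_encoding(
            voxel_patterns, synergy_model.weights,
            hs.EncodingConfig(5000, 1000, 10, seed=1),
        )
        assert 0 <= res.overall_accuracy <= 100


class TestPermutationNull:
    def test_null_centred_at_chance_and_signal_significant(
        self, voxel_patterns, synergy_model
    ):
        cfg = hs.EncodingConfig(600, 200, 10, n_perm=30, seed=5)
        res = hs.permutation_null_encoding(voxel_patterns, synergy_model.weights, cfg)
        assert abs(np.mean(res.null_distribution) - 50.0) < 6.0
        assert res.p_value == 1.0 / 31.0  # observed beats every permutation

    def test_within_column_shuffle_preserves_variance(self):
        rng = np.random.default_rng(14)
        w = rng.normal(size=(18, 5))
        idx = np.argsort(rng.random((18, 5)), axis=0)
        shuffled = w[idx, np.arange(5)[np.newaxis, :]]
        np.testing.assert_allclose(
            shuffled.var(axis=0), w.var(axis=0), rtol=1e-12
        )
        np.testing.assert_allclose(np.sort(shuffled, axis=0), np.sort(w, axis=0))


class TestGroupMaps:
    def test_identical_maps_overlap_everywhere(self):
        m = np.array([0, 2, 5, 0, 1])
        overlap, mask = hs.group_probability_map([m] * 9, min_subjects=4)
        np.testing.assert_array_equal(overlap, [0, 9, 9, 0, 9])
        np.testing.assert_array_equal(mask, m > 0)

    def test_disjoint_maps_give_empty_threshold(self):
        maps = [np.eye(5)[i] for i in range(5)]
        overlap, mask = hs.group_probability_map(maps, min_subjects=2)
        assert overlap.max() == 1 and not mask.any()

    def test_shared_blob_survives(self):
        rng = np.random.default_rng(15)
        maps = []
        for s in range(9):
            m = np.zeros(100)
            m[40:60] = rng.integers(1, 10, 20)  # shared signal
            scatter = rng.choice(100, 10, replace=False)
            m[scatter] += rng.integers(0, 3, 10)
            maps.append(m)
        _, mask = hs.group_probability_map(maps, min_subjects=4)
        assert mask[40:60].all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hs.group_probability_map([np.zeros(5), np.zeros(6)])

    def test_heatmap_mean_and_symmetry(self):
        n = 4
        po_a = np.full((n, n), 100.0)
        po_b = np.full((n, n), 0.0)
        np.fill_diagonal(po_a, np.nan)
        np.fill_diagonal(po_b, np.nan)
        res_a = hs.EncodingResult(100.0, po_a, np.zeros(5))
        res_b = hs.EncodingResult(0.0, po_b, np.zeros(5))
        hm = hs.pair_accuracy_heatmap([res_a, res_b])
        off = ~np.eye(n, dtype=bool)
        assert np.all(hm[off] == 50.0)
        np.testing.assert_allclose(hm, hm.T, equal_nan=True)
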