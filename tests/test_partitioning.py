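import numpy as np
import pytest

from nirmoist import SplitResult, ks_split, split_diagnostics, spxy_split


def naive_maxmin_train(d: np.ndarray, n_train: int) -> set[int]:
    """Independent loop-based max-min selection (the oracle).

    Scans all pairs for the seed and all candidates per growth step with
    explicit python loops, breaking ties toward the lowest index.
    """
    n = d.shape[0]
    best, seed_pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, seed_pair = d[i, j], (i, j)
    selected = list(seed_pair)
    while len(selected) < n_train:
        best_cand, best_min = None, -1.0
        for cand in range(n):
            if cand in selected:
                continue
            dmin = min(d[cand, s] for s in selected)
            if dmin > best_min:
                best_min, best_cand = dmin, cand
        selected.append(best_cand)
    return set(selected)


def joint_distance(x, y):
    dx = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    return d


class TestOracleEquivalence:
    def test_spxy_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            p = int(rng.integers(1, 5))
            x = rng.normal(0, 1, (n, p))
            y = rng.normal(0, 1, n)
            n_train = int(rng.integers(2, n + 1))
            split = spxy_split(x, y, n_train)
            oracle = naive_maxmin_train(joint_distance(x, y), n_train)
            assert set(split.train_indices.tolist()) == oracle

    def test_ks_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            x = rng.normal(0, 1, (n, 3))
            n_train = int(rng.integers(2, n + 1))
            split = ks_split(x, n_train)
            d = joint_distance(x, np.zeros(n))
            assert set(split.train_indices.tolist()) == naive_maxmin_train(d, n_train)


class TestWorkedExamples:
    def test_colinear_three_points_train_on_extremes(self):
        split = spxy_split(np.array([[0.0], [1.0], [2.0]]), np.array([0.0, 1.0, 2.0]), 2)
        assert set(split.train_indices.tolist()) == {0, 2}
        assert split.test_indices.tolist() == [1]

    def test_full_train_leaves_empty_test(self):
        x = np.random.default_rng(1).normal(0, 1, (5, 2))
        split = spxy_split(x, np.arange(5.0), 5)
        assert sorted(split.train_indices.tolist()) == [0, 1, 2, 3, 4]
        assert split.test_indices.size == 0

    def test_identical_spectra_selection_driven_by_y(self):
        x = np.ones((3, 4))
        with pytest.warns(UserWarning, match="spectral"):
            split = spxy_split(x, np.array([0.0, 5.0, 10.0]), 2)
        assert set(split.train_indices.tolist()) == {0, 2}

    def test_ks_equals_spxy_when_y_affine_in_x(self):
        x = np.array([[0.0], [1.0], [2.0], [3.5]])
        y = 2.0 * x.ravel() + 1.0
        assert np.array_equal(spxy_split(x, y, 3).train_indices, ks_split(x, 3).train_indices)

    def test_all_identical_rows_tie_break_lowest_indices(self):
        x = np.ones((5, 3))
        with pytest.warns(UserWarning):
            split = ks_split(x, 3)
        assert split.train_indices.tolist() == [0, 1, 2]

    def test_deterministic_across_calls(self, small_xy):
        x, y = small_xy
        a = spxy_split(x, y, 90)
        b = spxy_split(x, y, 90)
        assert np.array_equal(a.train_indices, b.train_indices)


class TestContracts:
    def test_partition_is_disjoint_and_exhaustive(self, small_xy):
        x, y = small_xy
        split = spxy_split(x, y, 90)
        merged = np.sort(np.concatenate([split.train_indices, split.test_indices]))
        assert np.array_equal(merged, np.arange(x.shape[0]))
        assert split.n_train == 90

    def test_default_sizes_match_study_design(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (380, 6))
        y = rng.normal(10, 2, 380)
        split = spxy_split(x, y, 300)
        assert len(split.train_indices) == 300
        assert len(split.test_indices) == 80

    def test_invalid_n_train_rejected(self):
        with pytest.raises(ValueError, match="n_train"):
            spxy_split(np.zeros((3, 1)), np.arange(3.0), 1)

    def test_json_round_trip(self, tmp_path, small_xy):
        x, y = small_xy
        split = spxy_split(x, y, 40)
        path = tmp_path / "split.json"
        split.to_json(path)
        back = SplitResult.from_json(path)
        assert np.array_equal(back.train_indices, split.train_indices)
        assert back.method == "spxy"

    def test_diagnostics_reports_range_containment(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        split = SplitResult(np.array([0, 3]), np.array([1, 2]), "spxy", 2)
        diag = split_diagnostics(y, split)
        assert diag["test_range_within_train"] is True
        split2 = SplitResult(np.array([1, 2]), np.array([0, 3]), "spxy", 2)
        assert split_diagnostics(y, split2)["test_range_within_train"] is False
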