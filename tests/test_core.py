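import numpy as np
import pytest

import spheremml as sm
from spheremml.core import MODEL_FORMAT_VERSION

from _oracle import learn_oracle


class TestSplitByClass:
    def test_partition_preserves_order(self):
        data = sm.LabeledDataset(np.arange(6.0).reshape(3, 2), [1, 2, 1])
        y1, y2 = sm.split_by_class(data)
        assert np.array_equal(y1, [[0, 1], [4, 5]])
        assert np.array_equal(y2, [[2, 3]])

    def test_single_class_raises(self):
        data = sm.LabeledDataset(np.zeros((3, 2)), [1, 1, 1])
        with pytest.raises(sm.DegenerateTrainingError):
            sm.split_by_class(data)

    def test_counts_add_up(self, shells):
        y1, y2 = sm.split_by_class(shells)
        assert y1.shape[0] + y2.shape[0] == shells.n_patterns


class TestTMeans:
    def test_midpoint_of_class_means(self):
        prof = sm.t_means(np.array([[0.0], [2.0]]), np.array([[3.0], [5.0]]))
        assert prof.m1[0] == 1 and prof.m2[0] == 4 and prof.t_means[0] == 2.5

    def test_identical_classes(self):
        y = np.array([[1.0], [3.0]])
        assert sm.t_means(y, y).t_means[0] == 2.0

    def test_matches_independent_means(self):
        rng = np.random.default_rng(1)
        y1, y2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        prof = sm.t_means(y1, y2)
        for j in range(3):
            expected = (sum(y1[:, j]) / 5 + sum(y2[:, j]) / 5) / 2
            assert prof.t_means[j] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            sm.t_means(np.zeros((2, 2)), np.zeros((2, 3)))


class TestErrorVectors:
    def test_perfect_below_separation(self):
        y1 = np.array([[0.0], [1.0]])
        y2 = np.array([[5.0], [6.0], [7.0]])
        e1, e2 = sm.error_vectors(y1, y2, np.array([3.0]))
        assert e1[0] == 0 and e2[0] == 5

    def test_threshold_ties_count_in_neither(self):
        y1 = np.array([[2.0], [1.0]])
        y2 = np.array([[2.0], [3.0]])
        e1, e2 = sm.error_vectors(y1, y2, np.array([2.0]))
        # the two values at exactly 2.0 are errors for neither hypothesis
        assert e1[0] == 0 and e2[0] == 2

    def test_counts_partition_with_ties(self, tiny):
        y1, y2 = sm.split_by_class(tiny)
        prof = sm.t_means(y1, y2)
        e1, e2 = sm.error_vectors(y1, y2, prof.t_means)
        n = tiny.n_patterns
        for j in range(tiny.n_attributes):
            ties = int((y1[:, j] == prof.t_means[j]).sum() + (y2[:, j] == prof.t_means[j]).sum())
            assert e1[j] + e2[j] + ties == n


class TestOrientation:
    @pytest.mark.parametrize(
        "e1, e2, expected",
        [
            ([17.5355], [17.4606], False),
            ([0, 0], [1, 1], True),
            ([3, 5], [3, 5], False),  # tie -> class 1 outside
        ],
    )
    def test_strict_mean_comparison(self, e1, e2, expected):
        assert sm.orientation(np.array(e1), np.array(e2)) is expected

    def test_label_swap_flips_everything(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = rng.normal(size=(8, 4))
            labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
            d = sm.LabeledDataset(values, labels)
            dswap = sm.LabeledDataset(values, 3 - labels)
            y1, y2 = sm.split_by_class(d)
            s1, s2 = sm.split_by_class(dswap)
            tm = sm.t_means(y1, y2).t_means
            e1, e2 = sm.error_vectors(y1, y2, tm)
            f1, f2 = sm.error_vectors(s1, s2, sm.t_means(s1, s2).t_means)
            assert np.array_equal(e1, f2) and np.array_equal(e2, f1)
            if np.mean(e1) != np.mean(e2):
                assert sm.orientation(e1, e2) != sm.orientation(f1, f2)


class TestRanking:
    @pytest.mark.parametrize(
        "errors, att, expected",
        [
            ([5, 1, 3], 2, [1, 2]),
            ([2, 2, 2], 3, [0, 1, 2]),
            ([0], 1, [0]),
        ],
    )
    def test_stable_ascending(self, errors, att, expected):
        r = sm.rank_attributes(np.array(errors), att)
        assert list(r.ordered_indices) == expected
        assert np.all(np.diff(r.ordered_errors) >= 0)

    def test_att_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            r = sm.rank_attributes(np.array([1, 2]), 5)
        assert len(r.ordered_indices) == 2


class TestRadiiAndBoundaries:
    def test_midpoint_inside(self):
        assert sm.attribute_radius([1, 2, 3], [5, 6, 7], True) == 4.0

    def test_midpoint_outside(self):
        assert sm.attribute_radius([5, 6, 7], [1, 2, 3], False) == 4.0

    def test_boundary_between_extremes(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            r1 = rng.random(5) * 10
            r2 = rng.random(5) * 10
            for c1_in in (True, False):
                b = sm.attribute_radius(r1, r2, c1_in)
                lo, hi = ((r1.max(), r2.min()) if c1_in else (r1.min(), r2.max()))
                assert min(lo, hi) <= b <= max(lo, hi)

    def test_empty_class_raises(self):
        with pytest.raises(sm.DegenerateTrainingError):
            sm.attribute_radius([], [1.0], True)

    @pytest.mark.parametrize(
        "r1, r2, boundary, c1_in, expected",
        [
            ([1], [9], 5.0, True, 0),
            ([9], [1], 5.0, False, 0),
            ([6, 1], [4, 9], 5.0, True, 2),
            ([5.0], [5.0], 5.0, True, 0),  # on-boundary radii are not errors
        ],
    )
    def test_boundary_errors(self, r1, r2, boundary, c1_in, expected):
        assert sm.boundary_errors(r1, r2, boundary, c1_in) == expected

    def test_progressive_single_attribute_midpoint(self):
        b, e = sm.progressive_boundaries(np.array([[3.0]]), np.array([[7.0]]), 1, True)
        assert b[0] == 5.0 and e[0] == 0

    def test_progressive_origin_vs_shell(self):
        rng = np.random.default_rng(3)
        y1 = np.zeros((6, 2))
        direction = rng.normal(size=(6, 2))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        y2 = 10.0 * direction
        b, e = sm.progressive_boundaries(y1, y2, 2, True)
        assert np.all(e == 0)
        assert np.all(b > 0)

    def test_norms_nondecreasing_in_k(self, shells):
        y1, y2 = sm.split_by_class(shells)
        model = sm.learn(shells, att=5, bound=5)
        n1 = np.sqrt(np.cumsum(y1[:, model.learning_attributes] ** 2, axis=1))
        assert np.all(np.diff(n1, axis=1) >= -1e-12)


class TestLearn:
    def test_separable_shells(self, shells):
        model = sm.learn(shells, att=5, bound=3)
        assert model.training_error == 0
        assert model.c1_in is True
        assert set(model.learning_attributes) <= {0, 1, 2}

    def test_perfect_single_attribute_gives_zero_error(self, tiny):
        model = sm.learn(tiny, att=3, bound=1)
        assert model.training_error == 0
        assert model.learning_attributes[0] == 1

    def test_minimal_two_pattern_dataset(self):
        d = sm.LabeledDataset(np.array([[1.0], [5.0]]), [1, 2])
        model = sm.learn(d, att=1, bound=1)
        assert len(model.learning_attributes) == 1 and len(model.boundaries) == 1

    def test_constant_dataset_raises(self):
        d = sm.LabeledDataset(np.full((4, 3), 2.0), [1, 1, 2, 2])
        with pytest.raises(sm.DegenerateTrainingError):
            sm.learn(d, att=1, bound=1)

    def test_att_percentage_mode(self, shells):
        # 10% of 53 attributes rounds to 5
        m_pct = sm.learn(shells, att=10, bound=3, att_is_percent=True)
        m_abs = sm.learn(shells, att=5, bound=3)
        assert m_pct.att == m_abs.att == 5
        assert np.array_equal(m_pct.learning_attributes, m_abs.learning_attributes)

    def test_bound_clamped_to_att(self, tiny):
        with pytest.warns(UserWarning, match="clamping"):
            model = sm.learn(tiny, att=2, bound=5)
        assert model.bound == 2

    def test_missing_values_rejected(self, tiny):
        v = tiny.values.copy()
        v[0, 0] = np.nan
        with pytest.raises(ValueError, match="attribute 0"):
            sm.learn(sm.LabeledDataset(v, tiny.labels), att=1, bound=1)


class TestBruteForceEquivalence:
    """The vectorized learning phase must agree exactly with a direct-loop
    re-implementation on small random datasets."""

    def test_matches_oracle(self):
        rng = np.random.default_rng(11)
        from conftest import random_dataset

        checked = 0
        while checked < 40:
            data = random_dataset(rng)
            att = int(rng.integers(1, data.n_attributes + 1))
            bound = int(rng.integers(1, att + 1))
            expected = learn_oracle(data.values.tolist(), data.labels.tolist(), att, bound)
            y1, y2 = sm.split_by_class(data)
            e1, e2 = sm.error_vectors(y1, y2, sm.t_means(y1, y2).t_means)
            assert list(e1) == expected["e1"]
            assert list(e2) == expected["e2"]
            model = sm.learn(data, att, bound)
            assert model.c1_in == expected["c1_in"]
            assert list(model.learning_attributes) == expected["learning_attributes"]
            assert model.training_error == expected["training_error"]
            assert model.boundaries == pytest.approx(expected["boundaries"], rel=1e-12)
            checked += 1


class TestModelSerialization:
    def test_round_trip_bit_exact(self, shells, tmp_path):
        model = sm.learn(shells, att=5, bound=3)
        model.provenance = {"seed": 7}
        path = tmp_path / "model.json"
        sm.write_model(model, path)
        loaded = sm.read_model(path)
        assert loaded.c1_in == model.c1_in
        assert np.array_equal(loaded.learning_attributes, model.learning_attributes)
        assert np.array_equal(loaded.boundaries, model.boundaries)  # bit-exact floats
        assert loaded.att == model.att and loaded.bound == model.bound
        assert loaded.class_names == model.class_names

    def test_serialized_attributes_are_one_based(self, shells, tmp_path):
        model = sm.learn(shells, att=3, bound=1)
        d = model.to_dict()
        assert d["learning_attributes"][0] == int(model.learning_attributes[0]) + 1
        assert d["format_version"] == MODEL_FORMAT_VERSION

    def test_large_attribute_index_survives(self):
        m = sm.BoundaryModel(
            c1_in=False,
            learning_attributes=np.array([7450]),  # 1-based 7451
            boundaries=np.array([49.0]),
            att=14, bound=1, training_error=0,
        )
        assert sm.BoundaryModel.from_dict(m.to_dict()).learning_attributes[0] == 7450

    def test_version_mismatch(self, shells, tmp_path):
        model = sm.learn(shells, att=3, bound=1)
        d = model.to_dict()
        d["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            sm.BoundaryModel.from_dict(d)

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"format_version": 1, "c1_in"')
        with pytest.raises(ValueError, match="parse"):
            sm.read_model(path)
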