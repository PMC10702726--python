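"""Dataset loading, one-hot coding, stratified splits, synthetic generators."""

import numpy as np
import pytest

from dpelm.datasets import (
    LabeledDataset,
    SplitSpec,
    load_csv_dataset,
    make_blobs_dataset,
    make_teacher_dataset,
    minmax_scale,
    one_hot,
    save_dataset,
    split_train_test,
)
from dpelm.exceptions import (
    DegenerateDatasetError,
    InfeasibleParameterError,
    InfeasibleSplitError,
    InvalidInputError,
    MissingDataError,
    ParseError,
)


def write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadCSV:
    def test_basic_construction(self, tmp_path):
        p = write(tmp_path, "1.0,2.0,a\n3.0,4.0,b\n5.0,6.0,a\n7.0,8.0,b\n")
        ds = load_csv_dataset(p)
        assert (ds.n_features, ds.n_samples, ds.n_classes) == (2, 4, 2)
        np.testing.assert_array_equal(ds.labels, [1, 2, 1, 2])
        assert ds.class_names == ["a", "b"]
        np.testing.assert_array_equal(ds.X[:, 0], [1.0, 2.0])

    def test_three_class_one_hot_matrix(self, tmp_path):
        p = write(tmp_path, "".join(f"{i},0,1,{c}\n" for i, c in enumerate("xyzxyz")))
        ds = load_csv_dataset(p)
        expected = np.zeros((3, 6))
        for j, c in enumerate([1, 2, 3, 1, 2, 3]):
            expected[c - 1, j] = 1.0
        np.testing.assert_array_equal(ds.T, expected)

    def test_constant_label_column_is_degenerate(self, tmp_path):
        p = write(tmp_path, "1,2,a\n3,4,a\n")
        with pytest.raises(DegenerateDatasetError):
            load_csv_dataset(p)

    def test_unparseable_cell_reports_row_and_column(self, tmp_path):
        p = write(tmp_path, "1,2,a\n3,oops,b\n")
        with pytest.raises(ParseError, match="row 1"):
            load_csv_dataset(p)

    def test_missing_values_rejected_without_imputation(self, tmp_path):
        p = write(tmp_path, "1,2,a\n3,,b\n")
        with pytest.raises(MissingDataError):
            load_csv_dataset(p)

    def test_header_and_named_label_column(self, tmp_path):
        p = write(tmp_path, "x1,x2,cls\n1,2,a\n3,4,b\n")
        ds = load_csv_dataset(p, label_column="cls", header=True)
        assert ds.class_names == ["a", "b"]


class TestOneHot:
    def test_columns_sum_to_one_and_argmax_recovers_labels(self, rng):
        labels = rng.integers(1, 5, size=40)
        T = one_hot(labels, 4)
        np.testing.assert_array_equal(T.sum(axis=0), np.ones(40))
        np.testing.assert_array_equal(np.argmax(T, axis=0) + 1, labels)


class TestSplits:
    def balanced(self):
        X = np.arange(20, dtype=float).reshape(2, 10)
        labels = np.array([1, 2] * 5)
        return LabeledDataset(X, labels, ["a", "b"])

    def test_balanced_stratified_counts(self):
        train, test = split_train_test(self.balanced(), SplitSpec(n_train=6, seed=0))
        np.testing.assert_array_equal(train.class_counts(), [3, 3])
        np.testing.assert_array_equal(test.class_counts(), [2, 2])

    def test_different_seeds_same_counts_different_indices(self):
        ds = self.balanced()
        t1, _ = split_train_test(ds, SplitSpec(n_train=6, seed=1))
        t2, _ = split_train_test(ds, SplitSpec(n_train=6, seed=2))
        np.testing.assert_array_equal(t1.class_counts(), t2.class_counts())
        assert not np.array_equal(t1.X, t2.X)

    def test_split_is_deterministic(self):
        ds = self.balanced()
        a = split_train_test(ds, SplitSpec(n_train=6, seed=3))
        b = split_train_test(ds, SplitSpec(n_train=6, seed=3))
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_breast_tumor_sized_apportionment(self):
        """Class counts (357, 212) with 450 training samples apportion to (282, 168)."""
        labels = np.array([1] * 357 + [2] * 212)
        ds = LabeledDataset(np.random.default_rng(0).normal(size=(3, 569)), labels, ["benign", "malignant"])
        train, test = split_train_test(ds, SplitSpec(n_train=450, seed=5))
        np.testing.assert_array_equal(train.class_counts(), [282, 168])
        np.testing.assert_array_equal(test.class_counts(), [75, 44])

    def test_infeasible_stratified_split_raises(self):
        labels = np.array([1] * 9 + [2])
        ds = LabeledDataset(np.zeros((2, 10)), labels, ["a", "b"])
        with pytest.raises(InfeasibleSplitError):
            split_train_test(ds, SplitSpec(n_train=9, seed=0))


class TestTeacher:
    def test_targets_reproduce_forward_pass(self):
        reg, teacher = make_teacher_dataset(10, 5, 2, 8, seed=11)
        np.testing.assert_allclose(reg.T, teacher.forward(reg.X), atol=1e-12)
        assert np.linalg.matrix_rank(reg.X) == 8
        assert np.linalg.matrix_rank(teacher.beta_true) == 2

    def test_infeasible_shapes_raise(self):
        with pytest.raises(InfeasibleParameterError):
            make_teacher_dataset(10, 2, 3, 8)  # m > L_true
        with pytest.raises(InfeasibleParameterError, match="rank"):
            make_teacher_dataset(4, 5, 2, 8)  # N > n

    def test_same_seed_bit_identical(self):
        a, _ = make_teacher_dataset(10, 5, 2, 8, seed=3)
        b, _ = make_teacher_dataset(10, 5, 2, 8, seed=3)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.T, b.T)


class TestBlobs:
    def test_near_equal_class_sizes(self):
        ds = make_blobs_dataset(5, 3, 301, separation=3.0, noise_sd=1.0, seed=0)
        assert sorted(ds.class_counts().tolist()) == [100, 100, 101]

    def test_huge_separation_is_perfectly_separable_by_nearest_centroid(self):
        ds = make_blobs_dataset(8, 4, 1000, separation=50.0, noise_sd=1.0, seed=1)
        centres = np.stack([ds.X[:, ds.labels == c].mean(axis=1) for c in range(1, 5)])
        d = ((ds.X.T[:, None, :] - centres[None]) ** 2).sum(axis=2)
        pred = np.argmin(d, axis=1) + 1
        assert np.mean(pred == ds.labels) == 1.0

    def test_zero_separation_is_chance_level(self):
        ds = make_blobs_dataset(8, 2, 2000, separation=0.0, noise_sd=1.0, seed=2)
        centres = np.stack([ds.X[:, ds.labels == c].mean(axis=1) for c in range(1, 3)])
        d = ((ds.X.T[:, None, :] - centres[None]) ** 2).sum(axis=2)
        pred = np.argmin(d, axis=1) + 1
        assert abs(np.mean(pred == ds.labels) - 0.5) < 0.07

    def test_explicit_class_sizes(self):
        ds = make_blobs_dataset(30, 2, 0, separation=4.0, noise_sd=1.0, seed=3, class_sizes=[357, 212])
        np.testing.assert_array_equal(ds.class_counts(), [357, 212])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            make_blobs_dataset(5, 3, 11, separation=1.0, noise_sd=1.0)


def test_minmax_scale_bounds_features():
    ds = make_blobs_dataset(4, 2, 50, separation=5.0, noise_sd=2.0, seed=4)
    scaled = minmax_scale(ds)
    assert scaled.X.min() == 0.0 and scaled.X.max() == 1.0
    np.testing.assert_array_equal(scaled.labels, ds.labels)


def test_save_then_load_round_trip(tmp_path):
    ds = make_blobs_dataset(4, 3, 30, separation=3.0, noise_sd=1.0, seed=5)
    path = tmp_path / "blobs.csv"
    save_dataset(ds, path, sidecar={"seed": 5})
    back = load_csv_dataset(path, label_column="label", header=True)
    np.testing.assert_allclose(back.X, ds.X, atol=1e-15)
    # the loader numbers classes by first appearance, so compare by name
    assert [back.class_names[c - 1] for c in back.labels] == [ds.class_names[c - 1] for c in ds.labels]
    assert sorted(back.class_names) == sorted(ds.class_names)
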