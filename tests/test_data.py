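import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from trustauc import (
    ImageDataset,
    ImageRecord,
    SyntheticSpec,
    balanced_validation_split,
    generate_synthetic_dataset,
    kfold_splits,
    read_manifest,
    roc_auc,
    write_manifest,
)
from trustauc.data import DatasetValidationError, ManifestFormatError


def _records(n=3):
    return [
        ImageRecord(f"r{i}", f"images/r{i}.png", i % 2, "train") for i in range(n)
    ]


class TestManifest:
    def test_roundtrip_identity(self, tmp_path):
        ds = ImageDataset(_records(3))
        path = write_manifest(ds, tmp_path / "manifest.csv")
        back = read_manifest(path)
        assert [(r.id, r.path, r.label, r.split) for r in back.records] == [
            (r.id, r.path, r.label, r.split) for r in ds.records
        ]

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path,label\na,x.png,0\n")
        with pytest.raises(ManifestFormatError):
            read_manifest(p)

    def test_label_outside_binary_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path,label,split\na,x.png,2,train\n")
        with pytest.raises(DatasetValidationError):
            read_manifest(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path,label,split\na,x.png,0,train\na,y.png,1,train\n")
        with pytest.raises(DatasetValidationError):
            read_manifest(p)

    def test_strict_mode_checks_image_existence(self, tmp_path):
        ds = ImageDataset(_records(2))
        path = write_manifest(ds, tmp_path / "manifest.csv")
        with pytest.raises(DatasetValidationError, match="not found"):
            read_manifest(path, strict=True)


class TestSyntheticGenerator:
    def test_counts_and_manifest(self, tmp_path):
        spec = SyntheticSpec(n_neg=6, n_pos=1, seed=3)
        ds = generate_synthetic_dataset(spec, tmp_path)
        assert len(ds) == 7
        assert ds.counts() == (6, 1)
        back = read_manifest(tmp_path / "manifest.csv", strict=True)
        assert len(back) == 7

    def test_bitwise_determinism(self, tmp_path):
        spec = SyntheticSpec(n_neg=4, n_pos=2, seed=11)
        generate_synthetic_dataset(spec, tmp_path / "a")
        generate_synthetic_dataset(spec, tmp_path / "b")
        for rel in sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file()):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_zero_signal_is_uninformative(self, tmp_path):
        """With no planted signal, mean intensity carries no class information."""
        spec = SyntheticSpec(n_neg=200, n_pos=200, signal_amplitude=0.0, seed=5)
        ds = generate_synthetic_dataset(spec, tmp_path)
        X = ds.load().mean(axis=(1, 2, 3)).reshape(-1, 1)
        y = ds.labels()
        fit, hold = slice(0, 200), slice(200, 400)
        order = np.random.default_rng(0).permutation(400)
        Xs, ys = X[order], y[order]
        model = LogisticRegression().fit(Xs[fit], ys[fit])
        auc = roc_auc(model.predict_proba(Xs[hold])[:, 1], ys[hold])
        assert abs(auc - 0.5) <= 0.05

    def test_strong_signal_is_linearly_separable(self, tmp_path):
        """At signal 5x the noise sd, held-out AUC of a linear read-out > 0.95."""
        spec = SyntheticSpec(
            n_neg=150, n_pos=150, signal_amplitude=0.75, noise_sd=0.15, seed=9
        )
        ds = generate_synthetic_dataset(spec, tmp_path)
        X = ds.load().mean(axis=(1, 2, 3)).reshape(-1, 1)
        y = ds.labels()
        order = np.random.default_rng(1).permutation(len(y))
        Xs, ys = X[order], y[order]
        model = LogisticRegression().fit(Xs[:150], ys[:150])
        assert roc_auc(model.predict_proba(Xs[150:])[:, 1], ys[150:]) > 0.95

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SyntheticSpec(n_neg=0, n_pos=0)

    def test_unwritable_directory_errors(self, tmp_path):
        blocker = tmp_path / "not_a_dir"
        blocker.write_text("")  # a file where the output dir should go
        with pytest.raises(OSError):
            generate_synthetic_dataset(
                SyntheticSpec(n_neg=1, n_pos=1), blocker / "sub"
            )


class TestBalancedValidationSplit:
    def _dataset(self, n_neg, n_pos):
        recs = [ImageRecord(f"n{i}", f"n{i}.png", 0, "train") for i in range(n_neg)]
        recs += [ImageRecord(f"p{i}", f"p{i}.png", 1, "train") for i in range(n_pos)]
        return ImageDataset(recs)

    def test_imbalanced_quota(self):
        train, val = balanced_validation_split(self._dataset(100, 20), 0.10, seed=0)
        assert len(val) == 12
        assert val.counts() == (6, 6)
        assert len(train) == 108

    def test_balanced_symmetric(self):
        train, val = balanced_validation_split(self._dataset(50, 50), 0.2, seed=0)
        assert val.counts() == (10, 10)
        assert train.counts() == (40, 40)

    def test_seed_determinism(self):
        _, v1 = balanced_validation_split(self._dataset(30, 30), 0.2, seed=4)
        _, v2 = balanced_validation_split(self._dataset(30, 30), 0.2, seed=4)
        assert [r.id for r in v1.records] == [r.id for r in v2.records]

    def test_odd_slot_goes_to_majority(self):
        _, val = balanced_validation_split(self._dataset(80, 10), 0.10, seed=1)
        # val size 9 -> quotas 4/4 plus one extra negative (majority)
        assert val.counts() == (5, 4)

    def test_shortfall_takes_whole_class_with_warning(self):
        ds = self._dataset(96, 4)
        with pytest.warns(UserWarning, match="taking all"):
            _, val = balanced_validation_split(ds, 0.2, seed=0)
        assert val.counts()[1] == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_union_invariant(self, seed):
        ds = self._dataset(37, 13)
        train, val = balanced_validation_split(ds, 0.15, seed=seed)
        tids = {r.id for r in train.records}
        vids = {r.id for r in val.records}
        assert not tids & vids
        assert tids | vids == {r.id for r in ds.records}
        n_neg, n_pos = val.counts()
        assert abs(n_neg - n_pos) <= 1

    def test_single_class_rejected(self):
        recs = [ImageRecord(f"n{i}", "x.png", 0, "train") for i in range(5)]
        ds = ImageDataset(recs)
        with pytest.raises(DatasetValidationError):
            balanced_validation_split(ds, 0.2, seed=0)

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.1])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            balanced_validation_split(self._dataset(10, 10), fraction, seed=0)


class TestKFold:
    def _dataset(self, n_neg, n_pos):
        recs = [ImageRecord(f"n{i}", "x.png", 0, "train") for i in range(n_neg)]
        recs += [ImageRecord(f"p{i}", "x.png", 1, "train") for i in range(n_pos)]
        return ImageDataset(recs)

    def test_partition_property(self):
        ds = self._dataset(50, 50)
        folds = kfold_splits(ds, 5, seed=0)
        all_val = [r.id for _, va in folds for r in va.records]
        assert len(all_val) == 100
        assert set(all_val) == {r.id for r in ds.records}
        assert all(len(va) == 20 for _, va in folds)

    def test_stratification_on_imbalance(self):
        folds = kfold_splits(self._dataset(90, 10), 5, seed=0)
        assert all(va.counts()[1] == 2 for _, va in folds)

    def test_fold_positive_counts_differ_by_at_most_one(self):
        folds = kfold_splits(self._dataset(83, 17), 5, seed=3)
        pos_counts = [va.counts()[1] for _, va in folds]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_splits(self._dataset(10, 10), 1, seed=0)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(DatasetValidationError):
            kfold_splits(self._dataset(20, 3), 5, seed=0)

    def test_assignments_depend_only_on_seed(self):
        ds = self._dataset(20, 10)
        f1 = kfold_splits(ds, 5, seed=9)
        f2 = kfold_splits(ds, 5, seed=9)
        for (_, a), (_, b) in zip(f1, f2):
            assert [r.id for r in a.records] == [r.id for r in b.records]


def test_loaded_images_are_unit_range(separable_ds):
    X = separable_ds.load("train")
    assert X.ndim == 4 and X.shape[1] == 1
    assert X.min() >= 0.0 and X.max() <= 1.0
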