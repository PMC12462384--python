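import json

import numpy as np
import pytest

from conftest import planted_matrix
from cppkit.descriptors import ATOMIC_NAMES, DescriptorConfig, featurize_all
from cppkit.errors import (
    ColumnMismatchError,
    HashMismatchError,
    SingleClassError,
    TooFewPerClassError,
    VersionMismatchError,
)
from cppkit.evaluation import evaluate_predictions
from cppkit.matrix import FeatureMatrix
from cppkit.modeling import (
    TrainingParams,
    cross_validate,
    dataset_hash,
    fit_two_stage,
    load_model,
    predict,
    predict_two_stage,
    save_model,
    train,
)
from cppkit.synthetic_data import (
    GeneratorParams,
    generate_binary_dataset,
    generate_efficiency_dataset,
)

FAST = TrainingParams(n_estimators=100)


@pytest.fixture(scope="module")
def bundle():
    cpp = generate_binary_dataset(GeneratorParams(n_per_class=80, seed=5))
    eff = generate_efficiency_dataset(GeneratorParams(n_per_class=40, seed=5))
    cfg = DescriptorConfig(blocks=("AAC", "CKSAAGP", "PHYSCHEM", "ATOMIC", "LENGTH"))
    return fit_two_stage(cpp, eff, cfg, top_k=40, params=FAST)


class TestTrainPredict:
    def test_separable_training_set_is_interpolated(self):
        m = planted_matrix(n_per_class=100, n_noise=20, seed=7)
        model = train(m, FAST)
        scores, labels = predict(model, m)
        report = evaluate_predictions(m.labels, labels, scores)
        assert report.mcc == 1.0
        assert report.acc == 1.0

    def test_deterministic_under_seed(self):
        m = planted_matrix(n_per_class=50, n_noise=30, seed=3)
        runs = []
        for _ in range(2):
            model = train(m, FAST)
            runs.append(predict(model, m))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_single_class_rejected(self):
        m = planted_matrix(n_per_class=20, n_noise=5)
        m.labels = np.ones(m.n_rows, dtype=int)
        with pytest.raises(SingleClassError):
            train(m, FAST)

    def test_shuffled_columns_rejected(self):
        m = planted_matrix(n_per_class=20, n_noise=5, seed=1)
        model = train(m, FAST)
        shuffled = m.subset(list(reversed(m.names)))
        with pytest.raises(ColumnMismatchError):
            predict(model, shuffled)

    def test_single_row_prediction(self):
        m = planted_matrix(n_per_class=20, n_noise=5, seed=1)
        model = train(m, FAST)
        one = FeatureMatrix([m.ids[0]], list(m.names), m.values[:1])
        scores, labels = predict(model, one)
        assert scores.shape == labels.shape == (1,)

    def test_monotone_column_transform_invariance(self):
        m = planted_matrix(n_per_class=30, n_noise=4, seed=9)
        model = train(m, FAST)
        warped = m.values.copy()
        warped[:, 2] = np.exp(3 * warped[:, 2])
        m2 = FeatureMatrix(m.ids, list(m.names), warped, m.labels)
        model2 = train(m2, FAST)
        probe = m.values[::3]
        probe2 = warped[::3]
        p1 = model.estimator.predict_proba(probe)
        p2 = model2.estimator.predict_proba(probe2)
        assert np.allclose(p1, p2)


class TestCrossValidate:
    def test_strong_signal_high_auc(self):
        m = planted_matrix(n_per_class=100, n_noise=20, seed=11)
        result = cross_validate(m, FAST, k=10, seed=11)
        assert len(result.folds) == 10
        assert result.mean("auc") >= 0.95

    def test_pure_noise_chance_level(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(200, 20))
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        m = FeatureMatrix(
            [f"r{i}" for i in range(200)],
            [f"f{j}" for j in range(20)],
            values,
            labels,
        )
        result = cross_validate(m, FAST, k=10, seed=11)
        assert 0.35 <= result.mean("auc") <= 0.65

    def test_stratified_folds_preserve_ratio(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.r_[np.ones(60, int), np.zeros(40, int)]
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test_idx in splitter.split(np.zeros((100, 1)), labels):
            positives = labels[test_idx].sum()
            assert abs(positives - 6) <= 1

    def test_too_many_folds_rejected(self):
        m = planted_matrix(n_per_class=5, n_noise=3)
        with pytest.raises(TooFewPerClassError):
            cross_validate(m, FAST, k=10)


class TestTwoStage:
    def test_stage2_uses_atomic_features_only(self, bundle):
        assert bundle.stage2.feature_names == list(ATOMIC_NAMES)

    def test_cationic_peptides_called_cpp(self, bundle):
        """Fresh R/K-enriched peptides are overwhelmingly labeled CPP at
        stage 1, seed after seed."""
        majority = 0
        called = total = 0
        for seed in range(1, 11):
            probe = generate_binary_dataset(
                GeneratorParams(n_per_class=10, seed=100 + seed)
            )
            table = predict_two_stage(bundle, probe)
            truth = np.array([p.label for p in probe])
            positives = table["stage1_label"].to_numpy()[truth == 1]
            called += positives.sum()
            total += positives.size
            majority += positives.mean() > 0.5
        assert majority >= 9
        assert called / total >= 0.8

    def test_stage2_not_applicable_for_stage1_negatives(self, bundle):
        probe = generate_binary_dataset(GeneratorParams(n_per_class=20, seed=77))
        table = predict_two_stage(bundle, probe)
        negatives = table["stage1_label"] == 0
        assert negatives.any()
        assert table.loc[negatives, "stage2_score"].isna().all()
        assert table.loc[negatives, "stage2_label"].isna().all()
        positives = table["stage1_label"] == 1
        assert table.loc[positives, "stage2_score"].notna().all()

    def test_dataset_hash_binds_content(self):
        a = generate_binary_dataset(GeneratorParams(n_per_class=5, seed=1))
        b = generate_binary_dataset(GeneratorParams(n_per_class=5, seed=2))
        assert dataset_hash(a) != dataset_hash(b)
        assert dataset_hash(a) == dataset_hash(
            generate_binary_dataset(GeneratorParams(n_per_class=5, seed=1))
        )


class TestPersistence:
    def test_roundtrip_predictions_bit_stable(self, bundle, tmp_path):
        probe = generate_binary_dataset(GeneratorParams(n_per_class=25, seed=13))
        before = predict_two_stage(bundle, probe)
        save_model(bundle, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        after = predict_two_stage(loaded, probe)
        assert np.array_equal(
            before["stage1_score"].to_numpy(), after["stage1_score"].to_numpy()
        )
        assert before.equals(after)

    def test_tampered_manifest_detected(self, bundle, tmp_path):
        save_model(bundle, tmp_path / "model")
        manifest_path = tmp_path / "model" / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["stage1"]["feature_names"] = manifest["stage1"]["feature_names"][:-1]
        manifest_path.write_text(json.dumps(manifest))
        with pytest.raises(HashMismatchError):
            load_model(tmp_path / "model")

    def test_corrupted_estimator_detected(self, bundle, tmp_path):
        save_model(bundle, tmp_path / "model")
        blob = tmp_path / "model" / "stage2.joblib"
        blob.write_bytes(blob.read_bytes() + b"x")
        with pytest.raises(HashMismatchError):
            load_model(tmp_path / "model")

    def test_future_format_version_rejected(self, bundle, tmp_path):
        save_model(bundle, tmp_path / "model")
        manifest_path = tmp_path / "model" / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["format_version"] = 99
        manifest_path.write_text(json.dumps(manifest))
        with pytest.raises(VersionMismatchError):
            load_model(tmp_path / "model")
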