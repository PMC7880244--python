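"""Classification: assembly, L1 selection, grid search, Platt, maps."""

import json

import numpy as np
import pytest

from ramanmargin.classify import (
    ClassifierBundle,
    ClassifierConfig,
    LabeledDataset,
    assemble_datasets,
    compute_metrics,
    grid_search_train,
    pearson_diagnostics,
    predict_with_probability,
    render_margin_map,
    select_features_l1,
)
from ramanmargin.errors import AssemblyError, ConfigurationError, ParameterError, SelectionError
from ramanmargin.preprocess import PreprocessConfig, ProcessedCube, QCReport

WN = np.linspace(400, 1900, 341)
CH_1001 = int(np.argmin(np.abs(WN - 1001)))
CH_1442 = int(np.argmin(np.abs(WN - 1442)))


def _dataset(features, labels, role="train", image_id="img"):
    n = len(labels)
    prov = np.array([(image_id, i, 0) for i in range(n)], dtype=object)
    return LabeledDataset(np.asarray(features, float), np.asarray(labels, dtype=object).astype(str), prov, role)


def _two_band_data(rng, n_per_class=120, contrast=1.5, n_channels=341):
    """Noise everywhere; class contrast only at the 1001 and 1442 channels."""
    x = rng.normal(0.0, 1.0, size=(2 * n_per_class, n_channels))
    y = np.array(["muscle"] * n_per_class + ["adipose"] * n_per_class)
    x[:n_per_class, CH_1001] += contrast  # muscle carries 1001
    x[n_per_class:, CH_1442] += contrast  # adipose carries 1442
    return x, y


def _processed(data, retained=None):
    nx, ny, nc = data.shape
    if retained is None:
        retained = np.ones((nx, ny), bool)
    qc = QCReport(nx * ny, 0, 0, int(retained.sum()))
    return ProcessedCube(data, WN[:nc], retained, np.zeros_like(data), qc)


class TestAssembly:
    def test_half_image_split_by_line(self):
        rng = np.random.default_rng(0)
        pa = _processed(rng.normal(size=(40, 42, 20)))
        pm = _processed(rng.normal(size=(40, 42, 20)))
        train, val = assemble_datasets(pa, pm, None, None)
        xs = np.array([p[1] for p in train.provenance])
        assert xs.max() == 19  # first 20 lines only
        assert len(train) == 2 * 20 * 42
        assert len(val) == 2 * 20 * 42
        assert set(train.labels) == {"adipose", "muscle"}

    def test_exact_bookkeeping_with_margin_and_masks(self):
        rng = np.random.default_rng(1)
        ret = np.ones((40, 42), bool)
        ret[0, :] = False  # border-like rejection
        pa = _processed(rng.normal(size=(40, 42, 20)), ret.copy())
        pm = _processed(rng.normal(size=(40, 42, 20)))
        margin = _processed(rng.normal(size=(40, 42, 20)))
        truth = np.where(np.arange(40)[:, None] < 20, "adipose", "muscle")
        truth = np.broadcast_to(truth, (40, 42)).astype(object)
        train, val = assemble_datasets(pa, pm, margin, truth)
        assert len(train) == (20 * 42 - 42) + 20 * 42
        assert len(val) == 20 * 42 + 20 * 42 + 40 * 42
        # margin contributes its per-class counts exactly
        margin_labels = val.labels[[p[0] == "margin" for p in val.provenance]]
        assert (margin_labels == "adipose").sum() == 20 * 42

    def test_margin_without_truth_raises(self):
        rng = np.random.default_rng(2)
        pa = _processed(rng.normal(size=(4, 4, 10)))
        pm = _processed(rng.normal(size=(4, 4, 10)))
        with pytest.raises(AssemblyError):
            assemble_datasets(pa, pm, _processed(rng.normal(size=(4, 4, 10))), None)


class TestFeatureSelection:
    def test_planted_contrast_channels_recovered(self):
        """On tissue spectra whose templates differ only at the 1001 and
        1442 bands, the L1-SVM keeps only channels within +-6 1/cm of those
        bands (seeds 0-9): the very sparse regime."""
        from conftest import two_band_contrast_dataset

        window = 6.0
        for seed in range(10):
            ds, axis = two_band_contrast_dataset(seed)
            selected = select_features_l1(ds, l1_C=0.1, seed=seed)
            assert 0 < selected.size <= 10
            for ch in selected:
                assert (
                    abs(axis[ch] - 1001) <= window or abs(axis[ch] - 1442) <= window
                )
            # both planted bands are represented
            assert any(abs(axis[ch] - 1001) <= window for ch in selected)
            assert any(abs(axis[ch] - 1442) <= window for ch in selected)

    def test_single_class_raises(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 20))
        with pytest.raises(SelectionError):
            select_features_l1(_dataset(x, ["muscle"] * 50), 0.1)

    def test_overpenalized_selection_raises(self):
        rng = np.random.default_rng(4)
        x, y = _two_band_data(rng, contrast=0.3)
        with pytest.raises(SelectionError):
            select_features_l1(_dataset(x, y), l1_C=1e-6)

    def test_duplicated_channel_stays_sparse(self):
        """An exact duplicate of an informative channel does not blow up the
        selected set (L1 splits or drops collinear features)."""
        from conftest import two_band_contrast_dataset

        ds, axis = two_band_contrast_dataset(5)
        base = select_features_l1(ds, l1_C=0.1, seed=5)
        dup_col = ds.features[:, base[0]]
        x_dup = np.column_stack([ds.features, dup_col])
        ds_dup = LabeledDataset(x_dup, ds.labels, ds.provenance, "train")
        selected = select_features_l1(ds_dup, l1_C=0.1, seed=5)
        assert selected.size <= base.size + 2


def _separable_sets(rng, n=60, gap=10.0, n_channels=8):
    xa = rng.normal(size=(n, n_channels))
    xb = rng.normal(size=(n, n_channels))
    xa[:, 0] += gap
    x = np.vstack([xa, xb])
    y = np.array(["adipose"] * n + ["muscle"] * n)
    idx = rng.permutation(2 * n)
    return x[idx], y[idx]


class TestGridSearch:
    def test_default_grids_evaluate_39_configurations(self):
        rng = np.random.default_rng(6)
        x, y = _separable_sets(rng)
        xv, yv = _separable_sets(rng)
        _, leaderboard = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"),
            ClassifierConfig(),
        )
        assert len(leaderboard) == 5 + 25 + 9

    def test_single_point_grid(self):
        rng = np.random.default_rng(7)
        x, y = _separable_sets(rng)
        xv, yv = _separable_sets(rng)
        cfg = ClassifierConfig(
            svm_C_grid=(1.0,), svm_gamma_grid=(0.1,),
            rf_n_estimators_grid=(100,), rf_max_samples_grid=(0.6,),
        )
        bundle, leaderboard = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"), cfg
        )
        assert len(leaderboard) == 1 + 1 + 1  # linear, rbf, rf: one point each

    def test_separable_data_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(8)
        x, y = _separable_sets(rng)
        xv, yv = _separable_sets(rng)
        _, leaderboard = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"),
            ClassifierConfig(),
        )
        assert max(r["validation_accuracy"] for r in leaderboard) == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierConfig(svm_C_grid=())

    def test_validation_permutation_does_not_change_fit(self):
        """Standardization, model and Platt parameters depend on training only."""
        rng = np.random.default_rng(9)
        x, y = _separable_sets(rng, gap=3.0)
        xv, yv = _separable_sets(rng, gap=3.0)
        b1, lb1 = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"),
            ClassifierConfig(seed=1),
        )
        perm = np.random.default_rng(10).permutation(len(yv))
        b2, lb2 = grid_search_train(
            _dataset(x, y), _dataset(xv[perm], yv[perm], role="validation", image_id="v"),
            ClassifierConfig(seed=1),
        )
        assert np.array_equal(b1.mean, b2.mean)
        assert np.array_equal(b1.scale, b2.scale)
        assert b1.platt == b2.platt
        assert [r["validation_accuracy"] for r in lb1] == [
            r["validation_accuracy"] for r in lb2
        ]

    def test_determinism_with_fixed_seed(self):
        rng1 = np.random.default_rng(11)
        x, y = _separable_sets(rng1, gap=2.0)
        xv, yv = _separable_sets(rng1, gap=2.0)
        out1 = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"),
            ClassifierConfig(seed=3),
        )
        out2 = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"),
            ClassifierConfig(seed=3),
        )
        assert out1[1] == out2[1]
        assert out1[0].platt == out2[0].platt


class TestProbabilities:
    def _trained_bundle(self, seed=12, gap=3.0):
        rng = np.random.default_rng(seed)
        x, y = _separable_sets(rng, gap=gap)
        xv, yv = _separable_sets(rng, gap=gap)
        cfg = ClassifierConfig(
            svm_kernels=("linear",), rf_n_estimators_grid=(100,),
            rf_max_samples_grid=(0.6,), seed=seed,
        )
        bundle, _ = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"), cfg
        )
        return bundle, x, y

    def test_confidence_in_valid_range_and_complementary(self):
        bundle, x, _ = self._trained_bundle()
        labels, conf = predict_with_probability(bundle, x)
        assert np.all(conf >= 0.5) and np.all(conf <= 1.0)
        p1 = bundle.predict_proba(x)
        assert np.allclose(p1 + (1 - p1), 1.0, atol=1e-9)

    def test_far_points_saturate(self):
        bundle, x, y = self._trained_bundle(gap=10.0)
        far = np.zeros((2, x.shape[1]))
        far[0, 0] = 100.0  # 10x beyond the class gap
        far[1, 0] = -100.0
        _, conf = predict_with_probability(bundle, far)
        assert np.all(conf >= 0.99)

    def test_confidence_monotone_in_decision_magnitude(self):
        """Confidence grows with distance from the Platt-sigmoid midpoint
        (the decision value at which both classes are equally likely)."""
        bundle, x, _ = self._trained_bundle()
        a, b = bundle.platt
        z = np.abs(a * bundle.decision_function(x) + b)
        _, conf = predict_with_probability(bundle, x)
        order = np.argsort(z)
        assert np.all(np.diff(conf[order]) >= -1e-12)

    def test_dimension_mismatch_raises(self):
        bundle, x, _ = self._trained_bundle()
        with pytest.raises(Exception):
            predict_with_probability(bundle, x[:, :3])


class TestBundleSerialization:
    @pytest.mark.parametrize("kernels,rf", [
        (("rbf",), (1,)),  # RBF SVM route
        (("linear",), (1,)),  # linear SVM route
    ])
    def test_svm_round_trip(self, kernels, rf):
        rng = np.random.default_rng(13)
        x, y = _separable_sets(rng, gap=2.0)
        xv, yv = _separable_sets(rng, gap=2.0)
        cfg = ClassifierConfig(
            svm_kernels=kernels, svm_C_grid=(1.0,), svm_gamma_grid=(0.1,),
            rf_n_estimators_grid=(10,), rf_max_samples_grid=(0.6,), seed=13,
        )
        bundle, _ = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"), cfg
        )
        if bundle.model_kind != "svm":
            pytest.skip("grid chose RF on this data")
        reloaded = ClassifierBundle.from_json(bundle.to_json())
        l1, c1 = predict_with_probability(bundle, xv)
        l2, c2 = predict_with_probability(reloaded, xv)
        assert np.array_equal(l1, l2)
        assert np.allclose(c1, c2, atol=1e-9)

    def test_rf_round_trip(self):
        rng = np.random.default_rng(14)
        x, y = _separable_sets(rng, gap=2.0)
        xv, yv = _separable_sets(rng, gap=2.0)
        cfg = ClassifierConfig(
            svm_kernels=(), svm_C_grid=(1.0,), svm_gamma_grid=(0.1,),
            rf_n_estimators_grid=(25,), rf_max_samples_grid=(0.7,), seed=14,
        )
        bundle, _ = grid_search_train(
            _dataset(x, y), _dataset(xv, yv, role="validation", image_id="v"), cfg
        )
        assert bundle.model_kind == "rf"
        reloaded = ClassifierBundle.from_json(bundle.to_json())
        l1, c1 = predict_with_probability(bundle, xv)
        l2, c2 = predict_with_probability(reloaded, xv)
        assert np.array_equal(l1, l2)
        assert np.allclose(c1, c2, atol=1e-12)


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,acc,sens,spec",
        [
            (9, 1, 8, 2, 0.85, 0.9, 0.8),
            (10, 0, 10, 0, 1.0, 1.0, 1.0),
            (10, 0, 0, 10, 0.5, 1.0, 0.0),  # all-adipose predictor, balanced set
        ],
    )
    def test_confusion_arithmetic(self, tp, fn, tn, fp, acc, sens, spec):
        truth = ["adipose"] * (tp + fn) + ["muscle"] * (tn + fp)
        pred = (
            ["adipose"] * tp + ["muscle"] * fn + ["muscle"] * tn + ["adipose"] * fp
        )
        rep = compute_metrics(pred, truth)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.sensitivity == pytest.approx(sens)
        assert rep.specificity == pytest.approx(spec)

    def test_pearson_extremes(self):
        rng = np.random.default_rng(15)
        s = rng.random(100)
        assert pearson_diagnostics(s, s) == pytest.approx(1.0)
        assert pearson_diagnostics(s, -s) == pytest.approx(-1.0)
        with pytest.raises(ParameterError):
            pearson_diagnostics(np.ones(10), s[:10])


class TestMarginMap:
    def _margin_bundle_and_cube(self, margin_col=12, nx=24, ny=10):
        rng = np.random.default_rng(16)
        n_channels = 8
        # simple two-class cube: class contrast on channel 0
        data = rng.normal(0, 0.05, size=(nx, ny, n_channels))
        data[:margin_col, :, 0] += 2.0
        x, y = _separable_sets(rng, n=80, gap=2.0, n_channels=n_channels)
        cfg = ClassifierConfig(
            svm_kernels=("linear",), svm_C_grid=(1.0,), svm_gamma_grid=(0.1,),
            rf_n_estimators_grid=(10,), rf_max_samples_grid=(0.6,), seed=16,
        )
        bundle, _ = grid_search_train(
            _dataset(x, y), _dataset(x, y, role="validation", image_id="v"), cfg
        )
        return bundle, _processed(data), margin_col

    def test_planted_margin_column_recovered(self):
        bundle, cube, margin_col = self._margin_bundle_and_cube()
        m = render_margin_map(bundle, cube)
        assert m.margin_column is not None
        assert abs(m.margin_column - margin_col) <= 1
        assert not m.no_transition

    def test_uniform_cube_has_no_transition(self):
        bundle, _, _ = self._margin_bundle_and_cube()
        rng = np.random.default_rng(17)
        data = rng.normal(0, 0.05, size=(10, 6, 8))
        data[:, :, 0] += 2.0
        m = render_margin_map(bundle, _processed(data))
        assert m.no_transition
        assert m.low_confidence_width == 0.0
        assert len(set(m.class_map.ravel())) == 1

    def test_confidence_map_range_and_mask(self):
        bundle, cube, _ = self._margin_bundle_and_cube()
        m = render_margin_map(bundle, cube)
        assert np.all(m.confidence_map >= 0.5)
        assert np.all(m.confidence_map <= 1.0)
        assert m.mask.shape == m.class_map.shape
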