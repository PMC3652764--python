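import numpy as np
import pandas as pd
import pytest

from psse import (
    ConfigError,
    EvaluationReport,
    FeatureMatrix,
    SVMConfig,
    accuracy_report,
    assemble_features,
    feature_set,
    grid_search,
    jackknife_evaluate,
)
from psse.classify import DEFAULT_GRID, PBF11CBF_COLUMNS
from psse.synthetic import generate_dataset


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(8, seed=3).dataset


def blob_matrix(n_per_class=12, seed=0):
    """Two well-separated Gaussian blobs, labels alternating."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.3, size=(n_per_class, 2))
    b = rng.normal(4.0, 0.3, size=(n_per_class, 2))
    X = np.vstack([a, b])
    ids = [f"s{i}" for i in range(len(X))]
    labels = {
        ids[i]: "all-alpha" if i < n_per_class else "all-beta"
        for i in range(len(X))
    }
    fm = FeatureMatrix(
        values=pd.DataFrame(X, index=ids, columns=["x", "y"])
    )
    return fm, labels


class TestFeatureSets:
    @pytest.mark.parametrize(
        "name, n_cols",
        [
            ("pbf", 3),
            ("content", 3),
            ("content+cf", 6),
            ("tpm+cf", 7),
            ("cbf", 38),
            ("pbf11cbf", 14),
        ],
    )
    def test_preset_arity(self, small_dataset, name, n_cols):
        fm = assemble_features(small_dataset, feature_set(name))
        assert len(fm.columns) == n_cols
        assert len(fm.ids) == len(small_dataset)

    def test_pbf11cbf_composition(self):
        spec = feature_set("pbf11cbf")
        assert spec.column_names() == list(PBF11CBF_COLUMNS) + [
            "CF_C", "CF_H", "CF_E",
        ]

    def test_pbf_k_in_column_names(self, small_dataset):
        fm = assemble_features(small_dataset, feature_set("pbf", pbf_k=5))
        assert fm.columns == ["C5_C", "C5_H", "C5_E"]
        assert fm.recipe["pbf_k"] == 5

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            feature_set("sheets")

    def test_scaling_standardizes_columns(self, small_dataset):
        fm = assemble_features(small_dataset, feature_set("content"))
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-12)
        stds = fm.values.std(axis=0, ddof=0).to_numpy()
        assert all(np.isclose(s, 1.0) or np.isclose(s, 0.0) for s in stds)


class TestGridSearch:
    def test_grid_has_eleven_powers_of_two(self):
        assert len(DEFAULT_GRID) == 11
        assert DEFAULT_GRID[0] == 2.0**-5 and DEFAULT_GRID[-1] == 2.0**5
        assert len(SVMConfig().c_grid) * len(SVMConfig().gamma_grid) == 121

    def test_separable_blobs_reach_perfect_cv(self):
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC

        fm, labels = blob_matrix()
        cfg = SVMConfig(folds=4, seed=0)
        c, gamma = grid_search(fm, labels, cfg)
        assert (c, gamma) in {
            (ci, gi) for ci in DEFAULT_GRID for gi in DEFAULT_GRID
        }
        X = fm.values.to_numpy()
        y = [labels[i] for i in fm.ids]
        cv = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        score = cross_val_score(SVC(kernel="rbf", C=c, gamma=gamma), X, y, cv=cv)
        assert score.mean() == 1.0

    def test_duplicated_columns_do_not_change_selection(self):
        fm, labels = blob_matrix()
        # standardize, then duplicate every column
        vals = (fm.values - fm.values.mean()) / fm.values.std(ddof=0)
        dup = pd.concat(
            [vals, vals.rename(columns={"x": "x2", "y": "y2"})], axis=1
        )
        cfg = SVMConfig(folds=4, seed=0, gamma_grid=(0.5,))
        base = grid_search(FeatureMatrix(values=vals), labels, cfg)
        # duplication doubles the squared distances; halving gamma compensates
        dup_cfg = SVMConfig(folds=4, seed=0, gamma_grid=(0.25,))
        dupd = grid_search(FeatureMatrix(values=dup), labels, dup_cfg)
        assert base[0] == dupd[0]

    def test_single_class_rejected(self):
        fm, labels = blob_matrix()
        labels = {k: "all-alpha" for k in labels}
        with pytest.raises(ConfigError):
            grid_search(fm, labels, SVMConfig())

    def test_folds_reduced_for_small_classes(self):
        fm, labels = blob_matrix(n_per_class=4)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            grid_search(fm, labels, SVMConfig(folds=10, c_grid=(1.0,), gamma_grid=(0.5,)))


def _report_from_confusion(confusion: pd.DataFrame, c=1.0, gamma=1.0):
    sizes = confusion.sum(axis=1)
    per_class = {
        cls: confusion.loc[cls, cls] / sizes[cls] for cls in confusion.index
    }
    overall = float(np.trace(confusion.to_numpy()) / sizes.sum())
    return EvaluationReport(
        confusion=confusion, per_class=per_class, overall=overall,
        c=c, gamma=gamma,
    )


class TestEvaluationReport:
    def test_accuracy_arithmetic(self):
        classes = ["all-alpha", "all-beta", "alpha/beta", "alpha+beta"]
        confusion = pd.DataFrame(
            np.diag([3, 4, 4, 4]), index=classes, columns=classes
        )
        confusion.loc["all-alpha", "all-beta"] = 1
        report = _report_from_confusion(confusion)
        assert report.per_class["all-alpha"] == 0.75
        assert report.overall == 15 / 16

    def test_weighted_mean_identity_enforced(self):
        classes = ["all-alpha", "all-beta"]
        confusion = pd.DataFrame(np.diag([5, 5]), index=classes, columns=classes)
        with pytest.raises(ValueError, match="weighted mean"):
            EvaluationReport(
                confusion=confusion,
                per_class={"all-alpha": 1.0, "all-beta": 1.0},
                overall=0.5,  # inconsistent with the confusion counts
                c=1.0, gamma=1.0,
            )

    def test_report_formatting(self):
        classes = ["all-alpha", "all-beta", "alpha/beta", "alpha+beta"]
        confusion = pd.DataFrame(
            np.diag([3, 4, 4, 4]), index=classes, columns=classes
        )
        confusion.loc["all-alpha", "all-beta"] = 1
        text = accuracy_report(_report_from_confusion(confusion))
        assert "93.75" in text and "75.00" in text


class TestJackknife:
    def test_all_correct_gives_unit_accuracies(self):
        fm, labels = blob_matrix()
        report = jackknife_evaluate(
            fm, labels, SVMConfig(folds=4, seed=0), chosen=(1.0, 0.5)
        )
        assert report.overall == 1.0
        assert set(report.per_class.values()) == {1.0}

    def test_singleton_class_warns_in_report(self):
        fm, labels = blob_matrix(n_per_class=5)
        lone = list(labels)[0]
        labels = dict(labels)
        labels[lone] = "alpha/beta"
        report = jackknife_evaluate(
            fm, labels, SVMConfig(folds=2, seed=0), chosen=(1.0, 0.5)
        )
        assert any("single member" in w for w in report.warnings)
        assert report.per_class["alpha/beta"] == 0.0

    def test_deterministic_given_seed(self, small_dataset):
        fm = assemble_features(small_dataset, feature_set("content"))
        cfg = SVMConfig(seed=11, folds=4)
        r1 = jackknife_evaluate(fm, small_dataset.labels, cfg)
        r2 = jackknife_evaluate(fm, small_dataset.labels, cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_nested_selection_runs(self):
        fm, labels = blob_matrix(n_per_class=5)
        cfg = SVMConfig(folds=2, seed=0, c_grid=(1.0, 2.0), gamma_grid=(0.5,))
        report = jackknife_evaluate(fm, labels, cfg, nested=True)
        assert report.overall == 1.0


class TestFeatureSubsetsBeatChance:
    """Every feature subset should separate the synthetic classes far
    better than the ~25% expected from random assignment."""

    @pytest.mark.parametrize("name", ["pbf", "content", "content+cf"])
    def test_beats_chance(self, name):
        ds = generate_dataset(15, seed=7).dataset
        fm = assemble_features(ds, feature_set(name))
        cfg = SVMConfig(seed=7, c_grid=(1.0, 8.0), gamma_grid=(0.125, 1.0))
        report = jackknife_evaluate(fm, ds.labels, cfg)
        n = len(ds)
        three_sigma = 3 * np.sqrt(0.25 * 0.75 / n)
        assert report.overall > 0.25 + three_sigma
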