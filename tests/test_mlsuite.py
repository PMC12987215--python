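import numpy as np
import pandas as pd
import pytest

from craniomorph import mlsuite
from craniomorph.descriptors import DESCRIPTOR_COLUMNS
from craniomorph.errors import CraniomorphError
from craniomorph.mlsuite import (
    MLP_LOW_ALT,
    RATIO_PRESETS,
    SEARCH_SPACES,
    TIER_CONFIGS,
    ModelConfig,
    SplitSpec,
)


def toy_table(n_per_class=40, n_classes=2, sep=50.0, seed=0):
    """Linearly separated Gaussian clusters shaped like a feature table."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls in range(n_classes):
        X = rng.normal(cls * sep, 1.0, size=(n_per_class, 138))
        rows.append(X)
    X = np.vstack(rows)
    table = pd.DataFrame(X, columns=DESCRIPTOR_COLUMNS)
    table.insert(0, "cloud_id", [f"c{i}" for i in range(len(table))])
    table.insert(1, "base_id", [f"b{i // 4}" for i in range(len(table))])
    table.insert(2, "label_code", np.repeat(np.arange(1, n_classes + 1), n_per_class))
    table.insert(3, "split", "unassigned")
    return table


class TestSplitDataset:
    def test_exact_row_counts(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.6, 0.2, 0.2), seed=0))
        counts = tagged["split"].value_counts()
        assert counts["train"] == 2160
        assert counts["validation"] == 720
        assert counts["test"] == 720

    def test_stratification_within_one(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.6, 0.2, 0.2), seed=1))
        global_prop = feature_table["label_code"].value_counts(normalize=True)
        for part, frac in (("train", 0.6), ("validation", 0.2), ("test", 0.2)):
            sub = tagged[tagged["split"] == part]
            expected = global_prop * len(sub)
            observed = sub["label_code"].value_counts()
            for code in global_prop.index:
                assert abs(observed[code] - expected[code]) <= 1

    def test_grouped_split_no_base_leakage(self, feature_table):
        tagged = mlsuite.split_dataset(
            feature_table, SplitSpec((0.6, 0.2, 0.2), seed=2, group_level="base")
        )
        parts = tagged.groupby("base_id")["split"].nunique()
        assert (parts == 1).all()

    def test_disjoint_exhaustive(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.7, 0.15, 0.15), seed=3))
        assert set(tagged["split"]) == {"train", "validation", "test"}
        assert len(tagged) == len(feature_table)

    def test_bad_ratios_rejected(self):
        with pytest.raises(CraniomorphError):
            SplitSpec((0.5, 0.2, 0.2))


class TestPreprocess:
    def test_mean_imputation(self):
        table = toy_table(n_per_class=2)
        table.loc[:3, "split"] = ["train", "train", "test", "test"]
        table = table.iloc[:4].copy()
        table.loc[table.index[:2], "d001"] = [10.0, 12.0]
        table.loc[table.index[2], "d001"] = np.nan
        tr, va, te = mlsuite.preprocess(
            table[table["split"] == "train"],
            table[table["split"] == "validation"],
            table[table["split"] == "test"],
            "DT",
        )
        assert te["d001"].iloc[0] == pytest.approx(11.0)

    def test_standardisation_contract(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.6, 0.2, 0.2), seed=4))
        tr, _, _ = mlsuite.preprocess(
            tagged[tagged["split"] == "train"],
            tagged[tagged["split"] == "validation"],
            tagged[tagged["split"] == "test"],
            "MLP",
        )
        X = tr[DESCRIPTOR_COLUMNS].to_numpy()
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-9)

    def test_tree_passthrough_when_complete(self):
        table = toy_table(n_per_class=10)
        table["split"] = ["train"] * 15 + ["test"] * 5
        tr, _, te = mlsuite.preprocess(
            table[table["split"] == "train"],
            table[table["split"] == "validation"],
            table[table["split"] == "test"],
            "DT",
        )
        np.testing.assert_array_equal(
            tr[DESCRIPTOR_COLUMNS].to_numpy(),
            table[table["split"] == "train"][DESCRIPTOR_COLUMNS].to_numpy(),
        )

    def test_all_missing_column_rejected(self):
        table = toy_table(n_per_class=4)
        table["split"] = "train"
        table["d002"] = np.nan
        with pytest.raises(CraniomorphError, match="entirely missing"):
            mlsuite.preprocess(table, table.iloc[:0], table.iloc[:0], "DT")


class TestSearchAccounting:
    def test_grid_cardinalities(self):
        assert SEARCH_SPACES["RF"].n_candidates == 960
        assert SEARCH_SPACES["MLP"].n_candidates == 48
        assert SEARCH_SPACES["DT"].n_candidates == 100
        assert SEARCH_SPACES["RF"].planned_fits == 2880
        assert SEARCH_SPACES["MLP"].planned_fits == 144
        assert SEARCH_SPACES["DT"].planned_fits == 300

    def test_dt_randomized_search_logs_300_fits(self, small_search_data):
        X, y = small_search_data
        best, log = mlsuite.run_search(SEARCH_SPACES["DT"], X, y, seed=0)
        assert len(log) == 300
        assert best.model == "DT"
        assert set(best.params) == {"max_depth", "min_samples_split", "min_samples_leaf"}

    def test_empty_grid_rejected(self, small_search_data):
        X, y = small_search_data
        space = mlsuite.SearchSpace("DT", {}, "exhaustive")
        with pytest.raises(CraniomorphError):
            mlsuite.run_search(space, X, y)


class TestTierConfigs:
    def test_canonical_tier_values(self):
        dt_high = TIER_CONFIGS[("DT", "high")].params
        assert dt_high == {"min_samples_split": 3, "min_samples_leaf": 1, "max_depth": 19}
        dt_low = TIER_CONFIGS[("DT", "low")].params
        assert dt_low == {"min_samples_split": 20, "min_samples_leaf": 18, "max_depth": 3}
        mlp_low = TIER_CONFIGS[("MLP", "low")].params
        assert mlp_low["hidden_layer_sizes"] == (4,)
        assert mlp_low["solver"] == "sgd"
        assert MLP_LOW_ALT.params["hidden_layer_sizes"] == (100, 50)
        rf_high = TIER_CONFIGS[("RF", "high")].params
        assert rf_high["max_depth"] == 10 and rf_high["max_features"] == "sqrt"
        rf_low = TIER_CONFIGS[("RF", "low")].params
        assert rf_low["max_depth"] == 3 and rf_low["max_features"] == "log2"
        mlp_high = TIER_CONFIGS[("MLP", "high")].params
        assert mlp_high["hidden_layer_sizes"] == (100, 50)
        assert mlp_high["solver"] == "adam"

    def test_unknown_model_rejected(self):
        with pytest.raises(CraniomorphError):
            ModelConfig("SVM", {})


class TestTrainEval:
    @pytest.mark.parametrize("model", ["DT", "RF", "MLP"])
    def test_separable_toy_perfect(self, model):
        table = toy_table()
        tagged = mlsuite.split_dataset(table, SplitSpec((0.6, 0.2, 0.2), seed=0))
        cfg = TIER_CONFIGS[(model, "high")]
        res = mlsuite.train_eval(cfg, tagged, seed=0)
        assert res.f1 == pytest.approx(1.0)

    def test_confusion_totals(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.6, 0.2, 0.2), seed=0))
        res = mlsuite.train_eval(TIER_CONFIGS[("DT", "high")], tagged, seed=0)
        assert res.confusion.sum() == 720
        # row sums equal test-class counts
        test_counts = (
            tagged[tagged["split"] == "test"]["label_code"].value_counts().sort_index()
        )
        np.testing.assert_array_equal(res.confusion.sum(axis=1), test_counts.to_numpy())

    def test_macro_f1_bounded_by_max_class_f1(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.6, 0.2, 0.2), seed=1))
        res = mlsuite.train_eval(TIER_CONFIGS[("DT", "low")], tagged, seed=1)
        assert res.f1 <= res.per_class["f1"].max() + 1e-12
        assert 0 <= res.precision <= 1 and 0 <= res.recall <= 1 and 0 <= res.f1 <= 1

    def test_missing_class_in_training_named(self):
        table = toy_table(n_per_class=10)
        table["split"] = "test"
        table.loc[table["label_code"] == 1, "split"] = "train"
        with pytest.raises(CraniomorphError, match="2"):
            mlsuite.train_eval(TIER_CONFIGS[("DT", "high")], table, seed=0)

    def test_deterministic_given_seed(self, feature_table):
        tagged = mlsuite.split_dataset(feature_table, SplitSpec((0.6, 0.2, 0.2), seed=2))
        a = mlsuite.train_eval(TIER_CONFIGS[("DT", "high")], tagged, seed=7)
        b = mlsuite.train_eval(TIER_CONFIGS[("DT", "high")], tagged, seed=7)
        assert a.f1 == b.f1
        np.testing.assert_array_equal(a.confusion, b.confusion)


class TestExperimentMatrix:
    def test_grid_cardinality_small(self):
        table = toy_table(n_per_class=60, n_classes=3)
        report = mlsuite.run_experiment_matrix(table, seeds=(0,), models=("DT",))
        assert len(report["results"]) == 1 * 2 * 3  # models x tiers x ratios
        assert set(report["metrics"].columns) >= {
            "ratios",
            "model",
            "f1_high",
            "f1_low",
        }

    def test_full_grid_is_18_cells(self, feature_table):
        # counted without running: 3 models x 2 tiers x 3 ratio presets
        n = len(mlsuite.MODELS) * 2 * len(RATIO_PRESETS)
        assert n == 18

    def test_high_tier_beats_low_tier_majority_of_seeds(self, feature_table):
        import warnings

        seeds = (0, 1, 2)
        for model in mlsuite.MODELS:
            wins = 0
            for seed in seeds:
                spec = SplitSpec((0.6, 0.2, 0.2), seed=seed)
                tagged = mlsuite.split_dataset(feature_table, spec)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hi = mlsuite.train_eval(TIER_CONFIGS[(model, "high")], tagged, seed=seed)
                    lo = mlsuite.train_eval(TIER_CONFIGS[(model, "low")], tagged, seed=seed)
                wins += hi.f1 >= lo.f1 - 1e-9
            assert wins >= 2, model
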