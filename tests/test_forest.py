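"""Random-forest model families, OOB reporting and contribution analysis."""

import numpy as np
import pandas as pd
import pytest

from beaknest import forest, synth
from beaknest.forest import FittedForest, ModelError, RFConfig
from beaknest.materials import MIXED


def _iid_predictors(n, seed):
    """A schema-conformant table with no structure at all."""
    cfg = synth.SynthConfig(
        n_species=n, n_trees=1, seed=seed, signal_mix=0.0,
        effect_matrix=np.zeros((7, 12)), phylo_effect_sd=0.0,
    )
    return synth.generate_dataset(cfg).predictors


class TestFitForest:
    def test_learnable_threshold_signal(self):
        X = _iid_predictors(500, seed=41)
        y = pd.Series(
            np.where(X["body_mass_g"] > X["body_mass_g"].median(), "heavy", "light"),
            index=X.index,
        )
        rep = forest.report(forest.fit_forest(X, y, RFConfig(n_trees=200, seed=0)))
        assert rep.overall_accuracy > 95

    def test_no_signal_two_balanced_classes_near_chance(self):
        X = _iid_predictors(500, seed=43)
        rng = np.random.default_rng(2)
        y = pd.Series(rng.permutation(np.repeat(["a", "b"], 250)), index=X.index)
        rep = forest.report(forest.fit_forest(X, y, RFConfig(n_trees=200, seed=0)))
        assert abs(rep.overall_accuracy - 50) < 5

    def test_single_class_rejected(self):
        X = _iid_predictors(20, seed=47)
        y = pd.Series("a", index=X.index)
        with pytest.raises(ModelError):
            forest.fit_forest(X, y, RFConfig(n_trees=10, seed=0))

    def test_tiny_ensemble_warns_about_missing_oob(self):
        X = _iid_predictors(10, seed=53)
        y = pd.Series(["a", "b"] * 5, index=X.index)
        with pytest.warns(UserWarning, match="out-of-bag"):
            fitted = forest.fit_forest(X, y, RFConfig(n_trees=1, seed=0))
        rep = forest.report(fitted)
        assert rep.n_total + rep.n_without_oob == 10

    def test_seed_reproducibility_and_stability(self):
        X = _iid_predictors(1000, seed=59)
        y = pd.Series(
            np.where(X["hand_wing_index"] > X["hand_wing_index"].median(), "hi", "lo"),
            index=X.index,
        )
        a1 = forest.report(forest.fit_forest(X, y, RFConfig(n_trees=500, seed=1))).overall_accuracy
        a1b = forest.report(forest.fit_forest(X, y, RFConfig(n_trees=500, seed=1))).overall_accuracy
        a2 = forest.report(forest.fit_forest(X, y, RFConfig(n_trees=500, seed=2))).overall_accuracy
        assert a1 == a1b  # bit-reproducible under a fixed seed
        assert abs(a1 - a2) < 2  # seed sensitivity bounded


class TestReport:
    def test_hand_counted_confusion(self):
        fitted = FittedForest(
            model=None, species=list("wxyz"),
            observed=np.array(["a", "a", "b", "b"]),
            oob_predicted=np.array(["a", "b", "b", "b"], dtype=object),
            classes=["a", "b"], encoded_columns=[], n_dropped_missing=0,
            config=RFConfig(n_trees=1),
        )
        rep = forest.report(fitted)
        assert rep.overall_accuracy == pytest.approx(75.0)
        assert rep.confusion.loc["a"].tolist() == [1, 1]
        assert rep.confusion.loc["b"].tolist() == [0, 2]
        assert rep.confusion_normalized.loc["b", "b"] == pytest.approx(1.0)

    def test_trace_identity(self, small_dataset, small_rf_config):
        rep = forest.run_primary_model(
            small_dataset.profiles, small_dataset.predictors, small_rf_config
        )
        conf = rep.confusion.to_numpy()
        assert rep.overall_accuracy == pytest.approx(100 * np.trace(conf) / conf.sum())
        for cls, n in rep.n_per_class.items():
            assert rep.confusion.loc[cls].sum() == n


class TestModelFamilies:
    def test_seven_binary_reports(self, small_dataset, small_rf_config):
        reports = forest.run_binary_models(
            small_dataset.profiles, small_dataset.predictors, small_rf_config
        )
        assert len(reports) == 7

    def test_majority_frequency_drives_binary_accuracy(self):
        # a material used by ~94% of species with uninformative predictors is
        # "predicted" at ~94% by majority guessing - the frequency bias the
        # downsampling null is built to expose
        X = _iid_predictors(500, seed=61)
        rng = np.random.default_rng(3)
        y = pd.Series(
            np.where(rng.random(500) < 0.94, "used", "not_used"), index=X.index
        )
        rep = forest.report(forest.fit_forest(X, y, RFConfig(n_trees=200, seed=0)))
        majority = 100 * (y == "used").mean()
        assert abs(rep.overall_accuracy - majority) < 4

    def test_include_mixed_only_changes_membership(self, small_dataset, small_rf_config):
        with_mixed = forest.primary_labels(small_dataset.profiles, include_mixed=True)
        without = forest.primary_labels(small_dataset.profiles, include_mixed=False)
        assert set(without.index) <= set(with_mixed.index)
        assert (with_mixed.loc[without.index] == without).all()
        assert MIXED not in set(without)

    def test_specialist_model_restricted_sample(self, small_dataset, small_rf_config):
        rep = forest.run_specialist_model(
            small_dataset.profiles, small_dataset.predictors, small_rf_config
        )
        n_specialists = sum(p.specialist for p in small_dataset.profiles)
        assert rep.n_total + rep.n_without_oob == n_specialists

    def test_specialist_model_needs_enough_specialists(self, small_rf_config):
        from beaknest.materials import MaterialCategory, MaterialProfile

        profiles = [
            MaterialProfile(f"s{i}", frozenset({MaterialCategory.TWIG, MaterialCategory.GRASS}),
                            MaterialCategory.TWIG, False)
            for i in range(10)
        ]
        X = _iid_predictors(10, seed=67)
        X.index = [f"s{i}" for i in range(10)]
        with pytest.raises(ModelError):
            forest.run_specialist_model(profiles, X, small_rf_config)


class TestContributions:
    def test_single_informative_predictor(self):
        X = _iid_predictors(300, seed=71)
        y = pd.Series(
            np.where(X["body_mass_g"] > X["body_mass_g"].median(), "heavy", "light"),
            index=X.index,
        )
        profiles = _profiles_from_binary(y)
        table = forest.contribution_analysis(
            profiles, X, RFConfig(n_trees=150, seed=0), model_family="binary:twig"
        )
        assert table.loc["body_mass_g", "independent_accuracy"] > 95
        others = table.drop("body_mass_g")
        assert (others["independent_accuracy"] < table.loc["body_mass_g", "independent_accuracy"] - 20).all()
        # dropping an uninformative predictor barely moves the needle
        assert others["marginal_contribution"].abs().max() < 5

    def test_duplicated_predictor_has_no_marginal_contribution(self):
        X = _iid_predictors(300, seed=73)
        X["bill_length_nares_mm"] = X["bill_length_total_mm"]  # redundant copy
        y = pd.Series(
            np.where(X["bill_length_total_mm"] > X["bill_length_total_mm"].median(),
                     "big", "small"),
            index=X.index,
        )
        profiles = _profiles_from_binary(y)
        table = forest.contribution_analysis(
            profiles, X, RFConfig(n_trees=150, seed=0), model_family="binary:twig"
        )
        for col in ("bill_length_total_mm", "bill_length_nares_mm"):
            assert abs(table.loc[col, "marginal_contribution"]) < 5
            assert table.loc[col, "independent_accuracy"] > 90


def _profiles_from_binary(y: pd.Series):
    """Wrap a used/not_used label series as twig-use profiles."""
    from beaknest.materials import MaterialCategory, MaterialProfile

    out = []
    for sp, v in y.items():
        if v in ("used", "heavy", "big"):
            used = frozenset({MaterialCategory.TWIG})
            out.append(MaterialProfile(sp, used, MaterialCategory.TWIG, True))
        else:
            used = frozenset({MaterialCategory.GRASS})
            out.append(MaterialProfile(sp, used, MaterialCategory.GRASS, True))
    return out
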