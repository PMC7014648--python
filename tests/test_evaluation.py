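"""Classifier training, preprocessing, metrics and relative evaluation."""

import numpy as np
import pandas as pd
import pytest

from anonlearn import (
    ClassifierSpec,
    Dataset,
    GeneralizationScheme,
    KAnonymity,
    anonymize,
    brier_score,
    brier_skill_score,
    evaluate_relative,
    one_vs_all,
    preprocess_features,
    relative_auc,
    roc_and_auc,
    train,
)
from anonlearn.errors import DegenerateModelError, UndefinedMetricError
from anonlearn.fixtures import make_inflammation_like

from conftest import pairwise_auc


class TestPreprocessFeatures:
    def test_identity_scheme_passes_through(self, toy_dataset, toy_config):
        s = GeneralizationScheme.from_dict({"age": 0, "sex": 0})
        out = preprocess_features(toy_dataset.df, s, toy_config.hierarchies)
        assert out.equals(toy_dataset.df)

    def test_generalized_attribute_mapped(self, toy_dataset, toy_config):
        s = GeneralizationScheme.from_dict({"age": 2, "sex": 0})
        out = preprocess_features(toy_dataset.df, s, toy_config.hierarchies)
        assert out["age"].tolist()[:3] == ["<50", "<50", "<50"]
        assert out["sex"].equals(toy_dataset.df["sex"])

    def test_unknown_value_maps_to_top(self, toy_dataset, toy_config):
        df = toy_dataset.df.copy()
        df.loc[0, "age"] = "200"
        s = GeneralizationScheme.from_dict({"age": 2, "sex": 0})
        out = preprocess_features(df, s, toy_config.hierarchies)
        assert out.loc[0, "age"] == "*"

    def test_untouched_attributes_pass_through(self, toy_dataset, toy_config):
        # aggregation/sampling/suppression preserve the domain: no mapping
        s = GeneralizationScheme.from_dict({"age": 0, "sex": 1})
        out = preprocess_features(toy_dataset.df, s, toy_config.hierarchies)
        assert out["age"].equals(toy_dataset.df["age"])
        assert set(out["sex"]) == {"*"}


class TestTrain:
    def test_zero_rule_predicts_majority(self):
        df = pd.DataFrame({"f": ["1", "2", "3"], "t": ["a", "a", "b"]})
        d = Dataset(df, {"f": "numeric"})
        model = train(ClassifierSpec(kind="zero_rule"), d, ["f"], "t")
        pred = model.predict(df[["f"]])
        assert list(pred) == ["a", "a", "a"]
        proba = model.predict_proba(df[["f"]])
        assert proba[0] == pytest.approx([2 / 3, 1 / 3])

    def test_separable_logistic_fits_perfectly(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-3, 0.3, 30), rng.normal(3, 0.3, 30)])
        y = ["neg"] * 30 + ["pos"] * 30
        df = pd.DataFrame({"x": [f"{v:.3f}" for v in x], "t": y})
        d = Dataset(df, {"x": "numeric"})
        model = train(ClassifierSpec(kind="logistic_regression"), d, ["x"], "t")
        assert (model.predict(df[["x"]]) == np.array(y)).mean() == 1.0

    def test_random_forest_seeded_determinism(self):
        b = make_inflammation_like(80, seed=4)
        spec = ClassifierSpec(kind="random_forest", n_trees=20, seed=7)
        X = b.dataset.df[b.config.quasi_identifiers]
        m1 = train(spec, b.dataset, b.config.quasi_identifiers, "nephritis")
        m2 = train(spec, b.dataset, b.config.quasi_identifiers, "nephritis")
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_training_rejected(self):
        df = pd.DataFrame({"f": ["1", "2"], "t": ["a", "a"]})
        d = Dataset(df, {"f": "numeric"})
        with pytest.raises(DegenerateModelError):
            train(ClassifierSpec(kind="logistic_regression"), d, ["f"], "t")
        train(ClassifierSpec(kind="zero_rule"), d, ["f"], "t")  # allowed


class TestRocAuc:
    def test_perfect_separation(self):
        _, _, auc = roc_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, _, auc = roc_and_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_known_small_case(self):
        _, _, auc = roc_and_auc([0.9, 0.8, 0.4], [1, 0, 1])
        assert auc == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_and_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        fpr, tpr, _ = roc_and_auc(scores, labels)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_equals_pairwise_rank_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.random(n), 2)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, _, auc = roc_and_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


class TestOneVsAll:
    def test_binary_symmetry(self):
        rng = np.random.default_rng(6)
        p1 = rng.random(40)
        proba = np.column_stack([1 - p1, p1])
        labels = np.where(rng.random(40) < 0.5, "b", "a").astype(object)
        per_class, macro = one_vs_all(proba, labels, ["a", "b"])
        assert per_class[0].auc == pytest.approx(per_class[1].auc)
        assert macro == pytest.approx(per_class[0].auc)

    def test_absent_class_excluded_with_warning(self):
        proba = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
        labels = np.array(["a", "b", "a"], dtype=object)
        with pytest.warns(UserWarning, match="'c'"):
            per_class, macro = one_vs_all(proba, labels, ["a", "b", "c"])
        assert per_class[2].auc is None

    def test_random_scores_concentrate_at_half(self):
        rng = np.random.default_rng(7)
        macros = []
        for _ in range(300):
            proba = rng.dirichlet([1, 1, 1], size=60)
            labels = rng.choice(np.array(["a", "b", "c"], dtype=object), 60)
            _, macro = one_vs_all(proba, labels, ["a", "b", "c"])
            macros.append(macro)
        se = np.std(macros) / np.sqrt(len(macros))
        assert abs(np.mean(macros) - 0.5) < 3 * se + 0.01


class TestBrier:
    def test_perfect_predictions(self):
        proba = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert brier_score(proba, np.array(["a", "b"], dtype=object), ["a", "b"]) == 0.0

    def test_uniform_binary(self):
        proba = np.full((4, 2), 0.5)
        labels = np.array(["a", "b", "a", "b"], dtype=object)
        assert brier_score(proba, labels, ["a", "b"]) == pytest.approx(0.5)

    def test_confidently_wrong_is_two(self):
        proba = np.array([[1.0, 0.0]] * 3)
        labels = np.array(["b"] * 3, dtype=object)
        assert brier_score(proba, labels, ["a", "b"]) == pytest.approx(2.0)

    def test_malformed_distribution_rejected(self):
        with pytest.raises(ValueError):
            brier_score(np.array([[0.5, 0.6]]), np.array(["a"], dtype=object), ["a", "b"])


class TestSkillAndRelative:
    @pytest.mark.parametrize(
        "ba,bo,expected", [(0.3, 0.3, 0.0), (0.1, 0.2, 0.5), (0.4, 0.1, -3.0)]
    )
    def test_skill_score_formula(self, ba, bo, expected):
        assert brier_skill_score(ba, bo) == pytest.approx(expected)

    def test_skill_score_degenerate_denominator(self):
        assert brier_skill_score(0.0, 0.0) == 0.0
        assert brier_skill_score(0.1, 0.0) == float("-inf")

    @pytest.mark.parametrize(
        "anon,orig,base,expected", [(0.9, 0.9, 0.5, 100.0), (0.5, 0.9, 0.5, 0.0),
                                    (0.7, 0.9, 0.5, 50.0)]
    )
    def test_relative_auc_linearity(self, anon, orig, base, expected):
        assert relative_auc(anon, orig, base) == pytest.approx(expected)

    def test_relative_auc_floor_and_degenerate(self):
        assert relative_auc(0.1, 0.9, 0.5) == 0.0  # clipped at the default floor
        assert relative_auc(0.1, 0.9, 0.5, floor=None) == pytest.approx(-100.0)
        with pytest.raises(UndefinedMetricError):
            relative_auc(0.6, 0.5, 0.5)


class TestEvaluateRelative:
    def test_identity_anonymization_is_exact(self):
        b = make_inflammation_like(100, seed=2, noise=0.05)
        res = anonymize(b.dataset, b.config, KAnonymity(1))
        assert res.scheme.total == 0
        rep = evaluate_relative(
            b.dataset, res, b.config, ClassifierSpec(kind="logistic_regression"),
            target="bladder_inflammation", folds=5, seed=0,
        )
        assert rep.relative_auc == 100.0
        assert rep.brier_skill == 0.0
        assert rep.anonymized.macro_auc == rep.original.macro_auc

    def test_fully_generalized_release_has_no_skill(self):
        b = make_inflammation_like(100, seed=3, noise=0.0)
        res = anonymize(b.dataset, b.config, KAnonymity(100))
        assert res.partition.min_size >= 100
        rep = evaluate_relative(
            b.dataset, res, b.config, ClassifierSpec(kind="logistic_regression"),
            target="bladder_inflammation", folds=5, seed=0,
        )
        # constant features: anonymized model can do no better than priors
        assert rep.relative_auc <= 20.0

    def test_structure_preserved_at_mild_k(self):
        # the qualitative core claim: mild k-anonymization leaves the
        # deterministic diagnosis rule learnable while bounding risk
        rels = []
        for seed in range(5):
            b = make_inflammation_like(120, seed=seed, noise=0.05)
            res = anonymize(b.dataset, b.config, KAnonymity(5))
            assert res.risk_after.max_risk <= 1 / 5 + 1e-12
            rep = evaluate_relative(
                b.dataset, res, b.config,
                ClassifierSpec(kind="random_forest", n_trees=50, seed=0),
                target="bladder_inflammation", folds=5, seed=seed,
            )
            rels.append(rep.relative_auc)
        assert np.mean(rels) > 90.0

    def test_accuracy_paired_with_original_across_seeds(self):
        diffs = []
        for seed in range(20):
            b = make_inflammation_like(120, seed=seed, noise=0.05)
            res = anonymize(b.dataset, b.config, KAnonymity(5))
            rep = evaluate_relative(
                b.dataset, res, b.config,
                ClassifierSpec(kind="logistic_regression"),
                target="nephritis", folds=5, seed=seed,
            )
            diffs.append(rep.anonymized.accuracy - rep.original.accuracy)
        # anonymized-trained accuracy within sampling error of original
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < max(3 * se, 0.02)

    def test_fold_lacking_class_is_an_error(self):
        b = make_inflammation_like(30, seed=1)
        res = anonymize(b.dataset, b.config, KAnonymity(1))
        with pytest.raises(UndefinedMetricError):
            evaluate_relative(
                b.dataset, res, b.config, ClassifierSpec(), folds=25, seed=0,
            )
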