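import numpy as np
import pandas as pd
import pytest

from vfarch import qol, synthetic
from vfarch.qol import (
    AspectModel,
    Item,
    ItemMap,
    archetype_clinical_correlations,
    aspect_scores,
    bonferroni_threshold,
    fit_association,
    predict_qol,
    score_items,
    score_subscales,
)


@pytest.fixture(scope="module")
def default_map():
    return ItemMap.default()


def small_map():
    return ItemMap.from_dict(
        {
            "items": [
                {"id": "a1", "levels": 5, "subscale": "sub"},
                {"id": "a2", "levels": 5, "subscale": "sub"},
                {"id": "b1", "levels": 5},
                {"id": "c1", "levels": 3, "level1_best": False},
                {"id": "d1", "levels": 5, "missing_codes": [6]},
            ]
        }
    )


def responses(rows):
    return pd.DataFrame(rows, columns=["patient_id", "item_id", "response_level"])


class TestItemMap:
    def test_default_shape(self, default_map):
        assert len(default_map.items) == 43
        assert len(default_map.aspects) == 37
        assert set(default_map.subscales) == {
            "driving", "near_activities", "distance_activities", "social_functioning",
        }
        assert all(len(v) >= 1 for v in default_map.subscales.values())

    def test_levels_validation(self):
        with pytest.raises(ValueError):
            Item(id="bad", levels=1)

    def test_duplicate_item_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ItemMap.from_dict({"items": [{"id": "x", "levels": 5}, {"id": "x", "levels": 5}]})


class TestScoreItems:
    def test_best_level_scores_100(self):
        out = score_items(responses([("P", "b1", 1)]), small_map())
        assert out.at["P", "b1"] == pytest.approx(100.0)

    def test_worst_level_scores_0(self):
        out = score_items(responses([("P", "b1", 5)]), small_map())
        assert out.at["P", "b1"] == pytest.approx(0.0)

    def test_midpoint(self):
        out = score_items(responses([("P", "b1", 3)]), small_map())
        assert out.at["P", "b1"] == pytest.approx(50.0)

    def test_direction_flip(self):
        # c1 declares level 3 (of 3) as best
        out = score_items(responses([("P", "c1", 3), ("Q", "c1", 1)]), small_map())
        assert out.at["P", "c1"] == pytest.approx(100.0)
        assert out.at["Q", "c1"] == pytest.approx(0.0)

    def test_missing_code(self):
        out = score_items(responses([("P", "d1", 6)]), small_map())
        assert np.isnan(out.at["P", "d1"])

    def test_out_of_range_names_item(self):
        with pytest.raises(ValueError, match="b1"):
            score_items(responses([("P", "b1", 9)]), small_map())

    def test_unknown_item_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            score_items(responses([("P", "zz", 1)]), small_map())


class TestSubscales:
    def test_mean_of_members(self):
        scores = score_items(responses([("P", "a1", 1), ("P", "a2", 3)]), small_map())
        subs = score_subscales(scores, small_map())
        assert subs.at["P", "sub"] == pytest.approx(75.0)

    def test_one_missing_member(self):
        scores = score_items(responses([("P", "a1", 1)]), small_map())
        subs = score_subscales(scores, small_map())
        assert subs.at["P", "sub"] == pytest.approx(100.0)

    def test_all_missing(self):
        scores = score_items(responses([("P", "b1", 1)]), small_map())
        subs = score_subscales(scores, small_map())
        assert np.isnan(subs.at["P", "sub"])

    def test_aspect_frame(self):
        scores = score_items(
            responses([("P", "a1", 1), ("P", "b1", 5), ("P", "c1", 3), ("P", "d1", 1)]),
            small_map(),
        )
        asp = aspect_scores(scores, small_map())
        assert list(asp.columns) == ["sub", "b1", "c1", "d1"]
        assert asp.at["P", "sub"] == pytest.approx(100.0)


class TestBonferroni:
    def test_threshold_value(self):
        assert bonferroni_threshold(0.05, 43) == pytest.approx(0.05 / 43)

    def test_classification_near_threshold(self):
        thr = bonferroni_threshold()
        assert 0.0010 < thr
        assert 0.0020 > thr

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _ordinal_sim(n, beta, seed, cut_shift=0.0):
    """Simulate one aspect from a proportional-odds model; returns (y, X)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "w": rng.uniform(0, 60, size=n),
            "age": rng.uniform(50, 85, size=n),
        },
        index=[f"P{i}" for i in range(n)],
    )
    eta = X.to_numpy() @ np.asarray(beta)
    cuts = np.array([-1.5, -0.5, 0.5, 1.5]) + eta.mean() + cut_shift
    cum = 1 / (1 + np.exp(-(cuts[:, None] - eta[None, :])))
    probs = np.vstack([cum, np.ones((1, n))])
    probs[1:] -= cum
    u = rng.random(n)
    g = (u[None, :] > np.cumsum(probs, axis=0)).sum(axis=0) + 1
    y = pd.Series(100.0 * (g - 1) / 4.0, index=X.index)
    return y, X


class TestFitAssociation:
    def test_recovers_signs_and_scale(self):
        beta = np.array([-0.04, -0.02])
        y, X = _ordinal_sim(2000, beta, seed=0)
        res = fit_association(pd.DataFrame({"aspect": y}), X, n_tests=1)
        m = res.models["aspect"]
        assert m.kind == "ordinal"
        assert m.beta["w"] == pytest.approx(-0.04, abs=0.01)
        assert m.beta["age"] == pytest.approx(-0.02, abs=0.012)

    def test_flags_match_threshold_exactly(self):
        y, X = _ordinal_sim(400, np.array([-0.05, 0.0]), seed=1)
        res = fit_association(pd.DataFrame({"aspect": y}), X, alpha=0.05, n_tests=43)
        thr = res.threshold
        for row in res.table.itertuples():
            assert row.significant == (row.p < thr)

    def test_binary_fallback(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"w": rng.uniform(0, 50, 200), "age": rng.uniform(50, 80, 200)},
            index=[f"P{i}" for i in range(200)],
        )
        p = 1 / (1 + np.exp(-(X["w"] - 25) / 10))
        y = pd.Series((rng.random(200) < p).astype(float) * 100.0, index=X.index)
        res = fit_association(pd.DataFrame({"aspect": y}), X, n_tests=1)
        m = res.models["aspect"]
        assert m.kind == "binary"
        assert m.beta["w"] > 0

    def test_order_independent(self):
        y1, X = _ordinal_sim(300, np.array([-0.03, 0.01]), seed=3)
        y2, _ = _ordinal_sim(300, np.array([0.02, -0.01]), seed=4)
        aspects = pd.DataFrame({"one": y1, "two": y2})
        r_fwd = fit_association(aspects, X, n_tests=2)
        r_rev = fit_association(aspects[["two", "one"]], X, n_tests=2)
        merged = r_fwd.table.set_index(["aspect", "predictor"]).sort_index()
        merged_rev = r_rev.table.set_index(["aspect", "predictor"]).sort_index()
        pd.testing.assert_frame_equal(merged, merged_rev)

    def test_too_few_patients(self):
        y, X = _ordinal_sim(5, np.zeros(2), seed=5)
        with pytest.raises(ValueError, match="overlapping"):
            fit_association(pd.DataFrame({"a": y}), X)


class TestPredictQol:
    def test_null_model_symmetric_categories(self):
        m = AspectModel(
            aspect="a",
            kind="ordinal",
            categories=[0.0, 50.0, 100.0],
            thresholds=[-1.0, 1.0],
            beta={"w": 0.0},
            se={"w": 0.0},
            pvalues={"w": 1.0},
            n_obs=10,
        )
        X = pd.DataFrame({"w": [0.0, 10.0, 50.0]})
        np.testing.assert_allclose(m.expected_score(X), 50.0)

    def test_probabilities_sum_to_one(self):
        y, X = _ordinal_sim(500, np.array([-0.04, -0.01]), seed=6)
        res = fit_association(pd.DataFrame({"a": y}), X, n_tests=1)
        probs = res.models["a"].category_probs(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_in_negative_coefficient(self):
        y, X = _ordinal_sim(1500, np.array([-0.05, 0.0]), seed=7)
        res = fit_association(pd.DataFrame({"a": y}), X, n_tests=1)
        lo = pd.DataFrame({"w": [0.0], "age": [60.0]})
        hi = pd.DataFrame({"w": [60.0], "age": [60.0]})
        pred = predict_qol(res, pd.concat([lo, hi], ignore_index=True))
        assert pred.iloc[1, 0] < pred.iloc[0, 0]

    def test_predictions_within_category_range(self):
        y, X = _ordinal_sim(500, np.array([-0.04, -0.01]), seed=8)
        res = fit_association(pd.DataFrame({"a": y}), X, n_tests=1)
        pred = predict_qol(res, X)
        assert pred["a"].between(0.0, 100.0).all()

    def test_missing_predictor_errors(self):
        y, X = _ordinal_sim(300, np.array([-0.04, 0.0]), seed=9)
        res = fit_association(pd.DataFrame({"a": y}), X, n_tests=1)
        with pytest.raises(ValueError, match="missing"):
            predict_qol(res, X[["age"]])


class TestCorrelations:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        corr, pvals, sig = archetype_clinical_correlations(df)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        assert (sig.to_numpy() == sig.to_numpy().T).all()

    def test_zero_variance_column(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.full(20, 3.0)})
        corr, _, sig = archetype_clinical_correlations(df)
        assert np.isnan(corr.loc["a", "b"])
        assert not sig.loc["a", "b"]

    def test_synthetic_weight_vs_severity_signs(self):
        # general-depression weight lowers mean sensitivity; normal weight raises it
        cohort = synthetic.simulate_cohort(150, k_true=5, noise_sigma=1.0, seed=12)
        truth = cohort.truth
        T = truth.target_matrix()
        df = pd.DataFrame(
            {
                "w_normal": truth.weights[:, 0],
                "w_general": truth.weights[:, truth.template_names.index("general_depression")],
                "ivf_ms": T.mean(axis=1),
            }
        )
        corr, _, sig = archetype_clinical_correlations(df)
        assert corr.loc["w_normal", "ivf_ms"] > 0
        assert corr.loc["w_general", "ivf_ms"] < 0
        assert sig.loc["w_general", "ivf_ms"]

    def test_needs_three_patients(self):
        with pytest.raises(ValueError):
            archetype_clinical_correlations(pd.DataFrame({"a": [1.0, 2.0]}))
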