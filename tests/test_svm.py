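import math

import numpy as np
import pandas as pd
import pytest

from oracles import qp_svm, rotation_search_angle

from warmcool.svm import (
    LinearClassifier,
    TrainingSet,
    border_angle,
    cross_validate,
    normalize_features,
    select_variables,
    svmic,
    train_linear_svm,
    weight_importance,
)


def make_clf(w_norm, b_norm=0.0, xi=None, n=10):
    """Assemble a LinearClassifier directly (unit norm params)."""
    w_norm = np.asarray(w_norm, dtype=float)
    d = len(w_norm)
    xi = np.zeros(n) if xi is None else np.asarray(xi, dtype=float)
    norm = np.linalg.norm(w_norm)
    return LinearClassifier(
        W=w_norm.copy(), b=b_norm, W_norm=w_norm, b_norm=b_norm,
        d=(1.0 / norm if norm > 0 else np.inf), xi=xi, cost=1.0,
        norm_params=(np.zeros(d), np.ones(d)),
        variable_names=tuple(f"x{i}" for i in range(d)),
    )


class TestNormalize:
    def test_two_point_column(self):
        xn, (mu, sd) = normalize_features(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(xn.ravel(), [-1.0, 1.0])
        assert mu[0] == pytest.approx(2.0)
        assert sd[0] == pytest.approx(1.0)  # population sd of {1, 3}

    def test_idempotent_on_normalized_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 2))
        xn, _ = normalize_features(x)
        xnn, _ = normalize_features(xn)
        np.testing.assert_allclose(xnn, xn, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_features(np.array([[1.0, 2.0], [1.0, 3.0]]))


class TestTrain:
    def test_symmetric_1d_boundary_at_zero(self):
        ts = TrainingSet(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        clf = train_linear_svm(ts)
        assert clf.b == pytest.approx(0.0, abs=1e-6)
        # both points sit exactly on the margins: |decision| = 1, no slack
        np.testing.assert_allclose(np.abs(clf.decision_function(ts.X)), 1.0, atol=1e-6)
        assert clf.total_slack == pytest.approx(0.0, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(TrainingSet(np.array([[0.0], [1.0]]), np.array([1, 1])))

    def test_scale_roundtrip(self):
        """Raw-scale (W, b) and normalized-scale weights give identical
        decisions."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3)) * np.array([5.0, 0.2, 1.0]) + np.array([1.0, -2.0, 0.0])
        y = np.where(X[:, 0] + X[:, 1] > 0, 1, -1)
        ts = TrainingSet(X, y)
        clf = train_linear_svm(ts)
        xn = (X - clf.norm_params[0]) / clf.norm_params[1]
        np.testing.assert_allclose(
            clf.decision_function(X), xn @ clf.W_norm + clf.b_norm, atol=1e-9)

    @pytest.mark.parametrize("overlap", [False, True])
    def test_matches_qp_oracle(self, overlap):
        """Decision values equal an independent quadratic-programming solution
        of the primal, on separable and overlapping data."""
        rng = np.random.default_rng(42 if overlap else 7)
        n = 14
        X = rng.normal(size=(n, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        if overlap:
            y[:3] = -y[:3]
        ts = TrainingSet(X, y)
        clf = train_linear_svm(ts)
        xn, _ = normalize_features(X)
        w, b, xi = qp_svm(xn, y, cost=1.0)
        ours = xn @ clf.W_norm + clf.b_norm
        theirs = xn @ w + b
        assert np.linalg.norm(ours - theirs) / np.linalg.norm(theirs) < 1e-4
        assert clf.total_slack == pytest.approx(xi.sum(), abs=1e-3)


class TestCrossValidate:
    def test_separable_data_perfect(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(-5, 0.1, (20, 1)), rng.normal(5, 0.1, (20, 1))])
        y = np.array([-1] * 20 + [1] * 20)
        assert cross_validate(TrainingSet(X, y), 5, seed=0) == 1.0

    def test_loo_on_four_separable_points(self):
        ts = TrainingSet(np.array([[-2.0], [-1.0], [1.0], [2.0]]),
                         np.array([-1, -1, 1, 1]))
        assert cross_validate(ts, 4, seed=0) == 1.0

    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = rng.choice([-1, 1], size=200)
        acc = cross_validate(TrainingSet(X, y), 10, seed=3)
        assert 0.35 < acc < 0.65  # chance within binomial error

    def test_invalid_folds(self):
        ts = TrainingSet(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        with pytest.raises(ValueError):
            cross_validate(ts, 1)
        with pytest.raises(ValueError):
            cross_validate(ts, 3)


class TestImportanceAndCriteria:
    def test_w2_example(self):
        w2 = weight_importance(make_clf([2.0, 0.2]))
        np.testing.assert_allclose(w2.to_numpy(), [4.0, 0.04])
        assert w2.iloc[0] / w2.iloc[1] == pytest.approx(100.0)

    def test_single_variable(self):
        w2 = weight_importance(make_clf([1.5]))
        assert len(w2) == 1

    def test_svmic_formulas(self):
        clf = make_clf([1.0], xi=np.array([0.5, 0.25, 0.0]))
        a = svmic(clf, "a")
        b = svmic(clf, "b")
        assert a.value == pytest.approx(0.75 + 2.0)
        assert b.value == pytest.approx(0.75 + math.log(3))
        # adding a variable at equal slack costs exactly ln(n) under variant b
        clf3 = make_clf([1.0, 2.0, 0.3], xi=np.array([0.5, 0.25, 0.0]))
        clf2 = make_clf([1.0, 2.0], xi=np.array([0.5, 0.25, 0.0]))
        assert svmic(clf3, "b").value - svmic(clf2, "b").value == pytest.approx(math.log(3))
        assert svmic(clf3, "a").value - svmic(clf2, "a").value == pytest.approx(2.0)

    def test_svmic_requires_slacks(self):
        clf = make_clf([1.0], xi=np.array([]))
        with pytest.raises(ValueError):
            svmic(clf)

    def test_select_variables_flags_noise(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=120)
        x2 = rng.normal(size=120)
        y = np.where(x1 > 0, 1, -1)
        table = select_variables(TrainingSet(np.column_stack([x1, x2]), y,
                                             ("inf", "noise")))
        by_model = table.set_index("model")
        assert bool(by_model.loc["drop_noise", "non_contributing"])
        assert not bool(by_model.loc["drop_inf", "non_contributing"])

    def test_select_variables_keeps_joint_contributors(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 2))
        y = np.where(X.sum(axis=1) > 0, 1, -1)
        table = select_variables(TrainingSet(X, y))
        assert not table["non_contributing"].iloc[1:].any()

    def test_table_shape_two_variables(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        table = select_variables(TrainingSet(X, y))
        assert list(table["model"])[:1] == ["full"] and len(table) == 3


class TestBorderAngle:
    def test_border_along_second_axis_is_zero(self):
        # hyperplane x0 = 0: the border line IS the second axis
        assert border_angle(make_clf([1.0, 0.0]), axis_index=1) == pytest.approx(0.0)

    def test_equal_weights_unit_scales_45deg(self):
        assert border_angle(make_clf([1.0, 1.0]), axis_index=0) == pytest.approx(45.0)

    @pytest.mark.parametrize("w, scales", [
        ((1.0, 0.3), (1.0, 1.0)),
        ((0.8, -0.1), (2.0, 0.5)),
        ((-0.2, 1.4), (0.3, 3.0)),
    ])
    def test_matches_rotation_search_oracle(self, w, scales):
        clf = make_clf(list(w))
        ours = border_angle(clf, axis_index=1, axis_scales=scales)
        oracle = rotation_search_angle(np.array(w), 0.0, 1, scales)
        assert ours == pytest.approx(oracle, abs=0.01)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            border_angle(make_clf([0.0, 0.0]), axis_index=0)


class TestParameterRecovery:
    def test_recovers_rlm_boundary_on_chips(self, chipset_large_beta):
        """Chips labeled by sign(R_LM): the classifier leans almost entirely
        on R_LM, crosses the R_LM axis near 0, and cross-validates >= 0.99."""
        chips = chipset_large_beta.chips
        chips = chips[(~chips["is_reference"]) & (chips["R_LM"] != 0)]
        labels = np.where(chips["N_w"] > chips["N_c"], 1, -1)
        ts = TrainingSet(chips[["R_LM", "R_Y"]].to_numpy(), labels, ("R_LM", "R_Y"))
        clf = train_linear_svm(ts)
        w2 = weight_importance(clf)
        assert w2["R_Y"] / w2["R_LM"] < 0.05
        assert abs(-clf.b / clf.W[0]) < 0.01
        acc = cross_validate(ts, 10, seed=0)
        assert acc >= 0.99
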