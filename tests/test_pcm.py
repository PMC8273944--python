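"""Partial credit model: probability primitives, MML-EM calibration and
person measurement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from briefmds.pcm import (
    PartialCreditModel,
    category_probabilities,
    expected_score_and_information,
    fit_pcm,
    validate_responses,
)
from briefmds.simulate import (
    PersonSpec,
    SimulationConfig,
    TrueItemSpec,
    generate_pcm_responses,
)
from tests.conftest import small_item_bank


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "thresholds, theta, expected",
        [
            # equal thresholds at theta: all cumulative sums equal -> uniform
            ((0, 0, 0, 0), 0.0, [0.2, 0.2, 0.2, 0.2, 0.2]),
            # closed form with numerators (1, e, 1)
            ((-1, 1), 0.0, [1 / (2 + np.e), np.e / (2 + np.e), 1 / (2 + np.e)]),
        ],
    )
    def test_closed_form(self, thresholds, theta, expected):
        p = category_probabilities(thresholds, theta)
        np.testing.assert_allclose(p, expected, atol=1e-10)

    def test_extreme_theta_concentrates(self):
        p = category_probabilities((-1, 1), 30.0)
        assert p[-1] > 1 - 1e-9
        p = category_probabilities((0, 0, 0, 0), -50.0)
        assert p[0] > 1 - 1e-9

    @given(
        st.lists(st.floats(-4, 4), min_size=1, max_size=6),
        st.floats(-8, 8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sums_to_one(self, thresholds, theta):
        p = category_probabilities(thresholds, theta)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            category_probabilities((np.inf, 0), 0.0)
        with pytest.raises(ValueError):
            category_probabilities((0, 1), np.nan)


class TestExpectedScore:
    def test_uniform_moments(self):
        # discrete uniform on {0..4}: mean 2, variance 2
        e, w, info = expected_score_and_information((0, 0, 0, 0), 0.0)
        assert e == pytest.approx(2.0, abs=1e-12)
        assert w == pytest.approx(2.0, abs=1e-12)
        assert info == pytest.approx(w)

    def test_low_theta_limit(self):
        e, w, _ = expected_score_and_information((0, 0), -40.0)
        assert e < 1e-12 and w < 1e-12

    def test_expectation_increasing_in_theta(self):
        grid = np.linspace(-6, 6, 61)
        e, _, _ = expected_score_and_information((-1.2, 0.3, 1.7), grid)
        assert np.all(np.diff(e) > 0)


class TestValidation:
    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [0, 1, 2, 1], "b": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            validate_responses(df)

    def test_null_middle_category_rejected(self):
        df = pd.DataFrame({"a": [0, 1, 2, 0], "b": [0, 1, 3, 3]})
        with pytest.raises(ValueError, match="recode"):
            validate_responses(df)

    def test_duplicate_person_ids_rejected(self):
        df = pd.DataFrame({"a": [0, 1], "b": [1, 0]}, index=[1, 1])
        with pytest.raises(ValueError, match="duplicate"):
            validate_responses(df)


def _grid_search_oracle(X, n_items, n_cats, n_quadrature=31, rounds=6):
    """Brute-force marginal-likelihood maximisation by iterated coordinate
    grid refinement, independent of the EM path."""
    model = PartialCreditModel(n_quadrature=n_quadrature)
    labels = list(X.columns)
    thresholds = {lab: np.zeros(n_cats - 1) for lab in labels}
    sigma = 1.0

    def ll(ths, sig):
        return model.marginal_loglik(X, ths, sig)

    width = 2.0
    for _ in range(rounds):
        for lab in labels:
            for j in range(n_cats - 1):
                base = thresholds[lab][j]
                grid = base + np.linspace(-width, width, 9)
                vals = []
                for g in grid:
                    trial = {k: v.copy() for k, v in thresholds.items()}
                    trial[lab][j] = g
                    vals.append(ll(trial, sigma))
                thresholds[lab][j] = grid[int(np.argmax(vals))]
        sgrid = np.clip(sigma + np.linspace(-width / 2, width / 2, 9), 0.2, 4.0)
        svals = [ll(thresholds, s) for s in sgrid]
        sigma = sgrid[int(np.argmax(svals))]
        width /= 2.5
    return thresholds, sigma


class TestCalibration:
    def test_mml_matches_grid_search_oracle(self):
        """3 items x 3 categories, n = 200: EM solution equals brute-force
        marginal-likelihood grid search within 1e-2 per threshold."""
        items = [
            TrueItemSpec("a", (-0.8, 0.5)),
            TrueItemSpec("b", (-0.2, 1.0)),
            TrueItemSpec("c", (-1.1, 0.1)),
        ]
        X = generate_pcm_responses(
            items, PersonSpec(n=200, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=7))
        model = PartialCreditModel(n_quadrature=31, tol=1e-7).fit(X)
        oracle_th, oracle_sigma = _grid_search_oracle(X, 3, 3)
        for lab in X.columns:
            np.testing.assert_allclose(
                model.thresholds_[lab], oracle_th[lab], atol=1e-2)
        # and the EM solution cannot have lower marginal likelihood
        assert model.loglik_ >= model.marginal_loglik(X, oracle_th, oracle_sigma) - 1e-3

    def test_parameter_recovery_rmse(self):
        """Thresholds recovered from n = 2000 with RMSE < 0.15 logits."""
        items = small_item_bank(n_items=6)
        X = generate_pcm_responses(
            items, PersonSpec(n=2000, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=11))
        model = fit_pcm(X)
        errs = np.concatenate([
            model.thresholds_[it.item_id] - np.asarray(it.thresholds)
            for it in items])
        rmse = float(np.sqrt(np.mean(errs**2)))
        assert rmse < 0.15

    def test_location_threshold_identity(self, calibrated):
        _, _, _, model, _ = calibrated
        items = model.item_parameters_
        for lab in items.labels:
            assert items.location(lab) == pytest.approx(
                float(np.mean(items.thresholds[lab])), abs=1e-12)

    def test_deterministic_given_data(self, conforming_data):
        _, _, X = conforming_data
        m1 = fit_pcm(X)
        m2 = fit_pcm(X)
        for lab in X.columns:
            np.testing.assert_array_equal(m1.thresholds_[lab], m2.thresholds_[lab])

    def test_sklearn_param_interface(self):
        model = PartialCreditModel(n_quadrature=21)
        assert model.get_params()["n_quadrature"] == 21
        model.set_params(tol=1e-5)
        assert model.tol == 1e-5


class TestAbilities:
    def test_score_sufficiency(self, calibrated):
        """Persons with identical complete raw scores share one theta."""
        _, _, X, model, abilities = calibrated
        persons = abilities.persons
        complete = persons[persons["n_items"] == X.shape[1]]
        grouped = complete.groupby("raw_score")["theta"].nunique()
        assert (grouped == 1).all()

    def test_score_table_strictly_increasing(self, calibrated):
        _, _, _, _, abilities = calibrated
        assert np.all(np.diff(abilities.score_table["theta"]) > 0)

    def test_se_largest_at_extremes(self, calibrated):
        _, _, _, _, abilities = calibrated
        se = abilities.score_table["se"].to_numpy()
        assert se.argmax() in (0, len(se) - 1)
        assert se[0] > se[len(se) // 2] and se[-1] > se[len(se) // 2]

    def test_wle_finite_at_extremes(self, calibrated):
        _, _, _, _, abilities = calibrated
        assert np.isfinite(abilities.score_table["theta"]).all()

    def test_single_item_symmetric_mle(self):
        """One extra anchor item to satisfy the 2-item minimum; the target
        item with thresholds (0,0) answered 1-of-2 has MLE theta = 0 by
        symmetry, checked through the score-table midpoint."""
        model = PartialCreditModel(ability_estimator="mle")
        from briefmds.pcm import ItemParameters
        params = ItemParameters(["x"], {"x": np.array([0.0, 0.0])})
        m = PartialCreditModel.from_parameters(params, ability_estimator="mle")
        X = pd.DataFrame({"x": [1.0]})
        at = m.estimate_abilities(X)
        assert at.persons["theta"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_incomplete_persons_measured_on_answered_items(self, calibrated):
        _, _, X, model, _ = calibrated
        Xm = X.copy()
        Xm.iloc[0, 0] = np.nan
        at = model.estimate_abilities(Xm)
        assert at.persons.loc[Xm.index[0], "n_items"] == X.shape[1] - 1
        assert np.isfinite(at.persons.loc[Xm.index[0], "theta"])

    def test_all_missing_person_excluded(self, calibrated):
        _, _, X, model, _ = calibrated
        Xm = X.copy()
        Xm.iloc[1, :] = np.nan
        at = model.estimate_abilities(Xm)
        assert Xm.index[1] in at.excluded
        assert Xm.index[1] not in at.persons.index
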