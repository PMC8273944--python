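"""Diagnostics: ordering, recoding, residuals, local dependence, testlets,
infit/outfit, targeting."""

import math

import numpy as np
import pandas as pd
import pytest

from briefmds.diagnostics import (
    RecodingStrategy,
    TestletSpec,
    apply_recoding,
    build_testlet,
    build_testlets,
    check_threshold_ordering,
    infit_outfit,
    propose_recoding,
    residual_correlations,
    standardized_residuals,
    targeting_summary,
)
from briefmds.pcm import AbilityTable, ItemParameters, fit_pcm
from briefmds.simulate import (
    PersonSpec,
    SimulationConfig,
    generate_pcm_responses,
    inject_local_dependence,
)
from tests.conftest import small_item_bank


class TestThresholdOrdering:
    @pytest.mark.parametrize(
        "thresholds, disordered",
        [
            ((-1.453, -0.209), False),   # published ordered pair
            ((0.5, -0.2), True),         # decreasing
            ((0.3,), False),             # single threshold: vacuously ordered
            ((0.0, 0.0), True),          # ties count as disordered (not strict)
        ],
    )
    def test_flags(self, thresholds, disordered):
        items = ItemParameters(["x", "y"], {"x": np.array(thresholds),
                                            "y": np.array([-1.0, 1.0])})
        flags = dict(check_threshold_ordering(items))
        assert flags["x"] is disordered
        assert flags["y"] is False


class TestRecoding:
    @pytest.mark.parametrize(
        "strategy, original, recoded",
        [
            ("01112", [0, 1, 2, 3, 4], [0, 1, 1, 1, 2]),
            ("00122", [0, 1, 2, 3, 4], [0, 0, 1, 2, 2]),
            ("01234", [0, 1, 2, 3, 4], [0, 1, 2, 3, 4]),
        ],
    )
    def test_strategy_mapping(self, strategy, original, recoded):
        df = pd.DataFrame({"a": original, "b": original})
        out = apply_recoding(df, [RecodingStrategy("a", strategy)])
        assert out["a"].tolist() == recoded
        assert out["b"].tolist() == original  # untouched item

    def test_missing_preserved(self):
        df = pd.DataFrame({"a": [0, np.nan, 4], "b": [1, 2, 3]})
        out = apply_recoding(df, [RecodingStrategy("a", "00122")])
        assert np.isnan(out["a"].iloc[1])

    @pytest.mark.parametrize("bad", ["01021", "1234", "0113"])
    def test_invalid_strategies_rejected(self, bad):
        with pytest.raises(ValueError):
            RecodingStrategy("a", bad)

    def test_propose_recoding_merges_at_disordered_boundary(self):
        # delta_2 <= delta_1: category 1 merged downward
        assert propose_recoding("01234", [0.5, -0.2, 0.6, 1.0]) == "00123"
        # ordered -> no proposal
        assert propose_recoding("01234", [-1, 0, 1, 2]) is None
        # binary item cannot collapse further
        assert propose_recoding("00011", [0.3]) is None


def _manual_ability_table(index, thetas):
    persons = pd.DataFrame({"theta": thetas, "se": 0.5,
                            "raw_score": 0, "n_items": 2}, index=index)
    table = pd.DataFrame({"raw_score": [0], "theta": [0.0], "se": [1.0]})
    return AbilityTable(score_table=table, persons=persons)


class TestStandardizedResiduals:
    def test_hand_computed_fixture(self):
        """2 persons x 2 items against spreadsheet-style arithmetic done with
        explicit exponentials, independent of the package's vectorised
        implementation."""
        items = ItemParameters(["a", "b"], {"a": np.array([-1.0, 1.0]),
                                            "b": np.array([0.0])})
        X = pd.DataFrame({"a": [2.0, 0.0], "b": [1.0, 0.0]}, index=["p", "q"])
        ab = _manual_ability_table(["p", "q"], [0.5, -1.0])
        res = standardized_residuals(X, items, ab).values

        def manual(theta, deltas, x):
            terms = [math.exp(sum(theta - d for d in deltas[:k]))
                     for k in range(len(deltas) + 1)]
            tot = sum(terms)
            p = [t / tot for t in terms]
            e = sum(k * pk for k, pk in enumerate(p))
            w = sum((k - e) ** 2 * pk for k, pk in enumerate(p))
            return (x - e) / math.sqrt(w)

        assert res.loc["p", "a"] == pytest.approx(manual(0.5, [-1, 1], 2.0), abs=1e-10)
        assert res.loc["p", "b"] == pytest.approx(manual(0.5, [0], 1.0), abs=1e-10)
        assert res.loc["q", "a"] == pytest.approx(manual(-1.0, [-1, 1], 0.0), abs=1e-10)
        assert res.loc["q", "b"] == pytest.approx(manual(-1.0, [0], 0.0), abs=1e-10)

    def test_zero_residual_when_response_equals_expectation(self):
        items = ItemParameters(["a", "b"], {"a": np.array([0.0, 0.0]),
                                            "b": np.array([0.0])})
        # thresholds (0,0) at theta 0: symmetric, E = 1 exactly
        X = pd.DataFrame({"a": [1.0], "b": [0.0]}, index=["p"])
        ab = _manual_ability_table(["p"], [0.0])
        res = standardized_residuals(X, items, ab).values
        assert res.loc["p", "a"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_cells_stay_missing(self, calibrated):
        _, _, X, model, abilities = calibrated
        Xm = X.copy()
        Xm.iloc[0, 0] = np.nan
        res = standardized_residuals(Xm, model.item_parameters_, abilities)
        assert np.isnan(res.values.iloc[0, 0])

    def test_mean_residual_near_zero_on_conforming_data(self):
        items = small_item_bank()
        X = generate_pcm_responses(
            items, PersonSpec(n=5000, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=21))
        model = fit_pcm(X)
        ab = model.estimate_abilities(X)
        res = standardized_residuals(X, model.item_parameters_, ab)
        assert res.values.mean().abs().max() < 0.05


class TestResidualCorrelations:
    def test_injected_dependence_flagged_and_independent_not(self):
        items = small_item_bank()
        X = generate_pcm_responses(
            items, PersonSpec(n=3000, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=31))
        X = inject_local_dependence(X, ("i1", "i2"), 0.5, seed=31)
        model = fit_pcm(X)
        res = standardized_residuals(X, model.item_parameters_,
                                     model.estimate_abilities(X))
        corr = residual_correlations(res)
        flagged = {tuple(sorted((r.item_a, r.item_b)))
                   for r in corr.itertuples() if r.flagged}
        assert ("i1", "i2") in flagged
        assert flagged == {("i1", "i2")}

    def test_diagonal_excluded(self, calibrated):
        _, _, X, model, abilities = calibrated
        res = standardized_residuals(X, model.item_parameters_, abilities)
        corr = residual_correlations(res)
        assert not (corr["item_a"] == corr["item_b"]).any()
        assert len(corr) == X.shape[1] * (X.shape[1] - 1) // 2

    def test_sparse_pair_reported_not_flagged(self):
        z = pd.DataFrame({"a": [0.1, np.nan, np.nan, 0.3],
                          "b": [np.nan, 0.2, 0.1, np.nan],
                          "c": [0.5, -0.2, 0.1, -0.4]})
        from briefmds.diagnostics import ResidualMatrix
        corr = residual_correlations(ResidualMatrix(values=z))
        row = corr[(corr.item_a == "a") & (corr.item_b == "b")].iloc[0]
        assert np.isnan(row["r"]) and not row["flagged"]


class TestTestlets:
    def test_sum_and_missing_rule(self):
        df = pd.DataFrame({"a": [2.0, 1.0, np.nan], "b": [3.0, 0.0, 2.0],
                           "c": [1.0, 1.0, 1.0]})
        out = build_testlet(df, TestletSpec(("a", "b"), "a & b"))
        assert out["a & b"].tolist()[:2] == [5.0, 1.0]
        assert np.isnan(out["a & b"].iloc[2])  # any member missing -> missing
        assert "a" not in out.columns and "b" not in out.columns

    def test_two_five_category_items_give_nine_categories(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.integers(0, 5, 400).astype(float),
                           "b": rng.integers(0, 5, 400).astype(float),
                           "c": rng.integers(0, 5, 400).astype(float)})
        out = build_testlet(df, TestletSpec(("a", "b"), "t"))
        assert set(out["t"].unique()) <= set(range(9))
        assert out["t"].max() == 8  # 8 thresholds on refit

    def test_overlapping_testlets_rejected(self):
        df = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [2.0]})
        with pytest.raises(ValueError, match="overlap"):
            build_testlets(df, [TestletSpec(("a", "b"), "t1"),
                                TestletSpec(("b", "c"), "t2")])


class TestInfitOutfit:
    def test_conforming_data_statistics_near_one(self):
        """Model-conforming on-target data: corrected infit/outfit in
        [0.9, 1.1] for every item at n = 5000."""
        items = small_item_bank(n_items=8)
        X = generate_pcm_responses(
            items, PersonSpec(n=5000, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=41))
        model = fit_pcm(X)
        fs = infit_outfit(X, model.item_parameters_, model.estimate_abilities(X))
        assert all(0.9 < v < 1.1 for v in fs.infit.values()), fs.infit
        assert all(0.9 < v < 1.1 for v in fs.outfit.values()), fs.outfit

    def test_permuted_item_shows_misfit(self):
        items = small_item_bank()
        X = generate_pcm_responses(
            items, PersonSpec(n=3000, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=43))
        rng = np.random.default_rng(43)
        X["i3"] = rng.permutation(X["i3"].to_numpy())
        model = fit_pcm(X)
        fs = infit_outfit(X, model.item_parameters_, model.estimate_abilities(X))
        assert fs.outfit["i3"] > 1.2
        assert fs.flags["i3"] == "misfit"

    def test_duplicated_item_shows_overfit(self):
        items = small_item_bank()
        X = generate_pcm_responses(
            items, PersonSpec(n=3000, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=44))
        X["i1"] = X["i2"]  # fully dependent pair
        model = fit_pcm(X)
        fs = infit_outfit(X, model.item_parameters_, model.estimate_abilities(X))
        assert fs.infit["i1"] < 0.8 and fs.infit["i2"] < 0.8


def test_recoding_then_refitting_never_increases_disorder():
    """On PCM-conforming data, applying the proposed collapses and refitting
    does not increase the number of disordered items (20 seeds)."""
    from briefmds.diagnostics import propose_recoding

    def n_disordered(params):
        return sum(d for _, d in check_threshold_ordering(params))

    for seed in range(20):
        items = small_item_bank(n_items=5)
        X = generate_pcm_responses(
            items, PersonSpec(n=600, ability_mean=0.0, ability_sd=1.0),
            SimulationConfig(seed=900 + seed))
        model = fit_pcm(X)
        before = n_disordered(model.item_parameters_)
        if before == 0:
            continue
        strategies = []
        for lab in X.columns:
            prop = propose_recoding("01234", model.item_parameters_.thresholds[lab])
            if prop is not None:
                strategies.append(RecodingStrategy(lab, prop))
        X2 = apply_recoding(X, strategies)
        after = n_disordered(fit_pcm(X2).item_parameters_)
        assert after <= before, (seed, before, after)


class TestTargeting:
    def test_on_target_construction(self, calibrated):
        _, _, _, model, abilities = calibrated
        summary = targeting_summary(model.item_parameters_, abilities)
        assert abs(summary["offset"]) < 0.15

    def test_translation_equivariance(self, calibrated):
        _, _, _, model, abilities = calibrated
        items = model.item_parameters_
        shifted = ItemParameters(items.labels,
                                 {lab: items.thresholds[lab] + 0.7
                                  for lab in items.labels})
        s0 = targeting_summary(items, abilities)
        s1 = targeting_summary(shifted, abilities)
        assert s1["difficulty"]["mean"] == pytest.approx(
            s0["difficulty"]["mean"] + 0.7, abs=1e-10)

    def test_report_shape(self, calibrated):
        _, _, _, model, abilities = calibrated
        summary = targeting_summary(model.item_parameters_, abilities)
        assert set(summary) == {"difficulty", "ability", "offset"}
        assert set(summary["difficulty"]) == {"mean", "sd"}
        assert set(summary["ability"]) == {"mean", "sd"}
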