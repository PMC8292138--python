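"""DII engine: z-scores, centered percentiles, decomposition, tertiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from diindex.reference import FoodParameterReference, ReferenceTableError
from diindex.scoring import (
    DIIScorer,
    IntakeValidationError,
    UnscorableRecordError,
    assign_tertiles,
    centered_percentile,
    dii_score,
    parameter_score,
    score_frame,
    z_score,
)

# frozen oracle values: 2*Phi(z)-1 via numerical integration of the normal pdf
CP_Z196 = 0.9500042097035591
CP_Z2 = 0.9544997361036416


def _phi_numeric(z: float) -> float:
    """Independent standard-normal CDF by quadrature of the density."""
    val, _ = quad(lambda t: math.exp(-t * t / 2) / math.sqrt(2 * math.pi), -12, z)
    return val


class TestZScore:
    @pytest.mark.parametrize(
        "intake, expected",
        [(18.8, 0.0), (28.6, 2.0), (18.8 - 2 * 4.9, -2.0)],
    )
    def test_standardisation(self, fiber_ref, intake, expected):
        assert z_score(intake, fiber_ref) == pytest.approx(expected, abs=1e-12)

    def test_negative_intake_names_parameter(self, fiber_ref):
        with pytest.raises(IntakeValidationError, match="fiber"):
            z_score(-1.0, fiber_ref)

    def test_nonfinite_intake_rejected(self, fiber_ref):
        with pytest.raises(IntakeValidationError):
            z_score(float("nan"), fiber_ref)

    def test_nonpositive_sd_rejected_at_reference_construction(self):
        with pytest.raises(ReferenceTableError):
            FoodParameterReference("x", "g", 1.0, 0.0, 0.1)


class TestCenteredPercentile:
    def test_zero_maps_to_zero(self):
        assert centered_percentile(0.0) == pytest.approx(0.0, abs=1e-15)

    def test_value_at_196(self):
        assert centered_percentile(1.96) == pytest.approx(CP_Z196, abs=1e-10)

    def test_agrees_with_quadrature_oracle_on_grid(self):
        zs = np.linspace(-5, 5, 81)
        ours = centered_percentile(zs)
        oracle = np.array([2 * _phi_numeric(z) - 1 for z in zs])
        assert np.max(np.abs(ours - oracle)) < 1e-8

    @given(st.floats(-8, 8))
    @settings(deadline=None, max_examples=100)
    def test_odd_function(self, z):
        assert centered_percentile(-z) == pytest.approx(-centered_percentile(z), abs=1e-12)

    def test_strictly_increasing(self):
        zs = np.linspace(-6, 6, 500)
        assert np.all(np.diff(centered_percentile(zs)) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(IntakeValidationError):
            centered_percentile(float("inf"))


class TestParameterScore:
    def test_at_mean_is_zero_for_any_effect(self):
        for effect in (-0.663, 0.0, 0.373):
            ref = FoodParameterReference("x", "g", 10.0, 2.0, effect)
            assert parameter_score(10.0, ref) == pytest.approx(0.0, abs=1e-15)

    def test_fiber_two_sd_above_mean(self, fiber_ref):
        expected = CP_Z2 * -0.663  # ~ -0.6328
        assert parameter_score(28.6, fiber_ref) == pytest.approx(expected, abs=1e-9)

    def test_sign_rule(self):
        pro = FoodParameterReference("satfat", "g", 10.0, 2.0, 0.373)
        assert parameter_score(14.0, pro) > 0
        anti = FoodParameterReference("fib", "g", 10.0, 2.0, -0.663)
        assert parameter_score(14.0, anti) < 0


class TestDIIScore:
    def test_all_at_global_means_scores_zero(self, reference):
        record = {name: reference[name].global_mean for name in reference.names}
        result = dii_score(record, reference)
        assert result.n_parameters_used == 26
        assert result.total == pytest.approx(0.0, abs=1e-12)

    def test_single_parameter_equals_parameter_score(self, reference, fiber_ref):
        result = dii_score({"fiber": 28.6}, reference, min_parameters=1)
        assert result.total == pytest.approx(parameter_score(28.6, fiber_ref), abs=1e-12)

    def test_below_floor_flagged_not_zeroed(self, reference):
        with pytest.raises(UnscorableRecordError, match="minimum 20"):
            dii_score({"fiber": 10.0, "zinc": 5.0}, reference)

    def test_unknown_parameter_rejected(self, reference):
        with pytest.raises(IntakeValidationError, match="unknown"):
            dii_score({"pixie_dust": 1.0}, reference, min_parameters=0)

    def test_decomposition_and_bound_fuzz(self, reference):
        """Total == sum of contributions (1e-12) and |total| <= sum |effect|."""
        rng = np.random.default_rng(42)
        n = 10_000
        frame = pd.DataFrame(
            {
                name: reference[name].global_mean
                * np.exp(rng.normal(0, 0.8, n))
                for name in reference.names
            }
        )
        scored = score_frame(frame, reference, contributions=True)
        contrib = scored.filter(like="contrib_").to_numpy()
        assert np.allclose(scored["dii_total"], contrib.sum(axis=1), atol=1e-12)
        bound = sum(abs(reference[nm].effect_score) for nm in reference.names)
        assert np.all(np.abs(scored["dii_total"]) <= bound)
        cps = contrib / np.array([reference[nm].effect_score for nm in reference.names])
        assert np.all(np.abs(cps[np.isfinite(cps)]) < 1)

    def test_monotone_in_single_parameter(self, reference):
        base = {name: reference[name].global_mean for name in reference.names}
        low = dii_score({**base, "fiber": 10.0}, reference).total
        high = dii_score({**base, "fiber": 30.0}, reference).total
        assert high < low  # fiber is anti-inflammatory
        low = dii_score({**base, "saturated_fat": 10.0}, reference).total
        high = dii_score({**base, "saturated_fat": 50.0}, reference).total
        assert high > low

    def test_absent_parameters_excluded_from_count(self, reference):
        record = {name: reference[name].global_mean for name in reference.names}
        record.pop("alcohol")
        assert dii_score(record, reference).n_parameters_used == 25


class TestScoreFrame:
    def test_negative_intake_names_row_and_column(self, tiny_reference):
        frame = pd.DataFrame({"fiber": [10.0, -2.0], "magnesium": [300.0, 300.0]})
        with pytest.raises(IntakeValidationError, match="fiber"):
            score_frame(frame, tiny_reference, min_parameters=1)

    def test_unscorable_rows_are_nan_flagged(self, tiny_reference):
        frame = pd.DataFrame(
            {"fiber": [18.8, np.nan], "magnesium": [310.1, np.nan],
             "saturated_fat": [28.6, np.nan]}
        )
        out = score_frame(frame, tiny_reference, min_parameters=2)
        assert bool(out["scorable"].iloc[0]) and not bool(out["scorable"].iloc[1])
        assert np.isnan(out["dii_total"].iloc[1])


class TestTertiles:
    def test_paper_sized_split(self):
        rng = np.random.default_rng(0)
        tert = assign_tertiles(rng.normal(0, 1.7, 1382))
        assert tert.counts == {"T1": 460, "T2": 461, "T3": 461}

    def test_six_scores(self):
        tert = assign_tertiles([1, 2, 3, 4, 5, 6])
        assert tert.counts == {"T1": 2, "T2": 2, "T3": 2}
        assert list(tert.labels[:2]) == ["T1", "T1"]

    def test_order_consistency(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=1000)
        tert = assign_tertiles(scores)
        assert scores[tert.labels == "T1"].max() <= scores[tert.labels == "T2"].min()
        assert scores[tert.labels == "T2"].max() <= scores[tert.labels == "T3"].min()

    def test_boundary_tie_goes_to_lower_tertile(self):
        # six distinct + one duplicate of the T1 upper bound
        tert = assign_tertiles([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        assert tert.boundaries[0] == 2.0
        labels_of_twos = tert.labels[np.array([1, 2])]
        assert list(labels_of_twos) == ["T1", "T2"]  # stable input order breaks ties

    def test_midrange_score_lands_in_t2(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.uniform(-4, -1, 400), [0.0],
                                 rng.uniform(1.2, 4.5, 400)])
        tert = assign_tertiles(scores)
        assert tert.labels[400] == "T2"
        assert tert.boundaries[0] < 0.0 < tert.boundaries[1]

    @pytest.mark.parametrize("scores", [[1.0, 2.0], [3.0, 3.0, 3.0]])
    def test_degenerate_inputs_rejected(self, scores):
        with pytest.raises(ValueError):
            assign_tertiles(scores)


class TestDIIScorerTransformer:
    def test_transform_matches_score_frame(self, reference):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {name: reference[name].global_mean * np.exp(rng.normal(0, 0.5, 50))
             for name in reference.names}
        )
        scorer = DIIScorer().fit(X)
        totals = scorer.transform(X).ravel()
        expected = score_frame(X, reference)["dii_total"].to_numpy()
        assert np.allclose(totals, expected)
        assert scorer.get_feature_names_out().tolist() == ["dii_total"]

    def test_pipeline_composition(self, reference):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {name: reference[name].global_mean * np.exp(rng.normal(0, 0.5, 40))
             for name in reference.names}
        )
        pipe = Pipeline([("dii", DIIScorer()), ("scale", StandardScaler())])
        out = pipe.fit_transform(X)
        assert out.shape == (40, 1)

    def test_requires_reference_columns(self):
        with pytest.raises(IntakeValidationError):
            DIIScorer().fit(pd.DataFrame({"not_a_nutrient": [1.0]}))
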