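"""Descriptive comparisons: chi-square oracle, Levene-driven test selection."""

import numpy as np
import pandas as pd
import pytest

from diindex.compare import (
    compare_continuous,
    format_p,
    percent,
    summarize_categorical,
    tertile_table,
)


def brute_force_chi2(table: np.ndarray) -> float:
    """Textbook sum (O-E)^2 / E with hand-computed expected counts."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _cat_frame(counts_by_group: dict[str, dict[str, int]]) -> pd.DataFrame:
    rows = []
    for g, counts in counts_by_group.items():
        for level, n in counts.items():
            rows += [{"group": g, "var": level}] * n
    return pd.DataFrame(rows)


class TestPercent:
    def test_sex_row_identity(self):
        # 778 of 1,382 male HF participants
        assert percent(778, 1382) == 56.30

    def test_denominator_must_be_positive(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    def test_p_formatting(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.0421) == "0.042"


class TestCategorical:
    def test_chi_square_matches_brute_force_2x2(self):
        counts = {"HF": {"male": 778, "female": 604},
                  "non-HF": {"male": 8472, "female": 9213}}
        frame = _cat_frame(counts)
        res = summarize_categorical(frame, "var")
        table = np.array([[778, 8472], [604, 9213]])
        assert res.statistic == pytest.approx(brute_force_chi2(table), abs=1e-9)
        assert res.groups["HF"]["percent"]["male"] == 56.30

    def test_chi_square_matches_brute_force_3xk(self):
        rng = np.random.default_rng(8)
        counts = {
            g: {lv: int(rng.integers(20, 200)) for lv in ("a", "b", "c", "d")}
            for g in ("T1", "T2", "T3")
        }
        frame = _cat_frame(counts)
        res = summarize_categorical(frame, "var")
        table = np.array([[counts[g][lv] for g in ("T1", "T2", "T3")]
                          for lv in ("a", "b", "c", "d")])
        assert res.statistic == pytest.approx(brute_force_chi2(table), abs=1e-9)

    def test_identical_proportions_give_zero_statistic(self):
        counts = {"A": {"x": 30, "y": 70}, "B": {"x": 60, "y": 140}}
        res = summarize_categorical(_cat_frame(counts), "var")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_missing_is_reported_but_not_tested(self):
        frame = _cat_frame({"A": {"x": 10, "y": 10}, "B": {"x": 12, "y": 8}})
        frame.loc[len(frame)] = {"group": "A", "var": None}
        res = summarize_categorical(frame, "var")
        assert res.groups["A"]["missing"] == 1
        assert res.groups["A"]["n"] == 21  # denominator includes missing
        # percentages computed on the full group size
        assert res.groups["A"]["percent"]["x"] == percent(10, 21)

    def test_single_level_rejected(self):
        frame = _cat_frame({"A": {"x": 5}, "B": {"x": 5}})
        with pytest.raises(ValueError, match="single level"):
            summarize_categorical(frame, "var")


class TestContinuous:
    def test_identical_samples_give_t0_p1(self):
        frame = pd.DataFrame({
            "group": ["A"] * 5 + ["B"] * 5,
            "v": [1.0, 2.0, 3.0, 4.0, 5.0] * 2,
        })
        res = compare_continuous(frame, "v")
        assert res.method == "t_test"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_means_with_permutation_oracle(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(0, 1, 500), rng.normal(1, 1, 500)
        frame = pd.DataFrame({"group": ["A"] * 500 + ["B"] * 500,
                              "v": np.r_[x, y]})
        res = compare_continuous(frame, "v")
        assert res.p_value < 1e-3
        # permutation oracle: observed |mean diff| is never exceeded
        pooled = np.r_[x, y]
        obs = abs(x.mean() - y.mean())
        exceed = 0
        for _ in range(10_000):
            rng.shuffle(pooled)
            if abs(pooled[:500].mean() - pooled[500:].mean()) >= obs:
                exceed += 1
        assert (exceed + 1) / 10_001 < 1e-3

    def test_welch_selected_when_levene_rejects(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({
            "group": ["A"] * 300 + ["B"] * 300,
            "v": np.r_[rng.normal(0, 1, 300), rng.normal(0, 6, 300)],
        })
        res = compare_continuous(frame, "v")
        assert res.homogeneity[1] < 0.05
        assert res.method == "welch_t_test"

    def test_anova_with_lsd_posthoc_when_homogeneous(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({
            "group": ["A"] * 200 + ["B"] * 200 + ["C"] * 200,
            "v": np.r_[rng.normal(0, 1, 200), rng.normal(0, 1, 200),
                       rng.normal(0.8, 1, 200)],
        })
        res = compare_continuous(frame, "v")
        assert res.method == "anova"
        assert res.p_value < 0.05
        assert res.posthoc[0] == "LSD"
        assert res.posthoc[1][("A", "C")] < 0.01
        assert res.posthoc[1][("A", "B")] > 0.05

    def test_dunnett_t3_selected_under_heteroscedasticity(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame({
            "group": ["A"] * 200 + ["B"] * 200 + ["C"] * 200,
            "v": np.r_[rng.normal(0, 1, 200), rng.normal(0, 5, 200),
                       rng.normal(2, 5, 200)],
        })
        res = compare_continuous(frame, "v")
        assert res.homogeneity[1] < 0.05
        assert res.posthoc[0] == "Dunnett_T3"
        # T3 is conservative: adjusted p >= unadjusted Welch pairwise p
        from scipy.stats import ttest_ind
        a = frame.loc[frame.group == "A", "v"]
        c = frame.loc[frame.group == "C", "v"]
        _, welch_p = ttest_ind(a, c, equal_var=False)
        assert res.posthoc[1][("A", "C")] >= welch_p

    def test_no_posthoc_without_significant_omnibus(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame({
            "group": ["A", "B", "C"] * 100,
            "v": rng.normal(0, 1, 300),
        })
        res = compare_continuous(frame, "v")
        assert res.posthoc is None or res.p_value < 0.05

    def test_tiny_group_rejected_by_name(self):
        frame = pd.DataFrame({"group": ["A", "A", "B"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'B'"):
            compare_continuous(frame, "v")

    def test_missing_dropped_with_n_reported(self):
        frame = pd.DataFrame({
            "group": ["A"] * 4 + ["B"] * 4,
            "v": [1.0, 2.0, np.nan, 3.0, 2.0, 3.0, 4.0, np.nan],
        })
        res = compare_continuous(frame, "v")
        assert res.groups["A"]["n"] == 3
        assert res.groups["B"]["n"] == 3


class TestTertileTable:
    def test_hf_restricted_sizes_and_variables(self, small_cohort, reference):
        from diindex.cohort import build_cohort, intake_frame
        from diindex.scoring import score_frame

        participants, _ = small_cohort
        scored = score_frame(intake_frame(participants), reference)
        ds = build_cohort(participants, reference=reference,
                          scorable=scored["scorable"])
        records = ds.records
        scores = scored["dii_total"].reindex(records.index)
        tert, results = tertile_table(records, scores)
        n_hf = ds.flow.n_hf
        sizes = sorted(tert.counts.values())
        assert sum(sizes) == n_hf and sizes[-1] - sizes[0] <= 1
        assert "age" in results and results["age"].method == "anova"
        assert "sex" in results and results["sex"].method == "chi_square"

    def test_score_required_for_every_participant(self):
        records = pd.DataFrame({"group": ["HF"] * 4, "age": [60, 61, 62, 63]})
        scores = pd.Series([0.1, np.nan, 0.3, 0.4], index=records.index)
        with pytest.raises(ValueError, match="required"):
            tertile_table(records, scores)
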