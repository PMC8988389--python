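"""Forward-window labeling, AUC/DeLong machinery, threshold tables,
efficiency curves and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ewsbench as eb
from ewsbench.evaluation import (
    DegenerateLabelsError,
    compute_auc,
    delong_compare,
    efficiency_curve,
    format_percent,
    label_observations,
    round_half_away,
    summarize_cohort,
    threshold_metrics,
    threshold_table,
)

from conftest import make_cohort, simple_encounter


def brute_force_auc(scores, labels):
    """O(n^2) pair counting with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def _events(*pairs):
    return pd.DataFrame(
        [(pid, "DETERIORATION", pd.Timestamp(t), "") for pid, t in pairs],
        columns=["patient_id", "kind", "event_time", "evidence_summary"],
    )


def _wide(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "time", "S"])
    df["time"] = pd.to_datetime(df["time"])
    return df


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


class TestLabeling:
    def test_event_within_window_labels_one(self):
        series = label_observations(
            _wide([("p1", "2024-01-01 00:00", 3)]),
            _events(("p1", "2024-01-01 10:00")),
        )
        assert series.labels.tolist() == [1]

    def test_event_beyond_window_labels_zero_then_one(self):
        series = label_observations(
            _wide([("p1", "2024-01-01 00:00", 3), ("p1", "2024-01-01 12:00", 4)]),
            _events(("p1", "2024-01-02 06:00")),  # 30 h after first obs
        )
        assert series.labels.tolist() == [0, 1]

    def test_no_events_all_zero(self):
        series = label_observations(_wide([("p1", "2024-01-01 00:00", 3)]), _events())
        assert series.labels.tolist() == [0]

    def test_observations_at_or_after_event_excluded(self):
        series = label_observations(
            _wide([("p1", "2024-01-01 00:00", 3), ("p1", "2024-01-02 00:00", 9)]),
            _events(("p1", "2024-01-01 12:00")),
        )
        assert len(series.frame) == 1 and series.n_excluded == 1

    def test_boundary_exactly_at_horizon_is_positive(self):
        series = label_observations(
            _wide([("p1", "2024-01-01 00:00", 3)]),
            _events(("p1", "2024-01-02 00:00")),  # exactly t + 24 h
        )
        assert series.labels.tolist() == [1]

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            label_observations(_wide([("p1", "2024-01-01 00:00", 3)]), _events(), horizon_h=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        offsets=st.lists(st.integers(1, 72), min_size=1, max_size=20),
        event_h=st.integers(1, 96),
        h1=st.integers(1, 48),
        shrink=st.integers(1, 24),
    )
    def test_shrinking_horizon_never_adds_positives(self, offsets, event_h, h1, shrink):
        t0 = pd.Timestamp("2024-01-01")
        rows = [("p1", t0 + pd.Timedelta(hours=o), 1.0) for o in sorted(set(offsets))]
        ev = _events(("p1", t0 + pd.Timedelta(hours=event_h)))
        wide = _wide([(p, t, s) for p, t, s in rows])
        big = label_observations(wide, ev, horizon_h=h1 + shrink).labels.sum()
        small = label_observations(wide, ev, horizon_h=h1).labels.sum()
        assert small <= big


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


class TestAuc:
    def test_perfect_ranking_is_one(self):
        assert compute_auc([4, 3, 2, 1], [1, 1, 0, 0]).auc == 1.0

    def test_constant_scores_are_half_with_zero_variance(self):
        r = compute_auc([2, 2, 2, 2], [1, 0, 1, 0])
        assert r.auc == 0.5 and r.variance == 0.0
        assert (r.ci_lower, r.ci_upper) == (0.5, 0.5)

    def test_worked_pair_counting_example(self):
        # pos {3, 2}, neg {2, 1}: (1 + 1 + 0.5 + 1)/4 = 0.875
        r = compute_auc([3, 2, 2, 1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.875)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            compute_auc([1, 2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 200),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    def test_midrank_auc_equals_bruteforce_and_sklearn(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = rng.integers(0, 6, n).astype(float) if ties else rng.normal(size=n)
        got = compute_auc(scores, labels).auc
        assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# DeLong comparison
# ---------------------------------------------------------------------------


class TestDeLong:
    def test_score_compared_with_itself_is_exactly_null(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.4).astype(int)
        diff, z, p = delong_compare(scores, scores, labels)
        assert diff == 0.0 and p == 1.0

    def test_identical_auc_zero_variance_gives_p_one(self):
        labels = [1, 1, 0, 0]
        diff, _, p = delong_compare([4, 3, 2, 1], [40, 30, 20, 10], labels)
        assert diff == 0.0 and p == 1.0

    def test_perfect_vs_constant_is_significant_at_moderate_n(self):
        rng = np.random.default_rng(7)
        labels = np.array([1] * 50 + [0] * 50)
        perfect = labels * 1.0 + rng.normal(scale=1e-6, size=100)
        constant = np.zeros(100)
        diff, z, p = delong_compare(perfect, constant, labels)
        assert diff == pytest.approx(0.5, abs=1e-3)
        assert p < 0.05

    def test_sign_of_difference_matches_auc_order(self):
        labels = np.array([1] * 20 + [0] * 20)
        good = np.r_[np.full(20, 2.0), np.full(20, 1.0)]
        rng = np.random.default_rng(0)
        noise = rng.normal(size=40)
        d_ab, _, _ = delong_compare(good, noise, labels)
        d_ba, _, _ = delong_compare(noise, good, labels)
        assert d_ab > 0 and d_ba == pytest.approx(-d_ab)


# ---------------------------------------------------------------------------
# Threshold tables and efficiency curves
# ---------------------------------------------------------------------------


class TestThresholds:
    SCORES = [0, 1, 1, 2, 3, 5]
    LABELS = [0, 0, 1, 0, 1, 1]

    def test_threshold_below_min_alerts_everything(self):
        (m,) = threshold_metrics(self.SCORES, self.LABELS, thresholds=[-1])
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_threshold_above_max_alerts_nothing(self):
        (m,) = threshold_metrics(self.SCORES, self.LABELS, thresholds=[99])
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_hand_counted_confusion_at_two(self):
        (m,) = threshold_metrics(self.SCORES, self.LABELS, thresholds=[2])
        # alerts: scores {2,3,5} -> TP {3,5}=2, FP {2}=1, FN {1}=1, TN {0,1}=2
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 1, 2, 1)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.ppv == pytest.approx(2 / 3)
        assert m.npv == pytest.approx(2 / 3)

    def test_sweep_monotone_and_integrates_to_auc(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(0, 10, 400).astype(float)
        labels = (rng.random(400) < 0.3).astype(int)
        table = threshold_table(scores, labels)
        sens = table["sensitivity"].to_numpy()
        spec = table["specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()      # non-increasing in threshold
        assert (np.diff(spec) >= -1e-12).all()     # non-decreasing in threshold
        # ROC sweep (1-spec, sens) + corners integrates to the midrank AUC
        fpr = np.r_[1.0, 1.0 - spec, 0.0]
        tpr = np.r_[1.0, sens, 0.0]
        auc_trap = -np.trapezoid(tpr, fpr)
        assert auc_trap == pytest.approx(compute_auc(scores, labels).auc, abs=1e-9)


class TestEfficiencyCurve:
    def test_constant_scores_single_point(self):
        c = efficiency_curve([1, 1, 1], [0, 1, 0])
        assert c.points == [(1.0, 1.0)]

    def test_positives_first_curve_passes_prevalence_point(self):
        scores = [5, 4, 3, 2, 1, 0]
        labels = [1, 1, 1, 0, 0, 0]
        c = efficiency_curve(scores, labels)
        assert (0.5, 1.0) in c.points       # alert fraction n_pos/n at sens 1
        assert c.points[-1] == (1.0, 1.0)   # threshold at min score

    def test_sensitivity_nondecreasing_in_alert_fraction(self):
        rng = np.random.default_rng(5)
        c = efficiency_curve(rng.integers(0, 8, 300), (rng.random(300) < 0.2).astype(int))
        sens = [s for _, s in c.points]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


class TestSummaries:
    def test_percent_rounding_half_away_from_zero(self):
        assert round_half_away(0.25, 1) == 0.3
        assert round_half_away(0.15, 1) == 0.2
        assert format_percent(43, 19611) == 0.2
        assert format_percent(88, 19611) == 0.4

    def test_single_patient_group_medians_and_na_comparisons(self):
        cohort = make_cohort(
            encounters=[
                simple_encounter("p1", age_years=30.0),
                simple_encounter("p2", age_years=25.0),
            ],
        )
        summary = summarize_cohort(cohort.encounters, _events(("p1", "2024-01-02 00:00")))
        age_row = summary[summary["characteristic"].str.startswith("Age")].iloc[0]
        assert age_row.iloc[2] == "30 (30, 30)"

    def test_empty_event_group_marks_comparisons_na(self):
        cohort = make_cohort(encounters=[simple_encounter("p1"), simple_encounter("p2")])
        summary = summarize_cohort(cohort.encounters, _events())
        dm = summary[summary["characteristic"].str.startswith("Diabetes")].iloc[0]
        assert dm["p_value"] == "NA"


# ---------------------------------------------------------------------------
# Orchestrated comparison bundle
# ---------------------------------------------------------------------------


class TestCompareAll:
    def _series(self, k_systems, n=60, seed=4):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "time": pd.Timestamp("2024-01-01"),
            "label": (rng.random(n) < 0.4).astype(int),
        })
        for j in range(k_systems):
            df[f"S{j}"] = rng.normal(size=n)
        from ewsbench.evaluation import LabeledScoreSeries

        return LabeledScoreSeries(
            frame=df, systems=tuple(f"S{j}" for j in range(k_systems)),
            horizon_h=24.0, outcome_kind="DETERIORATION",
        )

    def test_matrix_shapes_and_symmetry(self):
        bundle = eb.compare_all_systems(self._series(6))
        assert bundle.delong_pvalues.shape == (6, 6)
        assert np.allclose(np.diag(bundle.delong_pvalues), 1.0)
        assert np.allclose(bundle.delong_pvalues, bundle.delong_pvalues.T)
        assert np.allclose(bundle.delong_differences, -bundle.delong_differences.T)
        assert len(bundle.auc_table) == 6

    def test_duplicated_score_column_gives_p_one(self):
        series = self._series(1)
        series.frame["S_copy"] = series.frame["S0"]
        series.systems = ("S0", "S_copy")
        bundle = eb.compare_all_systems(series)
        assert bundle.delong_pvalues.loc["S0", "S_copy"] == 1.0

    def test_auc_table_sorted_descending(self):
        bundle = eb.compare_all_systems(self._series(4))
        aucs = bundle.auc_table["auc"].to_numpy()
        assert (np.diff(aucs) <= 0).all()
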