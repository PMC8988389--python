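"""Observation-level evaluation of early warning scores.

The unit of analysis is the ward observation: the score is computed at each
charting time and the label is whether the patient's first outcome event
falls in the forward window ``(t, t + 24 h]``.  Observations at or after the
event are excluded.  Discrimination is the AUC with DeLong variance; systems
are compared pairwise with the paired DeLong z-test; threshold tables give
sensitivity/specificity/PPV/NPV at each cutoff (alert rule: score >=
threshold); efficiency curves plot sensitivity against the fraction of
observations that alert.

The DeLong machinery is implemented from the structural components
(midrank / placement-value formulation), which makes the AUC identical to
pair counting with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import OutcomeEvent

DEFAULT_HORIZON_H = 24.0


class DegenerateLabelsError(ValueError):
    """Labels contain fewer than one positive or one negative."""


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


@dataclass
class LabeledScoreSeries:
    """Per-observation score values paired with the forward-window label.

    ``frame`` columns: patient_id, time, label, plus one numeric column per
    system.  ``n_excluded`` counts observations dropped because they fell at
    or after the patient's first event.
    """

    frame: pd.DataFrame
    systems: tuple[str, ...]
    horizon_h: float
    outcome_kind: str
    n_excluded: int = 0

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def scores(self, system: str) -> np.ndarray:
        return self.frame[system].to_numpy(dtype=float)


def pivot_scores(scores_long: pd.DataFrame) -> pd.DataFrame:
    """Long score table (one row per snapshot x system) -> wide (one column
    per system)."""
    wide = scores_long.pivot_table(
        index=["patient_id", "time"], columns="system", values="ordinal_value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return wide


def label_observations(
    scores_wide: pd.DataFrame,
    events: Sequence[OutcomeEvent] | pd.DataFrame,
    horizon_h: float = DEFAULT_HORIZON_H,
    outcome_kind: str = "DETERIORATION",
) -> LabeledScoreSeries:
    """Attach the forward-looking outcome label to each scored observation.

    label = 1 iff the patient's first event of ``outcome_kind`` occurs in
    ``(t, t + horizon_h]``; observations with ``t >= event_time`` are
    excluded and counted in ``n_excluded``.
    """
    if horizon_h <= 0:
        raise ValueError("horizon must be positive")
    if isinstance(events, pd.DataFrame):
        ev = events
    else:
        from .phenotypes import events_to_frame

        ev = events_to_frame(list(events))
    ev = ev[ev["kind"].str.upper() == outcome_kind.upper()] if not ev.empty else ev
    first = (
        ev.groupby("patient_id")["event_time"].min()
        if not ev.empty
        else pd.Series(dtype="datetime64[ns]")
    )

    df = scores_wide.copy()
    df["event_time"] = df["patient_id"].map(first)
    after = df["event_time"].notna() & (df["time"] >= df["event_time"])
    n_excluded = int(after.sum())
    df = df[~after].copy()
    window = pd.Timedelta(hours=horizon_h)
    df["label"] = (
        df["event_time"].notna()
        & (df["event_time"] > df["time"])
        & (df["event_time"] <= df["time"] + window)
    ).astype(int)
    df = df.drop(columns=["event_time"]).reset_index(drop=True)

    systems = tuple(c for c in df.columns if c not in ("patient_id", "time", "label"))
    return LabeledScoreSeries(
        frame=df,
        systems=systems,
        horizon_h=horizon_h,
        outcome_kind=outcome_kind.upper(),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# DeLong AUC machinery
# ---------------------------------------------------------------------------


@dataclass
class AucResult:
    system: str
    auc: float
    variance: float
    ci_lower: float
    ci_upper: float
    n_pos: int
    n_neg: int


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = labels == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise DegenerateLabelsError(
            "degenerate_labels: need at least one positive and one negative"
        )
    return pos, neg


def _delong_placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Placement values (structural components) and the AUC.

    V10[i] = fraction of negatives that positive i outranks (ties half);
    V01[j] = fraction of positives that negative j is outranked by.
    Computed with midranks, equivalent to exhaustive pair counting.
    """
    x = np.asarray(scores, dtype=float)
    m = int(pos.sum())
    n = int(neg.sum())
    tz = stats.rankdata(np.concatenate([x[pos], x[neg]]))
    tx = stats.rankdata(x[pos])
    ty = stats.rankdata(x[neg])
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def compute_auc(scores: Sequence[float], labels: Sequence[int], system: str = "") -> AucResult:
    """AUC with DeLong variance and normal-approximation 95% CI.

    Constant scores give AUC exactly 0.5 (all pairs tied, counted one half)
    with zero variance.
    """
    pos, neg = _check_labels(np.asarray(labels))
    auc, v10, v01 = _delong_placements(np.asarray(scores, dtype=float), pos, neg)
    m, n = int(pos.sum()), int(neg.sum())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(var)
    return AucResult(
        system=system,
        auc=auc,
        variance=float(var),
        ci_lower=float(max(0.0, auc - half)),
        ci_upper=float(min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
    )


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """Paired DeLong test of two correlated AUCs on the same observations.

    Returns ``(auc_a - auc_b, z, two-sided p)``.  When the variance of the
    difference is zero (e.g. a score compared with itself) the difference is
    0 and p = 1 exactly.
    """
    labels = np.asarray(labels)
    pos, neg = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors must align with labels")

    auc_a, v10_a, v01_a = _delong_placements(a, pos, neg)
    auc_b, v10_b, v01_b = _delong_placements(b, pos, neg)
    m, n = int(pos.sum()), int(neg.sum())

    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n

    diff = auc_a - auc_b
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 0.0, 1.0
        return float(diff), float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(z), float(p)


# ---------------------------------------------------------------------------
# Threshold tables and efficiency curves
# ---------------------------------------------------------------------------


@dataclass
class ThresholdMetrics:
    system: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def threshold_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] | None = None,
    system: str = "",
) -> list[ThresholdMetrics]:
    """Confusion-matrix accuracy at each cutoff; alert rule is score >= threshold."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.unique(x)
    out = []
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    for thr in thresholds:
        alert = x >= thr
        tp = int((alert & (y == 1)).sum())
        fp = int((alert & (y == 0)).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        out.append(
            ThresholdMetrics(
                system=system,
                threshold=float(thr),
                tp=tp, fp=fp, tn=tn, fn=fn,
                sensitivity=tp / n_pos if n_pos else float("nan"),
                specificity=tn / n_neg if n_neg else float("nan"),
                ppv=tp / (tp + fp) if tp + fp else float("nan"),
                npv=tn / (tn + fn) if tn + fn else float("nan"),
            )
        )
    return out


def threshold_table(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] | None = None,
    system: str = "",
) -> pd.DataFrame:
    rows = threshold_metrics(scores, labels, thresholds, system=system)
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class EfficiencyCurve:
    """Alarm-burden trade-off: one point per distinct threshold.

    ``alert_fraction`` — proportion of observations with score >= threshold;
    ``sensitivity`` — sensitivity at that threshold.  Sorted by alert
    fraction; the last point (threshold at the minimum score) is (1, 1).
    """

    system: str
    points: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["alert_fraction", "sensitivity"]).assign(
            system=self.system
        )[["system", "alert_fraction", "sensitivity"]]


def efficiency_curve(
    scores: Sequence[float], labels: Sequence[int], system: str = ""
) -> EfficiencyCurve:
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(x)
    n_pos = int((y == 1).sum())
    pts = []
    for thr in np.unique(x):
        alert = x >= thr
        frac = float(alert.sum()) / n
        sens = float((alert & (y == 1)).sum()) / n_pos if n_pos else float("nan")
        pts.append((frac, sens))
    pts.sort()
    return EfficiencyCurve(system=system, points=pts)


# ---------------------------------------------------------------------------
# Cohort summarization (characteristics tables)
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables;
    Python's builtin rounds half to even)."""
    factor = 10 ** ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def format_percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage of ``numerator/denominator`` rounded half-away-from-zero."""
    if denominator == 0:
        return float("nan")
    return float(round_half_away(100.0 * numerator / denominator, ndigits))


def _median_iqr(x: pd.Series) -> str:
    x = pd.to_numeric(x, errors="coerce").dropna()
    if x.empty:
        return "NA"
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:g} ({q1:g}, {q3:g})"


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.2f}"


def summarize_cohort(
    encounters: pd.DataFrame,
    events: Sequence[OutcomeEvent] | pd.DataFrame,
    outcome_kind: str = "DETERIORATION",
) -> pd.DataFrame:
    """Characteristics table comparing outcome vs no-outcome patients.

    Continuous covariates: median (IQR), Wilcoxon rank-sum p.  Categorical:
    n (percent, one decimal, half-away-from-zero), chi-squared p.  With an
    empty group the comparison is marked not computable (p = NA).
    """
    if isinstance(events, pd.DataFrame):
        ev = events
    else:
        from .phenotypes import events_to_frame

        ev = events_to_frame(list(events))
    if not ev.empty:
        ev = ev[ev["kind"].str.upper() == outcome_kind.upper()]
    event_pids = set(ev["patient_id"]) if not ev.empty else set()

    df = encounters.copy()
    df["outcome"] = df["patient_id"].isin(event_pids)
    df["los_days"] = (
        (df["discharge_time"] - df["admit_time"]).dt.total_seconds() / 86400.0
    )
    df["died"] = df["death_time"].notna() if "death_time" in df else False
    g1 = df[df["outcome"]]
    g0 = df[~df["outcome"]]
    n1, n0 = len(g1), len(g0)

    rows: list[dict] = []

    def _add(characteristic, v0, v1, p):
        rows.append(
            {
                "characteristic": characteristic,
                f"no_outcome (n={n0})": v0,
                f"outcome (n={n1})": v1,
                "p_value": p,
            }
        )

    _add("n", n0, n1, "")
    _add(
        "event rate (%)",
        "",
        f"{format_percent(n1, n0 + n1)}%",
        "",
    )

    def _ranksum(col):
        a = pd.to_numeric(g0[col], errors="coerce").dropna()
        b = pd.to_numeric(g1[col], errors="coerce").dropna()
        if len(a) == 0 or len(b) == 0:
            return float("nan")
        if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    def _chi2(flag_col):
        tab = pd.crosstab(df["outcome"], df[flag_col].astype(bool))
        if tab.shape != (2, 2):
            return float("nan")
        return float(stats.chi2_contingency(tab, correction=False).pvalue)

    for col, label in (
        ("age_years", "Age, years (median, IQR)"),
        ("bmi", "Body mass index, kg/m2 (median, IQR)"),
        ("los_days", "Total length of stay, days (median, IQR)"),
    ):
        if col in df.columns:
            _add(label, _median_iqr(g0[col]), _median_iqr(g1[col]), _fmt_p(_ranksum(col)))

    for col, label in (
        ("diabetes", "Diabetes mellitus (n, %)"),
        ("hypertensive_disorder", "Hypertensive disorders (n, %)"),
        ("died", "In-hospital mortality (n, %)"),
    ):
        if col in df.columns:
            k0 = int(g0[col].astype(bool).sum())
            k1 = int(g1[col].astype(bool).sum())
            _add(
                label,
                f"{k0} ({format_percent(k0, n0)}%)" if n0 else "NA",
                f"{k1} ({format_percent(k1, n1)}%)" if n1 else "NA",
                _fmt_p(_chi2(col)) if n0 and n1 else "NA",
            )

    if "race_ethnicity" in df.columns and df["race_ethnicity"].notna().any():
        tab = pd.crosstab(df["outcome"], df["race_ethnicity"])
        p = (
            float(stats.chi2_contingency(tab).pvalue)
            if tab.shape[0] == 2 and tab.shape[1] > 1
            else float("nan")
        )
        _add("Race/ethnicity (n, %)", "", "", _fmt_p(p))
        for cat in sorted(df["race_ethnicity"].dropna().unique()):
            k0 = int((g0["race_ethnicity"] == cat).sum())
            k1 = int((g1["race_ethnicity"] == cat).sum())
            _add(
                f"  {cat}",
                f"{k0} ({format_percent(k0, n0)}%)" if n0 else "NA",
                f"{k1} ({format_percent(k1, n1)}%)" if n1 else "NA",
                "",
            )

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration: full comparison bundle
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All comparison statistics for one labeled series."""

    auc_table: pd.DataFrame            # system, auc, variance, ci, n_pos, n_neg
    delong_pvalues: pd.DataFrame       # symmetric matrix, unit diagonal
    delong_differences: pd.DataFrame   # antisymmetric matrix of AUC differences
    threshold_tables: pd.DataFrame     # stacked per-system threshold metrics
    efficiency_curves: pd.DataFrame    # stacked per-system curves
    horizon_h: float = DEFAULT_HORIZON_H
    outcome_kind: str = "DETERIORATION"


def compare_all_systems(series: LabeledScoreSeries) -> ReportBundle:
    """AUC per system, pairwise DeLong matrix, threshold tables and
    efficiency curves for every scored system in the labeled series."""
    y = series.labels
    systems = list(series.systems)

    aucs = [compute_auc(series.scores(s), y, system=s) for s in systems]
    auc_table = pd.DataFrame(
        [
            {
                "system": r.system,
                "auc": r.auc,
                "variance": r.variance,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
            for r in aucs
        ]
    ).sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)

    k = len(systems)
    pmat = np.ones((k, k))
    dmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff, _, p = delong_compare(series.scores(systems[i]), series.scores(systems[j]), y)
            pmat[i, j] = pmat[j, i] = p
            dmat[i, j] = diff
            dmat[j, i] = -diff
    delong_p = pd.DataFrame(pmat, index=systems, columns=systems)
    delong_d = pd.DataFrame(dmat, index=systems, columns=systems)

    thr = pd.concat(
        [threshold_table(series.scores(s), y, system=s) for s in systems],
        ignore_index=True,
    )
    eff = pd.concat(
        [efficiency_curve(series.scores(s), y, system=s).to_frame() for s in systems],
        ignore_index=True,
    )
    return ReportBundle(
        auc_table=auc_table,
        delong_pvalues=delong_p,
        delong_differences=delong_d,
        threshold_tables=thr,
        efficiency_curves=eff,
        horizon_h=series.horizon_h,
        outcome_kind=series.outcome_kind,
    )
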