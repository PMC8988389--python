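"""Rule-based early warning scores over observation snapshots.

Five systems are shipped as declarative threshold-band configurations:

* **MEWS** / **NEWS** — general aggregate weighted scores: each variable maps
  to integer points through threshold bands, the score is the sum.
* **MEOWS** — obstetric red/yellow trigger system: trigger on one markedly
  abnormal (red) observation or two simultaneous mildly abnormal (yellow) ones.
* **MEWC** — obstetric single-parameter criteria: any one abnormal value
  triggers.
* **MEWT** — obstetric two-tier trigger: one severe or two non-severe
  abnormalities trigger.

Trigger systems are ordinalized for ROC analysis as
``ordinal = (#mild) + 2*(#marked)`` so the published trigger rule is exactly
the cutoff ``ordinal >= 2`` (MEOWS, MEWT) or ``>= 1`` (MEWC).

Subjective elements of the obstetric systems (nursing concern, headache in
pre-eclampsia) are not representable in coded EHR streams and are excluded.

Derived inputs: MEWT uses mean arterial pressure ``MAP = (SBP + 2*DBP)/3``
when both pressures are present; the MEWC oliguria criterion uses the urine
rate ``URINE_OUT / 12`` mL/h and is only evaluated when a positive
(quantified) 12-h urine volume is recorded, since unquantified urine is
charted as 0.

Every threshold is configuration, not code: band tables can be loaded from
YAML/JSON files to match a site's exact variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import ALL_VARIABLES, AVPU_LEVELS

INF = math.inf

#: Variables computable from other slots at scoring time.
DERIVED_VARIABLES = ("MAP", "URINE_RATE")
KNOWN_VARIABLES = tuple(ALL_VARIABLES) + DERIVED_VARIABLES

SYSTEMS = ("MEWS", "NEWS", "MEOWS", "MEWC", "MEWT")

#: Severity-level weights used for trigger-system ordinalization.
LEVEL_WEIGHTS = {
    "YELLOW": 1, "RED": 2,          # MEOWS
    "NONSEVERE": 1, "SEVERE": 2,    # MEWT
    "CRITERION": 1,                 # MEWC
}

#: Trigger cutoff on the ordinalized score, per combination rule.
RULE_TRIGGER_CUTOFF = {
    "RED_YELLOW": 2,        # >=1 red or >=2 yellow
    "SEVERE_NONSEVERE": 2,  # >=1 severe or >=2 non-severe
    "ANY_CRITERION": 1,     # any single criterion
}

COMBINATION_RULES = ("SUM_POINTS",) + tuple(RULE_TRIGGER_CUTOFF)


class ScoreConfigError(ValueError):
    """Invalid band table: overlap, coverage gap, or unknown variable."""


@dataclass(frozen=True)
class Band:
    """One threshold band for one variable.

    Numeric bands are intervals with explicit open/closed endpoints so that no
    value can fall in two bands.  Categorical bands (AVPU) list the categories
    they match.  ``points`` is set for SUM_POINTS systems, ``level`` for
    trigger systems.
    """

    variable: str
    lower: float = -INF
    upper: float = INF
    lower_closed: bool = True
    upper_closed: bool = False
    categories: tuple[str, ...] | None = None
    points: int | None = None
    level: str | None = None

    def contains(self, value) -> bool:
        if self.categories is not None:
            return str(value) in self.categories
        try:
            x = float(value)
        except (TypeError, ValueError):
            return False
        lo_ok = x >= self.lower if self.lower_closed else x > self.lower
        hi_ok = x <= self.upper if self.upper_closed else x < self.upper
        return lo_ok and hi_ok

    @property
    def weight(self) -> int:
        if self.points is not None:
            return self.points
        return LEVEL_WEIGHTS[self.level]

    def to_dict(self) -> dict:
        d: dict = {"variable": self.variable}
        if self.categories is not None:
            d["categories"] = list(self.categories)
        else:
            d.update(
                lower=None if self.lower == -INF else self.lower,
                upper=None if self.upper == INF else self.upper,
                lower_closed=self.lower_closed,
                upper_closed=self.upper_closed,
            )
        if self.points is not None:
            d["points"] = self.points
        if self.level is not None:
            d["level"] = self.level
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "Band":
        if "categories" in d:
            return Band(
                variable=d["variable"],
                categories=tuple(d["categories"]),
                points=d.get("points"),
                level=d.get("level"),
            )
        lo = d.get("lower")
        hi = d.get("upper")
        return Band(
            variable=d["variable"],
            lower=-INF if lo is None else float(lo),
            upper=INF if hi is None else float(hi),
            lower_closed=bool(d.get("lower_closed", True)),
            upper_closed=bool(d.get("upper_closed", False)),
            points=d.get("points"),
            level=d.get("level"),
        )


@dataclass(frozen=True)
class ScoreConfig:
    """A complete scoring system: named band table plus combination rule."""

    name: str
    rule: str
    bands: tuple[Band, ...]
    version: str = "default"

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.bands:
            if b.variable not in seen:
                seen.append(b.variable)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rule": self.rule,
            "version": self.version,
            "bands": [b.to_dict() for b in self.bands],
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ScoreConfig":
        cfg = ScoreConfig(
            name=str(d["name"]).upper(),
            rule=d["rule"],
            bands=tuple(Band.from_dict(b) for b in d["bands"]),
            version=str(d.get("version", "file")),
        )
        validate_score_config(cfg)
        return cfg


@dataclass
class ScoreResult:
    """Outcome of scoring one snapshot with one system."""

    system: str
    ordinal_value: int
    trigger: bool
    components: dict[str, tuple[float | str, Band, int]]
    completeness: float
    patient_id: str | None = None
    time: pd.Timestamp | None = None


# ---------------------------------------------------------------------------
# Shipped default band tables
# ---------------------------------------------------------------------------

def _pt(var, lo, hi, points, lc=True, uc=False):
    return Band(var, lo, hi, lc, uc, points=points)


def _lv(var, lo, hi, level, lc=True, uc=False):
    return Band(var, lo, hi, lc, uc, level=level)


#: MEWS (Subbe): five variables, points 0-3, score is the sum.
MEWS_CONFIG = ScoreConfig(
    "MEWS", "SUM_POINTS",
    (
        _pt("RR", -INF, 9, 2), _pt("RR", 9, 15, 0), _pt("RR", 15, 21, 1),
        _pt("RR", 21, 30, 2), _pt("RR", 30, INF, 3),
        _pt("HR", -INF, 40, 2), _pt("HR", 40, 51, 1), _pt("HR", 51, 101, 0),
        _pt("HR", 101, 111, 1), _pt("HR", 111, 130, 2), _pt("HR", 130, INF, 3),
        _pt("SBP", -INF, 71, 3), _pt("SBP", 71, 81, 2), _pt("SBP", 81, 101, 1),
        _pt("SBP", 101, 200, 0), _pt("SBP", 200, INF, 2),
        _pt("TEMP", -INF, 35, 2), _pt("TEMP", 35, 38.5, 0), _pt("TEMP", 38.5, INF, 2),
        Band("AVPU", categories=("A",), points=0),
        Band("AVPU", categories=("V",), points=1),
        Band("AVPU", categories=("P",), points=2),
        Band("AVPU", categories=("U",), points=3),
    ),
)

#: NEWS: seven inputs, points 0-3, score is the sum.
NEWS_CONFIG = ScoreConfig(
    "NEWS", "SUM_POINTS",
    (
        _pt("RR", -INF, 9, 3), _pt("RR", 9, 12, 1), _pt("RR", 12, 21, 0),
        _pt("RR", 21, 25, 2), _pt("RR", 25, INF, 3),
        _pt("SPO2", -INF, 92, 3), _pt("SPO2", 92, 94, 2), _pt("SPO2", 94, 96, 1),
        _pt("SPO2", 96, INF, 0),
        _pt("SUPP_O2", -INF, 0.5, 0), _pt("SUPP_O2", 0.5, INF, 2),
        _pt("TEMP", -INF, 35.1, 3), _pt("TEMP", 35.1, 36.1, 1),
        _pt("TEMP", 36.1, 38.1, 0), _pt("TEMP", 38.1, 39.1, 1), _pt("TEMP", 39.1, INF, 2),
        _pt("SBP", -INF, 91, 3), _pt("SBP", 91, 101, 2), _pt("SBP", 101, 111, 1),
        _pt("SBP", 111, 220, 0), _pt("SBP", 220, INF, 3),
        _pt("HR", -INF, 41, 3), _pt("HR", 41, 51, 1), _pt("HR", 51, 91, 0),
        _pt("HR", 91, 111, 1), _pt("HR", 111, 131, 2), _pt("HR", 131, INF, 3),
        Band("AVPU", categories=("A",), points=0),
        Band("AVPU", categories=("V", "P", "U"), points=3),
    ),
)

#: MEOWS (Singh): red = markedly abnormal, yellow = mildly abnormal;
#: trigger on 1 red or 2 yellow.  Unbanded ranges are normal.
MEOWS_CONFIG = ScoreConfig(
    "MEOWS", "RED_YELLOW",
    (
        _lv("RR", -INF, 10, "RED"),
        _lv("RR", 21, 30, "YELLOW", lc=True, uc=True),
        _lv("RR", 30, INF, "RED", lc=False),
        _lv("HR", -INF, 40, "RED"),
        _lv("HR", 40, 50, "YELLOW", lc=True, uc=True),
        _lv("HR", 100, 120, "YELLOW", lc=True, uc=True),
        _lv("HR", 120, INF, "RED", lc=False),
        _lv("SBP", -INF, 90, "RED"),
        _lv("SBP", 90, 100, "YELLOW", lc=True, uc=True),
        _lv("SBP", 150, 160, "YELLOW", lc=True, uc=True),
        _lv("SBP", 160, INF, "RED", lc=False),
        _lv("DBP", 90, 100, "YELLOW", lc=True, uc=True),
        _lv("DBP", 100, INF, "RED", lc=False),
        _lv("TEMP", -INF, 35, "RED"),
        _lv("TEMP", 35, 36, "YELLOW", lc=True, uc=True),
        _lv("TEMP", 38, INF, "RED", lc=False),
        _lv("SPO2", -INF, 95, "RED"),
        Band("AVPU", categories=("V",), level="YELLOW"),
        Band("AVPU", categories=("P", "U"), level="RED"),
    ),
)

#: MEWC (Mhyre): any single abnormal value triggers.  The oliguria criterion
#: (< 35 mL/h sustained) is evaluated on the derived URINE_RATE slot.
MEWC_CONFIG = ScoreConfig(
    "MEWC", "ANY_CRITERION",
    (
        _lv("SBP", -INF, 90, "CRITERION"),
        _lv("SBP", 160, INF, "CRITERION", lc=False),
        _lv("DBP", 100, INF, "CRITERION", lc=False),
        _lv("HR", -INF, 50, "CRITERION"),
        _lv("HR", 120, INF, "CRITERION", lc=False),
        _lv("RR", -INF, 10, "CRITERION"),
        _lv("RR", 30, INF, "CRITERION", lc=False),
        _lv("SPO2", -INF, 95, "CRITERION"),
        _lv("URINE_RATE", -INF, 35, "CRITERION"),
    ),
)

#: MEWT (Shields): one severe or two non-severe abnormalities trigger.
#: Severity tiers are encoded as disjoint ranges (the higher tier governs).
MEWT_CONFIG = ScoreConfig(
    "MEWT", "SEVERE_NONSEVERE",
    (
        _lv("HR", -INF, 50, "NONSEVERE"),
        _lv("HR", 110, 130, "NONSEVERE", lc=False, uc=True),
        _lv("HR", 130, INF, "SEVERE", lc=False),
        _lv("RR", -INF, 12, "NONSEVERE"),
        _lv("RR", 24, 30, "NONSEVERE", lc=False, uc=True),
        _lv("RR", 30, INF, "SEVERE", lc=False),
        _lv("MAP", -INF, 55, "SEVERE"),
        _lv("SPO2", -INF, 90, "SEVERE"),
        _lv("SPO2", 90, 93, "NONSEVERE"),
        _lv("TEMP", -INF, 36, "NONSEVERE", uc=True),
        _lv("TEMP", 38, INF, "NONSEVERE"),
        _lv("SBP", -INF, 80, "NONSEVERE"),
        _lv("SBP", 155, INF, "NONSEVERE", lc=False),
        _lv("DBP", -INF, 45, "NONSEVERE"),
        _lv("DBP", 105, INF, "NONSEVERE", lc=False),
        _lv("FHR", 160, INF, "NONSEVERE", lc=False),
    ),
)

DEFAULT_CONFIGS: dict[str, ScoreConfig] = {
    "MEWS": MEWS_CONFIG,
    "NEWS": NEWS_CONFIG,
    "MEOWS": MEOWS_CONFIG,
    "MEWC": MEWC_CONFIG,
    "MEWT": MEWT_CONFIG,
}


# ---------------------------------------------------------------------------
# Config loading and validation
# ---------------------------------------------------------------------------


def _bands_overlap(a: Band, b: Band) -> bool:
    if a.categories is not None or b.categories is not None:
        if a.categories is None or b.categories is None:
            return False
        return bool(set(a.categories) & set(b.categories))
    # order by lower endpoint (closed before open at the same value)
    first, second = (a, b) if (a.lower, not a.lower_closed) <= (b.lower, not b.lower_closed) else (b, a)
    if first.upper < second.lower:
        return False
    if first.upper > second.lower:
        return True
    # touching endpoints overlap only if both sides closed
    return first.upper_closed and second.lower_closed


def validate_score_config(config: ScoreConfig) -> None:
    """Check rule validity, variable names, band overlap and (for point
    systems) full real-line coverage per variable."""
    if config.rule not in COMBINATION_RULES:
        raise ScoreConfigError(f"{config.name}: unknown combination rule {config.rule!r}")
    for b in config.bands:
        if b.variable not in KNOWN_VARIABLES:
            raise ScoreConfigError(
                f"{config.name}: unknown_variable {b.variable!r}"
            )
        if config.rule == "SUM_POINTS" and b.points is None:
            raise ScoreConfigError(f"{config.name}: band on {b.variable} lacks points")
        if config.rule != "SUM_POINTS" and b.level is None:
            raise ScoreConfigError(f"{config.name}: band on {b.variable} lacks level")
        if b.level is not None and b.level not in LEVEL_WEIGHTS:
            raise ScoreConfigError(f"{config.name}: unknown level {b.level!r}")

    by_var: dict[str, list[Band]] = {}
    for b in config.bands:
        by_var.setdefault(b.variable, []).append(b)

    for var, bands in by_var.items():
        for i in range(len(bands)):
            for j in range(i + 1, len(bands)):
                if _bands_overlap(bands[i], bands[j]):
                    raise ScoreConfigError(
                        f"{config.name}: overlapping bands for {var}: "
                        f"{bands[i].to_dict()} / {bands[j].to_dict()}"
                    )
        if config.rule == "SUM_POINTS":
            if bands[0].categories is not None:
                cats = set()
                for b in bands:
                    cats |= set(b.categories or ())
                if var == "AVPU" and not set(AVPU_LEVELS) <= cats:
                    raise ScoreConfigError(
                        f"{config.name}: coverage gap for {var}: missing "
                        f"{set(AVPU_LEVELS) - cats}"
                    )
                continue
            ordered = sorted(bands, key=lambda b: (b.lower, b.upper))
            if ordered[0].lower != -INF or ordered[-1].upper != INF:
                raise ScoreConfigError(f"{config.name}: coverage gap for {var} at infinity")
            for prev, nxt in zip(ordered, ordered[1:]):
                if prev.upper != nxt.lower or prev.upper_closed == nxt.lower_closed:
                    raise ScoreConfigError(
                        f"{config.name}: coverage gap for {var} near {prev.upper}"
                    )


def load_score_config(name_or_path: str | Path) -> ScoreConfig:
    """Load a built-in config by name ("mews", ...) or a YAML/JSON file."""
    key = str(name_or_path).upper()
    if key in DEFAULT_CONFIGS:
        return DEFAULT_CONFIGS[key]
    path = Path(name_or_path)
    if not path.exists():
        raise ScoreConfigError(
            f"unknown score system {name_or_path!r} (built-ins: "
            f"{', '.join(s.lower() for s in SYSTEMS)}) and no such file"
        )
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScoreConfig.from_dict(data)


def save_score_config(config: ScoreConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Derived slots
# ---------------------------------------------------------------------------


def derive_slots(values: Mapping[str, float | str]) -> dict[str, float | str]:
    """Add MAP and URINE_RATE to a snapshot mapping when computable.

    MAP = (SBP + 2*DBP) / 3.  URINE_RATE = URINE_OUT / 12 mL/h, only when a
    positive quantified volume is present (0 means unquantified).
    """
    out = dict(values)
    sbp, dbp = out.get("SBP"), out.get("DBP")
    if sbp is not None and dbp is not None:
        out["MAP"] = (float(sbp) + 2.0 * float(dbp)) / 3.0
    urine = out.get("URINE_OUT")
    if urine is not None and float(urine) > 0:
        out["URINE_RATE"] = float(urine) / 12.0
    return out


# ---------------------------------------------------------------------------
# Scoring (single snapshot; reference linear-scan path)
# ---------------------------------------------------------------------------


def score_snapshot(
    snapshot: Mapping[str, float | str] | pd.Series,
    config: ScoreConfig,
) -> ScoreResult:
    """Score one snapshot by a linear scan over the system's bands.

    Missing variables contribute nothing and lower ``completeness`` (the
    fraction of the system's variables present after slot derivation).
    """
    if isinstance(snapshot, pd.Series):
        from .data_model import snapshot_to_dict

        values = snapshot_to_dict(snapshot)
        pid = snapshot.get("patient_id")
        time = snapshot.get("time")
    else:
        values = {k: v for k, v in snapshot.items() if v is not None and pd.notna(v)}
        pid = time = None
    values = derive_slots(values)

    ordinal = 0
    components: dict[str, tuple[float | str, Band, int]] = {}
    n_present = 0
    for var in config.variables:
        if var not in values:
            continue
        n_present += 1
        val = values[var]
        for band in config.bands:
            if band.variable == var and band.contains(val):
                w = band.weight
                if w:
                    ordinal += w
                    components[var] = (val, band, w)
                break

    cutoff = RULE_TRIGGER_CUTOFF.get(config.rule)
    trigger = ordinal >= cutoff if cutoff is not None else False
    completeness = n_present / len(config.variables) if config.variables else 0.0
    return ScoreResult(
        system=config.name,
        ordinal_value=int(ordinal),
        trigger=bool(trigger),
        components=components,
        completeness=float(completeness),
        patient_id=pid,
        time=time,
    )


def score_mews(snapshot, config: ScoreConfig = MEWS_CONFIG) -> ScoreResult:
    return score_snapshot(snapshot, config)


def score_news(snapshot, config: ScoreConfig = NEWS_CONFIG) -> ScoreResult:
    return score_snapshot(snapshot, config)


def score_meows(snapshot, config: ScoreConfig = MEOWS_CONFIG) -> ScoreResult:
    return score_snapshot(snapshot, config)


def score_mewc(snapshot, config: ScoreConfig = MEWC_CONFIG) -> ScoreResult:
    return score_snapshot(snapshot, config)


def score_mewt(snapshot, config: ScoreConfig = MEWT_CONFIG) -> ScoreResult:
    return score_snapshot(snapshot, config)


# ---------------------------------------------------------------------------
# Scoring (vectorized batch path)
# ---------------------------------------------------------------------------


def _derived_columns(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    sbp = pd.to_numeric(frame.get("SBP"), errors="coerce") if "SBP" in frame else None
    dbp = pd.to_numeric(frame.get("DBP"), errors="coerce") if "DBP" in frame else None
    if sbp is not None and dbp is not None:
        out["MAP"] = ((sbp + 2.0 * dbp) / 3.0).to_numpy()
    if "URINE_OUT" in frame:
        urine = pd.to_numeric(frame["URINE_OUT"], errors="coerce")
        rate = urine / 12.0
        out["URINE_RATE"] = rate.where(urine > 0).to_numpy()
    return out


def score_frame(snapshots: pd.DataFrame, config: ScoreConfig) -> pd.DataFrame:
    """Vectorized scoring of a snapshot frame with one system.

    Returns a frame aligned to ``snapshots`` with columns ``ordinal_value``,
    ``trigger`` and ``completeness``.  Equivalent to applying
    :func:`score_snapshot` row-wise (a tested invariant), but O(bands) vector
    operations instead of O(rows x bands) Python.
    """
    n = len(snapshots)
    derived = _derived_columns(snapshots)
    total = np.zeros(n, dtype=np.int64)
    present = np.zeros(n, dtype=np.int64)

    for var in config.variables:
        if var in derived:
            col = derived[var]
        elif var in snapshots.columns:
            raw = snapshots[var]
            if var == "AVPU":
                # object array with "" for missing so vectorized isin is safe
                col = raw.where(raw.notna(), "").astype(str).to_numpy(dtype=object)
            else:
                col = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        else:
            continue

        if var == "AVPU":
            is_present = col != ""
        else:
            col = np.asarray(col, dtype=float)
            is_present = ~np.isnan(col)
        present += is_present.astype(np.int64)

        var_pts = np.zeros(n, dtype=np.int64)
        for band in config.bands:
            if band.variable != var:
                continue
            w = band.weight
            if not w:
                continue
            if band.categories is not None:
                hit = np.isin(np.asarray(col, dtype=object), list(band.categories))
            else:
                lo_ok = col >= band.lower if band.lower_closed else col > band.lower
                hi_ok = col <= band.upper if band.upper_closed else col < band.upper
                with np.errstate(invalid="ignore"):
                    hit = is_present & lo_ok & hi_ok
            var_pts = np.where(hit, w, var_pts)
        total += var_pts

    cutoff = RULE_TRIGGER_CUTOFF.get(config.rule)
    trigger = total >= cutoff if cutoff is not None else np.zeros(n, dtype=bool)
    nvars = len(config.variables) or 1
    return pd.DataFrame(
        {
            "ordinal_value": total,
            "trigger": trigger,
            "completeness": present / nvars,
        },
        index=snapshots.index,
    )


def score_all(
    snapshots: pd.DataFrame,
    configs: Sequence[ScoreConfig] | None = None,
    risk_model: "SurrogateRiskModel | None" = None,
) -> pd.DataFrame:
    """Score every snapshot with every system.

    Returns a long frame with columns ``patient_id, time, system,
    ordinal_value, trigger, completeness`` — one row per snapshot x system.
    When a fitted continuous risk model is supplied its probability is
    appended as an extra system (named by the model), with the probability in
    the ``ordinal_value`` column and ``trigger`` unset.
    """
    configs = list(configs) if configs is not None else list(DEFAULT_CONFIGS.values())
    pieces = []
    meta = snapshots[["patient_id", "time"]] if not snapshots.empty else pd.DataFrame(
        columns=["patient_id", "time"]
    )
    for cfg in configs:
        part = score_frame(snapshots, cfg) if not snapshots.empty else pd.DataFrame(
            columns=["ordinal_value", "trigger", "completeness"]
        )
        part = pd.concat([meta.reset_index(drop=True), part.reset_index(drop=True)], axis=1)
        part.insert(2, "system", cfg.name)
        pieces.append(part)
    if risk_model is not None and not snapshots.empty:
        probs = risk_model.predict(snapshots)
        part = meta.reset_index(drop=True).copy()
        part["system"] = risk_model.name
        part["ordinal_value"] = probs
        part["trigger"] = False
        part["completeness"] = 1.0
        pieces.append(part)
    out = pd.concat(pieces, ignore_index=True)
    return out[["patient_id", "time", "system", "ordinal_value", "trigger", "completeness"]]


# ---------------------------------------------------------------------------
# Pluggable continuous risk model (surrogate for ML scores such as eCART)
# ---------------------------------------------------------------------------


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


#: Numeric feature slots used by the surrogate model.
SURROGATE_FEATURES = (
    "RR", "HR", "TEMP", "SBP", "DBP", "SPO2", "SUPP_O2",
    "WBC", "BUN", "CREATININE", "AST", "ALT", "HEMOGLOBIN", "PLATELETS",
)

_AVPU_ORDINAL = {"A": 0.0, "V": 1.0, "P": 2.0, "U": 3.0}


class SurrogateRiskModel:
    """Random-forest risk model over snapshot features.

    Implements the continuous-score interface (fit / predict probability in
    [0, 1]) that any externally derived ML deterioration score would plug
    into.  Missing values are median-imputed with training-set medians;
    predictions are deterministic given a fitted model and seed.
    """

    def __init__(self, seed: int = 0, n_estimators: int = 100, name: str = "SURROGATE"):
        self.seed = int(seed)
        self.n_estimators = int(n_estimators)
        self.name = name
        self._model = None
        self._medians: pd.Series | None = None
        self.training_report: dict = {}

    # -- features ----------------------------------------------------------
    def _features(self, snapshots: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(index=snapshots.index)
        for var in SURROGATE_FEATURES:
            X[var] = pd.to_numeric(snapshots.get(var), errors="coerce")
        if "AVPU" in snapshots.columns:
            X["AVPU"] = snapshots["AVPU"].map(_AVPU_ORDINAL)
        else:
            X["AVPU"] = np.nan
        return X

    def fit(self, snapshots: pd.DataFrame, labels: Sequence[int]) -> "SurrogateRiskModel":
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold, cross_val_predict

        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError("degenerate_labels: training labels are single-class")
        X = self._features(snapshots)
        self._medians = X.median(numeric_only=True)
        Xf = X.fillna(self._medians).fillna(0.0)

        self._model = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.seed,
            min_samples_leaf=5,
            n_jobs=1,
        )
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=self.seed)
        cv_prob = cross_val_predict(self._model, Xf, y, cv=cv, method="predict_proba")[:, 1]
        self._model.fit(Xf, y)
        self.training_report = {
            "n_observations": int(len(y)),
            "n_positive": int(y.sum()),
            "cv_auc": float(roc_auc_score(y, cv_prob)),
            "seed": self.seed,
            "variables": list(Xf.columns),
        }
        return self

    def predict(self, snapshots: pd.DataFrame) -> np.ndarray:
        """Probability of the outcome for each snapshot row."""
        if self._model is None:
            raise RuntimeError("model is not fitted")
        X = self._features(snapshots).fillna(self._medians).fillna(0.0)
        return self._model.predict_proba(X)[:, 1]


def fit_surrogate_risk_model(
    snapshots: pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 100,
) -> SurrogateRiskModel:
    """Fit the surrogate continuous risk model; see :class:`SurrogateRiskModel`."""
    return SurrogateRiskModel(seed=seed, n_estimators=n_estimators).fit(snapshots, labels)
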