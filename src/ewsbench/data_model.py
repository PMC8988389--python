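"""Longitudinal ward-EHR event model: typed event streams, CSV I/O, validation,
and last-observation-carried-forward (LOCF) snapshot assembly.

A *cohort* is a set of long-format event tables for one hospital population:
encounters (admit/discharge/death plus demographics), location intervals
(ward / labor & delivery / ICU), vital-sign observations, laboratory results,
medication administrations and blood-culture orders.  Scores are computed on
:class:`ObservationSnapshot` rows: one per distinct vital-charting time per
patient while the patient is located on the ward, with each physiologic
variable filled by its most recent value within a configurable staleness
horizon.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

#: Recognized ward units.  LND = labor & delivery.
UNITS = ("WARD", "LND", "ICU", "OTHER")

#: Vital-sign variables (long-format ``variable`` column of vitals.csv).
#: AVPU is categorical (A/V/P/U); SUPP_O2 is boolean (0/1); URINE_OUT is the
#: volume in mL over the preceding 12 h, with unquantified urine recorded as 0.
VITAL_VARIABLES = (
    "RR", "HR", "TEMP", "SBP", "DBP", "SPO2", "AVPU", "SUPP_O2",
    "URINE_OUT", "FHR",
)

#: Laboratory analytes (long-format ``analyte`` column of labs.csv).
LAB_VARIABLES = (
    "WBC", "BUN", "CREATININE", "AST", "ALT", "HEMOGLOBIN", "PLATELETS",
)

ALL_VARIABLES = VITAL_VARIABLES + LAB_VARIABLES

AVPU_LEVELS = ("A", "V", "P", "U")

#: Physiologic plausibility bounds applied at read time; rows outside the
#: closed interval are rejected (never silently dropped).  All overridable
#: through the ``data:`` block of a run config.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "RR": (0, 80),
    "HR": (20, 250),
    "TEMP": (30.0, 43.0),
    "SBP": (30, 300),
    "DBP": (10, 200),
    "SPO2": (50, 100),
    "SUPP_O2": (0, 1),
    "URINE_OUT": (0, 10_000),
    "FHR": (50, 250),
    "WBC": (0, 200),
    "BUN": (0, 300),
    "CREATININE": (0, 30),
    "AST": (0, 20_000),
    "ALT": (0, 20_000),
    "HEMOGLOBIN": (0, 25),
    "PLATELETS": (0, 2_000),
}


@dataclass(frozen=True)
class LocfConfig:
    """Carry-forward horizons, in hours, per variable class.

    Vitals are carried 24 h and labs 48 h by default; carrying is always
    limited to the same encounter.  A horizon of 0 keeps only values charted
    at the snapshot time itself.
    """

    vitals_hours: float = 24.0
    labs_hours: float = 48.0

    def horizon_hours(self, variable: str) -> float:
        return self.labs_hours if variable in LAB_VARIABLES else self.vitals_hours


# ---------------------------------------------------------------------------
# Typed event records (row-level views; tables are stored as DataFrames)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Encounter:
    patient_id: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    death_time: pd.Timestamp | None = None
    age_years: float | None = None
    bmi: float | None = None
    hypertensive_disorder: bool = False
    diabetes: bool = False
    race_ethnicity: str | None = None


@dataclass(frozen=True)
class LocationInterval:
    patient_id: str
    unit: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp


@dataclass(frozen=True)
class VitalEvent:
    patient_id: str
    time: pd.Timestamp
    variable: str
    value: float | str


@dataclass(frozen=True)
class LabEvent:
    patient_id: str
    time: pd.Timestamp
    analyte: str
    value: float


@dataclass(frozen=True)
class MedicationEvent:
    patient_id: str
    time: pd.Timestamp
    is_antibiotic: bool
    route: str  # IV or PO


@dataclass(frozen=True)
class CultureOrder:
    patient_id: str
    order_time: pd.Timestamp


# Canonical column orders for each table (also the write order).
ENCOUNTER_COLUMNS = [
    "patient_id", "admit_time", "discharge_time", "death_time", "age_years",
    "bmi", "hypertensive_disorder", "diabetes", "race_ethnicity",
]
LOCATION_COLUMNS = ["patient_id", "unit", "start_time", "end_time"]
VITAL_COLUMNS = ["patient_id", "time", "variable", "value"]
LAB_COLUMNS = ["patient_id", "time", "analyte", "value"]
MED_COLUMNS = ["patient_id", "time", "is_antibiotic", "route"]
CULTURE_COLUMNS = ["patient_id", "order_time"]

TABLE_COLUMNS = {
    "encounters": ENCOUNTER_COLUMNS,
    "locations": LOCATION_COLUMNS,
    "vitals": VITAL_COLUMNS,
    "labs": LAB_COLUMNS,
    "meds": MED_COLUMNS,
    "cultures": CULTURE_COLUMNS,
}

TABLE_FILES = {name: f"{name}.csv" for name in TABLE_COLUMNS}


@dataclass
class Cohort:
    """All typed event streams for one population, time-sorted.

    ``rejects`` collects rows dropped at read time (file, row index, reason);
    it is empty for programmatically generated cohorts.
    """

    encounters: pd.DataFrame
    locations: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    meds: pd.DataFrame
    cultures: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "encounters": self.encounters,
            "locations": self.locations,
            "vitals": self.vitals,
            "labs": self.labs,
            "meds": self.meds,
            "cultures": self.cultures,
        }

    @property
    def n_patients(self) -> int:
        return len(self.encounters)


@dataclass
class Violation:
    patient_id: str
    rule: str
    detail: str = ""


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.patient_id, v.rule, v.detail) for v in self.violations],
            columns=["patient_id", "rule", "detail"],
        )


class SchemaError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


class CohortValidationError(ValueError):
    """Raised in strict mode when invariant violations are present."""


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _parse_times(df: pd.DataFrame, column: str) -> pd.Series:
    return pd.to_datetime(df[column], errors="coerce")


def _reject(rows: list, table: str, idx, reason: str) -> None:
    rows.append((table, int(idx), reason))


def read_cohort(
    paths: Mapping[str, str | Path] | str | Path,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> Cohort:
    """Read a cohort from CSV files.

    Parameters
    ----------
    paths
        Either a directory containing the canonical file names
        (``encounters.csv`` etc.) or a mapping from table name to path.
    bounds
        Plausibility bounds per variable; defaults to :data:`DEFAULT_BOUNDS`.
        Numeric vital/lab rows outside their closed bound interval are
        rejected with reason ``out_of_bounds``.

    Malformed rows (unparseable timestamp, unknown variable, non-numeric or
    out-of-bounds value) are collected in ``cohort.rejects`` with a reason,
    never silently dropped.  A missing required column is a hard
    :class:`SchemaError`.
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {name: root / fn for name, fn in TABLE_FILES.items()}

    raw: dict[str, pd.DataFrame] = {}
    for name in TABLE_COLUMNS:
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(f"cohort table '{name}' not found at {p}")
        raw[name] = pd.read_csv(p, dtype={"patient_id": str})
        _require_columns(raw[name], TABLE_COLUMNS[name], p.name)

    rejects: list = []

    # encounters -----------------------------------------------------------
    enc = raw["encounters"].copy()
    for col in ("admit_time", "discharge_time"):
        enc[col] = _parse_times(enc, col)
    enc["death_time"] = _parse_times(enc, "death_time")
    bad = enc["admit_time"].isna() | enc["discharge_time"].isna()
    for i in enc.index[bad]:
        _reject(rejects, "encounters", i, "bad_timestamp")
    enc = enc[~bad]
    for col in ("age_years", "bmi"):
        enc[col] = pd.to_numeric(enc[col], errors="coerce")
    for col in ("hypertensive_disorder", "diabetes"):
        enc[col] = enc[col].astype(str).str.lower().isin(("true", "1", "1.0", "yes"))

    # locations ------------------------------------------------------------
    loc = raw["locations"].copy()
    loc["start_time"] = _parse_times(loc, "start_time")
    loc["end_time"] = _parse_times(loc, "end_time")
    loc["unit"] = loc["unit"].astype(str).str.upper()
    bad = loc["start_time"].isna() | loc["end_time"].isna()
    for i in loc.index[bad]:
        _reject(rejects, "locations", i, "bad_timestamp")
    unknown = ~loc["unit"].isin(UNITS) & ~bad
    for i in loc.index[unknown]:
        _reject(rejects, "locations", i, "unknown_unit")
    loc = loc[~bad & ~unknown]

    # vitals ---------------------------------------------------------------
    vit = raw["vitals"].copy()
    vit["time"] = _parse_times(vit, "time")
    vit["variable"] = vit["variable"].astype(str).str.upper()
    keep = np.ones(len(vit), dtype=bool)
    times_bad = vit["time"].isna().to_numpy()
    var_bad = (~vit["variable"].isin(VITAL_VARIABLES)).to_numpy()
    values = vit["value"]
    numeric = pd.to_numeric(values, errors="coerce")
    is_avpu = (vit["variable"] == "AVPU").to_numpy()
    avpu_bad = is_avpu & ~values.astype(str).str.upper().isin(AVPU_LEVELS).to_numpy()
    num_bad = ~is_avpu & numeric.isna().to_numpy()
    lo = vit["variable"].map({k: v[0] for k, v in bounds.items()})
    hi = vit["variable"].map({k: v[1] for k, v in bounds.items()})
    oob = (~is_avpu) & ~num_bad & ((numeric < lo) | (numeric > hi)).to_numpy()
    for i, reason in _first_reason(
        vit.index,
        [times_bad, var_bad, avpu_bad | num_bad, oob],
        ["bad_timestamp", "unknown_variable", "bad_value", "out_of_bounds"],
    ):
        _reject(rejects, "vitals", i, reason)
        keep[vit.index.get_loc(i)] = False
    vit = vit[keep]
    vit["value"] = np.where(
        vit["variable"] == "AVPU",
        vit["value"].astype(str).str.upper(),
        pd.to_numeric(vit["value"], errors="coerce"),
    )

    # labs -----------------------------------------------------------------
    lab = raw["labs"].copy()
    lab["time"] = _parse_times(lab, "time")
    lab["analyte"] = lab["analyte"].astype(str).str.upper()
    numeric = pd.to_numeric(lab["value"], errors="coerce")
    times_bad = lab["time"].isna().to_numpy()
    var_bad = (~lab["analyte"].isin(LAB_VARIABLES)).to_numpy()
    num_bad = (numeric.isna() | (numeric < 0) | ~np.isfinite(numeric)).to_numpy()
    lo = lab["analyte"].map({k: v[0] for k, v in bounds.items()})
    hi = lab["analyte"].map({k: v[1] for k, v in bounds.items()})
    oob = ~num_bad & ((numeric < lo) | (numeric > hi)).to_numpy()
    keep = np.ones(len(lab), dtype=bool)
    for i, reason in _first_reason(
        lab.index,
        [times_bad, var_bad, num_bad, oob],
        ["bad_timestamp", "unknown_variable", "bad_value", "out_of_bounds"],
    ):
        _reject(rejects, "labs", i, reason)
        keep[lab.index.get_loc(i)] = False
    lab = lab[keep]
    lab["value"] = pd.to_numeric(lab["value"])

    # meds -----------------------------------------------------------------
    med = raw["meds"].copy()
    med["time"] = _parse_times(med, "time")
    med["is_antibiotic"] = (
        med["is_antibiotic"].astype(str).str.lower().isin(("true", "1", "1.0", "yes"))
    )
    med["route"] = med["route"].astype(str).str.upper()
    bad = med["time"].isna() | ~med["route"].isin(("IV", "PO"))
    for i in med.index[bad]:
        _reject(
            rejects, "meds", i,
            "bad_timestamp" if pd.isna(med.loc[i, "time"]) else "unknown_route",
        )
    med = med[~bad]

    # cultures -------------------------------------------------------------
    cul = raw["cultures"].copy()
    cul["order_time"] = _parse_times(cul, "order_time")
    bad = cul["order_time"].isna()
    for i in cul.index[bad]:
        _reject(rejects, "cultures", i, "bad_timestamp")
    cul = cul[~bad]

    cohort = Cohort(
        encounters=enc.reset_index(drop=True),
        locations=loc.sort_values(["patient_id", "start_time"], kind="stable").reset_index(drop=True),
        vitals=vit.sort_values(["patient_id", "time"], kind="stable").reset_index(drop=True),
        labs=lab.sort_values(["patient_id", "time"], kind="stable").reset_index(drop=True),
        meds=med.sort_values(["patient_id", "time"], kind="stable").reset_index(drop=True),
        cultures=cul.sort_values(["patient_id", "order_time"], kind="stable").reset_index(drop=True),
        rejects=pd.DataFrame(rejects, columns=["table", "row", "reason"]),
    )
    return cohort


def _first_reason(index, masks, reasons):
    """Yield (row index, first matching reason) over parallel boolean masks."""
    combined = np.zeros(len(index), dtype=bool)
    out = {}
    for mask, reason in zip(masks, reasons):
        new = mask & ~combined
        for pos in np.flatnonzero(new):
            out[index[pos]] = reason
        combined |= mask
    return out.items()


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _format_times(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    df = df.copy()
    for c in columns:
        if c in df.columns:
            s = pd.to_datetime(df[c])
            df[c] = s.dt.strftime("%Y-%m-%dT%H:%M")
    return df


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables as canonical CSV (ISO-8601 minute timestamps).

    Output is deterministic: fixed column order, stable sort, fixed float
    formatting — identical cohorts produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    time_cols = {
        "encounters": ["admit_time", "discharge_time", "death_time"],
        "locations": ["start_time", "end_time"],
        "vitals": ["time"],
        "labs": ["time"],
        "meds": ["time"],
        "cultures": ["order_time"],
    }
    written = {}
    for name, df in cohort.tables().items():
        cols = TABLE_COLUMNS[name]
        out = _format_times(df, time_cols[name]).reindex(columns=cols)
        path = outdir / TABLE_FILES[name]
        out.to_csv(path, index=False, float_format="%.6g")
        written[name] = path
    return written


def cohort_to_csv_bytes(cohort: Cohort) -> dict[str, bytes]:
    """Render each table to CSV bytes in memory (used for checksums)."""
    time_cols = {
        "encounters": ["admit_time", "discharge_time", "death_time"],
        "locations": ["start_time", "end_time"],
        "vitals": ["time"],
        "labs": ["time"],
        "meds": ["time"],
        "cultures": ["order_time"],
    }
    out = {}
    for name, df in cohort.tables().items():
        buf = io.StringIO()
        _format_times(df, time_cols[name]).reindex(columns=TABLE_COLUMNS[name]).to_csv(
            buf, index=False, float_format="%.6g"
        )
        out[name] = buf.getvalue().encode()
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_cohort(cohort: Cohort, strict: bool = False) -> ValidationReport:
    """Check cross-table invariants; report-only unless ``strict``.

    Rules: unique patient ids; admit < discharge; death inside the encounter;
    location intervals well-formed, non-overlapping and inside the encounter;
    timed events (vitals, labs, meds, cultures) inside their encounter.
    """
    report = ValidationReport()
    enc = cohort.encounters

    dup = enc["patient_id"][enc["patient_id"].duplicated()]
    for pid in dup:
        report.violations.append(Violation(pid, "duplicate_patient_id"))

    bad_order = enc["admit_time"] >= enc["discharge_time"]
    for pid in enc.loc[bad_order, "patient_id"]:
        report.violations.append(Violation(pid, "encounter_times_inverted"))

    if "death_time" in enc.columns:
        death = enc["death_time"]
        outside = death.notna() & (
            (death < enc["admit_time"]) | (death > enc["discharge_time"])
        )
        for pid in enc.loc[outside, "patient_id"]:
            report.violations.append(Violation(pid, "death_outside_encounter"))

    spans = enc.set_index("patient_id")[["admit_time", "discharge_time"]]

    loc = cohort.locations
    bad = loc["start_time"] >= loc["end_time"]
    for pid in loc.loc[bad, "patient_id"]:
        report.violations.append(Violation(pid, "interval_times_inverted"))
    for pid, grp in loc.groupby("patient_id", sort=False):
        g = grp.sort_values("start_time")
        overlap = g["start_time"].iloc[1:].to_numpy() < g["end_time"].iloc[:-1].to_numpy()
        if overlap.any():
            report.violations.append(Violation(pid, "interval_overlap"))
        if pid in spans.index:
            a, d = spans.loc[pid]
            if (g["start_time"] < a).any() or (g["end_time"] > d).any():
                report.violations.append(Violation(pid, "interval_outside_encounter"))
        else:
            report.violations.append(Violation(pid, "unknown_patient"))

    def _check_events(df: pd.DataFrame, time_col: str, rule: str) -> None:
        if df.empty:
            return
        merged = df.merge(spans, left_on="patient_id", right_index=True, how="left")
        unknown = merged["admit_time"].isna()
        outside = ~unknown & (
            (merged[time_col] < merged["admit_time"])
            | (merged[time_col] > merged["discharge_time"])
        )
        for pid in merged.loc[unknown, "patient_id"].unique():
            report.violations.append(Violation(pid, "unknown_patient"))
        for pid in merged.loc[outside, "patient_id"].unique():
            report.violations.append(Violation(pid, rule))

    _check_events(cohort.vitals, "time", "event_outside_encounter")
    _check_events(cohort.labs, "time", "event_outside_encounter")
    _check_events(cohort.meds, "time", "event_outside_encounter")
    _check_events(cohort.cultures, "order_time", "event_outside_encounter")

    if strict and not report.ok:
        raise CohortValidationError(
            f"{len(report.violations)} invariant violation(s); first: "
            f"{report.violations[0].rule} for patient {report.violations[0].patient_id}"
        )
    return report


# ---------------------------------------------------------------------------
# Snapshot assembly (LOCF)
# ---------------------------------------------------------------------------

#: Snapshot frame layout: one row per (patient_id, time); per variable a value
#: column named after the variable plus an age column ``<VAR>_age_min``
#: (minutes since the source measurement; NaN when absent).
SNAPSHOT_META_COLUMNS = ["patient_id", "time", "in_scope_unit"]


def _ward_mask(times: pd.DataFrame, locations: pd.DataFrame, unit: str = "WARD") -> pd.Series:
    """For rows (patient_id, time), True when the patient is in ``unit``.

    A time on an interval boundary belongs to the interval starting there
    (half-open [start, end) convention).
    """
    if times.empty or locations.empty:
        return pd.Series(False, index=times.index)
    loc = locations.sort_values(["start_time", "patient_id"], kind="stable")
    t = times.reset_index().sort_values(["time", "patient_id"], kind="stable")
    merged = pd.merge_asof(
        t, loc,
        left_on="time", right_on="start_time",
        by="patient_id", direction="backward",
    )
    ok = (merged["unit"] == unit) & (merged["time"] < merged["end_time"])
    return ok.set_axis(merged["index"]).reindex(times.index).fillna(False)


def assemble_snapshots(
    cohort: Cohort,
    locf: LocfConfig | None = None,
    unit: str = "WARD",
) -> pd.DataFrame:
    """Build one observation snapshot per distinct vital-charting time on the ward.

    Snapshot times are the distinct times at which >= 1 vital is charted while
    the patient is located in ``unit`` (labs alone never create snapshots).
    Each variable slot carries the most recent value within its class horizon,
    else is absent (NaN); ``<VAR>_age_min`` gives its staleness in minutes.
    """
    locf = locf or LocfConfig()
    vit, lab = cohort.vitals, cohort.labs

    if vit.empty:
        cols = SNAPSHOT_META_COLUMNS + list(ALL_VARIABLES) + [
            f"{v}_age_min" for v in ALL_VARIABLES
        ]
        return pd.DataFrame(columns=cols)

    times = vit[["patient_id", "time"]].drop_duplicates()
    on_ward = _ward_mask(times.copy(), cohort.locations, unit=unit)
    times = times[on_ward.to_numpy()]
    if times.empty:
        cols = SNAPSHOT_META_COLUMNS + list(ALL_VARIABLES) + [
            f"{v}_age_min" for v in ALL_VARIABLES
        ]
        return pd.DataFrame(columns=cols)

    snap = times.sort_values(["time", "patient_id"], kind="stable").reset_index(drop=True)

    def _attach(events: pd.DataFrame, var_col: str, variable: str) -> None:
        horizon = pd.Timedelta(hours=locf.horizon_hours(variable))
        ev = events[events[var_col] == variable]
        if ev.empty:
            snap[variable] = np.nan
            snap[f"{variable}_age_min"] = np.nan
            return
        ev = ev[["patient_id", "time", "value"]].sort_values(
            ["time", "patient_id"], kind="stable"
        )
        # keep the last value per (patient, time) if duplicated
        ev = ev.groupby(["patient_id", "time"], as_index=False, sort=False).last()
        ev = ev.sort_values(["time", "patient_id"], kind="stable")
        merged = pd.merge_asof(
            snap[["patient_id", "time"]], ev.rename(columns={"time": "src_time"}),
            left_on="time", right_on="src_time",
            by="patient_id", direction="backward", tolerance=horizon,
        )
        snap[variable] = merged["value"].to_numpy()
        age = (merged["time"] - merged["src_time"]).dt.total_seconds() / 60.0
        snap[f"{variable}_age_min"] = age.to_numpy()

    for v in VITAL_VARIABLES:
        _attach(vit, "variable", v)
    for v in LAB_VARIABLES:
        _attach(lab, "analyte", v)

    snap["in_scope_unit"] = unit
    snap = snap.sort_values(["patient_id", "time"], kind="stable").reset_index(drop=True)
    return snap[SNAPSHOT_META_COLUMNS + [c for c in snap.columns if c not in SNAPSHOT_META_COLUMNS]]


def snapshot_to_dict(row: pd.Series) -> dict:
    """Extract the {variable: value} mapping of present slots from a snapshot row."""
    out = {}
    for v in ALL_VARIABLES:
        if v in row.index and pd.notna(row[v]):
            out[v] = row[v]
    return out
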