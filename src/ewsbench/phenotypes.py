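"""EHR phenotyping of outcomes on obstetric wards.

Two outcome definitions operate on the cohort's event streams:

* **Deterioration** — ward-to-ICU transfer or death.  A transfer qualifies
  when a ward stay is immediately followed by an ICU stay, or when the
  patient goes ward -> labor & delivery -> ICU with ICU entry within 24 h of
  leaving the ward.  Direct L&D-to-ICU transfers that never touched the ward
  are excluded.  Death during or after ward care without a qualifying ICU
  transfer is an event at the time of death.

* **Infection** — a Rhee-style pharmacy/microbiology criterion: IV
  antibiotics within 2 calendar days before or after a blood-culture order,
  followed by antibiotics (IV or oral) on at least 4 consecutive calendar
  days, or on every day from the qualifying IV day through the day before
  discharge.

"Days" are calendar days (midnight truncation).  The event time anchor for
infection defaults to the earliest qualifying culture-order time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Cohort

DETERIORATION = "DETERIORATION"
INFECTION = "INFECTION"

#: Maximum L&D dwell for a ward -> L&D -> ICU chain to count as a ward event.
VIA_LND_WINDOW_H = 24.0


@dataclass(frozen=True)
class OutcomeEvent:
    patient_id: str
    kind: str
    event_time: pd.Timestamp
    evidence: dict = field(default_factory=dict, hash=False, compare=False)


def events_to_frame(events: list[OutcomeEvent]) -> pd.DataFrame:
    rows = [
        (e.patient_id, e.kind, e.event_time, _summarize_evidence(e.evidence))
        for e in events
    ]
    return pd.DataFrame(rows, columns=["patient_id", "kind", "event_time", "evidence_summary"])


def _summarize_evidence(ev: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(ev.items()))


# ---------------------------------------------------------------------------
# Deterioration composite
# ---------------------------------------------------------------------------


def detect_deterioration(
    cohort: Cohort,
    via_lnd_window_h: float = VIA_LND_WINDOW_H,
) -> list[OutcomeEvent]:
    """Emit at most one deterioration event per encounter (the first).

    Qualifying ICU transfers, in interval-sequence terms:

    a. ``... WARD, ICU ...`` — event at ICU entry;
    b. ``... WARD, LND+, ICU ...`` (one or more consecutive L&D intervals)
       with ICU entry <= ``via_lnd_window_h`` after the ward interval ends —
       event at ICU entry.

    A death during the encounter with prior ward care and no earlier
    qualifying transfer is an event at ``death_time``.
    """
    events: list[OutcomeEvent] = []
    enc = cohort.encounters.set_index("patient_id")
    window = pd.Timedelta(hours=via_lnd_window_h)

    for pid, grp in cohort.locations.groupby("patient_id", sort=True):
        ivs = grp.sort_values("start_time").reset_index(drop=True)
        units = ivs["unit"].tolist()
        transfer: OutcomeEvent | None = None
        for i, unit in enumerate(units):
            if unit != "WARD":
                continue
            ward_end = ivs.loc[i, "end_time"]
            j = i + 1
            via_lnd = False
            while j < len(units) and units[j] == "LND":
                j += 1
                via_lnd = True
            if j < len(units) and units[j] == "ICU":
                icu_entry = ivs.loc[j, "start_time"]
                if via_lnd and icu_entry - ward_end > window:
                    continue  # dwell in L&D too long; not a ward event
                transfer = OutcomeEvent(
                    pid, DETERIORATION, icu_entry,
                    evidence={
                        "route": "ward_lnd_icu" if via_lnd else "ward_icu",
                        "ward_exit": str(ward_end),
                    },
                )
                break

        death_event: OutcomeEvent | None = None
        if pid in enc.index:
            death = enc.loc[pid, "death_time"]
            had_ward = "WARD" in units
            if pd.notna(death) and had_ward:
                first_ward_start = ivs.loc[ivs["unit"] == "WARD", "start_time"].min()
                if death >= first_ward_start:
                    death_event = OutcomeEvent(
                        pid, DETERIORATION, death, evidence={"route": "death"}
                    )

        candidates = [e for e in (transfer, death_event) if e is not None]
        if candidates:
            events.append(min(candidates, key=lambda e: e.event_time))

    events.sort(key=lambda e: (e.patient_id,))
    return events


# ---------------------------------------------------------------------------
# Infection (Rhee criterion)
# ---------------------------------------------------------------------------


@dataclass
class AntibioticDayLedger:
    """Per-calendar-day antibiotic exposure flags for one encounter.

    Day 0 is the admit calendar day; the ledger runs through the discharge
    calendar day.  ``iv[d]`` — any IV antibiotic on day d; ``any[d]`` — any
    IV-or-PO antibiotic on day d.
    """

    patient_id: str
    admit_day: pd.Timestamp  # midnight of admit calendar day
    discharge_day_index: int
    iv: np.ndarray
    any: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.iv)

    def day_index(self, t: pd.Timestamp) -> int:
        return (t.normalize() - self.admit_day).days


def build_antibiotic_ledger(meds: pd.DataFrame, encounter: pd.Series) -> AntibioticDayLedger:
    """Build the day-indexed antibiotic flags from medication events.

    Only antibiotic events count; doses on the same calendar day flag the
    day once (idempotent).
    """
    admit_day = pd.Timestamp(encounter["admit_time"]).normalize()
    discharge_idx = (pd.Timestamp(encounter["discharge_time"]).normalize() - admit_day).days
    n = discharge_idx + 1
    iv = np.zeros(n, dtype=bool)
    any_abx = np.zeros(n, dtype=bool)
    if not meds.empty:
        abx = meds[meds["is_antibiotic"].astype(bool)]
        for t, route in zip(abx["time"], abx["route"]):
            d = (pd.Timestamp(t).normalize() - admit_day).days
            if 0 <= d < n:
                any_abx[d] = True
                if route == "IV":
                    iv[d] = True
    return AntibioticDayLedger(
        patient_id=str(encounter["patient_id"]),
        admit_day=admit_day,
        discharge_day_index=discharge_idx,
        iv=iv,
        any=any_abx,
    )


def _qualifying_iv_day(ledger: AntibioticDayLedger, d0: int) -> bool:
    """Does an IV antibiotic day d0 start a qualifying antibiotic course?

    Qualifies when antibiotics (IV or PO) run on >= 4 consecutive days
    starting at d0, or on every day from d0 through the day before discharge
    (the censoring clause; a start on the discharge day itself cannot use it).
    """
    if not (0 <= d0 < ledger.n_days and ledger.iv[d0]):
        return False
    run = 0
    while d0 + run < ledger.n_days and ledger.any[d0 + run]:
        run += 1
    if run >= 4:
        return True
    last_full_day = ledger.discharge_day_index - 1
    return d0 <= last_full_day and d0 + run - 1 >= last_full_day


def detect_infection(
    ledger: AntibioticDayLedger,
    cultures: pd.DataFrame,
    encounter: pd.Series,
    first_only: bool = True,
    min_separation_days: int = 1,
) -> list[OutcomeEvent]:
    """Apply the infection criterion; event time = qualifying culture order.

    For each blood-culture order on calendar day d, the criterion is met when
    some IV-antibiotic day d0 with ``|d0 - d| <= 2`` starts a qualifying
    course (see :func:`_qualifying_iv_day`).  By default only the first
    qualifying episode per encounter is emitted; with ``first_only=False``,
    later qualifying cultures at least ``min_separation_days`` apart are also
    emitted.
    """
    if cultures.empty:
        return []
    events: list[OutcomeEvent] = []
    last_day: int | None = None
    for t in sorted(cultures["order_time"]):
        d = ledger.day_index(pd.Timestamp(t))
        start = next(
            (
                d0
                for d0 in range(max(0, d - 2), min(ledger.n_days, d + 3))
                if _qualifying_iv_day(ledger, d0)
            ),
            None,
        )
        if start is None:
            continue
        if last_day is not None and d - last_day < min_separation_days:
            continue
        events.append(
            OutcomeEvent(
                ledger.patient_id, INFECTION, pd.Timestamp(t),
                evidence={"culture_day": d, "iv_start_day": start},
            )
        )
        last_day = d
        if first_only:
            break
    return events


def detect_infections_cohort(cohort: Cohort, first_only: bool = True) -> list[OutcomeEvent]:
    """Run the infection phenotype over every encounter in a cohort."""
    events: list[OutcomeEvent] = []
    meds_by_pid = dict(tuple(cohort.meds.groupby("patient_id", sort=False))) if not cohort.meds.empty else {}
    cult_by_pid = dict(tuple(cohort.cultures.groupby("patient_id", sort=False))) if not cohort.cultures.empty else {}
    empty_meds = cohort.meds.iloc[0:0]
    for _, enc in cohort.encounters.iterrows():
        pid = enc["patient_id"]
        cultures = cult_by_pid.get(pid)
        if cultures is None or cultures.empty:
            continue
        ledger = build_antibiotic_ledger(meds_by_pid.get(pid, empty_meds), enc)
        events.extend(detect_infection(ledger, cultures, enc, first_only=first_only))
    events.sort(key=lambda e: (e.patient_id,))
    return events


def detect_outcomes(cohort: Cohort, kind: str) -> list[OutcomeEvent]:
    """Dispatch to the requested phenotype (DETERIORATION or INFECTION)."""
    if kind.upper() == DETERIORATION:
        return detect_deterioration(cohort)
    if kind.upper() == INFECTION:
        return detect_infections_cohort(cohort)
    raise ValueError(f"unknown outcome kind {kind!r}")
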