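"""Deterioration and infection phenotypes: hand traces, brute-force oracle,
and invariances."""

import numpy as np
import pandas as pd
import pytest

import ewsbench as eb
from ewsbench.phenotypes import (
    build_antibiotic_ledger,
    detect_deterioration,
    detect_infection,
)

from conftest import make_cohort, simple_encounter


# ---------------------------------------------------------------------------
# Deterioration composite
# ---------------------------------------------------------------------------


def _loc_cohort(locations, death=None):
    return make_cohort(
        encounters=[simple_encounter(discharge="2024-01-20 00:00", death=death)],
        locations=locations,
    )


class TestDeterioration:
    def test_direct_ward_to_icu(self):
        events = detect_deterioration(_loc_cohort([
            ("p1", "WARD", "2024-01-01 00:00", "2024-01-03 00:00"),
            ("p1", "ICU", "2024-01-03 00:00", "2024-01-05 00:00"),
        ]))
        assert len(events) == 1
        assert events[0].event_time == pd.Timestamp("2024-01-03 00:00")

    def test_ward_lnd_icu_within_24h(self):
        events = detect_deterioration(_loc_cohort([
            ("p1", "WARD", "2024-01-01 00:00", "2024-01-03 00:00"),
            ("p1", "LND", "2024-01-03 00:00", "2024-01-03 06:00"),
            ("p1", "ICU", "2024-01-03 06:00", "2024-01-05 00:00"),
        ]))
        assert len(events) == 1
        assert events[0].event_time == pd.Timestamp("2024-01-03 06:00")
        assert events[0].evidence["route"] == "ward_lnd_icu"

    def test_ward_lnd_icu_beyond_24h_is_not_an_event(self):
        events = detect_deterioration(_loc_cohort([
            ("p1", "WARD", "2024-01-01 00:00", "2024-01-03 00:00"),
            ("p1", "LND", "2024-01-03 00:00", "2024-01-04 06:00"),  # 30 h dwell
            ("p1", "ICU", "2024-01-04 06:00", "2024-01-05 00:00"),
        ]))
        assert events == []

    def test_direct_lnd_to_icu_without_ward_excluded(self):
        events = detect_deterioration(_loc_cohort([
            ("p1", "LND", "2024-01-01 00:00", "2024-01-03 00:00"),
            ("p1", "ICU", "2024-01-03 00:00", "2024-01-05 00:00"),
        ]))
        assert events == []

    def test_death_on_ward_without_transfer(self):
        events = detect_deterioration(_loc_cohort(
            [("p1", "WARD", "2024-01-01 00:00", "2024-01-10 00:00")],
            death="2024-01-10 00:00",
        ))
        assert len(events) == 1
        assert events[0].evidence["route"] == "death"
        assert events[0].event_time == pd.Timestamp("2024-01-10 00:00")

    def test_first_qualifying_event_only_and_idempotence(self):
        cohort = _loc_cohort([
            ("p1", "WARD", "2024-01-01 00:00", "2024-01-03 00:00"),
            ("p1", "ICU", "2024-01-03 00:00", "2024-01-05 00:00"),
            ("p1", "WARD", "2024-01-05 00:00", "2024-01-07 00:00"),
            ("p1", "ICU", "2024-01-07 00:00", "2024-01-09 00:00"),
        ])
        first = detect_deterioration(cohort)
        assert len(first) == 1 and first[0].event_time == pd.Timestamp("2024-01-03 00:00")
        assert detect_deterioration(cohort) == first  # rerun changes nothing

    def test_translation_invariance_by_whole_days(self):
        base = [
            ("p1", "WARD", "2024-01-01 00:00", "2024-01-03 00:00"),
            ("p1", "LND", "2024-01-03 00:00", "2024-01-03 12:00"),
            ("p1", "ICU", "2024-01-03 12:00", "2024-01-05 00:00"),
        ]
        shift = pd.Timedelta(days=7)
        shifted = [(p, u, pd.Timestamp(s) + shift, pd.Timestamp(e) + shift) for p, u, s, e in base]
        enc = simple_encounter(admit="2024-01-08 00:00", discharge="2024-01-27 00:00")
        e0 = detect_deterioration(_loc_cohort(base))
        e1 = detect_deterioration(make_cohort(encounters=[enc], locations=shifted))
        assert e1[0].event_time - e0[0].event_time == shift


# ---------------------------------------------------------------------------
# Antibiotic ledger
# ---------------------------------------------------------------------------


def _enc(pid="p1", admit="2024-01-01 00:00", discharge="2024-01-10 00:00"):
    return pd.Series({
        "patient_id": pid,
        "admit_time": pd.Timestamp(admit),
        "discharge_time": pd.Timestamp(discharge),
    })


def _meds(*rows):
    df = pd.DataFrame(rows, columns=["patient_id", "time", "is_antibiotic", "route"])
    df["time"] = pd.to_datetime(df["time"])
    return df


def _cultures(*times):
    df = pd.DataFrame({"patient_id": "p1", "order_time": pd.to_datetime(list(times))})
    return df


class TestLedger:
    def test_no_antibiotics_all_false(self):
        ledger = build_antibiotic_ledger(_meds(), _enc())
        assert not ledger.iv.any() and not ledger.any.any()
        assert ledger.n_days == 10

    def test_same_day_doses_flag_day_once(self):
        ledger = build_antibiotic_ledger(
            _meds(("p1", "2024-01-01 08:00", True, "IV"),
                  ("p1", "2024-01-01 20:00", True, "IV")),
            _enc(),
        )
        assert ledger.iv.sum() == 1 and ledger.iv[0]

    def test_iv_and_po_flags_tracked_separately(self):
        ledger = build_antibiotic_ledger(
            _meds(("p1", "2024-01-01 08:00", True, "IV"),
                  ("p1", "2024-01-02 08:00", True, "PO"),
                  ("p1", "2024-01-03 08:00", True, "PO"),
                  ("p1", "2024-01-04 08:00", True, "PO")),
            _enc(),
        )
        assert list(np.flatnonzero(ledger.iv)) == [0]
        assert list(np.flatnonzero(ledger.any)) == [0, 1, 2, 3]

    def test_non_antibiotic_meds_ignored(self):
        ledger = build_antibiotic_ledger(
            _meds(("p1", "2024-01-01 08:00", False, "IV")), _enc()
        )
        assert not ledger.any.any()


# ---------------------------------------------------------------------------
# Infection criterion: hand traces
# ---------------------------------------------------------------------------


def _day(d, hour=10):
    return pd.Timestamp("2024-01-01") + pd.Timedelta(days=d, hours=hour)


def _course(iv_days, po_days=()):
    rows = [("p1", _day(d), True, "IV") for d in iv_days]
    rows += [("p1", _day(d), True, "PO") for d in po_days]
    return _meds(*rows)


class TestInfection:
    def test_four_consecutive_days_after_culture(self):
        # culture day 3, IV starts day 4, antibiotics days 4-7
        ledger = build_antibiotic_ledger(_course([4], [5, 6, 7]), _enc())
        events = detect_infection(ledger, _cultures(_day(3)), _enc())
        assert len(events) == 1
        assert events[0].event_time == _day(3)

    def test_short_course_far_from_discharge_fails(self):
        ledger = build_antibiotic_ledger(_course([4], [5]), _enc())
        assert detect_infection(ledger, _cultures(_day(3)), _enc()) == []

    def test_short_course_censored_by_discharge_qualifies(self):
        enc = _enc(discharge="2024-01-07 00:00")  # discharge day 6
        ledger = build_antibiotic_ledger(_course([4], [5]), enc)
        events = detect_infection(ledger, _cultures(_day(3)), enc)
        assert len(events) == 1

    def test_antibiotics_without_culture_fail(self):
        ledger = build_antibiotic_ledger(_course([1], [2, 3, 4, 5, 6, 7]), _enc())
        assert detect_infection(ledger, _cultures(), _enc()) == []

    def test_iv_outside_two_day_window_fails(self):
        # culture day 0, IV starts day 3 (outside +/- 2 days)
        ledger = build_antibiotic_ledger(_course([3], [4, 5, 6]), _enc())
        assert detect_infection(ledger, _cultures(_day(0)), _enc()) == []

    def test_gap_breaks_the_streak(self):
        ledger = build_antibiotic_ledger(_course([2], [3, 5, 6]), _enc())
        assert detect_infection(ledger, _cultures(_day(2)), _enc()) == []


# ---------------------------------------------------------------------------
# Brute-force oracle on random ledgers
# ---------------------------------------------------------------------------


def infection_oracle(iv_days, any_days, culture_days, discharge_day):
    """Exhaustive day-by-day enumeration of the infection rule; independent
    of the run-length implementation."""
    qualifying = []
    for d in sorted(culture_days):
        for d0 in sorted(iv_days):
            if abs(d0 - d) > 2:
                continue
            streak4 = all(k in any_days for k in range(d0, d0 + 4))
            censored = d0 <= discharge_day - 1 and all(
                k in any_days for k in range(d0, discharge_day)
            )
            if streak4 or censored:
                qualifying.append(d)
                break
    return min(qualifying) if qualifying else None


def random_ledger_case(rng):
    discharge_day = int(rng.integers(2, 30))
    n_days = discharge_day + 1

    def pick(k_max):
        k = min(int(rng.integers(0, k_max)), n_days)
        return set(rng.choice(n_days, size=k, replace=False).tolist())

    iv_days = pick(6)
    any_days = iv_days | pick(8)
    culture_days = sorted(pick(4))
    return iv_days, any_days, culture_days, discharge_day


def run_oracle_comparison(n_cases, seed):
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_cases):
        iv_days, any_days, culture_days, discharge_day = random_ledger_case(rng)
        enc = _enc(discharge=str(pd.Timestamp("2024-01-01") + pd.Timedelta(days=discharge_day)))
        rows = [("p1", _day(d), True, "IV") for d in sorted(iv_days)]
        rows += [("p1", _day(d, hour=20), True, "PO") for d in sorted(any_days - iv_days)]
        ledger = build_antibiotic_ledger(_meds(*rows), enc)
        cultures = _cultures(*[_day(d, hour=8) for d in culture_days])
        got = detect_infection(ledger, cultures, enc)
        expected_day = infection_oracle(iv_days, any_days, culture_days, discharge_day)
        got_day = ledger.day_index(got[0].event_time) if got else None
        if got_day != expected_day:
            mismatches += 1
    return mismatches


def test_detector_matches_bruteforce_enumeration_on_random_ledgers():
    assert run_oracle_comparison(300, seed=2024) == 0


# ---------------------------------------------------------------------------
# Cohort-level dispatch
# ---------------------------------------------------------------------------


def test_cohort_level_infection_respects_ground_truth(small_sim):
    _, cohort, truth = small_sim
    events = eb.detect_outcomes(cohort, "INFECTION")
    detected = {e.patient_id for e in events}
    infected = set(truth.loc[truth.is_infected, "patient_id"])
    decoys = set(truth.loc[truth.has_decoy, "patient_id"])
    assert detected == infected          # sensitivity 1.0 on constructions
    assert not (detected & decoys)       # no false events on decoys


def test_cohort_level_deterioration_matches_qualifying_chains(small_sim):
    _, cohort, truth = small_sim
    events = eb.detect_outcomes(cohort, "DETERIORATION")
    detected = {e.patient_id for e in events}
    qualifying = set(truth.loc[truth.chain_qualifies, "patient_id"])
    non_qualifying = set(
        truth.loc[truth.is_deteriorator & ~truth.chain_qualifies
                  & (truth.chain_type == "non_qualifying"), "patient_id"]
    )
    assert qualifying <= detected
    assert not (detected & non_qualifying)
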