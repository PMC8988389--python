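"""Shared fixtures: tiny hand-built cohorts and a reusable simulated cohort."""

import pandas as pd
import pytest

from ewsbench.data_model import Cohort


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


def make_cohort(
    encounters=None, locations=None, vitals=None, labs=None, meds=None, cultures=None
) -> Cohort:
    """Build a Cohort from lists of tuples, with parsed timestamps."""
    enc = pd.DataFrame(
        encounters or [],
        columns=[
            "patient_id", "admit_time", "discharge_time", "death_time",
            "age_years", "bmi", "hypertensive_disorder", "diabetes",
            "race_ethnicity",
        ],
    )
    for c in ("admit_time", "discharge_time", "death_time"):
        enc[c] = pd.to_datetime(enc[c]) if len(enc) else pd.to_datetime(pd.Series([], dtype=object))
    loc = pd.DataFrame(locations or [], columns=["patient_id", "unit", "start_time", "end_time"])
    for c in ("start_time", "end_time"):
        loc[c] = pd.to_datetime(loc[c]) if len(loc) else pd.to_datetime(pd.Series([], dtype=object))
    vit = pd.DataFrame(vitals or [], columns=["patient_id", "time", "variable", "value"])
    vit["time"] = pd.to_datetime(vit["time"]) if len(vit) else pd.to_datetime(pd.Series([], dtype=object))
    lab = pd.DataFrame(labs or [], columns=["patient_id", "time", "analyte", "value"])
    lab["time"] = pd.to_datetime(lab["time"]) if len(lab) else pd.to_datetime(pd.Series([], dtype=object))
    med = pd.DataFrame(meds or [], columns=["patient_id", "time", "is_antibiotic", "route"])
    med["time"] = pd.to_datetime(med["time"]) if len(med) else pd.to_datetime(pd.Series([], dtype=object))
    cul = pd.DataFrame(cultures or [], columns=["patient_id", "order_time"])
    cul["order_time"] = (
        pd.to_datetime(cul["order_time"]) if len(cul) else pd.to_datetime(pd.Series([], dtype=object))
    )
    return Cohort(encounters=enc, locations=loc, vitals=vit, labs=lab, meds=med, cultures=cul)


def simple_encounter(pid="p1", admit="2024-01-01 00:00", discharge="2024-01-10 00:00",
                     death=None, **kw):
    return (
        pid, admit, discharge, death,
        kw.get("age_years", 28.0), kw.get("bmi", 31.0),
        kw.get("hypertensive_disorder", False), kw.get("diabetes", False),
        kw.get("race_ethnicity", "Black"),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated cohort with events, shared across tests."""
    import ewsbench as eb

    cfg = eb.SimConfig.test_scale(n_patients=300, seed=11, drift_scale=2.0)
    cohort, truth = eb.simulate_cohort(cfg)
    return cfg, cohort, truth
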