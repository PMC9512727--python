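from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from osteoepi import ClaimsBundle, SimConfig, default_code_map


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


def make_bundle(enrollment=None, prescriptions=None, diagnoses=None,
                procedures=None) -> ClaimsBundle:
    """Build a small claims bundle from row dicts, filling sensible defaults."""
    enr = pd.DataFrame(enrollment or [], columns=[
        "person_id", "birth_date", "enroll_start", "enroll_end", "death_date"])
    rx = pd.DataFrame(prescriptions or [], columns=[
        "person_id", "drug_class", "fill_date", "days_supplied"])
    dx = pd.DataFrame(diagnoses or [], columns=["person_id", "code", "date", "setting"])
    px = pd.DataFrame(procedures or [], columns=["person_id", "code", "date"])
    for df, cols in ((enr, ["birth_date", "enroll_start", "enroll_end", "death_date"]),
                     (rx, ["fill_date"]), (dx, ["date"]), (px, ["date"])):
        for c in cols:
            df[c] = pd.to_datetime(df[c]) if len(df) else pd.Series(dtype="datetime64[ns]")
    return ClaimsBundle(enr, rx, dx, px, default_code_map())


def enrolled(person_id="P1", birth="1945-06-01", start="2011-01-01",
             end="2018-12-31", death=None) -> dict:
    return {"person_id": person_id, "birth_date": birth, "enroll_start": start,
            "enroll_end": end, "death_date": death}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_patients=400, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    from osteoepi import generate_bundle

    return generate_bundle(small_cfg)
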