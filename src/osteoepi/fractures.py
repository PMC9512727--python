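"""Fracture-event ascertainment from claims diagnoses and procedures.

A fracture diagnosis qualifies as an event candidate when it is either an
inpatient diagnosis, or an outpatient diagnosis accompanied by a
fracture-related procedure within ``proc_window_days`` (default +/-30 days).
Qualified diagnoses are then de-duplicated into events: per person and
fracture site, diagnoses are chained while consecutive gaps are at most 90
days ("within 3 months of each other"), so a chain of follow-up codings for
one fracture collapses into a single event dated at its first diagnosis.
Different sites never merge.  Codes that the code map does not recognise are
ignored (counted in the module log).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codes import CodeMap

logger = logging.getLogger(__name__)

MERGE_WINDOW_DAYS = 90

EVENT_COLS = ["person_id", "site", "event_date", "source", "n_diagnoses"]


def qualify_diagnoses(diagnoses: pd.DataFrame, procedures: pd.DataFrame,
                      code_map: CodeMap, proc_window_days: int = 30) -> pd.DataFrame:
    """Return qualifying fracture diagnoses with site labels and source arm."""
    for col in ("person_id", "code", "date", "setting"):
        if col not in diagnoses.columns:
            raise ValueError(f"diagnoses table missing required column {col!r}")
    dx = diagnoses.copy()
    dx["site"] = code_map.site_series(dx["code"])
    unmapped = int(dx["site"].isna().sum())
    if unmapped:
        logger.info("ignored %d diagnoses with unmapped codes", unmapped)
    dx = dx.dropna(subset=["site"])
    if dx.empty:
        return pd.DataFrame(columns=["person_id", "site", "date", "source"])

    inpatient = dx["setting"] == "inpatient"
    out = dx[~inpatient]
    linked = pd.Series(False, index=out.index)
    if len(out):
        px = procedures.loc[
            code_map.fracture_procedure_mask(procedures["code"]), ["person_id", "date"]]
        proc_days = {p: np.sort(g["date"].values.astype("datetime64[D]").astype(int))
                     for p, g in px.groupby("person_id")}
        win = int(proc_window_days)
        days = out["date"].values.astype("datetime64[D]").astype(int)
        ok = np.zeros(len(out), dtype=bool)
        for j, (pid, d) in enumerate(zip(out["person_id"].to_numpy(), days)):
            pdays = proc_days.get(pid)
            if pdays is None:
                continue
            lo = np.searchsorted(pdays, d - win, side="left")
            ok[j] = lo < len(pdays) and pdays[lo] <= d + win
        linked = pd.Series(ok, index=out.index)

    keep = dx[inpatient | linked.reindex(dx.index, fill_value=False)].copy()
    keep["source"] = np.where(keep["setting"] == "inpatient",
                              "inpatient", "outpatient_plus_procedure")
    return (keep[["person_id", "site", "date", "source"]]
            .sort_values(["person_id", "site", "date"], kind="stable")
            .reset_index(drop=True))


def merge_events(qualified: pd.DataFrame,
                 merge_window_days: int = MERGE_WINDOW_DAYS) -> pd.DataFrame:
    """Collapse qualified diagnoses into fracture events (rolling chain).

    Within each (person, site) group sorted by date, a diagnosis at most
    ``merge_window_days`` after the previous one in the chain belongs to the
    same event; the event is dated and sourced from the chain's first
    diagnosis.  The operation is idempotent and independent of input order.
    """
    if qualified.empty:
        return pd.DataFrame(columns=EVENT_COLS)
    q = qualified.sort_values(["person_id", "site", "date"], kind="stable").copy()
    same_group = (
        q["person_id"].eq(q["person_id"].shift())
        & q["site"].eq(q["site"].shift())
    )
    gap = q["date"].diff().dt.days
    new_event = ~(same_group & (gap <= merge_window_days))
    q["event_id"] = new_event.cumsum()
    events = q.groupby("event_id", sort=True).agg(
        person_id=("person_id", "first"),
        site=("site", "first"),
        event_date=("date", "first"),
        source=("source", "first"),
        n_diagnoses=("date", "size"),
    ).reset_index(drop=True)
    return events


def find_fracture_events(diagnoses: pd.DataFrame, procedures: pd.DataFrame,
                         code_map: CodeMap, proc_window_days: int = 30,
                         merge_window_days: int = MERGE_WINDOW_DAYS) -> pd.DataFrame:
    """Qualification followed by same-event merging."""
    qualified = qualify_diagnoses(diagnoses, procedures, code_map, proc_window_days)
    return merge_events(qualified, merge_window_days)
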