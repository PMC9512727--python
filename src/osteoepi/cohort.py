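"""Cohort selection: eligibility funnel and hierarchical treatment assignment.

The analysis population is new users of an osteoporosis medication: women aged
50+ at their index date (first fill of the assigned class inside the inclusion
window), with at least 24 months of pre-index enrollment, no blanket-exclusion
diagnosis (cancer, Paget's disease, osteogenesis imperfecta) anywhere in their
pre-index history, and no fill of the index class during the 24-month washout.
Patients filling several classes are assigned to a single treatment group by a
fixed hierarchy (denosumab > IV bisphosphonates > oral bisphosphonates >
teriparatide > raloxifene > HRT); within the IV tier the first-filled
sub-class wins.  Oestrogen-only fills qualify as HRT only for women with a
hysterectomy procedure on record before the fill.

``select_cohort`` returns the members plus an attrition table, one row per
criterion, so the funnel can be audited.  Members with less than 6 months of
observable follow-up are flagged (kept for treatment-pattern analyses,
excluded from the fracture analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codes import CodeMap
from .config import HIERARCHY, SelectionParams
from .simulate import ClaimsBundle

_TIER_OF = {cls: t for t, tier in enumerate(HIERARCHY) for cls in tier}

_REQUIRED = {
    "enrollment": ["person_id", "birth_date", "enroll_start", "enroll_end", "death_date"],
    "prescriptions": ["person_id", "drug_class", "fill_date", "days_supplied"],
    "diagnoses": ["person_id", "code", "date", "setting"],
    "procedures": ["person_id", "code", "date"],
}


def _check_schema(bundle: ClaimsBundle) -> None:
    for name, cols in _REQUIRED.items():
        df = getattr(bundle, name)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing required columns: {missing}")


def normalize_fills(prescriptions: pd.DataFrame, procedures: pd.DataFrame,
                    code_map: CodeMap) -> pd.DataFrame:
    """Resolve qualifying drug classes: map oestrogen-only fills to ``hrt``
    when a hysterectomy procedure precedes the fill, drop them otherwise."""
    fills = prescriptions.copy()
    est = fills["drug_class"] == "estrogen"
    if est.any():
        px = procedures.loc[code_map.hysterectomy_mask(procedures["code"])]
        first_hyst = px.groupby("person_id")["date"].min()
        hyst_date = fills["person_id"].map(first_hyst)
        ok = est & hyst_date.notna() & (hyst_date <= fills["fill_date"])
        fills = fills[~est | ok].copy()
        fills.loc[fills["drug_class"] == "estrogen", "drug_class"] = "hrt"
    return fills


def assign_treatment_group(person_fills: pd.DataFrame) -> tuple[str, pd.Timestamp] | None:
    """Hierarchical assignment for one person's qualifying in-window fills.

    Returns ``(treatment_group, index_date)`` with the index date the first
    fill of the winning class, or None when no fill maps to a known class.
    """
    fills = person_fills[person_fills["drug_class"].isin(_TIER_OF)]
    if fills.empty:
        return None
    tiers = fills["drug_class"].map(_TIER_OF)
    top = fills[tiers == tiers.min()].sort_values(["fill_date", "drug_class"], kind="stable")
    group = top.iloc[0]["drug_class"]
    index_date = top.loc[top["drug_class"] == group, "fill_date"].min()
    return group, pd.Timestamp(index_date)


def _assign_all(fills_window: pd.DataFrame) -> pd.DataFrame:
    """Vectorised hierarchical assignment over all persons."""
    fills = fills_window[fills_window["drug_class"].isin(_TIER_OF)].copy()
    if fills.empty:
        return pd.DataFrame(columns=["person_id", "treatment_group", "index_date"])
    fills["tier"] = fills["drug_class"].map(_TIER_OF)
    min_tier = fills.groupby("person_id")["tier"].transform("min")
    top = fills[fills["tier"] == min_tier].sort_values(
        ["person_id", "fill_date", "drug_class"], kind="stable")
    first = top.drop_duplicates("person_id", keep="first")[
        ["person_id", "drug_class"]].rename(columns={"drug_class": "treatment_group"})
    chosen = top.merge(first, on="person_id")
    chosen = chosen[chosen["drug_class"] == chosen["treatment_group"]]
    index_date = chosen.groupby("person_id")["fill_date"].min().rename("index_date")
    return first.merge(index_date, on="person_id")


def select_cohort(bundle: ClaimsBundle,
                  params: SelectionParams | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility funnel; return (members, attrition)."""
    params = params or SelectionParams()
    _check_schema(bundle)
    code_map = bundle.code_map
    enrollment = bundle.enrollment

    attrition_rows: list[tuple[str, int, int, int]] = []
    n_start = enrollment["person_id"].nunique()

    fills = normalize_fills(bundle.prescriptions, bundle.procedures, code_map)
    lo, hi = pd.Timestamp(params.inclusion_start), pd.Timestamp(params.inclusion_end)
    in_window = fills[(fills["fill_date"] >= lo) & (fills["fill_date"] <= hi)]
    members = _assign_all(in_window)
    members["index_date"] = pd.to_datetime(members["index_date"])

    def step(name: str, keep: pd.Series) -> None:
        nonlocal members
        before = len(members)
        members = members[keep.values].copy() if before else members
        attrition_rows.append((name, before, before - len(members), len(members)))

    attrition_rows.append((
        "osteoporosis_medication_in_window", n_start, n_start - len(members), len(members)))

    members = members.merge(
        enrollment[["person_id", "birth_date", "enroll_start", "enroll_end", "death_date"]],
        on="person_id", how="left")

    age = (members["index_date"] - members["birth_date"]).dt.days / 365.25
    members["age_at_index"] = age
    step("age_ge_50", age >= params.min_age)

    history_days = (members["index_date"] - members["enroll_start"]).dt.days
    step("history_ge_24_months", history_days >= params.lookback_days)

    dx = bundle.diagnoses
    excl_dx = dx.loc[code_map.exclusion_mask(dx["code"]), ["person_id", "date"]]
    idx_of = members.set_index("person_id")["index_date"]
    if len(excl_dx) and len(members):
        pre = excl_dx[excl_dx["date"] < excl_dx["person_id"].map(idx_of)]
        has_excl = members["person_id"].isin(pre["person_id"].unique())
    else:
        has_excl = pd.Series(False, index=members.index)
    step("no_exclusion_diagnosis", ~has_excl)

    if len(members):
        mm = members[["person_id", "treatment_group", "index_date"]]
        f = fills.merge(mm, on="person_id")
        washout = f[
            (f["drug_class"] == f["treatment_group"])
            & (f["fill_date"] < f["index_date"])
            & (f["fill_date"] >= f["index_date"] - pd.Timedelta(days=params.lookback_days))
        ]
        violates = members["person_id"].isin(washout["person_id"].unique())
    else:
        violates = pd.Series(False, index=members.index, dtype=bool)
    step("new_user_washout_24_months", ~violates)

    fup_end = members["enroll_end"].clip(upper=pd.Timestamp(params.admin_censor_date))
    followup_days = (fup_end - members["index_date"]).dt.days
    members["followup_days_observable"] = followup_days
    members["followup_ok"] = followup_days >= params.min_followup_days
    n_ok = int(members["followup_ok"].sum())
    attrition_rows.append((
        "min_6_months_followup_for_fracture_analysis",
        len(members), len(members) - n_ok, n_ok))

    attrition = pd.DataFrame(
        attrition_rows, columns=["criterion", "n_before", "n_excluded", "n_after"])
    members = members.sort_values("person_id").reset_index(drop=True)
    return members, attrition


def baseline_covariates(members: pd.DataFrame, bundle: ClaimsBundle,
                        lookback_days: int = 730,
                        proc_window_days: int = 30) -> pd.DataFrame:
    """Pre-index baseline flags: prior fracture (any and per key site) from
    qualified pre-index fracture diagnoses, and prior osteoporosis treatment
    (any non-index-class fill in the lookback window)."""
    from .fractures import qualify_diagnoses

    out = members.copy()
    for col in ("prior_fracture", "prior_vertebral", "prior_hip", "prior_wrist",
                "prior_osteoporosis_treatment"):
        out[col] = False
    if out.empty:
        return out
    idx_of = out.set_index("person_id")["index_date"]

    dx = bundle.diagnoses[bundle.diagnoses["person_id"].isin(idx_of.index)]
    qualified = qualify_diagnoses(dx, bundle.procedures, bundle.code_map,
                                  proc_window_days=proc_window_days)
    if len(qualified):
        q = qualified.copy()
        q["index_date"] = q["person_id"].map(idx_of)
        q = q[(q["date"] < q["index_date"])
              & (q["date"] >= q["index_date"] - pd.Timedelta(days=lookback_days))]
        flags = {
            "prior_fracture": set(q["person_id"]),
            "prior_vertebral": set(q.loc[q["site"] == "clinical_vertebral", "person_id"]),
            "prior_hip": set(q.loc[q["site"] == "hip", "person_id"]),
            "prior_wrist": set(q.loc[q["site"] == "wrist_forearm", "person_id"]),
        }
        for col, persons in flags.items():
            out[col] = out["person_id"].isin(persons)

    fills = normalize_fills(bundle.prescriptions, bundle.procedures, bundle.code_map)
    f = fills.merge(out[["person_id", "treatment_group", "index_date"]], on="person_id")
    prior = f[
        (f["fill_date"] < f["index_date"])
        & (f["fill_date"] >= f["index_date"] - pd.Timedelta(days=lookback_days))
        & (f["drug_class"] != f["treatment_group"])
    ]
    out["prior_osteoporosis_treatment"] = out["person_id"].isin(prior["person_id"].unique())
    return out
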