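"""Windowed incidence rates and own-control incidence rate ratios.

As-treated person-time runs from the index date to the episode end and is cut
at fixed day boundaries into an early-treatment window (days 0-89, the
within-person baseline, assumed free of treatment effect) and four
on-treatment windows (months 4-12, 13-24, 25-36, 37-48; days 90-1460).
Follow-up is capped at 48 months.  All fracture events inside the as-treated
span are counted (recurrent events included); rates are reported per 1000
person-years.

Effectiveness is the incidence rate ratio (IRR) of each on-treatment window
against the early window, each patient serving as their own control.  Two
interval methods are provided and reported in the output metadata: a Wald
interval on the log rate ratio, exp(ln IRR +/- 1.96 sqrt(1/N1 + 1/N0)), and
an exact-conditional interval from the binomial distribution of the
on-treatment event count given the total (used automatically when either
count is small).  Within-person correlation of recurrent events is not
adjusted for.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import FOLLOWUP_CAP_DAYS, ON_TREATMENT_WINDOWS, WINDOW_BOUNDS

logger = logging.getLogger(__name__)

WINDOW_IDS = tuple(w for w, _, _ in WINDOW_BOUNDS)
_BOUNDS = {w: (lo, hi) for w, lo, hi in WINDOW_BOUNDS}
DAYS_PER_YEAR = 365.25

RATE_COLS = ["window", "events", "person_years", "rate_per_1000py"]


def split_person_time(duration_days: int) -> dict[str, int]:
    """Days contributed to each analysis window by one episode.

    The contributions partition ``[0, min(duration, 1460))`` exactly.
    """
    if duration_days < 0:
        raise ValueError("negative episode duration")
    capped = min(int(duration_days), FOLLOWUP_CAP_DAYS)
    return {w: max(0, min(capped, hi) - lo) for w, (lo, hi) in _BOUNDS.items()}


def person_days_by_window(durations: pd.Series) -> pd.DataFrame:
    """Vectorised :func:`split_person_time` over a duration series."""
    if (durations < 0).any():
        raise ValueError("negative episode duration")
    capped = np.minimum(durations.to_numpy(dtype=float), FOLLOWUP_CAP_DAYS)
    out = {}
    for w, (lo, hi) in _BOUNDS.items():
        out[w] = np.maximum(0, np.minimum(capped, hi) - lo)
    return pd.DataFrame(out, index=durations.index)


def assign_event_windows(events: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Attach an analysis window to each event falling inside as-treated
    follow-up; events outside ``[index, min(episode_end, index+1460))`` drop."""
    if events.empty or episodes.empty:
        return events.assign(window=pd.Series(dtype=object)).iloc[0:0]
    df = events.merge(
        episodes[["person_id", "treatment_group", "start", "duration_days"]],
        on="person_id", how="inner")
    df["day"] = (df["event_date"] - df["start"]).dt.days
    cap = np.minimum(df["duration_days"], FOLLOWUP_CAP_DAYS)
    df = df[(df["day"] >= 0) & (df["day"] < cap)].copy()
    edges = [lo for _, lo, _ in WINDOW_BOUNDS] + [FOLLOWUP_CAP_DAYS]
    df["window"] = pd.cut(df["day"], bins=edges, right=False,
                          labels=list(WINDOW_IDS)).astype(object)
    return df


def window_rates(event_windows: pd.Series, person_days: dict | pd.Series) -> pd.DataFrame:
    """Events, person-years and rate per 1000 PY for every analysis window."""
    counts = pd.Series(event_windows).value_counts()
    rows = []
    for w in WINDOW_IDS:
        n = int(counts.get(w, 0))
        py = float(person_days.get(w, 0.0)) / DAYS_PER_YEAR
        if py <= 0 and n > 0:
            raise RuntimeError(f"window {w}: {n} events with zero person-time")
        rate = 1000.0 * n / py if py > 0 else 0.0
        rows.append((w, n, py, rate))
    return pd.DataFrame(rows, columns=RATE_COLS)


def pct_reduction(irr_value: float) -> float:
    """Percent reduction in the fracture rate implied by an IRR."""
    return (1.0 - irr_value) * 100.0


def _exact_ci(n1: int, n0: int, py1: float, py0: float,
              alpha: float = 0.05) -> tuple[float, float]:
    """Exact-conditional CI for the rate ratio: Clopper-Pearson on the
    binomial share p = n1/(n1+n0), mapped to r = odds(p) * py0/py1."""
    scale = py0 / py1
    lo = 0.0 if n1 == 0 else float(stats.beta.ppf(alpha / 2, n1, n0 + 1))
    hi = 1.0 if n0 == 0 else float(stats.beta.ppf(1 - alpha / 2, n1 + 1, n0))
    r_lo = scale * lo / (1 - lo) if lo < 1 else np.inf
    r_hi = scale * hi / (1 - hi) if hi < 1 else np.inf
    return r_lo, r_hi


def irr(early_events: int, early_py: float, ontx_events: int, ontx_py: float,
        method: str = "auto", small_count_threshold: int = 5) -> dict:
    """Own-control IRR of an on-treatment window versus the early window.

    Returns a dict with the point estimate, 95% CI, percent reduction,
    the interval method actually used, and a ``flagged`` marker when the
    early window has no events (IRR undefined; exact bounds still given).
    """
    n0, n1 = int(early_events), int(ontx_events)
    py0, py1 = float(early_py), float(ontx_py)
    if py0 <= 0 or py1 <= 0:
        raise ValueError("irr requires positive person-time in both windows")
    use = method
    if method == "auto":
        use = "wald" if min(n0, n1) >= small_count_threshold else "exact"
    if use not in ("wald", "exact"):
        raise ValueError(f"unknown CI method {method!r}")

    flagged = n0 == 0
    if flagged:
        lo, hi = _exact_ci(n1, n0, py1, py0)
        return {"N": n1, "irr": np.nan, "ci_low": lo, "ci_high": hi,
                "pct_reduction": np.nan, "method_used": "exact", "flagged": True}

    point = (n1 / py1) / (n0 / py0)
    if use == "wald" and n1 > 0:
        se = np.sqrt(1.0 / n1 + 1.0 / n0)
        lo, hi = np.exp(np.log(point) - 1.96 * se), np.exp(np.log(point) + 1.96 * se)
        used = "wald"
    else:
        lo, hi = _exact_ci(n1, n0, py1, py0)
        used = "exact"
    return {"N": n1, "irr": point, "ci_low": lo, "ci_high": hi,
            "pct_reduction": pct_reduction(point), "method_used": used,
            "flagged": False}


# ---------------------------------------------------------------------------
# cohort-level tables

def _type_mask(events: pd.DataFrame, fracture_type: str) -> pd.Series:
    if fracture_type == "all":
        return pd.Series(True, index=events.index)
    return events["site"] == fracture_type


def rate_table(episodes: pd.DataFrame, events: pd.DataFrame,
               fracture_types=("all", "clinical_vertebral", "hip", "wrist_forearm"),
               ) -> pd.DataFrame:
    """Long rate table: one row per treatment group x fracture type x window."""
    if episodes.empty:
        return pd.DataFrame(
            columns=["treatment_group", "fracture_type"] + RATE_COLS)
    ew = assign_event_windows(events, episodes)
    pieces = []
    for group, epi in episodes.groupby("treatment_group", sort=True):
        days = person_days_by_window(epi["duration_days"]).sum()
        gev = ew[ew["treatment_group"] == group]
        for ftype in fracture_types:
            sub = gev[_type_mask(gev, ftype)]
            rates = window_rates(sub["window"], days)
            rates.insert(0, "fracture_type", ftype)
            rates.insert(0, "treatment_group", group)
            pieces.append(rates)
    return pd.concat(pieces, ignore_index=True)


def irr_table(rates: pd.DataFrame, method: str = "auto",
              small_count_threshold: int = 5) -> pd.DataFrame:
    """Own-control IRRs for every (group, fracture type, on-treatment window)."""
    rows = []
    keys = ["treatment_group", "fracture_type"]
    for (group, ftype), sub in rates.groupby(keys, sort=True):
        sub = sub.set_index("window")
        early = sub.loc["early"]
        if early["person_years"] <= 0:
            logger.info("no early-window person-time for %s/%s; skipped", group, ftype)
            continue
        for w in ON_TREATMENT_WINDOWS:
            ontx = sub.loc[w]
            if ontx["person_years"] <= 0:
                continue
            res = irr(early["events"], early["person_years"],
                      ontx["events"], ontx["person_years"],
                      method=method, small_count_threshold=small_count_threshold)
            rows.append({"treatment_group": group, "fracture_type": ftype,
                         "window": w, **res})
    return pd.DataFrame(rows)


def stratified_analysis(members: pd.DataFrame, episodes: pd.DataFrame,
                        events: pd.DataFrame, stratifier: str,
                        method: str = "auto",
                        small_count_threshold: int = 5,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rate and IRR tables per stratum of a baseline flag.

    ``stratifier`` names a boolean column of ``members`` (e.g.
    ``prior_fracture`` or ``prior_osteoporosis_treatment``).  Strata with no
    person-time are omitted with a log notice.
    """
    if stratifier not in members.columns:
        raise ValueError(f"members has no stratifier column {stratifier!r}")
    rate_parts, irr_parts = [], []
    for value, label in ((False, f"no_{stratifier}"), (True, stratifier)):
        persons = members.loc[members[stratifier] == value, "person_id"]
        epi = episodes[episodes["person_id"].isin(persons)]
        if epi.empty or epi["duration_days"].sum() == 0:
            logger.info("stratum %s empty; omitted", label)
            continue
        ev = events[events["person_id"].isin(persons)]
        rates = rate_table(epi, ev)
        irrs = irr_table(rates, method=method,
                         small_count_threshold=small_count_threshold)
        rates.insert(0, "stratum", label)
        if len(irrs):
            irrs.insert(0, "stratum", label)
        rate_parts.append(rates)
        irr_parts.append(irrs)
    rates = (pd.concat(rate_parts, ignore_index=True) if rate_parts
             else pd.DataFrame())
    irrs = (pd.concat(irr_parts, ignore_index=True) if irr_parts
            else pd.DataFrame())
    return rates, irrs


def format_irr_display(irrs: pd.DataFrame) -> pd.DataFrame:
    """Display table: N and 'IRR (low-high)' strings, 2 decimals."""
    out = irrs.copy()
    def fmt(row):
        if row["flagged"] or not np.isfinite(row["irr"]):
            return "--"
        return f"{row['irr']:.2f} ({row['ci_low']:.2f}-{row['ci_high']:.2f})"
    out["irr_95ci"] = out.apply(fmt, axis=1) if len(out) else pd.Series(dtype=object)
    cols = [c for c in ("stratum", "treatment_group", "fracture_type", "window", "N")
            if c in out.columns]
    return out[cols + ["irr_95ci"]]
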