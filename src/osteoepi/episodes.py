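"""Treatment episodes from prescription fills: the refill-gap persistence rule.

A patient is continuously treated while each subsequent index-class fill
occurs no more than ``gap_days`` (default 60) after the *expected refill
date* (previous fill date + days supplied).  When the grace period passes
without an index refill, the episode ends:

* at the fill date of a different osteoporosis class started inside the
  grace window -> ``switched`` (chronological precedence: if both an index
  refill and another class appear in the window, whichever is filled first
  decides, index refill winning a same-day tie);
* otherwise at the expected refill date -> ``discontinued`` (the supplied
  coverage end; as-treated person-time excludes unexposed grace days; the
  alternative convention ``grace_end`` is available via configuration).

Death, disenrollment and the administrative study end truncate episodes
earlier, whatever the fill schedule says.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import EpisodeParams

logger = logging.getLogger(__name__)

EPISODE_COLS = ["person_id", "treatment_group", "start", "supply_end",
                "episode_end", "end_reason", "switched_to", "duration_days"]


def episode_end_days(fill_days, other_fills, days_supplied: int,
                     censor_day: int, censor_reason: str,
                     gap_days: int = 60, switch_window_days: int = 60,
                     discontinuation_at: str = "supply_end",
                     ) -> tuple[int, str, str | None, int]:
    """Core gap-rule scan on integer days relative to the index date.

    ``fill_days``: index-class fill days (day 0 = index fill); ``other_fills``:
    iterable of ``(day, drug_class)`` for fills of any other class.  Returns
    ``(end_day, end_reason, switched_to, supply_end_day)``.
    """
    fills = sorted(set(int(d) for d in fill_days))
    if not fills:
        raise ValueError("episode requires at least one index-class fill")
    if len(fills) != len(list(fill_days)):
        logger.warning("duplicate same-day fills collapsed")
    dropped = [d for d in fills if d > censor_day]
    if dropped:
        logger.warning("%d fill(s) after censor date dropped", len(dropped))
        fills = [d for d in fills if d <= censor_day]
        if not fills:
            raise ValueError("all fills fall after the censor date")
    others = sorted((int(d), c) for d, c in other_fills)

    k = 0
    while True:
        expected_refill = fills[k] + days_supplied
        supply_end = expected_refill
        if expected_refill >= censor_day:
            return censor_day, censor_reason, None, supply_end
        nxt = fills[k + 1] if k + 1 < len(fills) else None
        switch = next(
            (
                (d, c) for d, c in others
                if expected_refill < d <= expected_refill + switch_window_days
                and d <= censor_day
            ),
            None,
        )
        if nxt is not None and nxt <= expected_refill + gap_days and (
                switch is None or nxt <= switch[0]):
            k += 1
            continue
        if switch is not None:
            return switch[0], "switched", switch[1], supply_end
        if discontinuation_at == "grace_end":
            end = expected_refill + gap_days
            if end >= censor_day:
                return censor_day, censor_reason, None, supply_end
            return end, "discontinued", None, supply_end
        return expected_refill, "discontinued", None, supply_end


def hard_censor(index_date: pd.Timestamp, enroll_end: pd.Timestamp,
                death_date, admin_end: pd.Timestamp) -> tuple[int, str]:
    """Observable end of follow-up (day relative to index) and its reason.

    Death takes precedence on ties; an enrollment end that coincides with the
    administrative study end is administrative censoring, an earlier one is
    disenrollment.
    """
    end = min(enroll_end, admin_end)
    if pd.notna(death_date) and death_date <= end:
        return (death_date - index_date).days, "death"
    if end < admin_end:
        return (end - index_date).days, "disenrolled"
    return (end - index_date).days, "admin_end"


def build_episode(index_fills: pd.Series, other_fills: pd.DataFrame,
                  index_date: pd.Timestamp, days_supplied: int,
                  enroll_end: pd.Timestamp, death_date, admin_end: pd.Timestamp,
                  params: EpisodeParams | None = None) -> dict:
    """Build one member's index-treatment episode (date-level wrapper)."""
    params = params or EpisodeParams()
    censor_day, censor_reason = hard_censor(index_date, enroll_end, death_date, admin_end)
    fill_days = [(pd.Timestamp(d) - index_date).days for d in index_fills]
    others = [
        ((pd.Timestamp(d) - index_date).days, c)
        for d, c in zip(other_fills["fill_date"], other_fills["drug_class"])
    ]
    end, reason, switched_to, supply_end = episode_end_days(
        fill_days, others, days_supplied, censor_day, censor_reason,
        gap_days=params.gap_days, switch_window_days=params.switch_window_days,
        discontinuation_at=params.discontinuation_at)
    return {
        "start": index_date,
        "supply_end": index_date + pd.Timedelta(days=supply_end),
        "episode_end": index_date + pd.Timedelta(days=end),
        "end_reason": reason,
        "switched_to": switched_to,
        "duration_days": int(end),
    }


def build_episodes(members: pd.DataFrame, fills: pd.DataFrame,
                   days_supplied: dict, admin_end,
                   params: EpisodeParams | None = None) -> pd.DataFrame:
    """Episodes for every cohort member.  ``fills`` must be normalised
    (oestrogen-only resolved) prescription rows."""
    params = params or EpisodeParams()
    admin_end = pd.Timestamp(admin_end)
    if members.empty:
        return pd.DataFrame(columns=EPISODE_COLS)

    fills = fills.merge(
        members[["person_id", "treatment_group", "index_date"]], on="person_id")
    fills["day"] = (fills["fill_date"] - fills["index_date"]).dt.days
    fills = fills[fills["day"] >= 0]
    is_index = fills["drug_class"] == fills["treatment_group"]
    idx_days = {p: g["day"].to_numpy()
                for p, g in fills[is_index].groupby("person_id")}
    oth = {p: list(zip(g["day"], g["drug_class"]))
           for p, g in fills[~is_index].groupby("person_id")}

    rows = []
    for m in members.itertuples(index=False):
        censor_day, censor_reason = hard_censor(
            m.index_date, m.enroll_end, m.death_date, admin_end)
        end, reason, switched_to, supply_end = episode_end_days(
            idx_days.get(m.person_id, [0]), oth.get(m.person_id, []),
            int(days_supplied[m.treatment_group]), censor_day, censor_reason,
            gap_days=params.gap_days,
            switch_window_days=params.switch_window_days,
            discontinuation_at=params.discontinuation_at)
        rows.append((m.person_id, m.treatment_group, m.index_date,
                     m.index_date + pd.Timedelta(days=supply_end),
                     m.index_date + pd.Timedelta(days=end),
                     reason, switched_to, int(end)))
    return pd.DataFrame(rows, columns=EPISODE_COLS)


def duration_summary(episodes: pd.DataFrame,
                     prior_treatment: pd.Series | None = None) -> pd.DataFrame:
    """Median (IQR) episode duration per treatment group, overall and by
    prior-osteoporosis-treatment stratum."""
    df = episodes.copy()
    strata = {"overall": pd.Series(True, index=df.index)}
    if prior_treatment is not None:
        flag = df["person_id"].map(prior_treatment).astype(bool)
        strata["no_prior_treatment"] = ~flag
        strata["prior_treatment"] = flag

    rows = []
    groups = sorted(df["treatment_group"].unique())
    for group in groups:
        for stratum, mask in strata.items():
            d = df.loc[(df["treatment_group"] == group) & mask, "duration_days"]
            if d.empty:
                rows.append((group, stratum, 0, np.nan, np.nan))
            else:
                q1, med, q3 = np.percentile(d, [25, 50, 75])
                rows.append((group, stratum, len(d), med, q3 - q1))
    return pd.DataFrame(
        rows, columns=["treatment_group", "stratum", "n", "median_days", "iqr_days"])
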