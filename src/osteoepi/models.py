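"""Secondary analyses: rate trend over on-treatment periods and an
age-adjusted conditional Poisson sensitivity model.

*Trend*: a weighted linear model of the on-treatment window rates (per 1000
person-years) on the window index 1..4; the slope is the change in fracture
rate per on-treatment period.  The weights are the window person-years by
default (precision weighting), configurable to equal weights; the choice is
echoed in the output.

*Age adjustment*: fracture counts per (person, window) with a log
person-years offset follow a Poisson model with a person-specific baseline
rate.  Conditioning on each person's total event count removes the baseline
(the person's nuisance parameter) via the multinomial representation of the
within-person counts, leaving the within-person effects: age at the window's
exposure midpoint (a time-varying covariate) and, optionally, on-treatment
window indicators.  The exponentiated age coefficient is the rate ratio per
additional year of age.  Persons with no events or a single observed window
drop out of the conditional likelihood by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ON_TREATMENT_WINDOWS, WINDOW_BOUNDS, FOLLOWUP_CAP_DAYS
from .incidence import DAYS_PER_YEAR, assign_event_windows, person_days_by_window

logger = logging.getLogger(__name__)


def fit_trend(rates: pd.DataFrame, weights: str = "person_years") -> dict:
    """Weighted linear fit of on-treatment rates against window index 1..4.

    ``rates`` is one group's rate table (long form).  Windows with zero
    person-years are unusable; with fewer than two usable windows the fit is
    flagged missing.
    """
    sub = rates.set_index("window").reindex(list(ON_TREATMENT_WINDOWS)).dropna()
    sub = sub[sub["person_years"] > 0]
    if len(sub) < 2:
        return {"slope": np.nan, "intercept": np.nan,
                "weights_used": weights, "n_windows": len(sub), "fitted": False}
    period = np.array([ON_TREATMENT_WINDOWS.index(w) + 1 for w in sub.index], float)
    y = sub["rate_per_1000py"].to_numpy(dtype=float)
    if weights == "person_years":
        w = sub["person_years"].to_numpy(dtype=float)
    elif weights == "equal":
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown trend weights {weights!r}")
    X = sm.add_constant(period)
    fit = sm.WLS(y, X, weights=w).fit()
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "weights_used": weights, "n_windows": len(sub), "fitted": True}


def trend_table(rates: pd.DataFrame, weights: str = "person_years") -> pd.DataFrame:
    """Trend slope per treatment group x fracture type."""
    rows = []
    for (group, ftype), sub in rates.groupby(
            ["treatment_group", "fracture_type"], sort=True):
        res = fit_trend(sub, weights=weights)
        rows.append({"treatment_group": group, "fracture_type": ftype, **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# age-adjusted conditional Poisson

def build_age_panel(members: pd.DataFrame, episodes: pd.DataFrame,
                    events: pd.DataFrame) -> pd.DataFrame:
    """(person, window) panel: event count, person-days and age at the
    exposure midpoint of the window (years, advancing across windows)."""
    epi = episodes.merge(members[["person_id", "age_at_index"]], on="person_id")
    days = person_days_by_window(epi["duration_days"])
    bounds = {w: (lo, hi) for w, lo, hi in WINDOW_BOUNDS}

    ew = assign_event_windows(events, episodes)
    counts = (ew.groupby(["person_id", "window"]).size()
              if len(ew) else pd.Series(dtype=int))

    rows = []
    for i, m in enumerate(epi.itertuples(index=False)):
        cap = min(m.duration_days, FOLLOWUP_CAP_DAYS)
        for w, (lo, hi) in bounds.items():
            d = days.iloc[i][w]
            if d <= 0:
                continue
            mid_day = (lo + min(cap, hi)) / 2.0
            rows.append((
                m.person_id, w,
                int(counts.get((m.person_id, w), 0)) if len(counts) else 0,
                float(d), m.age_at_index + mid_day / DAYS_PER_YEAR,
            ))
    return pd.DataFrame(
        rows, columns=["person_id", "window", "events", "person_days", "age_mid"])


def conditional_poisson(y, X, groups, offset, max_iter: int = 100,
                        tol: float = 1e-9) -> dict:
    """Maximise the person-stratified Poisson (multinomial) log-likelihood.

    Conditioning on each group's total count turns the within-group counts
    into a multinomial with cell probabilities proportional to
    ``exp(offset + X beta)``; the group baseline rates drop out.  Newton
    iterations with step halving; standard errors from the observed
    information.  Groups whose total count is zero contribute nothing and are
    ignored; unlike a drop-on-constant-outcome rule, groups with equal
    nonzero counts are retained (their likelihood still depends on ``beta``
    through the offsets and covariates).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.asarray(offset, float)
    _, inv = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = inv.max() + 1

    def loglik_parts(beta):
        eta = X @ beta + offset
        grp_max = np.full(n_groups, -np.inf)
        np.maximum.at(grp_max, inv, eta)
        w = np.exp(eta - grp_max[inv])
        denom = np.zeros(n_groups)
        np.add.at(denom, inv, w)
        p = w / denom[inv]
        n_i = np.zeros(n_groups)
        np.add.at(n_i, inv, y)
        ll = float(y @ (eta - (np.log(denom) + grp_max)[inv]))
        mu = n_i[inv] * p
        xbar = np.zeros((n_groups, X.shape[1]))
        np.add.at(xbar, inv, p[:, None] * X)
        Xc = X - xbar[inv]
        grad = X.T @ (y - mu)
        hess = (Xc * mu[:, None]).T @ Xc
        return ll, grad, hess

    beta = np.zeros(X.shape[1])
    ll, grad, hess = loglik_parts(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):  # step halving
            ll_new, grad_new, hess_new = loglik_parts(beta + scale * step)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll, grad, hess = ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol * (1.0 + abs(ll)):
            converged = True
            break
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        converged = False
    return {"beta": beta, "se": se, "loglik": ll, "converged": converged}


def fit_age_adjusted(panel: pd.DataFrame,
                     include_window_terms: bool = False) -> dict:
    """Person-stratified (conditional) Poisson fit of the age effect.

    Returns the rate ratio per year of age with a 95% CI, plus age-adjusted
    on-treatment window IRRs when ``include_window_terms`` is set.  Inputs
    that leave no informative person (no within-person contrast) are flagged
    rather than raised.
    """
    out = {"irr_per_year": np.nan, "ci_low": np.nan, "ci_high": np.nan,
           "coef": np.nan, "se": np.nan, "converged": False,
           "n_persons": 0, "n_informative": 0, "window_irrs": {}}
    if panel.empty:
        return out
    grp = panel.groupby("person_id")
    informative = panel[(grp["events"].transform("sum") > 0)
                        & (grp["person_id"].transform("size") > 1)]
    out["n_persons"] = panel["person_id"].nunique()
    out["n_informative"] = informative["person_id"].nunique()
    if out["n_informative"] < 2:
        logger.warning("conditional likelihood degenerate: "
                       "%d informative person(s)", out["n_informative"])
        return out

    age = informative["age_mid"].to_numpy(dtype=float)
    X = pd.DataFrame({"age": age - age.mean()}, index=informative.index)
    if include_window_terms:
        for w in ON_TREATMENT_WINDOWS:
            X[w] = (informative["window"] == w).astype(float)
    groups = pd.factorize(informative["person_id"])[0]
    offset = np.log(informative["person_days"].to_numpy(dtype=float) / DAYS_PER_YEAR)

    fit = conditional_poisson(
        informative["events"].to_numpy(dtype=float), X.to_numpy(), groups, offset)
    if not fit["converged"] or not np.all(np.isfinite(fit["se"])):
        logger.warning("conditional Poisson did not converge")
        out["converged"] = False
        return out

    params = pd.Series(fit["beta"], index=X.columns)
    bse = pd.Series(fit["se"], index=X.columns)
    coef, se = float(params["age"]), float(bse["age"])
    out.update({
        "coef": coef, "se": se,
        "irr_per_year": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.96 * se)),
        "ci_high": float(np.exp(coef + 1.96 * se)),
        "converged": True,
    })
    if include_window_terms:
        # window terms are near-collinear with within-person age (age advances
        # with the window clock); intervals can be arbitrarily wide, so wide
        # bounds are reported as inf rather than raised
        with np.errstate(over="ignore"):
            out["window_irrs"] = {
                w: {"irr": float(np.exp(params[w])),
                    "ci_low": float(np.exp(params[w] - 1.96 * bse[w])),
                    "ci_high": float(np.exp(params[w] + 1.96 * bse[w]))}
                for w in ON_TREATMENT_WINDOWS
            }
    return out
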