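"""Synthetic administrative-claims generator with known ground truth.

Emulates the structure of a German statutory-health-insurance claims extract:
an enrollment table, prescription fills, diagnoses (inpatient/outpatient) and
procedures for women initiating one of seven osteoporosis treatment classes.
Fracture events are drawn from an inhomogeneous Poisson process whose rate is
piecewise constant on the analysis windows anchored at each patient's index
date: a baseline hazard during the first 90 days (the own-control window) and
baseline x r_w inside each later on-treatment window w.  Because r_w is a
generator input, every downstream estimate (rates, IRRs, trend, age effect)
has a testable truth; :func:`truth_table` echoes it.

Each simulated fracture emits either one inpatient diagnosis (probability
``p_inpatient``) or an outpatient diagnosis plus a fracture-related procedure
on the same date, so both arms of the claims case definition are exercised.
Identical config + seed produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import CodeMap, default_code_map
from .config import (DRUG_CLASSES, FOLLOWUP_CAP_DAYS, HIERARCHY, WINDOW_BOUNDS,
                     SimConfig)

_TIER = {cls: t for t, tier in enumerate(HIERARCHY) for cls in tier}

ENROLLMENT_COLS = ["person_id", "birth_date", "enroll_start", "enroll_end", "death_date"]
PRESCRIPTION_COLS = ["person_id", "drug_class", "fill_date", "days_supplied"]
DIAGNOSIS_COLS = ["person_id", "code", "date", "setting"]
PROCEDURE_COLS = ["person_id", "code", "date"]

_DATE_COLS = {
    "enrollment": ["birth_date", "enroll_start", "enroll_end", "death_date"],
    "prescriptions": ["fill_date"],
    "diagnoses": ["date"],
    "procedures": ["date"],
}

_EXCLUSION_EXAMPLES = ["C50.9", "C61", "M88.0", "Q78.0"]
_FRACTURE_PROC_CODE = "5-790.0"
_HYSTERECTOMY_CODE = "5-683.0"
_NOISE_DX = "I10.0"  # unmapped non-fracture diagnosis


@dataclass
class ClaimsBundle:
    """The four raw claims tables plus the code map they were coded against."""

    enrollment: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    code_map: CodeMap

    def to_dir(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("enrollment", "prescriptions", "diagnoses", "procedures"):
            df = getattr(self, name).copy()
            for col in _DATE_COLS[name]:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            df.to_csv(path / f"{name}.csv", index=False)
        self.code_map.to_yaml(path / "code_map.yaml")

    @classmethod
    def from_dir(cls, path, code_map: CodeMap | None = None) -> "ClaimsBundle":
        from pathlib import Path

        path = Path(path)
        tables = {}
        for name in ("enrollment", "prescriptions", "diagnoses", "procedures"):
            df = pd.read_csv(path / f"{name}.csv")
            for col in _DATE_COLS[name]:
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
            tables[name] = df
        if code_map is None:
            cm_path = path / "code_map.yaml"
            code_map = CodeMap.from_yaml(cm_path) if cm_path.exists() else default_code_map()
        return cls(code_map=code_map, **tables)


def _empty_tables() -> dict[str, pd.DataFrame]:
    mk = lambda cols, dates: pd.DataFrame(
        {c: pd.Series(dtype="datetime64[ns]" if c in dates else "object") for c in cols}
    )
    return {
        "enrollment": mk(ENROLLMENT_COLS, _DATE_COLS["enrollment"]),
        "prescriptions": mk(PRESCRIPTION_COLS, _DATE_COLS["prescriptions"]),
        "diagnoses": mk(DIAGNOSIS_COLS, _DATE_COLS["diagnoses"]),
        "procedures": mk(PROCEDURE_COLS, _DATE_COLS["procedures"]),
    }


def _hazard_segments(cfg: SimConfig, t0: int, t1: int) -> list[tuple[int, int, float]]:
    """Piecewise-constant total-hazard segments (lo, hi, mult) on days relative
    to index, clipped to the enrollment span [t0, t1)."""
    ratios = cfg.hazard_ratio_by_window
    last_r = ratios.get("m37_48", 1.0)
    breaks: list[tuple[float, float, float]] = [(-math.inf, 0, cfg.pre_index_rate_mult)]
    for wid, lo, hi in WINDOW_BOUNDS:
        breaks.append((lo, hi, 1.0 if wid == "early" else ratios.get(wid, 1.0)))
    breaks.append((FOLLOWUP_CAP_DAYS, math.inf, last_r))
    out = []
    for lo, hi, mult in breaks:
        a, b = max(lo, t0), min(hi, t1)
        if b > a:
            out.append((int(a), int(b), mult))
    return out


def generate_bundle(cfg: SimConfig) -> ClaimsBundle:
    """Simulate a claims bundle under ``cfg``; deterministic for a given seed."""
    cfg.validate()
    code_map = default_code_map()
    n = cfg.n_patients
    if n == 0:
        return ClaimsBundle(code_map=code_map, **_empty_tables())

    rng = np.random.default_rng(cfg.seed)
    study_start = pd.Timestamp(cfg.study_start)
    study_end = pd.Timestamp(cfg.study_end)
    incl_lo = (pd.Timestamp(cfg.inclusion_start) - study_start).days
    incl_hi = (pd.Timestamp(cfg.inclusion_end) - study_start).days
    horizon = (study_end - study_start).days

    sites = sorted(cfg.baseline_hazard)
    site_rates = np.array([cfg.baseline_hazard[s] for s in sites], dtype=float)
    total_rate = site_rates.sum()
    site_probs = site_rates / total_rate if total_rate > 0 else None
    site_codes = {s: code_map.example_code(s) for s in sites}
    vertebral_code = code_map.example_code("clinical_vertebral")
    log_age_rr = math.log(cfg.age_rate_ratio_per_year)

    classes = list(DRUG_CLASSES)
    probs = np.array([cfg.drug_mix.get(c, 0.0) for c in classes])
    probs = probs / probs.sum()

    # population-level draws (one block, then a per-patient loop for the
    # variable-length fill and event histories)
    cls_idx = rng.choice(len(classes), size=n, p=probs)
    index_day = rng.integers(incl_lo, incl_hi + 1, size=n)
    age = np.maximum(
        rng.normal([cfg.age_mean[classes[k]] for k in cls_idx], cfg.age_sd), cfg.min_age
    )
    short_hist = rng.random(n) < cfg.short_history_prob
    history = np.where(
        short_hist,
        rng.integers(90, 730, size=n),
        730 + rng.exponential(500.0, size=n).astype(int),
    )
    death_t = (
        rng.exponential(365.25 / cfg.death_rate, size=n).astype(int)
        if cfg.death_rate > 0 else np.full(n, 10**9)
    )
    disenroll_t = (
        rng.exponential(365.25 / cfg.disenroll_rate, size=n).astype(int)
        if cfg.disenroll_rate > 0 else np.full(n, 10**9)
    )
    has_exclusion = rng.random(n) < cfg.exclusion_prev
    excl_code = rng.integers(0, len(_EXCLUSION_EXAMPLES), size=n)
    washout_violation = rng.random(n) < cfg.washout_violation_prob
    prior_tx = rng.random(n) < cfg.prior_treatment_prob
    forced_prior_frac = rng.random(n) < cfg.prior_fracture_frac
    estrogen_only = rng.random(n) < cfg.estrogen_only_frac
    hysterectomy = rng.random(n) < cfg.hysterectomy_frac
    noise_dx = rng.random(n) < cfg.noise_outpatient_prob

    enr_rows, rx_rows, dx_rows, px_rows = [], [], [], []

    for i in range(n):
        pid = f"P{i:06d}"
        c = classes[cls_idx[i]]
        idx = int(index_day[i])
        t0 = max(-idx, -int(history[i]))             # enrollment start, rel. index
        if washout_violation[i]:
            t0 = -idx  # prevalent users are enrolled from study start
        t1 = min(horizon - idx, int(death_t[i]), int(disenroll_t[i]))
        if t1 <= t0:
            t1 = t0  # degenerate span; enrollment of zero length
        died = death_t[i] <= min(horizon - idx, disenroll_t[i])

        enr_rows.append((
            pid,
            idx - int(round(age[i] * 365.25)),       # birth, rel. study start
            idx + t0, idx + t1,
            idx + t1 if died else None,
        ))

        # --- index-class fills -------------------------------------------
        supply = int(cfg.days_supplied[c])
        stop_p = float(cfg.persistence_stop_prob[c])
        gap_mean = float(cfg.refill_gap_mean[c])
        rx_class = "estrogen" if (c == "hrt" and estrogen_only[i]) else c
        day = 0
        while day <= t1:
            rx_rows.append((pid, rx_class, idx + day, supply))
            if rng.random() < stop_p:
                break
            day += supply + int(rng.exponential(gap_mean)) if gap_mean > 0 else supply
        if c == "hrt" and estrogen_only[i] and hysterectomy[i] and t0 < -10:
            px_rows.append((pid, _HYSTERECTOMY_CODE, idx + int(rng.integers(t0, -9))))

        # --- pre-index medication history --------------------------------
        if washout_violation[i]:
            # prevalent user: an index-class refill chain reaching back more
            # than 24 months before the inclusion window, so the new-user
            # washout (or, if enrollment starts later, the 24-month history
            # criterion) excludes this patient
            d = max((incl_lo - idx) - 731 - int(rng.integers(0, 300)), t0 + 1)
            while d < 0:
                rx_rows.append((pid, c, idx + d, supply))
                d += supply + (int(rng.exponential(gap_mean)) if gap_mean > 0 else 0)
        if prior_tx[i] and t0 < -30:
            # draw the previous therapy from lower-hierarchy classes so the
            # hierarchical assignment stays anchored at the intended index
            # class; for HRT (lowest tier) prior fills go before the
            # inclusion window for the same reason
            lower = [o for o in classes if _TIER[o] > _TIER[c]]
            if lower:
                oc, d_hi = lower[int(rng.integers(0, len(lower)))], -29
            else:
                oc, d_hi = classes[int(rng.integers(0, len(classes) - 1))], \
                    min(-29, incl_lo - idx)
            d_lo = max(t0, -730)
            if d_lo < d_hi:
                for _ in range(int(rng.integers(1, 3))):
                    d = int(rng.integers(d_lo, d_hi))
                    rx_rows.append((pid, oc, idx + d, int(cfg.days_supplied[oc])))

        # --- exclusion / prior-fracture / noise diagnoses -----------------
        if has_exclusion[i] and t0 < -1:
            d = int(rng.integers(t0, 0))
            dx_rows.append((pid, _EXCLUSION_EXAMPLES[excl_code[i]], idx + d, "outpatient"))
        frailty = 1.0
        if forced_prior_frac[i]:
            frailty = cfg.prior_fracture_hazard_mult
            if t0 < -30:
                d = int(rng.integers(max(t0, -700), -29))
                dx_rows.append((pid, vertebral_code, idx + d, "inpatient"))
        if noise_dx[i] and t1 > t0:
            d = int(rng.integers(t0, t1))
            dx_rows.append((pid, _NOISE_DX, idx + d, "outpatient"))

        # --- fracture events: piecewise-constant Poisson ------------------
        if total_rate > 0 and t1 > t0:
            for lo, hi, mult in _hazard_segments(cfg, t0, t1):
                age_mult = (
                    math.exp(log_age_rr * ((lo + hi) / 2.0) / 365.25)
                    if log_age_rr != 0.0 else 1.0
                )
                lam = total_rate * mult * frailty * age_mult * (hi - lo) / 365.25
                k = rng.poisson(lam) if lam > 0 else 0
                if k == 0:
                    continue
                days = np.floor(rng.uniform(lo, hi, size=k)).astype(int)
                which = rng.choice(len(sites), size=k, p=site_probs)
                for d, si in zip(days, which):
                    code = site_codes[sites[si]]
                    d = int(d)
                    if rng.random() < cfg.p_inpatient:
                        dx_rows.append((pid, code, idx + d, "inpatient"))
                    else:
                        dx_rows.append((pid, code, idx + d, "outpatient"))
                        px_rows.append((pid, _FRACTURE_PROC_CODE, idx + d))
                    if rng.random() < cfg.duplicate_dx_prob:
                        d2 = d + int(rng.integers(7, 81))
                        if d2 <= t1:
                            dx_rows.append((pid, code, idx + d2, "outpatient"))
                            px_rows.append((pid, _FRACTURE_PROC_CODE, idx + d2))

    def _dates(series):
        return study_start + pd.to_timedelta(series, unit="D")

    enrollment = pd.DataFrame(enr_rows, columns=ENROLLMENT_COLS)
    for col in ("birth_date", "enroll_start", "enroll_end"):
        enrollment[col] = _dates(enrollment[col].astype(int))
    death_days = np.array(
        [np.nan if d is None else float(d) for d in enrollment["death_date"]]
    )
    enrollment["death_date"] = study_start + pd.to_timedelta(death_days, unit="D")

    prescriptions = pd.DataFrame(rx_rows, columns=PRESCRIPTION_COLS)
    prescriptions["fill_date"] = _dates(prescriptions["fill_date"].astype(int))
    diagnoses = pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLS)
    diagnoses["date"] = _dates(diagnoses["date"].astype(int))
    procedures = pd.DataFrame(px_rows, columns=PROCEDURE_COLS)
    procedures["date"] = _dates(procedures["date"].astype(int))

    prescriptions = prescriptions.sort_values(
        ["person_id", "fill_date", "drug_class"], kind="stable").reset_index(drop=True)
    diagnoses = diagnoses.sort_values(
        ["person_id", "date", "code", "setting"], kind="stable").reset_index(drop=True)
    procedures = procedures.sort_values(
        ["person_id", "date", "code"], kind="stable").reset_index(drop=True)

    return ClaimsBundle(enrollment, prescriptions, diagnoses, procedures, code_map)


def truth_table(cfg: SimConfig) -> dict[str, float]:
    """The generator's true on-treatment rate ratio per analysis window."""
    cfg.validate()
    return {w: float(cfg.hazard_ratio_by_window.get(w, 1.0))
            for w in ("m4_12", "m13_24", "m25_36", "m37_48")}
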