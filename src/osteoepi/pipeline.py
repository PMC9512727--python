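"""End-to-end orchestration: claims in (or simulated), result tables out.

``run`` executes generate/load -> cohort selection -> baseline covariates ->
treatment episodes -> fracture events -> windowed rates and own-control IRRs
(overall and stratified by prior fracture / prior treatment) -> trend and
age-adjusted models, writing each stage's CSV plus a JSON manifest (config
echo, seed, library versions, row counts, stage timings) into the output
directory.  Identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codes import CodeMap, default_code_map
from .cohort import baseline_covariates, normalize_fills, select_cohort
from .config import RunConfig
from .episodes import build_episodes, duration_summary
from .fractures import find_fracture_events
from .incidence import format_irr_display, irr_table, rate_table, stratified_analysis
from .models import build_age_panel, fit_age_adjusted, trend_table
from .simulate import ClaimsBundle, generate_bundle

logger = logging.getLogger(__name__)


def observed_days_supplied(fills: pd.DataFrame) -> dict[str, int]:
    """Per-class days supplied, taken as the median of the observed fills."""
    if fills.empty:
        return {}
    med = fills.groupby("drug_class")["days_supplied"].median()
    return {cls: max(1, int(round(v))) for cls, v in med.items()}


def load_bundle(config: RunConfig) -> ClaimsBundle:
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = config.seed
        return generate_bundle(sim)
    code_map = (CodeMap.from_yaml(config.code_map_path)
                if config.code_map_path else default_code_map())
    tables = {}
    from .simulate import _DATE_COLS
    for name in ("enrollment", "prescriptions", "diagnoses", "procedures"):
        df = pd.read_csv(config.inputs[name])
        for col in _DATE_COLS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], errors="coerce")
        tables[name] = df
    return ClaimsBundle(code_map=code_map, **tables)


def _write(df: pd.DataFrame, path: Path) -> int:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return len(out)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "osteoepi",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "row_counts": {},
        "timings_s": {},
    }
    timings = manifest["timings_s"]
    counts = manifest["row_counts"]

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_
            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc[0] is not None:
                    logger.error("stage %r failed", name)
                return False
        return _T()

    with stage("load_or_simulate"):
        bundle = load_bundle(config)
        bundle.to_dir(outdir / "tables")
        for name in ("enrollment", "prescriptions", "diagnoses", "procedures"):
            counts[name] = len(getattr(bundle, name))

    with stage("cohort"):
        members, attrition = select_cohort(bundle, config.selection)
        members = baseline_covariates(
            members, bundle, lookback_days=config.selection.lookback_days,
            proc_window_days=config.analysis.proc_window_days)
        counts["cohort"] = _write(members, outdir / "cohort.csv")
        counts["attrition_rows"] = _write(attrition, outdir / "attrition.csv")

    with stage("episodes"):
        fills = normalize_fills(bundle.prescriptions, bundle.procedures, bundle.code_map)
        supply = observed_days_supplied(fills)
        episodes = build_episodes(
            members, fills, supply,
            admin_end=config.selection.admin_censor_date, params=config.episodes)
        counts["episodes"] = _write(episodes, outdir / "episodes.csv")
        prior_flag = members.set_index("person_id")["prior_osteoporosis_treatment"] \
            if len(members) else None
        summary = duration_summary(episodes, prior_flag)
        _write(summary, outdir / "duration_summary.csv")

    with stage("fractures"):
        events = find_fracture_events(
            bundle.diagnoses, bundle.procedures, bundle.code_map,
            proc_window_days=config.analysis.proc_window_days)
        counts["fracture_events"] = _write(events, outdir / "events.csv")

    with stage("incidence"):
        fx_members = members[members["followup_ok"]] if len(members) else members
        fx_episodes = episodes[episodes["person_id"].isin(fx_members["person_id"])]
        rates = rate_table(fx_episodes, events)
        irrs = irr_table(rates, method=config.analysis.ci_method,
                         small_count_threshold=config.analysis.small_count_threshold)
        counts["rate_rows"] = _write(rates, outdir / "rates.csv")
        counts["irr_rows"] = _write(irrs, outdir / "irr.csv")
        _write(format_irr_display(irrs), outdir / "irr_display.csv")
        for strat in ("prior_fracture", "prior_osteoporosis_treatment"):
            if len(fx_members):
                s_rates, s_irrs = stratified_analysis(
                    fx_members, fx_episodes, events, strat,
                    method=config.analysis.ci_method,
                    small_count_threshold=config.analysis.small_count_threshold)
            else:
                s_rates, s_irrs = pd.DataFrame(), pd.DataFrame()
            _write(s_rates, outdir / f"rates_by_{strat}.csv")
            _write(s_irrs, outdir / f"irr_by_{strat}.csv")

    with stage("models"):
        trends = trend_table(rates, weights=config.analysis.trend_weights)
        _write(trends, outdir / "trend.csv")
        panel = build_age_panel(fx_members, fx_episodes, events)
        age_fit = fit_age_adjusted(panel, include_window_terms=False)
        age_adj = fit_age_adjusted(panel, include_window_terms=True)
        age_out = {"age_only": age_fit, "age_plus_window_terms": age_adj}
        with open(outdir / "age_model.json", "w") as fh:
            json.dump(age_out, fh, indent=2, sort_keys=True, default=float)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete: %s", outdir)
    return manifest
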