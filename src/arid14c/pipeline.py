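"""End-to-end analysis pipeline over a site table.

Stages, in order: radiocarbon corrections (F¹⁴C → Δ¹⁴C_sample → background
correction where fraction modern was supplied), carbonate partition and
screening, the Δ¹⁴C endmember-mixing suite, one-pool fits for bulk SOC age
and (on included sites) respired-CO₂ transit time, the bulk-vs-respired
difference, cohort summaries, a two-pool fit to the cohort means, and
breakpoint fits along configured gradients.

Sign convention: the difference is respired − bulk, so a positive value
means respiration draws on younger carbon than the bulk stock, and "the
difference increases with aridity" is a positive trend.

Sites lacking a respired Δ¹⁴C measurement participate in bulk-only
analyses and carry status ``missing_respired`` in the per-site table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atmos import AtmosphericCurve, load_curve, synthetic_bomb_curve
from .config import load_config
from .isotopes import background_correct, f14c_to_delta14c
from .mixing import f_old, f_old_suite
from .pools import TwoPoolFit, fit_one_pool, fit_two_pool
from .sic import partition_site
from .thresholds import fit_breakpoint

__all__ = ["CohortSummary", "run_pipeline", "difference_bulk_respired",
           "load_sites", "SITE_COLUMNS"]

log = logging.getLogger("arid14c")

SITE_COLUMNS = [
    "site_id", "region", "sampling_year", "aridity", "mat", "map_mm", "npp",
    "plant_cover", "species_richness", "soc", "sic", "ph", "clay_silt",
    "fe_al", "resp_rate", "d13c_tc", "d13c_soc", "d13c_sic", "d13c_co2",
    "f14c_bulk", "delta14c_bulk", "f14c_co2", "delta14c_co2",
    "w_poc", "w_maoc",
]

REQUIRED_COLUMNS = ["site_id", "sampling_year", "sic"]

#: statuses under which a site's respired Δ¹⁴C enters the cohort analyses
INCLUDED_STATUSES = ("assumed_zero_sic", "included_original")


@dataclass
class CohortSummary:
    """Cohort-level outputs: counts, mean ± SE summaries, model fits."""

    n_total: int
    n_included_resp: int
    stats: dict                    # name -> {mean, se, n}
    f_old_summary: dict            # assumption -> both averaging orders
    two_pool: TwoPoolFit | None
    breakpoints: dict              # "response~predictor" -> BreakpointFit


def load_sites(source) -> pd.DataFrame:
    """Read and validate a site table (CSV path or DataFrame).

    Every site needs an id, a sampling year, a SIC content, and at least
    one of (F¹⁴C, Δ¹⁴C) for the bulk pool. Offending rows are listed in
    the error.
    """
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) \
        else source.copy()
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"site table missing columns: {missing_cols}")
    for col in SITE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    problems = []
    for idx, row in df.iterrows():
        if pd.isna(row["sampling_year"]):
            problems.append(f"row {idx}: missing sampling_year")
        if pd.isna(row["f14c_bulk"]) and pd.isna(row["delta14c_bulk"]):
            problems.append(f"row {idx}: needs f14c_bulk or delta14c_bulk")
        if pd.isna(row["sic"]):
            problems.append(f"row {idx}: missing sic content")
    if problems:
        raise ValueError("schema violations:\n" + "\n".join(problems))
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_id values: {dups}")
    return df


def _resolve_curve(curve_source, last_year: float) -> AtmosphericCurve:
    if isinstance(curve_source, AtmosphericCurve):
        return curve_source
    if curve_source in (None, "synthetic"):
        return synthetic_bomb_curve(last_year=max(2020.0, last_year))
    return load_curve(curve_source)


def difference_bulk_respired(site) -> float:
    """Respired-minus-bulk Δ¹⁴C (‰); positive = respired carbon younger."""
    co2 = site["delta14c_co2"]
    bulk = site["delta14c_bulk"]
    if co2 is None or (isinstance(co2, float) and math.isnan(co2)):
        raise ValueError("site lacks respired Δ¹⁴C")
    if bulk is None or (isinstance(bulk, float) and math.isnan(bulk)):
        raise ValueError("site lacks bulk Δ¹⁴C")
    return float(co2 - bulk)


def _corrected_delta(row, pool: str, curve: AtmosphericCurve):
    """Background-corrected Δ¹⁴C for one pool of one site.

    Reported Δ¹⁴C columns are taken as already background-corrected (the
    convention site data are published in); F¹⁴C columns are converted and
    corrected here.
    """
    delta = row[f"delta14c_{pool}"]
    if not pd.isna(delta):
        return float(delta)
    f14c = row[f"f14c_{pool}"]
    if pd.isna(f14c):
        return None
    year = float(row["sampling_year"])
    return float(background_correct(
        f14c_to_delta14c(float(f14c), year), curve, year))


def run_pipeline(sites, curve_source=None, config=None):
    """Run the full analysis; returns ``(CohortSummary, per-site table)``.

    ``sites`` is a CSV path or DataFrame following the site schema;
    ``curve_source`` is "synthetic" (default), a curve CSV path, or an
    AtmosphericCurve. Deterministic for a given config seed.
    """
    cfg = load_config(config)
    df = load_sites(sites)
    curve = _resolve_curve(curve_source, float(df["sampling_year"].max()))
    sic_cfg = cfg["sic"]
    one_cfg = cfg["one_pool"]
    young_from_atm = cfg["mixing"]["young_from_atmosphere"]

    rows = []
    for _, site in df.iterrows():
        year = float(site["sampling_year"])
        rec = {"site_id": site["site_id"], "region": site["region"],
               "sampling_year": year, "aridity": site["aridity"]}

        bulk = _corrected_delta(site, "bulk", curve)
        co2 = _corrected_delta(site, "co2", curve)
        rec["delta14c_bulk"] = bulk
        rec["delta14c_co2"] = co2

        # carbonate partition + screening
        if co2 is None:
            rec.update(status="missing_respired", f_sic=np.nan,
                       d13c_sic_eq=np.nan, delta14c_co2_soc=np.nan,
                       status_reason="no respired measurement")
        else:
            part = partition_site(
                d13c_co2=_opt(site["d13c_co2"]),
                d13c_soc=_opt(site["d13c_soc"]),
                d13c_sic=_opt(site["d13c_sic"]),
                sic_content=float(site["sic"]),
                delta14c_co2=co2,
                region=_opt(site["region"]),
                config=sic_cfg,
            )
            rec.update(
                status=part.status, status_reason=part.reason,
                f_sic=part.f_sic,
                d13c_sic_eq=np.nan if part.d13c_sic_eq is None
                else part.d13c_sic_eq,
                delta14c_co2_soc=np.nan if part.delta14c_co2_soc is None
                else part.delta14c_co2_soc,
            )
        included = rec["status"] in INCLUDED_STATUSES

        # mixing suite (needs both pools)
        for key in ("f_old_bulk_soc", "f_old_petrogenic", "f_old_maoc"):
            rec[key] = np.nan
        if co2 is not None and bulk is not None:
            suite = f_old_suite(
                {"delta14c_co2": co2, "delta14c_bulk": bulk,
                 "sampling_year": year, "w_maoc": _opt(site["w_maoc"])},
                curve, young_from_atmosphere=young_from_atm,
            )
            rec["f_old_bulk_soc"] = suite["bulk_soc"].f_old
            rec["f_old_petrogenic"] = suite["petrogenic"].f_old
            if "maoc" in suite:
                rec["f_old_maoc"] = suite["maoc"].f_old

        # one-pool fits
        rec["age_bulk"] = _safe_age(bulk, curve, year, one_cfg)
        rec["transit_respired"] = (
            _safe_age(co2, curve, year, one_cfg) if included else np.nan
        )
        rec["d14c_diff"] = (co2 - bulk
                            if co2 is not None and bulk is not None
                            and included else np.nan)
        rows.append(rec)

    per_site = pd.DataFrame(rows)
    for rec in rows:
        if rec["status"] not in INCLUDED_STATUSES:
            log.info("site %s: %s (%s)", rec["site_id"], rec["status"],
                     rec.get("status_reason", ""))

    included_mask = per_site["status"].isin(INCLUDED_STATUSES)
    summary = _summarize(per_site, included_mask, curve, cfg)
    return summary, per_site


def _summarize(per_site: pd.DataFrame, included: pd.Series,
               curve: AtmosphericCurve, cfg: dict) -> CohortSummary:
    stats = {}

    def add(name, values):
        vals = np.asarray(values, float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            stats[name] = {"mean": np.nan, "se": np.nan, "n": 0}
        else:
            stats[name] = {
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else np.nan,
                "n": int(vals.size),
            }

    add("delta14c_bulk", per_site["delta14c_bulk"])
    add("delta14c_co2", per_site.loc[included, "delta14c_co2"])
    add("d14c_diff", per_site.loc[included, "d14c_diff"])
    add("age_bulk", per_site["age_bulk"])
    add("transit_respired", per_site.loc[included, "transit_respired"])
    for key in ("f_old_bulk_soc", "f_old_petrogenic", "f_old_maoc"):
        add(key, per_site.loc[included, key])

    # f_old both ways: mean of site-level fractions, and the fraction
    # implied by the cohort-mean Δ¹⁴C values (averaging order is ambiguous
    # in cohort reporting, so both are given).
    f_old_summary = {}
    mean_year = float(per_site["sampling_year"].mean())
    young = curve.at(min(mean_year, curve.last_year))
    mb = stats["delta14c_bulk"]["mean"]
    mc = stats["delta14c_co2"]["mean"]
    if np.isfinite(mb) and np.isfinite(mc):
        f_old_summary["bulk_soc"] = {
            "mean_of_sites": stats["f_old_bulk_soc"]["mean"],
            "at_cohort_means": f_old(mc, mb, young).f_old,
        }
        f_old_summary["petrogenic"] = {
            "mean_of_sites": stats["f_old_petrogenic"]["mean"],
            "at_cohort_means": f_old(mc, -1000.0, young).f_old,
        }

    # two-pool fit to the cohort means
    two_pool = None
    if np.isfinite(mb) and np.isfinite(mc):
        tp_cfg = cfg["two_pool"]
        try:
            two_pool = fit_two_pool(
                mb, mc, tp_cfg["structure"], curve,
                min(round(mean_year), curve.last_year),
                k_fast_age_min=tp_cfg["k_fast_age_min"],
                k_fast_age_max=tp_cfg["k_fast_age_max"],
                k_fast_points=tp_cfg["k_fast_points"],
                k_slow_min=tp_cfg["k_slow_min"],
                tol_permil=tp_cfg["tol_permil"],
            )
        except ValueError as err:
            log.warning("two-pool fit failed: %s", err)

    # breakpoint fits along configured gradients
    th_cfg = cfg["thresholds"]
    breakpoints = {}
    for response, predictor in th_cfg["pairs"]:
        sub = per_site[[predictor, response]].dropna()
        key = f"{response}~{predictor}"
        try:
            breakpoints[key] = fit_breakpoint(
                sub[predictor], sub[response],
                edge_margin=th_cfg["edge_margin"],
                min_per_side=th_cfg["min_per_side"],
                n_boot=th_cfg["n_boot"],
                seed=cfg["seed"],
            )
        except ValueError as err:
            log.warning("breakpoint fit %s failed: %s", key, err)

    n_total = len(per_site)
    n_included = int(included.sum())
    if n_included == 0:
        log.warning("all sites excluded from respired analyses")
    return CohortSummary(
        n_total=n_total,
        n_included_resp=n_included,
        stats=stats,
        f_old_summary=f_old_summary,
        two_pool=two_pool,
        breakpoints=breakpoints,
    )


def _safe_age(delta, curve, year, one_cfg):
    if delta is None:
        return np.nan
    try:
        fit = fit_one_pool(delta, curve, year,
                           k_min=one_cfg["k_min"], k_max=one_cfg["k_max"],
                           n_grid=one_cfg["n_grid"],
                           tol_permil=one_cfg["tol_permil"])
        return fit.age_years
    except ValueError as err:
        log.warning("one-pool fit failed for Δ¹⁴C=%s‰ (%s)", delta, err)
        return np.nan


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value
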