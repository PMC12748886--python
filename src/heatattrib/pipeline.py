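"""End-to-end pipeline: counterfactual temperatures -> first-stage DLNMs ->
meta-regression with BLUPs -> attribution -> trends.

The stages are plain functions over DataFrames so they can be driven from
Python, from the ``attrib`` command line, or stage-by-stage from persisted
CSV intermediates.  A :class:`RunConfig` carries every switch, including the
four sensitivity variants (5-year moving-average GMST smoothing, day-of-year
baseline mortality, five 6-year subperiods, exclusion of 2003), and is
serialised into the run manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gmst as gmst_mod
from .gmst import ensure_datetime
from .attribution import (
    aggregate,
    baseline_mortality_variant,
    climate_attribution,
    find_mmt,
    scenario_attribution,
)
from .dlnm import LagBasisSpec, SubperiodScheme, fit_city_subperiods
from .metareg import (
    compute_blups,
    counterfactual_blups,
    fit_mvmeta,
    heterogeneity,
    select_model,
)
from .trends import compare_trends, fit_trend

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    study_start: int = 1993
    study_end: int = 2022
    scheme: str = "6x5"                      # or "5x6" (sensitivity)
    gmst_smoothing: str = "ssa"              # or "annual-ma-5" (sensitivity)
    ssa_window: int = 120
    reference_period: tuple[int, int] = (1850, 1900)
    fit_years: tuple[int, int] = (1950, 2022)
    mortality_baseline: str = "observed"     # or "doy-mean" (sensitivity)
    exclude_years: tuple[int, ...] = ()      # e.g. (2003,) (sensitivity)
    max_lag: int = 10
    seasonal_df: int = 3
    n_mc: int = 1000
    seed: int = 17
    meta_predictors: tuple[str, ...] = (
        "le", "tmean_annual", "trange", "heat_alert_days",
        "mean_age", "pct_over65",
    )
    selection: str = "forward-backward"      # or "fixed"
    fixed_predictors: tuple[str, ...] = ("le",)
    ensemble_trends: bool = True             # per-variant trend Wilcoxon stage

    def subperiod_scheme(self) -> SubperiodScheme:
        block = {"6x5": 5, "5x6": 6}[self.scheme]
        return SubperiodScheme.from_range(self.study_start, self.study_end, block)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_inputs(
    gmst: pd.DataFrame,
    citytemp: pd.DataFrame,
    citymort: pd.DataFrame,
    metapred: pd.DataFrame | None = None,
) -> list[str]:
    """Schema and consistency checks; returns a list of violation messages."""
    issues = []
    for name, df, cols in (
        ("gmst", gmst, ["year", "month", "anomaly", "anomaly_lower", "anomaly_upper"]),
        ("citytemp", citytemp, ["city", "date", "tmean"]),
        ("citymort", citymort, ["city", "date", "deaths"]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            issues.append(f"{name}: missing column(s) {missing}")
    if issues:
        return issues

    m = gmst.sort_values(["year", "month"])
    steps = m["year"].to_numpy() * 12 + m["month"].to_numpy()
    if np.any(np.diff(steps) != 1):
        issues.append("gmst: months are not contiguous")
    if (gmst["anomaly_lower"] > gmst["anomaly"]).any() or (
        gmst["anomaly"] > gmst["anomaly_upper"]
    ).any():
        issues.append("gmst: CI bounds not ordered lower <= central <= upper")

    if (citymort["deaths"] < 0).any():
        issues.append("citymort: negative death counts")

    for name, df in (("citytemp", citytemp), ("citymort", citymort)):
        dts = ensure_datetime(df["date"])
        dup = df.assign(_d=dts).duplicated(["city", "_d"])
        if dup.any():
            issues.append(f"{name}: duplicated city/date rows ({int(dup.sum())})")

    t = citytemp.assign(_d=ensure_datetime(citytemp["date"]))
    for city, grp in t.groupby("city"):
        for year in sorted(grp["_d"].dt.year.unique()):
            season = grp[
                (grp["_d"] >= pd.Timestamp(year, 5, 22))
                & (grp["_d"] <= pd.Timestamp(year, 9, 30))
            ]
            expected = pd.date_range(f"{year}-05-22", f"{year}-09-30")
            got = pd.DatetimeIndex(season["_d"]).unique()
            if 0 < len(got) < len(expected):
                gap = expected.difference(got)
                issues.append(
                    f"citytemp: {city} {year} warm-season gap starting {gap[0].date()}"
                )
    return issues


# ---------------------------------------------------------------------------

def run_pipeline(
    gmst: pd.DataFrame,
    citytemp: pd.DataFrame,
    citymort: pd.DataFrame,
    metapred: pd.DataFrame,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute all stages; optionally persist CSV/JSON outputs to ``outdir``.

    Returns a dict with the smoothed GMST, scaling fits, counterfactual
    ensemble, reduced associations, meta model, BLUP sets, per-scenario
    attribution, climate attribution with Monte Carlo eCIs, and trend
    summaries.
    """
    cfg = config or RunConfig()
    scheme = cfg.subperiod_scheme()
    issues = validate_inputs(gmst, citytemp, citymort, metapred)
    if issues:
        raise ValueError("input validation failed:\n" + "\n".join(issues))

    # ---- stage 1: counterfactual temperatures -----------------------------
    logger.info("stage counterfactual: smoothing GMST (%s)", cfg.gmst_smoothing)
    sm = gmst_mod.smooth_gmst(
        gmst, window=cfg.ssa_window, reference=cfg.reference_period,
        method=cfg.gmst_smoothing,
    )
    annual_g = gmst_mod.annual_gmst_mean(sm)
    temps_by_city = {c: g.reset_index(drop=True) for c, g in citytemp.groupby("city")}
    morts_by_city = {c: g.reset_index(drop=True) for c, g in citymort.groupby("city")}
    # the day-of-year-mean baseline replaces observed deaths only in the
    # attribution accounting; first-stage fits always use observed counts
    if cfg.mortality_baseline == "doy-mean":
        attrib_morts = {
            c: baseline_mortality_variant(df) for c, df in morts_by_city.items()
        }
    else:
        attrib_morts = morts_by_city

    scalings, ensembles, factual_study = {}, {}, {}
    for city, tdf in temps_by_city.items():
        tdf = tdf.copy()
        tdf["date"] = ensure_datetime(tdf["date"])
        ann = gmst_mod.annual_warm_season_mean(tdf)
        scalings[city] = gmst_mod.fit_city_scaling(
            ann, annual_g, years=cfg.fit_years, city=city
        )
        study = tdf[tdf["date"].dt.year.between(cfg.study_start, cfg.study_end)]
        factual_study[city] = study.reset_index(drop=True)
        ensembles[city] = gmst_mod.build_ensemble(
            factual_study[city], scalings[city], sm
        )
        logger.info("stage counterfactual: %s slope=%.3f", city, scalings[city].slope)

    # ---- stage 2: first-stage DLNMs on factual temperatures ---------------
    lag = LagBasisSpec(max_lag=cfg.max_lag)
    reduced, exposures = [], {}
    for city in sorted(temps_by_city):
        red, exp_spec = fit_city_subperiods(
            factual_study[city], morts_by_city[city], scheme,
            lag=lag, seasonal_df=cfg.seasonal_df, exclude_years=cfg.exclude_years,
        )
        reduced.extend(red)
        exposures[city] = exp_spec
        logger.info("stage first-stage: %s -> %d subperiod fits", city, len(red))

    # ---- stage 3: meta-regression -----------------------------------------
    if cfg.selection == "forward-backward":
        model, trace = select_model(
            reduced, metapred, scheme, candidates=cfg.meta_predictors
        )
        selected = [c for c in model.data.columns if c in cfg.meta_predictors]
        if "le" not in selected:
            logger.warning("LE not selected by AIC; refitting with LE included "
                           "(required for the no-LE-improvement scenario)")
            model = fit_mvmeta(
                reduced, metapred, scheme, predictors=tuple(selected) + ("le",)
            )
    else:
        # fixed predictor set; the year-spline trend still competes on AIC
        # (kept only if it improves on the predictors alone)
        m_trend = fit_mvmeta(
            reduced, metapred, scheme, predictors=cfg.fixed_predictors
        )
        m_plain = fit_mvmeta(
            reduced, metapred, scheme, predictors=cfg.fixed_predictors,
            year_spline=False,
        )
        model = m_plain if m_plain.aic < m_trend.aic else m_trend
        trace = pd.DataFrame([
            {"predictors": ",".join(cfg.fixed_predictors),
             "action": "fixed+year_spline", "aic": m_trend.aic,
             "bic": m_trend.bic, "lr_p": np.nan},
            {"predictors": ",".join(cfg.fixed_predictors), "action": "fixed",
             "aic": m_plain.aic, "bic": m_plain.bic, "lr_p": np.nan},
        ])
    het = heterogeneity(model)
    blups = compute_blups(model)
    cf_blups = counterfactual_blups(model, blups, metapred, predictor="le")
    logger.info("stage meta: AIC=%.1f I2=%.1f%%", model.aic, het.I2)

    # ---- stage 4: attribution under the four scenarios --------------------
    keys = list(zip(blups.city, blups.subperiod))
    th_f = {k: blups.theta[i] for i, k in enumerate(keys)}
    th_cf = {k: cf_blups.theta[i] for i, k in enumerate(keys)}
    cov_f = {k: blups.cov[i] for i, k in enumerate(keys)}

    def _drop_excluded(res: pd.DataFrame) -> pd.DataFrame:
        return res[~res.index.isin(cfg.exclude_years)]

    cf_central = {c: ensembles[c]["cf_central_central"] for c in ensembles}
    scenarios = {
        ("withCC", "withLE"): (factual_study, th_f),
        ("w/oCC", "withLE"): (cf_central, th_f),
        ("withCC", "w/oLE"): (factual_study, th_cf),
        ("w/oCC", "w/oLE"): (cf_central, th_cf),
    }
    per_city, agg = {}, {}
    for key, (tv, th) in scenarios.items():
        res = scenario_attribution(
            th, tv, attrib_morts, exposures, scheme,
            max_lag=cfg.max_lag, variant="/".join(key),
        )
        res = {c: _drop_excluded(r) for c, r in res.items()}
        per_city[key] = res
        agg[key] = aggregate(res)

    cc_with_le = climate_attribution(agg[("withCC", "withLE")], agg[("w/oCC", "withLE")])
    cc_wo_le = climate_attribution(agg[("withCC", "w/oLE")], agg[("w/oCC", "w/oLE")])

    # Monte Carlo eCIs on the aggregated annual quantities
    if cfg.n_mc > 0:
        eci = _monte_carlo(
            cfg, scheme, exposures, factual_study, cf_central, attrib_morts,
            th_f, th_cf, cov_f,
        )
    else:
        eci = {}

    # ---- stage 5: trends ---------------------------------------------------
    trends_out, comparisons = _trend_stage(
        cfg, scheme, exposures, factual_study, ensembles, attrib_morts,
        th_f, th_cf, agg, cc_with_le, per_city,
    )

    result = {
        "config": cfg,
        "scheme": scheme,
        "smoothed_gmst": sm,
        "scalings": scalings,
        "ensembles": ensembles,
        "reduced": reduced,
        "exposures": exposures,
        "model": model,
        "selection_trace": trace,
        "heterogeneity": het,
        "blups": blups,
        "cf_blups": cf_blups,
        "per_city": per_city,
        "aggregated": agg,
        "climate_attribution_with_le": cc_with_le,
        "climate_attribution_wo_le": cc_wo_le,
        "eci": eci,
        "trends": trends_out,
        "comparisons": comparisons,
    }
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _monte_carlo(cfg, scheme, exposures, factual, cf_central, morts,
                 th_f, th_cf, cov_f) -> dict:
    """eCIs for annual aggregated AF under the four scenarios and for the
    climate-change quantities, resampling coefficients (MMT held fixed).

    Factual and no-LE-improvement coefficients share the same normal
    residual draw per city x subperiod, mirroring the construction of the
    counterfactual BLUPs (whose covariance is carried over unchanged).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_mc = cfg.n_mc
    keys = sorted(th_f)
    draws = {}
    for k in keys:
        cov = 0.5 * (cov_f[k] + cov_f[k].T)
        vals, vecs = np.linalg.eigh(cov)
        root = vecs * np.sqrt(np.maximum(vals, 0.0))
        draws[k] = rng.standard_normal((n_mc, cov.shape[0])) @ root.T

    an_draws = {}   # (temp, assoc) -> (n_mc, n_years) aggregated AN
    deaths_tot = {}
    for temp_label, temps in (("withCC", factual), ("w/oCC", cf_central)):
        for assoc_label, th in (("withLE", th_f), ("w/oLE", th_cf)):
            acc = None
            dth = None
            for city in sorted(temps):
                tdf = temps[city].copy()
                tdf["date"] = ensure_datetime(tdf["date"])
                ddf = morts[city].copy()
                ddf["date"] = ensure_datetime(ddf["date"])
                for label, s, e in scheme.blocks:
                    k = (city, label)
                    if k not in th:
                        continue
                    sub = tdf[tdf["date"].dt.year.between(s, e)]
                    warm = sub[sub["date"].dt.month.isin((6, 7, 8, 9))]
                    warm = warm[~warm["date"].dt.year.isin(cfg.exclude_years)]
                    mmt = find_mmt(th[k], exposures[city],
                                   warm["tmean"].to_numpy())
                    merged = warm.merge(ddf[["date", "deaths"]], on="date",
                                        how="left").sort_values("date")
                    A, yrs, dsum = _an_draws_city_sub(
                        merged, exposures[city], mmt.temperature,
                        th[k], draws[k], cfg.max_lag,
                    )
                    acc = _accumulate(acc, A, yrs)
                    dth = _accumulate(dth, dsum[None, :], yrs)
            yr_index = sorted(acc)
            an = np.stack([acc[y] for y in yr_index], axis=1)  # (n_mc, Y)
            dt = np.array([dth[y][0] for y in yr_index])
            an_draws[(temp_label, assoc_label)] = (np.asarray(yr_index), an)
            deaths_tot[(temp_label, assoc_label)] = dt

    out = {}
    for k, (yrs, an) in an_draws.items():
        af = 100.0 * an / deaths_tot[k][None, :]
        out[k] = pd.DataFrame({
            "year": yrs,
            "af_lo": np.percentile(af, 2.5, axis=0),
            "af_hi": np.percentile(af, 97.5, axis=0),
        }).set_index("year")
    for assoc in ("withLE", "w/oLE"):
        yrs, an_f = an_draws[("withCC", assoc)]
        _, an_c = an_draws[("w/oCC", assoc)]
        dtot = deaths_tot[("withCC", assoc)]
        an_cc = an_f - an_c
        af_cc = 100.0 * an_cc / dtot[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            p_cc = 100.0 * an_cc.sum(axis=1) / an_f.sum(axis=1)
        out[("CC", assoc)] = pd.DataFrame({
            "year": yrs,
            "an_cc_lo": np.percentile(an_cc, 2.5, axis=0),
            "an_cc_hi": np.percentile(an_cc, 97.5, axis=0),
            "af_cc_lo": np.percentile(af_cc, 2.5, axis=0),
            "af_cc_hi": np.percentile(af_cc, 97.5, axis=0),
        }).set_index("year")
        out[("CC", assoc, "period")] = {
            "p_cc_lo": float(np.percentile(p_cc, 2.5)),
            "p_cc_hi": float(np.percentile(p_cc, 97.5)),
        }
    return out


def _an_draws_city_sub(merged, exposure, mmt_temp, theta, eps, max_lag):
    """Vectorised per-draw seasonal AN for one city x subperiod block."""
    from .attribution import _forward_mean

    years_arr = merged["date"].dt.year.to_numpy()
    x = merged["tmean"].to_numpy(dtype=float)
    deaths = merged["deaths"].to_numpy(dtype=float)
    fm = np.empty_like(deaths)
    for y in np.unique(years_arr):
        m = years_arr == y
        fm[m] = _forward_mean(deaths[m], max_lag)
    hot = x > mmt_temp
    Brel = exposure.transform(x[hot]) - exposure.transform(np.array([mmt_temp]))
    th_draws = theta[None, :] + eps            # (n_mc, d)
    E = Brel @ th_draws.T                      # (n_hot, n_mc)
    an_daily = (1.0 - np.exp(-E)) * fm[hot][:, None]
    yrs_hot = years_arr[hot]
    uy = np.unique(years_arr)
    A = np.zeros((eps.shape[0], uy.size))
    for j, y in enumerate(uy):
        A[:, j] = an_daily[yrs_hot == y].sum(axis=0)
    dsum = np.array([deaths[years_arr == y].sum() for y in uy])
    return A, uy, dsum


def _accumulate(acc, A, yrs):
    acc = acc or {}
    for j, y in enumerate(yrs):
        if y in acc:
            acc[y] = acc[y] + A[:, j]
        else:
            acc[y] = A[:, j].copy()
    return acc


def _trend_stage(cfg, scheme, exposures, factual, ensembles, morts,
                 th_f, th_cf, agg, cc_with_le, per_city):
    """City-specific and aggregated trend fits plus Wilcoxon comparisons."""
    trends_rows = []
    for key, a in agg.items():
        tf = fit_trend(a.index.to_numpy(), a["af"].to_numpy())
        trends_rows.append({
            "level": "all-cities", "quantity": "AF",
            "temperature": key[0], "association": key[1],
            "slope_per_decade": tf.slope_per_decade,
            "ci_lower": tf.ci_lower, "ci_upper": tf.ci_upper,
            "best_family": tf.best_family,
        })
    ann = cc_with_le.drop(index="period")
    for qty in ("af_cc", "p_cc"):
        vals = ann[qty].to_numpy(dtype=float)
        tf = fit_trend(ann.index.to_numpy(dtype=float), vals)
        trends_rows.append({
            "level": "all-cities", "quantity": qty.upper(),
            "temperature": "withCC-w/oCC", "association": "withLE",
            "slope_per_decade": tf.slope_per_decade,
            "ci_lower": tf.ci_lower, "ci_upper": tf.ci_upper,
            "best_family": tf.best_family,
        })

    # city-level AF trends: factual (n cities) vs all 9 cf variants pooled
    comparisons = {}
    if not cfg.ensemble_trends:
        return pd.DataFrame(trends_rows), comparisons
    for assoc_label, th in (("withLE", th_f), ("w/oLE", th_cf)):
        factual_slopes = [
            fit_trend(r.index.to_numpy(), r["af"].to_numpy()).slope_per_decade
            for r in per_city[("withCC", assoc_label)].values()
        ]
        cf_slopes = []
        for variant in sorted(next(iter(ensembles.values()))):
            temps_v = {c: ensembles[c][variant] for c in ensembles}
            res = scenario_attribution(
                th, temps_v, morts, exposures, scheme, max_lag=cfg.max_lag,
                variant=variant,
            )
            for c, r in res.items():
                r = r[~r.index.isin(cfg.exclude_years)]
                cf_slopes.append(
                    fit_trend(r.index.to_numpy(), r["af"].to_numpy()).slope_per_decade
                )
        comp = compare_trends(
            np.asarray(factual_slopes), np.asarray(cf_slopes),
            grouping=f"withCC vs w/oCC ({assoc_label})",
        )
        comparisons[assoc_label] = comp

    # temperature trends, factual vs counterfactual ensemble
    t_slopes_f, t_slopes_cf = [], []
    for city in sorted(factual):
        ann_f = gmst_mod.annual_warm_season_mean(factual[city])
        ann_f = ann_f[~ann_f.index.isin(cfg.exclude_years)]
        t_slopes_f.append(
            fit_trend(ann_f.index.to_numpy(), ann_f.to_numpy()).slope_per_decade
        )
        for variant, cf in sorted(ensembles[city].items()):
            ann_c = gmst_mod.annual_warm_season_mean(cf)
            ann_c = ann_c[~ann_c.index.isin(cfg.exclude_years)]
            t_slopes_cf.append(
                fit_trend(ann_c.index.to_numpy(), ann_c.to_numpy()).slope_per_decade
            )
    comparisons["temperature"] = compare_trends(
        np.asarray(t_slopes_f), np.asarray(t_slopes_cf),
        grouping="temperature withCC vs w/oCC",
    )
    return pd.DataFrame(trends_rows), comparisons


# ---------------------------------------------------------------------------
# persistence

def _write_outputs(result: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result["config"]

    red_rows = []
    for r in result["reduced"]:
        row = {"city": r.city, "subperiod": r.subperiod, "center": r.center}
        for j, v in enumerate(r.theta):
            row[f"theta_{j + 1}"] = v
        iu = np.triu_indices(len(r.theta))
        for a, b in zip(*iu):
            row[f"S_{a + 1}{b + 1}"] = r.S[a, b]
        red_rows.append(row)
    pd.DataFrame(red_rows).to_csv(outdir / "reduced.csv", index=False,
                                  float_format="%.10g")

    model = result["model"]
    het = result["heterogeneity"]
    model_json = {
        "columns": model.data.columns,
        "fixed_effects": model.B.tolist(),
        "psi": model.psi.tolist(),
        "loglik": model.loglik, "aic": model.aic, "bic": model.bic,
        "converged": model.converged,
        "heterogeneity": {"Q": het.Q, "df": het.df, "p": het.p, "I2": het.I2},
        "selection_trace": result["selection_trace"].to_dict("records"),
    }
    (outdir / "model.json").write_text(json.dumps(model_json, indent=1))

    pd.concat(
        [result["blups"].to_frame(), result["cf_blups"].to_frame()],
        ignore_index=True,
    ).to_csv(outdir / "blups.csv", index=False, float_format="%.10g")

    rows = []
    for key, res in result["per_city"].items():
        for city, r in res.items():
            for year, rec in r.iterrows():
                rows.append({
                    "city": city, "year": year,
                    "temperature": key[0], "association": key[1],
                    "an": rec["an"], "af": rec["af"], "deaths": rec["deaths"],
                })
    pd.DataFrame(rows).to_csv(outdir / "attribution.csv", index=False,
                              float_format="%.10g")

    cc_rows = []
    for name, cc in (("withLE", result["climate_attribution_with_le"]),
                     ("w/oLE", result["climate_attribution_wo_le"])):
        for year, rec in cc.iterrows():
            cc_rows.append({
                "association": name, "period_or_year": year,
                "an_cc": rec["an_cc"], "af_cc": rec["af_cc"],
                "p_cc": rec["p_cc"],
            })
    pd.DataFrame(cc_rows).to_csv(outdir / "climate_attrib.csv", index=False,
                                 float_format="%.10g")

    result["trends"].to_csv(outdir / "trends.csv", index=False,
                            float_format="%.10g")
    comps = {
        k: {"grouping": v.grouping, "n_a": v.n_a, "n_b": v.n_b,
            "statistic": v.statistic, "p": v.p}
        for k, v in result["comparisons"].items()
    }
    (outdir / "comparisons.json").write_text(json.dumps(comps, indent=1))

    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "n_reduced": len(result["reduced"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
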