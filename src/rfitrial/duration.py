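"""Shortened-test analysis: recompute intake, gain, metabolic midweight
and RFI on truncated test windows and compare them to full-test values.

For a truncated duration d the animal's "final BW" is the single weight
taken at day d (no consecutive-day pair exists mid-test), ADG1 is
refitted on the weigh points up to day d, ADG2 uses the day-d weight
against the two-day initial mean, and mean DMI covers days 1..d.  RFI
at each duration is the residual from refitting the expected-DMI model
on that duration's own summaries — not a truncation of the full-test
residuals.  Full-test values are then regressed on the truncated ones
(slope, SE, R^2) alongside Pearson and Spearman correlations; the d
windows are nested inside the full test, so these statistics measure
how much of the 70-d ranking a shorter test already contains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, IdMismatchError, UndefinedCorrelationError
from .growth import adg_by_regression, metabolic_midweight, summarize_cohort
from .rfi import RFIModelSpec, fit_dmi_model

__all__ = ["DurationComparison", "truncate_trial", "compare_durations", "duration_table"]

DEFAULT_DURATIONS = (14, 28, 42, 56)
DEFAULT_METRICS = ("mean_dmi", "adg1", "adg2", "mmwt1", "mmwt2", "rfi1", "rfi2")


@dataclass
class DurationComparison:
    metric: str
    duration: int
    slope: float
    slope_se: float
    r_squared: float
    pearson: float
    spearman: float
    p_slope: float
    p_pearson: float
    p_spearman: float
    n: int


def truncate_trial(
    heifers: pd.DataFrame,
    intake: pd.DataFrame,
    weights: pd.DataFrame,
    d: int,
    ids: set[str] | None = None,
    legacy_lb_mode: bool = False,
) -> pd.DataFrame:
    """Growth summaries as if the test had ended on weigh day ``d``.

    ``d`` must be an interior weigh day (a multiple of the weigh
    interval) or the full test length, in which case the full-test
    summaries (two-day endpoint means) are returned unchanged.
    """
    full_days = int(heifers["days_on_test"].max())
    if d == full_days:
        return summarize_cohort(heifers, intake, weights, ids, legacy_lb_mode)
    observed_days = sorted(weights["day"].unique())
    if d not in observed_days or d <= 0:
        valid = [day for day in observed_days if day > 0]
        raise DomainError(f"{d} is not a weigh day; valid durations: {valid}")

    meta = heifers.set_index("id")
    rows = []
    for hid, w in weights.groupby("id", sort=True):
        if ids is not None and hid not in ids:
            continue
        w = w.sort_values("day")
        sub = w[w["day"] <= d]
        initial_bw = float(sub[sub["day"] <= 0]["bw_kg"].mean())
        final_bw = float(sub.loc[sub["day"] == d, "bw_kg"].iloc[0])
        adg1 = adg_by_regression(sub["day"].to_numpy(), sub["bw_kg"].to_numpy())
        adg2 = (final_bw - initial_bw) / d
        window = intake[(intake["id"] == hid) & (intake["day"] >= 1) & (intake["day"] <= d)]
        ubf = meta.at[hid, "ubf_mm"] if "ubf_mm" in meta.columns else np.nan
        rows.append(
            {
                "id": hid,
                "group": meta.at[hid, "group"],
                "initial_bw": initial_bw,
                "final_bw": final_bw,
                "adg1": adg1,
                "adg2": adg2,
                "mmwt1": metabolic_midweight(final_bw, adg1, d, legacy_lb_mode),
                "mmwt2": metabolic_midweight(final_bw, adg2, d, legacy_lb_mode),
                "mean_dmi": float(window["dmi_kg"].mean()),
                "days": d,
                "ubf_mm": None if pd.isna(ubf) else float(ubf),
            }
        )
    return pd.DataFrame(rows)


def compare_durations(
    full: pd.Series,
    short: pd.Series,
    metric: str = "",
    duration: int = 0,
    permutation: bool = False,
) -> DurationComparison:
    """Regress full-test values on truncated values and correlate them.

    Slope/SE/R^2 from simple OLS of full on short; Pearson r and
    Spearman rho (midranks for ties) with two-sided t-approximation
    p-values, or exact permutation p-values when ``permutation`` is
    set (intended for small n).
    """
    if set(full.index) != set(short.index):
        diff = sorted(set(full.index) ^ set(short.index))
        raise IdMismatchError(f"full/short cover different animals: {diff}")
    short = short.reindex(full.index)
    x = short.to_numpy(dtype=float)
    y = full.to_numpy(dtype=float)
    if x.size < 3:
        raise DomainError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"zero variance in {metric or 'metric'} values")

    ols = stats.linregress(x, y)
    method = stats.PermutationMethod(n_resamples=9999, rng=0) if permutation else None
    kw = {"method": method} if method is not None else {}
    pear = stats.pearsonr(x, y, **kw)
    spear = stats.spearmanr(x, y)
    p_spear = spear.pvalue
    if permutation:
        p_spear = stats.permutation_test(
            (x,),
            lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=0,
        ).pvalue
    return DurationComparison(
        metric=metric,
        duration=duration,
        slope=float(ols.slope),
        slope_se=float(ols.stderr),
        r_squared=float(ols.rvalue**2),
        pearson=float(pear.statistic),
        spearman=float(spear.statistic),
        p_slope=float(ols.pvalue),
        p_pearson=float(pear.pvalue),
        p_spearman=float(p_spear),
        n=int(x.size),
    )


def _metric_values(summaries: pd.DataFrame, metric: str, fit_scope: str) -> pd.Series:
    if metric in ("rfi1", "rfi2"):
        variant = "regression" if metric == "rfi1" else "difference"
        fit = fit_dmi_model(summaries, RFIModelSpec(variant, include_ubf=False, fit_scope=fit_scope))
        return fit.residuals
    return summaries.set_index("id")[metric].astype(float)


def duration_table(
    heifers: pd.DataFrame,
    intake: pd.DataFrame,
    weights: pd.DataFrame,
    durations=DEFAULT_DURATIONS,
    metrics=DEFAULT_METRICS,
    ids: set[str] | None = None,
    fit_scope: str = "pooled",
    legacy_lb_mode: bool = False,
) -> pd.DataFrame:
    """One comparison row per (metric, duration); RFI is refitted on each
    truncated window's own ADG/MMWT/DMI."""
    full_days = int(heifers["days_on_test"].max())
    full = truncate_trial(heifers, intake, weights, full_days, ids, legacy_lb_mode)
    rows = []
    for d in durations:
        short = truncate_trial(heifers, intake, weights, int(d), ids, legacy_lb_mode)
        for metric in metrics:
            comp = compare_durations(
                _metric_values(full, metric, fit_scope),
                _metric_values(short, metric, fit_scope),
                metric=metric,
                duration=int(d),
            )
            rows.append(
                {
                    "metric": metric,
                    "duration_d": comp.duration,
                    "slope": comp.slope,
                    "slope_se": comp.slope_se,
                    "r_squared": comp.r_squared,
                    "pearson": comp.pearson,
                    "spearman": comp.spearman,
                    "p_slope": comp.p_slope,
                    "p_pearson": comp.p_pearson,
                    "p_spearman": comp.p_spearman,
                }
            )
    return pd.DataFrame(rows)
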