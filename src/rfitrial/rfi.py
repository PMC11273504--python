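"""Expected-DMI regression models, residual feed intake, and efficiency classes.

Residual feed intake (RFI) is the residual of an ordinary-least-squares
regression of observed dry-matter intake on average daily gain and
metabolic midweight — the feed an animal eats beyond what its growth
and maintenance predict.  Four model variants are fitted, crossing the
ADG definition (regression slope vs endpoint difference) with an
optional ultrasound-backfat covariate:

    RFI_1   : DMI ~ ADG1 + MMWT1
    RFI_bf1 : DMI ~ ADG1 + MMWT1 + UBF
    RFI_2   : DMI ~ ADG2 + MMWT2
    RFI_bf2 : DMI ~ ADG2 + MMWT2 + UBF

Animals are then classed low / medium / high within contemporary group:
more than 1 SD below the group-mean RFI is low (efficient), more than
1 SD above is high (inefficient), the rest medium.  Boundary values at
exactly +/-1 SD are medium ("more than" read strictly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, IdMismatchError, SingularDesignError

log = logging.getLogger(__name__)

__all__ = [
    "RFIModelSpec",
    "RFIFit",
    "RFIClassification",
    "MODEL_SPECS",
    "fit_dmi_model",
    "compute_rfi_models",
    "classify_rfi",
    "class_summary",
    "rank_change_tally",
]

CLASS_ORDER = ("low", "medium", "high")


@dataclass(frozen=True)
class RFIModelSpec:
    """Which predictors enter the expected-DMI regression and over what scope.

    ``fit_scope``:
      pooled             one regression over all animals (default; the
                         model statements carry no group term)
      per_group          a separate regression within each contemporary group
      group_fixed_effect one regression with contemporary-group dummies
    """

    adg_variant: str  # "regression" (ADG1/MMWT1) or "difference" (ADG2/MMWT2)
    include_ubf: bool = False
    fit_scope: str = "pooled"

    def predictor_columns(self) -> list[str]:
        cols = ["adg1", "mmwt1"] if self.adg_variant == "regression" else ["adg2", "mmwt2"]
        if self.include_ubf:
            cols.append("ubf_mm")
        return cols


# The four canonical model variants, keyed by the conventional RFI labels.
MODEL_SPECS: dict[str, RFIModelSpec] = {
    "RFI_1": RFIModelSpec("regression", include_ubf=False),
    "RFI_bf1": RFIModelSpec("regression", include_ubf=True),
    "RFI_2": RFIModelSpec("difference", include_ubf=False),
    "RFI_bf2": RFIModelSpec("difference", include_ubf=True),
}


@dataclass
class RFIFit:
    spec: RFIModelSpec
    coefficients: dict[str, float]  # per scope when fit per_group
    r_squared: float
    residuals: pd.Series  # id -> kg/d; this IS the RFI
    n: int
    n_dropped_missing_ubf: int = 0


@dataclass
class RFIClassification:
    labels: pd.Series  # id -> {"low","medium","high"}
    group_stats: pd.DataFrame  # group -> mean, sd of RFI used for thresholds


def _design(table: pd.DataFrame, cols: list[str], add_groups: bool) -> pd.DataFrame:
    X = table[cols].astype(float).copy()
    if add_groups:
        dummies = pd.get_dummies(table["group"], prefix="group", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return sm.add_constant(X, has_constant="add")


def _fit_ols(X: pd.DataFrame, y: pd.Series) -> sm.regression.linear_model.RegressionResultsWrapper:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify which columns are linearly dependent for the message
        bad = []
        for c in X.columns:
            if c == "const":
                continue
            others = X.drop(columns=[c])
            if np.linalg.matrix_rank(others.to_numpy()) == rank:
                bad.append(c)
        raise SingularDesignError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return sm.OLS(y.astype(float), X).fit()


def fit_dmi_model(table: pd.DataFrame, spec: RFIModelSpec) -> RFIFit:
    """OLS of mean DMI on the spec's predictors; residuals are the RFI.

    Animals lacking UBF are dropped (with a logged count) from models
    that include it; other models keep them.
    """
    cols = spec.predictor_columns()
    work = table.set_index("id") if "id" in table.columns else table.copy()
    n_dropped = 0
    if spec.include_ubf:
        present = work["ubf_mm"].notna()
        n_dropped = int((~present).sum())
        if n_dropped:
            log.info("dropping %d animals without UBF from backfat-adjusted model", n_dropped)
        work = work[present]

    y = work["mean_dmi"].astype(float)
    if spec.fit_scope == "per_group":
        residuals, coefs, ss_res, ss_tot = [], {}, 0.0, 0.0
        for gid, sub in work.groupby("group", sort=True):
            if len(sub) < len(cols) + 2:
                raise DomainError(
                    f"group {gid}: {len(sub)} animals < {len(cols) + 2} required for per-group fit"
                )
            res = _fit_ols(_design(sub, cols, add_groups=False), sub["mean_dmi"].astype(float))
            residuals.append(res.resid)
            coefs[str(gid)] = dict(res.params)
            ss_res += float(res.ssr)
            ss_tot += float(res.centered_tss)
        resid = pd.concat(residuals)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return RFIFit(spec, coefs, float(r2), resid.loc[work.index], len(work), n_dropped)

    add_groups = spec.fit_scope == "group_fixed_effect"
    if len(work) < len(cols) + 2:
        raise DomainError(f"{len(work)} animals < {len(cols) + 2} required to fit")
    res = _fit_ols(_design(work, cols, add_groups), y)
    return RFIFit(
        spec=spec,
        coefficients=dict(res.params),
        r_squared=float(res.rsquared),
        residuals=res.resid,
        n=len(work),
        n_dropped_missing_ubf=n_dropped,
    )


def compute_rfi_models(table: pd.DataFrame, fit_scope: str = "pooled") -> dict[str, RFIFit]:
    """Fit all four model variants with one shared fit scope.

    Backfat-adjusted variants are skipped (with a log message) when no
    animal carries a UBF record.
    """
    fits: dict[str, RFIFit] = {}
    has_ubf = "ubf_mm" in table.columns and table["ubf_mm"].notna().any()
    for name, spec in MODEL_SPECS.items():
        if spec.include_ubf and not has_ubf:
            log.warning("skipping %s: no UBF records in the table", name)
            continue
        fits[name] = fit_dmi_model(
            table, RFIModelSpec(spec.adg_variant, spec.include_ubf, fit_scope)
        )
    return fits


def classify_rfi(fit: RFIFit, groups: pd.Series) -> RFIClassification:
    """Label each animal low / medium / high against its contemporary
    group's RFI mean +/- 1 sample SD (strict inequalities; a zero-SD
    group is all medium)."""
    groups = groups.reindex(fit.residuals.index)
    stats_rows = []
    labels = pd.Series(index=fit.residuals.index, dtype=object)
    for gid, resid in fit.residuals.groupby(groups):
        if len(resid) < 2:
            raise DomainError(f"group {gid}: needs >= 2 animals to classify")
        mean, sd = float(resid.mean()), float(resid.std(ddof=1))
        stats_rows.append({"group": gid, "mean": mean, "sd": sd, "n": len(resid)})
        if sd == 0:
            labels.loc[resid.index] = "medium"
            continue
        labels.loc[resid.index] = np.select(
            [resid > mean + sd, resid < mean - sd], ["high", "low"], default="medium"
        )
    return RFIClassification(labels=labels, group_stats=pd.DataFrame(stats_rows).set_index("group"))


def class_summary(table: pd.DataFrame, classification: RFIClassification, fit: RFIFit) -> pd.DataFrame:
    """Unadjusted per-class means and SEMs of RFI and the growth traits,
    plus the DMI excess of high- over low-RFI animals in integer percent.

    These are raw arithmetic class summaries, not least-squares means
    from a multi-factor model; treat comparisons across classes as
    descriptive.
    """
    work = table.set_index("id") if "id" in table.columns else table.copy()
    work = work.loc[classification.labels.index].copy()
    work["rfi"] = fit.residuals
    work["rfi_class"] = classification.labels
    traits = ["rfi", "initial_bw", "final_bw", "mean_dmi", "adg1", "adg2", "mmwt1", "mmwt2", "ubf_mm"]
    traits = [t for t in traits if t in work.columns]
    grouped = work.groupby("rfi_class")[traits]
    means = grouped.mean()
    sems = grouped.sem(ddof=1)
    counts = grouped.size()
    out = pd.concat({"mean": means, "sem": sems}, axis=1)
    out["n"] = counts
    out = out.reindex([c for c in CLASS_ORDER if c in out.index])
    lo = means.at["low", "mean_dmi"] if "low" in means.index else np.nan
    hi = means.at["high", "mean_dmi"] if "high" in means.index else np.nan
    out.attrs["dmi_excess_pct"] = dmi_excess_percent(lo, hi)
    return out


def dmi_excess_percent(low_mean_dmi: float, high_mean_dmi: float) -> float:
    """100 * (DMI_high - DMI_low) / DMI_low, rounded to integer percent."""
    if np.isnan(low_mean_dmi) or np.isnan(high_mean_dmi):
        return float("nan")
    return float(round(100.0 * (high_mean_dmi - low_mean_dmi) / low_mean_dmi))


def rank_change_tally(a: RFIClassification | pd.Series, b: RFIClassification | pd.Series):
    """3x3 transition matrix between two classifications of the same
    animals, plus the number that changed class."""
    la = a.labels if isinstance(a, RFIClassification) else a
    lb = b.labels if isinstance(b, RFIClassification) else b
    if set(la.index) != set(lb.index):
        diff = sorted(set(la.index) ^ set(lb.index))
        raise IdMismatchError(f"classifications cover different animals: {diff}")
    lb = lb.reindex(la.index)
    cats = pd.CategoricalDtype(categories=list(CLASS_ORDER), ordered=True)
    matrix = pd.crosstab(la.astype(cats), lb.astype(cats), dropna=False)
    matrix = matrix.reindex(index=CLASS_ORDER, columns=CLASS_ORDER, fill_value=0)
    matrix.index.name, matrix.columns.name = "from", "to"
    changed = int(matrix.to_numpy().sum() - np.trace(matrix.to_numpy()))
    return matrix, changed
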