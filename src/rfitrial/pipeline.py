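"""End-to-end orchestration: simulate/load -> qc -> growth -> rfi ->
duration -> agreement -> report bundle.

Every artifact is written with '.' decimal, LF newlines and fixed float
precision so identical (config, seed) runs produce byte-identical
bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import cohen_kappa, pearson_r, regress_pair, spearman_rho
from .duration import DEFAULT_DURATIONS, DEFAULT_METRICS, duration_table
from .errors import StageError
from .growth import summarize_cohort
from .qc import run_qc
from .rfi import classify_rfi, class_summary, compute_rfi_models, rank_change_tally
from .simulate import SimConfig, TrialData, default_config, generate_trial, read_trial, write_trial

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_report", "verify_bundle"]

# Model pairs whose agreement is reported (ADG-variant pairs and
# adjusted-vs-unadjusted pairs).
AGREEMENT_PAIRS = [
    ("RFI_1", "RFI_2"),
    ("RFI_bf1", "RFI_bf2"),
    ("RFI_2", "RFI_bf2"),
    ("RFI_1", "RFI_bf1"),
]


@dataclass
class RunConfig:
    outdir: str | Path = "rfitrial_out"
    input_dir: str | Path | None = None  # load CSVs from here; None -> simulate
    sim_config: SimConfig | None = None  # defaults to default_config() when simulating
    seed: int = 0
    min_start_age: int = 240
    max_end_age: int = 390
    intake_sd_k: float = 4.0
    fit_scope: str = "pooled"
    durations: tuple[int, ...] = DEFAULT_DURATIONS
    legacy_lb_mode: bool = False


@dataclass
class PipelineResult:
    trial: TrialData
    qc_report: pd.DataFrame
    retained_ids: set[str]
    growth: pd.DataFrame
    fits: dict
    classifications: dict
    class_summaries: dict
    durations: pd.DataFrame
    agreement: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full evaluation and write the report bundle to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        trial = _stage("load")(read_trial)(config.input_dir)
    else:
        sim = config.sim_config or default_config()
        trial = _stage("simulate")(generate_trial)(sim, config.seed)
        write_trial(trial, outdir / "inputs")

    days = int(trial.heifers["days_on_test"].max())
    qc = _stage("qc")(run_qc)(
        trial.heifers,
        trial.intake,
        required_days=days,
        min_start_age=config.min_start_age,
        max_end_age=config.max_end_age,
        intake_sd_k=config.intake_sd_k,
    )
    growth = _stage("growth")(summarize_cohort)(
        trial.heifers, trial.intake, trial.weights, qc.retained_ids, config.legacy_lb_mode
    )
    fits = _stage("rfi")(compute_rfi_models)(growth, config.fit_scope)
    groups = growth.set_index("id")["group"]
    classifications = {
        name: classify_rfi(fit, groups) for name, fit in fits.items()
    }
    class_summaries = {
        name: class_summary(growth, classifications[name], fits[name]) for name in fits
    }
    durations = _stage("duration")(duration_table)(
        trial.heifers,
        trial.intake,
        trial.weights,
        durations=config.durations,
        ids=qc.retained_ids,
        fit_scope=config.fit_scope,
        legacy_lb_mode=config.legacy_lb_mode,
    )
    agreement = _stage("agreement")(_agreement_reports)(fits, classifications)

    result = PipelineResult(
        trial=trial,
        qc_report=qc.to_frame(),
        retained_ids=qc.retained_ids,
        growth=growth,
        fits=fits,
        classifications=classifications,
        class_summaries=class_summaries,
        durations=durations,
        agreement=agreement,
    )
    result.paths = _write_bundle(result, config, outdir)
    return result


def _agreement_reports(fits: dict, classifications: dict) -> dict:
    out: dict[str, dict] = {}
    for a, b in AGREEMENT_PAIRS:
        if a not in fits or b not in fits:
            continue
        ra, rb = fits[a].residuals, fits[b].residuals
        common = ra.index.intersection(rb.index)
        la = classifications[a].labels.loc[common]
        lb = classifications[b].labels.loc[common]
        unweighted = cohen_kappa(la, lb, weighting="none")
        weighted = cohen_kappa(la, lb, weighting="linear")
        matrix, changed = rank_change_tally(la, lb)
        r, p_r = pearson_r(ra.loc[common], rb.loc[common])
        rho, p_rho = spearman_rho(ra.loc[common], rb.loc[common])
        reg = regress_pair(rb.loc[common], ra.loc[common])  # regress a on b
        out[f"{a}_vs_{b}"] = {
            "n": int(len(common)),
            "kappa": unweighted.kappa,
            "kappa_se": unweighted.se,
            "kappa_ci95": list(unweighted.ci95),
            "kappa_p": unweighted.p_value,
            "weighted_kappa": weighted.kappa,
            "weighted_kappa_se": weighted.se,
            "weighted_kappa_ci95": list(weighted.ci95),
            "weighted_kappa_p": weighted.p_value,
            "interpretation": unweighted.interpretation,
            "weighted_interpretation": weighted.interpretation,
            "confusion": matrix.to_numpy().tolist(),
            "n_changed": changed,
            "pearson": r,
            "pearson_p": p_r,
            "spearman": rho,
            "spearman_p": p_rho,
            "slope": reg.slope,
            "slope_se": reg.slope_se,
            "slope_ci95": list(reg.slope_ci95),
            "slope_ci_contains_1": reg.slope_ci_contains_1,
            "r_squared": reg.r_squared,
        }
    return out


def _write_bundle(result: PipelineResult, config: RunConfig, outdir: Path) -> dict[str, Path]:
    paths = {}

    paths["qc_report"] = outdir / "qc_report.csv"
    result.qc_report.to_csv(paths["qc_report"], index=False, lineterminator="\n")
    (outdir / "retained_ids.txt").write_text(
        "\n".join(sorted(result.retained_ids)) + "\n", encoding="utf-8"
    )

    paths["growth_summary"] = outdir / "growth_summary.csv"
    result.growth.to_csv(
        paths["growth_summary"], index=False, float_format="%.4f", lineterminator="\n"
    )

    rfi_table = result.growth[["id", "group"]].set_index("id")
    for name, fit in result.fits.items():
        col = name.lower()
        rfi_table[col] = fit.residuals
        rfi_table[f"{col}_class"] = result.classifications[name].labels
    paths["rfi_results"] = outdir / "rfi_results.csv"
    rfi_table.reset_index().to_csv(
        paths["rfi_results"], index=False, float_format="%.4f", lineterminator="\n"
    )

    fits_payload = {
        name: {
            "adg_variant": fit.spec.adg_variant,
            "include_ubf": fit.spec.include_ubf,
            "fit_scope": fit.spec.fit_scope,
            "coefficients": _round_floats(fit.coefficients),
            "r_squared": round(fit.r_squared, 6),
            "n": fit.n,
            "n_dropped_missing_ubf": fit.n_dropped_missing_ubf,
        }
        for name, fit in result.fits.items()
    }
    paths["model_fits"] = outdir / "model_fits.json"
    paths["model_fits"].write_text(json.dumps(fits_payload, indent=2, sort_keys=True) + "\n")

    paths["duration_table"] = outdir / "duration_table.csv"
    result.durations.to_csv(
        paths["duration_table"], index=False, float_format="%.6f", lineterminator="\n"
    )

    paths["agreement_report"] = outdir / "agreement_report.json"
    paths["agreement_report"].write_text(
        json.dumps(_round_floats(result.agreement), indent=2, sort_keys=True) + "\n"
    )

    n_excluded = len(result.qc_report)
    paths["run_log"] = outdir / "run_log.txt"
    paths["run_log"].write_text(
        "\n".join(
            [
                f"rfitrial version: {__version__}",
                f"seed: {config.seed}",
                f"fit_scope: {config.fit_scope}",
                f"animals retained: {len(result.retained_ids)}",
                f"animals excluded: {n_excluded}",
                f"models fitted: {', '.join(result.fits)}",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    return paths


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def make_report(result: PipelineResult) -> str:
    """Human-readable summary: per-group means +/- SD, per-class summaries,
    the duration table, and the agreement table."""
    lines = []
    lines.append("Per-group means (+/- SD) of growth and intake")
    g = result.growth.groupby("group")
    agg_cols = ["initial_bw", "final_bw", "mean_dmi", "adg1", "adg2", "mmwt1", "mmwt2"]
    mean, sd, n = g[agg_cols].mean(), g[agg_cols].std(ddof=1), g.size()
    header = f"{'group':>6} {'n':>4}" + "".join(f" {c:>18}" for c in agg_cols)
    lines.append(header)
    for gid in mean.index:
        row = f"{gid:>6} {n[gid]:>4}"
        for c in agg_cols:
            row += f" {mean.at[gid, c]:9.2f} ± {sd.at[gid, c]:5.2f}"
        lines.append(row)
    total = result.growth[agg_cols]
    row = f"{'all':>6} {len(total):>4}"
    for c in agg_cols:
        row += f" {total[c].mean():9.2f} ± {total[c].std(ddof=1):5.2f}"
    lines.append(row)

    for name, summary in result.class_summaries.items():
        lines.append("")
        lines.append(f"Unadjusted class means for {name} (low/medium/high within group)")
        lines.append(summary.round(3).to_string())
        excess = summary.attrs.get("dmi_excess_pct")
        if excess == excess:  # not NaN
            lines.append(f"high-RFI animals ate {excess:.0f}% more feed/day than low-RFI animals")

    lines.append("")
    lines.append("Truncated-test comparisons (full-test values regressed on shorter windows)")
    lines.append(result.durations.round(4).to_string(index=False))

    lines.append("")
    lines.append("Model-pair agreement")
    for pair, rep in result.agreement.items():
        lines.append(
            f"  {pair}: kappa {rep['kappa']:.3f} [{rep['kappa_ci95'][0]:.3f}, "
            f"{rep['kappa_ci95'][1]:.3f}] ({rep['interpretation']}), weighted "
            f"{rep['weighted_kappa']:.3f}, Pearson {rep['pearson']:.3f}, "
            f"Spearman {rep['spearman']:.3f}, slope {rep['slope']:.3f}, "
            f"{rep['n_changed']}/{rep['n']} changed class"
        )
    return "\n".join(lines) + "\n"


def verify_bundle(config: RunConfig) -> list[str]:
    """Recompute the bundle into a scratch directory and diff it against
    the bundle on disk; returns the names of artifacts that differ."""
    import filecmp
    import tempfile

    outdir = Path(config.outdir)
    mismatches = []
    with tempfile.TemporaryDirectory() as tmp:
        fresh_cfg = RunConfig(**{**config.__dict__, "outdir": tmp})
        fresh = run_pipeline(fresh_cfg)
        for name, fresh_path in fresh.paths.items():
            existing = outdir / fresh_path.name
            if not existing.exists() or not filecmp.cmp(existing, fresh_path, shallow=False):
                mismatches.append(fresh_path.name)
    return mismatches
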