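"""Seeded synthetic feed-trial generator.

Emulates a multi-group heifer performance test: contemporary groups of
animals with group-specific initial body weight and average daily gain
(ADG) distributions, daily dry-matter intake (DMI) driven by gain and
metabolic midweight plus an animal-level efficiency residual (the "true"
residual feed intake), biweekly weighing with measurement noise, and a
single end-of-test ultrasound backfat (UBF) measurement weakly coupled
to efficiency.

The latent intake model for each animal is

    mean DMI = b0 + b_adg * ADG + b_mmwt * MMWT + b_ubf * UBF + true_rfi

with ``true_rfi ~ Normal(0, sigma_rfi)``.  Daily intakes add i.i.d.
day-to-day noise around the animal's mean; weights follow a straight
line ``BW(t) = initial + ADG * t`` plus per-weighing noise.  Every
random draw descends from one root seed through per-animal substreams,
so adding a group to the configuration never perturbs earlier animals
and identical (config, seed) pairs reproduce output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "GroupConfig",
    "SimConfig",
    "TrialData",
    "default_config",
    "generate_trial",
    "write_trial",
    "read_trial",
    "save_config",
    "load_config",
]

# Nominal on-test date per contemporary group (trial period start).
_DEFAULT_ON_TEST = {
    "1": "2014-06-15",
    "2": "2015-06-15",
    "3": "2014-06-15",
    "4": "2015-08-15",
    "5": "2015-09-15",
    "6": "2014-12-15",
    "7": "2014-12-15",
}


@dataclass(frozen=True)
class GroupConfig:
    """One contemporary group: animals tested together from one farm."""

    group_id: str
    farm: str
    n: int
    initial_bw_mean: float  # kg
    initial_bw_sd: float  # kg
    adg_mean: float  # kg/d
    adg_sd: float  # kg/d
    age_on_test_mean: float = 275.0  # d
    age_on_test_sd: float = 15.0  # d
    on_test_date: str = ""  # ISO date; filled from _DEFAULT_ON_TEST if blank

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError(f"group {self.group_id}: n must be >= 2, got {self.n}")
        for name in ("initial_bw_sd", "adg_sd", "age_on_test_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(
                    f"group {self.group_id}: {name} must be >= 0, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration.

    DMI coefficients are on the scale of the intake model: kg DMI per
    kg/d of ADG, per kg^0.75 of metabolic midweight, and per mm of
    backfat.  ``sigma_rfi`` is the between-animal efficiency SD (kg/d),
    ``sigma_daily_intake`` the within-animal day-to-day intake SD
    (kg/d), and ``sigma_weighing`` the per-weighing scale noise (kg).
    """

    groups: tuple[GroupConfig, ...]
    dmi_intercept: float = -0.5
    dmi_coef_adg: float = 1.8
    dmi_coef_mmwt: float = 0.105
    dmi_coef_ubf: float = 0.05
    sigma_rfi: float = 0.95
    sigma_daily_intake: float = 1.5
    sigma_weighing: float = 4.0
    ubf_mean: float = 7.5  # mm
    ubf_sd: float = 1.5  # mm
    ubf_rfi_corr: float = 0.25
    days_on_test: int = 70
    weigh_interval: int = 14
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("groups: at least one group required")
        for g in self.groups:
            g.validate()
        for name in ("sigma_rfi", "sigma_daily_intake", "sigma_weighing", "ubf_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if abs(self.ubf_rfi_corr) > 1:
            raise ConfigError(f"ubf_rfi_corr must lie in [-1, 1], got {self.ubf_rfi_corr}")
        if self.days_on_test <= 0:
            raise ConfigError(f"days_on_test must be > 0, got {self.days_on_test}")
        if self.weigh_interval <= 0:
            raise ConfigError(f"weigh_interval must be > 0, got {self.weigh_interval}")
        if self.days_on_test % self.weigh_interval != 0:
            raise ConfigError(
                "days_on_test must be divisible by weigh_interval, got "
                f"{self.days_on_test} % {self.weigh_interval} != 0"
            )

    def weigh_days(self) -> list[int]:
        """Scale schedule: consecutive-day pairs at both test boundaries,
        evenly spaced weighings between."""
        interior = [d for d in range(self.weigh_interval, self.days_on_test - 1, self.weigh_interval)]
        return [-1, 0, *interior, self.days_on_test - 1, self.days_on_test]


@dataclass
class TrialData:
    """One generated trial: animal roster, long-format intake and weights,
    and the latent ground truth used by recovery tests."""

    heifers: pd.DataFrame  # id, group, farm, birth_date, on_test_date, days_on_test, ubf_mm
    intake: pd.DataFrame  # id, day, dmi_kg
    weights: pd.DataFrame  # id, day, bw_kg
    truth: pd.DataFrame  # id, true_adg, true_rfi, true_mean_dmi, true_initial_bw


# Group roster and per-group performance levels of a two-farm, seven-group
# 70-d heifer test (group sizes 20/46/22/23/22/12/41, total 186).
_DEFAULT_GROUPS = [
    # (id, farm, n, bw_mean, bw_sd, adg_mean, adg_sd)
    ("1", "1", 20, 301.87, 32.68, 1.30, 0.18),
    ("2", "1", 46, 301.70, 31.98, 1.29, 0.13),
    ("3", "2", 22, 278.24, 24.97, 1.19, 0.15),
    ("4", "2", 23, 292.08, 29.62, 1.50, 0.23),
    ("5", "1", 22, 323.72, 33.85, 1.61, 0.21),
    ("6", "1", 12, 325.38, 28.98, 1.55, 0.27),
    ("7", "2", 41, 299.49, 25.44, 1.46, 0.24),
]


def default_config() -> SimConfig:
    """Seven contemporary groups (186 heifers) at the performance levels of
    a southeastern U.S. Brangus heifer test; see the defaults on
    :class:`SimConfig` for the noise model."""
    groups = tuple(
        GroupConfig(
            group_id=gid,
            farm=farm,
            n=n,
            initial_bw_mean=bw_m,
            initial_bw_sd=bw_s,
            adg_mean=adg_m,
            adg_sd=adg_s,
            on_test_date=_DEFAULT_ON_TEST[gid],
        )
        for gid, farm, n, bw_m, bw_s, adg_m, adg_s in _DEFAULT_GROUPS
    )
    return SimConfig(groups=groups)


def _heifer_rng(seed: int, index: int) -> np.random.Generator:
    # Per-animal substream keyed on (root seed, global animal index):
    # appending groups leaves earlier animals' draws untouched.
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def generate_trial(config: SimConfig, seed: int | None = None) -> TrialData:
    """Generate one synthetic feed trial.

    Parameters
    ----------
    config
        Generator configuration; validated before any draw.
    seed
        Root seed; defaults to ``config.seed``.

    Returns
    -------
    TrialData
        Roster, daily intakes for days 1..D, weights on the scale
        schedule, and per-animal ground truth.
    """
    config.validate()
    root_seed = config.seed if seed is None else int(seed)
    days = config.days_on_test
    weigh_days = np.array(config.weigh_days())
    min_age, max_age = 240, 390  # permissible ages at test start / completion

    heifer_rows, intake_frames, weight_frames, truth_rows = [], [], [], []
    index = 0
    for grp in config.groups:
        on_test = datetime.date.fromisoformat(grp.on_test_date or "2015-01-01")
        for j in range(grp.n):
            rng = _heifer_rng(root_seed, index)
            hid = f"G{grp.group_id}-{j + 1:03d}"

            true_adg = grp.adg_mean + grp.adg_sd * rng.standard_normal()
            true_initial = grp.initial_bw_mean + grp.initial_bw_sd * rng.standard_normal()
            true_initial = max(true_initial, 50.0)

            z_rfi = rng.standard_normal()
            true_rfi = config.sigma_rfi * z_rfi
            # Backfat shares a bivariate-normal construction with the
            # efficiency residual so corr(UBF, true_rfi) -> ubf_rfi_corr.
            rho = config.ubf_rfi_corr
            z_ubf = rho * z_rfi + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
            ubf = max(config.ubf_mean + config.ubf_sd * z_ubf, 0.5)

            final_bw = true_initial + true_adg * days
            midweight = final_bw - 0.5 * days * true_adg
            mmwt = midweight**0.75
            mean_dmi = (
                config.dmi_intercept
                + config.dmi_coef_adg * true_adg
                + config.dmi_coef_mmwt * mmwt
                + config.dmi_coef_ubf * ubf
                + true_rfi
            )

            daily = mean_dmi + config.sigma_daily_intake * rng.standard_normal(days)
            daily = np.maximum(daily, 0.0)
            bw = (
                true_initial
                + true_adg * weigh_days
                + config.sigma_weighing * rng.standard_normal(len(weigh_days))
            )

            # Age drawn inside the permissible window so default rosters
            # pass the age screen; the window can still be exercised by
            # feeding the QC module hand-built records.
            age = grp.age_on_test_mean + grp.age_on_test_sd * rng.standard_normal()
            age = int(round(np.clip(age, min_age, max_age - days)))
            birth = on_test - datetime.timedelta(days=age)

            heifer_rows.append(
                {
                    "id": hid,
                    "group": grp.group_id,
                    "farm": grp.farm,
                    "birth_date": birth.isoformat(),
                    "on_test_date": on_test.isoformat(),
                    "days_on_test": days,
                    "ubf_mm": round(float(ubf), 4),
                }
            )
            intake_frames.append(
                pd.DataFrame(
                    {"id": hid, "day": np.arange(1, days + 1), "dmi_kg": np.round(daily, 4)}
                )
            )
            weight_frames.append(
                pd.DataFrame({"id": hid, "day": weigh_days, "bw_kg": np.round(bw, 4)})
            )
            truth_rows.append(
                {
                    "id": hid,
                    "true_adg": float(true_adg),
                    "true_rfi": float(true_rfi),
                    "true_mean_dmi": float(mean_dmi),
                    "true_initial_bw": float(true_initial),
                }
            )
            index += 1

    return TrialData(
        heifers=pd.DataFrame(heifer_rows),
        intake=pd.concat(intake_frames, ignore_index=True),
        weights=pd.concat(weight_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
    )


def write_trial(trial: TrialData, outdir: str | Path, include_truth: bool = True) -> dict[str, Path]:
    """Serialize a trial to CSV (ISO dates, '.' decimal, LF newlines)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "heifers": outdir / "heifers.csv",
        "intake": outdir / "intake.csv",
        "weights": outdir / "weights.csv",
    }
    trial.heifers.to_csv(paths["heifers"], index=False, lineterminator="\n")
    trial.intake.to_csv(paths["intake"], index=False, lineterminator="\n")
    trial.weights.to_csv(paths["weights"], index=False, lineterminator="\n")
    if include_truth:
        paths["truth"] = outdir / "truth.csv"
        trial.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    return paths


def read_trial(indir: str | Path) -> TrialData:
    """Load a trial written by :func:`write_trial` (or user data in the
    same dialect; truth.csv optional)."""
    indir = Path(indir)
    truth_path = indir / "truth.csv"
    return TrialData(
        heifers=pd.read_csv(indir / "heifers.csv", dtype={"id": str, "group": str, "farm": str}),
        intake=pd.read_csv(indir / "intake.csv", dtype={"id": str}),
        weights=pd.read_csv(indir / "weights.csv", dtype={"id": str}),
        truth=pd.read_csv(truth_path, dtype={"id": str}) if truth_path.exists() else pd.DataFrame(),
    )


def save_config(config: SimConfig, path: str | Path) -> None:
    """Write the configuration as YAML mirroring the field names exactly."""
    payload = dataclasses.asdict(config)
    payload["groups"] = [dataclasses.asdict(g) for g in config.groups]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_config(path: str | Path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        groups = tuple(GroupConfig(**g) for g in payload.pop("groups"))
        return SimConfig(groups=groups, **payload)
    except TypeError as exc:  # unknown/missing field
        raise ConfigError(str(exc)) from exc
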