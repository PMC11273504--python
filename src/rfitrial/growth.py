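"""Per-animal growth and intake summaries.

Two definitions of average daily gain are computed side by side:

* ADG1 — the ordinary-least-squares slope of body weight on day of
  test over every weigh point (the regression estimate);
* ADG2 — (final BW - initial BW) / days on test, with each endpoint
  weight taken as the mean of the two consecutive-day weighings.

Metabolic midweight scales the mid-test body weight by the classical
0.75 power of maintenance metabolism:

    MMWT = (final BW - 0.5 * days * ADG) ** 0.75

computed once with each ADG definition.  The canonical computation is
in kg; ``legacy_lb_mode`` instead raises the pound-scale midweight to
the 0.75 power and converts back ((mw * 2.20462)**0.75 / 2.20462),
matching datasets whose metabolic weights were produced on the pound
scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .errors import DomainError

log = logging.getLogger(__name__)

KG_PER_LB = 2.20462

__all__ = [
    "GrowthSummary",
    "endpoint_weight",
    "adg_by_regression",
    "adg_by_difference",
    "metabolic_midweight",
    "summarize_growth",
    "summarize_cohort",
]


@dataclass
class GrowthSummary:
    id: str
    initial_bw: float  # kg
    final_bw: float  # kg
    adg1: float  # kg/d, regression slope
    adg2: float  # kg/d, endpoint difference
    mmwt1: float  # kg^0.75, from adg1
    mmwt2: float  # kg^0.75, from adg2
    mean_dmi: float  # kg/d
    days: int
    ubf_mm: float | None = None


def endpoint_weight(weights: list[float] | np.ndarray) -> float:
    """Mean of the two consecutive-day weighings at a test boundary.

    A single available weight is returned as-is with a warning.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 1:
        log.warning("single boundary weight available; using it unaveraged")
        return float(weights[0])
    if weights.size != 2:
        raise DomainError(f"expected two boundary weights, got {weights.size}")
    return float(weights.mean())


def adg_by_regression(days: np.ndarray, weights: np.ndarray) -> float:
    """OLS slope of weight on day of test over all weigh points (kg/d)."""
    days = np.asarray(days, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if days.size < 2 or np.unique(days).size < 2:
        raise DomainError("ADG regression needs >= 2 distinct days")
    slope, _ = np.polyfit(days, weights, 1)
    return float(slope)


def adg_by_difference(initial_bw: float, final_bw: float, days: float) -> float:
    """(final BW - initial BW) / days on test (kg/d)."""
    if days <= 0:
        raise DomainError(f"days on test must be > 0, got {days}")
    return (final_bw - initial_bw) / days


def metabolic_midweight(
    final_bw: float, adg: float, days: float, legacy_lb_mode: bool = False
) -> float:
    """(final BW - 0.5 * days * ADG) ** 0.75, midweight in kg.

    With ``legacy_lb_mode`` the exponentiation happens on the pound
    scale and the result is rescaled back to kg units.
    """
    midweight = final_bw - 0.5 * days * adg
    if midweight <= 0:
        raise DomainError(f"mid-test weight must be > 0, got {midweight:.3f}")
    if legacy_lb_mode:
        return float((midweight * KG_PER_LB) ** 0.75 / KG_PER_LB)
    return float(midweight**0.75)


def summarize_growth(
    weights: pd.DataFrame,
    intake: pd.DataFrame,
    ubf_mm: float | None = None,
    days_on_test: int | None = None,
    legacy_lb_mode: bool = False,
) -> GrowthSummary:
    """Summarize one animal: endpoint weights, both ADGs, both MMWTs, and
    mean daily DMI over days 1..D.

    ``weights``/``intake`` are the single-animal long-format frames with
    columns (day, bw_kg) and (day, dmi_kg).
    """
    w = weights.sort_values("day")
    days = w["day"].to_numpy()
    if days_on_test is None:
        days_on_test = int(days.max())
    start = w[w["day"] <= 0]["bw_kg"].to_numpy()
    end = w[w["day"] >= days_on_test - 1]["bw_kg"].to_numpy()
    initial_bw = endpoint_weight(start)
    final_bw = endpoint_weight(end)
    adg1 = adg_by_regression(days, w["bw_kg"].to_numpy())
    adg2 = adg_by_difference(initial_bw, final_bw, days_on_test)
    window = intake[(intake["day"] >= 1) & (intake["day"] <= days_on_test)]
    hid = str(weights["id"].iloc[0]) if "id" in weights else ""
    return GrowthSummary(
        id=hid,
        initial_bw=initial_bw,
        final_bw=final_bw,
        adg1=adg1,
        adg2=adg2,
        mmwt1=metabolic_midweight(final_bw, adg1, days_on_test, legacy_lb_mode),
        mmwt2=metabolic_midweight(final_bw, adg2, days_on_test, legacy_lb_mode),
        mean_dmi=float(window["dmi_kg"].mean()),
        days=days_on_test,
        ubf_mm=None if ubf_mm is None or pd.isna(ubf_mm) else float(ubf_mm),
    )


def summarize_cohort(
    heifers: pd.DataFrame,
    intake: pd.DataFrame,
    weights: pd.DataFrame,
    ids: set[str] | None = None,
    legacy_lb_mode: bool = False,
) -> pd.DataFrame:
    """Growth summaries for every (retained) animal, one row each, with
    contemporary group carried along for downstream fitting."""
    meta = heifers.set_index("id")
    rows = []
    for hid, w in weights.groupby("id", sort=True):
        if ids is not None and hid not in ids:
            continue
        s = summarize_growth(
            w,
            intake[intake["id"] == hid],
            ubf_mm=meta.at[hid, "ubf_mm"] if "ubf_mm" in meta.columns else None,
            days_on_test=int(meta.at[hid, "days_on_test"]),
            legacy_lb_mode=legacy_lb_mode,
        )
        rows.append(
            {
                "id": hid,
                "group": meta.at[hid, "group"],
                "initial_bw": s.initial_bw,
                "final_bw": s.final_bw,
                "adg1": s.adg1,
                "adg2": s.adg2,
                "mmwt1": s.mmwt1,
                "mmwt2": s.mmwt2,
                "mean_dmi": s.mean_dmi,
                "days": s.days,
                "ubf_mm": s.ubf_mm,
            }
        )
    return pd.DataFrame(rows)
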