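"""Pre-analysis data editing for performance-test records.

Three screens, mirroring standard beef performance-test editing practice:

1. completeness — an animal must have an intake value for every feeding
   day of the test;
2. age window — at least ``min_start_age`` days old when the test starts
   and no older than ``max_end_age`` days when it ends (inclusive at
   both boundaries);
3. intake outliers — total test intake within ``k`` sample SDs of the
   animal's contemporary-group mean, candidate included in the group
   statistics.

Note the inclusive-statistics ceiling: with the candidate included, the
largest attainable |z| in a group of n is (n-1)/sqrt(n), so a lone
outlier in a group of 12 (max |z| ~ 3.18) can never trip a 4-SD screen,
while one in a group of 46 (max |z| ~ 6.64) can.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["QCReport", "check_age_window", "screen_intake_outliers", "drop_incomplete_records", "run_qc"]


@dataclass
class QCReport:
    """Outcome of one or more screens: retained ids and per-exclusion detail."""

    retained_ids: set[str]
    excluded: list[tuple[str, str, str]] = field(default_factory=list)  # (id, rule, detail)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["id", "rule", "detail"])

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            retained_ids=self.retained_ids & other.retained_ids,
            excluded=self.excluded + other.excluded,
        )


def _age_days(birth: str, on: str) -> int:
    return (datetime.date.fromisoformat(str(on)) - datetime.date.fromisoformat(str(birth))).days


def check_age_window(
    heifers: pd.DataFrame,
    min_start_age: int = 240,
    max_end_age: int = 390,
) -> QCReport:
    """Retain animals at least ``min_start_age`` d old on test and no older
    than ``max_end_age`` d at completion; both boundaries inclusive.

    Records missing a birth date are excluded under rule "missing-field"
    rather than aborting the screen.
    """
    retained: set[str] = set()
    excluded: list[tuple[str, str, str]] = []
    for row in heifers.itertuples(index=False):
        hid = str(row.id)
        if pd.isna(row.birth_date) or str(row.birth_date) == "":
            excluded.append((hid, "missing-field", "birth_date absent"))
            continue
        start_age = _age_days(row.birth_date, row.on_test_date)
        end_age = start_age + int(row.days_on_test)
        if start_age < min_start_age:
            excluded.append((hid, "age-window", f"age {start_age} d on test < {min_start_age}"))
        elif end_age > max_end_age:
            excluded.append((hid, "age-window", f"age {end_age} d at completion > {max_end_age}"))
        else:
            retained.add(hid)
    return QCReport(retained_ids=retained, excluded=excluded)


def screen_intake_outliers(
    totals: pd.Series,
    groups: pd.Series,
    k: float = 4.0,
) -> QCReport:
    """Retain animals whose total test intake lies within ``k`` sample SDs
    (n-1 denominator) of their contemporary-group mean; the candidate is
    included in its own group's mean/SD.

    A group with SD exactly 0 retains all members; a singleton group is
    retained with a warning, the screen being undefined there.
    """
    retained: set[str] = set()
    excluded: list[tuple[str, str, str]] = []
    frame = pd.DataFrame({"total": totals, "group": groups.reindex(totals.index)})
    for gid, sub in frame.groupby("group", sort=False):
        if len(sub) == 1:
            hid = str(sub.index[0])
            log.warning("intake screen undefined for singleton group %s; %s retained", gid, hid)
            retained.add(hid)
            continue
        mean = sub["total"].mean()
        sd = sub["total"].std(ddof=1)
        for hid, total in sub["total"].items():
            if sd == 0 or abs(total - mean) <= k * sd:
                retained.add(str(hid))
            else:
                z = (total - mean) / sd
                excluded.append(
                    (str(hid), "intake-outlier", f"total {total:.2f} kg, group z = {z:.2f}, |z| > {k}")
                )
    return QCReport(retained_ids=retained, excluded=excluded)


def drop_incomplete_records(intake: pd.DataFrame, required_days: int) -> QCReport:
    """Retain animals with a DMI value for every day 1..required_days."""
    retained: set[str] = set()
    excluded: list[tuple[str, str, str]] = []
    wanted = set(range(1, required_days + 1))
    valid = intake.dropna(subset=["dmi_kg"])
    days_by_id = valid.groupby("id")["day"].agg(set)
    for hid, have in days_by_id.items():
        missing = sorted(wanted - have)
        if missing:
            excluded.append((str(hid), "incomplete-record", f"missing days {missing}"))
        else:
            retained.add(str(hid))
    return QCReport(retained_ids=retained, excluded=excluded)


def run_qc(
    heifers: pd.DataFrame,
    intake: pd.DataFrame,
    required_days: int,
    min_start_age: int = 240,
    max_end_age: int = 390,
    intake_sd_k: float = 4.0,
) -> QCReport:
    """Composite screen: incomplete records, then the age window, then the
    intake-outlier screen with group statistics recomputed on the animals
    surviving the first two edits."""
    rep = drop_incomplete_records(intake, required_days)
    rep = rep.merge(check_age_window(heifers, min_start_age, max_end_age))
    survivors = sorted(rep.retained_ids)
    totals = intake[intake["id"].isin(survivors)].groupby("id")["dmi_kg"].sum()
    groups = heifers.set_index("id")["group"]
    rep = rep.merge(screen_intake_outliers(totals, groups, intake_sd_k))
    # merge() intersects, so ids dropped by the intake screen leave retained_ids
    return rep
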