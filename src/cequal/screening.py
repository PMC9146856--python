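"""Cohort screening: sequential inclusion/exclusion filters and flow counts.

Filters are applied in the flow-chart's narrative order so intermediate node
counts are directly comparable to the study's recruitment diagram:

1. remove capsules performed during the washout month between the two
   preparation periods;
2. restrict to the OGIB indication;
3. restrict to outpatients (hospitalisation predicts poor preparation);
4. split by preparation arm (study period);
5. remove records meeting any exclusion criterion (age < 18, CE
   contraindication, active bleeding, technical defect, endoscopic delivery,
   recent CE, gastric retention).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .synthetic import ARM_LABELS

EXCLUSION_FLAG_COLUMNS = (
    "technical_defect_flag",
    "endoscopic_delivery_flag",
    "recent_CE_flag",
    "gastric_retention_flag",
    "active_bleeding_flag",
    "contraindication_flag",
)

REQUIRED_COLUMNS = (
    "patient_id",
    "setting",
    "indication",
    "age",
    "washout_period_flag",
    "arm_label",
) + EXCLUSION_FLAG_COLUMNS

MIN_AGE_YEARS = 18


@dataclass(frozen=True)
class ScreeningFlow:
    """Node counts of the recruitment flow chart."""

    screened: int
    excluded_washout: int
    ogib: int
    inpatients_removed: int
    eligible_per_arm: dict
    excluded_criteria: int
    included_per_arm: dict

    @property
    def included_total(self) -> int:
        return sum(self.included_per_arm.values())

    def to_json_dict(self) -> dict:
        return asdict(self)


def _check_roster(roster: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in roster.columns]
    if missing_cols:
        raise ValueError(f"roster missing columns: {missing_cols}")
    flag_cols = ("washout_period_flag",) + EXCLUSION_FLAG_COLUMNS
    for col in list(flag_cols) + ["age", "setting", "indication", "arm_label"]:
        bad = roster[roster[col].isna()]
        if len(bad):
            pid = bad.iloc[0]["patient_id"]
            raise ValueError(f"record {pid}: missing value for {col!r}")


def meets_exclusion_criteria(roster: pd.DataFrame) -> pd.Series:
    """Boolean per record: any exclusion criterion (flags or age < 18)."""
    hit = roster["age"] < MIN_AGE_YEARS
    for col in EXCLUSION_FLAG_COLUMNS:
        hit = hit | roster[col].astype(bool)
    return hit


def apply_filters(roster: pd.DataFrame) -> tuple[ScreeningFlow, pd.DataFrame]:
    """Run the sequential screening filters over a roster.

    Returns the flow-chart node counts and the included (surviving) roster.
    """
    _check_roster(roster)
    screened = len(roster)

    after_washout = roster[~roster["washout_period_flag"].astype(bool)]
    excluded_washout = screened - len(after_washout)

    ogib = after_washout[after_washout["indication"] == "OGIB"]
    outpatients = ogib[ogib["setting"] == "outpatient"]
    inpatients_removed = len(ogib) - len(outpatients)

    eligible_per_arm = {
        arm: int((outpatients["arm_label"] == arm).sum()) for arm in ARM_LABELS
    }
    excluded_mask = meets_exclusion_criteria(outpatients)
    included = outpatients[~excluded_mask]
    included_per_arm = {
        arm: int((included["arm_label"] == arm).sum()) for arm in ARM_LABELS
    }
    flow = ScreeningFlow(
        screened=screened,
        excluded_washout=excluded_washout,
        ogib=len(ogib),
        inpatients_removed=inpatients_removed,
        eligible_per_arm=eligible_per_arm,
        excluded_criteria=int(excluded_mask.sum()),
        included_per_arm=included_per_arm,
    )
    return flow, included.reset_index(drop=True)
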