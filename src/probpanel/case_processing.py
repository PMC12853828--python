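"""Deterministic case verification, deduplication and panel validation.

Register-based recruitment allows a basic identity check of every respondent:
the sex at birth, birth year and birth month recorded in the register are
compared with the self-reported questionnaire values.  The rules are exact
matches with tolerances, applied per case in a fixed order:

* all three agree -> keep;
* a discrepancy in sex alone -> keep, correcting sex from the questionnaire;
  sex plus any other deviation -> exclude;
* any birth-year discrepancy -> exclude;
* a birth-month deviation of at most six months -> keep, correcting the month
  from the questionnaire; more than six -> exclude; if the register month is
  missing the tolerance widens to twelve months (i.e. any reported month is
  accepted and written back).

The same rule set is re-applied between the questionnaire and the fields
provided at panel registration.  Persons realised in more than one mode keep
exactly one record: highest completion first, then earliest completion date,
then web before paper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCLUSION_REASONS = {
    "year_mismatch", "month_out_of_tolerance", "multi_field_mismatch",
    "registration_mismatch",
}

_MODE_RANK = {"CAWI": 0, "PAPI": 1}


@dataclass
class MatchDecision:
    person_id: object
    action: str                       # keep | keep_corrected | exclude
    corrections: list[tuple[str, object, object]] = field(default_factory=list)
    reason: str | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.action == "keep_corrected" and not self.corrections:
            raise ValueError("keep_corrected requires corrections")
        if self.action == "exclude" and self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"invalid exclusion reason {self.reason!r}")


def _is_missing(v) -> bool:
    return v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v))


def match_case(register_row, self_report, exclude_reason_prefix: str | None = None) -> MatchDecision:
    """Verify one case against the register (or any reference record).

    ``register_row`` and ``self_report`` are mappings with keys ``sex``,
    ``birth_year`` and ``birth_month`` (the reference month may be missing).
    ``exclude_reason_prefix`` overrides the exclusion reason (used by the
    registration cross-check).
    """
    pid = register_row.get("person_id", self_report.get("person_id"))
    r_sex, q_sex = register_row["sex"], self_report["sex"]
    r_year, q_year = register_row["birth_year"], self_report["birth_year"]
    r_month, q_month = register_row["birth_month"], self_report["birth_month"]
    for v, name in ((r_year, "reference year"), (q_year, "reported year"), (q_sex, "reported sex")):
        if _is_missing(v):
            raise ValueError(f"malformed record: {name} missing")
    if not _is_missing(q_month) and not 1 <= int(q_month) <= 12:
        raise ValueError("malformed reported month")
    if not _is_missing(r_month) and not 1 <= int(r_month) <= 12:
        raise ValueError("malformed reference month")

    def _excl(reason):
        return MatchDecision(pid, "exclude",
                             reason=exclude_reason_prefix or reason)

    year_dev = int(q_year) != int(r_year)
    ref_month_missing = _is_missing(r_month)
    rep_month_missing = _is_missing(q_month)
    month_diff = 0
    if not ref_month_missing and not rep_month_missing:
        month_diff = abs(int(q_month) - int(r_month))
    # a month can only be observed to deviate when both values exist
    month_dev = month_diff != 0

    if q_sex != r_sex:
        if year_dev or month_dev:
            return _excl("multi_field_mismatch")
        return MatchDecision(pid, "keep_corrected",
                             corrections=[("sex", r_sex, q_sex)])
    if year_dev:
        return _excl("year_mismatch")
    if ref_month_missing and not rep_month_missing:
        # tolerance widens to twelve months: any reported month is accepted
        return MatchDecision(pid, "keep_corrected",
                             corrections=[("birth_month", None, int(q_month))])
    if month_dev:
        if month_diff <= 6:
            return MatchDecision(pid, "keep_corrected",
                                 corrections=[("birth_month", int(r_month), int(q_month))])
        return _excl("month_out_of_tolerance")
    if rep_month_missing:
        # no rule printed for a missing questionnaire month: keep, flagged
        return MatchDecision(pid, "keep", warning="reported month missing")
    return MatchDecision(pid, "keep")


def crosscheck_registration(self_report, registration_fields) -> MatchDecision:
    """Re-apply the matching rules between the questionnaire and the fields
    provided at panel registration; exclusions carry the reason
    ``registration_mismatch``."""
    return match_case(self_report, registration_fields,
                      exclude_reason_prefix="registration_mismatch")


def apply_matching(persons: pd.DataFrame) -> pd.DataFrame:
    """Run the register-vs-questionnaire check and the registration cross-check
    for every responder in a ledger frame; returns the per-case decisions log
    (person_id, stage, action, reason)."""
    rows = []
    resp = persons[persons["responded"]]
    for r in resp.itertuples(index=False):
        d = match_case(
            {"person_id": r.person_id, "sex": r.sex, "birth_year": r.birth_year,
             "birth_month": r.birth_month},
            {"sex": r.self_sex, "birth_year": r.self_birth_year,
             "birth_month": r.self_birth_month},
        )
        rows.append({"person_id": r.person_id, "stage": "register",
                     "action": d.action, "reason": d.reason})
        if d.action != "exclude" and not _is_missing(getattr(r, "reg_birth_year", None)):
            d2 = crosscheck_registration(
                {"person_id": r.person_id, "sex": r.self_sex,
                 "birth_year": r.self_birth_year, "birth_month": r.self_birth_month},
                {"sex": r.reg_sex, "birth_year": r.reg_birth_year,
                 "birth_month": r.reg_birth_month},
            )
            rows.append({"person_id": r.person_id, "stage": "registration",
                         "action": d2.action, "reason": d2.reason})
    return pd.DataFrame(rows, columns=["person_id", "stage", "action", "reason"])


def resolve_double(records: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Resolve one person's multiple interview records to a single retained one.

    Ordering: completion fraction descending, then completion date ascending,
    then CAWI before PAPI.  Deterministic and idempotent.
    """
    if len(records) == 0:
        raise ValueError("no records")
    ranked = records.assign(_m=records["mode"].map(_MODE_RANK)).sort_values(
        ["completion_fraction", "completion_date", "_m"],
        ascending=[False, True, True], kind="stable",
    ).drop(columns="_m")
    return ranked.iloc[0], ranked.iloc[1:]


def resolve_all_doubles(interviews: pd.DataFrame) -> pd.DataFrame:
    """Vectorised resolution over a full interview table: adds a boolean
    ``retained`` column marking exactly one record per person."""
    ranked = interviews.assign(_m=interviews["mode"].map(_MODE_RANK)).sort_values(
        ["person_id", "completion_fraction", "completion_date", "_m"],
        ascending=[True, False, True, True], kind="stable",
    )
    retained_ids = ranked.groupby("person_id", sort=False).head(1)["record_id"]
    out = interviews.copy()
    out["retained"] = out["record_id"].isin(set(retained_ids))
    return out


def finalize_panel(persons: pd.DataFrame, interviews: pd.DataFrame,
                   decisions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the validated panelist roster.

    A person becomes an active panelist iff they consented to recontact, were
    not excluded by case matching, and -- when their retained (deployment)
    mode is the web mode -- completed the double-opt-in e-mail confirmation.
    Paper registrations are confirmed by the returned consent form.  The
    deployment mode is the mode of the retained interview record and is
    immutable for later panel waves.
    """
    resolved = resolve_all_doubles(interviews)
    deploy = resolved[resolved["retained"]].set_index("person_id")["mode"]
    out = persons.copy()
    out["deployment_mode"] = out["person_id"].map(deploy)
    excluded = set()
    if decisions is not None and len(decisions):
        excluded = set(decisions.loc[decisions["action"] == "exclude", "person_id"])
    out["excluded"] = out["person_id"].isin(excluded)
    out["validated"] = (
        out["consented"]
        & ~out["excluded"]
        & ((out["deployment_mode"] != "CAWI") | out["confirmed"])
    )
    return out


def compute_bmi(weight_kg: float, height_m: float) -> tuple[float, str]:
    """Body-mass index and its category (cut-points left-closed at 18.5/25/30)."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / height_m ** 2
    if bmi < 18.5:
        cat = "underweight"
    elif bmi < 25:
        cat = "normal"
    elif bmi < 30:
        cat = "overweight"
    else:
        cat = "obesity"
    return bmi, cat
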