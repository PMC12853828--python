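"""AAPOR-adapted outcome rates for register-based panel recruitment.

Rates follow the AAPOR standard definitions adapted to the German
register-frame context.  With I complete interviews, P partial interviews
(consent given and at least the first two items completed), R refusals, NC
noncontacts, O other non-interviews and U cases of unknown eligibility:

* RR1 (minimum response rate) = I / (I + P + R + NC + O + U)
* RR2 = (I + P) / same denominator
* web rate = online interviews / all interviews (after double-realization
  resolution)
* panel consent rate = recontact consenters / (I + P) -- including web
  consenters who never completed the double opt-in
* RECR (recruitment rate) = validated (double-opt-in confirmed) panelists /
  RR1 denominator.

Ineligible cases (business/moved/deceased addresses) are removed from both
numerator and denominator during gross-sample cleaning, so the denominator is
the cleaned gross sample.  Rates are reported in percent to one decimal,
half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .germany import BIK4_LABELS


@dataclass(frozen=True)
class OutcomeCounts:
    complete: int = 0
    partial: int = 0
    refusal: int = 0
    noncontact: int = 0
    other: int = 0
    unknown_eligibility: int = 0
    ineligible: int = 0

    @property
    def denominator(self) -> int:
        return (self.complete + self.partial + self.refusal + self.noncontact
                + self.other + self.unknown_eligibility)


@dataclass
class OutcomeRateReport:
    rr1: float
    rr2: float
    web_rate: float
    panel_consent_rate: float
    recr: float
    counts: dict

    def to_dict(self) -> dict:
        return asdict(self)


def round1(x: float) -> float:
    """Round to one decimal, half-up (matching printed survey tables)."""
    return float(np.floor(x * 10 + 0.5) / 10)


def counts_from_ledger(persons: pd.DataFrame) -> OutcomeCounts:
    c = persons["final_code"].value_counts()
    return OutcomeCounts(
        complete=int(c.get("complete", 0)),
        partial=int(c.get("partial", 0)),
        refusal=int(c.get("refusal", 0)),
        noncontact=int(c.get("noncontact", 0)),
        other=int(c.get("other_noninterview", 0)),
        unknown_eligibility=int(c.get("unknown_eligibility", 0)),
        ineligible=int(c.get("ineligible", 0)),
    )


def _check_denominator(counts: OutcomeCounts) -> int:
    d = counts.denominator
    if d <= 0:
        raise ZeroDivisionError("empty rate denominator")
    return d


def rr1(counts: OutcomeCounts) -> float:
    """AAPOR response rate 1: completes over interviews plus non-interviews
    plus unknown-eligibility cases, in percent."""
    return 100.0 * counts.complete / _check_denominator(counts)


def rr2(counts: OutcomeCounts) -> float:
    """AAPOR response rate 2: completes plus partials over the RR1 denominator."""
    return 100.0 * (counts.complete + counts.partial) / _check_denominator(counts)


def web_rate(interviews: pd.DataFrame) -> float:
    """Share of interviews realised online among all retained interviews."""
    if "retained" in interviews:
        interviews = interviews[interviews["retained"]]
    n = len(interviews)
    if n == 0:
        raise ZeroDivisionError("no interviews")
    return 100.0 * float((interviews["mode"] == "CAWI").sum()) / n


def panel_consent_rate(persons: pd.DataFrame) -> float:
    """Share of (complete or partial) respondents consenting to recontact."""
    resp = persons[persons["final_code"].isin(["complete", "partial"])]
    if len(resp) == 0:
        raise ZeroDivisionError("no respondents")
    return 100.0 * float(resp["consented"].sum()) / len(resp)


def recr(n_validated: int, counts: OutcomeCounts) -> float:
    """Recruitment rate: validated panelists over the RR1 denominator."""
    return 100.0 * n_validated / _check_denominator(counts)


def report(persons: pd.DataFrame, interviews: pd.DataFrame) -> OutcomeRateReport:
    """Full outcome-rate report from a disposition ledger with a ``validated``
    column (see case_processing.finalize_panel)."""
    counts = counts_from_ledger(persons)
    n_valid = int(persons["validated"].sum())
    return OutcomeRateReport(
        rr1=round1(rr1(counts)),
        rr2=round1(rr2(counts)),
        web_rate=round1(web_rate(interviews)),
        panel_consent_rate=round1(panel_consent_rate(persons)),
        recr=round1(recr(n_valid, counts)),
        counts={**asdict(counts), "gross": counts.denominator,
                "consenters": int(persons["consented"].sum()),
                "validated": n_valid},
    )


_KEY_COLUMNS = {
    "age_group": "age_group7",
    "sex": "sex",
    "bik": "bik_class_4",
    "region": "region",
}


def subgroup_table(persons: pd.DataFrame, keys: list[str], by_sex: bool = True) -> pd.DataFrame:
    """RR1 and RECR by subgroup, each cell with its own denominator.

    ``keys`` may contain ``age_group``, ``sex``, ``bik`` and ``region``;
    with ``by_sex`` every key is additionally crossed with sex, mirroring the
    usual Men/Women/Total table layout.
    """
    rows = []

    def _cell(label_key, label_value, sub):
        c = counts_from_ledger(sub)
        if c.denominator == 0:
            return
        n_valid = int(sub["validated"].sum()) if "validated" in sub else 0
        rows.append({
            "characteristic": label_key,
            "level": label_value,
            "sex": "total",
            "n_respondents": c.complete,
            "rr1": round1(rr1(c)),
            "n_validated": n_valid,
            "recr": round1(recr(n_valid, c)),
        })
        if by_sex and label_key != "sex":
            for s, ssub in sub.groupby("sex"):
                cs = counts_from_ledger(ssub)
                if cs.denominator == 0:
                    continue
                nv = int(ssub["validated"].sum()) if "validated" in ssub else 0
                rows.append({
                    "characteristic": label_key,
                    "level": label_value,
                    "sex": s,
                    "n_respondents": cs.complete,
                    "rr1": round1(rr1(cs)),
                    "n_validated": nv,
                    "recr": round1(recr(nv, cs)),
                })

    _cell("total", "total", persons)
    for key in keys:
        col = _KEY_COLUMNS[key]
        for val, sub in persons.groupby(col):
            label = BIK4_LABELS.get(val, val) if key == "bik" else val
            _cell(key, label, sub)
    return pd.DataFrame(rows)
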