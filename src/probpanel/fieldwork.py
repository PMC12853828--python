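"""Age-differentiated mixed-mode fieldwork simulation.

Invited persons under 70 enter a sequential (push-to-web) arm: the invitation
and first reminder offer only the web questionnaire, the second reminder adds
a paper questionnaire.  Persons aged 70+ enter a simultaneous arm with both
modes offered from the invitation on.  At every contact event the not-yet
responders respond with a per-event hazard derived from their overall latent
participation propensity P (constant hazard q = 1 - (1-P)^(1/W) over the W
events, so a propensity of one responds at the invitation); the mode is drawn
among the offered modes by an age-dependent paper preference.  Paper returns
lag by a log-normal delay and are discarded after the field-end horizon.
A disposition ledger with AAPOR-style final codes is produced; a separate
overlay injects double realizations (the same person realised in more than
one mode/copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .register_synthesis import GroundTruthModel

#: precedence of final disposition codes (highest first)
CODE_PRECEDENCE = [
    "complete", "partial", "refusal", "other_noninterview",
    "unknown_eligibility", "ineligible", "noncontact",
]


@dataclass
class ContactProtocol:
    """Contact schedule and mode offers of the recruitment fieldwork."""

    schedule: tuple[int, int, int] = (0, 14, 28)      # invitation, reminder 1, reminder 2
    batch_starts: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 57, 2: 72})
    age_threshold_simultaneous: int = 70
    horizon_day: int = 142                             # field end; later paper returns dropped
    papi_delay_median_days: float = 10.0
    papi_delay_sigma: float = 0.5
    cawi_delay_max_days: float = 3.0
    # incentive structure carried as metadata only
    incentives: dict[str, str] = field(default_factory=lambda: {
        "unconditional": "EUR 5 cash with invitation",
        "conditional": "EUR 10 cash upon registration",
    })

    def offered_modes(self, arm: str, event: int) -> tuple[str, ...]:
        if arm == "simultaneous":
            return ("CAWI", "PAPI")
        if arm == "sequential":
            return ("CAWI",) if event < 2 else ("CAWI", "PAPI")
        raise ValueError(f"unknown design arm {arm!r}")


@dataclass
class DispositionLedger:
    """Per-invited-person outcomes plus the realised interview records."""

    persons: pd.DataFrame
    interviews: pd.DataFrame

    def counts(self) -> dict[str, int]:
        return self.persons["final_code"].value_counts().to_dict()


def assign_disposition(history: list[str]) -> str:
    """Collapse a person's contact history to one final code by precedence
    (complete > partial > refusal > other > unknown eligibility > ineligible >
    noncontact)."""
    if not history:
        raise ValueError("empty contact history")
    unknown = set(history) - set(CODE_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown codes {sorted(unknown)}")
    for code in CODE_PRECEDENCE:
        if code in history:
            return code
    raise AssertionError("unreachable")


def _report_with_errors(
    df: pd.DataFrame, truth: GroundTruthModel, rng: np.random.Generator, prefix: str
) -> pd.DataFrame:
    """Copy official sex/birthdate into self-reported fields with small error
    rates, to exercise the downstream case-matching rules."""
    n = len(df)
    err = truth.reporting_error_rates
    sex = df["sex"].to_numpy().copy()
    flip = rng.random(n) < err["sex"]
    sex[flip] = np.where(sex[flip] == "male", "female", "male")
    year = df["birth_year"].to_numpy().copy()
    ymask = rng.random(n) < err["year"]
    year[ymask] += rng.choice([-1, 1], size=int(ymask.sum()))
    true_month = df["birth_month"].fillna(7).to_numpy(dtype=np.int64)
    month = true_month.copy()
    mmask = rng.random(n) < err["month"]
    offsets = rng.integers(1, 12, size=int(mmask.sum()))
    month[mmask] = (month[mmask] - 1 + offsets) % 12 + 1
    out = df.copy()
    out[f"{prefix}_sex"] = sex
    out[f"{prefix}_birth_year"] = year
    out[f"{prefix}_birth_month"] = month
    return out


def run_field(
    gross: pd.DataFrame,
    register: pd.DataFrame,
    truth: GroundTruthModel,
    protocol: ContactProtocol,
    seed: int,
) -> DispositionLedger:
    """Simulate the field phase for the cleaned, invited gross sample."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    inv = gross[gross["invited"]].merge(
        register.drop(columns=["duplicate_of", "address_status"], errors="ignore"),
        on="person_id", how="left", validate="many_to_one",
    )
    missing = inv["age"].isna()
    if missing.any():
        raise ValueError("gross records reference persons missing from the register")
    n = len(inv)
    age = inv["age"].to_numpy()
    arm = np.where(age >= protocol.age_threshold_simultaneous, "simultaneous", "sequential")
    inv["arm"] = arm

    p_overall = inv["response_propensity"].to_numpy(dtype=float)
    n_events = len(protocol.schedule)
    hazard = 1.0 - (1.0 - p_overall) ** (1.0 / n_events)
    # propensity exactly one responds at the invitation
    hazard[p_overall >= 1.0] = 1.0

    responded = np.zeros(n, dtype=bool)
    wave = np.full(n, -1, dtype=np.int64)
    for w in range(n_events):
        hits = (~responded) & (rng.random(n) < hazard)
        wave[hits] = w
        responded |= hits

    mode = np.full(n, "", dtype=object)
    for w in range(n_events):
        for a in ("sequential", "simultaneous"):
            m = responded & (wave == w) & (arm == a)
            if not m.any():
                continue
            offered = protocol.offered_modes(a, w)
            if len(offered) == 1:
                mode[m] = offered[0]
            else:
                pref = (truth.papi_pref_simultaneous if a == "simultaneous"
                        else truth.papi_pref_sequential_wave3)
                mode[m] = np.where(rng.random(int(m.sum())) < pref, "PAPI", "CAWI")

    batch_start = inv["batch"].map(protocol.batch_starts).to_numpy(dtype=float)
    event_day = batch_start + np.array(protocol.schedule)[np.clip(wave, 0, None)]
    delay = np.where(
        mode == "PAPI",
        rng.lognormal(np.log(protocol.papi_delay_median_days), protocol.papi_delay_sigma, n),
        rng.uniform(0, protocol.cawi_delay_max_days, n),
    )
    completion_day = event_day + delay
    late = responded & (mode == "PAPI") & (completion_day > protocol.horizon_day)
    responded &= ~late       # paper returns after field end were never recorded
    inv["late_paper_return"] = late

    partial = responded & (rng.random(n) < truth.partial_rate)
    frac = np.where(responded, 1.0, np.nan)
    frac[partial] = rng.uniform(0.1, 0.9, int(partial.sum()))
    consent = responded & (rng.random(n) < inv["consent_propensity"].to_numpy(dtype=float))
    confirmed = consent & (
        (mode == "PAPI") | (rng.random(n) < inv["confirm_propensity"].to_numpy(dtype=float))
    )

    # final codes: responders complete/partial, the rest split into undeliverable
    # letters (unknown eligibility) and refusal/noncontact
    split = truth.nonresponse_split
    code = np.full(n, "", dtype=object)
    code[responded & ~partial] = "complete"
    code[partial] = "partial"
    nr = ~responded
    u = rng.random(n)
    code[nr & (u < split["unknown_eligibility"])] = "unknown_eligibility"
    rest = nr & (u >= split["unknown_eligibility"])
    r_share = split["refusal"] / (split["refusal"] + split["noncontact"])
    code[rest & (rng.random(n) < r_share)] = "refusal"
    code[rest & (code == "")] = "noncontact"

    inv["responded"] = responded
    inv["response_wave"] = np.where(responded, wave, -1)
    inv["mode"] = np.where(responded, mode, None)
    inv["completion_fraction"] = frac
    inv["completion_date"] = np.where(responded, completion_day, np.nan)
    inv["consented"] = consent
    inv["confirmed"] = confirmed
    inv["final_code"] = code
    inv = _report_with_errors(inv, truth, rng, prefix="self")
    resp = inv[inv["responded"]]
    interviews = pd.DataFrame({
        "person_id": resp["person_id"].to_numpy(),
        "mode": resp["mode"].to_numpy(),
        "completion_fraction": resp["completion_fraction"].to_numpy(),
        "completion_date": resp["completion_date"].to_numpy(),
        "record_id": [f"r{i:07d}" for i in range(len(resp))],
    })
    return DispositionLedger(persons=inv, interviews=interviews)


def simulate_double_realizations(
    ledger: DispositionLedger,
    truth: GroundTruthModel,
    seed: int,
) -> DispositionLedger:
    """Inject double realizations: a configurable share of responders holds
    more than one interview record, with the configured mix of web+paper,
    paper+paper and web+two-paper overlaps (paper copies arrive late because
    postal returns are slower)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    persons = ledger.persons
    resp = persons[persons["responded"]]
    n_overlap = int(round(truth.double_realization_rate * len(resp)))
    if n_overlap == 0:
        return ledger
    mix = truth.double_realization_mix
    types = list(mix)
    counts = np.round(np.array([mix[t] for t in types]) * n_overlap).astype(int)
    counts[0] = n_overlap - counts[1:].sum()

    cawi_pool = resp[resp["mode"] == "CAWI"]["person_id"].to_numpy()
    papi_pool = resp[resp["mode"] == "PAPI"]["person_id"].to_numpy()
    rng.shuffle(cawi_pool)
    rng.shuffle(papi_pool)
    any_pool = np.concatenate([cawi_pool, papi_pool])

    extra_rows = []
    used: set = set()
    ci = pi = ai = 0
    base = ledger.interviews.set_index("person_id")

    def _extra(pid, new_mode, k):
        row = base.loc[pid]
        lag = rng.lognormal(np.log(7.0), 0.4)
        frac = 1.0 if rng.random() < 0.7 else float(rng.uniform(0.3, 0.95))
        return {
            "person_id": pid,
            "mode": new_mode,
            "completion_fraction": frac,
            "completion_date": float(row["completion_date"]) + lag,
            "record_id": f"d{len(extra_rows) + k:07d}",
        }

    for t, cnt in zip(types, counts):
        for _ in range(int(cnt)):
            if t == "papi_papi":
                while pi < len(papi_pool) and papi_pool[pi] in used:
                    pi += 1
                if pi >= len(papi_pool):
                    continue
                pid = papi_pool[pi]; pi += 1
                used.add(pid)
                extra_rows.append(_extra(pid, "PAPI", 0))
            elif t == "cawi_2papi":
                while ci < len(cawi_pool) and cawi_pool[ci] in used:
                    ci += 1
                if ci >= len(cawi_pool):
                    continue
                pid = cawi_pool[ci]; ci += 1
                used.add(pid)
                extra_rows.append(_extra(pid, "PAPI", 0))
                extra_rows.append(_extra(pid, "PAPI", 1))
            else:  # cawi_papi: one record in each mode
                while ai < len(any_pool) and any_pool[ai] in used:
                    ai += 1
                if ai >= len(any_pool):
                    continue
                pid = any_pool[ai]; ai += 1
                used.add(pid)
                cur_mode = base.loc[pid, "mode"]
                other = "PAPI" if cur_mode == "CAWI" else "CAWI"
                extra_rows.append(_extra(pid, other, 0))

    interviews = pd.concat(
        [ledger.interviews, pd.DataFrame(extra_rows)], ignore_index=True
    )
    return DispositionLedger(persons=persons, interviews=interviews)
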