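"""Synthetic municipality frame, population register and ground-truth model.

Everything downstream of the sampling frame -- allocation, address draws,
fieldwork, outcome rates, selection models -- is exercised against data from
this module, so no restricted register extract is ever needed.  The generator
emulates a national residents' register: municipalities nested in districts
and federal states with BIK size classes and an age-structured 16+
population; persons with official demographics (sex at birth, birthdate,
citizenship), address-quality defects (business/moved/deceased/duplicate),
Casmin education, household type, and the health items of the recruitment
questionnaire.

The :class:`GroundTruthModel` holds logistic coefficient sets for (i)
participation in the recruitment survey and (ii) panel consent given
participation, plus mode preferences, the double-opt-in confirmation
probability and nuisance rates.  :func:`default_truth` derives its
coefficients in closed form from age-by-sex anchor rates that encode the
participation and registration gradients of German register-based mixed-mode
surveys: women above men, a U-shaped age profile with the youngest group
highest and 20-29 lowest, a reversal of the sex gap above age 70, an
education gradient and a strong citizenship barrier at registration, and
higher registration for people reporting chronic conditions but lower for
poor self-rated health.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import germany
from .germany import (
    BIK4_FROM_BIK10,
    DRAW_AGE_BOUNDS,
    DRAW_AGE_GROUPS,
    RATE_AGE_GROUPS,
    REGION_OF_STATE,
    STATE_CODE,
)
from .sampling_design import allocate_psus, cox_round

REFERENCE_YEAR = 2024


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# frame configuration and generation
# ---------------------------------------------------------------------------

#: Default 16+ age-group shares over the eight draw age groups.  The 65-79
#: group is sampled 40/60 between ages 65-69 and 70-79 so that the six
#: analysis groups reproduce the official margins (16.1% aged 60-69, 19.0%
#: aged 70+).
DEFAULT_DRAW_AGE_SHARES: dict[str, float] = {
    "16-29": 0.178,
    "30-39": 0.155,
    "40-49": 0.144,
    "50-59": 0.172,
    "60-64": 0.0805,
    "65-79": 0.2005,
    "80-84": 0.040,
    "85+": 0.030,
}

#: Weight of ages 65-69 within the 65-79 draw group
_P_65_69_WITHIN_65_79 = 0.40

#: National population share by collapsed BIK class (official margins)
DEFAULT_BIK4_POP_SHARES: dict[int, float] = {1: 0.108, 2: 0.346, 3: 0.268, 4: 0.278}

#: Municipality-count mixture by collapsed BIK class: more numerous, smaller
#: municipalities in the small classes, a handful of big cities.  At the
#: default 1/50 scale this keeps small-class municipalities large enough
#: (hundreds of residents) that a 600-address draw is feasible after merging
#: one or two neighbours into a synthetic sample point.
DEFAULT_BIK4_MUNI_SHARES: dict[int, float] = {1: 0.30, 2: 0.34, 3: 0.24, 4: 0.12}


@dataclass
class FrameConfig:
    """Configuration of the synthetic national frame.

    Defaults describe a ~1/50-scale nation (200 municipalities, 350,000
    residents aged 16+) so that a full pipeline run takes seconds while
    keeping realistic stratum structure.
    """

    schema_version: int = 1
    n_municipalities: int = 200
    total_pop_16plus: int = 350_000
    state_shares: dict[str, float] = field(
        default_factory=germany.normalized_state_shares
    )
    draw_age_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRAW_AGE_SHARES)
    )
    bik4_pop_shares: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BIK4_POP_SHARES)
    )
    bik4_muni_shares: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BIK4_MUNI_SHARES)
    )
    municipalities_per_district: int = 4

    def validate(self) -> None:
        for name, shares in (
            ("state_shares", self.state_shares),
            ("draw_age_shares", self.draw_age_shares),
            ("bik4_pop_shares", self.bik4_pop_shares),
        ):
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1 (got {total:.6f})")
            if any(v < 0 for v in shares.values()):
                raise ConfigError(f"{name} has negative entries")
        if self.n_municipalities < len(self.state_shares):
            raise ConfigError("need at least one municipality per state")


_BIK10_OF_BIK4 = {b4: [b10 for b10, v in BIK4_FROM_BIK10.items() if v == b4] for b4 in (1, 2, 3, 4)}


def generate_frame(config: FrameConfig, seed: int) -> pd.DataFrame:
    """Generate the municipality frame.

    State 16+ totals are fixed by controlled rounding of the configured
    shares, so realised state population shares match the margins exactly up
    to integer rounding.  Within a state, municipalities are spread over BIK
    classes; municipality sizes are log-normal within class; district keys
    group neighbouring municipalities of similar class.  Deterministic for a
    fixed (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    states = list(config.state_shares)

    muni_plan = allocate_psus(config.state_shares, config.n_municipalities, minimum=1)
    state_pops = cox_round(
        [config.total_pop_16plus * config.state_shares[s] for s in states],
        config.total_pop_16plus,
    )

    rows = []
    for state, state_pop in zip(states, state_pops):
        n_muni = muni_plan.psus_per_state[state]
        # municipalities per BIK4 class: largest-remainder counts, but every
        # class keeps at least one municipality whenever the state is large
        # enough, so its big-city population is not folded into small classes
        muni_counts = cox_round(
            [n_muni * config.bik4_muni_shares[b] for b in (1, 2, 3, 4)], n_muni
        )
        if n_muni >= 4:
            while (muni_counts == 0).any():
                muni_counts[np.argmax(muni_counts)] -= 1
                muni_counts[np.argmin(muni_counts)] += 1
        pop_shares = np.array([config.bik4_pop_shares[b] for b in (1, 2, 3, 4)])
        # a class that still has no municipality donates its population
        # proportionally to the classes that do
        have = muni_counts > 0
        pop_shares = np.where(have, pop_shares, 0.0)
        pop_shares = pop_shares / pop_shares.sum()
        class_pops = cox_round(state_pop * pop_shares, int(state_pop))
        for b4, n_c, pop_c in zip((1, 2, 3, 4), muni_counts, class_pops):
            if n_c == 0:
                continue
            w = rng.lognormal(mean=0.0, sigma=0.35, size=n_c)
            sizes = np.sort(cox_round(pop_c * w / w.sum(), int(pop_c)))
            # BIK-10 subclass by size tercile within the collapsed class, so
            # similarly sized neighbours share the full classification
            subclasses = _BIK10_OF_BIK4[b4]
            for j, sz in enumerate(sizes):
                sub10 = subclasses[min(len(subclasses) - 1, j * len(subclasses) // n_c)]
                rows.append({
                    "state": state,
                    "bik_class_4": b4,
                    "bik_class_10": int(sub10),
                    "pop_16plus": int(sz),
                })
    frame = pd.DataFrame(rows)

    # district keys: municipalities of similar class within a state share a
    # district (sorted by class and size, then chunked)
    frame = frame.sort_values(
        ["state", "bik_class_4", "pop_16plus"], kind="stable"
    ).reset_index(drop=True)
    ids, district_keys = [], []
    for state, grp in frame.groupby("state", sort=False):
        code = STATE_CODE[state]
        for i, (row_i, _) in enumerate(grp.iterrows()):
            district = i // config.municipalities_per_district
            district_key = f"{code:02d}{district:04d}"
            district_keys.append((row_i, district_key))
            ids.append((row_i, f"{district_key}{i % config.municipalities_per_district:02d}"))
    frame["district_key"] = pd.Series(dict(district_keys))
    frame["municipality_id"] = pd.Series(dict(ids))

    # age structure: multinomial split of each municipality's population
    shares = np.array([config.draw_age_shares[g] for g in DRAW_AGE_GROUPS])
    counts = rng.multinomial(frame["pop_16plus"].to_numpy(), shares)
    for j, g in enumerate(DRAW_AGE_GROUPS):
        frame[f"pop_{g}"] = counts[:, j]
    frame["pop_16plus"] = counts.sum(axis=1)

    cols = ["municipality_id", "district_key", "state", "bik_class_10", "bik_class_4",
            "pop_16plus"] + [f"pop_{g}" for g in DRAW_AGE_GROUPS]
    return frame[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# ground-truth model
# ---------------------------------------------------------------------------

#: P(complete interview) anchors by rate age group, (male, female).
#: These encode the default participation gradients: youngest group highest,
#: 20-29 lowest, women above men except above age 70 where the gap reverses.
PARTICIPATION_ANCHORS: dict[str, tuple[float, float]] = {
    "16-19": (0.399, 0.488),
    "20-29": (0.305, 0.395),
    "30-39": (0.324, 0.392),
    "40-49": (0.316, 0.398),
    "50-59": (0.346, 0.412),
    "60-69": (0.398, 0.408),
    "70+": (0.429, 0.350),
}

#: P(validated panelist | complete interview) anchors, (male, female):
#: highest for the young, a pronounced drop for women aged 70+.
REGISTRATION_ANCHORS: dict[str, tuple[float, float]] = {
    "16-19": (0.7458, 0.8014),
    "20-29": (0.7848, 0.8308),
    "30-39": (0.7995, 0.8237),
    "40-49": (0.7788, 0.7947),
    "50-59": (0.7692, 0.7888),
    "60-69": (0.7655, 0.7631),
    "70+": (0.7039, 0.6586),
}

#: Share of sequential-arm (under 70) completes realised online, and share of
#: simultaneous-arm (70+) completes realised on paper, under the default
#: age-differentiated design.
SEQUENTIAL_CAWI_SHARE = 0.884
SIMULTANEOUS_PAPI_SHARE = 0.767

#: Reference covariate margins used to centre the coefficient sets so that the
#: anchors above are hit marginally over region, BIK and the extended
#: covariates.  Age shares refer to the invited (draw-design-weighted) sample.
REF_INVITED_AGE_SHARES6: dict[str, float] = {
    "16-29": 0.185, "30-39": 0.152, "40-49": 0.121,
    "50-59": 0.169, "60-69": 0.154, "70+": 0.219,
}

#: Default marginal item distributions of the recruitment questionnaire.
#: These are stand-ins: their only contract is matching the item domains and
#: giving the registration model realistic covariate variation.
DEFAULT_ITEM_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "education": {"low": 0.336, "medium": 0.463, "high": 0.201},
    "srh": {"very good": 0.18, "good": 0.45, "fair": 0.29, "bad": 0.06, "very bad": 0.02},
    "srmh": {"excellent": 0.12, "very good": 0.28, "good": 0.35, "fair": 0.19, "poor": 0.06},
    "attention": {"not at all": 0.03, "less strong": 0.12, "moderate": 0.35,
                  "strong": 0.38, "very strong": 0.12},
    "bmi_category": {"underweight": 0.03, "normal": 0.44, "overweight": 0.33, "obesity": 0.20},
    "smoking": {"non-smoker": 0.70, "occasional": 0.10, "daily": 0.20},
    "sport": {"none": 0.30, "<1h": 0.20, "1-2h": 0.20, "2-4h": 0.18, "4h+": 0.12},
    "climate_band": {"1-3": 0.30, "4-7": 0.45, "8-10": 0.25},
    "satisfaction_band": {"1-3": 0.05, "4-7": 0.45, "8-10": 0.50},
    "red_meat": {"daily": 0.05, "4-6/week": 0.10, "1-3/week": 0.45,
                 "<1/week": 0.30, "never": 0.10},
    "sausage": {"daily": 0.08, "4-6/week": 0.14, "1-3/week": 0.43,
                "<1/week": 0.25, "never": 0.10},
    "waited_for_appointment": {"yes": 0.55, "no": 0.45},
}

#: P(chronic condition) by analysis age group
DEFAULT_CHRONIC_BY_AGE: dict[str, float] = {
    "16-29": 0.15, "30-39": 0.15, "40-49": 0.35,
    "50-59": 0.35, "60-69": 0.50, "70+": 0.60,
}


@dataclass
class GroundTruthModel:
    """Coefficients and rates fully determining propensities given a register row.

    ``participation`` and ``consent`` are log-odds coefficient sets applied by
    the inverse-logit link; every field defaults to zero effects so partial
    models are easy to construct in tests.
    """

    participation: dict = field(default_factory=dict)
    consent: dict = field(default_factory=dict)
    confirm_cawi: float = 0.9483
    partial_rate: float = 0.003
    papi_pref_sequential_wave3: float = 0.41
    papi_pref_simultaneous: float = SIMULTANEOUS_PAPI_SHARE
    double_realization_rate: float = 0.0436
    double_realization_mix: dict[str, float] = field(
        default_factory=lambda: {"cawi_papi": 0.860, "papi_papi": 0.134, "cawi_2papi": 0.006}
    )
    address_defect_rates: dict[str, float] = field(
        default_factory=lambda: {"business": 0.025, "moved": 0.045, "deceased": 0.011}
    )
    duplicate_rate: float = 0.005
    birth_month_missing_rate: float = 0.02
    reporting_error_rates: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.002, "month": 0.004, "year": 0.001,
                                 "registration": 0.002}
    )
    nonresponse_split: dict[str, float] = field(
        default_factory=lambda: {"unknown_eligibility": 0.03, "refusal": 0.30,
                                 "noncontact": 0.70}
    )
    female_share: float = 0.51
    german_share: float = 0.85
    single_household_share: float = 0.249
    item_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ITEM_DISTRIBUTIONS.items()}
    )
    chronic_by_age: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHRONIC_BY_AGE)
    )
    expected_recr_by_age: dict[str, float] = field(
        default_factory=lambda: {"16-29": 0.17, "30-39": 0.18, "40-49": 0.21,
                                 "50-59": 0.18, "60-64": 0.20, "65-79": 0.17,
                                 "80-84": 0.14, "85+": 0.12}
    )

    # -- linear predictors ---------------------------------------------------

    @staticmethod
    def _coef(coefs: dict, key: str, default=0.0):
        return coefs.get(key, default)

    def participation_logit(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor of recruitment-survey participation on the gross-
        frame covariates (age group, sex, region, BIK class, sex x 70+)."""
        c = self.participation
        eta = np.full(len(df), float(c.get("intercept", 0.0)))
        age = c.get("age", {})
        eta += df["age_group7"].map(lambda g: age.get(g, 0.0)).to_numpy(dtype=float)
        female = (df["sex"] == "female").to_numpy()
        eta += c.get("female", 0.0) * female
        eta += c.get("female_70plus", 0.0) * (female & (df["age_group7"] == "70+").to_numpy())
        reg = c.get("region", {})
        eta += df["region"].map(lambda r: reg.get(r, 0.0)).to_numpy(dtype=float)
        bik = c.get("bik4", {})
        eta += df["bik_class_4"].map(lambda b: bik.get(int(b), 0.0)).to_numpy(dtype=float)
        return eta

    def consent_logit(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor of panel consent given participation, on the
        extended covariate set of the recruitment questionnaire."""
        c = self.consent
        eta = np.full(len(df), float(c.get("intercept", 0.0)))
        age = c.get("age", {})
        eta += df["age_group7"].map(lambda g: age.get(g, 0.0)).to_numpy(dtype=float)
        female = (df["sex"] == "female").to_numpy()
        eta += c.get("female", 0.0) * female
        eta += c.get("female_70plus", 0.0) * (female & (df["age_group7"] == "70+").to_numpy())
        reg = c.get("region", {})
        eta += df["region"].map(lambda r: reg.get(r, 0.0)).to_numpy(dtype=float)
        edu = c.get("education", {})
        eta += df["education"].map(lambda e: edu.get(e, 0.0)).to_numpy(dtype=float)
        eta += c.get("non_german", 0.0) * (~df["citizenship_german"].to_numpy(dtype=bool))
        eta += c.get("chronic", 0.0) * df["chronic_disease"].to_numpy(dtype=bool)
        eta += c.get("srh_bad", 0.0) * df["srh"].isin(["bad", "very bad"]).to_numpy()
        eta += c.get("bmi_obesity", 0.0) * (df["bmi_category"] == "obesity").to_numpy()
        eta += c.get("smoking_occasional", 0.0) * (df["smoking"] == "occasional").to_numpy()
        sport = c.get("sport", {})
        eta += df["sport"].map(lambda s: sport.get(s, 0.0)).to_numpy(dtype=float)
        climate = c.get("climate", {})
        eta += df["climate_band"].map(lambda s: climate.get(s, 0.0)).to_numpy(dtype=float)
        eta += c.get("waited", 0.0) * (df["waited_for_appointment"] == "yes").to_numpy()
        eta += c.get("red_meat_daily", 0.0) * (df["red_meat"] == "daily").to_numpy()
        eta += c.get("household_multi", 0.0) * (~df["household_single"].to_numpy(dtype=bool))
        return eta

    def participation_propensity(self, df: pd.DataFrame) -> np.ndarray:
        return _inv_logit(self.participation_logit(df))

    def consent_propensity(self, df: pd.DataFrame) -> np.ndarray:
        return _inv_logit(self.consent_logit(df))

    # -- serialisation -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "GroundTruthModel":
        data = json.loads(payload)
        for key in ("bik4",):
            if key in data.get("participation", {}):
                data["participation"][key] = {int(k): v for k, v in data["participation"][key].items()}
        return cls(**data)


def _anchor_coefficients(anchors: dict[str, tuple[float, float]]) -> dict:
    """Decompose age-by-sex anchor probabilities into intercept, age offsets,
    a common female effect (mean female-male log-odds gap below 70) and a
    female x 70+ interaction absorbing the reversal of the sex gap."""
    male = {g: _logit(anchors[g][0]) for g in RATE_AGE_GROUPS}
    gaps = {g: _logit(anchors[g][1]) - male[g] for g in RATE_AGE_GROUPS}
    b0 = float(male["16-19"])
    female = float(np.mean([gaps[g] for g in RATE_AGE_GROUPS if g != "70+"]))
    return {
        "intercept": b0,
        "age": {g: float(male[g] - b0) for g in RATE_AGE_GROUPS},
        "female": female,
        "female_70plus": float(gaps["70+"] - female),
    }


def _region_pop_shares() -> dict[str, float]:
    shares = germany.normalized_state_shares()
    out: dict[str, float] = {}
    for state, share in shares.items():
        out[REGION_OF_STATE[state]] = out.get(REGION_OF_STATE[state], 0.0) + share
    return out


def default_truth() -> GroundTruthModel:
    """The default ground-truth model.

    Participation and consent coefficients are derived in closed form from
    the anchor tables; small region and BIK effects (highest in the
    Northwest, highest in the 20k-50k size class, lowest in the largest
    cities) are added and the intercepts are centred against the reference
    covariate margins so the anchors still hold marginally.
    """
    truth = GroundTruthModel()

    part = _anchor_coefficients(PARTICIPATION_ANCHORS)
    part["region"] = {"Northeast": 0.0, "Northwest": 0.08, "Central East": -0.02,
                      "Central West": 0.02, "South": 0.03}
    part["bik4"] = {1: 0.0, 2: 0.06, 3: 0.01, 4: -0.04}
    region_shares = _region_pop_shares()
    centering = sum(part["region"][r] * s for r, s in region_shares.items())
    centering += sum(part["bik4"][b] * s for b, s in DEFAULT_BIK4_POP_SHARES.items())
    part["intercept"] -= centering
    truth.participation = part

    # consent anchors: validated-per-complete ratios inflated by the expected
    # double-opt-in loss (only online registrations need confirmation)
    confirm = truth.confirm_cawi
    consent_anchors = {}
    for g, (m, f) in REGISTRATION_ANCHORS.items():
        web = SEQUENTIAL_CAWI_SHARE if g != "70+" else 1.0 - SIMULTANEOUS_PAPI_SHARE
        loss = 1.0 - web * (1.0 - confirm)
        consent_anchors[g] = (m / loss, f / loss)
    cons = _anchor_coefficients(consent_anchors)
    cons["region"] = {"Northeast": 0.0, "Northwest": 0.10, "Central East": 0.0,
                      "Central West": 0.06, "South": 0.07}
    cons["education"] = {"low": 0.0, "medium": 0.25, "high": 0.55}
    cons["non_german"] = -0.90
    cons["chronic"] = 0.12
    cons["srh_bad"] = -0.30
    cons["bmi_obesity"] = 0.12
    cons["smoking_occasional"] = -0.18
    cons["sport"] = {"none": 0.0, "<1h": 0.0, "1-2h": 0.05, "2-4h": 0.15, "4h+": 0.08}
    cons["climate"] = {"1-3": 0.0, "4-7": 0.10, "8-10": 0.18}
    cons["waited"] = 0.10
    cons["red_meat_daily"] = -0.25
    cons["household_multi"] = 0.10

    items = truth.item_distributions
    centering = sum(cons["region"][r] * s for r, s in region_shares.items())
    centering += sum(cons["education"][k] * p for k, p in items["education"].items())
    centering += cons["non_german"] * (1.0 - truth.german_share)
    centering += cons["chronic"] * sum(
        REF_INVITED_AGE_SHARES6[g] * truth.chronic_by_age[g]
        for g in REF_INVITED_AGE_SHARES6
    )
    centering += cons["srh_bad"] * (items["srh"]["bad"] + items["srh"]["very bad"])
    centering += cons["bmi_obesity"] * items["bmi_category"]["obesity"]
    centering += cons["smoking_occasional"] * items["smoking"]["occasional"]
    centering += sum(cons["sport"][k] * p for k, p in items["sport"].items())
    centering += sum(cons["climate"][k] * p for k, p in items["climate_band"].items())
    centering += cons["waited"] * items["waited_for_appointment"]["yes"]
    centering += cons["red_meat_daily"] * items["red_meat"]["daily"]
    centering += cons["household_multi"] * (1.0 - truth.single_household_share)
    cons["intercept"] -= centering
    truth.consent = cons
    return truth


# ---------------------------------------------------------------------------
# register generation
# ---------------------------------------------------------------------------

def _sample_ages(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample an integer age for every person given their draw age group."""
    ages = np.zeros(len(groups), dtype=np.int64)
    for g, (lo, hi) in DRAW_AGE_BOUNDS.items():
        mask = groups == g
        n = int(mask.sum())
        if n == 0:
            continue
        if g == "65-79":
            young = rng.random(n) < _P_65_69_WITHIN_65_79
            a = np.where(
                young,
                rng.integers(65, 70, size=n),
                rng.integers(70, 80, size=n),
            )
        else:
            a = rng.integers(lo, hi + 1, size=n)
        ages[mask] = a
    return ages


def _attach_demographic_groups(df: pd.DataFrame) -> pd.DataFrame:
    df["age_group"] = pd.cut(
        df["age"], bins=[15, 29, 39, 49, 59, 69, 200],
        labels=germany.ANALYSIS_AGE_GROUPS,
    ).astype(str)
    df["age_group7"] = pd.cut(
        df["age"], bins=[15, 19, 29, 39, 49, 59, 69, 200],
        labels=RATE_AGE_GROUPS,
    ).astype(str)
    df["region"] = df["state"].map(REGION_OF_STATE)
    return df


def _draw_items(df: pd.DataFrame, truth: GroundTruthModel, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the recruitment-questionnaire items.

    All items follow the configured marginal distributions; the chronic
    condition additionally depends on age.  Height/weight are back-filled
    from the BMI category so the arithmetic BMI check has raw inputs.
    """
    n = len(df)
    for item, dist in truth.item_distributions.items():
        levels = list(dist)
        df[item] = rng.choice(levels, size=n, p=[dist[k] for k in levels])
    p_chronic = df["age_group"].map(truth.chronic_by_age).to_numpy(dtype=float)
    df["chronic_disease"] = rng.random(n) < p_chronic
    df["life_satisfaction"] = df["satisfaction_band"].map(
        {"1-3": 2, "4-7": 5, "8-10": 9}
    ) + rng.integers(-1, 2, size=n)
    df["climate_risk"] = df["climate_band"].map({"1-3": 2, "4-7": 5, "8-10": 9})
    # raw anthropometrics consistent with the categorical BMI
    bmi_mid = df["bmi_category"].map(
        {"underweight": 17.5, "normal": 22.0, "overweight": 27.0, "obesity": 33.0}
    ).to_numpy(dtype=float)
    height = rng.normal(1.72, 0.09, size=n).clip(1.45, 2.10)
    df["height_m"] = np.round(height, 2)
    df["weight_kg"] = np.round(bmi_mid * df["height_m"] ** 2, 1)
    return df


def generate_register(frame: pd.DataFrame, truth: GroundTruthModel, seed: int) -> pd.DataFrame:
    """Generate one register row per person counted in the frame.

    Propensities are computed from the truth coefficients by the inverse-logit
    link; address defects, duplicates and missing birth months are injected at
    the configured rates.  Deterministic for fixed (frame, truth, seed).
    """
    if len(frame) == 0 or frame["pop_16plus"].sum() == 0:
        raise ValueError("empty frame")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))

    reps = []
    for g in DRAW_AGE_GROUPS:
        counts = frame[f"pop_{g}"].to_numpy()
        reps.append(pd.DataFrame({
            "municipality_id": np.repeat(frame["municipality_id"].to_numpy(), counts),
            "state": np.repeat(frame["state"].to_numpy(), counts),
            "bik_class_4": np.repeat(frame["bik_class_4"].to_numpy(), counts),
            "age_group_draw": g,
        }))
    df = pd.concat(reps, ignore_index=True)
    n = len(df)
    df["person_id"] = [f"p{i:07d}" for i in range(n)]

    df["age"] = _sample_ages(df["age_group_draw"].to_numpy(), rng)
    df["birth_year"] = REFERENCE_YEAR - df["age"]
    months = rng.integers(1, 13, size=n)
    df["birth_month"] = pd.array(months, dtype="Int64")
    df.loc[rng.random(n) < truth.birth_month_missing_rate, "birth_month"] = pd.NA
    df["sex"] = np.where(rng.random(n) < truth.female_share, "female", "male")
    df["citizenship_german"] = rng.random(n) < truth.german_share
    df["household_single"] = rng.random(n) < truth.single_household_share
    df = _attach_demographic_groups(df)
    df = _draw_items(df, truth, rng)

    # address quality
    defect = truth.address_defect_rates
    statuses = ["valid", "business", "moved", "deceased"]
    p_valid = 1.0 - sum(defect.values())
    df["address_status"] = rng.choice(
        statuses, size=n, p=[p_valid, defect["business"], defect["moved"], defect["deceased"]]
    )
    df["duplicate_of"] = pd.array([pd.NA] * n, dtype="string")
    n_dup = int(round(truth.duplicate_rate * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        shifted = df["person_id"].to_numpy()[(dup_idx + 1) % n]
        df.loc[df.index[dup_idx], "duplicate_of"] = shifted

    df["response_propensity"] = truth.participation_propensity(df)
    df["consent_propensity"] = truth.consent_propensity(df)
    df["confirm_propensity"] = truth.confirm_cawi
    return df


def simulate_cohort(truth: GroundTruthModel, n: int, seed: int) -> pd.DataFrame:
    """Simulate an invited cohort with covariates, propensities and drawn
    participation / consent outcomes, without running the sampling stages.

    Ages are drawn from the reference invited age distribution (the draw
    design over-invites older groups relative to the population), which is the
    covariate mix the selection models see.  Used for parameter-recovery and
    calibration studies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    age6 = list(REF_INVITED_AGE_SHARES6)
    shares = np.array([REF_INVITED_AGE_SHARES6[g] for g in age6])
    group6 = rng.choice(age6, size=n, p=shares / shares.sum())
    ages = np.zeros(n, dtype=np.int64)
    bounds = {"16-29": (16, 29), "30-39": (30, 39), "40-49": (40, 49),
              "50-59": (50, 59), "60-69": (60, 69), "70+": (70, 94)}
    for g, (lo, hi) in bounds.items():
        m = group6 == g
        ages[m] = rng.integers(lo, hi + 1, size=int(m.sum()))
    states = list(germany.STATES)
    st_shares = np.array([germany.normalized_state_shares()[s] for s in states])
    df = pd.DataFrame({
        "person_id": [f"c{i:06d}" for i in range(n)],
        "age": ages,
        "sex": np.where(rng.random(n) < truth.female_share, "female", "male"),
        "state": rng.choice(states, size=n, p=st_shares),
        "citizenship_german": rng.random(n) < truth.german_share,
        "household_single": rng.random(n) < truth.single_household_share,
    })
    b4 = list(DEFAULT_BIK4_POP_SHARES)
    df["bik_class_4"] = rng.choice(
        b4, size=n, p=[DEFAULT_BIK4_POP_SHARES[b] for b in b4]
    )
    df = _attach_demographic_groups(df)
    df = _draw_items(df, truth, rng)
    df["response_propensity"] = truth.participation_propensity(df)
    df["consent_propensity"] = truth.consent_propensity(df)
    df["participated"] = rng.random(n) < df["response_propensity"]
    df["consented"] = df["participated"] & (rng.random(n) < df["consent_propensity"])
    df["design_weight"] = 1.0
    df["psu_id"] = [f"psu{i % 400:04d}" for i in range(n)]
    return df
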