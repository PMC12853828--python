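"""Regional constants: federal states, analysis regions, BIK classes, age groups.

The 16 federal-state population shares (population aged 16+, end of 2023) are
the official margins also used as composition benchmarks.  The BIK
classification groups municipalities by size and commuter integration; the ten
official classes are collapsed to the four categories used in the selection
analyses.
"""

from __future__ import annotations

# Share of the 16+ population by federal state, in percent (official population
# figures, 31 Dec 2023).  Sums to 99.9 due to printed rounding; normalise at use.
STATE_POP_SHARES_PCT: dict[str, float] = {
    "Schleswig-Holstein": 3.5,
    "Hamburg": 2.2,
    "Lower Saxony": 9.6,
    "Bremen": 0.8,
    "North Rhine-Westphalia": 21.4,
    "Hesse": 7.6,
    "Rhineland-Palatinate": 4.9,
    "Baden-Wuerttemberg": 13.3,
    "Bavaria": 15.8,
    "Saarland": 1.2,
    "Berlin": 4.5,
    "Brandenburg": 3.1,
    "Mecklenburg-Western Pomerania": 2.0,
    "Saxony": 4.9,
    "Saxony-Anhalt": 2.6,
    "Thuringia": 2.5,
}

STATES: list[str] = list(STATE_POP_SHARES_PCT)

#: Two-digit state prefix used in the synthetic 8-digit municipality codes
STATE_CODE: dict[str, int] = {state: i + 1 for i, state in enumerate(STATES)}

#: Analysis regions used for subgroup rates and selection models
REGION_OF_STATE: dict[str, str] = {
    "Berlin": "Northeast",
    "Brandenburg": "Northeast",
    "Mecklenburg-Western Pomerania": "Northeast",
    "Schleswig-Holstein": "Northwest",
    "Hamburg": "Northwest",
    "Lower Saxony": "Northwest",
    "Bremen": "Northwest",
    "Saxony": "Central East",
    "Saxony-Anhalt": "Central East",
    "Thuringia": "Central East",
    "North Rhine-Westphalia": "Central West",
    "Hesse": "Central West",
    "Rhineland-Palatinate": "Central West",
    "Saarland": "Central West",
    "Baden-Wuerttemberg": "South",
    "Bavaria": "South",
}

REGIONS: list[str] = ["Northeast", "Northwest", "Central East", "Central West", "South"]

#: Deterministic collapse of the ten official BIK classes to four categories:
#: 1 = <20k inhabitants, 2 = 20k-<50k or surroundings of a 50k-<500k city,
#: 3 = core city 50k-<500k or surroundings of a 500k+ city, 4 = core city 500k+.
BIK4_FROM_BIK10: dict[int, int] = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2, 7: 3, 8: 3, 9: 3, 10: 4}

BIK4_LABELS: dict[int, str] = {
    1: "<20k inhabitants",
    2: "20k-<50k or surroundings 50k-<500k",
    3: "core city 50k-<500k or surroundings 500k+",
    4: "core city 500k+",
}

#: Age groups of the stratified address draw, with closed age bounds
DRAW_AGE_GROUPS: list[str] = ["16-29", "30-39", "40-49", "50-59", "60-64", "65-79", "80-84", "85+"]
DRAW_AGE_BOUNDS: dict[str, tuple[int, int]] = {
    "16-29": (16, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-64": (60, 64),
    "65-79": (65, 79),
    "80-84": (80, 84),
    "85+": (85, 99),
}

#: Six age groups used in the selection analyses and composition tables
ANALYSIS_AGE_GROUPS: list[str] = ["16-29", "30-39", "40-49", "50-59", "60-69", "70+"]

#: Seven age groups used for subgroup outcome rates (16-29 split once more)
RATE_AGE_GROUPS: list[str] = ["16-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70+"]


def analysis_age_group(age) -> "object":
    """Map integer ages to the six analysis age groups (vectorised via pandas cut
    at call sites; this scalar helper is kept for clarity)."""
    if age < 30:
        return "16-29"
    if age < 40:
        return "30-39"
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    return "70+"


def rate_age_group(age) -> str:
    if age < 20:
        return "16-19"
    if age < 30:
        return "20-29"
    return analysis_age_group(age)


def normalized_state_shares() -> dict[str, float]:
    total = sum(STATE_POP_SHARES_PCT.values())
    return {s: v / total for s, v in STATE_POP_SHARES_PCT.items()}
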