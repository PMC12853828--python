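"""Two-stage stratified cluster sampling design.

First stage: primary sampling units (sample points, SPs) are allocated to
federal states in proportion to the 16+ population, with a guaranteed minimum
per state enforced by an iterative rescaling rule, and spread across BIK size
classes within each state.  Counts are made integral by controlled rounding
(largest-remainder apportionment, the one-dimensional case of the Cox
controlled-rounding algorithm).  Municipalities are selected within each
state-BIK stratum by systematic probability-proportional-to-size sampling;
municipalities whose address draw would cover more than a threshold share of
their eligible population are merged with similar neighbours into synthetic
sample points.

Second stage: from every sample point, addresses are drawn by age-stratified
simple random sampling, where the per-age-group draw count is proportional to
the group's population share divided by its expected recruitment rate, then a
random subset is invited and the rest held as a reserve.  Each record carries
its inclusion probability and design weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .germany import BIK4_FROM_BIK10, DRAW_AGE_GROUPS

logger = logging.getLogger(__name__)

_EPS = 1e-9


class AllocationError(ValueError):
    """Raised when an allocation request is infeasible."""


# ---------------------------------------------------------------------------
# controlled rounding
# ---------------------------------------------------------------------------

def cox_round(values, total: int) -> np.ndarray:
    """Round non-negative reals to integers that sum exactly to ``total``.

    Each output lies in {floor(v), ceil(v)}.  Entries are bumped to their
    ceiling in order of decreasing fractional part, ties broken by lower
    index, which is the largest-remainder (Hamilton) apportionment rule --
    the deterministic one-dimensional special case of controlled rounding.

    Raises
    ------
    AllocationError
        If no vector within the floor/ceil bounds can reach ``total``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if (v < -_EPS).any():
        raise ValueError("values must be non-negative")
    total = int(total)
    base = np.floor(v + _EPS).astype(np.int64)
    # quantise fractional parts so equal decimals tie exactly despite binary
    # float representation (0.9 vs 0.9000000000000004)
    frac = np.round(v - base, 9)
    frac[frac < _EPS] = 0.0
    n_bumpable = int((frac > 0).sum())
    rem = total - int(base.sum())
    if rem < 0 or rem > n_bumpable:
        raise AllocationError(
            f"cannot round to total {total}: floor sum {int(base.sum())}, "
            f"ceil sum {int(base.sum()) + n_bumpable}"
        )
    if rem:
        order = np.lexsort((np.arange(len(v)), -frac))
        base[order[:rem]] += 1
    return base


# ---------------------------------------------------------------------------
# PSU allocation to states / strata
# ---------------------------------------------------------------------------

@dataclass
class AllocationPlan:
    """Allocation of sample points to states (and optionally strata)."""

    psus_per_state: dict[str, int]
    total_psus: int
    at_minimum_states: list[str]
    psus_per_stratum: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.psus_per_state.values()) != self.total_psus:
            raise AllocationError("state allocation does not sum to total")


def allocate_psus(state_shares: dict[str, float], total_psus: int, minimum: int) -> AllocationPlan:
    """Allocate ``total_psus`` sample points to states proportionally to their
    16+ population shares, guaranteeing ``minimum`` per state.

    The minimum is applied iteratively: states whose proportional target falls
    below the floor are fixed at the floor and the remaining total is
    redistributed over the remaining states; this repeats until no further
    state drops below the floor (a single pass can push a previously safe
    state under the floor).  The free states are then controlled-rounded to
    the remaining total.
    """
    if not state_shares:
        raise ValueError("no states given")
    if any(s < 0 for s in state_shares.values()):
        raise ValueError("negative share")
    share_sum = float(sum(state_shares.values()))
    if share_sum <= 0:
        raise ValueError("shares sum to zero")
    if abs(share_sum - 1.0) > 0.01:
        raise ValueError(f"shares must sum to 1 (got {share_sum:.4f})")
    shares = {s: v / share_sum for s, v in state_shares.items()}
    n_states = len(shares)
    if minimum * n_states > total_psus:
        raise AllocationError(
            f"minimum {minimum} x {n_states} states exceeds total {total_psus}"
        )

    fixed: dict[str, int] = {}
    while True:
        free = [s for s in shares if s not in fixed]
        remaining = total_psus - minimum * len(fixed)
        if not free:
            break
        free_share = sum(shares[s] for s in free)
        targets = {s: remaining * shares[s] / free_share for s in free}
        newly = [s for s in free if targets[s] < minimum]
        if newly:
            for s in newly:
                fixed[s] = minimum
            continue
        rounded = cox_round([targets[s] for s in free], remaining)
        if (rounded < minimum).any():
            for s, r in zip(free, rounded):
                if r < minimum:
                    fixed[s] = minimum
            continue
        alloc = dict(fixed)
        alloc.update({s: int(r) for s, r in zip(free, rounded)})
        return AllocationPlan(
            psus_per_state={s: alloc[s] for s in shares},
            total_psus=total_psus,
            at_minimum_states=sorted(fixed),
        )
    # every state fixed at the minimum: only feasible if it exhausts the total
    if minimum * n_states != total_psus:
        raise AllocationError("all states at minimum but totals do not match")
    return AllocationPlan(
        psus_per_state={s: minimum for s in shares},
        total_psus=total_psus,
        at_minimum_states=sorted(shares),
    )


def stratify_within_state(n_psus: int, stratum_pops: dict[int, int]) -> dict[int, int]:
    """Spread a state's sample points over its BIK strata proportionally to the
    16+ population, controlled-rounded to the state total.  Empty strata get 0."""
    total_pop = sum(stratum_pops.values())
    if total_pop <= 0:
        raise ValueError("state has zero 16+ population")
    keys = list(stratum_pops)
    targets = [n_psus * stratum_pops[k] / total_pop for k in keys]
    rounded = cox_round(targets, n_psus)
    return {k: int(r) for k, r in zip(keys, rounded)}


def per_psu_target(total_target: int, n_psus: int) -> int:
    """Smallest per-sample-point panelist count so that ``n_psus`` points reach
    ``total_target`` panelists in total."""
    if n_psus <= 0:
        raise ValueError("n_psus must be positive")
    return -(-int(total_target) // int(n_psus))


# ---------------------------------------------------------------------------
# PSU selection and synthetic sample points
# ---------------------------------------------------------------------------

def pps_systematic(sizes, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Systematic PPS selection of ``k`` draws from units with the given sizes.

    Returns ``(hits, pi)`` where ``hits[i]`` is the number of selection points
    falling in unit *i* (large units may be hit more than once) and ``pi`` is
    the expected number of hits ``k * size / total`` -- for units with
    ``pi < 1`` this is the exact inclusion probability.
    """
    sizes = np.asarray(sizes, dtype=float)
    n = len(sizes)
    hits = np.zeros(n, dtype=np.int64)
    total = sizes.sum()
    if k == 0 or n == 0 or total <= 0:
        return hits, np.zeros(n)
    pi = k * sizes / total
    order = rng.permutation(n)
    cum = np.cumsum(sizes[order])
    step = total / k
    points = rng.uniform(0.0, step) + step * np.arange(k)
    idx = np.searchsorted(cum, points, side="right")
    for i in idx:
        hits[order[min(i, n - 1)]] += 1
    return hits, pi


def build_synthetic_psus(
    frame: pd.DataFrame,
    selected: pd.DataFrame,
    coverage_threshold: float = 0.70,
) -> pd.DataFrame:
    """Form sample points from selected municipalities, merging over-covered
    ones with similar neighbours into synthetic sample points.

    ``selected`` must carry columns ``municipality_id``, ``address_need`` and
    ``selection_prob``.  A municipality triggers merging iff
    ``address_need / pop_16plus > coverage_threshold`` (strictly greater, so
    equality does not trigger).  Merge candidates share the district key
    (first six digits of the municipality code) and the BIK class, and are
    taken nearest-first by ``|log(pop_neighbour / pop_seed)|``.  If candidates
    run out before coverage drops below the threshold, the sample point is
    kept and flagged.
    """
    if not 0 < coverage_threshold <= 1:
        raise ValueError("coverage_threshold must be in (0, 1]")
    fidx = frame.set_index("municipality_id")
    used: set[str] = set(selected["municipality_id"])
    rows = []
    for n, sel in enumerate(selected.itertuples(index=False)):
        muni = fidx.loc[sel.municipality_id]
        members = [sel.municipality_id]
        pop = int(muni["pop_16plus"])
        need = float(sel.address_need)
        flagged = False
        if need / pop > coverage_threshold:
            cand = fidx[
                (fidx["district_key"] == muni["district_key"])
                & (fidx["bik_class_10"] == muni["bik_class_10"])
                & (~fidx.index.isin(used))
            ]
            dist = np.abs(np.log(cand["pop_16plus"] / pop))
            for mid in dist.sort_values(kind="stable").index:
                members.append(mid)
                used.add(mid)
                pop += int(fidx.loc[mid, "pop_16plus"])
                if need / pop <= coverage_threshold:
                    break
            flagged = need / pop > coverage_threshold
            if flagged:
                logger.warning(
                    "sample point %s: neighbour pool exhausted, coverage %.2f",
                    sel.municipality_id, need / pop,
                )
        age_pops = {
            f"pop_{g}": int(sum(fidx.loc[m, f"pop_{g}"] for m in members))
            for g in DRAW_AGE_GROUPS
        }
        rows.append({
            "psu_id": f"psu{n:04d}",
            "seed_municipality_id": sel.municipality_id,
            "member_municipality_ids": ",".join(members),
            "state": muni["state"],
            "bik_class_10": int(muni["bik_class_10"]),
            "bik_class_4": BIK4_FROM_BIK10[int(muni["bik_class_10"])],
            "pop_16plus": pop,
            "is_synthetic": len(members) > 1,
            "flagged": flagged,
            "selection_prob": float(sel.selection_prob),
            "address_need": need,
            **age_pops,
        })
    return pd.DataFrame(rows)


def select_psus(
    frame: pd.DataFrame,
    plan: AllocationPlan,
    n_draw: int,
    oversample_factors: dict[str, float],
    coverage_threshold: float,
    rng: np.random.Generator,
    stratify_by: str = "bik_class_4",
) -> pd.DataFrame:
    """Select municipalities within every state-BIK stratum by systematic PPS
    and assemble (possibly synthetic) sample points.

    ``stratify_by`` names the BIK column defining strata.  The collapsed
    4-class level is the default: with a scaled-down number of sample points
    the full 10-class subdivision leaves stratum targets far below one and
    small-municipality strata would deterministically round to zero.

    A municipality hit *m* times becomes a single sample point with an
    ``address_need`` of ``m * n_draw * oversample``; its first-stage
    probability is approximated by ``min(1, k * size / stratum size)``.
    """
    selected_rows = []
    for state, n_state in plan.psus_per_state.items():
        sub = frame[frame["state"] == state]
        strata = sub.groupby(stratify_by)["pop_16plus"].sum().to_dict()
        counts = stratify_within_state(n_state, strata)
        plan.psus_per_stratum.update({(state, b): c for b, c in counts.items()})
        over = float(oversample_factors.get(state, 1.0))
        for bik, k in counts.items():
            if k == 0:
                continue
            cell = sub[sub[stratify_by] == bik]
            hits, pi = pps_systematic(cell["pop_16plus"].to_numpy(), k, rng)
            for (mid, h, p) in zip(cell["municipality_id"], hits, pi):
                if h > 0:
                    selected_rows.append({
                        "municipality_id": mid,
                        "address_need": h * n_draw * over,
                        "selection_prob": min(1.0, p),
                        "oversample_factor": over,
                    })
    selected = pd.DataFrame(selected_rows)
    psus = build_synthetic_psus(frame, selected, coverage_threshold)
    psus["oversample_factor"] = selected["oversample_factor"].to_numpy()
    return psus


# ---------------------------------------------------------------------------
# address draw
# ---------------------------------------------------------------------------

def capped_apportion(weights, caps, total: int) -> np.ndarray:
    """Apportion ``total`` over groups proportionally to ``weights`` with per-
    group caps, re-apportioning the remainder when a group saturates."""
    weights = np.asarray(weights, dtype=float)
    caps = np.asarray(caps, dtype=np.int64)
    n = len(weights)
    out = np.zeros(n, dtype=np.int64)
    free = weights > 0
    remaining = int(total)
    while remaining > 0 and free.any():
        w = weights * free
        targets = remaining * w / w.sum()
        alloc = cox_round(targets, remaining)
        over = free & (alloc > caps - out)
        if not over.any():
            out[free] += alloc[free]
            return out
        out[over] = caps[over]
        remaining = int(total - out.sum())
        free = free & ~over
    if remaining > 0:
        logger.warning("address draw short by %d: groups exhausted", remaining)
    return out


def draw_addresses(
    psu: pd.Series,
    register_psu: pd.DataFrame,
    n_draw: int,
    n_invite: int,
    expected_recr_by_age: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Age-stratified address draw for one sample point.

    Per-age-group draw counts are proportional to the group's share of the
    sample-point population divided by the group's expected recruitment rate,
    controlled-rounded to the (oversampled) total.  A simple random subset of
    the drawn addresses is invited; the rest form the reserve.  Inclusion
    probability = P(sample point) x (drawn in group / group population) x
    (invited / drawn).
    """
    if any(not 0 < r <= 1 for r in expected_recr_by_age.values()):
        raise ValueError("expected recruitment rates must be in (0, 1]")
    over = float(psu.get("oversample_factor", 1.0))
    # address_need already folds in oversampling and selection multiplicity
    # (a big city hit m times carries m draws' worth of addresses)
    n_draw_tot = int(round(psu.get("address_need", n_draw * over)))
    pops = register_psu.groupby("age_group_draw", observed=False)["person_id"].count()
    groups = [g for g in DRAW_AGE_GROUPS if pops.get(g, 0) > 0]
    gpop = np.array([pops[g] for g in groups], dtype=np.int64)
    share = gpop / gpop.sum()
    raw = share / np.array([expected_recr_by_age[g] for g in groups])
    n_draw_tot = min(n_draw_tot, int(gpop.sum()))
    n_inv_tot = int(round(n_draw_tot * n_invite / n_draw))
    counts = capped_apportion(raw, gpop, n_draw_tot)

    parts = []
    for g, n_g, pop_g in zip(groups, counts, gpop):
        if n_g == 0:
            continue
        grp = register_psu[register_psu["age_group_draw"] == g]
        take = grp.sample(n=int(n_g), random_state=rng)
        part = take[["person_id"]].copy()
        part["age_stratum"] = g
        part["p_within_group"] = n_g / pop_g
        parts.append(part)
    drawn = pd.concat(parts, ignore_index=True)
    n_drawn = len(drawn)
    n_inv = min(n_inv_tot, n_drawn)
    invited_idx = rng.choice(n_drawn, size=n_inv, replace=False)
    invited = np.zeros(n_drawn, dtype=bool)
    invited[invited_idx] = True
    drawn["psu_id"] = psu["psu_id"]
    drawn["invited"] = invited
    drawn["reserve"] = ~invited
    drawn["inclusion_probability"] = (
        psu["selection_prob"] * drawn["p_within_group"] * (n_inv / n_drawn)
    ).clip(upper=1.0)
    drawn["design_weight"] = 1.0 / drawn["inclusion_probability"]
    return drawn.drop(columns="p_within_group")


def clean_gross(
    records: pd.DataFrame,
    register: pd.DataFrame,
    rng: np.random.Generator,
    batch_shares: tuple[float, float, float] = (0.10, 0.50, 0.40),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove defective addresses from the gross sample and assign mailing
    batches.

    Business, moved and deceased addresses are removed; records pointing at a
    duplicate address are dropped when the canonical person is also drawn,
    otherwise redirected to the canonical person.  Kept records are split into
    batches 0/1/2 by a seeded random draw with the configured shares.
    """
    reg = register.set_index("person_id")
    out = records.merge(
        reg[["address_status", "duplicate_of"]],
        left_on="person_id", right_index=True, how="left",
    )
    log: dict[str, int] = {}
    bad = out["address_status"].isin(["business", "moved", "deceased"])
    for reason in ("business", "moved", "deceased"):
        log[reason] = int((out["address_status"] == reason).sum())
    out = out[~bad].copy()

    dup = out["duplicate_of"].notna()
    present = set(out["person_id"])
    drop_dup = dup & out["duplicate_of"].isin(present)
    redirect = dup & ~drop_dup
    log["duplicate"] = int(drop_dup.sum())
    log["duplicate_redirected"] = int(redirect.sum())
    out.loc[redirect, "person_id"] = out.loc[redirect, "duplicate_of"]
    out = out[~drop_dup].copy()

    out["batch"] = rng.choice(3, size=len(out), p=list(batch_shares))
    return out.drop(columns=["address_status", "duplicate_of"]), log
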