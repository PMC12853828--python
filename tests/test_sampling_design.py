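import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from probpanel import germany
from probpanel.register_synthesis import FrameConfig, generate_frame
from probpanel.sampling_design import (
    AllocationError,
    allocate_psus,
    build_synthetic_psus,
    capped_apportion,
    clean_gross,
    cox_round,
    draw_addresses,
    per_psu_target,
    pps_systematic,
    select_psus,
    stratify_within_state,
)

from .oracles import brute_force_controlled_round


class TestCoxRound:
    @pytest.mark.parametrize("values,total,expected", [
        ([2, 3, 5], 10, [2, 3, 5]),                 # already integral
        ([1.4, 1.4, 1.2], 4, [2, 1, 1]),            # largest remainder, index tie-break
        ([12.6, 7.9, 2.9], 24, [13, 8, 3]),
    ])
    def test_examples(self, values, total, expected):
        assert cox_round(values, total).tolist() == expected

    def test_outputs_within_floor_ceil_and_sum(self):
        v = [0.3, 2.7, 1.1, 0.9]
        out = cox_round(v, 5)
        assert out.sum() == 5
        assert all(np.floor(x) <= o <= np.ceil(x) for x, o in zip(v, out))

    @pytest.mark.parametrize("values,total", [([1.2, 1.2], 5), ([1.2, 1.2], 1), ([2.0, 3.0], 6)])
    def test_infeasible_raises(self, values, total):
        with pytest.raises(AllocationError):
            cox_round(values, total)

    def test_exhaustive_grid_matches_brute_force(self):
        """Every one-decimal vector of length 3 over 0..3.0 matches the
        enumeration oracle at every feasible total."""
        grid = [round(0.1 * i, 1) for i in range(0, 31, 3)]
        for a in grid:
            for b in grid:
                for c in grid:
                    v = [a, b, c]
                    lo = int(sum(np.floor(np.array(v) + 1e-9)))
                    hi = int(sum(np.ceil(np.array(v) - 1e-9)))
                    for total in range(lo, hi + 1):
                        assert cox_round(v, total).tolist() == \
                            brute_force_controlled_round(v, total)

    @given(st.lists(st.integers(0, 200).map(lambda i: i / 10), min_size=1, max_size=6),
           st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_property_matches_brute_force(self, values, data):
        lo = int(sum(np.floor(np.array(values) + 1e-9)))
        hi = int(sum(np.ceil(np.array(values) - 1e-9)))
        total = data.draw(st.integers(lo, hi))
        assert cox_round(values, total).tolist() == \
            brute_force_controlled_round(values, total)


class TestAllocatePsus:
    def test_symmetric(self):
        plan = allocate_psus({c: 0.25 for c in "abcd"}, 40, 5)
        assert plan.psus_per_state == {c: 10 for c in "abcd"}
        assert plan.at_minimum_states == []

    def test_two_states_pushed_to_floor(self):
        plan = allocate_psus({"a": 0.7, "b": 0.2, "c": 0.1}, 20, 5)
        assert plan.psus_per_state == {"a": 10, "b": 5, "c": 5}
        assert sorted(plan.at_minimum_states) == ["b", "c"]

    def test_iterative_floor_on_national_shares(self):
        """The guaranteed minimum of 14 points puts exactly nine of the 16
        states at the floor under the official population shares."""
        plan = allocate_psus(germany.normalized_state_shares(), 359, 14)
        assert len(plan.at_minimum_states) == 9
        assert sum(plan.psus_per_state.values()) == 359
        assert min(plan.psus_per_state.values()) == 14

    def test_infeasible_minimum(self):
        with pytest.raises(AllocationError):
            allocate_psus({"a": 0.5, "b": 0.5}, 5, 3)

    def test_totals_conserved_through_strata(self):
        plan = allocate_psus({"a": 0.6, "b": 0.4}, 30, 5)
        for state, n in plan.psus_per_state.items():
            strata = stratify_within_state(n, {1: 600, 2: 300, 3: 100})
            assert sum(strata.values()) == n


class TestStratify:
    def test_single_stratum(self):
        assert stratify_within_state(14, {1: 1000}) == {1: 14}

    def test_proportional_matches_oracle(self):
        pops = {1: 60, 2: 30, 3: 10}
        out = stratify_within_state(14, pops)
        targets = [14 * p / 100 for p in pops.values()]
        assert list(out.values()) == brute_force_controlled_round(targets, 14)

    def test_zero_population_state(self):
        with pytest.raises(ValueError):
            stratify_within_state(5, {1: 0})

    def test_city_stratum_can_hold_multiple_psus(self):
        out = stratify_within_state(10, {1: 100, 4: 900})
        assert out[4] >= 2


def test_per_psu_target_power_arithmetic():
    assert per_psu_target(30_000, 359) == 84
    assert per_psu_target(100, 10) == 10
    assert per_psu_target(101, 10) == 11


def _mini_frame():
    return pd.DataFrame({
        "municipality_id": ["01000100", "01000101", "01000102", "01000200"],
        "district_key": ["010001", "010001", "010001", "010002"],
        "state": ["Schleswig-Holstein"] * 4,
        "bik_class_10": [2, 2, 3, 2],
        "bik_class_4": [1, 1, 1, 1],
        "pop_16plus": [500, 700, 650, 800],
        **{f"pop_{g}": [0, 0, 0, 0] for g in germany.DRAW_AGE_GROUPS},
    }).assign(**{"pop_16-29": [500, 700, 650, 800]})


class TestSyntheticPsus:
    def _selected(self, mid, need):
        return pd.DataFrame([{"municipality_id": mid, "address_need": need,
                              "selection_prob": 0.5}])

    def test_below_threshold_singleton(self):
        frame = _mini_frame()
        frame.loc[0, "pop_16plus"] = 10_000
        psus = build_synthetic_psus(frame, self._selected("01000100", 600), 0.7)
        assert not psus.loc[0, "is_synthetic"] and not psus.loc[0, "flagged"]

    def test_equality_does_not_trigger(self):
        frame = _mini_frame()
        frame.loc[0, "pop_16plus"] = 1000
        psus = build_synthetic_psus(frame, self._selected("01000100", 700), 0.7)
        assert not psus.loc[0, "is_synthetic"]

    def test_merge_until_covered(self):
        """pop 500 with need 600 merges the same-district same-class
        neighbour (pop 700): coverage 600/1200 = 50% <= 70%."""
        psus = build_synthetic_psus(_mini_frame(), self._selected("01000100", 600), 0.7)
        assert psus.loc[0, "is_synthetic"]
        assert psus.loc[0, "member_municipality_ids"] == "01000100,01000101"
        assert psus.loc[0, "pop_16plus"] == 1200
        assert not psus.loc[0, "flagged"]

    def test_nearest_by_log_pop_ratio(self):
        frame = _mini_frame()
        # neighbour pops 700 and (same bik) 520: |log(520/500)| < |log(700/500)|
        frame.loc[2, "bik_class_10"] = 2
        frame.loc[2, "pop_16plus"] = 520
        psus = build_synthetic_psus(frame, self._selected("01000100", 600), 0.7)
        assert psus.loc[0, "member_municipality_ids"].split(",")[1] == "01000102"

    def test_exhaustion_flagged_not_fatal(self):
        frame = _mini_frame()
        frame["bik_class_10"] = [2, 9, 9, 2]   # no same-district same-class neighbour
        psus = build_synthetic_psus(frame, self._selected("01000100", 600), 0.7)
        assert psus.loc[0, "flagged"] and not psus.loc[0, "is_synthetic"]


class TestDrawAddresses:
    def _register(self, group_sizes):
        rows = []
        for g, size in group_sizes.items():
            for i in range(size):
                rows.append({"person_id": f"{g}-{i}", "age_group_draw": g})
        return pd.DataFrame(rows)

    def _psu(self, need=600.0):
        return pd.Series({"psu_id": "psu0001", "selection_prob": 0.5,
                          "address_need": need, "oversample_factor": 1.0})

    def test_share_over_rate_apportionment(self, rng):
        """Equal shares with expected rates 12% and 22% give 388/212 of 600."""
        reg = self._register({"16-29": 5000, "30-39": 5000})
        rates = {"16-29": 0.12, "30-39": 0.22}
        out = draw_addresses(self._psu(), reg, 600, 400, rates, rng)
        counts = out.groupby("age_stratum")["person_id"].count()
        assert counts["16-29"] == 388 and counts["30-39"] == 212

    def test_uniform_symmetry(self, rng):
        reg = self._register({"16-29": 3000, "30-39": 3000, "40-49": 3000})
        rates = {g: 0.2 for g in ["16-29", "30-39", "40-49"]}
        out = draw_addresses(self._psu(), reg, 600, 400, rates, rng)
        assert set(out.groupby("age_stratum").size()) == {200}

    def test_oversampling_scales_draw_and_invite(self, rng):
        reg = self._register({"16-29": 5000})
        psu = self._psu(need=900.0)   # 600 x 1.5 for an oversampled state
        out = draw_addresses(psu, reg, 600, 400, {"16-29": 0.2}, rng)
        assert len(out) == 900 and out["invited"].sum() == 600

    def test_small_group_taken_fully(self, rng):
        reg = self._register({"16-29": 5000, "85+": 30})
        out = draw_addresses(self._psu(), reg, 600, 400,
                             {"16-29": 0.2, "85+": 0.01}, rng)
        counts = out.groupby("age_stratum").size()
        assert counts["85+"] == 30 and counts.sum() == 600

    def test_invited_xor_reserve_and_weights(self, rng):
        reg = self._register({"16-29": 2000})
        out = draw_addresses(self._psu(), reg, 600, 400, {"16-29": 0.2}, rng)
        assert (out["invited"] ^ out["reserve"]).all()
        assert (out["design_weight"] > 0).all() and np.isfinite(out["design_weight"]).all()
        # inclusion probability: 0.5 x (600/2000) x (400/600)
        assert np.allclose(out["inclusion_probability"], 0.5 * 0.3 * (2 / 3))

    def test_bad_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_addresses(self._psu(), self._register({"16-29": 100}), 600, 400,
                           {"16-29": 0.0}, rng)


def test_capped_apportion_respects_caps():
    out = capped_apportion([5, 5, 1], [100, 3, 100], 60)
    assert out.sum() == 60 and out[1] == 3


class TestCleanGross:
    def _records(self, ids):
        return pd.DataFrame({"person_id": ids, "invited": True})

    def _register(self, n, status="valid", dup=None):
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "address_status": [status] * n,
            "duplicate_of": [dup] * n,
        })

    def test_all_valid_zero_removals(self, rng):
        reg = self._register(50)
        kept, log = clean_gross(self._records(reg["person_id"]), reg, rng)
        assert len(kept) == 50
        assert sum(v for k, v in log.items() if k != "duplicate_redirected") == 0

    def test_defect_fraction_removed(self, rng):
        reg = self._register(1000)
        bad = rng.choice(1000, size=50, replace=False)
        reg.loc[bad, "address_status"] = "moved"
        kept, log = clean_gross(self._records(reg["person_id"]), reg, rng)
        assert log["moved"] == 50 and len(kept) == 950

    def test_duplicate_collapsed_to_canonical(self, rng):
        reg = self._register(10)
        reg.loc[3, "duplicate_of"] = "p0"      # canonical also drawn -> dropped
        reg.loc[5, "duplicate_of"] = "p99"     # canonical absent -> redirected
        kept, log = clean_gross(self._records(reg["person_id"]), reg, rng)
        assert log["duplicate"] == 1 and log["duplicate_redirected"] == 1
        assert "p99" in set(kept["person_id"]) and len(kept) == 9

    def test_batch_split_10_50_40(self, rng):
        reg = self._register(10_000)
        kept, _ = clean_gross(self._records(reg["person_id"]), reg, rng)
        shares = kept["batch"].value_counts(normalize=True)
        assert abs(shares[0] - 0.10) < 0.02
        assert abs(shares[1] - 0.50) < 0.02
        assert abs(shares[2] - 0.40) < 0.02


def test_horvitz_thompson_estimate_unbiased():
    """Design-weighted totals from the invited sample estimate the frame's
    16+ population without bias (Monte Carlo over 30 design draws, on a
    configuration without selection certainties)."""
    cfg = FrameConfig(n_municipalities=40, total_pop_16plus=80_000,
                      state_shares={"Bavaria": 1.0})
    frame = generate_frame(cfg, seed=7)
    total = frame["pop_16plus"].sum()
    plan = allocate_psus({"Bavaria": 1.0}, 6, 1)
    n_draw, n_invite = 200, 150   # small enough that no municipality needs merging
    reg_rows = []
    for g in germany.DRAW_AGE_GROUPS:
        counts = frame[f"pop_{g}"].to_numpy()
        reg_rows.append(pd.DataFrame({
            "person_id": [f"{m}-{g}-{i}" for m, c in zip(frame["municipality_id"], counts)
                          for i in range(c)],
            "municipality_id": np.repeat(frame["municipality_id"].to_numpy(), counts),
            "age_group_draw": g,
        }))
    register = pd.concat(reg_rows, ignore_index=True)
    rates = {g: 0.2 for g in germany.DRAW_AGE_GROUPS}

    estimates = []
    for s in range(30):
        rng = np.random.default_rng(1000 + s)
        psus = select_psus(frame, plan, n_draw, {}, 0.7, rng)
        assert (psus["selection_prob"] < 1).all()   # no certainties: probs exact
        assert not psus["is_synthetic"].any()       # no merging: probs exact
        est = 0.0
        for i, psu in psus.iterrows():
            members = psu["member_municipality_ids"].split(",")
            sub = register[register["municipality_id"].isin(members)]
            drawn = draw_addresses(psu, sub, n_draw, n_invite, rates, rng)
            est += drawn.loc[drawn["invited"], "design_weight"].sum()
        estimates.append(est)
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - total) < 2 * se + 1e-9


def test_pps_systematic_inclusion_probabilities():
    sizes = np.array([10, 20, 30, 40])
    rng = np.random.default_rng(0)
    draws = np.zeros(4)
    n_rep = 4000
    for _ in range(n_rep):
        hits, pi = pps_systematic(sizes, 2, rng)
        draws += hits
    expected = 2 * sizes / sizes.sum()
    assert np.allclose(draws / n_rep, expected, atol=0.03)
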