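"""End-to-end pipeline: synthetic register -> design -> fieldwork -> rates ->
selection models -> composition benchmark.

A single master seed governs all randomness through named substreams, so the
full run is reproducible and every stage can be re-run independently.  Stage
boundaries log record counts in and out, from which the recruitment funnel
(drawn -> invited -> cleaned gross -> interviews -> consenters -> validated
panelists) is assembled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import case_processing, outcome_rates, selection_models
from .composition import composition_table, deviation_table
from .fieldwork import ContactProtocol, DispositionLedger, run_field, simulate_double_realizations
from .register_synthesis import (
    FrameConfig, GroundTruthModel, default_truth, generate_frame, generate_register,
)
from .sampling_design import allocate_psus, clean_gross, draw_addresses, select_psus

logger = logging.getLogger(__name__)

#: substream labels -> offsets mixed into the master seed
_STREAMS = {"design": 606, "clean": 707, "field": 808, "double": 909}


@dataclass
class PipelineConfig:
    """Scaled default: a ~1/50 nation with 72 sample points (~28,000 invited),
    so the full pipeline runs in well under a minute."""

    schema_version: int = 1
    frame: FrameConfig = field(default_factory=FrameConfig)
    total_psus: int = 72
    min_psus_per_state: int = 3
    n_draw: int = 600
    n_invite: int = 400
    oversample_factors: dict[str, float] = field(
        default_factory=lambda: {"Berlin": 1.5, "Schleswig-Holstein": 1.5}
    )
    coverage_threshold: float = 0.70
    stratify_by: str = "bik_class_4"
    run_models: bool = True
    write_register: bool = False

    def to_yaml(self, path=None) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("schema_version", 1) != 1:
            raise ValueError("unsupported config schema version")
        frame_data = data.pop("frame", {})
        if "bik4_pop_shares" in frame_data:
            frame_data["bik4_pop_shares"] = {int(k): v for k, v in frame_data["bik4_pop_shares"].items()}
        if "bik4_muni_shares" in frame_data:
            frame_data["bik4_muni_shares"] = {int(k): v for k, v in frame_data["bik4_muni_shares"].items()}
        return cls(frame=FrameConfig(**frame_data), **data)


@dataclass
class FunnelReport:
    """Counts at every recruitment stage, with shares of the cleaned gross."""

    drawn: int
    invited: int
    cleaned_gross: int
    completes: int
    partials: int
    consenters: int
    validated: int

    def __post_init__(self) -> None:
        chain = [self.cleaned_gross, self.completes + self.partials,
                 self.consenters, self.validated]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"funnel is not monotone: {chain}")

    def pct_of_cleaned_gross(self) -> dict[str, float]:
        g = self.cleaned_gross
        return {k: outcome_rates.round1(100.0 * v / g)
                for k, v in asdict(self).items() if k != "drawn"}


@dataclass
class PipelineResult:
    config: PipelineConfig
    seed: int
    funnel: FunnelReport
    rates: outcome_rates.OutcomeRateReport
    subgroups: pd.DataFrame
    frame: pd.DataFrame
    register: pd.DataFrame
    psus: pd.DataFrame
    gross: pd.DataFrame
    ledger: DispositionLedger
    decisions: pd.DataFrame
    removal_log: dict
    allocation: object
    ame_participation: pd.DataFrame | None = None
    ame_registration: pd.DataFrame | None = None
    composition_table: pd.DataFrame | None = None
    deviations: pd.DataFrame | None = None


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    truth: GroundTruthModel | None = None,
    out_dir=None,
    protocol: ContactProtocol | None = None,
) -> PipelineResult:
    """Run every stage and return all artifacts (optionally persisting them)."""
    config = config or PipelineConfig()
    truth = truth or default_truth()
    protocol = protocol or ContactProtocol()

    frame = generate_frame(config.frame, seed)
    register = generate_register(frame, truth, seed)
    logger.info("stage register: %d municipalities, %d persons", len(frame), len(register))

    shares = (frame.groupby("state")["pop_16plus"].sum()
              / frame["pop_16plus"].sum()).to_dict()
    plan = allocate_psus(shares, config.total_psus, config.min_psus_per_state)
    rng_design = _rng(seed, "design")
    psus = select_psus(frame, plan, config.n_draw, config.oversample_factors,
                       config.coverage_threshold, rng_design,
                       stratify_by=config.stratify_by)

    members = psus["member_municipality_ids"].str.split(",")
    muni_to_psu = {m: i for i, ms in zip(psus.index, members) for m in ms}
    reg_by_muni = register.assign(
        _psu=register["municipality_id"].map(muni_to_psu)
    )
    draws = []
    for i, psu in psus.iterrows():
        sub = reg_by_muni[reg_by_muni["_psu"] == i]
        draws.append(draw_addresses(psu, sub, config.n_draw, config.n_invite,
                                    truth.expected_recr_by_age, rng_design))
    gross = pd.concat(draws, ignore_index=True)
    logger.info("stage draw: %d addresses drawn, %d invited",
                len(gross), int(gross["invited"].sum()))

    cleaned, removal_log = clean_gross(gross[gross["invited"]], register, _rng(seed, "clean"))
    logger.info("stage clean: %d kept, removals %s", len(cleaned), removal_log)

    ledger = run_field(cleaned, register, truth, protocol, seed)
    ledger = simulate_double_realizations(ledger, truth, seed)

    # registration entries for consenters: questionnaire values with rare typos
    persons = ledger.persons
    rng_reg = _rng(seed, "double")
    n = len(persons)
    consent = persons["consented"].to_numpy()
    flip = consent & (rng_reg.random(n) < truth.reporting_error_rates["registration"])
    persons["reg_sex"] = np.where(consent, persons["self_sex"], None)
    persons["reg_birth_year"] = np.where(
        consent, persons["self_birth_year"] + np.where(flip, 1, 0), np.nan
    )
    persons["reg_birth_month"] = np.where(consent, persons["self_birth_month"], np.nan)

    decisions = case_processing.apply_matching(persons)
    persons = case_processing.finalize_panel(persons, ledger.interviews, decisions)
    interviews = case_processing.resolve_all_doubles(ledger.interviews)
    ledger = DispositionLedger(persons=persons, interviews=interviews)

    rates = outcome_rates.report(persons, interviews)
    subgroups = outcome_rates.subgroup_table(persons, ["age_group", "sex", "bik", "region"])

    counts = rates.counts
    funnel = FunnelReport(
        drawn=len(gross),
        invited=int(gross["invited"].sum()),
        cleaned_gross=counts["gross"],
        completes=counts["complete"],
        partials=counts["partial"],
        consenters=counts["consenters"],
        validated=counts["validated"],
    )

    result = PipelineResult(
        config=config, seed=seed, funnel=funnel, rates=rates, subgroups=subgroups,
        frame=frame, register=register, psus=psus, gross=gross, ledger=ledger,
        decisions=decisions, removal_log=removal_log, allocation=plan,
    )

    if config.run_models:
        mf = selection_models.prepare_model_frame(persons)
        mf["participated"] = mf["responded"]
        part_fit = selection_models.fit_weighted_logit(
            mf, selection_models.gross_frame_spec("participated")
        )
        result.ame_participation = selection_models.ame(part_fit, mf)
        resp = mf[mf["responded"]].copy()
        resp["registered"] = resp["validated"]
        reg_fit = selection_models.fit_weighted_logit(
            resp, selection_models.extended_spec("registered")
        )
        result.ame_registration = selection_models.ame(reg_fit, resp)

        stages = {
            "gross": (persons, None),
            "rs": (persons[persons["responded"]], None),
            "panel": (persons[persons["validated"]], None),
            "rs_weighted": (persons[persons["responded"]],
                            persons.loc[persons["responded"], "design_weight"]),
            "panel_weighted": (persons[persons["validated"]],
                               persons.loc[persons["validated"], "design_weight"]),
        }
        comp = composition_table(stages)
        n_by_stage = {
            "gross": len(persons),
            "rs": int(persons["responded"].sum()),
            "panel": int(persons["validated"].sum()),
            "rs_weighted": int(persons["responded"].sum()),
            "panel_weighted": int(persons["validated"].sum()),
        }
        result.composition_table = comp
        result.deviations = deviation_table(comp, list(stages), n_by_stage)

    if out_dir is not None:
        _persist(result, truth, Path(out_dir))
    return result


def _persist(result: PipelineResult, truth: GroundTruthModel, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.frame.to_csv(out / "frame.csv", index=False)
    if result.config.write_register:
        result.register.to_csv(out / "register.csv", index=False)
    result.psus.drop(columns=[], errors="ignore").to_csv(out / "psus.csv", index=False)
    result.gross.to_csv(out / "gross_sample.csv", index=False)
    ledger_cols = [c for c in [
        "person_id", "psu_id", "batch", "age_stratum", "inclusion_probability",
        "design_weight", "arm", "final_code", "mode", "deployment_mode",
        "completion_fraction", "completion_date", "consented", "confirmed",
        "excluded", "validated",
    ] if c in result.ledger.persons.columns]
    result.ledger.persons[ledger_cols].to_csv(out / "ledger.csv", index=False)
    result.ledger.interviews.to_csv(out / "interviews.csv", index=False)
    result.decisions.to_csv(out / "matching_decisions.csv", index=False)
    result.subgroups.to_csv(out / "subgroup_rates.csv", index=False)
    truth.to_json(out / "truth.json")
    result.config.to_yaml(out / "config.yaml")
    with open(out / "rates.json", "w") as fh:
        json.dump(result.rates.to_dict(), fh, indent=2)
    with open(out / "funnel.json", "w") as fh:
        json.dump({"counts": asdict(result.funnel),
                   "pct_of_cleaned_gross": result.funnel.pct_of_cleaned_gross(),
                   "removals": result.removal_log}, fh, indent=2)
    if result.ame_participation is not None:
        result.ame_participation.to_csv(out / "ame_participation.csv", index=False)
        result.ame_registration.to_csv(out / "ame_registration.csv", index=False)
        result.composition_table.to_csv(out / "composition.csv", index=False)
        result.deviations.to_csv(out / "composition_deviation.csv", index=False)
        selection_models.forest_plot(
            result.ame_participation, out / "ame_participation.png",
            title="Participation in the recruitment survey",
        )
        selection_models.forest_plot(
            result.ame_registration, out / "ame_registration.png",
            title="Panel registration",
        )
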