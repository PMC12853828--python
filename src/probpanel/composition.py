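"""Sample-composition tables and deviation from population benchmarks.

Composition of the sample is tracked across recruitment stages (gross sample,
recruitment-study respondents, registered panelists), unweighted and design-
weighted, and compared against official population margins (population
figures by state/age/sex/BIK; microcensus margins for education, citizenship
and household size).  Deviation is quantified by a one-sample chi-square
goodness-of-fit statistic against the benchmark treated as a known population
distribution, with Cramer's V = sqrt(chi2 / (n * (k - 1))) as effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

#: characteristics only observed from the interview stage onward
INTERVIEW_ONLY = {"education", "citizenship", "household"}

_CHARACTERISTIC_COLUMNS = {
    "sex": "sex",
    "age": "age_group",
    "bik": "bik_class_4",
    "state": "state",
    "education": "education",
    "citizenship": "citizenship_german",
    "household": "household_single",
}

_VALUE_LABELS = {
    "citizenship": {True: "yes", False: "no"},
    "household": {True: "single", False: "multi"},
}


@dataclass(frozen=True)
class DeviationStat:
    chi2: float
    df: int
    p: float
    cramers_v: float
    n: int


def load_benchmarks() -> pd.DataFrame:
    """Packaged benchmark margins (characteristic, level, benchmark_pct)."""
    with resources.files("probpanel.data").joinpath("benchmarks.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def composition(
    sample: pd.DataFrame,
    characteristic: str,
    weights: pd.Series | np.ndarray | None = None,
    stage: str = "interview",
) -> pd.Series | None:
    """(Weighted) relative frequencies of one characteristic, in percent.

    Returns ``None`` for characteristics that are not observed at the given
    stage (education, citizenship and household size exist only from the
    interview onward), mirroring the empty gross-sample cells of composition
    tables.
    """
    if characteristic not in _CHARACTERISTIC_COLUMNS:
        raise KeyError(f"unknown characteristic {characteristic!r}")
    if stage == "gross" and characteristic in INTERVIEW_ONLY:
        return None
    col = _CHARACTERISTIC_COLUMNS[characteristic]
    values = sample[col]
    if characteristic in _VALUE_LABELS:
        values = values.map(_VALUE_LABELS[characteristic])
    if weights is None:
        weights = np.ones(len(sample))
    w = pd.Series(np.asarray(weights, dtype=float), index=sample.index)
    if (w < 0).any():
        raise ValueError("negative weights")
    totals = w.groupby(values.to_numpy()).sum()
    return 100.0 * totals / totals.sum()


def composition_table(
    stages: dict[str, tuple[pd.DataFrame, pd.Series | None]],
    characteristics: list[str] | None = None,
    benchmarks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stage-by-stage composition table with the benchmark column.

    ``stages`` maps a stage label to (sample, weights-or-None); the gross
    stage must be labelled ``"gross"`` so that interview-only characteristics
    get an absent marker there.
    """
    if benchmarks is None:
        benchmarks = load_benchmarks()
    if characteristics is None:
        characteristics = list(dict.fromkeys(benchmarks["characteristic"]))
    rows = []
    for char in characteristics:
        bench = benchmarks[benchmarks["characteristic"] == char]
        comps = {}
        for stage_name, (sample, weights) in stages.items():
            comp = composition(
                sample, char, weights,
                stage="gross" if stage_name == "gross" else "interview",
            )
            if comp is not None:
                comp.index = comp.index.astype(str)
            comps[stage_name] = comp
        for level, bench_pct in zip(bench["level"], bench["benchmark_pct"]):
            row = {"characteristic": char, "level": level}
            for stage_name, comp in comps.items():
                row[stage_name] = (
                    float(comp.get(str(level), 0.0)) if comp is not None else np.nan
                )
            row["benchmark"] = float(bench_pct)
            rows.append(row)
    return pd.DataFrame(rows)


def gof_deviation(p, pi, n: int) -> DeviationStat:
    """Chi-square goodness of fit of sample proportions ``p`` against known
    benchmark proportions ``pi`` at sample size ``n``, with Cramer's V.

    chi2 = n * sum((p - pi)^2 / pi); df = k - 1; V = sqrt(chi2 / (n (k-1))).
    Zero benchmark cells are an error -- collapse categories first.
    """
    p = np.asarray(p, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if p.shape != pi.shape:
        raise ValueError("shape mismatch")
    if (pi <= 0).any():
        raise ValueError("zero benchmark cell: collapse categories first")
    if abs(p.sum() - 1) > 1e-6 or abs(pi.sum() - 1) > 1e-6:
        raise ValueError("proportions must sum to 1")
    k = len(p)
    chi2 = float(n * np.sum((p - pi) ** 2 / pi))
    dof = k - 1
    v = float(np.sqrt(chi2 / (n * dof))) if dof > 0 else 0.0
    return DeviationStat(chi2=chi2, df=dof, p=float(stats.chi2.sf(chi2, dof)),
                         cramers_v=v, n=int(n))


def deviation_table(comp_table: pd.DataFrame, stage_columns: list[str],
                    n_by_stage: dict[str, int]) -> pd.DataFrame:
    """Deviation statistics of every stage column against the benchmark, one
    row per (characteristic, stage)."""
    rows = []
    for char, sub in comp_table.groupby("characteristic", sort=False):
        pi = sub["benchmark"].to_numpy() / 100.0
        pi = pi / pi.sum()
        for stage in stage_columns:
            p = sub[stage].to_numpy(dtype=float) / 100.0
            if np.isnan(p).any() or p.sum() <= 0:
                continue
            p = p / p.sum()
            d = gof_deviation(p, pi, n_by_stage[stage])
            rows.append({"characteristic": char, "stage": stage, "chi2": d.chi2,
                         "df": d.df, "p": d.p, "cramers_v": d.cramers_v, "n": d.n})
    return pd.DataFrame(rows)
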