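"""Design-weighted logistic selection models and average marginal effects.

Participation in the recruitment survey and registration for the panel are
modelled by logistic regression with inverse-inclusion-probability (design)
weights, all predictors categorical with declared reference levels.  The
weighted score equations are solved by iteratively reweighted least squares;
variances are cluster-robust sandwich estimates aggregating score
contributions within primary sampling units, which stands in for a fully
linearised design-based variance.

Average marginal effects (AME) express, in percentage points, by how much the
average predicted probability changes when a predictor is switched from its
reference level to the level of interest for every observation (weighted
mean of counterfactual probability differences).  Confidence intervals use
the delta method on the same weighted mean with the cluster-robust
coefficient covariance.

A design-effect helper quantifies the variance inflation from cluster
sampling, deff = 1 + (m - 1) * ICC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .germany import ANALYSIS_AGE_GROUPS, RATE_AGE_GROUPS, REGIONS


class SeparationError(RuntimeError):
    """Perfect separation: a predictor category determines the outcome."""


@dataclass
class Predictor:
    name: str                 # column in the data
    levels: list              # all levels, reference first
    label: str | None = None

    @property
    def reference(self):
        return self.levels[0]


@dataclass
class SelectionModelSpec:
    """Specification of one selection model."""

    outcome: str
    predictors: list[Predictor]
    weight_col: str = "design_weight"
    cluster_col: str = "psu_id"
    #: optional interaction terms as (name_a, level_a, name_b, level_b)
    interactions: list[tuple] = field(default_factory=list)


@dataclass
class SelectionModelResult:
    spec: SelectionModelSpec
    term_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    vcov: np.ndarray
    n_obs: int
    n_clusters: int
    iterations: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term_names,
            "logodds": self.coef,
            "se": self.se,
            "p": self.pvalues,
            "significant": self.pvalues < 0.05,
        })


def build_design(df: pd.DataFrame, spec: SelectionModelSpec) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design matrix (intercept plus one dummy per non-
    reference level, plus any interaction columns)."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for p in spec.predictors:
        observed = set(df[p.name].unique())
        extra = observed - set(p.levels)
        if extra:
            raise ValueError(f"unexpected levels {sorted(map(str, extra))} in {p.name}")
        for level in p.levels[1:]:
            cols.append((df[p.name] == level).to_numpy(dtype=float))
            names.append(f"{p.name}[{level}]")
    for (na, la, nb, lb) in spec.interactions:
        cols.append(((df[na] == la) & (df[nb] == lb)).to_numpy(dtype=float))
        names.append(f"{na}[{la}]:{nb}[{lb}]")
    return np.column_stack(cols), names


def _check_cells(df: pd.DataFrame, spec: SelectionModelSpec) -> None:
    for p in spec.predictors:
        counts = df[p.name].value_counts()
        empty = [lv for lv in p.levels if counts.get(lv, 0) == 0]
        if empty:
            raise ValueError(
                f"empty cells for predictor {p.name}: {empty}; collapse levels first"
            )


def fit_weighted_logit(
    df: pd.DataFrame,
    spec: SelectionModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SelectionModelResult:
    """Fit the weighted logistic model by IRLS with a cluster-robust sandwich.

    The coefficients solve sum_i w_i (y_i - p_i) x_i = 0.  Non-convergence is
    returned flagged, not raised; perfect separation raises
    :class:`SeparationError` naming the offending term.
    """
    _check_cells(df, spec)
    X, names = build_design(df, spec)
    y = df[spec.outcome].to_numpy(dtype=float)
    w = df[spec.weight_col].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    clusters = df[spec.cluster_col].to_numpy()
    n, k = X.shape

    beta = np.zeros(k)
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        mu = w * p * (1.0 - p)
        score = X.T @ (w * (y - p))
        info = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from e
        beta = beta + step
        if np.abs(beta).max() > 30.0:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(f"separation detected on term {worst!r}")
        if np.abs(step).max() < tol:
            converged = True
            break

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    mu = w * p * (1.0 - p)
    bread = np.linalg.inv(X.T @ (X * mu[:, None]))
    resid = (w * (y - p))[:, None] * X
    g = pd.DataFrame(resid).groupby(clusters).sum().to_numpy()
    n_clusters = g.shape[0]
    meat = g.T @ g
    if n_clusters > 1:
        meat *= n_clusters / (n_clusters - 1)
    vcov = bread @ meat @ bread
    se = np.sqrt(np.diag(vcov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return SelectionModelResult(
        spec=spec, term_names=names, coef=beta, se=se, pvalues=pvals, vcov=vcov,
        n_obs=n, n_clusters=int(n_clusters), iterations=it, converged=converged,
    )


def ame(result: SelectionModelResult, df: pd.DataFrame) -> pd.DataFrame:
    """Average marginal effects with delta-method 95% confidence intervals.

    For level c of predictor X the AME is the weighted mean over all
    observations of p_hat(X:=c) - p_hat(X:=reference), times 100.  The
    reference level has AME 0 by definition.
    """
    spec = result.spec
    w = df[spec.weight_col].to_numpy(dtype=float)
    W = w.sum()
    beta, V = result.coef, result.vcov
    rows = []
    for pred in spec.predictors:
        ref_df = df.copy()
        ref_df[pred.name] = pred.reference
        Xr, _ = build_design(ref_df, spec)
        pr = 1.0 / (1.0 + np.exp(-(Xr @ beta)))
        rows.append({"predictor": pred.name, "level": pred.reference,
                     "ame_pp": 0.0, "se_pp": 0.0, "ci_low": 0.0, "ci_high": 0.0,
                     "reference": True})
        for level in pred.levels[1:]:
            cf = df.copy()
            cf[pred.name] = level
            Xc, _ = build_design(cf, spec)
            pc = 1.0 / (1.0 + np.exp(-(Xc @ beta)))
            delta = float(np.sum(w * (pc - pr)) / W)
            grad = (Xc * (w * pc * (1 - pc))[:, None]
                    - Xr * (w * pr * (1 - pr))[:, None]).sum(axis=0) / W
            var = float(grad @ V @ grad)
            se = math.sqrt(max(var, 0.0))
            rows.append({
                "predictor": pred.name, "level": level,
                "ame_pp": 100 * delta, "se_pp": 100 * se,
                "ci_low": 100 * (delta - 1.959963984540054 * se),
                "ci_high": 100 * (delta + 1.959963984540054 * se),
                "reference": False,
            })
    return pd.DataFrame(rows)


def deff(cluster_size: float, icc: float) -> tuple[float, float]:
    """Design effect of cluster sampling and the implied SE inflation.

    deff = 1 + (m - 1) * ICC;  inflation% = (sqrt(deff) - 1) * 100.
    """
    if cluster_size < 1:
        raise ValueError("cluster size must be >= 1")
    if not 0 <= icc <= 1:
        raise ValueError("ICC must be in [0, 1]")
    d = 1.0 + (cluster_size - 1.0) * icc
    return d, (math.sqrt(d) - 1.0) * 100.0


# ---------------------------------------------------------------------------
# model presets
# ---------------------------------------------------------------------------

def gross_frame_spec(outcome: str = "participated") -> SelectionModelSpec:
    """The gross-sample model: register covariates only (six age groups with
    the youngest as reference, male, Northeast and smallest BIK class as
    references)."""
    return SelectionModelSpec(
        outcome=outcome,
        predictors=[
            Predictor("age_group", ANALYSIS_AGE_GROUPS),
            Predictor("sex", ["male", "female"]),
            Predictor("region", REGIONS),
            Predictor("bik_class_4", [1, 2, 3, 4]),
        ],
    )


def truth_parameterization_spec(outcome: str = "participated") -> SelectionModelSpec:
    """The generating parameterization: seven age groups plus the sex x 70+
    interaction; used for parameter-recovery studies."""
    return SelectionModelSpec(
        outcome=outcome,
        predictors=[
            Predictor("age_group7", RATE_AGE_GROUPS),
            Predictor("sex", ["male", "female"]),
            Predictor("region", REGIONS),
            Predictor("bik_class_4", [1, 2, 3, 4]),
        ],
        interactions=[("sex", "female", "age_group7", "70+")],
    )


def extended_spec(outcome: str = "registered") -> SelectionModelSpec:
    """Registration model on recruitment-survey participants: gross-frame
    covariates plus education, household type, citizenship and the health
    items."""
    return SelectionModelSpec(
        outcome=outcome,
        predictors=[
            Predictor("age_group", ANALYSIS_AGE_GROUPS),
            Predictor("sex", ["male", "female"]),
            Predictor("region", REGIONS),
            Predictor("bik_class_4", [1, 2, 3, 4]),
            Predictor("education", ["low", "medium", "high"]),
            Predictor("household", ["multi", "single"]),
            Predictor("citizenship", ["german", "other"]),
            Predictor("bmi_category", ["normal", "underweight", "overweight", "obesity"]),
            Predictor("chronic", ["no", "yes"]),
            Predictor("srh_group", ["good", "bad"]),
            Predictor("srmh_group", ["good", "bad"]),
            Predictor("attention_group", ["low", "high"]),
            Predictor("satisfaction_band", ["8-10", "4-7", "1-3"]),
            Predictor("red_meat", ["never", "<1/week", "1-3/week", "4-6/week", "daily"]),
            Predictor("sausage", ["never", "<1/week", "1-3/week", "4-6/week", "daily"]),
            Predictor("smoking", ["non-smoker", "occasional", "daily"]),
            Predictor("sport", ["none", "<1h", "1-2h", "2-4h", "4h+"]),
            Predictor("climate_band", ["1-3", "4-7", "8-10"]),
            Predictor("waited_for_appointment", ["no", "yes"]),
        ],
    )


def prepare_model_frame(persons: pd.DataFrame) -> pd.DataFrame:
    """Derive the grouped categorical predictors the models expect from a
    ledger/register frame (e.g. good-vs-bad self-rated health)."""
    df = persons.copy()
    df["household"] = np.where(df["household_single"], "single", "multi")
    df["citizenship"] = np.where(df["citizenship_german"], "german", "other")
    df["chronic"] = np.where(df["chronic_disease"], "yes", "no")
    df["srh_group"] = np.where(df["srh"].isin(["bad", "very bad"]), "bad", "good")
    df["srmh_group"] = np.where(df["srmh"].isin(["fair", "poor"]), "bad", "good")
    df["attention_group"] = np.where(
        df["attention"].isin(["strong", "very strong"]), "high", "low"
    )
    return df


def forest_plot(ame_table: pd.DataFrame, path=None, title: str = "Average marginal effects"):
    """Horizontal forest plot of AMEs with 95% CIs (one row per level)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = ame_table[~ame_table["reference"]]
    labels = tab["predictor"].astype(str) + ": " + tab["level"].astype(str)
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(tab) + 1.5))
    ypos = np.arange(len(tab))[::-1]
    ax.errorbar(
        tab["ame_pp"], ypos,
        xerr=[tab["ame_pp"] - tab["ci_low"], tab["ci_high"] - tab["ame_pp"]],
        fmt="o", markersize=3, capsize=2,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("AME (percentage points)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
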