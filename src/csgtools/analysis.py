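"""Cohort stratification and outcome analysis.

Implements the immunotherapy stratification workflow: median splits of
wGII and neoantigen burden (cohort-wide medians, "high" inclusive of the
median), quadrant response tables with Fisher's exact test, Kaplan–Meier
comparisons with log-rank tests, multivariable Cox proportional-hazards
models including the CSG3 × wGII × neoantigen three-way interaction, and
a per-cancer-type fixed-effect meta-analysis of CSG hazard ratios versus
the CSG1 reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .types import RESPONDER_CATEGORIES, CohortTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StratifiedCohort:
    """Clinical table augmented with csg, median-split flags and responder."""

    data: pd.DataFrame
    wgii_median: float
    neo_median: float


def stratify(
    cohort: CohortTable,
    metrics: pd.DataFrame,
    csg_labels: pd.Series,
) -> StratifiedCohort:
    """Join metrics and CSG labels onto the clinical table and median-split.

    ``metrics`` is indexed by sample id and must carry ``wgii``;
    ``csg_labels`` maps sample id → CSG.  High/low flags use the
    cohort-wide median with "high" inclusive of the median value; the
    medians are recorded on the result.
    """
    df = cohort.data.copy().set_index("sample_id")
    df["wgii"] = metrics["wgii"]
    if "tmb" in metrics.columns:
        df["tmb"] = metrics["tmb"]
    df["csg"] = csg_labels
    missing = df.index[df[["wgii", "csg"]].isna().any(axis=1)].tolist()
    if missing:
        raise ValidationError(f"samples missing wgii or csg: {missing[:5]}")
    for col in ("wgii", "neoantigen_burden"):
        if df[col].isna().all():
            raise ValidationError(f"metric {col} is all-NA; cannot median-split")
        if df[col].nunique() == 1:
            warnings.warn(f"metric {col} is constant; every sample is 'high'", stacklevel=2)
    wgii_median = float(df["wgii"].median())
    neo_median = float(df["neoantigen_burden"].median())
    df["wgii_high"] = df["wgii"] >= wgii_median
    df["neo_high"] = df["neoantigen_burden"] >= neo_median
    df["responder"] = df["response"].isin(RESPONDER_CATEGORIES)
    return StratifiedCohort(
        data=df.reset_index(), wgii_median=wgii_median, neo_median=neo_median
    )


@dataclass
class QuadrantResult:
    """2×2 response table for the double-high quadrant vs the rest."""

    table: pd.DataFrame  # rows: high_high / others; columns: responder / non_responder
    quadrant_counts: pd.DataFrame  # 4 quadrants × (responder, non_responder)
    p_value: float
    test: str


def quadrant_response(
    strat: StratifiedCohort,
    csg_filter: str | list[str] | None = "CSG3",
    test: str = "fisher",
) -> QuadrantResult:
    """Response association of the high-wGII ∩ high-neoantigen quadrant.

    Within the CSG filter (default CSG3; None = whole cohort), counts
    responders in the double-high quadrant versus all other samples and
    tests the 2×2 table (two-sided Fisher exact by default; ``test="chi2"``
    for the chi-square alternative).
    """
    df = strat.data
    if csg_filter is not None:
        wanted = [csg_filter] if isinstance(csg_filter, str) else list(csg_filter)
        df = df[df["csg"].isin(wanted)]
    if df.empty:
        raise ValidationError("quadrant_response: no samples after CSG filter")
    hh = df["wgii_high"] & df["neo_high"]
    table = pd.DataFrame(
        {
            "responder": [int((hh & df["responder"]).sum()), int((~hh & df["responder"]).sum())],
            "non_responder": [int((hh & ~df["responder"]).sum()), int((~hh & ~df["responder"]).sum())],
        },
        index=["high_high", "others"],
    )
    quadrants = (
        df.assign(
            quadrant=np.select(
                [
                    df["wgii_high"] & df["neo_high"],
                    df["wgii_high"] & ~df["neo_high"],
                    ~df["wgii_high"] & df["neo_high"],
                ],
                ["wgii_high/neo_high", "wgii_high/neo_low", "wgii_low/neo_high"],
                default="wgii_low/neo_low",
            )
        )
        .groupby("quadrant")["responder"]
        .agg(responder="sum", n="count")
    )
    quadrants["non_responder"] = quadrants["n"] - quadrants["responder"]
    if test == "fisher":
        _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    elif test == "chi2":
        _, p, _, _ = stats.chi2_contingency(table.to_numpy())
    else:
        raise ValueError(f"unknown test {test!r}")
    return QuadrantResult(
        table=table,
        quadrant_counts=quadrants[["responder", "non_responder", "n"]],
        p_value=float(p),
        test=test,
    )


@dataclass
class KMResult:
    """Per-group product-limit curves with medians and a log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> timeline/survival columns
    medians: pd.Series
    logrank_statistic: float
    logrank_p: float


def km_compare(strat: StratifiedCohort, grouping: str | pd.Series) -> KMResult:
    """Kaplan–Meier curves and log-rank comparison across groups.

    ``grouping`` is a column name of the stratified table (e.g. ``"csg"``)
    or a sample-aligned Series.  Median survival is NA when a group's
    curve never crosses 0.5.
    """
    df = strat.data
    groups = df[grouping] if isinstance(grouping, str) else grouping.reset_index(drop=True)
    curves, medians = {}, {}
    for grp in pd.unique(groups):
        mask = (groups == grp).to_numpy()
        km = KaplanMeierFitter()
        km.fit(df.loc[mask, "os_months"], df.loc[mask, "os_event"], label=str(grp))
        curve = km.survival_function_.reset_index()
        curve.columns = ["timeline", "survival"]
        curves[str(grp)] = curve
        med = km.median_survival_time_
        medians[str(grp)] = float(med) if np.isfinite(med) else np.nan
    res = multivariate_logrank_test(df["os_months"], groups, df["os_event"])
    return KMResult(
        curves=curves,
        medians=pd.Series(medians, name="median_os_months"),
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


@dataclass
class SurvivalModelSpec:
    """Covariate layout for the proportional-hazards fit.

    ``covariates`` may mix categorical fields (``csg``, ``cancer_type`` —
    expanded to dummies against the recorded reference) with numeric
    columns used on their natural scale.  ``interaction_terms`` are
    product terms over resolved columns, with ``"csg3"`` available as the
    CSG3 indicator.
    """

    covariates: list[str] = field(
        default_factory=lambda: ["csg", "wgii", "neoantigen_burden", "stage"]
    )
    interaction_terms: list[tuple[str, ...]] = field(default_factory=list)
    reference_csg: str = "CSG1"


@dataclass
class CoxResult:
    """Per-term hazard ratios with CIs and p-values, plus fit metadata."""

    summary: pd.DataFrame
    n: int
    n_events: int
    log_likelihood: float
    design_columns: list[str]
    covariate_scales: pd.Series


def _design_matrix(df: pd.DataFrame, spec: SurvivalModelSpec) -> pd.DataFrame:
    cols = {}
    for cov in spec.covariates:
        if cov == "csg":
            levels = [l for l in sorted(df["csg"].unique()) if l != spec.reference_csg]
            for lev in levels:
                cols[f"csg_{lev}"] = (df["csg"] == lev).astype(float)
        elif cov == "cancer_type":
            levels = sorted(df["cancer_type"].unique())[1:]
            for lev in levels:
                cols[f"cancer_type_{lev}"] = (df["cancer_type"] == lev).astype(float)
        else:
            cols[cov] = pd.to_numeric(df[cov]).astype(float)
    for term in spec.interaction_terms:
        parts = []
        for name in term:
            if name == "csg3":
                parts.append((df["csg"] == "CSG3").astype(float))
            elif name in cols:
                parts.append(cols[name])
            else:
                parts.append(pd.to_numeric(df[name]).astype(float))
        prod = parts[0]
        for p in parts[1:]:
            prod = prod * p
        cols["_x_".join(term)] = prod
    return pd.DataFrame(cols, index=df.index)


def cox_model(strat: StratifiedCohort, spec: SurvivalModelSpec | None = None) -> CoxResult:
    """Multivariable Cox proportional-hazards fit (Efron tie handling).

    Raises rather than returning silent estimates on constant covariates,
    exact collinearity, under-determined designs (events < terms), or
    non-convergence.
    """
    if spec is None:
        spec = SurvivalModelSpec()
    df = strat.data
    design = _design_matrix(df, spec)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValidationError(f"constant covariates in Cox design: {constant}")
    rank = np.linalg.matrix_rank(design.to_numpy() - design.to_numpy().mean(axis=0))
    if rank < design.shape[1]:
        raise ValidationError(
            f"collinear Cox design (rank {rank} < {design.shape[1]} columns): "
            f"{list(design.columns)}"
        )
    n_events = int(df["os_event"].sum())
    if n_events < design.shape[1]:
        raise ValidationError(
            f"{n_events} events for {design.shape[1]} model terms; simplify the model"
        )
    fit_df = design.copy()
    fit_df["os_months"] = df["os_months"].to_numpy()
    fit_df["os_event"] = df["os_event"].astype(bool).to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="os_months", event_col="os_event")
    except ConvergenceError as err:
        raise ValidationError(
            f"Cox model failed to converge (possible separation): {err}"
        ) from err
    summary = cph.summary[
        ["coef", "se(coef)", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].rename(
        columns={
            "coef": "log_hr",
            "se(coef)": "se",
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_lower95",
            "exp(coef) upper 95%": "hr_upper95",
            "p": "p_value",
        }
    )
    return CoxResult(
        summary=summary,
        n=len(df),
        n_events=n_events,
        log_likelihood=float(cph.log_likelihood_),
        design_columns=list(design.columns),
        covariate_scales=design.std(axis=0, ddof=1),
    )


def pool_fixed_effect(log_hrs: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Inverse-variance fixed-effect pooling; returns (pooled log-HR, pooled SE)."""
    log_hrs = np.asarray(log_hrs, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(log_hrs) == 0:
        raise ValidationError("nothing to pool")
    w = 1.0 / ses**2
    pooled = float((w * log_hrs).sum() / w.sum())
    return pooled, float(np.sqrt(1.0 / w.sum()))


@dataclass
class MetaResult:
    """Per-cancer-type CSG hazard ratios and the pooled fixed-effect estimates."""

    per_type: pd.DataFrame  # cancer_type, term, log_hr, se, hr, p_value
    pooled: pd.DataFrame  # term, log_hr, se, hr, hr_lower95, hr_upper95, p_value
    excluded_types: list[str]


def meta_by_type(
    strat: StratifiedCohort, spec: SurvivalModelSpec | None = None
) -> MetaResult:
    """Per-cancer-type Cox fits of CSG vs CSG1, pooled by inverse variance.

    Types whose model cannot be fitted (too few events, missing CSG
    levels, collinearity) are excluded with a warning and reported.
    """
    if spec is None:
        spec = SurvivalModelSpec(covariates=["csg"])
    df = strat.data
    types = sorted(df["cancer_type"].unique())
    rows, excluded = [], []
    for ct in types:
        sub = StratifiedCohort(
            data=df[df["cancer_type"] == ct].reset_index(drop=True),
            wgii_median=strat.wgii_median,
            neo_median=strat.neo_median,
        )
        try:
            res = cox_model(sub, spec)
        except ValidationError as err:
            warnings.warn(f"cancer type {ct} excluded from meta-analysis: {err}", stacklevel=2)
            excluded.append(ct)
            continue
        for term, r in res.summary.iterrows():
            rows.append(
                {
                    "cancer_type": ct,
                    "term": term,
                    "log_hr": r["log_hr"],
                    "se": r["se"],
                    "hr": r["hr"],
                    "p_value": r["p_value"],
                }
            )
    per_type = pd.DataFrame(rows)
    if per_type.empty or per_type["cancer_type"].nunique() < 2:
        raise ValidationError("meta-analysis needs >= 2 cancer types with fittable models")
    pooled_rows = []
    for term, grp in per_type.groupby("term"):
        log_hr, se = pool_fixed_effect(grp["log_hr"].to_numpy(), grp["se"].to_numpy())
        z = log_hr / se
        pooled_rows.append(
            {
                "term": term,
                "log_hr": log_hr,
                "se": se,
                "hr": float(np.exp(log_hr)),
                "hr_lower95": float(np.exp(log_hr - 1.959964 * se)),
                "hr_upper95": float(np.exp(log_hr + 1.959964 * se)),
                "p_value": float(2 * stats.norm.sf(abs(z))),
            }
        )
    return MetaResult(
        per_type=per_type, pooled=pd.DataFrame(pooled_rows).set_index("term"),
        excluded_types=excluded,
    )
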