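"""Survival analysis: Kaplan-Meier curves, log-rank tests, univariate Cox screen.

Prognosis-related genes are screened one at a time: a univariate Cox
proportional-hazards fit of survival on the gene's expression (Efron tie
handling), keeping genes with hazard ratio > 1 and Wald p < 0.05, then a
median-expression split (ties to the low group, mirroring the GMT-score
stratification) compared by the log-rank test.

Estimation is delegated to lifelines; this module owns the screening
rules, the tie conventions and the result containers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .core_io import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "prognosis_screen",
]


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk counts and median survival."""

    times: np.ndarray
    survival: np.ndarray  # S(t) just after each time in `times`
    at_risk: np.ndarray
    median: float  # nan when S never reaches 0.5

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")


@dataclass
class CoxResult:
    covariate: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must contain the hazard ratio")


def km_estimate(table: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimate; median = first time with S <= 0.5."""
    if table.event.sum() == 0:
        logger.warning("no events: survival curve flat at 1, median undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(table.time, table.event)
    times = kmf.survival_function_.index.to_numpy()[1:]  # drop t=0 row
    surv = kmf.survival_function_["KM_estimate"].to_numpy()[1:]
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
    below = surv <= 0.5
    median = float(times[below][0]) if below.any() else float("nan")
    return KMCurve(times=times, survival=surv, at_risk=at_risk, median=median)


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    if len(group_a.data) == 0 or len(group_b.data) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.event.sum() + group_b.event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(group_a.time, group_b.time, group_a.event, group_b.event)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(table: SurvivalTable, covariate: str) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties) for one covariate."""
    x = table.data[covariate]
    if not np.isfinite(x).all():
        raise ValueError(f"covariate {covariate!r} has non-finite values")
    if x.nunique() == 1:
        raise ValueError(f"covariate {covariate!r} is constant")
    df = pd.DataFrame({"time": table.time, "event": table.event, covariate: x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("Cox fit for %r did not converge (monotone likelihood?)", covariate)
        sign = float(np.sign(np.corrcoef(x, table.time)[0, 1]) or 1.0)
        return CoxResult(covariate, beta=-sign * np.inf, hr=np.inf if sign < 0 else 0.0,
                         ci_low=0.0, ci_high=np.inf, p=np.nan, n=len(df),
                         events=int(table.event.sum()), converged=False)
    s = cph.summary.loc[covariate]
    return CoxResult(
        covariate=covariate,
        beta=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        n=len(df),
        events=int(table.event.sum()),
    )


def median_split(values: pd.Series) -> pd.Series:
    """'high' for values strictly above the median, 'low' otherwise."""
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def prognosis_screen(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    genes,
    hr_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox screen of candidate genes against survival.

    Returns a frame per gene with the Cox fit, the keep verdict
    (HR > ``hr_threshold`` and p < ``p_threshold``) and, for kept genes,
    the median-expression-split log-rank chi-square and p.
    """
    common = [s for s in expr.sample_ids if s in surv.data.index]
    if len(common) < 10:
        raise ValueError(f"only {len(common)} overlapping samples; need >=10")
    sub_surv = surv.subset(common)
    rows = []
    for gene in genes:
        gene = str(gene).upper()
        if gene not in expr.data.index:
            logger.warning("gene %s not in expression matrix; skipped", gene)
            continue
        x = expr.data.loc[gene, common]
        tab = SurvivalTable(sub_surv.data.assign(**{gene: x.to_numpy()}))
        try:
            res = cox_univariate(tab, gene)
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", gene, exc)
            continue
        keep = bool(res.converged and res.hr > hr_threshold and res.p < p_threshold)
        row = {
            "gene": gene, "beta": res.beta, "hr": res.hr, "p": res.p,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "keep": keep,
            "logrank_chi2": np.nan, "logrank_p": np.nan,
        }
        if keep:
            groups = median_split(x)
            ga = SurvivalTable(sub_surv.data.loc[groups[groups == "high"].index].copy())
            gb = SurvivalTable(sub_surv.data.loc[groups[groups == "low"].index].copy())
            try:
                chi2, p = logrank_test(ga, gb)
                row["logrank_chi2"], row["logrank_p"] = chi2, p
            except ValueError as exc:
                logger.warning("log-rank skipped for %s: %s", gene, exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
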