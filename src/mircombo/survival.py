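"""Co-expression and average-z-score survival stratification.

The three miRNAs' expression columns are standardised across patients
(sample SD), averaged into a per-patient score, and the cohort is split at a
quantile of that score (median by default, ties to the low group) for
Kaplan-Meier estimation and a two-group log-rank test. Pairwise Pearson
correlations quantify miRNA co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


class ExpressionError(ValueError):
    pass


def zscore_average(expr: pd.DataFrame) -> pd.Series:
    """Per-patient mean of column-wise z-scores (sample SD, ddof=1)."""
    if len(expr) < 2:
        raise ExpressionError("need at least two patients")
    sd = expr.std(ddof=1)
    zero = sd[sd == 0]
    if not zero.empty:
        raise ExpressionError(
            f"zero-variance expression column(s): {list(zero.index)}"
        )
    z = (expr - expr.mean()) / sd
    return z.mean(axis=1)


def split_by_score(scores: pd.Series, quantile: float = 0.5) -> pd.Series:
    """Label patients ``high`` if score > the quantile threshold, else ``low``."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    threshold = scores.quantile(quantile)
    return pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index
    )


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> step table (time, survival, at_risk)
    logrank_stat: float
    p_value: float
    threshold: float
    group_sizes: dict[str, int]
    median_survival: dict[str, float]
    low_information: bool  # a group had zero events


def km_logrank(
    cohort: pd.DataFrame,
    scores: pd.Series | None = None,
    *,
    split_quantile: float = 0.5,
    expr_columns: list[str] | None = None,
) -> KMResult:
    """Kaplan-Meier curves and log-rank test for a score-split cohort.

    ``cohort`` needs ``time`` and ``event`` columns; ``scores`` defaults to
    the average z-score over ``expr_columns`` (every column except
    patient_id/time/event when unspecified).
    """
    if scores is None:
        if expr_columns is None:
            expr_columns = [
                c for c in cohort.columns if c not in ("patient_id", "time", "event")
            ]
        scores = zscore_average(cohort[expr_columns])
    groups = split_by_score(scores, split_quantile)
    threshold = float(scores.quantile(split_quantile))
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise ValueError("score split left one group empty")

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    low_info = False
    for name in ("low", "high"):
        mask = (groups == name).to_numpy()
        t = cohort.loc[mask, "time"]
        e = cohort.loc[mask, "event"]
        if e.sum() == 0:
            low_info = True
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=name)
        step = kmf.survival_function_.reset_index()
        step.columns = ["time", "survival"]
        step["at_risk"] = (
            kmf.event_table["at_risk"].reindex(step["time"]).to_numpy()
        )
        curves[name] = step
        medians[name] = float(kmf.median_survival_time_)

    lo = groups == "low"
    res = logrank_test(
        cohort.loc[lo.to_numpy(), "time"],
        cohort.loc[(~lo).to_numpy(), "time"],
        event_observed_A=cohort.loc[lo.to_numpy(), "event"],
        event_observed_B=cohort.loc[(~lo).to_numpy(), "event"],
    )
    return KMResult(
        curves=curves,
        logrank_stat=float(res.test_statistic),
        p_value=float(res.p_value),
        threshold=threshold,
        group_sizes={"low": int(lo.sum()), "high": int((~lo).sum())},
        median_survival=medians,
        low_information=low_info,
    )


def pearson_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p (t transform) between columns."""
    if len(expr) < 3:
        raise ExpressionError("need at least three patients for correlation")
    if (expr.std(ddof=1) == 0).any():
        bad = list(expr.columns[expr.std(ddof=1) == 0])
        raise ExpressionError(f"zero-variance expression column(s): {bad}")
    cols = list(expr.columns)
    m = len(cols)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            rr, pp = stats.pearsonr(expr[cols[i]], expr[cols[j]])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
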