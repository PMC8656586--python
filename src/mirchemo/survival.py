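"""Expression-dichotomized Kaplan-Meier survival analysis with log-rank tests.

Patients are split into low/high expressors of a target gene using a z-score
cutoff (strictly below the cutoff counts as "low"; defaults -0.82 SD for
disease-free and -0.75 SD for disease-specific survival), Kaplan-Meier curves
are estimated per group, and group differences are assessed with the standard
unweighted log-rank test (1 df).  Cohorts can additionally be split into
treatment (chemotherapy yes/no) or receptor-status (ER+/-, HER2+/-) subgroups
with the dichotomization and test run independently per subgroup.

Product-limit estimation and the log-rank statistic are delegated to
lifelines behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.base import BaseEstimator

__all__ = [
    "DEFAULT_CUTOFFS",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "subgroup_analysis",
    "LogRankResult",
    "ExpressionSurvivalAnalysis",
]

# endpoint -> z-score cutoff defining "low" expression (strictly below)
DEFAULT_CUTOFFS = {"DFS": -0.82, "DSS": -0.75}

COHORT_COLUMNS = ("patient_id", "time_months", "event", "expression_z")


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_groups: tuple[int, int]
    events: tuple[int, int]
    degenerate: bool = False


def dichotomize(cohort: pd.DataFrame, cutoff_sd: float = -0.82,
                z_column: str = "expression_z") -> pd.DataFrame:
    """Label each patient low/high by expression z-score (low iff z < cutoff).

    Records with missing z are excluded; the number excluded is recorded in
    ``result.attrs['n_excluded']`` alongside the group counts.
    """
    out = cohort.copy()
    missing = out[z_column].isna()
    out = out[~missing].copy()
    out["expression_group"] = np.where(out[z_column] < cutoff_sd, "low", "high")
    out.attrs["n_excluded"] = int(missing.sum())
    out.attrs["n_low"] = int((out["expression_group"] == "low").sum())
    out.attrs["n_high"] = int((out["expression_group"] == "high").sum())
    return out


def km_estimate(time_months, event) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns a frame with event times, at-risk counts, observed events and the
    survival estimate; ties between events and censorings at the same time are
    resolved events-first (the standard convention).
    """
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(event, dtype=bool)
    if len(t) == 0:
        raise ValueError("need at least one record")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time_months": tbl.index.values,
            "at_risk": tbl["at_risk"].values,
            "events": tbl["observed"].values,
            "censored": tbl["censored"].values,
            "survival": surv.reindex(tbl.index).values,
        }
    )
    return out


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Unweighted log-rank test (1 df) between two cohort groups.

    Each frame needs ``time_months`` and ``event``.  If neither group has any
    events, the result is degenerate (statistic 0, p 1, flagged).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ev = (int(group_a["event"].sum()), int(group_b["event"].sum()))
    if sum(ev) == 0:
        return LogRankResult(0.0, 1.0, (len(group_a), len(group_b)), ev, degenerate=True)
    res = _ll_logrank(
        group_a["time_months"], group_b["time_months"],
        event_observed_A=group_a["event"].astype(bool),
        event_observed_B=group_b["event"].astype(bool),
    )
    return LogRankResult(
        float(res.test_statistic), float(res.p_value),
        (len(group_a), len(group_b)), ev,
    )


_SPLITS = {
    "chemo": ("chemo_treated", {True: "chemo", False: "no_chemo"}),
    "er": ("er_status", {"positive": "ER_positive", "negative": "ER_negative"}),
    "her2": ("her2_status", {"positive": "HER2_positive", "negative": "HER2_negative"}),
}


def subgroup_analysis(
    cohort: pd.DataFrame,
    split: str,
    cutoff_sd: float = -0.82,
    rescale_within_subgroup: bool = False,
) -> dict[str, LogRankResult]:
    """Dichotomized log-rank run independently within each subgroup of a split.

    ``split`` is one of ``chemo``, ``er``, ``her2``.  Records whose split
    annotation is unknown/missing are excluded and counted in the returned
    mapping's ``attrs``-style entry ``'_excluded'`` (an int).  Empty subgroups,
    or subgroups where one expression group is empty, are reported as None.
    """
    if split not in _SPLITS:
        raise ValueError(f"split must be one of {sorted(_SPLITS)}")
    col, labels = _SPLITS[split]
    results: dict[str, LogRankResult | None] = {}
    known = cohort[col].isin(labels.keys())
    results["_excluded"] = int((~known).sum())
    for value, name in labels.items():
        sub = cohort[cohort[col] == value].copy()
        if sub.empty:
            results[name] = None
            continue
        if rescale_within_subgroup:
            z = sub["expression_z"]
            sub["expression_z"] = (z - z.mean()) / z.std(ddof=0)
        labelled = dichotomize(sub, cutoff_sd)
        low = labelled[labelled["expression_group"] == "low"]
        high = labelled[labelled["expression_group"] == "high"]
        if len(low) == 0 or len(high) == 0:
            results[name] = None
            continue
        results[name] = logrank_test(low, high)
    return results


class ExpressionSurvivalAnalysis(BaseEstimator):
    """Expression-dichotomized survival fitter (METABRIC-style cohort tables).

    Parameters
    ----------
    cutoff_sd : float, default -0.82
        z-score cutoff below which expression is "low".
    endpoint : str, default "DFS"
        Label recorded in outputs; the event indicator supplied in the cohort
        determines the endpoint, the module is endpoint-agnostic.
    rescale_within_subgroup : bool, default False
        If True, re-standardize z within each subgroup before dichotomizing.

    Attributes
    ----------
    cohort_ : labelled cohort (expression_group column added).
    km_low_, km_high_ : Kaplan-Meier curve frames per expression group.
    logrank_ : LogRankResult for low vs high on the full cohort.
    """

    def __init__(self, cutoff_sd: float = -0.82, endpoint: str = "DFS",
                 rescale_within_subgroup: bool = False):
        self.cutoff_sd = cutoff_sd
        self.endpoint = endpoint
        self.rescale_within_subgroup = rescale_within_subgroup

    def fit(self, X: pd.DataFrame, y=None):
        if missing := set(COHORT_COLUMNS) - set(X.columns):
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        self.cohort_ = dichotomize(X, self.cutoff_sd)
        low = self.cohort_[self.cohort_["expression_group"] == "low"]
        high = self.cohort_[self.cohort_["expression_group"] == "high"]
        self.km_low_ = km_estimate(low["time_months"], low["event"]) if len(low) else None
        self.km_high_ = km_estimate(high["time_months"], high["event"]) if len(high) else None
        self.logrank_ = (
            logrank_test(low, high) if len(low) and len(high) else None
        )
        return self

    def subgroups(self, split: str) -> dict[str, LogRankResult]:
        if not hasattr(self, "cohort_"):
            raise ValueError("estimator is not fitted")
        return subgroup_analysis(
            self.cohort_, split, self.cutoff_sd, self.rescale_within_subgroup
        )
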