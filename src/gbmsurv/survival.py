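"""Kaplan-Meier curves, log-rank comparison, and cohort group tests.

The reporting layer: once the classifier assigns each subject a predicted
survival class, the product-limit estimator gives each predicted group's
survival curve and the k-group log-rank test asks whether the predicted
groups actually separate in survival.  Cohort characteristics are compared
across the three true survival groups with Chi-squared tests (categorical
variables, no continuity correction) and Kruskal-Wallis tests (continuous
variables); p-values are reported unadjusted with a Benjamini-Hochberg
column alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateDataError


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "group"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"survival table missing columns: {sorted(missing)}")
    if (table["time"] <= 0).any():
        raise DataError("survival times must be positive")
    return table


def km_estimate(table: pd.DataFrame) -> dict[str, KMCurve]:
    """Product-limit survival estimate per group.

    ``table`` needs columns time (months), event (1 = death observed) and
    group.  At each distinct event time t_i with d_i events among n_i
    subjects still at risk, the curve drops by the factor (1 - d_i/n_i);
    censored subjects leave the risk set without a drop.
    """
    table = _check_table(table)
    curves = {}
    for group, sub in table.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        times = sf.index.to_numpy(float)
        surv = sf.iloc[:, 0].to_numpy(float)
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
        curves[str(group)] = KMCurve(group=str(group), times=times,
                                     survival=surv, at_risk=at_risk)
    return curves


def logrank_test(table: pd.DataFrame) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p)."""
    table = _check_table(table)
    groups = table["group"].unique()
    if len(groups) < 2:
        raise DegenerateDataError("log-rank comparison needs at least 2 groups")
    if int(table["event"].sum()) == 0:
        raise DegenerateDataError("log-rank comparison needs at least one event")
    res = multivariate_logrank_test(table["time"], table["group"], table["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def km_table(curves: Mapping[str, KMCurve]) -> pd.DataFrame:
    rows = []
    for curve in curves.values():
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
            rows.append({"group": curve.group, "time": t, "survival": s, "at_risk": r})
    return pd.DataFrame(rows)


def group_tests(
    cohort: pd.DataFrame,
    categorical: Sequence[str] = ("sex",),
    continuous: Sequence[str] = ("age",),
    group_col: str = "survival_class",
) -> pd.DataFrame:
    """Compare cohort characteristics across survival groups.

    Categorical variables get a Chi-squared test on the variable-by-group
    contingency table; continuous variables get a Kruskal-Wallis test.
    Returns one row per variable with statistic, df, p and BH-adjusted p.
    """
    rows = []
    for var in categorical:
        tab = pd.crosstab(cohort[var], cohort[group_col])
        if tab.to_numpy().sum() == 0:
            raise DegenerateDataError(f"{var}: empty contingency table")
        if tab.shape[0] < 2:
            # single observed level: no deviation from expectation possible
            rows.append({"variable": var, "test": "chi2", "statistic": 0.0,
                         "df": 0, "p": 1.0})
            continue
        chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "df": int(dof), "p": float(p)})
    for var in continuous:
        samples = [g[var].to_numpy(float) for _, g in cohort.groupby(group_col)]
        if len(samples) < 2:
            raise DegenerateDataError(f"{var}: need at least two groups")
        if np.ptp(np.concatenate(samples)) == 0:
            h, p = 0.0, 1.0  # scipy refuses all-identical values
        else:
            h, p = stats.kruskal(*samples)
        rows.append({"variable": var, "test": "kruskal", "statistic": float(h),
                     "df": len(samples) - 1, "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def plot_km(curves: Mapping[str, KMCurve], path: str) -> None:
    """Step plot of the per-group survival curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in curves.items():
        ax.step(np.concatenate([[0.0], c.times]),
                np.concatenate([[1.0], c.survival]),
                where="post", label=name)
    ax.set_xlabel("months since first MRI")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="predicted class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
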