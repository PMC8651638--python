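"""Survival and categorical association inference.

Kaplan-Meier product-limit curves with Greenwood variance, the log-rank test
across subgroups, Cox proportional-hazards regression with Efron tie handling
(lifelines backend, matching R survival's default), the continuity-corrected
two-sample proportion test (R ``prop.test`` convention) and Fisher's exact
test for 2x2 tables.

Times are stored in days; the time origin (sampling vs diagnosis) is an
explicit attribute because subgroup survival is reported from sampling in the
discovery cohort and from diagnosis in the validation cohort.  Death and
transplant both count as events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "two_proportion_test",
    "fisher_exact_2x2",
]


@dataclass
class SurvivalData:
    """Per-sample follow-up records.

    ``data`` columns: ``time`` (days, > 0), ``event`` (1 = death/transplant,
    0 = censored), ``group``, plus any covariate columns.
    """

    data: pd.DataFrame
    time_origin: str = "sampling"  # or "diagnosis"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival data missing column {col!r}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event flag must be 0/1")

    def for_group(self, group) -> pd.DataFrame:
        if "group" not in self.data.columns:
            raise ValueError("no group column")
        return self.data[self.data["group"] == group]


@dataclass
class KMCurve:
    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    group: object = None

    def at(self, t: float) -> float:
        """S(t): step-function value at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: coef, hr, se, ci_lower, ci_upper, p
    ties: str = "efron"
    converged: bool = True
    warnings: list = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def km_estimate(d: SurvivalData, group=None) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i) with
    Greenwood standard errors, restricted to one group if given."""
    df = d.for_group(group) if group is not None else d.data
    if df.empty:
        raise ValueError(f"group {group!r} is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    # keep only rows where the estimate can change (event times), drop t=0
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy()
    # Greenwood SE from lifelines' variance calculation
    ci = kmf.survival_function_.loc[ev.index]
    var = (kmf._cumulative_sq_.loc[ev.index].to_numpy().ravel()) * surv**2
    se = np.sqrt(var)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    return KMCurve(event_times=times, at_risk=at_risk, survival=surv, greenwood_se=se, group=group)


def logrank_test(d: SurvivalData, groups=None) -> tuple[float, float]:
    """Chi-square log-rank test (g-1 df) across subgroups; returns (statistic, p)."""
    df = d.data if groups is None else d.data[d.data["group"].isin(groups)]
    labels = df["group"]
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("empty group in log-rank test")
    res = multivariate_logrank_test(df["time"], labels, df["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(d: SurvivalData, covariates: list[str], ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit by partial likelihood (Efron ties default)."""
    df = d.data[["time", "event", *covariates]].copy()
    const = [c for c in covariates if df[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    n_events = int(df["event"].sum())
    if n_events < len(covariates) + 1:
        raise ValueError("too few events for the number of covariates")
    cph = CoxPHFitter()
    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
        msgs = [str(c.message) for c in caught]
    sep = [m for m in msgs if "convergence" in m.lower() or "complete separation" in m.lower()]
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "se": s["se(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxResult(summary=out, ties=ties, converged=not sep, warnings=sep)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sample test for equality of proportions with Yates continuity
    correction (R prop.test convention); returns (chi-square statistic, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts outside [0, n]")
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if col[0] in (0, total):  # identical degenerate proportions
        return 0.0, 1.0
    expected = np.outer(row, col) / total
    correction = min(0.5, np.abs(obs - expected).min())
    chi2 = (((np.abs(obs - expected) - correction) ** 2) / expected).sum()
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration:
    sum of probabilities of tables at most as likely as the observed one)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table must hold non-negative integers")
        t = t.astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)
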