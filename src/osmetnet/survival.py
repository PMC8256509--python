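"""Median-split Kaplan-Meier screening of candidate prognostic genes.

For each gene, samples are split at the median expression (ties to the low
group), the product-limit survival curves of the high and low groups are
compared with the two-group log-rank test, and genes with p < alpha are
called prognostic. Direction is defined by restricted mean survival over
the observed window: "positive" means the high-expression group survives
longer (expression positively associated with overall survival).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "median_split",
    "km_curve",
    "logrank_test",
    "restricted_mean_survival",
    "screen_prognostic",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray  # n_i at each event time
    events: np.ndarray  # d_i at each event time
    survival: np.ndarray  # S(t_i) = prod_{j<=i} (1 - d_j/n_j)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation: S carried forward between event times."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p: float
    observed: tuple[float, float]  # event totals (group 0, group 1)
    expected: tuple[float, float]


def median_split(values: pd.Series | np.ndarray) -> np.ndarray:
    """Label each sample ``high`` (value > median) or ``low`` (<= median)."""
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("median split needs >=4 samples")
    median = np.median(values)
    labels = np.where(values > median, "high", "low")
    if len(set(labels)) < 2:
        raise ValueError("degenerate split: all values on one side of the median")
    return labels


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator from right-censored data."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty survival table")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event flags must be 0 (censored) or 1 (death)")
    event_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in event_times], float)
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times], float)
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=event_times, at_risk=at_risk, events=d, survival=survival)


def logrank_test(
    time: np.ndarray, event: np.ndarray, labels: np.ndarray
) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time, the expected events per group come from the
    at-risk proportions and the variance from the hypergeometric draw of
    d events among n at risk; the squared standardized difference is a
    chi-square statistic on one degree of freedom.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.asarray(labels)
    group_names = np.unique(labels)
    if group_names.size != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {group_names.tolist()}")
    in_g1 = labels == group_names[1]

    o1 = e1 = var = 0.0
    obs = [float(event[~in_g1].sum()), float(event[in_g1].sum())]
    exp = [0.0, 0.0]
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & in_g1).sum())
        d = float(((time == t) & (event == 1)).sum())
        d1 = float(((time == t) & (event == 1) & in_g1).sum())
        e = d * n1 / n
        o1 += d1
        e1 += e
        exp[1] += e
        exp[0] += d - e
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        statistic = 0.0
    else:
        statistic = (o1 - e1) ** 2 / var
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(statistic=float(statistic), p=p, observed=tuple(obs), expected=tuple(exp))


def restricted_mean_survival(curve: KMCurve, tau: float) -> float:
    """Area under the KM step function from 0 to ``tau``."""
    grid = np.concatenate([[0.0], curve.times[curve.times < tau], [tau]])
    heights = np.concatenate([[1.0], curve.survival[curve.times < tau]])
    return float(np.sum(np.diff(grid) * heights))


def screen_prognostic(
    clinical: pd.DataFrame, genes: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Median-split log-rank screen over ``genes``.

    ``clinical`` holds columns ``sample``, ``time_months``, ``event`` plus
    one expression column per gene. Genes with log-rank p < alpha are
    retained; direction is positive when the high-expression group has the
    larger restricted mean survival over the observed window.
    """
    required = {"sample", "time_months", "event"}
    if not required <= set(clinical.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    time = clinical["time_months"].to_numpy(float)
    event = clinical["event"].to_numpy(int)
    tau = float(time.max())

    rows = []
    for gene in genes:
        if gene not in clinical.columns:
            warnings.warn(f"gene {gene!r} absent from the clinical table; skipped")
            continue
        try:
            labels = median_split(clinical[gene])
        except ValueError as exc:
            warnings.warn(f"gene {gene!r}: {exc}; skipped")
            continue
        result = logrank_test(time, event, labels)
        high = labels == "high"
        rmst_high = restricted_mean_survival(km_curve(time[high], event[high]), tau)
        rmst_low = restricted_mean_survival(km_curve(time[~high], event[~high]), tau)
        rows.append(
            {
                "gene": gene,
                "statistic": result.statistic,
                "p": result.p,
                "direction": "positive" if rmst_high > rmst_low else "negative",
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "statistic", "p", "direction"])
    table = table[table["p"] < alpha]
    return table.sort_values("p").reset_index(drop=True)
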