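"""Two-group differential expression with empirical-Bayes variance moderation.

Each gene is fit by ordinary least squares on the two-group design (the
log2 fold change is the difference of group means and the residual variance
is the pooled within-group variance). Per-gene variances are then shrunk
toward a common prior estimated by moment matching on the log variances
(Smyth's hierarchical model: s2_g | sigma2_g ~ sigma2_g * chi2_{d_g}/d_g,
1/sigma2_g ~ chi2_{d0}/(d0 * s2_0)), giving moderated t-statistics on
d0 + d_g degrees of freedom. Multiple testing is controlled by the
Benjamini-Hochberg step-up procedure.

Also provides the 2^-ddCt relative-quantification formula used for qPCR
validation of candidate genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneFit",
    "ModeratedStats",
    "collapse_probes",
    "fit_gene_models",
    "moderate_statistics",
    "adjust_bh",
    "call_degs",
    "ddct_relative_expression",
]

#: variance floor applied before moderation so that noiseless (simulated)
#: genes keep finite log-variances in the moment equations
VARIANCE_FLOOR = np.finfo(float).eps


@dataclass(frozen=True)
class GeneFit:
    """Per-gene OLS results on the two-group design."""

    genes: pd.Index
    log2fc: np.ndarray  # case mean - control mean, log2 scale
    s2: np.ndarray  # pooled residual variance
    df_residual: int  # n_case + n_control - 2
    stdev_unscaled: float  # sqrt(1/n_case + 1/n_control)


@dataclass(frozen=True)
class ModeratedStats:
    """Empirical-Bayes moderated statistics for every gene."""

    genes: pd.Index
    log2fc: np.ndarray
    s2: np.ndarray
    s2_post: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    d0: float
    s2_0: float
    df_residual: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "log2FC": self.log2fc,
                "s2": self.s2,
                "s2_post": self.s2_post,
                "t": self.t,
                "p": self.p,
                "q": self.q,
            }
        )


def collapse_probes(probe_table: pd.DataFrame, symbol_col: str = "gene") -> pd.DataFrame:
    """Collapse a probe-by-sample table to one row per gene symbol.

    Genes matched by multiple probes are replaced by the per-sample
    arithmetic mean of their probes; probes without a symbol are dropped.
    """
    if probe_table.empty:
        raise ValueError("probe table is empty")
    if symbol_col not in probe_table.columns:
        raise ValueError(f"probe table lacks symbol column {symbol_col!r}")
    tab = probe_table.copy()
    tab[symbol_col] = tab[symbol_col].astype("string")
    tab = tab[tab[symbol_col].notna() & (tab[symbol_col].str.strip() != "")]
    if tab.empty:
        raise ValueError("no probes with a gene symbol remain")
    collapsed = tab.groupby(symbol_col, sort=True).mean(numeric_only=True)
    collapsed.index.name = "gene"
    return collapsed


def _split_groups(expr: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        missing = expr.columns[groups.isna()].tolist()
        raise ValueError(f"samples without a group label: {missing}")
    case = expr.loc[:, (groups == "case").to_numpy()].to_numpy(float)
    control = expr.loc[:, (groups == "control").to_numpy()].to_numpy(float)
    return case, control


def fit_gene_models(expr: pd.DataFrame, groups: pd.Series) -> GeneFit:
    """Fit the two-group linear model to every gene.

    Equivalent to per-gene OLS of expression on a group indicator:
    log2FC is the case-minus-control mean difference, s2 the pooled
    residual variance on ``n_case + n_control - 2`` degrees of freedom.
    """
    case, control = _split_groups(expr, groups)
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (case={n1}, control={n2})")
    if not np.isfinite(case).all() or not np.isfinite(control).all():
        raise ValueError("expression matrix contains non-finite values")
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    rss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return GeneFit(
        genes=expr.index,
        log2fc=log2fc,
        s2=rss / df,
        df_residual=df,
        stdev_unscaled=float(np.sqrt(1.0 / n1 + 1.0 / n2)),
    )


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing convexity of trigamma; the iteration
    x <- x + (1 - trigamma(x)/y) / psi'' -style update converges from the
    asymptotic start x0 = 0.5 + 1/y.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 for small x
        return 1.0 / np.sqrt(y)
    if y < 1e-6:  # trigamma(x) ~ 1/x for large x
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df_residual: int) -> tuple[float, float]:
    """Estimate (d0, s2_0) by moment matching on log sample variances.

    Writes e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2); under the
    hierarchical model E[e_g] = log(s2_0) - digamma(d0/2) + log(d0/2) and
    Var[e_g] = trigamma(d0/2) + trigamma(d_g/2). d0 = inf (no excess
    dispersion of the variances) is returned when the moment estimate of
    trigamma(d0/2) is non-positive.
    """
    s2 = np.maximum(np.asarray(s2, float), VARIANCE_FLOOR)
    n = s2.size
    if n < 2:
        raise ValueError("need >=2 genes to estimate the variance prior")
    if np.allclose(s2, VARIANCE_FLOOR):
        raise ValueError("all residual variances are zero; moderation is degenerate")
    dg = df_residual
    e = np.log(s2) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    e_bar = e.mean()
    # unbiased moment estimate of trigamma(d0/2)
    target = ((e - e_bar) ** 2).sum() / (n - 1) - special.polygamma(1, dg / 2.0)
    if target <= 0:
        # no excess dispersion: variances consistent with one common value
        d0 = np.inf
        s2_0 = float(s2.mean())
    else:
        d0 = 2.0 * _trigamma_inverse(float(target))
        s2_0 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s2_0


def moderate_statistics(fit: GeneFit) -> ModeratedStats:
    """Shrink per-gene variances toward the estimated prior and test.

    The posterior variance is the prior-weighted average
    ``(d0*s2_0 + d_g*s2_g) / (d0 + d_g)``; the moderated t replaces s2_g in
    the ordinary t denominator and is referred to a t distribution on
    ``d0 + d_g`` degrees of freedom (normal when d0 is infinite).
    """
    s2 = np.maximum(fit.s2, VARIANCE_FLOOR)
    d0, s2_0 = estimate_prior(s2, fit.df_residual)
    dg = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(s2, s2_0)
    else:
        s2_post = (d0 * s2_0 + dg * s2) / (d0 + dg)
    # total df capped at the pooled residual df across genes; the cap keeps
    # the reference distribution finite when the prior df is infinite
    df_total = min(d0 + dg, len(s2) * dg)
    t = fit.log2fc / (np.sqrt(s2_post) * fit.stdev_unscaled)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedStats(
        genes=fit.genes,
        log2fc=fit.log2fc,
        s2=fit.s2,
        s2_post=s2_post,
        t=t,
        p=p,
        q=adjust_bh(p),
        d0=d0,
        s2_0=s2_0,
        df_residual=dg,
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    statistics: ModeratedStats, lfc_threshold: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Call differentially expressed genes at q < alpha and |log2FC| > lfc.

    Both inequalities are strict. Returns gene, log2FC, t, p, q and an
    up/down direction column, sorted by q then p.
    """
    frame = statistics.as_frame()
    kept = frame[(frame["q"] < alpha) & (frame["log2FC"].abs() > lfc_threshold)].copy()
    kept["direction"] = np.where(kept["log2FC"] > 0, "up", "down")
    return kept.sort_values(["q", "p"]).reset_index(drop=True)


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator; the fold change is 2 to the minus ddCt.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
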