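"""Marker screening: moderated t-test, fold change, hierarchical clustering.

With a handful of subjects per group, per-assay variance estimates are
noisy. The random-variance model pools them: assay precisions 1/sigma^2 are
taken as Gamma(a, scale b), under which the observed residual variance
satisfies s^2 * a * b ~ F(df, 2a). Fitting (a, b) by maximum likelihood
across the panel gives each assay the shrunken variance

    s~^2 = (df * s^2 + 2/b) / (df + 2a)

and a t statistic with df + 2a degrees of freedom — the small-sample
moderation used by BRB-ArrayTools-style screens. With no hyperparameters
the test reduces exactly to the classical pooled two-sample t.

Markers are called significant at raw p < 0.05 with signed fold change
|FC| >= 1.5 (no multiple-testing correction in the selection, matching the
screening design; BH q-values are reported for information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RvmHyper:
    """Fitted inverse-gamma variance-prior hyperparameters (a shape, b scale)."""

    a: float
    b: float
    log_likelihood: float
    converged: bool

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("hyperparameters must be finite")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("hyperparameters must be positive")


def _rvm_negloglik(log_ab: np.ndarray, variances: np.ndarray, dfs: np.ndarray) -> float:
    a, b = np.exp(log_ab)
    # s^2 * a * b ~ F(df, 2a); change of variables adds log(a*b)
    ll = np.log(a * b) + stats.f.logpdf(a * b * variances, dfs, 2.0 * a)
    if not np.isfinite(ll).all():
        return np.inf
    return -float(ll.sum())


def fit_rvm_hyperparams(variances, dfs) -> RvmHyper:
    """Maximum-likelihood fit of the variance prior across assays.

    *variances* are per-assay pooled residual variances with *dfs* degrees
    of freedom (scalar or per-assay). Needs >= 10 assays with df >= 1 and
    not-all-zero variances.
    """
    variances = np.asarray(variances, dtype=float)
    dfs = np.broadcast_to(np.asarray(dfs, dtype=float), variances.shape).copy()
    ok = dfs >= 1
    if ok.sum() < 10:
        raise ValueError("need >= 10 assays with df >= 1 to fit the variance prior")
    variances, dfs = variances[ok], dfs[ok]
    if np.all(variances == 0):
        raise ValueError("all residual variances are zero; prior is degenerate")
    # F densities at 0 are fine for df >= 3 but -inf otherwise; nudge zeros
    tiny = np.finfo(float).tiny
    variances = np.maximum(variances, tiny)

    mean_var = float(np.mean(variances))
    best = None
    for a0 in (1.0, 2.0, 4.0, 8.0):
        # start b so the prior precision mean 1/(a*b) matches the mean variance
        x0 = np.log([a0, 1.0 / (a0 * mean_var)])
        res = optimize.minimize(
            _rvm_negloglik, x0, args=(variances, dfs), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    return RvmHyper(a=float(a), b=float(b), log_likelihood=-float(best.fun),
                    converged=bool(best.success))


def _group_stats(expr: pd.DataFrame, labels: np.ndarray):
    x1 = expr.loc[:, labels].to_numpy(dtype=float)
    x0 = expr.loc[:, ~labels].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need >= 2 samples")
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    return m1, m0, ss / df, df, n1, n0


def pooled_variances(expr: pd.DataFrame, labels) -> tuple[np.ndarray, int]:
    """Per-assay pooled two-group variance and its degrees of freedom."""
    labels = np.asarray(labels, dtype=bool)
    _, _, s2, df, _, _ = _group_stats(expr, labels)
    return s2, df


def signed_fold_change(delta_log2: np.ndarray) -> np.ndarray:
    """Signed linear fold change from a log2 difference (|FC| >= 1)."""
    return np.where(delta_log2 >= 0, np.exp2(delta_log2), -np.exp2(-delta_log2))


def fold_change(expr: pd.DataFrame, labels) -> pd.Series:
    """Per-assay signed fold change, cancer vs non-cancer."""
    labels = np.asarray(labels, dtype=bool)
    m1, m0, *_ = _group_stats(expr, labels)
    return pd.Series(signed_fold_change(m1 - m0), index=expr.index, name="fc")


def rvm_t_test(
    expr: pd.DataFrame,
    labels,
    hyper: RvmHyper | None = None,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Moderated (or classical, if ``hyper is None``) two-sample t per assay.

    *labels* are boolean cancer flags aligned to ``expr`` columns. Returns
    the marker table with columns (mean_cancer, mean_noncancer, delta_log2,
    fc, t, df, p, bh_q, direction, significant).
    """
    labels = np.asarray(labels, dtype=bool)
    m1, m0, s2, df, n1, n0 = _group_stats(expr, labels)
    if hyper is None:
        var, dof = s2, float(df)
    else:
        var = (df * s2 + 2.0 / hyper.b) / (df + 2.0 * hyper.a)
        dof = df + 2.0 * hyper.a
    delta = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(var * (1.0 / n1 + 1.0 / n0))
    t = np.where(np.isfinite(t), t, 0.0)  # zero-variance, zero-difference assays
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    fc = signed_fold_change(delta)
    table = pd.DataFrame(
        {
            "mean_cancer": m1,
            "mean_noncancer": m0,
            "delta_log2": delta,
            "fc": fc,
            "t": t,
            "df": dof,
            "p": p,
            "bh_q": multipletests(p, method="fdr_bh")[1],
            "direction": np.where(delta >= 0, "up", "down"),
        },
        index=expr.index,
    )
    table["significant"] = (table["p"] < p_max) & (table["fc"].abs() >= fc_min)
    return table


def select_markers(
    table: pd.DataFrame,
    p_max: float = 0.05,
    fc_min: float = 1.5,
    direction: str | None = "up",
) -> list[str]:
    """Assays passing the p / fold-change filter, optionally one-directional."""
    keep = (table["p"] < p_max) & (table["fc"].abs() >= fc_min)
    if direction == "up":
        keep &= table["fc"] > 0
    elif direction == "down":
        keep &= table["fc"] < 0
    elif direction is not None:
        raise ValueError(f"direction must be 'up', 'down' or None, got {direction!r}")
    return table.index[keep].tolist()


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix
    order: list[str]             # dendrogram leaf order
    labels: list[str]


def _correlation_cluster(values: np.ndarray, names: list[str]) -> ClusterResult:
    sd = values.std(axis=1, ddof=1)
    dead = [names[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance item(s), correlation undefined: {dead}")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    order = hierarchy.leaves_list(link)
    return ClusterResult(linkage=link, order=[names[i] for i in order], labels=names)


def hierarchical_cluster(expr: pd.DataFrame) -> tuple[ClusterResult, ClusterResult]:
    """Complete-linkage clustering with 1 - Pearson correlation distance.

    Returns ``(assay_clusters, sample_clusters)`` — the two orderings used
    to lay out expression heatmaps.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need >= 2 assays and >= 2 samples")
    values = expr.to_numpy(dtype=float)
    return (
        _correlation_cluster(values, expr.index.tolist()),
        _correlation_cluster(values.T, expr.columns.tolist()),
    )
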