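"""geNorm-style endogenous-control selection.

Given linear-scale relative quantities for a set of candidate reference
miRNAs, the gene-stability measure of candidate *j* is

    M_j = mean over partners k != j of  sd_samples( log2(q_j / q_k) )

— low M means the candidate keeps a constant ratio to the rest of the
panel. The least stable candidate (highest M) is excluded and M recomputed,
down to a final pair. The pairwise variation V(n/n+1) is the sd across
samples of log2(NF_n / NF_{n+1}) where NF_n is the geometric mean of the n
most stable candidates; it measures how much adding the (n+1)-th reference
changes the normalization factor (geNorm's published cut-off 0.15 is
reported, not enforced).

Candidates are pre-filtered to abundant, fully detected assays
(mean Cq < 20 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def prefilter_candidates(matrix: pd.DataFrame, mean_cq_max: float = 20.0) -> list[str]:
    """Assays fully detected with arithmetic mean Cq strictly below the cap."""
    detected = matrix.notna().all(axis=1)
    abundant = matrix.mean(axis=1) < mean_cq_max
    return matrix.index[detected & abundant].tolist()


def _check_quantities(expr: pd.DataFrame, min_candidates: int = 3) -> np.ndarray:
    if expr.shape[0] < min_candidates:
        raise ValueError(f"need >= {min_candidates} candidates, got {expr.shape[0]}")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    q = expr.to_numpy(dtype=float)
    if not np.isfinite(q).all() or (q <= 0).any():
        raise ValueError("quantities must be finite and strictly positive")
    return q


def genorm_m(expr: pd.DataFrame) -> pd.Series:
    """Stability measure M per candidate (rows = candidates, linear scale)."""
    q = _check_quantities(expr)
    logq = np.log2(q)
    n = logq.shape[0]
    m = np.empty(n)
    for j in range(n):
        ratios = logq[j] - logq            # (n, samples) log ratios vs every partner
        sds = ratios.std(axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return pd.Series(m, index=expr.index, name="M")


@dataclass
class StabilityRanking:
    """Result of the serial-exclusion stability analysis."""

    candidates: list[str]
    exclusion_order: list[str]              # least stable first
    final_pair: tuple[str, str]
    final_pair_m: float                     # average M of the pair at the last round
    m_by_round: list[pd.Series] = field(default_factory=list)
    v_series: dict[int, float] = field(default_factory=dict)  # n -> V(n/n+1)
    #: most-stable-first ordering (final pair first, then reverse exclusions)
    stability_order: list[str] = field(default_factory=list)


def genorm_rank(expr: pd.DataFrame) -> StabilityRanking:
    """Serial exclusion of the least stable candidate down to a pair.

    Ties in M break by assay-name lexicographic order (alphabetically first
    excluded), so the procedure is deterministic. Also computes the
    pairwise-variation series V(n/n+1) for n = 2..(candidates - 1).
    """
    q = _check_quantities(expr)
    del q  # validation only; work on the DataFrame

    remaining = expr.copy()
    exclusion: list[str] = []
    rounds: list[pd.Series] = []
    while remaining.shape[0] > 2:
        m = genorm_m(remaining)
        rounds.append(m)
        worst = m[m == m.max()].index.min()  # lexicographic tie-break
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)

    # M of the final pair: each member's M is the sd of their log ratio
    logpair = np.log2(remaining.to_numpy(dtype=float))
    pair_sd = float((logpair[0] - logpair[1]).std(ddof=1))
    pair = tuple(sorted(remaining.index.tolist()))
    rounds.append(pd.Series([pair_sd, pair_sd], index=list(remaining.index), name="M"))

    stability_order = list(pair) + exclusion[::-1]

    # pairwise variation V(n/n+1) over the most-stable-first ordering
    logq_ordered = np.log2(expr.loc[stability_order].to_numpy(dtype=float))
    v_series: dict[int, float] = {}
    for n in range(2, expr.shape[0]):
        nf_n = logq_ordered[:n].mean(axis=0)        # log2 geometric mean
        nf_n1 = logq_ordered[: n + 1].mean(axis=0)
        v_series[n] = float((nf_n - nf_n1).std(ddof=1))

    return StabilityRanking(
        candidates=expr.index.tolist(),
        exclusion_order=exclusion,
        final_pair=pair,  # type: ignore[arg-type]
        final_pair_m=pair_sd,
        m_by_round=rounds,
        v_series=v_series,
        stability_order=stability_order,
    )


def quantities_from_log2(expr_log2: pd.DataFrame) -> pd.DataFrame:
    """Linear relative quantities from a log2 expression matrix."""
    return np.exp2(expr_log2)
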