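"""Brute-force reference implementations used only to check the package.

Each oracle is written as plain loops over the defining formulas, kept
deliberately independent of the vectorized implementations it validates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def livak_oracle(cq: pd.DataFrame, retained, control_samples) -> pd.DataFrame:
    """-ddCt by explicit per-cell loops (undetected imputed at 40)."""
    retained = list(retained)
    filled = {a: {s: (40.0 if pd.isna(cq.at[a, s]) else float(cq.at[a, s]))
                  for s in cq.columns} for a in retained}
    reference = {s: sum(filled[a][s] for a in retained) / len(retained)
                 for s in cq.columns}
    dct = {a: {s: filled[a][s] - reference[s] for s in cq.columns} for a in retained}
    calibrator = {a: sum(dct[a][s] for s in control_samples) / len(control_samples)
                  for a in retained}
    out = pd.DataFrame(index=retained, columns=cq.columns, dtype=float)
    for a in retained:
        for s in cq.columns:
            out.at[a, s] = -(dct[a][s] - calibrator[a])
    return out


def livak_endogenous_oracle(cq, targets, references, control_samples) -> pd.DataFrame:
    reference = {s: sum(float(cq.at[r, s]) for r in references) / len(references)
                 for s in cq.columns}
    dct = {a: {s: float(cq.at[a, s]) - reference[s] for s in cq.columns}
           for a in targets}
    calibrator = {a: sum(dct[a][s] for s in control_samples) / len(control_samples)
                  for a in targets}
    out = pd.DataFrame(index=list(targets), columns=cq.columns, dtype=float)
    for a in targets:
        for s in cq.columns:
            out.at[a, s] = -(dct[a][s] - calibrator[a])
    return out


def _sd(values) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def genorm_m_oracle(quantities: pd.DataFrame) -> dict[str, float]:
    """geNorm M by double loop over candidate pairs."""
    names = list(quantities.index)
    m = {}
    for j in names:
        vs = []
        for k in names:
            if k == j:
                continue
            ratios = [math.log2(quantities.at[j, s] / quantities.at[k, s])
                      for s in quantities.columns]
            vs.append(_sd(ratios))
        m[j] = sum(vs) / len(vs)
    return m


def genorm_rank_oracle(quantities: pd.DataFrame):
    """Serial exclusion recomputing M exhaustively at every round."""
    remaining = quantities.copy()
    exclusion = []
    while remaining.shape[0] > 2:
        m = genorm_m_oracle(remaining)
        worst_m = max(m.values())
        worst = min(name for name, v in m.items() if v == worst_m)
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    return exclusion, sorted(remaining.index)


def complete_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration on a distance matrix."""
    clusters = [{i} for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def auc_pair_oracle(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs correctly ordered."""
    scores = list(map(float, scores))
    labels = list(map(bool, labels))
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def accuracy_at_threshold(scores, labels, threshold) -> float:
    correct = sum((s > threshold) == l for s, l in zip(scores, labels))
    return correct / len(scores)
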