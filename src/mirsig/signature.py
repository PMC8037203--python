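"""Marker-combination classifiers and the published four-miRNA score.

The published plasma signature is a fixed linear score

    score = 1.037 * let-7e-5p + 0.9 * miR-106a-5p
          + 0.247 * miR-28-3p + 0.903 * miR-542-5p

applied to log2-normalized expression, with scale-specific decision
thresholds: 1.024 on array-card (TLDA) data, 2.442 on single TaqMan
assays, and — with all weights set to 1 — 19.14 on external RNA-seq-style
matrices. A sample is called cancer iff its score is strictly above the
threshold. The published models are immutable constants; new signatures
are trained by linear SVM with recursive feature elimination and
leave-one-out cross-validation (elimination re-run inside every fold so
the LOOCV estimate carries no selection bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SCALES = ("tlda", "single_assay", "external_equal_weight")

_PUBLISHED_MARKERS = ("hsa-let-7e-5p", "hsa-miR-106a-5p", "hsa-miR-28-3p", "hsa-miR-542-5p")
_PUBLISHED_WEIGHTS = (1.037, 0.9, 0.247, 0.903)
_PUBLISHED_THRESHOLDS = {"tlda": 1.024, "single_assay": 2.442,
                         "external_equal_weight": 19.14}


@dataclass(frozen=True)
class SignatureModel:
    """A linear marker score with a strict decision threshold (no intercept)."""

    markers: tuple[str, ...]
    weights: tuple[float, ...]
    threshold: float
    scale: str
    note: str = ""

    def __post_init__(self):
        if len(self.markers) != len(self.weights):
            raise ValueError("markers and weights must have equal length")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if not all(np.isfinite(w) for w in self.weights):
            raise ValueError("weights must be finite")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"markers": list(self.markers), "weights": list(self.weights),
             "threshold": self.threshold, "scale": self.scale, "note": self.note},
            indent=2))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(markers=tuple(d["markers"]), weights=tuple(d["weights"]),
                   threshold=float(d["threshold"]), scale=d["scale"],
                   note=d.get("note", ""))


def published_signature(scale: str) -> SignatureModel:
    """The four-miRNA diagnostic score at one of the three published scales."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    weights = (1.0,) * 4 if scale == "external_equal_weight" else _PUBLISHED_WEIGHTS
    return SignatureModel(
        markers=_PUBLISHED_MARKERS,
        weights=weights,
        threshold=_PUBLISHED_THRESHOLDS[scale],
        scale=scale,
        note="published four-miRNA plasma CRC signature",
    )


def _canonical(name: str) -> str:
    name = name.strip().lower()
    if name.startswith("hsa-"):
        name = name[4:]
    return name


def match_markers(assays, markers) -> dict[str, str]:
    """Map model marker names to assay row names (case/hsa- insensitive)."""
    lookup: dict[str, str] = {}
    for a in assays:
        lookup.setdefault(_canonical(a), a)
    mapping, missing = {}, []
    for m in markers:
        key = _canonical(m)
        if key in lookup:
            mapping[m] = lookup[key]
        else:
            missing.append(m)
    if missing:
        raise ValueError(f"markers not found in expression matrix: {missing}")
    return mapping


def score_samples(expr: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """Per-sample linear score sum_i w_i * expr(marker_i, sample)."""
    mapping = match_markers(expr.index, model.markers)
    rows = expr.loc[[mapping[m] for m in model.markers]].to_numpy(dtype=float)
    scores = np.asarray(model.weights, dtype=float) @ rows
    return pd.Series(scores, index=expr.columns, name="score")


def classify(scores, model: SignatureModel) -> pd.Series:
    """Cancer prediction per sample: score strictly above the threshold."""
    scores = pd.Series(scores, dtype=float)
    if len(scores) and not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    return (scores > model.threshold).rename("predicted_cancer")


def calibrate_threshold(scores, labels) -> float:
    """Cut-point maximizing overall accuracy for the rule ``score > t``.

    Candidates are midpoints between adjacent sorted unique scores, plus an
    all-positive and an all-negative cut. Ties in accuracy break toward
    higher specificity, then the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = [uniq.min() - 1.0, float(uniq.max())]
    candidates += ((uniq[:-1] + uniq[1:]) / 2.0).tolist()

    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    best = None
    for t in candidates:
        pred = scores > t
        acc = float((pred == labels).mean())
        spec = float((~pred[~labels]).sum()) / n_neg
        key = (acc, spec, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


@dataclass
class RfeResult:
    """Per-model-size selections and accuracies of the SVM-RFE search."""

    sizes: list[int]
    markers_by_size: dict[int, list[str]]
    apparent_accuracy: dict[int, float]
    loocv_accuracy: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "markers": [";".join(self.markers_by_size[k]) for k in self.sizes],
                "apparent_accuracy": [self.apparent_accuracy[k] for k in self.sizes],
                "loocv_accuracy": [self.loocv_accuracy[k] for k in self.sizes],
            }
        )


def _fit_svm(x: np.ndarray, y: np.ndarray, c: float) -> tuple[SVC, StandardScaler]:
    scaler = StandardScaler().fit(x)
    clf = SVC(kernel="linear", C=c).fit(scaler.transform(x), y)
    return clf, scaler


def _rfe_path(x: np.ndarray, y: np.ndarray, feature_idx: list[int], c: float) -> list[list[int]]:
    """Nested feature subsets from full panel down to one feature.

    Returns subsets of decreasing size (first = all features); at each step
    the feature with the smallest squared SVM weight is dropped.
    """
    active = list(feature_idx)
    path = [list(active)]
    while len(active) > 1:
        clf, _ = _fit_svm(x[:, active], y, c)
        w2 = (clf.coef_[0] ** 2)
        active.pop(int(np.argmin(w2)))
        path.append(list(active))
    return path


def train_svm_rfe(
    expr: pd.DataFrame,
    labels,
    candidate_markers,
    sizes=range(1, 7),
    c: float = 1.0,
) -> RfeResult:
    """Linear SVM recursive feature elimination with honest LOOCV.

    *candidate_markers* (typically the up-regulated significant markers)
    are ranked by repeatedly dropping the feature with the smallest squared
    weight; at each requested size the apparent (resubstitution) accuracy
    and the leave-one-out accuracy — with elimination re-run inside every
    fold — are recorded. Features are standardized within each training set.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    candidate_markers = list(candidate_markers)
    missing = [m for m in candidate_markers if m not in expr.index]
    if missing:
        raise ValueError(f"candidate markers not in matrix: {missing}")
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and (sizes[0] < 1 or sizes[-1] > len(candidate_markers)):
        raise ValueError("sizes must lie in 1..len(candidate_markers)")

    x = expr.loc[candidate_markers].to_numpy(dtype=float).T  # samples x features
    y = labels.astype(int)
    n = x.shape[0]

    def subsets_by_size(path):
        return {len(s): s for s in path}

    full_path = subsets_by_size(_rfe_path(x, y, list(range(len(candidate_markers))), c))

    apparent, markers_by_size = {}, {}
    for k in sizes:
        idx = full_path[k]
        clf, scaler = _fit_svm(x[:, idx], y, c)
        pred = clf.predict(scaler.transform(x[:, idx]))
        apparent[k] = float((pred == y).mean())
        markers_by_size[k] = [candidate_markers[i] for i in idx]

    hits = {k: 0 for k in sizes}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if y[mask].all() or not y[mask].any():
            continue  # fold lost a class; counts as a miss for every size
        fold_path = subsets_by_size(
            _rfe_path(x[mask], y[mask], list(range(len(candidate_markers))), c)
        )
        for k in sizes:
            idx = fold_path[k]
            clf, scaler = _fit_svm(x[mask][:, idx], y[mask], c)
            pred = clf.predict(scaler.transform(x[i : i + 1, idx]))
            hits[k] += int(pred[0] == y[i])
    loocv = {k: hits[k] / n for k in sizes}

    return RfeResult(sizes=sizes, markers_by_size=markers_by_size,
                     apparent_accuracy=apparent, loocv_accuracy=loocv)
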