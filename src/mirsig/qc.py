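"""Sample- and assay-level quality control.

Two screens run before any normalization:

* **hemolysis screen** — red-cell contamination inflates plasma miR-451a;
  a sample is flagged when Cq(miR-23a) - Cq(miR-451a) exceeds 7 cycles
  (strict). The delta is translation-invariant, so loading differences do
  not move it.
* **detection filter** — an assay is kept only if it is detected in at
  least ``min_rate`` (default 95%) of the samples of the cancer or of the
  non-cancer super-group. Undetected values are never imputed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import cancer_labels
from .synthetic import HEMOLYSIS_PAIR

HEMOLYSIS_DELTA_MAX = 7.0


def hemolysis_screen(
    matrix: pd.DataFrame,
    assay_23a: str = HEMOLYSIS_PAIR[0],
    assay_451: str = HEMOLYSIS_PAIR[1],
    delta_max: float = HEMOLYSIS_DELTA_MAX,
) -> pd.DataFrame:
    """Per-sample hemolysis delta and status.

    Returns a DataFrame indexed by sample with columns ``delta`` (cycles;
    NaN when either assay is undetected) and ``status`` in
    ``{"pass", "hemolysed", "indeterminate"}``. A sample is hemolysed iff
    delta > ``delta_max`` strictly.
    """
    for name in (assay_23a, assay_451):
        if name not in matrix.index:
            raise ValueError(f"assay {name!r} not present in Cq matrix")
    delta = matrix.loc[assay_23a] - matrix.loc[assay_451]
    status = np.where(
        delta.isna(), "indeterminate", np.where(delta > delta_max, "hemolysed", "pass")
    )
    return pd.DataFrame({"delta": delta, "status": status}, index=matrix.columns)


@dataclass
class QcReport:
    """Outcome of the QC stage; ``retained + excluded`` partition the panel."""

    hemolysis: pd.DataFrame | None
    detection_rates: pd.DataFrame
    retained: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "retained": self.retained,
            "excluded": self.excluded,
            "n_retained": len(self.retained),
            "n_excluded": len(self.excluded),
            "detection_rates": self.detection_rates.round(6).to_dict(orient="index"),
        }
        if self.hemolysis is not None:
            payload["hemolysis"] = {
                s: {"delta": (None if pd.isna(r.delta) else round(float(r.delta), 4)),
                    "status": r.status}
                for s, r in self.hemolysis.iterrows()
            }
        Path(path).write_text(json.dumps(payload, indent=2))


def detection_filter(
    matrix: pd.DataFrame, sheet: pd.DataFrame, min_rate: float = 0.95
) -> QcReport:
    """Keep assays detected in >= ``min_rate`` of either super-group.

    The two groups are cancer (CRC + metastatic CRC) and non-cancer
    (healthy + hyperplastic polyp + adenoma); an assay survives if its
    detection rate reaches the threshold in at least one of them.
    """
    if not 0.0 < min_rate <= 1.0 and min_rate != 0.0:
        raise ValueError(f"min_rate must be in (0, 1] (or 0 to disable), got {min_rate}")
    labels = cancer_labels(sheet, matrix.columns).to_numpy()
    n_cancer, n_noncancer = int(labels.sum()), int((~labels).sum())
    if n_cancer == 0 or n_noncancer == 0:
        raise ValueError("both cancer and non-cancer groups must be non-empty")

    detected = matrix.notna().to_numpy()
    rate_cancer = detected[:, labels].sum(axis=1) / n_cancer
    rate_noncancer = detected[:, ~labels].sum(axis=1) / n_noncancer
    rates = pd.DataFrame(
        {"cancer": rate_cancer, "non_cancer": rate_noncancer}, index=matrix.index
    )
    keep = (rates["cancer"] >= min_rate) | (rates["non_cancer"] >= min_rate)
    return QcReport(
        hemolysis=None,
        detection_rates=rates,
        retained=matrix.index[keep].tolist(),
        excluded=matrix.index[~keep].tolist(),
    )


def run_qc(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    min_rate: float = 0.95,
    delta_max: float = HEMOLYSIS_DELTA_MAX,
) -> QcReport:
    """Hemolysis screen + detection filter in one report."""
    report = detection_filter(matrix, sheet, min_rate=min_rate)
    report.hemolysis = hemolysis_screen(matrix, delta_max=delta_max)
    return report
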