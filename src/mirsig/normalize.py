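"""Livak relative quantification and quantile normalization.

The 2^-ddCt scheme on the cycle scale: for assay *a* in sample *s*,

    dCt(a, s)  = Cq(a, s) - reference(s)
    ddCt(a, s) = dCt(a, s) - calibrator(a)
    output     = -ddCt = log2 relative quantification

Two choices of per-sample reference are supported:

* **global mode** (array-card data): the geometric mean of the relative
  quantities of all retained assays, which on the cycle scale is the
  arithmetic mean of the sample's Cq values;
* **endogenous mode** (single TaqMan assays): the arithmetic mean Cq of a
  small set of stable reference miRNAs (default miR-423-5p + miR-361-5p).

The calibrator is the arithmetic mean dCt over the control samples
(healthy volunteers by default), so outputs are log2 fold differences
relative to the average control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CQ_LIMIT

DEFAULT_REFERENCES = ("hsa-miR-423-5p", "hsa-miR-361-5p")


def _impute_censored(matrix: pd.DataFrame, limit: float) -> pd.DataFrame:
    n_missing = int(matrix.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(
            f"imputing {n_missing} undetected Cq value(s) at the censoring "
            f"limit {limit}",
            stacklevel=3,
        )
    return matrix.fillna(limit)


def livak_normalize_global(
    matrix: pd.DataFrame,
    retained_assays=None,
    control_sample_ids=None,
    censor_limit: float = CQ_LIMIT,
) -> pd.DataFrame:
    """Global-mean 2^-ddCt normalization (TLDA mode).

    ``reference(s)`` is the mean Cq of *retained_assays* in sample *s*;
    undetected cells are imputed at the censoring limit (with a warning)
    before normalization. Output is log2 relative quantification for the
    retained assays, invariant to per-sample additive Cq shifts.
    """
    if control_sample_ids is None or len(list(control_sample_ids)) == 0:
        raise ValueError("control_sample_ids must be a non-empty list")
    control_sample_ids = list(control_sample_ids)
    missing = [s for s in control_sample_ids if s not in matrix.columns]
    if missing:
        raise ValueError(f"control samples not in matrix: {missing}")
    if retained_assays is None:
        retained_assays = matrix.index.tolist()
    retained_assays = list(retained_assays)
    missing = [a for a in retained_assays if a not in matrix.index]
    if missing:
        raise ValueError(f"retained assays not in matrix: {missing}")

    sub = matrix.loc[retained_assays]
    all_missing = sub[control_sample_ids].isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            "assay(s) undetected in every control sample: "
            f"{sub.index[all_missing].tolist()}"
        )
    cq = _impute_censored(sub, censor_limit)
    reference = cq.mean(axis=0)                       # per-sample normalization factor
    dct = cq.sub(reference, axis=1)
    calibrator = dct[control_sample_ids].mean(axis=1)  # per-assay control mean dCt
    return -dct.sub(calibrator, axis=0)


def livak_normalize_endogenous(
    matrix: pd.DataFrame,
    targets=None,
    references=DEFAULT_REFERENCES,
    control_sample_ids=None,
) -> pd.DataFrame:
    """Endogenous-control 2^-ddCt normalization (single-assay mode).

    The per-sample reference is the mean Cq of the *references* assays,
    which must be detected in every sample. *targets* defaults to every
    non-reference assay.
    """
    if control_sample_ids is None or len(list(control_sample_ids)) == 0:
        raise ValueError("control_sample_ids must be a non-empty list")
    control_sample_ids = list(control_sample_ids)
    references = list(references)
    missing = [a for a in references if a not in matrix.index]
    if missing:
        raise ValueError(f"reference assays not in matrix: {missing}")
    ref_block = matrix.loc[references]
    undet = ref_block.columns[ref_block.isna().any(axis=0)].tolist()
    if undet:
        raise ValueError(
            f"reference assay undetected in sample(s): {undet}"
        )
    if targets is None:
        targets = [a for a in matrix.index if a not in references]
    targets = list(targets)
    missing = [a for a in targets if a not in matrix.index]
    if missing:
        raise ValueError(f"target assays not in matrix: {missing}")

    target_cq = _impute_censored(matrix.loc[targets], CQ_LIMIT)
    reference = ref_block.mean(axis=0)
    dct = target_cq.sub(reference, axis=1)
    calibrator = dct[control_sample_ids].mean(axis=1)
    return -dct.sub(calibrator, axis=0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    The target distribution is the across-sample mean of sorted columns;
    within a column, tied input values share the mean of their rank
    quantiles, which makes the map deterministic and idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if matrix.isna().to_numpy().any():
        raise ValueError("missing values present; normalize/impute first")

    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    target = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        assigned = target.copy()
        # average the target quantiles over each tie group
        i = 0
        while i < n:
            k = i + 1
            while k < n and col_sorted[k] == col_sorted[i]:
                k += 1
            if k - i > 1:
                assigned[i:k] = assigned[i:k].mean()
            i = k
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
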