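"""Reading and writing the pipeline's tabular formats.

All matrices are plain pandas DataFrames:

* **Cq matrix** — rows are assays (miRNAs), columns are samples, cells hold
  quantification cycles in ``(0, 40]``; undetected reactions are ``NaN``
  (written as ``NA``).
* **expression matrix** — same layout, log2 relative quantification, all
  finite.
* **sample sheet** — one row per sample with ``sample_id``, ``group``,
  ``cancer`` and ``cohort`` columns.
"""

from __future__ import annotations

import pandas as pd

#: the five histology strata of the cohort design
GROUPS = ("healthy", "hyperplastic_polyp", "adenoma", "crc", "metastatic_crc")

#: strata forming the cancer super-group
CANCER_GROUPS = frozenset({"crc", "metastatic_crc"})

COHORTS = ("screening", "discovery", "validation")

#: censoring limit of the qPCR instrument (cycles)
CQ_LIMIT = 40.0

_NA_VALUES = ["NA", "Undetermined", "undetermined", ""]


def validate_cq_matrix(matrix: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *matrix* is not a valid Cq matrix."""
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate assay names: {dup}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    values = matrix.to_numpy(dtype=float)
    defined = values[~pd.isna(values)]
    if len(defined) and (defined <= 0).any():
        raise ValueError("Cq values must be > 0")
    if len(defined) and (defined > CQ_LIMIT).any():
        raise ValueError(f"Cq values must be <= censoring limit {CQ_LIMIT}")


def read_cq_matrix(path) -> pd.DataFrame:
    """Read a TSV Cq matrix (assays x samples, ``NA`` = undetected)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES,
                         keep_default_na=False)
    matrix = matrix.astype(float)
    validate_cq_matrix(matrix)
    return matrix


def write_cq_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a generic TSV expression matrix (assay-name column first).

    Accepts GEO series-matrix-style tables after header stripping; values
    must be numeric and finite.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES,
                         keep_default_na=False).astype(float)
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    required = {"sample_id", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dup}")
    unknown = set(sheet["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown histology groups: {sorted(unknown)}")
    if "cohort" in sheet.columns:
        unknown = set(sheet["cohort"]) - set(COHORTS)
        if unknown:
            raise ValueError(f"unknown cohorts: {sorted(unknown)}")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a CSV sample sheet; derives the binary ``cancer`` flag."""
    sheet = pd.read_csv(path)
    validate_sample_sheet(sheet)
    sheet["cancer"] = sheet["group"].isin(CANCER_GROUPS)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def cancer_labels(sheet: pd.DataFrame, sample_ids) -> pd.Series:
    """Boolean cancer flags aligned to *sample_ids*.

    Raises if any requested sample is absent from the sheet.
    """
    lookup = sheet.set_index("sample_id")["group"].isin(CANCER_GROUPS)
    missing = [s for s in sample_ids if s not in lookup.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    return lookup.reindex(sample_ids)
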