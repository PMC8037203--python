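"""Synthetic plasma-qPCR cohorts with known ground truth.

The generator emulates the structure of a TaqMan low-density-array screen of
circulating miRNAs: a ~381-assay panel measured on five histology strata
(healthy, hyperplastic polyp, adenoma, CRC, metastatic CRC), with

* per-assay baseline abundance (one baseline Cq per assay, normally
  distributed across the panel),
* per-sample technical noise (sd 0.5 cycles, typical qPCR replicate
  variability),
* censoring at 40 cycles (``NaN`` = undetected),
* a planted set of assays up-regulated in cancer — a Cq *decrease* of
  ``effect_log2`` cycles, since one PCR cycle is one doubling,
* a pair of low-variance endogenous-control-like assays, and
* the erythrocyte-contamination pair miR-23a-3p / miR-451a so the hemolysis
  screen is always applicable.

Every run is reproducible bit-for-bit from ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CANCER_GROUPS, CQ_LIMIT, GROUPS, write_cq_matrix, write_sample_sheet

HEMOLYSIS_PAIR = ("hsa-miR-23a-3p", "hsa-miR-451a")

#: planted up-regulated assays take the names of the six over-expressed
#: plasma markers of the motivating study, in order
PLANTED_NAMES = (
    "hsa-let-7e-5p",
    "hsa-miR-106a-5p",
    "hsa-miR-28-3p",
    "hsa-miR-542-5p",
    "hsa-miR-454-3p",
    "hsa-miR-203a-3p",
)

#: stable endogenous-like assays take the names of the study's reference pair
STABLE_NAMES = ("hsa-miR-423-5p", "hsa-miR-361-5p")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the screening design the pipeline targets: a 381-assay
    panel, six planted cancer markers shifted 1.5 log2 units, two stable
    endogenous candidates, 20 subjects per histology stratum.
    """

    n_per_group: int = 20
    n_assays: int = 381
    n_planted_up: int = 6
    effect_log2: float = 1.5
    baseline_cq_mean: float = 26.0
    baseline_cq_sd: float = 3.0
    noise_sd: float = 0.5
    dropout_cq_limit: float = CQ_LIMIT
    n_stable: int = 2
    stable_noise_sd: float = 0.1
    hemolysis_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_per_group", "n_assays", "n_planted_up", "n_stable"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        # the hemolysis pair occupies two panel slots of its own
        if self.n_planted_up + self.n_stable + len(HEMOLYSIS_PAIR) > self.n_assays:
            raise ValueError(
                "n_assays too small: n_planted_up + n_stable + 2 hemolysis "
                f"assays = {self.n_planted_up + self.n_stable + 2} > {self.n_assays}"
            )
        if not 0.0 <= self.hemolysis_fraction <= 1.0:
            raise ValueError(
                f"hemolysis_fraction must be in [0, 1], got {self.hemolysis_fraction}"
            )
        if not np.isfinite(self.effect_log2):
            raise ValueError("effect_log2 must be finite")
        for name in ("baseline_cq_sd", "noise_sd", "stable_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.dropout_cq_limit <= 0:
            raise ValueError(f"dropout_cq_limit must be > 0, got {self.dropout_cq_limit}")


@dataclass
class GroundTruth:
    """Which assays/samples carry the planted structure."""

    planted_up_assays: list[str] = field(default_factory=list)
    stable_assays: list[str] = field(default_factory=list)
    hemolysed_samples: list[str] = field(default_factory=list)
    cancer_samples: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _assay_names(config: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    planted = [
        PLANTED_NAMES[i] if i < len(PLANTED_NAMES) else f"hsa-miR-up-{i + 1:03d}"
        for i in range(config.n_planted_up)
    ]
    stable = [
        STABLE_NAMES[i] if i < len(STABLE_NAMES) else f"hsa-miR-stable-{i + 1:03d}"
        for i in range(config.n_stable)
    ]
    n_filler = config.n_assays - len(planted) - len(stable) - len(HEMOLYSIS_PAIR)
    filler = [f"hsa-miR-sim-{i + 1:04d}" for i in range(n_filler)]
    return planted, stable, filler


def generate_cq_dataset(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a Cq matrix, its sample sheet and the ground truth.

    Returns ``(cq, sheet, truth)`` where ``cq`` has ``n_assays`` rows and
    ``5 * n_per_group`` columns, undetected cells are ``NaN``, and ``truth``
    records the planted assays and hemolysed samples.
    """
    rng = np.random.default_rng(config.seed)

    planted, stable, filler = _assay_names(config)
    assays = planted + stable + list(HEMOLYSIS_PAIR) + filler

    sample_ids, groups = [], []
    for group in GROUPS:
        for i in range(config.n_per_group):
            sample_ids.append(f"{group}-{i + 1:03d}")
            groups.append(group)
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "cancer": [g in CANCER_GROUPS for g in groups],
            "cohort": "discovery",
        }
    )
    n_samples = len(sample_ids)

    # one baseline per assay, drawn once
    baselines = np.empty(len(assays))
    baselines[: len(planted)] = rng.normal(
        config.baseline_cq_mean, config.baseline_cq_sd, size=len(planted)
    )
    # stable / hemolysis assays sit in the abundant range so they are fully
    # detected and pass the mean-Cq < 20 reference-candidate prefilter
    baselines[len(planted) : len(planted) + len(stable)] = rng.normal(
        18.0, 0.8, size=len(stable)
    )
    i23, i451 = len(planted) + len(stable), len(planted) + len(stable) + 1
    baselines[i23] = rng.normal(20.0, 0.5)
    baselines[i451] = rng.normal(17.0, 0.5)
    baselines[i451 + 1 :] = rng.normal(
        config.baseline_cq_mean, config.baseline_cq_sd, size=len(filler)
    )

    noise_sd = np.full(len(assays), config.noise_sd)
    noise_sd[len(planted) : len(planted) + len(stable)] = config.stable_noise_sd

    values = baselines[:, None] + rng.normal(
        0.0, 1.0, size=(len(assays), n_samples)
    ) * noise_sd[:, None]

    cancer_mask = sheet["cancer"].to_numpy()
    values[: len(planted), cancer_mask] -= config.effect_log2

    values = np.maximum(values, 0.01)
    values[values > config.dropout_cq_limit] = np.nan

    cq = pd.DataFrame(values, index=assays, columns=sample_ids)

    truth = GroundTruth(
        planted_up_assays=planted,
        stable_assays=stable,
        cancer_samples=sheet.loc[sheet["cancer"], "sample_id"].tolist(),
    )

    if config.hemolysis_fraction > 0:
        n_hem = int(round(config.hemolysis_fraction * n_samples))
        chosen = sorted(rng.choice(sample_ids, size=n_hem, replace=False).tolist())
        cq = inject_hemolysis(cq, chosen, seed=rng.integers(0, 2**31))
        truth.hemolysed_samples = chosen

    return cq, sheet, truth


def inject_hemolysis(
    matrix: pd.DataFrame,
    sample_ids,
    seed: int = 0,
    margin_range: tuple[float, float] = (0.5, 3.0),
) -> pd.DataFrame:
    """Contaminate *sample_ids* with erythrocyte miR-451a.

    Hemolysis floods plasma with red-cell miR-451a, lowering its Cq; the
    affected samples end with Cq(miR-23a) - Cq(miR-451a) strictly above the
    7-cycle exclusion rule. Other assays are untouched; returns a new matrix.
    """
    sample_ids = list(sample_ids)
    unknown = [s for s in sample_ids if s not in matrix.columns]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown}")
    out = matrix.copy()
    if not sample_ids:
        return out
    a23, a451 = HEMOLYSIS_PAIR
    for name in (a23, a451):
        if name not in out.index:
            raise ValueError(f"assay {name!r} not present in matrix")
    rng = np.random.default_rng(seed)
    for s in sample_ids:
        cq23 = out.at[a23, s]
        if np.isnan(cq23):
            cq23 = CQ_LIMIT
        margin = rng.uniform(*margin_range)
        out.at[a451, s] = max(cq23 - 7.0 - margin, 0.01)
    return out


def write_dataset(
    cq: pd.DataFrame, sheet: pd.DataFrame, truth: GroundTruth, outdir
) -> None:
    """Write the TSV/CSV/JSON trio to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cq_matrix(cq, outdir / "cq_matrix.tsv")
    write_sample_sheet(sheet, outdir / "samples.csv")
    truth.to_json(outdir / "ground_truth.json")
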