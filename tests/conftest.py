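import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mirsig import SynthConfig, generate_cq_dataset, livak_normalize_global


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    cfg = SynthConfig(n_per_group=6, n_assays=60, n_planted_up=6, effect_log2=2.0,
                      n_stable=2, seed=42)
    return generate_cq_dataset(cfg)


@pytest.fixture(scope="session")
def small_expression(small_cohort):
    cq, sheet, truth = small_cohort
    controls = sheet.loc[sheet["group"] == "healthy", "sample_id"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = livak_normalize_global(cq, control_sample_ids=controls)
    labels = sheet.set_index("sample_id").loc[expr.columns, "cancer"].to_numpy()
    return expr, labels, truth


def random_cq_matrix(rng: np.random.Generator, n_assays=5, n_samples=5):
    values = rng.uniform(15.0, 35.0, size=(n_assays, n_samples))
    return pd.DataFrame(values,
                        index=[f"assay-{i}" for i in range(n_assays)],
                        columns=[f"s{i}" for i in range(n_samples)])
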