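import numpy as np
import pandas as pd
import pytest

from mspanel.cohort import validate_manifest
from mspanel.preprocess import (
    apply_covariate_correction,
    bridge_normalize,
    fit_covariate_correction,
)
from mspanel.cohort import derive_binary_labels, filter_gd_window
from mspanel.simulate import GeneratorConfig, generate_cohorts


def make_manifest(rows: list[dict]) -> pd.DataFrame:
    """Build a small manifest from row dicts, filling defaults."""
    defaults = {
        "cohort": "CLIMB-like",
        "batch_id": "B1",
        "age": 40.0,
        "sex": "F",
        "disease_duration": 5.0,
        "draw_date": "2018-01-01",
        "is_bridge": False,
        "gd_lesion_count": np.nan,
        "mri_offset_days": np.nan,
        "crs": np.nan,
        "arr": np.nan,
        "bridge_aliquot": np.nan,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study reused across test modules."""
    cfg = GeneratorConfig(
        n_proteins=20,
        rng_seed=11,
        n_samples={"CLIMB-like": 150, "EPIC-like": 80, "ACP-like": 60},
    )
    expr, table, truth = generate_cohorts(cfg)
    return cfg, expr, validate_manifest(table), truth


@pytest.fixture(scope="session")
def corrected_study(small_study):
    """The small study taken through bridge normalization and covariate
    correction, plus its window-filtered table."""
    cfg, expr, table, truth = small_study
    normalized = bridge_normalize(expr, table)
    filtered = filter_gd_window(table)
    reference = derive_binary_labels(filtered, "GDA")
    model = fit_covariate_correction(normalized, table, reference)
    corrected = apply_covariate_correction(normalized, table, model)
    return cfg, corrected, filtered, truth
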