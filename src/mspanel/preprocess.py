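"""Bridge-sample batch normalization and covariate-residual correction.

Two preprocessing passes produce the model-ready feature sets:

1. **Bridge normalization** removes additive batch offsets.  Bridge
   aliquots — the same pooled serum measured in every batch — estimate each
   batch's offset per protein as the difference between that batch's bridge
   median and the grand bridge median (pooled over all bridge
   measurements); the shift is subtracted from every sample in the batch.
   Medians keep single outlying bridge wells from dragging a whole batch.

2. **Covariate correction** removes linear demographic effects.  For each
   protein, ordinary least squares regresses the bridge-normalized NPX on
   age, sex (0/1) and disease duration using only a *reference class* —
   the endpoint-negative samples, e.g. lesion-free patients — and the
   fitted value is subtracted from *all* samples.  The residuals are the
   multivariate features; univariate analyses consume the bridge-normalized
   values directly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .cohort import BinaryLabeling
from .exceptions import (
    AlignmentError,
    FitError,
    InsufficientDataError,
    NormalizationError,
)

logger = logging.getLogger(__name__)

SEX_CODES = {"F": 0.0, "M": 1.0}
COVARIATES = ("age", "sex", "disease_duration")


def _check_alignment(matrix: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    tab = table.set_index("sample_id")
    missing = matrix.index.difference(tab.index)
    if len(missing):
        raise AlignmentError(
            f"{len(missing)} matrix samples absent from the manifest, "
            f"e.g. {list(missing[:3])}"
        )
    if matrix.columns.duplicated().any():
        raise AlignmentError("duplicated protein ids in the expression matrix")
    return tab.loc[matrix.index]


def drop_high_missingness(
    matrix: pd.DataFrame, max_missing: float = 0.2
) -> pd.DataFrame:
    """Drop proteins whose missing fraction exceeds ``max_missing``
    (missing values are never imputed)."""
    frac = matrix.isna().mean(axis=0)
    bad = frac.index[frac > max_missing]
    if len(bad):
        logger.warning(
            "dropping %d proteins with > %.0f%% missing values: %s",
            len(bad),
            100 * max_missing,
            list(bad[:5]),
        )
    return matrix.drop(columns=bad)


def bridge_normalize(matrix: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Shift every batch so its bridge medians match the grand bridge median.

    Per protein j and batch b, ``shift_bj = median(bridge NPX in b) -
    median(all bridge NPX)``; the shift is subtracted from all samples of
    batch b.  With a single batch the input is returned unchanged.  A batch
    without bridge samples raises :class:`NormalizationError` naming it.
    """
    tab = _check_alignment(matrix, table)
    batches = tab["batch_id"]
    is_bridge = tab["is_bridge"].astype(bool)
    unique_batches = batches.unique()
    if len(unique_batches) == 1:
        return matrix.copy()

    bridge_vals = matrix[is_bridge.to_numpy()]
    if bridge_vals.empty:
        raise NormalizationError("no bridge samples present in the matrix")
    empty = [b for b in unique_batches if not (is_bridge & (batches == b)).any()]
    if empty:
        raise NormalizationError(f"batches without bridge samples: {sorted(empty)}")

    grand = bridge_vals.median(axis=0)
    shifts = (
        bridge_vals.groupby(batches[is_bridge.to_numpy()]).median() - grand
    )  # batches x proteins
    out = matrix - shifts.reindex(batches).to_numpy()
    return out


@dataclasses.dataclass
class CorrectionModel:
    """Per-protein OLS of NPX on (1, age, sex01, disease_duration).

    ``coef`` and ``stderr`` are (4 x proteins) DataFrames with rows
    intercept/age/sex/disease_duration; units are NPX per covariate unit.
    """

    coef: pd.DataFrame
    stderr: pd.DataFrame
    reference: str
    n_reference: int
    sex_codes: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(SEX_CODES)
    )

    @property
    def protein_ids(self) -> pd.Index:
        return self.coef.columns


def _design(tab: pd.DataFrame) -> np.ndarray:
    sex01 = tab["sex"].map(SEX_CODES)
    if sex01.isna().any():
        raise FitError("sex must be F or M for every reference sample")
    return np.column_stack(
        [
            np.ones(len(tab)),
            tab["age"].to_numpy(float),
            sex01.to_numpy(float),
            tab["disease_duration"].to_numpy(float),
        ]
    )


def fit_covariate_correction(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    reference: BinaryLabeling,
) -> CorrectionModel:
    """Fit the demographic correction on the reference-negative samples.

    ``matrix`` must already be bridge-normalized.  Requires at least
    covariates + 2 = 5 reference samples and a full-rank design (a constant
    covariate raises :class:`FitError` naming it).
    """
    tab = _check_alignment(matrix, table)
    ref_ids = matrix.index.intersection(reference.negatives)
    ref_ids = ref_ids[~tab.loc[ref_ids, "is_bridge"].astype(bool)]
    n_cov = len(COVARIATES)
    if len(ref_ids) < n_cov + 2:
        raise InsufficientDataError(
            f"need >= {n_cov + 2} reference samples, got {len(ref_ids)}"
        )
    X = _design(tab.loc[ref_ids])
    for k, name in enumerate(COVARIATES, start=1):
        if np.ptp(X[:, k]) == 0:
            raise FitError(f"covariate {name!r} is constant in the reference class")
    Y = matrix.loc[ref_ids].to_numpy(float)
    if np.isnan(Y).any():
        raise FitError("missing NPX values in the reference class; drop or filter first")

    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise FitError("rank-deficient covariate design")
    resid = Y - X @ beta
    dof = max(len(ref_ids) - X.shape[1], 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    rows = ["intercept", *COVARIATES]
    return CorrectionModel(
        coef=pd.DataFrame(beta, index=rows, columns=matrix.columns),
        stderr=pd.DataFrame(se, index=rows, columns=matrix.columns),
        reference=reference.endpoint,
        n_reference=len(ref_ids),
    )


def apply_covariate_correction(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    model: CorrectionModel,
) -> pd.DataFrame:
    """Residualize every patient sample: observed minus the model's
    demographic prediction.  Bridge aliquots (no demographics) are dropped
    from the output — they have served their purpose after normalization.
    """
    if list(model.protein_ids) != list(matrix.columns):
        raise AlignmentError("correction model proteins do not match the matrix")
    tab = _check_alignment(matrix, table)
    keep = ~tab["is_bridge"].astype(bool).to_numpy()
    sub = matrix[keep]
    X = _design(tab[keep])
    pred = X @ model.coef.to_numpy()
    return sub - pred


def preprocess_report(
    matrix: pd.DataFrame, table: pd.DataFrame, model: CorrectionModel
) -> dict:
    """Machine-readable summary: per-batch bridge shifts and per-protein
    covariate coefficients."""
    tab = _check_alignment(matrix, table)
    is_bridge = tab["is_bridge"].astype(bool)
    bridge_vals = matrix[is_bridge.to_numpy()]
    grand = bridge_vals.median(axis=0)
    shifts = bridge_vals.groupby(tab["batch_id"][is_bridge.to_numpy()]).median() - grand
    return {
        "batch_shifts": shifts.round(6).to_dict(orient="index"),
        "reference_class": model.reference,
        "n_reference": model.n_reference,
        "covariate_coefficients": model.coef.round(6).to_dict(orient="index"),
    }

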