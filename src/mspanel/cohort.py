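"""Cohort manifest model, endpoint labeling, and lesion-count utilities.

A *cohort table* is a plain :class:`pandas.DataFrame` with one row per serum
sample, validated against the column dictionary shipped in
``schema/manifest_v1.yaml``.  Demographics (age, sex, disease duration) and
batch membership are required for every patient sample; endpoint annotations
(gadolinium-enhancing lesion count with its MRI-to-draw offset, clinical
relapse status, annualized relapse rate) are each optional per sample, but a
non-bridge sample must carry at least one of them.  Bridge aliquots — pooled
serum re-measured in every batch for normalization — carry no demographics
and no endpoint annotations.

Binary endpoints
----------------
Five binary contrasts are derived from the annotations:

``GDA``
    general disease activity — 0 lesions (negative) vs any positive count.
``SDA``
    subtle disease activity — 0 lesions vs exactly 1; counts >= 2 excluded.
``EDA``
    extreme disease activity — 0 lesions vs >= 3; counts 1-2 excluded.
``CRS``
    clinical relapse status — quiescence (negative) vs exacerbation.
``ARR``
    annualized relapse rate — low (<= 0.2 relapses/year, negative) vs high
    (>= 1.0, positive); intermediate rates excluded.

Samples with a missing annotation for the requested endpoint are *excluded*,
never imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyLabelingError,
    ParameterError,
    SchemaError,
    ValidationError,
)

ENDPOINTS = ("GDA", "SDA", "EDA", "CRS", "ARR")

#: Columns every manifest must contain.
REQUIRED_COLUMNS = (
    "sample_id",
    "cohort",
    "batch_id",
    "age",
    "sex",
    "disease_duration",
    "draw_date",
    "is_bridge",
)

#: Optional annotation columns (created as missing when absent).
OPTIONAL_COLUMNS = (
    "gd_lesion_count",
    "mri_offset_days",
    "crs",
    "arr",
    "bridge_aliquot",
)

COHORTS = ("CLIMB-like", "EPIC-like", "ACP-like")
SEXES = ("F", "M")
CRS_STATES = ("quiescence", "exacerbation")

#: Inclusive annualized-relapse-rate class bounds (relapses/year).
ARR_LOW_MAX = 0.2
ARR_HIGH_MIN = 1.0

#: Symmetric window (days) between blood draw and MRI for lesion endpoints.
GD_WINDOW_DAYS = 30

#: Lesion-count cap applied before regression modeling.
LESION_CLIP_CAP = 5


def schema_path() -> Path:
    """Path of the versioned manifest column dictionary shipped with the
    package."""
    return Path(__file__).parent / "schema" / "manifest_v1.yaml"


@dataclasses.dataclass(frozen=True)
class BinaryLabeling:
    """Per-sample positive / negative / excluded assignment for one endpoint.

    ``labels`` is a string Series indexed by sample_id covering *every*
    sample of the source table; bridge aliquots and samples missing the
    relevant annotation are ``"excluded"``.
    """

    endpoint: str
    labels: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"positive", "negative", "excluded"}
        if bad:
            raise ValidationError(f"invalid label states: {sorted(bad)}")

    @property
    def positives(self) -> pd.Index:
        return self.labels.index[self.labels == "positive"]

    @property
    def negatives(self) -> pd.Index:
        return self.labels.index[self.labels == "negative"]

    @property
    def excluded(self) -> pd.Index:
        return self.labels.index[self.labels == "excluded"]

    def encode(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        """Integer encoding aligned to ``sample_ids`` (default: own order):
        positive -> 1, negative -> 0, excluded -> -1."""
        lab = self.labels
        if sample_ids is not None:
            lab = lab.reindex(list(sample_ids), fill_value="excluded")
        return lab.map({"positive": 1, "negative": 0, "excluded": -1}).to_numpy()

    def counts(self) -> Mapping[str, int]:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in ("positive", "negative", "excluded")}


def _row_diagnostics(table: pd.DataFrame) -> list[str]:
    """Collect human-readable row-level invariant violations."""
    problems: list[str] = []
    dup = table["sample_id"][table["sample_id"].duplicated()]
    for sid in dup.unique():
        problems.append(f"duplicate sample_id {sid!r}")

    patients = table[~table["is_bridge"].astype(bool)]
    bad_age = patients[~(patients["age"] > 0)]
    for sid in bad_age["sample_id"]:
        problems.append(f"sample {sid!r}: age must be > 0")
    bad_dd = patients[~(patients["disease_duration"] >= 0)]
    for sid in bad_dd["sample_id"]:
        problems.append(f"sample {sid!r}: disease_duration must be >= 0")
    bad_sex = patients[~patients["sex"].isin(SEXES)]
    for sid in bad_sex["sample_id"]:
        problems.append(f"sample {sid!r}: sex must be one of {SEXES}")

    # Lesion count and MRI offset must be jointly present or jointly missing.
    gd, off = table["gd_lesion_count"], table["mri_offset_days"]
    mismatch = table[gd.notna() != off.notna()]
    for sid in mismatch["sample_id"]:
        problems.append(
            f"sample {sid!r}: gd_lesion_count and mri_offset_days must be "
            "present together"
        )
    neg = table[table["gd_lesion_count"].fillna(0) < 0]
    for sid in neg["sample_id"]:
        problems.append(f"sample {sid!r}: gd_lesion_count must be >= 0")

    bridges = table[table["is_bridge"].astype(bool)]
    annotated = bridges[
        bridges[["gd_lesion_count", "crs", "arr"]].notna().any(axis=1)
    ]
    for sid in annotated["sample_id"]:
        problems.append(f"bridge sample {sid!r} carries endpoint annotations")

    bare = patients[~patients[["gd_lesion_count", "crs", "arr"]].notna().any(axis=1)]
    for sid in bare["sample_id"]:
        problems.append(f"sample {sid!r}: no endpoint annotation present")

    bad_crs = table[table["crs"].notna() & ~table["crs"].isin(CRS_STATES)]
    for sid in bad_crs["sample_id"]:
        problems.append(f"sample {sid!r}: crs must be one of {CRS_STATES}")
    bad_arr = table[table["arr"].fillna(0) < 0]
    for sid in bad_arr["sample_id"]:
        problems.append(f"sample {sid!r}: arr must be >= 0")
    return problems


def validate_manifest(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a manifest DataFrame in place of a schema.

    Raises :class:`SchemaError` for missing columns, and
    :class:`ValidationError` (listing every offending row) for invariant
    violations.  Returns the table with optional columns materialized and
    dtypes coerced.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"manifest is missing required columns: {missing}")
    table = table.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table["is_bridge"] = (
        table["is_bridge"]
        .map(
            lambda v: v
            if isinstance(v, (bool, np.bool_))
            else str(v).strip().lower() in {"true", "1", "yes"}
        )
        .astype(bool)
    )
    for col in ("age", "disease_duration", "gd_lesion_count", "mri_offset_days", "arr"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    problems = _row_diagnostics(table)
    if problems:
        raise ValidationError(
            "manifest validation failed:\n  " + "\n  ".join(problems)
        )
    return table.reset_index(drop=True)


def load_manifest(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a cohort manifest from CSV or TSV and validate it.

    ``format`` is ``"csv"`` or ``"tsv"``; when omitted it is inferred from
    the file suffix (default csv).  Dates stay as ISO-8601 strings and are
    compared at day resolution.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if format not in {"csv", "tsv"}:
        raise ParameterError(f"unknown manifest format {format!r}")
    sep = "\t" if format == "tsv" else ","
    return validate_manifest(pd.read_csv(path, sep=sep))


def write_manifest(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Serialize a cohort table as plain CSV/TSV with ISO-8601 dates."""
    sep = "\t" if format == "tsv" else ","
    table.to_csv(path, sep=sep, index=False)


def filter_gd_window(table: pd.DataFrame, window_days: int = GD_WINDOW_DAYS) -> pd.DataFrame:
    """Blank the lesion annotation of samples drawn too far from their MRI.

    A lesion count is only trusted when the blood draw happened within
    ``window_days`` days of the MRI, before or after (|draw - MRI| <=
    window).  Out-of-window samples keep their row — they remain usable for
    the clinical endpoints — but their ``gd_lesion_count`` and
    ``mri_offset_days`` are cleared, so they are excluded from every
    lesion-based endpoint.  Idempotent.
    """
    if window_days < 0:
        raise ParameterError("window_days must be >= 0")
    table = table.copy()
    out = table["mri_offset_days"].abs() > window_days
    out = out.fillna(False)
    table.loc[out, ["gd_lesion_count", "mri_offset_days"]] = np.nan
    return table


def derive_binary_labels(table: pd.DataFrame, endpoint: str) -> BinaryLabeling:
    """Assign positive / negative / excluded to every sample for one endpoint.

    See the module docstring for the per-endpoint rules.  ARR bounds are
    inclusive (low <= 0.2, high >= 1.0); rates strictly between the bounds
    are excluded.  Raises :class:`EmptyLabelingError` when no sample carries
    the relevant annotation at all.
    """
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINTS:
        raise ParameterError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    idx = pd.Index(table["sample_id"])
    labels = pd.Series("excluded", index=idx, name=endpoint)
    bridge = table.set_index("sample_id")["is_bridge"].astype(bool)

    if endpoint in ("GDA", "SDA", "EDA"):
        ann = table.set_index("sample_id")["gd_lesion_count"]
        present = ann.notna() & ~bridge
        if not present.any():
            raise EmptyLabelingError("no sample carries a lesion-count annotation")
        count = ann[present]
        labels[present & (ann == 0)] = "negative"
        if endpoint == "GDA":
            labels[count.index[count >= 1]] = "positive"
        elif endpoint == "SDA":
            labels[count.index[count == 1]] = "positive"
        else:  # EDA
            labels[count.index[count >= 3]] = "positive"
    elif endpoint == "CRS":
        ann = table.set_index("sample_id")["crs"]
        present = ann.notna() & ~bridge
        if not present.any():
            raise EmptyLabelingError("no sample carries a relapse-status annotation")
        labels[present & (ann == "quiescence")] = "negative"
        labels[present & (ann == "exacerbation")] = "positive"
    else:  # ARR
        ann = table.set_index("sample_id")["arr"]
        present = ann.notna() & ~bridge
        if not present.any():
            raise EmptyLabelingError("no sample carries an ARR annotation")
        labels[present & (ann <= ARR_LOW_MAX)] = "negative"
        labels[present & (ann >= ARR_HIGH_MIN)] = "positive"
    return BinaryLabeling(endpoint=endpoint, labels=labels)


def bin_lesion_counts(table: pd.DataFrame) -> tuple[int, int, int, int]:
    """Tally lesion-annotated samples into the bins 0 / 1 / 2 / >=3.

    Expects an MRI-window-filtered table; samples without a lesion
    annotation are not counted.
    """
    counts = table["gd_lesion_count"].dropna().to_numpy()
    return (
        int((counts == 0).sum()),
        int((counts == 1).sum()),
        int((counts == 2).sum()),
        int((counts >= 3).sum()),
    )


def clip_lesion_count(count, cap: int = LESION_CLIP_CAP):
    """Clip lesion counts at ``cap`` (default 5) before regression modeling.

    Counts above the cap are rare and their model behavior unreliable, so
    regression treats them as the cap.  Accepts scalars or arrays.
    """
    if cap < 1:
        raise ParameterError("cap must be >= 1")
    arr = np.asarray(count)
    if (arr < 0).any():
        raise ParameterError("lesion counts must be >= 0")
    clipped = np.minimum(arr, cap)
    if np.isscalar(count) or np.ndim(count) == 0:
        return int(clipped)
    return clipped
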