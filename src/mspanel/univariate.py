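"""Univariate endpoint associations and box-plot summaries.

Three statistics describe each protein's marginal association with an
endpoint:

* Spearman's rho between NPX level and lesion count (rank correlation with
  average-rank tie handling; ties are the norm since counts repeat),
* a two-sided Student's t (pooled variance) comparing the positive against
  the negative class of a binary endpoint, sign positive when the positive
  class has the higher mean,
* the AUROC of the protein as a lone classifier — the Mann-Whitney pair
  fraction.

Significance is flagged at alpha = 0.05, unadjusted, matching the screening
convention; a Benjamini-Hochberg column can be added on request.  A protein
whose lesion-count correlation and lesion-presence t statistic disagree in
sign is internally inconsistent for the lesion endpoint and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .cohort import BinaryLabeling, derive_binary_labels, filter_gd_window
from .exceptions import InsufficientDataError, UndefinedStatisticError

ALPHA = 0.05


def spearman_vs_count(values: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between NPX values and lesion counts.

    Average ranks handle the heavy count ties; the two-sided p-value uses
    the large-sample t approximation.  Needs >= 3 pairs and non-constant
    values.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(counts, dtype=float)
    if v.size != c.size or v.size < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        raise UndefinedStatisticError("Spearman correlation undefined on constant input")
    rho, p = stats.spearmanr(v, c)
    return float(rho), float(p)


def two_sample_t(values: np.ndarray, labeling: BinaryLabeling | np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t between positives and negatives.

    ``labeling`` is either a :class:`BinaryLabeling` aligned with
    ``values`` through its own sample order, or an integer array with 1 =
    positive, 0 = negative, -1 = excluded.  Positive t means the positive
    class has the higher mean.
    """
    v = np.asarray(values, dtype=float)
    y = labeling.encode() if isinstance(labeling, BinaryLabeling) else np.asarray(labeling)
    pos, neg = v[y == 1], v[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientDataError("each class needs >= 2 samples for the t test")
    t, p = stats.ttest_ind(pos, neg, equal_var=True)
    return float(t), float(p)


def univariate_auroc(values: np.ndarray, labeling: BinaryLabeling | np.ndarray) -> float:
    """AUROC of the protein alone: fraction of (positive, negative) pairs
    ranked correctly, ties counted one half."""
    v = np.asarray(values, dtype=float)
    y = labeling.encode() if isinstance(labeling, BinaryLabeling) else np.asarray(labeling)
    keep = y >= 0
    return metrics.auroc(y[keep], v[keep])


def directionality_check(results: pd.DataFrame) -> pd.Series:
    """Within-lesion-endpoint sign consistency per protein.

    ``results`` needs columns ``spearman_rho`` (count correlation) and
    ``t_stat`` (presence separation) indexed by protein.  Returns a boolean
    Series, True when the two statistics agree in sign (zero agrees with
    everything).
    """
    s = np.sign(results["spearman_rho"])
    t = np.sign(results["t_stat"])
    return pd.Series((s * t) >= 0, index=results.index, name="direction_consistent")


def boxplot_summary(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Per-group median, quartiles, 5th/95th percentiles and outlier values.

    Whiskers cover the central 90% of each group; observations outside
    [p5, p95] are the plotted outliers.  Quantiles use linear interpolation
    of order statistics.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.size == 0:
        raise InsufficientDataError("no observations to summarize")
    rows = []
    for label in pd.unique(g):
        sub = v[g == label]
        if sub.size == 0:
            raise InsufficientDataError(f"empty group {label!r}")
        q = np.quantile(sub, [0.05, 0.25, 0.5, 0.75, 0.95])
        outliers = sub[(sub < q[0]) | (sub > q[4])]
        rows.append(
            {
                "group": label,
                "n": int(sub.size),
                "p5": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "p95": q[4],
                "outliers": sorted(float(x) for x in outliers),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def run_univariate(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    endpoints: tuple[str, ...] = ("GDA", "CRS", "ARR"),
    alpha: float = ALPHA,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Tidy per-protein univariate statistics over the requested endpoints.

    Consumes bridge-normalized NPX values.  For lesion endpoints the table
    is MRI-window-filtered first and a ``spearman_rho`` / ``spearman_p``
    pair against the raw count is added alongside the binary statistics.
    """
    out = []
    gd_table = filter_gd_window(table)
    for endpoint in endpoints:
        tab = gd_table if endpoint in ("GDA", "SDA", "EDA") else table
        labeling = derive_binary_labels(tab, endpoint)
        y = labeling.encode(matrix.index)
        counts = (
            tab.set_index("sample_id")["gd_lesion_count"].reindex(matrix.index)
            if endpoint in ("GDA", "SDA", "EDA")
            else None
        )
        for protein in matrix.columns:
            v = matrix[protein].to_numpy(float)
            t, p = two_sample_t(v, y)
            row = {
                "protein_id": protein,
                "endpoint": endpoint,
                "t_stat": t,
                "t_p": p,
                "auroc": univariate_auroc(v, y),
                "significant": p < alpha,
                "direction": int(np.sign(t)),
            }
            if counts is not None:
                mask = counts.notna().to_numpy()
                rho, sp = spearman_vs_count(v[mask], counts[mask])
                row["spearman_rho"] = rho
                row["spearman_p"] = sp
            out.append(row)
    df = pd.DataFrame(out)
    if add_bh:
        df["t_q_bh"] = np.nan
        for endpoint in df["endpoint"].unique():
            m = df["endpoint"] == endpoint
            df.loc[m, "t_q_bh"] = stats.false_discovery_control(df.loc[m, "t_p"])
    return df
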