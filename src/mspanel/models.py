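"""Final endpoint models and their bootstrap evaluation.

Every evaluation in this module runs over a shared :class:`BootstrapPlan`
(see :mod:`mspanel.gfs`): the sample set is split into train (two thirds)
and test (one third) many times; a fresh model is fit on each train fold
and scored on its test fold; performance is reported as mean +/- standard
deviation across the folds.  Re-using one plan across feature sets makes
their comparison paired, so differences reflect the features and not the
splits.

Models: an L2 logistic regression for the binary endpoints, and a log-link
Poisson regression for the lesion count, fitted on counts clipped at five
(higher counts are too rare to model) and evaluated by the square of
Pearson's correlation between actual and predicted counts on the test
fold.  Predictions are the expected counts — continuous, not rounded.
Features are standardized with train-fold parameters inside every fit.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, PoissonRegressor

from . import metrics
from .cohort import clip_lesion_count
from .exceptions import ParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

LOGISTIC_C = 1.0
POISSON_ALPHA = 1e-6
ROC_GRID_POINTS = 101


@dataclasses.dataclass
class EvaluationReport:
    """Bootstrap-ensemble performance of one feature set on one endpoint."""

    metric: str
    mean: float
    sd: float
    per_rep: np.ndarray  # NaN where the rep was dropped
    n_dropped: int
    endpoint: str = ""
    feature_set: str = ""
    roc: metrics.RocBand | None = None
    slope: float | None = None
    intercept: float | None = None
    rmse: float | None = None

    def __post_init__(self) -> None:
        vals = self.per_rep[~np.isnan(self.per_rep)]
        if len(vals) and not (vals.min() - 1e-12 <= self.mean <= vals.max() + 1e-12):
            raise ValueError("report mean outside the per-rep range")


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _fit_scores(
    kind: str, Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray
) -> np.ndarray:
    """Fit one fold's model and return test scores (decision values for the
    classifier, expected counts for the Poisson regression)."""
    Ztr, Zte = _standardize(Xtr, Xte)
    if kind == "logistic":
        model = LogisticRegression(C=LOGISTIC_C, max_iter=1000)
        model.fit(Ztr, ytr)
        return model.decision_function(Zte)
    if kind == "poisson":
        model = PoissonRegressor(alpha=POISSON_ALPHA, max_iter=300)
        model.fit(Ztr, ytr)
        return model.predict(Zte)
    raise ParameterError(f"unknown model kind {kind!r}")


def bootstrap_metric(
    X: np.ndarray,
    target: np.ndarray,
    plan,
    kind: str = "logistic",
    metric: str = "auroc",
) -> np.ndarray:
    """Per-rep test metric of one feature set over a bootstrap plan.

    Returns an array of length ``plan.n_reps`` with NaN where the rep was
    dropped (single-class test fold or a failed fit).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(target):
        X = X.T
    out = np.full(plan.n_reps, np.nan)
    for r, (train, test) in enumerate(plan.splits):
        try:
            scores = _fit_scores(kind, X[train], target[train], X[test])
            if metric == "auroc":
                out[r] = metrics.auroc(target[test], scores)
            elif metric == "r_squared":
                out[r] = metrics.pearson_r2(target[test], scores)
            else:
                raise ParameterError(f"unknown metric {metric!r}")
        except (UndefinedStatisticError, np.linalg.LinAlgError):
            continue
        except ParameterError:
            raise
        except Exception:
            logger.debug("rep %d dropped (fit failure)", r)
            continue
    return out


def fit_eval_classifier(
    X: np.ndarray,
    y: np.ndarray,
    plan,
    endpoint: str = "",
    feature_set: str = "",
    roc_grid: int = ROC_GRID_POINTS,
) -> EvaluationReport:
    """Bootstrap-evaluate a logistic classifier: per-rep test AUROC plus a
    vertically averaged ROC band on a fixed FPR grid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    per_rep = np.full(plan.n_reps, np.nan)
    curves = []
    for r, (train, test) in enumerate(plan.splits):
        try:
            scores = _fit_scores("logistic", X[train], y[train], X[test])
            per_rep[r] = metrics.auroc(y[test], scores)
            curves.append(metrics.roc_points(y[test], scores))
        except UndefinedStatisticError:
            continue
    vals = per_rep[~np.isnan(per_rep)]
    if len(vals) == 0:
        raise UndefinedStatisticError("every bootstrap rep was dropped")
    return EvaluationReport(
        metric="auroc",
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        per_rep=per_rep,
        n_dropped=int(np.isnan(per_rep).sum()),
        endpoint=endpoint,
        feature_set=feature_set,
        roc=metrics.roc_band(curves, roc_grid),
    )


def fit_eval_poisson(
    X: np.ndarray,
    counts: np.ndarray,
    plan,
    cap: int = 5,
    endpoint: str = "lesion_count",
    feature_set: str = "",
) -> EvaluationReport:
    """Bootstrap-evaluate the clipped Poisson lesion-count regression.

    Counts are clipped at ``cap`` before fitting *and* evaluation.  The
    report's R^2 is the square of Pearson's correlation between actual and
    predicted counts on the test fold; the pooled actual-vs-predicted cloud
    yields the best-fit line and RMSE.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(counts):
        X = X.T
    c = clip_lesion_count(np.asarray(counts, dtype=float), cap=cap)
    per_rep = np.full(plan.n_reps, np.nan)
    pooled_actual: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for r, (train, test) in enumerate(plan.splits):
        try:
            mu = _fit_scores("poisson", X[train], c[train], X[test])
            per_rep[r] = metrics.pearson_r2(c[test], mu)
            pooled_actual.append(c[test])
            pooled_pred.append(mu)
        except (UndefinedStatisticError, Exception) as err:  # noqa: BLE001
            if isinstance(err, ParameterError):
                raise
            continue
    vals = per_rep[~np.isnan(per_rep)]
    if len(vals) == 0:
        raise UndefinedStatisticError("every bootstrap rep was dropped")
    actual = np.concatenate(pooled_actual)
    pred = np.concatenate(pooled_pred)
    slope, intercept = np.polyfit(actual, pred, 1)
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    return EvaluationReport(
        metric="r_squared",
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        per_rep=per_rep,
        n_dropped=int(np.isnan(per_rep).sum()),
        endpoint=endpoint,
        feature_set=feature_set,
        slope=float(slope),
        intercept=float(intercept),
        rmse=rmse,
    )


def evaluate_gda_sda_eda(
    X: np.ndarray,
    y_gda: np.ndarray,
    sub_labels: Mapping[str, np.ndarray],
    plan,
    feature_set: str = "gfs",
) -> dict[str, EvaluationReport]:
    """Score a GDA-trained classifier ensemble on the GDA, SDA and EDA
    contrasts.

    ``sub_labels`` maps endpoint name to an integer array aligned with the
    rows of ``X`` (1 positive, 0 negative, -1 excluded); the GDA entry
    should equal ``y_gda``.  Each rep's model is trained once under the GDA
    labeling and its test AUROC recomputed on the test samples belonging to
    each sub-endpoint's positive/negative sets; reps whose restricted test
    fold is single-class are dropped for that sub-endpoint only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y_gda):
        X = X.T
    per_rep = {k: np.full(plan.n_reps, np.nan) for k in sub_labels}
    for r, (train, test) in enumerate(plan.splits):
        scores = _fit_scores("logistic", X[train], y_gda[train], X[test])
        for name, lab in sub_labels.items():
            lab_test = lab[test]
            keep = lab_test >= 0
            try:
                per_rep[name][r] = metrics.auroc(lab_test[keep], scores[keep])
            except UndefinedStatisticError:
                continue
    out = {}
    for name, vals_all in per_rep.items():
        vals = vals_all[~np.isnan(vals_all)]
        if len(vals) == 0:
            raise UndefinedStatisticError(f"every rep dropped for {name}")
        out[name] = EvaluationReport(
            metric="auroc",
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=0)),
            per_rep=vals_all,
            n_dropped=int(np.isnan(vals_all).sum()),
            endpoint=name,
            feature_set=feature_set,
        )
    return out


def feature_set_comparison(
    features: pd.DataFrame,
    target: np.ndarray,
    plan,
    gfs_set: Sequence[str],
    anchor: str,
    kind: str = "logistic",
    endpoint: str = "",
    cap: int = 5,
) -> dict[str, EvaluationReport]:
    """Paired comparison of three feature sets on one plan: the GFS
    selection, the anchor analyte alone, and everything except the anchor.
    """
    if anchor not in features.columns:
        raise ParameterError(f"anchor {anchor!r} not in the feature pool")
    if len(gfs_set) == 0:
        raise ParameterError("GFS feature set is empty")
    sets = {
        "gfs": list(gfs_set),
        "anchor_only": [anchor],
        "all_except_anchor": [c for c in features.columns if c != anchor],
    }
    out = {}
    for name, cols in sets.items():
        X = features[cols].to_numpy(float)
        if kind == "logistic":
            out[name] = fit_eval_classifier(
                X, target, plan, endpoint=endpoint, feature_set=name
            )
        else:
            out[name] = fit_eval_poisson(
                X, target, plan, cap=cap, endpoint=endpoint, feature_set=name
            )
    return out


def permutation_importance(
    features: pd.DataFrame,
    target: np.ndarray,
    plan,
    kind: str = "logistic",
    metric: str = "auroc",
    n_permutations: int = 1,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-feature performance decrease under within-test-fold permutation.

    For every bootstrap rep the model is fit on the train fold; each
    feature's column in the test fold is then shuffled (``n_permutations``
    times, default one shuffle per rep) and the drop in the test metric
    recorded.  Returns a DataFrame indexed by feature with the mean and sd
    of the decrease across reps.
    """
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    X = features.to_numpy(float)
    cols = list(features.columns)
    decreases = np.full((plan.n_reps, len(cols)), np.nan)
    for r, (train, test) in enumerate(plan.splits):
        Ztr, Zte = _standardize(X[train], X[test])
        yte = target[test]
        try:
            if kind == "logistic":
                model = LogisticRegression(C=LOGISTIC_C, max_iter=1000)
                model.fit(Ztr, target[train])
                base = metrics.auroc(yte, model.decision_function(Zte))
            else:
                model = PoissonRegressor(alpha=POISSON_ALPHA, max_iter=300)
                model.fit(Ztr, target[train])
                base = metrics.pearson_r2(yte, model.predict(Zte))
        except UndefinedStatisticError:
            continue
        for j in range(len(cols)):
            drops = []
            for _ in range(n_permutations):
                Zp = Zte.copy()
                Zp[:, j] = Zp[rng.permutation(len(test)), j]
                try:
                    if kind == "logistic":
                        m = metrics.auroc(yte, model.decision_function(Zp))
                    else:
                        m = metrics.pearson_r2(yte, model.predict(Zp))
                except UndefinedStatisticError:
                    continue
                drops.append(base - m)
            if drops:
                decreases[r, j] = float(np.mean(drops))
    return pd.DataFrame(
        {
            "mean_decrease": np.nanmean(decreases, axis=0),
            "sd_decrease": np.nanstd(decreases, axis=0),
            "n_reps": np.sum(~np.isnan(decreases), axis=0),
        },
        index=pd.Index(cols, name="protein_id"),
    )
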