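"""Anchor-seeded randomized-subset importance ensemble and panel selection.

The multivariate screen asks which proteins keep showing up as important
across *many* small models rather than in one hand-picked model.  For each
model size (3-21 proteins in steps of three) and each architecture
(logistic regression, linear-kernel SVC, random forest), random feature
subsets are drawn, always seeded with the anchor analyte (the NfL analog),
the model is fit on the full dataset, and its training AUROC recorded — a
deliberately optimistic protocol whose bias is shared by every candidate
protein and therefore cancels in the ranking.

Per-model feature importances are architecture-specific:

* logistic regression — ``|coef_j| * sd(x_j)`` (standardized-coefficient
  magnitude; on a log-like NPX scale the spread differs little across
  proteins, so this mainly removes units),
* linear SVC — ``|coef_j|``,
* random forest — impurity (Gini) importances of the fitted forest.

Each model's importance vector is normalized to unit sum, weighted by the
model's AUROC, and a protein's aggregate score is the mean of those
weighted importances over the models *containing* it.  Panel selection
integrates each endpoint's univariate and multivariate rankings by summed
rank and keeps the top ``panel_budget`` proteins (default 20; a reserved
analyte may be appended afterwards).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from . import metrics
from .cohort import BinaryLabeling
from .exceptions import (
    DegenerateImportanceError,
    ParameterError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

ARCHITECTURES = ("logistic", "linear_svc", "random_forest")
DEFAULT_SIZES = (3, 6, 9, 12, 15, 18, 21)


@dataclasses.dataclass
class ScreenConfig:
    """Randomized-subset screen settings.

    ``repeats`` is per (size, architecture) combination; 2,000 is the
    desk-scale default, 100,000 the full-scale study setting.  Model
    hyperparameters are fixed here and echoed in the run manifest: unit-C
    L2 logistic regression and linear SVC, and a shallow 25-tree forest
    (depth 6), which is ample for subsets of at most 21 features.
    """

    sizes: Sequence[int] = DEFAULT_SIZES
    architectures: Sequence[str] = ARCHITECTURES
    repeats: int = 2000
    anchor_protein: str = "NEFL"
    rng_seed: int = 0
    panel_budget: int = 20
    logistic_C: float = 1.0
    svc_C: float = 1.0
    rf_n_estimators: int = 25
    rf_max_depth: int | None = 6
    importance_rule: str = "coef_times_sd"  # or "coef_over_variance"

    def validate(self, protein_ids: Iterable[str]) -> None:
        ids = set(protein_ids)
        if self.anchor_protein not in ids:
            raise ParameterError(f"anchor {self.anchor_protein!r} not in the matrix")
        if min(self.sizes) < 2:
            raise ParameterError("model sizes must be >= 2")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")
        unknown = set(self.architectures) - set(ARCHITECTURES)
        if unknown:
            raise ParameterError(f"unknown architectures: {sorted(unknown)}")


def draw_subset(
    protein_ids: Sequence[str],
    size: int,
    anchor: str,
    rng: np.random.Generator,
) -> list[str]:
    """Anchor plus ``size - 1`` distinct uniformly drawn other proteins."""
    if anchor not in protein_ids:
        raise ParameterError(f"anchor {anchor!r} not in the pool")
    if size > len(protein_ids):
        raise ParameterError("subset size exceeds the protein pool")
    others = [p for p in protein_ids if p != anchor]
    if size == 1:
        return [anchor]
    chosen = rng.choice(len(others), size=size - 1, replace=False)
    return [anchor] + [others[i] for i in sorted(chosen)]


def _make_model(architecture: str, config: ScreenConfig, seed: int):
    if architecture == "logistic":
        return LogisticRegression(C=config.logistic_C, max_iter=500)
    if architecture == "linear_svc":
        return LinearSVC(C=config.svc_C, max_iter=2000)
    if architecture == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            random_state=seed,
            n_jobs=1,
        )
    raise ParameterError(f"unknown architecture {architecture!r}")


def model_importance(
    architecture: str,
    model,
    feature_sds: np.ndarray,
    rule: str = "coef_times_sd",
) -> np.ndarray:
    """Raw (unnormalized) per-feature importance of one fitted model."""
    if architecture == "logistic":
        coef = np.abs(np.ravel(model.coef_))
        if rule == "coef_times_sd":
            return coef * np.asarray(feature_sds)
        if rule == "coef_over_variance":
            return coef / np.maximum(np.asarray(feature_sds) ** 2, 1e-12)
        raise ParameterError(f"unknown importance rule {rule!r}")
    if architecture == "linear_svc":
        kernel = getattr(model, "kernel", "linear")
        if kernel != "linear":
            raise ParameterError("SVC importance requires a linear kernel")
        return np.abs(np.ravel(model.coef_))
    if architecture == "random_forest":
        return np.asarray(model.feature_importances_)
    raise ParameterError(f"unknown architecture {architecture!r}")


def normalize_importance(raw: np.ndarray) -> np.ndarray:
    """Scale a nonnegative importance vector to unit sum."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ParameterError("importances must be nonnegative")
    total = raw.sum()
    if total == 0:
        raise DegenerateImportanceError("all-zero importance vector")
    return raw / total


def train_eval_screen_model(
    subset: Sequence[str],
    features: pd.DataFrame,
    labeling: BinaryLabeling | np.ndarray,
    architecture: str,
    config: ScreenConfig | None = None,
    seed: int = 0,
    held_out_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Fit one subset model and score it by AUROC.

    By default the model is trained on the entire dataset and scored on the
    same samples (training AUROC — the screen's optimistic-by-design
    protocol).  ``held_out_fraction > 0`` switches to a random held-out
    split scored on the held-out part.
    """
    config = config or ScreenConfig()
    y = labeling.encode(features.index) if isinstance(labeling, BinaryLabeling) else np.asarray(labeling)
    keep = y >= 0
    X = features.loc[keep, list(subset)].to_numpy(float)
    yk = y[keep]
    model = _make_model(architecture, config, seed)
    if held_out_fraction > 0:
        rng = rng or np.random.default_rng(seed)
        n = len(yk)
        perm = rng.permutation(n)
        n_hold = max(1, int(round(held_out_fraction * n)))
        hold, train = perm[:n_hold], perm[n_hold:]
        model.fit(X[train], yk[train])
        scores = _scores(model, X[hold])
        return model, metrics.auroc(yk[hold], scores)
    model.fit(X, yk)
    return model, metrics.auroc(yk, _scores(model, X))


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def aggregate_importance(
    records: Iterable[tuple[Sequence[int], float, np.ndarray]],
    protein_ids: Sequence[str],
) -> pd.DataFrame:
    """Aggregate per-model unit-sum importances into an importance table.

    ``records`` yields ``(feature indices, model AUROC, unit-sum
    importances)``.  A protein's score is the mean over the models it
    appeared in of (AUROC x importance); proteins never sampled get a
    missing score and rank.
    """
    p = len(protein_ids)
    sums = np.zeros(p)
    n_models = np.zeros(p, dtype=int)
    for idx, auroc, unit_imp in records:
        idx = np.asarray(idx, dtype=int)
        sums[idx] += auroc * np.asarray(unit_imp)
        n_models[idx] += 1
    score = np.where(n_models > 0, sums / np.maximum(n_models, 1), np.nan)
    table = pd.DataFrame(
        {"importance": score, "n_models": n_models}, index=pd.Index(protein_ids, name="protein_id")
    )
    table["rank"] = table["importance"].rank(ascending=False, method="first")
    return table.sort_values("rank")


def run_screen(
    features: pd.DataFrame,
    labeling: BinaryLabeling,
    config: ScreenConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run the full randomized-subset screen for one endpoint.

    Returns the aggregated importance table (proteins indexed, columns
    ``importance`` / ``n_models`` / ``appearances`` / ``rank``) and a run
    manifest recording seeds, settings, and degenerate/failed model counts.
    The anchor is part of every sampled subset by construction, so its
    appearance count equals the total number of models sampled.
    """
    protein_ids = list(features.columns)
    config.validate(protein_ids)
    y = labeling.encode(features.index)
    keep = y >= 0
    X_all = features.loc[keep].to_numpy(float)
    yk = y[keep]
    if len(np.unique(yk)) < 2:
        raise UndefinedStatisticError("screen needs both classes present")
    sds = X_all.std(axis=0, ddof=0)
    id_to_col = {pid: j for j, pid in enumerate(protein_ids)}
    anchor_col = id_to_col[config.anchor_protein]
    other_cols = np.array([j for j in range(len(protein_ids)) if j != anchor_col])

    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    p = len(protein_ids)
    sums = np.zeros(p)
    n_models = np.zeros(p, dtype=int)
    appearances = np.zeros(p, dtype=int)
    degenerate = 0
    failures = 0
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for size in config.sizes:
            if size > p:
                raise ParameterError(f"model size {size} exceeds pool of {p}")
            for architecture in config.architectures:
                for rep in range(config.repeats):
                    chosen = rng.choice(len(other_cols), size=size - 1, replace=False)
                    cols = np.r_[anchor_col, other_cols[chosen]]
                    total += 1
                    appearances[cols] += 1
                    Xs = X_all[:, cols]
                    model = _make_model(architecture, config, seed=int(rng.integers(2**31)))
                    try:
                        model.fit(Xs, yk)
                        auroc = metrics.auroc(yk, _scores(model, Xs))
                        unit = normalize_importance(
                            model_importance(
                                architecture, model, sds[cols], config.importance_rule
                            )
                        )
                    except DegenerateImportanceError:
                        degenerate += 1
                        continue
                    except Exception:  # fit failure: record and move on
                        failures += 1
                        continue
                    sums[cols] += auroc * unit
                    n_models[cols] += 1
    score = np.where(n_models > 0, sums / np.maximum(n_models, 1), np.nan)
    table = pd.DataFrame(
        {
            "importance": score,
            "n_models": n_models,
            "appearances": appearances,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    table["rank"] = table["importance"].rank(ascending=False, method="first")
    table = table.sort_values("rank")
    manifest = {
        "endpoint": labeling.endpoint,
        "rng_seed": config.rng_seed,
        "sizes": list(config.sizes),
        "architectures": list(config.architectures),
        "repeats": config.repeats,
        "anchor_protein": config.anchor_protein,
        "importance_rule": config.importance_rule,
        "hyperparameters": {
            "logistic_C": config.logistic_C,
            "svc_C": config.svc_C,
            "rf_n_estimators": config.rf_n_estimators,
            "rf_max_depth": config.rf_max_depth,
        },
        "n_models_sampled": total,
        "n_degenerate": degenerate,
        "n_failures": failures,
    }
    if degenerate or failures:
        logger.info(
            "screen for %s: %d degenerate, %d failed of %d models",
            labeling.endpoint,
            degenerate,
            failures,
            total,
        )
    return table, manifest


def select_panel(
    rank_lists: Mapping[str, pd.Series],
    budget: int = 20,
    reserved: Sequence[str] = (),
) -> list[str]:
    """Integrate univariate and multivariate rankings into one panel.

    ``rank_lists`` maps list names (e.g. ``"GDA_univariate"``,
    ``"GDA_multivariate"``) to Series of ranks (1 = best) indexed by
    protein.  Integration is by summed rank over all lists, a protein
    missing from a list contributing that list's length + 1.  The top
    ``budget`` proteins are returned, with any ``reserved`` analytes
    appended afterwards (uncomputed, post-hoc panel slots).
    """
    if not rank_lists:
        raise ParameterError("need at least one ranking list")
    pool: set[str] = set()
    for ranks in rank_lists.values():
        pool.update(ranks.index)
    if budget > len(pool):
        raise ParameterError(f"budget {budget} exceeds pool of {len(pool)}")
    total = pd.Series(0.0, index=sorted(pool))
    for ranks in rank_lists.values():
        total = total.add(ranks.reindex(total.index).fillna(len(ranks) + 1))
    ordered = total.sort_values(kind="mergesort")  # stable: ties by protein id
    panel = list(ordered.index[:budget])
    return panel + [r for r in reserved if r not in panel]
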