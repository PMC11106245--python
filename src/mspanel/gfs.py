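"""Bootstrap-ensembled greedy forward selection and plateau-based sizing.

Greedy forward selection (GFS) builds a nested sequence of feature sets:
it seeds with the single feature whose mean test metric over the bootstrap
plan is highest, then repeatedly adds whichever remaining feature most
improves that mean, until the pool is exhausted.  The resulting curve of
mean +/- sd versus model size typically climbs, plateaus, then degrades as
pure-noise features arrive; the working model size is where adding a
feature stops improving performance significantly — concretized here as a
one-standard-error rule on the step improvement (the z multiplier is
configurable).

All candidate evaluations at a given step reuse the same
:class:`BootstrapPlan`, so the comparison between candidates is paired.
Ties are broken toward the lexicographically smaller protein id.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import models
from .exceptions import ParameterError, PlanningError

logger = logging.getLogger(__name__)

TRAIN_FRACTION = 2.0 / 3.0


@dataclasses.dataclass
class BootstrapPlan:
    """Reproducible list of train/test splits (two-thirds / one-third).

    Splits are stratified by class so every train and every test fold
    contains both classes; each rep's train and test sets partition the
    samples.
    """

    splits: list[tuple[np.ndarray, np.ndarray]]
    n_reps: int
    train_fraction: float
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for train, test in self.splits:
            n = len(train) + len(test)
            if len(np.union1d(train, test)) != n:
                raise PlanningError("train and test must partition the samples")


def make_bootstrap_plan(
    n_samples: int,
    strata: np.ndarray | None,
    n_reps: int = 1000,
    train_fraction: float = TRAIN_FRACTION,
    rng_seed: int = 0,
) -> BootstrapPlan:
    """Draw ``n_reps`` stratified train/test splits of ``n_samples`` rows.

    ``strata`` is a per-sample class array (binary endpoint labels, or a
    binarized surrogate for regression targets); pass None for plain
    unstratified splits.  Every stratum must have >= 2 members so it can
    appear on both sides of each split.
    """
    if n_samples < 6:
        raise PlanningError("need at least 6 samples to split 2/3 - 1/3")
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    if strata is None:
        strata = np.zeros(n_samples, dtype=int)
    strata = np.asarray(strata)
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for g in groups:
        if len(g) < 2:
            raise PlanningError(
                "a stratum has fewer than 2 samples and cannot appear in "
                "both partitions"
            )
    splits = []
    for _ in range(n_reps):
        train_parts, test_parts = [], []
        for g in groups:
            perm = g[rng.permutation(len(g))]
            k = int(round(train_fraction * len(g)))
            k = min(max(k, 1), len(g) - 1)
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        splits.append(
            (np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts)))
        )
    return BootstrapPlan(
        splits=splits,
        n_reps=n_reps,
        train_fraction=train_fraction,
        rng_seed=rng_seed,
    )


@dataclasses.dataclass
class GFSCurve:
    """Ordered selected features with the bootstrap metric at each size."""

    features: list[str]
    means: np.ndarray
    sds: np.ndarray
    metric: str
    n_reps: int
    n_dropped: np.ndarray

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, len(self.features) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "added_feature": self.features,
                "mean": self.means,
                "sd": self.sds,
                "n_dropped": self.n_dropped,
            }
        )


def greedy_forward_select(
    features: pd.DataFrame,
    target: np.ndarray,
    plan: BootstrapPlan,
    kind: str = "logistic",
    metric: str = "auroc",
) -> GFSCurve:
    """Greedy forward selection over the full feature pool.

    ``features`` is a samples x proteins DataFrame restricted to the
    endpoint's included samples; ``target`` the 0/1 labels (classification)
    or clipped counts (regression).  The first selected feature maximizes
    the mean univariate test metric over the plan; each later step adds the
    feature maximizing the mean test metric of the grown set.  Candidates
    whose metric is undefined on some rep (e.g. a single-class restricted
    fold) simply lose that rep; the drop count of the selected set is
    recorded per size.
    """
    pool = sorted(features.columns)
    if len(pool) < 1:
        raise ParameterError("need at least one candidate feature")
    X = features.to_numpy(float)
    col = {pid: j for j, pid in enumerate(features.columns)}
    selected: list[str] = []
    means, sds, dropped = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while pool:
            best_id, best_mean, best_rep = None, -np.inf, None
            for pid in pool:  # sorted order makes ties lexicographic
                cols = [col[p] for p in selected + [pid]]
                per_rep = models.bootstrap_metric(
                    X[:, cols], target, plan, kind=kind, metric=metric
                )
                vals = per_rep[~np.isnan(per_rep)]
                if len(vals) == 0:
                    continue
                m = float(vals.mean())
                if m > best_mean:
                    best_id, best_mean, best_rep = pid, m, per_rep
            if best_id is None:
                raise PlanningError("no candidate feature evaluable on this plan")
            selected.append(best_id)
            pool.remove(best_id)
            vals = best_rep[~np.isnan(best_rep)]
            means.append(best_mean)
            sds.append(float(vals.std(ddof=0)))
            dropped.append(int(np.isnan(best_rep).sum()))
    return GFSCurve(
        features=selected,
        means=np.asarray(means),
        sds=np.asarray(sds),
        metric=metric,
        n_reps=plan.n_reps,
        n_dropped=np.asarray(dropped),
    )


def optimal_size(curve: GFSCurve, z: float = 1.0) -> int:
    """Plateau-based model size: the smallest k whose next step is not a
    significant improvement.

    Step k -> k+1 counts as significant when ``mean(k+1) - mean(k) >=
    z * sd(k) / sqrt(n_reps)`` (a one-standard-error rule on the ensemble
    mean by default).  A curve that never improves returns 1 with a
    warning; a curve that improves significantly everywhere returns its
    full length.
    """
    if len(curve.features) < 2:
        return len(curve.features)
    se = curve.sds / np.sqrt(max(curve.n_reps, 1))
    gains = np.diff(curve.means)
    if (gains <= 0).all():
        logger.warning("GFS curve never improves; optimal size is 1")
        return 1
    for k in range(len(gains)):
        if gains[k] < z * se[k]:
            return k + 1
    return len(curve.features)
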