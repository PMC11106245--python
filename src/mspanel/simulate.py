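"""Synthetic multi-cohort serum-proteomics generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at the scale of a three-cohort MS serum study (~630 samples):

* a CLIMB-like cohort carrying gadolinium-lesion counts (with MRI-to-draw
  offsets) and annualized relapse rates,
* an EPIC-like cohort carrying lesion counts only,
* an ACP-like cohort carrying clinical relapse status only,
* assay batches with additive per-protein offsets, plus shared bridge
  aliquots re-measured in every batch,
* linear demographic effects (age, sex, disease duration) on protein levels,
* sparse true protein-endpoint effects with one dominant anchor analyte
  (an NfL analog) shared by every endpoint.

Generative model
----------------
Each sample carries a latent standardized protein score ``z_ij ~ N(0,1)``.
The measured level on the log-like NPX scale is

    NPX_ij = baseline_j + batch_offset[b(i), j]
             + gamma_age_j * age_i + gamma_sex_j * sex01_i
             + gamma_dd_j * duration_i + s * z_ij + eps_ij,

with ``s`` the signal scale and ``eps ~ N(0, noise_sd^2)``.  Endpoints are
driven by the same latents through sparse coefficient vectors ``beta``:

* lesion count  ~ Poisson(exp(alpha + sum_j beta_j z_ij)),
* relapse state ~ Bernoulli(logistic(c_CRS + sum_j beta_j z_ij)),
* ARR class high ~ Bernoulli(logistic(c_H + sum_j beta_j z_ij)), with the
  numeric rate then drawn inside the class band; the low class is drawn
  among the remainder with a negatively loaded logistic.  The class
  intercepts are calibrated on the realized latents so the requested
  prevalences are met in expectation.

ARR shares its latent predictor with relapse status by default, so the
clinical endpoints are correlated, as in real MS cohorts.

Everything is reproducible bit-for-bit from ``rng_seed`` through one seed
sequence with fixed substreams per cohort, for batches, and for bridges.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import ConfigError

ANCHOR_NAME = "NEFL"

#: Demographic distributions, loosely matching the pooled cohort summaries:
#: age ~ N(39, 9) years, disease duration ~ |N(7, 6)| years, P(F) = 0.73.
AGE_MEAN, AGE_SD = 39.0, 9.0
DD_MEAN, DD_SD = 7.0, 6.0
P_FEMALE = 0.73


def _default_n_samples() -> dict[str, int]:
    # Cohort sizes of the emulated study: 326 / 180 / 124.
    return {"CLIMB-like": 326, "EPIC-like": 180, "ACP-like": 124}


def _default_covariate_effects() -> dict[str, float]:
    # NPX units per covariate unit (year, F->M indicator, year).
    return {"age": 0.01, "sex": 0.2, "disease_duration": 0.02}


def default_causal_sets(
    n_proteins: int,
    anchor: int = 0,
    anchor_beta: float = 0.9,
    secondary_beta: float = 0.35,
    n_secondary: int = 9,
) -> dict[str, list[tuple[int, float]]]:
    """Sparse true effects: the anchor dominates every endpoint; each
    endpoint adds ``n_secondary`` weaker proteins.  The lesion endpoint and
    the clinical endpoints use overlapping but distinct secondary sets; ARR
    shares the CRS set (shared latent relapse process)."""
    pool = [j for j in range(n_proteins) if j != anchor]
    if len(pool) < n_secondary + 3:
        raise ConfigError("n_proteins too small for the default causal sets")
    gd = pool[:n_secondary]
    crs = pool[3 : 3 + n_secondary]
    sets = {
        "GD": [(anchor, anchor_beta)] + [(j, secondary_beta) for j in gd],
        "CRS": [(anchor, 0.8 * anchor_beta)] + [(j, 0.85 * secondary_beta) for j in crs],
    }
    sets["ARR"] = list(sets["CRS"])
    return sets


@dataclasses.dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions.

    ``causal_sets`` maps latent endpoints ("GD", "CRS", "ARR") to lists of
    ``(protein index, beta)``; when None the defaults of
    :func:`default_causal_sets` are built at generation time.
    """

    n_samples: Mapping[str, int] = dataclasses.field(default_factory=_default_n_samples)
    n_proteins: int = 100
    n_batches: int = 3
    n_bridge: int = 8
    batch_offset_sd: float = 0.5
    noise_sd: float = 0.4
    signal_scale: float = 1.0
    covariate_effects: Mapping[str, float] = dataclasses.field(
        default_factory=_default_covariate_effects
    )
    causal_sets: Mapping[str, Sequence[tuple[int, float]]] | None = None
    anchor_protein: int = 0
    poisson_intercept: float = -0.7
    crs_prevalence: float = 0.48
    arr_high_prevalence: float = 0.08
    arr_low_prevalence: float = 0.80
    bridge_pool_sd: float = 0.5
    rng_seed: int = 0

    def resolved_causal_sets(self) -> dict[str, list[tuple[int, float]]]:
        if self.causal_sets is None:
            return default_causal_sets(self.n_proteins, self.anchor_protein)
        return {k: list(v) for k, v in self.causal_sets.items()}

    def validate(self, check_causal: bool = True) -> None:
        if self.n_proteins < 2:
            raise ConfigError("n_proteins must be >= 2")
        for name in ("batch_offset_sd", "noise_sd", "signal_scale", "bridge_pool_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if self.n_batches > 1 and self.n_bridge < 2:
            raise ConfigError("n_bridge must be >= 2 when n_batches > 1")
        if not 0 <= self.anchor_protein < self.n_proteins:
            raise ConfigError("anchor_protein outside the protein range")
        if not check_causal:
            return
        sets = self.resolved_causal_sets()
        for endpoint, pairs in sets.items():
            idx = [j for j, _ in pairs]
            if any(j < 0 or j >= self.n_proteins for j in idx):
                raise ConfigError(
                    f"causal index out of range for endpoint {endpoint!r}"
                )
            if self.anchor_protein not in idx:
                raise ConfigError(
                    f"anchor protein must appear in the causal set of {endpoint!r}"
                )

    def protein_ids(self) -> list[str]:
        ids = [f"P{j:04d}" for j in range(self.n_proteins)]
        ids[self.anchor_protein] = ANCHOR_NAME
        return ids

    def beta_matrix(self) -> dict[str, np.ndarray]:
        """Dense per-endpoint coefficient vectors over all proteins."""
        out = {}
        for endpoint, pairs in self.resolved_causal_sets().items():
            beta = np.zeros(self.n_proteins)
            for j, b in pairs:
                beta[j] = b
            out[endpoint] = beta
        return out


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    beta: dict[str, np.ndarray]
    batch_offsets: np.ndarray  # (n_batches, n_proteins)
    covariate_coefs: pd.DataFrame  # proteins x (age, sex, disease_duration)
    baselines: np.ndarray
    poisson_intercept: float
    crs_intercept: float
    arr_intercepts: tuple[float, float]
    causal_indices: dict[str, list[int]]
    anchor_protein: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": {k: v.tolist() for k, v in self.beta.items()},
            "batch_offsets": self.batch_offsets.tolist(),
            "covariate_coefs": self.covariate_coefs.to_dict(orient="index"),
            "baselines": self.baselines.tolist(),
            "poisson_intercept": self.poisson_intercept,
            "crs_intercept": self.crs_intercept,
            "arr_intercepts": list(self.arr_intercepts),
            "causal_indices": self.causal_indices,
            "anchor_protein": self.anchor_protein,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(logistic(c + eta)) == target on realized eta."""
    if not 0 < target < 1:
        raise ConfigError("prevalence targets must lie in (0, 1)")

    def gap(c: float) -> float:
        return float(special.expit(c + eta).mean() - target)

    span = float(np.abs(eta).max()) + 40.0
    return float(optimize.brentq(gap, -span, span))


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), 1.0, None)
    sex = np.where(rng.random(n) < P_FEMALE, "F", "M")
    dd = np.abs(rng.normal(DD_MEAN, DD_SD, n))
    days = rng.integers(0, 1096, n)
    dates = (np.datetime64("2017-01-01") + days.astype("timedelta64[D]")).astype(str)
    return pd.DataFrame(
        {"age": age, "sex": sex, "disease_duration": dd, "draw_date": dates}
    )


def expected_variance_components(config: GeneratorConfig) -> dict[str, float]:
    """Closed-form marginal NPX variance decomposition for one protein:
    batch + covariate + latent-signal + noise terms of the generative
    equation (disease-duration variance via the folded normal)."""
    eff = config.covariate_effects
    dd_var = float(stats.foldnorm(c=DD_MEAN / DD_SD, scale=DD_SD).var())
    return {
        "batch": config.batch_offset_sd**2,
        "covariates": (
            eff["age"] ** 2 * AGE_SD**2
            + eff["sex"] ** 2 * P_FEMALE * (1 - P_FEMALE)
            + eff["disease_duration"] ** 2 * dd_var
        ),
        "signal": config.signal_scale**2,
        "noise": config.noise_sd**2,
    }


def generate_bridge_aliquots(
    config: GeneratorConfig,
    baselines: np.ndarray | None = None,
    batch_offsets: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bridge rows: ``n_bridge`` pooled aliquots, each re-measured once per
    batch.  A measurement differs from the aliquot's underlying value only
    by its batch offset plus measurement noise.

    Returns ``(expression, manifest)`` for the bridge rows alone.  When
    called standalone, baselines / offsets / rng are drawn from the config
    seed, matching :func:`generate_cohorts`.
    """
    config.validate(check_causal=False)
    if config.n_batches > 1 and config.n_bridge == 0:
        raise ConfigError("bridging requires n_bridge > 0 when n_batches > 1")
    p = config.n_proteins
    if rng is None:
        ss = np.random.SeedSequence(config.rng_seed)
        kids = ss.spawn(3)
        rng_struct = np.random.default_rng(kids[0])
        baselines = rng_struct.normal(3.0, 1.0, p) if baselines is None else baselines
        batch_offsets = (
            np.random.default_rng(kids[1]).normal(
                0.0, config.batch_offset_sd, (config.n_batches, p)
            )
            if batch_offsets is None
            else batch_offsets
        )
        rng = np.random.default_rng(kids[2])
    assert baselines is not None and batch_offsets is not None

    pool = baselines + rng.normal(0.0, config.bridge_pool_sd, (config.n_bridge, p))
    rows, meta = [], []
    for a in range(config.n_bridge):
        for b in range(config.n_batches):
            noise = rng.normal(0.0, config.noise_sd, p)
            rows.append(pool[a] + batch_offsets[b] + noise)
            meta.append(
                {
                    "sample_id": f"BRIDGE{a:02d}-B{b + 1}",
                    "cohort": "bridge",
                    "batch_id": f"B{b + 1}",
                    "age": np.nan,
                    "sex": np.nan,
                    "disease_duration": np.nan,
                    "draw_date": "2017-01-01",
                    "is_bridge": True,
                    "bridge_aliquot": f"BRIDGE{a:02d}",
                }
            )
    manifest = pd.DataFrame(meta)
    expr = pd.DataFrame(
        np.vstack(rows), index=manifest["sample_id"], columns=config.protein_ids()
    )
    return expr, manifest


def generate_cohorts(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the full synthetic study.

    Returns ``(expression, manifest, ground_truth)``: a samples x proteins
    NPX matrix (bridge rows included), a cohort manifest DataFrame matching
    the manifest schema, and the :class:`GroundTruth` recovery oracle.
    """
    config.validate()
    p = config.n_proteins
    protein_ids = config.protein_ids()
    beta = config.beta_matrix()
    eff = config.covariate_effects

    ss = np.random.SeedSequence(config.rng_seed)
    kids = ss.spawn(3 + len(config.n_samples))
    rng_struct = np.random.default_rng(kids[0])
    baselines = rng_struct.normal(3.0, 1.0, p)
    batch_offsets = np.random.default_rng(kids[1]).normal(
        0.0, config.batch_offset_sd, (config.n_batches, p)
    )
    gamma = pd.DataFrame(
        {
            "age": np.full(p, eff["age"]),
            "sex": np.full(p, eff["sex"]),
            "disease_duration": np.full(p, eff["disease_duration"]),
        },
        index=protein_ids,
    )

    frames, metas = [], []
    etas: dict[str, dict[str, np.ndarray]] = {}
    for ci, (cohort, n) in enumerate(sorted(config.n_samples.items())):
        rng = np.random.default_rng(kids[3 + ci])
        cov = _covariates(n, rng)
        z = rng.normal(0.0, 1.0, (n, p))
        batches = rng.integers(0, config.n_batches, n)
        sex01 = (cov["sex"] == "M").to_numpy(dtype=float)
        npx = (
            baselines
            + batch_offsets[batches]
            + np.outer(cov["age"], gamma["age"].to_numpy())
            + np.outer(sex01, gamma["sex"].to_numpy())
            + np.outer(cov["disease_duration"], gamma["disease_duration"].to_numpy())
            + config.signal_scale * z
            + rng.normal(0.0, config.noise_sd, (n, p))
        )
        meta = cov.copy()
        meta.insert(0, "sample_id", [f"{cohort.split('-')[0]}-{i:04d}" for i in range(n)])
        meta.insert(1, "cohort", cohort)
        meta.insert(2, "batch_id", [f"B{b + 1}" for b in batches])
        meta["is_bridge"] = False
        meta["gd_lesion_count"] = np.nan
        meta["mri_offset_days"] = np.nan
        meta["crs"] = np.nan
        meta["arr"] = np.nan
        meta["bridge_aliquot"] = np.nan

        eta_cohort = {k: z @ beta[k] for k in beta}
        etas[cohort] = eta_cohort

        if cohort in ("CLIMB-like", "EPIC-like"):
            lam = np.exp(np.clip(config.poisson_intercept + eta_cohort["GD"], -30, 30))
            meta["gd_lesion_count"] = rng.poisson(lam).astype(float)
            meta["mri_offset_days"] = np.round(rng.normal(0.0, 15.0, n)).astype(float)
        if cohort == "ACP-like":
            c_crs = _calibrate_intercept(eta_cohort["CRS"], config.crs_prevalence)
            active = rng.random(n) < special.expit(c_crs + eta_cohort["CRS"])
            meta["crs"] = np.where(active, "exacerbation", "quiescence")
            etas["_crs_intercept"] = {"c": np.array([c_crs])}
        if cohort == "CLIMB-like":
            eta_arr = eta_cohort["ARR"]
            c_high = _calibrate_intercept(eta_arr, config.arr_high_prevalence)
            high = rng.random(n) < special.expit(c_high + eta_arr)
            low_target = config.arr_low_prevalence / max(
                1e-12, 1.0 - special.expit(c_high + eta_arr).mean()
            )
            low_target = min(low_target, 0.999)
            c_low = _calibrate_intercept(-eta_arr[~high], low_target)
            low = np.zeros(n, dtype=bool)
            low[~high] = rng.random((~high).sum()) < special.expit(
                c_low - eta_arr[~high]
            )
            arr = rng.uniform(0.25, 0.95, n)
            arr[low] = rng.uniform(0.0, 0.2, int(low.sum()))
            arr[high] = 1.0 + rng.exponential(0.5, int(high.sum()))
            meta["arr"] = arr
            etas["_arr_intercepts"] = {"c": np.array([c_high, c_low])}
        frames.append(
            pd.DataFrame(npx, index=meta["sample_id"], columns=protein_ids)
        )
        metas.append(meta)

    bridge_rng = np.random.default_rng(kids[2])
    bridge_expr, bridge_meta = generate_bridge_aliquots(
        config, baselines=baselines, batch_offsets=batch_offsets, rng=bridge_rng
    )
    for col in ("gd_lesion_count", "mri_offset_days", "crs", "arr"):
        bridge_meta[col] = np.nan

    manifest = pd.concat(metas + [bridge_meta], ignore_index=True)
    col_order = [
        "sample_id",
        "cohort",
        "batch_id",
        "age",
        "sex",
        "disease_duration",
        "draw_date",
        "is_bridge",
        "gd_lesion_count",
        "mri_offset_days",
        "crs",
        "arr",
        "bridge_aliquot",
    ]
    manifest = manifest[col_order]
    expression = pd.concat(frames + [bridge_expr])
    expression.index.name = "sample_id"

    crs_c = float(etas.get("_crs_intercept", {"c": np.array([np.nan])})["c"][0])
    arr_c = etas.get("_arr_intercepts", {"c": np.array([np.nan, np.nan])})["c"]
    truth = GroundTruth(
        beta={k: v for k, v in beta.items()},
        batch_offsets=batch_offsets,
        covariate_coefs=gamma,
        baselines=baselines,
        poisson_intercept=config.poisson_intercept,
        crs_intercept=crs_c,
        arr_intercepts=(float(arr_c[0]), float(arr_c[1])),
        causal_indices={
            k: sorted(j for j, b in config.resolved_causal_sets()[k]) for k in beta
        },
        anchor_protein=protein_ids[config.anchor_protein],
    )
    return expression, manifest, truth
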