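"""End-to-end orchestration: simulate -> validate -> preprocess ->
univariate -> screen -> gfs -> evaluate -> report.

A run is one immutable directory.  Every stage reads only the serialized
artifacts of earlier stages and writes its own, so a run can be resumed or
partially re-executed from any midpoint; every artifact set carries the
config hash in ``run_manifest.json``.  All randomness derives from the
single ``rng_seed`` through fixed substreams, making reruns bit-identical.

Two presets scale the stochastic depth: ``desk`` (200 bootstrap reps,
2,000 screen repeats per size x architecture) for interactive work, and
``paper`` (1,000 reps, 100,000 repeats) for full-scale runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gfs as gfs_mod
from . import models as models_mod
from . import preprocess as pre
from . import screen as screen_mod
from . import univariate as uni
from .cohort import (
    GD_WINDOW_DAYS,
    LESION_CLIP_CAP,
    clip_lesion_count,
    derive_binary_labels,
    filter_gd_window,
    load_manifest,
)
from .exceptions import EmptyLabelingError, StageError
from .simulate import GeneratorConfig, generate_cohorts

logger = logging.getLogger(__name__)

MODES = {
    "desk": {"n_bootstrap_reps": 200, "screen_repeats": 2000},
    "paper": {"n_bootstrap_reps": 1000, "screen_repeats": 100000},
}

STAGES = (
    "simulate",
    "validate",
    "preprocess",
    "univariate",
    "screen",
    "gfs",
    "evaluate",
    "report",
)

#: (name, endpoint, model kind, metric) of the four multivariate analyses.
ANALYSES = (
    ("lesion_regression", "GDA", "poisson", "r_squared"),
    ("gda", "GDA", "logistic", "auroc"),
    ("crs", "CRS", "logistic", "auroc"),
    ("arr", "ARR", "logistic", "auroc"),
)


def _substream_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global
    seed and a stage label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "run"
    mode: str = "desk"
    rng_seed: int = 0
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    screen: screen_mod.ScreenConfig = dataclasses.field(
        default_factory=screen_mod.ScreenConfig
    )
    panel: list[str] | None = None  # explicit panel bypassing the screen
    bootstrap_reps: int | None = None  # override the mode's bootstrap depth
    screen_repeats: int | None = None  # override the mode's screen repeats
    reserved_analytes: list[str] = dataclasses.field(default_factory=list)
    gd_window_days: int = GD_WINDOW_DAYS
    lesion_cap: int = LESION_CLIP_CAP
    screen_endpoints: tuple[str, ...] = ("GDA", "CRS", "ARR")

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise StageError(f"unknown mode {self.mode!r}")

    @property
    def n_bootstrap_reps(self) -> int:
        if self.bootstrap_reps is not None:
            return self.bootstrap_reps
        return MODES[self.mode]["n_bootstrap_reps"]

    def resolved_screen(self) -> screen_mod.ScreenConfig:
        repeats = (
            self.screen_repeats
            if self.screen_repeats is not None
            else MODES[self.mode]["screen_repeats"]
        )
        return dataclasses.replace(
            self.screen,
            repeats=repeats,
            rng_seed=_substream_seed(self.rng_seed, "screen"),
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["generator"]["n_samples"] = dict(d["generator"]["n_samples"])
        if d["generator"]["causal_sets"] is not None:
            d["generator"]["causal_sets"] = {
                k: [list(t) for t in v]
                for k, v in d["generator"]["causal_sets"].items()
            }
        d["screen"]["sizes"] = list(d["screen"]["sizes"])
        d["screen"]["architectures"] = list(d["screen"]["architectures"])
        d["screen_endpoints"] = list(d["screen_endpoints"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            g = dict(d["generator"])
            if g.get("causal_sets"):
                g["causal_sets"] = {
                    k: [tuple(t) for t in v] for k, v in g["causal_sets"].items()
                }
            d["generator"] = GeneratorConfig(**g)
        if "screen" in d:
            s = dict(d["screen"])
            s["sizes"] = tuple(s.get("sizes", screen_mod.DEFAULT_SIZES))
            s["architectures"] = tuple(
                s.get("architectures", screen_mod.ARCHITECTURES)
            )
            d["screen"] = screen_mod.ScreenConfig(**s)
        if "screen_endpoints" in d:
            d["screen_endpoints"] = tuple(d["screen_endpoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"missing artifact {path.name} from stage {stage!r}")
    return path


def _load_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _endpoint_data(config: RunConfig, run_dir: Path, endpoint: str):
    """Corrected features + encoded labels/counts for one endpoint."""
    table = load_manifest(_need(run_dir / "manifest.csv", "simulate"))
    corrected = _load_matrix(_need(run_dir / "corrected.csv", "preprocess"))
    tab = filter_gd_window(table, config.gd_window_days)
    labeling = derive_binary_labels(tab, endpoint)
    y = labeling.encode(corrected.index)
    keep = y >= 0
    feats = corrected[keep]
    counts = None
    if endpoint in ("GDA", "SDA", "EDA"):
        counts = (
            tab.set_index("sample_id")["gd_lesion_count"]
            .reindex(feats.index)
            .to_numpy(float)
        )
    return feats, y[keep], counts, tab


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order inside ``config.out_dir``."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_log": [],
    }

    def log_stage(name: str, **info: Any) -> None:
        manifest["stage_log"].append({"stage": name, **info})

    if config.stages.get("simulate", True):
        gen = dataclasses.replace(config.generator, rng_seed=config.generator.rng_seed)
        expr, table, truth = generate_cohorts(gen)
        expr.to_csv(run_dir / "matrix.csv")
        table.to_csv(run_dir / "manifest.csv", index=False)
        truth.to_json(run_dir / "ground_truth.json")
        log_stage("simulate", n_samples=len(table), n_proteins=expr.shape[1])

    if config.stages.get("validate", True):
        table = load_manifest(_need(run_dir / "manifest.csv", "simulate"))
        log_stage("validate", n_rows=len(table))

    if config.stages.get("preprocess", True):
        table = load_manifest(_need(run_dir / "manifest.csv", "simulate"))
        matrix = _load_matrix(_need(run_dir / "matrix.csv", "simulate"))
        matrix = pre.drop_high_missingness(matrix)
        normalized = pre.bridge_normalize(matrix, table)
        normalized.to_csv(run_dir / "normalized.csv")
        tab = filter_gd_window(table, config.gd_window_days)
        try:
            reference = derive_binary_labels(tab, "GDA")
        except EmptyLabelingError:
            reference = derive_binary_labels(tab, "CRS")
        model = pre.fit_covariate_correction(normalized, table, reference)
        corrected = pre.apply_covariate_correction(normalized, table, model)
        corrected.to_csv(run_dir / "corrected.csv")
        (run_dir / "preprocess_report.json").write_text(
            json.dumps(pre.preprocess_report(normalized, table, model), indent=1)
        )
        log_stage("preprocess", reference=reference.endpoint, n_reference=model.n_reference)

    if config.stages.get("univariate", True):
        table = load_manifest(_need(run_dir / "manifest.csv", "simulate"))
        normalized = _load_matrix(_need(run_dir / "normalized.csv", "preprocess"))
        patients = table[~table["is_bridge"].astype(bool)]["sample_id"]
        norm_pat = normalized.loc[normalized.index.intersection(patients)]
        stats = uni.run_univariate(norm_pat, table, add_bh=True)
        stats.to_csv(run_dir / "univariate.csv", index=False)
        tab = filter_gd_window(table, config.gd_window_days)
        counts = tab.set_index("sample_id")["gd_lesion_count"].reindex(norm_pat.index)
        bins = np.where(counts >= 3, "3+", counts.astype("string"))
        mask = counts.notna().to_numpy()
        box = {
            protein: uni.boxplot_summary(
                norm_pat[protein].to_numpy(float)[mask], bins[mask]
            )
            .reset_index()
            .to_dict(orient="records")
            for protein in norm_pat.columns
        }
        (run_dir / "boxplots.json").write_text(json.dumps(box, indent=1, default=str))
        log_stage("univariate", n_tests=len(stats))

    if config.stages.get("screen", True):
        table = load_manifest(_need(run_dir / "manifest.csv", "simulate"))
        corrected = _load_matrix(_need(run_dir / "corrected.csv", "preprocess"))
        univ = pd.read_csv(_need(run_dir / "univariate.csv", "univariate"))
        tab = filter_gd_window(table, config.gd_window_days)
        rank_lists: dict[str, pd.Series] = {}
        screen_manifests = {}
        for endpoint in config.screen_endpoints:
            labeling = derive_binary_labels(tab, endpoint)
            cfg = dataclasses.replace(
                config.resolved_screen(),
                rng_seed=_substream_seed(config.rng_seed, f"screen:{endpoint}"),
            )
            importance, smanifest = screen_mod.run_screen(corrected, labeling, cfg)
            importance.to_csv(run_dir / f"importance_{endpoint.lower()}.csv")
            screen_manifests[endpoint] = smanifest
            rank_lists[f"{endpoint}_multivariate"] = importance["rank"]
            u = univ[univ["endpoint"] == endpoint].set_index("protein_id")
            rank_lists[f"{endpoint}_univariate"] = u["auroc"].rank(
                ascending=False, method="first"
            )
        panel = screen_mod.select_panel(
            rank_lists,
            budget=min(config.screen.panel_budget, corrected.shape[1]),
            reserved=config.reserved_analytes,
        )
        (run_dir / "panel.json").write_text(json.dumps({"panel": panel}, indent=1))
        (run_dir / "screen_manifest.json").write_text(
            json.dumps(screen_manifests, indent=1)
        )
        log_stage("screen", panel_size=len(panel))

    if config.stages.get("gfs", True):
        if config.panel is not None:
            panel = list(config.panel)
        else:
            panel = json.loads(
                _need(run_dir / "panel.json", "screen").read_text()
            )["panel"]
        selections = {}
        for name, endpoint, kind, metric in ANALYSES:
            feats, y, counts, _ = _endpoint_data(config, run_dir, endpoint)
            cols = [p for p in panel if p in feats.columns]
            target = (
                clip_lesion_count(counts, config.lesion_cap)
                if kind == "poisson"
                else y
            )
            strata = (np.asarray(target) > 0).astype(int) if kind == "poisson" else y
            plan = gfs_mod.make_bootstrap_plan(
                len(feats),
                strata,
                n_reps=config.n_bootstrap_reps,
                rng_seed=_substream_seed(config.rng_seed, f"plan:{name}"),
            )
            curve = gfs_mod.greedy_forward_select(
                feats[cols], np.asarray(target), plan, kind=kind, metric=metric
            )
            k = gfs_mod.optimal_size(curve)
            curve.to_frame().to_csv(run_dir / f"gfs_{name}.csv", index=False)
            selections[name] = {
                "features": curve.features[:k],
                "optimal_size": k,
                "metric": metric,
            }
            log_stage("gfs", analysis=name, optimal_size=k)
        (run_dir / "gfs_selection.json").write_text(json.dumps(selections, indent=1))

    if config.stages.get("evaluate", True):
        selections = json.loads(
            _need(run_dir / "gfs_selection.json", "gfs").read_text()
        )
        anchor = config.screen.anchor_protein
        rows = []
        for name, endpoint, kind, metric in ANALYSES:
            feats, y, counts, tab = _endpoint_data(config, run_dir, endpoint)
            target = (
                clip_lesion_count(counts, config.lesion_cap)
                if kind == "poisson"
                else y
            )
            strata = (np.asarray(target) > 0).astype(int) if kind == "poisson" else y
            plan = gfs_mod.make_bootstrap_plan(
                len(feats),
                strata,
                n_reps=config.n_bootstrap_reps,
                rng_seed=_substream_seed(config.rng_seed, f"plan:{name}"),
            )
            gfs_set = selections[name]["features"]
            reports = models_mod.feature_set_comparison(
                feats,
                np.asarray(target),
                plan,
                gfs_set,
                anchor,
                kind=kind,
                endpoint=name,
                cap=config.lesion_cap,
            )
            for fs, rep in reports.items():
                rows.append(
                    {
                        "analysis": name,
                        "feature_set": fs,
                        "metric": rep.metric,
                        "mean": rep.mean,
                        "sd": rep.sd,
                        "n_dropped": rep.n_dropped,
                    }
                )
                if rep.roc is not None:
                    pd.DataFrame(
                        {
                            "fpr": rep.roc.fpr,
                            "tpr_mean": rep.roc.tpr_mean,
                            "tpr_sd": rep.roc.tpr_sd,
                        }
                    ).to_csv(run_dir / f"roc_{name}_{fs}.csv", index=False)
            if name == "gda":
                sub = {
                    ep: derive_binary_labels(tab, ep).encode(feats.index)
                    for ep in ("GDA", "SDA", "EDA")
                }
                subrep = models_mod.evaluate_gda_sda_eda(
                    feats[gfs_set].to_numpy(float), y, sub, plan
                )
                for ep, rep in subrep.items():
                    rows.append(
                        {
                            "analysis": ep.lower(),
                            "feature_set": "gfs",
                            "metric": "auroc",
                            "mean": rep.mean,
                            "sd": rep.sd,
                            "n_dropped": rep.n_dropped,
                        }
                    )
            perm = models_mod.permutation_importance(
                feats[gfs_set],
                np.asarray(target),
                plan,
                kind=kind,
                metric=metric,
                rng_seed=_substream_seed(config.rng_seed, f"perm:{name}"),
            )
            perm.to_csv(run_dir / f"permutation_importance_{name}.csv")
        pd.DataFrame(rows).to_csv(run_dir / "eval_table.csv", index=False)
        log_stage("evaluate", n_rows=len(rows))

    (run_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )

    if config.stages.get("report", True):
        render_report(run_dir)
        log_stage("report")
        (run_dir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str)
        )
    return run_dir


def render_report(run_dir: str | Path) -> Path:
    """Assemble the summary artifacts from a (possibly partial) run.

    Emits into ``run_dir/report``: a performance comparison table
    (analysis x feature set, "mean +/- sd"), the tidy univariate
    statistics, the GFS curves, and the ROC-band / permutation-importance
    data.  Stages that did not run are skipped with a notice in
    ``notes.json``; a run with no reportable stage at all raises
    :class:`StageError`.
    """
    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    notes = []
    produced = []

    eval_path = run_dir / "eval_table.csv"
    if eval_path.exists():
        ev = pd.read_csv(eval_path)
        ev["cell"] = ev.apply(lambda r: f"{r['mean']:.3f} ± {r['sd']:.3f}", axis=1)
        table2 = ev.pivot_table(
            index="analysis", columns="feature_set", values="cell", aggfunc="first"
        )
        table2.to_csv(report_dir / "performance_table.csv")
        produced.append("performance_table.csv")
        rocs = []
        for f in sorted(run_dir.glob("roc_*.csv")):
            df = pd.read_csv(f)
            df.insert(0, "source", f.stem)
            rocs.append(df)
        if rocs:
            pd.concat(rocs).to_csv(report_dir / "roc_bands.csv", index=False)
            produced.append("roc_bands.csv")
        perms = []
        for f in sorted(run_dir.glob("permutation_importance_*.csv")):
            df = pd.read_csv(f)
            df.insert(0, "analysis", f.stem.replace("permutation_importance_", ""))
            perms.append(df)
        if perms:
            pd.concat(perms).to_csv(
                report_dir / "permutation_importance.csv", index=False
            )
            produced.append("permutation_importance.csv")
    else:
        notes.append("evaluate stage missing: no performance table")

    uni_path = run_dir / "univariate.csv"
    if uni_path.exists():
        df = pd.read_csv(uni_path)
        keep = [
            c
            for c in (
                "protein_id",
                "endpoint",
                "spearman_rho",
                "spearman_p",
                "t_stat",
                "t_p",
                "auroc",
                "significant",
                "direction",
            )
            if c in df.columns
        ]
        df[keep].to_csv(report_dir / "univariate_stats.csv", index=False)
        produced.append("univariate_stats.csv")
    else:
        notes.append("univariate stage missing: no univariate table")

    curves = []
    for f in sorted(run_dir.glob("gfs_*.csv")):
        if f.name == "gfs_selection.json":
            continue
        df = pd.read_csv(f)
        df.insert(0, "analysis", f.stem.replace("gfs_", ""))
        curves.append(df)
    if curves:
        pd.concat(curves).to_csv(report_dir / "gfs_curves.csv", index=False)
        produced.append("gfs_curves.csv")
    else:
        notes.append("gfs stage missing: no GFS curves")

    if not produced:
        raise StageError("no reportable stage output found in the run directory")
    (report_dir / "notes.json").write_text(
        json.dumps({"produced": produced, "notes": notes}, indent=1)
    )
    return report_dir
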