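"""End-to-end orchestration: simulate -> preprocess -> univariate ->
stability -> rf-eval -> report, with one master seed, per-stage RNG streams,
and a run manifest of config/artifact checksums.

The default :class:`RunConfig` reproduces the reference analysis parameters:
q-value cut 0.15, Shapiro level 0.10, 100 stability subsamples at 75% of the
case group, majority rule at 50%, 500 forests of 500 trees with 40 candidate
variables per split trained on 70% balanced subsets, outlier screen at
alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .feature_table import DialectConfig, FeatureTable, read_feature_table, write_feature_table
from .preprocessing import FilterConfig, preprocess
from .pls import stability_selection
from .rf import error_curve_summary, rf_evaluate
from .synthetic import SyntheticConfig, generate_dataset
from .univariate import screen

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report", "load_config"]

log = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "univariate", "stability", "rf")


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # inputs (ignored when the simulate stage is enabled)
    matrix_path: str | None = None
    samples_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    pqn_reference: str = "auto"
    outlier_alpha: float = 0.05
    q_threshold: float = 0.15
    shapiro_threshold: float = 0.10
    n_sub: int = 100
    case_frac: float = 0.75
    freq_threshold: float = 0.5
    freq_inclusive: bool = False
    a_max: int = 5
    rf_reps: int = 500
    rf_trees: int = 500
    mtry: int = 40
    rf_frac: float = 0.70

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {_STAGES}")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if isinstance(self.filter, dict):
            self.filter = FilterConfig(**self.filter)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


@dataclass
class RunManifest:
    config: dict[str, Any]
    config_hash: str
    seeds: dict[str, int]
    artifacts: dict[str, str]  # relative path -> sha256
    timings: dict[str, float]  # stage -> seconds

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    """Independent per-stage seeds so changing one stage's workload cannot
    perturb another stage's draws."""
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(_STAGES, children)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the enabled stages in fixed order, writing all artifacts under
    ``out_dir``.  A stage failure aborts with the stage named; artifacts from
    completed stages are retained."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stages = set(config.stages)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0

    table: FeatureTable | None = None
    truth = None

    def _simulate():
        nonlocal table, truth
        cfg = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
        table, truth = generate_dataset(cfg)
        write_feature_table(table, out / "matrix.tsv", out / "samples.tsv")
        pd.DataFrame(
            {
                "feature": sorted(truth.directions),
                "direction": [truth.directions[k] for k in sorted(truth.directions)],
            }
        ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        pd.Series(truth.dilution, name="dilution").rename_axis("sample_id").to_csv(
            out / "dilution.tsv", sep="\t"
        )
        artifacts["matrix.tsv"] = out / "matrix.tsv"
        artifacts["samples.tsv"] = out / "samples.tsv"
        artifacts["ground_truth.tsv"] = out / "ground_truth.tsv"
        artifacts["dilution.tsv"] = out / "dilution.tsv"

    if "simulate" in stages:
        run_stage("simulate", _simulate)
    elif stages - {"simulate"}:
        if config.matrix_path is None:
            raise ValueError("matrix_path required when the simulate stage is disabled")
        table = read_feature_table(config.matrix_path, config.samples_path)

    clean: FeatureTable | None = None

    def _preprocess():
        nonlocal clean
        clean, rep = preprocess(
            table,
            filter_config=config.filter,
            rng=seeds["preprocess"],
            pqn_reference=config.pqn_reference,
            outlier_alpha=config.outlier_alpha,
        )
        write_feature_table(clean, out / "clean.tsv", out / "clean.samples.tsv")
        payload = {
            "filter": {
                "n_input": rep.filter_report.n_input,
                "n_after_blank_rules": rep.filter_report.n_after_blank_rules,
                "n_retained": rep.filter_report.n_retained,
            },
            "degenerate_features": rep.degenerate_features,
            "outliers": (
                rep.outlier_report.table.to_dict(orient="records")
                if rep.outlier_report is not None
                else None
            ),
        }
        (out / "preprocess_report.json").write_text(json.dumps(payload, indent=2) + "\n")
        rep.quotients.rename_axis("sample_id").to_csv(out / "pqn_quotients.tsv", sep="\t")
        artifacts["clean.tsv"] = out / "clean.tsv"
        artifacts["clean.samples.tsv"] = out / "clean.samples.tsv"
        artifacts["preprocess_report.json"] = out / "preprocess_report.json"
        artifacts["pqn_quotients.tsv"] = out / "pqn_quotients.tsv"

    if "preprocess" in stages:
        run_stage("preprocess", _preprocess)

    def _analysis_matrix() -> tuple[np.ndarray, np.ndarray, list[str]]:
        t = clean if clean is not None else table
        study = t.subset_samples(t.study_mask)
        return study.intensities, study.case_mask, study.feature_names

    def _univariate():
        xt = clean if clean is not None else table
        res = screen(
            xt.subset_samples(xt.study_mask),
            q_threshold=config.q_threshold,
            shapiro_threshold=config.shapiro_threshold,
        )
        res.table.to_csv(out / "univariate.tsv", sep="\t")
        artifacts["univariate.tsv"] = out / "univariate.tsv"

    if "univariate" in stages:
        run_stage("univariate", _univariate)

    def _stability():
        x, is_case, names = _analysis_matrix()
        res = stability_selection(
            x,
            is_case,
            n_sub=config.n_sub,
            case_frac=config.case_frac,
            freq_threshold=config.freq_threshold,
            freq_inclusive=config.freq_inclusive,
            a_max=config.a_max,
            rng=seeds["stability"],
            feature_names=names,
        )
        pd.DataFrame({"n_selected": res.counts, "selected": res.selected}).rename_axis(
            "feature"
        ).to_csv(out / "stability_counts.tsv", sep="\t")
        payload = {
            "n_models": res.n_models,
            "selected": res.selected_names,
            "auc_pred": [None if not np.isfinite(a) else float(a) for a in res.auc_pred],
            "auc_percentiles": res.auc_percentiles,
            "confusion": res.confusion.to_dict(orient="records"),
        }
        (out / "stability.json").write_text(json.dumps(payload, indent=2) + "\n")
        artifacts["stability_counts.tsv"] = out / "stability_counts.tsv"
        artifacts["stability.json"] = out / "stability.json"

    if "stability" in stages:
        run_stage("stability", _stability)

    def _rf():
        x, is_case, _ = _analysis_matrix()
        res = rf_evaluate(
            x,
            is_case,
            n_reps=config.rf_reps,
            n_trees=config.rf_trees,
            mtry=config.mtry,
            frac=config.rf_frac,
            rng=seeds["rf"],
        )
        res.errors.to_csv(out / "rf_errors.tsv", sep="\t", index=False)
        error_curve_summary(res).to_csv(out / "rf_error_curves.tsv", sep="\t", index=False)
        payload = {
            "percentiles": res.percentiles,
            "m_case": res.m_case,
            "m_control": res.m_control,
            "n_reps": res.n_reps,
            "n_trees": res.n_trees,
        }
        (out / "rf.json").write_text(json.dumps(payload, indent=2) + "\n")
        artifacts["rf_errors.tsv"] = out / "rf_errors.tsv"
        artifacts["rf_error_curves.tsv"] = out / "rf_error_curves.tsv"
        artifacts["rf.json"] = out / "rf.json"

    if "rf" in stages:
        run_stage("rf", _rf)

    cfg_dict = config.to_dict()
    manifest = RunManifest(
        config=cfg_dict,
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        seeds=seeds,
        artifacts={name: _sha256(p) for name, p in sorted(artifacts.items())},
        timings=timings,
    )
    manifest.write(out / "manifest.json")
    return manifest


def report(out_dir: str | Path, report_dir: str | Path | None = None) -> dict[str, Any]:
    """Aggregate stage artifacts into reader-facing tables and a JSON summary.

    Emits a selected-features table (feature id, direction, p-values, AUC),
    a stability-counts table, and summary.json.  Missing artifacts for
    disabled stages are skipped; an empty selection is reported as such.
    """
    out = Path(out_dir)
    rep_dir = Path(report_dir) if report_dir is not None else out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    uni_path = out / "univariate.tsv"
    if uni_path.exists():
        uni = pd.read_csv(uni_path, sep="\t", index_col=0)
        sel = uni[uni["selected_both"]].sort_values("t_p", kind="stable")
        cols = ["direction", "t_p", "mw_p", "t_q", "mw_q", "auc", "auc_ci_low", "auc_ci_high"]
        sel[cols].rename_axis("feature").to_csv(rep_dir / "selected_features.tsv", sep="\t")
        summary["univariate"] = {
            "n_features": int(len(uni)),
            "n_selected_mw": int(uni["selected_mw"].sum()),
            "n_selected_t": int(uni["selected_t"].sum()),
            "n_selected_both": int(sel.shape[0]),
        }
        if sel.empty:
            log.info("univariate screen selected zero features")
    stab_path = out / "stability.json"
    if stab_path.exists():
        stab = json.loads(stab_path.read_text())
        counts = pd.read_csv(out / "stability_counts.tsv", sep="\t", index_col=0)
        counts[counts["selected"]].sort_values("n_selected", ascending=False).to_csv(
            rep_dir / "stable_features.tsv", sep="\t"
        )
        summary["stability"] = {
            "n_selected": len(stab["selected"]),
            "auc_percentiles": stab["auc_percentiles"],
        }
    rf_path = out / "rf.json"
    if rf_path.exists():
        summary["rf"] = json.loads(rf_path.read_text())
    (rep_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
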