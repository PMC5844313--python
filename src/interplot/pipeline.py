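"""End-to-end real-data analysis: clean, cross-validate, select, report.

Mirrors the automated analysis contract: from a field CSV and a kinship
matrix, fit the Base model and a grid of competition candidates, pick
the most predictive one by cross-validation, and write BLUP
predictions, CV metrics, a selection report, the failed-fit count and a
run log to an output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import SelectionReport, select_model, total_phenotypic_variance
from .geometry import CompetitionFunction, FunctionKind, build_incidence
from .io import CleanDataset, load_and_clean, read_field_csv
from .kinship import KinshipMatrix
from .mixed_model import ModelKind, ModelSpec

logger = logging.getLogger("interplot")

#: default competition-function grid for model selection
DEFAULT_FD_K = (0.1, 0.2, 0.4, 1.0, 2.0)
DEFAULT_SD_B = (0.1, 0.01, 0.001)
DEFAULT_SD_DMAX = (5.0, 10.0)


@dataclass
class RunConfig:
    field_csv: str
    trait: str
    kinship_csv: str
    outdir: str
    plot_width: float = 1.0
    plot_length: float = 2.0
    long_edge: str = "ranges"
    model_kinds: tuple = (ModelKind.M1, ModelKind.M2, ModelKind.M3)
    nn_variants: tuple = (FunctionKind.NN_LONG, FunctionKind.NN_ALL)
    fd_k: tuple = DEFAULT_FD_K
    sd_b: tuple = DEFAULT_SD_B
    sd_dmax: tuple = DEFAULT_SD_DMAX
    folds: int = 10
    repeats: int = 5
    n_restarts: int = 2
    seed: int = 0
    drop_outliers: bool = True

    def function_grid(self) -> list:
        funcs = [CompetitionFunction(kind) for kind in self.nn_variants]
        funcs += [CompetitionFunction(FunctionKind.FD, k=k) for k in self.fd_k]
        funcs += [
            CompetitionFunction(FunctionKind.SD, b=b, dmax=d)
            for b in self.sd_b
            for d in self.sd_dmax
        ]
        return funcs


def build_candidates(data: CleanDataset, config: RunConfig) -> tuple[ModelSpec, dict]:
    """Base spec plus one candidate per (model kind x function)."""
    base_inc = build_incidence(
        data.layout, data.clone_index, CompetitionFunction(FunctionKind.NN_LONG)
    )
    base = ModelSpec(ModelKind.BASE, base_inc, data.K, label="Base")
    candidates: dict = {}
    for func in config.function_grid():
        inc = build_incidence(data.layout, data.clone_index, func)
        for kind in config.model_kinds:
            label = f"{kind.value}|{func.label()}"
            candidates[label] = ModelSpec(kind, inc, data.K, label=label)
    return base, candidates


def run_pipeline(config: RunConfig) -> dict:
    """Run the full selection pipeline and write the output bundle.

    Writes exactly five artifacts under ``outdir``: blups.csv,
    cv_metrics.csv, selection_report.csv, failures.json and run.log.
    Returns their paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("interplot %s starting; seed=%d", __version__, config.seed)
        logger.info("config: %s", json.dumps({k: str(v) for k, v in vars(config).items()}))
        fieldframe = read_field_csv(
            config.field_csv, config.plot_width, config.plot_length, config.long_edge
        )
        kin = KinshipMatrix.from_csv(config.kinship_csv)
        data = load_and_clean(
            fieldframe,
            config.trait,
            kin,
            config.plot_width,
            config.plot_length,
            config.long_edge,
            drop_outliers=config.drop_outliers,
            seed=config.seed,
        )
        logger.info(
            "clean data: %d plots, %d genotypes (%d missing-trait rows, "
            "%d unmatched rows dropped; %d duplicate records averaged; %d outliers)",
            data.layout.n_plots,
            len(data.genotype_ids),
            data.n_dropped_missing,
            data.n_dropped_unmatched,
            data.n_averaged,
            len(data.removed_outlier_plots),
        )
        base, candidates = build_candidates(data, config)
        report = select_model(
            data.y,
            base,
            candidates,
            folds=config.folds,
            repeats=config.repeats,
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        paths = _write_bundle(outdir, data, report, config)
        logger.info("selected %s in %.1f s", report.best_label, time.time() - t0)
        return paths
    finally:
        logger.removeHandler(handler)
        handler.close()


def config_from_yaml(path, **overrides) -> RunConfig:
    """RunConfig from a YAML mapping; keyword overrides win."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "model_kinds" in raw:
        raw["model_kinds"] = tuple(ModelKind(m) for m in raw["model_kinds"])
    if "nn_variants" in raw:
        raw["nn_variants"] = tuple(FunctionKind(f) for f in raw["nn_variants"])
    for key in ("fd_k", "sd_b", "sd_dmax"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _write_bundle(outdir: Path, data: CleanDataset, report: SelectionReport, config: RunConfig) -> dict:
    sel = report.selected_fit
    base = report.base_fit
    blups = pd.DataFrame({"clone": data.genotype_ids, "g_base": base.blup_g})
    blups["g_selected"] = sel.blup_g
    blups["c_selected"] = sel.blup_c if sel.blup_c is not None else np.nan
    blups_path = outdir / "blups.csv"
    blups.to_csv(blups_path, index=False, float_format="%.6g")

    rows = []
    for label, cv in report.cv.items():
        per = cv.per_fold.copy()
        per.insert(0, "model", label)
        rows.append(per)
    metrics = pd.concat(rows, ignore_index=True)
    metrics_path = outdir / "cv_metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.6g")

    sel_rows = {
        "trait": config.trait,
        "best_model": report.best_label,
        "prmse_base": report.cv["Base"].prmse,
        "prmse_selected": report.cv[report.best_label].prmse,
        "pcor_base": report.cv["Base"].pcor,
        "pcor_selected": report.cv[report.best_label].pcor,
        "decrease_prmse_pct": report.delta_prmse_pct,
        "increase_pcor_pct": report.delta_pcor_pct,
        "chisq": report.chisq,
        "pvalue": report.pvalue,
        "significant_alpha_0.1": report.significant,
        "h2_base": report.h2_base,
        "h2_selected": report.h2_selected,
    }
    for label, tv in report.total_variance.items():
        sel_rows[f"total_variance_{label}"] = tv
    for name, value in report.selected_fit.components.as_dict().items():
        sel_rows[f"selected_{name}"] = value
    sel_path = outdir / "selection_report.csv"
    pd.DataFrame([sel_rows]).to_csv(sel_path, index=False, float_format="%.6g")

    failures = {label: cv.n_failed_fits for label, cv in report.cv.items()}
    fail_path = outdir / "failures.json"
    fail_path.write_text(json.dumps({"n_failed_fits": failures}, indent=2))
    return {
        "blups": blups_path,
        "cv_metrics": metrics_path,
        "selection_report": sel_path,
        "failures": fail_path,
        "log": outdir / "run.log",
    }
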