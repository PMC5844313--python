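"""Model evaluation: outlier screening, cross-validated selection,
relative predictability changes, Cullis heritability and variance
accounting.

Model selection runs a 10-fold cross-validation repeated five times with
identical, seed-deterministic fold partitions for every candidate.  The
winning model has the lowest prediction RMSE between observed and
predicted response on held-out plots; its significance against the Base
model is then judged with a chi-square likelihood-ratio test on the
full data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed_model import (
    FitResult,
    ModelKind,
    ModelSpec,
    fit_reml,
    lrt,
    pev_genetic,
    predict,
)

__all__ = [
    "OutlierReport",
    "CVResult",
    "SelectionReport",
    "remove_outliers",
    "make_folds",
    "cross_validate",
    "relative_changes",
    "cullis_h2",
    "total_phenotypic_variance",
    "select_model",
]

OUTLIER_SD_MULTIPLE = 2.5


@dataclass
class OutlierReport:
    keep_rows: np.ndarray
    removed_rows: np.ndarray
    removed_plot_ids: list
    base_fit: FitResult | None


@dataclass
class CVResult:
    """Pooled and per-fold predictability of one candidate model."""

    label: str
    prmse: float
    pcor: float
    per_fold: pd.DataFrame
    n_failed_fits: int
    fold_assignment: np.ndarray  # (repeats, n) fold index per plot
    usable: bool = True


@dataclass
class SelectionReport:
    best_label: str
    best_kind: ModelKind
    cv: dict
    delta_prmse_pct: float
    delta_pcor_pct: float
    chisq: float
    pvalue: float
    significant: bool
    h2_base: float
    h2_selected: float
    total_variance: dict
    base_fit: FitResult = field(repr=False, default=None)
    selected_fit: FitResult = field(repr=False, default=None)


def remove_outliers(
    y: np.ndarray, base_spec: ModelSpec, plot_ids=None, seed: int = 0
) -> OutlierReport:
    """Drop plots whose Base-model residual exceeds 2.5 error SDs.

    A single screening pass: fit the Base model, compute residuals
    y - (mu + Z1 g_hat), and remove observations with |residual| larger
    than 2.5 * sigma_e.  A degenerate response that the Base model
    cannot fit is returned untouched with the fit flagged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    plot_ids = np.arange(n) if plot_ids is None else np.asarray(plot_ids)
    fit = fit_reml(y, base_spec, seed=seed)
    if not fit.converged:
        return OutlierReport(np.arange(n), np.array([], dtype=int), [], fit)
    resid = y - predict(fit)
    sd = np.sqrt(max(fit.components.sigma_e2, fit.components.sigma_r2))
    bad = np.abs(resid) > OUTLIER_SD_MULTIPLE * sd
    return OutlierReport(
        keep_rows=np.where(~bad)[0],
        removed_rows=np.where(bad)[0],
        removed_plot_ids=list(plot_ids[bad]),
        base_fit=fit,
    )


def make_folds(n: int, folds: int, repeats: int, seed: int) -> np.ndarray:
    """(repeats, n) array of fold labels; seeded and candidate-independent."""
    if n < folds:
        raise ValueError(f"cannot split {n} plots into {folds} folds")
    rng = np.random.default_rng(seed)
    out = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        perm = rng.permutation(n)
        out[r, perm] = np.arange(n) % folds
    return out


def cross_validate(
    y: np.ndarray,
    candidates: dict,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    n_restarts: int = 2,
) -> dict:
    """k-fold cross-validation of every candidate on shared partitions.

    For each repeat the plots are partitioned into ``folds`` test sets;
    each candidate is refit on the training plots only and predicts the
    held-out plots.  pRMSE and pCOR pool all held-out predictions over
    folds and repeats.  Failed fold fits are counted and their test
    plots excluded for that candidate; a candidate failing everywhere is
    marked unusable.  Constant predictions give pCOR 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    assignment = make_folds(n, folds, repeats, seed)
    results = {}
    for label, spec in candidates.items():
        obs_all, pred_all, fold_rows, n_failed = [], [], [], 0
        for r in range(repeats):
            for f in range(folds):
                test = np.where(assignment[r] == f)[0]
                train = np.where(assignment[r] != f)[0]
                fit = fit_reml(y, spec, rows=train, n_restarts=n_restarts, seed=seed + r)
                if not fit.converged:
                    n_failed += 1
                    fold_rows.append((r, f, np.nan, np.nan, False))
                    continue
                yhat = predict(fit, spec, test)
                obs_all.append(y[test])
                pred_all.append(yhat)
                fold_rows.append(
                    (
                        r,
                        f,
                        float(np.sqrt(np.mean((y[test] - yhat) ** 2))),
                        _safe_cor(y[test], yhat, warn=False),
                        True,
                    )
                )
        per_fold = pd.DataFrame(
            fold_rows, columns=["repeat", "fold", "prmse", "pcor", "converged"]
        )
        if not obs_all:
            results[label] = CVResult(
                label, np.nan, np.nan, per_fold, n_failed, assignment, usable=False
            )
            continue
        obs = np.concatenate(obs_all)
        pred = np.concatenate(pred_all)
        results[label] = CVResult(
            label=label,
            prmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
            pcor=_safe_cor(obs, pred),
            per_fold=per_fold,
            n_failed_fits=n_failed,
            fold_assignment=assignment,
        )
    return results


def _safe_cor(a: np.ndarray, b: np.ndarray, warn: bool = True) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        if warn:
            warnings.warn("constant predictions: pCOR undefined, recorded as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def relative_changes(base: CVResult, model: CVResult) -> tuple[float, float]:
    """Percent pRMSE reduction and pCOR gain of a model over Base.

    delta_pRMSE% = 100 (pRMSE_base - pRMSE_model) / pRMSE_base and
    delta_pCOR%  = 100 (pCOR_model - pCOR_base) / (1 - pCOR_base);
    undefined ratios are returned as NaN.
    """
    d_rmse = (
        100.0 * (base.prmse - model.prmse) / base.prmse if base.prmse > 0 else np.nan
    )
    d_cor = (
        100.0 * (model.pcor - base.pcor) / (1.0 - base.pcor)
        if base.pcor < 1
        else np.nan
    )
    return d_rmse, d_cor


def cullis_h2(fit: FitResult) -> float:
    """Cullis heritability h2 = 1 - mean pairwise BLUP-difference
    variance / (2 sigma_g2), clipped to [0, 1].

    The mean variance of BLUP differences comes from the prediction
    error covariance of the direct genetic effects:
    Var(g_i - g_j - (ghat_i - ghat_j)) = PEV_ii + PEV_jj - 2 PEV_ij.
    """
    sg2 = fit.components.sigma_g2
    if sg2 <= 1e-9:
        return 0.0
    pev = pev_genetic(fit)
    g = pev.shape[0]
    diag = np.diag(pev)
    # mean over unordered pairs i < j of PEV_ii + PEV_jj - 2 PEV_ij
    total = g * diag.sum() - pev.sum()
    vbar = 2.0 * total / (g * (g - 1))
    return float(np.clip(1.0 - vbar / (2.0 * sg2), 0.0, 1.0))


def total_phenotypic_variance(fit: FitResult) -> float:
    """Sum of the active variance components (covariances excluded)."""
    if not fit.converged:
        raise ValueError("total variance requires a converged fit")
    vc = fit.components
    spec = fit.spec
    total = vc.sigma_g2
    if spec.has_genetic_competition:
        total += vc.sigma_c2
    if spec.has_error_competition:
        total += vc.sigma_p2 + vc.sigma_r2
    else:
        total += vc.sigma_e2
    if spec.has_spatial:
        total += vc.sigma_s2
    return float(total)


def select_model(
    y: np.ndarray,
    base_spec: ModelSpec,
    candidates: dict,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    n_restarts: int = 2,
) -> SelectionReport:
    """Cross-validate Base plus all candidates and pick the lowest pRMSE.

    The winner is compared with Base by a likelihood-ratio test on the
    full data (one extra df per additional variance component beyond the
    genetic-variance/residual pair) and both Cullis heritabilities and
    per-model total phenotypic variances are attached.  Ties in pRMSE
    break in favour of Base, then by candidate order.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    all_specs = {"Base": base_spec, **candidates}
    cv = cross_validate(
        y, all_specs, folds=folds, repeats=repeats, seed=seed, n_restarts=n_restarts
    )
    usable = {k: v for k, v in cv.items() if v.usable}
    best_label = min(usable, key=lambda k: (usable[k].prmse, k != "Base"))
    best_spec = all_specs[best_label]
    base_fit = fit_reml(y, base_spec, n_restarts=n_restarts, seed=seed)
    if best_label == "Base":
        best_fit = base_fit
        chisq, pvalue, significant = 0.0, 1.0, False
    else:
        best_fit = fit_reml(y, best_spec, n_restarts=n_restarts, seed=seed)
        extra_df = best_spec.n_variance_params - base_spec.n_variance_params
        chisq, pvalue, significant = lrt(base_fit, best_fit, extra_df)
    d_rmse, d_cor = relative_changes(cv["Base"], cv[best_label])
    return SelectionReport(
        best_label=best_label,
        best_kind=best_spec.model_kind,
        cv=cv,
        delta_prmse_pct=d_rmse,
        delta_pcor_pct=d_cor,
        chisq=chisq,
        pvalue=pvalue,
        significant=significant,
        h2_base=cullis_h2(base_fit) if base_fit.converged else np.nan,
        h2_selected=cullis_h2(best_fit) if best_fit.converged else np.nan,
        total_variance={
            label: total_phenotypic_variance(f)
            for label, f in (("Base", base_fit), (best_label, best_fit))
            if f.converged
        },
        base_fit=base_fit,
        selected_fit=best_fit,
    )
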