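"""REML mixed models for direct and competitive genetic effects.

Model hierarchy (intercept is the only fixed effect throughout):

* Base: y = mu + Z1 g + e,               g ~ N(0, K sg2), e ~ N(0, I se2)
* M1:   adds Z2 c with [g; c] ~ N(0, [[sg2, sgc], [sgc, sc2]] (x) K)
* M2:   partitions e into II p + r with
        [p; r] ~ N(0, [[sp2, spr], [spr, sr2]] (x) I)
* M3:   both extensions together
* M4:   Base plus a spatial effect s ~ N(0, S ss2)
* M5:   the selected competition model (M1/M2/M3) plus the spatial term

The marginal covariance of y is a linear combination of fixed matrices,

    V = sg2 Z1 K Z1' + sgc (Z1 K Z2' + Z2 K Z1') + sc2 Z2 K Z2'
      + sp2 II II' + spr (II + II') + ss2 S + sr2 I,

so each likelihood evaluation is one matrix combination plus a Cholesky
factorisation.  The restricted log-likelihood is maximised over
(log variance, atanh correlation) coordinates with L-BFGS-B and
multiple seeded starts.  BLUPs follow as u_hat = Cov(u, y) V^-1 (y - mu_hat).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .geometry import IncidenceSet

__all__ = [
    "ModelKind",
    "VarianceComponents",
    "ModelSpec",
    "FitResult",
    "assemble_V",
    "reml_loglik",
    "fit_reml",
    "lrt",
    "predict",
    "CHISQ_CRIT_1DF",
    "CHISQ_CRIT_2DF",
]

#: chi-square critical values at alpha = 0.1 used for model significance
CHISQ_CRIT_1DF = 2.706
CHISQ_CRIT_2DF = 4.605

VARIANCE_FLOOR = 1e-10
RHO_BOUND = 0.999


class ModelKind(str, enum.Enum):
    BASE = "Base"
    M1 = "Model1"
    M2 = "Model2"
    M3 = "Model3"
    M4 = "Model4"
    M5 = "Model5"


@dataclass(frozen=True)
class VarianceComponents:
    """Variance and covariance parameters of the full model.

    Inactive components are zero.  The two 2x2 blocks
    [[sigma_g2, sigma_gc], [sigma_gc, sigma_c2]] (genetic) and
    [[sigma_p2, sigma_pr], [sigma_pr, sigma_r2]] (error) must be PSD.
    """

    sigma_g2: float = 0.0
    sigma_c2: float = 0.0
    sigma_gc: float = 0.0
    sigma_p2: float = 0.0
    sigma_r2: float = 0.0
    sigma_pr: float = 0.0
    sigma_s2: float = 0.0
    sigma_e2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_g2", "sigma_c2", "sigma_p2", "sigma_r2", "sigma_s2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        tol = 1e-9
        if self.sigma_gc**2 > self.sigma_g2 * self.sigma_c2 * (1 + 1e-6) + tol:
            raise ValueError("|sigma_gc| exceeds sqrt(sigma_g2 * sigma_c2)")
        if self.sigma_pr**2 > self.sigma_p2 * self.sigma_r2 * (1 + 1e-6) + tol:
            raise ValueError("|sigma_pr| exceeds sqrt(sigma_p2 * sigma_r2)")

    def as_dict(self) -> dict:
        return {
            "sigma_g2": self.sigma_g2,
            "sigma_c2": self.sigma_c2,
            "sigma_gc": self.sigma_gc,
            "sigma_p2": self.sigma_p2,
            "sigma_r2": self.sigma_r2,
            "sigma_pr": self.sigma_pr,
            "sigma_s2": self.sigma_s2,
            "sigma_e2": self.sigma_e2,
        }


@dataclass(frozen=True)
class ModelSpec:
    """Which model is fit, with its incidence, kinship and spatial matrices.

    For ``M5`` the competition part is given by ``competition_kind``
    (one of M1/M2/M3); the spatial matrix ``S`` is required for M4/M5.
    """

    model_kind: ModelKind
    incidence: IncidenceSet
    K: np.ndarray
    S: np.ndarray | None = None
    competition_kind: ModelKind = ModelKind.M3
    label: str = ""

    def __post_init__(self) -> None:
        if self.model_kind in (ModelKind.M4, ModelKind.M5) and self.S is None:
            raise ValueError(f"{self.model_kind.value} requires a spatial matrix S")
        if self.model_kind is ModelKind.M5 and self.competition_kind not in (
            ModelKind.M1,
            ModelKind.M2,
            ModelKind.M3,
        ):
            raise ValueError("M5 wraps one of M1/M2/M3")
        if not self.label:
            object.__setattr__(self, "label", self.model_kind.value)

    @property
    def _competition_part(self) -> ModelKind:
        if self.model_kind is ModelKind.M5:
            return self.competition_kind
        return self.model_kind

    @property
    def has_genetic_competition(self) -> bool:
        return self._competition_part in (ModelKind.M1, ModelKind.M3)

    @property
    def has_error_competition(self) -> bool:
        return self._competition_part in (ModelKind.M2, ModelKind.M3)

    @property
    def has_spatial(self) -> bool:
        return self.model_kind in (ModelKind.M4, ModelKind.M5)

    @property
    def n_variance_params(self) -> int:
        n = 2  # sigma_g2 + (sigma_e2 or sigma_r2)
        if self.has_genetic_competition:
            n += 2
        if self.has_error_competition:
            n += 2
        if self.has_spatial:
            n += 1
        return n


@dataclass
class FitResult:
    """A converged (or flagged) REML fit with BLUPs of every random effect.

    ``blup_g``/``blup_c`` are per genotype (length g, all genotypes in K);
    ``blup_p``/``blup_r`` are per fitted plot; ``blup_s`` is evaluated at
    every plot of the layout.
    """

    spec: ModelSpec
    mu_hat: float
    components: VarianceComponents
    reml_loglik: float
    blup_g: np.ndarray
    blup_c: np.ndarray | None
    blup_p: np.ndarray | None
    blup_r: np.ndarray
    blup_s: np.ndarray | None
    converged: bool
    n_restarts_used: int
    rows: np.ndarray = field(default=None, repr=False)
    _resid: np.ndarray = field(default=None, repr=False)
    _Vinv_resid: np.ndarray = field(default=None, repr=False)
    _cho: tuple = field(default=None, repr=False)
    _Vinv_one: np.ndarray = field(default=None, repr=False)


def _submatrices(spec: ModelSpec, rows: np.ndarray | None):
    """Row-restricted Z1, Z2, II, S for fitting on a subset of plots."""
    inc = spec.incidence
    if rows is None:
        rows = np.arange(inc.n_plots)
    Z1 = inc.Z1[rows]
    Z2 = inc.Z2[rows] if spec.has_genetic_competition else None
    II = inc.II[np.ix_(rows, rows)] if spec.has_error_competition else None
    S = spec.S[np.ix_(rows, rows)] if spec.has_spatial else None
    return rows, Z1, Z2, II, S


def _component_matrices(spec: ModelSpec, rows: np.ndarray | None):
    """Named covariance building blocks so V is a linear combination."""
    rows, Z1, Z2, II, S = _submatrices(spec, rows)
    n = len(rows)
    K = spec.K
    KZ1t = K @ Z1.T
    comps = [("sigma_g2", Z1 @ KZ1t)]
    if spec.has_genetic_competition:
        KZ2t = K @ Z2.T
        comps.append(("sigma_gc", Z1 @ KZ2t + Z2 @ KZ1t))
        comps.append(("sigma_c2", Z2 @ KZ2t))
    if spec.has_error_competition:
        comps.append(("sigma_p2", II @ II.T))
        comps.append(("sigma_pr", II + II.T))
        comps.append(("sigma_r2", np.eye(n)))
    else:
        comps.append(("sigma_e2", np.eye(n)))
    if spec.has_spatial:
        comps.append(("sigma_s2", S))
    names = [c[0] for c in comps]
    stack = np.stack([c[1] for c in comps])
    return rows, names, stack


def assemble_V(
    spec: ModelSpec, vc: VarianceComponents, rows: np.ndarray | None = None
) -> np.ndarray:
    """Marginal covariance of y for the active model terms."""
    _, names, stack = _component_matrices(spec, rows)
    theta = np.array([getattr(vc, name) for name in names])
    V = np.tensordot(theta, stack, axes=1)
    return (V + V.T) / 2.0


def _restricted_loglik_chol(V: np.ndarray, y: np.ndarray):
    """(loglik, mu_hat, cho, Vinv_one, Vinv_resid) or None if V not PD."""
    n = len(y)
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    one = np.ones(n)
    Vinv_one = cho_solve(cho, one)
    denom = one @ Vinv_one
    if denom <= 0:
        return None
    mu = (Vinv_one @ y) / denom
    resid = y - mu
    Vinv_resid = cho_solve(cho, resid)
    quad = resid @ Vinv_resid
    ll = -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(denom) + quad)
    return ll, mu, cho, Vinv_one, Vinv_resid


def reml_loglik(
    y: np.ndarray, spec: ModelSpec, vc: VarianceComponents, rows: np.ndarray | None = None
) -> float:
    """Restricted log-likelihood at the given variance components.

    Includes all constants, so values are comparable across nested
    models fitted to the same response (as the LRT requires).
    """
    y = np.asarray(y, dtype=float)
    if rows is not None:
        y = y[rows]
    V = assemble_V(spec, vc, rows)
    out = _restricted_loglik_chol(V, y)
    if out is None:
        raise np.linalg.LinAlgError("V is singular at the requested components")
    return out[0]


# ---------------------------------------------------------------------------
# parameter transforms: variances on log scale, correlations via tanh


def _pack_names(spec: ModelSpec):
    names = ["sigma_g2"]
    if spec.has_genetic_competition:
        names += ["sigma_c2", "rho_g"]
    if spec.has_error_competition:
        names += ["sigma_p2", "sigma_r2", "rho_e"]
    else:
        names += ["sigma_e2"]
    if spec.has_spatial:
        names += ["sigma_s2"]
    return names


def _theta_to_vc(theta: np.ndarray, names) -> VarianceComponents:
    vals = {}
    for t, name in zip(theta, names):
        if name.startswith("rho"):
            vals[name] = RHO_BOUND * np.tanh(t)
        else:
            vals[name] = max(np.exp(t), VARIANCE_FLOOR)
    kw = {k: v for k, v in vals.items() if k.startswith("sigma")}
    if "rho_g" in vals:
        kw["sigma_gc"] = vals["rho_g"] * np.sqrt(kw["sigma_g2"] * kw["sigma_c2"])
    if "rho_e" in vals:
        kw["sigma_pr"] = vals["rho_e"] * np.sqrt(kw["sigma_p2"] * kw["sigma_r2"])
    return VarianceComponents(**kw)


def _start_points(spec: ModelSpec, var_y: float, n_restarts: int, rng: np.random.Generator):
    names = _pack_names(spec)
    n_var = sum(1 for nm in names if nm.startswith("sigma"))
    base = []
    for nm in names:
        base.append(0.0 if nm.startswith("rho") else np.log(max(var_y, 1e-8) / n_var))
    starts = [np.array(base)]
    for _ in range(max(0, n_restarts - 1)):
        pert = []
        for nm, b in zip(names, base):
            if nm.startswith("rho"):
                pert.append(np.arctanh(rng.uniform(-0.5, 0.5)))
            else:
                pert.append(b + rng.uniform(-1.5, 1.5))
        starts.append(np.array(pert))
    return names, starts


def _blups(spec: ModelSpec, vc: VarianceComponents, rows, mu, cho, Vinv_resid):
    """BLUPs u_hat = Cov(u, y) V^-1 (y - mu) for every active effect."""
    _, Z1, Z2, II, _ = _submatrices(spec, rows)
    K = spec.K
    vr = Vinv_resid
    a1 = Z1.T @ vr
    if spec.has_genetic_competition:
        a2 = Z2.T @ vr
        g_hat = K @ (vc.sigma_g2 * a1 + vc.sigma_gc * a2)
        c_hat = K @ (vc.sigma_gc * a1 + vc.sigma_c2 * a2)
    else:
        g_hat = vc.sigma_g2 * (K @ a1)
        c_hat = None
    if spec.has_error_competition:
        p_hat = vc.sigma_p2 * (II.T @ vr) + vc.sigma_pr * vr
        r_hat = vc.sigma_pr * (II.T @ vr) + vc.sigma_r2 * vr
    else:
        p_hat = None
        r_hat = vc.sigma_e2 * vr
    if spec.has_spatial:
        s_hat = vc.sigma_s2 * (spec.S[:, rows] @ vr)
    else:
        s_hat = None
    return g_hat, c_hat, p_hat, r_hat, s_hat


def fit_reml(
    y: np.ndarray,
    spec: ModelSpec,
    rows: np.ndarray | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    maxiter: int = 200,
) -> FitResult:
    """Maximise the restricted likelihood and return estimates with BLUPs.

    ``rows`` restricts the fit to a subset of plots (the layout's
    incidence matrices are sliced accordingly), which is how
    cross-validation trains on a fold's complement.  Optimisation runs
    on (log sigma2, atanh rho) coordinates from ``n_restarts`` seeded
    starting points; a degenerate response (zero variance) or failure of
    every start yields ``converged=False`` rather than an exception.
    """
    y_full = np.asarray(y, dtype=float)
    rows = np.arange(len(y_full)) if rows is None else np.asarray(rows)
    yr = y_full[rows]
    n = len(yr)
    var_y = float(np.var(yr))
    rng = np.random.default_rng(seed)

    def _failed() -> FitResult:
        g = spec.K.shape[0]
        return FitResult(
            spec=spec,
            mu_hat=float(np.mean(yr)) if n else np.nan,
            components=VarianceComponents(),
            reml_loglik=np.nan,
            blup_g=np.zeros(g),
            blup_c=np.zeros(g) if spec.has_genetic_competition else None,
            blup_p=np.zeros(n) if spec.has_error_competition else None,
            blup_r=np.zeros(n),
            blup_s=np.zeros(spec.incidence.n_plots) if spec.has_spatial else None,
            converged=False,
            n_restarts_used=n_restarts,
            rows=rows,
        )

    if n < 3 or var_y <= 0 or not np.isfinite(yr).all():
        return _failed()

    rows_used, comp_names, stack = _component_matrices(spec, rows)
    names = _pack_names(spec)
    _, starts = _start_points(spec, var_y, n_restarts, rng)
    log_floor, log_cap = np.log(VARIANCE_FLOOR), np.log(max(var_y, 1.0) * 1e4)
    bounds = [
        (-3.0, 3.0) if nm.startswith("rho") else (log_floor, log_cap) for nm in names
    ]
    penalty = 1e10

    def negloglik(theta: np.ndarray) -> float:
        vc = _theta_to_vc(theta, names)
        coef = np.array([getattr(vc, nm) for nm in comp_names])
        V = np.tensordot(coef, stack, axes=1)
        out = _restricted_loglik_chol(V, yr)
        if out is None or not np.isfinite(out[0]):
            return penalty
        return -out[0]

    best = None
    used = 0
    for theta0 in starts:
        used += 1
        res = optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol * 1e-3, "gtol": 1e-6},
        )
        if res.fun >= penalty / 2:
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        return _failed()

    vc = _theta_to_vc(best.x, names)
    coef = np.array([getattr(vc, nm) for nm in comp_names])
    V = np.tensordot(coef, stack, axes=1)
    ll, mu, cho, Vinv_one, Vinv_resid = _restricted_loglik_chol(V, yr)
    g_hat, c_hat, p_hat, r_hat, s_hat = _blups(spec, vc, rows_used, mu, cho, Vinv_resid)
    return FitResult(
        spec=spec,
        mu_hat=float(mu),
        components=vc,
        reml_loglik=float(ll),
        blup_g=g_hat,
        blup_c=c_hat,
        blup_p=p_hat,
        blup_r=r_hat,
        blup_s=s_hat,
        converged=True,
        n_restarts_used=used,
        rows=rows_used,
        _resid=yr - mu,
        _Vinv_resid=Vinv_resid,
        _cho=cho,
        _Vinv_one=Vinv_one,
    )


def lrt(fit_reduced: FitResult, fit_full: FitResult, extra_df: int):
    """Chi-square likelihood-ratio test between nested REML fits.

    Significance is judged at alpha = 0.1: critical value 2.706 for one
    extra variance component, 4.605 for two.
    """
    raw = 2.0 * (fit_full.reml_loglik - fit_reduced.reml_loglik)
    if raw < -1e-6:
        warnings.warn(
            f"full-model log-likelihood below reduced by {-raw / 2:.3g}: "
            "optimizer may not have converged",
            stacklevel=2,
        )
    chisq = max(raw, 0.0)
    pvalue = float(stats.chi2.sf(chisq, extra_df))
    crit = {1: CHISQ_CRIT_1DF, 2: CHISQ_CRIT_2DF}.get(
        extra_df, float(stats.chi2.isf(0.1, extra_df))
    )
    return chisq, pvalue, bool(chisq > crit)


def predict(
    fit: FitResult, spec: ModelSpec | None = None, target_rows: np.ndarray | None = None
) -> np.ndarray:
    """Predicted response for target plots from a (training) fit.

    Y_hat = mu + Z1 g_hat + Z2 c_hat + II[target, train] p_hat + s_hat,
    with only the model's active terms contributing.  Competition-error
    and spatial effects propagate from training plots onto targets via
    the cross incidence.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    spec = fit.spec if spec is None else spec
    inc = spec.incidence
    target_rows = np.arange(inc.n_plots) if target_rows is None else np.asarray(target_rows)
    yhat = fit.mu_hat + inc.Z1[target_rows] @ fit.blup_g
    if spec.has_genetic_competition:
        yhat = yhat + inc.Z2[target_rows] @ fit.blup_c
    if spec.has_error_competition:
        yhat = yhat + inc.II[np.ix_(target_rows, fit.rows)] @ fit.blup_p
    if spec.has_spatial:
        yhat = yhat + fit.blup_s[target_rows]
    return yhat


def pev_genetic(fit: FitResult) -> np.ndarray:
    """Prediction-error covariance of the direct genetic BLUPs.

    PEV = Var(g - g_hat) = sg2 K - C P C' with C = Cov(g, y) on the
    training plots and P the REML projection accounting for the
    estimated intercept.  Used by the Cullis heritability.
    """
    if not fit.converged:
        raise ValueError("PEV requires a converged fit")
    spec, vc = fit.spec, fit.components
    _, Z1, Z2, _, _ = _submatrices(spec, fit.rows)
    K = spec.K
    C = vc.sigma_g2 * (K @ Z1.T)
    if spec.has_genetic_competition:
        C = C + vc.sigma_gc * (K @ Z2.T)
    VinvC = cho_solve(fit._cho, C.T)  # n x g
    one = np.ones(len(fit.rows))
    denom = one @ fit._Vinv_one
    PC = VinvC - fit._Vinv_one[:, None] * (one @ VinvC) / denom
    pev = vc.sigma_g2 * K - C @ PC
    return (pev + pev.T) / 2.0
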