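"""Field-trial simulation engine for the competition models.

Phenotypes are generated on a real or synthetic layout as

    Y = Z1 g + Z2 c + II p + r          (zero general mean)

where the direct (g) and competitive (c) genetic effects are jointly
Gaussian with covariance [[1, sigma_gc], [sigma_gc, sigma_c2]] (x) K and
the competition (p) and residual (r) errors are jointly Gaussian with
covariance [[sigma_p2, sigma_pr], [sigma_pr, sigma_r2]] (x) I.  Effects
are drawn by applying the Cholesky factors of the 2 x 2 block and of K
to i.i.d. standard normals, exactly the construction the model assumes.

The driving parameters are the competitive variance ``sigma_c2``, the
genetic correlation ``gcor``, the direct genotypic ratio

    gr = sigma_g2 / (sigma_g2 + sigma_c2 + sigma_e2),  sigma_g2 = 1,

the error correlation ``ecor`` and the fraction ``fra_e`` of the error
variance assigned to competition error:

    sigma_e2 = (1 - gr) / gr - sigma_c2,
    sigma_p2 = fra_e * sigma_e2,   sigma_r2 = (1 - fra_e) * sigma_e2,
    sigma_gc = gcor * sqrt(sigma_c2).

Genotypic competition (Z2) is simulated with either the long-edge
nearest-neighbour rule or the slow-decay function; the competition
error incidence (II) always uses the long-edge rule, on 2 m x 1 m plots.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    CompetitionFunction,
    FieldLayout,
    FunctionKind,
    IncidenceSet,
    build_incidence,
)
from .kinship import KINSHIP_RIDGE
from .mixed_model import ModelKind, ModelSpec, fit_reml
from .synth import SyntheticConfig, layout_from_clone_sequence

__all__ = [
    "ReplicationScenario",
    "SimParams",
    "SimTruth",
    "derive_variances",
    "simulate_genetic_effects",
    "simulate_error_effects",
    "apply_replication_scenario",
    "assemble_phenotype",
    "simulate_trial",
    "run_simulation_study",
    "accuracy_gain_summary",
    "SIM_NN",
    "SIM_SD",
    "DEFAULT_ANALYSIS_FUNCTIONS",
    "scenario_grid",
    "reduced_scenario_grid",
]

#: the two generating competition functions of the simulation study
SIM_NN = CompetitionFunction(FunctionKind.NN_LONG)
SIM_SD = CompetitionFunction(FunctionKind.SD, b=0.1, dmax=5.0)
#: competition error always propagates to long-edge neighbours
II_FUNCTION = SIM_NN

#: analysis candidates fitted against each simulated dataset
DEFAULT_ANALYSIS_FUNCTIONS = {
    "NN": SIM_NN,
    "FD": CompetitionFunction(FunctionKind.FD, k=0.4),
    "SD": SIM_SD,
}

SIGMA_C2_GRID = {0.7: (0.1, 0.2, 0.3, 0.4), 0.3: (0.1, 0.25, 0.5, 0.75, 1.0)}
GCOR_GRID = (0.0, 0.4)
ECOR_GRID = (0.0, 0.8)
FRAE_GRID = (0.3, 0.5, 0.7, 0.9)


class ReplicationScenario(str, enum.Enum):
    CHECKS_ONLY = "checks_only"
    HALF_DUPLICATED = "half_duplicated"
    ALL_DUPLICATED = "all_duplicated"


@dataclass(frozen=True)
class SimParams:
    """One simulation scenario; see the module docstring for the roles."""

    sigma_c2: float
    gcor: float = 0.0
    gr: float = 0.7
    ecor: float = 0.0
    fra_e: float = 0.5
    sim_function: CompetitionFunction = SIM_NN
    replication: ReplicationScenario = ReplicationScenario.CHECKS_ONLY

    def __post_init__(self) -> None:
        if self.sigma_c2 < 0:
            raise ValueError("sigma_c2 must be non-negative")
        for name in ("gcor", "ecor"):
            if not (-1 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be a correlation in (-1, 1)")
        if not (0 < self.gr < 1):
            raise ValueError("gr must be in (0, 1)")
        if not (0 <= self.fra_e <= 1):
            raise ValueError("fra_e must be in [0, 1]")

    def scenario_label(self) -> str:
        return (
            f"{self.sim_function.label()}|gr={self.gr:g}|sc2={self.sigma_c2:g}"
            f"|Gcor={self.gcor:g}|Ecor={self.ecor:g}|fraE={self.fra_e:g}"
            f"|{self.replication.value}"
        )


@dataclass
class SimTruth:
    """True effects and the realised phenotype of one simulated trial."""

    layout: FieldLayout
    clone_index: dict
    incidence: IncidenceSet
    g: np.ndarray
    c: np.ndarray
    p: np.ndarray
    r: np.ndarray
    y: np.ndarray


def derive_variances(params: SimParams) -> tuple[float, float, float, float]:
    """(sigma_e2, sigma_p2, sigma_r2, sigma_gc) implied by the scenario.

    Exact bookkeeping: sigma_p2 + sigma_r2 = sigma_e2 and
    1 / (1 + sigma_c2 + sigma_e2) = gr by construction.
    """
    sigma_e2 = (1.0 - params.gr) / params.gr - params.sigma_c2
    if sigma_e2 <= 0:
        raise ValueError(
            f"gr={params.gr} with sigma_c2={params.sigma_c2} leaves no error "
            f"variance (sigma_e2={sigma_e2:.4g} <= 0)"
        )
    sigma_p2 = params.fra_e * sigma_e2
    sigma_r2 = (1.0 - params.fra_e) * sigma_e2
    sigma_gc = params.gcor * math.sqrt(1.0 * params.sigma_c2)
    return sigma_e2, sigma_p2, sigma_r2, sigma_gc


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _correlated_pair(chol_outer: np.ndarray | None, block: np.ndarray, n: int, rng):
    """n x 2 draws with covariance block (x) (L L') via Cholesky factors."""
    w = np.linalg.eigvalsh(block)
    if w.min() < -1e-10:
        raise ValueError("2 x 2 covariance block is not PSD")
    # upper-triangular factor R with R'R = block (guard the PSD boundary)
    R = np.linalg.cholesky(block + 1e-12 * np.eye(2)).T
    Z = rng.standard_normal((n, 2))
    E = Z @ R
    if chol_outer is not None:
        E = chol_outer @ E
    return E


def simulate_genetic_effects(
    K: np.ndarray, sigma_c2: float, sigma_gc: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated direct and competitive genetic effects over kinship K.

    Applies chol(G)' then chol(K) to i.i.d. standard normals so that
    [g; c] has covariance [[1, sigma_gc], [sigma_gc, sigma_c2]] (x) K.
    """
    rng = _as_rng(seed)
    K = np.asarray(K, dtype=float)
    G = np.array([[1.0, sigma_gc], [sigma_gc, sigma_c2]])
    L = np.linalg.cholesky(K + KINSHIP_RIDGE * np.eye(len(K)))
    E = _correlated_pair(L, G, len(K), rng)
    return E[:, 0], E[:, 1]


def simulate_error_effects(
    n: int, sigma_p2: float, sigma_r2: float, ecor: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Per-plot competition and residual errors with correlation ``ecor``."""
    rng = _as_rng(seed)
    sigma_pr = ecor * math.sqrt(sigma_p2 * sigma_r2)
    B = np.array([[sigma_p2, sigma_pr], [sigma_pr, sigma_r2]])
    E = _correlated_pair(None, B, n, rng)
    return E[:, 0], E[:, 1]


def apply_replication_scenario(
    genotype_ids,
    check_ids,
    scenario: ReplicationScenario,
    seed,
    config: SyntheticConfig | None = None,
) -> FieldLayout:
    """Clone-to-plot assignment under the chosen replication scenario.

    Checks are always planted twice.  Test clones appear once
    (CHECKS_ONLY), a random half of them twice (HALF_DUPLICATED), or all
    twice (ALL_DUPLICATED).  The plot order is a seeded permutation and
    the field is filled row-major.
    """
    rng = _as_rng(seed)
    check_set = set(check_ids)
    missing = check_set - set(genotype_ids)
    if missing:
        raise ValueError(f"checks absent from the genotype pool: {sorted(missing)[:5]}")
    tests = [gid for gid in genotype_ids if gid not in check_set]
    plots = list(check_ids) * 2
    if scenario is ReplicationScenario.CHECKS_ONLY:
        plots += tests
    elif scenario is ReplicationScenario.HALF_DUPLICATED:
        dup = rng.choice(len(tests), size=len(tests) // 2, replace=False)
        plots += tests + [tests[i] for i in dup]
    else:
        plots += tests * 2
    order = rng.permutation(len(plots))
    clones = [plots[i] for i in order]
    config = config or SyntheticConfig(
        n_genotypes=len(genotype_ids), n_checks=len(check_ids)
    )
    return layout_from_clone_sequence(clones, config)


def assemble_phenotype(
    layout: FieldLayout,
    clone_index: dict,
    g: np.ndarray,
    c: np.ndarray,
    p: np.ndarray,
    r: np.ndarray,
    sim_function: CompetitionFunction,
) -> tuple[np.ndarray, IncidenceSet]:
    """Y = Z1 g + Z2 c + II p + r with Z2 from ``sim_function`` and II
    from the long-edge nearest-neighbour rule."""
    inc = build_incidence(layout, clone_index, sim_function, ii_func=II_FUNCTION)
    y = inc.Z1 @ g + inc.Z2 @ c + inc.II @ p + r
    return y, inc

def simulate_trial(
    params: SimParams,
    K: np.ndarray,
    genotype_ids,
    check_ids,
    seed,
    config: SyntheticConfig | None = None,
) -> SimTruth:
    """Simulate one trial: layout, true effects and phenotype."""
    rng = _as_rng(seed)
    sigma_e2, sigma_p2, sigma_r2, sigma_gc = derive_variances(params)
    layout = apply_replication_scenario(
        genotype_ids, check_ids, params.replication, rng, config
    )
    clone_index = {gid: i for i, gid in enumerate(genotype_ids)}
    g, c = simulate_genetic_effects(K, params.sigma_c2, sigma_gc, rng)
    p, r = simulate_error_effects(layout.n_plots, sigma_p2, sigma_r2, params.ecor, rng)
    y, inc = assemble_phenotype(layout, clone_index, g, c, p, r, params.sim_function)
    return SimTruth(layout, clone_index, inc, g, c, p, r, y)


def _score(est: np.ndarray | None, truth: np.ndarray):
    if est is None:
        return np.nan, np.nan
    rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
    cor = float(np.corrcoef(est, truth)[0, 1]) if np.std(est) > 0 else np.nan
    return rmse, cor


def run_simulation_study(
    K: np.ndarray,
    genotype_ids,
    check_ids,
    scenarios,
    analysis_functions: dict | None = None,
    n_reps: int = 20,
    seed: int = 0,
    n_restarts: int = 1,
    include_base: bool = True,
) -> pd.DataFrame:
    """Simulate each scenario ``n_reps`` times and score Base and Model 3.

    Every analysis candidate refits the data with Z2 rebuilt under its
    own competition function (II stays the long-edge rule, matching the
    generator).  Returns a long-format table with RMSE and accuracy
    (correlation with truth) for the direct and competitive effects;
    failed fits are recorded with NaN scores and counted, never raised.
    """
    analysis_functions = (
        DEFAULT_ANALYSIS_FUNCTIONS if analysis_functions is None else analysis_functions
    )
    ss = np.random.SeedSequence(seed)
    records = []
    for params in scenarios:
        rep_seeds = ss.spawn(n_reps)
        for rep, rep_seed in enumerate(rep_seeds):
            rng = np.random.default_rng(rep_seed)
            truth = simulate_trial(params, K, genotype_ids, check_ids, rng)
            fits = {}
            if include_base:
                base_inc = build_incidence(
                    truth.layout, truth.clone_index, II_FUNCTION
                )
                fits["Base"] = ModelSpec(ModelKind.BASE, base_inc, K, label="Base")
            for name, func in analysis_functions.items():
                inc = build_incidence(
                    truth.layout, truth.clone_index, func, ii_func=II_FUNCTION
                )
                fits[f"M3_{name}"] = ModelSpec(ModelKind.M3, inc, K, label=f"M3_{name}")
            for label, spec in fits.items():
                fit = fit_reml(
                    truth.y, spec, n_restarts=n_restarts, seed=int(rep_seed.entropy) % (2**31)
                )
                rmse_g, cor_g = _score(fit.blup_g if fit.converged else None, truth.g)
                rmse_c, cor_c = _score(
                    fit.blup_c if fit.converged and fit.blup_c is not None else None,
                    truth.c,
                )
                records.append(
                    {
                        "scenario": params.scenario_label(),
                        "sim_function": params.sim_function.label(),
                        "gr": params.gr,
                        "sigma_c2": params.sigma_c2,
                        "gcor": params.gcor,
                        "ecor": params.ecor,
                        "fra_e": params.fra_e,
                        "replication": params.replication.value,
                        "rep": rep,
                        "model": label,
                        "converged": fit.converged,
                        "rmse_g": rmse_g,
                        "cor_g": cor_g,
                        "rmse_c": rmse_c,
                        "cor_c": cor_c,
                    }
                )
    return pd.DataFrame.from_records(records)


def scenario_grid(
    sim_function: CompetitionFunction,
    gr_values=(0.3, 0.7),
    gcor_values=GCOR_GRID,
    ecor_values=ECOR_GRID,
    fra_e_values=FRAE_GRID,
    replication: ReplicationScenario = ReplicationScenario.CHECKS_ONLY,
):
    """Cross the simulation parameter grids for one generating function."""
    out = []
    for gr in gr_values:
        for sc2, gcor, ecor, fra_e in itertools.product(
            SIGMA_C2_GRID[gr], gcor_values, ecor_values, fra_e_values
        ):
            out.append(
                SimParams(
                    sigma_c2=sc2,
                    gcor=gcor,
                    gr=gr,
                    ecor=ecor,
                    fra_e=fra_e,
                    sim_function=sim_function,
                    replication=replication,
                )
            )
    return out


def reduced_scenario_grid(sim_function: CompetitionFunction):
    """Scaled-down study grid: full sigma_c2 and Gcor axes at both gr
    levels, with uncorrelated errors and an even error split."""
    return scenario_grid(
        sim_function, gcor_values=(0.0, 0.4), ecor_values=(0.0,), fra_e_values=(0.5,)
    )


def accuracy_gain_summary(study: pd.DataFrame, model: str) -> pd.DataFrame:
    """Per-scenario accuracy of ``model`` vs Base and the relative gain.

    Accuracies are averaged over replicates within a scenario; the gain
    is 100 * (cor_model - cor_Base) / cor_Base.
    """
    ok = study[study["converged"]]
    mean_cor = (
        ok.pivot_table(index="scenario", columns="model", values="cor_g", aggfunc="mean")
    )
    out = mean_cor[["Base", model]].dropna().copy()
    out["gain_pct"] = 100.0 * (out[model] - out["Base"]) / out["Base"]
    return out
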