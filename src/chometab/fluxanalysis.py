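"""Constraint-based flux analysis: FBA, MFA refinement and derived metrics.

FBA solves max c'v s.t. S v = 0 and bounds, with measured exchange fluxes
constrained to +/-10% of their value. Among alternate LP optima the reported
distribution is the one of minimal Euclidean norm (secondary QP), so results
are reproducible. MFA refines the FBA solution by weighted least squares
against the measured fluxes subject to the steady-state constraint and the
structural (irreversibility) bounds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .network import MetabolicNetwork

__all__ = [
    "FluxDistribution",
    "MfaResult",
    "PhaseWindow",
    "FluxAnalysisError",
    "MEASUREMENT_MAP",
    "CONDITIONS",
    "apply_measurement_constraints",
    "solve_fba",
    "run_mfa",
    "mfa_validation_r2",
    "lactate_glucose_ratio",
    "phase_windows",
]

CONDITIONS = ("STD_FB", "HSD_CONTROL", "HSD_LAC_CYS", "HSD_BM")

#: measured quantity -> reaction id in the default network
MEASUREMENT_MAP = {
    "Glc": "EX_glc",
    "Lac": "EX_lac",
    "Amm": "EX_nh4",
    "Asn": "EX_asn",
    "Asp": "EX_asp",
    "Glu": "EX_glu",
    "Ser": "EX_ser",
    "Ile": "EX_ile",
    "Leu": "EX_leu",
    "mu": "BIOMASS",
    "qp": "PROD_MAB",
}


class FluxAnalysisError(RuntimeError):
    """Raised when an LP/QP subproblem fails (infeasible, unbounded, ...)."""


@dataclass
class FluxDistribution:
    v: pd.Series  # indexed by reaction id [umol/g_DW/h]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def steady_state_violation(self, network: MetabolicNetwork) -> float:
        S = network.stoichiometric_matrix()
        resid = S @ self.v.to_numpy()
        scale = max(1.0, float(np.abs(self.v.to_numpy()).max()))
        return float(np.abs(resid).max() / scale)


@dataclass
class MfaResult:
    v_fit: FluxDistribution
    r_squared: float
    residuals: pd.Series  # fitted - measured, per measured reaction


@dataclass
class PhaseWindow:
    condition: str
    start_day: int
    end_day: int
    objective: str  # biomass | product

    def __post_init__(self) -> None:
        if self.start_day >= self.end_day:
            raise ValueError("start_day must be < end_day")


def apply_measurement_constraints(
    network: MetabolicNetwork,
    q: dict[str, float] | pd.Series,
    fraction: float = 0.1,
    measurement_map: dict[str, str] | None = None,
    unmeasured_bound: float = 1000.0,
) -> MetabolicNetwork:
    """Return a copy of the network with measurement-derived bounds applied.

    Each measured flux q_j constrains its reaction to
    [q_j - fraction*|q_j|, q_j + fraction*|q_j|]; unmeasured reactions keep
    lower bound 0 (irreversible) or -1000 (reversible) and upper bound 1000.
    """
    mm = dict(MEASUREMENT_MAP if measurement_map is None else measurement_map)
    out = network.copy()
    rxn_ids = set(out.reaction_ids)
    targeted: dict[str, float] = {}
    for key, value in dict(q).items():
        rid = mm.get(key, key)
        if rid not in rxn_ids:
            raise FluxAnalysisError(f"measured flux {key!r} has no matching reaction")
        targeted[rid] = float(value)
    for rxn in out.reactions:
        if rxn.id in targeted:
            qj = targeted[rxn.id]
            half = fraction * abs(qj)
            rxn.lower_bound = qj - half
            rxn.upper_bound = qj + half
            rxn.reversible = rxn.lower_bound < 0
        else:
            rxn.lower_bound = -unmeasured_bound if rxn.reversible else 0.0
            rxn.upper_bound = unmeasured_bound
    return out


def _independent_rows(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Full-row-rank matrix A with A v = 0  <=>  S v = 0 (via SVD)."""
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(sv > tol * sv[0])) if sv.size else 0
    return Vt[:rank]


def _min_norm_polish(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    v0: np.ndarray,
    opt: float,
) -> np.ndarray:
    """Among optima of the LP, find the minimal-||v||_2 solution (SLSQP)."""
    A = _independent_rows(S)
    cons = [
        {"type": "eq", "fun": lambda v: A @ v, "jac": lambda v: A},
        {"type": "eq", "fun": lambda v: c @ v - opt, "jac": lambda v: c},
    ]
    res = minimize(
        lambda v: 0.5 * float(v @ v),
        v0,
        jac=lambda v: v,
        bounds=list(zip(lb, ub)),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    v = res.x if res.success else v0
    # accept the polish only if it kept feasibility and optimality
    ok = (
        np.abs(S @ v).max() <= 1e-6
        and abs(c @ v - opt) <= 1e-6 * max(1.0, abs(opt))
        and np.all(v >= lb - 1e-6)
        and np.all(v <= ub + 1e-6)
    )
    return v if ok else v0


def solve_fba(
    network: MetabolicNetwork,
    objective: str = "biomass",
    minimize_norm: bool = True,
) -> FluxDistribution:
    """LP optimum of the objective flux subject to S v = 0 and bounds.

    ``objective`` is "biomass", "product" or an explicit reaction id.
    Infeasibility/unboundedness is surfaced as :class:`FluxAnalysisError`.
    """
    obj_id = {"biomass": "BIOMASS", "product": "PROD_MAB"}.get(objective, objective)
    if obj_id not in network.reaction_ids:
        raise FluxAnalysisError(f"objective reaction {obj_id!r} not in network")
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds()
    n = S.shape[1]
    c = np.zeros(n)
    c[network.reaction_ids.index(obj_id)] = -1.0  # maximize
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        raise FluxAnalysisError("FBA infeasible under the supplied bounds")
    if res.status == 3:
        raise FluxAnalysisError("FBA unbounded; check exchange bounds")
    if res.status != 0:
        raise FluxAnalysisError(f"LP failed: {res.message}")
    opt = -res.fun
    v = res.x
    if minimize_norm:
        v = _min_norm_polish(S, lb, ub, -c, v, opt)
    return FluxDistribution(
        v=pd.Series(v, index=network.reaction_ids),
        objective_value=float(opt),
        status="optimal",
    )


def run_mfa(
    network: MetabolicNetwork,
    q_measured: dict[str, float] | pd.Series,
    v_start: FluxDistribution,
    measurement_map: dict[str, str] | None = None,
    eps: float = 1e-6,
    structural_bound: float = 1000.0,
) -> MfaResult:
    """Weighted least-squares reconciliation of measured exchange fluxes.

    Minimizes sum_j w_j (v_j - q_j)^2 over the measured set with
    w_j = 1/max(q_j^2, eps), subject to S v = 0 and the irreversibility
    bounds of the original network, starting at the FBA solution.
    Reports pooled R^2 = 1 - SSR/SST across measured fluxes.
    """
    mm = dict(MEASUREMENT_MAP if measurement_map is None else measurement_map)
    q = {mm.get(k, k): float(val) for k, val in dict(q_measured).items()}
    if not q:
        raise FluxAnalysisError("no measured fluxes supplied")
    rxn_ids = network.reaction_ids
    for rid in q:
        if rid not in rxn_ids:
            raise FluxAnalysisError(f"measured flux {rid!r} has no matching reaction")

    S = network.stoichiometric_matrix()
    # structural bounds: keep only irreversibility, not measurement windows
    lb = np.array(
        [-structural_bound if r.reversible else 0.0 for r in network.reactions]
    )
    ub = np.full(len(rxn_ids), structural_bound)

    idx = np.array([rxn_ids.index(rid) for rid in q])
    qv = np.array([q[rid] for rid in q])
    w = 1.0 / np.maximum(qv**2, eps)

    def cost(v: np.ndarray) -> float:
        return float(w @ (v[idx] - qv) ** 2)

    # parametrize the steady-state space: v = N z with N an orthonormal
    # nullspace basis of S, so only the box bounds remain as inequalities
    _, sv, Vt = np.linalg.svd(S, full_matrices=True)
    rank = int(np.sum(sv > 1e-10 * sv[0])) if sv.size else 0
    N = Vt[rank:].T  # (n_reactions, n_free)
    M = N[idx]  # measured rows
    scale = np.sqrt(w)

    def z_cost(z: np.ndarray) -> float:
        return float(np.sum((scale * (M @ z - qv)) ** 2))

    def z_grad(z: np.ndarray) -> np.ndarray:
        return 2.0 * (M.T @ (w * (M @ z - qv)))

    G = np.vstack([N, -N])
    h = np.concatenate([lb, -ub])
    z0 = N.T @ v_start.v.to_numpy()
    res = minimize(
        z_cost,
        z0,
        jac=z_grad,
        constraints=[{"type": "ineq", "fun": lambda z: G @ z - h, "jac": lambda z: G}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success and "Iteration limit" not in str(res.message):
        raise FluxAnalysisError(f"MFA solver failed: {res.message}")
    v = N @ res.x
    # descent property: never report a point worse than the start
    v_init = N @ z0
    if (
        np.all(v_init >= lb - 1e-9)
        and np.all(v_init <= ub + 1e-9)
        and cost(v_init) < cost(v)
    ):
        v = v_init
    fitted = v[idx]
    ssr = float(np.sum((fitted - qv) ** 2))
    sst = float(np.sum((qv - qv.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else (1.0 if ssr == 0 else -np.inf)
    return MfaResult(
        v_fit=FluxDistribution(
            v=pd.Series(v, index=rxn_ids), objective_value=cost(v), status="optimal"
        ),
        r_squared=r2,
        residuals=pd.Series(fitted - qv, index=list(q)),
    )


def lactate_glucose_ratio(
    q_lac: np.ndarray | pd.Series,
    q_glc: np.ndarray | pd.Series,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Lactate/glucose uptake-flux ratio with efficiency classification.

    ratio = q_lac/q_glc. Positive means co-uptake; a value in (0, 1) is
    flagged efficient (glucose the main carbon source), > 1 means lactate is
    the primary carbon source; negative means lactate is produced while
    glucose is consumed. Points with |q_glc| < eps are returned as NaN.
    """
    ql = np.asarray(q_lac, dtype=float)
    qg = np.asarray(q_glc, dtype=float)
    ratio = np.where(np.abs(qg) < eps, np.nan, ql / np.where(qg == 0, np.nan, qg))
    efficient = (ratio > 0) & (ratio < 1)
    return pd.DataFrame({"ratio": ratio, "efficient": efficient})


def mfa_validation_r2(
    network: MetabolicNetwork,
    seeds: Iterable[int] = range(20),
    magnitude: float = 10.0,
    noise_cv: float = 0.05,
    objective: str = "biomass",
) -> list[float]:
    """Stoichiometric-model validation on synthetic consistent flux sets.

    For each seed: sample a steady-state-consistent flux distribution,
    perturb the measured exchange fluxes with multiplicative noise, run FBA
    under +/-10% measurement bounds (widened stepwise if the noisy bounds
    are infeasible) and refine by MFA; collect the pooled R^2 values.
    """
    from .synthetic import make_consistent_flux_set

    r2s = []
    for seed in seeds:
        meas, _ = make_consistent_flux_set(
            network, magnitude=magnitude, seed=seed, noise_cv=noise_cv
        )
        frac = 0.1
        sol = None
        while sol is None:
            try:
                constrained = apply_measurement_constraints(network, meas, fraction=frac)
                sol = solve_fba(constrained, objective)
            except FluxAnalysisError:
                frac *= 1.5
                if frac > 10:
                    raise
        r2s.append(run_mfa(network, meas, sol).r_squared)
    return r2s


#: analysis span per condition (start day, end day)
_CONDITION_SPANS = {
    "STD_FB": (4, 13),
    "HSD_CONTROL": (0, 11),
    "HSD_LAC_CYS": (2, 13),
    "HSD_BM": (2, 13),
}


def phase_windows(condition: str, changeover_day: int = 7) -> list[PhaseWindow]:
    """Per-condition FBA windows with growth/production objective tags.

    STD FB is analysed on days 4-13 (skipping the lag phase), the HSD control
    on its 11-day span, and the supplemented HSD runs on days 2-13. The
    growth->production objective changeover defaults to day 7.
    """
    if condition not in _CONDITION_SPANS:
        raise ValueError(f"unknown condition {condition!r}")
    start, end = _CONDITION_SPANS[condition]
    windows = []
    if changeover_day <= start:
        windows.append(PhaseWindow(condition, start, end, "product"))
    elif changeover_day >= end:
        windows.append(PhaseWindow(condition, start, end, "biomass"))
    else:
        windows.append(PhaseWindow(condition, start, changeover_day, "biomass"))
        windows.append(PhaseWindow(condition, changeover_day, end, "product"))
    return windows
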