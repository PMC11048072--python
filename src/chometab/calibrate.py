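"""Model calibration, AIC selection, viable-space sampling and ensembles.

Fitting uses a scatter-search-flavoured global strategy: a Latin-hypercube
diverse set in log-parameter space, recombination of the best candidates,
and Nelder-Mead local polishing, all deterministic for a fixed seed. Model
structures are compared by a Gaussian-residual Akaike information criterion;
the ensemble keeps the AIC-selected structures with the five lowest-cost
parameter sets each, and predicts with the member mean plus min-max band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .kinetics import (
    FeedSchedule,
    ModelStructure,
    ParameterSet,
    StateVector,
    Trajectory,
    SimulationError,
    simulate,
)
from .preprocess import DW_PER_CELL, CultureTimeSeries

__all__ = [
    "CalibrationResult",
    "EnsembleModel",
    "ViableSpaceError",
    "DEFAULT_FREE_PARAMS",
    "observed_dataframe",
    "simulate_at",
    "cost_function",
    "fit_parameters",
    "compute_aic",
    "sample_viable_space",
    "build_ensemble",
    "ensemble_predict",
    "global_sensitivity",
]

#: default free parameters for calibration: the lactate-shift core
DEFAULT_FREE_PARAMS = (
    "vmax_gly",
    "ka_asn_gly",
    "vmax_ldh",
    "ki_lac",
    "vmax_lup",
    "alpha_gly",
    "vmax_tca",
    "vmax_asn",
)


class ViableSpaceError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    structure_id: int
    params: ParameterSet
    cost: float
    n_obs: int
    n_params: int
    converged: bool
    seed: int

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be >= 0")


@dataclass
class EnsembleModel:
    """Selected structures x their lowest-cost parameter sets (max 5 each)."""

    members: list[tuple[ModelStructure, ParameterSet]]
    member_costs: list[float]
    selected_structures: list[int]


# ---------------------------------------------------------------------------
# observation handling and cost


def observed_dataframe(
    data: CultureTimeSeries, dw_per_cell: float = DW_PER_CELL
) -> pd.DataFrame:
    """Measured model states indexed by time: concentrations plus X [g_DW/L]
    (from VCD) and mAb [mg/L] (from titer)."""
    df = data.concentrations.copy()
    df.index = data.time
    df["X"] = data.vcd * dw_per_cell
    df["mAb"] = data.titer * 1000.0
    return df


def simulate_at(
    structure: ModelStructure,
    params: ParameterSet,
    schedule: FeedSchedule,
    times: np.ndarray,
    init: StateVector | np.ndarray,
) -> pd.DataFrame:
    """Model states at the requested times (linear interpolation of the
    dense trajectory record)."""
    t_end = float(np.max(times))
    traj = simulate(structure, params, schedule, (0.0, max(t_end, 1.0)), init)
    out = {}
    for col in traj.states.columns:
        out[col] = np.interp(times, traj.time, traj.states[col].to_numpy())
    return pd.DataFrame(out, index=np.asarray(times, dtype=float))


def cost_function(
    trajectory: pd.DataFrame,
    data: pd.DataFrame,
    weights: dict[str, float] | None = None,
    scales: dict[str, float] | None = None,
) -> float:
    """Weighted SSR: sum over states and times of ((sim-obs)/scale)^2.

    scale_state defaults to the maximum observed magnitude of that state.
    States present in the data but absent from the trajectory are skipped
    with a warning.
    """
    total = 0.0
    for col in data.columns:
        if col not in trajectory.columns:
            warnings.warn(f"state {col!r} missing from trajectory; skipped")
            continue
        obs = data[col].to_numpy(dtype=float)
        sim = trajectory[col].reindex(data.index).to_numpy(dtype=float)
        scale = (scales or {}).get(col, np.max(np.abs(obs)))
        if not np.isfinite(scale) or scale <= 0:
            scale = 1.0
        w = (weights or {}).get(col, 1.0)
        total += w * float(np.sum(((sim - obs) / scale) ** 2))
    return total


def _count_obs(data: pd.DataFrame, states: list[str] | None = None) -> int:
    cols = states if states is not None else list(data.columns)
    return int(sum(data[c].notna().sum() for c in cols if c in data.columns))


# ---------------------------------------------------------------------------
# global fitting (scatter-search flavour)


def _make_residuals(
    structure: ModelStructure,
    obs: pd.DataFrame,
    schedule: FeedSchedule,
    init: StateVector | np.ndarray,
    base_params: ParameterSet,
    free: tuple[str, ...],
):
    """Scaled residual vector ((sim-obs)/scale) as a function of theta;
    the cost is the sum of squared residuals."""
    times = obs.index.to_numpy(dtype=float)
    cols = [c for c in obs.columns]
    scales = np.array([max(float(np.max(np.abs(obs[c]))), 1e-12) for c in cols])
    obs_mat = obs[cols].to_numpy(dtype=float)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = base_params.replace(**dict(zip(free, theta)))
        try:
            sim = simulate_at(structure, p, schedule, times, init)
        except (SimulationError, ValueError):
            return np.full(obs_mat.size, 1e6)
        sim_mat = sim[cols].to_numpy(dtype=float)
        return ((sim_mat - obs_mat) / scales).ravel()

    return residuals


def fit_parameters(
    structure: ModelStructure,
    data: CultureTimeSeries | pd.DataFrame,
    bounds: dict[str, tuple[float, float]],
    budget: int = 1000,
    seed: int = 0,
    schedule: FeedSchedule | None = None,
    init: StateVector | np.ndarray | None = None,
    base_params: ParameterSet | None = None,
    free: tuple[str, ...] | None = None,
    cost_fn=None,
    refset_size: int = 5,
) -> CalibrationResult:
    """Global parameter estimation within box bounds (log-space search).

    Strategy: Latin-hypercube diversification, recombination of the best
    candidates (pairwise geometric means), then Nelder-Mead polishing with
    the remaining budget. Deterministic for a fixed seed. If ``cost_fn`` is
    given it overrides the model-based cost (useful for surrogate tests).
    """
    if budget < 100:
        raise ValueError("budget must be >= 100 evaluations")
    free = tuple(free) if free else tuple(bounds)
    lo = np.array([bounds[n][0] for n in free], dtype=float)
    hi = np.array([bounds[n][1] for n in free], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")

    base_params = base_params or ParameterSet()
    residual_fn = None
    if cost_fn is None:
        obs = (
            observed_dataframe(data) if isinstance(data, CultureTimeSeries) else data
        )
        if schedule is None or init is None:
            raise ValueError("schedule and init are required for model-based fits")
        residual_fn = _make_residuals(structure, obs, schedule, init, base_params, free)
        cost_fn = lambda theta: float(np.sum(residual_fn(theta) ** 2))  # noqa: E731
        n_obs = _count_obs(obs)
    else:
        n_obs = 0

    log_lo, log_hi = np.log(lo), np.log(hi)
    evals = 0
    k = len(free)

    def eval_log(z: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        z = np.clip(z, log_lo, log_hi)
        return float(cost_fn(np.exp(z)))

    converged = False
    if residual_fn is not None:
        from scipy.optimize import differential_evolution, least_squares

        # global stage: evolutionary recombination over the log-space box
        # (~2/3 of the budget), then trust-region least-squares polishing
        polish_budget = max(budget // 3, 20 * (k + 1))
        global_budget = max(budget - polish_budget, 10 * k)
        popsize = max(4, min(12, global_budget // (8 * k)))
        maxiter = max(global_budget // (popsize * k) - 1, 3)
        de = differential_evolution(
            eval_log,
            bounds=list(zip(log_lo, log_hi)),
            seed=seed,
            popsize=popsize,
            maxiter=maxiter,
            init="sobol",
            mutation=(0.5, 1.0),
            recombination=0.9,
            tol=1e-10,
            polish=False,
            updating="deferred",
        )
        z_best, s_best = de.x, float(de.fun)
        res = least_squares(
            lambda z: residual_fn(np.exp(z)),
            z_best,
            bounds=(log_lo, log_hi),
            method="trf",
            max_nfev=max(polish_budget // (k + 1), 5),
            xtol=1e-12,
            ftol=1e-12,
        )
        evals += res.nfev * (k + 1)
        if 2 * res.cost <= s_best:  # least_squares cost = 0.5 * SSR
            z_best, s_best = res.x, float(2 * res.cost)
            converged = bool(res.status > 0)
    else:
        # scalar surrogate cost: LHS diversification, recombination of the
        # reference set (log-space midpoints), Nelder-Mead polish
        n_init = max(2 * k, min(budget // 4, 64))
        sampler = qmc.LatinHypercube(d=k, seed=seed)
        Z = log_lo + sampler.random(n_init) * (log_hi - log_lo)
        scores = np.array([eval_log(z) for z in Z])
        order = np.argsort(scores)
        refset = [Z[i] for i in order[:refset_size]]
        ref_scores = [scores[i] for i in order[:refset_size]]
        for i in range(len(refset)):
            for j in range(i + 1, len(refset)):
                if evals >= budget - budget // 3:
                    break
                z = 0.5 * (refset[i] + refset[j])
                s = eval_log(z)
                worst = int(np.argmax(ref_scores))
                if s < ref_scores[worst]:
                    refset[worst], ref_scores[worst] = z, s
        best_i = int(np.argmin(ref_scores))
        z_best, s_best = refset[best_i], ref_scores[best_i]
        res = minimize(
            eval_log,
            z_best,
            method="Nelder-Mead",
            options={"maxfev": max(budget - evals, 10), "xatol": 1e-8, "fatol": 1e-12},
        )
        if res.fun <= s_best:
            z_best, s_best = res.x, float(res.fun)
        converged = bool(res.success)
    theta = np.exp(np.clip(z_best, log_lo, log_hi))
    known = set(ParameterSet.__dataclass_fields__)
    params = base_params.replace(
        **{n: v for n, v in zip(free, theta) if n in known}
    )
    return CalibrationResult(
        structure_id=structure.variant_id,
        params=params,
        cost=s_best,
        n_obs=n_obs,
        n_params=len(free),
        converged=converged,
        seed=seed,
    )


def identifiability(
    structure: ModelStructure,
    data: CultureTimeSeries | pd.DataFrame,
    params: ParameterSet,
    free: tuple[str, ...],
    schedule: FeedSchedule,
    init: StateVector | np.ndarray,
    rel_step: float = 1e-4,
) -> pd.DataFrame:
    """Practical identifiability at a fit: relative standard errors.

    Linearizes the residual vector in log-parameter space (finite
    differences), forms the Gauss-Newton covariance (J'J)^-1 * s2 with
    s2 = SSR/(n-k), and reports each free parameter's fractional standard
    error (rel_sd column). Parameters with small rel_sd are practically
    identifiable from these data; strongly correlated pairs show large
    rel_sd even when the fit is good.
    """
    obs = observed_dataframe(data) if isinstance(data, CultureTimeSeries) else data
    residual_fn = _make_residuals(structure, obs, schedule, init, params, free)
    theta = np.array([getattr(params, n) for n in free], dtype=float)
    z = np.log(theta)
    r0 = residual_fn(np.exp(z))
    n, k = len(r0), len(free)
    J = np.empty((n, k))
    for j in range(k):
        dz = z.copy()
        dz[j] += rel_step
        J[:, j] = (residual_fn(np.exp(dz)) - r0) / rel_step
    s2 = float(r0 @ r0) / max(n - k, 1)
    JTJ = J.T @ J
    cov = np.linalg.pinv(JTJ) * s2
    rel_sd = np.sqrt(np.maximum(np.diag(cov), 0.0))  # sd in log space ~ fractional
    return pd.DataFrame({"rel_sd": rel_sd}, index=list(free)).sort_values("rel_sd")


# ---------------------------------------------------------------------------
# AIC


def compute_aic(result: CalibrationResult, corrected: bool = False) -> float:
    """Gaussian-residual AIC: n ln(cost/n) + 2k (optionally AICc)."""
    n, k = result.n_obs, result.n_params
    if n <= k + 1:
        raise ValueError("n_obs must exceed n_params + 1 for AIC")
    aic = n * np.log(result.cost / n) + 2 * k
    if corrected:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return float(aic)


# ---------------------------------------------------------------------------
# viable-space sampling (flat-acceptance adaptive walk + ellipsoid resampling)


def sample_viable_space(
    cost_fn,
    x0: np.ndarray,
    bounds: np.ndarray,
    cost_threshold: float,
    n_samples: int = 200,
    seed: int = 0,
    n_walk: int = 1000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Characterize {x : cost(x) <= threshold} within box bounds.

    Stage (i): adaptive random walk from a known viable point, accepting any
    in-bounds move below the threshold (flat acceptance), with step-size
    adaptation towards ~30% acceptance. Stage (ii): an ellipsoid is fitted
    to the accepted cloud and points are resampled uniformly inside it,
    keeping the viable ones, until >= n_samples points are collected.

    Returns (samples, per-parameter viable ranges). Raises
    :class:`ViableSpaceError` if the start point is not viable.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if cost_fn(x0) > cost_threshold:
        raise ViableSpaceError("no viable start point: cost(x0) > threshold")
    d = len(x0)
    step = 0.1 * (hi - lo)
    x = x0.copy()
    accepted = [x0.copy()]
    acc_window = []
    for _ in range(n_walk):
        prop = x + step * rng.standard_normal(d)
        ok = np.all(prop >= lo) and np.all(prop <= hi) and cost_fn(prop) <= cost_threshold
        acc_window.append(ok)
        if ok:
            x = prop
            accepted.append(x.copy())
        if len(acc_window) >= 50:
            rate = np.mean(acc_window)
            step *= 1.2 if rate > 0.35 else (0.8 if rate < 0.2 else 1.0)
            acc_window = []
    A = np.array(accepted)

    samples = list(A)
    if len(A) >= d + 1:
        mean = A.mean(axis=0)
        cov = np.cov(A.T) + 1e-12 * np.eye(d)
        L = np.linalg.cholesky(cov)
        # scale so the ellipsoid covers the accepted cloud
        mah = np.sqrt(
            np.sum((np.linalg.solve(L, (A - mean).T)) ** 2, axis=0)
        )
        radius = 1.3 * max(mah.max(), 1e-6)
        tries = 0
        while len(samples) < max(n_samples, len(A)) and tries < 50 * n_samples:
            tries += 1
            u = rng.standard_normal(d)
            u /= np.linalg.norm(u)
            r = radius * rng.uniform() ** (1.0 / d)
            prop = mean + L @ (r * u)
            if np.all(prop >= lo) and np.all(prop <= hi) and cost_fn(prop) <= cost_threshold:
                samples.append(prop)
    S = np.array(samples[: max(n_samples, len(samples))])
    ranges = pd.DataFrame(
        {"min": S.min(axis=0), "max": S.max(axis=0)},
        index=[f"p{i}" for i in range(d)],
    )
    return S, ranges


# ---------------------------------------------------------------------------
# ensemble


def build_ensemble(
    results: list[CalibrationResult],
    sampled_sets: dict[int, list[tuple[float, ParameterSet]]] | None = None,
    delta_aic: float = 10.0,
    top_k: int = 5,
    corrected: bool = False,
) -> EnsembleModel:
    """Retain structures within delta_aic of the best; per structure keep the
    top_k (default 5) lowest-cost parameter sets."""
    if not results:
        raise ValueError("need at least one calibration result")
    by_structure: dict[int, list[CalibrationResult]] = {}
    for r in results:
        by_structure.setdefault(r.structure_id, []).append(r)
    aics = {}
    for sid, rs in by_structure.items():
        best = min(rs, key=lambda r: r.cost)
        aics[sid] = compute_aic(best, corrected) if best.n_obs > best.n_params + 1 else -np.inf
    finite = {sid: a for sid, a in aics.items() if np.isfinite(a)}
    if finite:
        a_best = min(finite.values())
        selected = sorted(sid for sid, a in finite.items() if a - a_best <= delta_aic)
    else:
        selected = sorted(by_structure)
    members: list[tuple[ModelStructure, ParameterSet]] = []
    costs: list[float] = []
    for sid in selected:
        cands: list[tuple[float, ParameterSet]] = [
            (r.cost, r.params) for r in by_structure[sid]
        ]
        cands.extend((sampled_sets or {}).get(sid, []))
        cands.sort(key=lambda t: t[0])
        for c, p in cands[:top_k]:
            members.append((ModelStructure(sid), p))
            costs.append(c)
    order = np.argsort(costs, kind="stable")
    members = [members[i] for i in order]
    costs = [costs[i] for i in order]
    return EnsembleModel(members=members, member_costs=costs, selected_structures=selected)


def ensemble_predict(
    ensemble: EnsembleModel,
    schedule: FeedSchedule,
    t_grid: np.ndarray,
    init: StateVector | np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pointwise mean and min-max band across ensemble members.

    Members whose integration fails are excluded with a warning.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    preds = []
    for k, (structure, params) in enumerate(ensemble.members):
        try:
            preds.append(simulate_at(structure, params, schedule, t_grid, init))
        except SimulationError as exc:
            warnings.warn(f"ensemble member {k} failed and was excluded: {exc}")
    if not preds:
        raise SimulationError("all ensemble members failed")
    stack = np.stack([p.to_numpy() for p in preds])
    cols = preds[0].columns
    mean = pd.DataFrame(stack.mean(axis=0), index=t_grid, columns=cols)
    lo = pd.DataFrame(stack.min(axis=0), index=t_grid, columns=cols)
    hi = pd.DataFrame(stack.max(axis=0), index=t_grid, columns=cols)
    return mean, lo, hi


# ---------------------------------------------------------------------------
# Morris elementary-effects screening


def global_sensitivity(
    func,
    ranges: dict[str, tuple[float, float]],
    n_trajectories: int = 10,
    seed: int = 0,
    levels: int = 4,
) -> pd.DataFrame:
    """Morris elementary-effects screening of a scalar function.

    Returns per-parameter mu_star (mean |elementary effect|) and sigma,
    sorted by mu_star descending. ``func`` takes a dict of parameter values.
    """
    names = list(ranges)
    k = len(names)
    if n_trajectories < 2:
        raise ValueError("n_trajectories must be >= 2")
    rng = np.random.default_rng(seed)
    lo = np.array([ranges[n][0] for n in names], dtype=float)
    hi = np.array([ranges[n][1] for n in names], dtype=float)
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(levels - 1) / (levels - 1)  # start levels allowing +delta
    effects: dict[str, list[float]] = {n: [] for n in names}
    for _ in range(n_trajectories):
        x = grid[rng.integers(0, len(grid), size=k)].astype(float)
        order = rng.permutation(k)
        y = func(dict(zip(names, lo + x * (hi - lo))))
        for idx in order:
            x_new = x.copy()
            sign = 1.0 if x[idx] + delta <= 1.0 else -1.0
            x_new[idx] = x[idx] + sign * delta
            y_new = func(dict(zip(names, lo + x_new * (hi - lo))))
            effects[names[idx]].append((y_new - y) / (sign * delta))
            x, y = x_new, y_new
    rows = []
    for n in names:
        e = np.array(effects[n])
        rows.append({"parameter": n, "mu_star": float(np.mean(np.abs(e))), "sigma": float(np.std(e))})
    df = pd.DataFrame(rows).set_index("parameter")
    return df.sort_values("mu_star", ascending=False)
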