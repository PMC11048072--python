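"""Synthetic fed-batch datasets emulating the HSD/STD FB study conditions.

Generates culture time series by simulating the shipped reference kinetic
model under condition-specific feed schedules, sampling 13 daily points and
adding multiplicative Gaussian noise, and steady-state-consistent flux sets
for exercising the MFA machinery. All absolute scales (initial
concentrations, feed composition, bolus sizes) are documented package
defaults, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .kinetics import (
    Bolus,
    FeedSchedule,
    ModelStructure,
    ParameterSet,
    StateVector,
    Trajectory,
    reference_parameters,
    simulate,
)
from .network import MetabolicNetwork
from .preprocess import DW_PER_CELL, CultureTimeSeries

__all__ = [
    "SyntheticSpec",
    "CONDITIONS",
    "INITIAL_STATE",
    "default_spec",
    "standard_schedule",
    "initial_state",
    "generate_dataset",
    "make_consistent_flux_set",
]

CONDITIONS = ("STD_FB", "HSD_CONTROL", "HSD_LAC_CYS", "HSD_BM")

#: documented default initial broth composition [mmol/L]
INITIAL_STATE = {
    "Glc": 40.0,
    "Pyr": 0.5,
    "Lac": 1.0,
    "Amm": 1.0,
    "Asn": 10.0,
    "Asp": 2.0,
    "Glu": 2.0,
    "Ser": 5.0,
    "Ile": 3.0,
    "Leu": 3.0,
    "mAb": 0.0,
}

#: initial working volume [L] (3-L reactor scale)
V0 = 1.5

#: continuous feed composition [mmol/L]
FEED_COMPOSITION = {
    "Glc": 150.0,
    "Asn": 40.0,
    "Asp": 5.0,
    "Glu": 5.0,
    "Ser": 25.0,
    "Ile": 12.0,
    "Leu": 15.0,
}

#: amino-acid-enriched bolus medium composition [mmol/L]
BM_COMPOSITION = {
    "Asn": 100.0,
    "Asp": 20.0,
    "Glu": 20.0,
    "Ser": 40.0,
    "Ile": 40.0,
    "Leu": 40.0,
}

#: lactate trigger 2 g/L as mmol/L (sodium-free lactate mass basis, 90.08 g/mol)
LAC_TRIGGER_MM = 2.0 / 90.08 * 1000.0

#: default noise CVs per variable class
DEFAULT_NOISE_CV = {"conc": 0.05, "vcd": 0.08, "titer": 0.05}


@dataclass
class SyntheticSpec:
    condition: str
    seeding_density: float  # cells/mL
    duration_days: int
    n_samples: int = 13
    sample_interval_h: float = 24.0
    noise_cv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_CV))
    truth_structure: ModelStructure = field(default_factory=ModelStructure)
    truth_params: ParameterSet = field(default_factory=reference_parameters)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.seeding_density <= 0:
            raise ValueError("seeding_density must be > 0")
        if any(v < 0 for v in self.noise_cv.values()):
            raise ValueError("noise_cv must be >= 0")


def standard_schedule(condition: str) -> FeedSchedule:
    """Condition-specific feed schedule at the documented defaults.

    All conditions: continuous feed from day 1 and glucose-threshold bolus
    control (trigger 11 mmol/L, restore to 33 mmol/L from a 2775 mmol/L
    stock). LAC+CYS adds daily-checked lactate boluses on days 3-13 when
    lactate falls below 2 g/L plus volume-only cysteine boluses on days 1-5.
    BM adds amino-acid bolus medium on days 1-6.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    sched = FeedSchedule(
        continuous_rate=0.002,
        feed_start=24.0,
        composition=dict(FEED_COMPOSITION),
        glucose_control=(11.0, 33.0, 2775.0),
    )
    if condition == "HSD_LAC_CYS":
        sched.lactate_control = (3, 13, LAC_TRIGGER_MM, 0.015, 1785.0)
        sched.boluses.extend(
            Bolus(24.0 * d, 0.007, {}) for d in range(1, 6)  # cysteine: dilution only
        )
    elif condition == "HSD_BM":
        sched.boluses.extend(
            Bolus(24.0 * d, 0.030, dict(BM_COMPOSITION)) for d in range(1, 7)
        )
    return sched


def default_spec(condition: str, seed: int = 0) -> SyntheticSpec:
    """Study-condition defaults: HSD at 10e6 cells/mL for 12 days, STD FB at
    0.7e6 cells/mL for 14 days; 13 daily samples everywhere."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "STD_FB":
        return SyntheticSpec(condition, seeding_density=0.7e6, duration_days=14, seed=seed)
    return SyntheticSpec(condition, seeding_density=10e6, duration_days=12, seed=seed)


def initial_state(spec: SyntheticSpec, dw_per_cell: float = DW_PER_CELL) -> StateVector:
    x0 = spec.seeding_density * 1000.0 * dw_per_cell  # g_DW/L
    vals = dict(INITIAL_STATE)
    return StateVector(
        Glc=vals["Glc"], Pyr=vals["Pyr"], Lac=vals["Lac"], Amm=vals["Amm"],
        Asn=vals["Asn"], Asp=vals["Asp"], Glu=vals["Glu"], Ser=vals["Ser"],
        Ile=vals["Ile"], Leu=vals["Leu"], X=x0, mAb=vals["mAb"], V=V0,
    )


def _viability_curve(days: np.ndarray, condition: str) -> np.ndarray:
    # synthetic sigmoid decline; supplemented conditions retain viability longer
    mid = {"STD_FB": 12.0, "HSD_CONTROL": 8.0, "HSD_LAC_CYS": 10.0, "HSD_BM": 10.5}[condition]
    return 0.55 + 0.43 / (1.0 + np.exp((days - mid) / 1.8))


def generate_dataset(
    spec: SyntheticSpec,
    seed: int | None = None,
    dw_per_cell: float = DW_PER_CELL,
) -> tuple[CultureTimeSeries, dict]:
    """Simulate the truth model, sample and add noise.

    Returns the noisy measurements plus a sealed truth record (noise-free
    samples, true parameters/structure, trajectory) for recovery tests.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    schedule = standard_schedule(spec.condition)
    init = initial_state(spec, dw_per_cell)
    t_end = spec.duration_days * 24.0
    traj = simulate(spec.truth_structure, spec.truth_params, schedule, (0.0, t_end), init)

    t_grid = np.arange(spec.n_samples) * spec.sample_interval_h
    t_grid = t_grid[t_grid <= t_end + 1e-9]
    states = traj.samples.reindex(t_grid, method="nearest")

    cv_c = spec.noise_cv.get("conc", 0.0)
    cv_x = spec.noise_cv.get("vcd", 0.0)
    cv_p = spec.noise_cv.get("titer", 0.0)

    conc_names = ["Glc", "Pyr", "Lac", "Amm", "Asn", "Asp", "Glu", "Ser", "Ile", "Leu"]
    conc_true = states[conc_names].to_numpy()
    conc_noisy = np.clip(conc_true * (1 + cv_c * rng.standard_normal(conc_true.shape)), 0, None)

    x_true = states["X"].to_numpy()
    vcd_true = x_true / dw_per_cell  # cells/L
    vcd_noisy = np.clip(vcd_true * (1 + cv_x * rng.standard_normal(len(t_grid))), 0, None)

    titer_true = states["mAb"].to_numpy() / 1000.0  # g/L
    titer_noisy = np.clip(titer_true * (1 + cv_p * rng.standard_normal(len(t_grid))), 0, None)

    days = t_grid / 24.0
    viability = np.clip(
        _viability_curve(days, spec.condition) * (1 + 0.01 * rng.standard_normal(len(t_grid))),
        0.0,
        1.0,
    )

    # record of what was actually added, so preprocessing can correct for it
    record_feed = FeedSchedule(
        continuous_rate=schedule.continuous_rate,
        feed_start=schedule.feed_start,
        composition=dict(schedule.composition),
        boluses=list(traj.bolus_log),
    )

    measured = CultureTimeSeries(
        time=t_grid,
        concentrations=pd.DataFrame(conc_noisy, columns=conc_names),
        vcd=vcd_noisy,
        viability=viability,
        titer=titer_noisy,
        volume=states["V"].to_numpy(),
        feed=record_feed,
    )
    truth = {
        "params": spec.truth_params,
        "structure": spec.truth_structure,
        "samples": states,
        "trajectory": traj,
        "vcd": vcd_true,
        "titer": titer_true,
        "schedule": schedule,
        "dw_per_cell": dw_per_cell,
    }
    return measured, truth


# ---------------------------------------------------------------------------
# steady-state-consistent flux sets for MFA testing


def make_consistent_flux_set(
    network: MetabolicNetwork,
    magnitude: float = 10.0,
    seed: int = 0,
    noise_cv: float = 0.0,
    n_vertices: int = 5,
) -> tuple[pd.Series, pd.Series]:
    """Sample v with S v = 0 and report measured-exchange 'measurements'.

    A random convex combination of LP vertices of the flux polytope (bounds
    clipped to +/- magnitude) yields a steady-state-consistent interior
    point. Returns (measurements over is_measured reactions, optionally
    noise-perturbed; full truth flux vector).
    """
    rng = np.random.default_rng(seed)
    if magnitude == 0.0:
        v = np.zeros(len(network.reactions))
        truth = pd.Series(v, index=network.reaction_ids)
        meas = truth[[r.id for r in network.reactions if r.is_measured]].copy()
        return meas, truth
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds()
    lb = np.maximum(lb, -magnitude)
    ub = np.minimum(ub, magnitude)
    n = S.shape[1]
    vertices = []
    attempts = 0
    while len(vertices) < n_vertices and attempts < 20 * n_vertices:
        attempts += 1
        c = rng.standard_normal(n)
        res = linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs"
        )
        if res.status == 0 and np.abs(res.x).max() > 1e-9:
            vertices.append(res.x)
    if not vertices:
        raise RuntimeError("degenerate flux polytope: no non-trivial vertex found")
    w = rng.dirichlet(np.ones(len(vertices)))
    v = np.einsum("i,ij->j", w, np.array(vertices))
    truth = pd.Series(v, index=network.reaction_ids)
    measured_ids = [r.id for r in network.reactions if r.is_measured]
    meas = truth[measured_ids].copy()
    if noise_cv > 0:
        meas = meas * (1 + noise_cv * rng.standard_normal(len(meas)))
    return meas, truth
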