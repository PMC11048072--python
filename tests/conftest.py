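import numpy as np
import pandas as pd
import pytest

from chometab.kinetics import ModelStructure, reference_parameters
from chometab.network import default_network
from chometab.synthetic import default_spec, initial_state, standard_schedule


@pytest.fixture(scope="session")
def net():
    return default_network()


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def hsd_setup():
    """HSD control condition: spec, schedule, initial state."""
    spec = default_spec("HSD_CONTROL")
    return spec, standard_schedule("HSD_CONTROL"), initial_state(spec)


@pytest.fixture(scope="session")
def hsd_reference_trajectory(hsd_setup, ref_params):
    from chometab.kinetics import simulate

    spec, sched, init = hsd_setup
    return simulate(ModelStructure(1), ref_params, sched, (0.0, 288.0), init)


def toy_chain_network():
    """A_ext -> A -> B -> B_ext with an export objective."""
    from chometab.network import Metabolite, MetabolicNetwork, Reaction

    mets = [
        Metabolite("A_ext", compartment="extracellular", carbon_count=3),
        Metabolite("A", carbon_count=3),
        Metabolite("B", carbon_count=3),
        Metabolite("B_ext", compartment="extracellular", carbon_count=3),
    ]
    rxns = [
        Reaction("EX_A", {"A_ext": -1.0}, reversible=True, lower_bound=-5.0,
                 upper_bound=0.0, is_exchange=True),
        Reaction("T_A", {"A_ext": -1.0, "A": 1.0}),
        Reaction("CONV", {"A": -1.0, "B": 1.0}),
        Reaction("T_B", {"B": -1.0, "B_ext": 1.0}),
        Reaction("EX_B", {"B_ext": -1.0}, reversible=True, lower_bound=0.0,
                 upper_bound=1000.0, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns, objective_id="EX_B")


def toy_branched_network():
    """A -> B or C with different yields of the exported product P."""
    from chometab.network import Metabolite, MetabolicNetwork, Reaction

    mets = [
        Metabolite("A_ext", compartment="extracellular", carbon_count=6),
        Metabolite("A", carbon_count=6),
        Metabolite("P", carbon_count=3),
        Metabolite("P_ext", compartment="extracellular", carbon_count=3),
    ]
    rxns = [
        Reaction("EX_A", {"A_ext": -1.0}, reversible=True, lower_bound=-10.0,
                 upper_bound=0.0, is_exchange=True),
        Reaction("T_A", {"A_ext": -1.0, "A": 1.0}, upper_bound=10.0),
        Reaction("HIGH", {"A": -1.0, "P": 2.0}, upper_bound=4.0),
        Reaction("LOW", {"A": -1.0, "P": 1.0}, upper_bound=10.0),
        Reaction("T_P", {"P": -1.0, "P_ext": 1.0}),
        Reaction("EX_P", {"P_ext": -1.0}, reversible=True, lower_bound=0.0,
                 upper_bound=1000.0, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns, objective_id="EX_P")


def enumerate_lp_vertices(S, lb, ub, tol=1e-9):
    """Brute-force vertex enumeration of {v : S v = 0, lb <= v <= ub}.

    Works for small networks: the equality system leaves d degrees of
    freedom; every vertex has d bound constraints active. Enumerate all
    choices of active bounds, solve, keep feasible points.
    """
    import itertools

    import numpy as np

    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    _, sv, Vt = np.linalg.svd(S)
    rank = int(np.sum(sv > 1e-10 * max(sv[0], 1))) if sv.size else 0
    d = n - rank
    vertices = []
    for idx in itertools.combinations(range(n), d):
        for vals in itertools.product(*[(lb[i], ub[i]) for i in idx]):
            A = np.vstack([S] + [np.eye(n)[i] for i in idx])
            b = np.concatenate([np.zeros(S.shape[0]), np.array(vals)])
            v, res, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            if np.abs(A @ v - b).max() > tol:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(v)
    return np.array(vertices)
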