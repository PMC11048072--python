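"""Stoichiometric data model for the reduced CHO central-carbon network.

The network covers glycolysis, the pentose-phosphate entry, the TCA cycle,
anaplerotic routes (pyruvate carboxylase, malic enzyme), lactate exchange,
catabolism of the key amino acids (asparagine, aspartate, glutamate, serine,
isoleucine, leucine), ammonium release, oxidative phosphorylation with fixed
P/O ratios, an ATP maintenance drain, and biomass / mAb pseudo-reactions.

Every internal (non-exchange, non-biomass, non-product, non-ATP-drain)
reaction must be carbon- and nitrogen-balanced; redox and energy cofactors
are treated as carbon-free carrier pairs so conservation is checked on the
actual substrate skeletons.
"""

from __future__ import annotations

import importlib.resources as _resources
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkError",
    "build_network",
    "default_network",
    "stoichiometric_matrix",
    "check_balances",
    "parse_equation",
    "format_equation",
    "read_network_tsv",
    "write_network_tsv",
    "read_sbml",
    "write_sbml",
]

COMPARTMENTS = ("cytosol", "mitochondrion", "extracellular")
SUBSYSTEMS = (
    "glycolysis",
    "TCA",
    "PPP",
    "anaplerosis",
    "amino_acid",
    "transport",
    "biomass",
    "product",
    "energy",
)

#: reactions exempt from elemental balancing: exchanges plus lumped sinks
BALANCE_EXEMPT_SUBSYSTEMS = ("biomass", "product")


class NetworkError(ValueError):
    """Raised for structurally invalid networks or reaction tables."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    carbon_count: int = 0
    nitrogen_count: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r}")
        if self.carbon_count < 0 or self.nitrogen_count < 0:
            raise NetworkError(f"negative element count on {self.id}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    is_measured: bool = False
    subsystem: str = "transport"

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id}: empty stoichiometry")
        if self.subsystem not in SUBSYSTEMS:
            raise NetworkError(f"reaction {self.id}: unknown subsystem {self.subsystem!r}")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(f"reaction {self.id}: lower_bound > upper_bound")
        if not self.reversible and self.lower_bound < 0:
            raise NetworkError(f"reaction {self.id}: irreversible but lower_bound < 0")

    @property
    def is_balance_exempt(self) -> bool:
        return (
            self.is_exchange
            or self.subsystem in BALANCE_EXEMPT_SUBSYSTEMS
            or self.id == "ATPM"
        )


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str = "BIOMASS"

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise NetworkError("duplicate metabolite id")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise NetworkError("duplicate reaction id")
        known = set(met_ids)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - known
            if unknown:
                raise NetworkError(
                    f"reaction {rxn.id}: unknown metabolite(s) {sorted(unknown)}"
                )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self) -> np.ndarray:
        return stoichiometric_matrix(self)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicNetwork":
        rxns = [
            Reaction(
                id=r.id,
                stoichiometry=dict(r.stoichiometry),
                reversible=r.reversible,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                is_exchange=r.is_exchange,
                is_measured=r.is_measured,
                subsystem=r.subsystem,
            )
            for r in self.reactions
        ]
        return MetabolicNetwork(list(self.metabolites), rxns, self.objective_id)


# ---------------------------------------------------------------------------
# equation string handling ("A + 2 B -> C", "<->" marks reversibility)

_ARROWS = ("<->", "<=>", "->", "=>")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into a stoichiometry map and reversibility."""
    arrow = None
    for a in _ARROWS:
        if a in equation:
            arrow = a
            break
    if arrow is None:
        raise NetworkError(f"no arrow in equation {equation!r}")
    lhs, rhs = equation.split(arrow, 1)
    reversible = arrow in ("<->", "<=>")
    stoich: dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise NetworkError(f"cannot parse term {term!r} in {equation!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    _accumulate(lhs, -1.0)
    _accumulate(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise NetworkError(f"equation {equation!r} cancels to nothing")
    return stoich, reversible


def _fmt_coeff(c: float) -> str:
    return f"{c:g} " if c != 1.0 else ""


def format_equation(stoichiometry: Mapping[str, float], reversible: bool) -> str:
    lhs = [f"{_fmt_coeff(-c)}{m}" for m, c in stoichiometry.items() if c < 0]
    rhs = [f"{_fmt_coeff(c)}{m}" for m, c in stoichiometry.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ---------------------------------------------------------------------------
# construction & validation


def build_network(
    reaction_defs: pd.DataFrame,
    metabolite_defs: pd.DataFrame,
    objective_id: str = "BIOMASS",
    validate_balance: bool = True,
) -> MetabolicNetwork:
    """Build a validated network from structured reaction/metabolite tables.

    ``reaction_defs`` columns: id, equation, lower_bound, upper_bound,
    subsystem, is_exchange, is_measured. ``metabolite_defs`` columns: id,
    name, compartment, carbon, nitrogen.

    Raises :class:`NetworkError` on duplicate ids, unknown metabolites or
    (when ``validate_balance``) element-unbalanced internal reactions.
    """
    if len(reaction_defs) == 0:
        raise NetworkError("empty network")
    if reaction_defs["id"].duplicated().any():
        dups = reaction_defs.loc[reaction_defs["id"].duplicated(), "id"].tolist()
        raise NetworkError(f"duplicate reaction id(s): {dups}")

    mets = [
        Metabolite(
            id=str(row["id"]),
            name=str(row.get("name", "")),
            compartment=str(row["compartment"]),
            carbon_count=int(row["carbon"]),
            nitrogen_count=int(row["nitrogen"]),
        )
        for _, row in metabolite_defs.iterrows()
    ]
    rxns = []
    for _, row in reaction_defs.iterrows():
        stoich, reversible = parse_equation(str(row["equation"]))
        rxns.append(
            Reaction(
                id=str(row["id"]),
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                is_exchange=bool(int(row["is_exchange"])),
                is_measured=bool(int(row["is_measured"])),
                subsystem=str(row["subsystem"]),
            )
        )
    net = MetabolicNetwork(mets, rxns, objective_id)
    if validate_balance:
        report = check_balances(net)
        if len(report) > 0:
            bad = report["reaction"].tolist()
            raise NetworkError(f"element-unbalanced internal reaction(s): {bad}")
    return net


def stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense S with S[i, j] = coefficient of metabolite i in reaction j."""
    met_index = {m.id: i for i, m in enumerate(network.metabolites)}
    S = np.zeros((len(network.metabolites), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = coeff
    return S


def check_balances(network: MetabolicNetwork) -> pd.DataFrame:
    """Per-reaction carbon/nitrogen surplus for internal reactions.

    Returns only the reactions whose C or N surplus is non-zero; exchange,
    biomass, product and ATP-drain reactions are exempt.
    """
    carbon = {m.id: m.carbon_count for m in network.metabolites}
    nitrogen = {m.id: m.nitrogen_count for m in network.metabolites}
    rows = []
    for rxn in network.reactions:
        if rxn.is_balance_exempt:
            continue
        dc = sum(c * carbon[m] for m, c in rxn.stoichiometry.items())
        dn = sum(c * nitrogen[m] for m, c in rxn.stoichiometry.items())
        if abs(dc) > 1e-9 or abs(dn) > 1e-9:
            rows.append({"reaction": rxn.id, "carbon_surplus": dc, "nitrogen_surplus": dn})
    return pd.DataFrame(rows, columns=["reaction", "carbon_surplus", "nitrogen_surplus"])


def default_network() -> MetabolicNetwork:
    """The shipped ~46-reaction central-carbon network (validated)."""
    data = _resources.files("chometab") / "data"
    rxn = pd.read_csv(str(data / "default_reactions.tsv"), sep="\t")
    met = pd.read_csv(str(data / "default_metabolites.tsv"), sep="\t")
    return build_network(rxn, met)


# ---------------------------------------------------------------------------
# native TSV I/O


def write_network_tsv(network: MetabolicNetwork, reactions_path, metabolites_path) -> None:
    rxn_rows = [
        {
            "id": r.id,
            "equation": format_equation(r.stoichiometry, r.reversible),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "subsystem": r.subsystem,
            "is_exchange": int(r.is_exchange),
            "is_measured": int(r.is_measured),
        }
        for r in network.reactions
    ]
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "carbon": m.carbon_count,
            "nitrogen": m.nitrogen_count,
        }
        for m in network.metabolites
    ]
    pd.DataFrame(rxn_rows).to_csv(reactions_path, sep="\t", index=False)
    pd.DataFrame(met_rows).to_csv(metabolites_path, sep="\t", index=False)


def read_network_tsv(reactions_path, metabolites_path, objective_id: str = "BIOMASS") -> MetabolicNetwork:
    rxn = pd.read_csv(reactions_path, sep="\t")
    met = pd.read_csv(metabolites_path, sep="\t")
    return build_network(rxn, met, objective_id=objective_id)


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc) I/O via cobrapy

_COMPARTMENT_CODES = {"cytosol": "c", "mitochondrion": "m", "extracellular": "e"}
_COMPARTMENT_NAMES = {v: k for k, v in _COMPARTMENT_CODES.items()}


def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("chometab")
    for m in network.metabolites:
        cm = cobra.Metabolite(
            m.id, name=m.name, compartment=_COMPARTMENT_CODES[m.compartment]
        )
        cm.notes["carbon"] = m.carbon_count
        cm.notes["nitrogen"] = m.nitrogen_count
        model.add_metabolites([cm])
    for r in network.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.notes["subsystem"] = r.subsystem
        cr.notes["is_exchange"] = int(r.is_exchange)
        cr.notes["is_measured"] = int(r.is_measured)
        model.add_reactions([cr])
        cr.add_metabolites(
            {model.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
        )
    if network.objective_id in [r.id for r in network.reactions]:
        model.objective = network.objective_id
    return model


def write_sbml(network: MetabolicNetwork, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(_to_cobra(network), str(path))


def read_sbml(path, objective_id: str = "BIOMASS") -> MetabolicNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=_COMPARTMENT_NAMES.get(m.compartment, "cytosol"),
            carbon_count=int(m.notes.get("carbon", 0)),
            nitrogen_count=int(m.notes.get("nitrogen", 0)),
        )
        for m in model.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            reversible=r.lower_bound < 0,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            is_exchange=bool(int(r.notes.get("is_exchange", int(r.boundary)))),
            is_measured=bool(int(r.notes.get("is_measured", 0))),
            subsystem=str(r.notes.get("subsystem", "transport")),
        )
        for r in model.reactions
    ]
    return MetabolicNetwork(mets, rxns, objective_id)
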