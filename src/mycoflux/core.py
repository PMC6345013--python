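"""Domain types for compartmentalized stoichiometric models.

A :class:`MetabolicModel` is a set of metabolites (with elemental formulas and
charges), reactions (signed rational stoichiometries, flux bounds in
mmol/gDW/h, GPR rules) and a linear objective.  The module also provides the
structural operations that do not require an LP solver: stoichiometric matrix
assembly, elemental/charge balance checking and duplicate-reaction detection.

Conventions
-----------
* Metabolite ids carry a bracketed compartment suffix, e.g. ``accoa[c]``.
* Stoichiometric coefficients are negative for consumed species and are
  stored as exact :class:`fractions.Fraction` values so that duplicate and
  scaling comparisons are exact.
* Reversible reactions default to bounds (−1000, 1000), irreversible to
  (0, 1000); exchange uptake is a negative lower bound.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .gpr import GPRExpression, parse_gpr

logger = logging.getLogger(__name__)

#: Compartment codes: cytoplasm, extracellular, mitochondrion, nucleus,
#: plasma membrane, peroxisome, endoplasmic reticulum, vacuole.
COMPARTMENTS = ("c", "e", "m", "n", "pm", "x", "r", "v")

REACTION_KINDS = (
    "metabolic",
    "transport",
    "exchange",
    "sink",
    "demand",
    "biomass",
    "spontaneous",
)

#: Boundary kinds whose stoichiometry is intentionally unbalanced.
BOUNDARY_KINDS = frozenset({"exchange", "sink", "demand", "biomass"})

DEFAULT_UPPER = 1000.0
DEFAULT_LOWER = -1000.0

Number = Union[int, float, str, Fraction]


def as_coefficient(value: Number) -> Fraction:
    """Convert a number to an exact Fraction.

    Floats go through their shortest decimal repr so that e.g. ``0.1``
    becomes 1/10 rather than its binary expansion.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    return Fraction(str(value).strip())


def format_coefficient(value: Fraction) -> str:
    """Serialize a Fraction: finite decimals as decimals, else ``p/q``."""
    den = value.denominator
    while den % 2 == 0:
        den //= 2
    while den % 5 == 0:
        den //= 5
    if den == 1:
        if value.denominator == 1:
            return str(value.numerator)
        as_float = float(value)
        if Fraction(repr(as_float)) == value:
            return repr(as_float)
    return f"{value.numerator}/{value.denominator}"


# --------------------------------------------------------------------------
# Formulas
# --------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Standard atomic weights (g/mol) for the elements used in the bundled
#: fixtures plus common inorganic ions.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Fe": 55.845, "Cl": 35.45,
    "Mg": 24.305, "Ca": 40.078, "Zn": 65.38, "Mn": 54.938, "Cu": 63.546,
    "Se": 78.971, "Co": 58.933, "Mo": 95.95, "R": 0.0,
}


class FormulaError(ValueError):
    """Raised for formula strings that are not plain Hill-notation counts."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    Only integer counts are supported; charges are never embedded in the
    formula (they live on the metabolite).  An empty string parses to an
    empty map (unknown composition).
    """
    if not formula:
        return {}
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable formula {formula!r} near position {pos}")
        element = match.group(1)
        count = int(match.group(2)) if match.group(2) else 1
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} near position {pos}")
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol computed from standard atomic weights."""
    counts = parse_formula(formula)
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    except KeyError as exc:
        raise FormulaError(f"no atomic weight for element {exc.args[0]!r}") from exc


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``charge is None`` means unknown; balance checking then skips the charge
    residual for reactions touching this species.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: Optional[int] = None
    compartment: str = "c"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}")
        parse_formula(self.formula)  # fail fast on malformed formulas


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule."""

    id: str
    name: str = ""
    stoichiometry: Dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gpr: GPRExpression = field(default_factory=GPRExpression.empty)
    subsystem: str = ""
    kind: str = "metabolic"

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        self.stoichiometry = {
            met: as_coefficient(coeff) for met, coeff in self.stoichiometry.items()
        }
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self, arrow_rev: str = "<=>", arrow_irrev: str = "-->") -> str:
        """Human-readable equation string, e.g. ``a[c] + 2 b[c] --> c[c]``."""
        subs, prods = [], []
        for met in sorted(self.stoichiometry):
            coeff = self.stoichiometry[met]
            target = subs if coeff < 0 else prods
            mag = abs(coeff)
            target.append(met if mag == 1 else f"{format_coefficient(mag)} {met}")
        arrow = arrow_rev if self.reversible else arrow_irrev
        return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


@dataclass
class BalanceReport:
    """Per-reaction element/charge bookkeeping from :func:`check_balance`."""

    reaction_id: str
    element_residuals: Dict[str, Fraction] = field(default_factory=dict)
    charge_residual: Optional[Fraction] = None
    balanced: bool = False
    skipped: bool = False
    reason: str = ""


class ModelError(ValueError):
    """Raised when model invariants are violated."""


class MetabolicModel:
    """A compartmentalized reaction network with bounds, GPRs and objective."""

    def __init__(self, model_id: str = "model", name: str = ""):
        self.id = model_id
        self.name = name or model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.genes: set = set()
        self.compartments: Dict[str, str] = {}
        self.objective: Dict[str, float] = {}
        self.notes: List[str] = []

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references unknown metabolites: {missing}")
        for gene in rxn.gpr.genes():
            if gene not in self.genes:
                logger.warning(
                    "reaction %s: gene %s not in gene set, adding it", rxn.id, gene)
                self.genes.add(gene)
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, reaction_id: str) -> Reaction:
        rxn = self.reactions.pop(reaction_id)
        self.objective.pop(reaction_id, None)
        return rxn

    def set_objective(self, reaction_id: str, weight: float = 1.0) -> None:
        if reaction_id not in self.reactions:
            raise ModelError(f"objective references unknown reaction {reaction_id!r}")
        self.objective = {reaction_id: float(weight)}

    # -- views ------------------------------------------------------------
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def reactions_for_gene(self, gene: str) -> List[str]:
        return [r.id for r in self.reactions.values() if gene in r.gpr.genes()]

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelError` on any violated model invariant."""
        for rxn in self.reactions.values():
            missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
            if missing:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolites: {missing}")
            for gene in rxn.gpr.genes():
                if gene not in self.genes:
                    raise ModelError(
                        f"reaction {rxn.id!r}: gene {gene!r} missing from gene set")
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise ModelError(
                        f"exchange {rxn.id!r} must touch exactly one metabolite")
                met_id = next(iter(rxn.stoichiometry))
                if self.metabolites[met_id].compartment != "e":
                    raise ModelError(
                        f"exchange {rxn.id!r}: metabolite {met_id!r} not in "
                        f"compartment 'e'")
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelError(f"objective references unknown reaction {rid!r}")

    def copy(self) -> "MetabolicModel":
        other = MetabolicModel(self.id, self.name)
        other.metabolites = {
            mid: Metabolite(m.id, m.name, m.formula, m.charge, m.compartment)
            for mid, m in self.metabolites.items()
        }
        other.reactions = {
            rid: Reaction(
                r.id, r.name, dict(r.stoichiometry), r.lower_bound,
                r.upper_bound, r.gpr, r.subsystem, r.kind)
            for rid, r in self.reactions.items()
        }
        other.genes = set(self.genes)
        other.compartments = dict(self.compartments)
        other.objective = dict(self.objective)
        other.notes = list(self.notes)
        return other

    def __repr__(self) -> str:
        return (f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
                f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>")


# --------------------------------------------------------------------------
# Structural operations
# --------------------------------------------------------------------------


def stoichiometric_matrix(
    model: MetabolicModel,
) -> Tuple[np.ndarray, Dict[str, int], Dict[str, int]]:
    """Dense S matrix (metabolites x reactions) plus id -> index maps.

    ``S[i, j]`` is the signed coefficient of metabolite *i* in reaction *j*;
    the steady-state constraint of FBA is ``S v = 0``.
    """
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rxn_index = {rid: j for j, rid in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for rid, rxn in model.reactions.items():
        j = rxn_index[rid]
        for mid, coeff in rxn.stoichiometry.items():
            S[met_index[mid], j] = float(coeff)
    return S, met_index, rxn_index


def check_balance(model: MetabolicModel) -> List[BalanceReport]:
    """Element and charge balance bookkeeping for every reaction.

    Boundary reactions (exchange/sink/demand/biomass) and reactions touching
    a metabolite without a formula are reported as skipped, never as
    unbalanced.  The checker reports residuals; it does not auto-correct
    proton or charge conventions.
    """
    reports = []
    for rxn in model.reactions.values():
        if rxn.kind in BOUNDARY_KINDS:
            reports.append(BalanceReport(rxn.id, skipped=True,
                                         reason=f"{rxn.kind} reaction"))
            continue
        mets = [model.metabolites[mid] for mid in rxn.stoichiometry]
        if any(not m.formula for m in mets):
            missing = [m.id for m in mets if not m.formula]
            reports.append(BalanceReport(
                rxn.id, skipped=True,
                reason=f"missing formula for {', '.join(missing)}"))
            continue
        residuals: Dict[str, Fraction] = {}
        for mid, coeff in rxn.stoichiometry.items():
            try:
                counts = parse_formula(model.metabolites[mid].formula)
            except FormulaError as exc:
                raise FormulaError(f"metabolite {mid!r}: {exc}") from exc
            for el, n in counts.items():
                residuals[el] = residuals.get(el, Fraction(0)) + coeff * n
        residuals = {el: r for el, r in residuals.items() if r != 0}
        charge: Optional[Fraction]
        if any(m.charge is None for m in mets):
            charge = None
        else:
            charge = sum(
                (coeff * model.metabolites[mid].charge
                 for mid, coeff in rxn.stoichiometry.items()),
                Fraction(0))
        balanced = not residuals and (charge is None or charge == 0)
        reports.append(BalanceReport(
            rxn.id, element_residuals=residuals, charge_residual=charge,
            balanced=balanced))
    return reports


@dataclass
class DuplicateGroup:
    """A set of reactions with identical canonical stoichiometry."""

    reaction_ids: Tuple[str, ...]
    direction_conflict: bool = False


def _canonical_stoichiometry(rxn: Reaction) -> Tuple[Tuple[str, Fraction], ...]:
    """Scale so the coefficient of the first (sorted) metabolite is +1.

    Scaling by the signed first coefficient erases both overall scale and
    direction, so a reaction and its reverse share one canonical form.
    """
    mets = sorted(rxn.stoichiometry)
    first = rxn.stoichiometry[mets[0]]
    return tuple((m, rxn.stoichiometry[m] / first) for m in mets)


def find_duplicate_reactions(model: MetabolicModel) -> List[DuplicateGroup]:
    """Group reactions whose stoichiometries coincide after normalization.

    Grouping is an equivalence relation (same canonical key).  A group is
    flagged ``direction_conflict`` when its members disagree on orientation
    or reversibility, e.g. an irreversible A→B grouped with reversible B↔A.
    """
    groups: Dict[Tuple, List[str]] = {}
    for rid, rxn in model.reactions.items():
        groups.setdefault(_canonical_stoichiometry(rxn), []).append(rid)
    out = []
    for key, ids in groups.items():
        if len(ids) < 2:
            continue
        orientations = set()
        for rid in ids:
            rxn = model.reactions[rid]
            first_met = key[0][0]
            sign = 1 if rxn.stoichiometry[first_met] > 0 else -1
            orientations.add((sign, rxn.reversible))
        out.append(DuplicateGroup(tuple(sorted(ids)),
                                  direction_conflict=len(orientations) > 1))
    out.sort(key=lambda g: g.reaction_ids)
    return out
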