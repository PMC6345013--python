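"""Independent oracles used by the test suite.

These deliberately avoid the package's own solver paths: FBA/FVA go
through cobrapy's GLPK backend, the MOMA projection uses Dykstra's
alternating-projection algorithm, and GPR truth values come from a
shunting-yard evaluator that shares no code with the package parser.
"""

from __future__ import annotations

import re
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import linalg

import cobra

from mycoflux.core import MetabolicModel, stoichiometric_matrix


def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Translate to a cobrapy model (GPRs omitted; the LP is the point)."""
    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites.values():
        cmet = cobra.Metabolite(met.id, compartment=met.compartment)
        mets[met.id] = cmet
    cm.add_metabolites(list(mets.values()))
    reactions = []
    for rxn in model.reactions.values():
        crx = cobra.Reaction(rxn.id)
        crx.lower_bound = rxn.lower_bound
        crx.upper_bound = rxn.upper_bound
        reactions.append(crx)
    cm.add_reactions(reactions)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[mid]: float(c) for mid, c in rxn.stoichiometry.items()})
    return cm


def cobra_fba(model: MetabolicModel,
              objective: Optional[str] = None,
              bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None):
    """(status, objective value) from cobrapy/GLPK."""
    cm = to_cobra(model)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            crx = cm.reactions.get_by_id(rid)
            crx.lower_bound = lo
            crx.upper_bound = hi
    if objective is None:
        [objective] = [r for r, w in model.objective.items() if w]
    cm.objective = cm.reactions.get_by_id(objective)
    solution = cm.optimize()
    return solution.status, solution.objective_value


def cobra_fva(model: MetabolicModel, fraction: float = 1.0,
              reactions: Optional[Sequence[str]] = None):
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(model)
    [objective] = [r for r, w in model.objective.items() if w]
    cm.objective = cm.reactions.get_by_id(objective)
    reaction_list = None if reactions is None else [
        cm.reactions.get_by_id(r) for r in reactions]
    frame = flux_variability_analysis(cm, reaction_list=reaction_list,
                                      fraction_of_optimum=fraction)
    return {rid: (row["minimum"], row["maximum"])
            for rid, row in frame.iterrows()}


def dykstra_moma(model: MetabolicModel, reference: Mapping[str, float],
                 bound_overrides: Mapping[str, Tuple[float, float]],
                 iterations: int = 200000) -> Tuple[Dict[str, float], float]:
    """Euclidean projection of the reference flux onto {Sv=0} ∩ box.

    Dykstra's alternating projections converge to the exact projection,
    which is the MOMA optimum.  Returns (flux map, squared distance).
    """
    S, _, rxn_index = stoichiometric_matrix(model)
    n = len(rxn_index)
    lb = np.empty(n)
    ub = np.empty(n)
    ref = np.zeros(n)
    for rid, j in rxn_index.items():
        rxn = model.reactions[rid]
        lo, hi = rxn.lower_bound, rxn.upper_bound
        if rid in bound_overrides:
            lo, hi = bound_overrides[rid]
        lb[j], ub[j] = lo, hi
        ref[j] = reference.get(rid, 0.0)
    N = linalg.null_space(S)
    x = ref.copy()
    p = np.zeros(n)
    q = np.zeros(n)
    for _ in range(iterations):
        y = N @ (N.T @ (x + p))
        p = x + p - y
        x = np.clip(y + q, lb, ub)
        q = y + q - x
    distance = float(np.sum((x - ref) ** 2))
    return {rid: float(x[j]) for rid, j in rxn_index.items()}, distance


# -- independent GPR truth evaluation --------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def gpr_truth(text: str, knocked_out: Set[str]) -> bool:
    """Shunting-yard evaluation of a GPR string (independent of the
    package's recursive-descent parser)."""
    if not text.strip():
        return True
    output, ops = [], []
    precedence = {"or": 1, "and": 2}

    def apply(op):
        b, a = output.pop(), output.pop()
        output.append((a and b) if op == "and" else (a or b))

    for token in _TOKEN.findall(text):
        low = token.lower()
        if token == "(":
            ops.append(token)
        elif token == ")":
            while ops and ops[-1] != "(":
                apply(ops.pop())
            ops.pop()
        elif low in precedence:
            while (ops and ops[-1] != "(" and
                   precedence.get(ops[-1], 0) >= precedence[low]):
                apply(ops.pop())
            ops.append(low)
        else:
            output.append(token not in knocked_out)
    while ops:
        apply(ops.pop())
    return output[0]


def brute_force_essentials(model: MetabolicModel, threshold: float = 0.01):
    """Delete-and-resolve enumeration with the cobrapy/GLPK backend."""
    status, wt = cobra_fba(model)
    assert status == "optimal"
    essentials = []
    for gene in sorted(model.genes):
        overrides = {}
        for rxn in model.reactions.values():
            rule = rxn.gpr.to_string()
            if gene in rxn.gpr.genes() and not gpr_truth(rule, {gene}):
                overrides[rxn.id] = (0.0, 0.0)
        if not overrides:
            continue
        status, growth = cobra_fba(model, bound_overrides=overrides)
        if status != "optimal" or growth is None:
            growth = 0.0
        if max(growth, 0.0) < threshold * wt:
            essentials.append(gene)
    return essentials, wt
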