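"""Linear-programming core: FBA, media, flux variability, robustness scans.

Flux balance analysis solves

    max  c' v
    s.t. S v = 0,   lb <= v <= ub

where S is the stoichiometric matrix, v the flux vector (mmol/gDW/h) and c
the objective (typically the biomass pseudo-reaction, whose flux is the
specific growth rate mu in 1/h).  The LP backend is HiGHS via
``scipy.optimize.linprog``; feasibility/optimality tolerances are 1e-9,
well below the 4 significant digits at which fluxes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicModel, ModelError, stoichiometric_matrix

#: Reported fluxes smaller than this are treated as zero by downstream
#: consumers (connectivity counts, overexpression scans, TSV output).
FLUX_ZERO_TOL = 1e-6

_LINPROG_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


@dataclass
class FluxState:
    """One LP/QP solution: flux map, objective value and solver status."""

    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_reactions: Tuple[str, ...] = ()

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class MediumSpec:
    """Growth medium: maximum uptake rates for exchange reactions.

    ``uptakes`` maps exchange ids to maximum uptake rates (>= 0, applied as
    negative lower bounds).  Exchanges in ``unlimited`` are left effectively
    unconstrained (lower bound −1000), mirroring how inorganic ions are
    treated; every other exchange is closed for uptake.
    """

    uptakes: Dict[str, float] = field(default_factory=dict)
    unlimited: frozenset = frozenset()

    def __post_init__(self):
        bad = {k: v for k, v in self.uptakes.items() if v < 0}
        if bad:
            raise ValueError(f"uptake rates must be >= 0, got {bad}")
        self.unlimited = frozenset(self.unlimited)


def set_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from ``medium``."""
    unknown = [rid for rid in list(medium.uptakes) + list(medium.unlimited)
               if rid not in model.reactions]
    if unknown:
        raise ModelError(f"medium references unknown exchange reactions: {unknown}")
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind != "exchange":
            continue
        if rxn.id in medium.uptakes:
            rxn.lower_bound = -float(medium.uptakes[rxn.id])
        elif rxn.id in medium.unlimited:
            rxn.lower_bound = -1000.0
        else:
            rxn.lower_bound = 0.0
    return out


# --------------------------------------------------------------------------
# LP assembly
# --------------------------------------------------------------------------


def _lp_parts(model: MetabolicModel):
    S, met_index, rxn_index = stoichiometric_matrix(model)
    n = len(rxn_index)
    lb = np.empty(n)
    ub = np.empty(n)
    for rid, j in rxn_index.items():
        rxn = model.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
    return sparse.csr_matrix(S), rxn_index, lb, ub


def _objective_vector(model: MetabolicModel,
                      objective: Optional[Mapping[str, float]],
                      rxn_index: Mapping[str, int]) -> np.ndarray:
    if objective is None:
        objective = model.objective
    if isinstance(objective, str):
        objective = {objective: 1.0}
    if not objective:
        raise ModelError("no objective given and model has none set")
    c = np.zeros(len(rxn_index))
    for rid, weight in objective.items():
        if rid not in rxn_index:
            raise ModelError(f"objective references unknown reaction {rid!r}")
        c[rxn_index[rid]] = float(weight)
    return c


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(S, c, lb, ub, maximize: bool):
    res = linprog(
        -c if maximize else c,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    status = _STATUS.get(res.status, "infeasible")
    value = None
    x = None
    if status == "optimal":
        value = -res.fun if maximize else res.fun
        x = res.x
    return status, value, x


def solve_fba(
    model: MetabolicModel,
    objective: Optional[Mapping[str, float]] = None,
    direction: str = "max",
) -> FluxState:
    """Flux balance analysis.

    The objective value is the deterministic contract; the flux vector is
    one optimal vertex and may differ between backends when the optimum is
    degenerate (assert flux ranges via :func:`flux_variability` instead).
    Infeasible or unbounded problems are reported via ``status``, never
    silently.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    S, rxn_index, lb, ub = _lp_parts(model)
    c = _objective_vector(model, objective, rxn_index)
    status, value, x = _solve(S, c, lb, ub, maximize=direction == "max")
    fluxes = {}
    if x is not None:
        fluxes = {rid: float(x[j]) for rid, j in rxn_index.items()}
    obj_ids = tuple(
        rid for rid in (model.objective if objective is None else
                        ({objective: 1.0} if isinstance(objective, str) else objective)))
    return FluxState(fluxes, value, status, obj_ids)


def flux_variability(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
    objective: Optional[Mapping[str, float]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction [min, max] flux at >= ``objective_fraction`` x optimum.

    Solves two LPs per reaction with the objective constrained via an
    inequality row; raises on an infeasible base problem.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    S, rxn_index, lb, ub = _lp_parts(model)
    c = _objective_vector(model, objective, rxn_index)
    status, opt, _ = _solve(S, c, lb, ub, maximize=True)
    if status != "optimal":
        raise ModelError(f"FVA base problem is {status}")
    # c' v >= fraction * opt  encoded as  -c' v <= -fraction * opt
    A_ub = sparse.csr_matrix(-c)
    b_ub = np.array([-objective_fraction * opt])
    targets = list(model.reactions) if reactions is None else list(reactions)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = rxn_index[rid]
        e = np.zeros(len(rxn_index))
        e[j] = 1.0
        bounds = np.column_stack([lb, ub])
        lo = linprog(e, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                     b_eq=np.zeros(S.shape[0]), bounds=bounds,
                     method="highs", options=_LINPROG_OPTIONS)
        hi = linprog(-e, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                     b_eq=np.zeros(S.shape[0]), bounds=bounds,
                     method="highs", options=_LINPROG_OPTIONS)
        if lo.status != 0 or hi.status != 0:
            raise ModelError(f"FVA subproblem for {rid!r} failed")
        vmin, vmax = lo.fun, -hi.fun
        if vmin > vmax:  # numerical fuzz on collapsed ranges
            vmin = vmax = 0.5 * (vmin + vmax)
        out[rid] = (vmin, vmax)
    return out


@dataclass
class ScanPoint:
    value: float
    objective_value: Optional[float]
    status: str
    fluxes: Dict[str, float] = field(default_factory=dict)


def robustness_scan(
    model: MetabolicModel,
    control_reaction: str,
    values: Sequence[float],
    objective: Optional[Mapping[str, float]] = None,
    fix: bool = False,
) -> List[ScanPoint]:
    """Objective optimum as a function of a control reaction's bound.

    For each value v: with ``fix=True`` the control flux is pinned
    (lb = ub = v); otherwise v widens one bound toward itself (negative v
    sets the lower bound — e.g. an uptake allowance on an exchange —
    positive v sets the upper bound), so the scan is a pure relaxation and
    the optimum is monotone in |v|.  Infeasible points are flagged per
    point, not raised.
    """
    if control_reaction not in model.reactions:
        raise ModelError(f"unknown control reaction {control_reaction!r}")
    if list(values) != sorted(values) and list(values) != sorted(values, reverse=True):
        raise ValueError("scan values must be sorted")
    points = []
    for v in values:
        scan_model = model.copy()
        rxn = scan_model.reactions[control_reaction]
        if fix:
            rxn.lower_bound = rxn.upper_bound = float(v)
        elif v < 0:
            rxn.lower_bound = float(v)
        else:
            rxn.upper_bound = float(v)
        state = solve_fba(scan_model, objective=objective)
        points.append(ScanPoint(float(v), state.objective_value, state.status,
                                state.fluxes))
    return points


def metabolite_connectivity(
    model: MetabolicModel,
    flux_state: Optional[FluxState] = None,
    tolerance: float = FLUX_ZERO_TOL,
) -> List[Tuple[str, int]]:
    """Rank metabolites by the number of reactions they participate in.

    Structural mode (``flux_state is None``) counts every reaction touching
    the metabolite; flux mode counts only reactions carrying |flux| above
    ``tolerance`` in the given state.  Sorted by descending count, ties
    broken by metabolite id.
    """
    counts = {mid: 0 for mid in model.metabolites}
    for rxn in model.reactions.values():
        if flux_state is not None:
            if abs(flux_state.fluxes.get(rxn.id, 0.0)) <= tolerance:
                continue
        for mid in rxn.stoichiometry:
            counts[mid] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
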