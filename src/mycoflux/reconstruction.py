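"""Draft-model assembly from reference models and growth-restoring gap fill.

The draft reconstruction route mirrors standard ortholog-based practice:
protein-similarity hits against reference organisms are filtered at
identity >= 40% and e-value <= 1e-30 (inclusive, as printed), reactions are
imported from each reference model when their GPR is satisfiable with only
the mapped subject genes present, GPRs are rewritten in target-organism
gene ids, and duplicates across references are merged.  Gap filling adds a
minimal set of candidate reactions from a universal set so that a required
objective (typically growth on a given substrate) becomes feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .core import (MetabolicModel, Metabolite, ModelError, Reaction,
                   find_duplicate_reactions)
from .fba import FLUX_ZERO_TOL, solve_fba
from .gpr import GPRExpression, Or, UnsatisfiableGPR

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MAX_EVALUE = 1e-30


@dataclass(frozen=True)
class OrthologHit:
    """One BLAST-like hit row: target-organism query vs reference subject."""

    query: str
    subject: str
    identity: float
    evalue: float
    reference: str = ""

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity must lie in [0, 100], got {self.identity}")
        if self.evalue < 0:
            raise ValueError(f"e-value must be >= 0, got {self.evalue}")


def filter_orthologs(
    hits: Iterable[OrthologHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    qualify: bool = False,
) -> Dict[str, Set[str]]:
    """Gene mapping (query -> subject set) from hits passing both thresholds.

    Both thresholds are inclusive.  With ``qualify=True`` subjects are
    prefixed ``"<reference>:"`` to keep gene ids from different reference
    models apart.  The result is independent of row order.
    """
    mapping: Dict[str, Set[str]] = {}
    for hit in hits:
        if hit.identity >= min_identity and hit.evalue <= max_evalue:
            subject = f"{hit.reference}:{hit.subject}" if qualify else hit.subject
            mapping.setdefault(hit.query, set()).add(subject)
    return mapping


def _present_subjects(mapping: Mapping[str, Set[str]],
                      reference: MetabolicModel) -> Dict[str, Set[str]]:
    """Subject gene -> query set for subjects present in one reference.

    Accepts both plain subject ids and label-qualified ``"<model id>:gene"``
    ids in the mapping.
    """
    inverse: Dict[str, Set[str]] = {}
    for query, subjects in mapping.items():
        for subject in subjects:
            plain = subject
            if subject.startswith(f"{reference.id}:"):
                plain = subject.split(":", 1)[1]
            elif ":" in subject:
                continue  # qualified for a different reference
            if plain in reference.genes:
                inverse.setdefault(plain, set()).add(query)
    return inverse


def draft_from_references(
    mapping: Mapping[str, Set[str]],
    reference_models: Sequence[MetabolicModel],
    model_id: str = "draft",
) -> MetabolicModel:
    """Assemble a draft model by importing ortholog-supported reactions.

    A reference reaction is imported iff its GPR evaluates true when exactly
    the mapped subject genes are present (reactions without gene evidence
    are imported as-is).  Imported GPRs are rewritten in query gene ids;
    reactions appearing in several references are merged by duplicate
    detection, OR-ing their rewritten GPRs and widening bounds.
    """
    draft = MetabolicModel(model_id)
    for reference in reference_models:
        inverse = _present_subjects(mapping, reference)
        absent = reference.genes - set(inverse)
        for rxn in reference.reactions.values():
            if not rxn.gpr.evaluate(absent):
                continue
            try:
                new_gpr = rxn.gpr.substitute(inverse)
            except UnsatisfiableGPR:
                continue
            for mid in rxn.stoichiometry:
                if mid not in draft.metabolites:
                    met = reference.metabolites[mid]
                    draft.add_metabolite(Metabolite(
                        met.id, met.name, met.formula, met.charge, met.compartment))
            new_id = rxn.id
            if new_id in draft.reactions:
                new_id = f"{rxn.id}__{reference.id}"
            draft.add_reaction(Reaction(
                new_id, rxn.name, dict(rxn.stoichiometry), rxn.lower_bound,
                rxn.upper_bound, new_gpr, rxn.subsystem, rxn.kind))
    _merge_duplicates(draft)
    return draft


def _merge_duplicates(model: MetabolicModel) -> None:
    """Collapse duplicate reactions in place, OR-ing GPRs, widening bounds."""
    for group in find_duplicate_reactions(model):
        keep_id = group.reaction_ids[0]
        keep = model.reactions[keep_id]
        gpr_roots = []
        seen = set()
        for rid in group.reaction_ids:
            rxn = model.reactions[rid]
            keep.lower_bound = min(keep.lower_bound, rxn.lower_bound)
            keep.upper_bound = max(keep.upper_bound, rxn.upper_bound)
            if rxn.gpr.is_empty:
                gpr_roots = []  # no gene requirement at all
                seen = {None}
                break
            if rxn.gpr.root not in seen:
                seen.add(rxn.gpr.root)
                gpr_roots.append(rxn.gpr.root)
        if None in seen:
            keep.gpr = GPRExpression.empty()
        elif len(gpr_roots) == 1:
            keep.gpr = GPRExpression(gpr_roots[0])
        else:
            keep.gpr = GPRExpression(Or(tuple(gpr_roots)))
        for rid in group.reaction_ids[1:]:
            model.remove_reaction(rid)


def add_exchange_reactions(
    model: MetabolicModel,
    metabolite_ids: Sequence[str],
    lower_bound: float = 0.0,
    upper_bound: float = 1000.0,
) -> MetabolicModel:
    """Add one exchange reaction per extracellular metabolite (in place).

    Default bounds (0, 1000) leave uptake closed until a medium opens it.
    """
    existing = {next(iter(r.stoichiometry)) for r in model.exchanges()}
    for mid in metabolite_ids:
        if mid not in model.metabolites:
            raise ModelError(f"unknown metabolite {mid!r}")
        met = model.metabolites[mid]
        if met.compartment != "e":
            raise ModelError(
                f"exchange metabolite {mid!r} must be extracellular, "
                f"found compartment {met.compartment!r}")
        if mid in existing:
            raise ModelError(f"metabolite {mid!r} already has an exchange reaction")
        base = mid.split("[", 1)[0]
        rid = f"EX_{base}"
        if rid in model.reactions:
            raise ModelError(f"exchange id {rid!r} already present")
        model.add_reaction(Reaction(
            rid, name=f"{met.name or base} exchange",
            stoichiometry={mid: -1}, lower_bound=lower_bound,
            upper_bound=upper_bound, subsystem="exchange", kind="exchange"))
        existing.add(mid)
    return model


@dataclass
class UniversalReactionSet:
    """Candidate reactions (with any new metabolites) usable for gap filling."""

    reactions: Dict[str, Reaction] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)

    def add(self, rxn: Reaction, metabolites: Iterable[Metabolite] = ()) -> None:
        for met in metabolites:
            self.metabolites.setdefault(met.id, met)
        self.reactions[rxn.id] = rxn


class GapFillError(ModelError):
    """No candidate combination restores the objective; lists blocked precursors."""

    def __init__(self, message: str, blocked_precursors: Tuple[str, ...] = ()):
        super().__init__(message)
        self.blocked_precursors = blocked_precursors


def _augment(model: MetabolicModel, universal: UniversalReactionSet,
             ids: Iterable[str]) -> MetabolicModel:
    out = model.copy()
    for rid in ids:
        rxn = universal.reactions[rid]
        for mid in rxn.stoichiometry:
            if mid not in out.metabolites:
                if mid not in universal.metabolites:
                    raise ModelError(
                        f"universal reaction {rid!r} references metabolite "
                        f"{mid!r} defined nowhere")
                met = universal.metabolites[mid]
                out.add_metabolite(Metabolite(
                    met.id, met.name, met.formula, met.charge, met.compartment))
        new_id = rid if rid not in out.reactions else f"{rid}__gf"
        out.add_reaction(Reaction(
            new_id, rxn.name, dict(rxn.stoichiometry), rxn.lower_bound,
            rxn.upper_bound, rxn.gpr, rxn.subsystem, rxn.kind))
    return out


def _objective_flux(model: MetabolicModel, objective_reaction: str) -> float:
    state = solve_fba(model, objective=objective_reaction)
    if not state.optimal:
        return 0.0
    return state.objective_value


def gap_fill(
    model: MetabolicModel,
    universal: UniversalReactionSet,
    objective_reaction: str,
    min_objective: float = FLUX_ZERO_TOL,
) -> List[str]:
    """Minimal universal-reaction set restoring objective >= ``min_objective``.

    Deterministic greedy procedure: all candidates are added (if even that
    fails, the problem is reported unfillable together with the objective
    precursors that cannot be produced), then candidates are pruned in
    candidate order, keeping only those whose removal breaks the target.
    The returned set is minimal: removing any single member drops the
    objective below the target.
    """
    if objective_reaction not in model.reactions:
        raise ModelError(f"unknown objective reaction {objective_reaction!r}")
    if _objective_flux(model, objective_reaction) >= min_objective:
        return []
    candidates = list(universal.reactions)
    full = _augment(model, universal, candidates)
    if _objective_flux(full, objective_reaction) < min_objective:
        raise GapFillError(
            f"objective {objective_reaction!r} cannot reach {min_objective} even "
            f"with all {len(candidates)} universal reactions added",
            blocked_precursors=_blocked_precursors(full, objective_reaction))
    kept = list(candidates)
    for rid in candidates:
        trial = [r for r in kept if r != rid]
        trial_model = _augment(model, universal, trial)
        if _objective_flux(trial_model, objective_reaction) >= min_objective:
            kept = trial
    return kept


def _blocked_precursors(model: MetabolicModel, objective_reaction: str,
                        tol: float = FLUX_ZERO_TOL) -> Tuple[str, ...]:
    """Objective substrates that cannot be synthesized at all."""
    blocked = []
    rxn = model.reactions[objective_reaction]
    for mid, coeff in rxn.stoichiometry.items():
        if coeff >= 0:
            continue
        probe = model.copy()
        probe.reactions[objective_reaction].lower_bound = 0.0
        demand_id = f"DM__probe_{mid.replace('[', '_').replace(']', '')}"
        probe.add_reaction(Reaction(
            demand_id, stoichiometry={mid: -1}, lower_bound=0.0,
            upper_bound=1000.0, kind="demand"))
        state = solve_fba(probe, objective=demand_id)
        if not state.optimal or state.objective_value < tol:
            blocked.append(mid)
    return tuple(blocked)


def apply_gap_fill(model: MetabolicModel, universal: UniversalReactionSet,
                   reaction_ids: Sequence[str]) -> MetabolicModel:
    """Return a copy of ``model`` with the listed universal reactions added."""
    return _augment(model, universal, reaction_ids)
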