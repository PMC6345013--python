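"""Biomass pseudo-reaction assembly.

The biomass equation drains monomers in dry-weight proportions; its flux is
the specific growth rate mu (1/h).  Macromolecular mass fractions (g/gDW)
are split into monomers via per-macromolecule mass-fraction tables, then
converted to mmol/gDW coefficients by dividing by monomer molar masses
(g/mmol).  Growth-associated maintenance (GAM, mmol ATP/gDW) is added as an
ATP hydrolysis term inside the biomass reaction; non-growth-associated
maintenance (NGAM, mmol ATP/gDW/h) is a lower bound on a standalone ATP
hydrolysis reaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Mapping, Optional

from .core import MetabolicModel, Reaction, as_coefficient

FRACTION_TOL = 1e-9

#: Species of the ATP hydrolysis ledger used for GAM and NGAM:
#: atp + h2o -> adp + pi + h
DEFAULT_GAM_SPECIES = {
    "atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1, "h[c]": 1,
}


@dataclass
class BiomassComposition:
    """Macromolecular composition of 1 g dry weight plus monomer tables.

    ``macro_fractions`` are mass fractions (g/gDW) summing to 1;
    ``monomer_fractions[macro]`` are mass fractions within each
    macromolecule, each table summing to 1.  ``gam`` is in mmol ATP/gDW,
    ``ngam`` in mmol ATP/gDW/h.
    """

    macro_fractions: Dict[str, float]
    monomer_fractions: Dict[str, Dict[str, float]]
    gam: float = 60.0
    ngam: float = 1.0

    def __post_init__(self):
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be >= 0")
        total = sum(self.macro_fractions.values())
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValueError(
                f"macromolecular fractions sum to {total!r}, expected 1")
        for macro, table in self.monomer_fractions.items():
            if macro not in self.macro_fractions:
                raise ValueError(f"monomer table for unknown macromolecule {macro!r}")
            subtotal = sum(table.values())
            if abs(subtotal - 1.0) > FRACTION_TOL:
                raise ValueError(
                    f"monomer fractions for {macro!r} sum to {subtotal!r}, expected 1")
        missing = set(self.macro_fractions) - set(self.monomer_fractions)
        if missing:
            raise ValueError(f"missing monomer tables for: {sorted(missing)}")


def nucleotide_fractions_from_gc(gc_content: float) -> Dict[str, float]:
    """Mole fractions of dAMP/dTMP/dGMP/dCMP from genomic GC content.

    Assumes a double-stranded genome: dGMP = dCMP = gc/2 and
    dAMP = dTMP = (1 - gc)/2.
    """
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"GC content must lie strictly in (0, 1), got {gc_content}")
    gc_half = gc_content / 2.0
    at_half = (1.0 - gc_content) / 2.0
    return {"dAMP": at_half, "dTMP": at_half, "dGMP": gc_half, "dCMP": gc_half}


def build_biomass_reaction(
    composition: BiomassComposition,
    molar_masses: Mapping[str, float],
    reaction_id: str = "BIOMASS",
    gam_species: Optional[Mapping[str, int]] = None,
    precision: int = 9,
) -> Reaction:
    """Assemble the biomass pseudo-reaction.

    Each monomer m of macromolecule M gets the coefficient

        (macro_fraction[M] * monomer_fraction[M][m]) / molar_mass[m]

    in mmol/gDW (molar masses in g/mmol), so the consumed monomer mass sums
    to exactly 1 g/gDW.  GAM adds ``gam`` mmol of ATP hydrolysis.
    Coefficients are rounded to ``precision`` decimals (the model's printed
    precision) so the reaction serializes exactly through every format;
    mass closure still holds to well within 1e-6 g.
    """
    coeffs: Dict[str, Fraction] = {}
    for macro, macro_fraction in composition.macro_fractions.items():
        for monomer, mono_fraction in composition.monomer_fractions[macro].items():
            if mono_fraction == 0:
                continue
            if monomer not in molar_masses:
                raise ValueError(f"missing molar mass for monomer {monomer!r}")
            mmol = macro_fraction * mono_fraction / molar_masses[monomer]
            q = as_coefficient(round(mmol, precision))
            coeffs[monomer] = coeffs.get(monomer, Fraction(0)) - q
    if gam_species is None:
        gam_species = DEFAULT_GAM_SPECIES
    if composition.gam > 0:
        gam = as_coefficient(round(composition.gam, precision))
        for species, sign in gam_species.items():
            coeffs[species] = coeffs.get(species, Fraction(0)) + sign * gam
    coeffs = {m: c for m, c in coeffs.items() if c != 0}
    return Reaction(
        reaction_id,
        name="biomass assembly",
        stoichiometry=coeffs,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="biomass",
        kind="biomass",
    )


def monomer_mass(reaction: Reaction, molar_masses: Mapping[str, float]) -> float:
    """Total consumed monomer mass (g per unit flux), excluding GAM species.

    For a correctly assembled biomass reaction this is 1 g/gDW to within
    1e-6.
    """
    total = 0.0
    for met, coeff in reaction.stoichiometry.items():
        if met in DEFAULT_GAM_SPECIES or met not in molar_masses:
            continue
        if coeff < 0:
            total += float(-coeff) * molar_masses[met]
    return total


def add_ngam(model: MetabolicModel, ngam: float,
             reaction_id: str = "ATPM") -> MetabolicModel:
    """Pin the ATP maintenance reaction's lower bound to ``ngam``.

    The maintenance reaction (atp + h2o -> adp + pi + h) is created when
    absent.  Every feasible flux state then hydrolyses at least ``ngam``
    mmol ATP/gDW/h; if the network cannot sustain that turnover, FBA
    reports an infeasible status.
    """
    if ngam < 0:
        raise ValueError("NGAM must be >= 0")
    out = model.copy()
    if reaction_id not in out.reactions:
        out.add_reaction(Reaction(
            reaction_id, name="ATP maintenance",
            stoichiometry={m: Fraction(s) for m, s in DEFAULT_GAM_SPECIES.items()},
            lower_bound=0.0, upper_bound=1000.0,
            subsystem="energy", kind="metabolic"))
    out.reactions[reaction_id].lower_bound = float(ngam)
    return out
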