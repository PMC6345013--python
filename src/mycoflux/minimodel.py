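"""Deterministic generators for the bundled "mini-MG1" fixtures.

:func:`generate_mini_model` builds a compact, fully element- and
charge-balanced metabolic network of a resveratrol-producing filamentous
fungus, over cytosol and extracellular space.  It contains glycolysis
(with PFK), an oxidative/non-oxidative pentose phosphate shunt feeding
erythrose 4-phosphate, the seven-step shikimate chain from PEP + e4p to
chorismate, prephenate branches to tyrosine and phenylalanine, a
bifunctional phenylalanine/tyrosine ammonia-lyase (PTAL), cinnamate
4-hydroxylase, 4-coumarate-CoA ligase (4CL), acetyl-CoA carboxylase (ACC),
a chalcone synthase acting as stilbene synthase (CHS; 3 malonyl-CoA +
p-coumaroyl-CoA -> resveratrol), side branches to pterostilbene (ROMT) and
piceatannol (cytochrome P450), a naringenin-chalcone branch from the same
substrates (the CHS/STS substrate overlap), sucrose and rhamnose
utilization, an ethanol assimilation route whose acetate-activating step
is exactly ``ac[c] + coa[c] + atp[c] -> h[c] + accoa[c] + ppi[c] +
amp[c]`` (reaction id g0770), fatty-acid synthesis draining malonyl-CoA, a
truncated TCA entry to 2-oxoglutarate and glutamate, pseudo-respiration,
ATP maintenance, and a biomass reaction assembled by the biomass module.

Internal reactions are exact lumps of balanced elementary steps, so every
internal (non-boundary) reaction passes element and charge balance
checking; diphosphate is modeled as the fully deprotonated species so the
g0770 equation balances as written.  Generation is bit-reproducible: a
seed only matters when optional bound jitter is requested.

Also provided: a deterministic ortholog-hit table generator, the
transcribed growth-phenotype table (20 carbon + 12 nitrogen substrates)
and the organism's macromolecular biomass composition (32% cell wall, 20%
protein, 15% mannitol, 15% ash, 14% lipid, 4% nucleic acid) with monomer
breakdowns.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import numpy as np

from .biomass import (BiomassComposition, build_biomass_reaction,
                      nucleotide_fractions_from_gc)
from .core import (MetabolicModel, Metabolite, ModelError, Reaction,
                   molar_mass)
from .fba import MediumSpec
from .reconstruction import OrthologHit, UniversalReactionSet
from .validation import PhenotypeRecord

GENOME_GC_CONTENT = 0.5096  # genomic GC fraction of the modeled strain

F = Fraction

# --------------------------------------------------------------------------
# Metabolite catalogue: base id -> (name, formula, charge, compartments)
# --------------------------------------------------------------------------

_METABOLITES: Dict[str, Tuple[str, str, Optional[int], Tuple[str, ...]]] = {
    "glc": ("D-glucose", "C6H12O6", 0, ("c", "e")),
    "fru": ("D-fructose", "C6H12O6", 0, ("c",)),
    "suc": ("sucrose", "C12H22O11", 0, ("c", "e")),
    "rmn": ("L-rhamnose", "C6H12O5", 0, ("c", "e")),
    "rmna": ("L-rhamnonate", "C6H11O6", -1, ("c",)),
    "g6p": ("D-glucose 6-phosphate", "C6H11O9P", -2, ("c",)),
    "f6p": ("beta-D-fructose 6-phosphate", "C6H11O9P", -2, ("c",)),
    "fdp": ("beta-D-fructose 1,6-bisphosphate", "C6H10O12P2", -4, ("c",)),
    "g3p": ("glyceraldehyde 3-phosphate", "C3H5O6P", -2, ("c",)),
    "pep": ("phosphoenolpyruvate", "C3H2O6P", -3, ("c",)),
    "pyr": ("pyruvate", "C3H3O3", -1, ("c",)),
    "oaa": ("oxaloacetate", "C4H2O5", -2, ("c",)),
    "akg": ("2-oxoglutarate", "C5H4O5", -2, ("c", "e")),
    "glu": ("L-glutamate", "C5H8NO4", -1, ("c", "e")),
    "r5p": ("ribose 5-phosphate", "C5H9O8P", -2, ("c",)),
    "e4p": ("D-erythrose 4-phosphate", "C4H7O7P", -2, ("c",)),
    "3ddah7p": ("2-dehydro-3-deoxy-D-arabino-heptonate 7-phosphate",
                "C7H10O10P", -3, ("c",)),
    "dqt": ("3-dehydroquinate", "C7H9O6", -1, ("c",)),
    "dhsk": ("3-dehydroshikimate", "C7H7O5", -1, ("c",)),
    "sme": ("shikimate", "C7H9O5", -1, ("c",)),
    "sme3p": ("shikimate 3-phosphate", "C7H8O8P", -3, ("c",)),
    "3psme": ("5-O-(1-carboxyvinyl)-3-phosphoshikimate", "C10H9O10P", -4, ("c",)),
    "chor": ("chorismate", "C10H8O6", -2, ("c",)),
    "phen": ("prephenate", "C10H8O6", -2, ("c",)),
    "tyr": ("L-tyrosine", "C9H11NO3", 0, ("c", "e")),
    "phe": ("L-phenylalanine", "C9H11NO2", 0, ("c", "e")),
    "couma": ("4-coumarate", "C9H7O3", -1, ("c",)),
    "cinnm": ("trans-cinnamate", "C9H7O2", -1, ("c",)),
    "4cmcoa": ("p-coumaroyl-CoA", "C30H38N7O18P3S", -4, ("c",)),
    "malcoa": ("malonyl-CoA", "C24H33N7O19P3S", -5, ("c",)),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4, ("c",)),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4, ("c",)),
    "ac": ("acetate", "C2H3O2", -1, ("c", "e")),
    "acald": ("acetaldehyde", "C2H4O", 0, ("c",)),
    "etoh": ("ethanol", "C2H6O", 0, ("c", "e")),
    "resv": ("trans-resveratrol", "C14H12O3", 0, ("c", "e")),
    "ptsb": ("pterostilbene", "C16H16O3", 0, ("c", "e")),
    "pice": ("piceatannol", "C14H12O4", 0, ("c", "e")),
    "narchal": ("naringenin chalcone", "C15H12O5", 0, ("c",)),
    "amet": ("S-adenosyl-L-methionine", "C15H23N6O5S", 1, ("c",)),
    "ahcys": ("S-adenosyl-L-homocysteine", "C14H20N6O5S", 0, ("c",)),
    "atp": ("ATP", "C10H12N5O13P3", -4, ("c",)),
    "adp": ("ADP", "C10H12N5O10P2", -3, ("c",)),
    "amp": ("AMP", "C10H12N5O7P", -2, ("c",)),
    "pi": ("phosphate", "HO4P", -2, ("c", "e")),
    "ppi": ("diphosphate", "O7P2", -4, ("c",)),
    "nad": ("NAD+", "C21H26N7O14P2", -1, ("c",)),
    "nadh": ("NADH", "C21H27N7O14P2", -2, ("c",)),
    "nadp": ("NADP+", "C21H25N7O17P3", -3, ("c",)),
    "nadph": ("NADPH", "C21H26N7O17P3", -4, ("c",)),
    "h": ("proton", "H", 1, ("c", "e")),
    "h2o": ("water", "H2O", 0, ("c", "e")),
    "co2": ("carbon dioxide", "CO2", 0, ("c", "e")),
    "o2": ("oxygen", "O2", 0, ("c", "e")),
    "nh4": ("ammonium", "H4N", 1, ("c", "e")),
    "so3": ("sulfite", "O3S", -2, ("c", "e")),
    "ash": ("ash (mineral pseudo-species)", "", None, ("c",)),
    "glucan": ("beta-glucan repeat unit", "C6H10O5", 0, ("c",)),
    "mnl": ("D-mannitol", "C6H14O6", 0, ("c",)),
    "hdca": ("palmitate", "C16H31O2", -1, ("c",)),
}


def _m(base: str, comp: str = "c") -> str:
    return f"{base}[{comp}]"


# Reaction table: (id, name, stoichiometry, lb, ub, gpr, subsystem, kind)
# Every internal reaction is element- and charge-balanced by construction.
_REV = (-1000.0, 1000.0)
_FWD = (0.0, 1000.0)


def _reaction_table() -> List[Tuple]:
    m = _m
    return [
        # -- sugar uptake and glycolysis ---------------------------------
        ("GLCt", "glucose transport",
         {m("glc", "e"): -1, m("glc"): 1}, *_REV, "HXT1 or HXT2",
         "transport", "transport"),
        ("SUCt", "sucrose transport",
         {m("suc", "e"): -1, m("suc"): 1}, *_REV, "SUT1",
         "transport", "transport"),
        ("INV", "invertase",
         {m("suc"): -1, m("h2o"): -1, m("glc"): 1, m("fru"): 1}, *_FWD,
         "SUC2", "sucrose utilization", "metabolic"),
        ("HEX1", "hexokinase (glucose)",
         {m("glc"): -1, m("atp"): -1, m("g6p"): 1, m("adp"): 1, m("h"): 1},
         *_FWD, "HXK1 or GLK1", "glycolysis", "metabolic"),
        ("FRUK", "hexokinase (fructose)",
         {m("fru"): -1, m("atp"): -1, m("f6p"): 1, m("adp"): 1, m("h"): 1},
         *_FWD, "HXK1 or GLK1", "glycolysis", "metabolic"),
        ("PGI", "glucose-6-phosphate isomerase",
         {m("g6p"): -1, m("f6p"): 1}, *_REV, "PGI1", "glycolysis", "metabolic"),
        ("PFK", "phosphofructokinase",
         {m("f6p"): -1, m("atp"): -1, m("fdp"): 1, m("adp"): 1, m("h"): 1},
         *_FWD, "PFK1 and PFK2", "glycolysis", "metabolic"),
        ("FBP", "fructose-1,6-bisphosphatase",
         {m("fdp"): -1, m("h2o"): -1, m("f6p"): 1, m("pi"): 1}, *_FWD,
         "FBP1", "gluconeogenesis", "metabolic"),
        ("FBA_TPI", "aldolase + triose-phosphate isomerase (lumped)",
         {m("fdp"): -1, m("g3p"): 2}, *_REV, "FBA1", "glycolysis", "metabolic"),
        ("GAPD_ENO", "lower glycolysis g3p -> pep (lumped)",
         {m("g3p"): -1, m("nad"): -1, m("pi"): -1, m("adp"): -1,
          m("pep"): 1, m("nadh"): 1, m("atp"): 1, m("h2o"): 1, m("h"): 1},
         *_REV, "TDH1", "glycolysis", "metabolic"),
        ("PYK", "pyruvate kinase",
         {m("pep"): -1, m("adp"): -1, m("h"): -1, m("pyr"): 1, m("atp"): 1},
         *_FWD, "PYK1", "glycolysis", "metabolic"),
        # -- pentose phosphate shunt -------------------------------------
        ("PPP_OX", "oxidative PPP g6p -> r5p (lumped)",
         {m("g6p"): -1, m("nadp"): -2, m("h2o"): -1,
          m("r5p"): 1, m("nadph"): 2, m("co2"): 1, m("h"): 2},
         *_FWD, "ZWF1", "pentose phosphate pathway", "metabolic"),
        ("PPP_NONOX", "non-oxidative PPP 2 r5p <-> e4p + f6p (lumped)",
         {m("r5p"): -2, m("e4p"): 1, m("f6p"): 1}, *_REV, "TKL1",
         "pentose phosphate pathway", "metabolic"),
        # -- anaplerosis, TCA entry, nitrogen ----------------------------
        ("PDH", "pyruvate dehydrogenase",
         {m("pyr"): -1, m("coa"): -1, m("nad"): -1,
          m("accoa"): 1, m("co2"): 1, m("nadh"): 1},
         *_FWD, "PDA1 and PDB1", "pyruvate metabolism", "metabolic"),
        ("PC", "pyruvate carboxylase",
         {m("pyr"): -1, m("co2"): -1, m("atp"): -1, m("h2o"): -1,
          m("oaa"): 1, m("adp"): 1, m("pi"): 1, m("h"): 2},
         *_FWD, "PYC1", "anaplerosis", "metabolic"),
        ("PPCK", "PEP carboxykinase",
         {m("oaa"): -1, m("atp"): -1, m("pep"): 1, m("co2"): 1, m("adp"): 1},
         *_FWD, "PCK1", "gluconeogenesis", "metabolic"),
        ("CS_ICDH", "citrate synthase + isocitrate dehydrogenase (lumped)",
         {m("accoa"): -1, m("oaa"): -1, m("h2o"): -1, m("nadp"): -1,
          m("akg"): 1, m("co2"): 1, m("coa"): 1, m("nadph"): 1, m("h"): 1},
         *_FWD, "CIT1", "TCA cycle", "metabolic"),
        ("GDH", "glutamate dehydrogenase (NADPH)",
         {m("akg"): -1, m("nh4"): -1, m("nadph"): -1, m("h"): -1,
          m("glu"): 1, m("nadp"): 1, m("h2o"): 1},
         *_REV, "GDH1", "nitrogen assimilation", "metabolic"),
        # -- shikimate pathway -------------------------------------------
        ("DDPA", "DAHP synthase",
         {m("e4p"): -1, m("pep"): -1, m("h2o"): -1,
          m("3ddah7p"): 1, m("pi"): 1},
         *_FWD, "ARO3 or ARO4", "shikimate pathway", "metabolic"),
        ("DHQS", "3-dehydroquinate synthase",
         {m("3ddah7p"): -1, m("dqt"): 1, m("pi"): 1}, *_FWD, "ARO1",
         "shikimate pathway", "metabolic"),
        ("DHQD", "3-dehydroquinate dehydratase",
         {m("dqt"): -1, m("dhsk"): 1, m("h2o"): 1}, *_REV, "ARO1",
         "shikimate pathway", "metabolic"),
        ("SHKDH", "shikimate dehydrogenase",
         {m("dhsk"): -1, m("nadph"): -1, m("h"): -1, m("sme"): 1, m("nadp"): 1},
         *_FWD, "ARO1", "shikimate pathway", "metabolic"),
        ("SHKK", "shikimate kinase",
         {m("sme"): -1, m("atp"): -1, m("sme3p"): 1, m("adp"): 1, m("h"): 1},
         *_FWD, "ARO1", "shikimate pathway", "metabolic"),
        ("PSCVT", "EPSP synthase",
         {m("sme3p"): -1, m("pep"): -1, m("3psme"): 1, m("pi"): 1}, *_REV,
         "ARO1", "shikimate pathway", "metabolic"),
        ("CHORS", "chorismate synthase",
         {m("3psme"): -1, m("chor"): 1, m("pi"): 1}, *_FWD, "ARO2",
         "shikimate pathway", "metabolic"),
        ("CHORM", "chorismate mutase",
         {m("chor"): -1, m("phen"): 1}, *_FWD, "ARO7",
         "aromatic amino acids", "metabolic"),
        ("TYR_SYN", "prephenate -> tyrosine (lumped)",
         {m("phen"): -1, m("nad"): -1, m("glu"): -1,
          m("tyr"): 1, m("akg"): 1, m("co2"): 1, m("nadh"): 1},
         *_FWD, "TYR1", "aromatic amino acids", "metabolic"),
        ("PHE_SYN", "prephenate -> phenylalanine (lumped)",
         {m("phen"): -1, m("glu"): -1, m("h"): -1,
          m("phe"): 1, m("akg"): 1, m("co2"): 1, m("h2o"): 1},
         *_FWD, "PHA2", "aromatic amino acids", "metabolic"),
        # -- phenylpropanoid / stilbene pathway --------------------------
        ("PTAL_TYR", "tyrosine ammonia-lyase activity of PTAL",
         {m("tyr"): -1, m("couma"): 1, m("nh4"): 1}, *_FWD, "PTAL",
         "phenylpropanoid pathway", "metabolic"),
        ("PTAL_PHE", "phenylalanine ammonia-lyase activity of PTAL",
         {m("phe"): -1, m("cinnm"): 1, m("nh4"): 1}, *_FWD, "PTAL",
         "phenylpropanoid pathway", "metabolic"),
        ("C4H", "cinnamate 4-hydroxylase",
         {m("cinnm"): -1, m("o2"): -1, m("nadph"): -1, m("h"): -1,
          m("couma"): 1, m("h2o"): 1, m("nadp"): 1},
         *_FWD, "C4H", "phenylpropanoid pathway", "metabolic"),
        ("4CL", "4-coumarate-CoA ligase",
         {m("couma"): -1, m("coa"): -1, m("atp"): -1,
          m("4cmcoa"): 1, m("amp"): 1, m("ppi"): 1, m("h"): 1},
         *_FWD, "4CL", "phenylpropanoid pathway", "metabolic"),
        ("ACC", "acetyl-CoA carboxylase (lumped with bicarbonate formation)",
         {m("accoa"): -1, m("co2"): -1, m("atp"): -1, m("h2o"): -1,
          m("malcoa"): 1, m("adp"): 1, m("pi"): 1, m("h"): 2},
         *_FWD, "ACC1", "malonyl-CoA synthesis", "metabolic"),
        ("CHS", "chalcone synthase acting as stilbene synthase",
         {m("4cmcoa"): -1, m("malcoa"): -3, m("h"): -3,
          m("resv"): 1, m("co2"): 4, m("coa"): 4},
         *_FWD, "CHS", "stilbene biosynthesis", "metabolic"),
        ("CHS_NAR", "chalcone synthase (naringenin-chalcone-forming)",
         {m("4cmcoa"): -1, m("malcoa"): -3, m("h"): -3,
          m("narchal"): 1, m("co2"): 3, m("coa"): 4},
         *_FWD, "CHS", "flavonoid biosynthesis", "metabolic"),
        ("ROMT", "resveratrol di-O-methyltransferase",
         {m("resv"): -1, m("amet"): -2,
          m("ptsb"): 1, m("ahcys"): 2, m("h"): 2},
         *_FWD, "ROMT", "stilbene biosynthesis", "metabolic"),
        ("P450_PICE", "cytochrome P450 resveratrol 3'-hydroxylase",
         {m("resv"): -1, m("o2"): -1, m("nadph"): -1, m("h"): -1,
          m("pice"): 1, m("nadp"): 1, m("h2o"): 1},
         *_FWD, "P450", "stilbene biosynthesis", "metabolic"),
        # -- ethanol assimilation ----------------------------------------
        ("PDC", "pyruvate decarboxylase",
         {m("pyr"): -1, m("h"): -1, m("acald"): 1, m("co2"): 1},
         *_FWD, "PDC1", "pyruvate metabolism", "metabolic"),
        ("ALCD2x", "alcohol dehydrogenase (ethanol -> acetaldehyde)",
         {m("etoh"): -1, m("nad"): -1, m("acald"): 1, m("nadh"): 1, m("h"): 1},
         *_FWD, "ADH2", "ethanol assimilation", "metabolic"),
        ("ALDD2y", "acetaldehyde dehydrogenase (NADP)",
         {m("acald"): -1, m("nadp"): -1, m("h2o"): -1,
          m("ac"): 1, m("nadph"): 1, m("h"): 2},
         *_FWD, "ALD6", "ethanol assimilation", "metabolic"),
        ("g0770", "acetyl-CoA synthetase",
         {m("ac"): -1, m("coa"): -1, m("atp"): -1,
          m("h"): 1, m("accoa"): 1, m("ppi"): 1, m("amp"): 1},
         *_FWD, "ACS1", "ethanol assimilation", "metabolic"),
        # -- rhamnose utilization ----------------------------------------
        ("RMNt", "rhamnose transport",
         {m("rmn", "e"): -1, m("rmn"): 1}, *_REV, "RHT1",
         "transport", "transport"),
        ("RMND", "L-rhamnose:NADP+ 1-oxidoreductase",
         {m("rmn"): -1, m("nadp"): -1, m("h2o"): -1,
          m("rmna"): 1, m("nadph"): 1, m("h"): 2},
         *_FWD, "LRA1", "rhamnose utilization", "metabolic"),
        ("RMNCAT", "rhamnonate catabolism to pyruvate (lumped)",
         {m("rmna"): -1, m("nad"): -2, m("pyr"): 2, m("nadh"): 2, m("h"): 3},
         *_FWD, "LRA2", "rhamnose utilization", "metabolic"),
        # -- biomass precursor synthesis ---------------------------------
        ("FAS160", "fatty-acid synthase (palmitate, lumped)",
         {m("accoa"): -1, m("malcoa"): -7, m("nadph"): -14, m("h"): -20,
          m("hdca"): 1, m("co2"): 7, m("coa"): 8, m("nadp"): 14, m("h2o"): 6},
         *_FWD, "FAS1 and FAS2", "fatty-acid synthesis", "metabolic"),
        ("GLUCANS", "cell-wall glucan synthesis (lumped)",
         {m("g6p"): -1, m("glucan"): 1, m("pi"): 1}, *_FWD, "FKS1",
         "cell wall", "metabolic"),
        ("MNLS", "mannitol synthesis (lumped)",
         {m("f6p"): -1, m("nadph"): -1, m("h"): -1, m("h2o"): -1,
          m("mnl"): 1, m("pi"): 1, m("nadp"): 1},
         *_FWD, "MTD1", "mannitol metabolism", "metabolic"),
        ("ADE_SYN", "AMP de-novo synthesis (lumped)",
         {m("r5p"): -1, m("nh4"): -5, m("co2"): -5, m("nadph"): -5,
          m("atp"): -4, m("amp"): 1, m("nadp"): 5, m("adp"): 4, m("pi"): 4,
          m("h2o"): 7, m("h"): 4},
         *_FWD, "ADE1", "nucleotide metabolism", "metabolic"),
        ("ASHS", "mineral (ash) accumulation pseudo-reaction",
         {m("pi"): -F(1, 2), m("so3"): -F(1, 2), m("ash"): 1}, *_FWD, "",
         "biomass precursors", "metabolic"),
        # -- energy and cofactor housekeeping ----------------------------
        ("ADK1", "adenylate kinase",
         {m("amp"): -1, m("atp"): -1, m("adp"): 2}, *_REV, "ADK1",
         "energy", "metabolic"),
        ("PPA", "inorganic pyrophosphatase",
         {m("ppi"): -1, m("h2o"): -1, m("pi"): 2}, *_FWD, "IPP1",
         "energy", "metabolic"),
        ("THD", "transhydrogenase-like NADPH regeneration (lumped)",
         {m("nadh"): -1, m("nadp"): -1, m("nad"): 1, m("nadph"): 1},
         *_FWD, "", "cofactor balancing", "spontaneous"),
        ("OXPHOS", "respiratory chain + ATP synthase (P/O 2.5, lumped)",
         {m("nadh"): -1, m("o2"): -F(1, 2), m("adp"): -F(5, 2),
          m("pi"): -F(5, 2), m("h"): -F(7, 2),
          m("nad"): 1, m("atp"): F(5, 2), m("h2o"): F(7, 2)},
         *_FWD, "NDI1 and ATP1", "energy", "metabolic"),
        ("OXPHOS_NADPH", "external NADPH dehydrogenase + respiratory chain "
         "(P/O 2.5, lumped)",
         {m("nadph"): -1, m("o2"): -F(1, 2), m("adp"): -F(5, 2),
          m("pi"): -F(5, 2), m("h"): -F(7, 2),
          m("nadp"): 1, m("atp"): F(5, 2), m("h2o"): F(7, 2)},
         *_FWD, "NDE1 and ATP1", "energy", "metabolic"),
        ("ATPM", "ATP maintenance (NGAM)",
         {m("atp"): -1, m("h2o"): -1, m("adp"): 1, m("pi"): 1, m("h"): 1},
         1.0, 1000.0, "", "energy", "metabolic"),
        # -- boundary sinks for cycled cosubstrates ----------------------
        ("SK_amet", "S-adenosylmethionine supply (methionine cycle boundary)",
         {m("amet"): -1}, *_REV, "", "boundary", "sink"),
        ("DM_ahcys", "S-adenosylhomocysteine drain (methionine cycle boundary)",
         {m("ahcys"): -1}, *_FWD, "", "boundary", "demand"),
    ]


_TRANSPORTS = [
    # (base, gpr, reversible)  -- simple uniporters X[e] <-> X[c]
    ("etoh", "", True),
    ("ac", "", True),
    ("akg", "", True),
    ("resv", "ABC1 or ABC2", False),   # export only
    ("ptsb", "ABC1", False),
    ("pice", "ABC2", False),
    ("co2", "", True),
    ("o2", "", True),
    ("nh4", "MEP1", True),
    ("pi", "PHO84", True),
    ("so3", "SUL1", True),
    ("h2o", "", True),
    ("h", "", True),
    ("glu", "GAP1", True),
    ("phe", "GAP1", True),
    ("tyr", "GAP1", True),
]

_EXCHANGE_BASES = [
    "glc", "suc", "rmn", "etoh", "ac", "akg", "resv", "ptsb", "pice",
    "co2", "o2",
    "nh4", "pi", "so3", "h2o", "h", "glu", "phe", "tyr",
]

#: Extracellular ions / small species left unconstrained in every medium.
UNLIMITED_EXCHANGES = frozenset(
    {"EX_h2o", "EX_h", "EX_o2", "EX_nh4", "EX_pi", "EX_so3"})

BIOMASS_ID = "BIOMASS"

#: All exchanges exporting resveratrol-derived stilbenes; summing their
#: fluxes measures total stilbene-pathway output (equal to the CHS flux).
STILBENE_EXPORTS = ("EX_resv", "EX_ptsb", "EX_pice")


@dataclass
class MiniModelSpec:
    """Options for :func:`generate_mini_model`.

    Default generation is bit-reproducible; ``seed`` only matters when
    ``bound_jitter`` is non-zero, in which case exchange upper bounds are
    multiplicatively jittered by at most that relative amount.
    """

    include_rhamnose_pathway: bool = True
    include_ethanol_assimilation: bool = True
    knockouts: Tuple[str, ...] = ()
    seed: Optional[int] = None
    bound_jitter: float = 0.0


def mini_composition() -> BiomassComposition:
    """Reduced biomass composition used by the mini-model.

    Macromolecular fractions follow the organism's measured composition;
    each macromolecule is represented by the small monomer set actually
    present in the mini network (protein by glu/phe/tyr, lipid by
    palmitate, nucleic acid by AMP).
    """
    return BiomassComposition(
        macro_fractions={
            "cell_wall": 0.32, "protein": 0.20, "mannitol": 0.15,
            "ash": 0.15, "lipid": 0.14, "nucleic_acid": 0.04,
        },
        monomer_fractions={
            "cell_wall": {"glucan[c]": 1.0},
            "protein": {"glu[c]": 0.45, "phe[c]": 0.25, "tyr[c]": 0.30},
            "mannitol": {"mnl[c]": 1.0},
            "ash": {"ash[c]": 1.0},
            "lipid": {"hdca[c]": 1.0},
            "nucleic_acid": {"amp[c]": 1.0},
        },
        gam=60.0,
        ngam=1.0,
    )


#: Pseudo molar mass (g/mmol) assigned to the non-elemental ash species.
ASH_MOLAR_MASS = 0.1


def mini_monomer_masses() -> Dict[str, float]:
    """Molar masses (g/mmol) for the mini biomass monomers."""
    masses = {}
    for met in ("glucan", "glu", "phe", "tyr", "mnl", "hdca", "amp"):
        formula = _METABOLITES[met][1]
        masses[_m(met)] = molar_mass(formula) / 1000.0
    masses[_m("ash")] = ASH_MOLAR_MASS
    return masses


def generate_mini_model(spec: Optional[MiniModelSpec] = None) -> MetabolicModel:
    """Build the mini fungal network (see module docstring for contents).

    All exchanges start uptake-closed (bounds (0, 1000)); apply a
    :class:`~mycoflux.fba.MediumSpec` to open nutrients.  The biomass
    reaction is the default objective.
    """
    spec = spec or MiniModelSpec()
    model = MetabolicModel("mini_mg1", "mini fungal stilbene network")
    model.compartments = {"c": "cytosol", "e": "extracellular"}
    for base, (name, formula, charge, comps) in _METABOLITES.items():
        for comp in comps:
            model.add_metabolite(Metabolite(
                _m(base, comp), name=name, formula=formula, charge=charge,
                compartment=comp))

    rows = list(_reaction_table())
    for base, gpr, reversible in _TRANSPORTS:
        lb, ub = _REV if reversible else _FWD
        rows.append((
            f"{base.upper()}t", f"{base} transport",
            {_m(base, "e"): -1, _m(base): 1} if reversible
            else {_m(base): -1, _m(base, "e"): 1},
            lb, ub, gpr, "transport", "transport"))
    for base in _EXCHANGE_BASES:
        rows.append((
            f"EX_{base}", f"{base} exchange", {_m(base, "e"): -1},
            0.0, 1000.0, "", "exchange", "exchange"))

    drop = set()
    if not spec.include_rhamnose_pathway:
        drop |= {"RMNt", "RMND"}
    if not spec.include_ethanol_assimilation:
        drop |= {"EX_etoh", "ETOHt", "ALCD2x", "ALDD2y"}
    for rid in spec.knockouts:
        if rid not in {row[0] for row in rows} and rid != BIOMASS_ID:
            raise ModelError(f"knockout of absent reaction {rid!r}")
        drop.add(rid)

    from .gpr import parse_gpr
    for row in rows:
        if row[0] not in drop:
            model.genes |= parse_gpr(row[5]).genes()

    for rid, name, stoich, lb, ub, gpr, subsystem, kind in rows:
        if rid in drop:
            continue
        model.add_reaction(Reaction(
            rid, name=name, stoichiometry=dict(stoich), lower_bound=lb,
            upper_bound=ub, gpr=gpr, subsystem=subsystem, kind=kind))

    if BIOMASS_ID not in spec.knockouts:
        biomass = build_biomass_reaction(
            mini_composition(), mini_monomer_masses(), reaction_id=BIOMASS_ID)
        model.add_reaction(biomass)
        model.set_objective(BIOMASS_ID)

    if spec.bound_jitter:
        rng = np.random.default_rng(spec.seed)
        for rxn in model.exchanges():
            rxn.upper_bound *= float(
                1.0 + rng.uniform(-spec.bound_jitter, spec.bound_jitter))

    model.notes.append("synthetic mini network; fixture, not a reconstruction")
    model.validate()
    return model


# --------------------------------------------------------------------------
# Media
# --------------------------------------------------------------------------


def minimal_medium(carbon_exchange: str = "EX_glc",
                   uptake: float = 2.0) -> MediumSpec:
    """Minimal medium: one carbon source plus unconstrained basic nutrients
    (water, protons, oxygen, ammonium, sulfite, phosphate)."""
    return MediumSpec(uptakes={carbon_exchange: uptake},
                      unlimited=UNLIMITED_EXCHANGES)


def pdb_medium(glucose: float = 2.0, amino_acid: float = 0.01) -> MediumSpec:
    """Rich-medium approximation: glucose at 2.0 mmol/gDW/h plus every
    amino-acid exchange in the model at 0.01 mmol/gDW/h (the mini network
    carries glutamate, phenylalanine and tyrosine exchanges)."""
    return MediumSpec(
        uptakes={"EX_glc": glucose, "EX_glu": amino_acid,
                 "EX_phe": amino_acid, "EX_tyr": amino_acid},
        unlimited=UNLIMITED_EXCHANGES)


def stilbene_study_medium(glucose: float = 1.0,
                          aromatic_uptake: float = 1e-6) -> MediumSpec:
    """Constraint set of the cofactor/robustness analyses: glucose at
    1.0 mmol/gDW/h and trace phenylalanine/tyrosine uptake."""
    return MediumSpec(
        uptakes={"EX_glc": glucose, "EX_phe": aromatic_uptake,
                 "EX_tyr": aromatic_uptake},
        unlimited=UNLIMITED_EXCHANGES)


def fix_growth(model: MetabolicModel, rate: float,
               biomass_id: str = BIOMASS_ID) -> MetabolicModel:
    """Return a copy with the biomass flux pinned (lb = ub = rate)."""
    out = model.copy()
    rxn = out.reactions[biomass_id]
    rxn.lower_bound = rxn.upper_bound = float(rate)
    return out


# --------------------------------------------------------------------------
# Universal reactions for gap-filling demonstrations
# --------------------------------------------------------------------------


def mini_universal_set() -> UniversalReactionSet:
    """Candidate reactions for gap filling the mini network.

    Contains the rhamnose transporter and dehydrogenase (the classic fix
    for a model unable to grow on rhamnose), phosphofructokinase, and a
    decoy lactate branch that never restores growth on its own.
    """
    universal = UniversalReactionSet()
    by_id = {row[0]: row for row in _reaction_table()}
    for rid in ("RMNt", "RMND", "PFK"):
        _, name, stoich, lb, ub, gpr, subsystem, kind = by_id[rid]
        universal.add(Reaction(rid, name=name, stoichiometry=dict(stoich),
                               lower_bound=lb, upper_bound=ub, gpr=gpr,
                               subsystem=subsystem, kind=kind))
    lac = Metabolite(_m("lac"), "(R)-lactate", "C3H5O3", -1, "c")
    universal.add(
        Reaction("LDH_D", name="D-lactate dehydrogenase (decoy candidate)",
                 stoichiometry={_m("pyr"): -1, _m("nadh"): -1, _m("h"): -1,
                                _m("lac"): 1, _m("nad"): 1},
                 lower_bound=-1000.0, upper_bound=1000.0, gpr="DLD1",
                 subsystem="pyruvate metabolism", kind="metabolic"),
        metabolites=[lac])
    return universal


# --------------------------------------------------------------------------
# Ortholog-hit table generator
# --------------------------------------------------------------------------

REFERENCE_LABELS = ("refA", "refB", "refC")


def generate_ortholog_hits(seed: int, n_pass: int,
                           n_fail: int) -> List[OrthologHit]:
    """Deterministic BLAST-like hit table with known threshold structure.

    Exactly ``n_pass`` rows satisfy identity >= 40 and e-value <= 1e-30;
    ``n_fail`` rows violate at least one threshold (cycling through low
    identity, weak e-value, and both).  Rows are shuffled by ``seed``.
    """
    if n_pass < 0 or n_fail < 0:
        raise ValueError("row counts must be >= 0")
    rng = np.random.default_rng(seed)
    hits: List[OrthologHit] = []

    def _query(i: int) -> str:
        return f"Gglean{i:06d}.1"

    for i in range(n_pass):
        identity = min(95.0, max(40.0, round(rng.uniform(40.0, 95.0), 1)))
        evalue = float(10.0 ** rng.uniform(-180.0, -30.0))
        label = REFERENCE_LABELS[i % len(REFERENCE_LABELS)]
        hits.append(OrthologHit(_query(i + 1), f"{label}_g{i + 1:04d}",
                                identity, min(evalue, 1e-30), label))
    for i in range(n_fail):
        mode = i % 3
        label = REFERENCE_LABELS[i % len(REFERENCE_LABELS)]
        low_ident = min(39.9, max(5.0, round(rng.uniform(5.0, 39.9), 1)))
        good_ident = min(95.0, max(40.0, round(rng.uniform(40.0, 95.0), 1)))
        weak_evalue = float(10.0 ** rng.uniform(-29.0, -3.0))
        strong_evalue = float(min(10.0 ** rng.uniform(-180.0, -30.0), 1e-30))
        if mode == 0:
            identity, evalue = low_ident, strong_evalue
        elif mode == 1:
            identity, evalue = good_ident, weak_evalue
        else:
            identity, evalue = low_ident, weak_evalue
        hits.append(OrthologHit(_query(n_pass + i + 1),
                                f"{label}_g{n_pass + i + 1:04d}",
                                identity, evalue, label))
    order = rng.permutation(len(hits))
    return [hits[int(j)] for j in order]


# --------------------------------------------------------------------------
# Transcribed phenotype table and full biomass composition
# --------------------------------------------------------------------------

_TABLE3_CARBON = [
    # (substrate, in vivo, in silico, gap-filled)
    ("Glucose", "+", "+", False),
    ("Fructose", "+", "+", False),
    ("Galactose", "+", "+", False),
    ("Lactose", "+", "+", False),
    ("Maltose", "+", "+", False),
    ("Mannose", "+", "+", False),
    ("Pectin", "+", "-", False),
    ("Ribose", "+", "+", False),
    ("Starch", "+", "+", True),
    ("Sucrose", "+", "+", True),
    ("Xylose", "+", "+", False),
    ("Arabinose", "+", "+", False),
    ("Rhamnose", "+", "+", True),
    ("Raffinose", "+", "+", False),
    ("Glycerol", "+", "+", False),
    ("Dextrin", "+", "+", True),
    ("Citrate", "+", "-", False),
    ("Polygalacturonic acid", "+", "-", False),
    ("Cellobiose", "+", "+", False),
    ("Sorbose", "+", "+", False),
]

_TABLE3_NITROGEN = [
    ("NH4Cl", "+", "+", False),
    ("KNO3", "+", "+", False),
    ("NaNO2", "+", "+", False),
    ("Acetamide", "+", "-", False),
    ("Urea", "+", "+", False),
    ("Glycine", "+", "+", False),
    ("Glutamate", "+", "+", False),
    ("Arginine", "+", "+", False),
    ("Alanine", "+", "+", False),
    ("Aspartate", "+", "+", False),
    ("Asparagine", "+", "+", False),
    ("Tyrosine", "+", "+", False),
]


def table3_fixture() -> List[PhenotypeRecord]:
    """Transcription of the published growth-phenotype comparison:
    20 carbon and 12 nitrogen substrates with in vivo / in silico calls."""
    records = []
    for role, rows in (("carbon", _TABLE3_CARBON), ("nitrogen", _TABLE3_NITROGEN)):
        for substrate, in_vivo, in_silico, filled in rows:
            records.append(PhenotypeRecord(
                substrate=substrate, role=role, observed=in_vivo,
                predicted=in_silico, gap_filled=filled,
                note="transcribed growth-phenotype comparison"))
    return records


# Amino-acid mass fractions of total protein: a typical filamentous-fungus
# profile (placeholder; the organism's analyzer-measured profile is not
# published numerically).  Sums to 1.
_PROTEIN_AA_MASS_FRACTIONS = {
    "ala": 0.080, "arg": 0.050, "asn": 0.040, "asp": 0.060, "cys": 0.010,
    "gln": 0.040, "glu": 0.080, "gly": 0.080, "his": 0.020, "ile": 0.050,
    "leu": 0.090, "lys": 0.060, "met": 0.020, "phe": 0.040, "pro": 0.050,
    "ser": 0.070, "thr": 0.050, "trp": 0.010, "tyr": 0.030, "val": 0.070,
}

_AA_FORMULAS = {
    "ala": "C3H7NO2", "arg": "C6H14N4O2", "asn": "C4H8N2O3", "asp": "C4H7NO4",
    "cys": "C3H7NO2S", "gln": "C5H10N2O3", "glu": "C5H9NO4", "gly": "C2H5NO2",
    "his": "C6H9N3O2", "ile": "C6H13NO2", "leu": "C6H13NO2", "lys": "C6H14N2O2",
    "met": "C5H11NO2S", "phe": "C9H11NO2", "pro": "C5H9NO2", "ser": "C3H7NO3",
    "thr": "C4H9NO3", "trp": "C11H12N2O2", "tyr": "C9H11NO3", "val": "C5H11NO2",
}

_DNMP_FORMULAS = {
    "dAMP": "C10H14N5O6P", "dTMP": "C10H15N2O8P",
    "dGMP": "C10H14N5O7P", "dCMP": "C9H14N3O7P",
}

_LIPID_SPECIES = {"palmitate": ("C16H32O2", 0.45), "oleate": ("C18H34O2", 0.35),
                  "linoleate": ("C18H32O2", 0.20)}

_WALL_SPECIES = {"glucan": ("C6H10O5", 0.60), "chitin": ("C8H13NO5", 0.25),
                 "mannan": ("C6H10O5", 0.15)}


def composition_fixture(
    gc_content: float = GENOME_GC_CONTENT,
) -> Tuple[BiomassComposition, Dict[str, float]]:
    """Full macromolecular biomass composition plus monomer molar masses.

    Macromolecular fractions are the measured ones (cell wall 0.32,
    protein 0.20, mannitol 0.15, ash 0.15, lipid 0.14, nucleic acid 0.04).
    Nucleic-acid monomer mass fractions derive from the genomic GC content
    via :func:`nucleotide_fractions_from_gc`; amino-acid, lipid and
    cell-wall profiles are documented placeholders.  Returns
    ``(composition, molar_masses)`` with masses in g/mmol.
    """
    mole = nucleotide_fractions_from_gc(gc_content)
    dnmp_mass = {k: molar_mass(v) for k, v in _DNMP_FORMULAS.items()}
    weighted = {k: mole[k] * dnmp_mass[k] for k in mole}
    total = sum(weighted.values())
    na_fractions = {k: w / total for k, w in weighted.items()}

    composition = BiomassComposition(
        macro_fractions={
            "cell_wall": 0.32, "protein": 0.20, "mannitol": 0.15,
            "ash": 0.15, "lipid": 0.14, "nucleic_acid": 0.04,
        },
        monomer_fractions={
            "cell_wall": {k: v[1] for k, v in _WALL_SPECIES.items()},
            "protein": dict(_PROTEIN_AA_MASS_FRACTIONS),
            "mannitol": {"mannitol": 1.0},
            "ash": {"ash": 1.0},
            "lipid": {k: v[1] for k, v in _LIPID_SPECIES.items()},
            "nucleic_acid": na_fractions,
        },
        gam=60.0,
        ngam=1.0,
    )
    masses: Dict[str, float] = {}
    for aa, fraction in _PROTEIN_AA_MASS_FRACTIONS.items():
        masses[aa] = molar_mass(_AA_FORMULAS[aa]) / 1000.0
    for k, (formula, _w) in {**_LIPID_SPECIES, **_WALL_SPECIES}.items():
        masses[k] = molar_mass(formula) / 1000.0
    for k, mass in dnmp_mass.items():
        masses[k] = mass / 1000.0
    masses["mannitol"] = molar_mass("C6H14O6") / 1000.0
    masses["ash"] = ASH_MOLAR_MASS
    return composition, masses
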