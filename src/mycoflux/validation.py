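"""Growth-phenotype validation and agreement statistics.

Qualitative validation tests each substrate as the sole carbon or nitrogen
source: the substrate's exchange is opened at a fixed uptake rate (2.0
mmol/gDW/h, the rate used for carbon-source tests), every other source of
the same role is closed, and growth is called "+" when the FBA objective
exceeds the growth-call threshold.  The same threshold is used everywhere
a growth call is made.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Mapping, Optional, Sequence

from .core import MetabolicModel
from .fba import FLUX_ZERO_TOL, MediumSpec, set_medium, solve_fba

#: FBA growth above this is called "+" (single config value, shared with the
#: numeric-zero convention of the flux modules).
GROWTH_CALL_THRESHOLD = FLUX_ZERO_TOL

ROLES = ("carbon", "nitrogen")


@dataclass
class PhenotypeRecord:
    """One substrate x growth-call comparison (in vivo vs in silico)."""

    substrate: str
    role: str
    observed: str  # "+" or "-"
    predicted: str  # "+", "-" or "?" (untestable)
    exchange_id: Optional[str] = None
    gap_filled: bool = False
    growth_rate: Optional[float] = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.predicted in ("+", "-")

    @property
    def match(self) -> bool:
        return self.testable and self.observed == self.predicted


def sole_source_growth_test(
    model: MetabolicModel,
    substrates: Sequence[str],
    role: str,
    exchange_map: Mapping[str, str],
    role_exchanges: Iterable[str],
    base_medium: MediumSpec,
    uptake: float = 2.0,
    observed: Optional[Mapping[str, str]] = None,
    objective: Optional[Mapping[str, float]] = None,
) -> List[PhenotypeRecord]:
    """Predict growth on each substrate as the sole source of ``role``.

    ``exchange_map`` maps substrate names to exchange reaction ids;
    ``role_exchanges`` lists every exchange that can supply the varied
    element, all of which are closed except the tested one.
    ``base_medium`` supplies the non-varied element and minerals.  A
    substrate with no exchange in the model is recorded as untestable
    (predicted "?"), never silently skipped.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    role_exchanges = set(role_exchanges)
    observed = observed or {}
    records = []
    for substrate in substrates:
        exchange = exchange_map.get(substrate)
        if exchange is None or exchange not in model.reactions:
            records.append(PhenotypeRecord(
                substrate, role, observed.get(substrate, "?"), "?",
                exchange_id=exchange, note="no exchange reaction; untestable"))
            continue
        uptakes = {k: v for k, v in base_medium.uptakes.items()
                   if k not in role_exchanges}
        uptakes[exchange] = uptake
        unlimited = set(base_medium.unlimited) - role_exchanges
        medium = MediumSpec(uptakes=uptakes, unlimited=frozenset(unlimited))
        state = solve_fba(set_medium(model, medium), objective=objective)
        growth = state.objective_value if state.optimal else 0.0
        call = "+" if (growth or 0.0) > GROWTH_CALL_THRESHOLD else "-"
        records.append(PhenotypeRecord(
            substrate, role, observed.get(substrate, "?"), call,
            exchange_id=exchange, growth_rate=growth))
    return records


@dataclass
class AgreementScore:
    matches: int
    total: int
    percent: int  # rounded half-up to integer percent, as reported
    fraction: float  # raw matches/total


def agreement_score(records: Sequence[PhenotypeRecord]) -> AgreementScore:
    """Fraction of records whose predicted call matches the observed one.

    Reported percent is rounded half-up to the nearest integer (11/12 ->
    92); the raw fraction is retained.  Permutation-invariant.
    """
    testable = [r for r in records if r.testable and r.observed in ("+", "-")]
    if not testable:
        raise ValueError("no scorable records")
    matches = sum(r.match for r in testable)
    total = len(testable)
    fraction = matches / total
    percent = int((Decimal(100 * matches) / Decimal(total))
                  .quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return AgreementScore(matches, total, percent, fraction)


def relative_deviation(predicted: float, observed: float,
                       denominator: str = "observed") -> float:
    """Percent deviation 100 * |predicted - observed| / denominator value.

    The denominator defaults to the in-vivo (observed) value, which
    reproduces the printed growth-rate deviations.
    """
    if denominator not in ("observed", "predicted"):
        raise ValueError("denominator must be 'observed' or 'predicted'")
    denom = observed if denominator == "observed" else predicted
    if denom == 0:
        raise ZeroDivisionError("relative deviation undefined for zero denominator")
    return 100.0 * abs(predicted - observed) / abs(denom)


def gene_coverage(model_genes: int, genome_genes: int) -> float:
    """Percent of predicted protein-coding genes captured by the model."""
    if genome_genes <= 0:
        raise ValueError("genome gene count must be positive")
    return 100.0 * model_genes / genome_genes
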