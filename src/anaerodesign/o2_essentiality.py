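"""Oxygen-dependent reaction essentiality scan.

The scan asks, for every reaction whose stoichiometry touches molecular
oxygen, whether the model still predicts growth after that single reaction
is knocked out (both bounds zeroed).  O2 exchange and transport reactions
are excluded by default: deleting them merely re-creates anoxia and would
trivially flag them, whereas the interesting essentials are enzymatic O2
users with no anaerobic alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import pandas as pd

from .model_core import (
    GROWTH_EPSILON,
    ConfigurationError,
    MediumSpec,
    MetabolicModel,
    ModelError,
    apply_medium,
    delete_reaction,
)
from .fba_engine import fba

log = logging.getLogger("anaerodesign")


class BaselineNotGrowingError(ModelError):
    """The scan was started from a non-growing baseline, which is
    meaningless (every deletion would look 'essential')."""


@dataclass
class ScanRecord:
    reaction_id: str
    reaction_name: str
    mu_after_deletion: float
    essential: bool
    o2_role: str  # consumes | produces | both


def find_o2_reactions(
    model: MetabolicModel,
    include_exchange: bool = False,
    include_transport: bool = False,
) -> List[str]:
    """Sorted ids of reactions whose stoichiometry involves an O2 metabolite
    with a non-zero coefficient, filtered per flags."""
    if not model.o2_metabolite_ids:
        raise ConfigurationError(
            f"model {model.id!r}: no O2 metabolites configured or detected"
        )
    hits = []
    for rxn in model.reactions.values():
        coeffs = [
            rxn.stoichiometry[mid]
            for mid in rxn.stoichiometry
            if mid in model.o2_metabolite_ids
        ]
        if not coeffs:
            continue
        if all(c == 0 for c in coeffs):
            log.info("skipping %s: O2 coefficient is zero after normalization", rxn.id)
            continue
        if rxn.is_exchange and not include_exchange:
            continue
        if rxn.is_transport and not include_transport:
            continue
        hits.append(rxn.id)
    return sorted(hits)


def _o2_role(model: MetabolicModel, rid: str) -> str:
    coeffs = [
        c for mid, c in model.reactions[rid].stoichiometry.items()
        if mid in model.o2_metabolite_ids and c != 0
    ]
    consumes = any(c < 0 for c in coeffs)
    produces = any(c > 0 for c in coeffs)
    if consumes and produces:
        return "both"
    return "consumes" if consumes else "produces"


def o2_essentiality_scan(
    model: MetabolicModel,
    medium: Optional[MediumSpec] = None,
    epsilon: float = GROWTH_EPSILON,
    include_exchange: bool = False,
    include_transport: bool = False,
) -> List[ScanRecord]:
    """Single-deletion scan over O2-involving reactions under ``medium``.

    Each deletion is applied to a fresh copy of the conditioned model, so
    the scan is order-independent and the input is never mutated.  A record
    is essential iff the post-deletion growth rate falls below ``epsilon``
    (infeasible counts as 0).
    """
    conditioned = apply_medium(model, medium) if medium is not None else model.copy()
    baseline = fba(conditioned)
    if not baseline.grows(epsilon):
        raise BaselineNotGrowingError(
            f"baseline mu = {baseline.mu:.3e} 1/h ({baseline.status}) is below "
            f"epsilon = {epsilon:.0e}; the scan needs a growing baseline"
        )
    records = []
    for rid in find_o2_reactions(conditioned, include_exchange, include_transport):
        result = fba(delete_reaction(conditioned, rid))
        mu = result.mu if result.status == "optimal" else 0.0
        records.append(
            ScanRecord(
                reaction_id=rid,
                reaction_name=conditioned.reactions[rid].name,
                mu_after_deletion=mu,
                essential=mu < epsilon,
                o2_role=_o2_role(conditioned, rid),
            )
        )
    return records


def essential_ids(records: Sequence[ScanRecord]) -> set:
    return {r.reaction_id for r in records if r.essential}


def records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "name": r.reaction_name,
                "o2_role": r.o2_role,
                "mu_after_deletion": r.mu_after_deletion,
                "essential": r.essential,
            }
            for r in records
        ],
        columns=["reaction_id", "name", "o2_role", "mu_after_deletion", "essential"],
    )


def scan_to_tsv(records: Sequence[ScanRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
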