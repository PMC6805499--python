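"""Flux Balance Analysis: the single numeric kernel of the pipeline.

FBA solves the linear program

    max  c . v      subject to  S v = 0,   lb <= v <= ub

where S is the stoichiometric matrix, v the flux vector in mmol/(gdw h) and
c selects the biomass pseudo-reaction, whose optimal flux is the predicted
specific growth rate mu in 1/h.  The backend is the HiGHS solver behind
``scipy.optimize.linprog``; only mu is contract-stable across re-runs and
backends (flux vectors are one representative of possibly many alternate
optima).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import (
    GROWTH_EPSILON,
    MediumSpec,
    MetabolicModel,
    ModelError,
    apply_medium,
)

log = logging.getLogger("anaerodesign")

#: LP feasibility / steady-state tolerance
FEASIBILITY_TOL = 1e-9
#: maximal allowed steady-state residual ||S v||_inf at a reported optimum
STEADY_STATE_TOL = 1e-6


class SolverError(ModelError):
    """The LP backend failed numerically; carries backend diagnostics."""


class FBAUnboundedError(SolverError):
    """Unbounded biomass objective — a bounded medium precludes this, so it
    signals a mis-configured medium rather than a meaningful optimum."""


@dataclass
class FBAResult:
    """Outcome of one FBA solve.

    ``mu`` is the objective (growth) value when ``status == "optimal"`` and
    0.0 otherwise — infeasible problems count as "no growth" for screening
    but remain distinguishable through ``status``.
    """

    status: str  # optimal | infeasible
    mu: float
    objective_id: str
    fluxes: Dict[str, float] = field(default_factory=dict)

    def grows(self, epsilon: float = GROWTH_EPSILON) -> bool:
        return self.status == "optimal" and self.mu >= epsilon

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def stoichiometric_matrix(model: MetabolicModel) -> Tuple[np.ndarray, List[str], List[str]]:
    """Dense S (metabolites x reactions) plus row/column id orderings."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[mid], j] = coeff
    return S, met_ids, rxn_ids


def fba(model: MetabolicModel) -> FBAResult:
    """Maximize the biomass objective of a validated model.

    Raises :class:`FBAUnboundedError` for an unbounded objective and
    :class:`SolverError` on backend failure; infeasibility is returned as a
    regular result with ``status="infeasible"`` and ``mu=0``.
    """
    model.validate()
    S, _met_ids, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(model.objective_id)] = -1.0  # linprog minimizes
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound) for rid in rxn_ids
    ]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 2:
        return FBAResult(status="infeasible", mu=0.0, objective_id=model.objective_id)
    if res.status == 3:
        raise FBAUnboundedError(
            f"model {model.id!r}: unbounded biomass objective — check the medium; "
            f"backend said: {res.message}"
        )
    if res.status != 0:
        raise SolverError(f"LP backend failure (status {res.status}): {res.message}")
    v = np.asarray(res.x)
    residual = float(np.max(np.abs(S @ v))) if n else 0.0
    if residual > STEADY_STATE_TOL:
        raise SolverError(f"steady-state residual {residual:.3e} exceeds {STEADY_STATE_TOL:.0e}")
    mu = float(-res.fun)
    if mu == 0.0:
        mu = 0.0  # normalize -0.0
    return FBAResult(
        status="optimal",
        mu=mu,
        objective_id=model.objective_id,
        fluxes={rid: float(v[j]) for j, rid in enumerate(rxn_ids)},
    )


def growth_predicts(
    model: MetabolicModel,
    medium: Optional[MediumSpec],
    overlays: Sequence[MediumSpec],
) -> pd.DataFrame:
    """Sweep medium overlays and tabulate (condition, status, mu).

    The base ``medium`` (may be None for "model bounds as loaded") is applied
    first, then each overlay in turn on a fresh copy; each row is one
    independent FBA solve.
    """
    base = apply_medium(model, medium) if medium is not None else model
    rows = []
    for overlay in overlays:
        conditioned = apply_medium(base, overlay)
        result = fba(conditioned)
        rows.append({"condition": overlay.name, "status": result.status, "mu": result.mu})
    return pd.DataFrame(rows, columns=["condition", "status", "mu"])
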