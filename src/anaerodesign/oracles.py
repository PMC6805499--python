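"""Brute-force reference computations for validation.

These are deliberately naive, independent re-derivations used to check the
production code paths: FBA by basic-feasible-solution (vertex) enumeration
instead of an LP solver, and the exclusive core by a two-loop sweep over
the presence/absence matrix instead of set algebra.  They are exponential /
quadratic and only meant for desk-scale instances.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np

from .model_core import MetabolicModel
from .fba_engine import stoichiometric_matrix


def brute_force_fba(model: MetabolicModel, tol: float = 1e-7) -> Tuple[str, float]:
    """Maximize the objective by enumerating candidate vertices.

    Every vertex of {v : S v = 0, lb <= v <= ub} fixes at least
    n - rank(S) variables at a bound; enumerating all such fixings and
    solving the remaining square-ish linear system visits every vertex, so
    the best feasible candidate is the LP optimum.  Returns ("optimal", mu)
    or ("infeasible", 0.0).  Only for networks of ~a dozen reactions.
    """
    S, _mets, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    j_obj = rxn_ids.index(model.objective_id)

    rank = int(np.linalg.matrix_rank(S, tol=1e-10)) if S.size else 0
    k = n - rank
    best: Optional[float] = None
    for fixed in combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for pattern in product((0, 1), repeat=k):
            vf = np.array([ub[j] if p else lb[j] for j, p in zip(fixed, pattern)])
            b = -S[:, list(fixed)] @ vf if k else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            else:
                sol = np.zeros(0)
            v = np.empty(n)
            v[list(fixed)] = vf
            v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if best is None or v[j_obj] > best:
                best = float(v[j_obj])
    if best is None:
        return "infeasible", 0.0
    return "optimal", best


def brute_force_exclusive_core(
    domain_sets: Dict[str, Set[str]], target_ids: Sequence[str], background_ids: Sequence[str]
) -> Set[str]:
    """Exclusive core via an explicit presence/absence matrix double loop."""
    universe = sorted(set().union(*domain_sets.values()))
    genomes = list(target_ids) + list(background_ids)
    presence = {
        d: {g: (d in domain_sets[g]) for g in genomes} for d in universe
    }
    result = set()
    for d in universe:
        in_all_targets = True
        for g in target_ids:
            if not presence[d][g]:
                in_all_targets = False
                break
        if not in_all_targets:
            continue
        in_any_background = False
        for g in background_ids:
            if presence[d][g]:
                in_any_background = True
                break
        if not in_any_background:
            result.add(d)
    return result
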