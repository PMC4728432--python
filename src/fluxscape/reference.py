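"""Independent reference implementations used as test oracles.

These are intentionally slow, transparent algorithms for toy-scale models
(tens of reactions): an exhaustive-subset congruency search, and the
classical per-reaction iMAT-style classification that solves two MILPs per
reaction to decide whether it can carry flux in *some* maximally congruent
model.  They share no code path with the single-MILP landscape routine
they are used to check.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .calls import ABSENT, ReactionStateVector
from .exceptions import InfeasibleError, SolverError
from .gebra import BOUND_CAP, ZERO_TOL, MetabolicLandscape, max_congruency_milp
from .model import MetabolicModel, stoichiometric_matrix

__all__ = ["congruency_bruteforce", "imat_reference"]


def _lp_feasible(S, lb, ub) -> bool:
    res = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    return res.status == 0


def congruency_bruteforce(model: MetabolicModel, absent: Iterable[str]) -> int:
    """Maximal congruency by exhaustive subset enumeration.

    Checks, from the largest subset size downward, whether some subset of
    the absent reactions can simultaneously be pinned to zero flux while
    the LP stays feasible; the first feasible size is the optimum (zeroing
    fewer reactions only relaxes the system).  Exponential in |absent| —
    toy models only.
    """
    absent = list(dict.fromkeys(absent))
    idx = [model.reaction_index(r) for r in absent]
    S = stoichiometric_matrix(model)
    lb0, ub0 = model.bounds_arrays(cap=BOUND_CAP)
    if not _lp_feasible(S, lb0, ub0):
        raise InfeasibleError("model infeasible without expression constraints")
    # a reaction whose own bounds exclude zero can never be silenced, so
    # any subset containing it is infeasible outright
    zeroable = [j for j in idx if lb0[j] <= 0.0 <= ub0[j]]
    for size in range(len(zeroable), 0, -1):
        for subset in combinations(zeroable, size):
            lb, ub = lb0.copy(), ub0.copy()
            lb[list(subset)] = 0.0
            ub[list(subset)] = 0.0
            if _lp_feasible(S, lb, ub):
                return size
    return 0


def _congruency_with_flux_constraint(
    S, lb, ub, absent_idx: np.ndarray, j: int, j_lb: float, j_ub: float
) -> int | None:
    """Max congruency with reaction j's flux restricted to [j_lb, j_ub].

    Returns None when the restriction itself is infeasible.
    """
    n = S.shape[1]
    k = len(absent_idx)
    lb = lb.copy()
    ub = ub.copy()
    lb[j] = max(lb[j], j_lb)
    ub[j] = min(ub[j], j_ub)
    if lb[j] > ub[j]:
        return None
    c = np.zeros(n + k)
    c[n:] = -1.0
    integrality = np.zeros(n + k)
    integrality[n:] = 1
    lo = np.concatenate([lb, np.zeros(k)])
    hi = np.concatenate([ub, np.ones(k)])
    S_ext = sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))], format="csr")
    M = np.maximum(np.abs(lb[absent_idx]), np.abs(ub[absent_idx]))
    rows_v = sparse.csr_matrix((np.ones(k), (np.arange(k), absent_idx)), shape=(k, n))
    diag_M = sparse.diags(M)
    cons = [
        LinearConstraint(S_ext, 0.0, 0.0),
        LinearConstraint(sparse.hstack([rows_v, diag_M], format="csr"), -np.inf, M),
        LinearConstraint(sparse.hstack([rows_v, -diag_M], format="csr"), -M, np.inf),
    ]
    res = milp(c, constraints=cons, integrality=integrality, bounds=Bounds(lo, hi),
               options={"mip_rel_gap": 0.0})
    if res.status == 2:
        return None
    if res.status != 0:  # pragma: no cover
        raise SolverError(f"reference MILP failed: {res.message}")
    return int(round(-res.fun))


def imat_reference(
    model: MetabolicModel,
    states: ReactionStateVector,
    zero_tol: float = ZERO_TOL,
    eps: float = 1e-3,
) -> MetabolicLandscape:
    """Per-reaction iMAT-style classification (test oracle, toy scale).

    For every reaction, re-solves the congruency MILP with that reaction's
    flux forced nonzero (>= eps forward, <= -eps backward where the bounds
    permit).  A reaction that cannot reach the global maximal congruency
    under either restriction is pinned to zero in *every* maximally
    congruent model and classified -1; all others are active (0).
    """
    absent = states.absent_ids(model)
    best = max_congruency_milp(model, absent, zero_tol=zero_tol).congruency
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays(cap=BOUND_CAP)
    absent_idx = np.array([model.reaction_index(r) for r in absent], dtype=int)

    out = np.zeros(len(model.reactions), dtype=np.int8)
    for j, rxn in enumerate(model.reactions):
        can_carry = False
        for j_lb, j_ub in ((eps, np.inf), (-np.inf, -eps)):
            cong = _congruency_with_flux_constraint(S, lb, ub, absent_idx, j, j_lb, j_ub)
            if cong is not None and cong >= best:
                can_carry = True
                break
        out[j] = 0 if can_carry else ABSENT
    return MetabolicLandscape(sample_id=states.sample_id, states=out,
                              congruency=best, n_absent=len(absent))
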