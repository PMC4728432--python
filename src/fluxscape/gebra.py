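"""GEBRA: gene-expression-based reaction activity.

Given a metabolic model and a transcript-derived reaction state vector
(-1 absent / 0 present), GEBRA computes a *metabolic landscape* in three
steps:

1. one mixed-integer program maximizing *congruency* — the number of
   absent-classified reactions whose steady-state flux can be set to zero
   while the network still satisfies mass balance (S v = 0) and its flux
   bounds (simply zeroing every absent reaction is often infeasible, e.g.
   when a maintenance demand forces flux through one of several silenced
   supply routes);
2. fixing each absent reaction's flux to its value in the MILP optimum;
3. flux variability analysis (FVA) of all remaining reactions: a reaction
   whose feasible flux range is {0} within tolerance is classified
   non-active (-1), every other reaction active (0).

The MILP uses per-reaction big-M constraints with M taken from the
reaction's own bounds (infinite bounds capped at +/-1000 first), solved by
HiGHS via :func:`scipy.optimize.milp` with a zero relative gap, so results
are deterministic for identical inputs.  Ties between symmetric alternate
optima are resolved by the solver's fixed variable order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .calls import ABSENT, PRESENT, ReactionStateVector, call_presence, reaction_states
from .exceptions import InfeasibleError, SolverError, ValidationError
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "MILPResult",
    "FVAResult",
    "MetabolicLandscape",
    "max_congruency_milp",
    "fva",
    "gebra_landscape",
    "GebraLandscaper",
]

ZERO_TOL = 1e-6
BOUND_CAP = 1000.0


@dataclass
class MILPResult:
    """Optimal congruency solution for one sample."""

    flux: np.ndarray                      # one flux vector attaining the optimum
    zeroed: frozenset[str]                # absent reactions with indicator on
    congruency: int                       # |zeroed|
    status: str

    def fixed_fluxes(self, model: MetabolicModel, absent: Iterable[str]) -> dict[str, float]:
        """Flux values at which each absent reaction is subsequently fixed."""
        return {rid: float(self.flux[model.reaction_index(rid)]) for rid in absent}


@dataclass
class FVAResult:
    """Per-reaction feasible flux ranges."""

    min_flux: dict[str, float]
    max_flux: dict[str, float]

    def range(self, reaction_id: str) -> tuple[float, float]:
        return self.min_flux[reaction_id], self.max_flux[reaction_id]


@dataclass
class MetabolicLandscape:
    """Final per-sample activity assignment over model reaction order.

    -1 = non-active (feasible flux pinned to zero), 0 = active.
    """

    sample_id: str
    states: np.ndarray
    congruency: int = 0
    n_absent: int = 0
    wall_time: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (-1, 0)).all():
            raise ValidationError("landscape states must be -1 or 0")


# ---------------------------------------------------------------------------
# LP helpers
# ---------------------------------------------------------------------------

def _solve_lp(
    S: sparse.csr_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray | None = None,
):
    """Solve min c.v s.t. S v = 0, lb <= v <= ub with HiGHS."""
    n = S.shape[1]
    if c is None:
        c = np.zeros(n)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res


def _feasible(S, lb, ub) -> bool:
    return _solve_lp(S, lb, ub).status == 0


# ---------------------------------------------------------------------------
# Congruency MILP
# ---------------------------------------------------------------------------

def max_congruency_milp(
    model: MetabolicModel,
    absent: Iterable[str],
    zero_tol: float = ZERO_TOL,
    time_limit: float | None = None,
    mip_gap: float = 0.0,
) -> MILPResult:
    """Maximize the number of absent-classified reactions carrying zero flux.

    Solves max sum(y_r) over binary y_r (r in ``absent``) subject to
    S v = 0, lb <= v <= ub and the big-M implication y_r = 1 => v_r = 0
    (-M_r (1-y_r) <= v_r <= M_r (1-y_r), M_r = max(|lb_r|, |ub_r|)).
    After the MILP, indicators are rounded and a clean LP with the zeroed
    reactions fixed to exactly 0 produces the returned flux vector, so
    every zeroed reaction satisfies v_r = 0 to solver precision.

    Raises
    ------
    InfeasibleError
        If the model is infeasible before any expression constraint.
    SolverError
        If the time limit is hit before proven optimality (carries the
        best bound found).
    """
    absent = list(dict.fromkeys(absent))
    for rid in absent:
        model.reaction_index(rid)  # validates membership
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays(cap=BOUND_CAP)
    n = S.shape[1]
    k = len(absent)

    if not _feasible(S, lb, ub):
        raise InfeasibleError("model infeasible without expression constraints")

    if k == 0:
        res = _solve_lp(S, lb, ub)
        return MILPResult(flux=res.x, zeroed=frozenset(), congruency=0, status="optimal")

    absent_idx = np.array([model.reaction_index(r) for r in absent])
    # variables: [v (n), y (k)]
    c = np.zeros(n + k)
    c[n:] = -1.0  # maximize sum(y)

    integrality = np.zeros(n + k)
    integrality[n:] = 1

    lo = np.concatenate([lb, np.zeros(k)])
    hi = np.concatenate([ub, np.ones(k)])

    S_ext = sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))], format="csr")
    cons = [LinearConstraint(S_ext, 0.0, 0.0)]

    M = np.maximum(np.abs(lb[absent_idx]), np.abs(ub[absent_idx]))
    # v_r + M_r y_r <= M_r   and   v_r - M_r y_r >= -M_r
    rows_v = sparse.csr_matrix(
        (np.ones(k), (np.arange(k), absent_idx)), shape=(k, n))
    diag_M = sparse.diags(M)
    upper = sparse.hstack([rows_v, diag_M], format="csr")
    lower = sparse.hstack([rows_v, -diag_M], format="csr")
    cons.append(LinearConstraint(upper, -np.inf, M))
    cons.append(LinearConstraint(lower, -M, np.inf))

    options: dict = {"mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(c, constraints=cons, integrality=integrality,
               bounds=Bounds(lo, hi), options=options)
    if res.status == 1:  # iteration/time limit
        bound = getattr(res, "mip_dual_bound", None)
        raise SolverError(
            f"congruency MILP hit the time limit (best bound {bound})",
            best_bound=-bound if bound is not None else None)
    if res.status != 0:
        raise SolverError(f"congruency MILP failed: {res.message}")

    y = res.x[n:] > 0.5
    zeroed_idx = absent_idx[y]
    # clean LP: pin zeroed reactions to exactly 0
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[zeroed_idx] = 0.0
    ub2[zeroed_idx] = 0.0
    clean = _solve_lp(S, lb2, ub2)
    if clean.status != 0:  # pragma: no cover - guards MILP tolerance slack
        raise SolverError("clean LP after MILP rounding is infeasible")
    flux = clean.x.copy()
    flux[np.abs(flux) < zero_tol] = 0.0
    zeroed = frozenset(model.reaction_ids[i] for i in zeroed_idx)
    return MILPResult(flux=flux, zeroed=zeroed, congruency=int(y.sum()), status="optimal")


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def _apply_fixed(model, lb, ub, fixed: Mapping[str, float]):
    lb, ub = lb.copy(), ub.copy()
    for rid, value in fixed.items():
        j = model.reaction_index(rid)
        lb[j] = value
        ub[j] = value
    return lb, ub


def fva(
    model: MetabolicModel,
    fixed: Mapping[str, float] | None = None,
    subset: Sequence[str] | None = None,
) -> FVAResult:
    """Flux variability analysis: per-reaction (min, max) feasible flux.

    ``fixed`` pins reactions to given flux values before the analysis;
    ``subset`` restricts which reactions are analyzed (default: all).
    Two LPs per free reaction; fixed reactions report (value, value).

    Raises
    ------
    InfeasibleError
        If the fixed fluxes leave no feasible flux distribution.
    """
    fixed = dict(fixed or {})
    subset = list(subset) if subset is not None else model.reaction_ids
    S = stoichiometric_matrix(model)
    lb0, ub0 = model.bounds_arrays(cap=None)
    lb, ub = _apply_fixed(model, lb0, ub0, fixed)
    if not _feasible(S, lb, ub):
        raise InfeasibleError(
            "model infeasible after fixing fluxes "
            f"({', '.join(f'{r}={v:g}' for r, v in list(fixed.items())[:5])} ...)")
    n = S.shape[1]
    vmin: dict[str, float] = {}
    vmax: dict[str, float] = {}
    for rid in subset:
        j = model.reaction_index(rid)
        if rid in fixed:
            vmin[rid] = vmax[rid] = float(fixed[rid])
            continue
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve_lp(S, lb, ub, c)
        c[j] = -1.0
        hi = _solve_lp(S, lb, ub, c)
        if lo.status != 0 or hi.status != 0:  # pragma: no cover
            raise SolverError(f"FVA LP failed for reaction {rid!r}")
        vmin[rid] = float(lo.x[j])
        vmax[rid] = float(hi.x[j])
    return FVAResult(min_flux=vmin, max_flux=vmax)


def _zero_pinned(
    S, lb, ub, j: int, zero_tol: float
) -> bool:
    """True iff reaction j's feasible flux range lies within [-tol, tol].

    Evaluates max first and skips the min LP when the reaction is already
    known to reach positive flux (classification shortcut; the result is
    identical to full FVA followed by the range test).
    """
    n = S.shape[1]
    c = np.zeros(n)
    c[j] = -1.0
    hi = _solve_lp(S, lb, ub, c)
    if hi.status != 0:  # pragma: no cover
        raise SolverError(f"FVA LP failed for reaction index {j}")
    if hi.x[j] > zero_tol:
        return False
    c[j] = 1.0
    lo = _solve_lp(S, lb, ub, c)
    if lo.status != 0:  # pragma: no cover
        raise SolverError(f"FVA LP failed for reaction index {j}")
    return lo.x[j] >= -zero_tol


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def gebra_landscape(
    model: MetabolicModel,
    states: ReactionStateVector,
    zero_tol: float = ZERO_TOL,
    time_limit: float | None = None,
) -> MetabolicLandscape:
    """Compute the metabolic landscape for one sample.

    Pipeline: congruency MILP over the absent set, fix absent reactions at
    their MILP fluxes, FVA-classify the rest.  A reaction is -1 iff its
    feasible flux range (or its fixed value) lies within ``zero_tol`` of 0.
    """
    if len(states.states) != len(model.reactions):
        raise ValidationError("state vector length does not match model")
    absent = states.absent_ids(model)
    milp_res = max_congruency_milp(model, absent, zero_tol=zero_tol, time_limit=time_limit)
    fixed = milp_res.fixed_fluxes(model, absent)

    S = stoichiometric_matrix(model)
    lb0, ub0 = model.bounds_arrays(cap=None)
    lb, ub = _apply_fixed(model, lb0, ub0, fixed)

    out = np.zeros(len(model.reactions), dtype=np.int8)
    for j, rxn in enumerate(model.reactions):
        if rxn.id in fixed:
            out[j] = ABSENT if abs(fixed[rxn.id]) <= zero_tol else PRESENT
        else:
            out[j] = ABSENT if _zero_pinned(S, lb, ub, j, zero_tol) else PRESENT
    return MetabolicLandscape(
        sample_id=states.sample_id,
        states=out,
        congruency=milp_res.congruency,
        n_absent=len(absent),
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class GebraLandscaper(TransformerMixin, BaseEstimator):
    """Transform per-sample detection p-values into metabolic landscapes.

    Parameters
    ----------
    model : MetabolicModel
        The metabolic network providing stoichiometry, bounds and GPRs.
    alpha : float, default 0.01
        Detection-call threshold: a gene is present iff its detection
        p-value is strictly below ``alpha``.
    zero_tol : float, default 1e-6
        Absolute flux tolerance for "zero" in MILP fixing and FVA
        classification.
    time_limit : float or None
        Per-sample MILP wall-clock limit in seconds.

    Input ``X`` is a samples x genes DataFrame of detection p-values (or a
    boolean/0-1 call matrix, which bypasses thresholding).  ``transform``
    returns a samples x reactions DataFrame over {-1, 0}.  Samples with
    identical transcript-derived reaction states share one solve, so the
    output is independent of sample order.
    """

    def __init__(
        self,
        model: MetabolicModel,
        alpha: float = 0.01,
        zero_tol: float = ZERO_TOL,
        time_limit: float | None = None,
    ):
        self.model = model
        self.alpha = alpha
        self.zero_tol = zero_tol
        self.time_limit = time_limit

    def fit(self, X: pd.DataFrame, y=None) -> "GebraLandscaper":
        X = self._validate(X)
        self.reaction_ids_ = list(self.model.reaction_ids)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        # landscapes keyed by transcript-derived state vector; shared across
        # transform calls so repeated per-sample invocations reuse solves
        self._cache: dict[tuple, MetabolicLandscape] = {}
        return self

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a samples x genes DataFrame")
        if X.empty:
            raise ValidationError("X has no samples")
        return X

    def _states_for_row(self, sample_id: str, row: pd.Series) -> ReactionStateVector:
        values = row.to_numpy()
        if values.dtype == bool or set(np.unique(values)) <= {0.0, 1.0}:
            calls = {g: bool(v) for g, v in row.items()}
        else:
            calls = call_presence(row.to_dict(), alpha=self.alpha)
        return reaction_states(self.model, calls, sample_id=sample_id)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        if not hasattr(self, "reaction_ids_"):
            self.fit(X)
        cache = self._cache
        rows = []
        diagnostics = []
        for sample_id, row in X.iterrows():
            states = self._states_for_row(str(sample_id), row)
            key = tuple(states.states.tolist())
            if key not in cache:
                start = time.perf_counter()
                scape = gebra_landscape(
                    self.model, states, zero_tol=self.zero_tol,
                    time_limit=self.time_limit)
                scape.wall_time = time.perf_counter() - start
                cache[key] = scape
            scape = cache[key]
            rows.append(scape.states)
            diagnostics.append(
                {"sample_id": sample_id, "n_absent": scape.n_absent,
                 "congruency": scape.congruency, "status": "optimal",
                 "solve_seconds": scape.wall_time})
        self.diagnostics_ = pd.DataFrame(diagnostics).set_index("sample_id")
        return pd.DataFrame(
            np.vstack(rows), index=X.index, columns=self.reaction_ids_, dtype=np.int8)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.reaction_ids_, dtype=object)
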