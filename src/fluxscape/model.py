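"""Data model for genome-scale metabolic networks (GSMNs).

A :class:`MetabolicModel` is a stoichiometric network: metabolites,
reactions with flux bounds (irreversibility is encoded purely through a
nonnegative lower bound), and optional GPR rules linking reactions to the
genes encoding their enzymes.  Reaction order is fixed and defines the
coordinate order of every downstream state/landscape vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import sparse

from .exceptions import ValidationError
from .gpr import GPRNode

__all__ = ["Metabolite", "Reaction", "MetabolicModel", "stoichiometric_matrix"]


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A reaction with stoichiometry ``{metabolite_id: coefficient}``.

    Negative coefficients consume, positive produce.  Exchange reactions
    may have one-sided stoichiometry (a single metabolite).
    """

    id: str
    stoich: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GPRNode | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoich:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """A stoichiometric model with GPR rules.

    ``genes`` is the union of all gene ids referenced by any GPR plus any
    explicitly declared ids; the invariant that every referenced gene is a
    member therefore holds by construction.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: frozenset[str] = field(default_factory=frozenset)
    id: str = "model"

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValidationError("duplicate reaction ids")
        met_set = set(met_ids)
        referenced: set[str] = set(self.genes)
        for rxn in self.reactions:
            for met_id in rxn.stoich:
                if met_id not in met_set:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references undeclared species {met_id!r}"
                    )
            if rxn.gpr is not None:
                referenced |= rxn.gpr.genes()
        self.genes = frozenset(referenced)
        self._met_index = {m: i for i, m in enumerate(met_ids)}
        self._rxn_index = {r: i for i, r in enumerate(rxn_ids)}

    # -- lookups ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ValidationError(f"unknown reaction id {reaction_id!r}") from None

    def get_reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self.reaction_index(reaction_id)]

    def bounds_arrays(self, cap: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bound vectors in reaction order.

        With ``cap`` set, infinite bounds are replaced by ``±cap`` (used to
        obtain finite big-M values before MILP).
        """
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        if cap is not None:
            lb = np.where(np.isneginf(lb), -cap, lb)
            ub = np.where(np.isposinf(ub), cap, ub)
        return lb, ub


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """Sparse stoichiometric matrix S (metabolites x reactions).

    Entry (i, j) is the signed coefficient of metabolite i in reaction j;
    column order equals ``model.reactions`` order.  Steady state mass
    balance is S v = 0.
    """
    n_met = len(model.metabolites)
    n_rxn = len(model.reactions)
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoich.items():
            rows.append(model._met_index[met_id])
            cols.append(j)
            data.append(float(coef))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_met, n_rxn))
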