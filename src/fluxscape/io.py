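"""Readers and writers for models and tabular pipeline data.

Model input comes either from SBML (Level 2 with legacy COBRA-style
``GENE_ASSOCIATION`` notes / kinetic-law bounds, or Level 3 with the fbc
package) or from a human-editable tab-separated dialect with columns
``reaction_id, equation, lower_bound, upper_bound, gpr_string``.
Identifiers are carried verbatim; compartment suffixes such as ``_c`` are
not interpreted.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .gpr import gpr_to_string, parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_model_sbml",
    "read_model_tabular",
    "write_model_tabular",
    "read_detection_matrix",
    "write_detection_matrix",
    "read_survival",
    "write_survival",
    "read_landscape_matrix",
    "write_landscape_matrix",
]

# Default flux bounds when a file omits them: +/-1000 for reversible
# reactions, [0, 1000] for irreversible (common Recon-style convention).
DEFAULT_BOUND = 1000.0


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _gpa_to_node(assoc):
    """Convert a libsbml fbc GeneProductAssociation subtree to a GPRNode."""
    import libsbml
    from .gpr import GPRNode

    if isinstance(assoc, libsbml.GeneProductRef):
        return GPRNode("GENE", gene_id=assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        children = tuple(_gpa_to_node(assoc.getAssociation(i))
                         for i in range(assoc.getNumAssociations()))
        return GPRNode("AND", children=children)
    if isinstance(assoc, libsbml.FbcOr):
        children = tuple(_gpa_to_node(assoc.getAssociation(i))
                         for i in range(assoc.getNumAssociations()))
        return GPRNode("OR", children=children)
    raise ParseError(f"unsupported gene association element {type(assoc).__name__}")


_GA_NOTE_RE = re.compile(r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE)


def read_model_sbml(path: str | Path) -> MetabolicModel:
    """Read a metabolic model from an SBML file.

    Supports fbc gene-product associations and flux-bound parameters as
    well as the legacy dialect (``GENE_ASSOCIATION:`` notes strings and
    ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters).  When both are
    present, fbc wins.  Reaction order follows document order.

    Raises
    ------
    ParseError
        On unreadable files, undeclared species references, or malformed
        gene associations, naming the offending element.
    """
    import libsbml

    path = Path(path)
    if not path.exists():
        raise ParseError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ParseError(f"SBML parse error in {path.name}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError(f"no <model> element in {path.name}")

    metabolites = []
    species_ids = set()
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            # boundary species are outside the balanced system
            continue
        metabolites.append(Metabolite(sp.getId(), sp.getCompartment() or ""))
        species_ids.add(sp.getId())
    boundary_ids = {sp.getId() for sp in sbml_model.getListOfSpecies()
                    if sp.getBoundaryCondition()}

    def param_value(pid: str) -> float | None:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    reactions = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            sid = ref.getSpecies()
            if sid in boundary_ids:
                continue
            if sid not in species_ids:
                raise ParseError(
                    f"reaction {rxn.getId()!r} references undeclared species {sid!r}")
            stoich[sid] = stoich.get(sid, 0.0) - (ref.getStoichiometry() or 1.0)
        for ref in rxn.getListOfProducts():
            sid = ref.getSpecies()
            if sid in boundary_ids:
                continue
            if sid not in species_ids:
                raise ParseError(
                    f"reaction {rxn.getId()!r} references undeclared species {sid!r}")
            stoich[sid] = stoich.get(sid, 0.0) + (ref.getStoichiometry() or 1.0)
        if not stoich:
            raise ParseError(
                f"reaction {rxn.getId()!r} has no species inside the balanced system")

        lb = ub = None
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            lb_id = fbc_rxn.getLowerFluxBound()
            ub_id = fbc_rxn.getUpperFluxBound()
            if lb_id:
                lb = param_value(lb_id)
            if ub_id:
                ub = param_value(ub_id)
        if lb is None or ub is None:
            kl = rxn.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    p = kl.getParameter(j)
                    if p.getId() == "LOWER_BOUND" and lb is None:
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND" and ub is None:
                        ub = p.getValue()
        if lb is None:
            lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        gpr = None
        if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
            gpr = _gpa_to_node(fbc_rxn.getGeneProductAssociation().getAssociation())
        if gpr is None and rxn.isSetNotes():
            notes = rxn.getNotesString()
            m = _GA_NOTE_RE.search(notes)
            if m:
                rule = m.group(1).strip()
                if rule:
                    gpr = parse_gpr(rule)

        reactions.append(Reaction(rxn.getId(), stoich, float(lb), float(ub), gpr=gpr,
                                  name=rxn.getName() or ""))
    return MetabolicModel(metabolites, reactions, id=sbml_model.getId() or path.stem)


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "->")


def _parse_side(text: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError(f"line {lineno}: empty term in equation")
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: bad stoichiometric coefficient {parts[0]!r}") from None
            met = parts[1]
        else:
            raise ParseError(f"line {lineno}: malformed term {term!r}")
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(equation: str, lineno: int = 0) -> dict[str, float]:
    """Parse ``"1 A_c + 2 B_c -> 1 C_c"`` into a signed stoichiometry map.

    One side may be empty (exchange reactions, e.g. ``"-> A_c"``).
    """
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise ParseError(f"line {lineno}: no reaction arrow in equation {equation!r}")
    stoich: dict[str, float] = {}
    for met, coef in _parse_side(left, lineno).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(right, lineno).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ParseError(f"line {lineno}: equation {equation!r} has empty net stoichiometry")
    return stoich


def read_model_tabular(path: str | Path) -> MetabolicModel:
    """Read a model from the tab-separated dialect.

    Columns: ``reaction_id, equation, lower_bound, upper_bound, gpr_string``
    (header row required; empty ``gpr_string`` means no gene association).
    Produces a model equivalent to the SBML reader's on the same network.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"model file not found: {path}")
    reactions: list[Reaction] = []
    met_ids: dict[str, None] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path.name}: empty model file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: expected >=4 tab-separated fields")
            rid, equation = fields[0].strip(), fields[1]
            try:
                lb, ub = float(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric flux bound") from None
            gpr_string = fields[4].strip() if len(fields) > 4 else ""
            stoich = parse_equation(equation, lineno)
            gpr = parse_gpr(gpr_string) if gpr_string else None
            try:
                rxn = Reaction(rid, stoich, lb, ub, gpr=gpr)
            except ValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            reactions.append(rxn)
            for met in stoich:
                met_ids.setdefault(met, None)
    metabolites = [Metabolite(m, compartment=m.rsplit("_", 1)[-1] if "_" in m else "")
                   for m in met_ids]
    return MetabolicModel(metabolites, reactions, id=path.stem)


def write_model_tabular(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the tab-separated dialect (inverse of the reader)."""
    def fmt_coef(c: float) -> str:
        return f"{c:g}"

    with open(path, "w") as fh:
        fh.write("reaction_id\tequation\tlower_bound\tupper_bound\tgpr_string\n")
        for rxn in model.reactions:
            left = " + ".join(f"{fmt_coef(-c)} {m}" for m, c in rxn.stoich.items() if c < 0)
            right = " + ".join(f"{fmt_coef(c)} {m}" for m, c in rxn.stoich.items() if c > 0)
            equation = f"{left} -> {right}".strip()
            gpr = gpr_to_string(rxn.gpr) if rxn.gpr is not None else ""
            fh.write(f"{rxn.id}\t{equation}\t{rxn.lower_bound:g}\t{rxn.upper_bound:g}\t{gpr}\n")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def read_detection_matrix(path: str | Path) -> pd.DataFrame:
    """Read a detection p-value (or 0/1 call) matrix.

    Rows are genes, columns are samples, as produced by array-platform
    detection statistics.  Returned as a genes x samples DataFrame of
    floats; values must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty detection matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric entry in detection matrix ({exc})") from None
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in detection matrix")
    if ((df.values < 0) | (df.values > 1)).any():
        raise ValidationError(f"{path}: detection p-values must lie in [0, 1]")
    return df


def write_detection_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read survival records: columns ``sample_id, time, event`` (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: survival table needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    if (df["time"] < 0).any():
        raise ValidationError(f"{path}: negative survival time")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin((0, 1)).all():
        raise ValidationError(f"{path}: event indicator must be 0/1")
    return df[["time", "event"]]


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_sample_landscape(states, reaction_ids, path: str | Path) -> None:
    """Write one sample's per-reaction states as TSV (reaction_id, state)."""
    pd.Series(states, index=pd.Index(reaction_ids, name="reaction_id"),
              name="state").to_csv(path, sep="\t")


def read_sample_landscape(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    series = df["state"].astype(np.int8)
    if not series.isin((-1, 0)).all():
        raise ValidationError(f"{path}: landscape states must be -1 or 0")
    return series


def read_landscape_matrix(path: str | Path) -> pd.DataFrame:
    """Read a cohort landscape matrix (samples x reactions, values -1/0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin((-1, 0)).all().all():
        raise ValidationError(f"{path}: landscape values must be -1 or 0")
    return df.astype(np.int8)


def write_landscape_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")
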