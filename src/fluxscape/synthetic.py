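"""Synthetic benchmark cohorts with planted metabolic programs.

Builds toy metabolic networks and matched expression/survival cohorts so
every pipeline stage can be exercised with known ground truth:

* a toy network with parallel nutrient supply routes feeding a maintenance
  demand (whose positive lower bound makes naive zeroing of all silenced
  reactions infeasible — the situation the congruency MILP exists for) and
  one *marker pathway*: a linear chain of stoichiometrically coupled
  reactions where a single gate gene controls activity and the remaining
  steps are constitutively expressed (isozyme pairs);
* an expression cohort of ``n_pathways`` groups, group j silencing supply
  route j; group 0 is the poor-prognosis group and is the only one whose
  marker gate gene is present, so the marker chain is ACTIVE precisely in
  the poor group;
* exponential survival times with a higher event hazard in the poor group
  and administrative censoring.

Default cohort: 300 samples, poor fraction 0.13 (the share of the
poor-prognosis cluster in a ~1000-tumour breast-cancer cohort), 6 pathway
groups, marker chain length 5, call-flip noise 0.05, hazards 0.03 vs
0.01 events/month (hazard ratio 3), censoring at 120 months.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import DetectionSample
from .exceptions import ValidationError
from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "CohortConfig",
    "make_toy_gsmn",
    "random_toy_gsmn",
    "simulate_detection",
    "simulate_survival",
    "make_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults define the standard benchmark cohort."""

    n_samples: int = 300
    poor_fraction: float = 0.13
    n_pathways: int = 6
    marker_pathway_length: int = 5
    presence_noise: float = 0.05          # per-call flip probability
    hazard_poor: float = 0.03             # events per month
    hazard_rest: float = 0.01
    censor_time: float = 120.0            # months of follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        if not (0.0 < self.poor_fraction < 1.0):
            raise ValidationError("poor_fraction must lie in (0, 1)")
        if self.n_pathways < 2:
            raise ValidationError("n_pathways must be >= 2")
        if self.marker_pathway_length < 2:
            raise ValidationError("marker_pathway_length must be >= 2")
        if not (0.0 <= self.presence_noise < 0.5):
            raise ValidationError("presence_noise must lie in [0, 0.5)")
        if self.hazard_poor <= 0 or self.hazard_rest <= 0:
            raise ValidationError("hazards must be positive")
        if self.censor_time < 0:
            raise ValidationError("censor_time must be nonnegative")


MARKER_GATE_GENE = "g_gate"
# route j carries an isozyme pair per gene-bearing step: transporter (T)
# and enzyme (E), each "a or b"; the group program silences all four
ROUTE_GPRS = ("g_pathTa_{j} or g_pathTb_{j}", "g_pathEa_{j} or g_pathEb_{j}")
MAINTENANCE_LB = 1.0
PATHWAY_UB = 10.0


def marker_reaction_ids(marker_pathway_length: int) -> list[str]:
    return [f"MK{i+1}" for i in range(marker_pathway_length)]


def make_toy_gsmn(
    n_pathways: int = 6,
    marker_pathway_length: int = 5,
    seed: int = 0,
    maintenance_lb: float = MAINTENANCE_LB,
) -> MetabolicModel:
    """Toy network: parallel supply routes, forced maintenance, marker chain.

    Supply route j is a coupled four-step chain ``EX_N{j}: -> N{j}``,
    ``TR{j}: N{j} -> M{j}`` (transporter isozymes ``g_pathTa/b_{j}``),
    ``ACT{j}: M{j} -> P{j}``, ``CONV{j}: P{j} -> E`` (enzyme isozymes
    ``g_pathEa/b_{j}``); the chain is stoichiometrically coupled, so
    silencing either gene-bearing step switches the whole route, giving
    each route a multi-reaction landscape signature of weight comparable
    to the marker chain, like real multi-step pathways.  Isozyme pairs
    make spurious single-call silencing rare, exactly as for the marker
    chain's constitutive steps.  The demand ``DM_E: E ->``
    has lower bound ``maintenance_lb`` > 0, so at least one route must
    stay open.  The marker chain ``MK1..MK{L}`` (uptake -> intermediates
    -> secretion) is fully coupled; its second step carries the single
    variable gate gene, all other steps OR-pairs of constitutive isozymes.

    Raises
    ------
    ValidationError
        If the maintenance lower bound exceeds total supply capacity (the
        base network would be infeasible).
    """
    if n_pathways < 2:
        raise ValidationError("n_pathways must be >= 2")
    if marker_pathway_length < 2:
        raise ValidationError("marker_pathway_length must be >= 2")
    if maintenance_lb > n_pathways * PATHWAY_UB:
        raise ValidationError(
            f"maintenance demand {maintenance_lb} exceeds total supply capacity "
            f"{n_pathways * PATHWAY_UB}: base model infeasible")

    metabolites = [Metabolite("E_c", "c")]
    reactions: list[Reaction] = []

    # marker chain MK1..MKL over intermediates S1..S(L-1)
    L = marker_pathway_length
    for i in range(1, L):
        metabolites.append(Metabolite(f"S{i}_c", "c"))
    for i, rid in enumerate(marker_reaction_ids(L), start=1):
        if i == 1:
            stoich = {"S1_c": 1.0}
        elif i == L:
            stoich = {f"S{L-1}_c": -1.0}
        else:
            stoich = {f"S{i-1}_c": -1.0, f"S{i}_c": 1.0}
        if i == 2:
            gpr = parse_gpr(MARKER_GATE_GENE)
        else:
            gpr = parse_gpr(f"g_hk{i}a or g_hk{i}b")
        reactions.append(Reaction(rid, stoich, 0.0, PATHWAY_UB, gpr=gpr))

    # supply routes (four coupled steps each) and maintenance
    for j in range(n_pathways):
        metabolites.append(Metabolite(f"N{j}_c", "c"))
        metabolites.append(Metabolite(f"M{j}_c", "c"))
        metabolites.append(Metabolite(f"P{j}_c", "c"))
        reactions.append(Reaction(f"EX_N{j}", {f"N{j}_c": 1.0}, 0.0, PATHWAY_UB))
        reactions.append(Reaction(
            f"TR{j}", {f"N{j}_c": -1.0, f"M{j}_c": 1.0}, 0.0, PATHWAY_UB,
            gpr=parse_gpr(ROUTE_GPRS[0].format(j=j))))
        reactions.append(Reaction(
            f"ACT{j}", {f"M{j}_c": -1.0, f"P{j}_c": 1.0}, 0.0, PATHWAY_UB))
        reactions.append(Reaction(
            f"CONV{j}", {f"P{j}_c": -1.0, "E_c": 1.0}, 0.0, PATHWAY_UB,
            gpr=parse_gpr(ROUTE_GPRS[1].format(j=j))))
    reactions.append(Reaction("DM_E", {"E_c": -1.0}, maintenance_lb, PATHWAY_UB))

    return MetabolicModel(metabolites, reactions, id="toy_gsmn")


def random_toy_gsmn(
    seed: int,
    max_absent: int = 12,
) -> tuple[MetabolicModel, list[str]]:
    """Random small network plus a random absent-reaction set (oracle fodder).

    Structure: 2-4 supply routes into a hub metabolite with a maintenance
    demand (lower bound drawn from {0.5, 1}), plus 1-3 independent linear
    chains of length 2-3, occasionally reversible, occasionally with a
    forced nonzero flux (lb = ub > 0).  Feasible by construction (supply
    capacity always exceeds the demand).  Networks stay under ~20
    reactions.
    """
    rng = np.random.default_rng(seed)
    metabolites = [Metabolite("HUB", "c")]
    reactions: list[Reaction] = []

    n_routes = int(rng.integers(2, 5))
    for j in range(n_routes):
        metabolites.append(Metabolite(f"A{j}", "c"))
        ub = float(rng.choice([5.0, 10.0]))
        reactions.append(Reaction(f"IN{j}", {f"A{j}": 1.0}, 0.0, ub))
        reactions.append(Reaction(f"USE{j}", {f"A{j}": -1.0, "HUB": 1.0}, 0.0, ub))
    demand_lb = float(rng.choice([0.5, 1.0]))
    reactions.append(Reaction("DM", {"HUB": -1.0}, demand_lb, 20.0))

    n_chains = int(rng.integers(1, 4))
    for c in range(n_chains):
        length = int(rng.integers(2, 4))
        if len(reactions) + length + 1 > 20:  # keep oracle-sized networks
            break
        prev = None
        forced = rng.random() < 0.15
        for s in range(length):
            met = f"C{c}M{s}"
            metabolites.append(Metabolite(met, "c"))
            stoich = {met: 1.0} if prev is None else {prev: -1.0, met: 1.0}
            lb = -5.0 if rng.random() < 0.2 else 0.0
            ub = 5.0
            if forced and s == 0:
                lb = ub = 2.0
                forced = False
            reactions.append(Reaction(f"C{c}R{s}", stoich, lb, ub))
            prev = met
        reactions.append(Reaction(f"C{c}OUT", {prev: -1.0}, 0.0, 5.0))

    model = MetabolicModel(metabolites, reactions, id=f"random_toy_{seed}")
    rids = model.reaction_ids
    k = int(rng.integers(1, min(max_absent, len(rids)) + 1))
    absent = list(rng.choice(rids, size=k, replace=False))
    return model, absent


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_p(rng: np.random.Generator, present: bool) -> float:
    """Detection p-value from the present (p < 0.01) or absent slab."""
    if present:
        return float(rng.uniform(0.0, 0.005))
    return float(rng.uniform(0.05, 1.0))


def _group_assignment(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n_poor = int(round(config.n_samples * config.poor_fraction))
    n_poor = max(1, min(config.n_samples - 1, n_poor))
    groups = np.zeros(config.n_samples, dtype=int)
    rest = np.arange(config.n_samples - n_poor)
    groups[n_poor:] = 1 + rest % (config.n_pathways - 1)
    rng.shuffle(groups)
    return groups


def simulate_detection(
    model: MetabolicModel,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[DetectionSample], np.ndarray]:
    """Per-sample detection p-values with a planted group structure.

    Sample in group j has its supply route j silenced: all four route
    genes (both transporter and both enzyme isozymes) are absent, so a
    single flipped call cannot resurrect the route.  The marker gate gene
    is present only in group 0 (the poor group — its marker pathway is
    active).  All other genes are present.
    Each call is then flipped independently with probability
    ``presence_noise`` by redrawing the p-value from the opposite slab.
    Returns the samples and the group label array (0 = poor group).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = _group_assignment(config, rng)
    genes = sorted(model.genes)
    samples = []
    for i, group in enumerate(groups):
        p_map: dict[str, float] = {}
        for gene in genes:
            if gene == MARKER_GATE_GENE:
                present = group == 0
            elif gene.startswith("g_path"):
                present = gene.rsplit("_", 1)[1] != str(group)
            else:
                present = True
            if rng.random() < config.presence_noise:
                present = not present
            p_map[gene] = _draw_p(rng, present)
        samples.append(DetectionSample(sample_id=f"S{i:04d}", detection_p=p_map))
    return samples, groups


def simulate_survival(
    poor: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Exponential survival with group hazards and administrative censoring.

    ``poor`` is a boolean array; poor samples use ``hazard_poor``, the rest
    ``hazard_rest``.  ``event`` is 1 iff death precedes ``censor_time``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    poor = np.asarray(poor, dtype=bool)
    hazards = np.where(poor, config.hazard_poor, config.hazard_rest)
    raw = rng.exponential(scale=1.0 / hazards)
    event = (raw < config.censor_time).astype(int)
    time = np.minimum(raw, config.censor_time)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(len(poor))]
    return pd.DataFrame({"time": time, "event": event},
                        index=pd.Index(sample_ids, name="sample_id"))


def detection_to_frame(samples: list[DetectionSample]) -> pd.DataFrame:
    """Samples x genes DataFrame of detection p-values."""
    return pd.DataFrame(
        {s.sample_id: s.detection_p for s in samples}).T.rename_axis("sample_id")


def make_cohort(
    config: CohortConfig = CohortConfig(),
    out_dir: str | Path | None = None,
) -> tuple[MetabolicModel, list[DetectionSample], pd.DataFrame, np.ndarray]:
    """Model + detection cohort + survival + truth labels from one seed.

    With ``out_dir`` set, writes the fixture bundle: tabular model,
    detection-p TSV (genes x samples), survival TSV, truth-label TSV and a
    key=value echo of the configuration.
    """
    rng = np.random.default_rng(config.seed)
    model = make_toy_gsmn(config.n_pathways, config.marker_pathway_length)
    samples, groups = simulate_detection(model, config, rng)
    survival = simulate_survival(groups == 0, config, rng,
                                 sample_ids=[s.sample_id for s in samples])
    if out_dir is not None:
        from .io import write_detection_matrix, write_model_tabular, write_survival

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_model_tabular(model, out / "model.tsv")
        write_detection_matrix(detection_to_frame(samples).T, out / "detection_p.tsv")
        write_survival(survival, out / "survival.tsv")
        pd.DataFrame({
            "sample_id": [s.sample_id for s in samples],
            "group": groups,
            "poor": (groups == 0).astype(int),
        }).to_csv(out / "truth_labels.tsv", sep="\t", index=False)
        with open(out / "config.txt", "w") as fh:
            for key, value in asdict(config).items():
                fh.write(f"{key}={value}\n")
    return model, samples, survival, groups
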