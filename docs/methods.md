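# Methods

## Model and state coding

A metabolic model is a stoichiometric matrix `S` (metabolites × reactions),
flux bounds `lb ≤ v ≤ ub` (irreversibility is encoded purely as `lb ≥ 0`;
bounds omitted by an input file default to ±1000 for reversible and
[0, 1000] for irreversible reactions, the common convention in human GSMN
distributions), and optional GPR boolean rules over gene identifiers.
Compartment suffixes in identifiers (`_c` etc.) are carried verbatim and
never interpreted.

Transcript evidence enters only as *absence*: a gene is called present iff
its detection p-value is strictly below `alpha = 0.01`. Absence is the
robust end of a detection statistic; thresholds for "over-expressed" would
be arbitrary, so no up-regulated category exists. A reaction's
transcript-derived state is −1 iff it has a GPR and the rule evaluates
false with unmeasured genes defaulting to present; reactions without a GPR
are never constrained. This makes the state map monotone: silencing more
genes can only add −1 states.

## Landscape computation

Per sample, with absent set `A = {r : state_r = −1}`:

1. **Congruency MILP.** maximize `Σ_{r∈A} y_r`, `y_r ∈ {0,1}`, subject to
   `S·v = 0`, bounds, and the big-M pair
   `−M_r(1−y_r) ≤ v_r ≤ M_r(1−y_r)` with `M_r = max(|lb_r|, |ub_r|)`
   (infinite bounds capped at ±1000 first — the tightest valid M per
   reaction, chosen for numerical stability). Solved by HiGHS
   (`scipy.optimize.milp`) with relative gap 0 at toy scale; a gap and a
   time limit are exposed for large models. After solving, the indicators
   are rounded and one clean LP with the zeroed reactions pinned to
   exactly 0 produces the reported flux vector, removing big-M tolerance
   slack.
2. **Fixing.** Every reaction in `A` is fixed at its (cleaned) MILP flux;
   values with |v| < `zero_tol` are snapped to 0.
3. **FVA classification.** For each remaining reaction the feasible flux
   range is computed by two LPs; state −1 iff the range lies within
   `zero_tol = 1e-6` (absolute, flux units) of zero. The implementation
   evaluates the maximum first and skips the minimum LP when the maximum
   already exceeds the tolerance — a pure shortcut with identical output.
   Active reactions are *not* subdivided into must-be-active vs
   undetermined; only absence evidence is considered robust.

Alternate optima exist whenever symmetric routes can be silenced
interchangeably (the maintenance-forced two-feeder toy is the minimal
case). The pipeline commits to the single solution returned by a
deterministic solver configuration (fixed variable order, no randomized
heuristics); identical inputs therefore always give identical landscapes,
and ties among symmetric reactions are solver-order artifacts, documented
as such. Samples with identical transcript-derived state vectors share one
solve, which also makes results independent of sample order.

The per-reaction reference classifier (`imat_reference`) re-solves the
congruency MILP twice per reaction with that reaction's flux forced
≥ ε or ≤ −ε (ε = 1e-3 in toy flux units); a reaction that cannot reach the
global optimum either way is pinned to zero in every maximally congruent
model. It is quadratically more expensive and exists as an independent
cross-check at toy scale, not as a production path.

## Cohort analysis

Reactions with identical activity in all samples are removed before
clustering (they carry no information; the variable set is recomputed per
dataset). K-means uses the −1/0 coding directly as numeric features with
Euclidean distance, best of 25 seeded restarts, over k = 5…10; k is
selected as the granularity whose *best cluster-vs-rest* log-rank p is
smallest (ties toward smaller k). Selecting by the k-sample overall
statistic was tried and rejected: a larger cluster that has absorbed
noise samples gains log-rank power, so the overall statistic
systematically prefers coarser k where the survival-divergent group is
merged and diluted. Kaplan–Meier curves and log-rank tests come from
lifelines.

**Poor-cluster rule.** Scanning six values of k and up to ten clusters
each multiplies testing opportunities, so the pipeline first requires the
selected k's best cluster-vs-rest p to pass Bonferroni correction over
the total number of cluster tests examined (0.05/45 for k = 5…10);
without this gate a substantial fraction of null cohorts would flag a
spurious cluster. Among clusters that are then individually significant
vs the rest (log-rank p < 0.05) *and* adverse (lower KM survival than the
rest at the last follow-up time common to all clusters), the one with the
smallest vs-rest p is chosen, with lower KM as tie-break. Choosing by raw
KM depth instead was tried and rejected: a handful of samples that all
happen to die reach KM = 0 and outrank a 40-sample cluster with
p ≈ 1e-7.

**DARs and DAPs.** Per variable reaction, a two-sample t-test compares
mean activity (of the −1/0 coding) between the poor cluster and all other
samples; on binary data this is a proportion comparison. The
pooled-variance (Student) form is used: with a small poor group and rare
active states, the Welch variant's per-group variance estimate is noisy
and measurably anti-conservative (≈7% type-I under label permutation on
landscape columns, vs ≈4% for the pooled test at the nominal 5%).
Bonferroni divides by the
number of reactions actually tested (the variable set), not the full model
size: constant reactions carry no test. Reactions constant in both groups
get p = 1. Adjusted p < 0.05 defines a DAR. DARs with bitwise-identical
activity columns across *all* samples form a DAP — the signature of
stoichiometric coupling, since coupled reactions are zeroed and released
together. Each DAP reports active-sample counts per group with Wilson
score 95% intervals (the score interval is the standard choice near
boundary proportions, where Wald intervals degenerate), rounded to whole
percent in the formatted report.

## Synthetic benchmark

The generator emulates the statistical structure of a transcriptome cohort
with survival follow-up, at toy network scale:

* **Network.** `n_pathways` (default 6) parallel four-step supply routes
  (uptake → transport → activation → conversion) feed a maintenance
  demand with positive lower bound (1 flux unit), so silencing *all*
  routes is infeasible and congruency optimization is exercised. Each
  route's transport and conversion steps carry OR-pairs of isozymes,
  combined across steps by the chain's stoichiometric coupling into an
  effective `(Ta or Tb) and (Ea or Eb)` switch — the structure of real
  GPR rules. A marker pathway — a fully coupled chain of
  `marker_pathway_length` (default 5) reactions — carries a single
  variable gate gene on one step; the other steps carry OR-pairs of
  constitutive isozymes, so a single flipped call cannot sever the chain.
  Routes are multi-step with redundant gene pairs so that every planted
  group's landscape signature has weight comparable to the marker chain
  and is robust to single-call noise in both directions; with single-gene
  single-step routes, one flipped call either resurrects a silenced route
  or moves a background sample closer to the poor centroid than to its
  own, and no clustering method could recover the planted partition.
* **Cohort.** Each sample belongs to one of `n_pathways` expression
  groups (its route gene absent); group 0 is the poor-prognosis group
  (13% of samples, the poor-cluster share of a ~1000-tumour cohort) and is
  the only group whose marker gate gene is present — the marker pathway is
  *active* in the poor group. Detection p-values are drawn uniformly from
  [0, 0.005] (present) or [0.05, 1] (absent); each call flips
  independently with probability `presence_noise` (default 0.05) by
  redrawing from the opposite slab.
* **Survival.** Exponential event times with hazards 0.03 (poor) vs 0.01
  (rest) events/month — hazard ratio 3, medians ≈ 23 vs 69 months — under
  administrative censoring at 120 months, a typical follow-up horizon.
  Real cohorts have staggered entry and competing risks; none of that is
  modeled.

Everything is reproducible bit-for-bit from (config, seed). What passing
tests on this benchmark show is that the machinery — call propagation,
congruency optimization, FVA classification, clustering, survival
stratification, DAR/DAP detection — recovers a planted signal under
realistic noise; they do not show that real tumour cohorts contain such
clean group structure, that array detection calls behave like uniform
slabs, or that genome-scale models solve in comparable time.

## Problem sizes and numerical choices

Tests and the acceptance script run toy networks (≤ 30 reactions) and
cohorts of 300 samples; random oracle networks stay ≤ 20 reactions with
≤ 12 absent so the exhaustive-subset oracle (worst case 2^12 LPs) stays
exact and fast. `zero_tol = 1e-6` applies both to MILP flux snapping and
FVA zero classification. Degenerate inputs are rejected with named errors:
inverted bounds, undeclared species, p-values outside [0, 1], clusters
without survival records, empty variable sets. The brute-force congruency
search enumerates subsets largest-first and stops at the first feasible
size (monotonicity: relaxing a zeroed set keeps feasibility).

## Known limitations

* Genome-scale models are supported by the data structures and solver
  interfaces but not exercised in tests; MILP time limits and gaps are the
  intended control knobs there.
* The landscape committed per sample is one of possibly many maximally
  congruent solutions; downstream counts for symmetric routes depend on
  solver ordering (deterministically so).
* Exchange-medium constraints are not applied automatically; bounds are
  taken as given by the model file.
* The survival generator's administrative censoring is simplistic; the
  log-rank machinery itself is exact regardless.
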