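"""Cohort-level analysis of metabolic landscapes.

Input is a samples x reactions landscape matrix over {-1, 0} plus linked
survival records (time in months, event indicator).  The analysis:

* drops reactions with identical activity in every sample (they carry no
  information for classification);
* K-means clusters the remaining matrix (the -1/0 coding used directly as
  numeric features, Euclidean distance, best of ``restarts`` seeded
  initializations) for each k in a range, selecting the k whose best
  cluster-vs-rest log-rank p is smallest (ties -> smaller k);
* identifies the poor-prognosis cluster: among clusters whose
  cluster-vs-rest log-rank p is below 0.05 and whose survival is worse
  than the rest of the cohort, the one with the strongest association;
* tests every reaction for differential activity between the poor cluster
  and the rest (two-sample t-test on the -1/0 coding, Bonferroni over the
  tested set); significant reactions are DARs;
* groups DARs with bitwise-identical activity columns into DAPs —
  stoichiometrically coupled reaction sets that switch together — and
  reports per-group active-sample fractions with Wilson 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ValidationError

__all__ = [
    "ClusterAssignment",
    "KMSummary",
    "KSelection",
    "PoorClusterResult",
    "DAPGroup",
    "variable_reactions",
    "kmeans_cluster",
    "km_logrank",
    "select_k",
    "identify_poor_cluster",
    "dar_tests",
    "find_dars",
    "group_daps",
    "wilson_ci",
    "dap_report",
    "PoorPrognosisStratifier",
]

DEFAULT_K_RANGE = (5, 6, 7, 8, 9, 10)
DAR_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    k: int
    labels: pd.Series  # sample_id -> cluster index in 1..k
    inertia: float

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def variable_reactions(matrix: pd.DataFrame) -> list[str]:
    """Reactions whose activity differs between at least two samples."""
    values = matrix.to_numpy()
    varying = (values != values[0]).any(axis=0)
    return [c for c, v in zip(matrix.columns, varying) if v]


def kmeans_cluster(
    matrix: pd.DataFrame, k: int, restarts: int = 25, seed: int = 0
) -> ClusterAssignment:
    """Best-of-restarts K-means on the -1/0 matrix (Euclidean distance)."""
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > len(matrix):
        raise ValidationError(f"k={k} exceeds number of samples {len(matrix)}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    return ClusterAssignment(
        k=k,
        labels=pd.Series(labels + 1, index=matrix.index, name="cluster"),
        inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class KMSummary:
    """Kaplan-Meier curves and log-rank statistics for one clustering."""

    curves: dict[int, pd.DataFrame]          # cluster -> (time, survival, at_risk)
    overall_p: float
    overall_stat: float
    cluster_vs_rest_p: dict[int, float]


def _check_survival(labels: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    missing = labels.index.difference(survival.index)
    if len(missing):
        raise ValidationError(
            f"missing survival record for sample(s): {', '.join(map(str, missing[:5]))}")
    return survival.loc[labels.index]


def km_logrank(assignment: ClusterAssignment, survival: pd.DataFrame) -> KMSummary:
    """Per-cluster product-limit curves plus overall and one-vs-rest log-rank tests.

    ``survival`` is indexed by sample id with columns ``time`` and
    ``event`` (1 = death observed, 0 = censored).
    """
    labels = assignment.labels
    surv = _check_survival(labels, survival)
    curves: dict[int, pd.DataFrame] = {}
    vs_rest: dict[int, float] = {}
    for cluster in range(1, assignment.k + 1):
        mask = (labels == cluster).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"cluster {cluster} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(surv["time"][mask], surv["event"][mask])
        table = kmf.event_table
        curves[cluster] = pd.DataFrame({
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        }).reset_index(drop=True)
        res = logrank_test(
            surv["time"][mask], surv["time"][~mask],
            event_observed_A=surv["event"][mask],
            event_observed_B=surv["event"][~mask],
        )
        vs_rest[cluster] = float(res.p_value)
    overall = multivariate_logrank_test(surv["time"], labels, surv["event"])
    return KMSummary(
        curves=curves,
        overall_p=float(overall.p_value),
        overall_stat=float(overall.test_statistic),
        cluster_vs_rest_p=vs_rest,
    )


@dataclass
class KSelection:
    best_k: int
    assignments: dict[int, ClusterAssignment]
    summaries: dict[int, KMSummary]

    @property
    def p_by_k(self) -> dict[int, float]:
        return {k: s.overall_p for k, s in self.summaries.items()}

    @property
    def best_cluster_p_by_k(self) -> dict[int, float]:
        """Smallest cluster-vs-rest log-rank p at each k."""
        return {k: min(s.cluster_vs_rest_p.values())
                for k, s in self.summaries.items()}

    @property
    def n_cluster_tests(self) -> int:
        """Total number of cluster-vs-rest tests examined across the k range."""
        return sum(len(s.cluster_vs_rest_p) for s in self.summaries.values())


def select_k(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    restarts: int = 25,
    seed: int = 0,
) -> KSelection:
    """Cluster at each k; pick the k whose best cluster-vs-rest p is smallest.

    The selected granularity is the one that isolates the single most
    survival-divergent cluster (candidate poor-prognosis group); choosing
    by the k-sample overall statistic instead systematically favours
    coarser k where the divergent group is merged with (and diluted by) a
    neighbouring cluster.  Ties are broken toward the smaller k.
    """
    if not len(k_range):
        raise ValidationError("k_range is empty")
    assignments: dict[int, ClusterAssignment] = {}
    summaries: dict[int, KMSummary] = {}
    for k in k_range:
        assignments[k] = kmeans_cluster(matrix, k, restarts=restarts, seed=seed)
        summaries[k] = km_logrank(assignments[k], survival)
    best_k = min(sorted(k_range),
                 key=lambda k: (min(summaries[k].cluster_vs_rest_p.values()), k))
    return KSelection(best_k=best_k, assignments=assignments, summaries=summaries)


@dataclass
class PoorClusterResult:
    cluster: int | None                  # None => no significant poor cluster
    km_at_horizon: dict[int, float]
    horizon: float
    cluster_vs_rest_p: dict[int, float]

    @property
    def found(self) -> bool:
        return self.cluster is not None


def identify_poor_cluster(
    assignment: ClusterAssignment,
    survival: pd.DataFrame,
    summary: KMSummary | None = None,
    alpha: float = 0.05,
) -> PoorClusterResult:
    """Pick the poor-prognosis cluster.

    Candidates are clusters whose cluster-vs-rest log-rank p is below
    ``alpha`` *and* whose KM survival at the last follow-up time common to
    all clusters is below the rest of the cohort's (an adverse, not
    protective, association).  Among candidates the one with the smallest
    vs-rest p wins, with lower KM as tie-break: the strength of the
    survival association, not the raw depth of the KM curve, identifies
    the cluster — a tiny cluster in which every member happens to die
    reaches KM 0 without being the systematically poor group.  Returns a
    flagged result (``cluster=None``) when no cluster qualifies.
    """
    if summary is None:
        summary = km_logrank(assignment, survival)
    surv = _check_survival(assignment.labels, survival)
    horizon = min(
        surv["time"][(assignment.labels == c).to_numpy()].max()
        for c in range(1, assignment.k + 1)
    )
    km_at: dict[int, float] = {}
    adverse: dict[int, bool] = {}
    for cluster in range(1, assignment.k + 1):
        mask = (assignment.labels == cluster).to_numpy()
        kmf = KaplanMeierFitter().fit(surv["time"][mask], surv["event"][mask])
        km_at[cluster] = float(kmf.predict(horizon))
        rest = KaplanMeierFitter().fit(surv["time"][~mask], surv["event"][~mask])
        adverse[cluster] = km_at[cluster] < float(rest.predict(horizon))
    candidates = [c for c, p in summary.cluster_vs_rest_p.items()
                  if p < alpha and adverse[c]]
    chosen = (min(candidates,
                  key=lambda c: (summary.cluster_vs_rest_p[c], km_at[c], c))
              if candidates else None)
    return PoorClusterResult(
        cluster=chosen,
        km_at_horizon=km_at,
        horizon=float(horizon),
        cluster_vs_rest_p=summary.cluster_vs_rest_p,
    )


# ---------------------------------------------------------------------------
# Differentially activated reactions / pathways
# ---------------------------------------------------------------------------

def dar_tests(matrix: pd.DataFrame, poor_mask: np.ndarray) -> pd.DataFrame:
    """Two-sample t-tests of mean activity, poor cluster vs the rest, per reaction.

    Uses the pooled-variance (Student) form: on the binary -1/0 coding
    with a small poor group, the Welch variant's per-group variance
    estimate is noisy and measurably anti-conservative, while the pooled
    test holds the nominal level under label permutation.  Returns one row
    per tested reaction with ``mean_poor``, ``mean_rest``, ``raw_p`` and
    Bonferroni-``adjusted_p`` (divisor = number of tested reactions).
    Reactions constant within both groups get p = 1.
    """
    poor_mask = np.asarray(poor_mask, dtype=bool)
    if poor_mask.sum() < 2 or (~poor_mask).sum() < 2:
        raise ValidationError("both groups need at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    a, b = X[poor_mask], X[~poor_mask]
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # near-constant columns trigger a precision warning; their p is reset below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.asarray(p, dtype=float)
    p[np.isnan(p)] = 1.0  # constant in both groups: no evidence
    n_tests = matrix.shape[1]
    out = pd.DataFrame({
        "reaction_id": matrix.columns,
        "mean_poor": a.mean(axis=0),
        "mean_rest": b.mean(axis=0),
        "raw_p": p,
        "adjusted_p": np.minimum(1.0, p * n_tests),
    })
    return out.sort_values("adjusted_p", kind="stable").reset_index(drop=True)


def find_dars(
    matrix: pd.DataFrame, poor_mask: np.ndarray, alpha: float = DAR_ALPHA
) -> pd.DataFrame:
    """Reactions whose Bonferroni-adjusted p is below ``alpha``."""
    tests = dar_tests(matrix, poor_mask)
    return tests[tests["adjusted_p"] < alpha].reset_index(drop=True)


@dataclass
class DAPGroup:
    """A set of DARs with identical activity in every sample."""

    reaction_ids: tuple[str, ...]
    activity: np.ndarray           # shared -1/0 column over all samples
    adjusted_p: float              # representative (max over members)
    mixed_p: bool = False          # True if members' adjusted p differed

    def __len__(self) -> int:
        return len(self.reaction_ids)


def group_daps(dars: pd.DataFrame, matrix: pd.DataFrame) -> list[DAPGroup]:
    """Partition DARs by exact equality of their full activity columns.

    Reactions land in one group iff their -1/0 columns agree in every
    sample — the signature of stoichiometric coupling under the landscape
    computation.  Groups are ordered by ascending representative p.
    """
    groups: dict[tuple, list[tuple[str, float]]] = {}
    for _, row in dars.iterrows():
        col = matrix[row["reaction_id"]].to_numpy(dtype=np.int8)
        groups.setdefault(tuple(col.tolist()), []).append(
            (row["reaction_id"], float(row["adjusted_p"])))
    out = []
    for pattern, members in groups.items():
        ps = [p for _, p in members]
        out.append(DAPGroup(
            reaction_ids=tuple(r for r, _ in members),
            activity=np.array(pattern, dtype=np.int8),
            adjusted_p=max(ps),
            mixed_p=bool(max(ps) - min(ps) > 0),
        ))
    return sorted(out, key=lambda g: g.adjusted_p)


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1 or not (0 <= successes <= n):
        raise ValidationError(f"invalid counts: {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def _fmt_pct(count: int, n: int) -> str:
    frac = count / n
    lo, hi = wilson_ci(count, n)
    return (f"{round(100 * frac)}% "
            f"({round(100 * lo)}–{round(100 * hi)}%)")


def dap_report(daps: Iterable[DAPGroup], poor_mask: np.ndarray) -> pd.DataFrame:
    """Per-DAP active-sample fractions with Wilson 95% CIs, sorted by p.

    "Active" means state 0.  Columns include machine-readable counts and a
    formatted ``"79% (71–85%)"`` style string per group.
    """
    poor_mask = np.asarray(poor_mask, dtype=bool)
    n_poor = int(poor_mask.sum())
    n_rest = int((~poor_mask).sum())
    rows = []
    for dap in daps:
        active = dap.activity == 0
        c_poor = int(active[poor_mask].sum())
        c_rest = int(active[~poor_mask].sum())
        ci_poor = wilson_ci(c_poor, n_poor)
        ci_rest = wilson_ci(c_rest, n_rest)
        rows.append({
            "reactions": ";".join(dap.reaction_ids),
            "n_reactions": len(dap),
            "active_poor": c_poor,
            "n_poor": n_poor,
            "active_rest": c_rest,
            "n_rest": n_rest,
            "poor_pct_ci": _fmt_pct(c_poor, n_poor),
            "rest_pct_ci": _fmt_pct(c_rest, n_rest),
            "poor_ci_low": ci_poor[0],
            "poor_ci_high": ci_poor[1],
            "rest_ci_low": ci_rest[0],
            "rest_ci_high": ci_rest[1],
            "adjusted_p": dap.adjusted_p,
        })
    df = pd.DataFrame(rows, columns=[
        "reactions", "n_reactions", "active_poor", "n_poor", "active_rest",
        "n_rest", "poor_pct_ci", "rest_pct_ci", "poor_ci_low", "poor_ci_high",
        "rest_ci_low", "rest_ci_high", "adjusted_p"])
    return df.sort_values("adjusted_p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PoorPrognosisStratifier(BaseEstimator):
    """Survival-guided stratification of a landscape cohort.

    ``fit(X, y)`` takes a samples x reactions landscape DataFrame ``X``
    and survival records ``y`` (DataFrame indexed by sample id with
    ``time``/``event`` columns).  It filters variable reactions, clusters
    at every k in ``k_range``, selects k by the smallest overall log-rank
    p, and — provided the best cluster-vs-rest p survives Bonferroni
    correction over the total number of cluster tests examined across the
    k range (``gate_alpha / sum(k)``) — names a poor-prognosis cluster and
    derives DARs and DAPs against the rest of the cohort.  Without the
    gate, scanning several k values and up to ten clusters each would flag
    a spurious cluster in a substantial fraction of null cohorts.

    Fitted attributes: ``k_``, ``labels_``, ``selection_``, ``poor_cluster_``
    (None when not significant), ``poor_mask_``, ``dars_``, ``daps_``,
    ``report_``.
    """

    def __init__(
        self,
        k_range: Sequence[int] = DEFAULT_K_RANGE,
        restarts: int = 25,
        seed: int = 0,
        dar_alpha: float = DAR_ALPHA,
        gate_alpha: float = 0.05,
        cluster_alpha: float = 0.05,
    ):
        self.k_range = k_range
        self.restarts = restarts
        self.seed = seed
        self.dar_alpha = dar_alpha
        self.gate_alpha = gate_alpha
        self.cluster_alpha = cluster_alpha

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "PoorPrognosisStratifier":
        variable = variable_reactions(X)
        if not variable:
            raise ValidationError("no variable reactions: cohort landscape is constant")
        Xv = X[variable]
        self.variable_reactions_ = variable
        self.selection_ = select_k(
            Xv, y, k_range=self.k_range, restarts=self.restarts, seed=self.seed)
        self.k_ = self.selection_.best_k
        assignment = self.selection_.assignments[self.k_]
        summary = self.selection_.summaries[self.k_]
        self.labels_ = assignment.labels.to_numpy()
        self.logrank_p_ = summary.overall_p

        gate = self.gate_alpha / self.selection_.n_cluster_tests
        if min(summary.cluster_vs_rest_p.values()) < gate:
            poor = identify_poor_cluster(
                assignment, y, summary=summary, alpha=self.cluster_alpha)
        else:
            poor = PoorClusterResult(
                cluster=None, km_at_horizon={}, horizon=float("nan"),
                cluster_vs_rest_p=summary.cluster_vs_rest_p)
        self.poor_result_ = poor
        self.poor_cluster_ = poor.cluster
        if poor.found:
            self.poor_mask_ = (assignment.labels == poor.cluster).to_numpy()
            if self.poor_mask_.sum() >= 2 and (~self.poor_mask_).sum() >= 2:
                self.dars_ = find_dars(Xv, self.poor_mask_, alpha=self.dar_alpha)
                self.daps_ = group_daps(self.dars_, Xv)
                self.report_ = dap_report(self.daps_, self.poor_mask_)
            else:
                # a 1-sample group supports no t-test; cluster is still reported
                self.dars_ = None
                self.daps_ = None
                self.report_ = None
        else:
            self.poor_mask_ = None
            self.dars_ = None
            self.daps_ = None
            self.report_ = None
        return self

    def fit_predict(self, X: pd.DataFrame, y: pd.DataFrame) -> np.ndarray:
        return self.fit(X, y).labels_
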