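"""End-to-end orchestration: landscapes -> cohort analysis -> report files.

Per-sample landscape computation is independent across samples (results
are keyed by sample id and invariant to input order); the cohort stage
runs variable-reaction filtering, survival-guided k selection,
poor-cluster identification and DAR/DAP reporting, writing every table as
TSV together with a run log that records each threshold and seed used.

Exit-code convention (used by the CLI): 0 = success with a significant
poor-prognosis cluster, 2 = analysis completed but no cluster passed the
significance gate, 1 = hard failure.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .cohort import DEFAULT_K_RANGE, PoorPrognosisStratifier
from .exceptions import FluxscapeError, ValidationError
from .gebra import ZERO_TOL, GebraLandscaper
from .model import MetabolicModel

__all__ = ["RunConfig", "LandscapeRun", "AnalysisReport", "run_landscapes",
           "run_analysis", "run_all", "EXIT_OK", "EXIT_HARD", "EXIT_NO_CLUSTER"]

EXIT_OK = 0
EXIT_HARD = 1
EXIT_NO_CLUSTER = 2


@dataclass
class RunConfig:
    """Thresholds and knobs for a full run (defaults are the standard ones)."""

    alpha_detection: float = 0.01
    zero_tol: float = ZERO_TOL
    k_range: Sequence[int] = DEFAULT_K_RANGE
    restarts: int = 25
    seed: int = 0
    dar_alpha: float = 0.05
    time_limit: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha_detection < 1):
            raise ValidationError("alpha_detection must lie in (0,1)")
        if self.zero_tol <= 0:
            raise ValidationError("zero_tol must be positive")
        if not (0 < self.dar_alpha < 1):
            raise ValidationError("dar_alpha must lie in (0,1)")
        if min(self.k_range) < 2:
            raise ValidationError("k_range values must be >= 2")


@dataclass
class LandscapeRun:
    matrix: pd.DataFrame                 # samples x reactions, {-1, 0}
    diagnostics: pd.DataFrame            # per sample: n_absent, congruency
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_landscapes(
    model: MetabolicModel,
    detection: pd.DataFrame,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> LandscapeRun:
    """Compute one landscape per sample (columns of ``detection``).

    ``detection`` is a genes x samples matrix of detection p-values (or
    0/1 calls).  Samples whose solve fails are recorded in ``failures``
    and excluded from the matrix; the run continues.
    """
    X = detection.T  # samples x genes
    landscaper = GebraLandscaper(
        model, alpha=config.alpha_detection, zero_tol=config.zero_tol,
        time_limit=config.time_limit).fit(X)
    rows, diag, failures = [], [], {}
    for sample_id in X.index:
        try:
            part = landscaper.transform(X.loc[[sample_id]])
        except FluxscapeError as exc:
            failures[str(sample_id)] = str(exc)
            continue
        rows.append(part)
        diag.append(landscaper.diagnostics_)
    matrix = (pd.concat(rows) if rows
              else pd.DataFrame(columns=model.reaction_ids))
    diagnostics = (pd.concat(diag) if diag
                   else pd.DataFrame(columns=["n_absent", "congruency"]))
    run = LandscapeRun(matrix=matrix, diagnostics=diagnostics, failures=failures)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_landscape_matrix(run.matrix, out / "landscapes.tsv")
        run.diagnostics.to_csv(out / "landscape_diagnostics.tsv", sep="\t")
        if failures:
            pd.Series(failures, name="reason").to_csv(
                out / "landscape_failures.tsv", sep="\t", index_label="sample_id")
    return run


@dataclass
class AnalysisReport:
    stratifier: PoorPrognosisStratifier
    exit_code: int

    @property
    def poor_cluster(self) -> int | None:
        return self.stratifier.poor_cluster_


def run_analysis(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Cohort analysis of a landscape matrix against survival records.

    Writes cluster assignments, per-cluster KM curve points, log-rank
    summary, DAR table and the DAP report, plus a run log with every
    threshold and seed.  Raises ValidationError when a sample in the
    matrix lacks a survival record (named in the message).
    """
    missing = matrix.index.difference(survival.index)
    if len(missing):
        raise ValidationError(
            f"missing survival record for sample(s): {', '.join(map(str, missing[:5]))}")
    survival = survival.loc[matrix.index]

    strat = PoorPrognosisStratifier(
        k_range=config.k_range, restarts=config.restarts, seed=config.seed,
        dar_alpha=config.dar_alpha)
    strat.fit(matrix, survival)
    exit_code = EXIT_OK if strat.poor_cluster_ is not None else EXIT_NO_CLUSTER
    report = AnalysisReport(stratifier=strat, exit_code=exit_code)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sel = strat.selection_
        assignment = sel.assignments[strat.k_]
        assignment.labels.to_csv(out / "clusters.tsv", sep="\t",
                                 index_label="sample_id")
        summary = sel.summaries[strat.k_]
        curves = pd.concat(
            {c: df for c, df in summary.curves.items()}, names=["cluster", "row"]
        ).reset_index(level="cluster").reset_index(drop=True)
        curves.to_csv(out / "km_curves.tsv", sep="\t", index=False)
        pd.DataFrame({
            "k": list(sel.p_by_k),
            "overall_logrank_p": list(sel.p_by_k.values()),
        }).to_csv(out / "logrank_by_k.tsv", sep="\t", index=False)
        if strat.dars_ is not None:
            strat.dars_.to_csv(out / "dars.tsv", sep="\t", index=False)
            strat.report_.to_csv(out / "daps.tsv", sep="\t", index=False)
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"timestamp={time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
            fh.write(f"alpha_detection={config.alpha_detection}\n")
            fh.write(f"zero_tol={config.zero_tol}\n")
            fh.write(f"dar_alpha={config.dar_alpha}\n")
            fh.write(f"k_range={','.join(map(str, config.k_range))}\n")
            fh.write(f"restarts={config.restarts}\n")
            fh.write(f"seed={config.seed}\n")
            fh.write(f"selected_k={strat.k_}\n")
            fh.write(f"overall_logrank_p={strat.logrank_p_:.6g}\n")
            fh.write(f"poor_cluster={strat.poor_cluster_}\n")
            fh.write(f"n_variable_reactions={len(strat.variable_reactions_)}\n")
    return report


def run_all(
    model: MetabolicModel,
    detection: pd.DataFrame,
    survival: pd.DataFrame,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> tuple[LandscapeRun, AnalysisReport]:
    """Landscapes then analysis; returns both stage results."""
    run = run_landscapes(model, detection, config, out_dir=out_dir)
    report = run_analysis(run.matrix, survival, config, out_dir=out_dir)
    if not run.ok:
        report.exit_code = EXIT_HARD
    return run, report
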