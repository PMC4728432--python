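"""Presence/absence calls and transcript-derived reaction states.

Array platforms report a per-transcript detection p-value: small values
mean the transcript is reliably detected.  A gene is called *present*
when its detection p-value is strictly below ``alpha`` (default 0.01).
Absence calls, propagated through GPR rules, mark reactions whose enzyme
cannot be formed; everything else — including reactions without a GPR and
reactions whose genes were never measured — stays unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .gpr import evaluate_gpr
from .model import MetabolicModel

__all__ = ["DetectionSample", "ReactionStateVector", "call_presence", "reaction_states"]

DETECTION_ALPHA = 0.01

ABSENT = -1
PRESENT = 0


@dataclass
class DetectionSample:
    """Per-sample transcript detection p-values (gene id -> p)."""

    sample_id: str
    detection_p: dict[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, p in self.detection_p.items() if not (0.0 <= p <= 1.0)]
        if bad:
            raise ValidationError(
                f"sample {self.sample_id!r}: detection p outside [0,1] for {bad[:5]}")


@dataclass
class ReactionStateVector:
    """Transcript-derived per-reaction states over model reaction order.

    ``states[j]`` is -1 (enzyme absent by transcript evidence) or 0
    (present/unknown) for the j-th model reaction.
    """

    sample_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (ABSENT, PRESENT)).all():
            raise ValidationError("reaction states must be -1 or 0")

    def absent_ids(self, model: MetabolicModel) -> list[str]:
        if len(self.states) != len(model.reactions):
            raise ValidationError("state vector length does not match model")
        return [rid for rid, s in zip(model.reaction_ids, self.states) if s == ABSENT]


def call_presence(
    detection_p: Mapping[str, float], alpha: float = DETECTION_ALPHA
) -> dict[str, bool]:
    """Presence calls: gene present iff detection p-value < alpha (strict).

    A boundary value p == alpha is therefore called absent.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0,1), got {alpha}")
    calls: dict[str, bool] = {}
    for gene, p in detection_p.items():
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"detection p for gene {gene!r} outside [0,1]: {p}")
        calls[gene] = p < alpha
    return calls


def reaction_states(
    model: MetabolicModel, calls: Mapping[str, bool], sample_id: str = ""
) -> ReactionStateVector:
    """Map gene presence calls to per-reaction states via GPR rules.

    A reaction is -1 iff it has a GPR and that rule evaluates to absent
    with unmeasured genes defaulting to present; reactions without a GPR
    are never constrained (state 0).
    """
    states = np.zeros(len(model.reactions), dtype=np.int8)
    for j, rxn in enumerate(model.reactions):
        if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, calls, default_present=True):
            states[j] = ABSENT
    return ReactionStateVector(sample_id=sample_id, states=states)
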