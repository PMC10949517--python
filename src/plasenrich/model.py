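"""Closed-form prediction of adaptive-sampling enrichment.

The model treats each pore as a renewal process.  Every cycle starts
with a capture dead time, then a molecule is drawn from the library —
plasmid with read-level probability rho (derived from the base-level
plasmid abundance and the class mean read lengths).  On the control half
the molecule is always sequenced to completion.  On the adaptive-
sampling half a rejection decision falls after ``decision_time``
seconds: chromosomal molecules are rejected (unless a false accept
fires) and plasmid molecules are kept (unless a false rejection fires,
e.g. because the read prefix falls in a chromosome-identical region).  A
rejected molecule still leaves its prefix of ``decision_time * speed``
bases in the basecalled output when ``credit_rejected_prefix`` is on.

Expected base output per unit time follows from per-cycle expectations,
and the predicted enrichment factors are ratios of those rates between
the two halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class ModelParams:
    """Inputs of the analytic enrichment model.

    Defaults follow the standard nanopore operating point: 420 bp/s
    sequencing speed, 0.5 s capture time and a 1 s rejection decision.
    ``abundance_bases`` is the plasmid share of sequenced bases in the
    control composition (per sample); mean read lengths are per class.
    """

    abundance_bases: float
    speed: float = 420.0
    capture_time: float = 0.5
    decision_time: float = 1.0
    mean_len_plasmid: float = 4000.0
    mean_len_chromosome: float = 4000.0
    false_reject_rate: float = 0.0
    false_accept_rate: float = 0.0
    credit_rejected_prefix: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.abundance_bases < 1.0:
            raise ValueError("abundance_bases must be in the open interval (0, 1)")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.capture_time < 0 or self.decision_time < 0:
            raise ValueError("times must be >= 0")
        if self.mean_len_plasmid <= 0 or self.mean_len_chromosome <= 0:
            raise ValueError("mean read lengths must be positive")
        for rate in (self.false_reject_rate, self.false_accept_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("classification error rates must be in [0, 1]")


@dataclass(frozen=True)
class ModelPrediction:
    """Model outputs: predicted composition and enrichment factors."""

    enrichment_composition: float
    enrichment_yield: float
    composition_as: float
    read_fraction_plasmid: float


def base_to_read_fraction(
    abundance_bases: float, mean_len_plasmid: float, mean_len_chromosome: float
) -> float:
    """Convert a base-level plasmid abundance to a read-level fraction.

    Solves ``p = rho*L_p / (rho*L_p + (1-rho)*L_c)`` for rho, giving the
    probability that a randomly captured molecule is a plasmid when the
    base-level plasmid share is ``p``.
    """
    if not 0.0 < abundance_bases < 1.0:
        raise ValueError("abundance_bases must be in (0, 1)")
    if mean_len_plasmid <= 0 or mean_len_chromosome <= 0:
        raise ValueError("mean lengths must be positive")
    p = abundance_bases
    return (p * mean_len_chromosome) / (
        p * mean_len_chromosome + (1.0 - p) * mean_len_plasmid
    )


def expected_cycle_times(params: ModelParams) -> tuple[float, float]:
    """Expected seconds per capture cycle on the (AS, control) halves."""
    rho = base_to_read_fraction(
        params.abundance_bases, params.mean_len_plasmid, params.mean_len_chromosome
    )
    s = params.speed
    d = params.decision_time
    time_as = params.capture_time + rho * (
        (1.0 - params.false_reject_rate) * params.mean_len_plasmid / s
        + params.false_reject_rate * d
    ) + (1.0 - rho) * (
        params.false_accept_rate * params.mean_len_chromosome / s
        + (1.0 - params.false_accept_rate) * d
    )
    mean_len = rho * params.mean_len_plasmid + (1 - rho) * params.mean_len_chromosome
    time_ctrl = params.capture_time + mean_len / s
    return time_as, time_ctrl


def predict(params: ModelParams) -> ModelPrediction:
    """Predicted enrichment factors for one sample.

    ``enrichment_composition`` is the predicted AS plasmid base fraction
    divided by the control fraction (= ``abundance_bases`` by
    construction); ``enrichment_yield`` is the ratio of expected plasmid
    base production rates between the AS and control halves.
    """
    p = params.abundance_bases
    rho = base_to_read_fraction(
        p, params.mean_len_plasmid, params.mean_len_chromosome
    )
    s = params.speed
    d = params.decision_time
    fr = params.false_reject_rate
    fa = params.false_accept_rate
    prefix = d * s if params.credit_rejected_prefix else 0.0

    # expected bases and occupancy per capture cycle, AS half
    pl_bases_as = rho * ((1.0 - fr) * params.mean_len_plasmid + fr * prefix)
    ch_bases_as = (1.0 - rho) * (
        fa * params.mean_len_chromosome + (1.0 - fa) * prefix
    )
    time_as = params.capture_time + rho * (
        (1.0 - fr) * params.mean_len_plasmid / s + fr * d
    ) + (1.0 - rho) * (fa * params.mean_len_chromosome / s + (1.0 - fa) * d)

    # control half: everything is sequenced to completion
    pl_bases_ctrl = rho * params.mean_len_plasmid
    mean_len = rho * params.mean_len_plasmid + (1.0 - rho) * params.mean_len_chromosome
    time_ctrl = params.capture_time + mean_len / s

    total_as = pl_bases_as + ch_bases_as
    composition_as = pl_bases_as / total_as if total_as > 0 else float("nan")
    enrichment_composition = composition_as / p
    enrichment_yield = (pl_bases_as / time_as) / (pl_bases_ctrl / time_ctrl)
    return ModelPrediction(
        enrichment_composition=enrichment_composition,
        enrichment_yield=enrichment_yield,
        composition_as=composition_as,
        read_fraction_plasmid=rho,
    )


def pearson_correlation(
    observed: Sequence[float], predicted: Sequence[float]
) -> float:
    """Product-moment correlation of observed vs predicted factors.

    Returns ``nan`` when either vector has zero variance; raises for
    mismatched or too-short inputs.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and predicted must have equal length")
    if x.size < 2:
        raise ValueError("need at least two points for a correlation")
    if math.isclose(float(np.var(x)), 0.0) or math.isclose(float(np.var(y)), 0.0):
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
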