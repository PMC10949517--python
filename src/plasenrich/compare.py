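"""Cross-validation of the analytic model against the event simulator.

The closed-form renewal model and the discrete-event simulator describe
the same process, so on a run with pore death disabled their composition
and enrichment numbers must agree up to Monte-Carlo error.  This module
runs that comparison: it simulates the flow cell implied by a set of
:class:`~plasenrich.model.ModelParams`, splits the channels into batches
to estimate standard errors, and reports z-scores of the simulated
statistics against the model predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, ModelPrediction, expected_cycle_times, predict
from .records import Region, RepliconClass
from .simulate import (
    NO_PORE_DEATH,
    FlowCellConfig,
    LatencySpec,
    SampleMix,
    SampleSpec,
    simulate_run,
)


def flowcell_for_params(
    params: ModelParams, channels: int = 32, run_hours: float = 6.0
) -> FlowCellConfig:
    """Flow cell matching the model's timing, with pore death off."""
    return FlowCellConfig(
        channels_as=channels,
        channels_control=channels,
        speed=params.speed,
        capture_time=params.capture_time,
        decision_latency=LatencySpec("constant", mean=max(params.decision_time, 1e-9)),
        run_hours=run_hours,
        channel_lifetime=NO_PORE_DEATH,
    )


def mix_for_params(params: ModelParams) -> SampleMix:
    """Single-sample library matching the model's mixture.

    Read lengths are lognormal with sd = 0.75 * mean, the package's
    default heavy-tailed nanopore length profile; the model only sees
    the means, so the comparison also exercises that reduction.
    """
    from .simulate import LengthSpec

    return SampleMix(
        samples=(
            SampleSpec(
                name="sample1",
                barcode="RBK01",
                plasmid_abundance=params.abundance_bases,
                length_plasmid=LengthSpec(
                    mean=params.mean_len_plasmid, sd=0.75 * params.mean_len_plasmid
                ),
                length_chromosome=LengthSpec(
                    mean=params.mean_len_chromosome,
                    sd=0.75 * params.mean_len_chromosome,
                ),
                shared_region_fraction=params.false_reject_rate,
                classifier_false_accept=params.false_accept_rate,
            ),
        )
    )


@dataclass
class AgreementResult:
    """Simulated statistics with batch-based standard errors and z-scores."""

    prediction: ModelPrediction
    n_reads: int
    composition_as: float
    composition_as_se: float
    enrichment_composition: float
    enrichment_composition_se: float
    enrichment_yield: float
    enrichment_yield_se: float

    def zscores(self) -> dict[str, float]:
        return {
            "composition_as": (self.composition_as - self.prediction.composition_as)
            / self.composition_as_se,
            "enrichment_composition": (
                self.enrichment_composition - self.prediction.enrichment_composition
            )
            / self.enrichment_composition_se,
            "enrichment_yield": (
                self.enrichment_yield - self.prediction.enrichment_yield
            )
            / self.enrichment_yield_se,
        }

    def max_abs_z(self) -> float:
        return max(abs(z) for z in self.zscores().values())


def model_simulator_agreement(
    params: ModelParams,
    seed: int,
    channels: int = 32,
    run_hours: float | None = None,
    n_batches: int = 16,
    target_reads: int = 120_000,
) -> AgreementResult:
    """Simulate the run implied by ``params`` and compare with ``predict``.

    Channels are grouped into ``n_batches`` disjoint batches, each with
    the same number of AS and control channels; the per-batch statistics
    give the standard error of the simulated mean.  When ``run_hours``
    is not given, the run length is sized from the expected cycle times
    so the whole flow cell produces about ``target_reads`` reads.
    """
    if channels % n_batches != 0:
        raise ValueError("channels must be divisible by n_batches")
    if run_hours is None:
        time_as, time_ctrl = expected_cycle_times(params)
        rate = channels * (1.0 / time_as + 1.0 / time_ctrl)  # reads per second
        run_hours = target_reads / rate / 3600.0
    prediction = predict(params)
    flowcell = flowcell_for_params(params, channels=channels, run_hours=run_hours)
    mix = mix_for_params(params)
    result = simulate_run(flowcell, mix, seed)
    reads = result.reads

    plasmid = reads["replicon_class"] == RepliconClass.PLASMID.value
    is_as = reads["region"] == Region.AS.value
    channel = reads["channel"].to_numpy()
    lengths = reads["length"].to_numpy(dtype=float)

    comp_as, enr_comp, enr_yield = [], [], []
    for b in range(n_batches):
        in_batch_as = is_as & (((channel - 1) % n_batches) == b)
        in_batch_ctrl = (~is_as) & (((channel - flowcell.channels_as - 1) % n_batches) == b)
        pl_as = lengths[(in_batch_as & plasmid).to_numpy()].sum()
        ch_as = lengths[(in_batch_as & ~plasmid).to_numpy()].sum()
        pl_ct = lengths[(in_batch_ctrl & plasmid).to_numpy()].sum()
        ch_ct = lengths[(in_batch_ctrl & ~plasmid).to_numpy()].sum()
        c_as = pl_as / (pl_as + ch_as)
        c_ct = pl_ct / (pl_ct + ch_ct)
        comp_as.append(c_as)
        enr_comp.append(c_as / c_ct)
        enr_yield.append(pl_as / pl_ct)

    def mean_se(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))

    c_mean, c_se = mean_se(comp_as)
    ec_mean, ec_se = mean_se(enr_comp)
    ey_mean, ey_se = mean_se(enr_yield)
    return AgreementResult(
        prediction=prediction,
        n_reads=len(reads),
        composition_as=c_mean,
        composition_as_se=c_se,
        enrichment_composition=ec_mean,
        enrichment_composition_se=ec_se,
        enrichment_yield=ey_mean,
        enrichment_yield_se=ey_se,
    )
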