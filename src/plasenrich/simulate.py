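"""Discrete-event simulation of a split flow cell.

The simulator emulates a run in which the first block of channels
performs adaptive sampling (AS) and the remaining channels sequence
normally.  Each channel alternates capture dead time and sequencing:
a molecule is drawn from the barcoded sample mix (sample by library
share, class by the read-level plasmid fraction), its length comes from
a per-class distribution, and on the AS half a rejection decision falls
after a configurable latency.  Chromosomal molecules are rejected unless
a classifier false accept fires; plasmid molecules are falsely rejected
with the probability that their prefix falls in a chromosome-identical
region (``shared_region_fraction``).  A rejected molecule leaves a
prefix of ``latency * speed`` bases in the output.  Channels optionally
die with exponentially distributed lifetimes, with a multiplicative
hazard factor on the AS half.

No sequence content is simulated; alignments for downstream depth and
forensics analyses are synthesised geometrically from the ground truth
(:func:`synthesize_alignments`, :func:`forensic_alignments`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import base_to_read_fraction
from .records import (
    Alignment,
    ReadRecord,
    Region,
    Replicon,
    RepliconClass,
    RepliconTable,
    frame_to_records,
)

STANDARD_SPEED = 420.0  # bases per second
STANDARD_CAPTURE_TIME = 0.5  # seconds


@dataclass(frozen=True)
class LatencySpec:
    """Distribution of the rejection-decision latency (seconds).

    ``constant`` gives a fixed latency; ``lognormal`` is parametrised by
    its mean and standard deviation in seconds.  Rejected reads appear in
    the output with ``latency * speed`` bases, so the latency mean sets
    the mean rejected-read length.
    """

    family: str = "constant"
    mean: float = 1.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("constant", "lognormal"):
            raise ValueError(f"unknown latency family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("latency mean must be positive")
        if self.sd < 0:
            raise ValueError("latency sd must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "constant" or self.sd == 0:
            return np.full(n, self.mean)
        sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)


#: Latency presets emulating the two rejection tool behaviours observed in
#: practice: a fast mapper-based rejector (mean rejected read ~520 bp at
#: 420 bp/s) and a slower k-mer-based one (mean ~848 bp).
LATENCY_PRESETS: dict[str, LatencySpec] = {
    "minknow": LatencySpec("lognormal", mean=520.0 / STANDARD_SPEED,
                           sd=(520.0 / STANDARD_SPEED) / 3.0),
    "readbouncer": LatencySpec("lognormal", mean=848.0 / STANDARD_SPEED,
                               sd=(848.0 / STANDARD_SPEED) / 3.0),
}


@dataclass(frozen=True)
class LengthSpec:
    """Read-length distribution (bases) for one replicon class."""

    family: str = "lognormal"
    mean: float = 4000.0
    sd: float = 3000.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown length family {self.family!r}")
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("length mean and sd must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            raw = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        else:
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            raw = rng.gamma(shape, scale, size=n)
        return np.maximum(1, np.rint(raw)).astype(np.int64)


@dataclass(frozen=True)
class ChannelLifetime:
    """Pore-death model: exponential channel lifetimes or none."""

    family: str = "exponential"
    mean_seconds: float = 86400.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "none"):
            raise ValueError(f"unknown lifetime family {self.family!r}")
        if self.family == "exponential" and self.mean_seconds <= 0:
            raise ValueError("lifetime mean must be positive")

    def draw(self, rng: np.random.Generator, hazard_factor: float = 1.0) -> float:
        if self.family == "none":
            return math.inf
        return float(rng.exponential(self.mean_seconds / hazard_factor))


NO_PORE_DEATH = ChannelLifetime(family="none")


@dataclass(frozen=True)
class FlowCellConfig:
    """Flow-cell layout and timing parameters.

    Defaults mirror a standard half-and-half MinION setup: adaptive
    sampling on channels 1–256, control on 257–512, 420 bp/s, 0.5 s
    capture time, constant 1 s decision latency, 24 h run.
    """

    channels_as: int = 256
    channels_control: int = 256
    speed: float = STANDARD_SPEED
    capture_time: float = STANDARD_CAPTURE_TIME
    decision_latency: LatencySpec = field(default_factory=LatencySpec)
    run_hours: float = 24.0
    channel_lifetime: ChannelLifetime = field(default_factory=ChannelLifetime)
    as_hazard_factor: float = 1.0
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.channels_as < 1 or self.channels_control < 1:
            raise ValueError("channel counts must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.capture_time < 0:
            raise ValueError("capture_time must be >= 0")
        if self.run_hours <= 0:
            raise ValueError("run_hours must be positive")
        if self.as_hazard_factor <= 0:
            raise ValueError("as_hazard_factor must be positive")

    @property
    def run_seconds(self) -> float:
        return self.run_hours * 3600.0

    @property
    def region_boundary(self) -> int:
        return self.channels_as


@dataclass(frozen=True)
class SampleSpec:
    """One barcoded bacterial sample in the pooled library.

    ``plasmid_abundance`` is the plasmid share of bases within the
    sample (the control-composition abundance); ``library_fraction`` is
    the sample's base share of the whole pool.  The default abundance of
    5% represents a typical low-abundance plasmid; chromosome and
    plasmid sizes default to mid-range bacterial values.
    ``shared_region_fraction`` is the probability that a plasmid read's
    prefix falls in a chromosome-identical region and is therefore
    falsely rejected.
    """

    name: str
    barcode: str
    plasmid_abundance: float = 0.05
    library_fraction: float = 1.0
    length_plasmid: LengthSpec = field(default_factory=LengthSpec)
    length_chromosome: LengthSpec = field(default_factory=LengthSpec)
    chromosome_length: int = 3_000_000
    plasmid_lengths: tuple[int, ...] = (80_000,)
    shared_region_fraction: float = 0.0
    shared_region_span: Optional[tuple[int, int]] = None
    classifier_false_accept: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.plasmid_abundance < 1.0:
            raise ValueError("plasmid_abundance must be in (0, 1)")
        if not 0.0 < self.library_fraction <= 1.0:
            raise ValueError("library_fraction must be in (0, 1]")
        if not 0.0 <= self.shared_region_fraction <= 1.0:
            raise ValueError("shared_region_fraction must be in [0, 1]")
        if not 0.0 <= self.classifier_false_accept <= 1.0:
            raise ValueError("classifier_false_accept must be in [0, 1]")
        if self.chromosome_length < 1 or any(l < 1 for l in self.plasmid_lengths):
            raise ValueError("replicon lengths must be positive")
        if not self.plasmid_lengths:
            raise ValueError("a sample needs at least one plasmid contig")
        if self.shared_region_span is not None:
            lo, hi = self.shared_region_span
            if not (0 <= lo < hi <= self.chromosome_length):
                raise ValueError("shared_region_span outside the chromosome")

    @property
    def read_fraction_plasmid(self) -> float:
        return base_to_read_fraction(
            self.plasmid_abundance, self.length_plasmid.mean, self.length_chromosome.mean
        )

    @property
    def mean_read_length(self) -> float:
        rho = self.read_fraction_plasmid
        return rho * self.length_plasmid.mean + (1 - rho) * self.length_chromosome.mean

    def chromosome_contig(self) -> str:
        return f"{self.name}_chromosome"

    def plasmid_contigs(self) -> list[str]:
        return [f"{self.name}_plasmid{i + 1}" for i in range(len(self.plasmid_lengths))]

    def resolved_shared_span(self) -> tuple[int, int]:
        """Chromosome interval that is plasmid-identical.

        Explicit span if configured; otherwise a centred interval of
        length ``shared_region_fraction * total plasmid length``
        (minimum 200 bp), mimicking an insertion-sequence style locus.
        """
        if self.shared_region_span is not None:
            return self.shared_region_span
        length = max(200, round(self.shared_region_fraction * sum(self.plasmid_lengths)))
        length = min(length, self.chromosome_length)
        start = max(0, (self.chromosome_length - length) // 2)
        return (start, start + length)


@dataclass(frozen=True)
class SampleMix:
    """The pooled library: one or more barcoded samples."""

    samples: tuple[SampleSpec, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("mix must contain at least one sample")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        barcodes = [s.barcode for s in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        total = sum(s.library_fraction for s in self.samples)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"sample library fractions must sum to 1, got {total:.6f}"
            )

    def replicon_table(self) -> RepliconTable:
        entries: dict[str, Replicon] = {}
        for spec in self.samples:
            entries[spec.chromosome_contig()] = Replicon(
                spec.name, RepliconClass.CHROMOSOME, spec.chromosome_length
            )
            for contig, length in zip(spec.plasmid_contigs(), spec.plasmid_lengths):
                entries[contig] = Replicon(spec.name, RepliconClass.PLASMID, length)
        return RepliconTable(entries)

    def by_name(self, name: str) -> SampleSpec:
        for spec in self.samples:
            if spec.name == name:
                return spec
        raise KeyError(name)


def single_sample_mix(**kwargs) -> SampleMix:
    """Convenience constructor for a one-sample library."""
    kwargs.setdefault("name", "sample1")
    kwargs.setdefault("barcode", "RBK01")
    return SampleMix(samples=(SampleSpec(**kwargs),))


#: Columns of the simulated read table (ground-truth columns last).
SIM_COLUMNS = [
    "read_id",
    "channel",
    "region",
    "start_time",
    "duration",
    "length",
    "barcode",
    "replicon_class",
    "sample",
    "rejected",
    "true_sample",
    "true_class",
    "false_rejected",
]


@dataclass
class SimResult:
    """Output of a simulated run.

    ``reads`` carries the ground truth in its assignment columns
    (``replicon_class``/``sample`` are the true values, since every
    simulated molecule originates from a known replicon) plus explicit
    ``true_sample``/``true_class``/``false_rejected`` columns for the
    writers, which emit a truth-free sequencing-summary table.
    """

    reads: pd.DataFrame
    decision_log: pd.DataFrame
    replicon_table: RepliconTable
    flowcell: FlowCellConfig
    mix: SampleMix
    seed: int

    def records(self) -> list[ReadRecord]:
        return frame_to_records(self.reads)

    def decision_pairs(self) -> list[tuple[str, str]]:
        return list(
            zip(self.decision_log["read_id"], self.decision_log["decision"])
        )

    def write_summary(self, path) -> None:
        """Sequencing-summary-style TSV (no ground truth columns)."""
        out = pd.DataFrame(
            {
                "read_id": self.reads["read_id"],
                "channel": self.reads["channel"],
                "start_time": self.reads["start_time"].map("{:.4f}".format),
                "duration": self.reads["duration"].map("{:.4f}".format),
                "sequence_length_template": self.reads["length"],
                "barcode_arrangement": self.reads["barcode"],
            }
        )
        out.to_csv(path, sep="\t", index=False)

    def write_decision_log(self, path) -> None:
        self.decision_log.to_csv(path, sep="\t", index=False)

    def write_truth(self, path) -> None:
        self.reads[
            ["read_id", "true_sample", "true_class", "false_rejected"]
        ].to_csv(path, sep="\t", index=False)


def simulate_run(
    flowcell: FlowCellConfig, mix: SampleMix, seed: int
) -> SimResult:
    """Run the discrete-event simulation; reproducible for a fixed seed."""
    n_samples = len(mix.samples)
    # read-level sampling weights: base share / mean read length
    weights = np.array(
        [s.library_fraction / s.mean_read_length for s in mix.samples]
    )
    weights /= weights.sum()
    rho = np.array([s.read_fraction_plasmid for s in mix.samples])
    srf = np.array([s.shared_region_fraction for s in mix.samples])
    fa = np.array([s.classifier_false_accept for s in mix.samples])
    barcodes = np.array([s.barcode for s in mix.samples])
    names = np.array([s.name for s in mix.samples])

    total_channels = flowcell.channels_as + flowcell.channels_control
    children = np.random.SeedSequence(seed).spawn(total_channels)
    horizon = flowcell.run_seconds
    capture = flowcell.capture_time
    speed = flowcell.speed

    frames: list[pd.DataFrame] = []
    for ch_index in range(total_channels):
        channel = ch_index + 1
        is_as = channel <= flowcell.channels_as
        rng = np.random.default_rng(children[ch_index])
        hazard = flowcell.as_hazard_factor if is_as else 1.0
        end = min(horizon, flowcell.channel_lifetime.draw(rng, hazard))
        if end <= capture:
            continue

        # rough expected cycle length for chunk sizing
        if is_as and flowcell.adaptive:
            approx_cycle = capture + 0.25 * mix.samples[0].mean_read_length / speed \
                + 0.75 * flowcell.decision_latency.mean
        else:
            approx_cycle = capture + mix.samples[0].mean_read_length / speed
        t0 = 0.0
        ch_rows: list[dict[str, np.ndarray]] = []
        while t0 < end:
            m = int((end - t0) / approx_cycle * 1.3) + 32
            m = min(m, 200_000)
            si = rng.integers(0, n_samples, size=m) if n_samples == 1 else \
                rng.choice(n_samples, size=m, p=weights)
            is_pl = rng.random(m) < rho[si]
            lengths = _draw_lengths(rng, mix, si, is_pl)
            if is_as and flowcell.adaptive:
                lat = flowcell.decision_latency.draw(rng, m)
                u = rng.random(m)
                rejected = np.where(is_pl, u < srf[si], u >= fa[si])
                out_len = np.where(
                    rejected,
                    np.maximum(1, np.rint(lat * speed)).astype(np.int64),
                    lengths,
                )
                duration = np.where(rejected, lat, lengths / speed)
            else:
                rejected = np.zeros(m, dtype=bool)
                out_len = lengths
                duration = lengths / speed
            cycle_end = t0 + np.cumsum(capture + duration)
            n_fit = int(np.searchsorted(cycle_end, end, side="right"))
            done = n_fit < m
            starts = cycle_end[:n_fit] - duration[:n_fit]
            keep = {
                "start_time": starts,
                "duration": duration[:n_fit],
                "length": out_len[:n_fit],
                "sample_index": si[:n_fit],
                "is_plasmid": is_pl[:n_fit],
                "rejected": rejected[:n_fit],
            }
            if done:
                # the molecule in the pore at run end is cut short; its
                # decision (if any) had not fired yet, so it is unrejected
                trunc_start = (cycle_end[n_fit - 1] if n_fit else t0) + capture
                avail = end - trunc_start
                trunc_len = int(avail * speed)
                if trunc_len >= 1:
                    keep = {
                        "start_time": np.append(starts, trunc_start),
                        "duration": np.append(duration[:n_fit], avail),
                        "length": np.append(out_len[:n_fit], trunc_len),
                        "sample_index": np.append(si[:n_fit], si[n_fit]),
                        "is_plasmid": np.append(is_pl[:n_fit], is_pl[n_fit]),
                        "rejected": np.append(rejected[:n_fit], False),
                    }
            if len(keep["start_time"]) > 0:
                ch_rows.append(keep)
            if done:
                break
            t0 = float(cycle_end[-1])

        if not ch_rows:
            continue
        merged = {
            key: np.concatenate([rows[key] for rows in ch_rows])
            for key in ch_rows[0]
        }
        n = len(merged["start_time"])
        frame = pd.DataFrame(
            {
                "read_id": [f"r{channel:04d}-{i:06d}" for i in range(n)],
                "channel": np.full(n, channel, dtype=np.int64),
                "region": Region.AS.value if is_as else Region.CONTROL.value,
                "start_time": merged["start_time"],
                "duration": merged["duration"],
                "length": merged["length"].astype(np.int64),
                "barcode": barcodes[merged["sample_index"]],
                "replicon_class": np.where(
                    merged["is_plasmid"],
                    RepliconClass.PLASMID.value,
                    RepliconClass.CHROMOSOME.value,
                ),
                "sample": names[merged["sample_index"]],
                "rejected": merged["rejected"],
                "true_sample": names[merged["sample_index"]],
                "true_class": np.where(
                    merged["is_plasmid"],
                    RepliconClass.PLASMID.value,
                    RepliconClass.CHROMOSOME.value,
                ),
                "false_rejected": merged["is_plasmid"] & merged["rejected"],
            }
        )
        frames.append(frame)

    if frames:
        reads = pd.concat(frames, ignore_index=True)[SIM_COLUMNS]
    else:
        reads = pd.DataFrame(columns=SIM_COLUMNS)
    as_reads = reads[reads["region"] == Region.AS.value]
    decision_log = pd.DataFrame(
        {
            "read_id": as_reads["read_id"],
            "decision": np.where(
                as_reads["rejected"], "unblock", "stop_receiving"
            ),
        }
    ).reset_index(drop=True)
    return SimResult(
        reads=reads,
        decision_log=decision_log,
        replicon_table=mix.replicon_table(),
        flowcell=flowcell,
        mix=mix,
        seed=seed,
    )


def _draw_lengths(
    rng: np.random.Generator,
    mix: SampleMix,
    sample_index: np.ndarray,
    is_plasmid: np.ndarray,
) -> np.ndarray:
    lengths = np.empty(len(sample_index), dtype=np.int64)
    for i, spec in enumerate(mix.samples):
        for plasmid, dist in ((True, spec.length_plasmid), (False, spec.length_chromosome)):
            mask = (sample_index == i) & (is_plasmid == plasmid)
            k = int(mask.sum())
            if k:
                lengths[mask] = dist.draw(rng, k)
    return lengths


@dataclass
class AuditReport:
    """Conservation check over per-channel schedules."""

    passed: bool
    violations: list[str]
    per_channel: pd.DataFrame


def channel_schedule_audit(
    records,
    capture_time: float = STANDARD_CAPTURE_TIME,
    run_seconds: float = 86400.0,
    tol: float = 1e-6,
) -> AuditReport:
    """Verify per-channel time conservation.

    For every channel, reads must be non-overlapping in time and the
    total busy time ``sum(capture_time + duration)`` must not exceed the
    run duration.
    """
    from .records import records_to_frame

    frame = records_to_frame(records)
    violations: list[str] = []
    rows = []
    for channel, sub in frame.groupby("channel"):
        sub = sub.sort_values("start_time")
        starts = sub["start_time"].to_numpy(dtype=float)
        durations = sub["duration"].to_numpy(dtype=float)
        ends = starts + durations
        busy = float((capture_time + durations).sum())
        if np.any(starts[1:] < ends[:-1] - tol):
            violations.append(f"channel {channel}: overlapping reads")
        if busy > run_seconds + tol:
            violations.append(
                f"channel {channel}: busy {busy:.1f}s exceeds run {run_seconds:.1f}s"
            )
        if np.any(ends > run_seconds + tol):
            violations.append(f"channel {channel}: read ends after run end")
        rows.append(
            {"channel": channel, "n_reads": len(sub), "busy_seconds": busy}
        )
    per_channel = pd.DataFrame(rows, columns=["channel", "n_reads", "busy_seconds"])
    return AuditReport(passed=not violations, violations=violations, per_channel=per_channel)


def synthesize_alignments(result: SimResult, seed: int = 0) -> list[Alignment]:
    """Geometric stand-in alignments for the simulated reads.

    Each read is aligned to its true replicon contig at a uniformly
    random position (multi-plasmid samples choose a plasmid contig with
    probability proportional to contig length).  Spans are clipped to
    the contig; no sequence content is involved.  Synthetic: these are
    not real mappings, they carry the geometry the depth and assignment
    code expects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EC0]))
    table = result.replicon_table
    alignments: list[Alignment] = []
    plasmid_choice: dict[str, tuple[list[str], np.ndarray]] = {}
    for spec in result.mix.samples:
        contigs = spec.plasmid_contigs()
        lens = np.array(spec.plasmid_lengths, dtype=float)
        plasmid_choice[spec.name] = (contigs, lens / lens.sum())
    for row in result.reads.itertuples(index=False):
        sample = row.true_sample
        if row.true_class == RepliconClass.PLASMID.value:
            contigs, probs = plasmid_choice[sample]
            contig = contigs[int(rng.choice(len(contigs), p=probs))]
        else:
            contig = result.mix.by_name(sample).chromosome_contig()
        contig_len = table.contig_length(contig)
        span = min(int(row.length), contig_len)
        tstart = int(rng.integers(0, contig_len - span + 1))
        matching = max(1, int(round(0.95 * span)))
        alignments.append(
            Alignment(
                read_id=row.read_id,
                contig=contig,
                qstart=0,
                qend=int(row.length),
                tstart=tstart,
                tend=tstart + span,
                matching_bases=matching,
                block_length=span,
                mapq=60,
            )
        )
    return alignments


def forensic_alignments(
    result: SimResult, sample: Optional[str] = None, seed: int = 0
) -> list[Alignment]:
    """Map falsely rejected plasmid prefixes onto the shared chromosome locus.

    Emulates re-mapping the falsely rejected plasmid reads against the
    chromosome: each such read's prefix aligns inside the sample's
    chromosome-identical region, so per-base depth piles up there.
    Synthetic placements, seeded for reproducibility.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF03E]))
    alignments: list[Alignment] = []
    mask = result.reads["false_rejected"]
    if sample is not None:
        mask = mask & (result.reads["true_sample"] == sample)
    for row in result.reads[mask].itertuples(index=False):
        spec = result.mix.by_name(row.true_sample)
        lo, hi = spec.resolved_shared_span()
        contig = spec.chromosome_contig()
        read_len = int(row.length)
        start = int(rng.integers(lo, hi))
        end = min(start + read_len, hi, spec.chromosome_length)
        if end <= start:
            end = start + 1
        span = end - start
        alignments.append(
            Alignment(
                read_id=row.read_id,
                contig=contig,
                qstart=0,
                qend=min(read_len, span),
                tstart=start,
                tend=end,
                matching_bases=max(1, int(round(0.95 * span))),
                block_length=span,
                mapq=60,
            )
        )
    return alignments
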