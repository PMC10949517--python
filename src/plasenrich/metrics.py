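"""Time-resolved enrichment statistics for a split flow cell.

All statistics are cumulative: the snapshot at time ``t`` covers every
read whose ``start_time`` is at most ``t``.  The three classical
enrichment factors compare plasmid output between the adaptive-sampling
(AS) and control halves of the flow cell at each time point:

* enrichment by yield      — ratio of cumulative plasmid bases,
* enrichment by reads      — ratio of cumulative plasmid read counts,
* enrichment by depth      — ratio of mean plasmid fold-coverage,

and the compositional enrichment divides the plasmid base *fraction* in
the AS output by that of the control output.  Ratios with a zero
denominator are reported as ``nan`` (not-available) rather than raised,
so that early, sparsely covered time points do not abort an analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import primary_alignments
from .records import (
    Alignment,
    ReadRecord,
    Region,
    RepliconClass,
    RepliconTable,
    records_to_frame,
)

UNDEFINED = float("nan")


def is_undefined(value: float) -> bool:
    """True for the not-available marker returned by ratio metrics."""
    return isinstance(value, float) and math.isnan(value)


def _select(
    frame: pd.DataFrame,
    t: Optional[float] = None,
    region: Optional[Region] = None,
    sample: Optional[str] = None,
    replicon_class: Optional[RepliconClass] = None,
) -> pd.DataFrame:
    mask = pd.Series(True, index=frame.index)
    if t is not None:
        mask &= frame["start_time"] <= t
    if region is not None:
        mask &= frame["region"] == Region(region).value
    if sample is not None:
        mask &= frame["sample"] == sample
    if replicon_class is not None:
        mask &= frame["replicon_class"] == RepliconClass(replicon_class).value
    return frame[mask]


def cumulative_stats(
    records: Sequence[ReadRecord] | pd.DataFrame,
    t: float,
    region: Optional[Region] = None,
    sample: Optional[str] = None,
    replicon_class: Optional[RepliconClass] = None,
) -> tuple[int, int]:
    """Cumulative (bases, reads) up to time ``t`` for a selection.

    A read belongs to the snapshot at ``t`` iff ``start_time <= t``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    sub = _select(records_to_frame(records), t, region, sample, replicon_class)
    return int(sub["length"].sum()), int(len(sub))


def enrichment_ratio(as_value: float, ctrl_value: float) -> float:
    """AS/control ratio with a ``nan`` marker for a zero denominator."""
    if as_value < 0 or ctrl_value < 0:
        raise ValueError("enrichment inputs must be non-negative")
    if ctrl_value == 0 or is_undefined(ctrl_value) or is_undefined(as_value):
        return UNDEFINED
    return as_value / ctrl_value


def enrichment_yield(
    records: Sequence[ReadRecord] | pd.DataFrame,
    t: float,
    sample: Optional[str] = None,
) -> float:
    """Cumulative plasmid bases in AS divided by those in control."""
    bases_as, _ = cumulative_stats(records, t, Region.AS, sample, RepliconClass.PLASMID)
    bases_ctrl, _ = cumulative_stats(
        records, t, Region.CONTROL, sample, RepliconClass.PLASMID
    )
    return enrichment_ratio(bases_as, bases_ctrl)


def enrichment_reads(
    records: Sequence[ReadRecord] | pd.DataFrame,
    t: float,
    sample: Optional[str] = None,
) -> float:
    """Cumulative plasmid read count in AS divided by that in control."""
    _, reads_as = cumulative_stats(records, t, Region.AS, sample, RepliconClass.PLASMID)
    _, reads_ctrl = cumulative_stats(
        records, t, Region.CONTROL, sample, RepliconClass.PLASMID
    )
    return enrichment_ratio(reads_as, reads_ctrl)


def mean_depth(
    alignments: Sequence[Alignment],
    table: RepliconTable,
    sample: str,
    records: Optional[Sequence[ReadRecord] | pd.DataFrame] = None,
    t: Optional[float] = None,
    region: Optional[Region] = None,
) -> float:
    """Mean fold-coverage of a sample's plasmid reference(s).

    Sums the reference spans of each read's primary alignment to any
    plasmid contig of the sample and divides by the total plasmid
    reference length (all plasmid contigs for multi-plasmid samples).
    When ``records`` is given, only reads in the chosen region with
    ``start_time <= t`` contribute.  Spans are taken from the PAF target
    coordinates without CIGAR refinement.
    """
    plasmid_contigs = set(table.contigs_of(sample, RepliconClass.PLASMID))
    total_length = table.plasmid_length(sample)
    if total_length == 0:
        raise ValueError(f"sample {sample!r} has no plasmid reference length")
    allowed: Optional[set[str]] = None
    if records is not None:
        frame = _select(records_to_frame(records), t=t, region=region)
        allowed = set(frame["read_id"])
    covered = 0
    for aln in primary_alignments(list(alignments)).values():
        if aln.contig not in plasmid_contigs:
            continue
        if allowed is not None and aln.read_id not in allowed:
            continue
        covered += aln.ref_span_length
    return covered / total_length


def enrichment_depth(
    alignments: Sequence[Alignment],
    table: RepliconTable,
    sample: str,
    records: Sequence[ReadRecord] | pd.DataFrame,
    t: float,
) -> float:
    """Mean plasmid depth in AS divided by that in control at time ``t``."""
    depth_as = mean_depth(alignments, table, sample, records, t, Region.AS)
    depth_ctrl = mean_depth(alignments, table, sample, records, t, Region.CONTROL)
    return enrichment_ratio(depth_as, depth_ctrl)


def composition(
    records: Sequence[ReadRecord] | pd.DataFrame,
    t: float,
    region: Region,
    sample: Optional[str] = None,
) -> float:
    """Plasmid base fraction of the mapped output at time ``t``.

    Unmapped bases are excluded from the denominator; ``nan`` if no
    mapped bases exist for the selection.
    """
    plasmid, _ = cumulative_stats(records, t, region, sample, RepliconClass.PLASMID)
    chrom, _ = cumulative_stats(records, t, region, sample, RepliconClass.CHROMOSOME)
    if plasmid + chrom == 0:
        return UNDEFINED
    return plasmid / (plasmid + chrom)


def compositional_enrichment(comp_as: float, comp_ctrl: float) -> float:
    """Relative plasmid abundance in AS divided by that in control."""
    if is_undefined(comp_as) or is_undefined(comp_ctrl):
        return UNDEFINED
    return enrichment_ratio(comp_as, comp_ctrl)


def active_channels(
    records: Sequence[ReadRecord] | pd.DataFrame, t: float
) -> dict[Region, int]:
    """Count channels still active at time ``t`` per flow-cell region.

    A channel is active from the run start until it sequences its final
    molecule, provided it sequenced at least one molecule; so it counts
    at ``t`` iff it has any read and its last read starts at or after
    ``t``.
    """
    frame = records_to_frame(records)
    counts = {Region.AS: 0, Region.CONTROL: 0}
    if frame.empty:
        return counts
    last = frame.groupby(["region", "channel"])["start_time"].max()
    for (region, _channel), last_start in last.items():
        if last_start >= t:
            counts[Region(region)] += 1
    return counts


def capture_time_yield_loss(
    extra_reads: int, capture_time: float, speed: float
) -> float:
    """Sequencing capacity (bases) consumed by additional capture events.

    Each extra read sequenced on the AS half costs one capture dead time,
    during which the pore could otherwise have produced
    ``capture_time * speed`` bases.
    """
    if extra_reads < 0 or capture_time < 0 or speed < 0:
        raise ValueError("arguments must be non-negative")
    return extra_reads * capture_time * speed


@dataclass
class EnrichmentSeries:
    """Per-sample cumulative metrics on a regular time grid.

    ``table`` has one row per grid point with yields, read counts,
    depths, compositions and the derived enrichment factors.  Undefined
    ratios are ``nan``.
    """

    sample: str
    table: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    def endpoint(self) -> dict:
        """Metrics of the final grid point (run-end snapshot)."""
        return self.table.iloc[-1].to_dict()

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "sample", self.sample)
        return out


_SERIES_COLUMNS = [
    "time",
    "yield_as_plasmid",
    "yield_ctrl_plasmid",
    "yield_as_chromosome",
    "yield_ctrl_chromosome",
    "reads_as_plasmid",
    "reads_ctrl_plasmid",
    "depth_as_plasmid",
    "depth_ctrl_plasmid",
    "composition_as",
    "composition_ctrl",
    "enrichment_yield",
    "enrichment_reads",
    "enrichment_depth",
    "enrichment_composition",
]


def _cumulative_on_grid(
    starts: np.ndarray, values: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Cumulative sum of ``values`` for events with start <= each grid point."""
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    cumsum = np.concatenate([[0], np.cumsum(values[order])])
    idx = np.searchsorted(starts, grid, side="right")
    return cumsum[idx]


def time_series(
    records: Sequence[ReadRecord] | pd.DataFrame,
    alignments: Optional[Sequence[Alignment]] = None,
    table: Optional[RepliconTable] = None,
    bin_seconds: float = 1800.0,
    horizon: float = 86400.0,
    samples: Optional[Sequence[str]] = None,
) -> dict[str, EnrichmentSeries]:
    """Evaluate all cumulative metrics on the grid ``bin, 2*bin, ..., horizon``.

    With the defaults (30-minute bins over a 24 h run) the grid has 48
    points.  Depth metrics require ``alignments`` and ``table``;
    otherwise the depth columns are ``nan``.
    """
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be positive")
    if horizon < bin_seconds:
        raise ValueError("horizon must be >= bin_seconds")
    n_points = round(horizon / bin_seconds)
    if abs(n_points * bin_seconds - horizon) > 1e-9 * max(horizon, 1.0):
        raise ValueError("horizon must be a positive multiple of bin_seconds")
    grid = np.arange(1, n_points + 1) * bin_seconds

    frame = records_to_frame(records)
    if samples is None:
        samples = sorted(s for s in frame["sample"].dropna().unique())

    depth_spans: dict[str, Alignment] = {}
    if alignments is not None:
        if table is None:
            raise ValueError("depth metrics need a replicon table")
        depth_spans = primary_alignments(list(alignments))
    start_by_read = dict(zip(frame["read_id"], frame["start_time"]))
    region_by_read = dict(zip(frame["read_id"], frame["region"]))

    out: dict[str, EnrichmentSeries] = {}
    for sample in samples:
        cols: dict[str, np.ndarray] = {"time": grid}
        for region in (Region.AS, Region.CONTROL):
            tag = "as" if region is Region.AS else "ctrl"
            for cls in (RepliconClass.PLASMID, RepliconClass.CHROMOSOME):
                sub = _select(frame, None, region, sample, cls)
                starts = sub["start_time"].to_numpy(dtype=float)
                lengths = sub["length"].to_numpy(dtype=float)
                cols[f"yield_{tag}_{cls.value.lower()}"] = _cumulative_on_grid(
                    starts, lengths, grid
                )
                if cls is RepliconClass.PLASMID:
                    cols[f"reads_{tag}_plasmid"] = _cumulative_on_grid(
                        starts, np.ones_like(starts), grid
                    )
            if depth_spans and table is not None:
                plasmid_contigs = set(
                    table.contigs_of(sample, RepliconClass.PLASMID)
                )
                total_len = table.plasmid_length(sample)
                span_starts, span_lengths = [], []
                for aln in depth_spans.values():
                    if aln.contig not in plasmid_contigs:
                        continue
                    if region_by_read.get(aln.read_id) != region.value:
                        continue
                    if aln.read_id not in start_by_read:
                        continue
                    span_starts.append(start_by_read[aln.read_id])
                    span_lengths.append(aln.ref_span_length)
                if total_len > 0:
                    cols[f"depth_{tag}_plasmid"] = (
                        _cumulative_on_grid(
                            np.asarray(span_starts, dtype=float),
                            np.asarray(span_lengths, dtype=float),
                            grid,
                        )
                        / total_len
                    )
                else:
                    cols[f"depth_{tag}_plasmid"] = np.full(n_points, np.nan)
            else:
                cols[f"depth_{tag}_plasmid"] = np.full(n_points, np.nan)

        with np.errstate(divide="ignore", invalid="ignore"):
            cols["enrichment_yield"] = _safe_ratio(
                cols["yield_as_plasmid"], cols["yield_ctrl_plasmid"]
            )
            cols["enrichment_reads"] = _safe_ratio(
                cols["reads_as_plasmid"], cols["reads_ctrl_plasmid"]
            )
            cols["enrichment_depth"] = _safe_ratio(
                cols["depth_as_plasmid"], cols["depth_ctrl_plasmid"]
            )
            comp_as = _safe_ratio(
                cols["yield_as_plasmid"],
                cols["yield_as_plasmid"] + cols["yield_as_chromosome"],
            )
            comp_ctrl = _safe_ratio(
                cols["yield_ctrl_plasmid"],
                cols["yield_ctrl_plasmid"] + cols["yield_ctrl_chromosome"],
            )
            cols["composition_as"] = comp_as
            cols["composition_ctrl"] = comp_ctrl
            cols["enrichment_composition"] = _safe_ratio(comp_as, comp_ctrl)

        out[sample] = EnrichmentSeries(
            sample=sample, table=pd.DataFrame(cols)[_SERIES_COLUMNS]
        )
    return out


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def series_to_tidy(series: dict[str, EnrichmentSeries]) -> pd.DataFrame:
    """Concatenate per-sample series into one tidy table."""
    if not series:
        return pd.DataFrame(columns=["sample"] + _SERIES_COLUMNS)
    return pd.concat(
        [s.to_frame() for s in series.values()], ignore_index=True
    )
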