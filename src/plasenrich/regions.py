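"""False-rejection forensics.

When a target (plasmid) read is rejected by adaptive sampling, the
usual cause is a chromosome-identical stretch — an insertion sequence,
mobile element or shared gene — covering the read prefix used for the
rejection decision.  This module extracts the falsely rejected plasmid
reads, builds a per-base depth profile of their alignments against the
chromosome, and reports the maximal intervals whose depth clears a
threshold (default >= 10-fold), which localises the shared regions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    Alignment,
    DepthInterval,
    ReadRecord,
    RepliconClass,
    records_to_frame,
)


def select_false_rejected(
    records: Sequence[ReadRecord] | pd.DataFrame, sample: Optional[str] = None
) -> pd.DataFrame:
    """Reads assigned to a plasmid but ended by a rejection decision."""
    frame = records_to_frame(records)
    mask = (frame["replicon_class"] == RepliconClass.PLASMID.value) & frame[
        "rejected"
    ].astype(bool)
    if sample is not None:
        mask &= frame["sample"] == sample
    return frame[mask].reset_index(drop=True)


def depth_vector(
    alignments: Sequence[Alignment], contig: str, contig_length: int
) -> np.ndarray:
    """Per-base alignment depth over one contig.

    Position ``i`` counts the alignments (restricted to ``contig``)
    whose reference span contains ``i``.
    """
    if contig_length < 1:
        raise ValueError("contig_length must be positive")
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for aln in alignments:
        if aln.contig != contig:
            continue
        if aln.tend > contig_length:
            raise ValueError(
                f"alignment span [{aln.tstart}, {aln.tend}) exceeds contig "
                f"length {contig_length}"
            )
        diff[aln.tstart] += 1
        diff[aln.tend] -= 1
    return np.cumsum(diff[:-1])


def high_depth_regions(
    depth: np.ndarray,
    min_depth: float = 10,
    min_length: int = 1,
    max_gap: int = 0,
    contig: str = "",
) -> list[DepthInterval]:
    """Maximal runs of consecutive positions with depth >= ``min_depth``.

    Runs shorter than ``min_length`` are dropped.  With ``max_gap > 0``,
    neighbouring runs separated by a sub-threshold gap shorter than
    ``max_gap`` positions are joined first (the merged interval then
    contains positions below the threshold; mean/max depth are computed
    over the merged span).  The threshold is inclusive.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = np.asarray(depth)
    above = depth >= min_depth
    if not above.any():
        return []
    # boundaries of maximal runs
    padded = np.concatenate([[False], above, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[0::2], changes[1::2]

    if max_gap > 0:
        merged_starts, merged_ends = [int(starts[0])], [int(ends[0])]
        for s, e in zip(starts[1:], ends[1:]):
            if int(s) - merged_ends[-1] < max_gap:
                merged_ends[-1] = int(e)
            else:
                merged_starts.append(int(s))
                merged_ends.append(int(e))
        starts, ends = merged_starts, merged_ends

    intervals = []
    for s, e in zip(starts, ends):
        s, e = int(s), int(e)
        if e - s < min_length:
            continue
        window = depth[s:e]
        intervals.append(
            DepthInterval(
                contig=contig,
                start=s,
                end=e,
                mean_depth=float(window.mean()),
                max_depth=float(window.max()),
            )
        )
    return intervals


def intervals_to_frame(intervals: Sequence[DepthInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [iv.contig for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "length": [iv.length for iv in intervals],
            "mean_depth": [iv.mean_depth for iv in intervals],
            "max_depth": [iv.max_depth for iv in intervals],
        }
    )


def write_bed(intervals: Sequence[DepthInterval], path: str | Path) -> None:
    """Write intervals as 0-based half-open BED3."""
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
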