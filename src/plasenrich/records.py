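"""Core record types shared across the package.

A sequencing run is represented as a collection of :class:`ReadRecord`
objects — one per sequenced molecule — together with a
:class:`RepliconTable` mapping reference contigs to (sample, replicon
class, length), and a set of :class:`Alignment` objects parsed from PAF
output.  Most numeric work happens on the tabular form returned by
:func:`records_to_frame`; the dataclasses are the row-level contract.

Conventions: all times are seconds since run start, all coordinates are
0-based half-open, and all lengths are bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd


class Region(str, Enum):
    """Flow-cell half: adaptive sampling (AS) or standard sequencing."""

    AS = "AS"
    CONTROL = "CONTROL"


class RepliconClass(str, Enum):
    """Replicon assignment of a read (UNMAPPED until assigned)."""

    PLASMID = "PLASMID"
    CHROMOSOME = "CHROMOSOME"
    UNMAPPED = "UNMAPPED"


@dataclass
class ReadRecord:
    """One sequenced read from a split flow cell.

    ``rejected`` marks reads that were ended by an adaptive-sampling
    unblock decision; their already-sequenced prefix still appears in the
    basecalled output, so they carry a positive ``length``.
    """

    read_id: str
    channel: int
    region: Region
    start_time: float
    duration: float
    length: int
    barcode: str = ""
    replicon_class: RepliconClass = RepliconClass.UNMAPPED
    sample: Optional[str] = None
    rejected: bool = False

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        self.replicon_class = RepliconClass(self.replicon_class)
        if self.channel < 1:
            raise ValueError(f"channel must be positive, got {self.channel}")
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.replicon_class is RepliconClass.UNMAPPED and self.sample is not None:
            raise ValueError("unmapped reads cannot carry a sample assignment")


@dataclass(frozen=True)
class Alignment:
    """A single PAF alignment record (coordinates 0-based half-open)."""

    read_id: str
    contig: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    matching_bases: int
    block_length: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError(f"invalid query span [{self.qstart}, {self.qend})")
        if not (0 <= self.tstart < self.tend):
            raise ValueError(f"invalid target span [{self.tstart}, {self.tend})")
        if self.matching_bases > self.block_length:
            raise ValueError("matching_bases cannot exceed block_length")
        if not (0 <= self.mapq <= 255):
            raise ValueError(f"mapq out of range: {self.mapq}")

    @property
    def ref_span_length(self) -> int:
        return self.tend - self.tstart


@dataclass(frozen=True)
class Replicon:
    """One reference contig: which sample it belongs to, and what it is."""

    sample: str
    replicon_class: RepliconClass
    length: int

    def __post_init__(self) -> None:
        if self.replicon_class is RepliconClass.UNMAPPED:
            raise ValueError("a reference contig must be PLASMID or CHROMOSOME")
        if self.length < 1:
            raise ValueError("contig length must be positive")


class RepliconTable:
    """Lookup from contig name to (sample, class, length).

    Every sample must contribute at least one chromosome contig; plasmid
    contigs are optional per sample (but obviously required for any
    enrichment analysis to be meaningful).
    """

    def __init__(self, entries: Mapping[str, Replicon]):
        self.entries: dict[str, Replicon] = dict(entries)
        by_sample: dict[str, set[RepliconClass]] = {}
        for contig, rep in self.entries.items():
            by_sample.setdefault(rep.sample, set()).add(rep.replicon_class)
        for sample, classes in by_sample.items():
            if RepliconClass.CHROMOSOME not in classes:
                raise ValueError(f"sample {sample!r} has no chromosome contig")

    def __contains__(self, contig: str) -> bool:
        return contig in self.entries

    def __getitem__(self, contig: str) -> Replicon:
        return self.entries[contig]

    def __len__(self) -> int:
        return len(self.entries)

    def samples(self) -> list[str]:
        return sorted({rep.sample for rep in self.entries.values()})

    def contigs_of(
        self, sample: str, replicon_class: Optional[RepliconClass] = None
    ) -> list[str]:
        return sorted(
            contig
            for contig, rep in self.entries.items()
            if rep.sample == sample
            and (replicon_class is None or rep.replicon_class == replicon_class)
        )

    def plasmid_length(self, sample: str) -> int:
        """Summed length of all plasmid contigs of a sample."""
        return sum(
            self.entries[c].length
            for c in self.contigs_of(sample, RepliconClass.PLASMID)
        )

    def contig_length(self, contig: str) -> int:
        return self.entries[contig].length


#: Column order of the tabular read representation.
READ_COLUMNS = [
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
]


def records_to_frame(records: Sequence[ReadRecord] | pd.DataFrame) -> pd.DataFrame:
    """Tabular view of a read collection (pass-through for DataFrames)."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"read table is missing columns: {missing}")
        return records
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "channel": pd.array([r.channel for r in records], dtype="int64"),
            "region": [r.region.value for r in records],
            "start_time": pd.array([r.start_time for r in records], dtype="float64"),
            "duration": pd.array([r.duration for r in records], dtype="float64"),
            "length": pd.array([r.length for r in records], dtype="int64"),
            "barcode": [r.barcode for r in records],
            "replicon_class": [r.replicon_class.value for r in records],
            "sample": [r.sample for r in records],
            "rejected": pd.array([r.rejected for r in records], dtype="bool"),
        },
        columns=READ_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[ReadRecord]:
    """Materialise a read table back into :class:`ReadRecord` objects."""
    records = []
    for row in frame.itertuples(index=False):
        sample = row.sample
        if sample is not None and (isinstance(sample, float) and math.isnan(sample)):
            sample = None
        records.append(
            ReadRecord(
                read_id=str(row.read_id),
                channel=int(row.channel),
                region=Region(row.region),
                start_time=float(row.start_time),
                duration=float(row.duration),
                length=int(row.length),
                barcode="" if pd.isna(row.barcode) else str(row.barcode),
                replicon_class=RepliconClass(row.replicon_class),
                sample=sample,
                rejected=bool(row.rejected),
            )
        )
    return records


@dataclass(frozen=True)
class DepthInterval:
    """Maximal reference interval whose per-base depth clears a threshold."""

    contig: str
    start: int
    end: int
    mean_depth: float
    max_depth: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start
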