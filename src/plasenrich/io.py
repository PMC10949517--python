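"""Parsers and writers for the run's tabular inputs and outputs.

Inputs handled here: the per-read sequencing-summary TSV emitted by the
basecalling pipeline, PAF alignments of the reads against the combined
chromosome+plasmid reference set, the replicon table (contig -> sample,
class, length), and the adaptive-sampling decision log.  The module also
performs read-to-replicon assignment from the alignments.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import (
    READ_COLUMNS,
    Alignment,
    ReadRecord,
    Region,
    Replicon,
    RepliconClass,
    RepliconTable,
    frame_to_records,
    records_to_frame,
)


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


#: Default mapping from logical field -> sequencing-summary column name
#: (the names used by the stock basecaller output).
DEFAULT_SUMMARY_COLUMNS: dict[str, str] = {
    "read_id": "read_id",
    "channel": "channel",
    "start_time": "start_time",
    "duration": "duration",
    "length": "sequence_length_template",
    "barcode": "barcode_arrangement",
}

#: Channel index separating the adaptive-sampling half of the flow cell
#: (channels 1..boundary) from the control half.
DEFAULT_REGION_BOUNDARY = 256


def parse_sequencing_summary(
    path: str | Path,
    region_boundary: int = DEFAULT_REGION_BOUNDARY,
    columns: Optional[Mapping[str, str]] = None,
) -> list[ReadRecord]:
    """Parse a sequencing-summary TSV into :class:`ReadRecord` objects.

    Reads on channels ``<= region_boundary`` are labelled ``AS``, the rest
    ``CONTROL``.  Replicon class starts as ``UNMAPPED`` and the rejection
    flag as ``False``; both are filled in later from alignments and the
    decision log.
    """
    colmap = dict(DEFAULT_SUMMARY_COLUMNS)
    if columns:
        colmap.update(columns)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [name for name in colmap.values() if name not in frame.columns]
    if missing:
        raise FormatError(
            f"sequencing summary {path} is missing required column(s): "
            + ", ".join(missing)
        )
    if frame.empty:
        return []

    numeric = {}
    for field, caster in [
        ("channel", "Int64"),
        ("start_time", "Float64"),
        ("duration", "Float64"),
        ("length", "Int64"),
    ]:
        raw = frame[colmap[field]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any() or vals.isna().any():
            # +2: one for the header line, one for 0-based indexing
            line = int((bad | vals.isna()).idxmax()) + 2
            raise FormatError(
                f"{path}, line {line}: non-numeric value in column "
                f"{colmap[field]!r}"
            )
        numeric[field] = vals

    records = []
    for i in range(len(frame)):
        channel = int(numeric["channel"].iloc[i])
        records.append(
            ReadRecord(
                read_id=str(frame[colmap["read_id"]].iloc[i]),
                channel=channel,
                region=Region.AS if channel <= region_boundary else Region.CONTROL,
                start_time=float(numeric["start_time"].iloc[i]),
                duration=float(numeric["duration"].iloc[i]),
                length=int(numeric["length"].iloc[i]),
                barcode=str(frame[colmap["barcode"]].iloc[i]),
            )
        )
    return records


def parse_paf(path: str | Path) -> list[Alignment]:
    """Parse a PAF file (>= 12 mandatory columns, tags ignored)."""
    alignments = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}, line {lineno}: PAF requires >= 12 columns, "
                    f"got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[2]), int(fields[3])
                tstart, tend = int(fields[7]), int(fields[8])
                matching, block, mapq = (
                    int(fields[9]),
                    int(fields[10]),
                    int(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(
                    f"{path}, line {lineno}: non-integer coordinate field"
                ) from exc
            if min(qstart, qend, tstart, tend) < 0:
                raise FormatError(
                    f"{path}, line {lineno}: negative coordinates"
                )
            alignments.append(
                Alignment(
                    read_id=fields[0],
                    contig=fields[5],
                    qstart=qstart,
                    qend=qend,
                    tstart=tstart,
                    tend=tend,
                    matching_bases=matching,
                    block_length=block,
                    mapq=mapq,
                )
            )
    return alignments


def write_paf(
    alignments: Iterable[Alignment],
    read_lengths: Mapping[str, int],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write alignments back out as minimal 12-column PAF ('+' strand)."""
    with open(path, "w") as handle:
        for aln in alignments:
            fields = [
                aln.read_id,
                str(read_lengths[aln.read_id]),
                str(aln.qstart),
                str(aln.qend),
                "+",
                aln.contig,
                str(contig_lengths[aln.contig]),
                str(aln.tstart),
                str(aln.tend),
                str(aln.matching_bases),
                str(aln.block_length),
                str(aln.mapq),
            ]
            handle.write("\t".join(fields) + "\n")


def parse_replicon_table(path: str | Path) -> RepliconTable:
    """Parse a replicon TSV with columns contig, sample, class, length."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["contig", "sample", "class", "length"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"replicon table {path} is missing column(s): " + ", ".join(missing)
        )
    entries: dict[str, Replicon] = {}
    for contig, sample, cls, length in frame[required].itertuples(
        index=False, name=None
    ):
        if contig in entries:
            raise FormatError(f"duplicate contig {contig!r} in {path}")
        entries[str(contig)] = Replicon(
            sample=str(sample),
            replicon_class=RepliconClass(str(cls)),
            length=int(length),
        )
    return RepliconTable(entries)


def write_replicon_table(table: RepliconTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("contig\tsample\tclass\tlength\n")
        for contig in sorted(table.entries):
            rep = table[contig]
            handle.write(
                f"{contig}\t{rep.sample}\t{rep.replicon_class.value}\t{rep.length}\n"
            )


def parse_decision_log(path: str | Path) -> list[tuple[str, str]]:
    """Parse a two-column TSV decision log into (read_id, decision) pairs."""
    pairs = []
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(
                    f"{path}, line {lineno}: decision log needs 2 columns"
                )
            pairs.append((row[0], row[1]))
    return pairs


def primary_alignments(alignments: Sequence[Alignment]) -> dict[str, Alignment]:
    """Pick one primary alignment per read.

    Rule: highest ``matching_bases``; ties broken by higher ``mapq``, then
    lexicographically smallest contig name, then by target start so the
    choice is fully deterministic under permutation of the input.
    """
    best: dict[str, Alignment] = {}
    for aln in alignments:
        current = best.get(aln.read_id)
        if current is None or _primary_key(aln) < _primary_key(current):
            best[aln.read_id] = aln
    return best


def _primary_key(aln: Alignment) -> tuple:
    return (-aln.matching_bases, -aln.mapq, aln.contig, aln.tstart, aln.tend)


def assign_reads(
    records: Sequence[ReadRecord],
    alignments: Sequence[Alignment],
    table: RepliconTable,
) -> list[ReadRecord]:
    """Assign each read to the sample/replicon of its primary alignment.

    Reads without any alignment stay UNMAPPED.  Input order is preserved;
    a fresh list of records is returned.
    """
    unknown = sorted({a.contig for a in alignments} - set(table.entries))
    if unknown:
        raise ValueError(
            "alignments reference contigs absent from the replicon table: "
            + ", ".join(unknown)
        )
    best = primary_alignments(alignments)
    assigned = []
    for rec in records:
        aln = best.get(rec.read_id)
        if aln is None:
            assigned.append(
                ReadRecord(
                    rec.read_id,
                    rec.channel,
                    rec.region,
                    rec.start_time,
                    rec.duration,
                    rec.length,
                    rec.barcode,
                    RepliconClass.UNMAPPED,
                    None,
                    rec.rejected,
                )
            )
        else:
            rep = table[aln.contig]
            assigned.append(
                ReadRecord(
                    rec.read_id,
                    rec.channel,
                    rec.region,
                    rec.start_time,
                    rec.duration,
                    rec.length,
                    rec.barcode,
                    rep.replicon_class,
                    rep.sample,
                    rec.rejected,
                )
            )
    return assigned


def flag_rejections(
    records: Sequence[ReadRecord],
    decision_log: Sequence[tuple[str, str]],
    rejection_token: str = "unblock",
) -> list[ReadRecord]:
    """Set ``rejected=True`` for reads whose logged decision is the token.

    Reads absent from the log keep ``rejected=False``.  A read id logged
    twice with conflicting decisions is an error; consistent duplicates
    are tolerated.
    """
    decisions: dict[str, str] = {}
    for read_id, decision in decision_log:
        if read_id in decisions and decisions[read_id] != decision:
            raise ValueError(
                f"conflicting decisions for read {read_id!r}: "
                f"{decisions[read_id]!r} vs {decision!r}"
            )
        decisions[read_id] = decision
    flagged = []
    for rec in records:
        rejected = decisions.get(rec.read_id) == rejection_token
        flagged.append(
            ReadRecord(
                rec.read_id,
                rec.channel,
                rec.region,
                rec.start_time,
                rec.duration,
                rec.length,
                rec.barcode,
                rec.replicon_class,
                rec.sample,
                rejected,
            )
        )
    return flagged


def write_records(records: Sequence[ReadRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write assigned reads as a TSV with all record fields."""
    frame = records_to_frame(records)[READ_COLUMNS].copy()
    frame["sample"] = frame["sample"].fillna("")
    frame.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[ReadRecord]:
    """Read back a TSV written by :func:`write_records`."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"read_id": str, "barcode": str, "sample": str}
    )
    frame["sample"] = frame["sample"].where(frame["sample"].notna() & (frame["sample"] != ""), None)
    frame["barcode"] = frame["barcode"].fillna("")
    return frame_to_records(frame)
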