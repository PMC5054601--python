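"""Alignment-record ingestion and per-position coverage depth.

Two dialects are supported:

* ``truth_tsv`` — the simulator's tab-separated truth table (one row per
  read pair);
* ``sam_subset`` — a minimal SAM file (via pysam) with fixed-length
  matches, flags 99/147 for proper pairs, 65/129 for mapped improper
  pairs and 77/141 for unmapped artifact pairs.  This is the simulator's
  truth dialect, not a general-purpose SAM parser: unmapped pairs are
  assigned ``genome_id="artifact"``.  Real BAM ingestion should go through
  a thin adapter around :mod:`pysam` producing :class:`AlignmentRecord`.

Depth vectors use 0-based positions throughout; the samtools-depth TSV
dialect (1-based, sparse, zeros implicit) is converted at the file
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARTIFACT_GENOME_ID",
    "AlignmentRecord",
    "DepthVector",
    "MappingStats",
    "ParseError",
    "read_alignments",
    "write_alignments",
    "depth_from_alignments",
    "read_depth_tsv",
    "write_depth_tsv",
    "breadth",
    "mapping_stats",
    "read_genome_lengths",
]

ARTIFACT_GENOME_ID = "artifact"


class ParseError(ValueError):
    """Raised for malformed or bound-violating input records."""


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal alignment facts for one read pair.

    ``mate2_start`` is ``None`` for reads sequenced without a mate
    (singletons), which the unpaired-read filter removes.
    """

    pair_id: str
    genome_id: str
    mate1_start: int
    mate2_start: int | None
    read_length: int
    is_mapped: bool
    is_proper: bool
    mapq: int

    def __post_init__(self) -> None:
        if self.is_proper and not self.is_mapped:
            raise ValueError("a properly paired record must be mapped")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass
class DepthVector:
    """Per-position coverage depth over one genome."""

    genome_id: str
    depth: np.ndarray  # non-negative integers, length == genome length

    @property
    def length(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class MappingStats:
    """Read-pair accounting: what fraction mapped, and properly paired.

    Percentages are ``None`` when their denominator is zero (undefined,
    not 0).  ``properly_paired_percent`` is a percentage of *mapped* pairs.
    """

    total_pairs: int
    mapped_percent: float | None
    properly_paired_percent: float | None


# ---------------------------------------------------------------------------
# record I/O

_TSV_COLUMNS = [
    "pair_id", "genome_id", "mate1_start", "mate2_start",
    "read_length", "is_mapped", "is_proper", "mapq",
]


def read_alignments(path, dialect: str = "truth_tsv") -> list[AlignmentRecord]:
    """Read one :class:`AlignmentRecord` per read pair."""
    if dialect == "truth_tsv":
        return _read_tsv(path)
    if dialect == "sam_subset":
        return _read_sam(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path) -> list[AlignmentRecord]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    required = {"pair_id", "genome_id", "mate1_start", "mate2_start",
                "read_length", "is_proper", "mapq"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        genome_id = str(row.genome_id)
        if hasattr(row, "is_mapped"):
            is_mapped = bool(int(row.is_mapped))
        else:
            is_mapped = genome_id != ARTIFACT_GENOME_ID
        m2 = row.mate2_start
        try:
            records.append(AlignmentRecord(
                pair_id=str(row.pair_id), genome_id=genome_id,
                mate1_start=int(row.mate1_start),
                mate2_start=None if pd.isna(m2) else int(m2),
                read_length=int(row.read_length),
                is_mapped=is_mapped, is_proper=bool(int(row.is_proper)),
                mapq=int(row.mapq),
            ))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {line_no}: {exc}") from exc
    return records


def _read_sam(path) -> list[AlignmentRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        mates: dict[str, dict[int, "pysam.AlignedSegment"]] = {}
        for seg in fh.fetch(until_eof=True):
            slot = 2 if seg.is_read2 else 1
            mates.setdefault(seg.query_name, {})[slot] = seg
    records = []
    for qname, pair in mates.items():
        first = pair.get(1) or pair.get(2)
        second = pair.get(2) if 1 in pair else None
        read_length = first.query_length or (first.infer_query_length() or 0)
        if first.is_unmapped:
            records.append(AlignmentRecord(
                pair_id=qname, genome_id=ARTIFACT_GENOME_ID,
                mate1_start=0, mate2_start=0 if second is not None else None,
                read_length=read_length, is_mapped=False,
                is_proper=False, mapq=0,
            ))
            continue
        for seg in (s for s in (first, second) if s is not None):
            ref = seg.reference_name
            if seg.reference_start + read_length > lengths.get(ref, np.inf):
                raise ParseError(
                    f"{path}: read {qname} extends past end of {ref}"
                )
        records.append(AlignmentRecord(
            pair_id=qname, genome_id=first.reference_name,
            mate1_start=first.reference_start,
            mate2_start=second.reference_start if second is not None else None,
            read_length=read_length, is_mapped=True,
            is_proper=first.is_proper_pair,
            mapq=first.mapping_quality,
        ))
    return records


def write_alignments(
    records: Sequence[AlignmentRecord],
    path,
    dialect: str = "truth_tsv",
    genome_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records in the named dialect (SAM writing needs genome lengths)."""
    if dialect == "truth_tsv":
        df = pd.DataFrame(
            {
                "pair_id": [r.pair_id for r in records],
                "genome_id": [r.genome_id for r in records],
                "mate1_start": [r.mate1_start for r in records],
                "mate2_start": [r.mate2_start for r in records],
                "read_length": [r.read_length for r in records],
                "is_mapped": [int(r.is_mapped) for r in records],
                "is_proper": [int(r.is_proper) for r in records],
                "mapq": [r.mapq for r in records],
            },
            columns=_TSV_COLUMNS,
        )
        df["mate2_start"] = df["mate2_start"].astype("Int64")
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect == "sam_subset":
        if genome_lengths is None:
            raise ValueError("sam_subset writing requires genome_lengths")
        _write_sam(records, path, genome_lengths)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_sam(records, path, genome_lengths: Mapping[str, int]) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": gid, "LN": int(L)} for gid, L in genome_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        hdr = out.header
        for r in records:
            for mate_index, start in ((1, r.mate1_start), (2, r.mate2_start)):
                if mate_index == 2 and start is None:
                    continue
                seg = pysam.AlignedSegment(hdr)
                seg.query_name = r.pair_id
                seg.query_sequence = "N" * r.read_length
                seg.query_qualities = pysam.qualitystring_to_array("I" * r.read_length)
                flag = 0x1 | (0x40 if mate_index == 1 else 0x80)
                if r.mate2_start is None:
                    flag &= ~0x1  # singleton: not paired in sequencing
                if not r.is_mapped:
                    flag |= 0x4 | 0x8
                    seg.flag = flag
                    seg.mapping_quality = 0
                    out.write(seg)
                    continue
                if r.is_proper:
                    flag |= 0x2 | (0x20 if mate_index == 1 else 0x10)
                seg.flag = flag
                seg.reference_id = hdr.get_tid(r.genome_id)
                seg.reference_start = int(start)
                seg.mapping_quality = r.mapq
                seg.cigarstring = f"{r.read_length}M"
                other = r.mate2_start if mate_index == 1 else r.mate1_start
                if other is not None:
                    seg.next_reference_id = hdr.get_tid(r.genome_id)
                    seg.next_reference_start = int(other)
                if r.is_proper and r.mate2_start is not None:
                    span = r.mate2_start + r.read_length - r.mate1_start
                    seg.template_length = span if mate_index == 1 else -span
                out.write(seg)


# ---------------------------------------------------------------------------
# depth


def depth_from_alignments(
    records: Iterable[AlignmentRecord],
    genome_length: int,
    read_length: int | None = None,
) -> DepthVector:
    """Per-position depth from fixed-length end-to-end mates.

    Each mapped mate increments depth over ``[start, start + read_length)``;
    overlapping mates double-count, matching per-base depth semantics of
    standard depth tools.  All mapped records must belong to one genome.
    """
    mapped = [r for r in records if r.is_mapped]
    genomes = {r.genome_id for r in mapped}
    if len(genomes) > 1:
        raise ValueError(f"records span multiple genomes: {sorted(genomes)}")
    genome_id = genomes.pop() if genomes else ""
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    starts = []
    for r in mapped:
        rl = read_length if read_length is not None else r.read_length
        for s in (r.mate1_start, r.mate2_start):
            if s is None:
                continue
            if s < 0 or s + rl > genome_length:
                raise ValueError(
                    f"pair {r.pair_id}: mate at {s} extends past genome end "
                    f"({genome_length} bp)"
                )
            starts.append((s, rl))
    for s, rl in starts:
        diff[s] += 1
        diff[s + rl] -= 1
    return DepthVector(genome_id=genome_id, depth=np.cumsum(diff[:-1]))


def read_depth_tsv(path, genome_lengths: Mapping[str, int]) -> dict[str, DepthVector]:
    """Read a samtools-depth-style TSV: genome, 1-based position, depth.

    Positions absent from the file are zero.  Every genome in
    ``genome_lengths`` gets a vector, all-zero if it never appears.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["genome", "pos", "depth"],
                         dtype={"genome": str, "pos": np.int64, "depth": np.int64})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["genome", "pos", "depth"])
    out = {
        gid: DepthVector(gid, np.zeros(int(L), dtype=np.int64))
        for gid, L in genome_lengths.items()
    }
    for gid, sub in df.groupby("genome", sort=False):
        if gid not in out:
            raise ParseError(f"{path}: genome {gid!r} not in lengths table")
        L = len(out[gid].depth)
        pos = sub["pos"].to_numpy()
        if (pos < 1).any() or (pos > L).any():
            bad = pos[(pos < 1) | (pos > L)][0]
            raise ParseError(
                f"{path}: position {bad} outside genome {gid!r} (length {L})"
            )
        out[gid].depth[pos - 1] = sub["depth"].to_numpy()
    return out


def write_depth_tsv(depths: Iterable[DepthVector], path, sparse: bool = True) -> None:
    """Write depth vectors in samtools-depth dialect (1-based positions).

    With ``sparse=True`` (the samtools default) zero-depth rows are omitted.
    """
    with open(path, "w") as fh:
        for dv in depths:
            positions = np.flatnonzero(dv.depth) if sparse else np.arange(dv.length)
            for p in positions:
                fh.write(f"{dv.genome_id}\t{p + 1}\t{dv.depth[p]}\n")


# ---------------------------------------------------------------------------
# summary statistics


def breadth(depth: DepthVector, min_depth: int = 1) -> float:
    """Percent of genome positions covered at >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if depth.length == 0:
        raise ValueError("empty depth vector")
    return 100.0 * float(np.count_nonzero(depth.depth >= min_depth)) / depth.length


def mapping_stats(records: Sequence[AlignmentRecord]) -> MappingStats:
    """Mapped and properly-paired percentages over a read-pair set."""
    total = len(records)
    mapped = sum(r.is_mapped for r in records)
    proper = sum(r.is_proper for r in records)
    return MappingStats(
        total_pairs=total,
        mapped_percent=100.0 * mapped / total if total else None,
        properly_paired_percent=100.0 * proper / mapped if mapped else None,
    )


def read_genome_lengths(path) -> dict[str, int]:
    """Genome lengths from a FASTA file or a 2-column (id, length) TSV."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    df = pd.read_csv(path, sep="\t", header=None, names=["genome", "length"],
                     dtype={"genome": str, "length": np.int64})
    return dict(zip(df["genome"], df["length"]))
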