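"""Filtering and subsampling rules that make sequencing libraries comparable.

Two schemes:

* equal-data subsampling — every sample is downsampled (without
  replacement, at read-pair granularity) to the smallest sample's total
  bases, so breadth and abundance comparisons use the same amount of data;
* target-coverage subsampling — reads properly paired on one genome are
  downsampled to an average target depth (default 5x) for coverage-depth
  uniformity statistics.

"Amount of data" means total bases (pairs x 2 x read length); pair counts
are floored.  Mates are never split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .coverage import AlignmentRecord

__all__ = [
    "SampleReadSet",
    "InsufficientReadsError",
    "filter_unpaired",
    "filter_multimapped",
    "equal_data_subsample",
    "target_coverage_subsample",
]


class InsufficientReadsError(ValueError):
    """Fewer read pairs available than a coverage target requires."""

    def __init__(self, required: int, available: int, genome_id: str = ""):
        self.required = required
        self.available = available
        self.genome_id = genome_id
        where = f" on {genome_id}" if genome_id else ""
        super().__init__(
            f"need {required} read pairs{where} but only {available} available"
        )


@dataclass
class SampleReadSet:
    """A sample's read pairs plus the bookkeeping for equal-data comparisons."""

    sample_id: str
    records: list[AlignmentRecord]
    read_length: int

    @property
    def total_bases(self) -> int:
        return 2 * self.read_length * len(self.records)


def filter_unpaired(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Remove reads that were not paired in sequencing (missing mate)."""
    return [r for r in records if r.mate2_start is not None]


def filter_multimapped(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Remove multi-mapping reads (MAPQ 0, the BWA convention)."""
    return [r for r in records if r.mapq != 0]


def _take(records: list[AlignmentRecord], n: int, rng: np.random.Generator):
    idx = np.sort(rng.choice(len(records), size=n, replace=False))
    return [records[i] for i in idx]


def equal_data_subsample(
    samples: Sequence[SampleReadSet], seed: int
) -> list[SampleReadSet]:
    """Downsample every sample to the smallest sample's total bases.

    Uniform without replacement at pair granularity; pair counts are
    floored, so output totals differ pairwise by less than one pair's
    bases.  Sample order is preserved and the selection is deterministic
    for a fixed seed.
    """
    if not samples:
        raise ValueError("need at least one sample")
    target = min(s.total_bases for s in samples)
    children = np.random.SeedSequence(seed).spawn(len(samples))
    out = []
    for s, child in zip(samples, children):
        keep = target // (2 * s.read_length)
        if keep >= len(s.records):
            out.append(replace(s, records=list(s.records)))
            continue
        rng = np.random.default_rng(child)
        out.append(replace(s, records=_take(s.records, int(keep), rng)))
    return out


def target_coverage_subsample(
    records: Sequence[AlignmentRecord],
    genome_length: int,
    read_length: int,
    seed: int,
    target_depth: float = 5.0,
) -> list[AlignmentRecord]:
    """Downsample one genome's proper pairs to an average target depth.

    Selects ``floor(target_depth * genome_length / (2 * read_length))``
    pairs uniformly without replacement.  The caller is expected to have
    applied the unpaired and MAPQ-0 filters and restricted the records to
    proper pairs on a single genome.  Raises
    :class:`InsufficientReadsError` when the genome does not have enough
    pairs — for rare community members this mirrors real low-input runs,
    where deep-coverage comparisons are only possible for the most
    abundant species.
    """
    required = int(target_depth * genome_length // (2 * read_length))
    genome_id = records[0].genome_id if records else ""
    if len(records) < required:
        raise InsufficientReadsError(required, len(records), genome_id)
    rng = np.random.default_rng(seed)
    return _take(list(records), required, rng)
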