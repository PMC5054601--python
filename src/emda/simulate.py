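"""Stochastic simulator of multiple displacement amplification (MDA) of a
mock metagenome, in bulk and in emulsion droplets.

The model captures the features of MDA that drive species-distribution
distortion and coverage unevenness, without any sequence-level chemistry:

* a mock community of reference genomes mixed at known mass fractions,
  supplied to the reaction as random template fragments;
* Poisson loading of templates into picolitre droplets (emulsion mode);
* heavy-tailed per-template amplification: each template carries a
  lognormal amplification potential (median ``base_gain`` copies, shape
  ``gain_sigma``), and capacity-bound reactions additionally let a single
  "runaway" template — the one whose exponential takes off first — absorb
  most of the copy budget before the rest is split multinomially.  In
  emulsion the same race happens per droplet, so a runaway is confined to
  one droplet's capacity instead of dominating the whole reaction;
* paired-end read generation with chimeric (improperly paired),
  artifact ("contamination"/primer-dimer) and multi-mapping (MAPQ 0)
  read pairs.

All randomness flows through :class:`numpy.random.Generator` objects
seeded from a single integer, so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .coverage import ARTIFACT_GENOME_ID, AlignmentRecord

__all__ = [
    "Genome",
    "MockCommunity",
    "TemplateMolecule",
    "DropletPartition",
    "AmplificationResult",
    "SimulatedReadPair",
    "generate_mock_genomes",
    "fragment_templates",
    "partition_into_droplets",
    "partition_by_count",
    "amplify_unamplified",
    "amplify_bulk",
    "amplify_emulsion",
    "simulate_yield_curve",
    "generate_reads",
    "write_genomes_fasta",
    "write_reads_fastq",
    "write_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Genome:
    """A reference genome (or replicon) of the mock community."""

    id: str
    length: int
    gc_fraction: float = 0.5
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"genome {self.id!r}: length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"genome {self.id!r}: gc_fraction must be in [0, 1]")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"genome {self.id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class MockCommunity:
    """Known mixture of genomes: (genome_id, mass fraction of input DNA)."""

    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community must have at least one member")
        total = sum(f for _, f in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1 (got {total})")
        if any(f <= 0 for _, f in self.members):
            raise ValueError("all mass fractions must be > 0")

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)

    @property
    def mass_fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.members], dtype=float)


@dataclass(frozen=True)
class TemplateMolecule:
    """A denatured template fragment entering the MDA reaction."""

    template_id: int
    genome_id: str
    start: int  # 0-based inclusive
    length: int
    is_contaminant: bool = False


@dataclass
class DropletPartition:
    """Assignment of template molecules to emulsion droplets."""

    droplet_count: int
    droplet_of: np.ndarray  # droplet index per template, aligned with template order
    occupancy_lambda: float

    def occupancy_counts(self) -> np.ndarray:
        """Number of templates in each droplet (length ``droplet_count``)."""
        return np.bincount(self.droplet_of, minlength=self.droplet_count)

    def as_dict(self) -> dict[int, int]:
        return {int(i): int(d) for i, d in enumerate(self.droplet_of)}


@dataclass
class AmplificationResult:
    """Final copy number per template after (or without) amplification."""

    mode: str  # {"bulk", "emulsion", "unamplified"}
    copies: np.ndarray  # non-negative int64, aligned with template order
    yield_au: float  # total amplified mass, arbitrary units (copies x length)


@dataclass(frozen=True)
class SimulatedReadPair:
    """Truth record for one simulated paired-end read."""

    pair_id: str
    genome_id: str  # ARTIFACT_GENOME_ID for primer-dimer/contamination pairs
    mate1_start: int
    mate2_start: int
    read_length: int
    insert_size: int
    is_proper: bool
    is_chimera: bool
    mapq: int
    mate2_genome_id: str | None = None  # set for chimeras whose mate 2 is elsewhere

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.is_chimera and self.is_proper:
            raise ValueError("a chimeric pair cannot be properly paired")


# ---------------------------------------------------------------------------
# genome and template generation


def generate_mock_genomes(
    n: int,
    lengths: Sequence[int],
    gc: Sequence[float],
    seed: int,
    with_sequence: bool = True,
) -> list[Genome]:
    """Generate ``n`` random genomes with i.i.d. bases at the requested GC.

    Deterministic for a fixed seed.  Genome ids are ``genome_1..genome_n``.
    """
    if not (n == len(lengths) == len(gc)):
        raise ValueError(
            f"n={n} must match len(lengths)={len(lengths)} and len(gc)={len(gc)}"
        )
    if any(L < 1000 for L in lengths):
        raise ValueError("genome lengths must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    genomes = []
    for i, (L, g) in enumerate(zip(lengths, gc)):
        seq = None
        if with_sequence:
            p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
            seq = rng.choice(_BASES, size=int(L), p=p).tobytes().decode("ascii")
        genomes.append(
            Genome(id=f"genome_{i + 1}", length=int(L), gc_fraction=float(g), sequence=seq)
        )
    return genomes


def fragment_templates(
    community: MockCommunity,
    genomes: Iterable[Genome],
    total_templates: int,
    fragment_length_mean: int,
    seed: int,
    fragment_length_cv: float = 0.1,
) -> list[TemplateMolecule]:
    """Draw template fragments from the community's genomes.

    Template *counts* per genome are multinomial with probabilities equal to
    the mass fractions (all genomes share one fragment-length distribution,
    so count fractions and mass fractions coincide in expectation).  Start
    positions are uniform over valid positions; fragment lengths are normal
    with mean ``fragment_length_mean`` and CV ``fragment_length_cv``,
    clipped to [mean/2, genome length].
    """
    if total_templates < 1:
        raise ValueError("total_templates must be >= 1")
    by_id = {g.id: g for g in genomes}
    missing = [gid for gid in community.genome_ids if gid not in by_id]
    if missing:
        raise ValueError(f"community members missing from genomes: {missing}")
    shortest = min(by_id[gid].length for gid in community.genome_ids)
    if fragment_length_mean > shortest:
        raise ValueError(
            f"fragment_length_mean={fragment_length_mean} exceeds shortest "
            f"community genome ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_templates, community.mass_fractions)
    templates: list[TemplateMolecule] = []
    tid = 0
    for gid, count in zip(community.genome_ids, counts):
        if count == 0:
            continue
        L = by_id[gid].length
        lens = rng.normal(fragment_length_mean, fragment_length_cv * fragment_length_mean, count)
        lens = np.clip(np.rint(lens).astype(np.int64), max(1, fragment_length_mean // 2), L)
        starts = rng.integers(0, L - lens + 1)
        for s, fl in zip(starts, lens):
            templates.append(TemplateMolecule(tid, gid, int(s), int(fl)))
            tid += 1
    return templates


# ---------------------------------------------------------------------------
# droplet partitioning


def partition_by_count(
    templates: Sequence[TemplateMolecule], droplet_count: int, seed: int
) -> DropletPartition:
    """Assign each template to a uniformly random droplet.

    Uniform random assignment of ``n`` templates to ``D`` droplets gives
    Poisson(lambda = n/D) occupancy counts in the many-droplet limit.
    """
    if droplet_count < 1:
        raise ValueError("droplet_count must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(templates)
    droplet_of = rng.integers(0, droplet_count, size=n)
    return DropletPartition(
        droplet_count=int(droplet_count),
        droplet_of=droplet_of,
        occupancy_lambda=n / droplet_count,
    )


def partition_into_droplets(
    templates: Sequence[TemplateMolecule],
    droplet_volume_pl: float = 10.0,
    reaction_volume_ul: float = 1.0,
    seed: int = 0,
) -> DropletPartition:
    """Partition a reaction volume into droplets and load templates.

    The default 10-pl droplets give 1e5 droplets per microlitre of reaction
    mix.  ``droplet_count = floor(reaction_volume / droplet_volume)``.
    """
    if droplet_volume_pl <= 0 or reaction_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    droplet_count = int(reaction_volume_ul * 1e6 // droplet_volume_pl)
    if droplet_count < 1:
        raise ValueError("reaction volume smaller than one droplet")
    return partition_by_count(templates, droplet_count, seed)


# ---------------------------------------------------------------------------
# amplification


def _potentials(
    n: int, gain_sigma: float, base_gain: float, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal amplification potentials with median ``base_gain``."""
    return base_gain * np.exp(gain_sigma * rng.standard_normal(n))


def _allocate(
    potentials: np.ndarray,
    capacity: int,
    rng: np.random.Generator,
    runaway_strength: float,
    runaway_sigma: float,
) -> np.ndarray:
    """Allocate final copies for one capacity-limited reaction volume.

    If the summed potentials fit within ``capacity`` every template reaches
    its potential (no competition).  Otherwise the reaction is a race: one
    runaway template (ticket drawn with probability proportional to its
    potential) absorbs ``runaway_strength`` (lognormally jittered) times the
    remaining raw mass, and the capacity is then split multinomially.
    """
    total = float(potentials.sum())
    if total <= capacity:
        return np.floor(potentials).astype(np.int64)
    weights = potentials.astype(float).copy()
    if runaway_strength > 0 and len(weights) > 1:
        winner = rng.choice(len(weights), p=weights / total)
        rho = runaway_strength * np.exp(runaway_sigma * rng.standard_normal())
        weights[winner] += rho * (total - weights[winner])
    p = weights / weights.sum()
    return rng.multinomial(int(capacity), p).astype(np.int64)


def _yield_au(copies: np.ndarray, templates: Sequence[TemplateMolecule]) -> float:
    lengths = np.fromiter((t.length for t in templates), dtype=np.int64, count=len(templates))
    return float(np.sum(copies * lengths))


def amplify_unamplified(templates: Sequence[TemplateMolecule]) -> AmplificationResult:
    """No amplification: every template present in exactly one copy."""
    copies = np.ones(len(templates), dtype=np.int64)
    return AmplificationResult("unamplified", copies, _yield_au(copies, templates))


def amplify_bulk(
    templates: Sequence[TemplateMolecule],
    gain_sigma: float,
    reaction_capacity: int,
    seed: int,
    base_gain: float = 1e5,
    runaway_strength: float = 3.0,
    runaway_sigma: float = 0.5,
) -> AmplificationResult:
    """MDA in a single bulk reaction with one global copy budget.

    All templates compete for ``reaction_capacity`` copies; when the budget
    binds, the runaway winner systematically crowds out slow templates
    ("inhibition from other templates being amplified more rapidly").
    """
    if gain_sigma < 0:
        raise ValueError("gain_sigma must be >= 0")
    n = len(templates)
    if reaction_capacity < n:
        raise ValueError(f"reaction_capacity={reaction_capacity} < {n} templates")
    rng = np.random.default_rng(seed)
    if n == 0:
        return AmplificationResult("bulk", np.zeros(0, dtype=np.int64), 0.0)
    pot = _potentials(n, gain_sigma, base_gain, rng)
    copies = _allocate(pot, int(reaction_capacity), rng, runaway_strength, runaway_sigma)
    return AmplificationResult("bulk", copies, _yield_au(copies, templates))


def amplify_emulsion(
    templates: Sequence[TemplateMolecule],
    partition: DropletPartition,
    gain_sigma: float,
    droplet_capacity: int,
    seed: int,
    base_gain: float = 1e5,
    droplet_capacity_sigma: float = 0.6,
    runaway_strength: float = 3.0,
    runaway_sigma: float = 0.5,
) -> AmplificationResult:
    """MDA partitioned into droplets, each with its own copy budget.

    The competition model is identical to :func:`amplify_bulk` but applies
    per droplet: a template alone in its droplet saturates at the droplet
    capacity whatever its potential, so amplification bias and runaways are
    confined.  Per-droplet capacities are lognormally jittered
    (``droplet_capacity_sigma``) around ``droplet_capacity``, standing in
    for droplet-volume polydispersity and single-molecule kinetics.
    """
    if gain_sigma < 0:
        raise ValueError("gain_sigma must be >= 0")
    if droplet_capacity < 1:
        raise ValueError("droplet_capacity must be >= 1")
    n = len(templates)
    if len(partition.droplet_of) != n:
        raise ValueError(
            f"partition covers {len(partition.droplet_of)} templates, got {n}"
        )
    rng = np.random.default_rng(seed)
    copies = np.zeros(n, dtype=np.int64)
    if n == 0:
        return AmplificationResult("emulsion", copies, 0.0)
    pot = _potentials(n, gain_sigma, base_gain, rng)
    order = np.argsort(partition.droplet_of, kind="stable")
    sorted_drops = partition.droplet_of[order]
    # contiguous groups of templates sharing a droplet, in droplet order
    boundaries = np.flatnonzero(np.diff(sorted_drops)) + 1
    for group in np.split(order, boundaries):
        cap = droplet_capacity * np.exp(droplet_capacity_sigma * rng.standard_normal())
        cap = max(1, int(np.rint(cap)))
        copies[group] = _allocate(pot[group], cap, rng, runaway_strength, runaway_sigma)
    return AmplificationResult("emulsion", copies, _yield_au(copies, templates))


def simulate_yield_curve(
    concentrations: Sequence[float],
    mode: str,
    seed: int,
    droplet_count: int = 10_000,
    droplet_capacity: int = 2000,
    reaction_capacity: int | None = None,
    gain_sigma: float = 2.0,
    base_gain: float = 1e5,
    fragment_length: int = 2000,
    artifact_rate: float = 0.05,
    droplet_capacity_sigma: float = 0.0,
) -> list[tuple[float, float]]:
    """Total amplified mass (arbitrary units) as a function of input level.

    ``concentrations`` are mean templates per droplet (occupancy lambdas).
    Artifact templates (primer dimers / reagent contamination) are added at
    ``artifact_rate`` per droplet and amplify like genuine templates — in
    bulk they keep the reaction capacity-limited even with no input DNA,
    while in emulsion they occupy only a small fraction of droplets, so the
    emulsion yield tracks the occupied-droplet fraction 1 - exp(-lambda).
    """
    if mode not in ("bulk", "emulsion"):
        raise ValueError(f"mode must be 'bulk' or 'emulsion', got {mode!r}")
    if any(lam < 0 for lam in concentrations):
        raise ValueError("concentrations (occupancy lambdas) must be >= 0")
    if reaction_capacity is None:
        reaction_capacity = droplet_count * droplet_capacity
    out: list[tuple[float, float]] = []
    for child, lam in zip(np.random.SeedSequence(seed).spawn(len(concentrations)),
                          concentrations):
        sub = [int(s) for s in child.generate_state(2)]
        n_real = int(round(lam * droplet_count))
        n_art = int(round(artifact_rate * droplet_count))
        templates = [
            TemplateMolecule(i, "__template__", 0, fragment_length)
            for i in range(n_real)
        ] + [
            TemplateMolecule(n_real + j, ARTIFACT_GENOME_ID, 0, fragment_length,
                             is_contaminant=True)
            for j in range(n_art)
        ]
        if not templates:
            out.append((float(lam), 0.0))
            continue
        if mode == "bulk":
            res = amplify_bulk(
                templates, gain_sigma, reaction_capacity, sub[0] % 2**31,
                base_gain=base_gain,
            )
        else:
            part = partition_by_count(templates, droplet_count, sub[0] % 2**31)
            res = amplify_emulsion(
                templates, part, gain_sigma, droplet_capacity, sub[1] % 2**31,
                base_gain=base_gain,
                droplet_capacity_sigma=droplet_capacity_sigma,
            )
        out.append((float(lam), res.yield_au))
    return out


# ---------------------------------------------------------------------------
# read simulation


def generate_reads(
    amplification: AmplificationResult,
    templates: Sequence[TemplateMolecule],
    genomes: Iterable[Genome],
    n_pairs: int,
    read_length: int,
    insert_mean: int,
    chimera_rate: float,
    contamination_rate: float,
    multimap_rate: float,
    seed: int,
    insert_sigma: float | None = None,
) -> tuple[list[SimulatedReadPair], list[AlignmentRecord]]:
    """Draw paired-end reads from the amplified template pool.

    Source templates are chosen with probability proportional to
    ``copies x length``; both mate positions fall within the source
    fragment.  A chimeric pair takes its second mate from an independently
    drawn template (improperly paired); an artifact pair represents
    primer-dimer or contaminant material and does not map to any community
    genome; a multi-mapping pair is flagged MAPQ 0, all others MAPQ 60.

    Returns the truth read pairs and the matching alignment records.
    """
    for name, rate in (("chimera_rate", chimera_rate),
                       ("contamination_rate", contamination_rate),
                       ("multimap_rate", multimap_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if len(templates) != len(amplification.copies):
        raise ValueError("templates and amplification.copies are misaligned")
    copies = amplification.copies
    lengths = np.fromiter((t.length for t in templates), dtype=np.int64,
                          count=len(templates))
    weights = copies.astype(float) * lengths
    total = weights.sum()
    if n_pairs > 0 and total <= 0:
        raise ValueError("cannot generate reads: all template copy numbers are zero")
    usable = lengths[copies > 0]
    if n_pairs > 0:
        if read_length > insert_mean:
            raise ValueError("read_length must be <= insert_mean")
        if insert_mean > usable.min():
            raise ValueError(
                f"insert_mean={insert_mean} exceeds shortest amplified template "
                f"({usable.min()} bp)"
            )
    if insert_sigma is None:
        insert_sigma = 0.1 * insert_mean

    rng = np.random.default_rng(seed)
    starts = np.fromiter((t.start for t in templates), dtype=np.int64,
                         count=len(templates))
    gidx = np.array([t.genome_id for t in templates])

    p = weights / total if n_pairs > 0 else None
    src = rng.choice(len(templates), size=n_pairs, p=p)
    inserts = np.rint(rng.normal(insert_mean, insert_sigma, n_pairs)).astype(np.int64)
    inserts = np.minimum(np.maximum(inserts, read_length), lengths[src])
    offsets = rng.integers(0, lengths[src] - inserts + 1)
    m1 = starts[src] + offsets
    m2 = m1 + inserts - read_length

    is_chimera = rng.random(n_pairs) < chimera_rate
    is_artifact = rng.random(n_pairs) < contamination_rate
    is_chimera &= ~is_artifact
    is_multi = rng.random(n_pairs) < multimap_rate

    # chimeric second mates come from an independent template
    n_chi = int(is_chimera.sum())
    chi_src = rng.choice(len(templates), size=n_chi, p=p) if n_chi else np.empty(0, int)
    if n_chi:
        chi_off = rng.integers(0, np.maximum(lengths[chi_src] - read_length, 0) + 1)
        m2[is_chimera] = starts[chi_src] + chi_off

    pairs: list[SimulatedReadPair] = []
    records: list[AlignmentRecord] = []
    chi_iter = iter(gidx[chi_src])
    for i in range(n_pairs):
        if is_artifact[i]:
            pair = SimulatedReadPair(
                pair_id=f"p{i}", genome_id=ARTIFACT_GENOME_ID,
                mate1_start=0, mate2_start=0, read_length=read_length,
                insert_size=0, is_proper=False, is_chimera=False, mapq=0,
            )
        else:
            chimera = bool(is_chimera[i])
            m2g = next(chi_iter) if chimera else None
            pair = SimulatedReadPair(
                pair_id=f"p{i}", genome_id=str(gidx[src[i]]),
                mate1_start=int(m1[i]), mate2_start=int(m2[i]),
                read_length=read_length,
                insert_size=0 if chimera else int(inserts[i]),
                is_proper=not chimera, is_chimera=chimera,
                mapq=0 if is_multi[i] else 60,
                mate2_genome_id=str(m2g) if (chimera and m2g != gidx[src[i]]) else None,
            )
        pairs.append(pair)
        records.append(AlignmentRecord(
            pair_id=pair.pair_id, genome_id=pair.genome_id,
            mate1_start=pair.mate1_start, mate2_start=pair.mate2_start,
            read_length=read_length,
            is_mapped=pair.genome_id != ARTIFACT_GENOME_ID,
            is_proper=pair.is_proper, mapq=pair.mapq,
        ))
    return pairs, records


# ---------------------------------------------------------------------------
# file output (FASTA / FASTQ / truth table)


def write_genomes_fasta(genomes: Iterable[Genome], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = []
    for g in genomes:
        if g.sequence is None:
            raise ValueError(f"genome {g.id!r} has no sequence to write")
        recs.append(SeqRecord(Seq(g.sequence), id=g.id, description=""))
    SeqIO.write(recs, str(path), "fasta")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def write_reads_fastq(
    pairs: Sequence[SimulatedReadPair],
    genomes: Iterable[Genome],
    r1_path,
    r2_path,
    seed: int = 0,
    quality_char: str = "I",
) -> None:
    """Write the two mates as FASTQ with a fixed base quality.

    Mate 2 is written reverse-complemented (FR orientation).  Artifact pairs
    get random bases since they have no genomic origin.
    """
    seqs = {g.id: g.sequence for g in genomes}
    rng = np.random.default_rng(seed)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            qual = quality_char * p.read_length
            if p.genome_id == ARTIFACT_GENOME_ID:
                s1 = rng.choice(_BASES, size=p.read_length).tobytes().decode()
                s2 = rng.choice(_BASES, size=p.read_length).tobytes().decode()
            else:
                g1 = seqs[p.genome_id]
                g2 = seqs[p.mate2_genome_id or p.genome_id]
                if g1 is None or g2 is None:
                    raise ValueError("genomes must carry sequences to write FASTQ")
                s1 = g1[p.mate1_start:p.mate1_start + p.read_length]
                s2 = g2[p.mate2_start:p.mate2_start + p.read_length]
                s2 = s2.translate(_COMPLEMENT)[::-1]
            f1.write(f"@{p.pair_id}/1\n{s1}\n+\n{qual}\n")
            f2.write(f"@{p.pair_id}/2\n{s2}\n+\n{qual}\n")


def write_truth_table(pairs: Sequence[SimulatedReadPair], path) -> None:
    """Tab-separated truth table, one row per read pair."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "genome_id": [p.genome_id for p in pairs],
            "mate1_start": [p.mate1_start for p in pairs],
            "mate2_start": [p.mate2_start for p in pairs],
            "read_length": [p.read_length for p in pairs],
            "is_proper": [int(p.is_proper) for p in pairs],
            "is_chimera": [int(p.is_chimera) for p in pairs],
            "mapq": [p.mapq for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
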