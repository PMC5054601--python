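"""End-to-end three-arm experiment: unamplified vs emulsion vs bulk MDA.

One call to :func:`run_experiment` simulates a mock community, amplifies
one shared template pool under each arm (so arm differences are purely the
amplification model), sequences paired-end reads, applies the comparison
rules (unpaired filter, MAPQ-0 filter, equal-data subsampling, 5x
target-coverage subsampling) and reports:

* per-sample mapping statistics (mapped %, properly paired %),
* a species-abundance table from properly paired reads,
* per-genome coverage breadth at equal data,
* per-genome uniformity statistics (breadth, CV %, Gini) at matched 5x
  average depth — a genome that lacks enough proper pairs for 5x is
  reported as unavailable rather than failing the run.

Everything is regenerable from the config and master seed recorded in the
run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import coverage, simulate, subsample, uniformity

__all__ = [
    "ExperimentConfig",
    "SampleReport",
    "abundance_table",
    "run_experiment",
    "run_replicates",
]

ARMS = ("unamplified", "emulsion", "bulk")


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one simulated three-arm comparison.

    Defaults are the desk-scale analog of a low-input five-species mock
    community: five 50-kb genomes mixed on a mass-fraction staircase, a
    few thousand 2-kb template fragments loaded at a mean occupancy of
    0.2 templates per droplet, and heavy-tailed amplification gains
    (lognormal shape 2) with a capacity-bound winner-take-most race in
    bulk.  See docs/methods.md for the rationale behind each value.
    """

    genome_lengths: tuple[int, ...] = (50_000,) * 5
    gc_fractions: tuple[float, ...] = (0.35, 0.45, 0.50, 0.58, 0.65)
    mass_fractions: tuple[float, ...] = (0.45, 0.30, 0.15, 0.07, 0.03)
    fragment_length_mean: int = 2000
    droplet_count: int = 10_000
    occupancy_lambda: float = 0.2
    gain_sigma: float = 2.0
    base_gain: float = 1e5
    droplet_capacity: int = 2000
    droplet_capacity_sigma: float = 0.6
    runaway_strength: float = 3.0
    runaway_sigma: float = 0.5
    reaction_capacity: int | None = None  # default: droplet_count * droplet_capacity
    n_pairs: int = 50_000
    read_length: int = 100
    insert_mean: int = 300
    chimera_rate: float = 0.05
    chimera_rate_unamplified: float = 0.005
    contamination_rate: float = 0.01
    multimap_rate: float = 0.01
    target_depth: float = 5.0
    arms: tuple[str, ...] = ARMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.genome_lengths) == len(self.gc_fractions)
                == len(self.mass_fractions)):
            raise ValueError("genome_lengths, gc_fractions and mass_fractions "
                             "must have equal lengths")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")

    @property
    def total_capacity(self) -> int:
        if self.reaction_capacity is not None:
            return int(self.reaction_capacity)
        return int(self.droplet_count) * int(self.droplet_capacity)

    @property
    def n_templates(self) -> int:
        return int(round(self.occupancy_lambda * self.droplet_count))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for k in ("genome_lengths", "gc_fractions", "mass_fractions", "arms"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class SampleReport:
    """All report tables for one experiment, plus the run metadata."""

    mapping: pd.DataFrame          # sample, total_pairs, mapped_pct, proper_pct
    abundance: pd.DataFrame        # sample, genome, proper_pair_count, proportion
    breadth_equal_data: pd.DataFrame  # sample, genome, breadth_pct (at equal data)
    uniformity: pd.DataFrame       # sample, genome, breadth_pct, cv_pct, gini
    stage_counts: pd.DataFrame     # sample, stage, pairs
    metadata: dict

    _TABLES = ("mapping", "abundance", "breadth_equal_data", "uniformity",
               "stage_counts")

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t",
                                       index=False, float_format="%.10g")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.metadata, fh, sort_keys=True)


def abundance_table(samples: Sequence[subsample.SampleReadSet]) -> pd.DataFrame:
    """Proper read pairs per genome per sample, with per-sample proportions.

    Artifact (unmapped) pairs never count as proper and are excluded from
    the denominator; a sample with zero proper pairs yields no rows.
    """
    rows = []
    for s in samples:
        counts: dict[str, int] = {}
        for r in s.records:
            if r.is_proper:
                counts[r.genome_id] = counts.get(r.genome_id, 0) + 1
        total = sum(counts.values())
        for gid in sorted(counts):
            rows.append({
                "sample": s.sample_id, "genome": gid,
                "proper_pair_count": counts[gid],
                "proportion": counts[gid] / total,
            })
    return pd.DataFrame(rows, columns=["sample", "genome",
                                       "proper_pair_count", "proportion"])


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0]) % 2**31


def _simulate_arm(cfg: ExperimentConfig, arm: str, templates, genomes,
                  seeds: dict[str, np.random.SeedSequence]):
    if arm == "unamplified":
        amp = simulate.amplify_unamplified(templates)
        chimera = cfg.chimera_rate_unamplified
    elif arm == "bulk":
        amp = simulate.amplify_bulk(
            templates, cfg.gain_sigma, cfg.total_capacity,
            _seed_int(seeds["amp"]), base_gain=cfg.base_gain,
            runaway_strength=cfg.runaway_strength,
            runaway_sigma=cfg.runaway_sigma,
        )
        chimera = cfg.chimera_rate
    elif arm == "emulsion":
        part = simulate.partition_by_count(
            templates, cfg.droplet_count, _seed_int(seeds["partition"]))
        amp = simulate.amplify_emulsion(
            templates, part, cfg.gain_sigma, cfg.droplet_capacity,
            _seed_int(seeds["amp"]), base_gain=cfg.base_gain,
            droplet_capacity_sigma=cfg.droplet_capacity_sigma,
            runaway_strength=cfg.runaway_strength,
            runaway_sigma=cfg.runaway_sigma,
        )
        chimera = cfg.chimera_rate
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(arm)
    _, records = simulate.generate_reads(
        amp, templates, genomes, cfg.n_pairs, cfg.read_length,
        cfg.insert_mean, chimera, cfg.contamination_rate,
        cfg.multimap_rate, _seed_int(seeds["reads"]),
    )
    return records


def run_experiment(config: ExperimentConfig | None = None,
                   out_dir=None) -> SampleReport:
    """Run the full simulate -> filter -> subsample -> report analysis.

    The three arms share one template pool, so differences between them
    are attributable to the amplification model alone.  Deterministic for
    a fixed ``config.seed``; pass ``out_dir`` to also write the report
    TSVs and the reproducibility manifest.
    """
    cfg = config or ExperimentConfig()
    root = np.random.SeedSequence(cfg.seed)
    labels = ["genomes", "templates", "equal", "coverage"]
    for arm in cfg.arms:
        labels += [f"{arm}:partition", f"{arm}:amp", f"{arm}:reads"]
    seqs = dict(zip(labels, root.spawn(len(labels))))

    genomes = simulate.generate_mock_genomes(
        len(cfg.genome_lengths), list(cfg.genome_lengths),
        list(cfg.gc_fractions), _seed_int(seqs["genomes"]),
        with_sequence=False,
    )
    lengths = {g.id: g.length for g in genomes}
    community = simulate.MockCommunity(
        tuple(zip([g.id for g in genomes], cfg.mass_fractions)))
    templates = simulate.fragment_templates(
        community, genomes, cfg.n_templates, cfg.fragment_length_mean,
        _seed_int(seqs["templates"]))

    mapping_rows, stage_rows, filtered_sets = [], [], []
    for arm in cfg.arms:
        records = _simulate_arm(cfg, arm, templates, genomes, {
            "partition": seqs[f"{arm}:partition"],
            "amp": seqs[f"{arm}:amp"],
            "reads": seqs[f"{arm}:reads"],
        })
        ms = coverage.mapping_stats(records)
        mapping_rows.append({
            "sample": arm, "total_pairs": ms.total_pairs,
            "mapped_pct": ms.mapped_percent,
            "proper_pct": ms.properly_paired_percent,
        })
        stage_rows.append({"sample": arm, "stage": "raw", "pairs": len(records)})
        paired = subsample.filter_unpaired(records)
        stage_rows.append({"sample": arm, "stage": "paired", "pairs": len(paired)})
        uniq = subsample.filter_multimapped(paired)
        stage_rows.append({"sample": arm, "stage": "mapq_gt0", "pairs": len(uniq)})
        filtered_sets.append(subsample.SampleReadSet(arm, uniq, cfg.read_length))

    equal_sets = subsample.equal_data_subsample(filtered_sets,
                                               _seed_int(seqs["equal"]))
    for s in equal_sets:
        stage_rows.append({"sample": s.sample_id, "stage": "equal_data",
                           "pairs": len(s.records)})
    abundance = abundance_table(equal_sets)

    breadth_rows = []
    for s in equal_sets:
        by_genome: dict[str, list] = {gid: [] for gid in lengths}
        for r in s.records:
            if r.is_proper:
                by_genome[r.genome_id].append(r)
        for gid, recs in by_genome.items():
            dv = coverage.depth_from_alignments(recs, lengths[gid])
            dv.genome_id = gid
            breadth_rows.append({"sample": s.sample_id, "genome": gid,
                                 "breadth_pct": coverage.breadth(dv)
                                 if recs else 0.0})

    cov_children = iter(seqs["coverage"].spawn(len(cfg.arms) * len(lengths)))
    uniformity_rows = []
    for s in filtered_sets:
        proper_by_genome: dict[str, list] = {gid: [] for gid in lengths}
        for r in s.records:
            if r.is_proper:
                proper_by_genome[r.genome_id].append(r)
        for gid in lengths:
            child = next(cov_children)
            row = {"sample": s.sample_id, "genome": gid,
                   "breadth_pct": np.nan, "cv_pct": np.nan, "gini": np.nan,
                   "pairs_used": 0, "available": False}
            try:
                sel = subsample.target_coverage_subsample(
                    proper_by_genome[gid], lengths[gid], cfg.read_length,
                    _seed_int(child), target_depth=cfg.target_depth)
            except subsample.InsufficientReadsError:
                uniformity_rows.append(row)
                continue
            dv = coverage.depth_from_alignments(sel, lengths[gid])
            stats = uniformity.uniformity_report(dv)
            row.update({"breadth_pct": stats.breadth_percent,
                        "cv_pct": stats.cv_percent, "gini": stats.gini,
                        "pairs_used": len(sel), "available": True})
            uniformity_rows.append(row)

    from . import __version__

    report = SampleReport(
        mapping=pd.DataFrame(mapping_rows),
        abundance=abundance,
        breadth_equal_data=pd.DataFrame(breadth_rows),
        uniformity=pd.DataFrame(uniformity_rows),
        stage_counts=pd.DataFrame(stage_rows),
        metadata={"config": cfg.to_dict(), "seed": cfg.seed,
                  "emda_version": __version__},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_replicates(config: ExperimentConfig, n_replicates: int,
                   seed: int | None = None) -> list[SampleReport]:
    """Run independent replicates with per-replicate seeds spawned from one.

    ``seed`` defaults to ``config.seed``.  Each replicate draws a fresh
    template pool (shared across its arms).
    """
    master = config.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n_replicates)
    return [
        run_experiment(dataclasses.replace(config, seed=_seed_int(child)))
        for child in children
    ]
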