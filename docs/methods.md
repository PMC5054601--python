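# Methods

## The question the model answers

When a mixed-species DNA sample with very little input is whole-genome
amplified by MDA, two things degrade: the species distribution (rare
members lose read share) and the evenness of coverage depth along each
genome.  Partitioning the reaction into picolitre droplets is claimed to
fix both, because each droplet amplifies at most a few templates in
isolation.  `emda` implements a generative model of that claim plus the
measurement pipeline, so the direction of the effects can be reproduced,
probed and unit-tested at desk scale.  It is a *mechanistic toy*: it aims
at directions and orderings, not at the absolute values any particular
sequencing run would produce.

## Generative model

**Community and templates.**  A mock community is a set of genomes with
mass fractions summing to 1 (default: five 50-kb random genomes at
0.45/0.30/0.15/0.07/0.03 — a staircase spanning 15× between the most and
least abundant member).  Input DNA is represented as `n` template
fragments; since all genomes share one fragment-length distribution
(normal, mean 2 kb, CV 0.1, clipped), template counts are multinomial in
the mass fractions and fragment starts are uniform.

**Droplet loading.**  Each template is assigned to one of `D` droplets
uniformly at random, so occupancy is Poisson(λ = n/D).
`partition_into_droplets` converts physical volumes (default 10-pl
droplets, i.e. 1e5 droplets per µl); the pipeline default is `D` = 1e4
droplets at λ = 0.2 (2000 templates).

**Amplification.**  Template *i* draws a lognormal amplification
potential `Gᵢ = base_gain · exp(σ·Zᵢ)` (unit-median shape σ =
`gain_sigma`, default 2).  A reaction volume with copy budget `C`
(capacity) then resolves as:

* if `ΣG ≤ C`: every template reaches its potential (no competition);
* otherwise a single *runaway* template — the ticket drawn with
  probability ∝ `Gᵢ`, standing for the template whose stochastic
  exponential takes off first — has its raw weight boosted by
  `ρ · (ΣG − Gᵢ)` with `ρ = runaway_strength · exp(0.5·Z)` (default
  strength 3, so the winner absorbs roughly 60–80 % of the budget), and
  the budget is split multinomially over the boosted weights.

In **bulk** this race runs once over the whole reaction
(`C = D · droplet_capacity` by default): the winner and the heavy
lognormal tail systematically crowd out slow templates, which is what
erases rare species.  In **emulsion** the identical race runs per
droplet with budget `droplet_capacity` (default 2000 copies, lognormally
jittered with σ = 0.6 per droplet for volume polydispersity and
single-molecule kinetics): a lone template saturates its droplet whatever
its potential, so potentials — and runaways — stop mattering wherever
occupancy is ≤ 1.  The **unamplified** arm sets every copy number to 1.

Two parameter ratios matter.  `base_gain / droplet_capacity` (default 50)
controls how reliably a lone template saturates its droplet: large
headroom makes the emulsion arm insensitive to gain heterogeneity, which
is the mechanism behind abundance preservation.  The per-droplet capacity
jitter gives the emulsion arm its copy-number dispersion (CV ≈ 0.7),
placing its depth-evenness between the unamplified control and bulk
rather than on top of the control.

Choosing the competition as a single runaway plus a multinomial baseline
(rather than a plain multinomial over lognormal gains) is deliberate: in
any exchangeable per-template weight model the rare member's read share
*exceeds* its input share whenever its gain draws beat the other
species', which happens in ~20–35 % of realizations regardless of the
tail weight — too often to reproduce the systematic suppression seen in
practice.  With a runaway, the rare member's upside requires holding the
winning ticket, whose probability is its template-count share (3 % by
default), while the multinomial baseline keeps abundant species
5×-subsamplable.  Model exploration behind these choices is summarized in
the repository's decision notes; the defaults were fixed before the
acceptance checks were run and are not tuned per seed.

**Yield.**  Reported in arbitrary units as Σ copies × template length.
Artifact templates (primer dimers, reagent contamination) enter at
`artifact_rate` per droplet and amplify like real templates with the same
unit mass — so a bulk reaction saturates its capacity even with zero
input (flat yield curve), while the emulsion yield tracks the
occupied-droplet fraction `1 − e^(−λ)`.

**Reads.**  Read pairs sample templates ∝ copies × length; mates fall
within the source fragment with a normal insert (mean 300 bp, sd 10 %,
reads 2 × 100 bp).  With probability `chimera_rate` (default 0.05
amplified, 0.005 unamplified) the second mate comes from an independent
template — an improperly paired chimera.  With `contamination_rate`
(0.01) the pair is an unmapped artifact; with `multimap_rate` (0.01) it
is flagged MAPQ 0.  All other pairs are proper, MAPQ 60.

## Measurement pipeline

Per arm: flagstat-style accounting (% mapped, % of mapped properly
paired) → remove unpaired reads → remove MAPQ-0 pairs → subsample all
arms to the smallest arm's total bases ("amount of data" = pairs × 2 ×
read length, floored at pair granularity, mates never split) → species
proportions from proper pairs and per-genome ≥1× breadth.  Separately,
each genome's proper pairs are subsampled to ⌊5 × L / (2 × read
length)⌋ pairs; genomes with too few pairs are reported unavailable
rather than failing the run.  Depth statistics on the 5× sets: breadth,
CV (population SD / mean over all positions, zeros included) and Gini.

**Gini scale.**  Defining Gini as the raw area between the diagonal and
the Lorenz curve bounds it by 0.5, yet uniformity studies report values
above 0.5 — consistent only with the conventional 2×-area scaling.  Both
are exposed (`scale="standard"` default, `"area"` option); the ambiguity
is inherent to the verbal definition and left visible rather than
silently resolved.

**Lorenz basis.**  The x-axis defaults to covered positions only
(`covered_only`), since breadth is reported separately; `whole_genome`
includes zeros (required for the "all mass on one position → Gini → 1"
limit, which is degenerate on the covered-only basis).

## Numerical choices

* Midpoint-rule area on the piecewise-linear Lorenz polyline equals the
  exact polygon area; tests assert equality with an independent shoelace
  oracle to 1e-12.
* Population (divide-by-N) standard deviation for CV; at genome scale the
  ddof distinction is negligible but it must be pinned for exact tests.
* Depth-sort ties break by position index; all statistics are
  position-exchangeable so this only pins determinism.
* Coordinates are 0-based half-open internally; the samtools-depth TSV
  dialect (1-based, sparse, zeros implicit) and SAM are converted at file
  boundaries.
* All randomness flows through `numpy.random.Generator`; experiment-level
  streams are spawned from one master `SeedSequence`, recorded in the run
  manifest, and reports rerun from the same seed are byte-identical.
* One capacity allocation is a single `rng.multinomial` call even at a
  2e7-copy budget, so a full three-arm replicate (50 000 pairs per arm)
  runs in about two seconds on one core; the replicated analyses use 20
  replicates.

## Scale-down rationale

Real runs use ~Mb genomes, ~1e7 droplets and millions of reads; the
defaults shrink genomes to 50 kb and droplets to 1e4 while keeping the
quantities that drive the phenomena in the realistic low-input regime:
occupancy λ = 0.2, and a per-position template multiplicity of ~36 on the
most abundant genome (2000 fragments × 2 kb over 5 × 50 kb).  Multiplicity
is the knob that matters for depth statistics — at 1e5 droplets and equal
λ the multiplicity grows 10-fold and averages the bulk-vs-emulsion
contrast away at 50-kb genome scale, which is why the droplet count is
not set to the physical value in the pipeline defaults (the partitioning
function itself defaults to physical 10-pl volumes).

## What the simulator does not model

No sequence-level chemistry: no primer sequences, no base errors, no
GC-dependent amplification or library-prep bias, no CIGAR beyond
fixed-length end-to-end matches, no assembly.  Chimeric pairs keep the
first mate's genome label, so the (filtered-out) chimeras never
contribute depth to a second genome.  Artifact reads are labels, not
sequences drawn from a contaminant database.  Passing tests therefore
show that the *mechanism* — partitioning converts global amplification
competition into confined, saturating micro-reactions — produces the
observed orderings (species-distribution preservation; Gini/CV
unamplified < emulsion < bulk; yield plateaus), not that any particular
real dataset's numbers are matched.

## Known limitations

* The runaway race is a one-winner caricature of continuous exponential
  competition; relative arm orderings are robust to `runaway_strength`
  in the 1–4 range but absolute bulk Gini/CV values are not calibrated.
* The rare-member trends are probabilistic: with the default community
  the rare member jackpots the bulk runaway in ~3–5 % of replicates, so
  per-replicate win rates sit near, not at, 100 %.
* Equal-data subsampling assumes one read length per sample.
* Cross-community comparisons (two independently pooled mixes) are not
  modelled; each replicate has exactly one template pool.
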