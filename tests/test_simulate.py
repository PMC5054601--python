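"""Unit and property tests for the mock-community MDA simulator."""

import numpy as np
import pytest

from emda import (
    DropletPartition,
    Genome,
    MockCommunity,
    amplify_bulk,
    amplify_emulsion,
    amplify_unamplified,
    fragment_templates,
    generate_mock_genomes,
    generate_reads,
    partition_by_count,
    partition_into_droplets,
    simulate_yield_curve,
)
from emda.simulate import TemplateMolecule


def _uniform_templates(n, length=1000, genome_id="g"):
    return [TemplateMolecule(i, genome_id, 0, length) for i in range(n)]


class TestGenomeGeneration:
    def test_length_and_id_forced(self):
        (g,) = generate_mock_genomes(1, [1000], [0.5], seed=1)
        assert g.length == 1000 and len(g.sequence) == 1000

    def test_seed_determinism_is_byte_identical(self):
        a = generate_mock_genomes(5, [5000] * 5, [0.58] * 5, seed=7)
        b = generate_mock_genomes(5, [5000] * 5, [0.58] * 5, seed=7)
        assert [g.sequence for g in a] == [g.sequence for g in b]

    def test_observed_gc_matches_request(self):
        # binomial 3-sigma at n=1e6 and p=0.58 is ~0.0015
        (g,) = generate_mock_genomes(1, [1_000_000], [0.58], seed=5)
        gc = sum(c in "GC" for c in g.sequence) / g.length
        assert abs(gc - 0.58) < 3 * np.sqrt(0.58 * 0.42 / 1e6)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            generate_mock_genomes(2, [1000], [0.5, 0.5], seed=0)


class TestFragmentTemplates:
    def test_single_member_gets_all_templates(self):
        g = Genome("solo", 10_000)
        comm = MockCommunity((("solo", 1.0),))
        t = fragment_templates(comm, [g], 10, 1000, seed=0)
        assert len(t) == 10 and all(x.genome_id == "solo" for x in t)

    def test_counts_follow_mass_fractions(self):
        genomes = [Genome("a", 100_000), Genome("b", 100_000)]
        comm = MockCommunity((("a", 0.9), ("b", 0.1)))
        t = fragment_templates(comm, genomes, 100_000, 1000, seed=1)
        n_b = sum(x.genome_id == "b" for x in t)
        sigma = np.sqrt(100_000 * 0.1 * 0.9)
        assert abs(n_b - 10_000) < 3 * sigma

    @pytest.mark.parametrize("seed", range(5))
    def test_templates_never_overrun_genome(self, five_genomes,
                                            staircase_community, seed):
        lengths = {g.id: g.length for g in five_genomes}
        for t in fragment_templates(staircase_community, five_genomes,
                                    300, 1000, seed=seed):
            assert 0 <= t.start and t.start + t.length <= lengths[t.genome_id]

    def test_fragment_longer_than_genome_rejected(self):
        g = Genome("tiny", 1000)
        comm = MockCommunity((("tiny", 1.0),))
        with pytest.raises(ValueError):
            fragment_templates(comm, [g], 10, 2000, seed=0)


class TestPartition:
    def test_no_templates_means_empty_droplets(self):
        part = partition_into_droplets([], 10.0, 0.01, seed=0)
        assert part.droplet_of.size == 0
        assert part.occupancy_counts().sum() == 0

    def test_droplet_count_from_volumes(self):
        # 10-pl droplets in 1 ul of reaction mix
        part = partition_into_droplets([], 10.0, 1.0, seed=0)
        assert part.droplet_count == 100_000

    @pytest.mark.parametrize("lam,expected", [(np.log(2), 0.5), (0.1, 1 - np.exp(-0.1))])
    def test_occupied_fraction_matches_poisson(self, lam, expected):
        d = 100_000
        templates = _uniform_templates(int(round(lam * d)))
        part = partition_by_count(templates, d, seed=2)
        occupied = np.count_nonzero(part.occupancy_counts()) / d
        sigma = np.sqrt(expected * (1 - expected) / d)
        assert abs(occupied - expected) < 3 * sigma

    def test_reaction_smaller_than_droplet_rejected(self):
        with pytest.raises(ValueError):
            partition_into_droplets([], 10.0, 1e-6, seed=0)


class TestAmplification:
    def test_unamplified_is_single_copy(self, template_pool):
        res = amplify_unamplified(template_pool)
        assert (res.copies == 1).all()
        assert res.yield_au == sum(t.length for t in template_pool)

    def test_zero_sigma_no_competition_gives_equal_copies(self):
        t = _uniform_templates(10)
        res = amplify_bulk(t, gain_sigma=0.0, reaction_capacity=10**9,
                           seed=0, base_gain=1000)
        assert (res.copies == 1000).all()

    def test_single_template_caps_at_capacity(self):
        t = _uniform_templates(1)
        res = amplify_bulk(t, gain_sigma=0.0, reaction_capacity=500,
                           seed=0, base_gain=1e6)
        assert res.copies[0] == 500

    def test_capacity_binding_conserves_total(self, template_pool):
        res = amplify_bulk(template_pool, gain_sigma=2.0,
                           reaction_capacity=10_000, seed=4)
        assert res.copies.sum() == 10_000

    def test_heavier_tail_means_more_dropouts(self):
        # Monte-Carlo comparison: fraction of templates at 0 final copies
        drops = {0.1: [], 2.0: []}
        for rep in range(50):
            t = _uniform_templates(10_000)
            for sigma in drops:
                res = amplify_bulk(t, sigma, reaction_capacity=10**6,
                                   seed=1000 + rep, base_gain=1e5)
                drops[sigma].append(np.mean(res.copies == 0))
        assert np.mean(drops[2.0]) > np.mean(drops[0.1])

    def test_singly_occupied_droplets_saturate_exactly(self):
        t = _uniform_templates(50)
        part = DropletPartition(50, np.arange(50), 1.0)
        res = amplify_emulsion(t, part, gain_sigma=0.0, droplet_capacity=100,
                               seed=0, base_gain=1e6,
                               droplet_capacity_sigma=0.0)
        assert (res.copies == 100).all()

    def test_empty_partition_zero_yield(self):
        part = partition_by_count([], 1000, seed=0)
        res = amplify_emulsion([], part, 2.0, 100, seed=0)
        assert res.yield_au == 0.0

    def test_per_droplet_capacity_never_exceeded(self, template_pool):
        part = partition_by_count(template_pool, 300, seed=5)
        res = amplify_emulsion(template_pool, part, gain_sigma=2.0,
                               droplet_capacity=100, seed=6,
                               droplet_capacity_sigma=0.0)
        per_droplet = np.bincount(part.droplet_of, weights=res.copies,
                                  minlength=300)
        assert (per_droplet <= 100).all()

    def test_emulsion_disperses_less_than_bulk(self):
        # paired Monte-Carlo: same templates, same seeds per replicate
        wins = 0
        for rep in range(50):
            t = _uniform_templates(500)
            bulk = amplify_bulk(t, 2.0, 500 * 1000, seed=rep, base_gain=1e5)
            part = partition_by_count(t, 2500, seed=rep)
            emu = amplify_emulsion(t, part, 2.0, 1000, seed=rep,
                                   base_gain=1e5, droplet_capacity_sigma=0.0)
            cv = lambda c: c.std() / c.mean()
            wins += cv(emu.copies) < cv(bulk.copies)
        assert wins >= 45

    def test_partition_template_mismatch_rejected(self, template_pool):
        part = partition_by_count(template_pool[:-1], 1000, seed=0)
        with pytest.raises(ValueError):
            amplify_emulsion(template_pool, part, 2.0, 100, seed=0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            amplify_bulk(_uniform_templates(2), -1.0, 100, seed=0)


class TestYieldCurve:
    def test_zero_input_zero_artifacts_zero_yield(self):
        out = simulate_yield_curve([0.0], "emulsion", seed=0,
                                   droplet_count=1000, artifact_rate=0.0)
        assert out == [(0.0, 0.0)]

    def test_saturated_emulsion_approaches_total_capacity(self):
        d, cap, frag = 2000, 1000, 500
        out = simulate_yield_curve([20.0], "emulsion", seed=1,
                                   droplet_count=d, droplet_capacity=cap,
                                   fragment_length=frag, artifact_rate=0.0)
        assert out[0][1] == pytest.approx(d * cap * frag, rel=0.02)

    def test_emulsion_yield_monotone_in_lambda(self):
        lams = [0.05, 0.2, 1.0, 5.0]
        out = simulate_yield_curve(lams, "emulsion", seed=2,
                                   droplet_count=5000, artifact_rate=0.0)
        yields = [y for _, y in out]
        # closed form: yield ~ droplet_count * (1 - exp(-lambda)) * capacity
        for (lo, hi) in zip(yields, yields[1:]):
            assert hi >= lo * 0.97

    def test_emulsion_tracks_occupied_fraction(self):
        d, cap, frag = 20_000, 1000, 500
        out = simulate_yield_curve([0.1, 1.0], "emulsion", seed=3,
                                   droplet_count=d, droplet_capacity=cap,
                                   fragment_length=frag, artifact_rate=0.0)
        for lam, y in out:
            expected = d * (1 - np.exp(-lam)) * cap * frag
            assert y == pytest.approx(expected, rel=0.1)


class TestReads:
    def test_clean_rates_give_all_proper(self, template_pool, five_genomes):
        amp = amplify_unamplified(template_pool)
        pairs, records = generate_reads(amp, template_pool, five_genomes,
                                        2000, 100, 300, 0.0, 0.0, 0.0, seed=1)
        assert all(p.is_proper for p in pairs)
        assert all(r.mapq == 60 for r in records)

    def test_all_chimeras_means_none_proper(self, template_pool, five_genomes):
        amp = amplify_unamplified(template_pool)
        pairs, _ = generate_reads(amp, template_pool, five_genomes,
                                  500, 100, 300, 1.0, 0.0, 0.0, seed=2)
        assert not any(p.is_proper for p in pairs)
        assert all(p.is_chimera for p in pairs)

    def test_improper_fraction_tracks_chimera_rate(self, template_pool,
                                                   five_genomes):
        n = 20_000
        amp = amplify_unamplified(template_pool)
        pairs, _ = generate_reads(amp, template_pool, five_genomes,
                                  n, 100, 300, 0.05, 0.0, 0.0, seed=3)
        frac = np.mean([not p.is_proper for p in pairs])
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_unamplified_recovers_template_mass_fractions(
            self, template_pool, five_genomes):
        # oracle: multinomial over the realized per-genome template mass
        n = 50_000
        amp = amplify_unamplified(template_pool)
        _, records = generate_reads(amp, template_pool, five_genomes,
                                    n, 100, 300, 0.0, 0.0, 0.0, seed=4)
        mass = {}
        for t in template_pool:
            mass[t.genome_id] = mass.get(t.genome_id, 0) + t.length
        total = sum(mass.values())
        for gid, m in mass.items():
            p = m / total
            got = sum(r.genome_id == gid for r in records) / n
            assert abs(got - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_zero_copies_rejected(self, template_pool, five_genomes):
        amp = amplify_unamplified(template_pool)
        amp.copies[:] = 0
        with pytest.raises(ValueError):
            generate_reads(amp, template_pool, five_genomes, 10, 100, 300,
                           0.0, 0.0, 0.0, seed=0)

    def test_same_seed_same_reads(self, template_pool, five_genomes):
        amp = amplify_unamplified(template_pool)
        a, _ = generate_reads(amp, template_pool, five_genomes, 500, 100, 300,
                              0.05, 0.01, 0.01, seed=9)
        b, _ = generate_reads(amp, template_pool, five_genomes, 500, 100, 300,
                              0.05, 0.01, 0.01, seed=9)
        assert a == b
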