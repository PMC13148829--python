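"""Diploid genetic model: mutation, recombination, phenotype, mating, runs."""

import numpy as np
import pytest
from scipy import stats

from clunio import (
    DiploidIndividual,
    GeneticParams,
    MutationTable,
    draw_new_mutations,
    phenotype_of,
    recombine,
    run_genetic,
)
from clunio.genetic_model import (
    GeneticPopulation,
    _cross,
    _initial_population,
    mate_and_reproduce,
    step_generation_genetic,
)


def make_population(genetic_values, noises, sexes, rng=None, initial_T=15):
    """Population where individual i carries one hap-1 mutation of given effect."""
    table = MutationTable()
    n = len(genetic_values)
    ids = table.add_batch(
        np.arange(n) * 10, np.asarray(genetic_values, dtype=float), origin=0
    )
    empty = np.empty(0, dtype=np.int64)
    return GeneticPopulation(
        0,
        np.zeros(n),
        np.asarray(noises, dtype=float),
        np.asarray(sexes, dtype=bool),
        [np.array([i], dtype=np.int64) for i in ids],
        [empty] * n,
        np.asarray(genetic_values, dtype=float),
        np.zeros(n),
        table,
        0.0,
        initial_T,
    )


class TestDrawNewMutations:
    def test_poisson_count_calibration(self):
        # mean 0.1 per gamete at the default rates; chi-square GOF over 1e5 gametes
        rng = np.random.default_rng(7)
        table = MutationTable()
        counts = np.array([
            len(draw_new_mutations(1e-7, 1_000_000, 0.1, 0.5, rng, table=table))
            for _ in range(100_000)
        ])
        assert counts.mean() == pytest.approx(0.1, abs=0.005)
        kmax = 3
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), 0.1)
        probs = np.append(probs, 1 - probs.sum())
        res = stats.chisquare(obs, probs * counts.size)
        assert res.pvalue > 1e-3

    def test_effect_neutral_split(self, rng):
        table = MutationTable()
        recs = []
        for _ in range(3000):
            recs += draw_new_mutations(3e-6, 1_000_000, 0.25, 0.5, rng, table=table)
        frac_effect = np.mean([not r.is_neutral for r in recs])
        assert frac_effect == pytest.approx(0.25, abs=0.02)
        assert all(r.effect == 0.0 for r in recs if r.is_neutral)
        assert all(0 <= r.position < 1_000_000 for r in recs)

    def test_boundary_cases(self, rng):
        table = MutationTable()
        recs = []
        for _ in range(500):
            recs += draw_new_mutations(3e-6, 1_000_000, 0.0, 0.5, rng, table=table)
        assert recs and all(r.is_neutral for r in recs)
        recs = []
        for _ in range(500):
            recs += draw_new_mutations(3e-6, 1_000_000, 1.0, 0.0, rng, table=table)
        assert recs and all(r.effect == 0.0 for r in recs)


def naive_cross(hap1, hap2, pos, breaks, first):
    """Per-mutation segment-parity oracle for gamete splicing."""
    out = []
    for source, hap in enumerate((hap1, hap2)):
        for m in hap:
            segment = int(np.sum(np.asarray(breaks) <= pos[m]))
            if segment % 2 == (source if first == 0 else 1 - source):
                out.append(m)
    return sorted(out, key=lambda m: (pos[m], m))


class TestRecombine:
    def test_no_crossover_copies_one_parent(self, rng):
        table = MutationTable()
        h1 = table.add_batch([10, 50, 90], [0.1, 0.0, -0.2], 0)
        h2 = table.add_batch([20, 60], [0.0, 0.3], 0)
        seen = set()
        for _ in range(200):
            g = recombine(h1, h2, 0.0, 100, rng, table)
            assert g.tolist() in (h1.tolist(), h2.tolist())
            seen.add(tuple(g.tolist()))
        assert len(seen) == 2  # both parents chosen with the fair coin

    @pytest.mark.parametrize("k_breaks", [1, 2, 5])
    def test_splice_matches_naive_oracle(self, k_breaks, rng):
        for _ in range(60):
            table = MutationTable()
            n1, n2 = rng.integers(0, 12, size=2)
            h1 = table.add_batch(np.sort(rng.choice(100, n1, replace=False)),
                                 rng.normal(size=n1), 0)
            h2 = table.add_batch(np.sort(rng.choice(100, n2, replace=False)),
                                 rng.normal(size=n2), 0)
            breaks = np.sort(rng.uniform(0, 100, k_breaks))
            first = int(rng.integers(2))
            got = _cross(h1, h2, table.position, breaks, first)
            assert got.tolist() == naive_cross(h1, h2, table.position, breaks, first)

    def test_mendelian_transmission_ratio(self):
        # a heterozygous site is transmitted to half of 10^4 gametes
        rng = np.random.default_rng(11)
        table = MutationTable()
        h1 = table.add_batch([500_000], [0.2], 0)
        h2 = np.empty(0, dtype=np.int64)
        carried = sum(
            recombine(h1, h2, 1e-7, 1_000_000, rng, table).size for _ in range(10_000)
        )
        assert stats.binomtest(carried, 10_000, 0.5).pvalue > 1e-3


class TestPhenotype:
    def test_examples(self):
        def ind(gv, noise):
            e = np.empty(0, dtype=np.int64)
            return DiploidIndividual(e, e, "female", 0.0, noise, gv, 0)

        assert phenotype_of(ind(0.0, 0.0), 15) == 15
        assert phenotype_of(ind(7.9, -0.2), 15) == 22       # floor(22.7)
        assert phenotype_of(ind(16.0, 0.5), 15) == 1        # floor(31.5) wraps
        assert phenotype_of(ind(-20.0, 0.0), 15) == 25      # wraps below

    def test_sparse_matches_dense_array_oracle(self, rng):
        # toy genome L=100: phenotype from sparse haplotypes equals a dense
        # per-base effect array summed over both chromosomes
        L = 100
        table = MutationTable()
        n1, n2 = 8, 5
        h1 = table.add_batch(rng.integers(0, L, n1), rng.normal(0, 0.5, n1), 0)
        h2 = table.add_batch(rng.integers(0, L, n2), rng.normal(0, 0.5, n2), 0)
        dense = np.zeros(L)
        for m in np.concatenate([h1, h2]):
            dense[table.position[m]] += table.effect[m]
        pop = GeneticPopulation(
            0, np.zeros(1), np.array([0.3]), np.array([False]),
            [h1], [h2],
            np.array([table.effect[h1].sum()]), np.array([table.effect[h2].sum()]),
            table, 0.0, 15,
        )
        expected = int(np.floor(dense.sum() + 0.3 + 15) - 1) % 30 + 1
        assert pop.T[0] == expected


class TestMateAndReproduce:
    def test_brood_size_is_floored_mean_fitness(self, rng):
        pop = make_population([0.0, 0.0], [0.0, 0.0], [False, True])
        p = GeneticParams(mu_bp=0.0, r_bp=0.0, sigma_emergence=0.0)
        off = mate_and_reproduce(pop, np.array([0.8, 0.6]), p, rng)
        assert off.size == 7  # floor(0.7 * 10)
        off = mate_and_reproduce(pop, np.array([1.0, 1.0]), p, rng)
        assert off.size == 10

    def test_same_day_requirement(self, rng):
        # female on day 4 (gv -11), all males on day 5 (gv -10): no offspring
        pop = make_population([-11.0, -10.0, -10.0], [0.0] * 3, [False, True, True])
        assert pop.T.tolist() == [4, 5, 5]
        p = GeneticParams(sigma_emergence=0.0)
        off = mate_and_reproduce(pop, np.ones(3), p, rng)
        assert off.size == 0

    def test_single_sex_population_goes_extinct(self, rng):
        pop = make_population([0.0, 0.0], [0.0, 0.0], [False, False])
        off = mate_and_reproduce(pop, np.ones(2), GeneticParams(), rng)
        assert off.size == 0

    def test_offspring_born_at_shared_day_waterline(self, rng):
        from clunio import low_tide_depth

        pop = make_population([0.0] * 4, [0.0] * 4, [False, True, False, True])
        p = GeneticParams(sigma_emergence=0.0)
        off = mate_and_reproduce(pop, np.ones(4), p, rng)
        assert off.size > 0
        assert np.allclose(off.depth, low_tide_depth(15))

    def test_exact_sex_ratio_per_generation(self, rng):
        pop = make_population([0.0] * 40, [0.0] * 40, [False, True] * 20)
        p = GeneticParams(sigma_emergence=0.0)
        off = mate_and_reproduce(pop, np.full(40, 0.45), p, rng)
        males = int(off.is_male.sum())
        assert abs(2 * males - off.size) <= 1


class TestConsolidation:
    def test_phenotypes_invariant_under_consolidation(self, rng):
        p = GeneticParams(seed=5, generations=120, consolidate_every=0)
        res = run_genetic(p)
        pop = res.final_population
        T_before = pop.T.copy()
        gv_before = pop.genetic_values().copy()
        removed = pop.consolidate_fixed()
        pop.T = pop._phenotypes()
        assert np.array_equal(pop.T, T_before)
        assert pop.genetic_values() == pytest.approx(gv_before, abs=1e-9)
        # the consolidated background must absorb any fixed effects
        ids, counts = pop.allele_counts()
        assert not np.any(counts == 2 * pop.size)
        assert removed >= 0


class TestRunGenetic:
    def test_determinism_under_fixed_seed(self, quick_genetic):
        a, b = run_genetic(quick_genetic), run_genetic(quick_genetic)
        assert np.array_equal(a.histograms, b.histograms)
        assert np.array_equal(
            np.concatenate(a.final_population.haps1 + a.final_population.haps2),
            np.concatenate(b.final_population.haps1 + b.final_population.haps2),
        )

    def test_sex_ratio_through_a_run(self):
        res = run_genetic(GeneticParams(seed=9, generations=40))
        pop = res.final_population
        assert abs(2 * int(pop.is_male.sum()) - pop.size) <= 1

    def test_genotype_sampling_cadence(self):
        p = GeneticParams(seed=2, generations=100, sample_genotypes=True,
                          sample_every=40, sample_size=20)
        res = run_genetic(p)
        gens = [gs.generation for gs in res.genotype_samples]
        assert gens == [40, 80, 100]
        for gs in res.genotype_samples:
            assert gs.matrix.shape[0] <= 20
            assert set(np.unique(gs.matrix)) <= {0, 1, 2}

    def test_neutral_allele_frequencies_drift_without_bias(self):
        # sigma_effect = 0: all variation is neutral; mean frequency change
        # over an interval should vanish across replicates
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = GeneticParams(sigma_effect=0.0, sigma_emergence=0.25, seed=seed,
                              mu_bp=5e-7)
            pop = _initial_population(p, rng)
            for _ in range(50):
                pop = step_generation_genetic(pop, p, rng)
            ids, counts = pop.allele_counts()
            track = ids[(counts >= 4) & (counts <= 2 * pop.size - 4)]
            if track.size == 0 or pop.size == 0:
                continue
            f0 = {int(m): c / (2 * pop.size)
                  for m, c in zip(ids, counts) if m in set(track.tolist())}
            for _ in range(25):
                pop = step_generation_genetic(pop, p, rng)
            if pop.size == 0:
                continue
            ids1, counts1 = pop.allele_counts()
            lookup = dict(zip(ids1.tolist(), counts1.tolist()))
            for m, f in f0.items():
                deltas.append(lookup.get(m, 0) / (2 * pop.size) - f)
        assert len(deltas) > 30
        assert np.mean(deltas) == pytest.approx(0.0, abs=0.03)

    def test_heritability_decreases_with_emergence_noise(self):
        # parent-offspring regression slope is monotone decreasing over
        # sigma_emergence in {0.25, 1, 3} at fixed standing genetic variance.
        # Mating is strictly same-day, so the shared parental day is read off
        # by mating each day's adults separately.
        slopes = []
        for sigma_e in (0.25, 1.0, 3.0):
            rng = np.random.default_rng(99)
            n = 600
            gv = rng.normal(0, 2.0, n)
            noise = rng.normal(0, sigma_e, n)
            pop = make_population(gv, noise, np.arange(n) % 2 == 1, initial_T=15)
            p = GeneticParams(sigma_emergence=sigma_e, mu_bp=0.0, r_bp=0.0)
            xs, ys = [], []
            for day in range(5, 26):
                idx = np.flatnonzero(pop.T == day)
                if idx.size < 2:
                    continue
                sub = pop.take(idx)
                off = mate_and_reproduce(sub, np.full(idx.size, 0.4), p, rng)
                # unwrap offspring days to the branch nearest the parent day
                t_off = day + ((off.T - day + 15) % 30 - 15)
                xs += [day] * off.size
                ys += t_off.tolist()
            assert len(xs) > 200
            slopes.append(np.polyfit(xs, ys, 1)[0])
        assert slopes[0] > slopes[1] > slopes[2]
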