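"""The extended model: sexual diploids with an explicit polygenic basis.

Individuals carry two haplotypes of a 1-Mb genome.  Mutations arise at a
per-base-pair rate; a fraction ``P_effecting`` of them perturb the lunar
emergence phenotype with an additive effect ~ Normal(0, sigma_effect), the
rest are neutral.  The phenotype is

    T = wrap( floor( sum of effect sizes + noise + initial_T ) )

where ``noise`` ~ Normal(0, sigma_emergence) is a non-genetic offset drawn
once at birth (so an individual's emergence day is stable through its
life).  Mating is strictly assortative by emergence day: adults live only
hours, so a female can only mate with males that emerged on her exact lunar
day -- emergence timing is a magic trait.  Each offspring receives one
recombined, mutated gamete per parent and is born at the low-tide waterline
of the parents' shared emergence day.

Haplotypes are sparse: sorted arrays of mutation ids referencing a global
:class:`MutationTable`.  Gametes without crossovers or new mutations (the
overwhelming majority at the default rates) share the parental array, which
keeps a multi-thousand-generation run cheap.  Mutations fixed in the whole
population are periodically consolidated into a scalar background value;
phenotypes are invariant under consolidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .environment import (
    LUNAR_PERIOD,
    _tide_depth,
    environmental_fitness,
    wrap_lunar_day,
)
from .competition import competition_fitness, competition_strengths, total_fitness
from .clonal_model import _disperse
from .results import RunResult

__all__ = [
    "GeneticParams",
    "MutationRecord",
    "MutationTable",
    "DiploidIndividual",
    "GeneticPopulation",
    "draw_new_mutations",
    "recombine",
    "phenotype_of",
    "mate_and_reproduce",
    "run_genetic",
]

FEMALE, MALE = 0, 1


@dataclass
class GeneticParams:
    """Parameters of the genetic model (defaults: the reference parameter set)."""

    mu_bp: float = 1e-7              # mutations per bp per gamete per generation
    r_bp: float = 1e-7               # crossovers per bp per gamete per generation
    sigma_effect: float = 0.5        # s.d. of effect sizes (lunar days)
    P_effecting: float = 0.1         # fraction of mutations affecting the trait
    sigma_emergence: float = 0.25    # s.d. of the non-genetic phenotype offset
    genome_length: int = 1_000_000
    Cw: float = 0.1
    sigma_dispersal: float = 0.25
    K: int = 200
    max_offspring: int = 10          # cap per mating pair (5 per parent)
    initial_T: int = 15
    initial_depth: float = 0.0
    initial_N: int = 10
    generations: int = 1500
    fitness_variant: str = "sigmoid"
    seed: Optional[int] = None
    boundary: str = "none"
    record_depth_max: int = 100
    sex_assignment: str = "alternating"  # alternating (exact 1:1) | bernoulli
    sample_genotypes: bool = False
    sample_every: int = 200          # genotype sampling cadence (generations)
    sample_size: int = 100
    consolidate_every: int = 250     # fixed-mutation consolidation cadence

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MutationRecord:
    """One mutation: genomic position, additive effect (0 if neutral), origin."""

    id: int
    position: int
    effect: float
    origin_generation: int

    @property
    def is_neutral(self) -> bool:
        return self.effect == 0.0


class MutationTable:
    """Append-only registry of every mutation ever created in a run.

    Haplotypes store mutation *ids*; positions/effects live here in growable
    parallel arrays.  Recurrent mutation at an occupied position creates a
    new, independently tracked id (mutations stack, they never overwrite).
    """

    def __init__(self, capacity: int = 1024):
        self._pos = np.empty(capacity, dtype=np.int64)
        self._eff = np.empty(capacity, dtype=float)
        self._origin = np.empty(capacity, dtype=np.int64)
        self.n = 0

    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        if need > self._pos.size:
            cap = max(need, 2 * self._pos.size)
            for name in ("_pos", "_eff", "_origin"):
                old = getattr(self, name)
                new = np.empty(cap, dtype=old.dtype)
                new[: self.n] = old[: self.n]
                setattr(self, name, new)

    def add_batch(self, positions, effects, origin: int) -> np.ndarray:
        """Register new mutations; returns their freshly assigned ids."""
        positions = np.asarray(positions, dtype=np.int64)
        k = positions.size
        self._ensure(k)
        sl = slice(self.n, self.n + k)
        self._pos[sl] = positions
        self._eff[sl] = effects
        self._origin[sl] = origin
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.n += k
        return ids

    @property
    def position(self) -> np.ndarray:
        return self._pos[: self.n]

    @property
    def effect(self) -> np.ndarray:
        return self._eff[: self.n]

    @property
    def origin(self) -> np.ndarray:
        return self._origin[: self.n]

    def record(self, mid: int) -> MutationRecord:
        return MutationRecord(
            id=int(mid),
            position=int(self._pos[mid]),
            effect=float(self._eff[mid]),
            origin_generation=int(self._origin[mid]),
        )


@dataclass
class DiploidIndividual:
    """Read-only view of one diploid (haplotypes as mutation-id arrays)."""

    hap1: np.ndarray
    hap2: np.ndarray
    sex: str                 # "female" | "male"
    depth: float
    noise: float
    genetic_value: float     # sum of effects on both haplotypes (+ background)
    T: int


def phenotype_of(ind: DiploidIndividual, initial_T: int) -> int:
    """Lunar emergence day: wrap(floor(genetic value + noise + initial_T))."""
    return wrap_lunar_day(math.floor(ind.genetic_value + ind.noise + initial_T))


class GeneticPopulation:
    """Living diploid population: parallel arrays plus sparse haplotype lists."""

    def __init__(self, generation, depth, noise, is_male, haps1, haps2,
                 hsum1, hsum2, table: MutationTable, background: float,
                 initial_T: int):
        self.generation = generation
        self.depth = depth
        self.noise = noise
        self.is_male = is_male
        self.haps1 = haps1            # list of sorted id arrays (immutable)
        self.haps2 = haps2
        self.hsum1 = hsum1            # cached per-haplotype effect sums
        self.hsum2 = hsum2
        self.table = table
        self.background = background  # effect sum of consolidated fixed mutations
        self.initial_T = initial_T
        self.T = self._phenotypes()

    @property
    def size(self) -> int:
        return self.depth.size

    def _phenotypes(self) -> np.ndarray:
        g = self.hsum1 + self.hsum2 + self.background + self.noise + self.initial_T
        return (np.floor(g).astype(np.int64) - 1) % LUNAR_PERIOD + 1

    def genetic_values(self) -> np.ndarray:
        return self.hsum1 + self.hsum2 + self.background

    def histogram(self) -> np.ndarray:
        return np.bincount(self.T, minlength=LUNAR_PERIOD + 1)[1:]

    def individual(self, i: int) -> DiploidIndividual:
        return DiploidIndividual(
            hap1=self.haps1[i],
            hap2=self.haps2[i],
            sex="male" if self.is_male[i] else "female",
            depth=float(self.depth[i]),
            noise=float(self.noise[i]),
            genetic_value=float(self.hsum1[i] + self.hsum2[i] + self.background),
            T=int(self.T[i]),
        )

    def take(self, idx) -> "GeneticPopulation":
        """Subset view (shares the mutation table)."""
        idx = np.asarray(idx)
        return GeneticPopulation(
            self.generation, self.depth[idx].copy(), self.noise[idx].copy(),
            self.is_male[idx].copy(),
            [self.haps1[i] for i in idx], [self.haps2[i] for i in idx],
            self.hsum1[idx].copy(), self.hsum2[idx].copy(),
            self.table, self.background, self.initial_T,
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(ids, copy counts) of every mutation carried by the population."""
        if self.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        allh = [h for h in self.haps1 + self.haps2 if h.size]
        if not allh:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        return np.unique(np.concatenate(allh), return_counts=True)

    def consolidate_fixed(self) -> int:
        """Fold mutations fixed on every haplotype into the background sum.

        Phenotypes are unchanged; returns the number of mutations removed.
        """
        ids, counts = self.allele_counts()
        fixed = ids[counts == 2 * self.size]
        if fixed.size == 0:
            return 0
        shift = float(self.table.effect[fixed].sum())
        fixed_set = set(fixed.tolist())
        for haps, hsum in ((self.haps1, self.hsum1), (self.haps2, self.hsum2)):
            for i, h in enumerate(haps):
                keep = np.array([m not in fixed_set for m in h], dtype=bool)
                haps[i] = h[keep]
                hsum[i] -= shift
        # every individual carried two copies of each fixed mutation
        self.background += 2.0 * shift
        return int(fixed.size)


def _draw_mutation_batch(k, L, P_effecting, sigma_effect, rng):
    """k new mutations: uniform positions, Bernoulli effect/neutral split."""
    positions = rng.integers(0, L, size=k)
    effects = np.zeros(k)
    hit = rng.random(k) < P_effecting
    if sigma_effect > 0:
        effects[hit] = rng.normal(0.0, sigma_effect, size=int(hit.sum()))
    return positions, effects


def draw_new_mutations(mu_bp, L, P_effecting, sigma_effect, rng,
                       origin_generation: int = 0,
                       table: Optional[MutationTable] = None) -> list[MutationRecord]:
    """Mutations carried by one gamete: count ~ Poisson(mu_bp * L).

    Each lands at a uniform position; with probability ``P_effecting`` it
    carries an additive effect ~ Normal(0, sigma_effect), otherwise it is
    neutral (effect 0).  Registers in ``table`` (a fresh one if omitted).
    """
    if table is None:
        table = MutationTable()
    k = rng.poisson(mu_bp * L)
    positions, effects = _draw_mutation_batch(k, L, P_effecting, sigma_effect, rng)
    ids = table.add_batch(positions, effects, origin_generation)
    return [table.record(m) for m in ids]


def _cross(hap1, hap2, pos, breaks, first):
    """Splice a gamete from alternating parental segments at ``breaks``."""
    haps = (hap1, hap2) if first == 0 else (hap2, hap1)
    parts = []
    lo = 0.0
    for seg, hi in enumerate(list(breaks) + [np.inf]):
        h = haps[seg % 2]
        p = pos[h]
        a = np.searchsorted(p, lo, side="left")
        b = p.size if hi == np.inf else np.searchsorted(p, hi, side="left")
        if b > a:
            parts.append(h[a:b])
        lo = hi
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def recombine(hap1, hap2, r_bp, L, rng, table: MutationTable) -> np.ndarray:
    """One meiotic gamete: Poisson(r_bp * L) crossovers at uniform breakpoints.

    The gamete starts from a fair-coin choice of parental haplotype and
    switches at each breakpoint; with zero crossovers it is an exact copy of
    one haplotype.  Output is sorted by genomic position.
    """
    k = int(rng.poisson(r_bp * L))
    first = int(rng.integers(2))
    if k == 0:
        return hap1 if first == 0 else hap2
    breaks = np.sort(rng.uniform(0, L, size=k))
    return _cross(hap1, hap2, table.position, breaks, first)


def _assign_sexes(m, toggle, policy, rng):
    """Offspring sexes; 'alternating' keeps the generation ratio exact to +-1."""
    if policy == "alternating":
        sexes = (np.arange(m) + toggle) % 2 == 1
        return sexes, (toggle + m) % 2
    if policy == "bernoulli":
        return rng.random(m) < 0.5, toggle
    raise ValueError(f"unknown sex assignment policy {policy!r}")


def mate_and_reproduce(pop: GeneticPopulation, Ftot: np.ndarray,
                       p: GeneticParams, rng: np.random.Generator,
                       sex_toggle: int = 0) -> GeneticPopulation:
    """One round of same-day mating; returns the offspring population.

    Every female mates only with males sharing her exact emergence day; a
    female with no same-day males leaves no offspring.  Fathers are drawn
    uniformly with replacement (males may mate repeatedly).  Brood size is
    floor(mean(F_mother, F_father) * max_offspring).  Offspring get one
    recombined + mutated gamete per parent, a fresh non-genetic noise draw,
    a sex (exact 1:1 by default), and are born at the low-tide waterline of
    the parents' shared day.
    """
    L, table = p.genome_length, pop.table
    fem = np.flatnonzero(~pop.is_male)
    mal = np.flatnonzero(pop.is_male)
    empty = GeneticPopulation(
        pop.generation + 1, np.empty(0), np.empty(0), np.empty(0, bool),
        [], [], np.empty(0), np.empty(0), table, pop.background, pop.initial_T,
    )
    if fem.size == 0 or mal.size == 0:
        return empty

    # group males by emergence day, then match each female to a random
    # same-day male (uniform with replacement)
    order = np.argsort(pop.T[mal], kind="stable")
    mal_sorted = mal[order]
    days, starts, counts = np.unique(
        pop.T[mal_sorted], return_index=True, return_counts=True
    )
    gi = np.searchsorted(days, pop.T[fem])
    gi_c = np.minimum(gi, days.size - 1)
    has_mate = days[gi_c] == pop.T[fem]
    mothers = fem[has_mate]
    if mothers.size == 0:
        return empty
    g = gi_c[has_mate]
    fathers = mal_sorted[starts[g] + rng.integers(0, counts[g])]
    n_off = np.floor(
        0.5 * (Ftot[mothers] + Ftot[fathers]) * p.max_offspring
    ).astype(np.int64)
    M = int(n_off.sum())
    if M == 0:
        return empty

    mother_of = np.repeat(mothers, n_off)
    father_of = np.repeat(fathers, n_off)
    birth_depth = _tide_depth(pop.T[mother_of])  # parents share this day

    # pre-draw all meiotic randomness for the generation in one batch
    xo = rng.poisson(p.r_bp * L, size=2 * M)
    nmut = rng.poisson(p.mu_bp * L, size=2 * M)
    coin = rng.integers(0, 2, size=2 * M)
    noise = rng.normal(0.0, p.sigma_emergence, size=M) if p.sigma_emergence > 0 else np.zeros(M)
    total_xo = int(xo.sum())
    breaks_all = rng.uniform(0, L, size=total_xo)
    total_mut = int(nmut.sum())
    mpos, meff = _draw_mutation_batch(total_mut, L, p.P_effecting, p.sigma_effect, rng)
    new_ids = table.add_batch(mpos, meff, pop.generation + 1)
    eff = table.effect
    tpos = table.position

    haps1, haps2 = [], []
    hsum1 = np.empty(M)
    hsum2 = np.empty(M)
    xo_off, mut_off = 0, 0
    for o in range(M):
        for side in (0, 1):
            gidx = 2 * o + side
            parent = mother_of[o] if side == 0 else father_of[o]
            k_xo, k_mut, first = int(xo[gidx]), int(nmut[gidx]), int(coin[gidx])
            if k_xo == 0:
                gam = pop.haps1[parent] if first == 0 else pop.haps2[parent]
                gsum = pop.hsum1[parent] if first == 0 else pop.hsum2[parent]
            else:
                br = np.sort(breaks_all[xo_off : xo_off + k_xo])
                xo_off += k_xo
                gam = _cross(pop.haps1[parent], pop.haps2[parent], tpos, br, first)
                gsum = float(eff[gam].sum()) if gam.size else 0.0
            if k_mut:
                add = new_ids[mut_off : mut_off + k_mut]
                mut_off += k_mut
                merged = np.concatenate([gam, add])
                merged = merged[np.argsort(tpos[merged], kind="stable")]
                gam = merged
                gsum = gsum + float(eff[add].sum())
            if side == 0:
                haps1.append(gam)
                hsum1[o] = gsum
            else:
                haps2.append(gam)
                hsum2[o] = gsum

    sexes, _ = _assign_sexes(M, sex_toggle, p.sex_assignment, rng)
    return GeneticPopulation(
        pop.generation + 1, birth_depth.astype(float), noise, sexes,
        haps1, haps2, hsum1, hsum2, table, pop.background, pop.initial_T,
    )


def _initial_population(p: GeneticParams, rng: np.random.Generator) -> GeneticPopulation:
    n = p.initial_N
    noise = rng.normal(0.0, p.sigma_emergence, size=n) if p.sigma_emergence > 0 else np.zeros(n)
    empty_h = np.empty(0, dtype=np.int64)
    return GeneticPopulation(
        0,
        np.full(n, float(p.initial_depth)),
        noise,
        np.arange(n) % 2 == 1,           # exact 1:1 founders
        [empty_h] * n, [empty_h] * n,
        np.zeros(n), np.zeros(n),
        MutationTable(), 0.0, wrap_lunar_day(p.initial_T),
    )


def step_generation_genetic(pop: GeneticPopulation, p: GeneticParams,
                            rng: np.random.Generator, sex_toggle: int = 0,
                            record: Optional[dict] = None) -> GeneticPopulation:
    """One full generation: dispersal -> Fe -> I/Fc -> Ftot -> mating -> death."""
    n = pop.size
    if n == 0:
        return mate_and_reproduce(pop, np.empty(0), p, rng, sex_toggle)
    pop.depth = _disperse(pop.depth, p.sigma_dispersal, p.boundary, rng)
    Fe = environmental_fitness(pop.depth, p.fitness_variant)
    I = competition_strengths(pop.depth, p.Cw)
    Fc = competition_fitness(I, p.K)
    Ftot = total_fitness(Fe, Fc)
    if record is not None:
        record.update(depth=pop.depth.copy(), Fe=Fe, Fc=Fc, Ftot=Ftot)
    return mate_and_reproduce(pop, Ftot, p, rng, sex_toggle)


def run_genetic(p: GeneticParams, rng: Optional[np.random.Generator] = None) -> RunResult:
    """Run the genetic model for ``p.generations`` generations.

    Records per-generation phenotype histograms and depth subsamples; when
    ``p.sample_genotypes`` is set, takes a random sample of
    ``p.sample_size`` individuals every ``p.sample_every`` generations (and
    at the final generation) and stores their 0/1/2 genotype matrix at
    sites variable within the sample.  Extinction is recorded, not raised.
    """
    from .observables import count_chronotypes, genotype_matrix
    from .results import GenotypeSample

    if rng is None:
        rng = np.random.default_rng(p.seed)
    pop = _initial_population(p, rng)
    hists = np.zeros((p.generations + 1, LUNAR_PERIOD), dtype=np.int64)
    hists[0] = pop.histogram()
    depth_samples: list[np.ndarray] = []
    genotype_samples: list[GenotypeSample] = []

    def maybe_sample(g):
        if not p.sample_genotypes or pop.size == 0:
            return
        k = min(p.sample_size, pop.size)
        idx = rng.choice(pop.size, size=k, replace=False)
        mat, sites = genotype_matrix(pop.take(idx))
        genotype_samples.append(GenotypeSample(g, mat, sites))

    sex_toggle = 0
    for g in range(p.generations):
        rec: dict = {}
        pop = step_generation_genetic(pop, p, rng, sex_toggle, record=rec)
        sex_toggle = (sex_toggle + pop.size) % 2
        hists[g + 1] = pop.histogram()
        d = rec.get("depth", np.empty(0))
        if d.size > p.record_depth_max:
            d = rng.choice(d, size=p.record_depth_max, replace=False)
        depth_samples.append(np.asarray(d, dtype=float))
        gen = g + 1
        if p.sample_every and gen % p.sample_every == 0 and gen != p.generations:
            maybe_sample(gen)
        if p.consolidate_every and gen % p.consolidate_every == 0:
            pop.consolidate_fixed()
        if pop.size == 0:
            break
    maybe_sample(p.generations)

    census = hists.sum(axis=1)
    result = RunResult(
        params=p.to_dict(),
        histograms=hists,
        census=census,
        depth_samples=depth_samples,
        extinct=bool(census[-1] == 0),
        chronotype_count=count_chronotypes(hists[-1]),
        genotype_samples=genotype_samples,
        final_population=pop,
    )
    return result
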