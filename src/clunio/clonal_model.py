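"""The simple model: clonal reproduction with a directly mutating lunar-day trait.

Each individual carries an integer lunar day of emergence ``T`` (1..30, the
timing phenotype, set by its circalunar clock) and a larval depth.  One
non-overlapping generation proceeds:

1. larval dispersal -- depth perturbed by Normal(0, sigma_dispersal)
   (unbounded by default; confining boundary policies are available);
2. environmental fitness Fe from the post-dispersal depth;
3. competition load I over all larvae at once, giving Fc;
4. total fitness Ftot = Fe * Fc;
5. emergence -- adults move to the low-tide waterline of their day ``T``;
6. each adult leaves floor(Ftot * max_offspring) clonal offspring;
7. offspring inherit ``T`` with mutation and are born at the parent's
   oviposition depth; parents die.

Mutation adds Normal(0.5, mu) to the parental day and floors, so the
phenotype changes only when the draw falls outside [0, 1); days wrap
periodically (31 -> 1, 0 -> 30).  Because offspring number is fitness-capped,
the birth rate alone regulates population size around the carrying capacity.
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
from .results import RunResult

__all__ = [
    "ClonalParams",
    "PopulationState",
    "mutate_phenotype",
    "step_generation_clonal",
    "run_clonal",
]


@dataclass
class ClonalParams:
    """Parameters of the clonal model (defaults: the reference parameter set)."""

    mu: float = 0.18                 # mutation s.d. of the Normal(0.5, mu) draw
    Cw: float = 0.1                  # competition kernel width, tidal-range units
    sigma_dispersal: float = 0.25    # larval dispersal s.d., tidal-range units
    K: int = 100                     # carrying capacity
    max_offspring: int = 5           # offspring cap per adult
    initial_T: int = 15              # founding lunar day
    initial_depth: float = 0.0       # founding depth
    initial_N: int = 10              # founders
    generations: int = 500
    fitness_variant: str = "sigmoid"
    seed: Optional[int] = None
    boundary: str = "none"           # depth boundary: none | clamp | reflect | truncate
    record_depth_max: int = 100      # depth subsample size per generation

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PopulationState:
    """Living population at one generation: parallel arrays of depth and T."""

    generation: int
    depth: np.ndarray
    T: np.ndarray

    @property
    def size(self) -> int:
        return self.depth.size

    def histogram(self) -> np.ndarray:
        """30-bin phenotype histogram of the living population."""
        return np.bincount(self.T, minlength=LUNAR_PERIOD + 1)[1:]


def _disperse(depth: np.ndarray, sigma: float, policy: str,
              rng: np.random.Generator) -> np.ndarray:
    """Larval dispersal with the chosen depth boundary policy.

    ``truncate`` redraws each out-of-bounds displacement until the larva
    lands inside [-1, 1] (truncated-normal dispersal, the "reprising"
    boundary of spatial forward simulators): no density piles up at the
    walls and no larva leaves the intertidal.
    """
    new = depth + rng.normal(0.0, sigma, depth.size)
    if policy == "truncate":
        bad = np.flatnonzero((new < -1.0) | (new > 1.0))
        while bad.size:
            new[bad] = depth[bad] + rng.normal(0.0, sigma, bad.size)
            bad = bad[(new[bad] < -1.0) | (new[bad] > 1.0)]
        return new
    return _confine(new, policy)


def _confine(depth: np.ndarray, policy: str) -> np.ndarray:
    """Apply a static depth boundary policy."""
    if policy == "none":
        return depth
    if policy == "clamp":
        return np.clip(depth, -1.0, 1.0)
    if policy == "reflect":
        # fold the axis: reflect about +-1 until inside (one fold suffices
        # for any realistic dispersal draw, but loop to be safe)
        d = depth.copy()
        while True:
            over = d > 1.0
            under = d < -1.0
            if not (over.any() or under.any()):
                return d
            d[over] = 2.0 - d[over]
            d[under] = -2.0 - d[under]
    raise ValueError(f"unknown boundary policy {policy!r}")


def mutate_phenotype(T_parent: int, mu: float, rng: np.random.Generator) -> int:
    """Mutate one lunar-day phenotype: T' = wrap(floor(T + Normal(0.5, mu))).

    With the centring at 0.5, a draw inside [0, 1) leaves the integer day
    unchanged; mu tunes the per-birth probability of a +-1 (or larger) step.
    """
    eps = rng.normal(0.5, mu)
    return wrap_lunar_day(math.floor(T_parent + eps))


def _mutate_many(T_parent: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.5, mu, size=T_parent.size)
    return (np.floor(T_parent + eps).astype(np.int64) - 1) % LUNAR_PERIOD + 1


def step_generation_clonal(
    state: PopulationState,
    p: ClonalParams,
    rng: np.random.Generator,
    record: Optional[dict] = None,
) -> PopulationState:
    """Advance the population one full generation (dispersal through birth).

    Extinction is absorbing: an empty population yields an empty offspring
    population.  If ``record`` is a dict, post-dispersal depths and fitness
    components of the stepped cohort are stored in it.
    """
    n = state.size
    if n == 0:
        return PopulationState(state.generation + 1, np.empty(0), np.empty(0, np.int64))

    depth = _disperse(state.depth, p.sigma_dispersal, p.boundary, rng)
    Fe = environmental_fitness(depth, p.fitness_variant)
    I = competition_strengths(depth, p.Cw)
    Fc = competition_fitness(I, p.K)
    Ftot = total_fitness(Fe, Fc)

    ovi_depth = _tide_depth(state.T)  # emergence: adults move to their waterline
    n_off = np.floor(Ftot * p.max_offspring).astype(np.int64)
    parent = np.repeat(np.arange(n), n_off)
    T_off = _mutate_many(state.T[parent], p.mu, rng) if p.mu > 0 else state.T[parent].copy()
    depth_off = ovi_depth[parent]

    if record is not None:
        record.update(depth=depth, Fe=Fe, Fc=Fc, Ftot=Ftot, offspring=n_off)
    return PopulationState(state.generation + 1, depth_off, T_off)


def run_clonal(p: ClonalParams, rng: Optional[np.random.Generator] = None) -> RunResult:
    """Run the clonal model for ``p.generations`` generations.

    Records the 30-bin phenotype histogram at every generation and a
    subsample of post-dispersal larval depths for every stepped generation.
    The final chronotype count is the number of peaks in the last
    histogram.  Extinction is recorded, never raised.
    """
    from .observables import count_chronotypes

    if rng is None:
        rng = np.random.default_rng(p.seed)
    state = PopulationState(
        generation=0,
        depth=np.full(p.initial_N, float(p.initial_depth)),
        T=np.full(p.initial_N, wrap_lunar_day(p.initial_T), dtype=np.int64),
    )
    hists = np.zeros((p.generations + 1, LUNAR_PERIOD), dtype=np.int64)
    depth_samples: list[np.ndarray] = []
    hists[0] = state.histogram()
    for g in range(p.generations):
        rec: dict = {}
        state = step_generation_clonal(state, p, rng, record=rec)
        hists[g + 1] = state.histogram()
        d = rec.get("depth", np.empty(0))
        if d.size > p.record_depth_max:
            d = rng.choice(d, size=p.record_depth_max, replace=False)
        depth_samples.append(np.asarray(d, dtype=float))
        if state.size == 0:
            break  # absorbing; remaining histogram rows stay zero
    census = hists.sum(axis=1)
    return RunResult(
        params=p.to_dict(),
        histograms=hists,
        census=census,
        depth_samples=depth_samples,
        extinct=bool(census[-1] == 0),
        chronotype_count=count_chronotypes(hists[-1]),
    )
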