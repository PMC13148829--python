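"""Summary statistics and assays on simulated populations.

* chronotype counting -- peaks of the (circular) lunar-day phenotype
  histogram, the headline readout of divergence;
* pairwise invasibility -- can a rare mutant emergence day invade, fail, or
  coexist with a resident day;
* intermediate-frequency-allele fraction -- the genomic signature of a
  structured (diverged) population;
* genotype matrix construction for principal components analysis.
"""

from __future__ import annotations

import enum
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .environment import LUNAR_PERIOD, _tide_depth, wrap_lunar_day

__all__ = [
    "InvasionOutcome",
    "count_chronotypes",
    "chronotype_peaks",
    "smoothed_histogram",
    "invasion_assay",
    "intermediate_allele_fraction",
    "genotype_matrix",
]


class InvasionOutcome(str, enum.Enum):
    MUTANT_INVADED = "mutant_invaded"
    RESIDENT_PERSISTED = "resident_persisted"
    COEXISTENCE = "coexistence"
    BOTH_EXTINCT = "both_extinct"


def _circular_gaussian_kernel(sd: float) -> np.ndarray:
    """Gaussian kernel wrapped onto the 30-day circle, normalised to sum 1."""
    d = np.arange(LUNAR_PERIOD)
    w = np.zeros(LUNAR_PERIOD)
    for k in (-2, -1, 0, 1, 2):  # fold the tails; +-2 periods is ample for sd <= ~8
        w += np.exp(-((d + k * LUNAR_PERIOD) ** 2) / (2.0 * sd * sd))
    return w / w.sum()


def smoothed_histogram(hist: np.ndarray, smoothing_sd: float = 1.0) -> np.ndarray:
    """Circularly smooth a 30-bin histogram with a wrapped Gaussian (sd in days)."""
    hist = np.asarray(hist, dtype=float)
    if smoothing_sd <= 0:
        return hist
    w = _circular_gaussian_kernel(smoothing_sd)
    idx = (np.arange(LUNAR_PERIOD)[:, None] - np.arange(LUNAR_PERIOD)[None, :]) % LUNAR_PERIOD
    return w[idx] @ hist


def chronotype_peaks(hist, smoothing_sd: float = 0.5,
                     min_peak_fraction: float = 0.05) -> np.ndarray:
    """Lunar days (1..30) of the peaks of the smoothed circular histogram.

    A peak is a circular local maximum of the wrapped-Gaussian-smoothed
    histogram whose smoothed height is at least ``min_peak_fraction`` of
    the census; a plateau of equal adjacent maxima counts once (its middle
    day is reported).  Empty or perfectly uniform histograms have no
    well-defined peaks and yield an empty array.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (LUNAR_PERIOD,):
        raise ValueError(f"expected a {LUNAR_PERIOD}-bin histogram")
    census = hist.sum()
    if census == 0:
        return np.empty(0, dtype=np.int64)
    s = smoothed_histogram(hist, smoothing_sd)
    # treat numerically flat profiles as uniform (no well-defined peaks)
    if np.ptp(s) <= 1e-9 * max(1.0, census):
        return np.empty(0, dtype=np.int64)
    threshold = min_peak_fraction * census
    # run-length encode the circle starting at a value change, then test
    # each run against its (distinct-valued) neighbours
    start = int(np.flatnonzero(s != np.roll(s, 1))[0])
    r = np.roll(s, -start)
    change = np.flatnonzero(np.diff(r) != 0) + 1
    run_starts = np.concatenate([[0], change])
    run_lens = np.diff(np.concatenate([run_starts, [LUNAR_PERIOD]]))
    run_vals = r[run_starts]
    m = run_vals.size
    days = []
    for i in range(m):
        v = run_vals[i]
        if v < threshold:
            continue
        if v > run_vals[(i - 1) % m] and v > run_vals[(i + 1) % m]:
            mid = run_starts[i] + (run_lens[i] - 1) // 2  # middle of a plateau
            days.append((start + mid) % LUNAR_PERIOD + 1)
    return np.sort(np.asarray(days, dtype=np.int64))


def count_chronotypes(hist, smoothing_sd: float = 0.5,
                      min_peak_fraction: float = 0.05) -> int:
    """Number of chronotypes: peaks of the smoothed circular histogram.

    See :func:`chronotype_peaks` for the peak rule.  An empty histogram has
    0 chronotypes; a perfectly uniform non-empty one counts as a single
    undifferentiated chronotype.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (LUNAR_PERIOD,):
        raise ValueError(f"expected a {LUNAR_PERIOD}-bin histogram")
    census = hist.sum()
    if census == 0:
        return 0
    s = smoothed_histogram(hist, smoothing_sd)
    if np.ptp(s) <= 1e-9 * max(1.0, census):
        return 1
    return int(chronotype_peaks(hist, smoothing_sd, min_peak_fraction).size)


def invasion_assay(resident_T: int, mutant_T: int, p, rng: np.random.Generator,
                   introduce_at: int = 250, end_at: int = 500) -> InvasionOutcome:
    """Classify the fate of a rare mutant emergence day against a resident.

    A mutation-free resident population (clonal model, ``mu = 0``) is burnt
    in for ``introduce_at`` generations; a single mutant with lunar day
    ``mutant_T`` is then inserted at the waterline of its own day (as if its
    egg had been laid by a mutant parent), and the run continues to
    ``end_at``.  The outcome is read off from which phenotypes remain.  On
    the diagonal (mutant == resident) the two phenotypes are
    indistinguishable and the assay is degenerate; sweep drivers skip it.
    """
    from .clonal_model import ClonalParams, PopulationState, step_generation_clonal

    resident_T = wrap_lunar_day(resident_T)
    mutant_T = wrap_lunar_day(mutant_T)
    p = replace(p, mu=0.0, initial_T=resident_T)
    state = PopulationState(
        0,
        np.full(p.initial_N, float(p.initial_depth)),
        np.full(p.initial_N, resident_T, dtype=np.int64),
    )
    for _ in range(introduce_at):
        state = step_generation_clonal(state, p, rng)
    if state.size == 0:
        return InvasionOutcome.BOTH_EXTINCT
    state = PopulationState(
        state.generation,
        np.append(state.depth, _tide_depth(np.int64(mutant_T))),
        np.append(state.T, mutant_T),
    )
    for _ in range(end_at - introduce_at):
        state = step_generation_clonal(state, p, rng)
    res = bool(np.any(state.T == resident_T))
    mut = bool(np.any(state.T == mutant_T))
    if res and mut:
        return InvasionOutcome.COEXISTENCE
    if mut:
        return InvasionOutcome.MUTANT_INVADED
    if res:
        return InvasionOutcome.RESIDENT_PERSISTED
    return InvasionOutcome.BOTH_EXTINCT


def intermediate_allele_fraction(pop, lo: float = 0.3, hi: float = 0.7) -> float:
    """Fraction of segregating alleles at population frequency in [lo, hi].

    Frequencies are counted over the 2N chromosome copies of the living
    population; only segregating mutations (frequency strictly inside
    (0, 1); fixed and lost alleles excluded) enter numerator and
    denominator.  An excess of intermediate-frequency alleles is the
    genomic signature of a population split into coexisting chronotypes.
    Returns 0 when nothing segregates; raises on an empty population.
    """
    if not (lo < hi):
        raise ValueError("need lo < hi")
    if pop.size == 0:
        raise ValueError("allele frequencies undefined for an empty population")
    ids, counts = pop.allele_counts()
    seg = counts < 2 * pop.size  # counts are >= 1 by construction
    if not np.any(seg):
        return 0.0
    freq = counts[seg] / (2.0 * pop.size)
    return float(np.mean((freq >= lo) & (freq <= hi)))


def genotype_matrix(sample) -> tuple[np.ndarray, pd.DataFrame]:
    """0/1/2 genotype matrix of a sample at sites variable within the sample.

    Rows are individuals, columns are mutations segregating *within the
    sample* (monomorphic sites dropped), entries are copies carried.  Site
    metadata (genomic position, effect size, origin generation) comes back
    as a DataFrame aligned with the columns; pass the matrix straight to
    any standard PCA.
    """
    n = sample.size
    if n == 0:
        raise ValueError("empty sample")
    ids, counts = sample.allele_counts()
    keep = ids[(counts > 0) & (counts < 2 * n)]
    mat = np.zeros((n, keep.size), dtype=np.int8)
    if keep.size:
        for i in range(n):
            for h in (sample.haps1[i], sample.haps2[i]):
                if h.size == 0:
                    continue
                j = np.searchsorted(keep, h)  # keep is sorted (np.unique output)
                ok = (j < keep.size) & (keep[np.minimum(j, keep.size - 1)] == h)
                np.add.at(mat[i], j[ok], 1)
    table = sample.table
    sites = pd.DataFrame(
        {
            "id": keep,
            "position": table.position[keep] if keep.size else np.empty(0, np.int64),
            "effect": table.effect[keep] if keep.size else np.empty(0),
            "origin_generation": table.origin[keep] if keep.size else np.empty(0, np.int64),
        }
    )
    return mat, sites
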