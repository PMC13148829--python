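"""Run-level result containers shared by the clonal and genetic models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .environment import LUNAR_PERIOD

__all__ = ["GenotypeSample", "RunResult"]


@dataclass
class GenotypeSample:
    """Genotypes of a random sample of individuals at one generation.

    ``matrix`` has one row per sampled individual and one column per site
    that is variable within the sample; entries are the number of copies
    carried (0/1/2).  ``sites`` holds per-column metadata (position, effect
    size, origin generation).
    """

    generation: int
    matrix: np.ndarray
    sites: pd.DataFrame


@dataclass
class RunResult:
    """Full record of one simulation run.

    Attributes
    ----------
    params : dict
        The parameter set the run was executed with.
    histograms : (n_generations + 1, 30) int array
        Phenotype histogram of the living population at every generation
        (row 0 is the initial population; the last row is the final one).
    census : int array
        Population size per generation (row sums of ``histograms``).
    depth_samples : list of float arrays
        Post-dispersal larval depths, subsampled per generation.
    extinct : bool
        Whether the population hit size 0 (absorbing).
    chronotype_count : int
        Number of phenotype-distribution peaks in the final generation.
    genotype_samples : list of GenotypeSample
        Periodic genotype samples (genetic model only, when requested).
    final_population : object or None
        The living population at the last generation (genetic model only);
        carries the haplotypes needed for allele-frequency statistics.
    """

    params: dict[str, Any]
    histograms: np.ndarray
    census: np.ndarray
    depth_samples: list[np.ndarray]
    extinct: bool
    chronotype_count: int
    genotype_samples: list[GenotypeSample] = field(default_factory=list)
    final_population: Any = None

    @property
    def final_histogram(self) -> np.ndarray:
        return self.histograms[-1]

    def histogram_frame(self) -> pd.DataFrame:
        """Histograms as a tidy frame: generation, day_1 .. day_30."""
        cols = [f"day_{d}" for d in range(1, LUNAR_PERIOD + 1)]
        df = pd.DataFrame(self.histograms, columns=cols)
        df.insert(0, "generation", np.arange(len(df)))
        return df

    def depth_frame(self) -> pd.DataFrame:
        """Depth subsamples as a long frame: generation, depth."""
        gens = np.concatenate(
            [np.full(len(d), g) for g, d in enumerate(self.depth_samples)]
        ) if self.depth_samples else np.empty(0, dtype=int)
        depths = (
            np.concatenate(self.depth_samples) if self.depth_samples else np.empty(0)
        )
        return pd.DataFrame({"generation": gens.astype(int), "depth": depths})
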