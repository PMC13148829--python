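"""Replicated parameter sweeps over the ecological and genetic parameter spaces.

The reference experiments are grids of independent simulation runs:

* ecological grid -- chronotype count over (Cw, sigma_dispersal), clonal or
  genetic model (40 linearly spaced values per axis in [0.025, 1] at full
  scale);
* genetic grid -- intermediate-allele fraction over
  (P_effecting, sigma_effect, sigma_emergence) (21 values per axis in
  [0, 1] x [0, 0.5] x [0, 3]);
* fitness-function scan -- the ecological grid repeated for each
  environmental fitness variant (25 values per axis at full scale);
* initial-phenotype scan -- branching and final phenotypes for every
  founding lunar day 1..30;
* invasibility grid -- resident x mutant emergence-day pairs.

Every (grid point, replicate) task gets its own derived seed
(``base_seed + point_index * replicates + replicate``), so seeds are
collision-free, results are independent of execution order, and a sweep can
be resumed after interruption.  Full-scale grids with 1000 replicates are
cluster-sized runs; the default replicate count here is desk-scale (20).
"""

from __future__ import annotations

import itertools
import os
import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clonal_model import ClonalParams, run_clonal
from .genetic_model import GeneticParams, run_genetic
from .observables import (
    chronotype_peaks,
    count_chronotypes,
    intermediate_allele_fraction,
    invasion_assay,
)

__all__ = [
    "SweepSpec",
    "ecological_grid",
    "genetic_grid",
    "run_sweep",
    "aggregate_sweep",
    "initial_phenotype_scan",
    "fitness_function_scan",
    "invasion_grid",
]

STATISTICS = ("chronotype_count", "intermediate_allele_fraction", "invasion_outcome")


def ecological_grid(n: int = 40, lo: float = 0.025, hi: float = 1.0) -> dict:
    """(Cw, sigma_dispersal) grid: n linearly spaced values per axis."""
    vals = np.linspace(lo, hi, n)
    return {"Cw": vals.tolist(), "sigma_dispersal": vals.tolist()}


def genetic_grid(n: int = 21) -> dict:
    """(P_effecting, sigma_effect, sigma_emergence) grid, n values per axis."""
    return {
        "P_effecting": np.linspace(0.0, 1.0, n).tolist(),
        "sigma_effect": np.linspace(0.0, 0.5, n).tolist(),
        "sigma_emergence": np.linspace(0.0, 3.0, n).tolist(),
    }


@dataclass
class SweepSpec:
    """One sweep: model, grid axes, replication, statistic, base seed."""

    model: str = "clonal"                     # clonal | genetic
    grid: dict = field(default_factory=dict)  # axis name -> list of values
    replicates: int = 20
    generations: Optional[int] = None         # None -> model default
    statistic: str = "chronotype_count"
    base_seed: int = 0
    base_params: dict = field(default_factory=dict)  # non-swept overrides

    def validate(self) -> None:
        if self.model not in ("clonal", "genetic"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.statistic == "intermediate_allele_fraction" and self.model != "genetic":
            raise ValueError("allele-frequency statistics need the genetic model")
        cls = ClonalParams if self.model == "clonal" else GeneticParams
        if self.statistic == "invasion_outcome":
            axes = set(self.grid) - {"resident_T", "mutant_T"}
        else:
            axes = set(self.grid)
        bad = axes - set(cls.__dataclass_fields__)
        if bad:
            raise ValueError(f"grid axes not parameters of the {self.model} model: {bad}")

    def points(self) -> list[dict]:
        names = list(self.grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.grid[k] for k in names))
        ]


def _base_params(spec: SweepSpec):
    cls = ClonalParams if spec.model == "clonal" else GeneticParams
    p = cls(**spec.base_params)
    if spec.generations is not None:
        p = replace(p, generations=spec.generations)
    return p


def _run_task(spec: SweepSpec, point: dict, seed: int):
    """One (grid point, replicate) task; returns (value, extinct, census)."""
    if spec.statistic == "invasion_outcome":
        resident, mutant = int(point["resident_T"]), int(point["mutant_T"])
        overrides = {k: v for k, v in point.items() if k not in ("resident_T", "mutant_T")}
        p = replace(_base_params(spec), **overrides)
        if resident == mutant:
            return "skipped_diagonal", np.nan, np.nan
        out = invasion_assay(resident, mutant, p, np.random.default_rng(seed))
        return out.value, np.nan, np.nan
    p = replace(_base_params(spec), **point, seed=seed)
    res = run_clonal(p) if spec.model == "clonal" else run_genetic(p)
    if spec.statistic == "chronotype_count":
        value = res.chronotype_count
    else:  # intermediate_allele_fraction
        value = (
            0.0 if res.extinct
            else intermediate_allele_fraction(res.final_population)
        )
    return value, res.extinct, int(res.census[-1])


def run_sweep(spec: SweepSpec, out_csv: Optional[str] = None,
              progress: bool = False) -> pd.DataFrame:
    """Run every (grid point, replicate) task serially; long-format result.

    One row per task: the grid coordinates, replicate index, derived seed,
    statistic value, extinction flag, final census and runtime.  When
    ``out_csv`` is given, completed rows are appended incrementally and
    already-present (point, replicate) pairs are skipped on resume, so the
    aggregate is invariant to interruption and execution order.
    """
    spec.validate()
    points = spec.points()
    done: set[tuple[int, int]] = set()
    rows: list[dict] = []
    if out_csv and os.path.exists(out_csv):
        prev = pd.read_csv(out_csv)
        rows = prev.to_dict("records")
        done = set(zip(prev["point_index"].astype(int), prev["replicate"].astype(int)))
    for gi, point in enumerate(points):
        for r in range(spec.replicates):
            if (gi, r) in done:
                continue
            seed = spec.base_seed + gi * spec.replicates + r
            t0 = time.perf_counter()
            value, extinct, census = _run_task(spec, point, seed)
            row = {
                "point_index": gi, **point, "replicate": r, "seed": seed,
                "statistic": spec.statistic, "value": value,
                "extinct": extinct, "final_census": census,
                "runtime_s": round(time.perf_counter() - t0, 4),
            }
            rows.append(row)
            if out_csv:
                pd.DataFrame([row]).to_csv(
                    out_csv, mode="a", header=not os.path.exists(out_csv), index=False
                )
            if progress:
                print(f"[sweep] point {gi + 1}/{len(points)} rep {r + 1}/{spec.replicates}: "
                      f"{spec.statistic}={value}", flush=True)
    return pd.DataFrame(rows)


def aggregate_sweep(result: pd.DataFrame, spec: SweepSpec) -> pd.DataFrame:
    """Mean statistic (and extinction rate) per grid point."""
    axes = list(spec.grid)
    df = result.copy()
    if spec.statistic == "invasion_outcome":
        freq = (
            df.groupby(axes)["value"].value_counts(normalize=True)
            .unstack(fill_value=0.0).reset_index()
        )
        return freq
    df["value"] = pd.to_numeric(df["value"])
    agg = df.groupby(axes).agg(
        mean_value=("value", "mean"),
        extinct_fraction=("extinct", "mean"),
        n=("value", "size"),
    )
    return agg.reset_index()


def initial_phenotype_scan(p: ClonalParams | GeneticParams, reps: int = 20,
                           base_seed: int = 0) -> pd.DataFrame:
    """Branching and final phenotypes for every founding lunar day 1..30.

    For each initial day and replicate, records the first generation at
    which the population shows >= 2 chronotypes, the peak days at that
    branching generation, and the peak days of the final generation.
    Peak-day lists are semicolon-joined strings (tidy long CSV friendly).
    """
    runner = run_clonal if isinstance(p, ClonalParams) else run_genetic
    rows = []
    for i, T0 in enumerate(range(1, 31)):
        for r in range(reps):
            seed = base_seed + i * reps + r
            res = runner(replace(p, initial_T=T0, seed=seed))
            branch_gen = np.nan
            branch_peaks: list[int] = []
            for g, h in enumerate(res.histograms):
                if count_chronotypes(h) >= 2:
                    branch_gen = g
                    branch_peaks = chronotype_peaks(h).tolist()
                    break
            final_peaks = chronotype_peaks(res.histograms[-1]).tolist()
            rows.append({
                "initial_T": T0, "replicate": r, "seed": seed,
                "branch_generation": branch_gen,
                "branch_peaks": ";".join(map(str, branch_peaks)),
                "final_peaks": ";".join(map(str, final_peaks)),
                "final_count": res.chronotype_count,
                "extinct": res.extinct,
            })
    return pd.DataFrame(rows)


def fitness_function_scan(
    spec: SweepSpec,
    variants: Sequence[str] = ("flat", "linear", "unimodal", "bimodal"),
    out_csv: Optional[str] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """The ecological sweep repeated for each environmental fitness variant.

    ``fitness_variant`` is added to the grid as an extra axis (the
    full-scale reference uses 25 values per ecological axis).
    """
    spec = replace(spec, grid={**spec.grid, "fitness_variant": list(variants)})
    return run_sweep(spec, out_csv=out_csv, progress=progress)


def invasion_grid(days: Sequence[int] = range(1, 31), replicates: int = 20,
                  base_seed: int = 0, base_params: Optional[dict] = None) -> SweepSpec:
    """SweepSpec for the pairwise invasibility experiment (diagonal skipped)."""
    return SweepSpec(
        model="clonal",
        grid={"resident_T": list(days), "mutant_T": list(days)},
        replicates=replicates,
        statistic="invasion_outcome",
        base_seed=base_seed,
        base_params=base_params or {},
    )
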