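"""Grid-search inference of the KO viability coefficient from cage observations.

The observed quantity is the fraction of scored flies that are homozygous
wildtype (the marker-absent class).  For each candidate F_KO on a fixed grid,
the deterministic cage model is run and the mean absolute error (MAE) between
observed fractions and the model's post-selection homozygous-WT fraction at
the matching generations is computed; the grid minimizer is returned.  Model
selection repeats the fit under the three dominance scenarios and keeps the
global MAE minimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from .model import (
    FitnessScheme,
    Scenario,
    SexedPopulation,
    Trajectory,
    simulate_deterministic,
)

__all__ = [
    "Observation",
    "GridSpec",
    "FitResult",
    "mean_absolute_error",
    "fit_grid",
    "select_model",
]

# Fixed evaluation order for model selection; ties keep the earlier scenario.
SCENARIO_ORDER = (Scenario.HET_EQUALS_WT, Scenario.ADDITIVE, Scenario.HET_EQUALS_KO)


@dataclass(frozen=True)
class Observation:
    """One scored cage sample: replicate, generation, total and hom-WT counts."""

    replicate: str
    generation: int
    n_total: int
    n_hom_wt: int

    def __post_init__(self) -> None:
        if self.generation < 1:
            raise ValueError(f"generation {self.generation} must be >= 1")
        if self.n_total < 0 or self.n_hom_wt < 0:
            raise ValueError("counts must be non-negative")
        if self.n_hom_wt > self.n_total:
            raise ValueError(
                f"n_hom_wt={self.n_hom_wt} exceeds n_total={self.n_total} "
                f"(replicate {self.replicate}, generation {self.generation})"
            )

    @property
    def frac_hom_wt(self) -> float:
        if self.n_total == 0:
            raise ValueError("fraction undefined for n_total == 0")
        return self.n_hom_wt / self.n_total


@dataclass(frozen=True)
class GridSpec:
    """Inclusive F_KO grid lo..hi in steps of ``step``. Defaults 0.4-1.0 by 0.001."""

    lo: float = 0.4
    hi: float = 1.0
    step: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi <= 1.0):
            raise ValueError(f"require 0 < lo < hi <= 1, got lo={self.lo}, hi={self.hi}")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def values(self) -> list[float]:
        # lo + k*step rather than cumulative addition, to avoid float drift;
        # the upper endpoint is always included.
        n = int(math.floor((self.hi - self.lo) / self.step + 1e-9))
        vals = [self.lo + k * self.step for k in range(n + 1)]
        if vals[-1] < self.hi - 1e-12:
            vals.append(self.hi)
        vals[-1] = min(vals[-1], self.hi)
        return vals


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid fit: scenario, fitted F_KO, s = 1 - F_KO, and MAE."""

    scenario: Scenario
    f_ko_hat: float
    mae: float
    trajectory: Trajectory
    grid: GridSpec
    n_generations: int

    @property
    def s_hat(self) -> float:
        return 1.0 - self.f_ko_hat

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.value,
            "f_ko_hat": self.f_ko_hat,
            "s_hat": self.s_hat,
            "mae": self.mae,
            "grid": {"lo": self.grid.lo, "hi": self.grid.hi, "step": self.grid.step},
            "n_generations": self.n_generations,
        }


def mean_absolute_error(traj: Trajectory, observations: Sequence[Observation]) -> float:
    """Mean over datapoints of |observed hom-WT fraction - model value|.

    Replicates are pooled: every observation is one equally weighted datapoint
    compared against the post-selection homozygous-WT fraction at its
    generation.
    """
    if not observations:
        raise ValueError("no observations supplied")
    total = 0.0
    for obs in observations:
        if obs.n_total == 0:
            raise ValueError(
                f"n_total == 0 (replicate {obs.replicate}, generation {obs.generation})"
            )
        if obs.generation > len(traj):
            raise ValueError(
                f"observation at generation {obs.generation} beyond the "
                f"{len(traj)}-generation trajectory"
            )
        total += abs(obs.frac_hom_wt - traj.f_wt_hom_post(obs.generation))
    return total / len(observations)


# Trajectories depend only on (seed, scenario, f_ko, horizon) and are immutable,
# so repeated grid fits over the same seed share them.
@lru_cache(maxsize=16384)
def _cached_trajectory(
    seed: SexedPopulation, scenario: Scenario, f_ko: float, n_generations: int
) -> Trajectory:
    return simulate_deterministic(seed, FitnessScheme(scenario=scenario, f_ko=f_ko), n_generations)


def fit_grid(
    observations: Sequence[Observation],
    scenario: Scenario | str,
    grid: GridSpec | None = None,
    seed: SexedPopulation | None = None,
    n_generations: int = 35,
) -> FitResult:
    """Minimize MAE over the F_KO grid for one dominance scenario.

    Ties are broken toward the largest F_KO (the weakest selection consistent
    with the data).  ``seed`` defaults to the cage-experiment founder mix.
    """
    from .model import paper_seed_population

    if not observations:
        raise ValueError("no observations supplied")
    scenario = Scenario(scenario)
    grid = grid or GridSpec()
    seed = seed or paper_seed_population()

    best_f = None
    best_mae = math.inf
    best_traj = None
    for f_ko in grid.values():
        traj = _cached_trajectory(seed, scenario, f_ko, n_generations)
        mae = mean_absolute_error(traj, observations)
        if mae < best_mae or (mae == best_mae and best_f is not None and f_ko > best_f):
            best_f, best_mae, best_traj = f_ko, mae, traj
    assert best_traj is not None
    return FitResult(
        scenario=scenario,
        f_ko_hat=best_f,
        mae=best_mae,
        trajectory=best_traj,
        grid=grid,
        n_generations=n_generations,
    )


def select_model(
    observations: Sequence[Observation],
    grid: GridSpec | None = None,
    seed: SexedPopulation | None = None,
    n_generations: int = 35,
) -> FitResult:
    """Fit all three dominance scenarios and return the global MAE minimizer.

    Scenarios are evaluated in the fixed order WT-dominant, additive,
    WT-recessive; on an exact MAE tie the earlier scenario is kept.
    """
    best: FitResult | None = None
    for scenario in SCENARIO_ORDER:
        result = fit_grid(observations, scenario, grid=grid, seed=seed, n_generations=n_generations)
        if best is None or result.mae < best.mae:
            best = result
    assert best is not None
    return best
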