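"""Stochastic finite-population cage simulator.

Emulates the laboratory experiment the deterministic model idealizes: replicate
bottles founded by 50 KO/KO females with 25 KO/KO and 25 WT/WT males, a census
bottleneck of 50 females + 50 males passaged each generation, viability
selection on the progeny, and scoring of a fixed number of eclosed adults per
bottle per generation for the dominant fluorescent KO marker (marker-absent =
homozygous WT).  Genetic drift arises from the founder bottleneck and the
finite scored progeny pool; there is no mutation or migration, so fixation is
absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitting import Observation
from .model import FitnessScheme, Genotype

__all__ = ["CageConfig", "ResamplingError", "simulate_cage", "write_observations"]

# Genotypes are coded by KO-allele dosage: 0 = WT/WT, 1 = WT/KO, 2 = KO/KO.
_DOSAGE = {Genotype.WT_HOM: 0, Genotype.HET: 1, Genotype.KO_HOM: 2}


class ResamplingError(RuntimeError):
    """Too few scored survivors of one sex to found the next generation."""


@dataclass(frozen=True)
class CageConfig:
    """Experimental design of the replicate cage bottles.

    Defaults reproduce the real experiment: founders of 50 KO/KO females plus
    25 KO/KO and 25 WT/WT males, 50 founders per sex passaged each generation,
    and 400 scored progeny per bottle per generation (a realistic bottle yield;
    the scored pool size is the one free design knob).
    """

    n_generations: int
    rng_seed: int
    founder_females: dict[Genotype, int] = field(
        default_factory=lambda: {Genotype.KO_HOM: 50}
    )
    founder_males: dict[Genotype, int] = field(
        default_factory=lambda: {Genotype.KO_HOM: 25, Genotype.WT_HOM: 25}
    )
    founders_per_sex_per_generation: int = 50
    progeny_scored_per_generation: int = 400
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        for name in ("founders_per_sex_per_generation", "progeny_scored_per_generation",
                     "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name, pool in (("founder_females", self.founder_females),
                           ("founder_males", self.founder_males)):
            if sum(pool.values()) < 1:
                raise ValueError(f"{name} pool is empty")
            if any(n < 0 for n in pool.values()):
                raise ValueError(f"{name} has a negative count")


def _founder_array(pool: dict[Genotype, int]) -> np.ndarray:
    parts = [np.full(n, _DOSAGE[Genotype(g)], dtype=np.int8) for g, n in pool.items()]
    return np.concatenate(parts)


def _draw_progeny(
    females: np.ndarray,
    males: np.ndarray,
    scheme: FitnessScheme,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` viability-filtered offspring genotypes (KO dosage codes).

    Each candidate offspring takes a uniformly chosen mother and father and one
    allele from each; it survives scoring with probability viability / max
    viability (rejection sampling), so survivors are an exact draw from the
    selection-reweighted offspring distribution.
    """
    viab = np.array([scheme.f_wt, scheme.f_het, scheme.f_ko]) / max(
        scheme.f_wt, scheme.f_het, scheme.f_ko
    )
    out = np.empty(0, dtype=np.int8)
    while out.size < n:
        batch = max(64, int((n - out.size) * 1.6))
        mothers = females[rng.integers(0, females.size, batch)]
        fathers = males[rng.integers(0, males.size, batch)]
        # transmit the KO allele with probability dosage/2
        mat = (rng.random(batch) < mothers / 2.0).astype(np.int8)
        pat = (rng.random(batch) < fathers / 2.0).astype(np.int8)
        offspring = mat + pat
        keep = rng.random(batch) < viab[offspring]
        out = np.concatenate([out, offspring[keep]])
    return out[:n]


def _simulate_replicate(
    config: CageConfig, scheme: FitnessScheme, replicate: str, seed: int
) -> list[Observation]:
    rng = np.random.default_rng(seed)
    females = _founder_array(config.founder_females)
    males = _founder_array(config.founder_males)
    n_score = config.progeny_scored_per_generation
    n_found = config.founders_per_sex_per_generation
    observations = []
    for gen in range(1, config.n_generations + 1):
        scored = _draw_progeny(females, males, scheme, n_score, rng)
        sex_female = rng.random(n_score) < 0.5
        observations.append(
            Observation(
                replicate=replicate,
                generation=gen,
                n_total=n_score,
                n_hom_wt=int(np.count_nonzero(scored == 0)),
            )
        )
        if gen == config.n_generations:
            break
        new_parents = []
        for is_female, label in ((True, "female"), (False, "male")):
            pool = scored[sex_female] if is_female else scored[~sex_female]
            if pool.size < n_found:
                raise ResamplingError(
                    f"replicate {replicate}, generation {gen}: only {pool.size} "
                    f"scored {label} survivors, need {n_found} founders"
                )
            new_parents.append(rng.choice(pool, size=n_found, replace=False))
        females, males = new_parents
    return observations


def simulate_cage(config: CageConfig, scheme: FitnessScheme) -> list[Observation]:
    """Simulate all replicate bottles; one Observation per replicate-generation.

    Replicate ``r`` (0-based) runs on its own RNG stream seeded with
    ``rng_seed + r``, so replicates are independent and individually
    reproducible; the whole table is byte-identical for identical inputs.
    """
    table: list[Observation] = []
    for r in range(config.n_replicates):
        table.extend(
            _simulate_replicate(config, scheme, replicate=f"r{r + 1}", seed=config.rng_seed + r)
        )
    return table


def write_observations(table: Sequence[Observation], destination) -> None:
    """Write observations as TSV (replicate, generation, n_total, n_hom_wt).

    Rows are sorted by (replicate, generation); the file round-trips losslessly
    through :func:`cagefit.io.read_observations`.
    """
    rows = sorted(table, key=lambda o: (o.replicate, o.generation))
    own = isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__")
    handle = open(destination, "w", encoding="utf-8") if own else destination
    try:
        handle.write("replicate\tgeneration\tn_total\tn_hom_wt\n")
        for o in rows:
            handle.write(f"{o.replicate}\t{o.generation}\t{o.n_total}\t{o.n_hom_wt}\n")
    finally:
        if own:
            handle.close()
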