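"""Deterministic population-cage model: random mating plus viability selection.

The model tracks the three diploid genotypes at a single autosomal locus with a
wildtype (WT) and a knockout (KO) allele.  Each generation an infinite, freely
mating population produces offspring by Mendelian segregation over all nine
mother x father genotype pairings; viability selection then reweights the
offspring genotype frequencies by relative fitness coefficients and
renormalizes.  Iterating this recursion yields the expected trajectory of the
homozygous-WT fraction in a population cage founded with a known genotype mix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "Genotype",
    "Scenario",
    "GenotypeDist",
    "SexedPopulation",
    "FitnessScheme",
    "GenerationRecord",
    "Trajectory",
    "mendelian_offspring",
    "offspring_pool",
    "apply_viability_selection",
    "simulate_deterministic",
    "paper_seed_population",
    "DegeneratePopulationError",
]

_TOL = 1e-9


class Genotype(str, enum.Enum):
    """Diploid genotype at the WT/KO locus."""

    WT_HOM = "WT/WT"
    HET = "WT/KO"
    KO_HOM = "KO/KO"


class Scenario(str, enum.Enum):
    """Assumed heterozygote viability relative to the homozygotes."""

    HET_EQUALS_WT = "het-eq-wt"
    ADDITIVE = "additive"
    HET_EQUALS_KO = "het-eq-ko"


class DegeneratePopulationError(ValueError):
    """Raised when selection annihilates every genotype class."""


@dataclass(frozen=True)
class GenotypeDist:
    """Fractions of the three diploid genotypes in a pool.

    Fields must be non-negative and sum to 1 (within 1e-9).
    """

    f_wt_hom: float
    f_het: float
    f_ko_hom: float

    def __post_init__(self) -> None:
        for name, v in (
            ("f_wt_hom", self.f_wt_hom),
            ("f_het", self.f_het),
            ("f_ko_hom", self.f_ko_hom),
        ):
            if not (-_TOL <= v <= 1.0 + _TOL):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        total = self.f_wt_hom + self.f_het + self.f_ko_hom
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"genotype fractions sum to {total!r}, not 1")

    @property
    def q_ko(self) -> float:
        """KO-allele frequency q = f_ko_hom + f_het / 2."""
        return self.f_ko_hom + 0.5 * self.f_het

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_wt_hom, self.f_het, self.f_ko_hom)

    @classmethod
    def from_allele_frequency(cls, q_ko: float) -> "GenotypeDist":
        """Hardy-Weinberg genotype distribution ((1-q)^2, 2q(1-q), q^2)."""
        if not 0.0 <= q_ko <= 1.0:
            raise ValueError(f"allele frequency {q_ko!r} outside [0, 1]")
        p = 1.0 - q_ko
        return cls(p * p, 2.0 * p * q_ko, q_ko * q_ko)

    @classmethod
    def from_counts(cls, n_wt_hom: float, n_het: float, n_ko_hom: float) -> "GenotypeDist":
        total = n_wt_hom + n_het + n_ko_hom
        if total <= 0:
            raise ValueError("counts sum to zero")
        return cls(n_wt_hom / total, n_het / total, n_ko_hom / total)


@dataclass(frozen=True)
class SexedPopulation:
    """Genotype distributions of the two parental sexes at one generation."""

    females: GenotypeDist
    males: GenotypeDist
    generation: int = 0

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation index must be non-negative")


@dataclass(frozen=True)
class FitnessScheme:
    """Relative viabilities (F_WT, F_het, F_KO) under a dominance scenario.

    F_WT is fixed at 1; the heterozygote viability is determined by the
    scenario: equal to WT (WT fully dominant for fitness), equal to KO
    (WT recessive), or the arithmetic midpoint (additive).
    """

    scenario: Scenario
    f_ko: float
    f_wt: float = 1.0
    f_het: float = field(init=False)

    def __post_init__(self) -> None:
        if self.f_wt != 1.0:
            raise ValueError("F_WT is the reference viability and must equal 1")
        if not 0.0 < self.f_ko <= 1.0:
            raise ValueError(f"F_KO={self.f_ko!r} outside (0, 1]")
        scenario = Scenario(self.scenario)
        object.__setattr__(self, "scenario", scenario)
        if scenario is Scenario.HET_EQUALS_WT:
            f_het = self.f_wt
        elif scenario is Scenario.HET_EQUALS_KO:
            f_het = self.f_ko
        else:
            f_het = 0.5 * (self.f_wt + self.f_ko)
        object.__setattr__(self, "f_het", f_het)

    @property
    def s(self) -> float:
        """Selection coefficient against the KO homozygote, s = 1 - F_KO."""
        return 1.0 - self.f_ko

    @property
    def is_neutral(self) -> bool:
        return self.f_ko == 1.0

    def viability(self, genotype: Genotype) -> float:
        return {
            Genotype.WT_HOM: self.f_wt,
            Genotype.HET: self.f_het,
            Genotype.KO_HOM: self.f_ko,
        }[Genotype(genotype)]


def neutral_scheme() -> FitnessScheme:
    """All viabilities equal: no selection."""
    return FitnessScheme(scenario=Scenario.HET_EQUALS_WT, f_ko=1.0)


@dataclass(frozen=True)
class GenerationRecord:
    """One generation of the trajectory: offspring before and after selection."""

    generation: int
    pre_selection: GenotypeDist
    post_selection: GenotypeDist

    @property
    def q_ko_post(self) -> float:
        return self.post_selection.q_ko


@dataclass(frozen=True)
class Trajectory:
    """Per-generation genotype distributions produced by the recursion."""

    seed: SexedPopulation
    scheme: FitnessScheme
    records: tuple[GenerationRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, generation: int) -> GenerationRecord:
        """Record for generation ``generation`` (1-based)."""
        if not 1 <= generation <= len(self.records):
            raise IndexError(
                f"generation {generation} outside trajectory range 1..{len(self.records)}"
            )
        return self.records[generation - 1]

    def f_wt_hom_post(self, generation: int) -> float:
        return self.record(generation).post_selection.f_wt_hom

    def to_tsv(self, handle: TextIO) -> None:
        """Write the trajectory as a tab-delimited table with a header row."""
        handle.write(
            "generation\tf_wt_hom_pre\tf_het_pre\tf_ko_hom_pre\t"
            "f_wt_hom_post\tf_het_post\tf_ko_hom_post\tq_ko_post\n"
        )
        for rec in self.records:
            pre, post = rec.pre_selection, rec.post_selection
            handle.write(
                f"{rec.generation}\t{pre.f_wt_hom:.10g}\t{pre.f_het:.10g}\t"
                f"{pre.f_ko_hom:.10g}\t{post.f_wt_hom:.10g}\t{post.f_het:.10g}\t"
                f"{post.f_ko_hom:.10g}\t{post.q_ko:.10g}\n"
            )


_GENOTYPES = (Genotype.WT_HOM, Genotype.HET, Genotype.KO_HOM)

# Probability that a parent of the given genotype transmits the KO allele.
_KO_TRANSMISSION = {Genotype.WT_HOM: 0.0, Genotype.HET: 0.5, Genotype.KO_HOM: 1.0}


def mendelian_offspring(mother: Genotype | str, father: Genotype | str) -> GenotypeDist:
    """Offspring genotype distribution for one mating pair under Mendelian segregation."""
    qm = _KO_TRANSMISSION[Genotype(mother)]
    qf = _KO_TRANSMISSION[Genotype(father)]
    f_ko_hom = qm * qf
    f_wt_hom = (1.0 - qm) * (1.0 - qf)
    return GenotypeDist(f_wt_hom, 1.0 - f_wt_hom - f_ko_hom, f_ko_hom)


def offspring_pool(pop: SexedPopulation) -> GenotypeDist:
    """Pooled offspring distribution over all nine mother x father pairings.

    Random mating: the frequency of each pairing is the product of the maternal
    and paternal genotype fractions, and each pairing contributes its Mendelian
    offspring distribution weighted by that frequency.
    """
    fem = dict(zip(_GENOTYPES, pop.females.as_tuple()))
    mal = dict(zip(_GENOTYPES, pop.males.as_tuple()))
    wt = het = ko = 0.0
    for gm, pm in fem.items():
        if pm == 0.0:
            continue
        for gf, pf in mal.items():
            w = pm * pf
            if w == 0.0:
                continue
            off = mendelian_offspring(gm, gf)
            wt += w * off.f_wt_hom
            het += w * off.f_het
            ko += w * off.f_ko_hom
    total = wt + het + ko
    return GenotypeDist(wt / total, het / total, ko / total)


def apply_viability_selection(dist: GenotypeDist, scheme: FitnessScheme) -> GenotypeDist:
    """Reweight genotype fractions by viability and renormalize to sum to 1."""
    wt = dist.f_wt_hom * scheme.f_wt
    het = dist.f_het * scheme.f_het
    ko = dist.f_ko_hom * scheme.f_ko
    total = wt + het + ko
    if total <= 0.0:
        raise DegeneratePopulationError("viability selection removed every genotype")
    return GenotypeDist(wt / total, het / total, ko / total)


def paper_seed_population() -> SexedPopulation:
    """The cage-experiment founder composition: all-KO females; 50:50 WT:KO males.

    Fifty KO/KO females with 25 KO/KO and 25 WT/WT males give a founding
    KO-allele frequency of 0.75.
    """
    return SexedPopulation(
        females=GenotypeDist(0.0, 0.0, 1.0),
        males=GenotypeDist(0.5, 0.0, 0.5),
        generation=0,
    )


def simulate_deterministic(
    seed: SexedPopulation,
    scheme: FitnessScheme,
    n_generations: int,
) -> Trajectory:
    """Iterate mating, segregation and viability selection for ``n_generations``.

    Generation 0 is the (possibly sex-asymmetric) founder population; each
    subsequent generation's offspring pool is formed from the previous
    generation's post-selection distribution, which both sexes share from
    generation 1 onward.  Records cover generations 1..n_generations.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    records: list[GenerationRecord] = []
    current = seed
    for g in range(1, n_generations + 1):
        pre = offspring_pool(current)
        post = apply_viability_selection(pre, scheme)
        records.append(GenerationRecord(generation=g, pre_selection=pre, post_selection=post))
        current = SexedPopulation(females=post, males=post, generation=g)
    return Trajectory(seed=seed, scheme=scheme, records=tuple(records))
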