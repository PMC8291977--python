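"""McDonald-Kreitman counting and testing on a population codon alignment.

Given many aligned in-frame coding sequences from one species (the ingroup)
and a single outgroup sequence, the test compares the nonsynonymous:synonymous
ratio of fixed between-species differences (Dn:Ds) to the same ratio among
within-species polymorphisms (Pn:Ps).  An excess of fixed nonsynonymous
changes (Dn/Ds >> Pn/Ps) indicates adaptive protein evolution.

Filtering follows common practice for short-read population panels: strains
whose sequence contains any N can be dropped before counting, and rare
polymorphisms below a population-frequency threshold (default 5%) are ignored
because they have not yet faced full selective scrutiny.  Divergence is
unpolarized: a fixed difference counts regardless of which lineage it arose
on.  Codons carrying two or three changed positions are resolved by
enumerating every mutational ordering and averaging the synonymous /
nonsynonymous classification over paths, which yields fractional counts.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "MKOptions",
    "MKTestKind",
    "SiteChangeCounts",
    "MKResult",
    "filter_strains",
    "count_changes",
    "mk_2x2_test",
    "run_mk_test",
    "EmptyIngroupError",
    "PrematureStopError",
]

_ALPHABET = set("ACGTN-")

# Standard genetic code, codon -> amino acid ('*' for stop).
_CODON_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _CODON_TABLE[_stop] = "*"


class EmptyIngroupError(ValueError):
    """Strain filtering removed every ingroup sequence."""


class PrematureStopError(ValueError):
    """The ingroup major-allele sequence translates with an internal stop."""


class MKTestKind(str, enum.Enum):
    CHI2 = "chi2"
    FISHER_ONE_SIDED = "fisher_one_sided"
    FISHER_TWO_SIDED = "fisher_two_sided"
    G_TEST = "g_test"


@dataclass(frozen=True)
class MKOptions:
    """Filtering and test options.

    ``rare_frequency_threshold`` is the minor-variant population frequency
    below which a polymorphism is ignored (masked to the major variant);
    a variant is retained iff its frequency >= threshold.
    """

    drop_strains_with_n: bool = True
    rare_frequency_threshold: float = 0.05
    test: MKTestKind = MKTestKind.CHI2

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_frequency_threshold < 0.5:
            raise ValueError("rare_frequency_threshold must lie in [0, 0.5)")
        object.__setattr__(self, "test", MKTestKind(self.test))


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon alignment: many ingroup strains plus one outgroup."""

    ingroup: dict[str, str]
    outgroup_name: str
    outgroup_seq: str
    removed_strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ingroup:
            raise EmptyIngroupError("alignment has no ingroup sequences")
        seqs = {self.outgroup_name: self.outgroup_seq, **self.ingroup}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        clean = {}
        for name, seq in seqs.items():
            up = seq.upper()
            bad = set(up) - _ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} contains invalid characters {sorted(bad)}")
            clean[name] = up
        object.__setattr__(self, "outgroup_seq", clean.pop(self.outgroup_name))
        object.__setattr__(
            self, "ingroup", {n: clean[n] for n in self.ingroup}
        )

    @property
    def n_codons(self) -> int:
        return len(self.outgroup_seq) // 3

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup)

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        outgroup: str | None = None,
        outgroup_last: bool = False,
    ) -> "CodonAlignment":
        """Load an aligned FASTA; the outgroup is named or is the last record."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        names = [r.id for r in records]
        if outgroup is not None:
            if outgroup not in names:
                raise ValueError(f"outgroup {outgroup!r} not found in {path}")
            out_name = outgroup
        elif outgroup_last:
            out_name = names[-1]
        else:
            raise ValueError("specify the outgroup by name or set outgroup_last")
        ingroup = {r.id: str(r.seq) for r in records if r.id != out_name}
        out_seq = str(next(r.seq for r in records if r.id == out_name))
        return cls(ingroup=ingroup, outgroup_name=out_name, outgroup_seq=out_seq)


@dataclass(frozen=True)
class SiteChangeCounts:
    """The MK 2x2 table: polymorphic and fixed changes, split syn/nonsyn.

    Counts may be fractional because multi-hit codons are path-averaged.
    """

    pn: float
    ps: float
    dn: float
    ds: float

    def __post_init__(self) -> None:
        if min(self.pn, self.ps, self.dn, self.ds) < 0:
            raise ValueError("counts must be non-negative")

    def as_table(self) -> list[list[float]]:
        """Rows = (divergence, polymorphism); columns = (nonsyn, syn)."""
        return [[self.dn, self.ds], [self.pn, self.ps]]


@dataclass(frozen=True)
class MKResult:
    counts: SiteChangeCounts
    statistic: float
    p_value: float
    test_used: MKTestKind
    neutrality_index: float | None
    alpha: float | None
    n_strains_retained: int | None = None

    def to_dict(self) -> dict:
        return {
            "pn": self.counts.pn,
            "ps": self.counts.ps,
            "dn": self.counts.dn,
            "ds": self.counts.ds,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "neutrality_index": self.neutrality_index,
            "alpha": self.alpha,
            "test": self.test_used.value,
            "n_strains_retained": self.n_strains_retained,
        }


def filter_strains(aln: CodonAlignment, opts: MKOptions) -> CodonAlignment:
    """Drop ingroup strains containing any N base (outgroup always retained)."""
    if not opts.drop_strains_with_n:
        return aln
    kept = {n: s for n, s in aln.ingroup.items() if "N" not in s}
    removed = tuple(n for n in aln.ingroup if n not in kept)
    if removed:
        logger.info("removed %d strain(s) containing N: %s", len(removed), ", ".join(removed))
    if not kept:
        raise EmptyIngroupError("every ingroup strain contains an N base")
    return CodonAlignment(
        ingroup=kept,
        outgroup_name=aln.outgroup_name,
        outgroup_seq=aln.outgroup_seq,
        removed_strains=removed,
    )


def _classify_path_averaged(source: str, target: str, positions: list[int]) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over mutational orderings.

    Walks from ``source`` toward ``target`` applying the changes at
    ``positions`` in every possible order; each single-base step is synonymous
    iff the translation is unchanged.  A step to or from a stop codon counts
    as nonsynonymous.
    """
    syn = nonsyn = 0.0
    n_paths = 0
    for order in permutations(positions):
        codon = source
        for pos in order:
            mutated = codon[:pos] + target[pos] + codon[pos + 1 :]
            if _CODON_TABLE[codon] == _CODON_TABLE[mutated]:
                syn += 1
            else:
                nonsyn += 1
            codon = mutated
        n_paths += 1
    return syn / n_paths, nonsyn / n_paths


def count_changes(aln: CodonAlignment, opts: MKOptions | None = None) -> SiteChangeCounts:
    """Count Pn, Ps, Dn, Ds codon by codon.

    Per codon column:

    * columns with a gap or N in the outgroup or any retained ingroup strain
      are excluded entirely;
    * ingroup codon variants with frequency below the rare threshold are
      masked to the major variant;
    * each retained minor variant versus the major variant contributes
      path-averaged polymorphism counts;
    * positions at which every retained ingroup codon agrees but differs from
      the outgroup contribute path-averaged divergence counts (applied on the
      major-codon background); positions polymorphic within the ingroup never
      also count as divergence.
    """
    opts = opts or MKOptions()
    if aln.n_ingroup < 2:
        raise ValueError("need at least 2 ingroup strains to assess polymorphism")
    pn = ps = dn = ds = 0.0
    major_protein: list[str] = []
    for ci in range(aln.n_codons):
        lo, hi = 3 * ci, 3 * ci + 3
        out_codon = aln.outgroup_seq[lo:hi]
        in_codons = [s[lo:hi] for s in aln.ingroup.values()]
        if any(c in "N-" for codon in in_codons for c in codon) or any(
            c in "N-" for c in out_codon
        ):
            continue
        counts = Counter(in_codons)
        n = len(in_codons)
        # major variant: most frequent, alphabetical tie-break for determinism
        major = min(counts, key=lambda c: (-counts[c], c))
        retained = {c for c, k in counts.items() if k / n >= opts.rare_frequency_threshold}
        retained.add(major)
        if major not in _CODON_TABLE:
            logger.warning("codon %d: untranslatable major codon %r skipped", ci + 1, major)
            continue
        major_protein.append(_CODON_TABLE[major])

        for variant in sorted(retained - {major}):
            positions = [i for i in range(3) if variant[i] != major[i]]
            s, nsyn = _classify_path_averaged(major, variant, positions)
            ps += s
            pn += nsyn

        div_positions = [
            i
            for i in range(3)
            if all(c[i] == major[i] for c in retained) and major[i] != out_codon[i]
        ]
        if div_positions:
            target = "".join(
                out_codon[i] if i in div_positions else major[i] for i in range(3)
            )
            s, nsyn = _classify_path_averaged(major, target, div_positions)
            ds += s
            dn += nsyn
    if "*" in major_protein[:-1]:
        raise PrematureStopError(
            f"ingroup major-allele sequence has an internal stop at codon "
            f"{major_protein.index('*') + 1}"
        )
    return SiteChangeCounts(pn=pn, ps=ps, dn=dn, ds=ds)


def mk_2x2_test(counts: SiteChangeCounts, opts: MKOptions | None = None) -> MKResult:
    """Test the 2x2 table (divergence/polymorphism x nonsyn/syn) for neutrality.

    The default is a chi-squared test without continuity correction; Fisher's
    exact test (one- or two-sided; fractional counts rounded to integers) and
    the G-test are also available.  The neutrality index NI = (Pn/Ps)/(Dn/Ds)
    and alpha = 1 - NI are reported when Ps, Dn and Ds are all positive.
    """
    opts = opts or MKOptions()
    table = counts.as_table()
    total = counts.pn + counts.ps + counts.dn + counts.ds
    if total == 0:
        raise ValueError("all four MK cells are zero; test undefined")

    kind = opts.test
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    degenerate_margin = min(row_sums) == 0 or min(col_sums) == 0

    if kind in (MKTestKind.FISHER_ONE_SIDED, MKTestKind.FISHER_TWO_SIDED):
        int_table = [[round(x) for x in row] for row in table]
        alternative = "greater" if kind is MKTestKind.FISHER_ONE_SIDED else "two-sided"
        statistic, p_value = stats.fisher_exact(int_table, alternative=alternative)
    elif degenerate_margin:
        # an empty margin carries no contrast: conventionally no departure
        statistic, p_value = 0.0, 1.0
    else:
        lambda_ = "log-likelihood" if kind is MKTestKind.G_TEST else "pearson"
        statistic, p_value, _, _ = stats.chi2_contingency(
            table, correction=False, lambda_=lambda_
        )

    ni = alpha = None
    if counts.ps > 0 and counts.dn > 0 and counts.ds > 0:
        ni = (counts.pn / counts.ps) / (counts.dn / counts.ds)
        alpha = 1.0 - ni
    return MKResult(
        counts=counts,
        statistic=float(statistic),
        p_value=float(p_value),
        test_used=kind,
        neutrality_index=ni,
        alpha=alpha,
    )


def run_mk_test(aln: CodonAlignment, opts: MKOptions | None = None) -> MKResult:
    """Filter strains, count changes, and test: the full MK pipeline."""
    opts = opts or MKOptions()
    filtered = filter_strains(aln, opts)
    counts = count_changes(filtered, opts)
    result = mk_2x2_test(counts, opts)
    return MKResult(
        counts=result.counts,
        statistic=result.statistic,
        p_value=result.p_value,
        test_used=result.test_used,
        neutrality_index=result.neutrality_index,
        alpha=result.alpha,
        n_strains_retained=filtered.n_ingroup,
    )
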