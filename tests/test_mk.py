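"""McDonald-Kreitman counting, filtering, and 2x2 tests."""

import itertools
import random

import numpy as np
import pytest
from Bio.Data import CodonTable

from cagefit.mk import (
    CodonAlignment,
    EmptyIngroupError,
    MKOptions,
    MKTestKind,
    PrematureStopError,
    SiteChangeCounts,
    count_changes,
    filter_strains,
    mk_2x2_test,
    run_mk_test,
)

AA = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    AA[stop] = "*"
NON_STOP = sorted(c for c, a in AA.items() if a != "*")


def aln(ingroup_seqs, outgroup_seq, names=None):
    names = names or [f"s{i}" for i in range(1, len(ingroup_seqs) + 1)]
    return CodonAlignment(
        ingroup=dict(zip(names, ingroup_seqs)),
        outgroup_name="out",
        outgroup_seq=outgroup_seq,
    )


def oracle_counts(seq_a, seq_b, outgroup):
    """Independent per-codon MK oracle for a 2-strain ingroup at threshold 0.

    Path-averages each codon by explicit permutation enumeration, using the
    lexicographically smaller ingroup codon as the background, mirroring the
    major-variant convention (a 2-strain tie always breaks alphabetically).
    """

    def avg_steps(src, dst, positions):
        syn = nonsyn = 0.0
        orders = list(itertools.permutations(positions))
        for order in orders:
            cur = src
            for p in order:
                nxt = cur[:p] + dst[p] + cur[p + 1 :]
                if AA[cur] == AA[nxt]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
        return syn / len(orders), nonsyn / len(orders)

    pn = ps = dn = ds = 0.0
    for i in range(0, len(outgroup), 3):
        ca, cb, co = seq_a[i : i + 3], seq_b[i : i + 3], outgroup[i : i + 3]
        if any(ch in "N-" for ch in ca + cb + co):
            continue
        major = min(ca, cb)
        poly_pos = [k for k in range(3) if ca[k] != cb[k]]
        if poly_pos:
            s, n = avg_steps(major, max(ca, cb), poly_pos)
            ps += s
            pn += n
        div_pos = [k for k in range(3) if ca[k] == cb[k] and ca[k] != co[k]]
        if div_pos:
            target = "".join(co[k] if k in div_pos else major[k] for k in range(3))
            s, n = avg_steps(major, target, div_pos)
            ds += s
            dn += n
    return pn, ps, dn, ds


class TestFilterStrains:
    def test_drops_strains_with_n(self):
        a = aln(["ATGAAA", "ATGAAN", "ATGAAA"], "ATGAAA")
        out = filter_strains(a, MKOptions())
        assert set(out.ingroup) == {"s1", "s3"}
        assert out.removed_strains == ("s2",)

    def test_keep_all_mode(self):
        a = aln(["ATGAAA", "ATGAAN", "ATGAAA"], "ATGAAA")
        out = filter_strains(a, MKOptions(drop_strains_with_n=False))
        assert out.n_ingroup == 3

    def test_all_strains_removed_is_an_error(self):
        a = aln(["ATGAAN", "ATNAAA"], "ATGAAA")
        with pytest.raises(EmptyIngroupError):
            filter_strains(a, MKOptions())


class TestCountChanges:
    def test_no_variation(self):
        a = aln(["ATGATG", "ATGATG", "ATGATG"], "ATGATG")
        c = count_changes(a, MKOptions())
        assert (c.pn, c.ps, c.dn, c.ds) == (0, 0, 0, 0)

    def test_synonymous_polymorphism_at_the_rare_threshold_is_kept(self):
        """A 1/20 = 5% variant is retained under 'retain iff frequency >= 5%'."""
        seqs = ["AAA"] * 19 + ["AAG"]
        c = count_changes(aln(seqs, "AAA"), MKOptions(rare_frequency_threshold=0.05))
        assert (c.pn, c.ps, c.dn, c.ds) == (0, 1, 0, 0)

    def test_rare_variant_below_threshold_is_masked(self):
        seqs = ["AAA"] * 24 + ["AAG"]  # 4% < 5%
        c = count_changes(aln(seqs, "AAA"), MKOptions(rare_frequency_threshold=0.05))
        assert (c.pn, c.ps, c.dn, c.ds) == (0, 0, 0, 0)

    def test_nonsynonymous_divergence(self):
        c = count_changes(aln(["GAT", "GAT"], "GAA"), MKOptions())
        assert (c.pn, c.ps, c.dn, c.ds) == (0, 0, 1, 0)

    def test_multi_hit_codon_is_path_averaged(self):
        """GCA (Ala) vs GAT: via GAA both steps nonsyn; via GCT one step is syn."""
        c = count_changes(aln(["GCA", "GCA"], "GAT"), MKOptions())
        assert c.dn == pytest.approx(1.5)
        assert c.ds == pytest.approx(0.5)

    def test_codon_with_gap_or_n_is_excluded(self):
        c = count_changes(
            aln(["GATA-G", "GATACG"], "GAAACG"), MKOptions(drop_strains_with_n=False)
        )
        assert (c.pn, c.ps, c.dn, c.ds) == (0, 0, 1, 0)

    def test_polymorphic_position_never_counts_as_divergence(self):
        # position 3 segregates A/G in the ingroup and the outgroup carries G:
        # it is a polymorphism only, never also a fixed difference
        c = count_changes(aln(["AAA", "AAG"], "AAG"), MKOptions(rare_frequency_threshold=0.0))
        assert (c.pn, c.ps, c.dn, c.ds) == (0, 1, 0, 0)

    def test_duplicating_all_strains_leaves_counts_unchanged(self):
        seqs = ["AAAGATTTT", "AAGGATTTC", "AAAGATTTT"]
        base = count_changes(aln(seqs, "AAAGAATTT"), MKOptions(rare_frequency_threshold=0.0))
        doubled = count_changes(
            aln(seqs * 2, "AAAGAATTT"), MKOptions(rare_frequency_threshold=0.0)
        )
        assert (base.pn, base.ps, base.dn, base.ds) == (
            doubled.pn, doubled.ps, doubled.dn, doubled.ds,
        )

    def test_premature_stop_in_major_sequence_rejected(self):
        with pytest.raises(PrematureStopError):
            count_changes(aln(["TAAATG", "TAAATG"], "TACATG"), MKOptions())

    def test_needs_two_ingroup_strains(self):
        with pytest.raises(ValueError):
            count_changes(aln(["ATG"], "ATG"), MKOptions())

    def test_matches_brute_force_oracle_on_random_toy_alignments(self):
        """Threshold-0 counting on 2-strain ingroups equals per-codon enumeration."""
        rng = random.Random(20240901)
        for _ in range(200):
            n_codons = rng.randint(1, 30)
            while True:
                base = [rng.choice(NON_STOP) for _ in range(n_codons)]
                s2, out = [], []
                for codon in base:
                    def mutate(c, k):
                        c = list(c)
                        for _m in range(k):
                            pos = rng.randrange(3)
                            c[pos] = rng.choice("ACGT")
                        return "".join(c)
                    s2.append(mutate(codon, rng.choice([0, 0, 0, 1, 1, 2])))
                    out.append(mutate(codon, rng.choice([0, 0, 1, 1, 2, 3])))
                a = "".join(base)
                b = "".join(s2)
                o = "".join(out)
                majors = [min(a[i:i+3], b[i:i+3]) for i in range(0, len(a), 3)]
                if all(AA[m] != "*" for m in majors[:-1]):
                    break
            got = count_changes(aln([a, b], o), MKOptions(rare_frequency_threshold=0.0))
            want = oracle_counts(a, b, o)
            assert (got.pn, got.ps, got.dn, got.ds) == pytest.approx(want)


class TestMK2x2:
    def test_printed_table_chi2(self):
        """Dn:Ds = 23:29 against Pn:Ps = 1:9 departs from neutrality at p ~ 0.04."""
        res = mk_2x2_test(SiteChangeCounts(pn=1, ps=9, dn=23, ds=29), MKOptions())
        assert res.statistic == pytest.approx(4.1422, abs=1e-3)
        assert res.p_value == pytest.approx(0.0418, abs=1e-3)
        assert res.neutrality_index == pytest.approx(0.1401, abs=1e-3)
        assert res.alpha == pytest.approx(0.8599, abs=1e-3)

    def test_fisher_variants(self):
        counts = SiteChangeCounts(pn=1, ps=9, dn=23, ds=29)
        two = mk_2x2_test(counts, MKOptions(test=MKTestKind.FISHER_TWO_SIDED))
        one = mk_2x2_test(counts, MKOptions(test=MKTestKind.FISHER_ONE_SIDED))
        assert two.p_value == pytest.approx(0.0732, abs=1e-3)
        assert one.p_value == pytest.approx(0.0408, abs=1e-3)

    def test_g_test(self):
        res = mk_2x2_test(
            SiteChangeCounts(pn=1, ps=9, dn=23, ds=29), MKOptions(test=MKTestKind.G_TEST)
        )
        assert res.statistic == pytest.approx(4.866, abs=1e-2)

    def test_perfectly_neutral_table(self):
        res = mk_2x2_test(SiteChangeCounts(5, 5, 5, 5), MKOptions())
        assert res.p_value == pytest.approx(1.0)
        assert res.neutrality_index == pytest.approx(1.0)
        assert res.alpha == pytest.approx(0.0)

    def test_column_swap_preserves_chi2_p(self):
        a = mk_2x2_test(SiteChangeCounts(pn=1, ps=9, dn=23, ds=29), MKOptions())
        b = mk_2x2_test(SiteChangeCounts(pn=9, ps=1, dn=29, ds=23), MKOptions())
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_p_value_approaches_one_toward_the_expected_table(self):
        obs = np.array([[23.0, 29.0], [1.0, 9.0]])
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        ps = []
        for t in np.linspace(0.0, 1.0, 11):
            table = obs + t * (expected - obs)
            res = mk_2x2_test(
                SiteChangeCounts(
                    pn=table[1, 0], ps=table[1, 1], dn=table[0, 0], ds=table[0, 1]
                ),
                MKOptions(),
            )
            ps.append(res.p_value)
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))
        assert ps[-1] == pytest.approx(1.0)

    def test_neutrality_index_undefined_without_divergence(self):
        res = mk_2x2_test(SiteChangeCounts(pn=2, ps=3, dn=0, ds=0), MKOptions())
        assert res.neutrality_index is None
        assert res.alpha is None

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            mk_2x2_test(SiteChangeCounts(0, 0, 0, 0), MKOptions())


class TestPipeline:
    def test_full_run_with_filtering(self):
        a = aln(["GATAAA", "GATAAA", "GNTAAA"], "GAAAAA")
        res = run_mk_test(a, MKOptions())
        assert res.n_strains_retained == 2
        assert res.counts.dn == 1
        assert res.counts.ds == 0

    def test_alignment_validation(self):
        with pytest.raises(ValueError):
            aln(["ATG", "ATGA"], "ATG")
        with pytest.raises(ValueError):
            aln(["ATGA", "ATGA"], "ATGA")
        with pytest.raises(ValueError):
            aln(["AUG", "ATG"], "ATG")

    def test_from_fasta(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">a\nGATAAA\n>b\nGATAAA\n>sim\nGAAAAA\n")
        a = CodonAlignment.from_fasta(fa, outgroup="sim")
        assert a.outgroup_name == "sim"
        assert a.n_ingroup == 2
        b = CodonAlignment.from_fasta(fa, outgroup_last=True)
        assert b.outgroup_name == "sim"
        with pytest.raises(ValueError):
            CodonAlignment.from_fasta(fa, outgroup="missing")
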