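"""Codon alignment and Ka/Ks estimators against a brute-force oracle.

The oracle below re-derives NG86 from first principles — codon table
built from the classic TCAG string, neighbour enumeration for sites,
exhaustive permutation walks for multi-hit codons, closed-form
Jukes–Cantor — sharing no code with the implementation.
"""

import itertools
import math
import random

import numpy as np
import pytest

from paraminer.duplicate_classifier import DuplicateGroup
from paraminer.kaks_engine import (
    CodonAlignment,
    codon_align,
    group_kaks,
    jc_correct,
    kaks_pair,
    ng_counts,
)
from paraminer.synthetic_fixtures import simulate_cds_pair

# ---------------------------------------------------------------- oracle

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_TABLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_syn_sites(codon):
    aa = ORACLE_TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if ORACLE_TABLE[alt] == aa and aa != "*":
                syn += 1
        total += syn / 3.0
    return total


def oracle_path_counts(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur, syn, nonsyn, through_stop = ca, 0, 0, False
        for step_i, pos in enumerate(order):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if ORACLE_TABLE[nxt] == "*" and step_i < len(order) - 1:
                through_stop = True
            if (
                ORACLE_TABLE[cur] != "*"
                and ORACLE_TABLE[nxt] != "*"
                and ORACLE_TABLE[cur] == ORACLE_TABLE[nxt]
            ):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((through_stop, syn, nonsyn))
    clean = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in clean) / len(clean)
    nd = sum(p[2] for p in clean) / len(clean)
    return sd, nd


def oracle_ng(pairs):
    sa = sum(oracle_syn_sites(a) for a, _ in pairs)
    sb = sum(oracle_syn_sites(b) for _, b in pairs)
    S = (sa + sb) / 2.0
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for a, b in pairs:
        sd, nd = oracle_path_counts(a, b)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def oracle_jc(p):
    return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)


def random_codon(rng):
    while True:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if ORACLE_TABLE[c] != "*":
            return c


# ------------------------------------------------------------ alignment


class TestCodonAlign:
    def test_back_translation_with_gap_column(self):
        aln = codon_align(("M-A", "MKA"), "ATGGCT", "ATGAAAGCA")
        assert aln.pairs() == [("ATG", "ATG"), ("GCT", "GCA")]
        assert aln.n_trimmed_gap == 1
        assert aln.kept_column_mask == [True, False, True]

    def test_identical_inputs_trim_nothing(self):
        aln = codon_align(("MA", "MA"), "ATGGCT", "ATGGCT")
        assert aln.pairs() == [("ATG", "ATG"), ("GCT", "GCT")]
        assert aln.n_trimmed_gap == aln.n_trimmed_ambiguous == aln.n_trimmed_stop == 0

    def test_ambiguous_codon_column_dropped_and_counted(self):
        aln = codon_align(("MX", "MK"), "ATGANG", "ATGAAA")
        assert aln.pairs() == [("ATG", "ATG")]
        assert aln.n_trimmed_ambiguous == 1

    def test_stop_codon_column_dropped_and_counted(self):
        aln = codon_align(("M*", "MK"), "ATGTAA", "ATGAAA")
        assert aln.pairs() == [("ATG", "ATG")]
        assert aln.n_trimmed_stop == 1

    def test_terminal_stop_codon_tolerated(self):
        aln = codon_align(("MA", "MA"), "ATGGCTTAA", "ATGGCT")
        assert aln.pairs() == [("ATG", "ATG"), ("GCT", "GCT")]

    def test_length_mismatch_names_the_gene(self):
        with pytest.raises(ValueError, match="geneB"):
            codon_align(("MA", "MA"), "ATGGCT", "ATGGCTGCT", gene_a="geneA", gene_b="geneB")

    def test_ungapping_recovers_cds(self):
        rng = random.Random(2)
        cds_a = "".join(random_codon(rng) for _ in range(20))
        cds_b = "".join(random_codon(rng) for _ in range(22))
        prot_a = "".join(ORACLE_TABLE[cds_a[i:i + 3]] for i in range(0, 60, 3))
        prot_b = "".join(ORACLE_TABLE[cds_b[i:i + 3]] for i in range(0, 66, 3))
        aln = codon_align((prot_a + "--", prot_b), cds_a, cds_b)
        assert "".join(c for c, _ in zip(aln.codons_a, aln.codons_b)) == cds_a[:60]


# --------------------------------------------------------------- counts


class TestNGCounts:
    def test_identical_phe_codon(self):
        S, N, Sd, Nd = ng_counts([("TTT", "TTT")])
        assert S == pytest.approx(1 / 3)
        assert N == pytest.approx(8 / 3)
        assert Sd == Nd == 0.0

    def test_single_synonymous_difference(self):
        S, N, Sd, Nd = ng_counts([("TTT", "TTC")])
        assert S == pytest.approx(1 / 3)
        assert N == pytest.approx(8 / 3)
        assert (Sd, Nd) == (1.0, 0.0)

    def test_two_position_difference_averages_pathways(self):
        S, N, Sd, Nd = ng_counts([("TTT", "GTA")])
        sd_oracle, nd_oracle = oracle_path_counts("TTT", "GTA")
        assert Sd == pytest.approx(sd_oracle)
        assert Nd == pytest.approx(nd_oracle)
        assert (Sd, Nd) == (pytest.approx(0.5), pytest.approx(1.5))

    def test_site_conservation_is_exact(self):
        rng = random.Random(4)
        pairs = [(random_codon(rng), random_codon(rng)) for _ in range(120)]
        S, N, Sd, Nd = ng_counts(pairs)
        assert S + N == pytest.approx(3 * len(pairs), abs=1e-12)
        total_diffs = sum(a != b for pa, pb in pairs for a, b in zip(pa, pb))
        assert Sd + Nd == pytest.approx(total_diffs, abs=1e-9)

    def test_matches_oracle_on_random_pairs(self):
        rng = random.Random(8)
        for _ in range(50):
            n = rng.randint(1, 60)
            pairs = [(random_codon(rng), random_codon(rng)) for _ in range(n)]
            got = ng_counts(pairs)
            expected = oracle_ng(pairs)
            for g, e in zip(got, expected):
                assert g == pytest.approx(e, abs=1e-9)


class TestJukesCantor:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0, 0.0), (0.1, 0.10732), (0.3, 0.38311)],
    )
    def test_closed_form(self, p, expected):
        assert jc_correct(p) == pytest.approx(expected, abs=1e-5)

    def test_saturation_returns_none(self):
        assert jc_correct(0.8) is None
        assert jc_correct(0.75) is None

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            jc_correct(-0.1)


# ---------------------------------------------------------------- pairs


def aligned(pairs, ga="a", gb="b"):
    return CodonAlignment(
        gene_a=ga, gene_b=gb,
        codons_a=[p[0] for p in pairs], codons_b=[p[1] for p in pairs],
        kept_column_mask=[True] * len(pairs),
    )


class TestKaKsPair:
    def test_identical_pair_has_zero_rates_and_no_ratio(self):
        rng = random.Random(1)
        codons = [random_codon(rng) for _ in range(100)]
        result = kaks_pair(aligned(list(zip(codons, codons))), "NG")
        assert result.Ka == 0.0 and result.Ks == 0.0
        assert result.ratio is None

    def test_ng_matches_oracle_end_to_end(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a, b = simulate_cds_pair(50, 0.3, rng)
            prot = "".join(ORACLE_TABLE[a[i:i + 3]] for i in range(0, len(a) - 3, 3))
            prot_b = "".join(ORACLE_TABLE[b[i:i + 3]] for i in range(0, len(b) - 3, 3))
            aln = codon_align((prot, prot_b), a, b)
            result = kaks_pair(aln, "NG")
            S, N, Sd, Nd = oracle_ng(aln.pairs())
            assert result.S == pytest.approx(S, abs=1e-9)
            assert result.Nd == pytest.approx(Nd, abs=1e-9)
            expected_ks = oracle_jc(Sd / S)
            expected_ka = oracle_jc(Nd / N)
            if expected_ks is None:
                assert result.Ks is None
            else:
                assert result.Ks == pytest.approx(expected_ks, abs=1e-9)
            if expected_ka is None:
                assert result.Ka is None
            else:
                assert result.Ka == pytest.approx(expected_ka, abs=1e-9)

    def test_symmetry_in_every_field(self):
        rng = np.random.default_rng(12)
        a, b = simulate_cds_pair(80, 0.25, rng)
        pairs = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a) - 3, 3)]
        for method in ("NG", "MYN"):
            fwd = kaks_pair(aligned(pairs), method)
            rev = kaks_pair(aligned([(y, x) for x, y in pairs]), method)
            for fields in ("S", "N", "Sd", "Nd", "Ka", "Ks", "ratio", "kappa"):
                assert getattr(fwd, fields) == pytest.approx(getattr(rev, fields))

    def test_myn_agrees_with_ng_in_no_bias_limit(self):
        # JC simulation means kappa = 1 and near-equal base frequencies
        rng = np.random.default_rng(14)
        for ks in (0.1, 0.3):
            a, b = simulate_cds_pair(500, ks, rng)
            pairs = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a) - 3, 3)]
            pairs = [p for p in pairs if ORACLE_TABLE[p[0]] != "*" and ORACLE_TABLE[p[1]] != "*"]
            ng = kaks_pair(aligned(pairs), "NG")
            myn = kaks_pair(aligned(pairs), "MYN")
            assert abs(myn.Ks - ng.Ks) < 0.02
            assert abs(myn.Ka - ng.Ka) < 0.02
            assert 0.5 < myn.kappa < 2.0

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError, match="no codon columns"):
            kaks_pair(aligned([]))


class TestGroupKaks:
    def group(self, members):
        return DuplicateGroup(
            group_id="g1", klass="tandem", members=members, family_id="f1"
        )

    def catalog_for(self, cds_map, flags=()):
        from conftest import make_catalog

        genes = [(g, "c1", 100 * i + 1, 100 * i + 50) for i, g in enumerate(sorted(cds_map))]
        prots = {
            g: "".join(ORACLE_TABLE[c[i:i + 3]] for i in range(0, len(c), 3)).rstrip("*")
            for g, c in cds_map.items()
        }
        cat = make_catalog(genes, proteins=prots, cds=cds_map)
        for g in flags:
            cat.genes[g].flags.add("internal_stop")
        return cat

    def test_pair_gives_one_result(self):
        rng = np.random.default_rng(3)
        a, b = simulate_cds_pair(40, 0.1, rng)
        cat = self.catalog_for({"x": a[:-3], "y": b[:-3]})
        results, skipped = group_kaks(self.group(["x", "y"]), cat, "NG")
        assert len(results) == 1 and not skipped

    def test_group_of_four_gives_six_results(self):
        rng = np.random.default_rng(5)
        founder, _ = simulate_cds_pair(40, 0.0, rng)
        cds = {f"m{i}": simulate_cds_pair(40, 0.1, rng)[0][:len(founder)] for i in range(4)}
        cat = self.catalog_for(cds)
        results, _ = group_kaks(self.group(sorted(cds)), cat, "NG")
        assert len(results) == 6

    def test_internal_stop_member_skipped_with_reason(self):
        rng = np.random.default_rng(7)
        a, b = simulate_cds_pair(40, 0.1, rng)
        cat = self.catalog_for({"x": a[:-3], "y": b[:-3]}, flags=("y",))
        results, skipped = group_kaks(self.group(["x", "y"]), cat, "NG")
        assert results == []
        assert skipped[0].reason == "internal_stop:y"
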