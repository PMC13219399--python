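"""Gene-level Ka/Ks for duplicate pairs.

Implements codon back-translation of protein alignments, gap/ambiguity/
stop trimming, an exact Nei–Gojobori (1986) estimator, and a
kappa-aware approximation in the spirit of the modified Yang–Nielsen
method.

NG86 in brief: each codon position contributes a synonymous-site fraction
equal to the share of its three single-nucleotide neighbours that encode
the same amino acid; S is the mean of the two sequences' totals and
N = 3L - S.  Observed differences at multi-hit codons are averaged over
all orderings of single-nucleotide steps, excluding mutational pathways
that pass through stop codons (falling back to including them when every
pathway does).  The difference proportions ps = Sd/S and pn = Nd/N are
corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4) ln(1 - (4/3) p).

The MYN-style estimator additionally (i) estimates separate transitional
biases for pyrimidines (kappa_Y: T<->C) and purines (kappa_R: A<->G) from
normalized observed proportions, (ii) weights the per-position
synonymous-site fractions by those mutational rates, and (iii) replaces
the Jukes–Cantor correction with a Kimura-form two-parameter correction
on the (transition, transversion) split of the pathway-averaged
differences.  With kappa = 1 and equal base frequencies it reduces to
NG86 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .annotation_io import GeneCatalog
from .duplicate_classifier import DuplicateGroup

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "codon_align",
    "ng_counts",
    "jc_correct",
    "k80_correct",
    "kaks_pair",
    "group_kaks",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NTS = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _aa(codon: str) -> str | None:
    """Amino acid of a codon, None for stops."""
    return _CODON_TABLE.get(codon)


def _is_transition(n1: str, n2: str) -> bool:
    return (n1 in _PURINES and n2 in _PURINES) or (n1 in _PYRIMIDINES and n2 in _PYRIMIDINES)


@dataclass
class CodonAlignment:
    """Gap-trimmed codon alignment of one gene pair."""

    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]
    kept_column_mask: list[bool]  # over protein-alignment columns
    n_trimmed_gap: int = 0
    n_trimmed_ambiguous: int = 0
    n_trimmed_stop: int = 0

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.codons_a, self.codons_b))


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    method: str  # NG | MYN
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float | None
    pn: float | None
    Ka: float | None
    Ks: float | None
    ratio: float | None
    kappa: float | None = None
    n_codons: int = 0


def _split_codons(cds: str, gene: str, n_residues: int) -> list[str]:
    cds = cds.upper()
    if len(cds) == 3 * n_residues + 3 and cds[-3:] in _STOPS:
        cds = cds[:-3]  # tolerate an untrimmed terminal stop codon
    if len(cds) != 3 * n_residues:
        raise ValueError(
            f"CDS of {gene} has {len(cds)} nt but its aligned protein has "
            f"{n_residues} residues (expected {3 * n_residues} nt)"
        )
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def codon_align(
    prot_aln: tuple[str, str],
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Back-translate an aligned protein pair to codons and trim.

    Each residue is replaced by its codon, each gap by ``---``.  Columns
    with a gap in either sequence, a codon containing an ambiguous base,
    or a stop codon in either sequence are removed (counted separately in
    the trim report).
    """
    pa, pb = prot_aln
    if len(pa) != len(pb):
        raise ValueError("aligned protein strings must have equal length")
    codons_a_src = _split_codons(cds_a, gene_a, len(pa.replace("-", "")))
    codons_b_src = _split_codons(cds_b, gene_b, len(pb.replace("-", "")))

    kept_a: list[str] = []
    kept_b: list[str] = []
    mask: list[bool] = []
    n_gap = n_ambig = n_stop = 0
    ia = ib = 0
    for ra, rb in zip(pa, pb):
        ca = codons_a_src[ia] if ra != "-" else "---"
        cb = codons_b_src[ib] if rb != "-" else "---"
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
        if ca == "---" or cb == "---":
            n_gap += 1
            mask.append(False)
            continue
        if set(ca) - set(_NTS) or set(cb) - set(_NTS):
            n_ambig += 1
            mask.append(False)
            continue
        if ca in _STOPS or cb in _STOPS:
            n_stop += 1
            mask.append(False)
            continue
        kept_a.append(ca)
        kept_b.append(cb)
        mask.append(True)
    return CodonAlignment(
        gene_a=gene_a, gene_b=gene_b, codons_a=kept_a, codons_b=kept_b,
        kept_column_mask=mask, n_trimmed_gap=n_gap,
        n_trimmed_ambiguous=n_ambig, n_trimmed_stop=n_stop,
    )


@lru_cache(maxsize=65536)
def _syn_sites(codon: str, kappa_y: float = 1.0, kappa_r: float = 1.0) -> float:
    """Synonymous-site count of one codon (0..3).

    Each position contributes the rate-weighted share of its three
    neighbours that are synonymous; mutations to stop codons count as
    nonsynonymous.  With both kappas at 1 this is the NG86 count/3 rule.
    """
    aa = _aa(codon)
    total = 0.0
    for pos in range(3):
        syn_w = all_w = 0.0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            w = 1.0
            if _is_transition(codon[pos], nt):
                w = kappa_y if nt in _PYRIMIDINES else kappa_r
            all_w += w
            neighbor = codon[:pos] + nt + codon[pos + 1:]
            if _aa(neighbor) == aa:
                syn_w += w
        total += syn_w / all_w
    return total


@lru_cache(maxsize=65536)
def _path_differences(ca: str, cb: str) -> tuple[float, float, float, float, float, float]:
    """Average (Sd, Nd) and their transition/transversion splits over all
    orderings of single-nucleotide steps between two codons.

    Pathways through stop codons are excluded; if every ordering passes
    through a stop, all orderings are used instead.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[bool, float, float, float, float]:
        cur = ca
        sd = nd = sd_ts = nd_ts = 0.0
        hits_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in _STOPS and step < len(order) - 1:
                hits_stop = True
            is_ts = _is_transition(cur[pos], cb[pos])
            if _aa(cur) is not None and _aa(nxt) is not None and _aa(cur) == _aa(nxt):
                sd += 1.0
                sd_ts += 1.0 if is_ts else 0.0
            else:
                nd += 1.0
                nd_ts += 1.0 if is_ts else 0.0
            cur = nxt
        return hits_stop, sd, nd, sd_ts, nd_ts

    results = [walk(order) for order in permutations(diff_pos)]
    valid = [r for r in results if not r[0]]
    used = valid if valid else results
    n = len(used)
    sd = sum(r[1] for r in used) / n
    nd = sum(r[2] for r in used) / n
    sd_ts = sum(r[3] for r in used) / n
    nd_ts = sum(r[4] for r in used) / n
    return sd, nd, sd_ts, nd_ts, sd - sd_ts, nd - nd_ts


def ng_counts(codon_pairs: list[tuple[str, str]]) -> tuple[float, float, float, float]:
    """Exact NG86 site and difference counts (S, N, Sd, Nd) for gap-free
    codon pairs."""
    s, n, sd, nd, *_ = _counts(codon_pairs, 1.0, 1.0)
    return s, n, sd, nd


def _counts(
    codon_pairs: list[tuple[str, str]],
    kappa_y: float,
    kappa_r: float,
) -> tuple[float, float, float, float, float, float, float, float]:
    """(S, N, Sd, Nd, Sd_ts, Sd_tv, Nd_ts, Nd_tv) with rate-weighted sites."""
    L = len(codon_pairs)
    s_a = sum(_syn_sites(ca, kappa_y, kappa_r) for ca, _ in codon_pairs)
    s_b = sum(_syn_sites(cb, kappa_y, kappa_r) for _, cb in codon_pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * L - S
    Sd = Nd = Sd_ts = Nd_ts = 0.0
    for ca, cb in codon_pairs:
        sd, nd, sd_ts, nd_ts, _sd_tv, _nd_tv = _path_differences(ca, cb)
        Sd += sd
        Nd += nd
        Sd_ts += sd_ts
        Nd_ts += nd_ts
    return S, N, Sd, Nd, Sd_ts, Sd - Sd_ts, Nd_ts, Nd - Nd_ts


def jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p);
    None at saturation (p >= 3/4)."""
    if not -1e-9 <= p <= 1.0 + 1e-9:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    p = min(max(p, 0.0), 1.0)  # tolerate rounding at the boundaries
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def k80_correct(P: float, Q: float) -> float | None:
    """Kimura two-parameter distance from transition (P) and transversion
    (Q) difference proportions; None at saturation."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return None
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def _estimate_kappas(codon_pairs: list[tuple[str, str]]) -> tuple[float, float]:
    """Moment estimates of the pyrimidine and purine transitional biases.

    Observed proportions of T<->C, A<->G and transversion differences are
    normalized by their random expectations under the empirical base
    composition; the resulting rate ratios are clamped to [0.05, 20] and
    default to 1 when a class is unobservable.
    """
    n_sites = 3 * len(codon_pairs)
    if n_sites == 0:
        return 1.0, 1.0
    freq = {nt: 0 for nt in _NTS}
    p1 = p2 = q = 0
    for ca, cb in codon_pairs:
        for na, nb in zip(ca, cb):
            freq[na] += 1
            freq[nb] += 1
            if na == nb:
                continue
            pair = {na, nb}
            if pair == {"T", "C"}:
                p1 += 1
            elif pair == {"A", "G"}:
                p2 += 1
            else:
                q += 1
    tot = sum(freq.values())
    pi = {nt: freq[nt] / tot for nt in _NTS}
    pi_y = pi["T"] + pi["C"]
    pi_r = pi["A"] + pi["G"]
    exp_q = 2.0 * pi_y * pi_r
    exp_p1 = 2.0 * pi["T"] * pi["C"]
    exp_p2 = 2.0 * pi["A"] * pi["G"]
    q_rate = (q / n_sites) / exp_q if exp_q > 0 else 0.0

    def ratio(p_count: int, expectation: float) -> float:
        if expectation <= 0 or q_rate <= 0:
            return 1.0 if p_count == 0 else 20.0
        if p_count == 0:
            return 0.05
        return min(max(((p_count / n_sites) / expectation) / q_rate, 0.05), 20.0)

    return ratio(p1, exp_p1), ratio(p2, exp_p2)


def kaks_pair(aln: CodonAlignment, method: str = "NG") -> KaKsResult:
    """Ka, Ks and their ratio for one codon-aligned gene pair."""
    if method not in ("NG", "MYN"):
        raise ValueError(f"method must be NG or MYN, got {method!r}")
    pairs = aln.pairs()
    if not pairs:
        raise ValueError(f"no codon columns left for pair {aln.gene_a}/{aln.gene_b}")

    if method == "NG":
        S, N, Sd, Nd, *_ = _counts(pairs, 1.0, 1.0)
        ps = Sd / S if S > 0 else None
        pn = Nd / N if N > 0 else None
        # pathway-averaged differences can exceed the site count at
        # extreme divergence; that is saturation, not an error
        Ks = jc_correct(ps) if ps is not None and ps <= 1.0 else None
        Ka = jc_correct(pn) if pn is not None and pn <= 1.0 else None
        kappa = None
    else:
        kappa_y, kappa_r = _estimate_kappas(pairs)
        S, N, Sd, Nd, Sd_ts, Sd_tv, Nd_ts, Nd_tv = _counts(pairs, kappa_y, kappa_r)
        ps = Sd / S if S > 0 else None
        pn = Nd / N if N > 0 else None
        Ks = k80_correct(Sd_ts / S, Sd_tv / S) if S > 0 else None
        Ka = k80_correct(Nd_ts / N, Nd_tv / N) if N > 0 else None
        kappa = (kappa_y + kappa_r) / 2.0

    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(
        gene_a=aln.gene_a, gene_b=aln.gene_b, method=method,
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        Ka=Ka, Ks=Ks, ratio=ratio, kappa=kappa, n_codons=len(pairs),
    )


@dataclass
class SkippedPair:
    gene_a: str
    gene_b: str
    reason: str


def group_kaks(
    group: DuplicateGroup,
    catalog: GeneCatalog,
    method: str = "NG",
    align_proteins=None,
) -> tuple[list[KaKsResult], list[SkippedPair]]:
    """Ka/Ks for every unordered member pair of a duplicate group.

    Pairs whose members lack a CDS or carry internal-stop flags are
    skipped with a reason code, never fatal.  ``align_proteins`` may
    override the global protein aligner (signature ``(a, b) -> (a_aln,
    b_aln)``).
    """
    if align_proteins is None:
        from .orthology_synteny import _get_aligner

        def align_proteins(a: str, b: str) -> tuple[str, str]:
            aln = _get_aligner().align(a, b)[0]
            return str(aln[0]), str(aln[1])

    results: list[KaKsResult] = []
    skipped: list[SkippedPair] = []
    members = sorted(group.members)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            reason = None
            for g in (a, b):
                if "internal_stop" in catalog.genes[g].flags:
                    reason = f"internal_stop:{g}"
                elif catalog.representative_cds.get(g) is None:
                    reason = f"no_cds:{g}"
                if reason:
                    break
            if reason:
                skipped.append(SkippedPair(a, b, reason))
                continue
            prot_a = catalog.representative_protein[a]
            prot_b = catalog.representative_protein[b]
            try:
                aln = codon_align(
                    align_proteins(prot_a, prot_b),
                    catalog.representative_cds[a], catalog.representative_cds[b],
                    gene_a=a, gene_b=b,
                )
                results.append(kaks_pair(aln, method=method))
            except ValueError as exc:
                skipped.append(SkippedPair(a, b, str(exc)))
    return results, skipped
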