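"""Reference-mode ortholog assignment with synteny support.

Given forward (sample-vs-reference) candidate lists, each sample gene is
assigned at most one reference ortholog by combining independent evidence:

* best_local   — highest forward bit score;
* best_global  — highest identity in a global protein alignment
                 (column-occupancy filtered);
* synteny_pass — the candidate's reference neighbourhood contains the
                 best forward hits of the sample gene's flanking genes;
* tree_nearest — smallest evolutionary distance, either supplied by an
                 external tree runner (patristic distances) or computed
                 internally as a p-distance from the global alignments.

The candidate holding the most evidence flags wins (ties go to the local
best); the confidence tier reflects how much of the available evidence
agrees.  Downstream products: copy-number / presence-absence tables with
an orthologous-group confidence score (OGCS), and a nature label for
small-scale duplicate groups (locus expansion vs de novo placement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .alignment_scores import FwdScoreRecord
from .annotation_io import GeneCatalog
from .duplicate_classifier import DuplicateGroup, DuplicatePartition

__all__ = [
    "OrthologyParams",
    "OrthologCall",
    "CopyNumberCell",
    "assign_ortholog",
    "synteny_score",
    "copy_number_table",
    "group_nature",
    "global_identity",
]


@dataclass(frozen=True)
class OrthologyParams:
    n_candidates: int = 10
    flank: int = 5
    side: str = "one"  # one | both
    synteny_cutoff: float = 0.5
    occupancy: float = 0.1
    use_phylogeny: bool = False

    def __post_init__(self) -> None:
        if self.n_candidates < 1 or self.flank < 1:
            raise ValueError("n_candidates and flank must be >= 1")
        if self.side not in ("one", "both"):
            raise ValueError("side must be 'one' or 'both'")


@dataclass
class OrthologCall:
    sample_gene: str
    ref_gene: str | None
    evidence: dict[str, bool] = field(default_factory=dict)
    confidence: str = "low"
    synteny_score: float = 0.0


@dataclass
class CopyNumberCell:
    count: int
    members: list[str]
    ogcs: str  # very_high | high | moderate | low
    absent: bool


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        _aligner = a
    return _aligner


def _sanitize(prot: str) -> str:
    # BLOSUM62 has no J/U/O rows; map rare letters onto X
    return prot.replace("J", "X").replace("U", "X").replace("O", "X").replace("*", "X")


def global_identity(prot_a: str, prot_b: str, occupancy: float = 0.1) -> float:
    """Percent identity of a global protein alignment after dropping
    columns whose non-gap occupancy falls below ``occupancy``."""
    if not prot_a or not prot_b:
        return 0.0
    aln = _get_aligner().align(_sanitize(prot_a), _sanitize(prot_b))[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = compared = 0
    for c1, c2 in zip(s1, s2):
        occ = (c1 != "-") + (c2 != "-")
        if occ / 2.0 < occupancy or occ == 0:
            continue
        compared += 1
        if c1 == c2 and c1 != "-":
            matches += 1
    return 100.0 * matches / compared if compared else 0.0


def p_distance(prot_a: str, prot_b: str) -> float:
    """Proportion of differing residues over gap-free global-alignment
    columns — the built-in fallback for tree-based distances."""
    if not prot_a or not prot_b:
        return 1.0
    aln = _get_aligner().align(_sanitize(prot_a), _sanitize(prot_b))[0]
    s1, s2 = str(aln[0]), str(aln[1])
    diffs = compared = 0
    for c1, c2 in zip(s1, s2):
        if c1 == "-" or c2 == "-":
            continue
        compared += 1
        if c1 != c2:
            diffs += 1
    return diffs / compared if compared else 1.0


def synteny_score(
    sample_gene: str,
    ref_candidate: str,
    sample_catalog: GeneCatalog,
    ref_catalog: GeneCatalog,
    seed_map: dict[str, str],
    flank: int = 5,
    side: str = "one",
    synteny_cutoff: float = 0.5,
) -> tuple[float, bool]:
    """Fraction of flanking genes whose best forward hit lands near the
    candidate in the reference.

    Up to ``flank`` genes on each side of the sample gene are examined; a
    flank gene supports synteny iff ``seed_map`` places its best forward
    hit on the candidate's reference contig within +-(2*flank) order
    positions of the candidate.  ``side='both'`` additionally requires at
    least one supporter on each side for a pass.
    """
    left, right = sample_catalog.neighbors(sample_gene, flank)
    ref_model = ref_catalog.genes.get(ref_candidate)
    if ref_model is None:
        raise KeyError(f"reference gene {ref_candidate} not in reference catalog")
    ref_pos = ref_catalog.order_index[ref_candidate]
    window = 2 * flank

    def supports(flank_gene: str) -> bool:
        target = seed_map.get(flank_gene)
        if target is None or target not in ref_catalog.genes:
            return False
        tmodel = ref_catalog.genes[target]
        if tmodel.contig != ref_model.contig:
            return False
        return abs(ref_catalog.order_index[target] - ref_pos) <= window

    left_support = sum(supports(g) for g in left)
    right_support = sum(supports(g) for g in right)
    examined = len(left) + len(right)
    if examined == 0:
        return 0.0, False
    score = (left_support + right_support) / examined
    passed = score >= synteny_cutoff
    if side == "both":
        passed = passed and left_support >= 1 and right_support >= 1
    return score, passed


def assign_ortholog(
    gene: str,
    fwd: FwdScoreRecord,
    sample_catalog: GeneCatalog,
    ref_catalog: GeneCatalog,
    seed_map: dict[str, str],
    params: OrthologyParams,
    tree_distances: dict[str, float] | None = None,
) -> OrthologCall:
    """Pick the reference ortholog of one sample gene from its forward
    candidates by majority of evidence flags (tie -> local best)."""
    candidates = [c[0] for c in fwd.candidates[: params.n_candidates]]
    if not candidates:
        return OrthologCall(sample_gene=gene, ref_gene=None, confidence="low")

    best_local = candidates[0]

    identities = {
        c: global_identity(
            sample_catalog.representative_protein.get(gene, ""),
            ref_catalog.representative_protein.get(c, ""),
            params.occupancy,
        )
        for c in candidates
    }
    best_global = max(candidates, key=lambda c: (identities[c], c == best_local, c))

    synteny: dict[str, tuple[float, bool]] = {
        c: synteny_score(
            gene, c, sample_catalog, ref_catalog, seed_map,
            flank=params.flank, side=params.side, synteny_cutoff=params.synteny_cutoff,
        )
        for c in candidates
    }
    syntenic = [c for c in candidates if synteny[c][1]]
    best_syntenic = max(syntenic, key=lambda c: (synteny[c][0], c == best_local, c)) if syntenic else None

    best_tree: str | None = None
    if params.use_phylogeny:
        if tree_distances is None:
            tree_distances = {
                c: p_distance(
                    sample_catalog.representative_protein.get(gene, ""),
                    ref_catalog.representative_protein.get(c, ""),
                )
                for c in candidates
            }
        scored = [c for c in candidates if c in tree_distances]
        if scored:
            best_tree = min(scored, key=lambda c: (tree_distances[c], c != best_local, c))

    flag_holders = {"best_local": best_local, "best_global": best_global}
    if best_syntenic is not None:
        flag_holders["synteny_pass"] = best_syntenic
    if best_tree is not None:
        flag_holders["tree_nearest"] = best_tree

    votes: dict[str, int] = {}
    for holder in flag_holders.values():
        votes[holder] = votes.get(holder, 0) + 1
    top = max(votes.values())
    winners = [c for c, v in votes.items() if v == top]
    winner = best_local if best_local in winners else sorted(winners)[0]

    available = 2 + 1 + (1 if params.use_phylogeny else 0)  # local, global, synteny(, tree)
    evidence = {
        "best_local": winner == best_local,
        "best_global": winner == best_global,
        "synteny_pass": synteny[winner][1],
        "tree_nearest": params.use_phylogeny and winner == best_tree,
    }
    n_flags = sum(evidence.values())
    if n_flags == available:
        confidence = "very_high"
    elif n_flags == available - 1:
        confidence = "high"
    elif n_flags >= 2:
        confidence = "moderate"
    else:
        confidence = "low"

    return OrthologCall(
        sample_gene=gene, ref_gene=winner, evidence=evidence,
        confidence=confidence, synteny_score=synteny[winner][0],
    )


_OGCS_RANK = {"very_high": 3, "high": 2, "moderate": 1, "low": 0}


def _aggregate_ogcs(confidences: list[str]) -> str:
    if not confidences:
        return "low"
    if all(c == "very_high" for c in confidences):
        return "very_high"
    if any(c == "low" for c in confidences):
        return "low"
    n_high = sum(1 for c in confidences if c in ("very_high", "high"))
    return "high" if 2 * n_high > len(confidences) else "moderate"


def copy_number_table(
    ref_genes: list[str],
    calls_by_sample: dict[str, list[OrthologCall]],
    ref_catalog: GeneCatalog,
) -> dict[str, dict[str, CopyNumberCell]]:
    """Copies of each requested reference gene per sample, with OGCS.

    Rows are reference gene ids, columns sample names; a zero-count cell
    is flagged absent (rendered red in the optional spreadsheet export).
    """
    unknown = [g for g in ref_genes if g not in ref_catalog.genes]
    if unknown:
        raise ValueError(f"reference genes not in reference catalog: {unknown}")
    table: dict[str, dict[str, CopyNumberCell]] = {}
    for ref_gene in ref_genes:
        row: dict[str, CopyNumberCell] = {}
        for sample, calls in calls_by_sample.items():
            members = sorted(c.sample_gene for c in calls if c.ref_gene == ref_gene)
            confidences = [c.confidence for c in calls if c.ref_gene == ref_gene]
            row[sample] = CopyNumberCell(
                count=len(members), members=members,
                ogcs=_aggregate_ogcs(confidences), absent=not members,
            )
        table[ref_gene] = row
    return table


def group_nature(
    group: DuplicateGroup,
    calls: dict[str, OrthologCall],
) -> str:
    """Nature of a small-scale (tandem/proximal) duplicate array relative
    to the reference: ``expansion`` when the array grew at an ancestral
    locus (some member has a synteny-passing ortholog), ``de_novo`` when
    orthologs exist but none at a syntenic position, ``unresolved`` when
    no member has any candidate."""
    if group.klass not in ("tandem", "proximal"):
        raise ValueError(f"group_nature applies to tandem/proximal groups, not {group.klass}")
    member_calls = [calls.get(m) for m in group.members]
    member_calls = [c for c in member_calls if c is not None]
    if not any(c.ref_gene for c in member_calls):
        return "unresolved"
    if any(c.ref_gene and c.evidence.get("synteny_pass") for c in member_calls):
        return "expansion"
    return "de_novo"


def build_seed_map(fwd_table: dict[str, FwdScoreRecord]) -> dict[str, str]:
    """Best forward hit per sample gene — the synteny seeds."""
    return {
        gid: rec.candidates[0][0]
        for gid, rec in fwd_table.items()
        if rec.candidates
    }


def partition_calls(
    partition: DuplicatePartition,
    calls: dict[str, OrthologCall],
) -> dict[str, list[str]]:
    """Reference gene -> sample duplicate-group members mapped to it
    (convenience view used by the specific-genes report)."""
    out: dict[str, list[str]] = {}
    for gid in sorted(partition.duplicates | partition.singletons):
        call = calls.get(gid)
        if call is not None and call.ref_gene:
            out.setdefault(call.ref_gene, []).append(gid)
    return out
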