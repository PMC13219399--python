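"""Singleton/duplicate segregation and duplicate-array classification.

Every input gene ends up in exactly one of two spaces:

* singleton — no self hit, only a self hit, or a best non-self hit that
  fails the species-specific cutoff(s);
* duplicate — everything else.

Duplicates are clustered into *families* as connected components of the
graph whose edges are cutoff-passing hits.  Within a family, positional
structure on each contig yields the classical classes:

* tandem — members at consecutive positions in gene order;
* proximal — members separated by 1..proximity intervening genes;
* dispersed — members on different contigs or farther apart than
  ``proximity``.

``overlap`` mode emits every positional subgroup (a gene may appear in
several, linked through a relationships table); ``strict`` mode partitions
genes, merging multi-class families into a single ``mixed`` group that
keeps per-member subclass labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .alignment_scores import Hit, SelfScoreRecord
from .annotation_io import GeneCatalog
from .thresholding_qc import ThresholdDecision

__all__ = [
    "ClassifierParams",
    "DuplicateGroup",
    "DuplicatePartition",
    "segregate_singletons",
    "cluster_duplicates",
    "score_group_confidence",
    "DEFAULT_PROXIMITY",
]

DEFAULT_PROXIMITY = 10  # max intervening genes for a proximal pair


@dataclass(frozen=True)
class ClassifierParams:
    proximity: int = DEFAULT_PROXIMITY
    mode: str = "overlap"  # overlap | strict

    def __post_init__(self) -> None:
        if self.proximity < 1:
            raise ValueError("proximity must be >= 1")
        if self.mode not in ("overlap", "strict"):
            raise ValueError(f"mode must be overlap or strict, got {self.mode!r}")


@dataclass
class DuplicateGroup:
    group_id: str
    klass: str  # tandem | proximal | dispersed | mixed
    members: list[str]
    family_id: str
    confidence: str = "low"
    member_subclass: dict[str, str] = field(default_factory=dict)  # strict mixed only


@dataclass
class DuplicatePartition:
    singletons: set[str]
    duplicates: set[str]
    groups: list[DuplicateGroup]
    # family_id -> (group_ids sharing genes, the shared genes)
    relationships: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)


def _passes(rec: SelfScoreRecord, decision: ThresholdDecision) -> bool:
    """Does a gene's best non-self hit clear the segregation cutoff(s)?"""
    if rec.self_bitscore is None or rec.second_best_bitscore is None:
        return False
    if decision.method == "busco_auto":
        return rec.norm_score >= decision.score_cutoff
    if decision.method == "similarity_fallback":
        return (rec.second_best_similarity or 0.0) >= decision.self_simcut
    # manual: both cutoffs, conjunctively
    return (
        rec.norm_score >= decision.score_cutoff
        and (rec.second_best_similarity or 0.0) >= decision.self_simcut
    )


def segregate_singletons(
    self_table: dict[str, SelfScoreRecord],
    decision: ThresholdDecision,
) -> tuple[set[str], set[str]]:
    """Split all genes into singletons and duplicates under a decision."""
    singletons, duplicates = set(), set()
    for gid, rec in self_table.items():
        (duplicates if _passes(rec, decision) else singletons).add(gid)
    return singletons, duplicates


def _hit_passes(hit: Hit, self_table: dict[str, SelfScoreRecord], decision: ThresholdDecision) -> bool:
    """Same cutoffs as segregation, applied to an individual non-self hit
    normalized by the query's self bit score."""
    rec = self_table.get(hit.query_id)
    if rec is None or rec.self_bitscore is None:
        return False
    norm = hit.bitscore / rec.self_bitscore
    if decision.method == "busco_auto":
        return norm >= decision.score_cutoff
    if decision.method == "similarity_fallback":
        return hit.pct_similarity >= decision.self_simcut
    return norm >= decision.score_cutoff and hit.pct_similarity >= decision.self_simcut


def _gap(catalog: GeneCatalog, a: str, b: str) -> int | None:
    """Intervening genes between two genes, or None across contigs."""
    ma, mb = catalog.genes[a], catalog.genes[b]
    if ma.contig != mb.contig:
        return None
    return abs(catalog.order_index[a] - catalog.order_index[b]) - 1


def _contig_windows(positions: list[int], proximity: int) -> list[tuple[int, int]]:
    """Maximal windows [i, j] over sorted positions whose extremes are
    within ``proximity`` intervening genes (all pairs then are too)."""
    windows = []
    n = len(positions)
    j = 0
    for i in range(n):
        j = max(j, i + 1)
        while j < n and positions[j] - positions[i] - 1 <= proximity:
            j += 1
        if j - i >= 2:
            if not windows or windows[-1][1] < j - 1:
                windows.append((i, j - 1))
    return windows


def _decompose_family(
    members: list[str],
    catalog: GeneCatalog,
    proximity: int,
) -> tuple[list[list[str]], list[list[str]], list[list[str]]]:
    """Positional decomposition of one family into tandem runs, proximal
    windows, and dispersed link groups.

    Dispersed relations are taken between *units*: each tandem run or
    proximal window is collapsed to its representative gene (lowest order
    index, then id), remaining members stand alone.  Units on different
    contigs (or farther than ``proximity``) that belong to the same family
    form a dispersed group of their representatives.
    """
    by_contig: dict[str, list[str]] = {}
    for gid in members:
        by_contig.setdefault(catalog.genes[gid].contig, []).append(gid)
    for contig in by_contig:
        by_contig[contig].sort(key=lambda g: catalog.order_index[g])

    tandem_runs: list[list[str]] = []
    proximal_windows: list[list[str]] = []
    units: list[list[str]] = []  # collapsed units, each a member list

    for contig in sorted(by_contig):
        genes = by_contig[contig]
        pos = [catalog.order_index[g] for g in genes]
        # maximal consecutive runs (0 intervening genes)
        run_start = 0
        runs: list[tuple[int, int]] = []
        for k in range(1, len(genes) + 1):
            if k == len(genes) or pos[k] != pos[k - 1] + 1:
                if k - run_start >= 2:
                    runs.append((run_start, k - 1))
                run_start = k
        for i, j in runs:
            tandem_runs.append(genes[i:j + 1])
        # maximal proximity windows not fully consecutive
        covered_by_window: set[int] = set()
        for i, j in _contig_windows(pos, proximity):
            window = genes[i:j + 1]
            if pos[j] - pos[i] == j - i:  # fully consecutive => already a tandem run
                covered_by_window.update(range(i, j + 1))
                continue
            proximal_windows.append(window)
            covered_by_window.update(range(i, j + 1))
        # dispersed units on this contig: windows/runs collapse, loners stand alone
        unit_spans = sorted(set(_contig_windows(pos, proximity)) | set(runs))
        merged: list[tuple[int, int]] = []
        for i, j in unit_spans:
            if merged and i <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], j))
            else:
                merged.append((i, j))
        in_unit: set[int] = set()
        for i, j in merged:
            units.append(genes[i:j + 1])
            in_unit.update(range(i, j + 1))
        for k, g in enumerate(genes):
            if k not in in_unit:
                units.append([g])

    dispersed_groups: list[list[str]] = []
    if len(units) > 1:
        # all units of one family are homology-linked; any two units are a
        # dispersed relation by construction (different contig or > proximity)
        reps = sorted(
            (min(u, key=lambda g: (catalog.order_index[g], g)) for u in units),
            key=lambda g: (catalog.genes[g].contig, catalog.order_index[g]),
        )
        dispersed_groups.append(reps)
    elif not units:
        pass
    elif len(units) == 1 and len(units[0]) != len(members):
        # single contig but some members beyond proximity of the unit: the
        # loner branch above guarantees they formed their own units, so
        # this cannot happen; kept as a guard.
        raise AssertionError("family decomposition lost members")

    return tandem_runs, proximal_windows, dispersed_groups


def score_group_confidence(
    members: list[str],
    passing_pairs: set[frozenset[str]],
) -> str:
    """Confidence of a group from its internal hit connectivity: high when
    every member pair is joined by a passing hit (clique), moderate when at
    least half are, low when the group is held together transitively."""
    n = len(members)
    total = n * (n - 1) // 2
    if total == 0:
        return "low"
    connected = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((members[i], members[j])) in passing_pairs
    )
    if connected == total:
        return "high"
    if connected * 2 >= total:
        return "moderate"
    return "low"


def cluster_duplicates(
    duplicates: set[str],
    hits: list[Hit],
    decision: ThresholdDecision,
    catalog: GeneCatalog,
    params: ClassifierParams,
    singletons: set[str] | None = None,
) -> DuplicatePartition:
    """Cluster duplicate genes into families and classify their arrays."""
    missing = duplicates - set(catalog.genes)
    if missing:
        raise ValueError(f"duplicate genes missing from catalog: {sorted(missing)[:5]}")

    # recompute the per-gene self table locally for per-hit normalization
    self_table = {gid: SelfScoreRecord(gene_id=gid) for gid in catalog.genes}
    for hit in hits:
        if hit.query_id == hit.subject_id and hit.query_id in self_table:
            rec = self_table[hit.query_id]
            if rec.self_bitscore is None or hit.bitscore > rec.self_bitscore:
                rec.self_bitscore = hit.bitscore

    graph = nx.Graph()
    graph.add_nodes_from(sorted(duplicates))
    passing_pairs: set[frozenset[str]] = set()
    for hit in hits:
        a, b = hit.query_id, hit.subject_id
        if a == b or a not in duplicates or b not in duplicates:
            continue
        # one passing direction suffices (hit tables are near- but not
        # exactly symmetric)
        if _hit_passes(hit, self_table, decision):
            graph.add_edge(a, b)
            passing_pairs.add(frozenset((a, b)))

    groups: list[DuplicateGroup] = []
    relationships: dict[str, tuple[list[str], list[str]]] = {}
    counter = 0

    for comp in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        members = sorted(comp, key=lambda g: (catalog.genes[g].contig, catalog.order_index[g]))
        family_id = f"family_{min(comp)}"
        if len(members) < 2:
            continue
        tandem_runs, proximal_windows, dispersed_groups = _decompose_family(
            members, catalog, params.proximity
        )

        def subclass_of(gid: str) -> str:
            if any(gid in run for run in tandem_runs):
                return "tandem"
            if any(gid in w for w in proximal_windows):
                return "proximal"
            return "dispersed"

        if params.mode == "overlap":
            family_groups: list[DuplicateGroup] = []
            for klass, member_lists in (
                ("tandem", tandem_runs),
                ("proximal", proximal_windows),
                ("dispersed", dispersed_groups),
            ):
                for mlist in member_lists:
                    counter += 1
                    family_groups.append(
                        DuplicateGroup(
                            group_id=f"group_{counter:05d}",
                            klass=klass,
                            members=list(mlist),
                            family_id=family_id,
                            confidence=score_group_confidence(list(mlist), passing_pairs),
                        )
                    )
            groups.extend(family_groups)
            if len(family_groups) > 1:
                seen: dict[str, int] = {}
                for g in family_groups:
                    for gid in g.members:
                        seen[gid] = seen.get(gid, 0) + 1
                shared = sorted(g for g, n in seen.items() if n > 1)
                relationships[family_id] = ([g.group_id for g in family_groups], shared)
        else:  # strict
            classes = {subclass_of(g) for g in members}
            counter += 1
            if len(classes) == 1:
                klass = classes.pop()
                groups.append(
                    DuplicateGroup(
                        group_id=f"group_{counter:05d}", klass=klass,
                        members=members, family_id=family_id,
                        confidence=score_group_confidence(members, passing_pairs),
                    )
                )
            else:
                groups.append(
                    DuplicateGroup(
                        group_id=f"group_{counter:05d}", klass="mixed",
                        members=members, family_id=family_id,
                        confidence=score_group_confidence(members, passing_pairs),
                        member_subclass={g: subclass_of(g) for g in members},
                    )
                )

    # isolated "duplicates" (passed the score cutoff but whose partner hit
    # did not survive edge filtering) stay duplicates but form no group
    return DuplicatePartition(
        singletons=set(singletons) if singletons is not None else set(catalog.genes) - duplicates,
        duplicates=set(duplicates),
        groups=groups,
        relationships=relationships,
    )
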