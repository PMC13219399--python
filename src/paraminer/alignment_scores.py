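"""Local-alignment hit tables and normalized bit scores.

Works on 12-column tabular hits (BLAST ``outfmt 6`` compatible, as produced
by DIAMOND, BLAST or MMseqs2).  The scoring layer never depends on which
aligner produced the table.

Two normalizations drive the whole pipeline:

* self-normalized bit score — bit score of a gene's best *non-self* hit
  within its own genome divided by the bit score of the gene against
  itself; near 1 for recent duplicates, near 0 (or undefined) for
  singletons.
* forward-normalized bit score — bit score of a sample-vs-reference hit
  divided by the same self bit score; used to pre-filter ortholog
  candidates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import GeneCatalog

__all__ = [
    "Hit",
    "SelfScoreRecord",
    "FwdScoreRecord",
    "load_hits",
    "self_score_table",
    "forward_score_table",
    "DEFAULT_EVALUE_CUT",
    "DEFAULT_FWD_SIMCUT",
    "DEFAULT_FWD_SCORECUT",
]

DEFAULT_EVALUE_CUT = 1e-5
DEFAULT_FWD_SIMCUT = 40.0   # percent similarity for forward candidates
DEFAULT_FWD_SCORECUT = 0.3  # forward-normalized bit-score cutoff

_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    pct_similarity: float
    evalue: float
    bitscore: float


@dataclass
class SelfScoreRecord:
    gene_id: str
    self_bitscore: float | None = None
    second_best_subject: str | None = None
    second_best_bitscore: float | None = None
    second_best_similarity: float | None = None

    @property
    def norm_score(self) -> float | None:
        """Self-normalized bit score; defined only when both a self hit and
        a non-self hit exist."""
        if self.self_bitscore is None or self.second_best_bitscore is None:
            return None
        return self.second_best_bitscore / self.self_bitscore


@dataclass
class FwdScoreRecord:
    gene_id: str
    # (ref_gene_id, bitscore, pct_similarity, fwd_norm_score), bitscore-descending
    candidates: list[tuple[str, float, float, float]] = field(default_factory=list)


def load_hits(table: str, evalue_cut: float = DEFAULT_EVALUE_CUT) -> list[Hit]:
    """Parse a 12-column tabular hit stream.

    Hits above ``evalue_cut`` are dropped; for duplicate (query, subject)
    pairs only the highest-bitscore row (best HSP) is kept.  Non-numeric
    evalue/bitscore cells raise a ``ValueError`` naming the line.
    """
    if not table.strip():
        return []
    df = pd.read_csv(
        io.StringIO(table), sep="\t", comment="#", header=None,
        names=_COLUMNS, dtype=str, skip_blank_lines=True,
    )
    for col in ("identity", "evalue", "bitscore"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ValueError(f"non-numeric {col} value on hit-table line {lineno}")
        df[col] = converted
    df = df[df["evalue"] <= evalue_cut]
    # best HSP per pair
    df = df.sort_values("bitscore", ascending=False).drop_duplicates(["query", "subject"], keep="first")
    df = df.sort_index()
    return [
        Hit(
            query_id=row.query, subject_id=row.subject,
            pct_similarity=float(row.identity), evalue=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        for row in df.itertuples(index=False)
    ]


def self_score_table(hits: list[Hit], catalog: GeneCatalog) -> dict[str, SelfScoreRecord]:
    """Per-gene self bit score and best non-self hit within the same sample.

    Every catalog gene gets a record; absence of hits is encoded (fields
    ``None``), never raised.
    """
    records = {gid: SelfScoreRecord(gene_id=gid) for gid in catalog.genes}
    best_nonself: dict[str, Hit] = {}
    for hit in sorted(hits, key=lambda h: (h.query_id, -h.bitscore, h.subject_id)):
        if hit.query_id not in records:
            continue
        if hit.query_id == hit.subject_id:
            rec = records[hit.query_id]
            if rec.self_bitscore is None or hit.bitscore > rec.self_bitscore:
                rec.self_bitscore = hit.bitscore
        elif hit.subject_id in records:
            prev = best_nonself.get(hit.query_id)
            if prev is None or hit.bitscore > prev.bitscore:
                best_nonself[hit.query_id] = hit
    for gid, hit in best_nonself.items():
        rec = records[gid]
        rec.second_best_subject = hit.subject_id
        rec.second_best_bitscore = hit.bitscore
        rec.second_best_similarity = hit.pct_similarity
    return records


def forward_score_table(
    self_table: dict[str, SelfScoreRecord],
    fwd_hits: list[Hit],
    fwd_simcut: float = DEFAULT_FWD_SIMCUT,
    fwd_scorecut: float = DEFAULT_FWD_SCORECUT,
) -> tuple[dict[str, FwdScoreRecord], list[str]]:
    """Filter sample-vs-reference hits into per-gene ortholog candidate lists.

    A candidate survives iff its percent similarity >= ``fwd_simcut`` and
    its forward-normalized bit score >= ``fwd_scorecut``.  Genes without a
    self bit score cannot be normalized; they get no record and are
    returned in the second element.
    """
    by_query: dict[str, list[Hit]] = {}
    for hit in fwd_hits:
        by_query.setdefault(hit.query_id, []).append(hit)

    records: dict[str, FwdScoreRecord] = {}
    unnormalizable: list[str] = []
    for gid, rec in self_table.items():
        if rec.self_bitscore is None:
            if gid in by_query:
                unnormalizable.append(gid)
            continue
        candidates = []
        for hit in by_query.get(gid, []):
            fwd_norm = hit.bitscore / rec.self_bitscore
            if hit.pct_similarity >= fwd_simcut and fwd_norm >= fwd_scorecut:
                candidates.append((hit.subject_id, hit.bitscore, hit.pct_similarity, fwd_norm))
        candidates.sort(key=lambda c: (-c[1], c[0]))
        records[gid] = FwdScoreRecord(gene_id=gid, candidates=candidates)
    return records, sorted(unnormalizable)
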