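"""GFF3 + sequence ingestion across attribute-key dialects.

Structural annotations from different databases disagree on which GFF3
attribute carries the gene identifier and which attribute links mRNAs and
CDS segments to their parents.  This module parses a 9-column GFF3 stream
under a per-sample :class:`AttributeConfig`, validates it into structured
error/warning records (never exceptions for data problems), collapses
isoforms to a single representative transcript per gene, and builds a
:class:`GeneCatalog` with one protein and one CDS per gene plus a dense
per-contig gene-order index used by the positional duplicate classifier.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq

__all__ = [
    "AttributeConfig",
    "GeneModel",
    "GeneCatalog",
    "ValidationReport",
    "parse_annotation",
    "collapse_isoforms",
    "clean_fasta",
    "read_fasta",
    "catalog_to_gff3",
    "load_attribute_configs",
]

#: Fallback attribute keys when a sample has no config entry.
DEFAULT_GENE_KEY = "ID"
DEFAULT_MRNA_PARENT_KEY = "Parent"
DEFAULT_CDS_PARENT_KEY = "Parent"

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*")
_NT_ALPHABET = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class AttributeConfig:
    """Which GFF3 attribute keys identify genes and parent links for a sample."""

    sample_name: str
    gene_id_key: str = DEFAULT_GENE_KEY
    mrna_parent_key: str = DEFAULT_MRNA_PARENT_KEY
    cds_parent_key: str = DEFAULT_CDS_PARENT_KEY

    def __post_init__(self) -> None:
        for key in (self.gene_id_key, self.mrna_parent_key, self.cds_parent_key):
            if not key:
                raise ValueError("attribute keys must be non-empty")


@dataclass
class CDSSegment:
    start: int
    end: int
    phase: int = 0


@dataclass
class Transcript:
    mrna_id: str
    cds: list[CDSSegment] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(seg.end - seg.start + 1 for seg in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def representative(self) -> Transcript:
        """Longest-CDS transcript; ties broken by lexicographically smallest mRNA id."""
        return max(self.transcripts, key=lambda t: (t.cds_length, _neg_lex(t.mrna_id)))


def _neg_lex(s: str) -> tuple[int, ...]:
    # max() with reversed lexicographic order: smaller id wins on ties
    return tuple(-ord(c) for c in s)


@dataclass
class ValidationReport:
    sample_name: str
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def error(self, code: str, message: str, feature_id: str = "") -> None:
        self.errors.append((code, message, feature_id))

    def warn(self, code: str, message: str, feature_id: str = "") -> None:
        self.warnings.append((code, message, feature_id))


@dataclass
class GeneCatalog:
    """Ordered gene models of one sample with one representative sequence each."""

    sample_name: str
    genes: dict[str, GeneModel]
    order_index: dict[str, int]
    representative_protein: dict[str, str]
    representative_cds: dict[str, str | None]

    def contigs(self) -> dict[str, list[str]]:
        """Gene ids per contig, in gene-order (ascending order_index)."""
        by_contig: dict[str, list[str]] = {}
        for gid, model in self.genes.items():
            by_contig.setdefault(model.contig, []).append(gid)
        for contig in by_contig:
            by_contig[contig].sort(key=lambda g: self.order_index[g])
        return by_contig

    def neighbors(self, gene_id: str, flank: int) -> tuple[list[str], list[str]]:
        """Up to ``flank`` gene ids to the left and right of a gene on its contig."""
        model = self.genes[gene_id]
        contig_genes = self.contigs()[model.contig]
        pos = self.order_index[gene_id]
        left = contig_genes[max(0, pos - flank):pos]
        right = contig_genes[pos + 1:pos + 1 + flank]
        return left, right


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_annotation(
    gff_text: str | Iterable[str],
    config: AttributeConfig | None = None,
) -> tuple[list[GeneModel], ValidationReport]:
    """Parse a GFF3 stream into gene models under a sample's attribute dialect.

    Data problems become error/warning records on the returned
    :class:`ValidationReport`; only programming errors raise.  A gene is
    emitted only if it has at least one mRNA with at least one CDS whose
    parent chain resolves.
    """
    if config is None:
        config = AttributeConfig(sample_name="default")
    report = ValidationReport(sample_name=config.sample_name)
    lines = gff_text.splitlines() if isinstance(gff_text, str) else gff_text

    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    transcripts: dict[str, Transcript] = {}
    pending_cds: list[tuple[int, str, CDSSegment]] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            report.error(
                "malformed_line",
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}",
                f"line:{lineno}",
            )
            continue
        contig, _source, ftype, start_s, end_s, _score, strand, phase_s, col9 = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            report.error("bad_coordinates", f"line {lineno}: non-integer coordinates", f"line:{lineno}")
            continue
        if start > end:
            report.error("bad_coordinates", f"line {lineno}: start > end", f"line:{lineno}")
            continue
        attrs = _parse_attributes(col9)
        ftype_l = ftype.lower()

        if ftype_l == "gene":
            gene_id = attrs.get(config.gene_id_key)
            if gene_id is None:
                report.error(
                    "missing_attribute",
                    f"line {lineno}: gene feature lacks attribute '{config.gene_id_key}'",
                    f"line:{lineno}",
                )
                continue
            if strand not in "+-":
                report.warn("unstranded_gene", f"gene {gene_id} has strand '{strand}'; assuming '+'", gene_id)
                strand = "+"
            genes[gene_id] = GeneModel(gene_id=gene_id, contig=contig, strand=strand, start=start, end=end)
        elif ftype_l in ("mrna", "transcript"):
            mrna_id = attrs.get("ID")
            parent = attrs.get(config.mrna_parent_key)
            if mrna_id is None or parent is None:
                report.error(
                    "missing_attribute",
                    f"line {lineno}: mRNA lacks 'ID' or parent key '{config.mrna_parent_key}'",
                    f"line:{lineno}",
                )
                continue
            if parent not in genes:
                report.error("dangling_parent", f"mRNA {mrna_id} references unknown gene {parent}", mrna_id)
                continue
            mrna_to_gene[mrna_id] = parent
            transcripts[mrna_id] = Transcript(mrna_id=mrna_id)
        elif ftype_l == "cds":
            parent = attrs.get(config.cds_parent_key)
            if parent is None:
                report.error(
                    "missing_attribute",
                    f"line {lineno}: CDS lacks parent key '{config.cds_parent_key}'",
                    f"line:{lineno}",
                )
                continue
            phase = int(phase_s) if phase_s in ("0", "1", "2") else 0
            pending_cds.append((lineno, parent, CDSSegment(start=start, end=end, phase=phase)))
        # other feature types (exon, UTR, ...) are ignored

    for lineno, parent, seg in pending_cds:
        # a CDS may name its mRNA or (single-transcript dialects) its gene
        if parent in transcripts:
            transcripts[parent].cds.append(seg)
        elif parent in genes:
            tx = transcripts.setdefault(parent, Transcript(mrna_id=parent))
            mrna_to_gene.setdefault(parent, parent)
            tx.cds.append(seg)
        else:
            report.error("dangling_parent", f"line {lineno}: CDS references unknown mRNA {parent}", parent)

    models: list[GeneModel] = []
    for gene_id, model in genes.items():
        for mrna_id, parent_gene in mrna_to_gene.items():
            if parent_gene == gene_id and transcripts[mrna_id].cds:
                tx = transcripts[mrna_id]
                tx.cds.sort(key=lambda s: s.start)
                model.transcripts.append(tx)
        if not model.transcripts:
            report.warn("gene_without_cds", f"gene {gene_id} has no mRNA with CDS; excluded", gene_id)
            continue
        for tx in model.transcripts:
            for seg in tx.cds:
                if seg.start < model.start or seg.end > model.end:
                    report.warn("cds_outside_gene", f"CDS of {tx.mrna_id} extends beyond gene bounds", gene_id)
            if tx.cds_length % 3 != 0:
                model.flags.add("cds_not_multiple_of_3")
        models.append(model)
    return models, report


def clean_fasta(raw: str) -> tuple[str, ValidationReport, int]:
    """Normalize a FASTA stream: truncate headers at whitespace, uppercase,
    replace out-of-alphabet characters (X for protein-like records, N for
    nucleotide-like), and reject duplicate headers.

    Returns ``(cleaned_text, report, n_replaced)``.
    """
    report = ValidationReport(sample_name="fasta")
    out: list[str] = []
    seen: set[str] = set()
    n_replaced = 0
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal n_replaced
        if header is None:
            return
        seq = "".join(chunks).upper()
        letters = [ch for ch in seq if ch.isalpha()]
        # sniff the molecule type from the share of core nucleotide letters
        nt_share = sum(ch in "ACGTUN" for ch in letters) / len(letters) if letters else 1.0
        is_nt = nt_share >= 0.9
        allowed = _NT_ALPHABET if is_nt else _AA_ALPHABET
        repl = "N" if is_nt else "X"
        cleaned = []
        for ch in seq:
            if ch in allowed:
                cleaned.append(ch)
            else:
                cleaned.append(repl)
                n_replaced += 1
        out.append(f">{header}")
        out.append("".join(cleaned))

    for line in raw.splitlines():
        if line.startswith(">"):
            flush()
            chunks = []
            header = line[1:].split()[0] if line[1:].split() else ""
            if header in seen:
                report.error("duplicate_header", f"duplicate FASTA header '{header}'", header)
            seen.add(header)
        else:
            chunks.append(line.strip())
    flush()
    return "\n".join(out) + ("\n" if out else ""), report, n_replaced


def read_fasta(text: str) -> dict[str, str]:
    """Parse (already clean) FASTA text into an ordered id -> sequence mapping."""
    from Bio import SeqIO

    records = SeqIO.parse(io.StringIO(text), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in records}


def _extract_cds_from_genome(model: GeneModel, tx: Transcript, contig_seq: str) -> str:
    parts = []
    for seg in sorted(tx.cds, key=lambda s: s.start):
        if seg.end > len(contig_seq):
            raise ValueError(f"CDS of {tx.mrna_id} extends beyond contig end")
        parts.append(contig_seq[seg.start - 1:seg.end])
    if model.strand == "-":
        parts = [str(Seq(p).reverse_complement()) for p in reversed(parts)]
    return "".join(parts)


def _translate(cds: str) -> tuple[str, bool]:
    """Standard-table translation; trailing stop trimmed.  Returns (protein,
    has_internal_stop)."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(trimmed).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot, "*" in prot


def collapse_isoforms(
    models: list[GeneModel],
    sequences: dict[str, str],
    input_kind: str,
    sample_name: str = "sample",
    report: ValidationReport | None = None,
) -> GeneCatalog:
    """Pick one representative transcript per gene and derive its protein.

    ``input_kind`` is one of ``genome`` (sequences keyed by contig),
    ``cds`` or ``protein`` (keyed by mRNA or gene id).  The representative
    is the transcript with the longest total CDS length, ties broken by
    lexicographically smallest mRNA id.
    """
    if input_kind not in ("genome", "cds", "protein"):
        raise ValueError(f"unknown input_kind {input_kind!r}")
    if report is None:
        report = ValidationReport(sample_name=sample_name)

    genes: dict[str, GeneModel] = {}
    proteins: dict[str, str] = {}
    cds_seqs: dict[str, str | None] = {}

    for model in models:
        tx = model.representative()
        cds: str | None = None
        prot: str | None = None
        if input_kind == "genome":
            contig_seq = sequences.get(model.contig)
            if contig_seq is None:
                report.error("missing_contig", f"contig {model.contig} absent from genome FASTA", model.gene_id)
                continue
            try:
                cds = _extract_cds_from_genome(model, tx, contig_seq)
            except ValueError as exc:
                report.error("cds_out_of_range", str(exc), model.gene_id)
                continue
        elif input_kind == "cds":
            cds = sequences.get(tx.mrna_id) or sequences.get(model.gene_id)
            if cds is None:
                report.error("unresolved_header", f"no CDS sequence for {tx.mrna_id}/{model.gene_id}", model.gene_id)
                continue
        else:  # protein
            prot = sequences.get(tx.mrna_id) or sequences.get(model.gene_id)
            if prot is None:
                report.error("unresolved_header", f"no protein sequence for {tx.mrna_id}/{model.gene_id}", model.gene_id)
                continue
            if prot.endswith("*"):
                prot = prot[:-1]
            if "*" in prot:
                model.flags.add("internal_stop")

        if cds is not None:
            if len(cds) % 3 != 0:
                model.flags.add("cds_not_multiple_of_3")
            prot, internal_stop = _translate(cds)
            if internal_stop:
                model.flags.add("internal_stop")
                report.warn("internal_stop", f"gene {model.gene_id} has internal stop codon(s)", model.gene_id)

        genes[model.gene_id] = model
        proteins[model.gene_id] = prot or ""
        cds_seqs[model.gene_id] = cds

    order_index: dict[str, int] = {}
    by_contig: dict[str, list[GeneModel]] = {}
    for model in genes.values():
        by_contig.setdefault(model.contig, []).append(model)
    for contig_models in by_contig.values():
        contig_models.sort(key=lambda m: (m.start, m.end, m.gene_id))
        for rank, model in enumerate(contig_models):
            order_index[model.gene_id] = rank

    return GeneCatalog(
        sample_name=sample_name,
        genes=genes,
        order_index=order_index,
        representative_protein=proteins,
        representative_cds=cds_seqs,
    )


def catalog_to_gff3(catalog: GeneCatalog) -> str:
    """Serialize a catalog back to GFF3 (round-trip check / interchange)."""
    lines = ["##gff-version 3"]
    for contig, gene_ids in sorted(catalog.contigs().items()):
        for gid in gene_ids:
            m = catalog.genes[gid]
            lines.append(
                "\t".join([m.contig, "paraminer", "gene", str(m.start), str(m.end), ".", m.strand, ".", f"ID={gid}"])
            )
            for tx in m.transcripts:
                lines.append(
                    "\t".join(
                        [m.contig, "paraminer", "mRNA", str(min(s.start for s in tx.cds)),
                         str(max(s.end for s in tx.cds)), ".", m.strand, ".", f"ID={tx.mrna_id};Parent={gid}"]
                    )
                )
                for seg in tx.cds:
                    lines.append(
                        "\t".join(
                            [m.contig, "paraminer", "CDS", str(seg.start), str(seg.end), ".", m.strand,
                             str(seg.phase), f"ID=cds.{tx.mrna_id};Parent={tx.mrna_id}"]
                        )
                    )
    return "\n".join(lines) + "\n"


def load_attribute_configs(text: str) -> dict[str, AttributeConfig]:
    """Parse the plain-text per-sample config: one line per sample,
    ``sample<TAB>gene_key<TAB>mrna_key<TAB>cds_key``."""
    configs: dict[str, AttributeConfig] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"config line needs 4 tab-separated fields: {line!r}")
        sample, gene_key, mrna_key, cds_key = parts
        configs[sample] = AttributeConfig(
            sample_name=sample, gene_id_key=gene_key,
            mrna_parent_key=mrna_key, cds_parent_key=cds_key,
        )
    return configs
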