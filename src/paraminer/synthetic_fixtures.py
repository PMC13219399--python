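"""Reproducible synthetic genomes with planted, machine-readable truth.

The generator emits exactly the inputs the pipeline consumes — genome
FASTA, GFF3, protein/CDS FASTA, a 12-column hit table, a BUSCO-like full
table, and a TPM expression matrix — together with a
:class:`FixtureTruth` stating which genes belong to which planted family
and class.  All genes are single-CDS random-codon ORFs; duplicate family
members derive from a common founder by Jukes–Cantor substitution at a
controlled divergence; tandem members occupy consecutive gene slots,
proximal members are separated by a fixed intervening-gene gap, dispersed
members sit on different contigs.

The hit table comes from a built-in deterministic scorer (bit score
proportional to identity x length), so tests never depend on an external
aligner.  All randomness flows from the seed: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlantedFamily",
    "FixtureSpec",
    "FixtureTruth",
    "FixtureBundle",
    "generate_fixture",
    "simulate_cds_pair",
    "default_families",
]

_NTS = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PlantedFamily:
    klass: str            # tandem | proximal | dispersed
    size: int
    divergence: float     # expected substitutions/site, founder -> member
    gap: int = 2          # intervening genes between proximal members

    def __post_init__(self) -> None:
        if self.klass not in ("tandem", "proximal", "dispersed"):
            raise ValueError(f"unknown family class {self.klass!r}")
        if self.size < 2:
            raise ValueError("family size must be >= 2")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must lie in [0, 0.5]")


def default_families() -> list[PlantedFamily]:
    """A mixed set of small families at low divergence — the baseline
    planted-truth recovery condition."""
    return [
        PlantedFamily("tandem", 3, 0.05),
        PlantedFamily("tandem", 4, 0.10),
        PlantedFamily("proximal", 2, 0.05, gap=3),
        PlantedFamily("proximal", 3, 0.10, gap=2),
        PlantedFamily("dispersed", 2, 0.05),
        PlantedFamily("dispersed", 3, 0.10),
    ]


@dataclass
class FixtureSpec:
    n_contigs: int = 5
    genes_per_contig: int = 50
    planted_families: list[PlantedFamily] = field(default_factory=default_families)
    n_single_copy_markers: int = 120
    expression_rho: float = 0.8
    pseudogene_fraction: float = 0.0
    n_expression_samples: int = 200
    min_codons: int = 100
    max_codons: int = 250
    intergenic: int = 60
    seed: int = 0


@dataclass
class FixtureTruth:
    family_of: dict[str, str | None]          # gene -> family id or None
    families: dict[str, dict]                 # family id -> {class, members}
    markers: list[str]                        # planted single-copy genes
    pair_ks: dict[tuple[str, str], float]     # within-family nominal Ks


@dataclass
class FixtureBundle:
    genome_fasta: str
    gff3: str
    protein_fasta: str
    cds_fasta: str
    hit_table: str
    busco_table: str
    expression_tsv: str
    truth: FixtureTruth


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal-stop-free codons + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_NTS, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _jc_mutate(cds: str, distance: float, rng: np.random.Generator) -> str:
    """Evolve a CDS by per-site Jukes–Cantor substitution at the given
    expected distance; substitutions creating a stop codon are discarded
    (the site stays unchanged)."""
    if distance <= 0:
        return cds
    p_change = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    seq = list(cds)
    hit = rng.random(len(seq)) < p_change
    for i in np.nonzero(hit)[0]:
        if i >= len(seq) - 3 or i < 3:
            continue  # keep start/stop codons intact
        old = seq[i]
        new = rng.choice([n for n in "ACGT" if n != old])
        codon_start = (i // 3) * 3
        trial = seq[codon_start:codon_start + 3]
        trial[i % 3] = new
        if "".join(trial) in _STOPS:
            continue
        seq[i] = new
    return "".join(seq)


def simulate_cds_pair(
    n_codons: int, ks: float, rng: np.random.Generator
) -> tuple[str, str]:
    """A CDS and a copy evolved from it at Jukes–Cantor distance ``ks``
    (uniform over sites, so the synonymous-site distance equals ``ks`` in
    expectation) — the ground truth for Ks-recovery checks."""
    a = _random_orf(rng, n_codons + 2)  # +start/stop codons
    b = _jc_mutate(a, ks, rng)
    return a, b


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate(table=1))
    return prot[:-1] if prot.endswith("*") else prot


def _allocate_slots(spec: FixtureSpec) -> tuple[dict[tuple[int, int], tuple[str, int]], list[tuple[int, int]]]:
    """Reserve (contig, slot) positions for each planted family member.

    Returns ``position -> (family_id, member_index)`` plus the ordered
    list of free positions.  Raises when families exceed the grid.
    """
    reserved: dict[tuple[int, int], tuple[str, int]] = {}
    next_free = [0] * spec.n_contigs  # scan pointer per contig

    def find_block(contig: int, length: int, stride: int) -> int | None:
        start = next_free[contig]
        while start + (length - 1) * stride < spec.genes_per_contig:
            cells = [start + k * stride for k in range(length)]
            if all((contig, c) not in reserved for c in cells):
                return start
            start += 1
        return None

    for fidx, fam in enumerate(spec.planted_families):
        fam_id = f"fam_{fidx:02d}"
        if fam.klass in ("tandem", "proximal"):
            stride = 1 if fam.klass == "tandem" else fam.gap + 1
            placed = False
            for contig in range(spec.n_contigs):
                start = find_block(contig, fam.size, stride)
                if start is not None:
                    for k in range(fam.size):
                        reserved[(contig, start + k * stride)] = (fam_id, k)
                    next_free[contig] = start + (fam.size - 1) * stride + 1
                    placed = True
                    break
            if not placed:
                raise ValueError(f"cannot place family {fam_id} ({fam.klass}, size {fam.size})")
        else:  # dispersed: one member per distinct contig
            if fam.size > spec.n_contigs:
                raise ValueError(f"dispersed family {fam_id} needs {fam.size} contigs")
            for k, contig in enumerate(range(fam.size)):
                slot = next_free[contig]
                while (contig, slot) in reserved:
                    slot += 1
                if slot >= spec.genes_per_contig:
                    raise ValueError(f"cannot place dispersed family {fam_id}")
                reserved[(contig, slot)] = (fam_id, k)
                next_free[contig] = slot + 1

    free = [
        (c, s)
        for c in range(spec.n_contigs)
        for s in range(spec.genes_per_contig)
        if (c, s) not in reserved
    ]
    return reserved, free


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate the full input bundle plus ground truth for one sample."""
    rng = np.random.default_rng(spec.seed)
    reserved, free = _allocate_slots(spec)
    if spec.n_single_copy_markers > len(free):
        raise ValueError("not enough free gene slots for the requested markers")
    marker_positions = set(free[: spec.n_single_copy_markers])

    # founders per family
    founders: dict[str, str] = {}
    fam_meta: dict[str, PlantedFamily] = {}
    for fidx, fam in enumerate(spec.planted_families):
        fam_id = f"fam_{fidx:02d}"
        n_codons = int(rng.integers(spec.min_codons, spec.max_codons + 1))
        founders[fam_id] = _random_orf(rng, n_codons)
        fam_meta[fam_id] = fam

    gene_cds: dict[str, str] = {}
    family_of: dict[str, str | None] = {}
    member_depth: dict[str, float] = {}
    families: dict[str, dict] = {}
    markers: list[str] = []
    gff_lines = ["##gff-version 3"]
    genome_parts: dict[str, list[str]] = {}

    for contig in range(spec.n_contigs):
        contig_name = f"contig{contig + 1:02d}"
        genome_parts[contig_name] = []
        pos = 1
        for slot in range(spec.genes_per_contig):
            gid = f"g{contig + 1:02d}_{slot:03d}"
            key = (contig, slot)
            if key in reserved:
                fam_id, member_idx = reserved[key]
                fam = fam_meta[fam_id]
                depth = 0.0 if member_idx == 0 else fam.divergence
                cds = founders[fam_id] if member_idx == 0 else _jc_mutate(founders[fam_id], fam.divergence, rng)
                family_of[gid] = fam_id
                member_depth[gid] = depth
                families.setdefault(fam_id, {"class": fam.klass, "members": []})["members"].append(gid)
            else:
                n_codons = int(rng.integers(spec.min_codons, spec.max_codons + 1))
                cds = _random_orf(rng, n_codons)
                family_of[gid] = None
                if key in marker_positions:
                    markers.append(gid)
            gene_cds[gid] = cds

            spacer = "".join(rng.choice(_NTS, size=spec.intergenic))
            genome_parts[contig_name].append(spacer)
            start = pos + spec.intergenic
            end = start + len(cds) - 1
            genome_parts[contig_name].append(cds)
            pos = end + 1
            gff_lines.append(
                "\t".join([contig_name, "synthetic", "gene", str(start), str(end), ".", "+", ".", f"ID={gid}"])
            )
            gff_lines.append(
                "\t".join([contig_name, "synthetic", "mRNA", str(start), str(end), ".", "+", ".",
                           f"ID={gid}.1;Parent={gid}"])
            )
            gff_lines.append(
                "\t".join([contig_name, "synthetic", "CDS", str(start), str(end), ".", "+", "0",
                           f"Parent={gid}.1"])
            )

    genome_fasta = "".join(
        f">{contig}\n{''.join(parts)}\n" for contig, parts in genome_parts.items()
    )
    proteins = {gid: _translate(cds) for gid, cds in gene_cds.items()}
    protein_fasta = "".join(f">{gid}\n{prot}\n" for gid, prot in proteins.items())
    cds_fasta = "".join(f">{gid}\n{cds}\n" for gid, cds in gene_cds.items())

    # hit table from the built-in scorer: self hits for everyone,
    # within-family hits at identity-proportional bit scores
    hit_lines = []

    def hit_row(q: str, s: str, ident: float, length: int, bits: float) -> str:
        mism = int(round(length * (1 - ident / 100.0)))
        return "\t".join(
            [q, s, f"{ident:.1f}", str(length), str(mism), "0", "1", str(length),
             "1", str(length), "1e-30", f"{bits:.1f}"]
        )

    for gid, prot in proteins.items():
        hit_lines.append(hit_row(gid, gid, 100.0, len(prot), 2.0 * len(prot)))
    for fam_id, meta in families.items():
        members = meta["members"]
        for a in members:
            for b in members:
                if a == b:
                    continue
                pa, pb = proteins[a], proteins[b]
                L = min(len(pa), len(pb))
                matches = sum(1 for x, y in zip(pa, pb) if x == y)
                ident = 100.0 * matches / L
                hit_lines.append(hit_row(a, b, ident, L, 2.0 * matches))
    hit_table = "\n".join(hit_lines) + "\n"

    busco_lines = ["# Busco id\tStatus\tSequence"]
    for k, gid in enumerate(markers):
        busco_lines.append(f"busco{k:04d}\tComplete\t{gid}")
    busco_table = "\n".join(busco_lines) + "\n"

    # expression: family members share a latent log-profile at the target
    # correlation; everything else is independent
    n_s = spec.n_expression_samples
    sample_names = [f"sample{k + 1:03d}" for k in range(n_s)]
    expr_lines = ["gene\t" + "\t".join(sample_names)]
    rho = spec.expression_rho
    latent: dict[str, np.ndarray] = {
        fam_id: rng.normal(3.0, 1.0, size=n_s) for fam_id in families
    }
    pseudo_flags: dict[str, bool] = {}
    for fam_id, meta in families.items():
        n_pseudo = int(round(spec.pseudogene_fraction * len(meta["members"])))
        for k, gid in enumerate(meta["members"]):
            pseudo_flags[gid] = k >= len(meta["members"]) - n_pseudo

    for contig in range(spec.n_contigs):
        for slot in range(spec.genes_per_contig):
            gid = f"g{contig + 1:02d}_{slot:03d}"
            fam_id = family_of[gid]
            if fam_id is not None and pseudo_flags.get(gid):
                tpm = np.zeros(n_s)
            elif fam_id is not None:
                eps = rng.normal(0.0, 1.0, size=n_s)
                log_expr = 3.0 + rho * (latent[fam_id] - 3.0) + np.sqrt(1 - rho**2) * eps
                tpm = np.expm1(np.clip(log_expr, 0.0, None))
            else:
                tpm = np.expm1(np.clip(rng.normal(3.0, 1.0, size=n_s), 0.0, None))
            expr_lines.append(gid + "\t" + "\t".join(f"{v:.4f}" for v in tpm))
    expression_tsv = "\n".join(expr_lines) + "\n"

    pair_ks: dict[tuple[str, str], float] = {}
    for meta in families.values():
        ms = meta["members"]
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                a, b = sorted((ms[i], ms[j]))
                pair_ks[(a, b)] = member_depth[a] + member_depth[b]

    truth = FixtureTruth(
        family_of=family_of, families=families, markers=markers, pair_ks=pair_ks
    )
    return FixtureBundle(
        genome_fasta=genome_fasta,
        gff3="\n".join(gff_lines) + "\n",
        protein_fasta=protein_fasta,
        cds_fasta=cds_fasta,
        hit_table=hit_table,
        busco_table=busco_table,
        expression_tsv=expression_tsv,
        truth=truth,
    )
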