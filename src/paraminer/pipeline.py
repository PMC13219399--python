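"""End-to-end pipeline: validate -> score -> threshold -> classify
[-> orthology/synteny -> Ka/Ks -> expression].

The pipeline is a thin orchestration over the library modules.  Hits are
consumed from 12-column tabular files produced by any local aligner
(DIAMOND/BLAST/MMseqs2), or computed by a built-in deterministic
positional scorer (``aligner='builtin'``) so that fixture-scale runs need
no external binaries.  Reference-free runs never touch the orthology or
synteny code paths.

Output layout per sample::

    <out>/<sample>/validation_report.txt
    <out>/<sample>/Duplication_landscape_plots/<sample>_landscape.tsv
    <out>/<sample>/{tandem,proximal,dispersed,mixed}_duplicates.tsv
    <out>/<sample>/singletons.tsv
    <out>/<sample>/Duplicates_relationships.tsv
    <out>/<sample>/{orthologs,copy_number,kaks,expression_*}.tsv   (optional)
    <out>/manifest.json
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment_scores as scores
from . import annotation_io as ann
from . import duplicate_classifier as classifier
from . import expression_divergence as expr
from . import kaks_engine as kaks
from . import orthology_synteny as orth
from . import thresholding_qc as thr

__all__ = ["SampleInput", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class SampleInput:
    name: str
    gff: str
    sequences: str
    kind: str  # genome | cds | protein


@dataclass
class RunConfig:
    samples: list[SampleInput]
    reference: SampleInput | None = None
    output_dir: str = "paraminer_out"
    attribute_config: str | None = None
    hits: dict[str, str] = field(default_factory=dict)     # sample (or "sample__vs__ref") -> path
    busco: dict[str, str] = field(default_factory=dict)    # sample -> full_table path
    expression: dict[str, str] = field(default_factory=dict)
    aligner: str = "precomputed"  # precomputed | builtin
    evalue: float = scores.DEFAULT_EVALUE_CUT
    score: float | str = "auto"
    self_simcut: float = thr.DEFAULT_SELF_SIMCUT
    mode: str = "overlap"
    proximity: int = classifier.DEFAULT_PROXIMITY
    fwd_simcut: float = scores.DEFAULT_FWD_SIMCUT
    fwd_scorecut: float = scores.DEFAULT_FWD_SCORECUT
    n_candidates: int = 10
    flank: int = 5
    side: str = "one"
    synteny_cutoff: float = 0.5
    occupancy: float = 0.1
    phylogeny: bool = False
    kaks_method: str = "off"  # NG | MYN | off
    specific_genes: list[str] = field(default_factory=list)
    pseudo_cutoff: float = expr.DEFAULT_PSEUDO_CUTOFF
    r_cutoff: float = expr.DEFAULT_R_CUTOFF
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        samples = [SampleInput(**s) for s in raw.pop("samples")]
        ref = raw.pop("reference", None)
        reference = SampleInput(**ref) if ref else None
        return cls(samples=samples, reference=reference, **raw)


def _builtin_hits(
    cat_a: ann.GeneCatalog, cat_b: ann.GeneCatalog, min_identity: float = 30.0
) -> list[scores.Hit]:
    """Deterministic positional protein scorer (bit score = 2 x matches).

    A test/fixture-scale stand-in producing the same tabular semantics as
    a local aligner; adequate for equal-length divergent copies, not for
    indel-rich real data.
    """
    hits = []
    for qid, qprot in sorted(cat_a.representative_protein.items()):
        for sid, sprot in sorted(cat_b.representative_protein.items()):
            if not qprot or not sprot:
                continue
            L = min(len(qprot), len(sprot))
            matches = sum(1 for x, y in zip(qprot, sprot) if x == y)
            ident = 100.0 * matches / L
            same = cat_a is cat_b and qid == sid
            if ident < min_identity and not same:
                continue
            hits.append(
                scores.Hit(
                    query_id=qid, subject_id=sid, pct_similarity=round(ident, 1),
                    evalue=1e-30, bitscore=round(2.0 * matches, 1),
                )
            )
    return hits


def _load_sample(sample: SampleInput, configs: dict[str, ann.AttributeConfig]):
    gff_text = Path(sample.gff).read_text()
    seq_text = Path(sample.sequences).read_text()
    config = configs.get(sample.name, ann.AttributeConfig(sample_name=sample.name))
    models, report = ann.parse_annotation(gff_text, config)
    cleaned, fasta_report, _ = ann.clean_fasta(seq_text)
    report.errors.extend(fasta_report.errors)
    catalog = ann.collapse_isoforms(
        models, ann.read_fasta(cleaned), sample.kind, sample_name=sample.name, report=report
    )
    return catalog, report


def _write_groups(out: Path, partition: classifier.DuplicatePartition) -> None:
    by_class: dict[str, list[classifier.DuplicateGroup]] = {}
    for g in partition.groups:
        by_class.setdefault(g.klass, []).append(g)
    for klass in ("tandem", "proximal", "dispersed", "mixed"):
        lines = ["group_id\tclass\tconfidence\tfamily_id\tmembers"]
        for g in by_class.get(klass, []):
            members = ",".join(g.members)
            if g.member_subclass:
                members = ",".join(f"{m}({g.member_subclass[m]})" for m in g.members)
            lines.append(f"{g.group_id}\t{g.klass}\t{g.confidence}\t{g.family_id}\t{members}")
        if len(lines) > 1 or klass != "mixed":
            (out / f"{klass}_duplicates.tsv").write_text("\n".join(lines) + "\n")
    (out / "singletons.tsv").write_text(
        "gene_id\n" + "\n".join(sorted(partition.singletons)) + "\n"
    )
    rel_lines = ["family_id\tgroup_ids\tshared_genes"]
    for fam_id in sorted(partition.relationships):
        gids, shared = partition.relationships[fam_id]
        rel_lines.append(f"{fam_id}\t{','.join(gids)}\t{','.join(shared)}")
    (out / "Duplicates_relationships.tsv").write_text("\n".join(rel_lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    t0 = time.time()
    if not config.samples:
        raise PipelineError("at least one sample is required")
    if config.reference and any(s.name == config.reference.name for s in config.samples):
        raise PipelineError("reference must not also be listed as a sample")
    if (config.specific_genes or config.phylogeny) and config.reference is None:
        raise PipelineError("reference-only options set but no reference configured")

    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    attr_configs = (
        ann.load_attribute_configs(Path(config.attribute_config).read_text())
        if config.attribute_config
        else {}
    )

    manifest: dict = {
        "parameters": {
            "mode": config.mode, "proximity": config.proximity,
            "score": config.score, "self_simcut": config.self_simcut,
            "evalue": config.evalue, "aligner": config.aligner,
            "kaks": config.kaks_method, "phylogeny": config.phylogeny,
            "seed": config.seed,
        },
        "samples": {},
        "timings": {},
    }

    ref_catalog = None
    if config.reference is not None:
        ref_catalog, ref_report = _load_sample(config.reference, attr_configs)
        if not ref_report.passed:
            raise PipelineError(f"reference {config.reference.name} failed validation: {ref_report.errors[:3]}")

    failed = []
    for sample in config.samples:
        t_sample = time.time()
        sdir = out_root / sample.name
        sdir.mkdir(exist_ok=True)
        catalog, report = _load_sample(sample, attr_configs)
        (sdir / "validation_report.txt").write_text(
            f"sample: {sample.name}\npassed: {report.passed}\n"
            + "".join(f"ERROR\t{c}\t{m}\t{f}\n" for c, m, f in report.errors)
            + "".join(f"WARN\t{c}\t{m}\t{f}\n" for c, m, f in report.warnings)
        )
        if not report.passed:
            failed.append(sample.name)
            manifest["samples"][sample.name] = {"validation": "failed"}
            continue

        # self-alignment scores
        if config.aligner == "builtin":
            self_hits = _builtin_hits(catalog, catalog)
        else:
            hits_path = config.hits.get(sample.name)
            if hits_path is None:
                raise PipelineError(f"no hit table configured for sample {sample.name}")
            self_hits = scores.load_hits(Path(hits_path).read_text(), config.evalue)
        self_table = scores.self_score_table(self_hits, catalog)

        # threshold + landscape
        busco_table = None
        if sample.name in config.busco:
            busco_table = thr.parse_busco_table(Path(config.busco[sample.name]).read_text())
        decision = thr.derive_threshold(
            self_table, busco_table, user_score=config.score, user_simcut=config.self_simcut
        )
        land_dir = sdir / "Duplication_landscape_plots"
        land_dir.mkdir(exist_ok=True)
        land = thr.landscape_data(self_table)
        (land_dir / f"{sample.name}_landscape.tsv").write_text(thr.landscape_tsv(land))

        # classification
        singletons, duplicates = classifier.segregate_singletons(self_table, decision)
        partition = classifier.cluster_duplicates(
            duplicates, self_hits, decision, catalog,
            classifier.ClassifierParams(proximity=config.proximity, mode=config.mode),
            singletons=singletons,
        )
        _write_groups(sdir, partition)

        sample_info: dict = {
            "validation": "passed",
            "n_genes": len(catalog.genes),
            "n_singletons": len(partition.singletons),
            "n_duplicates": len(partition.duplicates),
            "n_groups": len(partition.groups),
            "threshold": {
                "method": decision.method,
                "score_cutoff": decision.score_cutoff,
                "self_simcut": decision.self_simcut,
                "n_single_copy_used": decision.n_single_copy_used,
            },
        }
        if busco_table is not None:
            sample_info["pseudo_ploidy"] = thr.pseudo_ploidy(busco_table)
            sample_info["busco_completeness"] = round(busco_table.completeness, 1)
            sample_info["busco_duplication"] = round(busco_table.duplication, 1)

        # orthology + synteny (reference mode only)
        calls: dict[str, orth.OrthologCall] = {}
        if ref_catalog is not None:
            if config.aligner == "builtin":
                fwd_hits = _builtin_hits(catalog, ref_catalog)
            else:
                key = f"{sample.name}__vs__{config.reference.name}"
                fwd_path = config.hits.get(key)
                if fwd_path is None:
                    raise PipelineError(f"no forward hit table configured ({key})")
                fwd_hits = scores.load_hits(Path(fwd_path).read_text(), config.evalue)
            fwd_table, _unnorm = scores.forward_score_table(
                self_table, fwd_hits, config.fwd_simcut, config.fwd_scorecut
            )
            seed_map = orth.build_seed_map(fwd_table)
            params = orth.OrthologyParams(
                n_candidates=config.n_candidates, flank=config.flank, side=config.side,
                synteny_cutoff=config.synteny_cutoff, occupancy=config.occupancy,
                use_phylogeny=config.phylogeny,
            )
            lines = ["sample_gene\tref_gene\tconfidence\tevidence\tsynteny_score"]
            for gid in sorted(catalog.genes):
                rec = fwd_table.get(gid)
                if rec is None:
                    continue
                call = orth.assign_ortholog(gid, rec, catalog, ref_catalog, seed_map, params)
                calls[gid] = call
                flags = ",".join(k for k, v in call.evidence.items() if v)
                lines.append(
                    f"{gid}\t{call.ref_gene or 'none'}\t{call.confidence}\t{flags}\t{call.synteny_score:.3f}"
                )
            (sdir / "orthologs.tsv").write_text("\n".join(lines) + "\n")

            nature_lines = ["group_id\tclass\tnature"]
            for g in partition.groups:
                if g.klass in ("tandem", "proximal"):
                    nature_lines.append(f"{g.group_id}\t{g.klass}\t{orth.group_nature(g, calls)}")
            (sdir / "group_nature.tsv").write_text("\n".join(nature_lines) + "\n")
            sample_info["n_ortholog_calls"] = sum(1 for c in calls.values() if c.ref_gene)

        # Ka/Ks
        if config.kaks_method in ("NG", "MYN"):
            def _fmt(v: float | None) -> str:
                return "NA" if v is None else f"{v:.6g}"

            lines = ["gene_a\tgene_b\tmethod\tS\tN\tSd\tNd\tKa\tKs\tratio\tkappa"]
            done: set[frozenset[str]] = set()
            for g in partition.groups:
                results, _skipped = kaks.group_kaks(g, catalog, method=config.kaks_method)
                for r in results:
                    key = frozenset((r.gene_a, r.gene_b))
                    if key in done:
                        continue
                    done.add(key)
                    lines.append(
                        f"{r.gene_a}\t{r.gene_b}\t{r.method}\t{r.S:.4f}\t{r.N:.4f}\t"
                        f"{r.Sd:.4f}\t{r.Nd:.4f}\t{_fmt(r.Ka)}\t{_fmt(r.Ks)}\t{_fmt(r.ratio)}\t{_fmt(r.kappa)}"
                    )
            (sdir / "kaks.tsv").write_text("\n".join(lines) + "\n")
            sample_info["n_kaks_pairs"] = len(done)

        # expression
        if sample.name in config.expression:
            matrix, _warn = expr.load_expression(
                Path(config.expression[sample.name]).read_text(), set(catalog.genes)
            )
            corr_lines = ["group_id\tgene_a\tgene_b\tr\tp\tn\tdivergent\tinvolves_pseudogene"]
            pseudo: set[str] = set()
            for g in partition.groups:
                gstats = expr.group_expression_stats(
                    g, matrix, config.pseudo_cutoff, config.r_cutoff
                )
                pseudo.update(gstats.pseudogenes)
                for p in gstats.pairs:
                    r_s = "NA" if p.r is None else f"{p.r:.4f}"
                    corr_lines.append(
                        f"{g.group_id}\t{p.gene_a}\t{p.gene_b}\t{r_s}\t"
                        f"{'NA' if p.p_value is None else f'{p.p_value:.3g}'}\t{p.n_samples}\t"
                        f"{int(p.divergent)}\t{int(p.involves_pseudogene)}"
                    )
            (sdir / "expression_correlations.tsv").write_text("\n".join(corr_lines) + "\n")
            (sdir / "perceived_pseudogenes.tsv").write_text(
                "gene_id\n" + "\n".join(sorted(pseudo)) + "\n"
            )
            sample_info["n_perceived_pseudogenes"] = len(pseudo)

        # specific-genes copy-number table
        if config.specific_genes and ref_catalog is not None:
            table = orth.copy_number_table(
                config.specific_genes, {sample.name: list(calls.values())}, ref_catalog
            )
            lines = ["ref_gene\tsample\tcopy_number\togcs\tmembers\tabsent"]
            for ref_gene in config.specific_genes:
                cell = table[ref_gene][sample.name]
                lines.append(
                    f"{ref_gene}\t{sample.name}\t{cell.count}\t{cell.ogcs}\t"
                    f"{','.join(cell.members)}\t{int(cell.absent)}"
                )
            (sdir / "copy_number.tsv").write_text("\n".join(lines) + "\n")

        manifest["samples"][sample.name] = sample_info
        manifest["timings"][sample.name] = round(time.time() - t_sample, 3)

    manifest["timings"]["total"] = round(time.time() - t0, 3)
    manifest["failed_samples"] = failed
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    if failed:
        raise PipelineError(f"validation failed for: {failed}")
    return manifest
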