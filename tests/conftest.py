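"""Shared builders for small in-memory catalogs and synthetic bundles."""

from __future__ import annotations

import pytest

from paraminer.annotation_io import GeneCatalog, GeneModel
from paraminer.synthetic_fixtures import FixtureBundle, FixtureSpec, generate_fixture


def make_catalog(
    genes: list[tuple[str, str, int, int]],
    proteins: dict[str, str] | None = None,
    cds: dict[str, str] | None = None,
    sample: str = "s",
) -> GeneCatalog:
    """Catalog from (gene_id, contig, start, end) rows; plus-strand,
    transcript-free models are enough for positional logic."""
    models = {
        gid: GeneModel(gene_id=gid, contig=contig, strand="+", start=start, end=end)
        for gid, contig, start, end in genes
    }
    order_index: dict[str, int] = {}
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models.values():
        by_contig.setdefault(m.contig, []).append(m)
    for contig_models in by_contig.values():
        contig_models.sort(key=lambda m: (m.start, m.end, m.gene_id))
        for rank, m in enumerate(contig_models):
            order_index[m.gene_id] = rank
    return GeneCatalog(
        sample_name=sample,
        genes=models,
        order_index=order_index,
        representative_protein=proteins or {g: "" for g in models},
        representative_cds=cds or {g: None for g in models},
    )


def collinear_catalog(n: int, prefix: str = "g", contig: str = "c1") -> GeneCatalog:
    return make_catalog([(f"{prefix}{i:03d}", contig, 1000 * i + 1, 1000 * i + 500) for i in range(n)])


@pytest.fixture(scope="session")
def bundle() -> FixtureBundle:
    """One deterministic synthetic sample reused across read-only tests."""
    return generate_fixture(FixtureSpec(seed=42))


@pytest.fixture()
def bundle_files(bundle, tmp_path):
    """The synthetic bundle written to disk in pipeline-consumable form."""
    paths = {}
    for name, text in [
        ("gff", bundle.gff3), ("faa", bundle.protein_fasta), ("fna", bundle.cds_fasta),
        ("hits", bundle.hit_table), ("busco", bundle.busco_table), ("expr", bundle.expression_tsv),
    ]:
        p = tmp_path / f"sample.{name}"
        p.write_text(text)
        paths[name] = str(p)
    return paths
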