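# paraminer

Mining, classification, and characterization of **gene duplication
arrays** from annotated genomes.

Paralogs — genes related by duplication rather than speciation — drive
the expansion of gene families and biosynthetic pathways, but most
duplication tools report duplicate *pairs* under fixed, species-agnostic
cutoffs and leave many genes unclassified. paraminer instead:

* segregates **every** input gene into singleton or duplicate space
  under a *species-specific* threshold anchored to BUSCO single-copy
  genes;
* clusters duplicates into whole **families/arrays** (connected
  components of the cutoff-passing hit graph) and classifies them as
  **tandem** (consecutive in gene order), **proximal** (≤ *proximity*
  intervening genes), or **dispersed** (far apart or on different
  contigs), in an `overlap` mode (genes may recur across groups, linked
  by a relationships table) or a `strict` mode (a partition, with a
  fourth `mixed` class);
* optionally characterizes duplicates by **reference orthology** with
  flank-based synteny support and confidence tiers, per-pair **Ka/Ks**
  (exact Nei–Gojobori and a kappa-aware MYN-style approximation), and
  **expression divergence** with perceived-pseudogene flags.

## The core quantities

For each gene *g*, with *B*(*g*,*h*) the local-alignment bit score of
*g* against *h* within its own genome:

```
norm_score(g) = max_{h ≠ g} B(g, h) / B(g, g)      (self-normalized bit score)
```

Recent duplicates have `norm_score` near 1; genes without a close
within-genome relative score near 0 (or have no non-self hit at all).
The singleton/duplicate cutoff is the **95th percentile of `norm_score`
over BUSCO single-copy genes** — genes that are single copy by
definition, so their distribution describes "not duplicated" in *this*
genome. With too few single-copy BUSCOs the method falls back to a
self-similarity cutoff; both cutoffs can also be set manually.

For divergence, per duplicate pair the NG86 estimator counts synonymous
(S) and nonsynonymous (N) sites from codon neighbourhoods, averages
observed differences (Sd, Nd) over all mutational pathways, and corrects
the proportions with Jukes–Cantor, `d = -3/4 ln(1 - 4p/3)`; `Ka/Ks < 1`
indicates purifying selection, `≈ 1` neutrality, `> 1` positive
selection.

## Worked example

`examples/01_mine_duplicate_arrays.py` plants six duplicate families in
a 250-gene synthetic genome and runs the reference-free pipeline:

```
genes: 250, duplicates: 17, singletons: 233 (every input gene lands in exactly one of the two spaces)
threshold: busco_auto at score_cutoff=0.000 from 120 single-copy markers
pseudo-ploidy: 1.0 (mean copies per complete BUSCO; 1.0 = haploid-like gene space)

duplicate groups found (class, members):
  tandem    high     g01_000,g01_001,g01_002
  tandem    high     g01_003,g01_004,g01_005,g01_006
  proximal  high     g01_007,g01_011
  proximal  high     g01_012,g01_015,g01_018
  dispersed high     g01_019,g02_000
  dispersed high     g01_020,g02_001,g03_000
```

All six planted families are recovered with their classes and members
exact; the 233 remaining genes (including the 120 single-copy markers
anchoring the threshold) are singletons, and counts conserve the input:
17 + 233 = 250. `examples/03_kaks_divergence.py` then estimates
divergence of a pair simulated at synonymous distance 0.2:

```
 NG: S=437.0 N=1366.0  Ka=0.1815 Ks=0.2306 Ka/Ks=0.787
MYN: S=440.0 N=1363.0  Ka=0.1821 Ks=0.2300 Ka/Ks=0.792, kappa=1.04
```

The other examples cover the duplication landscape
(`02_duplication_landscape.py`), reference-mode orthologs, synteny and
copy-number tables (`04_reference_orthologs_copy_number.py`), and
expression divergence (`05_expression_divergence.py`).

## Command line

The same pipeline runs from a shell over real files (GFF3 + one of
genome/CDS/protein FASTA, 12-column tabular hits from DIAMOND, BLAST or
MMseqs2, an optional BUSCO full table, an optional TPM matrix):

```bash
paraminer run --config run.json --mode overlap --proximity 10 --kaks NG
```

with a JSON config naming samples, file paths, an optional reference,
and parameter overrides (`--score auto|0..1`, `--self_simcut`,
`--evalue`, `--flank`, `--side`, `--synteny_score`, `--occupancy`,
`--phylogeny`, ...). Outputs per sample: validation report, duplication
landscape table, tandem/proximal/dispersed(/mixed) group TSVs,
singletons, `Duplicates_relationships.tsv`, and — when configured —
ortholog calls, group nature, copy-number, Ka/Ks, and expression tables,
plus a `manifest.json` of parameters, thresholds, and counts.

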