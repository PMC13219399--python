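# Methods

This note documents the models and procedures implemented in paraminer,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Input standardization

GFF3 files disagree on which attribute keys identify genes and link
mRNAs/CDS to parents. Parsing is driven by a per-sample
`AttributeConfig` (defaults `ID`/`Parent`/`Parent`), configurable via a
plain-text file (`sample<TAB>gene_key<TAB>mrna_key<TAB>cds_key`). Data
problems are collected as structured error/warning records on a
`ValidationReport` — malformed column counts, missing attributes,
dangling parent references — rather than raised; a sample failing
validation stops the pipeline with a nonzero exit. CDS features naming a
gene directly (single-transcript dialects) are accepted.

**Isoform collapse.** One representative transcript per gene: the one
with the longest total CDS length, ties broken by lexicographically
smallest mRNA id. This rule is a deterministic design choice —
"primary transcript" tags are not portable across annotation sources,
and longest-CDS is the common field convention. Coordinates stay 1-based
inclusive; gene order within a contig is the dense rank by start
coordinate (ties by end, then id), and each contig is an independent
ordering domain (unplaced contigs retained). Minus-strand CDS segments
are reverse-complemented and concatenated in translation order;
translation uses the standard code, trailing stops are trimmed, internal
stops flag the gene (`internal_stop`) without excluding it — such genes
may be genuine pseudogenes, and the flag only excludes them from Ka/Ks.

**FASTA cleaning.** Headers are truncated at the first whitespace,
sequences uppercased, out-of-alphabet characters replaced (N for
nucleotide records, X for protein, sniffed from the share of core
nucleotide letters ≥ 0.9) and counted; duplicate headers are an error.

## Scores and threshold

Hits are consumed from 12-column tabular files (BLAST `outfmt 6`
layout) regardless of the producing aligner; hits above the e-value
cutoff (default `1e-5`) are dropped and the best HSP per (query,
subject) pair kept. The *self-normalized bit score* of a gene is its
best non-self bit score divided by its self bit score; values > 1
(possible with HSP quirks) are kept, not clamped. "Similarity" is the
tabular identity column.

**BUSCO-anchored threshold.** In `auto` mode the score cutoff is the
95th percentile (type-7 linear interpolation, the numpy default) of the
norm scores of complete single-copy BUSCO genes; single-copy genes with
no non-self hit contribute 0 (they are the extreme singleton case).
"Enough" single-copy genes means ≥ 100 with self-alignment records
(configurable); below that the method falls back to a self-similarity
cutoff (default 50%). Manual mode applies both cutoffs conjunctively.
**Pseudo-ploidy** is the mean copy count over complete BUSCOs
(single + duplicated), reported to one decimal; a duplicated BUSCO
listed with a single row still counts ≥ 2 copies.

**Duplication landscape.** Histogram (50 bins over [0, max(1, max
score)]) plus a Gaussian KDE with Scott bandwidth on a grid padded 4
bandwidths past the data so the density integrates to ~1. Skew flags
summarize the mass: right skew (median ≥ 0.7) suggests extensive
duplication/polyploidy, left skew (median ≤ 0.3) very few duplications;
constant-score degenerate inputs are represented as a spike rather than
a KDE.

## Classification

A gene is a **singleton** iff it has no self hit, only a self hit, or
its best non-self hit fails the active cutoff(s); everything else is a
**duplicate**. Families are connected components of the graph on
duplicates whose edges are hits passing the same cutoffs (one passing
direction suffices; hit tables are near- but not exactly symmetric).

Within a family, per contig:

* **tandem** subgroups: maximal runs of consecutive gene-order
  positions (0 intervening genes; no tandem gap is allowed);
* **proximal** subgroups: maximal windows whose extreme members are
  within `proximity` intervening genes (so all pairs are) and that are
  not fully consecutive; the default `proximity = 10` follows the
  field-standard proximal definition;
* **dispersed** subgroups: tandem runs and proximal windows are
  collapsed to a representative (lowest order index), and the family's
  remaining cross-contig or beyond-proximity relations among
  units form one dispersed group of representatives.

This decomposition order (tandem first, then proximal, then dispersed)
is deterministic and a documented reconstruction — the combination of
classes a mixed family can exhibit is constrained by it. `overlap` mode
emits all subgroups and a relationships table linking subgroups of one
family through shared genes; `strict` mode emits single-class families
as that class and multi-class families as one `mixed` group carrying
per-member subclass labels.

**Group confidence** reflects internal hit connectivity: `high` when
every member pair is joined by a passing hit (clique), `moderate` when
at least half are, `low` when the group holds together only
transitively. This pair-density scheme is a reconstruction of an
unpublished scoring flow; the tiers, not raw densities, are the
contract.

## Orthology and synteny (reference mode)

Forward (sample-vs-reference) candidates are pre-filtered by percent
similarity (default 40%) and forward-normalized bit score (default 0.3;
lower both, e.g. to 30%/0.2, for distant references). The top
`n_candidates` (default 10) are then scored on independent evidence:

* `best_local`: highest forward bit score;
* `best_global`: highest identity in a Biopython global protein
  alignment (BLOSUM62, open −11 / extend −1) after dropping columns
  with non-gap occupancy below `occupancy` (default 0.1);
* `synteny_pass`: up to `flank` (default 5) genes each side of the
  sample gene; a flank gene supports a candidate iff its best forward
  hit lies on the candidate's contig within ±(2·flank) order positions —
  a window chosen to tolerate small local rearrangements while staying
  scale-free in `flank`; score = supporters/examined (contig edges
  reduce the denominator; 0 examined → score 0); `side=both`
  additionally demands ≥ 1 supporter per side;
* `tree_nearest`: smallest evolutionary distance, from an externally
  supplied patristic-distance table (tree inference is out of process by
  design) or, absent one, from the global-alignment p-distance computed
  internally.

The candidate holding the most flags wins; ties go to the local best.
Confidence: `very_high` when the winner holds all available flags,
`high` all but one, `moderate` exactly two, else `low` (with three
available flags, all-but-one takes precedence over the two-flag tier).
Copy-number rows aggregate member confidences into an OGCS by a
weakest-link rule (all `very_high` → `very_high`; any `low` → `low`;
otherwise majority). Small-scale (tandem/proximal) groups get a nature
label: `expansion` if any member has a synteny-passing ortholog,
`de_novo` if orthologs exist but none syntenic, `unresolved` if no
member has a candidate.

## Ka/Ks

Protein alignments are back-translated codon-wise; columns with a gap in
either sequence, an ambiguous base, or a stop codon are trimmed (each
class counted). A trailing stop codon on the CDS is tolerated.

**NG86 (exact).** Per codon position, the synonymous-site fraction is
the share of the three single-nucleotide neighbours encoding the same
amino acid (mutations to stops count as nonsynonymous); S is the mean of
the two sequences' totals and N = 3L − S, so S + N = 3L exactly.
Multi-hit codons average their difference counts over all orderings of
single steps; pathways through intermediate stop codons are excluded,
with an inclusive fallback when every pathway hits one (the literature
is ambiguous on this convention). `ps = Sd/S` and `pn = Nd/N` are
corrected with Jukes–Cantor; `p ≥ 3/4` is saturation, returned as
undefined rather than raised. Pathway averaging can push a difference
proportion slightly above 1 at extreme divergence; that too is treated
as saturation. The Ka/Ks ratio is undefined whenever Ks is 0 or
uncomputable.

**MYN-style approximation.** Transitional biases are estimated
separately for pyrimidines (κ_Y, T↔C) and purines (κ_R, A↔G) as moment
ratios of observed transition proportions over their base-composition
expectations, normalized by the transversion rate, clamped to
[0.05, 20] with κ = 1 when a class is unobservable. Site counts are
weighted by these relative rates (each position still contributes one
site, preserving S + N = 3L), and the correction is Kimura two-parameter
on the (transition, transversion) split of the pathway-averaged
differences. Pathways are averaged unweighted — one of the deliberate
simplifications. With κ = 1 and equal base frequencies the K2P
correction reduces algebraically to Jukes–Cantor, so the estimator's
contract is agreement with NG in that limit (tested to 0.02 at 500
codons) and recovery of simulated distances, not bit-identity with any
other implementation.

Outputs are per unordered member pair ("individual gene basis");
members flagged `internal_stop` or lacking a CDS are skipped with a
reason code, never fatally. The standard genetic code is assumed.

## Expression divergence

Pairwise Pearson correlation on log(1 + TPM) — matching the plotted
transformation; Spearman is a trivial swap but Pearson is the default —
with r defined only when both genes vary across ≥ 3 samples. Perceived
(putative) pseudogenes are genes with mean TPM below `pseudo_cutoff`
(default 1 TPM); a pair is divergent when r < `r_cutoff` (default 0.5)
or undefined. Both cutoffs are deliberate package defaults exposed as
parameters. Whole-matrix correlations without tissue resolution cannot
establish sub-/neo-functionalization, so divergence labels are
annotations, not conclusions. Plot data comes in a k×k `matrix` layout
(pair at cell (i, j), i < j) or a `compact` linear list, each pair
annotated with its sample count.

## Synthetic data generator

`synthetic_fixtures` emulates exactly the inputs the pipeline consumes:
multi-contig genomes of single-CDS random-codon ORFs (start codon, no
internal stops, stop codon), planted tandem/proximal/dispersed families
derived from a family founder by per-site Jukes–Cantor substitution at
a controlled divergence, a designated single-copy marker set with a
BUSCO-like table, a deterministic hit table (bit score = 2 × identical
residues, i.e. proportional to identity × length), and TPM matrices in
which family members share a latent log-normal profile at a target
correlation ρ. Defaults — 5 contigs × 50 genes, six mixed families at
divergence 0.05–0.10, 120 single-copy markers, ρ = 0.8 over 200
expression samples — are the baseline recovery conditions used
throughout the tests. All randomness flows from a single seed;
identical seeds give byte-identical outputs, different seeds change
sequences but not the planted topology.

What it does **not** emulate: isoform structure beyond a single
transcript (isoform collapse is tested on hand-built multi-transcript
records instead), introns, indels between family members (copies stay
length-aligned, so the deterministic positional scorer is exact),
intergenic realism, transposable elements, or cross-family homology
noise. Passing the recovery tests therefore demonstrates correctness of
the segregation/clustering/classification logic under clean homology
signal, not robustness to alignment noise — that robustness lives in
the cutoff parameters, which real runs should tune via the duplication
landscape. In the default fixture the single-copy markers have only
self hits (the archetypal singleton), so the auto threshold derived from
them is 0 and any hit-connected family passes; the percentile machinery
itself is exercised separately on randomized score sets.

Simulated mutations that would create a stop codon are discarded (the
site stays unchanged). Nonsense changes are nonsynonymous by
definition, so this leaves synonymous-site divergence — the quantity
the Ks-recovery checks target — unbiased, while mildly suppressing Ka.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale problems chosen as the
package's own verification conditions: 250-gene genomes (20 seeds for
class recovery), 200 random codon pairs of ≤ 60 codons for oracle
equivalence, 50 replicates of 1000 codons per true Ks for recovery, 20
reference shuffles for synteny, 50 replicates of 200 samples for
expression. Floating-point conventions: percentiles by numpy type-7;
Jukes–Cantor inputs clamped at the [0, 1] boundaries against one-ulp
overshoot; near the p = 3/4 singularity corrected distances are
reported but numerically dominated by the last bits of 1 − 4p/3, so no
exactness is claimed there; all tie-breaks (isoform choice, candidate
ranking, group numbering) are lexicographic and documented so identical
inputs give identical outputs.

## Known limitations

* Transposed/retro-duplicate subclasses and WGD/segmental-block
  detection are out of scope; dispersed groups absorb everything
  non-local.
* The dispersed-subgroup decomposition and both confidence schemes
  (group confidence, ortholog confidence/OGCS) are documented
  reconstructions; tiers are the public contract, not the internals.
* The MYN-style estimator is an approximation by design (unweighted
  pathway averaging, moment kappa estimates, K2P-form correction).
* Aligner execution (DIAMOND/BLAST/MMseqs2), BUSCO, and tree inference
  are consumed through file contracts, not run in-process; the built-in
  positional scorer is for fixture-scale, indel-free sequences only.
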