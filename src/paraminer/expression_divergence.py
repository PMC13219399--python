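"""Expression divergence of duplicate-group members.

After duplication, copies may retain correlated expression (redundancy),
diverge (sub-/neo-functionalization), or fall silent (pseudogenization).
With a genes x samples TPM matrix, this module computes pairwise Pearson
correlations on log(1 + TPM) within each duplicate group, flags perceived
(putative) pseudogenes by low mean expression, labels low-correlation
pairs as divergent, and exports plot-ready pairwise scatter data in
matrix or compact layout.

Whole-matrix correlations cannot by themselves establish functional fate
(tissue-level resolution is needed), so divergence labels are suggestive
annotations, not conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .duplicate_classifier import DuplicateGroup

__all__ = [
    "ExpressionMatrix",
    "PairStats",
    "GroupExpressionStats",
    "load_expression",
    "group_expression_stats",
    "plot_data",
    "DEFAULT_PSEUDO_CUTOFF",
    "DEFAULT_R_CUTOFF",
]

DEFAULT_PSEUDO_CUTOFF = 1.0  # mean TPM below this => perceived pseudogene
DEFAULT_R_CUTOFF = 0.5       # pairwise r below this => divergent expression


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x samples, TPM

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log1p(self) -> pd.DataFrame:
        return np.log1p(self.values)


@dataclass
class PairStats:
    gene_a: str
    gene_b: str
    r: float | None
    p_value: float | None
    n_samples: int
    divergent: bool
    involves_pseudogene: bool


@dataclass
class GroupExpressionStats:
    group_id: str
    pairs: list[PairStats] = field(default_factory=list)
    mean_tpm: dict[str, float] = field(default_factory=dict)
    pseudogenes: list[str] = field(default_factory=list)
    no_data: list[str] = field(default_factory=list)

    @property
    def divergent_pairs(self) -> list[tuple[str, str]]:
        return [(p.gene_a, p.gene_b) for p in self.pairs if p.divergent]


def load_expression(tsv: str, known_genes: set[str] | None = None) -> tuple[ExpressionMatrix, list[str]]:
    """Parse a genes x samples TPM TSV (header row of sample ids, first
    column gene ids).

    Missing and non-numeric cells are rejected with their coordinates;
    negative TPM is an error.  Genes absent from ``known_genes`` are
    returned as warnings but their rows are retained.
    """
    import io

    df = pd.read_csv(io.StringIO(tsv), sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(f"non-numeric or missing TPM at gene {gene!r}, sample {sample!r}")
    if (numeric < 0).any().any():
        gene = (numeric < 0).any(axis=1).idxmax()
        raise ValueError(f"negative TPM for gene {gene!r}")
    if numeric.index.duplicated().any():
        dupes = numeric.index[numeric.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
    warnings = []
    if known_genes is not None:
        warnings = sorted(set(numeric.index) - known_genes)
    return ExpressionMatrix(values=numeric), warnings


def group_expression_stats(
    group: DuplicateGroup,
    matrix: ExpressionMatrix,
    pseudo_cutoff: float = DEFAULT_PSEUDO_CUTOFF,
    r_cutoff: float = DEFAULT_R_CUTOFF,
) -> GroupExpressionStats:
    """Pairwise Pearson correlations (on log(1 + TPM)) and pseudogene /
    divergence flags for one duplicate group.

    r is defined only when both genes vary across >= 3 samples; an
    undefined r counts as divergent.  Pairs involving perceived
    pseudogenes are still reported, annotated as such.
    """
    stats_out = GroupExpressionStats(group_id=group.group_id)
    present = [g for g in group.members if g in matrix.values.index]
    stats_out.no_data = [g for g in group.members if g not in matrix.values.index]
    log_expr = matrix.log1p()

    for g in present:
        stats_out.mean_tpm[g] = float(matrix.values.loc[g].mean())
        if stats_out.mean_tpm[g] < pseudo_cutoff:
            stats_out.pseudogenes.append(g)

    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = present[i], present[j]
            xa = log_expr.loc[a].to_numpy()
            xb = log_expr.loc[b].to_numpy()
            n = xa.size
            r = p = None
            if n >= 3 and xa.std() > 0 and xb.std() > 0:
                r_val, p_val = stats.pearsonr(xa, xb)
                r, p = float(r_val), float(p_val)
            stats_out.pairs.append(
                PairStats(
                    gene_a=a, gene_b=b, r=r, p_value=p, n_samples=n,
                    divergent=(r is None or r < r_cutoff),
                    involves_pseudogene=(
                        a in stats_out.pseudogenes or b in stats_out.pseudogenes
                    ),
                )
            )
    return stats_out


@dataclass
class PairScatter:
    gene_a: str
    gene_b: str
    x: np.ndarray  # log(1+TPM) of gene_a
    y: np.ndarray  # log(1+TPM) of gene_b
    n: int
    cell: tuple[int, int] | None = None  # (i, j) in matrix layout, i < j


def plot_data(
    group: DuplicateGroup,
    matrix: ExpressionMatrix,
    layout: str = "matrix",
) -> list[PairScatter]:
    """Plot-ready pairwise scatter bundles.

    ``matrix`` layout addresses each pair at cell (i, j), i < j, of a
    k x k member grid; ``compact`` is a linear list of the same pairs.
    Coordinates are log(1 + TPM); each pair carries its sample count n.
    """
    if layout not in ("matrix", "compact"):
        raise ValueError(f"layout must be matrix or compact, got {layout!r}")
    present = [g for g in group.members if g in matrix.values.index]
    log_expr = matrix.log1p()
    bundles = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = present[i], present[j]
            bundles.append(
                PairScatter(
                    gene_a=a, gene_b=b,
                    x=log_expr.loc[a].to_numpy(), y=log_expr.loc[b].to_numpy(),
                    n=matrix.n_samples,
                    cell=(i, j) if layout == "matrix" else None,
                )
            )
    return bundles
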