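"""Species-specific singleton/duplicate threshold and duplication landscape.

The singleton-vs-duplicate boundary differs between genomes, so a fixed
cutoff is biologically wrong for most species.  The approach here anchors
the cutoff to BUSCO single-copy genes: those genes are single copy by
definition, so the distribution of *their* self-normalized bit scores
describes what "not duplicated" looks like in this particular genome.  The
95th percentile of that distribution is taken as the score cutoff.  When
no (or too few) single-copy BUSCOs are available the method falls back to
a self-similarity cutoff, and both cutoffs can be set manually.

Also provided: a pseudo-ploidy estimate from BUSCO copy counts and the
histogram + KDE data behind the duplication-landscape plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .alignment_scores import SelfScoreRecord

__all__ = [
    "BuscoRecord",
    "BuscoTable",
    "ThresholdDecision",
    "LandscapeData",
    "parse_busco_table",
    "derive_threshold",
    "pseudo_ploidy",
    "landscape_data",
    "landscape_tsv",
    "DEFAULT_SELF_SIMCUT",
    "MIN_SINGLE_COPY",
]

DEFAULT_SELF_SIMCUT = 50.0  # percent, similarity-fallback / manual default
MIN_SINGLE_COPY = 100       # minimum usable single-copy BUSCOs for auto mode
PERCENTILE = 95.0


@dataclass(frozen=True)
class BuscoRecord:
    busco_id: str
    status: str  # Complete | Duplicated | Fragmented | Missing
    gene_id: str | None


@dataclass
class BuscoTable:
    records: list[BuscoRecord] = field(default_factory=list)

    @property
    def completeness(self) -> float:
        ids = {r.busco_id for r in self.records}
        if not ids:
            return 0.0
        done = {r.busco_id for r in self.records if r.status in ("Complete", "Duplicated")}
        return 100.0 * len(done) / len(ids)

    @property
    def duplication(self) -> float:
        ids = {r.busco_id for r in self.records}
        if not ids:
            return 0.0
        dup = {r.busco_id for r in self.records if r.status == "Duplicated"}
        return 100.0 * len(dup) / len(ids)

    def single_copy_genes(self) -> list[str]:
        return [r.gene_id for r in self.records if r.status == "Complete" and r.gene_id]


@dataclass(frozen=True)
class ThresholdDecision:
    method: str  # busco_auto | similarity_fallback | manual
    score_cutoff: float | None
    self_simcut: float | None
    n_single_copy_used: int = 0
    percentile: float = PERCENTILE


@dataclass
class LandscapeData:
    bin_edges: np.ndarray
    counts: np.ndarray
    kde_x: np.ndarray
    kde_y: np.ndarray
    n_genes: int
    right_skew: bool = False
    left_skew: bool = False


def parse_busco_table(text: str) -> BuscoTable:
    """Parse a BUSCO full_table TSV (Busco id, Status, Sequence/Gene, ...).

    Comment lines start with '#'.  Missing BUSCOs have no gene column.
    """
    records: list[BuscoRecord] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        busco_id, status = parts[0], parts[1]
        gene_id = parts[2] if len(parts) > 2 and parts[2] else None
        records.append(BuscoRecord(busco_id=busco_id, status=status, gene_id=gene_id))
    return BuscoTable(records=records)


def _single_copy_scores(busco: BuscoTable, self_table: dict[str, SelfScoreRecord]) -> list[float]:
    """Norm scores of single-copy BUSCO genes that have a self-alignment
    record; a single-copy gene with no non-self hit is the extreme
    singleton case and contributes 0."""
    scores = []
    for gid in busco.single_copy_genes():
        rec = self_table.get(gid)
        if rec is None:
            continue
        scores.append(rec.norm_score if rec.norm_score is not None else 0.0)
    return scores


def derive_threshold(
    self_table: dict[str, SelfScoreRecord],
    busco: BuscoTable | None,
    user_score: float | str = "auto",
    user_simcut: float = DEFAULT_SELF_SIMCUT,
    min_single_copy: int = MIN_SINGLE_COPY,
) -> ThresholdDecision:
    """Decide how singletons are segregated from duplicates.

    * ``user_score == "auto"`` and enough single-copy BUSCOs: score cutoff
      = 95th percentile (linear interpolation) of their norm scores,
      similarity cutoff disabled (0).
    * ``auto`` without (enough) BUSCOs: similarity fallback at
      ``user_simcut``.
    * numeric ``user_score``: manual mode, both cutoffs applied.
    """
    if user_score != "auto":
        score = float(user_score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"--score must lie in [0, 1], got {score}")
        return ThresholdDecision(method="manual", score_cutoff=score, self_simcut=float(user_simcut))

    if busco is not None:
        scores = _single_copy_scores(busco, self_table)
        if len(scores) >= min_single_copy:
            cutoff = float(np.percentile(scores, PERCENTILE))  # type-7 linear interpolation
            return ThresholdDecision(
                method="busco_auto", score_cutoff=cutoff, self_simcut=None,
                n_single_copy_used=len(scores),
            )
    return ThresholdDecision(method="similarity_fallback", score_cutoff=None, self_simcut=float(user_simcut))


def pseudo_ploidy(busco: BuscoTable) -> float | None:
    """Mean copy count over complete BUSCOs (single + duplicated), to one
    decimal — an apparent ploidy indicator.

    A Duplicated BUSCO appears once per gene copy in the full table, so
    copies = row count per BUSCO id.
    """
    rows: dict[str, int] = {}
    duplicated: set[str] = set()
    for rec in busco.records:
        if rec.status in ("Complete", "Duplicated"):
            rows[rec.busco_id] = rows.get(rec.busco_id, 0) + 1
            if rec.status == "Duplicated":
                duplicated.add(rec.busco_id)
    if not rows:
        return None
    # a Duplicated BUSCO listed with a single row still has >= 2 copies
    total = sum(max(n, 2) if b in duplicated else n for b, n in rows.items())
    return round(total / len(rows), 1)


def landscape_data(self_table: dict[str, SelfScoreRecord], n_bins: int = 50) -> LandscapeData:
    """Histogram + Gaussian KDE (Scott bandwidth) of defined norm scores.

    The KDE grid extends past the data range so that the density
    integrates to ~1 on the grid.  Skew flags summarize where the mass
    sits: right skew (scores piled near 1) suggests extensive duplication
    or polyploidy; left skew suggests very few duplications.
    """
    scores = np.array([r.norm_score for r in self_table.values() if r.norm_score is not None])
    if scores.size == 0:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        return LandscapeData(
            bin_edges=edges, counts=np.zeros(n_bins, dtype=int),
            kde_x=np.array([]), kde_y=np.array([]), n_genes=0,
        )
    hi = max(1.0, float(scores.max()))
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _ = np.histogram(scores, bins=edges)

    if scores.size > 1 and float(scores.std()) > 0:
        kde = gaussian_kde(scores, bw_method="scott")
        pad = 4.0 * float(kde.factor) * float(scores.std())
        kde_x = np.linspace(float(scores.min()) - pad, float(scores.max()) + pad, 512)
        kde_y = kde(kde_x)
    else:
        # degenerate (constant scores): represent the spike directly
        kde_x = np.array([float(scores[0])])
        kde_y = np.array([np.inf])

    median = float(np.median(scores))
    return LandscapeData(
        bin_edges=edges, counts=counts, kde_x=kde_x, kde_y=kde_y,
        n_genes=int(scores.size),
        right_skew=median >= 0.7, left_skew=median <= 0.3,
    )


def landscape_tsv(data: LandscapeData) -> str:
    """Plot-ready tabular export: bin_mid, count, kde_y at bin mids."""
    lines = ["bin_mid\tcount\tkde_y"]
    mids = (data.bin_edges[:-1] + data.bin_edges[1:]) / 2.0
    if data.kde_x.size > 1:
        kde_at_mids = np.interp(mids, data.kde_x, data.kde_y, left=0.0, right=0.0)
    else:
        kde_at_mids = np.zeros_like(mids)
    for m, c, k in zip(mids, data.counts, kde_at_mids):
        lines.append(f"{m:.6g}\t{int(c)}\t{k:.6g}")
    return "\n".join(lines) + "\n"
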