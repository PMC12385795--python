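"""Chromosome-level RGA landscape statistics.

Counts, densities (RGA per Mbp), chromosome shares, per-chromosome means
(contigs excluded), ordinary least-squares regression of RGA count on
chromosome size, larger-but-not-more pairwise comparisons, and windowed
positional profiles with an end-bias summary.

All reported percentages and densities use round-half-even at 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import RGAAnnotation
from .model import AnnotationError, ChromosomeRecord, GeneModel


@dataclass(frozen=True)
class ChromosomeStats:
    chromosome: str
    length_mbp: float
    rga_count: int
    density: float     # RGA per Mbp, 2 dp
    share_pct: float   # percent of the species RGA total, 2 dp


@dataclass(frozen=True)
class SpeciesSummary:
    total_rgas: int
    pct_of_genes: float
    class_share_pct: dict[str, float]
    mean_rgas_per_chromosome: float  # chromosomes only, contigs excluded


def density(count: int, length_mbp: float) -> float:
    """RGA density in genes per Mbp, rounded half-even to 2 decimals."""
    if length_mbp <= 0:
        raise AnnotationError("length_mbp must be positive")
    return round(count / length_mbp, 2)


def chromosome_stats(
    counts: Mapping[str, int], lengths_mbp: Mapping[str, float]
) -> list[ChromosomeStats]:
    """Per-chromosome count/density/share records."""
    total = sum(counts.values())
    out = []
    for chrom, n in counts.items():
        length = lengths_mbp.get(chrom, float("nan"))
        out.append(
            ChromosomeStats(
                chromosome=chrom,
                length_mbp=length,
                rga_count=n,
                density=density(n, length) if length == length else float("nan"),
                share_pct=round(100.0 * n / total, 2) if total else 0.0,
            )
        )
    return out


def summary_stats(
    count_table: pd.DataFrame, genome_gene_total: int
) -> SpeciesSummary:
    """Species-level summary from a per-chromosome count table.

    ``count_table`` needs a ``Total`` column, one row per sequence, and an
    ``is_contig`` column; class columns are summarised as shares of the RGA
    total. The per-chromosome mean excludes contig rows.
    """
    if genome_gene_total <= 0:
        raise AnnotationError("genome_gene_total must be positive")
    total = int(count_table["Total"].sum())
    chrom_rows = count_table.loc[~count_table["is_contig"].astype(bool)]
    class_cols = [
        c for c in count_table.columns
        if c not in {"Total", "is_contig", "chromosome", "species", "length_mbp"}
    ]
    shares = {
        c: round(100.0 * count_table[c].sum() / total, 2) for c in class_cols
    }
    return SpeciesSummary(
        total_rgas=total,
        pct_of_genes=round(100.0 * total / genome_gene_total, 2),
        class_share_pct=shares,
        mean_rgas_per_chromosome=round(chrom_rows["Total"].sum() / len(chrom_rows), 2),
    )


def size_count_regression(
    sizes_mbp: Sequence[float], counts: Sequence[int]
) -> tuple[float, float, float]:
    """OLS of RGA count on chromosome size: (slope, intercept, pearson r)."""
    if len(sizes_mbp) != len(counts) or len(sizes_mbp) < 3:
        raise AnnotationError("need >= 3 paired (size, count) observations")
    if len(set(sizes_mbp)) == 1:
        raise AnnotationError("constant chromosome sizes: slope undefined")
    result = stats.linregress(np.asarray(sizes_mbp, float), np.asarray(counts, float))
    return result.slope, result.intercept, result.rvalue


def larger_but_not_more_pairs(
    sizes_mbp: Sequence[float], counts: Sequence[int]
) -> int:
    """Unordered chromosome pairs where the larger one has no more RGAs.

    Count ties are counted (the larger chromosome "does not have more");
    tied sizes are an error because larger/smaller is then undefined.
    """
    if len(sizes_mbp) != len(counts) or len(sizes_mbp) < 2:
        raise AnnotationError("need >= 2 paired (size, count) observations")
    if len(set(sizes_mbp)) != len(sizes_mbp):
        raise AnnotationError("tied chromosome sizes: comparison undefined")
    n = 0
    for i in range(len(sizes_mbp)):
        for j in range(i + 1, len(sizes_mbp)):
            big, small = (i, j) if sizes_mbp[i] > sizes_mbp[j] else (j, i)
            if counts[big] <= counts[small]:
                n += 1
    return n


def positional_profile(
    genes: Sequence[GeneModel],
    annotations: Sequence[RGAAnnotation],
    assembly: Sequence[ChromosomeRecord],
    window_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, float]:
    """Windowed RGA counts per chromosome and class, plus end-bias fraction.

    Windows tile each chromosome from position 1 (the last window may be
    short); a gene falls in the window containing its start coordinate.
    The end-bias fraction is the share of RGAs whose start lies in the two
    distal 25% segments of its chromosome.
    """
    if window_bp <= 0:
        raise AnnotationError("window_bp must be positive")
    class_of = {a.gene_id: a.rga_class for a in annotations}
    lengths = {c.name: c.length_bp for c in assembly}

    rows: dict[tuple[str, int, str], int] = {}
    n_rga = 0
    n_distal = 0
    for gene in genes:
        cls = class_of.get(gene.gene_id, "NONE")
        if cls == "NONE":
            continue
        n_rga += 1
        length = lengths[gene.chromosome]
        widx = (gene.start - 1) // window_bp
        rows[(gene.chromosome, widx, cls)] = rows.get(
            (gene.chromosome, widx, cls), 0
        ) + 1
        rel = gene.start / length
        if rel < 0.25 or rel > 0.75:
            n_distal += 1

    frame = pd.DataFrame(
        [
            (
                chrom,
                widx * window_bp + 1,
                min((widx + 1) * window_bp, lengths[chrom]),
                cls,
                count,
            )
            for (chrom, widx, cls), count in sorted(rows.items())
        ],
        columns=["chromosome", "window_start", "window_end", "rga_class", "count"],
    )
    end_bias = n_distal / n_rga if n_rga else float("nan")
    return frame, end_bias
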