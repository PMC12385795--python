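"""Co-localisation of genes with disease-resistance QTL intervals.

A gene is "within" a QTL iff the QTL fully contains it: qtl.start <=
gene.start and gene.end <= qtl.end on the same chromosome (1-based, closed
intervals, boundaries inclusive). Partial overlap is "outside" by default;
``mode="overlap"`` relaxes this for sensitivity analyses. The analysis unit
follows the receptor families (RLKs and RLPs), but any gene list works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .model import AnnotationError, GeneModel, QTLRecord


@dataclass(frozen=True)
class ColocalisationResult:
    gene_id: str
    qtl_name: str
    status: str  # within | outside


@dataclass
class ColocalisationSummary:
    results: list[ColocalisationResult]
    per_gene_qtls: dict[str, list[str]]
    per_qtl_counts: pd.DataFrame  # qtl_name x class counts
    genes_in_any_qtl: int
    max_qtl_gene: tuple[str, int] | None   # gene in the most QTL
    max_gene_qtl: tuple[str, int] | None   # QTL holding the most genes
    skipped_qtls: list[str] = field(default_factory=list)


def within_qtl(
    gene: GeneModel,
    qtl: QTLRecord,
    chromosome_map: Mapping[str, str] | None = None,
    mode: str = "containment",
) -> str:
    """'within' iff the QTL contains the gene (or overlaps it in overlap mode)."""
    gene_chrom = (chromosome_map or {}).get(gene.chromosome, gene.chromosome)
    if gene_chrom != qtl.chromosome:
        return "outside"
    if mode == "containment":
        inside = qtl.start <= gene.start and gene.end <= qtl.end
    elif mode == "overlap":
        inside = gene.start <= qtl.end and qtl.start <= gene.end
    else:
        raise AnnotationError(f"unknown mode: {mode!r}")
    return "within" if inside else "outside"


def colocalise_genes(
    genes: Sequence[GeneModel],
    qtls: Sequence[QTLRecord],
    class_of: Mapping[str, str] | None = None,
    chromosome_map: Mapping[str, str] | None = None,
    known_chromosomes: Sequence[str] | None = None,
    mode: str = "containment",
) -> ColocalisationSummary:
    """Flag every (gene, QTL) pair and summarise both directions.

    A gene inside n QTL contributes once to the genes-in-any-QTL total and
    once to each of the n per-QTL counts. QTL on chromosomes absent from
    ``known_chromosomes`` (when given) are skipped with a warning.
    """
    usable: list[QTLRecord] = []
    skipped: list[str] = []
    for qtl in qtls:
        if known_chromosomes is not None and qtl.chromosome not in known_chromosomes:
            skipped.append(qtl.qtl_name)
            warnings.warn(
                f"QTL {qtl.qtl_name}: chromosome {qtl.chromosome} absent "
                "from the assembly; skipped"
            )
            continue
        usable.append(qtl)

    results: list[ColocalisationResult] = []
    per_gene: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    classes = sorted(set((class_of or {}).values())) or ["gene"]
    counts = {q.qtl_name: dict.fromkeys(classes, 0) for q in usable}
    for gene in genes:
        cls = (class_of or {}).get(gene.gene_id, "gene")
        for qtl in usable:
            status = within_qtl(gene, qtl, chromosome_map, mode)
            results.append(ColocalisationResult(gene.gene_id, qtl.qtl_name, status))
            if status == "within":
                per_gene[gene.gene_id].append(qtl.qtl_name)
                counts[qtl.qtl_name][cls] += 1

    frame = pd.DataFrame.from_dict(counts, orient="index").rename_axis("qtl_name")
    frame["total"] = frame.sum(axis=1)
    in_any = sum(1 for v in per_gene.values() if v)
    max_qtl_gene = max(
        per_gene.items(), key=lambda kv: (len(kv[1]), kv[0])
    ) if per_gene else None
    max_gene_qtl = (
        (frame["total"].idxmax(), int(frame["total"].max())) if len(frame) else None
    )
    return ColocalisationSummary(
        results=results,
        per_gene_qtls={k: sorted(v) for k, v in per_gene.items()},
        per_qtl_counts=frame,
        genes_in_any_qtl=in_any,
        max_qtl_gene=(max_qtl_gene[0], len(max_qtl_gene[1])) if max_qtl_gene else None,
        max_gene_qtl=max_gene_qtl,
        skipped_qtls=skipped,
    )
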