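"""Domain-architecture classification of resistance gene analogues.

A gene's predicted domain complement is mapped onto one of the four primary
RGA classes — receptor-like kinase (RLK), receptor-like protein (RLP),
nucleotide-binding leucine-rich-repeat receptor (NLR, with its subtypes) and
transmembrane coiled-coil (TM-CC) — plus a standalone RPW8 class. The table
is total and deterministic over the closed domain vocabulary: every subset
of domains maps to exactly one verdict.

Precedence resolves multi-signature genes: NB-ARC-based classes first, then
TIR-only (TX), then RLK, RLP, standalone RPW8 and TM-CC. RPW8 carried next
to an NB-ARC architecture reclassifies it: bare NBS becomes RN, NL becomes
RNL, and the remaining subtypes (TNL, CNL, CN, TN — and TX) become OTHER.
TNL, CNL and RNL, carrying the full three-domain architecture, are the
"typical" NLRs; every other NLR-side subtype is "atypical".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AnnotationError,
    DOMAIN_VOCABULARY,
    DomainCall,
    GeneModel,
)

#: Subtypes counted as typical NLRs (full tripartite architecture).
TYPICAL_SUBTYPES = frozenset({"TNL", "CNL", "RNL"})

#: NLR-side subtypes with partial or disordered architectures.
ATYPICAL_SUBTYPES = frozenset({"CN", "RN", "NL", "TN", "TX", "OTHER", "NBS"})

#: Column order of the per-chromosome count table.
COUNT_COLUMNS = [
    "RLK", "LRR-RLK", "LysM-RLK", "OtherReceptor-RLK",
    "RLP", "LRR-RLP", "LysM-RLP", "OtherReceptor-RLP",
    "TM-CC",
    "TNL", "CNL", "RNL", "TX", "TN", "NL", "RN", "CN", "OTHER", "RPW8",
    "Total",
]


@dataclass(frozen=True)
class RGAAnnotation:
    """The classification verdict for one gene."""

    gene_id: str
    rga_class: str          # RLK | RLP | NLR | TMCC | RPW8 | NONE
    nlr_subtype: str        # TNL|CNL|RNL|TN|CN|RN|NL|TX|OTHER|NBS|none
    receptor_subclass: str  # LRR | LYSM | OTHER_RECEPTOR | none
    typical: str            # typical | atypical | n/a
    superfamily: str        # TM-LRR | NLR | TM-CC | RPW8 | none


def typical_flag(nlr_subtype: str) -> str:
    """Typical/atypical verdict for an NLR-side subtype."""
    if nlr_subtype in TYPICAL_SUBTYPES:
        return "typical"
    if nlr_subtype in ATYPICAL_SUBTYPES:
        return "atypical"
    raise AnnotationError(f"not an NLR-side subtype: {nlr_subtype!r}")


def _receptor_subclass(domains: frozenset[str]) -> str:
    if "LRR" in domains:
        return "LRR"
    if "LYSM" in domains:
        return "LYSM"
    return "OTHER_RECEPTOR"


def classify_gene(domains: Iterable[str], gene_id: str = "") -> RGAAnnotation:
    """Map a gene's domain set to its RGA annotation.

    Total and deterministic over subsets of the domain vocabulary; an
    unknown domain label is a hard error.
    """
    dset = frozenset(domains)
    unknown = dset - DOMAIN_VOCABULARY
    if unknown:
        raise AnnotationError(f"unknown domain labels: {sorted(unknown)}")

    def nlr(subtype: str) -> RGAAnnotation:
        return RGAAnnotation(
            gene_id, "NLR", subtype, "none", typical_flag(subtype), "NLR"
        )

    # 1. NB-ARC present: NLR side, with RPW8 reclassification.
    if "NBARC" in dset:
        if "TIR" in dset:
            subtype = "TNL" if "LRR" in dset else "TN"
        elif "CC" in dset:
            subtype = "CNL" if "LRR" in dset else "CN"
        elif "LRR" in dset:
            subtype = "NL"
        else:
            subtype = "NBS"
        if "RPW8" in dset:
            subtype = {"NBS": "RN", "NL": "RNL"}.get(subtype, "OTHER")
        return nlr(subtype)

    # 2. TIR without NB-ARC.
    if "TIR" in dset:
        return nlr("OTHER" if "RPW8" in dset else "TX")

    # 3. Kinase + transmembrane: RLK.
    if {"KINASE", "TM"} <= dset:
        return RGAAnnotation(
            gene_id, "RLK", "none", _receptor_subclass(dset), "n/a", "TM-LRR"
        )

    # 4. Transmembrane + ectodomain, no kinase: RLP.
    if "TM" in dset and dset & {"LRR", "LYSM", "OTHER_ECTO"}:
        return RGAAnnotation(
            gene_id, "RLP", "none", _receptor_subclass(dset), "n/a", "TM-LRR"
        )

    # 5. Standalone RPW8 (no NB-ARC reached here).
    if "RPW8" in dset:
        return RGAAnnotation(gene_id, "RPW8", "none", "none", "n/a", "RPW8")

    # 6. Transmembrane coiled-coil.
    if {"TM", "CC"} <= dset:
        return RGAAnnotation(gene_id, "TMCC", "none", "none", "n/a", "TM-CC")

    return RGAAnnotation(gene_id, "NONE", "none", "none", "n/a", "none")


def _count_column(annotation: RGAAnnotation) -> list[str]:
    """Count-table columns (besides Total) this annotation increments."""
    a = annotation
    if a.rga_class in {"RLK", "RLP"}:
        sub = {"LRR": "LRR", "LYSM": "LysM", "OTHER_RECEPTOR": "OtherReceptor"}[
            a.receptor_subclass
        ]
        return [a.rga_class, f"{sub}-{a.rga_class}"]
    if a.rga_class == "NLR":
        # The count table has no bare-NBS column; such genes are tabulated
        # under OTHER while the raw annotation keeps the distinct mark.
        return ["OTHER" if a.nlr_subtype == "NBS" else a.nlr_subtype]
    if a.rga_class == "TMCC":
        return ["TM-CC"]
    if a.rga_class == "RPW8":
        return ["RPW8"]
    return []


def classify_genome(
    genes: Sequence[GeneModel],
    domains: Sequence[DomainCall],
    assembly_order: Sequence[str] | None = None,
) -> tuple[list[RGAAnnotation], pd.DataFrame]:
    """Classify every gene and tabulate per-chromosome class counts.

    Returns one annotation per gene (input order) and a count table with one
    row per chromosome (ordered by ``assembly_order`` when given, otherwise
    by sorted name) plus a ``Total`` row, columns per class/subtype.
    """
    by_gene: dict[str, set[str]] = {}
    known = {g.gene_id for g in genes}
    if len(known) != len(genes):
        dupes = [k for k, v in Counter(g.gene_id for g in genes).items() if v > 1]
        raise AnnotationError(f"duplicate gene IDs: {dupes}")
    for call in domains:
        if call.gene_id not in known:
            raise AnnotationError(f"domain call for unknown gene: {call.gene_id}")
        by_gene.setdefault(call.gene_id, set()).add(call.domain)

    annotations = [
        classify_gene(by_gene.get(g.gene_id, frozenset()), g.gene_id) for g in genes
    ]

    chrom_of = {g.gene_id: g.chromosome for g in genes}
    counts: dict[str, Counter] = {}
    for ann in annotations:
        cols = _count_column(ann)
        if not cols:
            continue
        row = counts.setdefault(chrom_of[ann.gene_id], Counter())
        for col in cols:
            row[col] += 1
        row["Total"] += 1

    if assembly_order is None:
        order = sorted(counts)
    else:
        order = [c for c in assembly_order if c in counts]
        order += sorted(set(counts) - set(order))
    table = pd.DataFrame(
        [[counts[c].get(col, 0) for col in COUNT_COLUMNS] for c in order],
        index=pd.Index(order, name="chromosome"),
        columns=COUNT_COLUMNS,
    )
    table.loc["Total"] = table.sum(axis=0)
    return annotations, table


def annotations_frame(annotations: Iterable[RGAAnnotation]) -> pd.DataFrame:
    """Annotations as a tidy frame (the TSV the pipeline writes)."""
    return pd.DataFrame(
        [
            (a.gene_id, a.rga_class, a.nlr_subtype, a.receptor_subclass,
             a.typical, a.superfamily)
            for a in annotations
        ],
        columns=["gene_id", "rga_class", "nlr_subtype", "receptor_subclass",
                 "typical", "superfamily"],
    )
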