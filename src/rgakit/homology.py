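"""Cloned-R-gene homologue (CDRH) identification.

Alignment hits of the cloned R-gene queries against genome proteins pass a
three-rule filter chain — E-value at most 1e-45 (an E-value of exactly 0 is
the most significant possible hit and passes), similarity at least 60%, and
alignment length at least 148 aa, the length of the smallest reference
protein. Kept hits build many-to-many R-gene <-> gene maps, split into RGA
subjects (the CDRHs proper) and non-RGA subjects, and roll up by the
diseases the matched R genes confer resistance to.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .classify import RGAAnnotation
from .model import AlignmentHit, AnnotationError, RGeneCatalogEntry

DEFAULT_E_MAX = 1e-45
DEFAULT_SIM_MIN = 60.0
DEFAULT_LEN_MIN_AA = 148


@dataclass(frozen=True)
class CDRHRecord:
    """One subject gene with the R genes it is homologous to."""

    gene_id: str
    matched_r_genes: frozenset[str]
    rga_class: str
    nlr_subtype: str
    diseases: frozenset[str]


@dataclass(frozen=True)
class HomologySummary:
    n_r_genes_with_homologues: int
    n_r_genes_with_multiple: int
    per_r_gene_counts: dict[str, int]
    n_subjects: int
    n_subjects_multi_r: int
    class_composition: dict[str, int]


def filter_hits(
    hits: Sequence[AlignmentHit],
    e_max: float = DEFAULT_E_MAX,
    sim_min: float = DEFAULT_SIM_MIN,
    len_min_aa: int = DEFAULT_LEN_MIN_AA,
) -> list[AlignmentHit]:
    """Keep hits passing all three rules; order preserved.

    A hit survives iff evalue <= e_max AND similarity >= sim_min AND
    alignment length >= len_min_aa (all boundaries inclusive).
    """
    return [
        h
        for h in hits
        if h.evalue <= e_max
        and h.similarity_pct >= sim_min
        and h.aln_length_aa >= len_min_aa
    ]


def _aggregate(
    kept: Sequence[AlignmentHit],
    annotations: Mapping[str, RGAAnnotation],
    r_catalog: Mapping[str, RGeneCatalogEntry],
    keep_rga: bool,
) -> tuple[list[CDRHRecord], HomologySummary]:
    matched: dict[str, set[str]] = {}
    for hit in kept:
        ann = annotations.get(hit.subject_id)
        if ann is None:
            raise AnnotationError(f"subject gene not annotated: {hit.subject_id}")
        if (ann.rga_class != "NONE") != keep_rga:
            continue
        matched.setdefault(hit.subject_id, set()).add(hit.query_id)

    records = []
    for gene_id in sorted(matched):
        r_genes = matched[gene_id]
        diseases: set[str] = set()
        for r_gene in r_genes:
            entry = r_catalog.get(r_gene)
            if entry is None:
                raise AnnotationError(f"R gene not in catalogue: {r_gene}")
            diseases |= set(entry.diseases)
        ann = annotations[gene_id]
        records.append(
            CDRHRecord(
                gene_id=gene_id,
                matched_r_genes=frozenset(r_genes),
                rga_class=ann.rga_class,
                nlr_subtype=ann.nlr_subtype,
                diseases=frozenset(diseases),
            )
        )

    per_r: Counter = Counter()
    for rec in records:
        per_r.update(rec.matched_r_genes)
    composition: Counter = Counter()
    for rec in records:
        # NLR-side records are tabulated by subtype, receptors by class.
        key = rec.nlr_subtype if rec.rga_class == "NLR" else rec.rga_class
        composition[key] += 1
    summary = HomologySummary(
        n_r_genes_with_homologues=len(per_r),
        n_r_genes_with_multiple=sum(1 for n in per_r.values() if n > 1),
        per_r_gene_counts=dict(per_r),
        n_subjects=len(records),
        n_subjects_multi_r=sum(1 for r in records if len(r.matched_r_genes) > 1),
        class_composition=dict(composition),
    )
    return records, summary


def cdrh_map(
    kept: Sequence[AlignmentHit],
    annotations: Iterable[RGAAnnotation],
    r_catalog: Iterable[RGeneCatalogEntry],
) -> tuple[list[CDRHRecord], HomologySummary]:
    """CDRHs: RGA-classified subjects with at least one kept hit."""
    ann_map = {a.gene_id: a for a in annotations}
    cat_map = {e.r_gene_id: e for e in r_catalog}
    return _aggregate(kept, ann_map, cat_map, keep_rga=True)


def non_rga_homologues(
    kept: Sequence[AlignmentHit],
    annotations: Iterable[RGAAnnotation],
    r_catalog: Iterable[RGeneCatalogEntry],
) -> tuple[list[CDRHRecord], HomologySummary]:
    """Subjects classified NONE with at least one kept hit."""
    ann_map = {a.gene_id: a for a in annotations}
    cat_map = {e.r_gene_id: e for e in r_catalog}
    return _aggregate(kept, ann_map, cat_map, keep_rga=False)


def disease_rollup(
    records: Sequence[CDRHRecord],
    r_catalog: Iterable[RGeneCatalogEntry] | None = None,
) -> dict[str, int]:
    """Per-disease CDRH counts.

    A CDRH contributes once to each disease in its inherited set: matching
    several R genes of the same disease is deduplicated, matching R genes of
    different diseases counts under each.
    """
    rollup: Counter = Counter()
    for rec in records:
        for disease in rec.diseases:
            rollup[disease] += 1
    return dict(rollup)
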