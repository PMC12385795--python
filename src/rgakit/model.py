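"""Domain types shared by every pipeline stage.

Coordinate convention: all genomic intervals are 1-based and fully closed
(GFF3 convention), so a gene occupying positions ``start..end`` has length
``end - start + 1``. Strand is carried through the readers but ignored by
every downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Closed vocabulary of protein domains the classifier understands.
DOMAIN_VOCABULARY = frozenset(
    {"TIR", "NBARC", "LRR", "CC", "RPW8", "TM", "KINASE", "LYSM", "OTHER_ECTO"}
)

#: Synonym map normalising the many aliases domain-prediction tools emit
#: onto the canonical alphabet above. Matching is case-insensitive.
DOMAIN_SYNONYMS = {
    "NB-ARC": "NBARC",
    "NB_ARC": "NBARC",
    "NBS": "NBARC",
    "NB": "NBARC",
    "NACHT": "NBARC",
    "LYSM": "LYSM",
    "LYSIN": "LYSM",
    "COILED-COIL": "CC",
    "COILED_COIL": "CC",
    "COIL": "CC",
    "TOLL/INTERLEUKIN-1": "TIR",
    "TIR_2": "TIR",
    "TRANSMEMBRANE": "TM",
    "TMHMM": "TM",
    "PKINASE": "KINASE",
    "PROTEIN KINASE": "KINASE",
    "STTK": "KINASE",
    "ECTO": "OTHER_ECTO",
    "ECTODOMAIN": "OTHER_ECTO",
}

#: Disease codes used in the QTL table.
QTL_DISEASE_CODES = frozenset({"BL", "BR", "CR", "HR", "SSR", "WR"})

#: Disease codes used by the cloned R-gene catalogue (superset of the above).
R_GENE_DISEASE_CODES = frozenset(
    {"ABS", "BL", "BLS", "BR", "CR", "DM", "FW", "GM", "PM", "SSR", "WR"}
)


class AnnotationError(ValueError):
    """Raised on malformed or referentially inconsistent annotation input."""


def normalise_domain(label: str) -> str:
    """Map a raw domain label onto the canonical vocabulary.

    Raises :class:`AnnotationError` when the label is neither canonical nor
    a known synonym.
    """
    key = label.strip()
    if key.upper() in DOMAIN_VOCABULARY:
        return key.upper()
    mapped = DOMAIN_SYNONYMS.get(key.upper())
    if mapped is None:
        raise AnnotationError(f"unmappable domain label: {label!r}")
    return mapped


@dataclass(frozen=True)
class ChromosomeRecord:
    """One sequence of an assembly, chromosome or unplaced contig."""

    name: str
    length_bp: int
    is_contig: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise AnnotationError(f"chromosome {self.name}: length_bp must be > 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic interval plus (optionally) its protein product."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    protein_length: int | None = None
    protein_sequence: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if (
            self.protein_length is not None
            and self.protein_sequence is not None
            and self.protein_length != len(self.protein_sequence)
        ):
            raise AnnotationError(
                f"gene {self.gene_id}: protein_length does not match sequence"
            )


@dataclass(frozen=True)
class DomainCall:
    """One predicted domain on a gene's protein."""

    gene_id: str
    domain: str
    aa_start: int | None = None
    aa_end: int | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_VOCABULARY:
            raise AnnotationError(
                f"gene {self.gene_id}: domain {self.domain!r} not in vocabulary"
            )
        if (
            self.aa_start is not None
            and self.aa_end is not None
            and self.aa_start > self.aa_end
        ):
            raise AnnotationError(f"gene {self.gene_id}: aa_start > aa_end")


@dataclass(frozen=True)
class QTLRecord:
    """A disease-resistance QTL interval on one chromosome."""

    qtl_name: str
    species: str
    disease: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.disease not in QTL_DISEASE_CODES:
            raise AnnotationError(f"QTL {self.qtl_name}: bad disease {self.disease!r}")
        if self.start > self.end:
            raise AnnotationError(f"QTL {self.qtl_name}: start > end")


@dataclass(frozen=True)
class AlignmentHit:
    """One query-protein vs subject-gene alignment hit (BLASTP-style)."""

    query_id: str
    subject_id: str
    evalue: float
    similarity_pct: float
    aln_length_aa: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise AnnotationError(f"hit {self.query_id}->{self.subject_id}: evalue < 0")
        if not 0 <= self.similarity_pct <= 100:
            raise AnnotationError(
                f"hit {self.query_id}->{self.subject_id}: similarity outside [0, 100]"
            )
        if self.aln_length_aa < 1:
            raise AnnotationError(
                f"hit {self.query_id}->{self.subject_id}: alignment length < 1"
            )


@dataclass(frozen=True)
class RGeneCatalogEntry:
    """A cloned, functionally validated R gene with its disease codes."""

    r_gene_id: str
    diseases: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.diseases:
            raise AnnotationError(f"R gene {self.r_gene_id}: empty disease set")
        bad = set(self.diseases) - R_GENE_DISEASE_CODES
        if bad:
            raise AnnotationError(f"R gene {self.r_gene_id}: bad disease codes {bad}")
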