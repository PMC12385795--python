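"""Readers and writers for the formats the pipeline touches.

GFF3 carries gene intervals, FASTA the protein sequences, a TSV table the
per-gene domain calls (the normalised product of a domain-prediction run),
a BLAST-outfmt-6-like TSV the alignment hits and CSV the QTL intervals.
All readers accept a filesystem path (plain or ``.gz``) or an open text
stream.
"""

from __future__ import annotations

import csv
import gzip
import io as _io
import re
from importlib import resources
from typing import IO, Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentHit,
    AnnotationError,
    ChromosomeRecord,
    DomainCall,
    GeneModel,
    QTLRecord,
    RGeneCatalogEntry,
    normalise_domain,
)

#: Sequences whose names do NOT match this pattern are flagged as contigs.
DEFAULT_CHROMOSOME_PATTERN = r"^Chr"


def _open_text(source, mode: str = "rt") -> IO[str]:
    if hasattr(source, "read") or hasattr(source, "write"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_text(source) -> str:
    handle = _open_text(source)
    data = handle.read()
    if not hasattr(source, "read"):
        handle.close()
    return data


# ---------------------------------------------------------------------------
# annotation bundle (GFF3 + FASTA + domain table)
# ---------------------------------------------------------------------------

def read_annotation(
    gff3_source,
    fasta_source=None,
    domain_source=None,
    chromosome_pattern: str = DEFAULT_CHROMOSOME_PATTERN,
) -> tuple[list[ChromosomeRecord], list[GeneModel], list[DomainCall]]:
    """Load an assembly, its gene models and their domain calls.

    Chromosome lengths come from ``##sequence-region`` pragmas; sequences
    whose names fail ``chromosome_pattern`` are flagged ``is_contig``.
    Protein sequences (optional FASTA keyed by gene ID) are attached to the
    gene models. Referential integrity is enforced: duplicate gene IDs and
    domain rows naming unknown genes are hard errors.
    """
    text = _read_text(gff3_source)

    pattern = re.compile(chromosome_pattern)
    assembly: list[ChromosomeRecord] = []
    seen_chroms: set[str] = set()
    has_features = False
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            name, length = parts[1], int(parts[3])
            if name in seen_chroms:
                raise AnnotationError(f"duplicate sequence-region for {name}")
            seen_chroms.add(name)
            assembly.append(
                ChromosomeRecord(name, length, is_contig=not pattern.search(name))
            )
        elif line.strip() and not line.startswith("#"):
            has_features = True

    db = None
    if has_features:
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True, force=True, keep_order=True,
            merge_strategy="error",
        )

    proteins: dict[str, str] = {}
    if fasta_source is not None:
        handle = _open_text(fasta_source)
        for record in SeqIO.parse(handle, "fasta"):
            proteins[record.id] = str(record.seq)
        if not hasattr(fasta_source, "read"):
            handle.close()

    genes: list[GeneModel] = []
    seen_genes: set[str] = set()
    for feature in db.features_of_type("gene") if db is not None else ():
        gene_id = feature.attributes.get("ID", [feature.id])[0]
        if gene_id in seen_genes:
            raise AnnotationError(f"duplicate gene ID: {gene_id}")
        seen_genes.add(gene_id)
        seq = proteins.get(gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=feature.strand if feature.strand in "+-" else "unknown",
                protein_length=len(seq) if seq is not None else None,
                protein_sequence=seq,
            )
        )

    domains: list[DomainCall] = []
    if domain_source is not None:
        domains = _read_domain_table(domain_source)
        unknown = sorted({d.gene_id for d in domains} - seen_genes)
        if unknown:
            raise AnnotationError(
                f"domain calls reference unknown genes: {', '.join(unknown)}"
            )
    return assembly, genes, domains


def _read_domain_table(source) -> list[DomainCall]:
    handle = _open_text(source)
    frame = pd.read_csv(handle, sep="\t", dtype={"gene_id": str, "domain": str})
    if not hasattr(source, "read"):
        handle.close()
    required = {"gene_id", "domain"}
    if not required <= set(frame.columns):
        raise AnnotationError(f"domain table must carry columns {sorted(required)}")
    calls = []
    for row in frame.itertuples(index=False):
        aa_start = getattr(row, "aa_start", None)
        aa_end = getattr(row, "aa_end", None)
        calls.append(
            DomainCall(
                gene_id=row.gene_id,
                domain=normalise_domain(row.domain),
                aa_start=None if pd.isna(aa_start) else int(aa_start),
                aa_end=None if pd.isna(aa_end) else int(aa_end),
            )
        )
    return calls


def write_annotation(
    assembly: Sequence[ChromosomeRecord],
    genes: Sequence[GeneModel],
    domains: Sequence[DomainCall],
    gff3_sink,
    fasta_sink=None,
    domain_sink=None,
) -> None:
    """Write an annotation bundle in the dialects :func:`read_annotation` reads."""
    handle = _open_text(gff3_sink, "wt")
    handle.write("##gff-version 3\n")
    for chrom in assembly:
        handle.write(f"##sequence-region {chrom.name} 1 {chrom.length_bp}\n")
    for gene in genes:
        strand = gene.strand if gene.strand in "+-" else "."
        handle.write(
            f"{gene.chromosome}\trgakit\tgene\t{gene.start}\t{gene.end}\t.\t"
            f"{strand}\t.\tID={gene.gene_id}\n"
        )
    if not hasattr(gff3_sink, "write"):
        handle.close()

    if fasta_sink is not None:
        records = [
            SeqRecord(Seq(g.protein_sequence), id=g.gene_id, description="")
            for g in genes
            if g.protein_sequence is not None
        ]
        handle = _open_text(fasta_sink, "wt")
        SeqIO.write(records, handle, "fasta")
        if not hasattr(fasta_sink, "write"):
            handle.close()

    if domain_sink is not None:
        handle = _open_text(domain_sink, "wt")
        handle.write("gene_id\tdomain\taa_start\taa_end\n")
        for call in domains:
            handle.write(
                f"{call.gene_id}\t{call.domain}\t"
                f"{'' if call.aa_start is None else call.aa_start}\t"
                f"{'' if call.aa_end is None else call.aa_end}\n"
            )
        if not hasattr(domain_sink, "write"):
            handle.close()


# ---------------------------------------------------------------------------
# alignment hit tables
# ---------------------------------------------------------------------------

#: Default column mapping for the BLAST-outfmt-6-like hit table.
DEFAULT_HIT_COLUMNS = {
    "query": 0,
    "subject": 1,
    "evalue": 2,
    "similarity": 3,
    "length": 4,
}


def read_hits(source, columns: dict[str, int] | None = None) -> list[AlignmentHit]:
    """Parse a whitespace/tab-separated hit table, preserving row order.

    ``columns`` maps the five logical fields onto 0-based column indices;
    the default expects ``query subject evalue similarity length``.
    Invariant violations (negative E-value, similarity outside [0, 100])
    are hard errors reporting the 1-based row number.
    """
    cols = DEFAULT_HIT_COLUMNS if columns is None else columns
    hits: list[AlignmentHit] = []
    text = _read_text(source)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"\s+", line)
        try:
            hit = AlignmentHit(
                query_id=fields[cols["query"]],
                subject_id=fields[cols["subject"]],
                evalue=float(fields[cols["evalue"]]),
                similarity_pct=float(fields[cols["similarity"]]),
                aln_length_aa=int(fields[cols["length"]]),
            )
        except (AnnotationError, IndexError, ValueError) as exc:
            raise AnnotationError(f"hit table row {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hits(hits: Iterable[AlignmentHit], sink) -> None:
    handle = _open_text(sink, "wt")
    for hit in hits:
        handle.write(
            f"{hit.query_id}\t{hit.subject_id}\t{hit.evalue!r}\t"
            f"{hit.similarity_pct!r}\t{hit.aln_length_aa}\n"
        )
    if not hasattr(sink, "write"):
        handle.close()


# ---------------------------------------------------------------------------
# QTL tables and packaged fixtures
# ---------------------------------------------------------------------------

def read_qtl_table(source) -> list[QTLRecord]:
    """Read a QTL CSV with columns qtl_name, species, disease, chromosome, start, end."""
    text = _read_text(source)
    records = []
    for row in csv.DictReader(_io.StringIO(text)):
        records.append(
            QTLRecord(
                qtl_name=row["qtl_name"],
                species=row["species"],
                disease=row["disease"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
            )
        )
    return records


def write_qtl_table(qtls: Iterable[QTLRecord], sink) -> None:
    handle = _open_text(sink, "wt")
    handle.write("qtl_name,species,disease,chromosome,start,end\n")
    for q in qtls:
        handle.write(
            f"{q.qtl_name},{q.species},{q.disease},{q.chromosome},{q.start},{q.end}\n"
        )
    if not hasattr(sink, "write"):
        handle.close()


def _fixture(name: str):
    return resources.files("rgakit.data").joinpath(name)


def load_qtl_fixture() -> list[QTLRecord]:
    """The packaged table of 57 published Brassica disease-resistance QTL."""
    with _fixture("qtl_intervals.csv").open() as handle:
        return read_qtl_table(handle)


def load_r_gene_catalog() -> list[RGeneCatalogEntry]:
    """The packaged catalogue of 49 cloned R genes with disease codes.

    Entries flagged ``synthetic=yes`` in the CSV are constructed stand-ins
    padding the published gene names out to the full catalogue size; the
    disease-code vocabulary and catalogue shape are faithful.
    """
    with _fixture("r_gene_catalog_synthetic.csv").open() as handle:
        rows = list(csv.DictReader(handle))
    return [
        RGeneCatalogEntry(
            r_gene_id=row["r_gene_id"],
            diseases=frozenset(row["diseases"].split(";")),
        )
        for row in rows
    ]


def load_reference_counts() -> pd.DataFrame:
    """Published per-chromosome RGA class counts for the three mustard genomes.

    Returns a tidy frame with columns ``species, chromosome, length_mbp,
    is_contig`` plus one column per RGA class/subtype and ``Total``.
    Contig rows carry no length (NaN).
    """
    with _fixture("rga_reference_counts.csv").open() as handle:
        frame = pd.read_csv(handle)
    frame["is_contig"] = frame["is_contig"].astype(bool)
    return frame
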