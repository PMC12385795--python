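"""Synthetic multi-chromosome genomes with known RGA ground truth.

The generator emulates the statistical structure the analysis assumes so
every stage runs with no external data: class composition follows the
published black-mustard proportions by default, RGA positions are drawn from
a symmetric Beta(alpha, alpha) law rescaled to each chromosome (alpha < 1
pushes genes towards chromosome ends, matching the observed end bias),
clusters of genes with bounded intergenic gaps are planted at isolated
locations, homologue pairs receive controlled E-value/similarity/length
values that pass the filter chain while decoys each violate exactly one
rule, and QTL intervals are drawn with per-gene containment flags recorded
by direct check. A single integer seed drives one random generator instance,
so outputs are byte-identical across runs.

It makes no attempt to model real protein evolution, codon structure or
synteny; protein sequences are superfamily consensus blocks plus random
residues, just enough for similarity clustering to have recoverable
structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    AlignmentHit,
    AnnotationError,
    ChromosomeRecord,
    DomainCall,
    GeneModel,
    QTL_DISEASE_CODES,
    QTLRecord,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Planted architecture labels: canonical domain set and expected verdict.
ARCHITECTURES: dict[str, dict] = {
    "TNL":  {"domains": ("TIR", "NBARC", "LRR"), "rga_class": "NLR", "nlr_subtype": "TNL", "receptor_subclass": "none"},
    "CNL":  {"domains": ("CC", "NBARC", "LRR"), "rga_class": "NLR", "nlr_subtype": "CNL", "receptor_subclass": "none"},
    "RNL":  {"domains": ("NBARC", "LRR", "RPW8"), "rga_class": "NLR", "nlr_subtype": "RNL", "receptor_subclass": "none"},
    "TN":   {"domains": ("TIR", "NBARC"), "rga_class": "NLR", "nlr_subtype": "TN", "receptor_subclass": "none"},
    "CN":   {"domains": ("CC", "NBARC"), "rga_class": "NLR", "nlr_subtype": "CN", "receptor_subclass": "none"},
    "NL":   {"domains": ("NBARC", "LRR"), "rga_class": "NLR", "nlr_subtype": "NL", "receptor_subclass": "none"},
    "RN":   {"domains": ("NBARC", "RPW8"), "rga_class": "NLR", "nlr_subtype": "RN", "receptor_subclass": "none"},
    "TX":   {"domains": ("TIR",), "rga_class": "NLR", "nlr_subtype": "TX", "receptor_subclass": "none"},
    "OTHER": {"domains": ("TIR", "NBARC", "LRR", "RPW8"), "rga_class": "NLR", "nlr_subtype": "OTHER", "receptor_subclass": "none"},
    "RPW8": {"domains": ("RPW8",), "rga_class": "RPW8", "nlr_subtype": "none", "receptor_subclass": "none"},
    "LRR-RLK": {"domains": ("TM", "KINASE", "LRR"), "rga_class": "RLK", "nlr_subtype": "none", "receptor_subclass": "LRR"},
    "LysM-RLK": {"domains": ("TM", "KINASE", "LYSM"), "rga_class": "RLK", "nlr_subtype": "none", "receptor_subclass": "LYSM"},
    "OtherReceptor-RLK": {"domains": ("TM", "KINASE"), "rga_class": "RLK", "nlr_subtype": "none", "receptor_subclass": "OTHER_RECEPTOR"},
    "LRR-RLP": {"domains": ("TM", "LRR"), "rga_class": "RLP", "nlr_subtype": "none", "receptor_subclass": "LRR"},
    "LysM-RLP": {"domains": ("TM", "LYSM"), "rga_class": "RLP", "nlr_subtype": "none", "receptor_subclass": "LYSM"},
    "TM-CC": {"domains": ("TM", "CC"), "rga_class": "TMCC", "nlr_subtype": "none", "receptor_subclass": "none"},
}

_SUPERFAMILY_OF_CLASS = {
    "RLK": "TM-LRR", "RLP": "TM-LRR", "NLR": "NLR", "TMCC": "TM-CC", "RPW8": "RPW8",
}

#: Default class composition: the published black-mustard genome totals.
DEFAULT_CLASS_COUNTS = {
    "LRR-RLK": 325, "LysM-RLK": 6, "OtherReceptor-RLK": 490,
    "LRR-RLP": 162, "LysM-RLP": 2,
    "TM-CC": 272,
    "TNL": 119, "CNL": 37, "RNL": 9, "TX": 71, "TN": 30, "NL": 37,
    "RN": 9, "CN": 15, "OTHER": 30, "RPW8": 11,
}
DEFAULT_CLASS_PROPORTIONS = {
    k: v / sum(DEFAULT_CLASS_COUNTS.values()) for k, v in DEFAULT_CLASS_COUNTS.items()
}

#: Scaled-down eight-chromosome assembly (bp).
DEFAULT_CHROMOSOME_LENGTHS = [
    5_473_000, 7_374_000, 5_902_000, 5_141_000,
    6_789_000, 6_187_000, 5_987_000, 7_198_000,
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Everything the generator needs to emit one genome."""

    chromosome_lengths: Sequence[int] = tuple(DEFAULT_CHROMOSOME_LENGTHS)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    end_bias_alpha: float = 0.5
    cluster_spec: Sequence[tuple[str, int, int]] = ()  # (chromosome, n, max_gap)
    n_rga: int = 1000
    n_non_rga: int = 200
    n_rga_homologues: int = 20
    n_non_rga_homologues: int = 5
    with_proteins: bool = True  # skip sequence synthesis for positional studies
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise AnnotationError("class proportions must sum to 1")
        unknown = set(self.class_proportions) - set(ARCHITECTURES)
        if unknown:
            raise AnnotationError(f"unknown architecture labels: {sorted(unknown)}")
        if self.end_bias_alpha <= 0:
            raise AnnotationError("end_bias_alpha must be > 0")
        if any(gap < 0 for _, _, gap in self.cluster_spec):
            raise AnnotationError("cluster max_gap must be >= 0")


@dataclass
class GroundTruth:
    """The generator's manifest: what was planted, for recovery checks."""

    planted_class: dict[str, str]                    # gene -> architecture label
    expected_annotation: dict[str, dict]             # gene -> class/subtype/subclass
    clusters: list[tuple[str, tuple[str, ...]]]      # (chromosome, members)
    homologue_pairs: list[dict]                      # planted, pass all filters
    decoys: list[dict]                               # each violates one rule
    qtl_flags: dict[str, tuple[str, ...]]            # gene -> containing QTL names

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["clusters"] = [[c, list(m)] for c, m in self.clusters]
        payload["qtl_flags"] = {g: list(q) for g, q in self.qtl_flags.items()}
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        raw["clusters"] = [(c, tuple(m)) for c, m in raw["clusters"]]
        raw["qtl_flags"] = {g: tuple(q) for g, q in raw["qtl_flags"].items()}
        return cls(**raw)


def _sample_position(rng, alpha: float, low: int, high: int) -> int:
    """1-based start in [low, high] under the symmetric Beta end-bias law."""
    return low + int(rng.beta(alpha, alpha) * (high - low + 1 - 1e-9))


def _consensus_pool(rng) -> dict[str, np.ndarray]:
    return {
        fam: rng.choice(AMINO_ACIDS, size=240)
        for fam in ("TM-LRR", "NLR", "TM-CC", "RPW8")
    }


def _member_sequence(rng, consensus: np.ndarray, noise: float = 0.15) -> str:
    seq = consensus.copy()
    flip = rng.random(seq.size) < noise
    seq[flip] = rng.choice(AMINO_ACIDS, size=int(flip.sum()))
    return "".join(seq)


def generate_genome(
    profile: SpeciesProfile,
) -> tuple[list[ChromosomeRecord], list[GeneModel], list[DomainCall], GroundTruth]:
    """Emit an assembly, gene models, domain calls and the ground truth.

    Cluster members are placed first, with intergenic gaps drawn in
    [0, max_gap]; background genes are rejected from a 15 kb isolation zone
    around each planted cluster so cluster recovery is exact. Remaining RGA
    positions follow Beta(alpha, alpha) scaled to the chromosome. Non-RGA
    genes carry no domains or a single orphan domain.
    """
    rng = np.random.default_rng(profile.seed)
    assembly = [
        ChromosomeRecord(f"Chr{i + 1:02d}", int(length))
        for i, length in enumerate(profile.chromosome_lengths)
    ]
    lengths = {c.name: c.length_bp for c in assembly}

    labels = sorted(profile.class_proportions)
    probs = np.array([profile.class_proportions[l] for l in labels])
    consensus = _consensus_pool(rng)

    genes: list[GeneModel] = []
    domains: list[DomainCall] = []
    planted_class: dict[str, str] = {}
    expected: dict[str, dict] = {}
    counter = 0

    def add_gene(chrom: str, start: int, end: int, label: str | None) -> str:
        nonlocal counter
        counter += 1
        gene_id = f"g{counter:05d}"
        seq: str | None = None
        if label is None:
            if profile.with_proteins:
                seq = "".join(rng.choice(AMINO_ACIDS, size=200))
        else:
            arch = ARCHITECTURES[label]
            if profile.with_proteins:
                fam = _SUPERFAMILY_OF_CLASS[arch["rga_class"]]
                seq = _member_sequence(rng, consensus[fam])
            for dom in arch["domains"]:
                domains.append(DomainCall(gene_id, dom))
            planted_class[gene_id] = label
            expected[gene_id] = {
                "rga_class": arch["rga_class"],
                "nlr_subtype": arch["nlr_subtype"],
                "receptor_subclass": arch["receptor_subclass"],
            }
        genes.append(
            GeneModel(gene_id, chrom, start, end,
                      strand="+" if rng.random() < 0.5 else "-",
                      protein_length=None if seq is None else len(seq),
                      protein_sequence=seq)
        )
        return gene_id

    # 1. planted clusters, with isolation zones for exact recovery
    exclusion: dict[str, list[tuple[int, int]]] = {c.name: [] for c in assembly}
    clusters: list[tuple[str, tuple[str, ...]]] = []
    isolation = 15_000
    for chrom, n_members, max_gap in profile.cluster_spec:
        if chrom not in lengths:
            raise AnnotationError(f"cluster_spec names unknown chromosome {chrom}")
        gene_lens = rng.integers(1000, 3000, size=n_members)
        gaps = rng.integers(0, max_gap + 1, size=n_members - 1) if n_members > 1 else []
        span = int(gene_lens.sum() + sum(gaps))
        if span + 2 * isolation >= lengths[chrom]:
            raise AnnotationError(f"cluster does not fit on {chrom}")
        for _ in range(1000):
            start = int(rng.integers(isolation + 1, lengths[chrom] - span - isolation))
            if all(
                start + span + isolation < lo or start - isolation > hi
                for lo, hi in exclusion[chrom]
            ):
                break
        else:
            raise AnnotationError(f"could not place cluster on {chrom}")
        members = []
        pos = start
        for m in range(n_members):
            label = labels[rng.choice(len(labels), p=probs)]
            members.append(add_gene(chrom, pos, pos + int(gene_lens[m]) - 1, label))
            pos += int(gene_lens[m]) + (int(gaps[m]) if m < n_members - 1 else 0)
        clusters.append((chrom, tuple(members)))
        exclusion[chrom].append((start - isolation, start + span + isolation))

    # 2. background RGA genes, Beta-positioned away from planted clusters
    n_cluster_genes = sum(n for _, n, _ in profile.cluster_spec)
    n_background = profile.n_rga - n_cluster_genes
    if n_background < 0:
        raise AnnotationError("cluster_spec plants more genes than n_rga")
    chrom_names = [c.name for c in assembly]
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()

    def place(chrom: str, gene_len: int) -> int:
        for _ in range(1000):
            start = _sample_position(
                rng, profile.end_bias_alpha, 1, lengths[chrom] - gene_len + 1
            )
            end = start + gene_len - 1
            if all(
                end < lo or start > hi for lo, hi in exclusion[chrom]
            ):
                return start
        raise AnnotationError(f"could not place gene on {chrom}")

    for _ in range(n_background):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        gene_len = int(rng.integers(1000, 5000))
        start = place(chrom, gene_len)
        label = labels[rng.choice(len(labels), p=probs)]
        add_gene(chrom, start, start + gene_len - 1, label)

    # 3. non-RGA genes: no domains or a single orphan domain
    orphans = ["KINASE", "LRR", "CC", "LYSM", "TM"]
    for _ in range(profile.n_non_rga):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        gene_len = int(rng.integers(1000, 5000))
        start = place(chrom, gene_len)
        gene_id = add_gene(chrom, start, start + gene_len - 1, None)
        if rng.random() < 0.5:
            domains.append(DomainCall(gene_id, orphans[rng.choice(len(orphans))]))

    # 4. planted homologue pairs (RGA and non-RGA subjects)
    rga_ids = sorted(planted_class)
    non_rga_ids = sorted(set(g.gene_id for g in genes) - set(rga_ids))
    queries = [f"Rgene{i + 1:02d}" for i in range(12)]
    homologue_pairs: list[dict] = []

    def plant_pairs(subjects: list[str], n: int, is_rga: bool) -> None:
        chosen = rng.choice(len(subjects), size=min(n, len(subjects)), replace=False)
        for idx in chosen:
            evalue = 0.0 if rng.random() < 0.1 else 10.0 ** (-rng.uniform(46, 170))
            homologue_pairs.append(
                {
                    "query": queries[rng.choice(len(queries))],
                    "subject": subjects[int(idx)],
                    "evalue": float(evalue),
                    "similarity": float(rng.uniform(60.0, 100.0)),
                    "length": int(rng.integers(148, 500)),
                    "subject_is_rga": is_rga,
                }
            )

    plant_pairs(rga_ids, profile.n_rga_homologues, True)
    plant_pairs(non_rga_ids, profile.n_non_rga_homologues, False)

    truth = GroundTruth(
        planted_class=planted_class,
        expected_annotation=expected,
        clusters=clusters,
        homologue_pairs=homologue_pairs,
        decoys=[],
        qtl_flags={},
    )
    return assembly, genes, domains, truth


def simulate_hits(
    ground_truth: GroundTruth, n_decoys: int, seed: int = 0
) -> list[AlignmentHit]:
    """Planted homologue hits plus decoys violating exactly one filter each.

    Decoys cycle through the three rules (E-value too weak, similarity too
    low, alignment too short) and are appended to the ground truth with the
    violated rule named.
    """
    rng = np.random.default_rng(seed)
    hits = [
        AlignmentHit(p["query"], p["subject"], p["evalue"], p["similarity"], p["length"])
        for p in ground_truth.homologue_pairs
    ]
    if not hits and n_decoys:
        raise AnnotationError("ground truth has no planted homologue pairs")
    subjects = sorted({p["subject"] for p in ground_truth.homologue_pairs})
    queries = sorted({p["query"] for p in ground_truth.homologue_pairs})
    rules = ["evalue", "similarity", "length"]
    ground_truth.decoys = []
    for i in range(n_decoys):
        rule = rules[i % 3]
        evalue = 0.0 if rng.random() < 0.1 else 10.0 ** (-rng.uniform(46, 170))
        similarity = float(rng.uniform(60.0, 100.0))
        length = int(rng.integers(148, 500))
        if rule == "evalue":
            evalue = 10.0 ** (-rng.uniform(0, 44.5))
        elif rule == "similarity":
            similarity = float(rng.uniform(0.0, 59.9))
        else:
            length = int(rng.integers(1, 148))
        decoy = {
            "query": queries[rng.choice(len(queries))],
            "subject": subjects[rng.choice(len(subjects))],
            "evalue": float(evalue),
            "similarity": similarity,
            "length": length,
            "violates": rule,
        }
        ground_truth.decoys.append(decoy)
        hits.append(
            AlignmentHit(decoy["query"], decoy["subject"], evalue, similarity, length)
        )
    return hits


def generate_qtl_set(
    assembly: Sequence[ChromosomeRecord],
    genes: Sequence[GeneModel],
    n_qtl: int,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
) -> tuple[list[QTLRecord], dict[str, tuple[str, ...]]]:
    """Random QTL intervals plus per-gene containment flags.

    Each interval lies within one chromosome (width 2-15% of its length);
    flags are recorded by direct containment check and, when a ground truth
    is given, stored on it.
    """
    if not assembly:
        raise AnnotationError("assembly is empty")
    rng = np.random.default_rng(seed)
    diseases = sorted(QTL_DISEASE_CODES)
    qtls: list[QTLRecord] = []
    for i in range(n_qtl):
        chrom = assembly[rng.choice(len(assembly))]
        width = int(chrom.length_bp * rng.uniform(0.02, 0.15))
        start = int(rng.integers(1, chrom.length_bp - width + 1))
        qtls.append(
            QTLRecord(
                qtl_name=f"Q{i + 1:03d}",
                species="synthetic",
                disease=diseases[rng.choice(len(diseases))],
                chromosome=chrom.name,
                start=start,
                end=start + width - 1,
            )
        )
    flags = {
        g.gene_id: tuple(
            q.qtl_name
            for q in qtls
            if q.chromosome == g.chromosome and q.start <= g.start and g.end <= q.end
        )
        for g in genes
    }
    if ground_truth is not None:
        ground_truth.qtl_flags = flags
    return qtls, flags
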