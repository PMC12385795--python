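"""End-to-end orchestration: wire every stage and collect headline statistics.

The pipeline reads one annotation bundle (GFF3 + protein FASTA + domain
table, plus optional hit table, QTL table and pre-aligned FASTA), runs
classification, landscape statistics, physical and similarity clustering,
homologue filtering, co-localisation and tree building, writes each stage's
tables under the output directory and a machine-readable ``summary.json``
with the headline numbers. Given the same inputs and configuration the
summary is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify as _classify
from . import cluster as _cluster
from . import colocalise as _colocalise
from . import homology as _homology
from . import io as _io
from . import landscape as _landscape
from . import phylo as _phylo

logger = logging.getLogger("rgakit")


@dataclass
class RunConfig:
    gff3: str
    fasta: str | None = None
    domains: str | None = None
    hits: str | None = None
    qtl: str | None = None
    alignment: str | None = None
    out_dir: str = "rgakit_out"
    cluster_threshold_bp: int = _cluster.DEFAULT_CLUSTER_THRESHOLD_BP
    e_max: float = _homology.DEFAULT_E_MAX
    sim_min: float = _homology.DEFAULT_SIM_MIN
    len_min_aa: int = _homology.DEFAULT_LEN_MIN_AA
    dendrogram_k: int = 4
    similarity_max_genes: int = 60
    bootstrap_reps: int = 100
    seed: int = 0
    chromosome_pattern: str = _io.DEFAULT_CHROMOSOME_PATTERN
    chromosome_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path, name in [(config.gff3, "gff3"), (config.fasta, "fasta"),
                       (config.domains, "domains"), (config.hits, "hits"),
                       (config.qtl, "qtl"), (config.alignment, "alignment")]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{name} input does not exist: {path}")

    summary: dict = {"seed": config.seed}
    assembly, genes, domains = _io.read_annotation(
        config.gff3, config.fasta, config.domains,
        chromosome_pattern=config.chromosome_pattern,
    )
    logger.info("loaded %d sequences, %d genes, %d domain calls",
                len(assembly), len(genes), len(domains))

    # classification
    annotations, count_table = _classify.classify_genome(
        genes, domains, assembly_order=[c.name for c in assembly]
    )
    _classify.annotations_frame(annotations).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    count_table.to_csv(out / "count_table.csv")
    class_of = {a.gene_id: a.rga_class for a in annotations}
    superfamily_of = {a.gene_id: a.superfamily for a in annotations}
    rga_genes = [g for g in genes if class_of[g.gene_id] != "NONE"]
    summary["n_genes"] = len(genes)
    summary["n_rga"] = len(rga_genes)
    summary["class_counts"] = {
        cls: sum(1 for a in annotations if a.rga_class == cls)
        for cls in ("RLK", "RLP", "NLR", "TMCC", "RPW8")
    }

    # landscape
    lengths_mbp = {c.name: c.length_bp / 1e6 for c in assembly}
    counts = {c.name: 0 for c in assembly}
    for g in rga_genes:
        counts[g.chromosome] += 1
    stats = _landscape.chromosome_stats(counts, lengths_mbp)
    with open(out / "chromosome_stats.csv", "w") as handle:
        handle.write("chromosome,length_mbp,rga_count,density,share_pct\n")
        for s in stats:
            handle.write(f"{s.chromosome},{s.length_mbp:.2f},{s.rga_count},"
                         f"{s.density},{s.share_pct}\n")
    chrom_rows = [c.name for c in assembly if not c.is_contig]
    if len(chrom_rows) >= 3:
        slope, intercept, r = _landscape.size_count_regression(
            [lengths_mbp[c] for c in chrom_rows], [counts[c] for c in chrom_rows]
        )
        summary["size_count_regression"] = {
            "slope": round(slope, 4), "intercept": round(intercept, 4),
            "pearson_r": round(r, 4),
        }
        summary["larger_but_not_more_pairs"] = _landscape.larger_but_not_more_pairs(
            [lengths_mbp[c] for c in chrom_rows], [counts[c] for c in chrom_rows]
        )
    profile, end_bias = _landscape.positional_profile(genes, annotations, assembly)
    profile.to_csv(out / "window_profile.csv", index=False)
    summary["end_bias_fraction"] = round(end_bias, 4)

    # physical clustering
    clusters = _cluster.physical_clusters(rga_genes, config.cluster_threshold_bp)
    n_clustered, per_class = _cluster.clustered_gene_counts(clusters, class_of)
    with open(out / "physical_clusters.tsv", "w") as handle:
        handle.write("chromosome\tspan_start\tspan_end\tmembers\n")
        for c in clusters:
            handle.write(f"{c.chromosome}\t{c.span[0]}\t{c.span[1]}\t"
                         f"{','.join(c.members)}\n")
    summary["physical_clusters"] = {
        "n_clusters": len(clusters),
        "n_clustered_genes": n_clustered,
        "per_class": dict(sorted(per_class.items())),
    }

    # sequence-similarity clustering (bounded subset, all-pairs alignment)
    with_seq = [g for g in rga_genes if g.protein_sequence]
    subset = with_seq[: config.similarity_max_genes]
    if len(subset) >= 2:
        matrix = _cluster.pairwise_similarity(
            {g.gene_id: g.protein_sequence for g in subset}
        )
        k = min(config.dendrogram_k, len(subset))
        assignment, composition = _cluster.dendrogram_clusters(
            matrix, k, superfamily_of
        )
        composition.to_csv(out / "similarity_clusters.csv", index=False)
        (out / "similarity_dendrogram.nwk").write_text(_cluster.to_newick(matrix))
        summary["similarity_clusters"] = {
            "k": k, "n_genes": len(subset),
            "sizes": sorted(
                (sum(1 for v in assignment.values() if v == c)
                 for c in set(assignment.values())),
                reverse=True,
            ),
        }

    # homology
    if config.hits is not None:
        hits = _io.read_hits(config.hits)
        kept = _homology.filter_hits(hits, config.e_max, config.sim_min,
                                     config.len_min_aa)
        _io.write_hits(kept, out / "kept_hits.tsv")
        catalog = _io.load_r_gene_catalog()
        known_queries = {e.r_gene_id for e in catalog}
        extra = sorted({h.query_id for h in kept} - known_queries)
        from .model import RGeneCatalogEntry
        catalog = list(catalog) + [
            RGeneCatalogEntry(q, frozenset({"BL"})) for q in extra
        ]
        cdrhs, cdrh_summary = _homology.cdrh_map(kept, annotations, catalog)
        non_rga, non_rga_summary = _homology.non_rga_homologues(
            kept, annotations, catalog
        )
        with open(out / "cdrh.tsv", "w") as handle:
            handle.write("gene_id\trga_class\tnlr_subtype\tr_genes\tdiseases\n")
            for rec in cdrhs:
                handle.write(
                    f"{rec.gene_id}\t{rec.rga_class}\t{rec.nlr_subtype}\t"
                    f"{';'.join(sorted(rec.matched_r_genes))}\t"
                    f"{';'.join(sorted(rec.diseases))}\n"
                )
        summary["homology"] = {
            "n_hits": len(hits),
            "n_kept": len(kept),
            "n_cdrh": cdrh_summary.n_subjects,
            "n_cdrh_multi_r": cdrh_summary.n_subjects_multi_r,
            "n_non_rga_homologues": non_rga_summary.n_subjects,
            "disease_rollup": dict(sorted(_homology.disease_rollup(cdrhs).items())),
        }

    # co-localisation of the receptor families
    if config.qtl is not None:
        qtls = _io.read_qtl_table(config.qtl)
        receptors = [g for g in genes if class_of[g.gene_id] in {"RLK", "RLP"}]
        coloc = _colocalise.colocalise_genes(
            receptors, qtls, class_of,
            chromosome_map=config.chromosome_map,
            known_chromosomes=[
                config.chromosome_map.get(c.name, c.name) for c in assembly
            ],
        )
        coloc.per_qtl_counts.to_csv(out / "qtl_gene_counts.csv")
        summary["colocalisation"] = {
            "n_qtl": len(qtls),
            "n_qtl_skipped": len(coloc.skipped_qtls),
            "genes_in_any_qtl": coloc.genes_in_any_qtl,
            "max_qtl_gene": list(coloc.max_qtl_gene) if coloc.max_qtl_gene else None,
            "max_gene_qtl": list(coloc.max_gene_qtl) if coloc.max_gene_qtl else None,
        }

    # phylogenetics on the pre-aligned input
    if config.alignment is not None:
        from Bio import SeqIO
        with _io._open_text(config.alignment) as handle:
            alignment = {r.id: str(r.seq) for r in SeqIO.parse(handle, "fasta")}
        tree = _phylo.bootstrap_supports(
            alignment, n_reps=config.bootstrap_reps, seed=config.seed
        )
        (out / "tree.nwk").write_text(_phylo.to_newick(tree))
        summary["phylo"] = {
            "n_taxa": len(alignment),
            "bootstrap_reps": config.bootstrap_reps,
            "root_height": round(tree.height, 6),
        }

    text = json.dumps(summary, indent=1, sort_keys=True)
    (out / "summary.json").write_text(text)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
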