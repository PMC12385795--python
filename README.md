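# rgakit

Genome-wide characterisation of plant **resistance gene analogues (RGAs)** —
the receptor and immune-signalling gene families (NLRs, receptor-like
kinases and proteins, transmembrane coiled-coil and RPW8 genes) that
underpin disease resistance in Brassicaceae and other plants. The package is
aimed at plant genomicists who have per-gene domain predictions, gene
coordinates and protein alignments in hand and want the downstream analysis:
classification, chromosomal landscape, clustering, homologue discovery, QTL
co-localisation and phylogenetics.

## What it computes

**Classification.** Each gene's domain set maps deterministically onto an
RGA class. With NB-ARC present the NLR subtype follows the N-terminal and
C-terminal complement (TIR+LRR → TNL, CC+LRR → CNL, TIR → TN, CC → CN,
LRR → NL, none → bare NBS); an RPW8 domain reclassifies bare NBS → RN,
NL → RNL and any other NB-ARC subtype → OTHER. TIR without NB-ARC is TX.
A kinase plus transmembrane segment gives an RLK, a transmembrane segment
plus ectodomain (LRR, LysM or other) without kinase gives an RLP, standalone
RPW8 and TM+CC give the RPW8 and TM-CC classes. TNL/CNL/RNL are *typical*
NLRs; all other NLR-side subtypes are *atypical*.

**Landscape.** Per-chromosome counts, densities (RGA/Mbp), chromosome
shares, per-chromosome means (contigs excluded), OLS regression of count on
chromosome size, the number of chromosome pairs where the larger one carries
no more RGAs, and windowed positional profiles with an end-bias fraction
(share of RGAs in the two distal 25% chromosome segments).

**Clustering.** Physical clusters are maximal runs of genes whose
neighbour gaps (end→start) are all ≤ 10 kb (configurable, boundary
inclusive, ≥ 2 members). Sequence clusters come from all-pairs global
protein alignment similarity, average-linkage agglomeration on
1 − similarity, and a k-group cut.

**Homologues.** Alignment hits of cloned R-gene queries survive iff
E ≤ 1e-45, similarity ≥ 60% and alignment length ≥ 148 aa (the length of the
smallest reference protein). Kept hits build many-to-many
R-gene ↔ gene maps, split into RGA subjects (CDRHs) and non-RGA subjects,
with per-disease rollups.

**Co-localisation.** A gene is *within* a QTL iff the QTL interval fully
contains it (1-based closed coordinates); the packaged table of 57 published
Brassica disease-resistance QTL ships with the package.

**Phylogenetics.** From a pre-aligned protein FASTA: mismatch fraction *p*
under pairwise deletion, Jukes-Cantor protein correction
d = −(19/20)·ln(1 − (20/19)·p), UPGMA agglomeration (merge height = pair
distance/2, lexicographic tie-breaks), column-resampling bootstrap supports,
Newick export.

**Synthetic genomes.** A generator emits assemblies, gene models, domain
calls, hit tables and QTL sets with a ground-truth manifest: planted class
proportions (black-mustard composition by default), Beta(α, α) end-biased
positions, planted ≤ 10 kb clusters, homologues that pass the filter chain
and decoys that each violate exactly one rule.

## Worked example

```bash
rgakit simulate --out-dir bundle --seed 7 --n-rga 400 --n-non-rga 80
rgakit run --bundle bundle --out-dir out --seed 7
```

`out/summary.json` then contains (abridged):

```json
{
 "class_counts": {"NLR": 76, "RLK": 189, "RLP": 54, "RPW8": 2, "TMCC": 79},
 "end_bias_fraction": 0.645,
 "homology": {"n_hits": 40, "n_kept": 25, "n_cdrh": 20, "n_non_rga_homologues": 5},
 "physical_clusters": {"n_clusters": 44, "n_clustered_genes": 113},
 "size_count_regression": {"slope": 11.7193, "pearson_r": 0.8241},
 "n_genes": 480, "n_rga": 400, "seed": 7
}
```

Reading: of 480 simulated genes, 400 are RGAs, dominated by RLKs (189) as in
real crucifer genomes; 64.5% of RGAs sit in the distal chromosome quarters
(the generator's Beta(0.5, 0.5) placement predicts 2/3); 113 RGAs fall into
44 physical clusters at the 10 kb threshold; the homologue filter keeps 25
of 40 hits (the 15 decoys each violate one rule); RGA counts rise with
chromosome size (r = 0.82). Identical inputs and seed reproduce this file
byte for byte. Each stage is also available standalone
(`rgakit classify|cluster|homology|colocalise|phylo`).

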