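# Methods

## Scope and data model

`rgakit` analyses an annotated genome given as (i) gene intervals (GFF3,
1-based fully closed coordinates; `##sequence-region` pragmas supply
chromosome lengths), (ii) protein sequences (FASTA keyed by gene ID),
(iii) a per-gene domain table over a closed vocabulary
{TIR, NBARC, LRR, CC, RPW8, TM, KINASE, LYSM, OTHER_ECTO}, (iv) optional
BLASTP-style hit tables and QTL interval tables. Domain prediction itself
(InterProScan/HMMER-class tooling) is out of scope: the domain table is its
normalised product, and a shipped synonym map (e.g. "NB-ARC" → NBARC)
canonicalises the many aliases such tools emit. Strand is read and carried
but ignored by every computation. Sequences whose names do not match the
configurable chromosome pattern (default `^Chr`) are flagged as contigs;
several statistics exclude them (below).

## Classification

The decision table is total and deterministic over the 2^9 = 512 domain
subsets (exhaustively enumerated in tests). Precedence — NB-ARC-based
classes, then TIR-only, RLK, RLP, standalone RPW8, TM-CC — resolves
multi-signature genes; the classes are mutually exclusive in the count
table. Choices that were genuinely open:

- **Bare NBS** (NB-ARC alone, no RPW8) keeps a distinct `NBS` subtype mark
  in the per-gene annotation but is tabulated under OTHER in the count
  table, which carries no NBS column. It counts as atypical.
- **TX** (TIR without NB-ARC) is carried as an NLR-side subtype and in the
  atypical aggregate, consistent with family-level reporting conventions
  that pool TX with NLRs.
- **RPW8 reclassification** applies only on the NB-ARC/TIR side
  (NBS → RN, NL → RNL, TNL/CNL/CN/TN/TX → OTHER); it never changes a
  receptor-side or TM-CC verdict. Standalone RPW8 is its own class: the
  count table needs an RPW8 column with non-zero totals.
- **RLP** requires a transmembrane segment plus at least one ectodomain
  (LRR, LysM or other) and no kinase and no NB-ARC.

Typical NLRs are exactly {TNL, CNL, RNL}; everything else NLR-side is
atypical, so typical + atypical equals the NLR total by construction.

## Landscape statistics

Density is count/length in RGA/Mbp. All reported percentages, densities and
means use round-half-even at two decimals. Known cosmetic consequence: one
published species-level gene share prints as 3.03% where the underlying
division (1249/41132) gives 3.0366 → 3.04; the package reports 3.04 and
makes no attempt to mimic truncation.

Per-chromosome means exclude contig rows: with the packaged count table the
means 201.62, 180.22 and 103.83 are reproduced only under exclusion
(e.g. 1613/8 and 1246/12).

`larger_but_not_more_pairs` counts unordered chromosome pairs where the
larger chromosome has **no more** RGAs; count ties count, tied sizes are an
error. The tie rule is the unique convention reproducing all three published
values (11/10/30) from the packaged table, which contains two count ties.

Windowed profiles tile each chromosome with fixed windows from position 1
(last window short); a gene belongs to the window containing its **start**
coordinate — the simplest convention, stated here because midpoint
assignment would be equally defensible. The end-bias fraction is the share
of RGAs whose start lies in the first or last quarter of its chromosome.

Regression of count on size is ordinary least squares
(`scipy.stats.linregress`); only slope, intercept and Pearson r are
reported.

## Physical and similarity clustering

Physical clustering sorts genes by start within each chromosome and keeps
maximal runs whose neighbour gaps `start(next) − end(prev)` are all
≤ threshold (default 10,000 bp, boundary inclusive); runs of one gene are
not clusters. The gap is intergenic (end-to-start) rather than
start-to-start — the natural reading of a "within 10 kb" criterion — and the
threshold is configurable. A sweep over sorted genes equals the transitive
closure of the pairwise within-threshold relation (property-tested against a
union-find oracle). The default family partition for per-family runs pools
all NLR subtypes (TX included) and treats RLK, RLP, TM-CC and RPW8 as the
other units.

Pairwise similarity is matches/columns from global alignment with explicit
toy scoring (match +1, mismatch −1, linear gap −2, Biopython
`PairwiseAligner`). The original analysis's alignment parameters are not
recoverable, so the scoring is declared, configurable and excluded from any
numeric target; what is tested is structure recovery (three planted motif
families are recovered at Rand index > 0.9 from a k = 3 cut). Dendrograms
use scipy average linkage on 1 − similarity; k is a user parameter
(default 4, matching the published dendrogram cuts of 4–5 groups whose
selection rule was not stated).

## Homologue filtering

A hit survives iff E-value ≤ 1e-45 **and** similarity ≥ 60% **and**
alignment length ≥ 148 aa. The E-value rule reads the published "range of
E0 to E-45" as [0, 1e-45]: E0 denotes a reported E-value of zero (the most
significant end), and keeping only *weaker* hits would be nonsensical. The
148-aa rule (length of the smallest reference protein, 148 aa) is applied to
**alignment length** by default; subject-protein length is the other
defensible reading and the threshold is a parameter. No best-hit selection
is applied: the homology maps are many-to-many by design, matching how
multiplicities are reported (R genes with several homologues, subjects
matching several R genes). Disease rollups count a subject once per disease
in the union of its matched R genes' disease sets.

The packaged R-gene catalogue (`r_gene_catalog_synthetic.csv`) carries the
23 cloned R genes recoverable by name with their disease codes; the
remaining entries padding the catalogue to its published size of 49 are
constructed stand-ins flagged `synthetic=yes`. Analyses never depend on the
identity of catalogue entries, only on the (gene, disease-set) shape.

## QTL co-localisation

Containment, not overlap: a gene is within a QTL iff
`qtl.start ≤ gene.start` and `gene.end ≤ qtl.end` (closed intervals,
boundaries inclusive); `mode="overlap"` is available for sensitivity
analysis. Genes and QTL must share one coordinate system — a user-supplied
chromosome-name map is applied, but cross-assembly lift-over is explicitly
out of scope. QTL on chromosomes absent from the assembly are skipped with a
warning. A gene inside n QTL counts once in the any-QTL total and once in
each per-QTL count; overlapping QTL therefore produce multiple memberships.
The packaged QTL fixture carries 57 published Brassica disease-resistance
intervals (27 SSR, 19 BL, 4 BR, 3 CR, 3 WR, 1 HR).

## Phylogenetics

Distances are computed on pre-aligned protein sequences (alignment
construction is upstream). The mismatch fraction p uses pairwise deletion —
columns where either member of the pair has a gap are dropped for that pair
— which is more robust than complete deletion for ragged receptor-family
alignments. The 20-state Jukes-Cantor correction
d = −(19/20)·ln(1 − (20/19)·p) is finite for p < 19/20; saturated pairs are
a hard error rather than an arbitrary cap. Note the practical consequence:
unrelated random proteins have expected p ≈ 0.95, exactly the saturation
point, so trees are built within gene families, not across them.

UPGMA is implemented directly (it is a core deliverable, not delegated):
size-weighted Lance-Williams updates, merge height = pair distance/2, ties
broken on the lexicographically smallest pair of sorted leaf-label tuples so
output is platform-independent. Tests verify equality with a brute-force
reference that re-averages original leaf-pair distances at every step, exact
reconstruction of ultrametric inputs, and monotone heights. Bootstrap
resamples alignment columns with replacement; a clade's support is the
percentage of valid replicates containing its exact leaf set (trees are
rooted, so leaf-set identity is the right equivalence). Replicates in which
some pair has no comparable columns or a saturated distance are skipped with
a warning and removed from the denominator. Newick export writes branch
lengths (parent height − child height) and supports as internal labels, and
round-trips through an independent parser in tests.

## Synthetic genomes

The generator defines the study conditions for every property test:

- **Composition**: default class proportions are the published black-mustard
  genome totals over 16 architecture labels (e.g. 325/1625 LRR-RLK,
  119/1625 TNL, 11/1625 RPW8).
- **Assembly**: eight chromosomes, 5.1–7.4 Mbp — the published chromosome
  proportions scaled down tenfold so that tests run in seconds while gene
  spacing stays in a realistic range for clustering.
- **Positions**: Beta(α, α) scaled to chromosome length, default α = 0.5,
  the simplest symmetric end-biased law. The distal-quarter mass is
  2·F(0.25) = 2/3 at α = 0.5 and 1/2 at α = 1 (closed form, used as the test
  oracle); the real genomes' end bias is only qualitative, so the Beta model
  is a stand-in, not a claim.
- **Clusters**: planted member runs draw gene lengths of 1–3 kb and gaps
  uniform in [0, max_gap]; a 15 kb isolation zone around each planted
  cluster keeps background genes away, which is what makes *exact* recovery
  a guarantee rather than a probability. Background genes may still form
  incidental clusters among themselves — as real RGAs do — so tests assert
  planted-cluster recovery, not cluster-set equality.
- **Homologues**: planted pairs draw E in [1e-170, 1e-46] (10% exactly 0),
  similarity in [60, 100], length in [148, 500); decoys cycle through the
  three rules and violate exactly the named one.
- **Proteins**: per-superfamily consensus blocks (240 aa) with 15% random
  substitution per member — enough structure for similarity clustering to
  recover families, with no pretence of modelling protein evolution, indels
  or synteny. `with_proteins=False` skips sequence synthesis for large
  positional experiments.
- **Determinism**: one `numpy` generator seeded by a single integer drives
  every draw; same profile, same bytes.

Because the generator omits real-data features (paralogue gradients, TE
context, annotation noise, cross-species QTL coordinates), passing recovery
tests demonstrates correctness of the algorithms under their stated
assumptions, not performance on real genomes.

## Problem sizes and numerical choices

The test suite and the acceptance script use a 1,000-gene genome for
recovery checks (multinomial fluctuation at n = 1000 keeps class fractions
within ±3% of their expectations), n = 10,000 positions for end-bias
fractions (binomial 95% interval ≈ ±0.01, tested at ±0.02), 100 random
matrices of ≤ 6 taxa for the UPGMA oracle, and 100–1000 bootstrap
replicates. Reported statistics round half-even at 2 dp; alignment and
linkage tie-breaks are deterministic (diagonal-preferring alignment,
lexicographic merge order); degenerate inputs (zero-length chromosomes,
saturated distances, empty sequences, tied chromosome sizes) raise typed
errors rather than propagating NaNs.

## Known limitations

- Published genome-scale counts for the three mustard genomes cannot be
  recomputed without the original assemblies; the packaged count table is
  used as printed and only its internal arithmetic is reproduced.
- The similarity metric and dendrogram cut height of the original sequence
  clustering are unstated; memberships are therefore not comparable, only
  the methodology.
- Cross-assembly QTL coordinate transfer is not modelled.
- The classifier reconstructs a pipeline whose exact rules are not published
  in full; the decision table is documented above so that deviations are at
  least explicit.
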