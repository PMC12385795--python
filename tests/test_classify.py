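from itertools import combinations

import pytest

from rgakit.classify import (
    ATYPICAL_SUBTYPES,
    TYPICAL_SUBTYPES,
    classify_gene,
    classify_genome,
    typical_flag,
)
from rgakit.model import AnnotationError, DOMAIN_VOCABULARY, DomainCall, GeneModel


@pytest.mark.parametrize(
    "domains, rga_class, subtype, subclass",
    [
        ({"TIR", "NBARC", "LRR"}, "NLR", "TNL", "none"),
        ({"CC", "NBARC", "LRR"}, "NLR", "CNL", "none"),
        ({"TIR", "NBARC"}, "NLR", "TN", "none"),
        ({"CC", "NBARC"}, "NLR", "CN", "none"),
        ({"NBARC", "LRR"}, "NLR", "NL", "none"),
        ({"NBARC"}, "NLR", "NBS", "none"),
        ({"TIR"}, "NLR", "TX", "none"),
        # RPW8 reclassification on the NB-ARC side
        ({"NBARC", "RPW8"}, "NLR", "RN", "none"),
        ({"NBARC", "LRR", "RPW8"}, "NLR", "RNL", "none"),
        ({"TIR", "NBARC", "LRR", "RPW8"}, "NLR", "OTHER", "none"),
        ({"CC", "NBARC", "RPW8"}, "NLR", "OTHER", "none"),
        ({"TIR", "RPW8"}, "NLR", "OTHER", "none"),
        # receptor side
        ({"TM", "KINASE", "LRR"}, "RLK", "none", "LRR"),
        ({"TM", "KINASE", "LYSM"}, "RLK", "none", "LYSM"),
        ({"TM", "KINASE"}, "RLK", "none", "OTHER_RECEPTOR"),
        ({"TM", "LRR"}, "RLP", "none", "LRR"),
        ({"TM", "LYSM"}, "RLP", "none", "LYSM"),
        ({"TM", "OTHER_ECTO"}, "RLP", "none", "OTHER_RECEPTOR"),
        # remaining classes
        ({"RPW8"}, "RPW8", "none", "none"),
        ({"RPW8", "TM"}, "RPW8", "none", "none"),
        ({"TM", "CC"}, "TMCC", "none", "none"),
        (set(), "NONE", "none", "none"),
        ({"LRR"}, "NONE", "none", "none"),
        ({"KINASE"}, "NONE", "none", "none"),
    ],
)
def test_decision_table(domains, rga_class, subtype, subclass):
    ann = classify_gene(domains)
    assert (ann.rga_class, ann.nlr_subtype, ann.receptor_subclass) == (
        rga_class, subtype, subclass,
    )


def test_unknown_domain_label_is_error():
    with pytest.raises(AnnotationError):
        classify_gene({"NBARC", "WRKY"})


@pytest.mark.parametrize("subtype, flag", [
    ("TNL", "typical"), ("CNL", "typical"), ("RNL", "typical"),
    ("TX", "atypical"), ("TN", "atypical"), ("RN", "atypical"),
    ("NL", "atypical"), ("CN", "atypical"), ("OTHER", "atypical"),
])
def test_typical_flag(subtype, flag):
    assert typical_flag(subtype) == flag


def test_totality_and_consistency_over_all_domain_subsets():
    """Every one of the 512 domain subsets maps to exactly one verdict."""
    vocabulary = sorted(DOMAIN_VOCABULARY)
    seen = 0
    for r in range(len(vocabulary) + 1):
        for subset in combinations(vocabulary, r):
            ann = classify_gene(frozenset(subset))
            seen += 1
            assert ann.rga_class in {"RLK", "RLP", "NLR", "TMCC", "RPW8", "NONE"}
            # subtype assigned exactly for the NLR side
            assert (ann.nlr_subtype != "none") == (ann.rga_class == "NLR")
            assert (ann.receptor_subclass != "none") == (
                ann.rga_class in {"RLK", "RLP"}
            )
            if ann.rga_class == "NLR":
                assert ann.typical in {"typical", "atypical"}
                assert ann.superfamily == "NLR"
            if ann.rga_class in {"RLK", "RLP"}:
                assert ann.superfamily == "TM-LRR"
            # RPW8 never changes a non-NB-ARC, non-TIR gene's class
            if "NBARC" not in subset and "TIR" not in subset and "RPW8" in subset:
                without = classify_gene(frozenset(subset) - {"RPW8"})
                assert without.rga_class in {"RLK", "RLP", "TMCC", "NONE", "RPW8"}
    assert seen == 2 ** len(vocabulary)


def _tiny_genome():
    genes = [
        GeneModel("a", "Chr01", 100, 200),
        GeneModel("b", "Chr01", 300, 400),
        GeneModel("c", "Chr02", 100, 200),
    ]
    domains = [
        DomainCall("a", "TIR"), DomainCall("a", "NBARC"), DomainCall("a", "LRR"),
        DomainCall("b", "TM"), DomainCall("b", "KINASE"), DomainCall("b", "LRR"),
    ]
    return genes, domains


def test_classify_genome_counts():
    genes, domains = _tiny_genome()
    _, table = classify_genome(genes, domains)
    assert table.loc["Total", "Total"] == 2
    assert table.loc["Total", "TNL"] == 1
    assert table.loc["Total", "RLK"] == 1
    assert table.loc["Total", "LRR-RLK"] == 1


def test_classify_genome_order_invariance():
    genes, domains = _tiny_genome()
    _, table_fwd = classify_genome(genes, domains)
    _, table_rev = classify_genome(genes[::-1], domains[::-1])
    assert table_fwd.equals(table_rev)


def test_count_table_internal_sums(small_annotations):
    annotations, table = small_annotations
    totals = table.loc["Total"]
    nlr_side = ["TNL", "CNL", "RNL", "TX", "TN", "NL", "RN", "CN", "OTHER"]
    assert totals["Total"] == (
        totals["RLK"] + totals["RLP"] + totals["TM-CC"] + totals["RPW8"]
        + sum(totals[c] for c in nlr_side)
    )
    assert totals["RLK"] == (
        totals["LRR-RLK"] + totals["LysM-RLK"] + totals["OtherReceptor-RLK"]
    )
    n_nlr = sum(1 for a in annotations if a.rga_class == "NLR")
    assert sum(totals[c] for c in nlr_side) == n_nlr
    n_typical = sum(1 for a in annotations if a.typical == "typical")
    n_atypical = sum(1 for a in annotations if a.typical == "atypical")
    assert n_typical + n_atypical == n_nlr
    assert n_typical == sum(totals[c] for c in TYPICAL_SUBTYPES)


def test_planted_labels_fully_recovered(small_genome, small_annotations):
    _, _, _, truth = small_genome
    annotations, _ = small_annotations
    ann_of = {a.gene_id: a for a in annotations}
    for gene_id, expected in truth.expected_annotation.items():
        ann = ann_of[gene_id]
        assert ann.rga_class == expected["rga_class"]
        assert ann.nlr_subtype == expected["nlr_subtype"]
        assert ann.receptor_subclass == expected["receptor_subclass"]
    # non-planted genes carry no architecture and classify NONE or orphan NONE
    for ann in annotations:
        if ann.gene_id not in truth.planted_class:
            assert ann.rga_class == "NONE"
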