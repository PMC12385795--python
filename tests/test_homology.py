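import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgakit.classify import RGAAnnotation
from rgakit.homology import (
    cdrh_map,
    disease_rollup,
    filter_hits,
    non_rga_homologues,
)
from rgakit.model import AlignmentHit, AnnotationError, RGeneCatalogEntry
from rgakit.synthetic import simulate_hits


def _hit(evalue, sim, length, query="R1", subject="g1"):
    return AlignmentHit(query, subject, evalue, sim, length)


@pytest.mark.parametrize(
    "hit, kept",
    [
        (_hit(0.0, 80, 300), True),          # E-value 0: most significant end
        (_hit(1e-45, 60.0, 148), True),      # all three boundaries inclusive
        (_hit(1e-30, 90, 300), False),       # weaker than the E-value cutoff
        (_hit(1e-60, 59.9, 300), False),     # similarity below 60%
        (_hit(1e-60, 90, 147), False),       # alignment shorter than 148 aa
        (_hit(1e-60, 90, 148), True),
    ],
)
def test_filter_chain_boundaries(hit, kept):
    assert (filter_hits([hit]) == [hit]) is kept


hits_strategy = st.lists(
    st.builds(
        _hit,
        st.one_of(st.just(0.0), st.floats(1e-200, 1.0)),
        st.floats(0, 100),
        st.integers(1, 1000),
    ),
    max_size=30,
)


@settings(max_examples=100, deadline=None)
@given(
    hits_strategy,
    st.floats(1e-60, 1e-30),
    st.floats(40, 80),
    st.integers(100, 200),
)
def test_filter_monotonicity_and_order_independence(hits, e_max, sim_min, len_min):
    kept = filter_hits(hits, e_max, sim_min, len_min)
    relaxed = filter_hits(hits, e_max * 10, sim_min - 5, len_min - 10)
    tightened = filter_hits(hits, e_max / 10, sim_min + 5, len_min + 10)
    assert set(map(id, kept)) <= set(map(id, relaxed))
    assert set(map(id, tightened)) <= set(map(id, kept))
    reversed_kept = filter_hits(hits[::-1], e_max, sim_min, len_min)
    assert sorted(map(id, reversed_kept)) == sorted(map(id, kept))


def test_filter_keeps_exactly_planted_homologues(small_genome):
    _, _, _, truth = small_genome
    hits = simulate_hits(truth, n_decoys=9, seed=23)
    kept = filter_hits(hits)
    planted = {(p["query"], p["subject"]) for p in truth.homologue_pairs}
    assert {(h.query_id, h.subject_id) for h in kept} == planted
    assert len(kept) == len(truth.homologue_pairs)
    # each decoy violates exactly the named rule
    for decoy in truth.decoys:
        violations = {
            "evalue": decoy["evalue"] > 1e-45,
            "similarity": decoy["similarity"] < 60.0,
            "length": decoy["length"] < 148,
        }
        assert violations.pop(decoy["violates"])
        assert not any(violations.values())


def _annotations():
    return [
        RGAAnnotation("g1", "NLR", "TNL", "none", "typical", "NLR"),
        RGAAnnotation("g2", "RLK", "none", "LRR", "n/a", "TM-LRR"),
        RGAAnnotation("g3", "NONE", "none", "none", "n/a", "none"),
    ]


def _catalog():
    return [
        RGeneCatalogEntry("R1", frozenset({"WR"})),
        RGeneCatalogEntry("R2", frozenset({"WR"})),
        RGeneCatalogEntry("R3", frozenset({"BL"})),
    ]


def test_cdrh_aggregation_and_multiplicity():
    kept = [
        _hit(0.0, 80, 300, "R1", "g1"),
        _hit(0.0, 80, 300, "R2", "g1"),
        _hit(0.0, 80, 300, "R3", "g2"),
    ]
    records, summary = cdrh_map(kept, _annotations(), _catalog())
    assert summary.n_subjects == 2
    assert summary.n_subjects_multi_r == 1  # g1 matches R1 and R2
    assert summary.n_r_genes_with_homologues == 3
    assert summary.class_composition == {"TNL": 1, "RLK": 1}
    by_gene = {r.gene_id: r for r in records}
    assert by_gene["g1"].matched_r_genes == {"R1", "R2"}


def test_per_r_gene_count_shape():
    annotations = [
        RGAAnnotation(f"g{i}", "NLR", "TNL", "none", "typical", "NLR")
        for i in range(10)
    ]
    kept = [_hit(0.0, 80, 300, "R1", f"g{i}") for i in range(10)]
    _, summary = cdrh_map(kept, annotations, _catalog())
    assert summary.per_r_gene_counts == {"R1": 10}
    assert summary.n_r_genes_with_multiple == 1


def test_rga_and_non_rga_subjects_partition():
    kept = [
        _hit(0.0, 80, 300, "R1", "g1"),
        _hit(0.0, 80, 300, "R1", "g3"),
    ]
    cdrhs, _ = cdrh_map(kept, _annotations(), _catalog())
    non_rga, non_summary = non_rga_homologues(kept, _annotations(), _catalog())
    assert {r.gene_id for r in cdrhs} == {"g1"}
    assert {r.gene_id for r in non_rga} == {"g3"}
    assert non_summary.n_subjects == 1


def test_no_kept_hits_gives_empty_summaries():
    records, summary = cdrh_map([], _annotations(), _catalog())
    assert records == [] and summary.n_subjects == 0
    assert summary.n_r_genes_with_homologues == 0


def test_unknown_subject_or_r_gene_is_error():
    with pytest.raises(AnnotationError):
        cdrh_map([_hit(0.0, 80, 300, "R1", "gX")], _annotations(), _catalog())
    with pytest.raises(AnnotationError):
        cdrh_map([_hit(0.0, 80, 300, "RX", "g1")], _annotations(), _catalog())


def test_disease_rollup_dedup_and_union():
    kept = [
        _hit(0.0, 80, 300, "R1", "g1"),  # WR
        _hit(0.0, 80, 300, "R2", "g1"),  # WR again: dedup within disease
        _hit(0.0, 80, 300, "R3", "g2"),  # BL
    ]
    records, _ = cdrh_map(kept, _annotations(), _catalog())
    assert disease_rollup(records) == {"WR": 1, "BL": 1}

    mixed = [
        _hit(0.0, 80, 300, "R1", "g1"),  # WR
        _hit(0.0, 80, 300, "R3", "g1"),  # BL: union counts under both
    ]
    records, _ = cdrh_map(mixed, _annotations(), _catalog())
    assert disease_rollup(records) == {"WR": 1, "BL": 1}


def test_planted_rga_non_rga_split_recovered(small_genome):
    _, genes, domains, truth = small_genome
    from rgakit.classify import classify_genome

    annotations, _ = classify_genome(genes, domains)
    kept = filter_hits(simulate_hits(truth, n_decoys=0, seed=1))
    catalog = [
        RGeneCatalogEntry(q, frozenset({"BL"}))
        for q in {p["query"] for p in truth.homologue_pairs}
    ]
    cdrhs, _ = cdrh_map(kept, annotations, catalog)
    non_rga, _ = non_rga_homologues(kept, annotations, catalog)
    planted_rga = {p["subject"] for p in truth.homologue_pairs if p["subject_is_rga"]}
    planted_non = {p["subject"] for p in truth.homologue_pairs if not p["subject_is_rga"]}
    assert {r.gene_id for r in cdrhs} == planted_rga
    assert {r.gene_id for r in non_rga} == planted_non
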