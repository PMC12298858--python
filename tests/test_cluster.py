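"""Similarity-graph construction, OTU partitioning and the survey summary."""

import numpy as np
import pytest

from barcodegap.cluster import (
    OTUPartition,
    build_graph,
    components_partition,
    leiden_partition,
    read_partition,
    summarize_partition,
    write_partition,
)
from barcodegap.errors import ValidationError
from barcodegap.pairwise import PairwiseHit, all_vs_all
from barcodegap.seqio import Dataset, SequenceRecord


def hit(a, b, identity, af=1.0):
    return PairwiseHit(a, b, identity, af, 650)


def test_build_graph_rule_application():
    hits = [hit("a", "b", 99), hit("b", "c", 99), hit("a", "c", 80)]
    g = build_graph(hits, threshold=97, af_floor=0.8)
    assert set(g.nodes) == {"a", "b", "c"}
    assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("bc")}


def test_build_graph_coverage_gate_and_isolates():
    g = build_graph([hit("a", "b", 99, af=0.5)], 97, 0.8, all_ids=["a", "b", "c", "d"])
    assert g.number_of_edges() == 0
    assert set(g.nodes) == {"a", "b", "c", "d"}


def test_build_graph_inclusive_vs_strict():
    hits = [hit("a", "b", 97.0)]
    assert build_graph(hits, 97, 0.8).number_of_edges() == 1
    assert build_graph(hits, 97, 0.8, inclusive=False).number_of_edges() == 0


def test_leiden_partition_triangle_plus_isolate():
    hits = [hit("a", "b", 99), hit("b", "c", 99), hit("a", "c", 99)]
    g = build_graph(hits, 97, 0.8, all_ids=["a", "b", "c", "d"])
    part = leiden_partition(g, seed=0)
    assert part.otu_of("a") == part.otu_of("b") == part.otu_of("c") == "a"
    assert part.otu_of("d") == "d"
    assert part.n_otus == 2
    assert part.singletons() == ["d"]


def test_permutation_invariance_of_memberships(rng):
    ids = [f"s{i:02d}" for i in range(12)]
    hits = []
    for i in range(0, 12, 3):  # four triangles
        trio = ids[i : i + 3]
        hits += [hit(trio[0], trio[1], 99), hit(trio[1], trio[2], 99), hit(trio[0], trio[2], 99)]
    base = leiden_partition(build_graph(hits, 97, 0.8, all_ids=ids), seed=5)
    shuffled_hits = [hits[i] for i in rng.permutation(len(hits))]
    shuffled_ids = [ids[i] for i in rng.permutation(len(ids))]
    other = leiden_partition(build_graph(shuffled_hits, 97, 0.8, all_ids=shuffled_ids), seed=5)
    assert base.membership == other.membership


def test_threshold_monotonicity(rng):
    ids = [f"s{i}" for i in range(10)]
    hits = [
        hit(ids[i], ids[j], float(rng.uniform(90, 100)))
        for i in range(10)
        for j in range(i + 1, 10)
    ]
    counts = []
    for thr in (92, 95, 97, 99, 100):
        part = leiden_partition(build_graph(hits, thr, 0.8, all_ids=ids), seed=1)
        counts.append(part.n_otus)
    assert counts == sorted(counts)


def test_leiden_at_least_as_many_communities_as_components(rng):
    ids = [f"s{i}" for i in range(15)]
    hits = [
        hit(ids[i], ids[j], float(rng.uniform(96.5, 100)))
        for i in range(15)
        for j in range(i + 1, 15)
        if rng.random() < 0.3
    ]
    g = build_graph(hits, 97, 0.8, all_ids=ids)
    assert leiden_partition(g, seed=2).n_otus >= components_partition(g).n_otus


def _toy_dataset():
    return Dataset(
        [
            SequenceRecord("f1", "ACGT", "field", genus="Clavulinopsis"),
            SequenceRecord("f2", "ACGT", "field", genus="Clavulinopsis"),
            SequenceRecord("f3", "ACGT", "field", genus="Clavulinopsis"),
            SequenceRecord(
                "r1", "ACGT", "reference", species_name="X", genus="Clavulinopsis"
            ),
        ]
    )


def test_summarize_partition_single_genus_toy():
    ds = _toy_dataset()
    part = OTUPartition(membership={"f1": "f1", "f2": "f1", "r1": "f1", "f3": "f3"})
    table = summarize_partition(part, ds)
    row = table[table.genus == "Clavulinopsis"].iloc[0]
    assert row.n_field_otus == 2
    assert row.n_field_otus_matched == 1
    assert row.matched_percent == pytest.approx(50.0)
    assert row.n_ref_species == 1
    total = table[table.genus == "Total"].iloc[0]
    assert total.n_field_seqs == 3 and total.n_reference_seqs == 1


def test_summarize_partition_without_references():
    ds = Dataset(
        [
            SequenceRecord("f1", "ACGT", "field", genus="G"),
            SequenceRecord("f2", "AAAA", "field", genus="G"),
        ]
    )
    part = OTUPartition(membership={"f1": "f1", "f2": "f2"})
    table = summarize_partition(part, ds)
    assert (table.n_field_otus_matched == 0).all()


def test_summarize_requires_full_coverage():
    ds = _toy_dataset()
    part = OTUPartition(membership={"f1": "f1"})
    with pytest.raises(ValidationError, match="cover"):
        summarize_partition(part, ds)


def test_partition_tsv_round_trip(tmp_path):
    ds = _toy_dataset()
    part = OTUPartition(membership={"f1": "f1", "f2": "f1", "f3": "f3", "r1": "f1"})
    path = tmp_path / "partition.tsv"
    write_partition(part, ds, path)
    back = read_partition(path)
    assert back.membership == part.membership


def test_pipeline_regime_partition_equals_components(rng):
    """In the clean-gap regime the Leiden partition is exactly the
    connected-components partition (same members, same labels)."""
    base = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 400)
    records = []
    for s in range(4):  # four species, three specimens each, ~1% apart
        rep = base.copy()
        idx = rng.choice(400, 60, replace=False)
        rep[idx] = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 60)
        for k in range(3):
            m = rep.copy()
            idx = rng.choice(400, 4, replace=False)
            m[idx] = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 4)
            records.append(
                SequenceRecord(f"s{s}_{k}", m.tobytes().decode(), "field")
            )
    ds = Dataset(records)
    hits = all_vs_all(ds, coverage_floor=0.7)
    g = build_graph(hits, 97.0, 0.8, all_ids=ds.ids)
    assert leiden_partition(g, seed=9).membership == components_partition(g).membership
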