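"""The synthetic community generator: trees, sequence evolution, sampling."""

import json

import dendropy
import numpy as np
import pytest

from barcodegap.errors import ConfigError
from barcodegap.simulate import (
    CommunityConfig,
    _jc_d,
    _mutate,
    evolve_sequences,
    generate_community,
    simulate_species_tree,
    write_community,
)


def test_config_invariants_enforced():
    with pytest.raises(ConfigError, match="gap"):
        CommunityConfig(intraspecific_ceiling=0.1, interspecific_floor=0.08)
    with pytest.raises(ConfigError):
        CommunityConfig(n_species=1)
    with pytest.raises(ConfigError):
        CommunityConfig(ref_mislabel_rate=1.5)
    with pytest.raises(ConfigError):
        CommunityConfig(n_surveys=0)


def test_yule_tree_two_species_is_a_cherry():
    tree = simulate_species_tree(2, seed=1)
    leaves = list(tree.leaf_node_iter())
    assert len(leaves) == 2
    assert all(lf.edge.length > 0 for lf in leaves)


def test_yule_tree_binary_and_deterministic():
    t1 = simulate_species_tree(50, seed=8)
    t2 = simulate_species_tree(50, seed=8)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    internals = sum(1 for n in t1.preorder_node_iter() if not n.is_leaf())
    assert internals == 49  # binary tree with 50 leaves
    # ultrametric: all leaves equidistant from the root
    t1.calc_node_root_distances()
    depths = [lf.root_distance for lf in t1.leaf_node_iter()]
    assert max(depths) - min(depths) < 1e-9


def test_zero_length_branches_give_identical_sequences():
    tree = dendropy.Tree.get(data="(sp001:0,sp002:0);", schema="newick")
    cfg = CommunityConfig(n_species=2, seed=0)
    seqs = evolve_sequences(tree, cfg, rng=np.random.default_rng(0))
    assert seqs["sp001"] == seqs["sp002"]


def test_interspecific_floor_holds_with_near_certainty():
    """Two-species divergence clears the floor in >= 99% of seeds (the
    rescaling margin makes the binomial tail negligible at L=650)."""
    ok = 0
    n_seeds = 200
    for seed in range(n_seeds):
        cfg = CommunityConfig(n_species=2, seed=seed)
        tree = simulate_species_tree(2, seed=seed)
        seqs = evolve_sequences(tree, cfg, rng=np.random.default_rng(seed))
        a, b = (np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs.values())
        ok += float(np.mean(a != b)) >= cfg.interspecific_floor
    assert ok >= 0.99 * n_seeds


def test_branch_substitution_count_matches_binomial_mean():
    """A branch with expected site-difference 0.05 yields ~32.5 changed
    sites on a 650-mer (binomial mean oracle: 650 * 0.05)."""
    base = np.frombuffer(("ACGT" * 163)[:650].encode(), dtype=np.uint8)
    diffs = [
        int(np.sum(_mutate(base, 0.05, np.random.default_rng(s)) != base))
        for s in range(300)
    ]
    assert np.mean(diffs) == pytest.approx(32.5, abs=1.5)
    assert _jc_d(0.05) > 0.05  # JC correction inflates the branch length


def test_detection_limits():
    cfg_all = CommunityConfig(seed=1, detect_scale=50.0)
    _, inc, _, _ = generate_community(cfg_all)
    assert inc.s_obs == cfg_all.n_species
    assert (inc.matrix.values == 1).all()  # detected in every survey

    cfg_none = CommunityConfig(seed=1, detect_scale=1e-9)
    with pytest.warns(UserWarning, match="no species detected"):
        ds, inc, _, _ = generate_community(cfg_none)
    assert sum(1 for r in ds if r.source == "field") == 0


def test_singleton_heavy_incidence():
    """Geometric abundances with sparse detection make single-survey species
    common — the incomplete-sampling signature driving Chao2 upward."""
    fracs = []
    for seed in range(12):
        cfg = CommunityConfig(n_species=20, n_surveys=10, abundance_param=0.5, seed=seed)
        _, inc, _, _ = generate_community(cfg)
        freq = inc.matrix.sum(axis=1)
        fracs.append(float((freq == 1).sum()) / cfg.n_species)
    assert np.mean(fracs) >= 0.1
    assert max(fracs) >= 0.2


def test_truth_object_consistency():
    ds, inc, truth, _ = generate_community(CommunityConfig(seed=4))
    assert set(truth.species_of) == set(ds.ids)
    assert truth.n_species == 12
    for rid, entry in truth.mislabeled.items():
        assert entry["true_name"] != entry["assigned_name"]
        assert ds[rid].species_name == entry["assigned_name"]
    # mislabel volume matches the configured rate
    n_refs = sum(1 for r in ds if r.source == "reference")
    assert len(truth.mislabeled) == round(0.2 * n_refs)


def test_mislabels_are_swaps_between_distinct_species():
    _, _, truth, _ = generate_community(CommunityConfig(seed=6))
    names = [v["assigned_name"] for v in truth.mislabeled.values()]
    true_names = [v["true_name"] for v in truth.mislabeled.values()]
    assert sorted(names) == sorted(true_names)  # names conserved, just moved


def test_log_series_abundance_model_runs():
    ds, inc, truth, _ = generate_community(
        CommunityConfig(seed=2, abundance_model="log_series", abundance_param=0.8)
    )
    assert all(a >= 1 for a in truth.abundance.values())


def test_gap_property_of_generated_identities():
    """Pooled pairwise identities leave the configured gap band empty."""
    from barcodegap.pairwise import all_vs_all

    cfg = CommunityConfig(seed=0)
    ds, _, _, _ = generate_community(cfg)
    hits = all_vs_all(ds, coverage_floor=0.0)
    # epsilon of 2 points absorbs binomial sampling noise at L=650
    band_lo = 100.0 * (1 - cfg.interspecific_floor) + 2.0
    band_hi = 100.0 * (1 - cfg.intraspecific_ceiling) - 2.0
    inside = [h.identity for h in hits if band_lo < h.identity < band_hi]
    assert inside == []


def test_write_community_byte_identical_reruns(tmp_path):
    cfg = CommunityConfig(seed=9)
    p1 = write_community(cfg, tmp_path / "a")
    p2 = write_community(cfg, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_write_community_files_parse_back(tmp_path):
    from barcodegap.seqio import read_fasta
    from barcodegap.richness import IncidenceTable

    paths = write_community(CommunityConfig(seed=3), tmp_path)
    field = read_fasta(paths["field_fasta"], "field", paths["field_annotations"])
    refs = read_fasta(paths["reference_fasta"], "reference", paths["reference_annotations"])
    assert all(r.sampling_unit for r in field)
    assert all(r.species_name for r in refs)
    inc = IncidenceTable.read_tsv(paths["incidence"])
    assert inc.T == 8
    truth = json.loads(paths["truth"].read_text())
    assert truth["n_species"] == 12
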