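"""Shared fixtures: small record sets and the session-wide simulation study.

The simulation study runs the generator -> pairwise -> gap -> cluster ->
misannotation chain over many seeds once per session; the threshold-recovery,
partition-recovery and mislabel-recovery tests all read from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from barcodegap.cluster import (
    build_graph,
    components_partition,
    leiden_partition,
)
from barcodegap.gap import detect_gap
from barcodegap.errors import GapNotFoundError
from barcodegap.pairwise import all_vs_all
from barcodegap.seqio import Dataset, SequenceRecord
from barcodegap.simulate import CommunityConfig, generate_community

N_STUDY_SEEDS = 100


def make_records(seqs: dict[str, str], source: str = "field", **kwargs) -> Dataset:
    return Dataset(
        SequenceRecord(id=k, sequence=v, source=source, **kwargs)
        for k, v in seqs.items()
    )


def adjusted_rand_index(a: list, b: list) -> float:
    """Adjusted Rand index between two labelings (comb-based, no sklearn)."""
    from math import comb

    assert len(a) == len(b)
    pairs = {}
    ca, cb = {}, {}
    for x, y in zip(a, b):
        pairs[(x, y)] = pairs.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    n = len(a)
    sum_ij = sum(comb(v, 2) for v in pairs.values())
    sum_a = sum(comb(v, 2) for v in ca.values())
    sum_b = sum(comb(v, 2) for v in cb.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


@dataclass
class SeedResult:
    seed: int
    n_records: int
    gap_interval: tuple | None
    threshold: float | None
    ari: float
    leiden_equals_components: bool
    n_otus: int
    planted_mislabels: set
    recovered_mislabels: set
    truth_band: tuple


def _run_one_seed(seed: int) -> SeedResult:
    from barcodegap.taxonomy import misannotation_scan

    cfg = CommunityConfig(seed=seed)
    dataset, _, truth, _ = generate_community(cfg)
    hits = all_vs_all(dataset, coverage_floor=0.0)
    kept = [h for h in hits if h.aligned_fraction > 0.7]
    gap_interval = threshold = None
    try:
        report = detect_gap([h.identity for h in kept])
        gap_interval, threshold = report.gap_interval, report.threshold
    except GapNotFoundError:
        pass
    thr = threshold if threshold is not None else 97.0
    graph = build_graph(kept, thr, af_floor=0.8, all_ids=dataset.ids)
    partition = leiden_partition(graph, seed=seed)
    components = components_partition(graph)
    ari = adjusted_rand_index(
        [truth.species_of[r] for r in dataset.ids],
        [partition.otu_of(r) for r in dataset.ids],
    )
    scan = misannotation_scan(partition, dataset)
    planted = {v["assigned_name"] for v in truth.mislabeled.values()}
    recovered = planted & set(scan.multi_otu_names)
    band = (
        100.0 * (1.0 - cfg.interspecific_floor),
        100.0 * (1.0 - cfg.intraspecific_ceiling),
    )
    return SeedResult(
        seed=seed,
        n_records=len(dataset),
        gap_interval=gap_interval,
        threshold=threshold,
        ari=ari,
        leiden_equals_components=partition.membership == components.membership,
        n_otus=partition.n_otus,
        planted_mislabels=planted,
        recovered_mislabels=recovered,
        truth_band=band,
    )


@pytest.fixture(scope="session")
def simulation_study() -> list[SeedResult]:
    """Default-community recovery study over many independent seeds."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [_run_one_seed(seed) for seed in range(N_STUDY_SEEDS)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
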