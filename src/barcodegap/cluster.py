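"""Similarity-graph construction and OTU partitioning.

Sequences become nodes; pairs whose identity and aligned fraction both meet
the derived thresholds become edges. At a 97%-identity threshold the graph
is close to a disjoint union of cliques, so the Leiden/CPM partition
typically coincides with the connected components; Leiden earns its keep on
ambiguous bridged clusters, where determinism under a seed is the contract.

CPM resolution is interpreted on the percent-identity scale (the convention
of similarity-clustering tools fed with BLAST-style percent identities), so
the stored fractional edge weights are scaled by 100 inside
:func:`leiden_partition`; at the conventional resolution of 1.0 a clique of
>=97%-identity sequences is never split.

OTU labels are canonicalised to the lexicographically smallest member id, so
partitions are stable under any reordering of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .leiden import leiden_cpm
from .pairwise import PairwiseHit
from .seqio import Dataset


def build_graph(
    hits: Iterable[PairwiseHit],
    threshold: float,
    af_floor: float = 0.8,
    all_ids: Optional[Sequence[str]] = None,
    inclusive: bool = True,
) -> nx.Graph:
    """Similarity graph: edges where identity and coverage meet the cutoffs.

    ``inclusive`` keeps pairs at exactly the threshold (identity >= t);
    strict mode (identity > t) is exposed because ">97%" and "minimum 97%"
    both appear as conventions in the field. Edge weights are identity/100.
    Every id in ``all_ids`` is a node even if isolated.
    """
    if not (0 < threshold <= 100):
        raise ValidationError(f"threshold {threshold} outside (0, 100]")
    if not (0 < af_floor <= 1):
        raise ValidationError(f"af_floor {af_floor} outside (0, 1]")
    g = nx.Graph()
    if all_ids is not None:
        g.add_nodes_from(all_ids)
    for h in hits:
        g.add_nodes_from([h.id_a, h.id_b])
        if h.id_a == h.id_b:
            continue
        ok = h.identity >= threshold if inclusive else h.identity > threshold
        if ok and h.aligned_fraction >= af_floor:
            g.add_edge(h.id_a, h.id_b, weight=h.identity / 100.0)
    return g


@dataclass
class OTUPartition:
    """Assignment of record ids to OTUs with per-OTU provenance summaries."""

    membership: dict[str, str]  # record id -> otu id
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members: dict[str, list[str]] = {}
        for rid, otu in self.membership.items():
            self.members.setdefault(otu, []).append(rid)
        for otu in self.members:
            self.members[otu].sort()

    @property
    def n_otus(self) -> int:
        return len(self.members)

    def otu_of(self, rec_id: str) -> str:
        return self.membership[rec_id]

    def singletons(self) -> list[str]:
        return [otu for otu, mem in self.members.items() if len(mem) == 1]

    def composition(self, dataset: Dataset) -> pd.DataFrame:
        """Per-OTU member counts by source plus the reference-name multiset."""
        rows = []
        for otu in sorted(self.members):
            mem = self.members[otu]
            n_field = sum(1 for rid in mem if dataset[rid].source == "field")
            names = sorted(
                dataset[rid].species_name
                for rid in mem
                if dataset[rid].source == "reference" and dataset[rid].species_name
            )
            rows.append(
                {
                    "otu_id": otu,
                    "n_members": len(mem),
                    "n_field": n_field,
                    "n_reference": len(mem) - n_field,
                    "reference_names": ";".join(names),
                }
            )
        return pd.DataFrame(rows)


def _canonical_partition(groups: Iterable[Iterable[str]], params: dict) -> OTUPartition:
    membership = {}
    for group in groups:
        group = sorted(group)
        label = group[0]
        for rid in group:
            membership[rid] = label
    return OTUPartition(membership=membership, params=params)


def leiden_partition(
    graph: nx.Graph,
    resolution: float = 1.0,
    beta: float = 0.01,
    iterations: int = 10,
    seed: int = 0,
) -> OTUPartition:
    """Partition the similarity graph into OTUs by Leiden/CPM.

    ``resolution`` is on the percent-identity scale (see module docstring);
    ``beta`` is the refinement exploration parameter. Deterministic under
    ``seed``; OTU ids are the lexicographically smallest member ids.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return OTUPartition(membership={})
    index = {rid: i for i, rid in enumerate(nodes)}
    edges = [
        (index[u], index[v], 100.0 * data.get("weight", 1.0))
        for u, v, data in graph.edges(data=True)
    ]
    memb = leiden_cpm(
        len(nodes),
        edges,
        gamma=resolution,
        theta=beta,
        n_iterations=iterations,
        seed=seed,
    )
    groups: dict[int, list[str]] = {}
    for rid, i in index.items():
        groups.setdefault(memb[i], []).append(rid)
    params = {
        "resolution": resolution,
        "beta": beta,
        "iterations": iterations,
        "seed": seed,
    }
    return _canonical_partition(groups.values(), params)


def components_partition(graph: nx.Graph) -> OTUPartition:
    """Connected-components partition (the clean-gap reference behaviour)."""
    return _canonical_partition(
        nx.connected_components(graph), params={"method": "components"}
    )


def summarize_partition(partition: OTUPartition, dataset: Dataset) -> pd.DataFrame:
    """Per-genus (and overall) summary of sequences, OTUs and name matches.

    Columns mirror the canonical survey summary: sequence counts by source,
    number of OTUs containing at least one field sequence, how many of those
    contain a named reference (matched), the number of distinct named species
    among references, and how many of those names are split across >1 OTU.
    """
    missing = [rid for rid in dataset.ids if rid not in partition.membership]
    if missing:
        raise ValidationError(f"partition does not cover ids: {missing[:5]} ...")
    genera = sorted({r.genus or "" for r in dataset})
    rows = []
    for genus in genera + ["__total__"]:
        if genus == "__total__":
            recs = list(dataset)
        else:
            recs = [r for r in dataset if (r.genus or "") == genus]
        ids = {r.id for r in recs}
        n_field_seq = sum(1 for r in recs if r.source == "field")
        n_ref_seq = len(recs) - n_field_seq
        otus = {partition.otu_of(r.id) for r in recs}
        field_otus = {
            otu
            for otu in otus
            if any(
                dataset[rid].source == "field" and rid in ids
                for rid in partition.members[otu]
            )
        }
        named_by_otu: dict[str, set[str]] = {}
        for otu in otus:
            names = {
                dataset[rid].species_name
                for rid in partition.members[otu]
                if dataset[rid].source == "reference" and dataset[rid].species_name
            }
            if names:
                named_by_otu[otu] = names
        matched = sum(1 for otu in field_otus if otu in named_by_otu)
        ref_names = {
            r.species_name
            for r in recs
            if r.source == "reference" and r.species_name
        }
        multi_otu_names = 0
        for name in ref_names:
            otus_with = {
                partition.otu_of(r.id)
                for r in dataset
                if r.source == "reference" and r.species_name == name
            }
            if len(otus_with) > 1:
                multi_otu_names += 1
        rows.append(
            {
                "genus": "Total" if genus == "__total__" else (genus or "(none)"),
                "n_field_seqs": n_field_seq,
                "n_reference_seqs": n_ref_seq,
                "n_otus": len(otus),
                "n_field_otus": len(field_otus),
                "n_field_otus_matched": matched,
                "matched_percent": round(100.0 * matched / len(field_otus), 2)
                if field_otus
                else 0.0,
                "n_ref_species": len(ref_names),
                "n_ref_species_multi_otu": multi_otu_names,
            }
        )
    return pd.DataFrame(rows)


def write_partition(
    partition: OTUPartition, dataset: Dataset, path: str | Path
) -> None:
    rows = [
        {
            "id": rid,
            "otu_id": partition.otu_of(rid),
            "source": dataset[rid].source,
            "species_name": dataset[rid].species_name or "",
        }
        for rid in dataset.ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> OTUPartition:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return OTUPartition(
        membership={r.id: r.otu_id for r in frame.itertuples(index=False)}
    )
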