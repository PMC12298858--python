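"""Trees, cophenetic (patristic) distances, and a neighbor-joining fallback.

The gap analysis correlates pairwise identity with evolutionary distance on
a phylogeny. When an externally inferred tree is supplied (Newick) it is
used as-is; otherwise a neighbor-joining tree is built from the identity
matrix as a stand-in. NJ changes the absolute distance scale relative to a
likelihood tree, but the correlation analysis consumes only the (approximately
affine) relationship between identity and path distance, so r-squared is
robust to that choice.

Trees are dendropy objects throughout; distances travel as labelled pandas
DataFrames (square, symmetric).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .pairwise import PairwiseHit

Tree = dendropy.Tree


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a tree, with leaf-label validation."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValidationError(f"Newick parse error: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def read_newick(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def cophenetic_matrix(tree: Tree) -> pd.DataFrame:
    """Patristic distance between every leaf pair (sum of path branch lengths)."""
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    if len(taxa) < 2:
        raise ValidationError("cophenetic matrix needs >= 2 leaves")
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def neighbor_joining(distances: pd.DataFrame) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou–Nei agglomeration with the Q-matrix criterion; ties in
    the Q minimum are broken toward the lexicographically smallest leaf-label
    pair, so the result is fully deterministic and independent of input row
    order. For an additive input matrix the output tree's cophenetic matrix
    reproduces the input exactly (the classic NJ consistency guarantee).
    Branch lengths may be negative on non-additive input, as usual for NJ.
    """
    d = distances.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValidationError("NJ needs a square matrix with n >= 3")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("NJ input matrix is not symmetric")
    if list(distances.index) != list(distances.columns):
        raise ValidationError("row and column labels differ")
    labels = [str(x) for x in distances.index]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in distance matrix")

    tree = dendropy.Tree()
    tns = tree.taxon_namespace
    nodes = [dendropy.Node(taxon=tns.new_taxon(label=lab)) for lab in labels]
    # each active cluster is tagged with its smallest leaf label for tie-breaks
    tags = list(labels)
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((tags[active[a]], tags[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        a, b = best[1], best[2]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (n - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new internal node to every other cluster
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        k = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, active] = new_d
        d[active, k] = new_d
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    root = dendropy.Node()
    for idx in (i, j):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = d[i, j] / 2.0
    tree.seed_node = root
    return tree


def identity_to_distance(identity_percent: float, jukes_cantor: bool = False) -> float:
    """Map percent identity to a distance: p-distance, optionally JC-corrected."""
    p = 1.0 - identity_percent / 100.0
    if not jukes_cantor:
        return p
    if p >= 0.75:
        raise ValidationError(f"p-distance {p} saturates the JC correction")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def distance_matrix_from_hits(
    hits: Sequence[PairwiseHit],
    ids: Sequence[str],
    jukes_cantor: bool = False,
    missing_distance: float | None = None,
) -> pd.DataFrame:
    """Square distance matrix over ``ids`` from pairwise identities.

    Pairs without a hit (e.g. removed by a coverage filter) get
    ``missing_distance``; by default that is the matrix's largest observed
    distance, a conservative "at least this far" placeholder.
    """
    ids = list(ids)
    index = {rid: k for k, rid in enumerate(ids)}
    n = len(ids)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for h in hits:
        if h.id_a in index and h.id_b in index:
            v = identity_to_distance(h.identity, jukes_cantor)
            i, j = index[h.id_a], index[h.id_b]
            d[i, j] = d[j, i] = v
    if np.isnan(d).any():
        fill = missing_distance
        if fill is None:
            fill = float(np.nanmax(d))
        d = np.where(np.isnan(d), fill, d)
    return pd.DataFrame(d, index=ids, columns=ids)


def write_distance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
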