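"""Synthetic barcode communities with the structure the analysis assumes.

The generator produces everything the pipeline consumes — specimen and
reference FASTA, annotations, survey incidence — plus a ground-truth object
for recovery tests. Its statistical targets mirror a real barcoding survey:

* a bimodal pairwise-identity distribution with a clear barcode gap,
  created by keeping within-species divergence below
  ``intraspecific_ceiling`` and between-species divergence above
  ``interspecific_floor``;
* singleton-heavy OTU abundances (many species detected in one survey);
* multi-survey incidence sampling with abundance-dependent detection;
* a partially mislabeled reference set (name swaps between species),
  reproducing the multi-OTU-per-name signature of public databases.

Species relationships come from a Yule (pure-birth) tree; sequences evolve
by Jukes–Cantor substitution along its branches (no indels by default, so
identity arithmetic stays analytically checkable), and within-species
variation is star-shaped around each species representative. Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from math import exp, log
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigError
from .richness import IncidenceTable
from .seqio import Dataset, SequenceRecord, write_annotations, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunityConfig:
    """Knobs of the synthetic community; defaults define the study regime.

    ``interspecific_floor`` / ``intraspecific_ceiling`` bound between- and
    within-species divergence; their separation is what creates the barcode
    gap. ``divergence_margin`` oversizes the between-species rescaling
    target so the floor holds with near-certainty at finite sequence length
    (binomial sampling would otherwise put ~half of seeds below an
    expected-value target). Detection per survey is
    1 - exp(-detect_scale * abundance), so rare species are detected
    sporadically — the singleton-heavy regime of real surveys.
    """

    n_species: int = 12
    seq_length: int = 650
    birth_rate: float = 1.0
    interspecific_floor: float = 0.08
    intraspecific_ceiling: float = 0.015
    divergence_margin: float = 1.5
    abundance_model: str = "geometric"  # or "log_series"
    abundance_param: float = 0.5
    interspecific_depth_cap: float = 0.30
    n_surveys: int = 8
    detect_scale: float = 0.25
    ref_named_fraction: float = 0.8
    ref_mislabel_rate: float = 0.20
    n_refs_per_species: int = 2
    genus: str = "Simulina"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if not (0 <= self.ref_mislabel_rate <= 1):
            raise ConfigError("ref_mislabel_rate must be in [0, 1]")
        if not (0 <= self.ref_named_fraction <= 1):
            raise ConfigError("ref_named_fraction must be in [0, 1]")
        if self.intraspecific_ceiling >= self.interspecific_floor:
            raise ConfigError(
                "intraspecific_ceiling must be < interspecific_floor "
                "(this inequality is what creates the barcode gap)"
            )
        if self.n_surveys < 1:
            raise ConfigError("n_surveys must be >= 1")
        if self.abundance_model not in ("geometric", "log_series"):
            raise ConfigError(f"unknown abundance model {self.abundance_model!r}")
        if self.detect_scale <= 0:
            raise ConfigError("detect_scale must be positive")
        if self.interspecific_floor * self.divergence_margin >= 0.75:
            raise ConfigError("divergence target saturates Jukes-Cantor")
        if self.interspecific_depth_cap < self.interspecific_floor:
            raise ConfigError("depth cap below the interspecific floor")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    species_of: dict[str, str]  # record id -> true species label
    n_species: int
    species_names: dict[str, str]  # species label -> binomial name
    incidence_probability: dict[str, float]  # per-survey detection probability
    abundance: dict[str, int]
    mislabeled: dict[str, dict[str, str]]  # ref id -> {true_name, assigned_name}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_species_tree(
    n_species: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Ultrametric Yule tree with ``n_species`` leaves, deterministic per seed.

    A pure-birth process: with k lineages the waiting time to the next
    speciation is Exp(k * birth_rate) and a uniformly chosen lineage splits.
    After the n-th lineage appears the process runs one further Exp(n * rate)
    interval to the present, so terminal branches are almost surely positive
    (a stop-at-the-event construction would leave the youngest cherry with
    zero-length tips and no within-pair divergence to rescale).
    """
    if n_species < 2:
        raise ConfigError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ConfigError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(0, k)))
        node.edge.length = t - birth[id(node)] if node is not root else None
        for _ in range(2):
            child = node.new_child()
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (n_species * birth_rate))
    tns = tree.taxon_namespace
    for i, leaf in enumerate(active):
        leaf.edge.length = t - birth[id(leaf)]
        leaf.taxon = tns.new_taxon(label=f"sp{i + 1:03d}")
    return tree


def _jc_p(d: float) -> float:
    """Expected proportion of differing sites after branch length d (JC)."""
    return 0.75 * (1.0 - exp(-4.0 * d / 3.0))


def _jc_d(p: float) -> float:
    """Branch length giving expected site-difference proportion p (JC inverse)."""
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def _min_leaf_pair_distance(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    return min(
        pdm.patristic_distance(taxa[i], taxa[j])
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    )


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, uniformly to another base."""
    out = seq.copy()
    hit = rng.random(seq.size) < p
    idx = np.nonzero(hit)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        cur = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(cur + shift) % 4]
    return out


def _rescale_to_band(tree: dendropy.Tree, p_min: float, p_max: float) -> dendropy.Tree:
    """Rescale branch lengths so leaf-pair divergences span [p_min, p_max].

    Node *heights* (distance above the tips of an ultrametric tree) are
    mapped piecewise-linearly so the shallowest species pair sits at an
    expected site-difference of p_min and the deepest at p_max. Keeping the
    divergences in a band mirrors real congeneric barcode data, where
    between-species distances rarely exceed ~25-30%; an unconstrained deep
    tree would saturate the substitution process. Non-ultrametric input
    falls back to a single linear scale anchored at the shallowest pair.
    """
    tree = tree.clone(depth=1)
    root = tree.seed_node
    dists = tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaf_depths = [lf.root_distance for lf in tree.leaf_node_iter()]
    depth = max(leaf_depths)
    ultrametric = (depth - min(leaf_depths)) <= 1e-9 * max(depth, 1.0)
    d_min = _min_leaf_pair_distance(tree)
    t_lo = _jc_d(p_min) / 2.0
    if d_min <= 0.0:
        if depth <= 0.0:
            return tree  # fully degenerate tree: identical species, no rescale
        raise ConfigError(
            "tree has a zero-distance leaf pair; species cannot be separated"
        )
    if not ultrametric or d_min >= 2.0 * depth - 1e-12 or p_max <= p_min:
        scale = 2.0 * t_lo / d_min
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        return tree
    t_hi = _jc_d(p_max) / 2.0
    h_lo, h_hi = d_min / 2.0, depth  # shallowest cherry and root heights
    slope = (t_hi - t_lo) / (h_hi - h_lo)

    def remap(h: float) -> float:
        if h <= h_lo:
            return h * t_lo / h_lo
        return t_lo + (h - h_lo) * slope

    for node in tree.preorder_node_iter():
        node._height = remap(depth - node.root_distance)
    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length = node.parent_node._height - node._height
    return tree


def evolve_sequences(
    tree: dendropy.Tree, config: CommunityConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, str]:
    """One representative sequence per species by JC evolution along the tree.

    Branch lengths are first rescaled so the shallowest species pair carries
    an expected site-difference of ``interspecific_floor * divergence_margin``
    (every between-species divergence then clears the floor with near
    certainty at the configured sequence length) and the deepest pair one of
    ``interspecific_depth_cap``. Mutation along each branch applies the
    exact Jukes-Cantor transition, so expected leaf-pair differences equal
    the JC expectation of the path length.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != config.n_species:
        raise ConfigError(
            f"tree has {len(leaves)} leaves, config says {config.n_species}"
        )
    p_min = config.interspecific_floor * config.divergence_margin
    p_max = max(p_min, config.interspecific_depth_cap)
    tree = _rescale_to_band(tree, p_min, p_max)

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = _BASES[rng.integers(0, 4, size=config.seq_length)]
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            parent_seq = seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            seqs[id(node)] = _mutate(parent_seq, _jc_p(b), rng)
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)].tobytes().decode("ascii")
    return out


def _draw_abundances(config: CommunityConfig, rng: np.random.Generator) -> np.ndarray:
    if config.abundance_model == "geometric":
        return rng.geometric(config.abundance_param, size=config.n_species)
    return rng.logseries(config.abundance_param, size=config.n_species)


def sample_specimens(
    species_seqs: dict[str, str],
    config: CommunityConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Dataset, IncidenceTable, SyntheticTruth]:
    """Survey the community: specimens, true incidence, references, truth.

    Per species an abundance is drawn; in each of the T surveys the species
    is detected with probability 1 - exp(-detect_scale * abundance), and
    every detection yields one specimen record mutated from the species
    representative at a per-specimen rate drawn uniformly below
    ``intraspecific_ceiling``. A ``ref_named_fraction`` share of species get
    ``n_refs_per_species`` named reference accessions each;
    ``ref_mislabel_rate`` of those accessions have their names swapped
    pairwise between species.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    species = sorted(species_seqs)
    reps = {sp: np.frombuffer(species_seqs[sp].encode(), dtype=np.uint8) for sp in species}
    names = {sp: f"{config.genus} {sp}" for sp in species}
    abundances = _draw_abundances(config, rng)
    p_detect = {
        sp: 1.0 - exp(-config.detect_scale * int(a))
        for sp, a in zip(species, abundances)
    }

    records: list[SequenceRecord] = []
    species_of: dict[str, str] = {}
    detections: list[tuple[str, str]] = []
    units = [f"survey{u + 1:02d}" for u in range(config.n_surveys)]
    idx = 0
    for sp in species:
        for unit in units:
            if rng.random() < p_detect[sp]:
                idx += 1
                rid = f"F{idx:04d}"
                rate = rng.uniform(0.0, config.intraspecific_ceiling / 2.0)
                seq = _mutate(reps[sp], rate, rng).tobytes().decode("ascii")
                records.append(
                    SequenceRecord(
                        id=rid,
                        sequence=seq,
                        source="field",
                        genus=config.genus,
                        sampling_unit=unit,
                    )
                )
                species_of[rid] = sp
                detections.append((sp, unit))

    if not detections:
        warnings.warn("no species detected in any survey", stacklevel=2)

    # named reference accessions for a subset of species
    n_named = int(round(config.ref_named_fraction * config.n_species))
    named_species = [
        species[i] for i in sorted(rng.choice(config.n_species, n_named, replace=False))
    ]
    ref_ids: list[str] = []
    ref_true_name: dict[str, str] = {}
    ref_seq: dict[str, str] = {}
    ridx = 0
    for sp in named_species:
        for _ in range(config.n_refs_per_species):
            ridx += 1
            rid = f"R{ridx:04d}"
            rate = rng.uniform(0.0, config.intraspecific_ceiling / 2.0)
            ref_seq[rid] = _mutate(reps[sp], rate, rng).tobytes().decode("ascii")
            ref_ids.append(rid)
            ref_true_name[rid] = names[sp]
            species_of[rid] = sp

    # mislabeling: pairwise name swaps between accessions of distinct species
    assigned = dict(ref_true_name)
    mislabeled: dict[str, dict[str, str]] = {}
    n_swap_targets = int(round(config.ref_mislabel_rate * len(ref_ids)))
    pool = list(ref_ids)
    swapped: set[str] = set()
    order = [pool[i] for i in rng.permutation(len(pool))]
    for rid in order:
        if len(swapped) >= n_swap_targets:
            break
        if rid in swapped:
            continue
        partners = [
            o
            for o in order
            if o not in swapped and ref_true_name[o] != ref_true_name[rid]
        ]
        if not partners:
            break
        other = partners[int(rng.integers(0, len(partners)))]
        assigned[rid], assigned[other] = assigned[other], assigned[rid]
        swapped.update((rid, other))
    for rid in sorted(swapped):
        mislabeled[rid] = {
            "true_name": ref_true_name[rid],
            "assigned_name": assigned[rid],
        }

    for rid in ref_ids:
        records.append(
            SequenceRecord(
                id=rid,
                sequence=ref_seq[rid],
                source="reference",
                species_name=assigned[rid],
                genus=config.genus,
            )
        )

    dataset = Dataset(records)
    incidence = (
        IncidenceTable.from_detections(detections, units=units)
        if detections
        else IncidenceTable(pd.DataFrame(columns=units, dtype=int))
    )
    truth = SyntheticTruth(
        species_of=species_of,
        n_species=config.n_species,
        species_names=names,
        incidence_probability=p_detect,
        abundance={sp: int(a) for sp, a in zip(species, abundances)},
        mislabeled=mislabeled,
    )
    return dataset, incidence, truth


def generate_community(
    config: CommunityConfig,
) -> tuple[Dataset, IncidenceTable, SyntheticTruth, dendropy.Tree]:
    """Tree -> species sequences -> surveyed specimens, in one call.

    Sub-stage randomness is derived from ``config.seed`` via independent
    spawned streams, so the whole community is reproducible from one seed.
    """
    tree = simulate_species_tree(config.n_species, config.birth_rate, config.seed)
    ss = np.random.SeedSequence(config.seed)
    rng_evo, rng_sample = (np.random.default_rng(s) for s in ss.spawn(2))
    species_seqs = evolve_sequences(tree, config, rng=rng_evo)
    dataset, incidence, truth = sample_specimens(species_seqs, config, rng=rng_sample)
    return dataset, incidence, truth, tree


def write_community(
    config: CommunityConfig, outdir: str | Path
) -> dict[str, Path]:
    """Generate a community and write its files (FASTA/TSV/JSON/Newick).

    Identical config + seed reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, incidence, truth, tree = generate_community(config)
    field = dataset.subset(r.id for r in dataset if r.source == "field")
    refs = dataset.subset(r.id for r in dataset if r.source == "reference")
    paths = {
        "field_fasta": outdir / "field.fasta",
        "field_annotations": outdir / "field_annotations.tsv",
        "incidence": outdir / "incidence.tsv",
        "truth": outdir / "truth.json",
        "tree": outdir / "species_tree.nwk",
        "config": outdir / "community_config.json",
    }
    write_fasta(field, paths["field_fasta"])
    write_annotations(field, paths["field_annotations"])
    if len(refs):
        paths["reference_fasta"] = outdir / "reference.fasta"
        paths["reference_annotations"] = outdir / "reference_annotations.tsv"
        write_fasta(refs, paths["reference_fasta"])
        write_annotations(refs, paths["reference_annotations"])
    incidence.write_tsv(paths["incidence"])
    truth.to_json(paths["truth"])
    paths["tree"].write_text(tree.as_string(schema="newick"))
    paths["config"].write_text(json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")
    return paths
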