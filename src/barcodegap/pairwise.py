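"""All-vs-all pairwise nucleotide identity and aligned fraction.

Identity is defined on an optimal semi-global alignment (terminal gaps free)
under match +1, mismatch -2, and affine gaps costing 5 + 2k for a run of k
gap columns. Terminal overhangs are excluded: identity = 100 * matches /
aligned columns between the first and last aligned pair, and the aligned
fraction is the proportion of the *shorter* sequence covered by that core
region, so a self comparison is exactly (100, 1.0). IUPAC ambiguity codes
never score or count as matches, giving a conservative identity.

These two statistics — identity and aligned fraction — are all the
downstream gap analysis and similarity-graph clustering consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .seqio import Dataset, SequenceRecord

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = -5.0  # charged once per gap run, on top of the per-column extend
GAP_EXTEND = -2.0

_ALPHABET = "ACGTRYSWKMBDHVN"


def _substitution_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b and a in "ACGT":
                m[a, b] = MATCH
            else:
                m[a, b] = MISMATCH
    return m


def make_aligner() -> Align.PairwiseAligner:
    """Semi-global aligner implementing the scoring contract above."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix()
    # Biopython charges open_gap_score on the first gap column; our contract
    # prices a k-column gap at open + k*extend, hence open+extend on column 1.
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    aligner.end_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class PairwiseHit:
    """Identity/coverage summary for one unordered sequence pair."""

    id_a: str
    id_b: str
    identity: float  # percent in [0, 100]
    aligned_fraction: float  # covered share of the shorter sequence, [0, 1]
    alignment_length: int  # aligned columns, terminal overhangs excluded


def _hit_from_alignment(a: SequenceRecord, b: SequenceRecord, alignment) -> PairwiseHit:
    blocks = alignment.aligned  # (target blocks, query blocks)
    tb, qb = blocks[0], blocks[1]
    if len(tb) == 0:  # nothing aligned at all
        return PairwiseHit(a.id, b.id, 0.0, 0.0, 0)
    pairs = int(sum(int(e) - int(s) for s, e in tb))
    matches = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        sa = a.sequence[int(ts) : int(te)]
        sb = b.sequence[int(qs) : int(qe)]
        matches += sum(
            1 for x, y in zip(sa, sb) if x == y and x in "ACGT"
        )
    t_span = int(tb[-1][1]) - int(tb[0][0])
    q_span = int(qb[-1][1]) - int(qb[0][0])
    columns = pairs + (t_span - pairs) + (q_span - pairs)
    shorter_len = min(len(a), len(b))
    covered = t_span if len(a) <= len(b) else q_span
    identity = 100.0 * matches / columns if columns else 0.0
    return PairwiseHit(
        a.id, b.id, identity, covered / shorter_len, columns
    )


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> PairwiseHit:
    """Align one pair by full dynamic programming and summarise it.

    The pair is aligned in a canonical (lexicographic) argument order so the
    statistics are exactly symmetric even when several co-optimal alignments
    exist and the traceback could otherwise pick different representatives
    for (a, b) and (b, a).
    """
    if not a.sequence or not b.sequence:
        raise ValidationError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    first, second = (a, b) if a.sequence <= b.sequence else (b, a)
    alignment = aligner.align(first.sequence, second.sequence)[0]
    hit = _hit_from_alignment(first, second, alignment)
    if first is a:
        return hit
    return PairwiseHit(
        a.id, b.id, hit.identity, hit.aligned_fraction, hit.alignment_length
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def all_vs_all(
    dataset: Dataset,
    coverage_floor: float = 0.7,
    use_fast_path: bool = True,
) -> list[PairwiseHit]:
    """Compute one hit per unordered pair, dropping low-coverage hits.

    Hits with aligned_fraction <= coverage_floor are dropped when the floor
    is positive; pass ``coverage_floor=0`` to keep all C(n, 2) pairs.

    For equal-length pairs the ungapped alignment's score is checked against
    the optimal score; when they agree (the common case for sequences that
    diverged by substitution only) the ungapped identity is reported without
    a traceback. The result is identical to full DP up to the choice among
    co-optimal alignments.
    """
    records = list(dataset)
    if len(records) < 2:
        raise ValidationError("all_vs_all needs at least 2 records")
    aligner = make_aligner()
    arrs = [_encode(r.sequence) for r in records]
    acgt = [np.isin(arr, _encode("ACGT")) for arr in arrs]
    hits: list[PairwiseHit] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            ra, rb = records[i], records[j]
            hit = None
            if use_fast_path and len(ra) == len(rb):
                L = len(ra)
                matches = int(np.sum((arrs[i] == arrs[j]) & acgt[i]))
                ungapped = 3.0 * matches - 2.0 * L
                if aligner.score(ra.sequence, rb.sequence) == ungapped:
                    hit = PairwiseHit(
                        ra.id, rb.id, 100.0 * matches / L, 1.0, L
                    )
            if hit is None:
                hit = align_pair(ra, rb, aligner)
            if coverage_floor > 0 and hit.aligned_fraction <= coverage_floor:
                continue
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# TSV interchange

_COLUMNS = ["id_a", "id_b", "identity", "aligned_fraction", "alignment_length"]


def hits_to_frame(hits: Iterable[PairwiseHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[PairwiseHit]:
    return [
        PairwiseHit(
            str(r.id_a),
            str(r.id_b),
            float(r.identity),
            float(r.aligned_fraction),
            int(r.alignment_length),
        )
        for r in frame.itertuples(index=False)
    ]


def write_hits(hits: Sequence[PairwiseHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_hits(path: str | Path) -> list[PairwiseHit]:
    return frame_to_hits(pd.read_csv(path, sep="\t"))
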