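"""Empirical barcode-gap detection and threshold derivation.

DNA barcoding works when within-species and between-species identities form
two separated modes; the deficit between them — the barcode gap — yields an
identity threshold for species-level clustering. This module makes that
historically eyeballed judgment reproducible: build the identity histogram,
scan a search window for the longest run of (near-)empty bins, and take the
run's upper edge as the clustering threshold. It also quantifies how well
identity tracks evolutionary relatedness by regressing identity on
cophenetic distance (reporting r-squared and its t-test p-value).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, GapNotFoundError
from .pairwise import PairwiseHit


@dataclass
class GapReport:
    """Histogram, detected gap, derived threshold and identity-distance fit."""

    bin_edges: list[float]
    counts: list[int]
    gap_interval: Optional[tuple[float, float]]
    threshold: Optional[float]  # percent; the gap's upper edge
    r_squared: Optional[float] = None
    p_value: Optional[float] = None
    n_pairs_used: int = 0
    coverage_floor: float = 0.7
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GapReport":
        data = json.loads(Path(path).read_text())
        if data.get("gap_interval") is not None:
            data["gap_interval"] = tuple(data["gap_interval"])
        return cls(**data)


def identity_distance_regression(
    hits: Sequence[PairwiseHit],
    cophenetic: pd.DataFrame,
    coverage_floor: float = 0.7,
) -> tuple[float, float, pd.DataFrame]:
    """Correlate identity with cophenetic distance over well-covered pairs.

    Only hits with aligned_fraction strictly above ``coverage_floor`` enter.
    Returns (r_squared, p_value, paired values); the p-value is the
    t-distribution test of the Pearson correlation with n - 2 degrees of
    freedom. r-squared is invariant to affine rescaling of the distances,
    so the absolute scale of the input tree does not matter.
    """
    labels = set(cophenetic.index)
    rows = []
    for h in hits:
        if h.aligned_fraction <= coverage_floor:
            continue
        if h.id_a not in labels or h.id_b not in labels:
            raise EstimationError(
                f"pair ({h.id_a}, {h.id_b}) missing from the cophenetic matrix"
            )
        rows.append(
            {
                "id_a": h.id_a,
                "id_b": h.id_b,
                "identity": h.identity,
                "distance": float(cophenetic.at[h.id_a, h.id_b]),
            }
        )
    if len(rows) < 3:
        raise EstimationError(f"only {len(rows)} usable pairs; need >= 3")
    paired = pd.DataFrame(rows)
    if paired["identity"].nunique() == 1 or paired["distance"].nunique() == 1:
        raise EstimationError("zero variance; correlation undefined")
    res = stats.pearsonr(paired["identity"], paired["distance"])
    return float(res.statistic**2), float(res.pvalue), paired


def detect_gap(
    identities: Sequence[float],
    bin_width: float = 0.5,
    search_window: tuple[float, float] = (85.0, 100.0),
    emptiness_quantile: float = 0.05,
    min_gap_bins: int = 2,
) -> GapReport:
    """Find the barcode gap as the longest run of near-empty histogram bins.

    The histogram spans [0, 100] at ``bin_width``. Within ``search_window``,
    bins whose counts are <= the ``emptiness_quantile`` quantile of all
    in-window counts qualify as "empty"; the longest maximal run of
    consecutive qualifying bins is the gap (ties broken toward higher
    identity). The threshold is the run's upper edge — the species side of
    the gap. Runs shorter than ``min_gap_bins`` are sampling noise, not a
    gap: in any histogram some bin attains the in-window minimum, so a
    single near-empty bin carries no evidence of bimodality.
    """
    values = np.asarray(list(identities), dtype=float)
    if values.size < 100:
        warnings.warn(
            f"only {values.size} identity values; gap detection is unreliable "
            "below ~100",
            stacklevel=2,
        )
    if bin_width <= 0:
        raise EstimationError("bin_width must be positive")
    n_bins = int(round(100.0 / bin_width))
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)

    lo, hi = search_window
    in_window = np.where((edges[:-1] >= lo) & (edges[1:] <= hi))[0]
    if in_window.size == 0:
        raise GapNotFoundError("search window contains no bins")
    cutoff = float(np.quantile(counts[in_window], emptiness_quantile))
    empty = counts[in_window] <= cutoff

    best_run: Optional[tuple[int, int]] = None  # (start, stop) in window coords
    run_start = None
    for k in range(len(empty) + 1):
        if k < len(empty) and empty[k]:
            if run_start is None:
                run_start = k
        else:
            if run_start is not None:
                length = k - run_start
                # >= keeps the later (higher-identity) run on ties
                if best_run is None or length >= best_run[1] - best_run[0]:
                    best_run = (run_start, k)
                run_start = None

    report = GapReport(
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
        gap_interval=None,
        threshold=None,
        notes={
            "bin_width": bin_width,
            "search_window": list(search_window),
            "emptiness_quantile": emptiness_quantile,
            "emptiness_cutoff_count": cutoff,
            "min_gap_bins": min_gap_bins,
            "rule": "longest run of near-empty bins; threshold = upper edge",
        },
    )
    if best_run is None or best_run[1] - best_run[0] < min_gap_bins:
        raise GapNotFoundError(
            "no near-empty run in the search window; the identity "
            "distribution may be unimodal — set the threshold manually"
        )
    start_bin = in_window[best_run[0]]
    stop_bin = in_window[best_run[1] - 1]
    gap = (float(edges[start_bin]), float(edges[stop_bin + 1]))
    report.gap_interval = gap
    report.threshold = gap[1]
    return report


def choose_threshold(report: Optional[GapReport], fallback: float = 97.0) -> float:
    """The detected threshold if a gap was found, else the fallback.

    The fallback defaults to 97%, the literature-standard full-length ITS
    identity criterion for fungal species delineation.
    """
    if report is not None and report.threshold is not None:
        return float(report.threshold)
    return float(fallback)
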