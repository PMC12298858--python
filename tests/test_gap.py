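"""Barcode-gap detection, threshold choice and the identity-distance fit."""

import numpy as np
import pandas as pd
import pytest

from barcodegap.errors import EstimationError, GapNotFoundError
from barcodegap.gap import (
    GapReport,
    choose_threshold,
    detect_gap,
    identity_distance_regression,
)
from barcodegap.pairwise import PairwiseHit


def _hits_and_matrix(identities, distances, af=1.0):
    ids = [f"s{i}" for i in range(len(identities) + 1)]
    hits = [
        PairwiseHit(ids[0], ids[i + 1], identities[i], af, 100)
        for i in range(len(identities))
    ]
    n = len(ids)
    dm = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
    for i, d in enumerate(distances):
        dm.iat[0, i + 1] = dm.iat[i + 1, 0] = d
    return hits, dm


def test_regression_perfectly_affine_identity():
    distances = np.linspace(0.01, 0.5, 10)
    identities = 100.0 - 50.0 * distances
    hits, dm = _hits_and_matrix(identities, distances)
    r2, p, paired = identity_distance_regression(hits, dm, coverage_floor=0.7)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-6
    assert len(paired) == 10


def test_regression_zero_variance_is_an_error():
    hits, dm = _hits_and_matrix([97.0] * 5, np.linspace(0.1, 0.5, 5))
    with pytest.raises(EstimationError, match="variance"):
        identity_distance_regression(hits, dm)


def test_regression_respects_coverage_floor():
    distances = np.linspace(0.01, 0.5, 10)
    identities = 100.0 - 50.0 * distances
    hits, dm = _hits_and_matrix(identities, distances, af=0.6)
    with pytest.raises(EstimationError, match="usable pairs"):
        identity_distance_regression(hits, dm, coverage_floor=0.7)


def test_regression_invariant_to_affine_distance_rescaling():
    rngL = np.random.default_rng(3)
    distances = rngL.uniform(0.01, 0.6, 40)
    identities = 100 - 45 * distances + rngL.normal(0, 1.5, 40)
    hits, dm = _hits_and_matrix(identities, distances)
    r2a, _, _ = identity_distance_regression(hits, dm)
    r2b, _, _ = identity_distance_regression(hits, 10.0 * dm + 3.0)
    assert r2a == pytest.approx(r2b, abs=1e-12)


def test_detect_gap_hand_example():
    values = [85, 90, 91, 98, 99, 100]
    report = detect_gap(values, bin_width=1.0, search_window=(80, 100),
                        emptiness_quantile=0.0)
    assert report.gap_interval == (92.0, 98.0)
    assert report.threshold == 98.0


def test_detect_gap_bimodal_histogram(rng):
    low = rng.uniform(80, 92, 500)
    high = rng.uniform(97.5, 100, 500)
    report = detect_gap(np.concatenate([low, high]), bin_width=0.5)
    lo, hi = report.gap_interval
    assert lo == pytest.approx(92.0, abs=0.5)
    assert hi == pytest.approx(97.5, abs=0.5)
    assert report.threshold == hi


def test_detect_gap_unimodal_raises(rng):
    values = rng.uniform(90, 100, 2000)
    with pytest.raises(GapNotFoundError):
        detect_gap(values, emptiness_quantile=0.0, search_window=(90.0, 100.0))


def test_detect_gap_warns_on_few_values():
    with pytest.warns(UserWarning, match="unreliable"):
        detect_gap([85, 90, 98, 99], bin_width=1.0, emptiness_quantile=0.0)


def test_detect_gap_permutation_and_outside_window_invariance(rng):
    values = list(rng.uniform(80, 91, 300)) + list(rng.uniform(97.5, 100, 300))
    base = detect_gap(values)
    shuffled = list(values)
    rng.shuffle(shuffled)
    assert detect_gap(shuffled).gap_interval == base.gap_interval
    padded = values + list(rng.uniform(0, 70, 500))
    assert detect_gap(padded).gap_interval == base.gap_interval


def test_ties_break_toward_higher_identity():
    # two equally long empty runs: 86-90 and 92-96; the higher one wins
    values = [85.5, 90.5, 91.5, 96.5, 97.5, 98.5, 99.5]
    report = detect_gap(values, bin_width=1.0, search_window=(85, 100),
                        emptiness_quantile=0.0)
    assert report.gap_interval == (92.0, 96.0)


@pytest.mark.parametrize(
    "gap_interval, fallback, expected",
    [((92.0, 97.0), 97.0, 97.0), (None, 97.0, 97.0), ((90.0, 98.4), 97.0, 98.4)],
)
def test_choose_threshold(gap_interval, fallback, expected):
    report = None
    if gap_interval is not None:
        report = GapReport(
            bin_edges=[], counts=[], gap_interval=gap_interval,
            threshold=gap_interval[1],
        )
    assert choose_threshold(report, fallback=fallback) == expected


def test_gap_report_json_round_trip(tmp_path, rng):
    values = list(rng.uniform(80, 91, 200)) + list(rng.uniform(98, 100, 200))
    report = detect_gap(values)
    report.r_squared, report.p_value, report.n_pairs_used = 0.8, 1e-10, 400
    path = tmp_path / "gap.json"
    report.to_json(path)
    back = GapReport.from_json(path)
    assert back.gap_interval == report.gap_interval
    assert back.threshold == report.threshold
    assert back.r_squared == report.r_squared


def test_regression_on_simulated_communities_with_nj_tree():
    """Identity explains most cophenetic-distance variance (r^2 > 0.5) on
    default synthetic communities with the NJ stand-in tree."""
    import warnings

    from barcodegap.pairwise import all_vs_all
    from barcodegap.phylo import (
        cophenetic_matrix,
        distance_matrix_from_hits,
        neighbor_joining,
    )
    from barcodegap.simulate import CommunityConfig, generate_community

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(3):
            dataset, _, _, _ = generate_community(CommunityConfig(seed=seed))
            hits = all_vs_all(dataset, coverage_floor=0.0)
            tree = neighbor_joining(distance_matrix_from_hits(hits, dataset.ids))
            r2, _, _ = identity_distance_regression(
                hits, cophenetic_matrix(tree), coverage_floor=0.7
            )
            assert r2 > 0.5
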