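"""Chao2, rarefaction/extrapolation and the bootstrap accumulation curve."""

import numpy as np
import pandas as pd
import pytest

from barcodegap.errors import EstimationError, ValidationError
from barcodegap.richness import (
    IncidenceTable,
    bootstrap_curve,
    chao2,
    extrapolate,
    incidence_from_partition,
    interpolate,
    richness_at,
)
from barcodegap.cluster import OTUPartition
from barcodegap.seqio import Dataset, SequenceRecord

from .oracles import subset_mean_richness


def table_from_freqs(freqs: dict[str, list[int]], t: int) -> IncidenceTable:
    mat = pd.DataFrame(0, index=list(freqs), columns=[f"u{i}" for i in range(t)])
    for otu, units in freqs.items():
        for u in units:
            mat.iloc[mat.index.get_loc(otu), u] = 1
    return IncidenceTable(mat)


def test_chao2_hand_formula_q2_positive():
    # T=5; A in 3 units, B in 1, C in 1, D in 2 -> Q1=2, Q2=1
    t = table_from_freqs({"A": [0, 1, 2], "B": [0], "C": [1], "D": [3, 4]}, 5)
    assert t.s_obs == 4 and t.q(1) == 2 and t.q(2) == 1
    assert chao2(t) == pytest.approx(5.6, abs=1e-12)


def test_chao2_bias_corrected_q2_zero():
    t = table_from_freqs({"A": [0], "B": [1]}, 4)
    assert chao2(t) == pytest.approx(2.75, abs=1e-12)


def test_chao2_equals_s_obs_without_singletons():
    t = table_from_freqs({"A": [0, 1], "B": [2, 3], "C": [0, 3]}, 4)
    assert chao2(t) == pytest.approx(t.s_obs)


def test_chao2_requires_two_units():
    t = table_from_freqs({"A": [0]}, 1)
    with pytest.raises(EstimationError):
        chao2(t)


def test_interpolation_hand_case():
    # T=3; A in {u0,u1}, B in {u0}: S(1) = (2+1+0)/3 = 1
    t = table_from_freqs({"A": [0, 1], "B": [0]}, 3)
    assert interpolate(t, 1) == pytest.approx(1.0, abs=1e-12)
    assert interpolate(t, t.T) == pytest.approx(t.s_obs)


def test_interpolation_equals_subset_mean_oracle(rng):
    """Analytic rarefaction equals exhaustive subset enumeration, T <= 8."""
    for _ in range(30):
        t_units = int(rng.integers(2, 9))
        n_otus = int(rng.integers(2, 10))
        mat = (rng.random((n_otus, t_units)) < rng.uniform(0.15, 0.7)).astype(int)
        mat[rng.integers(0, n_otus), rng.integers(0, t_units)] = 1  # non-empty
        frame = pd.DataFrame(
            mat, index=[f"o{i}" for i in range(n_otus)],
            columns=[f"u{i}" for i in range(t_units)],
        )
        table = IncidenceTable(frame)
        for t in range(1, t_units + 1):
            exact = subset_mean_richness(table.matrix.to_numpy(), t)
            assert interpolate(table, t) == pytest.approx(exact, abs=1e-10)


def test_extrapolation_limits_and_continuity():
    t = table_from_freqs({"A": [0, 1, 2], "B": [0], "C": [1], "D": [3, 4]}, 5)
    assert extrapolate(t, 0) == pytest.approx(t.s_obs)
    assert extrapolate(t, 10**6) == pytest.approx(chao2(t), abs=1e-9)
    # monotone in t*
    vals = [extrapolate(t, k) for k in range(0, 50, 5)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    assert richness_at(t, t.T) == pytest.approx(t.s_obs)


def test_extrapolation_without_singletons_is_flat():
    t = table_from_freqs({"A": [0, 1], "B": [2, 3]}, 4)
    assert extrapolate(t, 100) == pytest.approx(t.s_obs)


def test_incidence_invariants():
    t = table_from_freqs({"A": [0, 1, 2], "B": [0], "C": [1], "D": [3, 4]}, 5)
    assert sum(t.q_counts.values()) == t.s_obs
    assert all(k <= t.T for k in t.q_counts)


def test_incidence_rejects_non_binary():
    frame = pd.DataFrame([[0, 2]], index=["A"], columns=["u0", "u1"])
    with pytest.raises(ValidationError):
        IncidenceTable(frame)


def test_bootstrap_degenerate_single_replicate():
    t = table_from_freqs({"A": [0, 1, 2], "B": [0], "C": [1], "D": [3, 4]}, 5)
    curve = bootstrap_curve(t, n_boot=1, seed=0, t_max=20)
    assert len(curve.curve) > 0
    assert (curve.curve.lower <= curve.curve.estimate + 1e-12).all()
    assert (curve.curve.upper >= curve.curve.estimate - 1e-12).all()


def test_bootstrap_complete_table_has_zero_width_ci():
    t = table_from_freqs({"A": [0, 1, 2], "B": [0, 1, 2]}, 3)
    curve = bootstrap_curve(t, n_boot=50, seed=1, t_max=10)
    assert np.allclose(curve.curve.lower, curve.curve.estimate)
    assert np.allclose(curve.curve.upper, curve.curve.estimate)
    assert (curve.curve.estimate == t.s_obs).all()


def test_curve_shape_and_phases():
    t = table_from_freqs({"A": [0, 1, 2], "B": [0], "C": [1], "D": [3, 4]}, 5)
    curve = bootstrap_curve(t, n_boot=100, seed=3, t_max=100)
    est = curve.curve.estimate.to_numpy()
    assert (np.diff(est) >= -1e-9).all()  # non-decreasing
    assert (curve.curve[curve.curve.phase == "extrapolated"].estimate
            <= curve.asymptote + 1e-9).all()
    assert set(curve.curve.phase) == {"interpolated", "extrapolated"}
    at_T = curve.curve[curve.curve["size"] == t.T].estimate.iloc[0]
    assert at_T == pytest.approx(t.s_obs)


def test_incidence_from_partition_detections():
    ds = Dataset(
        [
            SequenceRecord("f1", "ACGT", "field", sampling_unit="s1"),
            SequenceRecord("f2", "ACGT", "field", sampling_unit="s2"),
            SequenceRecord("f3", "AAAA", "field", sampling_unit="s1"),
            SequenceRecord("r1", "ACGT", "reference", species_name="X"),
        ]
    )
    part = OTUPartition(membership={"f1": "f1", "f2": "f1", "f3": "f3", "r1": "f1"})
    table = incidence_from_partition(part, ds)
    assert table.s_obs == 2
    assert table.T == 2
    assert table.matrix.loc["f1"].tolist() == [1, 1]
    assert table.matrix.loc["f3"].tolist() == [1, 0]


def test_incidence_tsv_round_trip(tmp_path):
    t = table_from_freqs({"A": [0, 1, 2], "B": [0]}, 4)
    path = tmp_path / "inc.tsv"
    t.write_tsv(path)
    back = IncidenceTable.read_tsv(path)
    assert back.matrix.equals(t.matrix)


def test_bootstrap_fast_path_matches_public_estimators(rng):
    """The vectorised bootstrap internals agree with the public functions."""
    from barcodegap.richness import _chao2_from_freq, _richness_at_from_freq

    for _ in range(10):
        t_units = int(rng.integers(3, 9))
        n_otus = int(rng.integers(3, 12))
        mat = (rng.random((n_otus, t_units)) < 0.4).astype(int)
        mat[0, 0] = 1
        frame = pd.DataFrame(
            mat, index=[f"o{i}" for i in range(n_otus)],
            columns=[f"u{i}" for i in range(t_units)],
        )
        table = IncidenceTable(frame)
        freq = table.matrix.sum(axis=1).to_numpy()
        assert _chao2_from_freq(freq, t_units) == pytest.approx(chao2(table))
        for size in (1, t_units, t_units + 7):
            assert _richness_at_from_freq(freq, t_units, size) == pytest.approx(
                richness_at(table, size), abs=1e-9
            )
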