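"""Alignment, replicate averaging, Welch testing, BH-FDR, fold-change display."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duomics.metabolomics import (
    FeatureTable,
    align_retention,
    average_technical_replicates,
    bh_adjust,
    differential_analysis,
    signed_fold_change,
)
from duomics.metabolomics import test_feature as feature_welch_test


def bh_brute_force(p):
    """Independent step-up BH oracle, written directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _run(ids, mzs, rts, intensity=100.0):
    return pd.DataFrame({"id": ids, "mz": mzs, "rt": rts, "intensity": intensity})


def test_align_identical_runs_is_identity():
    ids = [f"f{i}" for i in range(10)]
    mzs = np.linspace(100, 500, 10)
    rts = np.linspace(0.5, 9.5, 10)
    runs = [("s1", _run(ids, mzs, rts)), ("s2", _run(ids, mzs, rts))]
    table = align_retention(runs)
    merged = table.data.sort_values("mz")
    assert np.allclose(merged["rt"], rts)


def test_align_recovers_constant_offset():
    """A run shifted by +0.2 min maps back onto the unshifted run exactly."""
    ids = [f"f{i}" for i in range(12)]
    mzs = np.linspace(100, 600, 12)
    rts = np.linspace(0.5, 10.0, 12)
    runs = [("a", _run(ids, mzs, rts)), ("b", _run(ids, mzs, rts + 0.2))]
    table = align_retention(runs)
    merged = table.data.sort_values("mz")
    assert np.allclose(merged["rt"], rts, atol=1e-6)


def test_align_reduces_warp_spread():
    """Linear warps (slope 1.02 / 0.98) collapse onto the central run."""
    ids = [f"f{i}" for i in range(15)]
    mzs = np.linspace(100, 800, 15)
    rts = np.linspace(0.5, 12.0, 15)
    runs = [
        ("a", _run(ids, mzs, rts)),
        ("b", _run(ids, mzs, 1.02 * rts)),
        ("c", _run(ids, mzs, 0.98 * rts)),
    ]
    pre_spread = np.std([rts, 1.02 * rts, 0.98 * rts], axis=0).mean()
    table = align_retention(runs)
    merged = table.data.sort_values("mz")
    post_dev = np.abs(merged["rt"].to_numpy() - rts).mean()
    assert post_dev < pre_spread
    assert post_dev < 1e-9  # anchors collapse exactly onto the reference run


def test_align_requires_anchors():
    runs = [
        ("a", _run(["x"], [100.0], [1.0])),
        ("b", _run(["y"], [900.0], [2.0])),
    ]
    with pytest.raises(ValueError, match="tolerance"):
        align_retention(runs)


def test_align_requires_two_runs():
    with pytest.raises(ValueError):
        align_retention([("a", _run(["x"], [100.0], [1.0]))])


# ---------------------------------------------------------------------------
# averaging and testing
# ---------------------------------------------------------------------------


def test_average_technical_replicates():
    data = pd.DataFrame(
        {
            "id": ["f1", "f2"],
            "mz": [100.0, 200.0],
            "rt": [1.0, 2.0],
            "t1": [10.0, 0.0],
            "t2": [20.0, 0.0],
            "t3": [30.0, 0.0],
            "u1": [5.0, 7.0],
        }
    )
    table = FeatureTable(
        data=data,
        sample_groups={"t1": "control", "t2": "control", "t3": "control", "u1": "treated"},
    )
    averaged = average_technical_replicates(
        table, {"t1": "bioA", "t2": "bioA", "t3": "bioA", "u1": "bioB"}
    )
    assert averaged.data["bioA"].tolist() == [20.0, 0.0]  # mean and zeros
    assert averaged.data["bioB"].tolist() == [5.0, 7.0]  # singleton passthrough
    assert averaged.sample_groups == {"bioA": "control", "bioB": "treated"}


def test_average_rejects_mixed_groups():
    data = pd.DataFrame(
        {"id": ["f1"], "mz": [100.0], "rt": [1.0], "a": [1.0], "b": [2.0]}
    )
    table = FeatureTable(data=data, sample_groups={"a": "control", "b": "treated"})
    with pytest.raises(ValueError, match="mixes"):
        average_technical_replicates(table, {"a": "bio1", "b": "bio1"})


def test_feature_identical_groups():
    p, log2fc = feature_welch_test([100, 100, 100], [100, 100, 100])
    assert p == 1.0 and log2fc == 0.0


def test_feature_strong_separation_significant():
    p, log2fc = feature_welch_test([10, 12, 11], [80, 96, 88], pseudo=1.0)
    assert p < 0.01
    assert log2fc > 2.5


def test_feature_exact_eightfold_with_tiny_pseudo():
    control = np.array([10.0, 12.0, 11.0])
    p, log2fc = feature_welch_test(control, 8 * control, pseudo=1e-9)
    assert log2fc == pytest.approx(3.0, abs=1e-6)


def test_feature_small_groups_flagged():
    p, log2fc = feature_welch_test([10.0], [80.0])
    assert np.isnan(p)
    assert log2fc == pytest.approx(np.log2(81) - np.log2(11))


def test_welch_agrees_with_permutation_oracle(rng):
    """At n=10 per group the Welch p matches a 10,000-draw label-permutation
    oracle within 0.01.  (At n=3 the permutation null has only 20 distinct
    splits and cannot resolve small p-values, so the comparison is made at a
    sample size where the null has support.)"""
    control = 2.0 ** rng.normal(10.0, 0.5, size=10)
    treated = 2.0 ** rng.normal(10.7, 0.5, size=10)
    p_welch, _ = feature_welch_test(control, treated, pseudo=1e-9)

    pooled = np.log2(np.concatenate([control, treated]) + 1e-9)
    n = 10

    def welch_t(x, y):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        return (y.mean() - x.mean()) / np.sqrt(vx / len(x) + vy / len(y))

    observed = abs(welch_t(pooled[:n], pooled[n:]))
    draws = 10_000
    count = 0
    for _ in range(draws):
        perm = rng.permutation(pooled)
        count += abs(welch_t(perm[:n], perm[n:])) >= observed
    p_perm = (count + 1) / (draws + 1)
    assert 0.001 < p_welch < 0.2  # informative regime for the comparison
    assert abs(p_welch - p_perm) < 0.01


# ---------------------------------------------------------------------------
# BH and fold-change display
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([1.0, 1.0], [1.0, 1.0]),
    ],
)
def test_bh_known_values(p, expected):
    assert np.allclose(bh_adjust(p), expected)


def test_bh_matches_brute_force_on_random_vectors(rng):
    """1,000 random p-vectors: implementation == definitional BH oracle."""
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        assert np.allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_dominates_p_and_preserves_order(p):
    q = bh_adjust(p)
    p_arr = np.asarray(p)
    assert (q >= p_arr - 1e-12).all()
    order = np.argsort(p_arr, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


@pytest.mark.parametrize(
    "log2fc, expected",
    [(1.0, 2.0), (-np.log2(5), -5.0), (0.0, 1.0), (3.0, 8.0)],
)
def test_signed_fold_change_values(log2fc, expected):
    assert signed_fold_change(log2fc) == pytest.approx(expected)


@given(st.floats(min_value=-20, max_value=20))
def test_signed_fold_change_magnitude_at_least_one(log2fc):
    assert abs(signed_fold_change(log2fc)) >= 1.0 - 1e-12


def test_differential_analysis_structure(dataset):
    diff = differential_analysis(dataset.feature_table)
    assert list(diff.columns) == [
        "id", "mz", "rt", "signed_fold_change", "log2fc", "p_value", "q_value", "direction",
    ]
    valid = diff.dropna(subset=["p_value"])
    assert (valid["q_value"] >= valid["p_value"] - 1e-12).all()
    assert (np.sign(valid["log2fc"]).replace(0, 1)
            == valid["direction"].map({"up": 1, "down": -1})).all()
    assert (valid["signed_fold_change"].abs() >= 1.0 - 1e-12).all()
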