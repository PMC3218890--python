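"""Expression standardization, probe correlation, composites and MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisreg.expression_core import (
    ExpressionDataset,
    filter_intron_probes,
    make_composite,
    mds_coordinates,
    probe_r2_matrix,
    select_representative_group,
    standardize,
)


def dataset(values, probe_ids=None, intron_flags=None) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    probe_ids = probe_ids or [f"p{j + 1}" for j in range(k)]
    meta = pd.DataFrame(
        {
            "target": ["" for _ in probe_ids],
            "targets_intron": intron_flags or [False] * k,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ExpressionDataset(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        probe_ids=probe_ids,
        values=values,
        probe_meta=meta,
    )


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_simple_and_idempotent():
    e = standardize(dataset([[1], [2], [3]]))
    np.testing.assert_allclose(e.values[:, 0], [-1, 0, 1])
    e2 = standardize(e)
    np.testing.assert_allclose(e2.values, e.values, atol=1e-12)
    assert e.standardized and e.raw is not None


def test_standardize_moments(rng):
    e = standardize(dataset(rng.normal(5, 3, size=(40, 6))))
    assert np.abs(e.values.mean(axis=0)).max() < 1e-9
    assert np.abs(e.values.std(axis=0, ddof=1) - 1).max() < 1e-9


def test_standardize_zero_variance_names_probe():
    vals = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
    with pytest.raises(ValueError, match="p2"):
        standardize(dataset(vals))


# ---------------------------------------------------------------------------
# intron filter
# ---------------------------------------------------------------------------

def test_intron_filter_counts(rng):
    vals = rng.normal(size=(10, 5))
    e = dataset(vals, intron_flags=[False, True, False, True, False])
    out = filter_intron_probes(e)
    assert out.probe_ids == ["p1", "p3", "p5"]
    no_introns = filter_intron_probes(dataset(vals))
    assert no_introns.probe_ids == [f"p{j}" for j in range(1, 6)]
    with pytest.warns(UserWarning, match="all probes"):
        empty = filter_intron_probes(dataset(vals, intron_flags=[True] * 5))
    assert empty.n_probes == 0


# ---------------------------------------------------------------------------
# probe r2
# ---------------------------------------------------------------------------

def test_probe_r2_duplicate_and_negation(rng):
    x = rng.normal(size=30)
    e = standardize(dataset(np.column_stack([x, x, -x])))
    r2 = probe_r2_matrix(e)
    assert r2.loc["p1", "p2"] == pytest.approx(1.0)
    assert r2.loc["p1", "p3"] == pytest.approx(1.0)
    np.testing.assert_allclose(np.diag(r2), 1.0)


def test_probe_r2_attenuation(rng):
    """Two noisy observations of one signal: r2 follows the attenuation law."""
    n = 10_000
    signal = rng.normal(0, 1.0, n)
    sd_noise = 0.5
    probes = np.column_stack(
        [signal + rng.normal(0, sd_noise, n), signal + rng.normal(0, sd_noise, n)]
    )
    expected = (1.0 / (1.0 + sd_noise**2)) ** 2
    r2 = probe_r2_matrix(standardize(dataset(probes)))
    assert r2.loc["p1", "p2"] == pytest.approx(expected, abs=0.02)


@settings(max_examples=30, derandomize=True)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.1, 10.0),
    st.floats(-5.0, 5.0),
)
def test_probe_r2_affine_invariance(seed, scale, shift):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(25, 3))
    base = probe_r2_matrix(dataset(vals))
    transformed = vals.copy()
    transformed[:, 1] = scale * transformed[:, 1] + shift
    trans = probe_r2_matrix(dataset(transformed))
    np.testing.assert_allclose(trans.to_numpy(), base.to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# representative group selection
# ---------------------------------------------------------------------------

def test_group_all_identical(rng):
    x = rng.normal(size=20)
    e = standardize(dataset(np.column_stack([x, x, x])))
    group, mean_r2, excluded = select_representative_group(probe_r2_matrix(e), 0.5)
    assert group == ["p1", "p2", "p3"] and mean_r2 == pytest.approx(1.0)
    assert excluded == []


def test_group_two_blocks(rng):
    """Two orthogonal correlated blocks: the larger block is selected."""
    a = rng.normal(size=200)
    b = rng.normal(size=200)
    vals = np.column_stack(
        [a + rng.normal(0, 0.3, 200) for _ in range(4)]
        + [b + rng.normal(0, 0.3, 200) for _ in range(2)]
    )
    r2 = probe_r2_matrix(standardize(dataset(vals)))
    group, mean_r2, excluded = select_representative_group(r2, 0.5)
    assert group == ["p1", "p2", "p3", "p4"]
    assert excluded == ["p5", "p6"]
    assert mean_r2 >= 0.5


def test_group_signal_recovery_13_probes(rng):
    """8 of 13 probes share a latent signal and are recovered as the group."""
    n = 300
    signal = rng.normal(size=n)
    sig_probes = [signal + rng.normal(0, 0.4, n) for _ in range(8)]
    junk = [rng.normal(size=n) for _ in range(5)]
    vals = np.column_stack(sig_probes + junk)
    r2 = probe_r2_matrix(standardize(dataset(vals)))
    group, _, _ = select_representative_group(r2, 0.5)
    assert group == [f"p{j}" for j in range(1, 9)]


def test_group_permutation_invariant(rng):
    n = 150
    signal = rng.normal(size=n)
    vals = np.column_stack(
        [signal + rng.normal(0, 0.4, n) for _ in range(4)]
        + [rng.normal(size=n) for _ in range(3)]
    )
    ids = [f"p{j}" for j in range(1, 8)]
    r2 = probe_r2_matrix(standardize(dataset(vals, probe_ids=ids)))
    base, _, _ = select_representative_group(r2, 0.5)
    perm = [3, 5, 0, 6, 2, 4, 1]
    r2_perm = r2.iloc[perm, perm]
    permuted, _, _ = select_representative_group(r2_perm, 0.5)
    assert permuted == base


def test_group_no_pair_meets_threshold(rng):
    vals = rng.normal(size=(100, 4))
    r2 = probe_r2_matrix(standardize(dataset(vals)))
    group, mean_r2, excluded = select_representative_group(r2, 0.5)
    assert group == [] and np.isnan(mean_r2) and len(excluded) == 4


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def test_composite_identity_cancellation_and_mean(rng):
    x = rng.normal(size=30)
    e = standardize(dataset(np.column_stack([x, -x, x + rng.normal(0, 0.2, 30)])))
    single = make_composite(e, ["p1"], "one")
    np.testing.assert_allclose(single.values, e.probe("p1"))
    cancel = make_composite(e, ["p1", "p2"], "zero")
    np.testing.assert_allclose(cancel.values, 0.0, atol=1e-12)
    full = make_composite(e, ["p1", "p2", "p3"], "row")
    np.testing.assert_allclose(full.values, e.values.mean(axis=1))
    # composite of z-scores has mean 0 and sd <= 1
    assert abs(full.values.mean()) < 1e-9
    assert full.values.std(ddof=1) <= 1.0 + 1e-12
    with pytest.raises(ValueError, match="empty"):
        make_composite(e, [], "none")


def test_composite_sd_equals_one_iff_perfectly_correlated(rng):
    x = rng.normal(size=50)
    e = standardize(dataset(np.column_stack([x, 2 * x + 1])))
    comp = make_composite(e, ["p1", "p2"], "dup")
    assert comp.values.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

def test_mds_equilateral_and_collinear():
    ids = ["a", "b", "c"]
    r2 = pd.DataFrame(0.5, index=ids, columns=ids)
    np.fill_diagonal(r2.values, 1.0)
    xy = mds_coordinates(r2, dims=2).to_numpy()
    dists = [np.linalg.norm(xy[i] - xy[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
    np.testing.assert_allclose(dists, dists[0], atol=1e-9)

    # collinear points: distances from positions on a line
    pos = np.array([0.0, 0.4, 0.9])
    d2 = (pos[:, None] - pos[None, :]) ** 2
    r2_line = pd.DataFrame(1.0 - d2, index=ids, columns=ids)
    coords = mds_coordinates(r2_line, dims=2).to_numpy()
    assert np.abs(coords[:, 1]).max() < 1e-6


def test_mds_recovers_euclidean_distances(rng):
    pts = rng.normal(size=(6, 2)) * 0.3
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    r2 = pd.DataFrame(1.0 - d**2, index=list("abcdef"), columns=list("abcdef"))
    coords = mds_coordinates(r2, dims=2).to_numpy()
    d_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.testing.assert_allclose(d_hat, d, atol=1e-8)


def test_mds_requires_symmetry():
    r2 = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        mds_coordinates(r2)
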