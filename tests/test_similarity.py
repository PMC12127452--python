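"""Similarity measures: Pearson, TWDTW and the group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitt.similarity import (
    TWDTWParams,
    cross_crop_distinguishability,
    gas,
    gas_tas_by_scale,
    pearson,
    similarity_matrix,
    tas,
    twdtw,
)


def brute_force_twdtw(x, y, tx, ty, params: TWDTWParams) -> float:
    """Exhaustive enumeration over all monotone warping paths."""
    n, m = len(x), len(y)

    def cost(i, j):
        g = abs(tx[i] - ty[j])
        return abs(x[i] - y[j]) + 1.0 / (1.0 + np.exp(-params.alpha * (g - params.beta)))

    best = [np.inf]

    def rec(i, j, acc):
        acc += cost(i, j)
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            rec(i + 1, j, acc)
        if j + 1 < m:
            rec(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]


class TestPearson:
    def test_self_and_negated(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_returns_zero(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


class TestTwdtw:
    def test_identical_series_closed_form(self, rng):
        x = rng.normal(size=10)
        dates = np.arange(10, dtype=float)
        expected = 10 / (1 + np.exp(0.5))  # 10 diagonal steps of omega(0)
        assert twdtw(x, x, dates, dates, TWDTWParams(0.1, 5)) == pytest.approx(expected)

    def test_alpha_zero_is_dtw_plus_half_path(self, rng):
        # with alpha = 0 the time weight is the constant 1/2
        x, y = rng.normal(size=5), rng.normal(size=6)
        tx, ty = np.arange(5.0), np.arange(6.0)
        got = twdtw(x, y, tx, ty, TWDTWParams(0.0, 5))
        assert got == pytest.approx(brute_force_twdtw(x, y, tx, ty, TWDTWParams(0.0, 5)))

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(60):
            n, m = rng.integers(1, 7, size=2)
            x, y = rng.normal(size=n), rng.normal(size=m)
            tx = np.sort(rng.choice(40, size=n, replace=False)).astype(float)
            ty = np.sort(rng.choice(40, size=m, replace=False)).astype(float)
            params = TWDTWParams(0.1, 5) if trial % 2 else TWDTWParams(0.0, 5)
            assert twdtw(x, y, tx, ty, params) == pytest.approx(
                brute_force_twdtw(x, y, tx, ty, params)
            )

    def test_symmetric(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        d = np.arange(8.0)
        assert twdtw(x, y, d, d) == pytest.approx(twdtw(y, x, d, d))

    def test_large_beta_approaches_plain_dtw(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        d = np.arange(6.0)
        weighted = twdtw(x, y, d, d, TWDTWParams(0.1, 1e6))

        # independent plain-DTW enumeration (no time weight at all)
        def plain(i, j, acc, best=[np.inf]):
            acc += abs(x[i] - y[j])
            if acc >= best[0]:
                return best[0]
            if i == 5 and j == 5:
                best[0] = acc
                return best[0]
            if i < 5:
                plain(i + 1, j, acc, best)
            if j < 5:
                plain(i, j + 1, acc, best)
            if i < 5 and j < 5:
                plain(i + 1, j + 1, acc, best)
            return best[0]

        assert weighted == pytest.approx(plain(0, 0, 0.0, [np.inf]), abs=1e-3)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            twdtw([], [1.0])


class TestGasTas:
    def test_identical_group_gas_one(self, rng):
        x = rng.normal(size=10)
        assert gas(np.tile(x, (5, 1))) == pytest.approx(1.0)

    def test_two_uncorrelated_members(self):
        # PCC(a,b) = 0 exactly: (1 + 0 + 0 + 1)/4
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert gas(np.vstack([a, b])) == pytest.approx(0.5)

    def test_gas_matches_double_loop(self, rng):
        for _ in range(20):
            g = rng.normal(size=(rng.integers(1, 12), 8))
            brute = np.mean([[pearson(a, b) for b in g] for a in g])
            assert gas(g) == pytest.approx(brute)

    def test_tas_hand_example(self):
        typical = np.array([1.0, 2.0, 3.0, 4.0])
        group = np.vstack([typical, [1.0, -1.0, -1.0, 1.0]])  # r = 1 and 0
        assert tas(group, typical) == pytest.approx(0.5)

    def test_tas_matches_loop(self, rng):
        g = rng.normal(size=(7, 9))
        t = rng.normal(size=9)
        assert tas(g, t) == pytest.approx(np.mean([pearson(row, t) for row in g]))

    def test_gas_bounded(self, rng):
        g = rng.normal(size=(6, 10))
        assert -1.0 <= gas(g) <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gas(np.empty((0, 5)))


class TestCrossCrop:
    def test_singletons_give_single_pair(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert cross_crop_distinguishability([x], [y]) == pytest.approx(pearson(x, y))

    def test_twdtw_constant_offset_matches_brute_force(self, rng):
        d = np.arange(5.0)
        a = [rng.normal(size=5) for _ in range(3)]
        b = [v + 2.0 for v in a]
        got = cross_crop_distinguishability(a, b, "twdtw", d, TWDTWParams(0.0, 5))
        exp = np.mean(
            [brute_force_twdtw(x, y, d, d, TWDTWParams(0.0, 5)) for x in a for y in b]
        )
        assert got == pytest.approx(exp)


class TestByScale:
    def test_single_stratum_single_row(self, rng):
        series = rng.normal(size=(5, 10))
        table = gas_tas_by_scale(series, ["rape"] * 5, [9] * 5)
        assert len(table) == 1
        assert set(table.columns) >= {"size_level", "crop", "gas", "tas"}

    def test_empty_strata_omitted(self, rng):
        series = rng.normal(size=(4, 10))
        table = gas_tas_by_scale(series, ["rape", "rape", "wheat", "wheat"], [0, 0, 9, 9])
        assert len(table) == 2  # (0, rape) and (9, wheat) only

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        s = rng.normal(size=(6, 10))
        m = similarity_matrix(s, [f"p{i}" for i in range(6)])
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)


def test_wheat_group_less_coherent_than_rape(std_scene, std_records, std_truth_map):
    """The two crops' group-similarity contrast: the noisier wheat group
    shows lower off-diagonal similarity than rapeseed."""
    ids = std_scene.small_ids
    off = {}
    for crop in ("rape", "wheat"):
        members = [i for i in ids if std_truth_map[i] == crop][:60]
        m = similarity_matrix(
            np.vstack([std_records[i].values for i in members]), members
        ).values
        off[crop] = (m.sum() - np.trace(m)) / (m.size - len(members))
    assert off["wheat"] < off["rape"]


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000))
def test_twdtw_self_distance_depends_only_on_length(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    x = rng.normal(size=n)
    d = np.sort(rng.choice(200, size=n, replace=False)).astype(float)
    expected = n / (1 + np.exp(0.5))
    assert twdtw(x, x, d, d, TWDTWParams(0.1, 5)) == pytest.approx(expected)
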