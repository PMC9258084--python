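"""The nine statistics: frozen oracles, algebraic identities, smoothers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsaseq import (StatTrack, compute_all, delta_snp, ed_power_smooth,
                    euclidean_distance, g_statistic, lod_statistic,
                    loess_block_smooth, tricube_smooth)
from tests.conftest import make_counts

LN10 = np.log(10.0)


def longhand_g(ah, rh, al, rl):
    """Independent oracle: literal 2 sum o ln(o/e) over the 2x2 table."""
    obs = np.array([ah, rh, al, rl], dtype=float)
    row = np.array([ah + rh, ah + rh, al + rl, al + rl], dtype=float)
    col = np.array([ah + al, rh + rl, ah + al, rh + rl], dtype=float)
    exp = row * col / obs.sum()
    terms = [o * np.log(o / e) for o, e in zip(obs, exp) if o > 0]
    return 2.0 * sum(terms)


counts_2x2 = st.tuples(
    st.integers(0, 200), st.integers(0, 200),
    st.integers(0, 200), st.integers(0, 200),
).filter(lambda t: (t[0] + t[1]) > 0 and (t[2] + t[3]) > 0)


class TestPerSnpStatistics:
    @pytest.mark.parametrize("table,expected", [
        ((50, 50, 50, 50), 0.0),
        ((80, 20, 20, 80), 0.6),
        ((100, 0, 0, 100), 1.0),
    ])
    def test_delta_snp_examples(self, table, expected):
        track = delta_snp(make_counts(*table))
        assert track.values[0] == pytest.approx(expected)

    def test_zero_depth_is_undefined(self):
        track = delta_snp(make_counts([50, 0], [50, 0], [20, 10], [80, 10]))
        assert np.isfinite(track.values[0])
        assert np.isnan(track.values[1])

    def test_g_vanishes_when_observed_equals_expected(self):
        assert g_statistic(make_counts(50, 50, 50, 50)).values[0] == 0.0

    def test_g_longhand_value(self):
        got = g_statistic(make_counts(60, 40, 40, 60)).values[0]
        assert got == pytest.approx(longhand_g(60, 40, 40, 60), rel=1e-12)
        # longhand: 2 * (120 ln 1.2 + 80 ln 0.8)
        assert got == pytest.approx(8.05421, abs=1e-5)

    @given(counts_2x2)
    @settings(max_examples=200, derandomize=True)
    def test_g_matches_longhand_everywhere(self, table):
        got = g_statistic(make_counts(*table)).values[0]
        assert got == pytest.approx(longhand_g(*table), rel=1e-10, abs=1e-10)

    def test_g_is_linear_in_total_count(self, rng):
        ah, rh, al, rl = rng.integers(1, 100, 4)
        g1 = g_statistic(make_counts(ah, rh, al, rl)).values[0]
        g2 = g_statistic(make_counts(2 * ah, 2 * rh, 2 * al, 2 * rl)).values[0]
        assert g2 == pytest.approx(2 * g1, rel=1e-10)

    @pytest.mark.parametrize("table,expected", [
        ((30, 70, 30, 70), 0.0),
        ((100, 0, 0, 100), np.sqrt(2)),
    ])
    def test_euclidean_distance_examples(self, table, expected):
        assert euclidean_distance(make_counts(*table)).values[0] == \
            pytest.approx(expected)

    @given(counts_2x2)
    @settings(max_examples=200, derandomize=True)
    def test_ed_equals_sqrt2_abs_dsnp(self, table):
        bc = make_counts(*table)
        ed = euclidean_distance(bc).values[0]
        ds = delta_snp(bc).values[0]
        assert ed == pytest.approx(np.sqrt(2) * abs(ds), rel=1e-12, abs=1e-12)

    def test_lod_zero_at_equal_frequencies(self):
        assert lod_statistic(make_counts(30, 70, 30, 70)).values[0] == 0.0

    def test_lod_likelihood_ratio_identity_with_g(self):
        bc = make_counts(60, 40, 40, 60)
        lod = lod_statistic(bc).values[0]
        assert lod == pytest.approx(1.74895, abs=1e-5)
        assert lod == pytest.approx(g_statistic(bc).values[0] / (2 * LN10),
                                    rel=1e-12)

    def test_lod_symmetric_under_bulk_swap(self):
        a = lod_statistic(make_counts(75, 25, 33, 67)).values[0]
        b = lod_statistic(make_counts(33, 67, 75, 25)).values[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_lod_against_fixed_null_frequency(self):
        # testing both bulks against 0.5 instead of the pooled MLE
        bc = make_counts(60, 40, 60, 40)
        assert lod_statistic(bc).values[0] == 0.0
        assert lod_statistic(bc, null_p=0.5).values[0] > 0.0


class TestTricubeSmooth:
    def test_constant_track_is_preserved(self):
        pos = np.arange(1.0, 101.0) * 10
        track = StatTrack("dsnp", pos, np.full(100, 0.37))
        out = tricube_smooth(track, window_bp=100.0)
        assert out.name == "tdsnp"
        np.testing.assert_allclose(out.values, 0.37, rtol=1e-12)

    def test_single_defined_locus_keeps_its_value(self):
        pos = np.array([10.0, 20.0, 30.0])
        vals = np.array([np.nan, 0.8, np.nan])
        out = tricube_smooth(StatTrack("g", pos, vals), window_bp=15.0)
        assert out.values[1] == pytest.approx(0.8)

    def test_hand_evaluated_kernel_weights(self):
        # three loci at spacing h/2 with values (0, 1, 0): the middle
        # smooths to 1 / (1 + 2 w) with w = (1 - (1/2)^3)^3
        h = 100.0
        pos = np.array([0.0, h / 2, h])
        track = StatTrack("dsnp", pos, np.array([0.0, 1.0, 0.0]))
        out = tricube_smooth(track, window_bp=h)
        w = (1 - 0.5 ** 3) ** 3
        assert w == pytest.approx(0.669921875)
        assert out.values[1] == pytest.approx(1 / (1 + 2 * w))
        assert out.values[1] == pytest.approx(0.42737, abs=1e-5)

    def test_uniform_fast_path_matches_general_path(self, rng):
        # evenly spaced loci: convolution result == windowed loop result
        n = 200
        pos = np.arange(1.0, n + 1.0) * 50
        vals = rng.standard_normal(n)
        vals[rng.integers(0, n, 10)] = np.nan
        track = StatTrack("dsnp", pos, vals)
        fast = tricube_smooth(track, window_bp=500.0)
        jitter = pos.copy()
        jitter[0] -= 1e-7        # break exact uniformity only
        slow = tricube_smooth(StatTrack("dsnp", jitter, vals), 500.0)
        np.testing.assert_allclose(fast.values, slow.values,
                                   rtol=1e-8, atol=1e-8)

    def test_smoothing_reduces_variance(self, rng):
        pos = np.arange(1.0, 501.0) * 10
        track = StatTrack("g", pos, rng.exponential(1.0, 500))
        out = tricube_smooth(track, window_bp=200.0)
        assert np.nanvar(out.values) <= np.nanvar(track.values)


class TestLoessBlockSmooth:
    def _track(self, values, spacing=10_000.0):
        pos = np.arange(1.0, len(values) + 1.0) * spacing
        return StatTrack("dsnp", pos, np.asarray(values, dtype=float))

    def test_constant_track_is_preserved(self):
        out = loess_block_smooth(self._track(np.full(300, 0.2)),
                                 window_bp=300_000.0)
        assert out.name == "afdexp"
        np.testing.assert_allclose(out.values, 0.2, atol=1e-12)

    def test_linear_trend_is_reproduced(self):
        n = 300
        vals = np.linspace(-0.5, 0.5, n)
        track = self._track(vals)
        out = loess_block_smooth(track, window_bp=300_000.0)
        interior = slice(30, n - 30)
        np.testing.assert_allclose(out.values[interior], vals[interior],
                                   atol=1e-6)

    def test_block_values_bounded_by_neighbouring_block_means(self, rng):
        n = 400
        track = self._track(rng.standard_normal(n))
        wb = 400_000.0
        out = loess_block_smooth(track, window_bp=wb)
        block = np.floor((track.positions - track.positions.min()) / wb)
        means = np.array([track.values[block == b].mean()
                          for b in np.unique(block)])
        lo, hi = means.min(), means.max()
        assert (out.values >= lo - 1e-9).all()
        assert (out.values <= hi + 1e-9).all()

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            loess_block_smooth(self._track(np.zeros(10)), window_bp=1e9)


class TestEdPowerSmooth:
    def _track(self, values):
        pos = np.arange(1.0, len(values) + 1.0)
        return StatTrack("edm", pos, np.asarray(values, dtype=float))

    def test_constant_interior_value(self):
        out = ed_power_smooth(self._track(np.full(300, 0.5)),
                              ed_window_snps=100)
        assert out.name == "ed100_4"
        np.testing.assert_allclose(out.values[50:200], (100 * 0.5) ** 4,
                                   rtol=1e-12)

    def test_zero_track_stays_zero(self):
        out = ed_power_smooth(self._track(np.zeros(150)), 100)
        assert (out.values == 0).all()

    def test_impulse_plateau_spans_window_count(self):
        vals = np.zeros(400)
        vals[200] = 1.0
        out = ed_power_smooth(self._track(vals), ed_window_snps=100)
        covered = np.flatnonzero(out.values == 1.0)
        assert covered.size == 100
        # centred window: 50 left, 49 right of the focal SNP
        assert covered[0] == 200 - 49 and covered[-1] == 200 + 50

    def test_matches_bruteforce_windowed_sum(self, rng):
        vals = rng.random(120)
        out = ed_power_smooth(self._track(vals), ed_window_snps=30)
        brute = np.array([
            vals[max(0, i - 15): i + 15].sum() ** 4 for i in range(120)
        ])
        np.testing.assert_allclose(out.values, brute, rtol=1e-10)

    def test_window_longer_than_track_rejected(self):
        with pytest.raises(ValueError):
            ed_power_smooth(self._track(np.zeros(10)), 100)


class TestComputeAll:
    def test_returns_all_nine_aligned_tracks(self, rng):
        n = 400
        pos = np.arange(1.0, n + 1.0) * 10_000
        bc = make_counts(rng.integers(0, 60, n), rng.integers(1, 60, n),
                         rng.integers(0, 60, n), rng.integers(1, 60, n),
                         positions=pos)
        tracks = compute_all(bc, window_bp=300_000.0, ed_window_snps=20)
        assert set(tracks) == {"dsnp", "tdsnp", "afdexp", "g", "gprime",
                               "edm", "ed100_4", "lod", "smlod"}
        for t in tracks.values():
            assert t.values.shape == (n,)
            np.testing.assert_array_equal(t.positions, pos)

    def test_null_counts_have_centered_dsnp_and_chi2_like_g(self, rng):
        # equal true frequencies: dsnp mean ~ 0 and G mean ~ E[chi2(1)] = 1
        n = 40_000
        depth = 400
        alt_h = rng.binomial(depth, 0.5, n)
        alt_l = rng.binomial(depth, 0.5, n)
        bc = make_counts(alt_h, depth - alt_h, alt_l, depth - alt_l)
        ds = delta_snp(bc).values
        g = g_statistic(bc).values
        assert abs(ds.mean()) < 4 * ds.std() / np.sqrt(n)
        assert g.mean() == pytest.approx(1.0, abs=0.05)
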