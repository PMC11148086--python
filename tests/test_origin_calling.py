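import numpy as np
import pytest
from hypothesis import given, strategies as st

from okseq import (
    BinnedStrandedTrack,
    CallerParams,
    ValidationError,
    call_origins,
    call_regions,
    derivative,
    fwhm_cutoff,
    hann_window,
    smooth,
)
from okseq.origin_calling import SmoothedDerivative, _convolve_same


def brute_force_convolve(x, w):
    """Independent O(n*m) zero-padded convolution with the caller's alignment."""
    n, m = len(x), len(w)
    o = (m - 1) // 2
    out = np.zeros(n)
    for t in range(n):
        acc = 0.0
        for i in range(m):
            j = t + o - i
            if 0 <= j < n:
                acc += x[j] * w[i]
        out[t] = acc
    return out


class TestHannWindow:
    def test_m3_is_identity_kernel(self):
        assert np.allclose(hann_window(3), [0.0, 1.0, 0.0])

    def test_m5_matches_cosine_formula(self):
        assert np.allclose(hann_window(5), [0.0, 0.25, 0.5, 0.25, 0.0])

    @pytest.mark.parametrize("m", [3, 4, 5, 60, 61])
    def test_unit_sum_symmetric_zero_endpoints(self, m):
        w = hann_window(m)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, w[::-1])
        assert w[0] == w[-1] == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            hann_window(2)


class TestSmoothing:
    def test_impulse_response_is_kernel(self):
        track = BinnedStrandedTrack("c", 1000, np.array([0, 0, 4, 0, 0.0]), np.zeros(5))
        params = CallerParams(window_bp=5000, bin_size=1000)
        sw, _, _ = smooth(track, params)
        assert np.allclose(sw, [0.0, 1.0, 2.0, 1.0, 0.0])

    def test_constant_signal_invariant_in_interior(self, rng):
        track = BinnedStrandedTrack("c", 1000, np.full(200, 7.0), np.zeros(200))
        params = CallerParams(window_bp=20_000, bin_size=1000)
        sw, _, valid = smooth(track, params)
        assert np.allclose(sw[valid], 7.0)

    def test_matches_bruteforce_on_random_signal(self, rng):
        x = rng.uniform(0, 50, 300)
        track = BinnedStrandedTrack("c", 1000, x, x[::-1].copy())
        params = CallerParams(window_bp=60_000, bin_size=1000)
        sw, sc, _ = smooth(track, params)
        w = hann_window(60)
        assert np.allclose(sw, brute_force_convolve(x, w), rtol=1e-9, atol=1e-12)
        assert np.allclose(sc, brute_force_convolve(x[::-1], w), rtol=1e-9, atol=1e-12)

    def test_track_shorter_than_window_rejected(self):
        track = BinnedStrandedTrack("c", 1000, np.zeros(10), np.zeros(10))
        with pytest.raises(ValidationError):
            smooth(track, CallerParams(window_bp=60_000))

    def test_edge_mask_width(self):
        track = BinnedStrandedTrack("c", 1000, np.zeros(100), np.zeros(100))
        _, _, valid = smooth(track, CallerParams(window_bp=60_000))
        assert not valid[:30].any() and not valid[-30:].any()
        assert valid[30:70].all()


class TestDerivative:
    def test_forward_difference(self):
        assert np.allclose(derivative(np.array([1.0, 2.0, 4.0])), [1.0, 2.0])

    def test_telescoping_sum(self, rng):
        s = rng.normal(size=50)
        assert derivative(s).sum() == pytest.approx(s[-1] - s[0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            derivative(np.array([1.0]))


class TestCallRegions:
    @staticmethod
    def _der(der_w, der_c, valid=None):
        der_w = np.asarray(der_w, dtype=float)
        if valid is None:
            valid = np.ones(len(der_w), dtype=bool)
        return SmoothedDerivative("c", 1000, der_w, np.asarray(der_c, dtype=float), valid)

    def test_hand_enumerated_region(self):
        der = self._der([-1, -2, +1], [+1, +1, +1])
        calls = call_regions(der, CallerParams())
        assert len(calls) == 1
        (o,) = calls
        assert o.region == (0, 3)
        assert o.max_score == pytest.approx(2.0)
        assert o.summit_bp == 2000  # junction 1, leftmost argmax of scores {1, 2}

    def test_no_sign_pattern_gives_empty(self):
        assert call_regions(self._der([1, 2, 0.5], [1, 1, 1])) == []

    def test_region_respects_valid_mask(self):
        der = self._der([-1, -1, -1], [1, 1, 1], valid=np.array([False, True, False]))
        calls = call_regions(der)
        assert [o.region for o in calls] == [(1, 3)]

    def test_every_emitted_junction_satisfies_sign_pattern(self, rng):
        der = self._der(rng.normal(size=500), rng.normal(size=500))
        for o in call_regions(der):
            a, b = o.region
            assert (der.der_w[a : b - 1] < 0).all()
            assert (der.der_c[a : b - 1] > 0).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_min_region_bins_monotone(self, seed):
        r = np.random.default_rng(seed)
        der = self._der(r.normal(size=120), r.normal(size=120))
        counts = [
            len(call_regions(der, CallerParams(min_region_bins=k))) for k in (1, 2, 4, 8)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFwhmCutoff:
    def test_gaussian_half_maximum_location(self):
        scores = np.random.default_rng(0).normal(0, 1, 10_000)
        cutoff = fwhm_cutoff(scores)
        assert -1.35 <= cutoff <= -1.00  # theory: -sigma*sqrt(2 ln 2) = -1.1774
        retained = (scores >= cutoff).mean()
        assert retained == pytest.approx(0.879, abs=0.02)

    def test_median_shift_equivariance(self):
        scores = np.random.default_rng(1).normal(0, 1, 5_000)
        assert fwhm_cutoff(scores + 5.0) == pytest.approx(fwhm_cutoff(scores) + 5.0)

    def test_left_skewed_mixture_removes_low_component(self):
        # 90% N(0,1) + 10% N(-4,1): the cutoff sits at the main mode's lower
        # half-maximum (~ -1.18), so the analytic retained fraction is
        # 0.9*Phi(1.1774) + 0.1*Phi(-4 + 2.82 ...) ~= 0.792 and nearly all of
        # the low component falls below it
        r = np.random.default_rng(2)
        main = r.normal(0, 1, 9_000)
        low = r.normal(-4, 1, 1_000)
        scores = np.concatenate([main, low])
        cutoff = fwhm_cutoff(scores)
        assert -2.5 < cutoff < -0.8
        assert (scores >= cutoff).mean() == pytest.approx(0.792, abs=0.04)
        assert (low >= cutoff).mean() < 0.1  # low-score component mostly removed
        assert (main >= cutoff).mean() > 0.8

    def test_identical_scores_all_pass(self):
        assert fwhm_cutoff([1.5] * 100) == 1.5


class TestCallOrigins:
    def test_noiseless_single_origin(self, single_origin_track):
        track, cfg = single_origin_track
        origins = call_origins(track)
        assert len(origins) == 1
        assert abs(origins[0].summit_bp - cfg.origins[0].position) <= 1000

    def test_all_zero_track_empty(self):
        track = BinnedStrandedTrack("c", 1000, np.zeros(200), np.zeros(200))
        assert call_origins(track) == []

    def test_chromosome_order_invariance(self, rng):
        tracks = {}
        for chrom in ("chr1", "chr2", "chr3"):
            w = rng.poisson(20, 400).astype(float)
            c = rng.poisson(20, 400).astype(float)
            tracks[chrom] = BinnedStrandedTrack(chrom, 1000, w, c)
        a = call_origins(dict(tracks))
        b = call_origins(dict(reversed(list(tracks.items()))))
        assert [(o.chrom, o.region, o.summit_bp, o.passed_filter) for o in a] == [
            (o.chrom, o.region, o.summit_bp, o.passed_filter) for o in b
        ]

    def test_short_chromosome_skipped(self, single_origin_track, caplog):
        track, _ = single_origin_track
        short = BinnedStrandedTrack("tiny", 1000, np.zeros(5), np.zeros(5))
        origins = call_origins({"chrS": track, "tiny": short})
        assert {o.chrom for o in origins} == {"chrS"}


class TestAlignment:
    def test_even_window_keeps_step_derivative_peak_at_junction(self):
        # a unit step between bins 199 and 200: the smoothed derivative must
        # peak at the 200 kb junction for both even and odd window widths
        x = np.zeros(400)
        x[200:] = 1.0
        for m in (60, 61):
            d = np.diff(_convolve_same(x, hann_window(m)))
            assert int(np.argmax(d)) + 1 == 200
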