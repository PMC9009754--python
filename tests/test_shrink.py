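import numpy as np
import pytest

from thzshrink import (
    align,
    compute_thresholds,
    find_resonances,
    hard_threshold,
    la_filters,
    modwt_forward,
    modwt_inverse,
    reconstruct,
    run_identify,
)
from thzshrink.shrink import ThresholdSet
from thzshrink.synth import Scenario
from conftest import make_spectrum


def aligned_decomposition(values=None, n=321, J=6, seed=0):
    axis = 0.2 + 0.005 * np.arange(n)
    if values is None:
        values = np.random.default_rng(seed).normal(size=n)
    return align(
        modwt_forward(values, la_filters(8), J, freq=axis, band=(axis[0], axis[-1]))
    )


class TestThresholds:
    def test_zero_coefficients_give_zero_tau(self):
        d = aligned_decomposition()
        d = d.replace_levels({j: np.zeros(d.n) for j in d.W})
        ts = compute_thresholds(d, kept={3, 4})
        assert ts.tau == {3: 0.0, 4: 0.0}

    def test_tau_is_in_window_max(self):
        d = aligned_decomposition()
        w = np.zeros(d.n)
        w[np.argmin(np.abs(d.freq - 0.32))] = 0.4  # inside the 0.2-0.4 window
        w[np.argmin(np.abs(d.freq - 1.0))] = 9.0  # outside any window
        d = d.replace_levels({3: w})
        ts = compute_thresholds(d, kept={3})
        assert ts.tau[3] == pytest.approx(0.4)

    def test_window_clipped_to_band(self):
        # band ends at 1.6 THz: the upper window vanishes, tau comes from
        # the lower window only
        n = 281
        axis = 0.2 + 0.005 * np.arange(n)
        d = align(modwt_forward(np.ones(n) + np.eye(n)[40], la_filters(8), 6, freq=axis))
        w = np.zeros(n)
        w[np.argmin(np.abs(axis - 0.3))] = 0.7
        w[np.argmin(np.abs(axis - 1.55))] = 5.0
        d = d.replace_levels({3: w})
        ts = compute_thresholds(d, kept={3}, band=(0.2, 1.6))
        assert len(ts.source_index_ranges) == 1
        assert ts.tau[3] == pytest.approx(0.7)

    def test_all_windows_outside_band_fatal(self):
        d = aligned_decomposition()
        with pytest.raises(ValueError, match="window"):
            compute_thresholds(d, kept={3}, band=(0.5, 1.5))

    def test_requires_alignment(self):
        n = 321
        axis = 0.2 + 0.005 * np.arange(n)
        d = modwt_forward(np.random.default_rng(0).normal(size=n), la_filters(8), 6, freq=axis)
        with pytest.raises(ValueError, match="aligned"):
            compute_thresholds(d, kept={3})


class TestHardThreshold:
    def _with_level(self, j, seq):
        d = aligned_decomposition()
        w = np.zeros(d.n)
        w[: len(seq)] = seq
        return d.replace_levels({j: w}), w

    def _tau(self, mapping):
        return ThresholdSet(tau=mapping, windows=((0.3, 0.2),), source_index_ranges=((0, 1),))

    def test_rule_application(self):
        d, _ = self._with_level(3, [3.0, -1.0, 0.5])
        out = hard_threshold(d, self._tau({3: 1.0}))
        np.testing.assert_allclose(out.W[3][:3], [3.0, -1.0, 0.0])

    def test_zero_tau_is_identity(self):
        d = aligned_decomposition(seed=5)
        out = hard_threshold(d, self._tau({j: 0.0 for j in d.W}))
        for j in d.W:
            np.testing.assert_array_equal(out.W[j], d.W[j])

    def test_idempotence(self):
        d = aligned_decomposition(seed=6)
        ts = self._tau({j: 0.8 for j in d.W})
        once = hard_threshold(d, ts)
        twice = hard_threshold(once, ts)
        for j in d.W:
            np.testing.assert_array_equal(once.W[j], twice.W[j])

    def test_excluded_levels_fully_zeroed(self):
        d = aligned_decomposition(seed=7)
        out = hard_threshold(d, self._tau({3: 0.5}), excluded={1, 2})
        assert not out.W[1].any() and not out.W[2].any()
        np.testing.assert_array_equal(out.V, d.V)

    def test_raising_tau_never_adds_survivors(self):
        d = aligned_decomposition(seed=8)
        counts = []
        for tau in (0.0, 0.5, 1.0, 2.0, 5.0):
            out = hard_threshold(d, self._tau({j: tau for j in d.W}))
            counts.append(sum(int(np.count_nonzero(out.W[j])) for j in d.W))
        assert counts == sorted(counts, reverse=True)


class TestReconstruct:
    def test_no_shrinkage_reproduces_input(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=321)
        d = aligned_decomposition(values=x)
        ts = ThresholdSet(
            tau={j: 0.0 for j in d.W}, windows=((0.3, 0.2),), source_index_ranges=((0, 1),)
        )
        s = reconstruct(hard_threshold(d, ts))
        np.testing.assert_allclose(s.values, x, atol=1e-10 * np.abs(x).max())
        assert s.kind == "derivative"

    def test_all_excluded_leaves_scaling_baseline(self):
        # independent oracle: apply the inverse pyramid by explicit circulant
        # matrices to a decomposition whose detail levels are zeroed
        rng = np.random.default_rng(10)
        x = rng.normal(size=64)
        axis = 0.2 + 0.005 * np.arange(64)
        d = align(modwt_forward(x, la_filters(8), 4, freq=axis))
        ts = ThresholdSet(tau={}, windows=((0.3, 0.2),), source_index_ranges=((0, 1),))
        zeroed = hard_threshold(d, ts, excluded={1, 2, 3, 4})
        got = reconstruct(zeroed).values

        fp = la_filters(8)
        n = 64
        G = np.zeros((n, n))
        for t in range(n):
            for k in range(fp.L):
                G[t, :] += 0.0
        def inv_apply(v, taps, stride):
            out = np.zeros(n)
            for t in range(n):
                out[t] = sum(taps[k] * v[(t + stride * k) % n] for k in range(fp.L))
            return out

        v = d.V.copy()
        for j in range(4, 0, -1):
            v = inv_apply(v, fp.g, 2 ** (j - 1))
        np.testing.assert_allclose(got, v, atol=1e-12)


class TestFindResonances:
    def test_parabolic_bump_single_peak(self, thz_axis):
        y = 1.0 - ((thz_axis - 1.0) / 0.5) ** 2
        s = make_spectrum(y, thz_axis, kind="derivative")
        peaks = find_resonances(s)
        assert len(peaks) == 1
        assert peaks.peaks[0].frequency == pytest.approx(1.0)

    def test_flat_input_empty(self, thz_axis):
        s = make_spectrum(np.zeros(321), thz_axis, kind="derivative")
        assert len(find_resonances(s)) == 0

    def test_prominence_floor_suppresses_small_bump(self, thz_axis):
        y = np.zeros(321)
        y += 1.0 * np.exp(-((thz_axis - 0.7) ** 2) / (2 * 0.02**2))
        y += 0.03 * np.exp(-((thz_axis - 1.3) ** 2) / (2 * 0.02**2))
        peaks = find_resonances(make_spectrum(y, thz_axis, kind="derivative"), 0.05)
        assert len(peaks) == 1
        assert peaks.peaks[0].frequency == pytest.approx(0.7, abs=0.01)

    def test_negative_maxima_not_reported(self, thz_axis):
        y = -1.0 + 0.5 * np.exp(-((thz_axis - 1.0) ** 2) / (2 * 0.05**2))
        peaks = find_resonances(make_spectrum(y, thz_axis, kind="derivative"))
        assert len(peaks) == 0

    def test_matching_within_tolerance(self, thz_axis):
        y = np.exp(-((thz_axis - 0.915) ** 2) / (2 * 0.02**2))
        peaks = find_resonances(
            make_spectrum(y, thz_axis, kind="derivative"), reference=[0.9, 1.4], match_tol=0.02
        )
        assert peaks.matches[0.9] == pytest.approx(0.915)
        assert peaks.matches[1.4] is None


class TestPipelineProperties:
    def test_determinism_bit_identical(self):
        sc = Scenario(
            lines=(__import__("thzshrink").Line(0.9, 0.5, 0.03),),
            sigma=16.0,
            seed=3,
        )
        a = run_identify(sc)
        b = run_identify(sc)
        assert a.peaks == b.peaks
        np.testing.assert_array_equal(a.reconstructed.values, b.reconstructed.values)

    def test_null_scenario_yields_no_peaks(self):
        sc = Scenario(lines=(), sigma=0.0, snr_db=None, water_vapor=False, seed=0)
        res = run_identify(sc)
        assert len(res.peaks) == 0
        np.testing.assert_allclose(res.reconstructed.values, 0.0, atol=1e-10)
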