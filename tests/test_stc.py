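import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import icspread as ic
from icspread.neurometric import DPrimeMatrix
from icspread.stc import (
    InsufficientDataError,
    SpatialTuningCurve,
    TonotopicMap,
    _count_runs,
    assign_cf,
    best_site,
    build_stc,
    count_tips,
    measure_spread,
    reference_level,
    spatial_spread,
    spectral_spread,
)


def _dp_from_cumulative(cum, levels=None):
    """Wrap a cumulative-d' matrix (first row must be 0) as a DPrimeMatrix."""
    cum = np.asarray(cum, dtype=float)
    n_levels, n_channels = cum.shape
    levels = np.arange(n_levels, dtype=float) if levels is None else levels
    return DPrimeMatrix(
        pairwise=np.diff(cum, axis=0),
        cumulative=cum,
        levels=np.asarray(levels, dtype=float),
        levels_db=np.asarray(levels, dtype=float),
        modality="electric",
        n_trials=np.full(n_levels, 39),
        degenerate=np.zeros(n_channels, dtype=bool),
    )


def _monotone_cumulative(draw_matrix):
    cum = np.vstack([np.zeros(draw_matrix.shape[1]), np.cumsum(draw_matrix, axis=0)])
    return cum


class TestBuildStc:
    def test_separable_surface_best_site_and_threshold(self):
        # d'(L, ch) = L * g(ch), g peaked at channel 7: threshold is
        # exactly 1/g(ch) under linear interpolation, minimized at BS=7
        ch = np.arange(16)
        g = np.exp(-0.5 * ((ch - 7) / 2.0) ** 2)
        levels = np.linspace(0.0, 10.0, 11)
        cum = levels[:, None] * g[None, :]
        stc = build_stc(_dp_from_cumulative(cum, levels))
        assert stc.best_site == 7
        assert stc.threshold_level == pytest.approx(1.0 / g[7])
        assert best_site(stc) == (7, pytest.approx(1.0 / g[7]))

    def test_all_zero_matrix_flags_no_response(self):
        stc = build_stc(_dp_from_cumulative(np.zeros((5, 8))))
        assert not stc.has_response
        assert stc.best_site is None
        assert all(len(v) == 0 for v in stc.contours.values())
        with pytest.raises(InsufficientDataError):
            best_site(stc)

    def test_contours_extracted_at_1_2_4(self):
        levels = np.linspace(0.0, 10.0, 11)
        g = np.exp(-0.5 * ((np.arange(16) - 7) / 2.0) ** 2)
        stc = build_stc(_dp_from_cumulative(levels[:, None] * g[None, :], levels))
        assert set(stc.contours) == {1.0, 2.0, 4.0}
        assert all(len(stc.contours[lv]) >= 1 for lv in (1.0, 2.0, 4.0))
        # contour vertices live on the physical (level, channel) grid
        seg = stc.contours[1.0][0]
        assert seg[:, 0].min() >= levels[0] and seg[:, 0].max() <= levels[-1]
        assert seg[:, 1].min() >= 0 and seg[:, 1].max() <= 15

    @given(
        arrays(
            float,
            (4, 6),
            elements=st.floats(0.0, 2.0, allow_nan=False),
        )
    )
    def test_monotone_surface_single_valued_threshold(self, pw):
        """With cumulative d' non-decreasing in level, each channel crosses
        d'=1 at most once (brute-force crossing count)."""
        cum = _monotone_cumulative(pw)
        stc = build_stc(_dp_from_cumulative(cum))
        for ch in range(cum.shape[1]):
            crossings = np.sum(
                np.diff((cum[:, ch] >= 1.0).astype(int)) == 1
            )
            assert crossings <= 1
            if crossings == 1:
                assert np.isfinite(stc.channel_thresholds[ch])

    def test_tie_broken_toward_steeper_growth(self):
        cum = np.zeros((4, 4))
        # channels 1 and 2 both cross 1 at level index 1
        cum[:, 1] = [0.0, 1.0, 1.5, 2.0]
        cum[:, 2] = [0.0, 1.0, 3.0, 4.0]  # steeper one grid-step above
        stc = build_stc(_dp_from_cumulative(cum))
        assert stc.best_site == 2

    def test_tie_falls_back_to_lower_index(self):
        cum = np.zeros((4, 4))
        cum[:, 1] = [0.0, 1.0, 2.0, 3.0]
        cum[:, 3] = [0.0, 1.0, 2.0, 3.0]
        stc = build_stc(_dp_from_cumulative(cum))
        assert stc.best_site == 1


def _stc_with_mask(bs_profile, mask_rows, levels=None):
    """Build an STC whose BS follows ``bs_profile`` and whose other
    channels are shaped by ``mask_rows`` (levels x channels cumulative)."""
    cum = np.asarray(mask_rows, dtype=float)
    stc = build_stc(_dp_from_cumulative(cum, levels))
    return stc


class TestSpatialSpread:
    def _surface(self):
        # 4 levels x 16 channels; BS = 7 reaches d'=2 at level 2, d'=4 at 3
        cum = np.zeros((4, 16))
        cum[1, 7] = 1.0
        cum[2, 5:10] = [1.2, 1.5, 2.5, 1.5, 1.2]
        cum[3, 4:11] = [1.1, 1.6, 2.0, 4.5, 2.0, 1.6, 1.1]
        return cum

    def test_span_and_micrometres(self):
        stc = _stc_with_mask(None, self._surface())
        m = spatial_spread(stc, 2.0, channel_pitch_um=50.0)
        assert (m.ch_min, m.ch_max) == (5, 9)
        assert m.spread_channels == 4.0
        assert m.spread_um == 200.0
        assert not m.censored

    def test_only_bs_suprathreshold_gives_zero(self):
        cum = np.zeros((3, 16))
        cum[1, 7] = 1.1
        cum[2, 7] = 2.5
        stc = _stc_with_mask(None, cum)
        m = spatial_spread(stc, 2.0)
        assert m.spread_channels == 0.0
        assert m.spread_um == 0.0

    def test_edge_touching_marks_censored(self):
        cum = np.zeros((3, 6))
        cum[1, 0:3] = [1.5, 2.5, 1.5]
        cum[2, 0:4] = [2.0, 4.5, 2.0, 1.2]
        stc = _stc_with_mask(None, cum)
        m = spatial_spread(stc, 2.0)
        assert m.censored

    def test_unreached_reference_level_missing(self):
        cum = np.zeros((3, 6))
        cum[1, 2] = 1.1
        cum[2, 2] = 2.5
        stc = _stc_with_mask(None, cum)
        m = spatial_spread(stc, 4.0)
        assert m.spread_channels is None and m.censored

    def test_reference_level_interpolated(self):
        cum = np.zeros((3, 4))
        cum[:, 1] = [0.0, 1.0, 3.0]
        stc = _stc_with_mask(None, cum)
        # BS reaches 2 halfway between tested levels 1 and 2
        assert reference_level(stc, 2.0) == pytest.approx(1.5)

    @given(
        arrays(float, (5, 10), elements=st.floats(0.0, 1.5, allow_nan=False))
    )
    def test_spread_at_d4_at_least_d2(self, pw):
        cum = _monotone_cumulative(pw)
        stc = build_stc(_dp_from_cumulative(cum))
        if not stc.has_response:
            return
        m2 = spatial_spread(stc, 2.0)
        m4 = spatial_spread(stc, 4.0)
        if m2.spread_channels is None or m4.spread_channels is None:
            return
        assert m4.spread_channels >= m2.spread_channels


class TestTips:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            ("0001111000", 1),
            ("0110011000", 2),
            ("0000000000", 0),
            ("1111111111", 1),
            ("1010101010", 5),
        ],
    )
    def test_run_counting(self, mask, expected):
        arr = np.array([c == "1" for c in mask])
        assert _count_runs(arr) == expected

    def test_count_tips_on_surface(self):
        cum = np.zeros((3, 10))
        cum[1, 4] = 1.1
        cum[2, 1:3] = 1.4  # isolated second group
        cum[2, 4] = 2.5
        cum[2, 6] = 1.2  # isolated third group
        stc = _stc_with_mask(None, cum)
        assert count_tips(stc) == 3

    def test_missing_when_bs_below_two(self):
        cum = np.zeros((3, 10))
        cum[1, 4] = 1.1
        cum[2, 4] = 1.5
        stc = _stc_with_mask(None, cum)
        assert count_tips(stc) is None


class TestSpectralSpread:
    def test_two_octaves(self):
        tmap = TonotopicMap.from_cf([32.0, 16.0, 8.0])
        assert spectral_spread(0, 2, tmap) == pytest.approx(2.0)

    def test_zero_width(self):
        tmap = TonotopicMap.from_cf([32.0, 16.0, 8.0])
        assert spectral_spread(1, 1, tmap) == 0.0

    def test_flip_invariance(self):
        """Relabeling channel order (ventral/dorsal flip) leaves octave
        spread unchanged when the map flips consistently."""
        cf = ic.default_cf_map()
        tmap = TonotopicMap.from_cf(cf)
        flipped = TonotopicMap.from_cf(cf[::-1])
        n = cf.size - 1
        assert spectral_spread(3, 9, tmap) == pytest.approx(
            spectral_spread(n - 9, n - 3, flipped)
        )

    def test_out_of_range_channel_uses_fitted_map(self):
        tmap = TonotopicMap.from_cf(ic.default_cf_map())
        ratio = (8.0 / 48.0) ** (1 / 15)
        assert tmap.cf_at(16) == pytest.approx(8.0 * ratio, rel=1e-6)


class TestAssignCf:
    def test_two_point_fit_exact(self):
        tmap = assign_cf([12, 5], [8.0, 32.0], n_channels=16)
        assert tmap.cf_at(12) == pytest.approx(8.0)
        assert tmap.cf_at(5) == pytest.approx(32.0)
        assert tmap.extrapolated[0] and tmap.extrapolated[15]
        assert not tmap.extrapolated[8]

    def test_single_frequency_errors(self):
        with pytest.raises(InsufficientDataError):
            assign_cf([5], [32.0])

    def test_none_best_sites_dropped(self):
        with pytest.raises(InsufficientDataError):
            assign_cf([5, None], [32.0, 16.0])

    def test_non_monotone_sequence_warns_but_fits(self):
        with pytest.warns(UserWarning):
            tmap = assign_cf([2, 5, 8, 12], [48.0, 16.0, 24.0, 6.0])
        assert tmap.fit[1] != 0


class TestRecoveryFromSynthetic:
    def test_best_site_recovers_generator_center(self):
        """Acoustic runs at 32 kHz: BS lands within one channel of the
        generator's center in at least 90% of seeds."""
        proto = ic.default_protocol("acoustic")
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            truth = ic.default_truth("acoustic", seed=seed)
            rec = ic.generate_recording(truth, proto)
            stc = ic.build_stc(ic.cumulative_dprime(ic.compute_amua(rec)))
            center = np.argmin(np.abs(np.log2(truth.cf_khz / 32.0)))
            if stc.has_response and abs(stc.best_site - center) <= 1:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_tonotopic_map_recovered_within_half_octave(self):
        """Fitting CFs from acoustic best sites across frequencies
        recovers the generator's map within 0.5 octave on interpolated
        channels."""
        freqs = [8.0, 16.0, 32.0, 48.0]
        for seed in (0, 1):
            bs = []
            truth = ic.default_truth("acoustic", seed=seed)
            for f in freqs:
                proto = ic.default_protocol("acoustic", frequency_khz=f)
                rec = ic.generate_recording(truth, proto)
                stc = ic.build_stc(ic.cumulative_dprime(ic.compute_amua(rec)))
                bs.append(stc.best_site if stc.has_response else None)
            tmap = assign_cf(bs, freqs, n_channels=truth.n_channels)
            err = np.abs(np.log2(tmap.cf_khz / truth.cf_khz))
            assert np.max(err[~tmap.extrapolated]) < 0.5

    def test_rectangular_activation_recovers_width(self):
        """Flat-top recruitment of known width is recovered within one
        channel of its span."""
        proto = ic.default_protocol("electric")
        for width in (3, 6):
            truth = ic.default_truth(
                "electric", seed=41, profile="rect",
                rect_width_channels=width, center_channel=7.5,
            )
            rec = ic.generate_recording(truth, proto)
            stc = ic.build_stc(ic.cumulative_dprime(ic.compute_amua(rec)))
            m = spatial_spread(stc, 2.0)
            assert abs(m.spread_channels - (width - 1)) <= 1

    def test_spread_result_bundles_measures(self, small_acoustic):
        truth = small_acoustic["truth"]
        tmap = ic.tonotopic_ground_truth(truth)
        res = measure_spread(small_acoustic["stc"], 50.0, tmap)
        assert res.best_site == small_acoustic["stc"].best_site
        assert res.d2.octaves is not None
        assert res.n_tips >= 1
        assert res.bs_cf_khz == pytest.approx(
            float(truth.cf_khz[res.best_site])
        )
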