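"""Band power, wPLI and modulation-index primitives against closed forms
and brute-force oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmseegdx.features import (
    FeatureTable,
    band_power,
    compute_dif_features,
    compute_rst_features,
    compute_window_features,
    mi_from_distribution,
    mi_from_phase_amplitude,
    pac_mi,
    single_trace_features,
    wpli,
    wpli_from_cross_imag,
)
from tmseegdx.montage import BAND_MAP, BandDef
from tmseegdx.preprocess import EpochSet

FS = 500.0
ALPHA = BAND_MAP["alpha"]
BETA = BAND_MAP["beta"]
THETA = BAND_MAP["theta"]
GAMMA = BAND_MAP["gamma"]


def sine(freq: float, dur: float = 4.0, fs: float = FS, amp: float = 1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandPower:
    def test_sinusoid_concentrates_in_its_band(self):
        x = sine(10.0)
        assert band_power(x, ALPHA, FS) > 100 * band_power(x, BETA, FS)

    def test_white_noise_power_scales_with_bandwidth(self):
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(8):
            x = rng.standard_normal(int(30 * FS))
            ratios.append(band_power(x, BETA, FS) / band_power(x, ALPHA, FS))
        expected = (BETA.hi - BETA.lo) / (ALPHA.hi - ALPHA.lo)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.15)

    def test_zero_signal_has_zero_power(self):
        assert band_power(np.zeros(2000), ALPHA, FS) == 0.0

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="cycles"):
            band_power(np.zeros(100), THETA, FS)   # 0.2 s < 2 cycles of 4 Hz

    def test_short_signal_falls_back_to_single_segment(self):
        with pytest.warns(RuntimeWarning, match="single-segment"):
            band_power(sine(10.0, dur=0.4), ALPHA, FS)


class TestWpli:
    def test_worked_example_of_defining_formula(self):
        # |1 - 0.5 + 2 - 0.5| / (1 + 0.5 + 2 + 0.5) = 2/4
        assert wpli_from_cross_imag([1.0, -0.5, 2.0, -0.5]) == pytest.approx(0.5)

    def test_zero_denominator_convention(self):
        assert wpli_from_cross_imag([0.0, 0.0]) == 0.0

    def test_quarter_cycle_shift_gives_unity(self):
        x = sine(10.0)
        shift = int(FS / 10 / 4)           # quarter cycle of 10 Hz
        y = np.roll(x, shift)
        assert wpli(x, y, ALPHA, FS) > 0.99

    def test_identical_signals_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(4 * FS))
        assert wpli(x, x, ALPHA, FS) == pytest.approx(0.0, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            wpli(np.zeros(1000), np.zeros(999), ALPHA, FS)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_bounds_symmetry_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(3 * FS))
        y = rng.standard_normal(int(3 * FS))
        w_xy = wpli(x, y, ALPHA, FS)
        assert 0.0 <= w_xy <= 1.0
        assert wpli(y, x, ALPHA, FS) == pytest.approx(w_xy, abs=1e-12)
        assert wpli(scale * x, y, ALPHA, FS) == pytest.approx(w_xy, rel=1e-9)


class TestModulationIndex:
    def test_uniform_distribution_gives_zero(self):
        assert mi_from_distribution(np.full(18, 1 / 18)) == pytest.approx(0.0)

    def test_single_bin_gives_one(self):
        p = np.zeros(18)
        p[4] = 1.0
        assert mi_from_distribution(p) == pytest.approx(1.0)

    def test_two_equal_bins_closed_form(self):
        p = np.zeros(18)
        p[0] = p[9] = 0.5
        expected = 1 - np.log(2) / np.log(18)
        assert mi_from_distribution(p) == pytest.approx(expected, abs=1e-12)

    def test_amplitude_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        mi = mi_from_phase_amplitude(phase, amp)
        assert 0.0 <= mi <= 1.0
        assert mi_from_phase_amplitude(phase, 7.3 * amp) == pytest.approx(mi)

    def test_full_depth_modulation_matches_binned_closed_form(self):
        # s(t) = (1 + cos(phi)) * carrier + phase component: the binned
        # amplitude distribution is p_j ~ 1 + cos(phi_j); compare pac_mi
        # against the KL closed form evaluated on the exact bin averages
        fs, dur, fp, fa = 1000.0, 60.0, 6.0, 40.0
        t = np.arange(int(dur * fs)) / fs
        phi = 2 * np.pi * fp * t
        s = (1 + np.cos(phi)) * np.cos(2 * np.pi * fa * t) + 5 * np.cos(phi)
        edges = np.linspace(-np.pi, np.pi, 19)
        # exact mean of 1 + cos over each bin
        p = 1 + (np.sin(edges[1:]) - np.sin(edges[:-1])) / np.diff(edges)
        expected = mi_from_distribution(p)
        # bands wide enough that the modulation sidebands (fa +- fp) sit in
        # the amplitude band's flat passband
        measured = pac_mi(s, BandDef("phase", 4.0, 8.0), BandDef("amp", 25.0, 55.0), fs)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_unmodulated_carrier_near_zero(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        s = np.cos(2 * np.pi * 37.0 * t) + 5 * np.cos(2 * np.pi * 5.5 * t)
        assert pac_mi(s, THETA, GAMMA, fs) < 0.01

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pac_mi(np.zeros(4000), ALPHA, BandDef("custom", 12.0, 20.0), FS)



def _epochs(data: np.ndarray, fs: float = FS, window=(0.0, None)) -> EpochSet:
    end = window[1] if window[1] is not None else data.shape[-1] / fs
    names = [f"C{i}" for i in range(data.shape[-2])]
    ids = list(range(data.shape[0])) if data.ndim == 3 else [0]
    if data.ndim == 2:
        data = data[None]
    return EpochSet(data=data, fs=fs, window=(window[0], end),
                    channel_names=names, kept_epoch_ids=ids)


class TestFeatureVectors:
    def test_full_frontal_montage_yields_614_features(self, light_cfg):
        from tmseegdx.montage import FRONTAL_17

        rng = np.random.default_rng(0)
        data = rng.standard_normal((17, int(6 * FS)))
        vec = single_trace_features(data, FS, FRONTAL_17)
        assert len(vec) == 68 + 544 + 2 == 614
        kinds = pd.Series([n.split("_")[0] for n in vec.index]).value_counts()
        assert kinds["power"] == 68 and kinds["wPLI"] == 544 and kinds["MI"] == 2

    def test_identical_epochs_average_to_single_epoch_features(self):
        rng = np.random.default_rng(1)
        one = rng.standard_normal((3, int(6 * FS)))
        two = _epochs(np.stack([one, one]))
        single = _epochs(one)
        pd.testing.assert_series_equal(compute_rst_features(two),
                                       compute_rst_features(single))

    def test_amplitude_doubling_quadruples_band_power(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((2, int(6 * FS)))
        v1 = single_trace_features(base, FS, ["C0", "C1"])
        v2 = single_trace_features(2 * base, FS, ["C0", "C1"])
        assert v2["power_C0_beta"] == pytest.approx(4 * v1["power_C0_beta"], rel=1e-9)

    def test_dif_is_post_minus_pre(self):
        pre = pd.Series({"PRE_wPLI_F5-AF3_alpha": 0.4, "PRE_power_AFz_beta": 1.0})
        pst = pd.Series({"PST_wPLI_F5-AF3_alpha": 0.7, "PST_power_AFz_beta": 0.5})
        dif = compute_dif_features(pre, pst)
        assert dif["DIF_wPLI_F5-AF3_alpha"] == pytest.approx(0.3)
        assert dif["DIF_power_AFz_beta"] == pytest.approx(-0.5)

    def test_dif_requires_matching_names(self):
        with pytest.raises(ValueError, match="differ"):
            compute_dif_features(pd.Series({"PRE_power_A_beta": 1.0}),
                                 pd.Series({"PST_power_B_beta": 1.0}))

    def test_window_features_use_the_evoked_average(self):
        rng = np.random.default_rng(3)
        ep = rng.standard_normal((2, int(0.5 * FS)))
        stacked = _epochs(np.stack([ep, ep, ep]), window=(0.05, 0.55))
        single = _epochs(ep, window=(0.05, 0.55))
        pd.testing.assert_series_equal(
            compute_window_features(stacked, "PST"),
            compute_window_features(single, "PST"),
        )


class TestFeatureTable:
    def test_tsv_roundtrip(self, make_table, tmp_path):
        table = make_table(n_per_group=4, n_noise=6, seed=5)
        table.to_tsv(tmp_path / "feat.tsv")
        back = FeatureTable.from_tsv(tmp_path / "feat.tsv")
        pd.testing.assert_frame_equal(back.values, table.values)
        pd.testing.assert_series_equal(back.labels, table.labels,
                                       check_names=False)

    def test_subset_selects_by_modality_prefix(self, make_table):
        extra = {"DIF_wPLI_F5-AF3_alpha": np.zeros(8)}
        table = make_table(n_per_group=4, n_noise=3, extra=extra)
        sub = table.subset(["DIF"])
        assert list(sub.values.columns) == ["DIF_wPLI_F5-AF3_alpha"]

    def test_invalid_feature_name_rejected(self, make_table):
        with pytest.raises(ValueError):
            make_table(n_per_group=3, n_noise=1,
                       extra={"bad name": np.zeros(6)})
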