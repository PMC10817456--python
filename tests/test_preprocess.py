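"""Epoching, rejection, filtering, downsampling, window extraction and the
chain-order/provenance guarantees."""
from __future__ import annotations

import numpy as np
import pytest

from tmseegdx.features import band_power
from tmseegdx.montage import BAND_MAP
from tmseegdx.preprocess import (
    EpochSet,
    PreprocConfig,
    Recording,
    downsample,
    epoch_resting,
    epoch_tms,
    evoked_average,
    extract_windows,
    filter_epochs,
    ica_removal_cap,
    reject_bad,
)

FS = 500.0


def make_recording(dur_s: float, n_ch: int = 3, fs: float = FS, seed: int = 0,
                   markers=()) -> Recording:
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_ch, int(dur_s * fs))) * 10
    return Recording(data=data, fs=fs,
                     channel_names=[f"C{i}" for i in range(n_ch)],
                     markers=np.asarray(markers, dtype=int))


class TestEpochResting:
    def test_nonoverlapping_six_second_epochs(self):
        rec = make_recording(300.0, fs=1000.0)
        ep = epoch_resting(rec, 6.0)
        assert ep.n_epochs == 50
        assert ep.data.shape[2] == 6000

    def test_trailing_remainder_discarded(self):
        ep = epoch_resting(make_recording(11.9), 6.0)
        assert ep.n_epochs == 1

    def test_recording_shorter_than_one_epoch_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            epoch_resting(make_recording(5.9), 6.0)


class TestEpochTms:
    def test_one_epoch_per_marker(self):
        markers = (np.arange(10) * 5 * FS + 3 * FS).astype(int)
        rec = make_recording(60.0, markers=markers)
        ep = epoch_tms(rec)
        assert ep.n_epochs == len(markers)
        assert ep.data.shape[2] == int(4 * FS)

    def test_baseline_window_mean_is_zero(self):
        markers = (np.arange(5) * 5 * FS + 3 * FS).astype(int)
        ep = epoch_tms(make_recording(35.0, markers=markers))
        b0 = int(round((-1.55 + 2.0) * FS))
        b1 = int(round((-0.05 + 2.0) * FS))
        base = ep.data[:, :, b0:b1].mean(axis=2)
        assert np.allclose(base, 0.0, atol=1e-10)

    def test_constant_offset_removed(self):
        markers = (np.arange(3) * 5 * FS + 3 * FS).astype(int)
        rec = make_recording(25.0, markers=markers)
        rec.data[1] += 50.0
        ep = epoch_tms(rec)
        ep0 = epoch_tms(make_recording(25.0, markers=markers))
        assert np.allclose(ep.data[:, 1], ep0.data[:, 1], atol=1e-10)

    def test_marker_too_close_to_edge_dropped(self):
        markers = [int(0.5 * FS), int(10 * FS)]
        ep = epoch_tms(make_recording(20.0, markers=markers))
        assert ep.n_epochs == 1
        assert ep.kept_epoch_ids == [1]


class TestRejectBad:
    cfg = PreprocConfig()

    def epochs(self, seed=0, n_ep=8, n_ch=4):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_ep, n_ch, 500)) * 10
        return EpochSet(data=data, fs=FS, window=(0, 1),
                        channel_names=[f"C{i}" for i in range(n_ch)],
                        kept_epoch_ids=list(range(n_ep)))

    def test_clean_data_untouched(self):
        out, rep = reject_bad(self.epochs(), self.cfg)
        assert rep.dropped_channels == [] and rep.dropped_epochs == []
        assert out.n_epochs == 8

    def test_persistently_noisy_channel_dropped(self):
        ep = self.epochs()
        ep.data[:, 2, :] = 500.0 * np.sign(np.sin(np.arange(500)))
        out, rep = reject_bad(ep, self.cfg)
        assert rep.dropped_channels == ["C2"]
        assert out.channel_names == ["C0", "C1", "C3"]
        assert rep.dropped_epochs == []

    def test_single_spike_drops_epoch_not_channel(self):
        ep = self.epochs()
        ep.data[3, 1, 100] = 400.0
        out, rep = reject_bad(ep, self.cfg)
        assert rep.dropped_channels == []
        assert rep.dropped_epochs == [3]
        assert out.n_epochs == 7

    def test_flat_channel_dropped(self):
        ep = self.epochs()
        ep.data[:, 0, :] = 0.0
        _, rep = reject_bad(ep, self.cfg)
        assert rep.dropped_channels == ["C0"]

    def test_everything_rejected_is_an_error(self):
        # every epoch exceeds on some channel, but no channel does so in
        # more than 25 % of epochs, so all epochs (not channels) go
        ep = self.epochs()
        for i in range(ep.n_epochs):
            ep.data[i, i % 4, 5] = 400.0
        with pytest.raises(ValueError, match="all epochs"):
            reject_bad(ep, self.cfg)


class TestFilterAndDownsample:
    cfg = PreprocConfig()

    def _tone_epochs(self, freq, fs=1000.0, dur=4.0):
        t = np.arange(int(dur * fs)) / fs
        data = np.sin(2 * np.pi * freq * t)[None, None, :]
        return EpochSet(data=data, fs=fs, window=(0, dur),
                        channel_names=["C0"], kept_epoch_ids=[0])

    def test_line_noise_attenuated_20db(self):
        # steady-state attenuation, away from the filtfilt edge transients
        ep = self._tone_epochs(50.0)
        out = filter_epochs(ep, self.cfg)
        mid = slice(1000, 3000)
        atten = 20 * np.log10(np.std(ep.data[..., mid]) / np.std(out.data[..., mid]))
        assert atten >= 20

    def test_passband_flat_within_1db(self):
        ep = self._tone_epochs(10.0)
        out = filter_epochs(ep, self.cfg)
        gain = 20 * np.log10(np.std(out.data) / np.std(ep.data))
        assert abs(gain) <= 1.0

    def test_zero_in_zero_out(self):
        ep = self._tone_epochs(10.0)
        ep.data[:] = 0.0
        out = filter_epochs(ep, self.cfg)
        assert np.allclose(out.data, 0.0)

    def test_downsample_3k_to_1k_sample_count(self):
        rng = np.random.default_rng(0)
        ep = EpochSet(data=rng.standard_normal((2, 2, 12000)), fs=3000.0,
                      window=(-2, 2), channel_names=["a", "b"],
                      kept_epoch_ids=[0, 1])
        out = downsample(ep, 1000.0)
        assert out.data.shape[2] == 4000 and out.fs == 1000.0

    def test_downsample_at_target_is_identity(self):
        ep = self._tone_epochs(10.0)
        out = downsample(ep, 1000.0)
        assert out.data is ep.data and out.fs == ep.fs

    def test_alpha_band_power_preserved_through_downsampling(self):
        rng = np.random.default_rng(1)
        ep = EpochSet(data=rng.standard_normal((1, 1, 30000)), fs=3000.0,
                      window=(0, 10), channel_names=["a"], kept_epoch_ids=[0])
        out = downsample(ep, 1000.0)
        alpha = BAND_MAP["alpha"]
        p_before = band_power(ep.data[0, 0], alpha, 3000.0)
        p_after = band_power(out.data[0, 0], alpha, 1000.0)
        assert p_after == pytest.approx(p_before, rel=0.05)


class TestWindowsAndAveraging:
    def _tms_epochs(self, fs=1000.0, n_ep=3, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_ep, 2, int(4 * fs)))
        return EpochSet(data=data, fs=fs, window=(-2.0, 2.0),
                        channel_names=["a", "b"],
                        kept_epoch_ids=list(range(n_ep)))

    def test_window_sample_counts_at_1khz(self):
        wins = extract_windows(self._tms_epochs())
        assert wins["pre"].data.shape[2] == 1500
        assert wins["post"].data.shape[2] == 500

    def test_exclusion_interval_in_neither_window(self):
        wins = extract_windows(self._tms_epochs())
        assert wins["pre"].times.max() < -0.05 + 1e-9
        assert wins["post"].times.min() >= 0.05 - 1e-9
        for w in wins.values():
            assert not np.any((w.times > -0.049) & (w.times < 0.049))

    def test_boundary_samples_follow_half_open_convention(self):
        wins = extract_windows(self._tms_epochs())
        # 49 ms excluded, 50 ms is the first post sample, 51 ms included
        assert 0.049 not in np.round(wins["post"].times, 6)
        assert 0.050 == pytest.approx(wins["post"].times[0])
        assert 0.051 in np.round(wins["post"].times, 6)

    def test_short_epochs_rejected(self):
        short = self._tms_epochs()
        short = short.with_step("crop", data=short.data[:, :, :1000],
                                window=(-2.0, -1.0))
        with pytest.raises(ValueError, match="span"):
            extract_windows(short)

    def test_average_of_identical_epochs_is_the_epoch(self):
        ep = self._tms_epochs(n_ep=1)
        stacked = ep.with_step("dup", data=np.repeat(ep.data, 4, axis=0),
                               kept_epoch_ids=list(range(4)))
        avg = evoked_average(stacked)
        assert np.allclose(avg.data[0], ep.data[0])

    def test_opposite_epochs_cancel(self):
        ep = self._tms_epochs(n_ep=1)
        pm = ep.with_step("pm", data=np.concatenate([ep.data, -ep.data]),
                          kept_epoch_ids=[0, 1])
        assert np.allclose(evoked_average(pm).data, 0.0)

    def test_average_matches_bruteforce_loop(self):
        ep = self._tms_epochs(n_ep=5, seed=3)
        avg = evoked_average(ep).data[0]
        brute = np.zeros_like(avg)
        for k in range(5):
            brute += ep.data[k]
        brute /= 5
        assert np.allclose(avg, brute)


class TestChainContracts:
    def test_ica_removal_caps(self):
        assert ica_removal_cap(64, 0.20) == 12
        assert ica_removal_cap(64, 0.08) == 5
        assert ica_removal_cap(17, 0.20) == 3
        with pytest.raises(ValueError):
            ica_removal_cap(10, 0.0)

    def test_operations_do_not_mutate_input_and_record_provenance(self):
        markers = (np.arange(4) * 5 * FS + 3 * FS).astype(int)
        rec = make_recording(30.0, markers=markers)
        before = rec.data.copy()
        cfg = PreprocConfig()
        ep = epoch_tms(rec)
        ep2, _ = reject_bad(ep, cfg)
        ep3 = filter_epochs(ep2, cfg)
        ep4 = downsample(ep3, cfg.target_fs)
        assert np.array_equal(rec.data, before)
        assert ep.provenance == ("epoch_tms", "baseline")
        assert ep4.provenance[-1].startswith("downsample")
        assert list(ep4.provenance[:2]) == ["epoch_tms", "baseline"]

    def test_filtering_commutes_with_averaging(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((6, 2, 2000))
        ep = EpochSet(data=data, fs=FS, window=(0, 4), channel_names=["a", "b"],
                      kept_epoch_ids=list(range(6)))
        cfg = PreprocConfig()
        filt_then_avg = evoked_average(filter_epochs(ep, cfg)).data[0]
        avg_then_filt = filter_epochs(evoked_average(ep), cfg).data[0]
        assert np.allclose(filt_then_avg, avg_then_filt, atol=1e-8)
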