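"""Band power, weighted phase lag index, and phase-amplitude coupling features.

The three feature kinds computed on every recording modality:

* **Band power** — Welch power spectral density (500 ms Hann segments, 50 %
  overlap), integrated over the band as ``mean PSD in [lo, hi] * (hi - lo)``,
  in µV².
* **wPLI** — weighted phase lag index over the time-sample distribution of the
  analytic cross-term, ``|sum Im X| / sum |Im X|`` with
  ``X_t = x~_t conj(y~_t)``; insensitive to zero-lag coupling, 0 by convention
  when the denominator vanishes.
* **MI** — Tort modulation index: normalized KL divergence of the phase-binned
  amplitude distribution from uniform, ``(log N + sum p log p) / log N``.

A per-modality feature vector over the 17 frontal channels contains
68 power (17 x 4 bands), 544 wPLI (136 pairs x 4 bands) and 2 MI features
(theta-gamma and alpha-gamma coupling averaged over the left-DLPFC
electrodes), i.e. 614 features; four modalities give 2456.
"""
from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import (
    BANDS,
    COUPLINGS,
    DLPFC_CHANNELS,
    BandDef,
    pair_name,
)

#: Reflection padding used before band filtering / Hilbert transform, seconds.
EDGE_PAD_S = 0.25

#: Welch segment length, seconds (two cycles of the 4 Hz theta band edge).
WELCH_SEG_S = 0.5


def _check_min_cycles(n_samples: int, fs: float, lo: float, n_cycles: int = 2) -> None:
    if n_samples / fs + 1e-9 < n_cycles / lo:
        raise ValueError(
            f"signal of {n_samples / fs:.3f} s is shorter than "
            f"{n_cycles} cycles of {lo} Hz"
        )


def _reflect_pad(data: np.ndarray, n_pad: int) -> np.ndarray:
    n = data.shape[-1]
    n_pad = min(n_pad, n - 1)
    if n_pad <= 0:
        return data
    left = data[..., 1 : n_pad + 1][..., ::-1]
    right = data[..., -n_pad - 1 : -1][..., ::-1]
    return np.concatenate([left, data, right], axis=-1)


def _band_sos(band: BandDef, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz >= Nyquist {nyq} Hz")
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def band_filter(data: np.ndarray, band: BandDef, fs: float, pad_s: float = EDGE_PAD_S) -> np.ndarray:
    """Zero-phase band-pass of ``data`` (..., samples) with reflection padding."""
    n_pad = int(round(pad_s * fs))
    padded = _reflect_pad(np.asarray(data, dtype=float), n_pad)
    sos = _band_sos(band, fs)
    out = sps.sosfiltfilt(sos, padded, axis=-1)
    n_pad = padded.shape[-1] - data.shape[-1]
    return out[..., n_pad // 2 : n_pad // 2 + data.shape[-1]]


def analytic_band(data: np.ndarray, band: BandDef, fs: float, pad_s: float = EDGE_PAD_S) -> np.ndarray:
    """Analytic (Hilbert) signal of the band-filtered data; padding discarded
    only after the transform so edge effects stay in the pad."""
    n_pad = int(round(pad_s * fs))
    padded = _reflect_pad(np.asarray(data, dtype=float), n_pad)
    sos = _band_sos(band, fs)
    filtered = sps.sosfiltfilt(sos, padded, axis=-1)
    analytic = sps.hilbert(filtered, axis=-1)
    n_pad = padded.shape[-1] - data.shape[-1]
    return analytic[..., n_pad // 2 : n_pad // 2 + data.shape[-1]]


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

def band_power(x: np.ndarray, band: BandDef, fs: float) -> float:
    """Welch band power of a 1-D signal in µV²."""
    x = np.asarray(x, dtype=float)
    _check_min_cycles(x.shape[-1], fs, band.lo)
    freqs, psd = welch_psd(x, fs)
    return band_power_from_psd(freqs, psd, band)


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 500 ms Hann segments and 50 % overlap (last axis)."""
    n = x.shape[-1]
    nperseg = int(round(WELCH_SEG_S * fs))
    if nperseg > n:
        warnings.warn(
            f"signal shorter than the {WELCH_SEG_S * 1000:.0f} ms Welch segment; "
            "falling back to a single-segment periodogram",
            RuntimeWarning,
            stacklevel=2,
        )
        nperseg = n
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def band_power_from_psd(freqs: np.ndarray, psd: np.ndarray, band: BandDef) -> np.ndarray:
    """Mean PSD over frequency bins inside [lo, hi], times the bandwidth."""
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"no PSD bins fall inside band {band.name}")
    return psd[..., mask].mean(axis=-1) * (band.hi - band.lo)


# ---------------------------------------------------------------------------
# weighted phase lag index
# ---------------------------------------------------------------------------

def wpli_from_cross_imag(im_x: np.ndarray) -> float:
    """wPLI from the imaginary parts of the analytic cross-terms.

    ``|sum |Im X| sgn(Im X)| / sum |Im X|``; 0 when the denominator is 0.
    """
    im_x = np.asarray(im_x, dtype=float)
    den = np.abs(im_x).sum()
    if den == 0:
        return 0.0
    return float(abs(im_x.sum()) / den)


def wpli(x: np.ndarray, y: np.ndarray, band: BandDef, fs: float) -> float:
    """wPLI between two 1-D signals in a band, over the time-sample
    distribution of the analytic cross-term."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    _check_min_cycles(x.shape[-1], fs, band.lo)
    ax = analytic_band(x, band, fs)
    ay = analytic_band(y, band, fs)
    cross = ax * np.conj(ay)
    im = cross.imag
    # zero-lag coupling leaves only float noise in the imaginary part;
    # treat a denominator that small as the degenerate case (wPLI = 0)
    if np.abs(im).sum() <= 1e-9 * np.abs(cross).sum():
        return 0.0
    return wpli_from_cross_imag(im)


def wpli_matrix(analytic: np.ndarray) -> np.ndarray:
    """Pairwise wPLI matrix from analytic signals of shape (channels, samples)."""
    cross = analytic[:, None, :] * np.conj(analytic[None, :, :])
    im = cross.imag
    num = np.abs(im.sum(axis=-1))
    den = np.abs(im).sum(axis=-1)
    floor = 1e-9 * np.abs(cross).sum(axis=-1)
    ok = den > floor
    w = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    return w


# ---------------------------------------------------------------------------
# phase-amplitude coupling (Tort modulation index)
# ---------------------------------------------------------------------------

def mi_from_distribution(p: np.ndarray) -> float:
    """Modulation index of a phase-binned amplitude distribution.

    ``(log N + sum p log p) / log N`` with N = len(p); zero entries contribute
    nothing to the entropy sum.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("p must be a 1-D distribution over >= 2 bins")
    if (p < 0).any():
        raise ValueError("p must be non-negative")
    total = p.sum()
    if total == 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float((np.log(len(p)) + (nz * np.log(nz)).sum()) / np.log(len(p)))


def mi_from_phase_amplitude(phase: np.ndarray, amplitude: np.ndarray,
                            n_bins: int = 18) -> float:
    """Bin amplitude by phase (radians in [-pi, pi]) and evaluate the MI.

    Empty phase bins are merged into their neighbour (i.e. dropped from the
    distribution, reducing the effective bin count) with a warning.
    """
    phase = np.asarray(phase, float).ravel()
    amplitude = np.asarray(amplitude, float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have the same length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    nonempty = counts > 0
    if not nonempty.all():
        warnings.warn(
            f"{(~nonempty).sum()} empty phase bin(s) merged with neighbours",
            RuntimeWarning,
            stacklevel=2,
        )
    means = sums[nonempty] / counts[nonempty]
    if len(means) < 2:
        return 0.0
    return mi_from_distribution(means)


def pac_mi(signal: np.ndarray, phase_band: BandDef, amp_band: BandDef,
           fs: float, n_bins: int = 18) -> float:
    """Tort modulation index of phase-amplitude coupling in one signal."""
    if amp_band.lo <= phase_band.hi:
        raise ValueError(
            f"amplitude band {amp_band.name} must lie above phase band "
            f"{phase_band.name} (bands overlap)"
        )
    signal = np.asarray(signal, float)
    _check_min_cycles(signal.shape[-1], fs, phase_band.lo)
    phase = np.angle(analytic_band(signal, phase_band, fs))
    amp = np.abs(analytic_band(signal, amp_band, fs))
    return mi_from_phase_amplitude(phase, amp, n_bins=n_bins)


# ---------------------------------------------------------------------------
# per-modality feature vectors
# ---------------------------------------------------------------------------

def single_trace_features(data: np.ndarray, fs: float,
                          channel_names: list[str] | tuple[str, ...],
                          n_bins: int = 18) -> pd.Series:
    """All 614 unprefixed features of one (channels, samples) trace.

    68 power + 544 wPLI + 2 region-averaged MI features; names follow the
    ``<KIND>_<LOC>_<BAND>`` part of the grammar.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[0] != len(channel_names):
        raise ValueError("data must be (channels, samples) matching channel_names")
    names: list[str] = []
    values: list[float] = []

    freqs, psd = welch_psd(data, fs)
    analytic = {b.name: analytic_band(data, b, fs) for b in BANDS}

    for band in BANDS:
        bp = band_power_from_psd(freqs, psd, band)
        for ci, ch in enumerate(channel_names):
            names.append(f"power_{ch}_{band.name}")
            values.append(float(bp[ci]))

    for band in BANDS:
        w = wpli_matrix(analytic[band.name])
        for i, j in combinations(range(len(channel_names)), 2):
            names.append(f"wPLI_{pair_name(channel_names[i], channel_names[j])}_{band.name}")
            values.append(float(w[i, j]))

    ch_idx = {ch: i for i, ch in enumerate(channel_names)}
    pac_chs = [ch for ch in DLPFC_CHANNELS if ch in ch_idx]
    for tag, (pb, ab) in COUPLINGS.items():
        if pac_chs:
            mis = []
            for ch in pac_chs:
                i = ch_idx[ch]
                phase = np.angle(analytic[pb][i])
                amp = np.abs(analytic[ab][i])
                mis.append(mi_from_phase_amplitude(phase, amp, n_bins=n_bins))
            mi_val = float(np.mean(mis))
        else:
            mi_val = np.nan
        names.append(f"MI_DLPFC_{tag}")
        values.append(mi_val)

    return pd.Series(values, index=names, dtype=float)


def compute_rst_features(rest_epochs, n_bins: int = 18) -> pd.Series:
    """Resting-state features: per-epoch features averaged across epochs,
    names prefixed ``RST_``."""
    if rest_epochs.data.shape[0] < 1:
        raise ValueError("need at least one resting epoch")
    per_epoch = [
        single_trace_features(ep, rest_epochs.fs, rest_epochs.channel_names, n_bins)
        for ep in rest_epochs.data
    ]
    mean = pd.concat(per_epoch, axis=1).mean(axis=1)
    mean.index = ["RST_" + n for n in mean.index]
    return mean


def compute_window_features(window_epochs, set_tag: str, n_bins: int = 18) -> pd.Series:
    """Features of a pre- or post-stimulus window, computed on the
    epoch-averaged (evoked) trace; names prefixed ``PRE_`` or ``PST_``."""
    if set_tag not in ("PRE", "PST"):
        raise ValueError("set_tag must be PRE or PST")
    data = window_epochs.data
    trace = data.mean(axis=0) if data.ndim == 3 else data
    vec = single_trace_features(trace, window_epochs.fs, window_epochs.channel_names, n_bins)
    vec.index = [f"{set_tag}_" + n for n in vec.index]
    return vec


def compute_dif_features(pre_vec: pd.Series, pst_vec: pd.Series) -> pd.Series:
    """DIF_x = PST_x - PRE_x for every feature x."""
    pre_suffix = [n.removeprefix("PRE_") for n in pre_vec.index]
    pst_suffix = [n.removeprefix("PST_") for n in pst_vec.index]
    if pre_suffix != pst_suffix:
        raise ValueError("PRE and PST name sets differ")
    dif = pst_vec.to_numpy() - pre_vec.to_numpy()
    return pd.Series(dif, index=["DIF_" + n for n in pre_suffix], dtype=float)


# ---------------------------------------------------------------------------
# feature table container
# ---------------------------------------------------------------------------

from dataclasses import dataclass as _dataclass  # noqa: E402


@_dataclass
class FeatureTable:
    """Subjects x named features with labels and clinical covariates."""

    values: pd.DataFrame          # index = subject ids, columns = feature names
    labels: pd.Series             # "MDD" / "HC", aligned to values.index
    covariates: pd.DataFrame      # age, MADRS, STAI_state, STAI_trait, MMSE

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match values index")
        bad = set(self.labels.unique()) - {"MDD", "HC"}
        if bad:
            raise ValueError(f"unknown labels {bad}")
        for name in self.values.columns:
            from .montage import parse_feature_name
            parse_feature_name(name)
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def y(self) -> np.ndarray:
        """Binary target, positive class = MDD."""
        return (self.labels == "MDD").to_numpy().astype(int)

    def subset(self, sets: "list[str] | tuple[str, ...]") -> "FeatureTable":
        cols = [c for c in self.values.columns if c.split("_", 1)[0] in set(sets)]
        return FeatureTable(self.values[cols], self.labels, self.covariates)

    def to_tsv(self, path) -> None:
        """Write values as TSV plus a JSON sidecar with labels/covariates."""
        import json
        from pathlib import Path

        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="subject_id")
        sidecar = {
            "labels": self.labels.to_dict(),
            "covariates": self.covariates.to_dict(orient="index"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        import json
        from pathlib import Path

        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="subject_id")
        values.index.name = None
        sidecar = json.loads(path.with_suffix(".json").read_text())
        labels = pd.Series(sidecar["labels"]).reindex(values.index)
        covariates = pd.DataFrame.from_dict(
            sidecar["covariates"], orient="index"
        ).reindex(values.index)
        return cls(values, labels, covariates)
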