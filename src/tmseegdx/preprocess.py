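"""Preprocessing of continuous recordings into cleaned epoch sets.

The chain, in order, is: epoch (with per-epoch baseline correction for
TMS data) -> amplitude-based channel/epoch rejection -> first ICA (TMS only,
decay-artifact templates) -> zero-phase band-pass 0.5-100 Hz + 48-52 Hz
notch -> downsample to 1 kHz -> second ICA (blink topography / line-noise
heuristics).  Every operation returns a new object and appends its name to
the provenance list; the number of independent components removed across the
two TMS-stage ICAs is capped at ``floor(0.20 * n_components)`` and the
resting-stage ICA at ``floor(0.08 * n_components)``.

Analysis windows on TMS epochs: pre-stimulus [-1550, -50) ms and
post-stimulus [50, 550) ms; the +-50 ms interval around the pulse is never
used.  Intervals are half-open in seconds and converted to samples by
rounding.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

logger = logging.getLogger(__name__)


@dataclass
class Recording:
    """Continuous multichannel EEG in µV with TMS pulse markers."""

    data: np.ndarray              # (channels, samples), µV
    fs: float
    channel_names: list[str]
    markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.markers = np.asarray(self.markers, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.markers.size:
            if not np.all(np.diff(self.markers) > 0):
                raise ValueError("markers must be strictly increasing")
            if self.markers[0] < 0 or self.markers[-1] >= self.data.shape[1]:
                raise ValueError("markers out of bounds")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochSet:
    """Epoched EEG (epochs, channels, samples) with provenance."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]   # seconds relative to the epoch anchor
    channel_names: list[str]
    kept_epoch_ids: list[int]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[2]) / self.fs

    def with_step(self, name: str, **changes) -> "EpochSet":
        changes.setdefault("provenance", self.provenance + (name,))
        return replace(self, **changes)


@dataclass
class PreprocConfig:
    """Thresholds and filter settings for the preprocessing chain."""

    amp_reject_threshold: float = 150.0   # µV
    flat_threshold: float = 0.1           # µV peak-to-peak over the whole set
    bad_epoch_channel_frac: float = 0.25
    bandpass: tuple[float, float] = (0.5, 100.0)
    notch: tuple[float, float] = (48.0, 52.0)
    target_fs: float = 1000.0
    tms_combined_ica_frac: float = 0.20
    rest_ica_frac: float = 0.08
    baseline_window: tuple[float, float] = (-1.55, -0.05)
    exclusion_window: tuple[float, float] = (-0.050, 0.050)
    run_ica: bool = True
    ica_seed: int = 0
    decay_corr_threshold: float = 0.6
    blink_frontal_ratio: float = 2.0
    blink_lowfreq_frac: float = 0.65
    line_peak_ratio: float = 10.0


PRE_WINDOW = (-1.55, -0.05)
POST_WINDOW = (0.05, 0.55)


def ica_removal_cap(n_components: int, frac: float) -> int:
    """Maximum number of ICs that may be removed: floor(frac * n_components)."""
    if not 0 < frac <= 1:
        raise ValueError("cap fraction must be in (0, 1]")
    return math.floor(frac * n_components)


def _s2i(t: float, fs: float) -> int:
    return int(round(t * fs))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_resting(rec: Recording, dur_s: float = 6.0) -> EpochSet:
    """Cut a resting recording into consecutive non-overlapping epochs."""
    n_per = _s2i(dur_s, rec.fs)
    n_epochs = rec.data.shape[1] // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.1f} s holds no full {dur_s:.0f} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    data = trimmed.reshape(rec.data.shape[0], n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        data=data.copy(), fs=rec.fs, window=(0.0, dur_s),
        channel_names=list(rec.channel_names),
        kept_epoch_ids=list(range(n_epochs)),
        provenance=("epoch_resting",),
    )


def epoch_tms(rec: Recording, window: tuple[float, float] = (-2.0, 2.0),
              baseline_window: tuple[float, float] = (-1.55, -0.05)) -> EpochSet:
    """One epoch per TMS marker, baseline-corrected per channel.

    Markers without the full window margin are dropped with a warning.
    """
    if rec.markers.size == 0:
        raise ValueError("recording has no TMS markers")
    i0, i1 = _s2i(window[0], rec.fs), _s2i(window[1], rec.fs)
    n_samples = rec.data.shape[1]
    epochs, kept = [], []
    for k, m in enumerate(rec.markers):
        if m + i0 < 0 or m + i1 > n_samples:
            logger.warning("marker %d at sample %d too close to an edge; dropped", k, m)
            continue
        epochs.append(rec.data[:, m + i0 : m + i1])
        kept.append(k)
    if not epochs:
        raise ValueError("no marker has the full epoch window inside the recording")
    data = np.stack(epochs)
    b0 = _s2i(baseline_window[0] - window[0], rec.fs)
    b1 = _s2i(baseline_window[1] - window[0], rec.fs)
    baseline = data[:, :, b0:b1].mean(axis=2, keepdims=True)
    data = data - baseline
    return EpochSet(
        data=data, fs=rec.fs, window=window,
        channel_names=list(rec.channel_names), kept_epoch_ids=kept,
        provenance=("epoch_tms", "baseline"),
    )


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionReport:
    dropped_channels: list[str]
    dropped_epochs: list[int]
    thresholds: dict

    def to_dict(self) -> dict:
        return {
            "dropped_channels": self.dropped_channels,
            "dropped_epochs": self.dropped_epochs,
            "thresholds": self.thresholds,
        }


def reject_bad(epochs: EpochSet, cfg: PreprocConfig) -> tuple[EpochSet, RejectionReport]:
    """Drop flat or persistently noisy channels, then noisy epochs."""
    data = epochs.data
    amp = cfg.amp_reject_threshold
    ptp_total = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    flat = (ptp_total.max(axis=1) - ptp_total.min(axis=1)) < cfg.flat_threshold
    exceed = (np.abs(data) > amp).any(axis=2)          # (epochs, channels)
    noisy = exceed.mean(axis=0) > cfg.bad_epoch_channel_frac
    bad_ch = flat | noisy
    dropped_channels = [ch for ch, b in zip(epochs.channel_names, bad_ch) if b]

    keep_ch = ~bad_ch
    data = data[:, keep_ch, :]
    bad_ep = (np.abs(data) > amp).any(axis=(1, 2))
    dropped_epochs = [epochs.kept_epoch_ids[i] for i in np.flatnonzero(bad_ep)]
    data = data[~bad_ep]
    if data.shape[0] == 0:
        raise ValueError("all epochs rejected by amplitude threshold")
    report = RejectionReport(
        dropped_channels=dropped_channels,
        dropped_epochs=dropped_epochs,
        thresholds={"amplitude_uV": amp, "flat_uV": cfg.flat_threshold,
                    "bad_epoch_channel_frac": cfg.bad_epoch_channel_frac},
    )
    out = epochs.with_step(
        "reject_bad",
        data=data,
        channel_names=[ch for ch, b in zip(epochs.channel_names, bad_ch) if not b],
        kept_epoch_ids=[e for e, b in zip(epochs.kept_epoch_ids, bad_ep) if not b],
    )
    return out, report


# ---------------------------------------------------------------------------
# filtering and downsampling
# ---------------------------------------------------------------------------

def filter_epochs(epochs: EpochSet, cfg: PreprocConfig) -> EpochSet:
    """Zero-phase Butterworth band-pass (order 4) plus notch band-stop (order 2)."""
    lo, hi = cfg.bandpass
    nyq = epochs.fs / 2.0
    hi_eff = min(hi, 0.45 * epochs.fs)
    if hi_eff < hi:
        warnings.warn(
            f"band-pass upper edge clipped to {hi_eff:.1f} Hz for fs={epochs.fs} Hz",
            RuntimeWarning, stacklevel=2,
        )
    sos_bp = sps.butter(4, [lo, hi_eff], btype="bandpass", fs=epochs.fs, output="sos")
    data = sps.sosfiltfilt(sos_bp, epochs.data, axis=-1)
    n0, n1 = cfg.notch
    if n1 < nyq:
        sos_notch = sps.butter(2, [n0, n1], btype="bandstop", fs=epochs.fs, output="sos")
        data = sps.sosfiltfilt(sos_notch, data, axis=-1)
    return epochs.with_step("filter", data=data)


def downsample(epochs: EpochSet, target_fs: float = 1000.0) -> EpochSet:
    """Polyphase resampling with anti-alias filtering; identity at target rate.

    Upsampling is never performed: a recording already below the target rate
    is returned unchanged.
    """
    if epochs.fs <= target_fs:
        if epochs.fs == target_fs:
            return epochs.with_step("downsample(identity)")
        return epochs.with_step("downsample(skipped: fs below target)")
    from fractions import Fraction

    frac = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    data = sps.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    return epochs.with_step("downsample", data=data, fs=target_fs)


# ---------------------------------------------------------------------------
# ICA cleaning
# ---------------------------------------------------------------------------

@dataclass
class ICReport:
    stage: str
    scores: dict                 # criterion -> per-component score list
    removed: list[int]
    cap: int
    truncated: bool
    skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "scores": {k: list(map(float, v)) for k, v in self.scores.items()},
            "removed": self.removed,
            "cap": self.cap,
            "truncated": self.truncated,
            "skipped": self.skipped,
        }


def _decay_scores(sources: np.ndarray, n_epochs: int, fs: float,
                  window: tuple[float, float]) -> np.ndarray:
    """|Pearson r| between each component's epoch-averaged 10-500 ms
    post-stimulus course and an exponential decay template (tau = 100 ms)."""
    n_comp, n_total = sources.shape
    n_per = n_total // n_epochs
    i0 = _s2i(0.010 - window[0], fs)
    i1 = _s2i(0.500 - window[0], fs)
    i1 = min(i1, n_per)
    t = np.arange(i1 - i0) / fs
    template = np.exp(-t / 0.100)
    template = template - template.mean()
    scores = np.zeros(n_comp)
    for c in range(n_comp):
        avg = sources[c].reshape(n_epochs, n_per).mean(axis=0)[i0:i1]
        centered = avg - avg.mean()
        denom = np.linalg.norm(centered) * np.linalg.norm(template)
        corr = abs(centered @ template) / denom if denom > 0 else 0.0
        # decay artifacts are one-signed; evoked oscillations cross zero and
        # must not be flagged, so weight by amplitude-weighted sign consistency
        denom_abs = np.abs(avg).sum()
        consistency = abs(avg.sum()) / denom_abs if denom_abs > 0 else 0.0
        scores[c] = corr * consistency
    return scores


def _blink_line_scores(sources: np.ndarray, mixing: np.ndarray,
                       channel_names: list[str], fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blink heuristic (frontal-polar topography dominance and <4 Hz power
    fraction) and line-noise spectral-peak ratio per component."""
    frontal_polar = np.array([ch.startswith(("Fp", "AF")) for ch in channel_names])
    n_comp = sources.shape[0]
    topo_ratio = np.zeros(n_comp)
    lowfreq_frac = np.zeros(n_comp)
    line_ratio = np.zeros(n_comp)
    nperseg = min(sources.shape[1], int(round(2 * fs)))
    freqs, psd = sps.welch(sources, fs=fs, nperseg=nperseg, axis=-1)
    for c in range(n_comp):
        w = np.abs(mixing[:, c])
        fp = w[frontal_polar].mean() if frontal_polar.any() else 0.0
        rest = w[~frontal_polar].mean() if (~frontal_polar).any() else np.inf
        topo_ratio[c] = fp / rest if rest > 0 else np.inf
        total = psd[c].sum()
        if total > 0:
            lowfreq_frac[c] = psd[c][freqs < 4.0].sum() / total
        band = (freqs >= 48) & (freqs <= 52)
        neigh = ((freqs >= 40) & (freqs < 48)) | ((freqs > 52) & (freqs <= 60))
        if band.any() and neigh.any() and psd[c][neigh].mean() > 0:
            line_ratio[c] = psd[c][band].mean() / psd[c][neigh].mean()
    return topo_ratio, lowfreq_frac, line_ratio


def ica_clean(epochs: EpochSet, stage: str, cfg: PreprocConfig,
              already_removed: int = 0) -> tuple[EpochSet, ICReport]:
    """Decompose, flag artifact components by stage-specific heuristics,
    and reconstruct without them.

    ``stage`` is ``first_tms`` (decay templates), ``second`` or ``resting``
    (blink topography and line-noise peaks).  The number removed never
    exceeds the remaining cap: floor(frac * n_components) minus
    ``already_removed`` (TMS stages share the combined cap).
    """
    if stage not in ("first_tms", "second", "resting"):
        raise ValueError(f"unknown ICA stage {stage!r}")
    n_ep, n_ch, n_per = epochs.data.shape
    if n_ep * n_per < 20 * n_ch ** 2:
        warnings.warn(
            "too few samples for a stable ICA decomposition; stage skipped",
            RuntimeWarning, stacklevel=2,
        )
        report = ICReport(stage=stage, scores={}, removed=[], cap=0,
                          truncated=False, skipped=True)
        return epochs.with_step(f"ica_{stage}(skipped)"), report

    frac = cfg.rest_ica_frac if stage == "resting" else cfg.tms_combined_ica_frac
    cap = max(0, ica_removal_cap(n_ch, frac) - already_removed)

    x = epochs.data.transpose(1, 0, 2).reshape(n_ch, -1)   # (ch, total samples)
    mean = x.mean(axis=1, keepdims=True)
    ica = FastICA(n_components=n_ch, whiten="unit-variance",
                  random_state=cfg.ica_seed, max_iter=1000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")          # convergence warnings on noise
        sources = ica.fit_transform((x - mean).T).T   # (comp, samples)
    mixing = ica.mixing_                                # (ch, comp)

    scores: dict[str, np.ndarray] = {}
    flagged: list[tuple[float, int]] = []
    if stage == "first_tms":
        decay = _decay_scores(sources, n_ep, epochs.fs, epochs.window)
        scores["decay_corr"] = decay
        for c, s in enumerate(decay):
            if s > cfg.decay_corr_threshold:
                flagged.append((s, c))
    else:
        topo, lowf, line = _blink_line_scores(sources, mixing,
                                              epochs.channel_names, epochs.fs)
        scores["blink_topo_ratio"] = topo
        scores["lowfreq_frac"] = lowf
        scores["line_peak_ratio"] = line
        for c in range(n_ch):
            if topo[c] > cfg.blink_frontal_ratio and lowf[c] > cfg.blink_lowfreq_frac:
                flagged.append((topo[c] * lowf[c], c))
            elif line[c] > cfg.line_peak_ratio:
                flagged.append((line[c], c))

    flagged.sort(reverse=True)
    truncated = len(flagged) > cap
    if truncated:
        logger.warning("ICA stage %s: %d components flagged, cap %d; keeping "
                       "highest-scoring", stage, len(flagged), cap)
    removed = sorted(c for _, c in flagged[:cap])

    if removed:
        keep = np.setdiff1d(np.arange(sources.shape[0]), removed)
        recon = (mixing[:, keep] @ sources[keep]) + mean
        data = recon.reshape(n_ch, n_ep, n_per).transpose(1, 0, 2)
    else:
        data = epochs.data
    report = ICReport(stage=stage, scores=scores, removed=removed,
                      cap=cap, truncated=truncated)
    out = epochs.with_step(f"ica_{stage}(removed={len(removed)})", data=data)
    return out, report


# ---------------------------------------------------------------------------
# windows and averaging
# ---------------------------------------------------------------------------

def extract_windows(epochs: EpochSet) -> dict[str, EpochSet]:
    """Pre-stimulus [-1550, -50) ms and post-stimulus [50, 550) ms windows.

    Half-open intervals; the +-50 ms interval around the pulse is excluded
    from both.
    """
    w0, w1 = epochs.window
    if w0 > PRE_WINDOW[0] or w1 < POST_WINDOW[1]:
        raise ValueError("epochs do not span the [-1.55, 0.55] s analysis range")
    out = {}
    for name, (a, b) in (("pre", PRE_WINDOW), ("post", POST_WINDOW)):
        i0 = _s2i(a - w0, epochs.fs)
        i1 = _s2i(b - w0, epochs.fs)
        out[name] = epochs.with_step(
            f"extract_{name}", data=epochs.data[:, :, i0:i1], window=(a, b)
        )
    return out


def evoked_average(epochs: EpochSet) -> EpochSet:
    """Arithmetic mean across epochs, kept as a single-epoch set."""
    if epochs.n_epochs < 1:
        raise ValueError("no epochs to average")
    return epochs.with_step(
        "evoked_average", data=epochs.data.mean(axis=0, keepdims=True),
        kept_epoch_ids=[-1],
    )


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def preprocess_resting(rec: Recording, cfg: PreprocConfig,
                       epoch_dur_s: float = 6.0) -> tuple[EpochSet, dict]:
    """epoch -> reject -> filter -> downsample -> ICA (resting heuristics)."""
    epochs = epoch_resting(rec, epoch_dur_s)
    epochs, rej = reject_bad(epochs, cfg)
    epochs = filter_epochs(epochs, cfg)
    epochs = downsample(epochs, cfg.target_fs)
    reports: dict = {"rejection": rej.to_dict()}
    if cfg.run_ica:
        epochs, icr = ica_clean(epochs, "resting", cfg)
        reports["ica_resting"] = icr.to_dict()
    return epochs, reports


def preprocess_tms(rec: Recording, cfg: PreprocConfig) -> tuple[EpochSet, dict]:
    """epoch+baseline -> reject -> ICA#1 -> filter -> downsample -> ICA#2."""
    epochs = epoch_tms(rec, baseline_window=cfg.baseline_window)
    epochs, rej = reject_bad(epochs, cfg)
    reports: dict = {"rejection": rej.to_dict()}
    n_removed = 0
    if cfg.run_ica:
        epochs, ic1 = ica_clean(epochs, "first_tms", cfg)
        n_removed = len(ic1.removed)
        reports["ica_first"] = ic1.to_dict()
    epochs = filter_epochs(epochs, cfg)
    epochs = downsample(epochs, cfg.target_fs)
    if cfg.run_ica:
        epochs, ic2 = ica_clean(epochs, "second", cfg, already_removed=n_removed)
        reports["ica_second"] = ic2.to_dict()
    return epochs, reports
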