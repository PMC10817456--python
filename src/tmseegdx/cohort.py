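"""Synthetic two-group EEG / TMS-EEG cohorts with planted group effects.

Each subject gets a 5-minute eyes-closed resting recording and a single-pulse
TMS-EEG recording (80 pulses by default) over the 17 frontal electrodes.
Signals are 1/f background noise plus band-limited Gaussian oscillations
(band-filtered noise rather than pure tones, so phase estimates carry
realistic variance), plus optional blink and TMS-decay artifacts.

Group differences are *planted* through three mechanisms keyed to the feature
they should move:

* ``power_scale`` — a band-limited oscillation at one electrode whose
  amplitude is log-normally modulated by a subject latent that is shifted by
  the standardized effect size ``d`` in the patient group;
* ``shared_source_lag`` — a common band-limited source added to a channel
  pair with a 90° phase lag, so the weighted phase lag index between the two
  channels rises with the source-to-background ratio; for ``DIF`` features
  the source is a pulse-locked post-stimulus burst, giving a pre-to-post
  connectivity change that is smaller in the group planted lower;
* ``pac_depth`` — sinusoidal amplitude modulation of a high-band carrier by
  the phase of a low-band component.

Clinical covariates (age, MADRS, STAI, MMSE) are drawn from per-group
Gaussians truncated to the instrument ranges.  Within the patient group a
latent severity variable is shared between the resting beta-power effect and
the MADRS/STAI noise, so a positive rank correlation between that feature
and symptom scores is recoverable by design.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import analytic_band, band_filter
from .montage import BAND_MAP, FRONTAL_17, BandDef, parse_feature_name
from .preprocess import POST_WINDOW, Recording

# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A group difference planted into the generated signals."""

    feature_name: str
    direction: str                # "MDD_higher" or "MDD_lower"
    magnitude: float              # standardized effect size d on the latent
    mechanism: str                # power_scale | shared_source_lag | pac_depth

    def __post_init__(self) -> None:
        if self.direction not in ("MDD_higher", "MDD_lower"):
            raise ValueError(f"effect_table: bad direction {self.direction!r}")
        if self.magnitude < 0:
            raise ValueError("effect_table: magnitude must be >= 0")
        if self.mechanism not in ("power_scale", "shared_source_lag", "pac_depth"):
            raise ValueError(f"effect_table: bad mechanism {self.mechanism!r}")
        parse_feature_name(self.feature_name)

    @property
    def parsed(self) -> tuple[str, str, str, str]:
        return parse_feature_name(self.feature_name)

    @property
    def canonical_name(self) -> str:
        """The name under which the feature appears in a FeatureTable
        (channel pairs in montage order; wPLI is symmetric)."""
        from .montage import canonicalize_feature_name

        return canonicalize_feature_name(self.feature_name)


def default_effect_table(d: float = 1.2) -> tuple[PlantedEffect, ...]:
    """The five discriminative-feature analogues: resting beta power at AFz
    and F6-F4 gamma synchronization raised in MDD; three pre-to-post
    connectivity changes (F5-AF3 alpha, AFz-F5 alpha, AF3-F8 theta) lowered."""
    return (
        PlantedEffect("RST_power_AFz_beta", "MDD_higher", d, "power_scale"),
        PlantedEffect("RST_wPLI_F6-F4_gamma", "MDD_higher", d, "shared_source_lag"),
        PlantedEffect("DIF_wPLI_F5-AF3_alpha", "MDD_lower", d, "shared_source_lag"),
        PlantedEffect("DIF_wPLI_AFz-F5_alpha", "MDD_lower", d, "shared_source_lag"),
        PlantedEffect("DIF_wPLI_AF3-F8_theta", "MDD_lower", d, "shared_source_lag"),
    )


#: Per-group clinical score models: (mean, sd, lower bound, upper bound).
DEFAULT_CLINICAL_MODEL: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "MDD": {
        "age": (45.8, 12.2, 18, 65),
        "MADRS": (31.8, 7.8, 0, 60),
        "STAI_trait": (54.2, 20.1, 20, 80),
        "STAI_state": (55.4, 20.1, 20, 80),
        "MMSE": (29.1, 1.4, 0, 30),
    },
    "HC": {
        "age": (40.5, 12.2, 18, 65),
        "MADRS": (1.1, 2.0, 0, 60),
        "STAI_trait": (32.1, 9.2, 20, 80),
        "STAI_state": (34.2, 8.9, 20, 80),
        "MMSE": (28.5, 3.3, 0, 30),
    },
}


@dataclass(frozen=True)
class ArtifactFlags:
    blink: bool = False
    tms_decay: bool = False


@dataclass(frozen=True)
class CohortSpec:
    """Everything that determines a generated cohort (including the seed)."""

    n_per_group: int = 60
    seed: int = 0
    fs: float = 3000.0
    channels: tuple[str, ...] = FRONTAL_17
    rest_duration: float = 300.0          # seconds
    n_pulses: int = 80
    isi_s: float = 5.0                    # mean inter-pulse interval
    isi_jitter: float = 0.10              # fractional uniform jitter
    effect_table: tuple[PlantedEffect, ...] = field(default_factory=default_effect_table)
    clinical_model: dict = field(default_factory=lambda: DEFAULT_CLINICAL_MODEL)
    artifact_flags: ArtifactFlags = ArtifactFlags()
    background_rms: float = 10.0          # µV, 1/f process
    sensor_noise_rms: float = 1.0         # µV, white
    spectral_beta: float = 1.0            # PSD ~ 1/f^beta
    alpha_rhythm_rms: float = 3.0         # µV, per-channel independent alpha
    madrs_rho: float = 0.28               # target rank correlation, MDD group
    stai_rho: float = 0.36

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("CohortSpec.n_per_group must be >= 2")
        if self.fs < 200:
            raise ValueError("CohortSpec.fs must be >= 200 Hz to resolve gamma")
        if self.rest_duration < 12:
            raise ValueError("CohortSpec.rest_duration must be >= 12 s (two epochs)")
        if self.isi_s * (1 - self.isi_jitter) < 4.0:
            raise ValueError("CohortSpec.isi_s: inter-pulse spacing must stay >= 4 s")
        ch = set(self.channels)
        for eff in self.effect_table:
            _, kind, loc, _ = eff.parsed
            locs = loc.split("-") if kind == "wPLI" else [loc]
            for c in locs:
                if c != "DLPFC" and c not in ch:
                    raise ValueError(
                        f"CohortSpec.effect_table: channel {c!r} of "
                        f"{eff.feature_name!r} not in CohortSpec.channels"
                    )


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                    # "MDD" or "HC"
    age: float
    madrs: float
    stai_state: float
    stai_trait: float
    mmse: float
    resting: Recording
    tms: Recording


# ---------------------------------------------------------------------------
# mechanism calibration constants
# ---------------------------------------------------------------------------
# Chosen once so that a planted latent effect of size d is recovered with a
# comparable standardized separation on the measured feature (subject-level
# parameter spread dominating the estimator's measurement noise).

POWER_OSC_RMS = 12.0         # µV, base rms of the planted band oscillation
POWER_LOG_SD = 0.30          # log-amplitude spread per unit latent
POWER_OSC_MAX = 30.0         # µV, physiological cap on the oscillation rms
RST_WPLI_SRC_RMS = 5.0       # µV, constant total rms of the planted pair source
RST_WPLI_FRAC_BASE = 0.5     # logit of the coherent fraction at latent 0
RST_WPLI_FRAC_SLOPE = 0.6    # logit units per unit latent
PRE_BURST_RMS = 10.0          # µV, pulse-locked pre-window coupling
POST_BURST_RMS = 10.0         # µV, post-window burst (coherent + offset-tone mix)
PRE_FRAC_MEAN = 0.25         # subject baseline coherent fraction (pre window)
PRE_FRAC_SD = 0.16           # subject-to-subject spread of the baseline
DIF_FRAC_DELTA = 0.12        # mean pre-to-post change of the coherent fraction
DIF_FRAC_SLOPE = 0.13        # change per unit group latent
#: narrow slow bands have few effective phase samples in the 500 ms post
#: window; their change slope is scaled up so the realized feature
#: separation matches the planted effect size despite estimator noise
DIF_SLOPE_BAND_FACTOR = {"theta": 2.0}
FRAC_MIN, FRAC_MAX = 0.05, 0.95   # clip to keep both tones present
FEATURE_ATTENUATION = 0.85   # assumed latent-to-feature rank-correlation loss
PAC_CARRIER_RMS = 3.0        # µV
PAC_BASE_DEPTH = 0.5
PAC_DEPTH_SLOPE = 0.15
CLINICAL_LATENT_RHO = 0.5    # share of the severity latent in the coupled effect

EVOKED_AMP = 3.0             # µV, generic pulse-locked damped oscillation
DECAY_AMP = 120.0            # µV, TMS decay artifact at the most frontal site
DECAY_TAU = 0.100            # s
BLINK_AMP = 80.0             # µV
BLINK_RATE = 0.25            # blinks per second


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def synth_background(duration: float, fs: float, n_channels: int,
                     seed, beta: float = 1.0, rms: float = 10.0,
                     white_rms: float = 1.0) -> np.ndarray:
    """Mutually independent 1/f^beta noise plus white sensor noise, µV.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration * fs must be >= 1 sample")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    out = shaped / sd * rms
    if white_rms > 0:
        out = out + rng.standard_normal((n_channels, n)) * white_rms
    return out


def band_noise(n: int, fs: float, band: BandDef, rng: np.random.Generator) -> np.ndarray:
    """Unit-rms band-limited Gaussian noise."""
    x = band_filter(rng.standard_normal(n), band, fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def phase_shifted(x: np.ndarray, band: BandDef, fs: float, lag_deg: float) -> np.ndarray:
    """Copy of a narrowband signal phase-shifted by ``lag_deg`` degrees."""
    a = analytic_band(x, band, fs)
    return np.real(a * np.exp(-1j * np.deg2rad(lag_deg)))


def band_rms(x: np.ndarray, band: BandDef, fs: float) -> float:
    return float(band_filter(x, band, fs).std())


def plant_phase_coupling(signals: np.ndarray, ch_i: int, ch_j: int,
                         band: BandDef, lag_deg: float, strength: float,
                         fs: float, rng: np.random.Generator) -> np.ndarray:
    """Add a shared band-limited source to two channels with a phase lag.

    The source rms equals ``strength`` times the band rms of channel ``ch_i``
    (or 1 µV when that channel is silent), so the pairwise wPLI grows
    monotonically with ``strength``.  Returns a new array.
    """
    if not 0 <= strength:
        raise ValueError("strength must be >= 0")
    n_ch, n = signals.shape
    if not (0 <= ch_i < n_ch and 0 <= ch_j < n_ch and ch_i != ch_j):
        raise ValueError("unknown or identical channel indices")
    if strength == 0:
        return signals.copy()
    if lag_deg % 180 == 0:
        warnings.warn("lag of 0 or 180 degrees yields a zero wPLI target",
                      RuntimeWarning, stacklevel=2)
    ref = band_rms(signals[ch_i], band, fs)
    amp = strength * (ref if ref > 0 else 1.0)
    src = band_noise(n, fs, band, rng)
    out = signals.copy()
    out[ch_i] += amp * src
    out[ch_j] += amp * phase_shifted(src, band, fs, lag_deg)
    return out


def plant_pac(signal: np.ndarray, phase_band: BandDef, amp_band: BandDef,
              depth: float, fs: float, rng: np.random.Generator,
              carrier_rms: float = PAC_CARRIER_RMS) -> np.ndarray:
    """Add a high-band carrier whose amplitude follows
    ``1 + depth * cos(phase)`` of the signal's low-band component."""
    if not 0 <= depth <= 1:
        raise ValueError("depth must be in [0, 1]")
    if amp_band.lo <= phase_band.hi:
        raise ValueError("amplitude band must lie strictly above the phase band")
    phase = np.angle(analytic_band(signal, phase_band, fs))
    carrier = band_noise(len(signal), fs, amp_band, rng)
    env = np.abs(analytic_band(carrier, amp_band, fs))
    env[env < 1e-12] = 1e-12
    flat = carrier / env                      # unit-envelope carrier
    mod = flat * (1.0 + depth * np.cos(phase))
    sd = mod.std()
    if sd > 0:
        mod = mod / sd
    return signal + carrier_rms * mod


# ---------------------------------------------------------------------------
# subject-level generation
# ---------------------------------------------------------------------------

def _effect_latents(spec: CohortSpec, group: str, severity: float,
                    rng: np.random.Generator) -> dict[str, float]:
    """Latent effect variable per planted effect: standard normal, shifted by
    +-d in the patient group; the resting power effect shares the severity
    latent so clinical correlations are recoverable."""
    latents = {}
    for eff in spec.effect_table:
        set_tag, kind, _, _ = eff.parsed
        z = rng.standard_normal()
        if set_tag == "RST" and kind == "power" and group == "MDD":
            rho = CLINICAL_LATENT_RHO
            z = np.sqrt(1 - rho ** 2) * z + rho * severity
        if group == "MDD":
            z += eff.magnitude if eff.direction == "MDD_higher" else -eff.magnitude
        latents[eff.feature_name] = z
    return latents


def _clinical_scores(spec: CohortSpec, group: str, severity: float,
                     rng: np.random.Generator) -> dict[str, float]:
    model = spec.clinical_model[group]
    out = {}
    for name, (mu, sd, lo, hi) in model.items():
        if group == "MDD" and name == "MADRS":
            w = min(0.95, spec.madrs_rho / (CLINICAL_LATENT_RHO * FEATURE_ATTENUATION))
            z = w * severity + np.sqrt(1 - w ** 2) * rng.standard_normal()
        elif group == "MDD" and name.startswith("STAI"):
            w = min(0.95, spec.stai_rho / (CLINICAL_LATENT_RHO * FEATURE_ATTENUATION))
            z = w * severity + np.sqrt(1 - w ** 2) * rng.standard_normal()
        else:
            z = rng.standard_normal()
        out[name] = float(np.clip(mu + sd * z, lo, hi))
    return out


def generate_resting_recording(spec: CohortSpec, latents: dict[str, float],
                               rng: np.random.Generator) -> Recording:
    n_ch = len(spec.channels)
    data = synth_background(spec.rest_duration, spec.fs, n_ch, rng,
                            beta=spec.spectral_beta, rms=spec.background_rms,
                            white_rms=spec.sensor_noise_rms)
    n = data.shape[1]
    idx = {ch: i for i, ch in enumerate(spec.channels)}
    alpha = BAND_MAP["alpha"]
    if spec.alpha_rhythm_rms > 0:
        for i in range(n_ch):
            data[i] += spec.alpha_rhythm_rms * band_noise(n, spec.fs, alpha, rng)

    for eff in spec.effect_table:
        set_tag, kind, loc, band_tag = eff.parsed
        if set_tag != "RST":
            continue
        e = latents[eff.feature_name]
        if kind == "power" and eff.mechanism == "power_scale":
            band = BAND_MAP[band_tag]
            # plant inside a slightly narrowed band so the (large) oscillation
            # does not leak measurable power into the neighbouring bands
            inner = BandDef(band.name + "_core", band.lo + 1.0,
                            band.hi - 0.15 * (band.hi - band.lo))
            amp = min(POWER_OSC_RMS * np.exp(POWER_LOG_SD * e), POWER_OSC_MAX)
            data[idx[loc]] += amp * band_noise(n, spec.fs, inner, rng)
        elif kind == "wPLI" and eff.mechanism == "shared_source_lag":
            band = BAND_MAP[band_tag]
            ch_a, ch_b = loc.split("-")
            # constant-power pair source whose *coherent fraction* carries the
            # latent, so band power at the two electrodes stays uninformative
            frac = 1.0 / (1.0 + np.exp(-(RST_WPLI_FRAC_BASE
                                         + RST_WPLI_FRAC_SLOPE * e)))
            src = band_noise(n, spec.fs, band, rng)
            data[idx[ch_a]] += RST_WPLI_SRC_RMS * (
                np.sqrt(frac) * src
                + np.sqrt(1 - frac) * band_noise(n, spec.fs, band, rng))
            data[idx[ch_b]] += RST_WPLI_SRC_RMS * (
                np.sqrt(frac) * phase_shifted(src, band, spec.fs, 90.0)
                + np.sqrt(1 - frac) * band_noise(n, spec.fs, band, rng))
        elif kind == "MI" and eff.mechanism == "pac_depth":
            pb, ab = BAND_MAP["theta"], BAND_MAP["gamma"]
            if band_tag == "alphagamma":
                pb = BAND_MAP["alpha"]
            depth = float(np.clip(PAC_BASE_DEPTH + PAC_DEPTH_SLOPE * e, 0, 1))
            targets = ("F3", "F5", "AF3") if loc == "DLPFC" else (loc,)
            for ch in targets:
                data[idx[ch]] = plant_pac(data[idx[ch]], pb, ab, depth, spec.fs, rng)
        else:
            raise ValueError(
                f"unsupported RST mechanism {eff.mechanism!r} for kind {kind!r}"
            )

    if spec.artifact_flags.blink:
        _add_blinks(data, spec, rng)
    return Recording(data=data, fs=spec.fs, channel_names=list(spec.channels))


def _add_blinks(data: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> None:
    """Blink-like transients, strongest at the frontal-polar electrodes."""
    n = data.shape[1]
    duration = n / spec.fs
    n_blinks = rng.poisson(BLINK_RATE * duration)
    width = int(round(0.30 * spec.fs))
    shape = np.hanning(width)
    weights = np.array(
        [1.0 if ch.startswith("Fp") else 0.4 if ch.startswith("AF") else 0.1
         for ch in spec.channels]
    )
    for _ in range(n_blinks):
        start = rng.integers(0, max(1, n - width))
        amp = BLINK_AMP * (0.8 + 0.4 * rng.random())
        data[:, start : start + width] += np.outer(weights, amp * shape)


def _burst_frequencies(band: BandDef, window_s: float) -> tuple[float, float]:
    """Two in-band burst frequencies separated by a whole number of cycles
    per analysis window, so their cross-term integrates out.

    The separation is the largest multiple of 1/window that keeps both tones
    strictly inside the band (at least one cycle per window).
    """
    bw = band.hi - band.lo
    k = max(1, int(np.floor(0.8 * bw * window_s)))
    delta = k / window_s
    center = 0.5 * (band.lo + band.hi)
    return center - delta / 2, center + delta / 2


def _graded_tone_pair(n: int, fs: float, band: BandDef, frac: float,
                      ph_src: float) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-locked source tone and a graded partner wave.

    The source is a tapered in-band tone.  The partner mixes the 90°-lagged
    copy (weight ``frac``) with a tone offset by a whole number of cycles
    per window (weight ``sqrt(1 - frac^2)``); the offset tone's phase is
    chosen so its taper-weighted imaginary cross-term with the source
    integrates to zero, so the pairwise wPLI rises monotonically with
    ``frac`` from the noise floor to ~1.
    """
    frac = float(np.clip(frac, 0.0, 1.0))
    t = np.arange(n) / fs
    f1, f2 = _burst_frequencies(band, n / fs)
    taper = sps.windows.tukey(n, alpha=0.4)
    beat = np.sum(taper ** 2 * np.exp(1j * 2 * np.pi * (f1 - f2) * t))
    ph_inc = ph_src + float(np.angle(beat))

    def unit(w: np.ndarray) -> np.ndarray:
        return w / max(w.std(), 1e-12)

    src = unit(np.cos(2 * np.pi * f1 * t + ph_src) * taper)
    lag = unit(np.cos(2 * np.pi * f1 * t + ph_src - np.pi / 2) * taper)
    inc = unit(np.cos(2 * np.pi * f2 * t + ph_inc) * taper)
    # renormalize: the tones are not exactly orthogonal over a tapered
    # window, and band power must carry no trace of the coherent fraction
    return src, unit(frac * lag + np.sqrt(1 - frac ** 2) * inc)


def generate_tms_recording(spec: CohortSpec, latents: dict[str, float],
                           rng: np.random.Generator,
                           return_clean: bool = False):
    """Continuous TMS-EEG recording with ``n_pulses`` markers.

    Each pulse adds a generic evoked damped oscillation (phase-locked, so it
    survives additive averaging), the pulse-locked bursts implementing the
    planted pre-to-post connectivity changes, and, if enabled, an exponential
    decay artifact weighted toward the frontal-polar electrodes.
    """
    n_ch = len(spec.channels)
    margin = 3.0
    isis = spec.isi_s * (1 + spec.isi_jitter * (2 * rng.random(spec.n_pulses) - 1))
    onsets_s = margin + np.concatenate([[0.0], np.cumsum(isis[:-1])])
    duration = onsets_s[-1] + spec.isi_s + margin
    if np.any(np.diff(onsets_s) < 4.0):
        raise ValueError("inter-pulse spacing fell below 4 s; epochs would overlap")

    data = synth_background(duration, spec.fs, n_ch, rng,
                            beta=spec.spectral_beta, rms=spec.background_rms,
                            white_rms=spec.sensor_noise_rms)
    n = data.shape[1]
    markers = np.round(onsets_s * spec.fs).astype(int)
    idx = {ch: i for i, ch in enumerate(spec.channels)}

    # generic evoked response: damped 10 Hz oscillation, strongest near the
    # stimulation site (left DLPFC), identical phase at every pulse
    ev_len = int(round(0.6 * spec.fs))
    t = np.arange(ev_len) / spec.fs
    evoked = np.sin(2 * np.pi * 10 * t) * np.exp(-t / 0.15)
    site_w = np.array(
        [1.0 if ch in ("F3", "F5", "AF3") else 0.5 if ch.startswith(("F", "AF")) else 0.3
         for ch in spec.channels]
    )
    amp_jitter = 1 + 0.1 * rng.standard_normal(spec.n_pulses)

    # Pulse-locked bursts implementing the DIF connectivity effects.  Each
    # subject draws a latent baseline coupling (logit of the coherent
    # fraction) that drives the pre-stimulus window; the post-stimulus
    # window adds a pre-to-post change carrying the group-shifted subject
    # latent.  The shared baseline cancels in DIF = PST - PRE, so the
    # change signal lives in DIF rather than in PST alone, while PRE and
    # PST individually vary across subjects.  A channel shared by several
    # same-band effects ("hub") carries one common source tone, keeping the
    # planted pairs from contaminating each other.
    from .preprocess import PRE_WINDOW

    post_i0 = int(round(POST_WINDOW[0] * spec.fs))
    post_len = int(round((POST_WINDOW[1] - POST_WINDOW[0]) * spec.fs))
    pre_i0 = int(round(PRE_WINDOW[0] * spec.fs))
    pre_len = int(round((PRE_WINDOW[1] - PRE_WINDOW[0]) * spec.fs))
    dif_effects = [e for e in spec.effect_table if e.parsed[0] == "DIF"]
    use_count: dict[tuple[str, str], int] = {}
    for eff in dif_effects:
        _, _, loc, band_tag = eff.parsed
        for c in loc.split("-"):
            use_count[(band_tag, c)] = use_count.get((band_tag, c), 0) + 1
    hub_phases: dict[tuple[str, str], tuple[float, float]] = {}
    burst_waves: list[tuple[int, int, float, np.ndarray]] = []  # ch, offset, amp, wave
    for eff in dif_effects:
        set_tag, kind, loc, band_tag = eff.parsed
        if kind != "wPLI" or eff.mechanism != "shared_source_lag":
            raise ValueError(
                f"unsupported DIF effect {eff.feature_name!r} via {eff.mechanism!r}"
            )
        band = BAND_MAP[band_tag]
        ch_a, ch_b = loc.split("-")
        if use_count[(band_tag, ch_b)] > use_count[(band_tag, ch_a)]:
            hub, graded_ch = ch_b, ch_a
        else:
            hub, graded_ch = ch_a, ch_b
        key = (band_tag, hub)
        new_hub = key not in hub_phases
        if new_hub:
            hub_phases[key] = (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
        ph_post, ph_pre = hub_phases[key]
        e = latents[eff.feature_name]
        factor = DIF_SLOPE_BAND_FACTOR.get(band_tag, 1.0)
        base = PRE_FRAC_MEAN + PRE_FRAC_SD * rng.standard_normal()
        pre_frac = float(np.clip(base, FRAC_MIN, FRAC_MAX))
        post_frac = float(np.clip(base + factor * (DIF_FRAC_DELTA
                                                   + DIF_FRAC_SLOPE * e),
                                  FRAC_MIN, FRAC_MAX))
        post_src, post_graded = _graded_tone_pair(post_len, spec.fs, band,
                                                  post_frac, ph_post)
        pre_src, pre_graded = _graded_tone_pair(pre_len, spec.fs, band,
                                                pre_frac, ph_pre)
        if new_hub:   # the shared source tone is added once per hub
            burst_waves.append((idx[hub], post_i0, POST_BURST_RMS, post_src))
            burst_waves.append((idx[hub], pre_i0, PRE_BURST_RMS, pre_src))
        burst_waves.append((idx[graded_ch], post_i0, POST_BURST_RMS, post_graded))
        burst_waves.append((idx[graded_ch], pre_i0, PRE_BURST_RMS, pre_graded))

    clean = data.copy() if return_clean else None
    for k, m in enumerate(markers):
        seg = slice(m, min(m + ev_len, n))
        ln = seg.stop - seg.start
        contrib = np.outer(site_w, amp_jitter[k] * EVOKED_AMP * evoked[:ln])
        data[:, seg] += contrib
        if clean is not None:
            clean[:, seg] += contrib
        jit = 1 + 0.05 * rng.standard_normal()
        for ci, i0, amp, wave in burst_waves:
            b0 = m + i0
            ln = len(wave)
            data[ci, b0 : b0 + ln] += amp * jit * wave
            if clean is not None:
                clean[ci, b0 : b0 + ln] += amp * jit * wave

    if spec.artifact_flags.tms_decay:
        dec_len = int(round(0.5 * spec.fs))
        td = np.arange(dec_len) / spec.fs
        template = np.exp(-td / DECAY_TAU)
        frontal_w = np.array(
            [1.0 if ch.startswith("Fp") else 0.8 if ch.startswith("AF") else 0.4
             for ch in spec.channels]
        )
        for k, m in enumerate(markers):
            seg = slice(m, min(m + dec_len, n))
            ln = seg.stop - seg.start
            amp = DECAY_AMP * (0.9 + 0.2 * rng.random())
            data[:, seg] += np.outer(frontal_w, amp * template[:ln])

    rec = Recording(data=data, fs=spec.fs, channel_names=list(spec.channels),
                    markers=markers)
    if return_clean:
        clean_rec = Recording(data=clean, fs=spec.fs,
                              channel_names=list(spec.channels), markers=markers)
        return rec, clean_rec
    return rec


def generate_subject(spec: CohortSpec, group: str, subject_id: str,
                     seed_seq: np.random.SeedSequence) -> SubjectRecord:
    rng = np.random.default_rng(seed_seq)
    severity = rng.standard_normal()
    latents = _effect_latents(spec, group, severity, rng)
    clinical = _clinical_scores(spec, group, severity, rng)
    resting = generate_resting_recording(spec, latents, rng)
    tms = generate_tms_recording(spec, latents, rng)
    return SubjectRecord(
        subject_id=subject_id, group=group,
        age=clinical["age"], madrs=clinical["MADRS"],
        stai_state=clinical["STAI_state"], stai_trait=clinical["STAI_trait"],
        mmse=clinical["MMSE"], resting=resting, tms=tms,
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Deterministically generate 2 * n_per_group subjects (MDD then HC)."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_per_group)
    records = []
    for g, group in enumerate(("MDD", "HC")):
        for i in range(spec.n_per_group):
            sid = f"{group}{i + 1:03d}"
            records.append(
                generate_subject(spec, group, sid,
                                 children[g * spec.n_per_group + i])
            )
    return records
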