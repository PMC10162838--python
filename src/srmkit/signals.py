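"""Synthesis and measurement of the non-speech stimulus classes.

Covers the tone, frequency-modulated tone, modulated-noise (ripple), and
gap-marker click stimuli used by the battery, plus the shared DSP
primitives (band-pass filtering, rms normalization, envelope modulation
spectra).  Every synthesis routine is a pure function of its parameters and
an explicit seed, so identical calls give bit-identical waveforms.

Conventions
-----------
* FM depth is the total peak-to-peak frequency excursion: a 500 Hz carrier
  with depth 6 Hz sweeps between 497 and 503 Hz.
* Ripple depth ``M`` is in dB, measured from the middle to the peak of the
  log-amplitude excursion.
* The gap-marker click is a truncated-Gaussian envelope whose equivalent
  rectangular duration (ERD) is 2 ms inside a 4 ms window; its peak is set
  at peak-equivalent SPL (the level of a sinusoid with the same peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import brentq
from scipy.special import erf

from .audio import DEFAULT_CONVENTION, DEFAULT_RATE, AudioBuffer, LevelConvention

__all__ = [
    "FMSpec",
    "RippleSpec",
    "ClickSpec",
    "synth_tone",
    "synth_fm_tone",
    "synth_ripple_noise",
    "synth_gap_stimulus",
    "synth_click",
    "measure_erd",
    "measure_instantaneous_frequency",
    "bandpass_butter",
    "rms_normalize",
    "modulation_spectrum",
    "fit_tm_depth",
    "fit_sm_depth",
]


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class FMSpec:
    """Sinusoidal frequency modulation of a pure-tone carrier.

    ``depth_hz`` is the total peak-to-peak excursion; the instantaneous
    frequency is ``carrier + (depth/2) * sin(2*pi*rate*t + start_phase)``.
    With ``dichotic=True`` the right-ear modulator is inverted in phase, so
    the two ears' frequency deviations sum to zero at every instant.
    """

    carrier_hz: float = 500.0
    rate_hz: float = 2.0
    depth_hz: float = 6.0
    start_phase: float = 0.0
    dichotic: bool = False

    def __post_init__(self) -> None:
        if self.depth_hz < 0:
            raise ValueError("depth_hz must be non-negative")
        if self.carrier_hz - self.depth_hz / 2 <= 0:
            raise ValueError("modulation depth exceeds carrier frequency")


#: Carrier rove distribution for the FM tasks: uniform 460-550 Hz per interval.
FM_ROVE_LO = 460.0
FM_ROVE_HI = 550.0


@dataclass(frozen=True)
class RippleSpec:
    """Spectrally and/or temporally modulated broadband noise.

    ``tm_rate_hz`` is the temporal modulation rate (4 Hz for TM/STM, 0 for
    SM); ``sm_density_cpo`` the spectral density in cycles per octave (2 for
    SM/STM, 0 for TM).  ``depth_m_db`` is the mid-to-peak modulation depth M
    on a log-amplitude (dB) scale; depth 0 gives statistically unmodulated
    noise.
    """

    tm_rate_hz: float = 4.0
    sm_density_cpo: float = 2.0
    depth_m_db: float = 6.0
    band_lo_hz: float = 400.0
    band_hi_hz: float = 8000.0
    duration_ms: float = 500.0
    level_db_spl: float = 65.0

    def __post_init__(self) -> None:
        if self.depth_m_db < 0:
            raise ValueError("depth_m_db must be non-negative")
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("need 0 < band_lo < band_hi")


@dataclass(frozen=True)
class ClickSpec:
    """Truncated-Gaussian gap-marker click."""

    envelope_duration_ms: float = 4.0
    erd_ms: float = 2.0
    peak_level_db_pespl: float = 80.0

    def __post_init__(self) -> None:
        if not self.erd_ms < self.envelope_duration_ms:
            raise ValueError("erd_ms must be smaller than envelope_duration_ms")


# ---------------------------------------------------------------------------
# Tone and FM synthesis


def _check_nyquist(freq: float, rate: int) -> None:
    if freq >= rate / 2:
        raise ValueError(
            f"frequency {freq} Hz is at or above the Nyquist limit {rate / 2} Hz"
        )


def synth_tone(
    freq: float,
    duration_ms: float,
    level_db_spl: float,
    convention: LevelConvention = DEFAULT_CONVENTION,
    rate: int = DEFAULT_RATE,
) -> AudioBuffer:
    """Pure tone at ``freq`` Hz with rms set to ``level_db_spl``."""
    _check_nyquist(freq, rate)
    n = int(round(duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    amp = np.sqrt(2.0) * convention.rms_for_spl(level_db_spl)
    return AudioBuffer(amp * np.sin(2 * np.pi * freq * t), rate)


def measure_instantaneous_frequency(
    buf: AudioBuffer, channel: int = 0, trim_fraction: float = 0.02
) -> np.ndarray:
    """Instantaneous frequency (Hz) from the numerically differentiated
    unwrapped analytic phase, with edge samples trimmed.

    The FFT-based analytic signal assumes periodicity, so the estimate is
    only accurate when the buffer spans whole modulator cycles (e.g. 1 s of
    a 2 Hz FM tone); edge fractions are discarded either way.
    """
    x = buf.samples if buf.channels == 1 else buf.samples[:, channel]
    phase = np.unwrap(np.angle(sps.hilbert(x)))
    f_inst = np.diff(phase) * buf.rate / (2 * np.pi)
    k = int(len(f_inst) * trim_fraction)
    return f_inst[k : len(f_inst) - k] if k else f_inst


def fm_instantaneous_frequency(spec: FMSpec, t: np.ndarray) -> np.ndarray:
    """Closed-form instantaneous frequency of the (left-ear) FM tone."""
    return spec.carrier_hz + (spec.depth_hz / 2.0) * np.sin(
        2 * np.pi * spec.rate_hz * t + spec.start_phase
    )


def synth_fm_tone(
    spec: FMSpec,
    duration_ms: float = 400.0,
    level_db_spl: float = 75.0,
    convention: LevelConvention = DEFAULT_CONVENTION,
    rate: int = DEFAULT_RATE,
) -> AudioBuffer:
    """Frequency-modulated tone; stereo, with antiphase right-ear modulator
    when ``spec.dichotic`` is set, otherwise identical channels."""
    _check_nyquist(spec.carrier_hz + spec.depth_hz / 2.0, rate)
    n = int(round(duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    amp = np.sqrt(2.0) * convention.rms_for_spl(level_db_spl)

    def full_phase(mod_sign: float) -> np.ndarray:
        # phase = 2*pi * integral of f_inst; the modulator integrates to
        # (depth/2)/rate * (cos(phi0) - cos(2*pi*rate*t + phi0))
        base = 2 * np.pi * spec.carrier_hz * t
        if spec.rate_hz == 0 or spec.depth_hz == 0:
            return base
        return base + mod_sign * (spec.depth_hz / 2.0) / spec.rate_hz * (
            np.cos(spec.start_phase)
            - np.cos(2 * np.pi * spec.rate_hz * t + spec.start_phase)
        )

    left = amp * np.sin(full_phase(+1.0))
    right = amp * np.sin(full_phase(-1.0 if spec.dichotic else +1.0))
    return AudioBuffer(np.column_stack([left, right]), rate)


# ---------------------------------------------------------------------------
# Ripple noise


def synth_ripple_noise(
    spec: RippleSpec,
    seed: int | np.random.Generator = 0,
    rate: int = DEFAULT_RATE,
    convention: LevelConvention = DEFAULT_CONVENTION,
    components_per_octave: int = 40,
) -> AudioBuffer:
    """Modulated broadband noise built as a dense log-spaced tone complex.

    Each component at frequency ``f`` carries a random starting phase and a
    time-varying gain whose level in dB is
    ``M * sin(2*pi*density*log2(f/band_lo) + 2*pi*rate*t + phi)`` with the
    ripple phase ``phi`` randomized per stimulus.  Depth 0 (or both the
    temporal rate and spectral density 0) reduces to statistically flat
    noise across the band.
    """
    _check_nyquist(spec.band_hi_hz, rate)
    rng = np.random.default_rng(seed)
    n_oct = np.log2(spec.band_hi_hz / spec.band_lo_hz)
    n_comp = max(100, int(np.ceil(n_oct * components_per_octave)))
    freqs = spec.band_lo_hz * 2.0 ** (np.linspace(0.0, n_oct, n_comp))
    phases = rng.uniform(0, 2 * np.pi, n_comp)
    ripple_phase = rng.uniform(0, 2 * np.pi)

    n = int(round(spec.duration_ms / 1000.0 * rate))
    t = (np.arange(n) / rate)[:, None]  # (n, 1)
    spectral_arg = 2 * np.pi * spec.sm_density_cpo * np.log2(freqs / spec.band_lo_hz)
    if spec.depth_m_db == 0:
        gains_db = np.zeros((1, n_comp))
    else:
        gains_db = spec.depth_m_db * np.sin(
            spectral_arg[None, :] + 2 * np.pi * spec.tm_rate_hz * t + ripple_phase
        )
    carriers = np.sin(2 * np.pi * freqs[None, :] * t + phases[None, :])
    x = np.sum(10.0 ** (gains_db / 20.0) * carriers, axis=-1)

    target_rms = convention.rms_for_spl(spec.level_db_spl)
    x *= target_rms / np.sqrt(np.mean(x**2))
    return AudioBuffer(x, rate)


# ---------------------------------------------------------------------------
# Clicks and gaps


@lru_cache(maxsize=32)
def _click_sigma_ms(envelope_duration_ms: float, erd_ms: float) -> float:
    """Gaussian sigma (ms) whose envelope, truncated to the given window,
    has exactly the requested ERD.

    For e(t) = exp(-t^2 / (2 sigma^2)) truncated to |t| <= T:
    ERD = integral(e^2) / max(e^2) = sigma * sqrt(pi) * erf(T / sigma).
    """
    T = envelope_duration_ms / 2.0

    def f(sigma: float) -> float:
        return sigma * np.sqrt(np.pi) * erf(T / sigma) - erd_ms

    # untruncated solution erd/sqrt(pi) is a lower bracket; T an upper one
    return brentq(f, erd_ms / np.sqrt(np.pi), T)


def _click_envelope(spec: ClickSpec, rate: int) -> np.ndarray:
    n = int(round(spec.envelope_duration_ms / 1000.0 * rate))
    sigma = _click_sigma_ms(spec.envelope_duration_ms, spec.erd_ms) / 1000.0
    t = (np.arange(n) + 0.5) / rate - spec.envelope_duration_ms / 2000.0
    return np.exp(-(t**2) / (2 * sigma**2))


def synth_click(
    spec: ClickSpec = ClickSpec(),
    convention: LevelConvention = DEFAULT_CONVENTION,
    rate: int = DEFAULT_RATE,
) -> AudioBuffer:
    """A single gap-marker click at the spec's peak-equivalent SPL."""
    peak = np.sqrt(2.0) * convention.rms_for_spl(spec.peak_level_db_pespl)
    return AudioBuffer(peak * _click_envelope(spec, rate), rate)


def synth_gap_stimulus(
    spec: ClickSpec = ClickSpec(),
    gap_ms: float = 20.0,
    convention: LevelConvention = DEFAULT_CONVENTION,
    rate: int = DEFAULT_RATE,
) -> AudioBuffer:
    """Two identical clicks separated by ``gap_ms`` of silence.

    The gap is measured from the end of the first click's truncation window
    to the start of the second's, so gap 0 gives two abutting windows.
    """
    if gap_ms < 0:
        raise ValueError("gap_ms must be non-negative")
    click = synth_click(spec, convention, rate).samples
    n_gap = int(round(gap_ms / 1000.0 * rate))
    return AudioBuffer(
        np.concatenate([click, np.zeros(n_gap), click]), rate
    )


def measure_erd(buf: AudioBuffer, method: str = "abs") -> float:
    """Equivalent rectangular duration in ms.

    ERD = integral(e^2) dt / max(e^2), with the envelope ``e`` taken as the
    rectified waveform (``method="abs"``, exact for monophasic pulses such
    as the gap-marker clicks) or the analytic-signal magnitude
    (``method="analytic"``, for carrier-borne stimuli).
    """
    x = buf.samples
    if x.ndim == 2:
        x = x[:, 0]
    if not np.any(x):
        raise ValueError("cannot measure ERD of a silent buffer")
    if method == "abs":
        env = np.abs(x)
    elif method == "analytic":
        env = np.abs(sps.hilbert(x))
    else:
        raise ValueError(f"unknown method {method!r}")
    e2 = env**2
    return float(np.sum(e2) / np.max(e2) / buf.rate * 1000.0)


# ---------------------------------------------------------------------------
# Shared DSP


def bandpass_butter(
    buf: AudioBuffer, lo_hz: float = 80.0, hi_hz: float = 8000.0, order: int = 5
) -> AudioBuffer:
    """Butterworth band-pass (causal, second-order sections)."""
    nyq = buf.rate / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"need 0 < lo < hi < Nyquist ({nyq} Hz); got lo={lo_hz}, hi={hi_hz}"
        )
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=buf.rate, output="sos")
    y = sps.sosfilt(sos, buf.samples, axis=0)
    return AudioBuffer(y, buf.rate)


def rms_normalize(buf: AudioBuffer, target_rms: float = 0.1) -> AudioBuffer:
    """Scale a buffer so its rms equals ``target_rms`` (shape preserved)."""
    current = buf.rms()
    if current == 0:
        raise ValueError("cannot normalize a silent buffer")
    return AudioBuffer(buf.samples * (target_rms / current), buf.rate)


def modulation_spectrum(
    buf: AudioBuffer,
    f_lo: float = 0.5,
    f_hi: float = 32.0,
    env_rate: int = 200,
) -> pd.DataFrame:
    """Envelope modulation power spectrum between ``f_lo`` and ``f_hi`` Hz.

    The broadband Hilbert envelope is decimated to ``env_rate`` Hz,
    mean-normalized, and passed through a Welch periodogram.  Intended for
    quality-control comparisons (e.g. the syllabic-rate peak of a speech
    corpus); deterministic for a given buffer.
    """
    if buf.duration < 0.5:
        raise ValueError("buffer too short for a modulation spectrum (need >= 0.5 s)")
    x = buf.samples if buf.channels == 1 else buf.samples.mean(axis=1)
    env = np.abs(sps.hilbert(x))
    dec = max(1, int(buf.rate // env_rate))
    # anti-alias then decimate the envelope
    sos = sps.butter(4, (env_rate / 2.0) * 0.9, fs=buf.rate, output="sos")
    env = sps.sosfiltfilt(sos, env)[::dec]
    fs_env = buf.rate / dec
    env = env / np.mean(env) - 1.0
    nper = min(len(env), int(fs_env * 4))
    freqs, power = sps.welch(env, fs=fs_env, nperseg=nper)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    return pd.DataFrame({"frequency_hz": freqs[keep], "power": power[keep]})


def fit_sm_depth(
    buf: AudioBuffer,
    sm_density_cpo: float = 2.0,
    band_lo_hz: float = 400.0,
    band_hi_hz: float = 8000.0,
    band_fraction_octave: float = 1.0 / 12.0,
) -> float:
    """Recover the spectral modulation depth M (dB) of an SM stimulus.

    Integrates the Welch power spectrum into fractional-octave bands, fits
    a sinusoid in dB against log2(f / band_lo), and divides out the known
    sinc attenuation from band averaging.  A dB-amplitude ripple of depth M
    appears as a dB-power ripple of the same depth.
    """
    x = buf.samples if buf.channels == 1 else buf.samples.mean(axis=1)
    freqs, power = sps.welch(x, fs=buf.rate, nperseg=min(len(x), 16384))
    edges = band_lo_hz * 2.0 ** np.arange(
        0.0, np.log2(band_hi_hz / band_lo_hz) + 1e-9, band_fraction_octave
    )
    centers, band_power = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (freqs >= a) & (freqs < b)
        if np.any(sel):
            centers.append(np.sqrt(a * b))
            band_power.append(np.sum(power[sel]))
    xx = np.log2(np.asarray(centers) / band_lo_hz)
    db = 10.0 * np.log10(band_power)
    design = np.column_stack(
        [np.sin(2 * np.pi * sm_density_cpo * xx),
         np.cos(2 * np.pi * sm_density_cpo * xx),
         np.ones_like(xx), xx]
    )
    coef, *_ = np.linalg.lstsq(design, db, rcond=None)
    # ripple amplitude is attenuated by averaging over a band segment
    theta = np.pi * sm_density_cpo * band_fraction_octave
    correction = np.sin(theta) / theta if theta > 0 else 1.0
    return float(np.hypot(coef[0], coef[1]) / correction)


def fit_tm_depth(buf: AudioBuffer, tm_rate_hz: float = 4.0) -> float:
    """Recover the temporal modulation depth M (dB) of a TM stimulus.

    Fits a sinusoid at the known rate to the dB-scaled, low-passed Hilbert
    envelope by least squares and returns its amplitude (mid-to-peak dB).
    """
    x = buf.samples if buf.channels == 1 else buf.samples.mean(axis=1)
    env = np.abs(sps.hilbert(x))
    sos = sps.butter(4, max(tm_rate_hz * 4.0, 20.0), fs=buf.rate, output="sos")
    env = np.maximum(sps.sosfiltfilt(sos, env), 1e-12)
    db = 20.0 * np.log10(env)
    # drop filter edges
    n_edge = int(0.05 * len(db))
    db = db[n_edge : len(db) - n_edge]
    t = np.arange(len(db)) / buf.rate
    design = np.column_stack(
        [np.sin(2 * np.pi * tm_rate_hz * t), np.cos(2 * np.pi * tm_rate_hz * t),
         np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, db, rcond=None)
    return float(np.hypot(coef[0], coef[1]))
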