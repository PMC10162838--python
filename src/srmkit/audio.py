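"""Waveform container, digital level convention, and WAV I/O.

All stimuli live in :class:`AudioBuffer` objects: float samples in digital
full scale, a sample rate, and one or two channels.  Physical sound pressure
levels (the battery speaks in dB SPL) attach to digital amplitude through a
:class:`LevelConvention`, which plays the role of the hardware calibration a
deployed test would perform: it declares which dB SPL a full-scale-rms signal
corresponds to.  The default reference is 100 dB SPL at rms 1.0, so a 65 dB
SPL stimulus has digital rms 10**((65-100)/20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

DEFAULT_RATE = 44100


@dataclass
class AudioBuffer:
    """A sampled waveform.

    Parameters
    ----------
    samples:
        Array of shape ``(n,)`` for mono or ``(n, 2)`` for stereo, in
        dimensionless digital full scale.
    rate:
        Sample rate in Hz.
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            pass
        elif self.samples.ndim == 2 and self.samples.shape[1] in (1, 2):
            if self.samples.shape[1] == 1:
                self.samples = self.samples[:, 0]
        else:
            raise ValueError(
                f"samples must be (n,) or (n, 2); got shape {self.samples.shape}"
            )
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    def rms(self) -> float:
        """Root-mean-square amplitude over all channels."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def to_stereo(self) -> "AudioBuffer":
        """Duplicate a mono buffer into two identical channels."""
        if self.channels == 2:
            return self
        return AudioBuffer(np.column_stack([self.samples, self.samples]), self.rate)

    def copy(self) -> "AudioBuffer":
        return AudioBuffer(self.samples.copy(), self.rate)


@dataclass(frozen=True)
class LevelConvention:
    """Mapping between digital rms and nominal dB SPL.

    ``spl_at_full_scale_rms`` is the sound pressure level assigned to a
    signal of digital rms 1.0.  The mapping is monotone and linear in dB:
    a +1 dB SPL request multiplies rms by 10**(1/20).
    """

    spl_at_full_scale_rms: float = 100.0

    def rms_for_spl(self, spl: float) -> float:
        """Digital rms that realizes ``spl`` dB SPL."""
        return 10.0 ** ((spl - self.spl_at_full_scale_rms) / 20.0)

    def spl_for_rms(self, rms: float) -> float:
        """Nominal dB SPL of a signal with digital rms ``rms``."""
        if rms <= 0:
            raise ValueError("rms must be positive")
        return self.spl_at_full_scale_rms + 20.0 * np.log10(rms)

    def scale_to_spl(self, buf: AudioBuffer, spl: float) -> AudioBuffer:
        """Rescale a buffer so its rms sits at ``spl`` under this convention."""
        current = buf.rms()
        if current == 0:
            raise ValueError("cannot level a silent buffer")
        return AudioBuffer(buf.samples * (self.rms_for_spl(spl) / current), buf.rate)


DEFAULT_CONVENTION = LevelConvention()


def write_wav(path, buf: AudioBuffer, subtype: str = "float32") -> None:
    """Write a buffer as WAV (``float32`` or 16-bit ``pcm16``)."""
    data = buf.samples
    if subtype == "float32":
        wavfile.write(path, buf.rate, data.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(data, -1.0, 1.0 - 1.0 / 32768)
        wavfile.write(path, buf.rate, np.round(clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def read_wav(path) -> AudioBuffer:
    """Read a WAV file into float64 full-scale samples."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return AudioBuffer(data, rate)
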