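"""Virtual auditory space: HRIR handling, spatialization, and scene mixing.

The speech task places a target at 0 degrees azimuth and two maskers either
colocated (0/0/0) or separated (+45/-45).  Sources are leveled in mono,
convolved with a stereo head-related impulse response for their azimuth,
and summed.  A built-in fixture HRIR set implements a spherical-head
approximation (Woodworth interaural time delay plus a broadband interaural
level difference); real measured HRIRs (e.g. KEMAR) can be loaded from
stereo WAV files named ``hrir_<azimuth>.wav``.

Convention: positive azimuth is to the listener's right, so the right ear
leads (the left channel is delayed by the ITD) at +45 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .audio import DEFAULT_CONVENTION, DEFAULT_RATE, AudioBuffer, LevelConvention, read_wav

__all__ = [
    "HEAD_RADIUS_M",
    "SPEED_OF_SOUND_M_S",
    "woodworth_itd",
    "HRIRSet",
    "SpatialScene",
    "make_fixture_hrir",
    "load_hrir_directory",
    "spatialize",
    "mix_scene",
]

HEAD_RADIUS_M = 0.0875
SPEED_OF_SOUND_M_S = 343.0


def woodworth_itd(azimuth_deg: float, head_radius_m: float = HEAD_RADIUS_M,
                  c_m_s: float = SPEED_OF_SOUND_M_S) -> float:
    """Spherical-head interaural time difference in seconds.

    ITD(theta) = (a/c) * (theta + sin(theta)) with theta in radians; about
    0.38 ms at 45 degrees for a 8.75 cm head radius.  Sign follows the
    azimuth: positive for sources on the right.
    """
    theta = np.deg2rad(azimuth_deg)
    return (head_radius_m / c_m_s) * (theta + np.sin(theta))


@dataclass
class HRIRSet:
    """Stereo impulse responses keyed by azimuth (degrees)."""

    irs: dict[float, np.ndarray]  # azimuth -> (n, 2) array
    rate: int = DEFAULT_RATE
    source: str = "fixture"
    #: group delay (samples) of the 0-degree response; convolution output is
    #: trimmed from this offset so scenes from different angles stay aligned.
    center: int = 0

    def __post_init__(self) -> None:
        for az, ir in self.irs.items():
            ir = np.asarray(ir, dtype=np.float64)
            if ir.ndim != 2 or ir.shape[1] != 2:
                raise ValueError(f"HRIR for {az} deg must be (n, 2)")
            if not np.all(np.isfinite(ir)):
                raise ValueError(f"HRIR for {az} deg contains non-finite values")
            self.irs[az] = ir

    @property
    def azimuths(self) -> list[float]:
        return sorted(self.irs)

    def get(self, azimuth: float) -> np.ndarray:
        if azimuth not in self.irs:
            raise KeyError(
                f"no HRIR for azimuth {azimuth}; available: {self.azimuths}"
            )
        return self.irs[azimuth]


def _fractional_delay_kernel(delay_samples: float, n: int, center: int) -> np.ndarray:
    """Windowed-sinc fractional delay of length ``n`` about ``center``."""
    k = np.arange(n)
    x = k - center - delay_samples
    return np.sinc(x) * np.hanning(n)


def make_fixture_hrir(
    azimuths=(-45.0, 0.0, 45.0),
    rate: int = DEFAULT_RATE,
    ir_length: int = 256,
    ild_db_at_90: float = 6.0,
) -> HRIRSet:
    """Schematic spherical-head HRIR set (not a veridical head).

    Each azimuth gets a fractional-delay sinc kernel per ear implementing
    the Woodworth ITD split evenly between leading and lagging ears, plus a
    broadband interaural level difference of ``ild_db_at_90 * sin(theta)``
    dB favoring the near ear.  The 0-degree response is a unit-energy
    centered impulse, identical in both ears.
    """
    azimuths = tuple(float(a) for a in azimuths)
    for required in (-45.0, 0.0, 45.0):
        if required not in azimuths:
            raise ValueError(f"fixture azimuths must include {required}")
    center = ir_length // 2
    irs = {}
    for az in azimuths:
        itd_s = woodworth_itd(az)
        half = itd_s * rate / 2.0
        sin_t = np.sin(np.deg2rad(az))
        # positive az: source right -> right ear leads and is louder
        gain_l = 10.0 ** (-ild_db_at_90 * sin_t / 2.0 / 20.0)
        gain_r = 10.0 ** (+ild_db_at_90 * sin_t / 2.0 / 20.0)
        left = gain_l * _fractional_delay_kernel(+half, ir_length, center)
        right = gain_r * _fractional_delay_kernel(-half, ir_length, center)
        irs[az] = np.column_stack([left, right])
    return HRIRSet(irs=irs, rate=rate, source="fixture", center=center)


def load_hrir_directory(directory, rate: int | None = None) -> HRIRSet:
    """Load user HRIRs from ``hrir_<azimuth>.wav`` stereo files."""
    directory = Path(directory)
    irs = {}
    rates = set()
    for path in sorted(directory.glob("hrir_*.wav")):
        az = float(path.stem.split("_", 1)[1])
        buf = read_wav(path)
        if buf.channels != 2:
            raise ValueError(f"{path} is not stereo")
        irs[az] = buf.samples
        rates.add(buf.rate)
    if not irs:
        raise FileNotFoundError(f"no hrir_*.wav files in {directory}")
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates in {directory}: {sorted(rates)}")
    found_rate = rates.pop()
    if rate is not None and rate != found_rate:
        raise ValueError(f"HRIR rate {found_rate} != requested {rate}")
    n = max(ir.shape[0] for ir in irs.values())
    # centering convention for user files: peak of the 0-degree (or first) IR
    ref = irs.get(0.0, next(iter(irs.values())))
    center = int(np.argmax(np.abs(ref).sum(axis=1)))
    return HRIRSet(irs=irs, rate=found_rate, source="user", center=center)


def spatialize(buf: AudioBuffer, azimuth: float, hrirs: HRIRSet) -> AudioBuffer:
    """Convolve a mono source with the stereo HRIR for ``azimuth``.

    The full convolution is trimmed back to the input length starting at
    the HRIR set's center offset, so interaural delays are preserved and
    scenes rendered at different angles stay sample-aligned.
    """
    if buf.rate != hrirs.rate:
        raise ValueError(f"buffer rate {buf.rate} != HRIR rate {hrirs.rate}")
    x = buf.samples if buf.channels == 1 else buf.samples.mean(axis=1)
    ir = hrirs.get(azimuth)
    out = np.column_stack(
        [sps.fftconvolve(x, ir[:, ch], mode="full") for ch in (0, 1)]
    )
    start = hrirs.center
    return AudioBuffer(out[start : start + len(x)], buf.rate)


@dataclass
class SpatialScene:
    """A leveled, positioned target plus any number of maskers.

    Each source is (mono buffer, azimuth degrees, level dB SPL).  The
    target may be ``None`` to render maskers alone (diagnostics).
    """

    target: tuple[AudioBuffer, float, float] | None
    maskers: list[tuple[AudioBuffer, float, float]] = field(default_factory=list)

    def sources(self):
        out = [] if self.target is None else [self.target]
        return out + list(self.maskers)


def mix_scene(
    scene: SpatialScene,
    hrirs: HRIRSet,
    convention: LevelConvention = DEFAULT_CONVENTION,
) -> AudioBuffer:
    """Level each source in mono, spatialize it, and sum sample-wise."""
    sources = scene.sources()
    if not sources:
        raise ValueError("scene has no sources")
    rates = {buf.rate for buf, _, _ in sources}
    if len(rates) > 1:
        raise ValueError(f"sources have mixed sample rates: {sorted(rates)}")
    n = max(buf.n_samples for buf, _, _ in sources)
    acc = np.zeros((n, 2))
    for buf, azimuth, level in sources:
        leveled = convention.scale_to_spl(buf, level)
        rendered = spatialize(leveled, azimuth, hrirs)
        acc[: rendered.n_samples] += rendered.samples
    return AudioBuffer(acc, rates.pop())
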