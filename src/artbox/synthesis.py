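"""Shepard tone complex (STC) synthesis over a circular pitch-chroma space.

A Shepard tone is a sum of octave-spaced sinusoids whose amplitudes follow a
fixed bell-shaped spectral envelope over log-frequency.  Because every
component has partners one octave above and below, the percept carries a
clear pitch chroma (note identity) while pitch height (octave register) is
ambiguous; raising the fundamental by a full octave returns the identical
sound.  This module maps a 1-360 degree circular coordinate onto one octave
of fundamental frequencies and renders the corresponding waveforms.

Conventions
-----------
* Degree 1 is anchored at the base frequency; each degree step multiplies
  the fundamental by ``2**(1/360)``, so degree 360 sits one step below the
  octave (``2 * base * 2**(-1/360)``) and degree 361 would close the circle.
* The spectral envelope is a squared cosine over log2-frequency, centred on
  the log-midpoint of the component band and zero at both band edges.  The
  envelope is fixed relative to the band, not to the fundamental: this is
  what makes the space acoustically circular (degree 360 and degree 1 have
  nearly identical spectra).
* The component band is half-open, ``[band_low, band_high)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "ToneSpaceConfig",
    "ShepardTone",
    "degree_to_frequency",
    "frequency_to_degree",
    "component_frequencies",
    "spectral_envelope",
    "synthesize",
    "rms_equalize",
    "dmst_frequencies",
    "dmst_tone_set",
    "write_wav",
]

#: relative tolerance used when deciding band membership of an octave
#: transpose; protects exact band-edge components from float rounding.
_BAND_EPS = 1e-9


@dataclass(frozen=True)
class ToneSpaceConfig:
    """Parameters of the circular Shepard tone space.

    Defaults reproduce the single-octave space from 278.4375 Hz spanning
    360 degrees, with components confined to 30-16000 Hz at a 44.1 kHz
    sampling rate.
    """

    base_frequency: float = 278.4375
    degrees_per_octave: int = 360
    band_low: float = 30.0
    band_high: float = 16000.0
    sample_rate: int = 44100
    duration: float = 0.5
    ramp: float = 0.010
    envelope_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.band_high / self.band_low <= 2:
            raise ValueError("component band must span more than one octave")
        if not (self.band_low <= 2 * self.base_frequency <= self.band_high):
            raise ValueError("2 * base_frequency must lie inside the band")
        if self.duration <= 2 * self.ramp:
            raise ValueError("duration must exceed twice the ramp length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class ShepardTone:
    """A synthesized Shepard tone: spectrum plus rendered waveform."""

    degree: float
    fundamental: float
    components: tuple[tuple[float, float], ...]  # (frequency Hz, amplitude 0-1)
    samples: np.ndarray = field(repr=False)


def degree_to_frequency(degree: float, config: ToneSpaceConfig = ToneSpaceConfig()) -> float:
    """Fundamental frequency (Hz) at a point of the circular space.

    ``f(d) = base_frequency * 2**((d - 1) / degrees_per_octave)``; degree 1
    is the base frequency and each 1-degree step raises the fundamental by a
    factor of ``2**(1/360)`` for the default 360-degree space.
    """
    n = config.degrees_per_octave
    if not (1.0 <= degree <= float(n)):
        raise ValueError(f"degree must lie in [1, {n}], got {degree}")
    return config.base_frequency * 2.0 ** ((degree - 1.0) / n)


def frequency_to_degree(frequency: float, config: ToneSpaceConfig = ToneSpaceConfig()) -> float:
    """Inverse of :func:`degree_to_frequency`.

    The frequency must fall inside the single octave covered by the space
    (``[base, 2*base)``); reduce by octaves first if necessary.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    n = config.degrees_per_octave
    degree = 1.0 + n * math.log2(frequency / config.base_frequency)
    if not (1.0 - 1e-9 <= degree < n + 1.0):
        raise ValueError(
            f"{frequency} Hz is outside the octave starting at {config.base_frequency} Hz"
        )
    return min(max(degree, 1.0), float(n) + 1.0 - 1e-12)


def component_frequencies(
    fundamental: float, config: ToneSpaceConfig = ToneSpaceConfig()
) -> np.ndarray:
    """All octave transposes of ``fundamental`` inside ``[band_low, band_high)``.

    Returns the ascending frequencies ``fundamental * 2**k`` (k integer) that
    fall in the half-open component band.  A 500 Hz fundamental with the
    default band yields the nine components 31.25 ... 8000 Hz.
    """
    if fundamental <= 0:
        raise ValueError("fundamental must be positive")
    k_lo = math.ceil(math.log2(config.band_low / fundamental) - _BAND_EPS)
    k_hi = math.floor(math.log2(config.band_high / fundamental) + _BAND_EPS)
    freqs = [fundamental * 2.0**k for k in range(k_lo, k_hi + 1)]
    freqs = [f for f in freqs if f < config.band_high * (1.0 - _BAND_EPS)]
    if not freqs:
        raise ValueError(
            f"no octave transpose of {fundamental} Hz lies in "
            f"[{config.band_low}, {config.band_high})"
        )
    return np.asarray(freqs)


def spectral_envelope(
    frequency: float | np.ndarray, config: ToneSpaceConfig = ToneSpaceConfig()
) -> float | np.ndarray:
    """Amplitude (0-1) of the fixed cos^2 envelope at ``frequency``.

    With ``l = log2(frequency)``, ``c`` the midpoint of the log band and
    ``h`` its half-width, returns ``cos(pi * (l - c) / (2 * h)) ** 2``:
    1 at the geometric band centre, 0 at both edges, symmetric in
    log-frequency.  Frequencies outside the band clamp to 0.
    """
    f = np.asarray(frequency, dtype=float)
    c = 0.5 * (math.log2(config.band_low) + math.log2(config.band_high))
    h = 0.5 * (math.log2(config.band_high) - math.log2(config.band_low))
    with np.errstate(divide="ignore"):
        l = np.where(f > 0, np.log2(np.where(f > 0, f, 1.0)), -np.inf)
    amp = np.cos(np.pi * (l - c) / (2.0 * h)) ** 2
    amp = np.where((f >= config.band_low) & (f <= config.band_high), amp, 0.0)
    if np.isscalar(frequency):
        return float(amp)
    return amp


def _raised_cosine_ramps(n_samples: int, ramp: float, sample_rate: int) -> np.ndarray:
    """Tukey-style gating window: raised-cosine on/off ramps, flat middle."""
    window = np.ones(n_samples)
    n_ramp = int(round(ramp * sample_rate))
    if n_ramp > 0:
        t = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        rise = 0.5 * (1.0 - np.cos(np.pi * t))
        window[:n_ramp] = rise
        window[-n_ramp:] = rise[::-1]
    return window


def synthesize(degree: float, config: ToneSpaceConfig = ToneSpaceConfig()) -> ShepardTone:
    """Render the Shepard tone at ``degree`` as a waveform.

    The waveform is the sum of sine components (phase 0) weighted by the
    spectral envelope, peak-normalized to 0.99, with raised-cosine on/off
    ramps of ``config.ramp`` seconds.
    """
    if config.duration <= 0:
        raise ValueError("duration must be positive")
    fundamental = degree_to_frequency(degree, config)
    freqs = component_frequencies(fundamental, config)
    amps = spectral_envelope(freqs, config)
    keep = amps >= config.envelope_threshold
    freqs, amps = freqs[keep], amps[keep]

    n_samples = int(round(config.duration * config.sample_rate))
    t = np.arange(n_samples) / config.sample_rate
    wave = np.sin(2.0 * np.pi * np.outer(freqs, t)) * amps[:, None]
    wave = wave.sum(axis=0)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= 0.99 / peak
    wave *= _raised_cosine_ramps(n_samples, config.ramp, config.sample_rate)
    return ShepardTone(
        degree=float(degree),
        fundamental=fundamental,
        components=tuple(zip(freqs.tolist(), amps.tolist())),
        samples=wave,
    )


def rms_equalize(waveforms: list[np.ndarray]) -> list[np.ndarray]:
    """Scale each waveform so all share the mean RMS of the input list."""
    if not waveforms:
        raise ValueError("need at least one waveform")
    rms = np.array([math.sqrt(float(np.mean(np.square(w)))) for w in waveforms])
    if np.any(rms == 0):
        raise ValueError("cannot RMS-equalize a silent waveform")
    target = float(rms.mean())
    return [np.asarray(w) * (target / r) for w, r in zip(waveforms, rms)]


def dmst_frequencies(f_low: float = 1000.0, n: int = 12) -> np.ndarray:
    """Frequencies of the n-tone semitone ladder: ``f_low * 2**((i-1)/12)``."""
    if n < 2:
        raise ValueError("need at least two tones")
    return f_low * 2.0 ** (np.arange(n) / 12.0)


def dmst_tone_set(
    f_low: float = 1000.0,
    n: int = 12,
    duration: float = 0.5,
    sample_rate: int = 44100,
    ramp: float = 0.010,
) -> list[np.ndarray]:
    """Pure-tone set for the delayed-match-to-sample task.

    ``n`` sinusoids spaced by a factor of ``2**(1/12)`` upward from
    ``f_low`` (tone 13, if requested, closes the octave at ``2 * f_low``),
    RMS-equalized, with raised-cosine ramps.
    """
    freqs = dmst_frequencies(f_low, n)
    n_samples = int(round(duration * sample_rate))
    t = np.arange(n_samples) / sample_rate
    window = _raised_cosine_ramps(n_samples, ramp, sample_rate)
    tones = [0.9 * np.sin(2.0 * np.pi * f * t) * window for f in freqs]
    return rms_equalize(tones)


def write_wav(path: str, samples: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a waveform as 16-bit PCM mono WAV, clipping to [-1, 1]."""
    clipped = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    if np.max(np.abs(samples)) > 1.0:
        warnings.warn("samples clipped to [-1, 1] on WAV export")
    wavfile.write(path, sample_rate, (clipped * 32767.0).astype(np.int16))
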