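"""Amplitude-modulated tone synthesis.

The paradigm uses sinusoidally amplitude-modulated (AM) tones

.. math:: y(t) = (1 + d\\,\\sin 2\\pi f_m t)\\,\\sin 2\\pi f_c t

with carrier :math:`f_c`, modulation rate :math:`f_m` and modulation depth
:math:`d` (1.0 = 100 %).  Multiplying the two sinusoids places energy at the
carrier and at the two sidebands :math:`f_c \\pm f_m`, each sideband carrying
half the carrier amplitude — the spectral fingerprint the downstream
frequency-following-response analysis looks for.

Two tones are used by default: AM(220 Hz, 40 Hz) and AM(440 Hz, 80 Hz),
450 ms long with 10-ms raised-cosine onset/offset ramps, rendered at 48 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AMToneSpec",
    "LOW_TONE",
    "HIGH_TONE",
    "synthesize_am_tone",
    "apply_ramp",
    "write_stimulus_wav",
]


@dataclass(frozen=True)
class AMToneSpec:
    """Parametric description of one amplitude-modulated tone.

    Parameters
    ----------
    carrier_hz : float
        Carrier frequency :math:`f_c` in Hz.
    modulation_hz : float
        Modulation frequency :math:`f_m` in Hz; must be below the carrier.
    depth : float
        Modulation depth in (0, 1]; 1.0 means 100 % modulation. A depth of
        exactly 0 is accepted as the degenerate "modulation off" case.
    duration_s : float
        Total tone duration in seconds (including ramps).
    ramp_s : float
        Rise/fall time in seconds; raised-cosine tapers are applied at both
        ends to limit spectral splatter.
    audio_rate_hz : float
        Audio sampling rate in samples/second.
    """

    carrier_hz: float = 220.0
    modulation_hz: float = 40.0
    depth: float = 1.0
    duration_s: float = 0.45
    ramp_s: float = 0.010
    audio_rate_hz: float = 48_000.0

    def __post_init__(self) -> None:
        if not self.carrier_hz > self.modulation_hz >= 0:
            raise ValueError(
                "invalid AMToneSpec: requires carrier_hz > modulation_hz >= 0, "
                f"got carrier_hz={self.carrier_hz}, modulation_hz={self.modulation_hz}"
            )
        if self.modulation_hz == 0 and self.depth != 0:
            raise ValueError("invalid AMToneSpec: modulation_hz must be > 0 when depth > 0")
        if not (0 <= self.depth <= 1):
            raise ValueError(f"invalid AMToneSpec: depth must be in [0, 1], got {self.depth}")
        if not self.duration_s > 2 * self.ramp_s:
            raise ValueError(
                "invalid AMToneSpec: requires duration_s > 2*ramp_s, "
                f"got duration_s={self.duration_s}, ramp_s={self.ramp_s}"
            )
        if not self.audio_rate_hz > 2 * (self.carrier_hz + self.modulation_hz):
            raise ValueError(
                "invalid AMToneSpec: audio_rate_hz must exceed twice the highest "
                f"spectral component ({self.carrier_hz + self.modulation_hz} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.audio_rate_hz))

    @property
    def upper_sideband_hz(self) -> float:
        return self.carrier_hz + self.modulation_hz

    @property
    def lower_sideband_hz(self) -> float:
        return self.carrier_hz - self.modulation_hz


#: Default tone pair of the roving paradigm.
LOW_TONE = AMToneSpec(carrier_hz=220.0, modulation_hz=40.0)
HIGH_TONE = AMToneSpec(carrier_hz=440.0, modulation_hz=80.0)


def synthesize_am_tone(spec: AMToneSpec, sample_rate_hz: float | None = None) -> np.ndarray:
    """Synthesize one AM tone as a float64 waveform.

    The waveform is ``(1 + depth*sin(2*pi*fm*t)) * sin(2*pi*fc*t)`` evaluated
    at ``t = n / rate`` for ``n = 0 .. N-1`` with
    ``N = round(duration_s * rate)``, multiplied by raised-cosine
    onset/offset ramps of length ``ramp_s``.  Peak amplitude is bounded by
    ``1 + depth``; no normalization is applied here (see
    :func:`write_stimulus_wav`).

    Parameters
    ----------
    spec : AMToneSpec
        Tone parameters (validated on construction).
    sample_rate_hz : float, optional
        Override the spec's audio rate; used when rendering the same tone
        at an EEG simulation rate instead of the audio rate.
    """
    rate = float(sample_rate_hz if sample_rate_hz is not None else spec.audio_rate_hz)
    if not rate > 2 * (spec.carrier_hz + spec.modulation_hz):
        raise ValueError(
            f"sample rate {rate} Hz too low for carrier+modulation "
            f"{spec.carrier_hz + spec.modulation_hz} Hz"
        )
    n = int(round(spec.duration_s * rate))
    t = np.arange(n) / rate
    y = (1.0 + spec.depth * np.sin(2 * np.pi * spec.modulation_hz * t)) * np.sin(
        2 * np.pi * spec.carrier_hz * t
    )
    return apply_ramp(y, spec.ramp_s, rate)


def ramp_envelope(n_samples: int, ramp_s: float, sample_rate_hz: float) -> np.ndarray:
    """Raised-cosine (Hann half-window) onset/offset envelope.

    The first and last ``round(ramp_s * rate)`` samples are tapered with
    ``0.5 * (1 - cos(pi * k / (R - 1)))`` so the end samples are exactly
    zero; the middle of the envelope is 1.
    """
    n_ramp = int(round(ramp_s * sample_rate_hz))
    if 2 * n_ramp > n_samples:
        raise ValueError(
            f"ramp of {n_ramp} samples does not fit twice into a "
            f"{n_samples}-sample waveform"
        )
    env = np.ones(n_samples)
    if n_ramp >= 2:
        k = np.arange(n_ramp)
        taper = 0.5 * (1.0 - np.cos(np.pi * k / (n_ramp - 1)))
        env[:n_ramp] = taper
        env[-n_ramp:] = taper[::-1]
    elif n_ramp == 1:
        env[0] = 0.0
        env[-1] = 0.0
    return env


def apply_ramp(waveform: np.ndarray, ramp_s: float, sample_rate_hz: float) -> np.ndarray:
    """Apply raised-cosine onset/offset ramps to a waveform.

    ``ramp_s = 0`` returns the waveform unchanged.  Raises ``ValueError``
    if the two ramps would overlap.
    """
    waveform = np.asarray(waveform, dtype=float)
    if ramp_s == 0:
        return waveform.copy()
    env = ramp_envelope(waveform.shape[-1], ramp_s, sample_rate_hz)
    return waveform * env


def write_stimulus_wav(
    waveform: np.ndarray,
    audio_rate_hz: float,
    path,
    peak_level: float = 0.9,
) -> None:
    """Export a waveform as a mono float32 WAV file.

    The waveform is peak-normalized to ``peak_level`` of full scale (the
    delivery level is set at the amplifier, so absolute scale carries no
    information).  Raises on empty input.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size == 0:
        raise ValueError("cannot write an empty waveform")
    peak = np.max(np.abs(waveform))
    if peak > 0:
        waveform = waveform * (peak_level / peak)
    wavfile.write(str(path), int(round(audio_rate_hz)), waveform.astype(np.float32))


def read_stimulus_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file back as (waveform, rate). Counterpart of the writer."""
    rate, data = wavfile.read(str(path))
    return np.asarray(data, dtype=np.float64), float(rate)
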