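"""Synthetic two-channel EEG with known embedded auditory responses.

The simulator renders every response family the paradigm is designed to
elicit, time-locked to a :class:`~roving_aep.paradigm.ParadigmSchedule`, and
buries them in 1/f background noise:

* **FFR** — a scaled copy of the stimulus fine structure (carrier sinusoid
  plus upper sideband) for the tone presented, nanovolt-scale;
* **ASSR** — a sinusoid at the tone's modulation rate (40 or 80 Hz) for the
  stimulus duration, plus a 1-Hz entrainment term phase-locked to the fixed
  1-s onset asynchrony during each stimulation period;
* **ERP kernels** — Gaussian-windowed deflections (P1, N1, P2, sustained
  negativity, post-offset negativity) on every trial, with
  direction-specific extras on deviants: ascending transitions get enhanced
  N1/P2, descending transitions get MMN and P3a kernels;
* sparse high-amplitude artifact transients to exercise the ±150-μV
  rejection stage.

Everything is linear in the configured amplitudes and deterministic per
seed, so averaging noiseless epochs recovers the kernel sum exactly — the
property the downstream pipeline tests lean on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from roving_aep.io import Recording
from roving_aep.paradigm import ParadigmSchedule, TONE_LOW
from roving_aep.stimulus import ramp_envelope

__all__ = [
    "SimConfig",
    "ERPKernel",
    "simulate_background",
    "render_evoked",
    "inject_artifacts",
    "simulate_subject",
]

#: Tone parameters keyed by schedule tone label: (carrier, modulation) Hz.
_TONE_FREQS = {"low": (220.0, 40.0), "high": (440.0, 80.0)}

EVENT_CODES = {"low": 1, "high": 2}


@dataclass(frozen=True)
class ERPKernel:
    """One Gaussian-windowed deflection: ``sign*amp*exp(-(t-peak)^2/2σ^2)``."""

    peak_ms: float
    sigma_ms: float
    sign: int  # +1 positive-going, -1 negative-going at the scalp


#: Kernel shapes (latency/width/polarity); amplitudes live in SimConfig.
ERP_KERNELS: dict[str, ERPKernel] = {
    "P1": ERPKernel(peak_ms=50.0, sigma_ms=10.0, sign=+1),
    "N1": ERPKernel(peak_ms=110.0, sigma_ms=14.0, sign=-1),
    "P2": ERPKernel(peak_ms=200.0, sigma_ms=22.0, sign=+1),
    "SUSTAINED_NEG": ERPKernel(peak_ms=370.0, sigma_ms=85.0, sign=-1),
    "OFFSET_NEG": ERPKernel(peak_ms=720.0, sigma_ms=40.0, sign=-1),
    "MMN": ERPKernel(peak_ms=144.0, sigma_ms=11.0, sign=-1),
    "P3A": ERPKernel(peak_ms=240.0, sigma_ms=16.0, sign=+1),
}


def _default_amplitudes() -> dict[str, float]:
    # μV throughout; FFR terms are nanovolt-scale as at the human scalp.
    return {
        "FFR_220": 0.05,
        "FFR_440": 0.05,
        "SIDEBAND_260": 0.025,
        "SIDEBAND_520": 0.025,
        "ASSR_40": 0.8,
        "ASSR_80": 0.4,
        "ASSR_1HZ": 1.0,
        "P1": 1.0,
        "N1": 3.0,
        "P2": 2.0,
        "SUSTAINED_NEG": 2.0,
        "OFFSET_NEG": 1.5,
        "MMN": 2.0,
        "P3A": 1.5,
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic-EEG generator.

    Parameters
    ----------
    sample_rate_hz : float
        Simulation rate; 5 kHz by default (20 kHz supported).  Must exceed
        twice the highest nonzero spectral component (the 520-Hz sideband
        needs ≥ 1040 Hz).
    noise_scale_uv : float
        Target RMS of the 1/f background per channel, μV.
    noise_exponent : float
        Spectral slope α of the 1/f^α background (0 = white).
    component_amplitudes : dict
        Peak amplitude per component, μV (≥ 0); see
        :func:`_default_amplitudes` for the component taxonomy.
    ascending_gain : float
        Fractional enhancement of the N1/P2 kernels on ascending deviants
        (0.5 → deviant N1 is 1.5× the nondeviant N1).
    channel_gains : tuple
        Per-channel (Fz, Cz) multipliers applied to the evoked signal.
    artifact_rate_per_min : float
        Poisson rate of injected high-amplitude transients.
    trial_jitter_ms : float
        SD of Gaussian per-trial onset jitter (0 = perfectly locked).
    rng_seed : int
    """

    sample_rate_hz: float = 5000.0
    noise_scale_uv: float = 10.0
    noise_exponent: float = 1.0
    component_amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    ascending_gain: float = 1.0
    channel_gains: tuple[float, float] = (1.0, 1.0)
    artifact_rate_per_min: float = 0.0
    trial_jitter_ms: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        amps = dict(_default_amplitudes(), **self.component_amplitudes)
        object.__setattr__(self, "component_amplitudes", amps)
        if any(v < 0 for v in amps.values()):
            raise ValueError("component amplitudes must be >= 0")
        if self.noise_scale_uv < 0:
            raise ValueError("noise_scale_uv must be >= 0")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")
        top = 0.0
        if amps["FFR_440"] > 0:
            top = max(top, 440.0)
        if amps["SIDEBAND_520"] > 0:
            top = max(top, 520.0)
        if amps["FFR_220"] > 0:
            top = max(top, 220.0)
        if amps["SIDEBAND_260"] > 0:
            top = max(top, 260.0)
        if self.sample_rate_hz <= 2 * top:
            raise ValueError(
                f"sample_rate_hz={self.sample_rate_hz} cannot represent the "
                f"highest simulated frequency ({top} Hz)"
            )

    def with_amplitudes(self, **amps: float) -> "SimConfig":
        """Copy with selected component amplitudes replaced."""
        return replace(self, component_amplitudes=dict(self.component_amplitudes, **amps))

    def zeroed(self) -> "SimConfig":
        """Copy with every evoked component switched off (null recordings)."""
        return replace(
            self, component_amplitudes={k: 0.0 for k in self.component_amplitudes}
        )


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_background(duration_s: float, config: SimConfig) -> Recording:
    """Zero-mean 1/f^α background noise, independent per channel.

    Generated by shaping white Gaussian noise in the frequency domain with
    ``f**(-α/2)`` (DC removed) and rescaling to the requested RMS.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not np.isfinite(config.noise_exponent):
        raise ValueError("noise_exponent must be finite")
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    rng = _spawn(config.rng_seed, 0)
    data = np.zeros((2, n))
    if config.noise_scale_uv > 0:
        freqs = np.fft.rfftfreq(n, d=1 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-config.noise_exponent / 2)
        for ch in range(2):
            spec = (
                rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
            ) * shaping
            x = np.fft.irfft(spec, n=n)
            x *= config.noise_scale_uv / np.sqrt(np.mean(x**2))
            data[ch] = x
    return Recording(data=data, sample_rate_hz=fs, meta={"kind": "background"})


def _trial_template(
    tone: str,
    config: SimConfig,
    deviant_direction: str | None,
    tone_duration_s: float = 0.45,
    soa_s: float = 1.0,
) -> np.ndarray:
    """Evoked template for one trial, from onset to one SOA later."""
    fs = config.sample_rate_hz
    amps = config.component_amplitudes
    fc, fm = _TONE_FREQS[tone]
    n_stim = int(round(tone_duration_s * fs))
    n_total = int(round(soa_s * fs))
    t_stim = np.arange(n_stim) / fs
    env = ramp_envelope(n_stim, 0.010, fs)
    out = np.zeros(n_total)

    ffr_key = "FFR_220" if tone == TONE_LOW else "FFR_440"
    sb_key = "SIDEBAND_260" if tone == TONE_LOW else "SIDEBAND_520"
    assr_key = "ASSR_40" if tone == TONE_LOW else "ASSR_80"
    stim_locked = (
        amps[ffr_key] * np.sin(2 * np.pi * fc * t_stim)
        - amps[sb_key] * 0.5 * np.cos(2 * np.pi * (fc + fm) * t_stim)
        + amps[assr_key] * np.sin(2 * np.pi * fm * t_stim)
    )
    out[:n_stim] += env * stim_locked

    t_ms = np.arange(n_total) / fs * 1000.0
    kernel_gain = {k: 1.0 for k in ("P1", "N1", "P2", "SUSTAINED_NEG", "OFFSET_NEG")}
    kernel_gain["MMN"] = 0.0
    kernel_gain["P3A"] = 0.0
    if deviant_direction == "ascending":
        kernel_gain["N1"] += config.ascending_gain
        kernel_gain["P2"] += config.ascending_gain
    elif deviant_direction == "descending":
        kernel_gain["MMN"] = 1.0
        kernel_gain["P3A"] = 1.0
    for name, gain in kernel_gain.items():
        amp = amps[name] * gain
        if amp == 0:
            continue
        k = ERP_KERNELS[name]
        out += k.sign * amp * np.exp(-0.5 * ((t_ms - k.peak_ms) / k.sigma_ms) ** 2)
    return out


def render_evoked(
    schedule: ParadigmSchedule,
    config: SimConfig,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render the noiseless evoked signal for a schedule.

    Returns an array of shape ``(2, n_samples)`` (Fz, Cz).  Each trial adds
    its tone's stimulus-locked template (FFR + sideband + ASSR under the
    stimulus ramp, plus the ERP kernel stack, with deviant extras by
    transition direction); each block adds the 1-Hz entrainment sinusoid
    over its stimulation period.  Linear in every configured amplitude.
    """
    fs = config.sample_rate_hz
    duration_s = duration_s if duration_s is not None else schedule.total_duration_s
    n = int(round(duration_s * fs))
    signal = np.zeros(n)

    templates: dict[tuple[str, str | None], np.ndarray] = {}
    jitter_rng = rng if rng is not None else _spawn(config.rng_seed, 1)
    trials = schedule.trials
    directions = np.where(
        trials["deviant"].to_numpy(), trials["transition"].to_numpy(), None
    )
    for onset, tone, direction in zip(
        trials["onset_s"].to_numpy(), trials["tone"].to_numpy(), directions
    ):
        key = (tone, direction)
        if key not in templates:
            templates[key] = _trial_template(
                tone,
                config,
                direction,
                tone_duration_s=schedule.config.tone_duration_s,
                soa_s=schedule.config.soa_s,
            )
        tpl = templates[key]
        if config.trial_jitter_ms > 0:
            onset = onset + jitter_rng.normal(0, config.trial_jitter_ms / 1000.0)
        i0 = int(round(onset * fs))
        i1 = min(i0 + tpl.size, n)
        if i0 >= n or i1 <= max(i0, 0):
            continue
        signal[max(i0, 0) : i1] += tpl[max(i0, 0) - i0 : i1 - i0]

    amp_1hz = config.component_amplitudes["ASSR_1HZ"]
    if amp_1hz > 0:
        soa_rate = 1.0 / schedule.config.soa_s
        for b, (t0, stim_end, _) in schedule.blocks.items():
            i0, i1 = int(round(t0 * fs)), min(int(round(stim_end * fs)), n)
            if i1 <= i0:
                continue
            t = np.arange(i1 - i0) / fs
            signal[i0:i1] += amp_1hz * np.sin(2 * np.pi * soa_rate * t)

    gains = np.asarray(config.channel_gains, dtype=float)[:, None]
    return gains * signal[None, :]


def inject_artifacts(recording: Recording, config: SimConfig) -> Recording:
    """Add sparse high-amplitude transients (Poisson-timed, > 150 μV peak).

    Each artifact is a 150-ms Gaussian-windowed deflection with a peak drawn
    uniformly from 200–400 μV (random polarity), applied to both channels —
    guaranteed to trip the ±150-μV rejection threshold.
    """
    if config.artifact_rate_per_min == 0:
        return recording.copy()
    rng = _spawn(config.rng_seed, 2)
    fs = recording.sample_rate_hz
    minutes = recording.duration_s / 60.0
    n_art = rng.poisson(config.artifact_rate_per_min * minutes)
    data = recording.data.copy()
    half = int(round(0.075 * fs))
    t = np.arange(-half, half + 1) / fs
    window = np.exp(-0.5 * (t / 0.025) ** 2)
    onsets = np.sort(rng.uniform(0, recording.duration_s, size=n_art))
    for onset in onsets:
        center = int(round(onset * fs))
        amp = rng.uniform(200.0, 400.0) * rng.choice([-1.0, 1.0])
        i0, i1 = max(center - half, 0), min(center + half + 1, recording.n_samples)
        seg = window[i0 - (center - half) : i1 - (center - half)]
        data[:, i0:i1] += amp * seg
    out = recording.copy(data=data)
    out.meta["artifact_onsets_s"] = onsets.tolist()
    return out


def simulate_subject(schedule: ParadigmSchedule, config: SimConfig) -> Recording:
    """Background + evoked + artifacts for one synthetic subject.

    Events mark every trial onset with code 1 (low tone) / 2 (high tone).
    Deterministic per ``config.rng_seed``.
    """
    rec = simulate_background(schedule.total_duration_s, config)
    rec.data += render_evoked(schedule, config, duration_s=rec.duration_s)
    rec = inject_artifacts(rec, config)
    fs = config.sample_rate_hz
    onsets = schedule.trials["onset_s"].to_numpy()
    codes = schedule.trials["tone"].map(EVENT_CODES).to_numpy()
    samples = np.round(onsets * fs).astype(np.int64)
    keep = samples < rec.n_samples
    rec.events = np.column_stack([samples[keep], codes[keep]])
    rec.meta.update(
        {
            "kind": "simulated_subject",
            "rng_seed": config.rng_seed,
            "sample_rate_hz": fs,
            "n_trials": int(len(onsets)),
        }
    )
    return rec
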