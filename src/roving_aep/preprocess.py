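"""Filtering, resampling, epoching, rejection and condition selection.

The preprocessing chain mirrors standard evoked-EEG practice: zero-phase
Butterworth band-pass (with power-line notches for the high-frequency
analyses), optional anti-aliased down-sampling, segmentation into
baseline-corrected epochs around stimulus onsets, amplitude-threshold
artifact rejection (±150 μV on the broadband epochs), and selection of
condition subsets (nondeviant per tone, deviant/standard per transition
direction, resting-state pseudo-trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from roving_aep.io import Recording
from roving_aep.paradigm import TONE_HIGH, TONE_LOW, ParadigmSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "EpochSet",
    "bandpass",
    "bandpass_array",
    "notch_power_line",
    "resample",
    "epoch",
    "reject_epochs",
    "select_condition",
    "average_epochs",
    "rs_pseudo_onsets",
    "CONDITIONS",
]

#: Condition labels accepted by :func:`select_condition`.
CONDITIONS = (
    "NONDEVIANT_LOW",
    "NONDEVIANT_HIGH",
    "DEVIANT_ASC",
    "DEVIANT_DESC",
    "STANDARD_ASC",
    "STANDARD_DESC",
    "RS",
)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description (applied zero-phase, forward-backward)."""

    kind: str  # {"bandpass", "lowpass", "highpass"}
    band_hz: tuple[float, ...]
    order: int = 2

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        nyq = sample_rate_hz / 2
        if max(self.band_hz) >= nyq:
            raise ValueError(
                f"filter band {self.band_hz} reaches the Nyquist frequency "
                f"({nyq} Hz) at rate {sample_rate_hz}"
            )
        btype = {"bandpass": "bandpass", "lowpass": "lowpass", "highpass": "highpass"}[
            self.kind
        ]
        return sps.butter(self.order, self.band_hz, btype=btype, fs=sample_rate_hz, output="sos")


def bandpass_array(
    x: np.ndarray, sample_rate_hz: float, band_hz: tuple[float, float], order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass on the last axis of an array."""
    sos = FilterSpec("bandpass", tuple(band_hz), order).sos(sample_rate_hz)
    return sps.sosfiltfilt(sos, x, axis=-1)


def bandpass(
    recording: Recording, band_hz: tuple[float, float], order: int = 2
) -> Recording:
    """Zero-phase Butterworth band-pass of a continuous recording."""
    out = recording.copy(
        data=bandpass_array(recording.data, recording.sample_rate_hz, band_hz, order)
    )
    out.meta.setdefault("filters", []).append(("bandpass", tuple(band_hz), order))
    return out


def notch_power_line(
    recording: Recording, base_hz: float = 60.0, up_to_hz: float | None = None
) -> Recording:
    """Notch out the power-line frequency and its harmonics, zero-phase.

    Notches (−3-dB bandwidth 2 Hz) are placed at ``base_hz, 2*base_hz, …``
    strictly below min(``up_to_hz``, Nyquist).  With no harmonic in range
    the recording is returned unchanged.
    """
    nyq = recording.sample_rate_hz / 2
    top = min(up_to_hz, nyq) if up_to_hz is not None else nyq
    freqs = [f for f in np.arange(base_hz, top, base_hz) if f < nyq * 0.999]
    if not freqs:
        return recording.copy()
    sos_list = []
    for f in freqs:
        b, a = sps.iirnotch(w0=f, Q=f / 2.0, fs=recording.sample_rate_hz)
        sos_list.append(sps.tf2sos(b, a))
    sos = np.vstack(sos_list)
    out = recording.copy(data=sps.sosfiltfilt(sos, recording.data, axis=-1))
    out.meta.setdefault("filters", []).append(("notch", base_hz, len(freqs)))
    return out


def resample(recording: Recording, target_hz: float) -> Recording:
    """Anti-aliased down-sampling with event-index remapping.

    Up-sampling is refused (never needed in this pipeline).  Event indices
    are remapped by exact rational scaling, so the residual error is below
    one sample at the target rate.
    """
    fs = recording.sample_rate_hz
    if target_hz > fs:
        raise ValueError(f"refusing to upsample from {fs} to {target_hz} Hz")
    if target_hz == fs:
        return recording.copy()
    frac = Fraction(target_hz / fs).limit_denominator(10_000)
    data = sps.resample_poly(recording.data, frac.numerator, frac.denominator, axis=-1)
    events = recording.events.copy()
    if events.size:
        events[:, 0] = np.round(events[:, 0] * target_hz / fs).astype(np.int64)
        events[:, 0] = np.clip(events[:, 0], 0, data.shape[1] - 1)
    out = recording.copy(data=data, events=events)
    out.sample_rate_hz = target_hz
    out.meta["resampled_from_hz"] = fs
    return out


@dataclass
class EpochSet:
    """Windowed, baseline-corrected trials with labels and a rejection mask.

    ``data`` is ``(n_epochs, n_channels, n_times)`` in μV; ``info`` carries
    one metadata row per epoch (tone/role columns for stimulus epochs,
    ``is_rs`` for resting-state pseudo-trials, always ``block``);
    ``rejected`` marks epochs excluded by artifact rejection.
    """

    data: np.ndarray
    sample_rate_hz: float
    window_s: tuple[float, float]
    baseline_s: tuple[float, float] | None
    info: pd.DataFrame
    rejected: np.ndarray = None  # type: ignore[assignment]
    channel_names: list[str] = field(default_factory=lambda: ["Fz", "Cz"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if len(self.rejected) != len(self.data) or len(self.info) != len(self.data):
            raise ValueError("epochs, info rows and rejection mask must align")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_s[0] + np.arange(n) / self.sample_rate_hz

    @property
    def n_accepted(self) -> int:
        return int((~self.rejected).sum())

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask],
            sample_rate_hz=self.sample_rate_hz,
            window_s=self.window_s,
            baseline_s=self.baseline_s,
            info=self.info.loc[mask].reset_index(drop=True),
            rejected=self.rejected[mask],
            channel_names=list(self.channel_names),
        )


def epoch(
    recording: Recording,
    onsets_s: np.ndarray | pd.Series,
    window_s: tuple[float, float],
    baseline_s: tuple[float, float] | None = None,
    info: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut fixed-length epochs around onsets, baseline-correcting each.

    Onsets are absolute recording seconds; the epoch covers
    ``[onset + window[0], onset + window[1])``.  The baseline mean (per
    epoch, per channel) over ``baseline_s`` is subtracted when given.
    Epochs that would cross a recording edge are dropped with a logged
    count; if none survive, a ``ValueError`` is raised.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    fs = recording.sample_rate_hz
    n_times = int(round((window_s[1] - window_s[0]) * fs))
    starts = np.round((onsets + window_s[0]) * fs).astype(np.int64)
    ok = (starts >= 0) & (starts + n_times <= recording.n_samples)
    if not ok.all():
        logger.info("dropping %d edge epochs of %d", int((~ok).sum()), len(onsets))
    if not ok.any():
        raise ValueError("no epoch window falls inside the recording")
    starts = starts[ok]
    idx = starts[:, None] + np.arange(n_times)[None, :]
    data = recording.data[:, idx].transpose(1, 0, 2)  # epochs × ch × time

    if info is None:
        info = pd.DataFrame(index=range(len(onsets)))
    info = info.reset_index(drop=True).loc[ok].reset_index(drop=True)
    out = EpochSet(
        data=data,
        sample_rate_hz=fs,
        window_s=tuple(window_s),
        baseline_s=tuple(baseline_s) if baseline_s is not None else None,
        info=info,
        channel_names=list(recording.channel_names),
    )
    if baseline_s is not None:
        t = out.times
        bmask = (t >= baseline_s[0]) & (t < baseline_s[1])
        if not bmask.any():
            raise ValueError(f"baseline {baseline_s} lies outside window {window_s}")
        out.data -= out.data[:, :, bmask].mean(axis=2, keepdims=True)
    return out


def reject_epochs(epoch_set: EpochSet, threshold_uv: float = 150.0) -> EpochSet:
    """Reject epochs where any sample on any channel exceeds ±threshold.

    The mask only grows: previously rejected epochs stay rejected.
    """
    peaks = np.abs(epoch_set.data).max(axis=(1, 2))
    mask = epoch_set.rejected | (peaks > threshold_uv)
    out = EpochSet(
        data=epoch_set.data,
        sample_rate_hz=epoch_set.sample_rate_hz,
        window_s=epoch_set.window_s,
        baseline_s=epoch_set.baseline_s,
        info=epoch_set.info,
        rejected=mask,
        channel_names=list(epoch_set.channel_names),
    )
    logger.info(
        "rejected %d/%d epochs above ±%g μV", int(mask.sum()), len(mask), threshold_uv
    )
    return out


def _condition_mask(info: pd.DataFrame, condition: str) -> np.ndarray:
    is_rs = info["is_rs"].to_numpy() if "is_rs" in info else np.zeros(len(info), bool)
    if condition == "RS":
        return is_rs

    def col(name):
        if name not in info:
            return np.zeros(len(info), dtype=bool)
        return info[name].to_numpy(dtype=bool)

    tone = info["tone"].to_numpy() if "tone" in info else np.array([""] * len(info))
    transition = (
        info["transition"].to_numpy() if "transition" in info else np.array([""] * len(info))
    )
    base = ~is_rs & ~col("unlabeled_first")
    if condition == "NONDEVIANT_LOW":
        return base & col("nondeviant") & (tone == TONE_LOW)
    if condition == "NONDEVIANT_HIGH":
        return base & col("nondeviant") & (tone == TONE_HIGH)
    if condition == "DEVIANT_ASC":
        return base & col("deviant") & (transition == "ascending")
    if condition == "DEVIANT_DESC":
        return base & col("deviant") & (transition == "descending")
    # A standard's pairing direction follows from its own tone: a low-tone
    # standard precedes a switch to the high tone (ascending), and vice versa.
    if condition == "STANDARD_ASC":
        return base & col("standard") & (tone == TONE_LOW)
    if condition == "STANDARD_DESC":
        return base & col("standard") & (tone == TONE_HIGH)
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def select_condition(epoch_set: EpochSet, condition: str) -> EpochSet:
    """Select the accepted epochs of one condition.

    Rejected epochs and the per-block unlabeled first trial are always
    excluded.  Selecting ``RS`` from a set without resting-state
    pseudo-trials returns an empty set with a warning.
    """
    mask = _condition_mask(epoch_set.info, condition) & ~epoch_set.rejected
    if condition == "RS" and not mask.any():
        logger.warning("no resting-state epochs available in this epoch set")
    return epoch_set.subset(mask)


def average_epochs(epoch_set: EpochSet) -> np.ndarray:
    """Pointwise mean over accepted epochs, per channel → (n_ch, n_times)."""
    keep = ~epoch_set.rejected
    if not keep.any():
        raise ValueError("cannot average: no accepted epochs")
    return epoch_set.data[keep].mean(axis=0)


def rs_pseudo_onsets(
    schedule: ParadigmSchedule,
    n_per_block: int,
    window_s: tuple[float, float],
    usable_s: float | None = None,
) -> pd.DataFrame:
    """Place resting-state pseudo-trial onsets inside the rest intervals.

    Rest intervals contain no events, so pseudo-onsets are laid out as
    ``n_per_block`` evenly spaced (generally overlapping) windows per rest
    interval, mirroring the per-block stimulus-trial count.  ``usable_s``
    optionally restricts each rest interval to its leading portion.
    Returns a DataFrame with ``onset_s``, ``block`` and ``is_rs``.
    """
    w0, w1 = window_s
    rows = []
    for b in sorted(schedule.blocks):
        _, stim_end, rest_end = schedule.blocks[b]
        end = min(rest_end, stim_end + usable_s) if usable_s is not None else rest_end
        lo = stim_end - w0  # first onset whose window starts at rest start
        hi = end - w1
        if hi < lo:
            logger.warning("rest interval of block %d too short for window %s", b, window_s)
            continue
        if n_per_block == 1:
            onsets = [lo]
        else:
            onsets = np.linspace(lo, hi, n_per_block)
        for onset in np.atleast_1d(onsets):
            rows.append({"onset_s": float(onset), "block": b, "is_rs": True})
    return pd.DataFrame(rows)
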