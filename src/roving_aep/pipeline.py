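"""Subject-level orchestration: recording → detections.

Ties the preprocessing, spectral and transient stages together exactly in
the order the analysis prescribes:

* **gamma/FFR path** — broadband band-pass (2–1500 Hz, clipped below
  Nyquist at low simulation rates) + power-line notches → −100–450-ms
  epochs → ±150-μV rejection → per-tone nondeviant averages (and matched
  resting-state pseudo-trial averages) → per-component Butterworth
  band-pass of the averages → zero-padded PSD (0.25-Hz grid, 0–450-ms
  window) → normalized stimulus-minus-rest increment → frequency-wise
  permutation detection.
* **1-Hz path** — down-sample to 100 Hz, 0.1–20-Hz band-pass, nonoverlapping
  15-s segments per block (two per rest interval), averaging, 0.5–2.5-Hz
  band-pass, PSD on a 0.0125-Hz grid, then the same detection rule with
  ±0.1-Hz windows at 1 and 2 Hz.
* **ERP path** — down-sample to 250 Hz, 2–20-Hz band-pass, −100–900-ms
  epochs, rejection, block-wise averages, linear-SVM comparisons against a
  permutation null.

Preparation (filtering/epoching) is separated from detection so that
cumulative-duration analyses can reuse the prepared epochs and only redo
averaging/statistics per block increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from roving_aep.io import Recording
from roving_aep.paradigm import ParadigmSchedule, TONE_HIGH, TONE_LOW
from roving_aep.preprocess import (
    EpochSet,
    bandpass,
    bandpass_array,
    epoch,
    notch_power_line,
    reject_epochs,
    resample,
    rs_pseudo_onsets,
    select_condition,
    average_epochs,
)
from roving_aep.spectral import (
    COMPONENT_BANDS,
    SustainedDetection,
    compute_psd,
    individual_band_detection,
    normalize_psd,
    psd_increment,
)
from roving_aep.transient import ClassificationResult, run_transient_comparisons

__all__ = [
    "AnalysisConfig",
    "SustainedData",
    "prepare_sustained",
    "detect_sustained",
    "prepare_transient",
    "detect_transient",
    "slow_epoch_onsets",
    "analyze_subject",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters (filter bands, windows, thresholds, permutations)."""

    reject_uv: float = 150.0
    # gamma/FFR path
    broadband_hz: tuple[float, float] = (2.0, 1500.0)
    broadband_order: int = 4
    notch_base_hz: float = 60.0
    fast_window_s: tuple[float, float] = (-0.1, 0.45)
    fast_baseline_s: tuple[float, float] = (-0.1, 0.0)
    fast_psd_window_s: tuple[float, float] = (0.0, 0.45)
    fast_resolution_hz: float = 0.25
    # 1-Hz path
    slow_rate_hz: float = 100.0
    slow_band_hz: tuple[float, float] = (0.1, 20.0)
    slow_order: int = 2
    slow_segment_s: float = 15.0
    slow_window_s: tuple[float, float] = (-0.1, 15.0)
    slow_baseline_s: tuple[float, float] = (-0.1, 0.0)
    slow_psd_window_s: tuple[float, float] = (0.0, 15.0)
    slow_resolution_hz: float = 0.0125
    slow_rs_usable_s: float = 30.0
    # ERP path
    erp_rate_hz: float = 250.0
    erp_band_hz: tuple[float, float] = (2.0, 20.0)
    erp_order: int = 2
    erp_window_s: tuple[float, float] = (-0.1, 0.9)
    erp_baseline_s: tuple[float, float] = (-0.1, 0.0)
    # statistics
    n_permutations: int = 2000
    alpha: float = 0.05
    min_run: int = 3

    def broadband_for_rate(self, sample_rate_hz: float) -> tuple[float, float]:
        """Broadband edges clipped to 90 % of Nyquist (rate-agnostic)."""
        hi = min(self.broadband_hz[1], 0.45 * sample_rate_hz)
        return (self.broadband_hz[0], hi)


def _rs_per_block(schedule: ParadigmSchedule) -> int:
    """Resting pseudo-trials per block ≈ per-tone nondeviant trials per block."""
    nd = int(schedule.trials["nondeviant"].sum())
    return max(1, round(nd / (2 * len(schedule.blocks))))


@dataclass
class SustainedData:
    """Prepared (filtered, epoched, rejected) inputs of the sustained path."""

    fast_epochs: EpochSet
    fast_rs: EpochSet
    slow_epochs: EpochSet
    slow_rs: EpochSet
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def slow_epoch_onsets(
    schedule: ParadigmSchedule, segment_s: float = 15.0
) -> pd.DataFrame:
    """Onsets of the nonoverlapping slow segments within each block.

    A default 150-s block yields ten 15-s segments, so a 20-block run
    yields 200; shorter blocks yield proportionally fewer.
    """
    rows = []
    for b in sorted(schedule.blocks):
        t0, stim_end, _ = schedule.blocks[b]
        n_seg = int((stim_end - t0) // segment_s)
        for j in range(n_seg):
            rows.append({"onset_s": t0 + j * segment_s, "block": b, "is_rs": False})
    return pd.DataFrame(rows)


def _slow_rs_onsets(schedule: ParadigmSchedule, cfg: AnalysisConfig) -> pd.DataFrame:
    """Resting 15-s segments: the leading usable stretch of each rest interval."""
    rows = []
    span = cfg.slow_window_s[1] - cfg.slow_window_s[0]
    for b in sorted(schedule.blocks):
        _, stim_end, rest_end = schedule.blocks[b]
        usable_end = min(rest_end, stim_end + cfg.slow_rs_usable_s)
        onset = stim_end - cfg.slow_window_s[0]  # window starts at rest start
        j = 0
        while onset + cfg.slow_window_s[1] <= usable_end + 1e-9:
            rows.append({"onset_s": onset, "block": b, "is_rs": True})
            onset += cfg.slow_segment_s
            j += 1
    return pd.DataFrame(rows)


def prepare_sustained(
    recording: Recording,
    schedule: ParadigmSchedule,
    config: AnalysisConfig | None = None,
) -> SustainedData:
    """Filter and epoch a recording for the sustained-component analyses."""
    cfg = config or AnalysisConfig()
    fs = recording.sample_rate_hz
    band = cfg.broadband_for_rate(fs)
    broad = notch_power_line(
        bandpass(recording, band, order=cfg.broadband_order),
        cfg.notch_base_hz,
        up_to_hz=band[1],
    )
    trials = schedule.trials
    fast = epoch(
        broad,
        trials["onset_s"],
        cfg.fast_window_s,
        cfg.fast_baseline_s,
        info=trials.assign(is_rs=False),
    )
    fast = reject_epochs(fast, cfg.reject_uv)
    rs_info = rs_pseudo_onsets(
        schedule, _rs_per_block(schedule), cfg.fast_window_s
    )
    fast_rs = epoch(
        broad, rs_info["onset_s"], cfg.fast_window_s, cfg.fast_baseline_s, info=rs_info
    )
    fast_rs = reject_epochs(fast_rs, cfg.reject_uv)

    slow_rec = bandpass(
        resample(recording, cfg.slow_rate_hz), cfg.slow_band_hz, order=cfg.slow_order
    )
    slow_info = slow_epoch_onsets(schedule, cfg.slow_segment_s)
    slow = epoch(
        slow_rec, slow_info["onset_s"], cfg.slow_window_s, cfg.slow_baseline_s,
        info=slow_info,
    )
    slow = reject_epochs(slow, cfg.reject_uv)
    slow_rs_info = _slow_rs_onsets(schedule, cfg)
    slow_rs = epoch(
        slow_rec,
        slow_rs_info["onset_s"],
        cfg.slow_window_s,
        cfg.slow_baseline_s,
        info=slow_rs_info,
    )
    slow_rs = reject_epochs(slow_rs, cfg.reject_uv)
    return SustainedData(fast, fast_rs, slow, slow_rs, cfg)


#: Which tone's nondeviant average feeds each sustained component.
_COMPONENT_TONE = {
    "assr_40hz": TONE_LOW,
    "ffr_220hz": TONE_LOW,
    "assr_80hz": TONE_HIGH,
    "ffr_440hz": TONE_HIGH,
}


def _block_mask(info: pd.DataFrame, k_blocks: int | None) -> np.ndarray:
    if k_blocks is None:
        return np.ones(len(info), dtype=bool)
    blocks = sorted(info["block"].unique())
    keep = set(blocks[:k_blocks])
    return info["block"].isin(keep).to_numpy()


def component_increment(
    data: SustainedData, component: str, k_blocks: int | None = None
):
    """Normalized stimulus-minus-rest increment spectrum for one component.

    Averages the relevant epochs over the first ``k_blocks`` blocks (all
    blocks when None), applies the component's Butterworth passband to the
    stimulus and rest averages, computes zero-padded PSDs on the analysis
    window, normalizes both within the passband and returns the positive
    renormalized difference.
    """
    cfg = data.config
    band = COMPONENT_BANDS[component]
    if component == "assr_1hz":
        stim_set, rs_set = data.slow_epochs, data.slow_rs
        stim = stim_set.subset(_block_mask(stim_set.info, k_blocks))
        rs = rs_set.subset(_block_mask(rs_set.info, k_blocks))
        psd_window = cfg.slow_psd_window_s
        resolution = cfg.slow_resolution_hz
    else:
        tone = _COMPONENT_TONE[component]
        cond = "NONDEVIANT_LOW" if tone == TONE_LOW else "NONDEVIANT_HIGH"
        stim_all = data.fast_epochs.subset(_block_mask(data.fast_epochs.info, k_blocks))
        stim = select_condition(stim_all, cond)
        rs = data.fast_rs.subset(_block_mask(data.fast_rs.info, k_blocks))
        psd_window = cfg.fast_psd_window_s
        resolution = cfg.fast_resolution_hz

    fs = stim.sample_rate_hz
    avg_stim = average_epochs(stim)
    avg_rs = average_epochs(rs)
    avg_stim = bandpass_array(avg_stim, fs, band.analyzed_band_hz, band.filter_order)
    avg_rs = bandpass_array(avg_rs, fs, band.analyzed_band_hz, band.filter_order)
    spec_stim = normalize_psd(
        compute_psd(avg_stim, fs, resolution, times=stim.times, window_s=psd_window),
        band.analyzed_band_hz,
    )
    spec_rs = normalize_psd(
        compute_psd(avg_rs, fs, resolution, times=rs.times, window_s=psd_window),
        band.analyzed_band_hz,
    )
    return psd_increment(spec_stim, spec_rs)


def detect_sustained(
    data: SustainedData,
    rng_seed: int = 0,
    k_blocks: int | None = None,
    components: list[str] | None = None,
) -> dict[str, SustainedDetection]:
    """Individual-level detection of each sustained component."""
    cfg = data.config
    names = components or list(COMPONENT_BANDS)
    seeds = np.random.SeedSequence(rng_seed).spawn(len(names))
    out: dict[str, SustainedDetection] = {}
    for name, seq in zip(names, seeds):
        seed = int(seq.generate_state(1)[0] % (2**31))
        try:
            inc = component_increment(data, name, k_blocks)
        except ValueError:
            # degenerate increment (e.g. stimulus nowhere above rest): not detected
            out[name] = SustainedDetection(
                component=name, bin_pvalues={}, detected=False, run_length=0
            )
            continue
        out[name] = individual_band_detection(
            inc,
            COMPONENT_BANDS[name],
            n_permutations=cfg.n_permutations,
            alpha=cfg.alpha,
            min_run=cfg.min_run,
            rng_seed=seed,
        )
    return out


def prepare_transient(
    recording: Recording,
    schedule: ParadigmSchedule,
    config: AnalysisConfig | None = None,
) -> EpochSet:
    """ERP epochs (stimulus + resting pseudo-trials) ready for decoding."""
    cfg = config or AnalysisConfig()
    erp = bandpass(
        resample(recording, cfg.erp_rate_hz), cfg.erp_band_hz, order=cfg.erp_order
    )
    trials = schedule.trials
    stim = epoch(
        erp, trials["onset_s"], cfg.erp_window_s, cfg.erp_baseline_s,
        info=trials.assign(is_rs=False),
    )
    stim = reject_epochs(stim, cfg.reject_uv)
    rs_info = rs_pseudo_onsets(schedule, _rs_per_block(schedule), cfg.erp_window_s)
    rs = epoch(erp, rs_info["onset_s"], cfg.erp_window_s, cfg.erp_baseline_s, info=rs_info)
    rs = reject_epochs(rs, cfg.reject_uv)
    return _concat_epoch_sets(stim, rs)


def _concat_epoch_sets(a: EpochSet, b: EpochSet) -> EpochSet:
    if a.data.shape[1:] != b.data.shape[1:]:
        raise ValueError("epoch sets have incompatible shapes")
    info = pd.concat([a.info, b.info], ignore_index=True)
    if "is_rs" in info:
        info["is_rs"] = info["is_rs"].astype("boolean").fillna(False).astype(bool)
    return EpochSet(
        data=np.concatenate([a.data, b.data]),
        sample_rate_hz=a.sample_rate_hz,
        window_s=a.window_s,
        baseline_s=a.baseline_s,
        info=info,
        rejected=np.concatenate([a.rejected, b.rejected]),
        channel_names=list(a.channel_names),
    )


def detect_transient(
    epochs: EpochSet,
    config: AnalysisConfig | None = None,
    rng_seed: int = 0,
    k_blocks: int | None = None,
    comparisons: list[str] | None = None,
) -> dict[str, ClassificationResult | str]:
    """Run the SVM comparisons on the first ``k_blocks`` blocks.

    The fold count equals the number of available blocks (two-fold when a
    single block is analyzed, to keep a held-out set).
    """
    cfg = config or AnalysisConfig()
    sub = epochs.subset(_block_mask(epochs.info, k_blocks))
    n_blocks = int(sub.info["block"].nunique())
    n_folds = max(2, n_blocks if k_blocks is not None else min(n_blocks, 20))
    return run_transient_comparisons(
        sub,
        n_folds=n_folds,
        n_permutations=cfg.n_permutations,
        rng_seed=rng_seed,
        comparisons=comparisons,
    )


def analyze_subject(
    recording: Recording,
    schedule: ParadigmSchedule,
    config: AnalysisConfig | None = None,
    rng_seed: int = 0,
    comparisons: list[str] | None = None,
    components: list[str] | None = None,
) -> dict:
    """Full single-subject analysis → JSON-ready result dict."""
    cfg = config or AnalysisConfig()
    seeds = np.random.SeedSequence(rng_seed).spawn(2)
    sus_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    tra_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    sus_data = prepare_sustained(recording, schedule, cfg)
    sustained = detect_sustained(sus_data, rng_seed=sus_seed, components=components)
    erp_epochs = prepare_transient(recording, schedule, cfg)
    transient = detect_transient(
        erp_epochs, cfg, rng_seed=tra_seed, comparisons=comparisons
    )
    return {
        "seed": rng_seed,
        "sustained": {k: v.to_dict() for k, v in sustained.items()},
        "transient": {
            k: (v.to_dict() if isinstance(v, ClassificationResult) else v)
            for k, v in transient.items()
        },
    }
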