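"""Spectral detection of sustained frequency-tagged responses.

Power spectra are computed with a zero-padded DFT (rectangular window on the
stated analysis segment) so that the frequency grid reaches a prescribed
resolution (0.25 Hz for the gamma/FFR analyses on the 0–450-ms window,
0.0125 Hz for the 1-Hz analysis on 15-s segments).  Spectra are normalized
to unit total power within the analyzed band so that subjects are
comparable, and stimulus-minus-rest *increments* (positive part, renormalized)
isolate evoked power from background.

Two statistical routes operate on these spectra:

* **Group level** — paired spatiospectral cluster permutation across
  subjects with threshold-free cluster enhancement (TFCE) over the
  sensor × frequency grid (delegated to MNE-Python), reporting cluster
  onset/offset where both Fz and Cz are significant (conjunction rule).
* **Individual level** — a frequency-wise permutation test on the
  normalized increment: each bin is compared against the mean of all other
  bins of the analyzed spectrum, the null obtained by shuffling bin values,
  and a component is declared present when at least ``min_run`` consecutive
  bins within any of its target windows (fundamental or harmonic/sideband,
  e.g. 220 Hz or its 260-Hz sideband) fall below the significance level at
  the Fz electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "BandSpec",
    "ClusterResult",
    "SustainedDetection",
    "compute_psd",
    "normalize_psd",
    "psd_increment",
    "group_cluster_test",
    "individual_band_detection",
    "COMPONENT_BANDS",
]


@dataclass
class Spectrum:
    """Power spectrum on a uniform frequency grid.

    ``power`` has shape ``(n_channels, n_freqs)`` and is nonnegative;
    ``normalization`` records whether the bins were scaled to unit total
    power within ``band_hz``.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    resolution_hz: float
    normalization: str = "none"  # {"none", "total-power-in-band"}
    band_hz: tuple[float, float] | None = None
    channel_names: list[str] = field(default_factory=lambda: ["Fz", "Cz"])

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[1] != self.freqs_hz.size:
            raise ValueError("power columns must match the frequency grid")

    def channel(self, name: str) -> np.ndarray:
        return self.power[self.channel_names.index(name)]


@dataclass(frozen=True)
class BandSpec:
    """Target windows of one sustained component.

    ``center_hz`` lists the fundamental and its harmonic/sideband centers
    (e.g. ``(220, 260)`` for the low-tone FFR); ``halfwidth_hz`` is the
    half-width of each detection window; ``analyzed_band_hz`` is the extent
    of the analyzed spectrum (the component's filter passband);
    ``excluded_centers_hz`` documents centers deliberately not tested (the
    180/360-Hz lower sidebands coincide with power-line harmonics).
    """

    name: str
    center_hz: tuple[float, ...]
    halfwidth_hz: float
    analyzed_band_hz: tuple[float, float]
    filter_order: int = 2
    excluded_centers_hz: tuple[float, ...] = ()


#: The five sustained components: analyzed band = component filter passband.
COMPONENT_BANDS: dict[str, BandSpec] = {
    "assr_1hz": BandSpec("assr_1hz", (1.0, 2.0), 0.1, (0.5, 2.5), filter_order=2),
    "assr_40hz": BandSpec("assr_40hz", (40.0,), 2.0, (25.0, 55.0), filter_order=2),
    "assr_80hz": BandSpec("assr_80hz", (80.0,), 2.0, (65.0, 95.0), filter_order=2),
    "ffr_220hz": BandSpec(
        "ffr_220hz", (220.0, 260.0), 2.0, (200.0, 280.0), filter_order=4,
        excluded_centers_hz=(180.0,),
    ),
    "ffr_440hz": BandSpec(
        "ffr_440hz", (440.0, 520.0), 2.0, (420.0, 540.0), filter_order=4,
        excluded_centers_hz=(360.0,),
    ),
}


def compute_psd(
    avg_series: np.ndarray,
    sample_rate_hz: float,
    target_resolution_hz: float,
    times: np.ndarray | None = None,
    window_s: tuple[float, float] | None = None,
) -> Spectrum:
    """Zero-padded DFT power spectrum of an averaged series.

    The series (``(n_ch, n_times)`` or 1-D) is optionally cropped to the
    analysis window ``[window_s[0], window_s[1])`` using ``times``, then
    zero-padded to ``round(rate / resolution)`` points; power is the squared
    DFT magnitude on the one-sided grid (which includes 0 Hz).  The target
    resolution must be at least as fine as the native resolution of the
    window, otherwise zero-padding could not realize it.
    """
    x = np.atleast_2d(np.asarray(avg_series, dtype=float))
    if window_s is not None:
        if times is None:
            raise ValueError("window_s requires the matching times vector")
        mask = (times >= window_s[0]) & (times < window_s[1])
        x = x[:, mask]
    n_time = x.shape[1]
    n_fft = int(round(sample_rate_hz / target_resolution_hz))
    if n_fft < n_time:
        raise ValueError(
            f"target resolution {target_resolution_hz} Hz is coarser than the "
            f"native resolution {sample_rate_hz / n_time:.4g} Hz of the window"
        )
    spec = np.fft.rfft(x, n=n_fft, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    return Spectrum(
        freqs_hz=freqs, power=power, resolution_hz=sample_rate_hz / n_fft
    )


def normalize_psd(spectrum: Spectrum, band_hz: tuple[float, float]) -> Spectrum:
    """Restrict to a band and scale each channel to unit total power.

    Out-of-band bins are dropped; per channel, the in-band bins then sum to
    one.  A channel with zero in-band power is degenerate and raises.
    """
    eps = spectrum.resolution_hz * 1e-6
    mask = (spectrum.freqs_hz >= band_hz[0] - eps) & (
        spectrum.freqs_hz <= band_hz[1] + eps
    )
    if not mask.any():
        raise ValueError(f"band {band_hz} does not overlap the frequency grid")
    power = spectrum.power[:, mask]
    totals = power.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("degenerate spectrum: zero total power within the band")
    return Spectrum(
        freqs_hz=spectrum.freqs_hz[mask],
        power=power / totals,
        resolution_hz=spectrum.resolution_hz,
        normalization="total-power-in-band",
        band_hz=tuple(band_hz),
        channel_names=list(spectrum.channel_names),
    )


def psd_increment(stim_spectrum: Spectrum, rs_spectrum: Spectrum) -> Spectrum:
    """Positive part of (stimulus − rest), renormalized to unit power.

    Grids must match exactly.  A stimulus spectrum nowhere above rest is
    degenerate (no evoked increment) and raises.
    """
    if stim_spectrum.freqs_hz.shape != rs_spectrum.freqs_hz.shape or not np.allclose(
        stim_spectrum.freqs_hz, rs_spectrum.freqs_hz
    ):
        raise ValueError("stimulus and rest spectra are on different grids")
    diff = np.clip(stim_spectrum.power - rs_spectrum.power, 0.0, None)
    totals = diff.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("degenerate increment: stimulus nowhere exceeds rest")
    return Spectrum(
        freqs_hz=stim_spectrum.freqs_hz.copy(),
        power=diff / totals,
        resolution_hz=stim_spectrum.resolution_hz,
        normalization="total-power-in-band",
        band_hz=stim_spectrum.band_hz,
        channel_names=list(stim_spectrum.channel_names),
    )


@dataclass
class ClusterResult:
    """Outcome of a TFCE cluster permutation test with the Fz∧Cz conjunction.

    ``clusters`` lists contiguous axis runs where every sensor is
    significant: dicts with ``onset``, ``offset`` (axis units), ``peak_stat``
    (largest |t| within the run) and ``p_cluster`` (smallest corrected
    p-value within the run).  ``p_map``/``t_map`` are the per-point
    corrected p-values and paired t-statistics on the sensor × axis grid.
    """

    clusters: list[dict]
    p_map: np.ndarray
    t_map: np.ndarray
    axis_values: np.ndarray
    n_permutations: int
    alpha: float
    tail: int

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    def to_frame(self):
        """Cluster table (onset, offset, peak_stat, p_cluster) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            self.clusters, columns=["onset", "offset", "peak_stat", "p_cluster"]
        )


def group_cluster_test(
    per_subject_values: np.ndarray,
    axis_values: np.ndarray,
    tail: int = 1,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    tfce_start: float = 0.0,
    tfce_step: float = 0.1,
    tfce_e: float = 0.5,
    tfce_h: float = 2.0,
    seed: int | None = 0,
) -> ClusterResult:
    """Paired TFCE cluster permutation across subjects on a sensor × axis grid.

    ``per_subject_values`` has shape ``(n_subjects, n_sensors, n_axis)`` and
    holds per-subject paired differences (condition A − condition B); the
    test sign-flips subjects against zero.  The two sensors are treated as
    adjacent, the axis as a chain.  Cluster onsets/offsets are reported
    where *all* sensors are significant (conjunction rule).
    """
    from mne.stats import combine_adjacency, permutation_cluster_1samp_test

    X = np.asarray(per_subject_values, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n_subjects, n_sensors, n_axis) input")
    if X.shape[0] < 2:
        raise ValueError("cluster permutation requires at least 2 subjects")
    axis_values = np.asarray(axis_values, dtype=float)
    n_sensors, n_axis = X.shape[1], X.shape[2]
    if np.allclose(X, 0.0):
        # identically-zero differences carry no evidence (t undefined)
        return ClusterResult(
            clusters=[],
            p_map=np.ones((n_sensors, n_axis)),
            t_map=np.zeros((n_sensors, n_axis)),
            axis_values=axis_values,
            n_permutations=n_permutations,
            alpha=alpha,
            tail=tail,
        )
    threshold = dict(start=tfce_start, step=tfce_step, e_power=tfce_e, h_power=tfce_h)
    t_obs, clusters, cluster_pv, _ = permutation_cluster_1samp_test(
        X,
        threshold=threshold,
        n_permutations=n_permutations,
        tail=tail,
        adjacency=combine_adjacency(n_sensors, n_axis),
        out_type="mask",
        rng=np.random.default_rng(seed),
        verbose="error",
    )
    p_map = np.ones((n_sensors, n_axis))
    for mask, p in zip(clusters, cluster_pv):
        p_map[mask] = np.minimum(p_map[mask], p)

    sig = p_map < alpha
    conjunction = sig.all(axis=0)
    out_clusters: list[dict] = []
    i = 0
    while i < n_axis:
        if conjunction[i]:
            j = i
            while j + 1 < n_axis and conjunction[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            out_clusters.append(
                {
                    "onset": float(axis_values[i]),
                    "offset": float(axis_values[j]),
                    "peak_stat": float(np.max(np.abs(t_obs[:, seg]))),
                    "p_cluster": float(p_map[:, seg].min()),
                }
            )
            i = j + 1
        else:
            i += 1
    return ClusterResult(
        clusters=out_clusters,
        p_map=p_map,
        t_map=np.asarray(t_obs),
        axis_values=axis_values,
        n_permutations=n_permutations,
        alpha=alpha,
        tail=tail,
    )


@dataclass
class SustainedDetection:
    """Individual-level outcome for one sustained component.

    ``bin_pvalues`` maps each tested center frequency to the p-values of the
    bins in its window; ``run_length`` is the longest run of consecutive
    significant bins over all windows; ``detected`` is True when any single
    window contains a run of at least the configured minimum.
    """

    component: str
    bin_pvalues: dict[float, np.ndarray]
    detected: bool
    run_length: int
    electrode: str = "Fz"
    alpha: float = 0.05
    min_run: int = 3

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "detected": bool(self.detected),
            "run_length": int(self.run_length),
            "electrode": self.electrode,
            "alpha": self.alpha,
            "min_run": self.min_run,
            "bin_pvalues": {
                str(c): np.asarray(p).tolist() for c, p in self.bin_pvalues.items()
            },
        }


def _max_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def individual_band_detection(
    increment: Spectrum | np.ndarray,
    band_spec: BandSpec,
    freqs_hz: np.ndarray | None = None,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    min_run: int = 3,
    rng_seed: int = 0,
    electrode: str = "Fz",
) -> SustainedDetection:
    """Frequency-wise permutation detection of one component at one electrode.

    For every bin of the analyzed spectrum the statistic is the bin value
    minus the mean of all other bins; the null distribution comes from
    shuffling the bin values across the analyzed spectrum and recomputing.
    A bin's p-value is the proportion of permuted statistics ≥ the observed
    one (no +1 correction).  The component is detected when at least
    ``min_run`` consecutive bins with ``p < alpha`` occur within any one of
    its target windows (center ± halfwidth).
    """
    if isinstance(increment, Spectrum):
        values = increment.channel(electrode)
        freqs = increment.freqs_hz
    else:
        values = np.asarray(increment, dtype=float)
        if freqs_hz is None:
            raise ValueError("array input requires the freqs_hz grid")
        freqs = np.asarray(freqs_hz, dtype=float)

    n = values.size
    if n < 2:
        raise ValueError("analyzed spectrum must contain at least 2 bins")
    total = values.sum()
    obs = values - (total - values) / (n - 1)

    rng = np.random.default_rng(rng_seed)
    perm = rng.permuted(np.broadcast_to(values, (n_permutations, n)).copy(), axis=1)
    perm_stats = perm - (total - perm) / (n - 1)
    pvals = (perm_stats >= obs[None, :]).mean(axis=0)

    eps = 1e-9
    bin_pvalues: dict[float, np.ndarray] = {}
    run_length = 0
    detected = False
    for center in band_spec.center_hz:
        wmask = np.abs(freqs - center) <= band_spec.halfwidth_hz + eps
        if wmask.sum() < min_run:
            raise ValueError(
                f"window {center}±{band_spec.halfwidth_hz} Hz holds only "
                f"{int(wmask.sum())} bins; min_run={min_run} cannot be met"
            )
        p_win = pvals[wmask]
        bin_pvalues[float(center)] = p_win
        run = _max_run(p_win < alpha)
        run_length = max(run_length, run)
        if run >= min_run:
            detected = True
    return SustainedDetection(
        component=band_spec.name,
        bin_pvalues=bin_pvalues,
        detected=detected,
        run_length=run_length,
        electrode=electrode,
        alpha=alpha,
        min_run=min_run,
    )
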