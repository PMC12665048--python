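"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from roving_aep.paradigm import ParadigmConfig, build_paradigm
from roving_aep.preprocess import EpochSet


@pytest.fixture(scope="session")
def default_schedule():
    """Full-size default schedule (20 blocks × 150 trials), seed 0."""
    return build_paradigm(rng_seed=0)


@pytest.fixture(scope="session")
def small_schedule():
    """Scaled-down schedule (4 blocks × 30 trials) for pipeline tests."""
    return build_paradigm(rng_seed=0, config=ParadigmConfig(n_blocks=4, trials_per_block=30))


def make_epoch_set(
    schedule,
    n_times: int = 8,
    sample_rate_hz: float = 250.0,
    window_s=(-0.1, 0.9),
    fill=None,
    rs_per_block: int = 0,
    rng=None,
) -> EpochSet:
    """Build an EpochSet directly from a schedule (no recording needed).

    ``fill(info_row) -> (n_ch, n_times)`` optionally supplies epoch data;
    default is zeros (plus optional rs pseudo-epochs labelled is_rs).
    """
    trials = schedule.trials.assign(is_rs=False)
    if rs_per_block:
        rs_rows = []
        for b in sorted(schedule.blocks):
            for _ in range(rs_per_block):
                rs_rows.append({"block": b, "is_rs": True})
        trials = pd.concat([trials, pd.DataFrame(rs_rows)], ignore_index=True)
        trials["is_rs"] = trials["is_rs"].astype("boolean").fillna(True).astype(bool)
        for col in ("deviant", "standard", "nondeviant", "unlabeled_first"):
            trials[col] = trials[col].astype("boolean").fillna(False).astype(bool)
    n = len(trials)
    data = np.zeros((n, 2, n_times))
    if fill is not None:
        for i, row in trials.iterrows():
            data[i] = fill(row)
    elif rng is not None:
        data = rng.normal(size=(n, 2, n_times))
    return EpochSet(
        data=data,
        sample_rate_hz=sample_rate_hz,
        window_s=window_s,
        baseline_s=None,
        info=trials,
    )


# ---------------------------------------------------------------------------
# Independent oracles (never call the implementation they check)


def brute_force_psd(x: np.ndarray, n_fft: int) -> np.ndarray:
    """Direct O(N·K) DFT power oracle on the one-sided grid."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n_fft // 2 + 1)
    # explicit DFT sum: X_k = sum_n x_n exp(-2πi k n / n_fft)
    phase = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n_fft)
    return np.abs(phase @ x) ** 2


def tfce_enhance_grid(
    tmap: np.ndarray, step: float = 0.1, e_power: float = 0.5, h_power: float = 2.0
) -> np.ndarray:
    """Brute-force TFCE on a (n_sensors, n_axis) grid, 4-connectivity.

    One-tailed (positive) enhancement: integrates extent^E * height^H over
    thresholds start+step, start+2*step, … up to the map maximum.
    """
    out = np.zeros_like(tmap, dtype=float)
    top = tmap.max()
    if top <= 0:
        return out
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    h = step
    while h <= top + 1e-12:
        mask = tmap >= h
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            m = labels == lab
            out[m] += (m.sum() ** e_power) * (h**h_power)
        h += step
    return out


def exhaustive_sign_flip_pvals(
    X: np.ndarray, step: float = 0.1, e_power: float = 0.5, h_power: float = 2.0
) -> np.ndarray:
    """Exact one-tailed TFCE sign-flip p-values by full 2^n enumeration.

    For each of the 2^n_subjects sign patterns, computes the one-sample
    t-map, enhances it, and records the grid maximum; each point's p-value
    is the fraction of patterns whose maximum reaches that point's observed
    enhancement (the identity pattern included).
    """
    n_sub = X.shape[0]

    def tmap_of(signs):
        Xs = X * signs[:, None, None]
        mean = Xs.mean(axis=0)
        sd = Xs.std(axis=0, ddof=1)
        return mean / (sd / np.sqrt(n_sub))

    obs = tfce_enhance_grid(tmap_of(np.ones(n_sub)), step, e_power, h_power)
    maxima = []
    for bits in range(2**n_sub):
        signs = np.array([1 if bits >> i & 1 else -1 for i in range(n_sub)])
        maxima.append(tfce_enhance_grid(tmap_of(signs), step, e_power, h_power).max())
    maxima = np.asarray(maxima)
    pvals = np.empty_like(obs)
    for idx in np.ndindex(obs.shape):
        pvals[idx] = np.mean(maxima >= obs[idx])
    return pvals
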