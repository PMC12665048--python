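"""Recording-duration sensitivity curves and the stabilization rule.

For each component and subject, detection is re-evaluated on cumulatively
growing data — the first block (3 min of stimulation) alone, then the first
two, and so on up to the full recording, always in recording order.  The
*sensitivity* at increment k is the fraction of subjects detected with k
blocks, and the *stability block* is the smallest k at which sensitivity
reaches ≥ 0.90 and stays there for every later increment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from roving_aep.pipeline import (
    AnalysisConfig,
    SustainedData,
    detect_sustained,
    detect_transient,
)
from roving_aep.preprocess import EpochSet
from roving_aep.spectral import COMPONENT_BANDS
from roving_aep.transient import ClassificationResult

__all__ = [
    "MINUTES_PER_BLOCK",
    "SensitivityCurve",
    "stability_block",
    "cumulative_detection",
    "sensitivity_curves",
    "curves_to_frame",
    "plot_sensitivity_curves",
]

#: Each block contributes 3 min of analyzed stimulation data.
MINUTES_PER_BLOCK = 3.0


@dataclass
class SensitivityCurve:
    """Detection flags and sensitivity per cumulative block count.

    ``flags`` is (n_subjects, n_increments) boolean; ``sensitivity[k-1]``
    is the detected fraction with k blocks; ``stability_block`` is None
    when the ≥ 0.90 level is never reached and held.
    """

    component: str
    flags: np.ndarray
    sensitivity: np.ndarray
    stability_block: int | None

    @property
    def stability_minutes(self) -> float | None:
        if self.stability_block is None:
            return None
        return self.stability_block * MINUTES_PER_BLOCK


def stability_block(sensitivity: np.ndarray, level: float = 0.90) -> int | None:
    """Smallest k (1-based) with sensitivity ≥ level for all k' ≥ k.

    Implements the "reach and maintain" rule: a curve that crosses the
    level and later dips below it only stabilizes at the later, sustained
    crossing.
    """
    s = np.asarray(sensitivity, dtype=float)
    ok = s >= level
    # last index where the level is violated; stability starts after it
    if ok.all():
        return 1
    last_bad = int(np.max(np.nonzero(~ok)[0]))
    if last_bad == len(s) - 1:
        return None
    return last_bad + 2  # 1-based index after the last violation


def cumulative_detection(
    sustained_data: SustainedData | None,
    transient_epochs: EpochSet | None,
    component: str,
    k_blocks: int,
    config: AnalysisConfig | None = None,
    rng_seed: int = 0,
) -> bool:
    """Detection decision for one component with the first k blocks.

    Sustained components re-run the frequency-wise permutation detection on
    the cumulative average; transient comparisons re-run the SVM decoding
    with the fold count equal to k (two-fold at k = 1).
    """
    cfg = config or AnalysisConfig()
    if component in COMPONENT_BANDS:
        if sustained_data is None:
            raise ValueError("sustained data required for component " + component)
        det = detect_sustained(
            sustained_data, rng_seed=rng_seed, k_blocks=k_blocks, components=[component]
        )
        return bool(det[component].detected)
    if transient_epochs is None:
        raise ValueError("transient epochs required for comparison " + component)
    res = detect_transient(
        transient_epochs, cfg, rng_seed=rng_seed, k_blocks=k_blocks,
        comparisons=[component],
    )[component]
    return isinstance(res, ClassificationResult) and res.significant


def sensitivity_curves(
    detection_flags: dict[str, np.ndarray], level: float = 0.90
) -> list[SensitivityCurve]:
    """Build sensitivity curves from per-subject detection tables.

    ``detection_flags`` maps component name → boolean array of shape
    (n_subjects, n_increments), where column k-1 holds each subject's
    detection decision with k cumulative blocks.
    """
    curves = []
    for name, flags in detection_flags.items():
        flags = np.atleast_2d(np.asarray(flags, dtype=bool))
        sens = flags.mean(axis=0)
        curves.append(
            SensitivityCurve(
                component=name,
                flags=flags,
                sensitivity=sens,
                stability_block=stability_block(sens, level),
            )
        )
    return curves


def curves_to_frame(curves: list[SensitivityCurve]) -> pd.DataFrame:
    """Long-format table (component, k_blocks, minutes, sensitivity)."""
    rows = []
    for c in curves:
        for k, s in enumerate(c.sensitivity, start=1):
            rows.append(
                {
                    "component": c.component,
                    "k_blocks": k,
                    "minutes": k * MINUTES_PER_BLOCK,
                    "sensitivity": float(s),
                    "stability_block": c.stability_block,
                }
            )
    return pd.DataFrame(rows)


def plot_sensitivity_curves(curves: list[SensitivityCurve], path, level: float = 0.90):
    """Sensitivity-vs-cumulative-blocks plot with the 0.90 reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        k = np.arange(1, len(c.sensitivity) + 1)
        ax.plot(k, c.sensitivity, marker="o", label=c.component)
        if c.stability_block is not None:
            ax.axvline(c.stability_block, ls=":", lw=0.8, color="grey")
    ax.axhline(level, ls="--", color="red", lw=1)
    ax.set_xlabel("cumulative blocks (3 min each)")
    ax.set_ylabel("detection sensitivity")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
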