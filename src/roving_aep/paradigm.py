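"""Roving-sequence generation and trial-role labelling.

A roving oddball sequence alternates *trains* of identical tones; within a
block the same tone repeats 4–6 times before switching to the other tone.
The first tone of each new train is the **deviant** (except the block's very
first train), every later position is **nondeviant**, and the last position
of a train that is followed by another train is additionally the
**standard** paired with the next deviant.  Transitions from the low tone
(AM 220/40) to the high tone (AM 440/80) are *ascending*, the reverse
*descending*.

With the default block of 150 trials, 75 per tone and train lengths in
{4, 5, 6}, a block necessarily contains 31 alternating trains (16 of the
starting tone, 15 of the other), hence 30 transitions — 15 ascending and 15
descending regardless of the start tone.  Odd-numbered blocks start with the
low tone, even-numbered blocks with the high tone.  Trials are presented at
a fixed 1-s stimulus onset asynchrony (450-ms tone + 550-ms gap) and blocks
are separated by 35-s silent rest intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TONE_LOW",
    "TONE_HIGH",
    "ParadigmConfig",
    "ParadigmSchedule",
    "sample_train_lengths",
    "build_block",
    "label_roles",
    "build_paradigm",
    "export_events",
    "read_events",
]

TONE_LOW = "low"  # AM(220 Hz, 40 Hz)
TONE_HIGH = "high"  # AM(440 Hz, 80 Hz)

#: Columns of the trial/event table, in export order.
EVENT_COLUMNS = [
    "onset_s",
    "duration_s",
    "tone",
    "block",
    "train",
    "pos",
    "role",
    "transition",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Parameters of the roving paradigm.

    Defaults reproduce the standard protocol: 20 blocks of 150 one-second
    trials (2.5 min stimulation) separated by 35-s rests, giving 185 s per
    block and ~61 min total.
    """

    n_blocks: int = 20
    trials_per_block: int = 150
    soa_s: float = 1.0
    tone_duration_s: float = 0.45
    rest_s: float = 35.0
    train_len_min: int = 4
    train_len_max: int = 6
    #: recording time before the first block (lets the first trial carry a
    #: prestimulus baseline, as in any real acquisition)
    lead_in_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.trials_per_block < 2 or self.trials_per_block % 2:
            raise ValueError("trials_per_block must be an even count >= 2")
        if not 0 < self.train_len_min <= self.train_len_max:
            raise ValueError("train length bounds must satisfy 0 < min <= max")
        if self.soa_s < self.tone_duration_s:
            raise ValueError("soa_s must be at least the tone duration")

    @property
    def trials_per_tone(self) -> int:
        return self.trials_per_block // 2

    @property
    def block_span_s(self) -> float:
        """Stimulation plus rest duration of one block."""
        return self.trials_per_block * self.soa_s + self.rest_s

    def train_counts(self) -> tuple[int, int]:
        """Number of trains for the (start tone, other tone).

        The starting tone receives one extra train when feasible, which for
        the default 75-per-tone block yields 16 + 15 = 31 trains and hence
        exactly 30 transitions.  The baseline count targets a mean train
        length at the midpoint of the allowed range.
        """
        tpt = self.trials_per_tone
        lo, hi = self.train_len_min, self.train_len_max
        n_min = -(-tpt // hi)  # ceil
        n_max = tpt // lo
        if n_min > n_max:
            raise ValueError(
                f"no composition of {tpt} trials into trains of {lo}..{hi}"
            )
        mid = (lo + hi) / 2
        n_other = int(np.clip(round(tpt / mid), n_min, n_max))
        n_start = n_other + 1 if n_other + 1 <= n_max else n_other
        return n_start, n_other


def _enumerate_compositions(n_parts: int, total: int, lo: int, hi: int):
    """Yield every composition of ``total`` into ``n_parts`` parts in [lo, hi].

    Exponential in ``n_parts``; intended for small test oracles only.
    """
    if n_parts == 0:
        if total == 0:
            yield ()
        return
    for first in range(lo, hi + 1):
        rest = total - first
        if (n_parts - 1) * lo <= rest <= (n_parts - 1) * hi:
            for tail in _enumerate_compositions(n_parts - 1, rest, lo, hi):
                yield (first,) + tail


def _sample_composition(
    n_parts: int, total: int, lo: int, hi: int, rng: np.random.Generator,
    max_rejections: int = 10_000,
) -> list[int]:
    if not n_parts * lo <= total <= n_parts * hi:
        raise ValueError(
            f"cannot split {total} trials into {n_parts} trains of "
            f"length {lo}..{hi} (feasible range {n_parts * lo}..{n_parts * hi})"
        )
    # Rejection sampling: uniform over valid compositions.
    for _ in range(max_rejections):
        draw = rng.integers(lo, hi + 1, size=n_parts)
        if draw.sum() == total:
            return draw.tolist()
    # Bounded repair fallback: nudge random positions toward the target sum.
    draw = rng.integers(lo, hi + 1, size=n_parts)
    while draw.sum() != total:
        i = rng.integers(n_parts)
        if draw.sum() > total and draw[i] > lo:
            draw[i] -= 1
        elif draw.sum() < total and draw[i] < hi:
            draw[i] += 1
    return draw.tolist()


def sample_train_lengths(
    n_trains_start: int,
    n_trains_other: int,
    total_start: int,
    total_other: int,
    rng_seed: int | np.random.Generator,
    train_len_min: int = 4,
    train_len_max: int = 6,
) -> tuple[list[int], list[int]]:
    """Draw train-length lists for the two tones of one block.

    Each list is a composition of its tone's trial total into lengths from
    ``[train_len_min, train_len_max]``, drawn uniformly by rejection
    sampling (with a bounded repair fallback for pathological settings).
    Reproducible from the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lens_start = _sample_composition(
        n_trains_start, total_start, train_len_min, train_len_max, rng
    )
    lens_other = _sample_composition(
        n_trains_other, total_other, train_len_min, train_len_max, rng
    )
    return lens_start, lens_other


def build_block(
    start_tone: str,
    block_idx: int,
    rng_seed: int | np.random.Generator,
    config: ParadigmConfig | None = None,
) -> pd.DataFrame:
    """Build the ordered, role-labelled trial table of one block.

    Tone trains alternate strictly; the pseudorandom element is only the
    per-train length.  Onsets are relative to the block start at the
    configured SOA.
    """
    config = config or ParadigmConfig()
    if start_tone not in (TONE_LOW, TONE_HIGH):
        raise ValueError(f"unknown start tone {start_tone!r}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_start, n_other = config.train_counts()
    lens_start, lens_other = sample_train_lengths(
        n_start,
        n_other,
        config.trials_per_tone,
        config.trials_per_tone,
        rng,
        config.train_len_min,
        config.train_len_max,
    )
    other_tone = TONE_HIGH if start_tone == TONE_LOW else TONE_LOW
    tones, lengths = [], []
    it_start, it_other = iter(lens_start), iter(lens_other)
    for k in range(n_start + n_other):
        if k % 2 == 0:
            tones.append(start_tone)
            lengths.append(next(it_start))
        else:
            tones.append(other_tone)
            lengths.append(next(it_other))

    rows = []
    trial = 0
    for train_idx, (tone, length) in enumerate(zip(tones, lengths), start=1):
        for pos in range(1, length + 1):
            rows.append(
                {
                    "onset_s": trial * config.soa_s,
                    "duration_s": config.tone_duration_s,
                    "tone": tone,
                    "block": block_idx,
                    "train": train_idx,
                    "pos": pos,
                }
            )
            trial += 1
    return label_roles(pd.DataFrame(rows))


def label_roles(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach role flags and transition directions to a trial table.

    Adds boolean columns ``deviant``, ``standard``, ``nondeviant``,
    ``unlabeled_first`` and a ``transition`` column
    (``ascending``/``descending``/``none``).  Works per block:

    * deviant — first position of every train except the block's first;
    * nondeviant — every position after the first of a train;
    * standard — last position of a train that is followed by another train
      (always also a nondeviant, except in length-1 trains);
    * unlabeled_first — the very first trial of the block, which belongs to
      no condition (it neither continues a train nor violates one).
    """
    trials = trials.reset_index(drop=True)
    n = len(trials)
    deviant = np.zeros(n, dtype=bool)
    standard = np.zeros(n, dtype=bool)
    nondeviant = np.zeros(n, dtype=bool)
    unlabeled = np.zeros(n, dtype=bool)
    transition = np.array(["none"] * n, dtype=object)

    for _, idx in trials.groupby("block", sort=False).groups.items():
        sub = trials.loc[idx]
        pos = sub["pos"].to_numpy()
        train = sub["train"].to_numpy()
        tone = sub["tone"].to_numpy()
        first_train = train.min()
        last_train = train.max()
        loc = np.asarray(idx)

        is_first_of_train = pos == 1
        dev = is_first_of_train & (train > first_train)
        deviant[loc] = dev
        nondeviant[loc] = ~is_first_of_train
        unlabeled[loc] = is_first_of_train & (train == first_train)
        # standard: last position of each train except the block's last train
        is_last_of_train = np.r_[train[1:] != train[:-1], True]
        standard[loc] = is_last_of_train & (train < last_train)
        asc = dev & (tone == TONE_HIGH)
        desc = dev & (tone == TONE_LOW)
        transition[loc[asc]] = "ascending"
        transition[loc[desc]] = "descending"

    trials["deviant"] = deviant
    trials["standard"] = standard
    trials["nondeviant"] = nondeviant
    trials["unlabeled_first"] = unlabeled
    trials["transition"] = transition
    return trials


@dataclass
class ParadigmSchedule:
    """Full event table of a run plus block timing.

    ``trials`` is a DataFrame with one row per stimulus (columns:
    ``onset_s, duration_s, tone, block, train, pos, deviant, standard,
    nondeviant, unlabeled_first, transition``); onsets are absolute seconds
    from recording start.  ``blocks`` maps block index to
    ``(stim_start_s, stim_end_s, rest_end_s)``.
    """

    trials: pd.DataFrame
    blocks: dict[int, tuple[float, float, float]]
    config: ParadigmConfig = field(default_factory=ParadigmConfig)
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        return max(end for _, _, end in self.blocks.values())

    def rest_intervals(self) -> list[tuple[float, float]]:
        """(start, end) of each silent rest interval, in recording seconds."""
        out = []
        for b in sorted(self.blocks):
            start, stim_end, rest_end = self.blocks[b]
            out.append((stim_end, rest_end))
        return out

    def block_subset(self, k_blocks: int) -> "ParadigmSchedule":
        """Restrict to the first ``k_blocks`` blocks (cumulative-duration use)."""
        keep = sorted(self.blocks)[:k_blocks]
        return ParadigmSchedule(
            trials=self.trials[self.trials["block"].isin(keep)].reset_index(drop=True),
            blocks={b: self.blocks[b] for b in keep},
            config=self.config,
            seed=self.seed,
        )


def build_paradigm(
    n_blocks: int | None = None,
    rng_seed: int = 0,
    config: ParadigmConfig | None = None,
) -> ParadigmSchedule:
    """Generate the full roving schedule.

    Odd-numbered blocks start with the low tone, even-numbered blocks with
    the high tone.  Block ``b`` (1-based) occupies
    ``[lead_in + (b-1)*span, lead_in + b*span)`` with
    ``span = trials*soa + rest`` (185 s by default: 150-s stimulation plus
    the 35-s rest).  Deterministic per ``(config, rng_seed)``: each block
    draws from its own seed stream.
    """
    config = config or ParadigmConfig()
    if n_blocks is not None:
        config = ParadigmConfig(**{**asdict(config), "n_blocks": n_blocks})
    root = np.random.SeedSequence(rng_seed)
    block_seeds = root.spawn(config.n_blocks)
    frames = []
    blocks: dict[int, tuple[float, float, float]] = {}
    for b in range(1, config.n_blocks + 1):
        start_tone = TONE_LOW if b % 2 == 1 else TONE_HIGH
        tbl = build_block(
            start_tone, b, np.random.default_rng(block_seeds[b - 1]), config
        )
        t0 = config.lead_in_s + (b - 1) * config.block_span_s
        tbl["onset_s"] = tbl["onset_s"] + t0
        frames.append(tbl)
        stim_end = t0 + config.trials_per_block * config.soa_s
        blocks[b] = (t0, stim_end, stim_end + config.rest_s)
    trials = pd.concat(frames, ignore_index=True)
    return ParadigmSchedule(trials=trials, blocks=blocks, config=config, seed=rng_seed)


def _role_string(row) -> str:
    flags = [
        name
        for name in ("deviant", "standard", "nondeviant", "unlabeled_first")
        if row[name]
    ]
    return ",".join(flags) if flags else "none"


def export_events(schedule: ParadigmSchedule, path) -> None:
    """Write the schedule as a BIDS-events-like tab-separated table.

    Columns: onset_s, duration_s, tone, block, train, pos, role, transition.
    ``role`` holds comma-joined flags (e.g. ``nondeviant,standard``).
    """
    tbl = schedule.trials.copy()
    tbl["role"] = tbl.apply(_role_string, axis=1)
    tbl[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    """Read an events table written by :func:`export_events`.

    Returns the trial DataFrame with the boolean role columns restored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events table not found: {path}")
    tbl = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(tbl.columns)
    if missing:
        raise ValueError(f"events table {path} lacks columns {sorted(missing)}")
    roles = tbl["role"].fillna("none").astype(str)
    for name in ("deviant", "standard", "nondeviant", "unlabeled_first"):
        tbl[name] = roles.str.split(",").apply(lambda fl, n=name: n in fl)
    return tbl.drop(columns=["role"])


def schedule_from_events(
    trials: pd.DataFrame, config: ParadigmConfig | None = None
) -> ParadigmSchedule:
    """Rebuild a :class:`ParadigmSchedule` from a read-back events table."""
    config = config or ParadigmConfig()
    blocks: dict[int, tuple[float, float, float]] = {}
    for b, sub in trials.groupby("block"):
        t0 = config.lead_in_s + (b - 1) * config.block_span_s
        stim_end = t0 + config.trials_per_block * config.soa_s
        blocks[int(b)] = (t0, stim_end, stim_end + config.rest_s)
    return ParadigmSchedule(trials=trials.reset_index(drop=True), blocks=blocks, config=config)
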