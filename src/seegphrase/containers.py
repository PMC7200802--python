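"""Core data containers shared across the pipeline.

Conventions
-----------
* Times are seconds, 0-based, relative to the recording start; all analysis
  windows are half-open ``[t0, t1)``.
* Signals are stored channels-by-samples in microvolts.
* Epochs are locked to sentence onset with a fixed window of [-1.5, 4.5) s.
* Condition labels are ``"VP"`` (clitic + verb) and ``"NP"`` (article + noun).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fixed epoch window (s) relative to sentence onset
EPOCH_WINDOW = (-1.5, 4.5)
#: divisive-baseline window (s) relative to sentence onset
BASELINE_WINDOW = (-1.5, -0.005)
#: gamma band (Hz), half-open [lo, hi)
GAMMA_BAND = (50.0, 150.0)
#: high-gamma band (Hz), half-open [lo, hi); drives responsive-contact status
HIGH_GAMMA_BAND = (150.0, 300.0)

CONDITIONS = ("VP", "NP")
HEMISPHERES = ("DH", "NDH")
TISSUES = ("grey", "white")

#: event-table columns holding the four word-onset anchors, in order:
#: sentence onset, article/clitic onset, first word after (noun/verb) onset,
#: second word after onset
ANCHOR_COLUMNS = (
    "onset_sentence_s",
    "onset_artcl_s",
    "onset_word1_s",
    "onset_word2_s",
)


@dataclass
class ChannelInfo:
    """Metadata for one SEEG contact."""

    name: str
    hemisphere: str = "DH"
    lobe: str = ""
    gyrus: str = ""
    tissue: str = "grey"
    bad: bool = False

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channels : list of ChannelInfo
    start_time : float
        Time (s) of the first sample.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel metadata ({len(self.channels)}) does not match "
                f"data rows ({self.data.shape[0]})"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table (one row per sentence presentation).

    Required columns: ``sentence_id``, ``condition`` and the four anchor
    columns in :data:`ANCHOR_COLUMNS`.  Onsets must be strictly increasing
    within every row and conditions drawn from ``{"VP", "NP"}``.

    Returns the validated table; raises ``ValueError`` naming the first
    offending row otherwise.
    """
    required = ["sentence_id", "condition", *ANCHOR_COLUMNS]
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if events["sentence_id"].duplicated().any():
        dup = events["sentence_id"][events["sentence_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sentence_id {dup!r}")
    bad_cond = ~events["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(np.flatnonzero(bad_cond.to_numpy())[0])
        raise ValueError(
            f"row {row}: condition {events['condition'].iloc[row]!r} not in {CONDITIONS}"
        )
    onsets = events[list(ANCHOR_COLUMNS)].to_numpy(float)
    nonmono = np.diff(onsets, axis=1) <= 0
    if nonmono.any():
        row = int(np.flatnonzero(nonmono.any(axis=1))[0])
        raise ValueError(
            f"row {row} (sentence_id={events['sentence_id'].iloc[row]!r}): "
            f"anchor onsets not strictly increasing: {onsets[row].tolist()}"
        )
    return events


@dataclass
class EpochSet:
    """Fixed-window epochs locked to sentence onset.

    ``data`` has shape (n_trials, n_channels, n_samples) with the sample grid
    ``window[0] + k / fs`` for ``k = 0 .. n_samples-1`` (half-open window).
    ``anchors`` holds the four word onsets per trial, sentence-relative
    (so ``anchors[:, 0]`` is 0 up to jitter bookkeeping).
    """

    data: np.ndarray
    fs: float
    anchors: np.ndarray
    conditions: np.ndarray
    trial_ids: np.ndarray
    channels: list[ChannelInfo]
    window: tuple[float, float] = EPOCH_WINDOW
    warped: bool = False
    target_anchors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.anchors = np.asarray(self.anchors, float)
        self.conditions = np.asarray(self.conditions)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        n = self.data.shape[0]
        if not (len(self.anchors) == len(self.conditions) == len(self.trial_ids) == n):
            raise ValueError("trial-wise metadata length mismatch")
        if self.anchors.shape[1] != 4:
            raise ValueError("anchors must have four columns")
        if np.any(np.diff(self.anchors, axis=1) <= 0):
            raise ValueError("per-trial anchors must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times (s), sentence-relative, half-open window."""
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        names = [c.name for c in self.channels]
        try:
            return names.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None


@dataclass
class TFRSet:
    """Single-channel time-frequency power, trials x frequencies x samples.

    ``valid`` marks samples free of wavelet edge contamination per frequency.
    ``times`` may be decimated relative to the source epochs.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    conditions: np.ndarray
    valid: np.ndarray
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    normalized: bool = False
    #: wavelet envelope SD per frequency (s); the temporal resolution
    sigma_t: np.ndarray | None = None
    #: per-trial, per-frequency mean baseline power used by the divisive
    #: baseline (set during normalization; feeds the bootstrap null)
    baseline_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.power.shape[1] != len(self.freqs) or self.power.shape[2] != len(self.times):
            raise ValueError("power shape inconsistent with freqs/times")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def baseline_columns(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return np.flatnonzero((self.times >= t0) & (self.times < t1))


@dataclass
class BandTimecourse:
    """Per-condition band-specific ERSP (bERSP) over time.

    ``values`` maps condition label to the trial-averaged, frequency-averaged
    normalized power (ratio; 1 = baseline).  ``theta`` and ``l95`` are the
    screening thresholds when attached. ``valid`` marks edge-clean samples.
    """

    band: tuple[float, float]
    times: np.ndarray
    values: dict[str, np.ndarray]
    trial_values: np.ndarray
    conditions: np.ndarray
    valid: np.ndarray
    theta: float | None = None
    l95: float | None = None
    boot_mask: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ROIWindows:
    """Screening windows (s, sentence-relative, half-open).

    ``troi`` spans article/clitic onset to the end of the noun/verb (= onset
    of the following word); ``control_pre`` spans sentence onset to the
    article/clitic; ``control_post`` spans the second following word to the
    epoch end.
    """

    troi: tuple[float, float]
    control_pre: tuple[float, float]
    control_post: tuple[float, float]

    def __post_init__(self) -> None:
        seq = [*self.control_pre, *self.troi, *self.control_post]
        if any(b <= a for a, b in zip(seq[::2], seq[1::2])):
            raise ValueError("each window must have positive length")
        if not (self.control_pre[1] <= self.troi[0] and self.troi[1] <= self.control_post[0]):
            raise ValueError("windows must be disjoint and increasing")

    @classmethod
    def from_anchors(cls, anchors, epoch_end: float = EPOCH_WINDOW[1]) -> "ROIWindows":
        a1, a2, a3, a4 = np.asarray(anchors, float)
        return cls(troi=(a2, a4), control_pre=(a1, a2), control_post=(a4, epoch_end))

    @property
    def controls(self) -> list[tuple[float, float]]:
        return [self.control_pre, self.control_post]


@dataclass
class RCResult:
    """Screening outcome for one contact."""

    channel: str
    responsive: bool
    direction: str  # "VP>NP" or "NP>VP"
    a: float  # max band amplitude (ratio) in the tROI
    t: float  # total significant supra-threshold run length (s) in the tROI
    outside_terms: list[tuple[float, float]]  # (a_i, t_i) per control window
    contrast_p: float
    control_ps: list[float]
    theta: float
    l95: float
    #: sub-criteria: significant tROI span, condition specificity in the
    #: tROI, and time specificity (no significant span in control windows)
    roi_significant: bool = False
    condition_specific: bool = False
    time_specific: bool = False

    @property
    def at(self) -> float:
        return self.a * self.t

    @property
    def sig(self) -> float:
        """Ranking score a*t / sum(a_i * t_i); inf when no outside significance."""
        denom = sum(a * t for a, t in self.outside_terms)
        if denom == 0.0:
            return float("inf") if self.at > 0 else 0.0
        return self.at / denom


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for recovery tests."""

    planted_responsive: list[int]
    planted_direction: dict[int, bool]  # channel -> True when VP > NP
    planted_auditory: list[int] = field(default_factory=list)
    anchor_latencies: np.ndarray | None = None  # (n_trials, 4), sentence-relative
    surprisal_gap: float | None = None
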