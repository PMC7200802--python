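"""Synthetic SEEG sessions and n-gram corpora with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* continuous 1/f-shaped Gaussian background at 1000 Hz;
* 31 VP + 31 NP sentence presentations with four jittered word-onset anchors
  (sentence onset, article/clitic, noun/verb, following word);
* "responsive" channels receive a multiplicative high-gamma (150-300 Hz)
  power increase between the article/clitic onset and the end of the
  noun/verb, larger for VP trials (gain 2.0) than NP trials (1.2), so the
  divisive baseline recovers the planted gain directly as an ERSP ratio;
* "auditory" channels receive a phase-locked damped broadband transient at
  every word onset of every trial (the Heschl-like control that must fail
  the time-specificity screening);
* bigram/unigram count tables in which clitic-initiated bigrams are rarer
  than article-initiated ones by a planted factor exp(gap).

All generators are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .containers import (
    ANCHOR_COLUMNS,
    EPOCH_WINDOW,
    HIGH_GAMMA_BAND,
    ChannelInfo,
    GroundTruth,
    Recording,
    validate_events,
)
from .io import NgramTable
from .surprisal import SentenceSpec

_LOBES = ("temporal", "frontal", "parietal", "occipital")
_GYRI = {
    "temporal": ("middle temporal", "superior temporal"),
    "frontal": ("inferior frontal", "cingulate"),
    "parietal": ("supramarginal", "angular"),
    "occipital": ("lingual", "cuneus"),
}


@dataclass
class SynthConfig:
    """Parameters of a synthetic SEEG session.

    Defaults are the study conditions the pipeline is validated under:
    1000 Hz sampling, 31 trials per condition, high-gamma gains 2.0 (VP)
    and 1.2 (NP) inside the article-to-second-word window.
    """

    fs: float = 1000.0
    n_trials_per_condition: int = 31
    n_channels: int = 20
    responsive_channel_ids: tuple[int, ...] = (0, 1)
    auditory_channel_ids: tuple[int, ...] = (2, 3)
    vp_gain: float = 2.0
    np_gain: float = 1.2
    noise_exponent: float = 1.0
    anchor_means: tuple[float, float, float, float] = (0.0, 0.8, 1.2, 1.7)
    anchor_jitter_sd: float = 0.05
    intertrial_interval: float = 7.5
    burst_band: tuple[float, float] = HIGH_GAMMA_BAND
    transient_power_ratio: float = 4.0
    noise_rms_uv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.burst_band[1]:
            raise ValueError("fs must exceed twice the burst band upper edge")
        if np.any(np.diff(self.anchor_means) <= 0):
            raise ValueError("anchor_means must be strictly increasing")
        if self.vp_gain < 1 or self.np_gain < 1:
            raise ValueError("gains must be >= 1")
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if self.anchor_jitter_sd < 0:
            raise ValueError("anchor_jitter_sd must be nonnegative")
        bad = [i for i in (*self.responsive_channel_ids, *self.auditory_channel_ids)
               if not 0 <= i < self.n_channels]
        if bad:
            raise ValueError(f"channel ids out of range: {bad}")
        overlap = set(self.responsive_channel_ids) & set(self.auditory_channel_ids)
        if overlap:
            raise ValueError(f"channels cannot be both responsive and auditory: {sorted(overlap)}")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def default_channel_info(config: SynthConfig) -> list[ChannelInfo]:
    """Round-robin hemisphere/lobe/gyrus labels; all grey matter."""
    infos = []
    for i in range(config.n_channels):
        lobe = _LOBES[i % len(_LOBES)]
        infos.append(
            ChannelInfo(
                name=f"ch{i:02d}",
                hemisphere="DH" if i % 2 == 0 else "NDH",
                lobe=lobe,
                gyrus=_GYRI[lobe][(i // len(_LOBES)) % 2],
                tissue="grey",
                bad=False,
            )
        )
    return infos


def generate_trial_plan(
    config: SynthConfig, max_redraws: int = 1000
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the per-trial event table and the planted ground truth.

    One row per trial, equal VP/NP counts in shuffled order.  Each trial's
    four anchors are ``anchor_means + N(0, anchor_jitter_sd)``, redrawn until
    strictly increasing (at most 1000 redraws, then an error names the
    offending anchors).  Deterministic given ``config.seed``.
    """
    rng = _rng(config, 0)
    n = config.n_trials_per_condition
    conditions = np.array(["VP"] * n + ["NP"] * n)
    conditions = conditions[rng.permutation(2 * n)]
    means = np.asarray(config.anchor_means, float)

    anchors = np.empty((2 * n, 4))
    for i in range(2 * n):
        for attempt in range(max_redraws):
            draw = means + rng.normal(0.0, config.anchor_jitter_sd, size=4)
            if np.all(np.diff(draw) > 0):
                anchors[i] = draw
                break
        else:
            order = np.argsort(np.diff(draw))
            raise ValueError(
                f"could not draw strictly increasing anchors in {max_redraws} "
                f"redraws (worst gap between anchors {order[0] + 1} and "
                f"{order[0] + 2}); anchor means {means.tolist()}, "
                f"jitter sd {config.anchor_jitter_sd}"
            )

    # absolute trial reference times; first trial leaves room for the
    # pre-stimulus window
    refs = 2.0 + config.intertrial_interval * np.arange(2 * n)
    onsets = refs[:, None] + anchors
    events = pd.DataFrame(
        {
            "sentence_id": np.arange(1, 2 * n + 1),
            "condition": conditions,
            ANCHOR_COLUMNS[0]: onsets[:, 0],
            ANCHOR_COLUMNS[1]: onsets[:, 1],
            ANCHOR_COLUMNS[2]: onsets[:, 2],
            ANCHOR_COLUMNS[3]: onsets[:, 3],
        }
    )
    validate_events(events)
    truth = GroundTruth(
        planted_responsive=sorted(config.responsive_channel_ids),
        planted_direction={
            i: config.vp_gain >= config.np_gain for i in config.responsive_channel_ids
        },
        planted_auditory=sorted(config.auditory_channel_ids),
        # sentence-relative, derived exactly as a consumer would from the table
        anchor_latencies=onsets - onsets[:, :1],
    )
    return events, truth


def _shaped_noise_parts(
    rng: np.random.Generator, n: int, fs: float, exponent: float, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """1/f-shaped Gaussian noise split into out-of-band and in-band parts."""
    white = rng.standard_normal(n).astype(np.float32)
    spec = sp_fft.rfft(white)
    freqs = sp_fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs, dtype=np.float32)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    in_band = (freqs >= band[0]) & (freqs < band[1])
    low = sp_fft.irfft(spec * (shape * ~in_band), n).astype(np.float32)
    hi = sp_fft.irfft(spec * (shape * in_band), n).astype(np.float32)
    return low, hi


def generate_recording(
    plan: pd.DataFrame, config: SynthConfig, channels: list[ChannelInfo] | None = None
) -> Recording:
    """Synthesize the continuous multichannel recording for a trial plan.

    Responsive channels have the amplitude of their in-band (150-300 Hz)
    noise component multiplied by sqrt(gain) between the article/clitic
    onset and the second-word onset of each trial, so in-band *power* is
    multiplied by the condition gain.  Auditory channels receive a fixed
    damped white-noise kernel (phase-locked, hence visible in the trial
    average) at every anchor.
    """
    validate_events(plan)
    onsets = plan[ANCHOR_COLUMNS[0]].to_numpy(float)
    gaps = np.diff(np.sort(onsets))
    span = EPOCH_WINDOW[1] - EPOCH_WINDOW[0]
    if np.any(gaps < span):
        i = int(np.flatnonzero(gaps < span)[0])
        raise ValueError(
            f"epochs overlap: sentence onsets {i} and {i + 1} are {gaps[i]:.3f} s apart "
            f"(< epoch span {span} s)"
        )
    if np.min(onsets) + EPOCH_WINDOW[0] < 0:
        raise ValueError("first epoch under-runs the recording start")

    fs = config.fs
    duration = float(np.max(plan[ANCHOR_COLUMNS[3]])) + EPOCH_WINDOW[1] + 0.5
    n = int(round(duration * fs))
    rng = _rng(config, 1)
    if channels is None:
        channels = default_channel_info(config)
    if len(channels) != config.n_channels:
        raise ValueError("channel metadata length does not match n_channels")

    cond = plan["condition"].to_numpy()
    i_art = np.round(plan[ANCHOR_COLUMNS[1]].to_numpy(float) * fs).astype(int)
    i_w2 = np.round(plan[ANCHOR_COLUMNS[3]].to_numpy(float) * fs).astype(int)
    anchor_samples = np.round(plan[list(ANCHOR_COLUMNS)].to_numpy(float) * fs).astype(int)

    data = np.empty((config.n_channels, n), dtype=np.float32)
    for ci in range(config.n_channels):
        low, hi = _shaped_noise_parts(rng, n, fs, config.noise_exponent, config.burst_band)
        total_sd = float(np.sqrt(low.var() + hi.var()))
        scale = config.noise_rms_uv / total_sd
        low *= scale
        hi *= scale
        if ci in config.responsive_channel_ids:
            gain_profile = np.ones(n, dtype=np.float32)
            for k in range(len(plan)):
                g = config.vp_gain if cond[k] == "VP" else config.np_gain
                gain_profile[i_art[k]: i_w2[k]] = np.sqrt(g)
            data[ci] = low + hi * gain_profile
        elif ci in config.auditory_channel_ids:
            sig = low + hi
            kern = _auditory_kernel(rng, fs, float(hi.std()), config)
            for t0 in anchor_samples.ravel():
                seg = sig[t0: t0 + len(kern)]
                seg += kern[: len(seg)]
            data[ci] = sig
        else:
            data[ci] = low + hi
    return Recording(data=data, fs=fs, channels=channels, start_time=0.0)


def _auditory_kernel(
    rng: np.random.Generator, fs: float, band_sd: float, config: SynthConfig
) -> np.ndarray:
    """Fixed damped broadband transient; power in the burst band is
    ``transient_power_ratio`` times the background in-band power.

    The ~200 ms extent with a 60 ms decay mimics an auditory cortex
    high-gamma response following the syllable envelope of a spoken word.
    """
    dur, tau = 0.2, 0.06
    t = np.arange(int(dur * fs)) / fs
    kern = rng.standard_normal(len(t)).astype(np.float32) * np.exp(-t / tau).astype(np.float32)
    kern /= np.sqrt(np.mean(kern**2))
    band_fraction = (config.burst_band[1] - config.burst_band[0]) / (fs / 2.0)
    amp = np.sqrt(config.transient_power_ratio * band_sd**2 / band_fraction)
    return kern * amp


def generate_session(
    config: SynthConfig,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Trial plan + recording in one call."""
    plan, truth = generate_trial_plan(config)
    rec = generate_recording(plan, config)
    return rec, plan, truth


# ---------------------------------------------------------------------------
# synthetic n-gram corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Parameters of the synthetic stimulus corpus.

    ``surprisal_gap`` is the planted mean clitic-minus-article surprisal
    difference in natural-log units; ``noise_sd`` the per-sentence lognormal
    scatter of conditional probabilities.
    """

    n_pairs: int = 31
    surprisal_gap: float = 1.0
    noise_sd: float = 0.5
    base_surprisal_artcl: float = 2.0
    base_surprisal_word: float = 1.5
    missing_fraction: float = 0.0
    unigram_scale: float = 1e6
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 sentence pairs")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.unigram_scale <= 0 or self.zipf_exponent <= 0:
            raise ValueError("lexicon size and concentration must be positive")


@dataclass
class CorpusTruth:
    sentences: list[SentenceSpec]
    ngrams: NgramTable
    surprisal_gap: float
    planted_artcl_surprisal: dict[int, float] = field(default_factory=dict)


def generate_corpus(config: CorpusConfig) -> CorpusTruth:
    """Sentence specs plus unigram/bigram counts with a planted surprisal gap.

    Each pair i shares the homophonous target token ``t_i``; the NP sentence
    is ``[ctxN_i, t_i, wN_i, fill_i]`` (article reading) and the VP sentence
    ``[ctxV_i, t_i, wV_i, fill_i]`` (clitic reading).  The conditional
    probability of the clitic bigram ``(ctxV_i, t_i)`` is lower than the
    article bigram's by the factor ``exp(-surprisal_gap)``.  VP sentences get
    odd ids, NP sentences even ids, so pair k holds ids (2k+1, 2k+2).
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 2])
    m = config.n_pairs
    words: list[str] = []
    for i in range(m):
        words += [f"ctxN{i:03d}", f"ctxV{i:03d}", f"tgt{i:03d}", f"wN{i:03d}", f"wV{i:03d}", f"fill{i:03d}"]
    ranks = rng.permutation(len(words)) + 1
    unigrams = {
        w: int(max(1, round(config.unigram_scale / r**config.zipf_exponent)))
        for w, r in zip(words, ranks)
    }

    bigrams: dict[tuple[str, str], int] = {}
    planted: dict[int, float] = {}

    def _plant(prev: str, tok: str, s_value: float) -> None:
        if rng.random() < config.missing_fraction:
            bigrams[(prev, tok)] = 0
            return
        u = unigrams[prev]
        if u == 0:
            raise ValueError(f"zero unigram count for {prev!r} appearing in a bigram")
        bigrams[(prev, tok)] = int(np.clip(round(u * np.exp(-s_value)), 1, u))

    sentences: list[SentenceSpec] = []
    for i in range(m):
        s_art = config.base_surprisal_artcl + rng.normal(0, config.noise_sd)
        s_cl = config.base_surprisal_artcl + config.surprisal_gap + rng.normal(0, config.noise_sd)
        s_wn = config.base_surprisal_word + rng.normal(0, config.noise_sd)
        s_wv = config.base_surprisal_word + rng.normal(0, config.noise_sd)
        ctx_n, ctx_v = f"ctxN{i:03d}", f"ctxV{i:03d}"
        tgt, w_n, w_v, fill = f"tgt{i:03d}", f"wN{i:03d}", f"wV{i:03d}", f"fill{i:03d}"
        _plant(ctx_v, tgt, s_cl)
        _plant(ctx_n, tgt, s_art)
        _plant(tgt, w_v, s_wv)
        _plant(tgt, w_n, s_wn)
        planted[2 * i + 1] = s_cl
        planted[2 * i + 2] = s_art
        sentences.append(
            SentenceSpec(2 * i + 1, "VP", [ctx_v, tgt, w_v, fill], (1, 2))
        )
        sentences.append(
            SentenceSpec(2 * i + 2, "NP", [ctx_n, tgt, w_n, fill], (1, 2))
        )
    table = NgramTable(unigrams=unigrams, bigrams=bigrams)
    return CorpusTruth(
        sentences=sentences,
        ngrams=table,
        surprisal_gap=config.surprisal_gap,
        planted_artcl_surprisal=planted,
    )


def generate_ngram_counts(config: CorpusConfig) -> NgramTable:
    """Only the count table of :func:`generate_corpus`."""
    return generate_corpus(config).ngrams
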