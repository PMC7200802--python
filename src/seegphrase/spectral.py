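"""Time-frequency decomposition and event-related spectral perturbations.

Per-trial power is obtained by complex Morlet-wavelet convolution on 40
log-spaced frequencies (4-300 Hz by default) with cycles growing linearly
from 3 at the lowest to 15 at the highest frequency.  Each trial's power is
divided, frequency-wise, by its own mean pre-stimulus power (divisive
baseline over [-1.5, -0.005) s), giving a dimensionless ratio with 1 =
baseline level; trial averages of the ratio are the ERSPs.  Significance of
time-frequency voxels is assessed against a bootstrap distribution built by
resampling baseline time points within trials.  Band-specific ERSPs (bERSP)
average the ERSP over half-open frequency bands — gamma [50, 150) and high
gamma [150, 300) Hz.
"""
from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

from .containers import (
    BASELINE_WINDOW,
    BandTimecourse,
    EpochSet,
    TFRSet,
)

#: default frequency grid bounds and count
DEFAULT_FMIN, DEFAULT_FMAX, DEFAULT_NFREQS = 4.0, 300.0, 40
#: wavelet cycles at (fmin, fmax); linear in frequency in between
DEFAULT_CYCLES = (3.0, 15.0)
#: wavelet truncation, in units of the Gaussian envelope SD
_SUPPORT_SD = 3.5


def default_freqs(
    fmin: float = DEFAULT_FMIN, fmax: float = DEFAULT_FMAX, n: int = DEFAULT_NFREQS
) -> np.ndarray:
    return np.geomspace(fmin, fmax, n)


def wavelet_cycles(freqs: np.ndarray, cycles: tuple[float, float] = DEFAULT_CYCLES) -> np.ndarray:
    """Cycles per wavelet, linear in frequency from cycles[0] to cycles[1]."""
    freqs = np.asarray(freqs, float)
    lo, hi = freqs[0], freqs[-1]
    if hi == lo:
        return np.full_like(freqs, cycles[0])
    return cycles[0] + (cycles[1] - cycles[0]) * (freqs - lo) / (hi - lo)


def _make_wavelet(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(_SUPPORT_SD * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return (w / np.linalg.norm(w)).astype(np.complex64)


def compute_tfr(
    epochs: EpochSet,
    channel: int | str,
    freqs: np.ndarray | None = None,
    cycles: tuple[float, float] = DEFAULT_CYCLES,
    decim: int = 1,
) -> TFRSet:
    """Per-trial Morlet power for one channel.

    Samples within one wavelet half-support of either epoch edge are flagged
    invalid per frequency.  ``decim`` keeps every ``decim``-th power sample
    (the wavelet envelope is far smoother than the raw signal, so modest
    decimation loses nothing for band-power analyses).
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, float)
    if np.any(freqs >= epochs.fs / 2):
        raise ValueError(
            f"frequencies {freqs[freqs >= epochs.fs / 2]} at or above Nyquist "
            f"({epochs.fs / 2} Hz)"
        )
    ci = epochs.channel_index(channel)
    x = np.asarray(epochs.data[:, ci, :], dtype=np.float32)
    n_trials, n_s = x.shape
    ncyc = wavelet_cycles(freqs, cycles)
    wavelets = [_make_wavelet(f, c, epochs.fs) for f, c in zip(freqs, ncyc)]
    n_fft = sp_fft.next_fast_len(n_s + max(len(w) for w in wavelets) - 1)
    spec = sp_fft.fft(x.astype(np.complex64), n_fft, axis=1)

    cols = np.arange(0, n_s, decim)
    power = np.empty((n_trials, len(freqs), len(cols)), dtype=np.float32)
    valid = np.empty((len(freqs), len(cols)), dtype=bool)
    sigma_t = ncyc / (2.0 * np.pi * freqs)
    for k, w in enumerate(wavelets):
        wf = sp_fft.fft(w, n_fft)
        conv = sp_fft.ifft(spec * wf[None, :], axis=1)
        start = (len(w) - 1) // 2
        seg = conv[:, start: start + n_s][:, cols]
        power[:, k, :] = np.abs(seg) ** 2
        half = len(w) // 2
        valid[k] = (cols >= half) & (cols < n_s - half)

    return TFRSet(
        power=power,
        freqs=freqs,
        times=epochs.times[cols],
        fs=epochs.fs / decim,
        conditions=np.asarray(epochs.conditions),
        valid=valid,
        baseline_window=BASELINE_WINDOW,
        normalized=False,
        sigma_t=sigma_t,
    )


def divisive_baseline(tfr: TFRSet) -> TFRSet:
    """Divide each trial's power, per frequency, by its mean baseline power.

    The result is dimensionless (1 = baseline level) and invariant to
    channel-wise rescaling of the raw signal.
    """
    if tfr.normalized:
        raise ValueError("TFR is already baseline-normalized")
    t0, t1 = tfr.baseline_window
    if t0 < tfr.times[0] or t1 > tfr.times[-1] + 1.0 / tfr.fs:
        raise ValueError("baseline window outside the epoch window")
    base_cols = tfr.baseline_columns()
    if len(base_cols) == 0:
        raise ValueError("empty baseline window")
    denom = np.empty((tfr.n_trials, len(tfr.freqs)), dtype=np.float64)
    for k in range(len(tfr.freqs)):
        cols = base_cols[tfr.valid[k, base_cols]]
        if len(cols) == 0:
            cols = base_cols  # fully edge-contaminated baseline: use it anyway
        denom[:, k] = tfr.power[:, k, cols].mean(axis=1)
    bad = ~(denom > 0)
    if bad.any():
        ti, fi = np.argwhere(bad)[0]
        raise ValueError(
            f"zero baseline power for trial {ti}, frequency {tfr.freqs[fi]:.3g} Hz"
        )
    power = (tfr.power / denom[:, :, None].astype(np.float32))
    return TFRSet(
        power=power, freqs=tfr.freqs, times=tfr.times, fs=tfr.fs,
        conditions=tfr.conditions, valid=tfr.valid,
        baseline_window=tfr.baseline_window, normalized=True, sigma_t=tfr.sigma_t,
        baseline_mean=denom,
    )


def ersp(tfr: TFRSet, condition_labels: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-condition trial-average of normalized power (freqs x samples)."""
    labels = np.asarray(condition_labels if condition_labels is not None else tfr.conditions)
    out: dict[str, np.ndarray] = {}
    for cond in np.unique(labels):
        sel = labels == cond
        if sel.sum() < 2:
            raise ValueError(f"need at least 2 trials for condition {cond!r}")
        out[str(cond)] = tfr.power[sel].mean(axis=0)
    if not out:
        raise ValueError("no conditions present")
    return out


def bootstrap_mask(
    tfr: TFRSet,
    n_boot: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Voxel-wise significance mask from a baseline bootstrap.

    The null for each frequency is built by drawing, with replacement, one
    baseline time point per trial, averaging across trials, and repeating
    ``n_boot`` times; a voxel is significant when the observed trial-average
    lies outside the [alpha/2, 1-alpha/2] null quantiles.  Edge-contaminated
    samples are never significant.

    The observed statistic at a voxel outside the baseline is a mean of
    ratios x_i / m_i with the numerator independent of the trial's own
    baseline mean m_i.  A draw taken from trial i's own baseline is
    positively correlated with m_i and would understate both the variance
    and the small-sample bias of the ratio (severely so at low frequencies,
    where the baseline holds few independent wavelet widths).  The null
    draw for trial i therefore takes its numerator from the baseline of a
    *different*, exchangeable trial j and divides it by m_i — matching the
    observed statistic's distribution exactly under trial exchangeability
    and baseline stationarity.
    """
    if not tfr.normalized:
        raise ValueError("bootstrap_mask expects baseline-normalized power")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(rng)
    base_cols = tfr.baseline_columns()
    if len(base_cols) < 10:
        raise ValueError(f"baseline has only {len(base_cols)} samples (< 10)")

    if tfr.baseline_mean is None:
        raise ValueError("TFR lacks baseline means; normalize with divisive_baseline")

    observed = tfr.power.mean(axis=0)  # (freqs, times)
    n_trials = tfr.n_trials
    mask = np.zeros_like(observed, dtype=bool)
    trial_idx = np.arange(n_trials)
    for k in range(len(tfr.freqs)):
        cols = base_cols[tfr.valid[k, base_cols]]
        if len(cols) == 0:
            cols = base_cols
        nb = len(cols)
        b = tfr.power[:, k, cols].astype(np.float64)  # (trials, nb) ratios
        bm = tfr.baseline_mean[:, k].astype(np.float64)
        # numerator from a different trial's baseline (raw power is ratio
        # times that trial's baseline mean), denominator this trial's mean
        j = (trial_idx[None, :] + rng.integers(1, n_trials, size=(n_boot, n_trials))) % n_trials
        tau = rng.integers(0, nb, size=(n_boot, n_trials))
        vals = b[j, tau] * (bm[j] / bm[trial_idx[None, :]])
        null = vals.mean(axis=1)
        lo, hi = np.quantile(null, [alpha / 2.0, 1.0 - alpha / 2.0])
        mask[k] = ((observed[k] < lo) | (observed[k] > hi)) & tfr.valid[k]
    return mask


def band_timecourse(
    tfr: TFRSet,
    band: tuple[float, float],
    condition_labels: np.ndarray | None = None,
) -> BandTimecourse:
    """Band-specific ERSP: mean over frequency bins with lo <= f < hi.

    Carries both the per-condition trial averages and the per-trial band
    course (needed by the screening permutation test).
    """
    lo, hi = band
    bins = np.flatnonzero((tfr.freqs >= lo) & (tfr.freqs < hi))
    if len(bins) == 0:
        raise ValueError(f"no frequency bins in band [{lo}, {hi}) Hz")
    labels = np.asarray(condition_labels if condition_labels is not None else tfr.conditions)
    trial_values = tfr.power[:, bins, :].mean(axis=1)  # (trials, times)
    values = {}
    for cond in np.unique(labels):
        sel = labels == cond
        if sel.sum() < 2:
            raise ValueError(f"need at least 2 trials for condition {cond!r}")
        values[str(cond)] = trial_values[sel].mean(axis=0)
    return BandTimecourse(
        band=(float(lo), float(hi)),
        times=tfr.times,
        values=values,
        trial_values=trial_values,
        conditions=labels,
        valid=tfr.valid[bins].all(axis=0),
    )


def band_sigma_t(
    band: tuple[float, float],
    freqs: np.ndarray | None = None,
    cycles: tuple[float, float] = DEFAULT_CYCLES,
) -> float:
    """Largest wavelet envelope SD (s) among the band's frequency bins —
    the temporal resolution limit of the band course."""
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, float)
    bins = (freqs >= band[0]) & (freqs < band[1])
    if not bins.any():
        raise ValueError("band outside the frequency grid")
    ncyc = wavelet_cycles(freqs, cycles)
    return float(np.max(ncyc[bins] / (2.0 * np.pi * freqs[bins])))
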