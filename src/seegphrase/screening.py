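"""Responsive-contact (RC) screening and ranking.

A contact is deemed responsive when its high-gamma band course shows
significant amplitude *specifically* inside the tROI (article/clitic onset
to the end of the noun/verb):

1. amplitude significance — the band course exceeds θ, the 95th percentile
   of the trial-averaged normalized spectrogram pooled over all frequencies
   and baseline time points of that contact, for a span longer than both
   L95 (the 95th percentile of supra-θ run durations found in the baseline)
   and the band estimate's own temporal resolution (a few wavelet envelope
   widths — shorter excursions are unresolved single fluctuations of the
   smoothed course, not spans);
2. condition specificity — only one condition's course has such a run in
   the tROI, or both do but their window-mean trial powers differ
   (two-sided permutation test, p < alpha);
3. time specificity — no such supra-θ run in either control window
   (sentence onset to article/clitic; second following word to epoch end)
   for either condition.

Detected contacts are ranked by sig = a*t / sum_i(a_i * t_i), where a and t
are the peak band amplitude and total significant run length inside the
tROI and (a_i, t_i) their analogues in the control windows; contacts with
no outside significance rank first (among themselves by a*t).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    BASELINE_WINDOW,
    EPOCH_WINDOW,
    HIGH_GAMMA_BAND,
    GAMMA_BAND,
    BandTimecourse,
    EpochSet,
    RCResult,
    ROIWindows,
    Recording,
    TFRSet,
)
from .epoching import extract_epochs, median_anchors, reject_epochs, time_warp
from .spectral import band_sigma_t, band_timecourse, compute_tfr, divisive_baseline


def amplitude_threshold(tfr: TFRSet) -> float:
    """θ: 95th percentile of the trial-averaged normalized power pooled over
    all frequency bins and (edge-clean) baseline time points."""
    if not tfr.normalized:
        raise ValueError("amplitude_threshold expects baseline-normalized power")
    avg = tfr.power.mean(axis=0)  # (freqs, times)
    base_cols = tfr.baseline_columns()
    pool = []
    for k in range(len(tfr.freqs)):
        cols = base_cols[tfr.valid[k, base_cols]]
        if len(cols) == 0:
            cols = base_cols
        pool.append(avg[k, cols])
    pool = np.concatenate(pool)
    if not np.all(np.isfinite(pool)):
        raise ValueError("non-finite values in the baseline power pool")
    return float(np.percentile(pool, 95))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b - a)) for a, b in zip(starts, stops)]


def _window_runs(
    course: np.ndarray, valid: np.ndarray, times: np.ndarray,
    window: tuple[float, float], theta: float,
) -> list[float]:
    """Durations (s) of supra-θ runs of the course within a half-open window.

    Invalid (edge-contaminated) samples break runs.
    """
    dt = float(times[1] - times[0])
    inside = (times >= window[0]) & (times < window[1])
    mask = inside & valid & (course > theta)
    # restrict run detection to the window so a run crossing the boundary is
    # clipped to its in-window part
    return [length * dt for _, length in _runs(mask)]


def run_length_threshold(
    btc: BandTimecourse, theta: float,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> float:
    """L95: 95th percentile of supra-θ run durations of the band courses
    within the baseline (conditions pooled); 0 if the baseline has no runs."""
    durations: list[float] = []
    for course in btc.values.values():
        durations += _window_runs(course, btc.valid, btc.times, baseline_window, theta)
    if not durations:
        return 0.0
    return float(np.percentile(durations, 95))


def condition_contrast(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Two-sided permutation p for the difference of condition means.

    Uses the +1 correction so p is never exactly 0.  All-identical inputs
    give p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per condition")
    rng = np.random.default_rng(rng)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def _window_trial_means(
    btc: BandTimecourse, window: tuple[float, float]
) -> np.ndarray:
    inside = (btc.times >= window[0]) & (btc.times < window[1]) & btc.valid
    if not inside.any():
        raise ValueError(f"window {window} has no valid samples")
    return btc.trial_values[:, inside].mean(axis=1)


@dataclass
class ScreeningParams:
    band: tuple[float, float] = HIGH_GAMMA_BAND
    alpha: float = 0.05
    n_perm: int = 1000
    #: erosion (s) of the control-window edges adjacent to the tROI;
    #: ``None`` = 2 wavelet envelope SDs at the band's worst bin, guarding
    #: against spectral leakage of a genuine tROI response across the
    #: window boundary
    boundary_guard: float | None = None
    #: minimum duration (s) for a supra-θ run to count as a time span;
    #: ``None`` = 6 wavelet envelope SDs at the band's worst bin (three
    #: temporal-resolution widths) — the smallest span the band course can
    #: actually resolve
    min_run: float | None = None


def screen_contact(
    tfr: TFRSet,
    windows: ROIWindows,
    channel_name: str = "",
    params: ScreeningParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> RCResult:
    """Run the full RC screening for one contact's normalized TFR."""
    params = params or ScreeningParams()
    rng = np.random.default_rng(rng)
    btc = band_timecourse(tfr, params.band)
    theta = amplitude_threshold(tfr)
    l95 = run_length_threshold(btc, theta)

    sigma_t = band_sigma_t(params.band, tfr.freqs)
    guard = params.boundary_guard if params.boundary_guard is not None else 2.0 * sigma_t
    min_run = params.min_run if params.min_run is not None else 6.0 * sigma_t
    span = max(l95, min_run)

    conds = sorted(btc.values)
    if set(conds) != {"NP", "VP"}:
        raise ValueError(f"screening needs both VP and NP trials, have {conds}")

    # (i) amplitude + run-length significance inside the tROI, per condition
    sig_runs_roi = {
        c: [d for d in _window_runs(btc.values[c], btc.valid, btc.times, windows.troi, theta)
            if d > span]
        for c in conds
    }
    has_roi = {c: bool(sig_runs_roi[c]) for c in conds}

    vp_vals = _window_trial_means(btc, windows.troi)[btc.conditions == "VP"]
    np_vals = _window_trial_means(btc, windows.troi)[btc.conditions == "NP"]
    contrast_p = condition_contrast(vp_vals, np_vals, params.n_perm, rng)

    # (ii) condition specificity in the tROI
    n_sig = sum(has_roi.values())
    if n_sig == 1:
        cond_specific = True
    elif n_sig == 2:
        cond_specific = contrast_p < params.alpha
    else:
        cond_specific = False

    # (iii) time specificity: no significant run in either control window
    # for either condition; only the tROI-adjacent edge of each control
    # window is eroded (onset-locked activity at the outer edges must count)
    outside_terms: list[tuple[float, float]] = []
    control_ps: list[float] = []
    control_sig = []
    for win, erode_side in zip(windows.controls, ("right", "left")):
        if erode_side == "right":
            eroded = (win[0], win[1] - guard)
        else:
            eroded = (win[0] + guard, win[1])
        if eroded[1] <= eroded[0]:
            eroded = win
        a_i, t_i, any_sig = 0.0, 0.0, False
        for c in conds:
            runs = _window_runs(btc.values[c], btc.valid, btc.times, eroded, theta)
            sig = [d for d in runs if d > span]
            t_i = max(t_i, float(sum(sig)))
            any_sig = any_sig or bool(sig)
        inside = (btc.times >= eroded[0]) & (btc.times < eroded[1]) & btc.valid
        if inside.any():
            a_i = max(float(np.max(btc.values[c][inside])) for c in conds)
            vp_c = _window_trial_means(btc, eroded)[btc.conditions == "VP"]
            np_c = _window_trial_means(btc, eroded)[btc.conditions == "NP"]
            control_ps.append(condition_contrast(vp_c, np_c, params.n_perm, rng))
        else:
            control_ps.append(1.0)
        outside_terms.append((a_i, t_i))
        control_sig.append(any_sig)
    time_specific = not any(control_sig)

    roi_cols = (btc.times >= windows.troi[0]) & (btc.times < windows.troi[1]) & btc.valid
    a = max(float(np.max(btc.values[c][roi_cols])) for c in conds) if roi_cols.any() else 0.0
    t = max(float(sum(sig_runs_roi[c])) for c in conds)
    direction = "VP>NP" if vp_vals.mean() >= np_vals.mean() else "NP>VP"

    return RCResult(
        channel=channel_name,
        responsive=bool(n_sig >= 1 and cond_specific and time_specific),
        direction=direction,
        a=a,
        t=t,
        outside_terms=outside_terms,
        contrast_p=contrast_p,
        control_ps=control_ps,
        theta=theta,
        l95=l95,
        roi_significant=bool(n_sig >= 1),
        condition_specific=bool(cond_specific),
        time_specific=bool(time_specific),
    )


def rank_contacts(results: list[RCResult]) -> list[RCResult]:
    """Descending sig order; zero-denominator contacts rank first, ordered
    among themselves by a*t; a*t = 0 ranks last."""
    def key(r: RCResult):
        if np.isinf(r.sig):
            return (0, -r.at)
        return (1, -r.sig)

    return sorted(results, key=key)


def screen_session(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    params: ScreeningParams | None = None,
    decim: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[RCResult], pd.DataFrame]:
    """Screen every channel of a (warped) epoch set.

    Returns the RCResult list (channel order) and a summary table sorted by
    rank.  ``epochs`` must already be time-warped so all trials share the
    anchor latencies from which the screening windows are taken.
    """
    params = params or ScreeningParams()
    rng = np.random.default_rng(rng)
    if not epochs.warped:
        raise ValueError("screen_session expects time-warped epochs")
    windows = ROIWindows.from_anchors(epochs.target_anchors, EPOCH_WINDOW[1])
    results = []
    for ci, ch in enumerate(epochs.channels):
        tfr = divisive_baseline(compute_tfr(epochs, ci, freqs=freqs, decim=decim))
        results.append(
            screen_contact(tfr, windows, channel_name=ch.name, params=params, rng=rng)
        )
    ranked = rank_contacts(results)
    info = {c.name: c for c in epochs.channels}
    table = pd.DataFrame(
        [
            {
                "channel": r.channel,
                "hemisphere": info[r.channel].hemisphere,
                "lobe": info[r.channel].lobe,
                "gyrus": info[r.channel].gyrus,
                "responsive": r.responsive,
                "direction": r.direction,
                "a": r.a,
                "t": r.t,
                "sig": r.sig,
                "contrast_p": r.contrast_p,
            }
            for r in ranked
        ]
    )
    return results, table


def preprocess_session(
    recording: Recording,
    events: pd.DataFrame,
    z_max: float = 6.0,
    warp: bool = True,
) -> EpochSet:
    """Epoch, reject artifacts, and time-warp to the median anchors."""
    epochs = reject_epochs(extract_epochs(recording, events), z_max=z_max)
    if warp:
        epochs = time_warp(epochs, "median")
    return epochs


GAMMA_PARAMS = ScreeningParams(band=GAMMA_BAND)
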