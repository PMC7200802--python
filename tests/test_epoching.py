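"""Epoch extraction, artifact rejection, time-warping and ERP images."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seegphrase as sp
from seegphrase.containers import ChannelInfo, EPOCH_WINDOW, Recording
from seegphrase.epoching import (
    _warp_map,
    erp_image,
    extract_epochs,
    reject_epochs,
    time_warp,
)


def test_epoch_shape_and_count(small_session):
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events)
    assert epochs.n_trials == 62
    assert epochs.n_samples == 6000  # 6 s at 1000 Hz
    assert epochs.window == EPOCH_WINDOW
    np.testing.assert_allclose(epochs.anchors[:, 0], 0.0, atol=1e-12)


def test_epoch_window_underrun_names_trial():
    rng = np.random.default_rng(0)
    rec = Recording(
        data=rng.normal(size=(1, 10_000)), fs=1000.0, channels=[ChannelInfo("c0")]
    )
    events = sp.generate_trial_plan(
        sp.SynthConfig(n_channels=1, responsive_channel_ids=(), auditory_channel_ids=(), seed=0)
    )[0].iloc[:1].copy()
    for col in ["onset_sentence_s", "onset_artcl_s", "onset_word1_s", "onset_word2_s"]:
        events[col] = events[col] - events["onset_sentence_s"].iloc[0] + 0.5
    with pytest.raises(ValueError, match="sentence_id=1"):
        extract_epochs(rec, events)


def test_rejection_drops_exactly_the_spiked_epoch():
    cfg = sp.SynthConfig(
        n_channels=3, responsive_channel_ids=(), auditory_channel_ids=(), seed=17
    )
    rec, events, _ = sp.generate_session(cfg)
    epochs = extract_epochs(rec, events)
    spiked = epochs.data.copy()
    robust_sd = 1.4826 * np.median(np.abs(spiked[:, 2] - np.median(spiked[:, 2])))
    spiked[10, 2, 3000] += 20 * robust_sd
    bad = sp.EpochSet(
        data=spiked, fs=epochs.fs, anchors=epochs.anchors,
        conditions=epochs.conditions, trial_ids=epochs.trial_ids,
        channels=epochs.channels,
    )
    kept = reject_epochs(bad, z_max=6)
    dropped = set(epochs.trial_ids) - set(kept.trial_ids)
    assert dropped == {epochs.trial_ids[10]}
    # conditions of survivors unchanged
    survivors = np.isin(epochs.trial_ids, kept.trial_ids)
    np.testing.assert_array_equal(kept.conditions, epochs.conditions[survivors])


def test_rejection_with_infinite_threshold_is_identity(small_session):
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events)
    kept = reject_epochs(epochs, z_max=np.inf)
    assert kept.n_trials == epochs.n_trials


def test_clean_noise_rarely_rejected():
    zero = 0
    n_seeds = 10
    for s in range(n_seeds):
        cfg = sp.SynthConfig(
            n_channels=2, responsive_channel_ids=(), auditory_channel_ids=(), seed=300 + s
        )
        rec, events, _ = sp.generate_session(cfg)
        kept = reject_epochs(extract_epochs(rec, events), z_max=6)
        zero += kept.n_trials == 62
    assert zero >= int(0.9 * n_seeds)


def test_warp_identity_when_anchors_equal_targets():
    cfg = sp.SynthConfig(
        n_channels=1, responsive_channel_ids=(), auditory_channel_ids=(),
        anchor_jitter_sd=0.0, seed=9,
    )
    rec, events, _ = sp.generate_session(cfg)
    epochs = extract_epochs(rec, events)
    warped = time_warp(epochs, "median")
    err = np.abs(warped.data - epochs.data).max() / epochs.data.std()
    assert err < 1e-9
    assert warped.warped
    np.testing.assert_allclose(warped.anchors, np.tile(warped.target_anchors, (62, 1)))


def test_warp_map_is_piecewise_linear_and_hits_anchors():
    anchors = np.array([0.0, 0.8, 1.2, 1.7])
    targets = np.array([0.0, 1.0, 1.3, 1.8])
    # the sample that was at 0.8 s lands at 1.0 s exactly
    assert _warp_map(np.array([1.0]), anchors, targets, EPOCH_WINDOW)[0] == pytest.approx(0.8)
    # linear in between anchors 1 and 2: midpoint maps to midpoint
    assert _warp_map(np.array([0.5]), anchors, targets, EPOCH_WINDOW)[0] == pytest.approx(0.4)


@settings(max_examples=50, deadline=None)
@given(
    jitter=st.lists(st.floats(-0.2, 0.2), min_size=4, max_size=4),
    tjitter=st.lists(st.floats(-0.2, 0.2), min_size=4, max_size=4),
)
def test_warp_map_is_monotone(jitter, tjitter):
    base = np.array([0.0, 0.8, 1.2, 1.7])
    src = np.sort(base + np.asarray(jitter) * np.array([0.1, 1, 1, 1]))
    dst = np.sort(base + np.asarray(tjitter) * np.array([0.1, 1, 1, 1]))
    src += np.arange(4) * 1e-6  # break exact ties
    dst += np.arange(4) * 1e-6
    times = np.linspace(*EPOCH_WINDOW, 601)
    mapped = _warp_map(times, src, dst, EPOCH_WINDOW)
    assert np.all(np.diff(mapped) >= 0)


def test_warp_preserves_band_power(small_session):
    """The windowed-sinc interpolation must not low-pass the high-gamma band."""
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events)
    warped = time_warp(epochs, "median")
    from scipy import signal

    sos = signal.butter(6, [160, 290], btype="bandpass", fs=rec.fs, output="sos")
    ch = 3  # pure noise channel
    before = signal.sosfiltfilt(sos, epochs.data[:, ch, :].astype(float), axis=1).var()
    after = signal.sosfiltfilt(sos, warped.data[:, ch, :].astype(float), axis=1).var()
    assert abs(after / before - 1.0) < 0.05


def test_warp_twice_rejected(warped_epochs):
    with pytest.raises(ValueError, match="already warped"):
        time_warp(warped_epochs, "median")


def test_erp_image_single_trial_is_the_trace(small_session):
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events.iloc[:1])
    matrix, avg = erp_image(epochs, 0)
    np.testing.assert_array_equal(matrix[0], epochs.data[0, 0])
    np.testing.assert_array_equal(avg, epochs.data[0, 0])


def test_erp_average_shrinks_with_sqrt_trials(small_session):
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events)
    _, avg_few = erp_image(
        sp.EpochSet(
            data=epochs.data[:15], fs=epochs.fs, anchors=epochs.anchors[:15],
            conditions=epochs.conditions[:15], trial_ids=epochs.trial_ids[:15],
            channels=epochs.channels,
        ),
        3,
    )
    _, avg_all = erp_image(epochs, 3)
    ratio = np.std(avg_few) / np.std(avg_all)
    expected = np.sqrt(epochs.n_trials / 15)
    assert 0.6 * expected < ratio < 1.6 * expected


def test_erp_image_unknown_channel(small_session):
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events.iloc[:3])
    with pytest.raises(KeyError, match="nope"):
        erp_image(epochs, "nope")
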