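"""Generator contracts: trial plans, recordings, corpora, ground truth."""
import numpy as np
import pytest
from scipy import signal

import seegphrase as sp
from seegphrase.containers import ANCHOR_COLUMNS
from seegphrase.epoching import erp_image, extract_epochs
from seegphrase.synth import generate_trial_plan


def test_trial_plan_has_balanced_conditions_and_is_deterministic():
    cfg = sp.SynthConfig(n_channels=4, responsive_channel_ids=(0,), auditory_channel_ids=(1,), seed=11)
    plan, truth = generate_trial_plan(cfg)
    assert len(plan) == 62
    assert (plan["condition"] == "VP").sum() == 31
    assert (plan["condition"] == "NP").sum() == 31
    assert plan["sentence_id"].is_unique
    plan2, _ = generate_trial_plan(cfg)
    assert plan.equals(plan2)
    # planted anchors in the event table equal the ground truth exactly
    rel = plan[list(ANCHOR_COLUMNS)].to_numpy() - plan[[ANCHOR_COLUMNS[0]]].to_numpy()
    np.testing.assert_array_equal(rel, truth.anchor_latencies)


def test_zero_jitter_anchors_equal_means():
    cfg = sp.SynthConfig(
        n_channels=4, responsive_channel_ids=(), auditory_channel_ids=(),
        anchor_jitter_sd=0.0, seed=2,
    )
    plan, _ = generate_trial_plan(cfg)
    rel = plan[list(ANCHOR_COLUMNS)].to_numpy() - plan[[ANCHOR_COLUMNS[0]]].to_numpy()
    np.testing.assert_allclose(rel, np.tile(cfg.anchor_means, (62, 1)), atol=1e-12)


def test_unorderable_jitter_raises_naming_anchors():
    cfg = sp.SynthConfig(
        n_channels=4, responsive_channel_ids=(), auditory_channel_ids=(),
        anchor_means=(0.0, 0.01, 0.02, 0.03), anchor_jitter_sd=2.0, seed=0,
    )
    with pytest.raises(ValueError, match="anchors"):
        generate_trial_plan(cfg, max_redraws=1)


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="Nyquist|twice"):
        sp.SynthConfig(fs=500.0)
    with pytest.raises(ValueError, match="increasing"):
        sp.SynthConfig(anchor_means=(0.0, 1.2, 0.8, 1.7))
    with pytest.raises(ValueError, match=">= 1"):
        sp.SynthConfig(vp_gain=0.5)
    with pytest.raises(ValueError, match="both responsive and auditory"):
        sp.SynthConfig(responsive_channel_ids=(0,), auditory_channel_ids=(0,))


def test_recording_is_bit_reproducible(small_config):
    rec1, _, _ = sp.generate_session(small_config)
    rec2, _, _ = sp.generate_session(small_config)
    np.testing.assert_array_equal(rec1.data, rec2.data)


def _bandpass_ratio(rec, events, channel, band=(160.0, 290.0)):
    """Oracle: in-band power ratio tROI/baseline per trial, via an
    independent Butterworth filter on the raw signal."""
    sos = signal.butter(6, band, btype="bandpass", fs=rec.fs, output="sos")
    bp = signal.sosfiltfilt(sos, rec.data[channel].astype(float))
    fs = rec.fs
    out = {}
    for cond in ("VP", "NP"):
        ratios = []
        for _, r in events[events["condition"] == cond].iterrows():
            roi = bp[int((r.onset_artcl_s + 0.05) * fs): int((r.onset_word2_s - 0.05) * fs)]
            base = bp[int((r.onset_sentence_s - 1.4) * fs): int((r.onset_sentence_s - 0.1) * fs)]
            ratios.append(roi.var() / base.var())
        out[cond] = float(np.mean(ratios))
    return out


def test_planted_gain_recovered_by_bandpass_oracle(small_session):
    rec, events, _ = small_session
    ratios = _bandpass_ratio(rec, events, channel=0)
    assert abs(ratios["VP"] - 2.0) < 0.3
    assert abs(ratios["NP"] - 1.2) < 0.2


def test_unit_gain_recording_indistinguishable_from_noise():
    cfg = sp.SynthConfig(
        n_channels=2, responsive_channel_ids=(0,), auditory_channel_ids=(),
        vp_gain=1.0, np_gain=1.0, seed=5,
    )
    rec, events, _ = sp.generate_session(cfg)
    ratios = _bandpass_ratio(rec, events, channel=0)
    assert abs(ratios["VP"] - 1.0) < 0.15
    assert abs(ratios["NP"] - 1.0) < 0.15


def test_auditory_channel_shows_phase_locked_transients(small_session):
    rec, events, _ = small_session
    epochs = extract_epochs(rec, events)
    _, avg_aud = erp_image(epochs, 1)
    _, avg_resp = erp_image(epochs, 0)
    times = epochs.times
    floor = np.abs(avg_aud[(times > -1.0) & (times < -0.2)]).std()
    anchors = np.median(epochs.anchors, axis=0)
    for a in anchors:
        win = np.abs(avg_aud[(times >= a) & (times < a + 0.1)])
        assert win.max() > 5 * floor, f"no evoked transient after anchor at {a:.2f} s"
    # the multiplicative (non-phase-locked) channel shows no evoked response
    floor_resp = np.abs(avg_resp[(times > -1.0) & (times < -0.2)]).std()
    for a in anchors:
        win = np.abs(avg_resp[(times >= a) & (times < a + 0.1)])
        assert win.max() < 5 * floor_resp


def test_overlapping_epochs_rejected():
    cfg = sp.SynthConfig(
        n_channels=2, responsive_channel_ids=(), auditory_channel_ids=(),
        intertrial_interval=4.0, seed=0,
    )
    plan, _ = generate_trial_plan(cfg)
    with pytest.raises(ValueError, match="overlap"):
        sp.generate_recording(plan, cfg)


def test_ngram_null_gap_recovers_zero():
    gaps = []
    for s in range(20):
        corpus = sp.generate_corpus(sp.CorpusConfig(surprisal_gap=0.0, seed=s))
        table = sp.build_surprisal_table(corpus.sentences, corpus.ngrams)
        gaps.append(sp.condition_gap(table, "artcl"))
    se = np.std(gaps, ddof=1) / np.sqrt(len(gaps))
    assert abs(np.mean(gaps)) < 2 * se + 0.05


def test_ngram_missing_fraction_matches_request():
    flagged = total = 0
    for s in range(20):
        corpus = sp.generate_corpus(sp.CorpusConfig(missing_fraction=0.1, seed=100 + s))
        table = sp.build_surprisal_table(corpus.sentences, corpus.ngrams)
        flagged += int(table["artcl_missing"].sum() + table["nounverb_missing"].sum())
        total += 2 * len(table)
    assert abs(flagged / total - 0.1) < 0.03


def test_ngram_counts_deterministic(planted_corpus):
    again = sp.generate_corpus(sp.CorpusConfig(surprisal_gap=1.0, seed=7))
    assert again.ngrams.unigrams == planted_corpus.ngrams.unigrams
    assert again.ngrams.bigrams == planted_corpus.ngrams.bigrams
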