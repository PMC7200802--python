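# seegphrase

Analysis pipeline for stereo-EEG (SEEG) recordings of *homophonous* Italian
phrases — word strings such as *la porta* that sound identical but are
either a noun phrase ("the door": article + noun, **NP**) or a verb phrase
("brings her": clitic + verb, **VP**) depending on context.  Because the
acoustic input is the same, a contact whose response separates the two
readings carries syntactic, not acoustic, information.  The package is for
intracranial-electrophysiology researchers who want a tested, reproducible
implementation of this screening style, end to end, with a synthetic-data
generator that plants known ground truth for validation.

## What it computes

Given a continuous multichannel recording, a per-sentence event table with
four word-onset anchors, channel metadata, and an n-gram count table:

1. **Epoching** in [−1.5, 4.5) s around sentence onset, robust
   (median/MAD) artifact rejection, and piecewise-linear **time-warping**
   of every trial onto common anchor latencies (windowed-sinc value
   interpolation, so the high-gamma band survives).
2. **ERSP**: per-trial Morlet power (40 log-spaced frequencies, 4–300 Hz),
   divisive baseline over [−1.5, −0.005) s — each trial's power divided by
   its own pre-stimulus mean, so 1 = baseline level — and trial averages
   per condition, with a seeded bootstrap significance mask.  Band ERSPs
   for gamma [50, 150) and high gamma [150, 300) Hz.
3. **Responsive-contact (RC) screening**: a contact is responsive when its
   high-gamma course exceeds θ (95th percentile of the baseline spectrogram
   distribution across frequencies) for a significant span inside the tROI
   (article/clitic onset → end of noun/verb), with condition specificity
   (one condition over threshold, or both and a permutation p < 0.05) and
   time specificity (no such span in the control windows).  Contacts are
   ranked by sig = a·t / Σ aᵢtᵢ.
4. **Surprisal**: S(wᵢ) = −log[count(wᵢ₋₁, wᵢ) / count(wᵢ₋₁)] from bigram
   and unigram corpus counts, with missing-value handling, stimulus
   exclusions and cross-condition pairing, a median split into high/low
   surprisal, and paired t-tests.
5. **Decoding**: linear-kernel SVM with leave-one-out cross-validation on
   surprisal (and surprisal × tROI power) features, plus Kolmogorov–Smirnov
   normality checks and one-way ANOVA.
6. **Group statistics**: anatomical censuses of contacts and RCs and the
   hemisphere contrast via the two-sided Fisher exact test.

The `synth` module generates sessions with planted effects (1/f background,
multiplicative high-gamma gains of 2.0/1.2 for VP/NP in responsive
channels, phase-locked broadband transients in auditory channels) and
n-gram corpora with a planted clitic−article surprisal gap, all
bit-reproducible per seed.

## Worked example

```python
import seegphrase as sp

# one synthetic session: channel 0 responsive, channel 1 auditory, 2-3 noise
cfg = sp.SynthConfig(n_channels=4, responsive_channel_ids=(0,),
                     auditory_channel_ids=(1,), seed=42)
rec, events, truth = sp.generate_session(cfg)
epochs = sp.preprocess_session(rec, events)   # epoch, reject, time-warp
results, table = sp.screen_session(epochs, rng=0)
print(table[["channel", "responsive", "direction", "a", "t", "contrast_p"]])

corpus = sp.generate_corpus(sp.CorpusConfig(surprisal_gap=1.0, seed=7))
stable = sp.build_surprisal_table(corpus.sentences, corpus.ngrams)
t, df, p = sp.paired_condition_test(stable, "artcl")
print(f"clitic vs article surprisal: t({df}) = {t:.3f}, p = {p:.2e}")

split = sp.median_split(stable)
high = split[split["surprisal_level"] == "high"]
print(f"high-surprisal sentences that are VPs: {100 * (high['condition'] == 'VP').mean():.0f}%")

X, y, _ = sp.build_feature_matrix(stable, columns=("artcl_surprisal",))
print(f"LOOCV SVM score on surprisal: {sp.loocv_svm(X, y).score:.2f}")
```

Output:

```
channel  responsive direction      a     t  contrast_p
   ch00        True     VP>NP  2.283 0.915       0.001
   ch01       False     VP>NP 18.882 0.345       0.268
   ch02       False     NP>VP  1.341 0.000       0.330
   ch03       False     VP>NP  1.314 0.000       0.695
clitic vs article surprisal: t(30) = 7.844, p = 9.41e-09
high-surprisal sentences that are VPs: 87%
LOOCV SVM score on surprisal: 0.87
```

Reading it: the planted channel `ch00` is detected as responsive with the
VP>NP direction — its high-gamma course peaks at 2.28× baseline (`a`, the
planted VP gain was 2.0) and stays significant for 0.915 s of the tROI
(`t`), with a VP/NP permutation p of 0.001.  The auditory channel `ch01`
reaches huge amplitude (18.9× at word onsets) but is *not* responsive: its
activity appears in every window, so it fails time specificity — the
built-in control that separates genuine phrase-type contacts from plain
auditory responses.  The noise channels show no significant span (`t` = 0).
On the corpus side, the planted 1.0-nat clitic−article gap yields a
strongly significant paired test, 87% of high-surprisal sentences are VPs,
and a leave-one-out SVM decodes phrase type from the article/clitic
surprisal at 87%.

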