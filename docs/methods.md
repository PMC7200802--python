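# Methods

`seegphrase` analyses stereo-EEG (SEEG) recordings of subjects listening to
Italian sentences containing homophonous two-word phrases — strings such as
*la porta* that are acoustically identical but syntactically either a noun
phrase (article + noun, NP) or a verb phrase (clitic pronoun + verb, VP).
Because the sound is the same, any reliable electrophysiological difference
between the two readings isolates syntax from acoustics.  The pipeline
identifies the recording contacts whose high-gamma (150–300 Hz) power
discriminates the two readings, computes the bigram surprisal of the
critical words, and quantifies decodability and group-level anatomy.

## Signal model and pipeline

**Epoching.** Trials are extracted in a fixed half-open window
[−1.5, 4.5) s locked to sentence onset (6000 samples at 1 kHz).  All times
are seconds, 0-based, relative to recording start; windows are half-open to
remove off-by-one ambiguity.  Artifacted epochs are rejected by a robust
amplitude rule: per channel, the amplitude scale is 1.4826 × MAD of the
pooled samples, and an epoch is dropped when its peak absolute
(median-centred) amplitude on any channel exceeds `z_max` (default 6)
robust SDs.  This replaces visual artifact screening with a reproducible
criterion; on clean synthetic data it rejects essentially nothing, and a
planted 20-SD spike removes exactly its epoch.

**Time warping.** Each trial carries four word-onset anchors (sentence
onset, article/clitic, noun/verb, second following word).  Trials are
warped so that all anchors land on the per-anchor median over the kept
trials of both conditions, giving VP and NP one shared timeline.  The time
mapping is monotone piecewise-linear with knots at the window edges and
the four anchors; the segments outside the outermost anchors map linearly
onto the remaining window.  Sample values are interpolated with a 16-tap
Kaiser-windowed sinc kernel rather than linearly: linear interpolation at
fractional sample offsets is a strong low-pass (about two-thirds of the
power at 300 Hz on a 1 kHz recording disappears at half-sample offsets)
and would destroy the very band the screening measures, whereas the sinc
kernel is transparent across the analysis bands and reduces exactly to the
identity when a trial's anchors already sit on the targets.

**Time–frequency decomposition.** Per-trial power comes from complex
Morlet wavelets on 40 log-spaced frequencies, 4–300 Hz, with cycles
growing linearly from 3 at the lowest to 15 at the highest frequency —
a standard grid that keeps the time–frequency trade-off controlled at
high gamma (envelope SD ≈ 10 ms at 200 Hz).  Samples within one wavelet
half-support of an epoch edge are flagged invalid per frequency and
excluded from every statistic.  Power is decimated by 5 after convolution
(200 Hz sampling; the band envelopes have ≪ 100 Hz bandwidth).

**Divisive baseline and ERSP.** Each trial's power at each frequency is
divided by that trial's mean power over the baseline [−1.5, −0.005) s,
giving a dimensionless ratio (1 = baseline) that is invariant to
channel-wise amplitude rescaling.  Trial averages of the ratio per
condition are the event-related spectral perturbations (ERSP); averages
over half-open bands — gamma [50, 150) and high gamma [150, 300) Hz — are
the band-specific ERSPs (bERSP).  Ratios, not dB, feed all thresholds.

**Bootstrap significance mask.** A time–frequency voxel is significant
when its trial-averaged ratio leaves the [α/2, 1−α/2] quantiles of a
bootstrap null built from baseline time points (default n_boot = 500,
α = 0.05, seeded).  The null draw for trial *i* takes its numerator from
the baseline of a *different*, exchangeable trial and divides it by trial
*i*'s own baseline mean.  Drawing from the same trial's baseline would
understate both the variance and the small-sample bias of the ratio
(dividing by a noisy self-including mean suppresses within-baseline
variability; at 4 Hz the 1.5 s baseline holds ≈ 4 independent wavelet
widths and an independent voxel's expected ratio is ≈ 1.4).  With the
cross-trial construction the null matches the observed statistic exactly
under trial exchangeability and baseline stationarity; on null recordings
the significant-voxel fraction is ≈ 0.06 at α = 0.05, nominal above
~10 Hz, with the residual excess confined to the few lowest bins whose
wavelet width leaves under ten independent baseline samples.

## Responsive-contact screening

The time region of interest (tROI) runs from the article/clitic onset to
the end of the noun/verb (= onset of the following word); the control
windows are sentence-onset→article/clitic and second-word→epoch-end.
A contact is **responsive** when all three hold for its high-gamma bERSP:

1. **Amplitude/span significance.** The per-condition course exceeds θ —
   the 95th percentile of the trial-averaged normalized spectrogram pooled
   over all frequencies and baseline time points of that contact — for a
   contiguous span longer than both L95 (the 95th percentile of supra-θ
   run durations observed in the baseline, conditions pooled; 0 when the
   baseline has no runs) and a resolution floor of 6 wavelet-envelope SDs
   of the band's coarsest bin (≈ 57 ms for high gamma).  The floor exists
   because the band course is smoothed at the wavelet scale: the baseline
   yields few runs, so L95 is a noisy 10–20 ms, while ordinary noise
   produces 15–40 ms excursions throughout the several seconds of scanned
   windows; a "span" shorter than the estimator's own resolution is a
   single fluctuation, not a time span.
2. **Condition specificity.** In the tROI, either only one condition has
   such a span, or both do and the window-mean trial powers differ by a
   two-sided permutation test (n_perm = 1000, +1-corrected p < 0.05).
3. **Time specificity.** Neither condition has such a span in either
   control window.  Control windows are eroded by 2 wavelet SDs (≈ 20 ms)
   only on their tROI-adjacent edge, so spectral leakage of a genuine tROI
   response across the boundary does not count against the contact while
   onset-locked activity at the outer edges (the auditory-cortex pattern:
   transients at every word onset) still does.

Direction is the sign of the VP−NP mean tROI power.  Detected contacts are
ranked by sig = a·t / Σᵢ aᵢtᵢ, with a the peak band amplitude and t the
total significant span inside the tROI and (aᵢ, tᵢ) their analogues per
control window; contacts with no outside significance rank first (among
themselves by a·t), and a·t = 0 ranks last.  α = 0.05 throughout with no
correction across contacts — a documented limitation, matching common
practice for this screening style.  Gamma-band [50, 150) courses are
computed and reportable, but only high gamma determines responsiveness.

## Surprisal

For a target word w preceded by w′, S = −log(count(w′, w) / count(w′)) in
natural-log units (the base is configurable; nothing downstream depends on
it).  The ratio of raw counts is the conditional-probability estimate; a
value is missing when either count is zero, and zero counts are not
smoothed.  Sentences excluded by the stimulus design are dropped and the
remaining VP/NP sentences paired (by rank of sentence id, or an explicit
pairing list for re-pairing orphans).  The median split labels values
strictly above the pooled median "high", with ties going to "low"
(deterministic, documented).  Condition comparisons are classical paired
t-tests with listwise deletion of incomplete pairs; zero-variance
differences return t = 0, p = 1 when means agree, else a signed-infinite
sentinel with a warning.

## Decoding and companion statistics

VP/NP decoding uses a linear-kernel SVM (C = 1) with leave-one-out
cross-validation; columns are standardized on the training rows of each
fold only, and rows with missing features are dropped and counted.  The
linear kernel is the minimal choice consistent with a straight separating
boundary in the two published feature spaces (surprisal × surprisal and
surprisal × tROI power).  The normality check reports the KS statistic
against a normal with the sample mean/SD and a Lilliefors-calibrated
p-value — the naive KS p with estimated parameters has a true level near
0.002 and would make the test useless.  The two-group comparison is a
one-way ANOVA (F = t² exactly for two groups).

## Group statistics

Censuses count grey-matter contacts and responsive contacts by hemisphere
(language-dominant DH vs non-dominant NDH), lobe and gyrus; percentages
round half-away-from-zero to one decimal.  The hemisphere contrast is the
two-sided Fisher exact test under the point-probability rule (scipy's
implementation, cross-checked in the tests against exhaustive
hypergeometric enumeration over every 2×2 table with N ≤ 40).

## Synthetic data: what it emulates and what it does not

The generator produces continuous 1/f-shaped Gaussian noise (exponent 1.0,
10 µV RMS) at 1 kHz with 31 VP + 31 NP trials whose four anchors are drawn
at mean latencies (0, 0.8, 1.2, 1.7) s with 50 ms Gaussian jitter,
resampled until increasing.  *Responsive* channels have the amplitude of
their 150–300 Hz noise component multiplied by √gain between the
article/clitic and second-word anchors — multiplicative, so the divisive
baseline recovers the planted gain directly as an ERSP ratio (VP gain 2.0,
NP gain 1.2 by default); high gamma is synthesized as band-limited noise,
not an oscillation, because the analysis treats it as broadband power.
*Auditory* channels add a fixed (phase-locked) damped white-noise kernel,
200 ms long with a 60 ms decay — the time course of an auditory-cortex
high-gamma response following a syllable envelope — at every word onset,
with in-band power 4× background; being phase-locked it also produces a
clean evoked potential in the trial average.  The intertrial interval
defaults to 7.5 s, the smallest spacing that keeps epochs disjoint under
jitter; no analysed quantity depends on it.  Channel anatomy labels are
assigned round-robin purely so the census code can be exercised.

The n-gram generator draws Zipf-distributed unigram counts and plants a
clitic-minus-article conditional-probability gap of `surprisal_gap`
natural-log units (default 1.0) with 0.5-nat lognormal scatter per
sentence; the noun/verb position gets scatter but no gap.  With these
values the expected high-surprisal class composition is Φ(1) ≈ 84% VP —
the same order as the published real-corpus split.

Not emulated: realistic electrode geometry, epileptiform activity beyond
optional amplitude spikes, acoustic waveforms, phase structure of evoked
responses, cross-channel correlation, and corpus morphology (tokens are
synthetic symbols).  Passing the recovery tests therefore shows the
pipeline recovers effects of the assumed form at realistic SNR and trial
counts — not that real SEEG meets those assumptions.

## Validation studies and problem sizes

The validation module runs, at sizes chosen to finish in minutes on one
core: 20 sessions × 20 channels (10% planted responsive, two auditory) for
screening sensitivity/false positives/direction; 20 single-channel null
sessions for bootstrap calibration; 50 corpora for surprisal-gap recovery
and the median split; 20 corpora plus 50 label shuffles for decoding.
Published corpus-dependent numbers (the 1.9097 median, t(30) = −6.794, the
86%/83% decoder scores, the 74% VP>NP fraction, the anatomical census) are
not reproducible without the original recordings and corpus; the planted
analogues above check the same machinery for sign, ordering and magnitude.

## Numerical choices and degenerate inputs

Wavelets are L2-normalized and truncated at ±3.5 envelope SDs; FFT
convolution in complex64.  Zero baseline power raises (rather than
silently dividing by zero) naming the trial and frequency.  A band with no
grid frequencies, a missing condition, fewer than 2 trials per condition,
non-increasing anchors or targets, out-of-bounds epochs and all-rejected
sessions are all errors with specific messages.  Permutation p-values use
the +1 correction and are never exactly 0; all-identical inputs give
p = 1.  The sig ranking handles a zero denominator with a rank-first
sentinel instead of infinity arithmetic.  EDF output is 16-bit with one
data record per second; round-trips are exact up to that quantization
(verified by reading back through MNE, an independent implementation).

## Known limitations

No multiple-comparison correction across contacts; the bootstrap mask is
approximate in the lowest frequency bins (see above); signals are assumed
already referenced (white-matter reference at acquisition); the screening's
time-specificity rule is one defensible operationalization of "no
significance at other time intervals" among several; form-vs-lemma count
tables are handled as two separate inputs, the pipeline running on
whichever is supplied.
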