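# Methods

## Signal model and feature extraction

Input recordings are multichannel voltage time-series at 2 kHz (µV), one per
recording session, with each channel assigned to one of eight right-hemisphere
regions: inferior/middle/superior temporal gyrus (cortical) and thalamus,
insular gyrus, amygdala, parahippocampal gyrus, hippocampus (analysis class
"subcortical").  The parahippocampal gyrus is archi-/paleocortex anatomically,
but it lies beneath the neocortex and is therefore grouped with the
subcortical class; the class labels are analysis designations, not anatomy.

Per session the pipeline computes, per channel:

1. least-squares linear detrend over the whole session;
2. anti-alias low-pass at 500 Hz (8th-order Butterworth);
3. three parallel band features:
   * 1–30 Hz and 30–70 Hz series via 6th-order Butterworth band-passes,
   * the 70–150 Hz (high-gamma) amplitude envelope via band-pass + Hilbert
     transform — the envelope of this band tracks local population spiking
     and is the prior-expected carrier of speech information;
4. polyphase decimation ×10 to 200 Hz;
5. running z-score with a 30 s window.

Numerical choices where the procedure is underdetermined:

* **Zero-phase filtering.**  All IIR filters are applied forward-backward
  (`sosfiltfilt`), so the three band paths have no relative group delay and
  stay sample-aligned.  The effective magnitude response is |H(f)|², i.e.
  the effective order doubles; tests compare measured attenuation against
  this squared analytic response.
* **Decimation.**  `resample_poly(up=1, down=10)` supplies a linear-phase FIR
  anti-alias at ~100 Hz with compensated delay.  On the high-gamma path this
  doubles as a safety low-pass on the envelope, preventing envelope aliasing.
  Band-attenuation oracles probe tones well below 100 Hz so the decimator's
  roll-off near the output Nyquist does not contaminate the measurement.
* **Running z-score window placement.**  Centered, with the window shrinking
  *symmetrically* at session edges (at sample *i* the window is
  `[i-h, i+h]`, `h = min(W/2, i, T-1-i)`).  This is an offline analysis;
  no causality constraint applies.  The sd is floored at
  `max(1e-8 × global sd, 1e-12)` so flat segments yield zeros, never NaNs.
* **Detrending** is per whole session, before any segmentation.
* No notch filtering, artifact rejection, or re-referencing is applied.

## Labels

Mandarin initials form a 7-place × 8-manner chart of 21 consonants
(aspiration and voicing variants count as separate manners); tones are the
4 canonical lexical tones.  Pinyin parsing matches the digraphs zh/ch/sh
before single letters; "w"/"y" spellings and vowel-initial syllables are
zero-initial — they keep their tone label but are excluded from the place
and manner tasks.  The neutral (fifth) tone is rejected at labeling time,
fixing the tone task at exactly 4 classes (chance 1/4; place 1/7, manner
1/8).

## Decoder

A stacked bidirectional LSTM maps a 200 ms window (40 samples × channels·bands
features) to the one-hot target of the window's **center** sample (the model
is bidirectional, so symmetric alignment is the natural choice; a right-edge
alignment is config-exposed).  The output head is a linear layer of size K
trained by mean-squared error against the one-hot target; classification is
argmax.  Training uses Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), 50% inverted
dropout on every LSTM layer output, shuffled mini-batches (default 256), and
early stopping: a session-wise validation holdout (~10% of training
sessions, at least one), patience 5 epochs with min-delta 0, restoring the
best-validation checkpoint (the restored epoch is provably the arg-min of
the validation-loss log).  Defaults are 3 layers × 100 hidden units per
direction; `DecoderConfig.desk_scale()` (1 × 12, dropout 0.2, ≤25 epochs)
is the configuration used for the desk-scale synthetic studies, where the
full-size net only adds runtime and overfitting on minutes of data.

The network and its backpropagation-through-time are implemented directly on
numpy; gradients are verified against central-difference numerical gradients
in the test suite (relative error < 1e-4).  All stochastic elements
(initialisation, batch order, dropout masks, splits) derive from explicit
seeds; identical seeds give bit-identical training logs.

At inference the window slides sample by sample over a syllable segment
padded with 100 ms of context per side.  An even window length (40) over L
core samples would admit L+1 windows; the last is dropped (equivalently:
pad 20 left / 19 right) so that the decoder emits **exactly one output per
core sample** — the equal-length contract asserted for segment lengths 37,
40, 80 and 200.  Edge padding at session boundaries replicates the edge
value rather than inserting zeros, which would be extreme values after
z-scoring.  A syllable's predicted class is the majority vote over
per-sample argmaxes, ties broken by the summed score of the tied classes;
per-timepoint accuracy is logged alongside.

## Evaluation design

For each repeat, whole sessions are randomly assigned to train or test
(default 0.8 train), eliminating temporal leakage; the channel order fed to
the decoder is re-permuted per repeat.  Repeat seeds are derived
deterministically from the top-level seed, so two evaluations sharing a seed
share their split sequence — band comparisons and pair-vs-alone contrasts
are paired designs (asserted via split hashes).  The train fraction default
of 0.8 is the conventional ≈4:1 split; it is config-exposed, not asserted.

The cortical+subcortical pair analysis takes **one** channel per side.  The
channel within a region is selected by syllable-level validation accuracy on
one held-out *training* session (policy `best-val`; `random` is also
implemented), so the test set never influences selection.  The improvement
ratio is `(acc_pair − acc_cortical_alone) / acc_cortical_alone`, computed
from the mean accuracies over shared splits (per-repeat ratios are also
reported).  If the cortical-alone accuracy is 0 the ratio is NaN.

Significance against chance uses a two-sided exact binomial test on correct
counts pooled over repeats.  Pooling re-uses test syllables across repeats,
so the binomial n overstates the effective sample size; p-values are
reported as calibrated diagnostics, not as inference about real brains.  In
the null-calibration test (24 task × region cells) cells are judged
family-wise with a Bonferroni-corrected level, i.e. the whole grid is
required to be consistent with chance at 95% family confidence.

One subtlety: 1/K chance assumes balanced classes, but a corpus drawn
uniformly over the 21 initials spreads unevenly over the 7 places (3/1/3/4/
4/3/3 initials each) and 8 manners, so a decoder that merely learns the
class prior can sit slightly above 1/K on place and manner even with zero
signal.  The short null-training schedule keeps this bias small; it is one
reason the null grid is judged family-wise rather than cell-by-cell.

## Synthetic data generator

Each session is per-channel Gaussian noise with PSD ∝ 1/f^α (default α = 1,
amplitude 20 µV sd) — the canonical background spectrum of intracranial
recordings.  Syllables (default: uniform over the 21-initial × 4-tone
inventory, ~22/min, 0.25–0.45 s, non-overlapping with 1 s session margins)
each add a Tukey-tapered sinusoidal burst at the target band's center
frequency to the targeted channels.  For an effect of size *e* on task with
classes k = 0..K−1, class k's burst envelope amplitude is (k+1)·e·σ, where σ
is that channel's baseline band-envelope sd; adjacent classes are thus
separated by *e* baseline-sd units of event-locked band amplitude, which is
what `verify_spectrum` measures back (slope of mean event-locked envelope
vs class, in σ units; tolerance ~20%).  The taper is normalized to unit
mean so the event-mean envelope stays on target.

Information is carried by envelope **amplitude**, matching the pipeline's
power/envelope features; phase codes would be invisible by construction.
Two effects aimed at the same contacts and band superpose with random
relative carrier phase and partially mask each other, so the default
scenario assigns effects within a region to disjoint contacts (place →
STG contact 1, manner → STG contact 2 and thalamus contact 1, tone →
thalamus contact 2, all in 70–150 Hz) — emulating distinct neural
populations under different contacts.  Each session draws its background,
events and burst phases from independent seeded substreams, so adding or
removing effects never perturbs the background; with effect size 0 the
recordings are bit-identical to pure background and every decoder must sit
at chance.

What the generator does **not** emulate: biophysical neural-mass dynamics,
epileptiform transients, line noise, electrode drift or cross-channel
correlation structure, coarticulation, or any acoustic waveform.  Passing
tests therefore validate the *machinery* — that the pipeline recovers
exactly the information that is present, where it is present, and nothing
when none is — not decoding performance on real brains.

## Study conditions (desk scale)

The default scenario is 6 sessions × 40 s, 2 contacts per region
(16 channels), effect size 3, evaluated with the desk-scale decoder at 20
session-wise repeats and a training-window stride of 4 (test-time stride is
always 1, preserving the equal-length contract).  These sizes were chosen
once as the smallest study at which the ordering claims (STG best for
place; thalamus ≥ STG for tone; STG+thalamus pair above STG alone with
positive improvement ratio; 70–150 Hz the best band) separate cleanly from
their nulls; the null-calibration study uses an even smaller grid
(5 sessions × 35 s, 1 contact/region).  Full-size patient studies would use
hours of recordings, the 3×100 decoder, stride 1 and ~1,000 repeats; the
repeat count and all sizes are config-exposed.

## Known limitations

* The "325.82" train/test ratio notation seen in print for this protocol is
  ambiguous; the conventional 0.8 train fraction is used and config-exposed.
* MSE-on-one-hot is kept (rather than cross-entropy) to match the stated
  protocol; argmax classification is unaffected but scores are not
  calibrated probabilities.
* The EDF writer is a minimal encoder (16-bit, 0.25 s records, whole-record
  session lengths); reading goes through mne and is cross-checked against
  the writer in tests.
* Pooled binomial tests overstate the effective n across repeats (see above).
* Single-patient-style data: no cross-subject machinery is provided.
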