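# Methods

## Observation units: events versus intervals

A recording carries a list of non-overlapping fluency events (label,
onset, offset), half-open in time (`[onset, offset)`, 0-based sample
indexing). The five classes have fixed ordinal indices 0–4 (fluent,
prolongation, PWR, WWR, block), used consistently in confusion
matrices, score matrices and class-weight vectors.

**Event scheme.** One segment per annotated event; the label is copied
verbatim.

**Interval scheme.** Candidate windows `[kL, (k+1)L)` for L ∈ {2, 3, 4}
s; the trailing remainder shorter than L is dropped (fixed-length
windows only). A window's label is decided by which events have
non-zero intersection with it (an event ending exactly at the window
start does not overlap):

- only fluent events → `FLUENT`;
- exactly one distinct disfluent class (fluent co-occurrence allowed) →
  that class; the whole window is marked stuttered even if most of it
  is fluent, which is precisely the under-sampling mechanism the
  toolkit measures;
- two or more distinct disfluent classes → dropped (`multiple`);
- no events → dropped (`silent`).

Drop reasons are recorded for audit. An `interlocutor` reason exists
for corpora with an interlocutor tier but is never emitted otherwise.

**Lookback windows** give linguistic features context around short
events. `BEFORE` ends the window at the event's end; `MIDDLE` centres
it on the event midpoint (total window length preserved). Windows are
clipped to the recording; when clipped, the longest available extent is
used. Lookbacks may span neighbouring events of other classes; this
cross-class contamination is allowed deliberately, since fixed
intervals contain it inherently and the two schemes should be
comparable.

## Features

**Classic acoustic (32 per frame).** 25 ms frames, 10 ms hop (15 ms
overlap), trailing partial frame dropped; inputs shorter than one
window are zero-padded to a single frame. Base features: zero-crossing
rate (fraction of adjacent sign changes), spectral entropy, log-energy,
and MFCCs 1–13 (pre-emphasis 0.97, Hamming window, 26-filter mel bank,
orthonormal DCT-II; c0 is dropped in favour of the explicit log-energy
column, giving 16 base features whose regression deltas — ±2 frames,
edge-replicated — complete the 32). Spectral entropy is computed from
the raw (unwindowed) periodogram coarse-grained into 16 equal-width
bands; a single frame's per-bin periodogram fluctuates so strongly that
even white noise would sit far below the flat-spectrum limit, whereas
band energies are stable and a flat spectrum approaches log2 16 bits.

**Latent embedding (1,024 per frame).** The embedder is an interface;
production use plugs in a pretrained network (a wav2vec 2.0 XLSR-53
adapter is provided, requiring optional heavy dependencies). All tests
use the built-in *synthetic* embedder: a fixed, seeded Gaussian random
projection of log-compressed frame spectra with a tanh squash. It
learns nothing and is deterministic; it exists to exercise the
1,024-dimensional pathway (reduction, scaling, training) end to end.

**Per-segment reduction.** Each segment's frames × d matrix is reduced
to one row: the first principal-component loading of the column-centred
matrix — the unit-norm feature-space direction of dominant
frame-to-frame covariation, sign-fixed so its largest-magnitude element
is positive. Bursty classes put their weight on energy-linked columns,
sustained tonal classes on spectral-shape columns, so the loading
carries class-relevant temporal structure. Single-frame segments have
no covariation and return the raw frame values.

**Linguistic (80 per segment).** The lookback window's reference tokens
are decoded three times by the ASR (chunks with text, timestamps,
transcription and no-speech probabilities; chunks are assigned to the
window when their midpoint falls inside it). From each decoding, 16
base values: five orthographic repetition counts — sequential word
uni-/bigram repetitions (occurrence-counted: positions where the n-gram
repeats immediately), non-sequential uni-/bigram repetitions
(type-counted: distinct n-grams occurring ≥ 2 times anywhere), and a
character-level segmental scan on the lowercased, space-stripped string
(n-gram length from len−1 down to 3; the first length > 3 with a
repetition returns its count immediately, otherwise the count at n = 3;
the 3-gram floor avoids flagging ordinary repeated syllables and
inflectional morphemes, and the value is the count at the terminating
length, for consistency with the other count features) — two
probability means, and nine chunk-duration statistics (sum, max, min,
mean, median, population SD, quartiles by linear interpolation, IQR).
Five aggregators over the three decodings (sum, mean, max, min,
population SD) give (5+2+9) × 5 = 80 values. Population rather than
sample SD is used throughout the aggregators; with three decodings the
distinction is a constant factor and the choice is recorded here once.

With the default embedder the joined table has 32 + 1,024 + 80 = 1,136
columns, identical in order across schemes — the precondition for input
switching.

**Scaling.** Per-column z-scoring with mean/SD fitted on the
train+validation folds only; test rows are transformed with the fitted
parameters. Fitting on test rows raises. Zero-variance columns are
centred and flagged.

## Classifiers

**Gaussian-kernel SVM.** C = 1.15; kernel width γ = 1/(n · X_var) with
n = 5 classes and X_var the scalar variance over all entries of the
training matrix (≈ 0.2 after z-scoring). A `gamma_rule="n_features"`
switch substitutes the column count for n (the common library
heuristic). Training applies inverse-frequency class weights
ω_i = N/(n · N_i), which satisfy Σ ω_i N_i = N; absent classes get
weight 0 with a warning. Per-class scores for AUC come from
pairwise-coupling probability estimates.

**MLP.** Five 512-unit hidden layers, each layer-normalised with ReLU
and 10 % inverted dropout, softmax output; class-weighted categorical
cross-entropy, Adam, 15 epochs, batch size 32. Implemented directly on
numpy: a single `random_state` drives initialisation, shuffling and
dropout masks, so training is bit-reproducible. Class weights are
applied to both models by default and are switchable. The architecture
is fully config-driven; the defaults are a deliberate choice among
several plausible depth/width readings of its description.

## Evaluation

Unweighted (macro) one-vs-rest AUC-ROC over classes present in the test
truth is the headline metric; absent classes are excluded with a
warning, and a single-class truth is an error. Classification reports
carry per-class precision/recall/F1 (%), supports, accuracy, macro and
support-weighted averages and the 5×5 confusion matrix; undefined
precision (a class never predicted) is reported as 0 and flagged.

WER uses a minimal-edit alignment with unit costs. The S/D/I split of
an optimal alignment is not unique, so the backtrace is canonicalised
(prefer match/substitute, then delete, then insert at equal cost); the
total edit count is alignment-invariant. WER = (S+D+I)/N may exceed
100 %. Pooled WER sums component counts across files before dividing.

## Synthetic corpus

The generator emulates annotated stuttered monologue at the level the
pipeline consumes: per-speaker recordings built by concatenating events
sampled i.i.d. from the class probabilities (default 82.48 / 2.76 /
3.27 / 1.20 / 10.29 % for fluent / prolongation / PWR / WWR / block)
with 20–80 ms unlabelled silent gaps. Event lengths are truncated
normals (floor 30 ms) with per-class moments of 222±208, 521±311,
763±418, 237±155 and 578±467 ms. Each speaker has a pitch drawn from
90–300 Hz, a private pseudo-word vocabulary, and deterministic
per-speaker randomness; corpora are byte-identical for a fixed seed.

Waveform recipes are deliberately non-speech-like, with one distinct
temporal *and* spectral signature per class: an amplitude-modulated
harmonic burst (fluent), a sustained vibrato tone (prolongation), a
train of 2–4 narrowband noise bursts (PWR), two bright harmonic
renditions (WWR), and ≥ 50 % leading silence followed by an abrupt
broadband burst (block). Signature carriers are anchored to
class-specific bands with only a mild coupling to speaker pitch. This
is intentional: the kernel width γ = 1/(5·X_var) on z-scored
1,056-column rows leaves the RBF kernel useful only when within-class
scatter is small relative to between-class separation, and a generator
whose class spectra moved wholesale with speaker pitch would measure
speaker variation, not segmentation effects, under hard speaker splits.
Speaker individuality therefore lives in the carrier offset, envelopes,
amplitudes, noise and vocabulary.

Transcripts mirror the audio: one token per fluent syllable, duplicated
tokens for WWR, fragment tokens before the word for PWR, an elongated
initial character run for prolongations. The mock ASR corrupts the
window's reference tokens with deletion-dominated errors (default:
repeated tokens deleted with probability 0.5, any token with 0.05 —
mimicking how recognisers collapse stuttered repetitions), splits
survivors into 1–3 chunks with jittered boundaries spanning the window,
and draws chunk probabilities from Beta(8,2)/Beta(2,8).

**What passing tests do and do not show.** The synthetic corpus
demonstrates that the machinery is correct — segmentation rules, the
feature contracts, leakage-guarded scaling, training, evaluation, the
fluent-under-sampling arithmetic, and the *direction* of the
event-versus-interval effect under conditions where classes are
acoustically separable. It does not show that the feature set separates
real stuttered speech, nor predict absolute AUC values on clinical
recordings, which depend on pretrained embeddings and real acoustic
variability.

## Problem sizes and numerical choices

The default comparison corpus is 12 speakers × 50 s (~10 min audio,
≈ 1,500 events, ≈ 130 valid 3-s intervals) under a hard 7/2/3 speaker
split — large enough for stable directional results while keeping a
full run around twenty seconds. Temporal overlap checks use half-open
intervals with a 1e-9 tolerance; percentages are rounded only at
presentation; χ² uses exact counts, no continuity correction. Seeds
propagate explicitly: corpus and split seeds are user-supplied, and
per-segment mock-ASR seeds derive from the experiment seed XOR a CRC of
the segment id (kept below 2³¹).

## Known limitations

- The synthetic embedder is a random projection, not a learned
  representation; it preserves spectral geometry but models nothing.
- The mock ASR corrupts reference tokens; it does not synthesise
  plausible mis-recognitions (no substitutions by phonetic similarity).
- TextGrid support covers interval tiers with the standard long/short
  layouts only.
- Interval counts on short recordings are small; interval-side AUC
  estimates on the default corpus are correspondingly noisy (the
  event-side advantage is robust across seeds, the interval AUC value
  itself is not).
- The pretrained-model adapters (wav2vec 2.0, Whisper) are untested
  pass-throughs and require optional dependencies.
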