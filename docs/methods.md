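# Methods

## Problem and pipeline

The package analyses two-speaker clinic visits (a primary-care provider and a
patient) from a single-channel audio recording plus a diarized turn table
("who spoke when", exchanged as NIST RTTM). It predicts, per three-minute
*slice* of the visit, the level of four social signals — dominance,
interactiveness, engagement and warmth — for each speaker, on the 1–6 affect
scale used by the Roter Interaction Analysis System (RIAS) Global Affect
Rating. Predictions are aggregated into visit-level, visit-comparison and
population-level report data for provider-facing feedback dashboards.

The pipeline is deliberately content-free: no transcripts, no lexical
features. All evidence comes from *vocalics* — turn-taking dynamics and
prosodic/spectral properties of the voice.

## Slicing and labels

A slice is a successive 180 s window starting at time 0. A trailing partial
window is retained iff it is at least 60 s (one third of a slice) long;
shorter tails carry too little behaviour to score. Turns spanning a boundary
contribute their intersection to each neighbouring slice; all interval
arithmetic is half-open `[start, end)`.

Raw 1–6 affect ratings are sparse at the extremes, so they are clustered
into below-baseline (1–2), baseline (3) and above-baseline (4–6).
Below-baseline slices are so rare in clinic corpora that they cannot be
modelled; they are discarded before training and each classifier separates
*neutral* from *high*.

## Feature bank (178 per slice)

**Turn-based (26 = 13 × 2 roles).** Talk time (seconds and fraction of the
slice), turn count, mean/sd/max turn duration, interruptions initiated and
the rate per own turn, mean duration of the interrupting turn, pauses broken
by the role (count, mean, max) and solo-floor fraction. Every cross-role
overlap of at least 0.1 s is an interruption, attributed to the
later-starting speaker (exact ties go to the patient and are logged). A
silent gap of at least 0.3 s bounded by speech is a pause, attributed to the
speaker who breaks it. Both thresholds suppress diarizer jitter and are
config-exposed. Statistics over empty sets are 0, never missing, so the
vector length is constant. The published feature inventory gives the
category structure (turn statistics, interruptions including
post-interruption turn length, pauses) and the total of 26; the 13-per-role
list here is a concrete instantiation consistent with both.

**Speech-based (152 = 19 tracks × 4 statistics × 2 roles).** All of a
speaker's clipped turns in a slice are appended into one utterance (short
turns alone are too brief for stable spectral statistics). On 25 ms frames
with a 10 ms hop (Hann window): the first 13 MFCCs (26-filter mel bank,
orthonormal DCT-II of log mel energies), spectral centroid, 85%-energy
spectral rolloff, autocorrelation pitch, RMS energy, zero-crossing rate (per
second) and intensity `10·log10(mean square + 1e-10)` dB. Each track is
summarized by mean, sd, min, max — the unique factorization of the
152-feature total given the 19 named tracks. Pitch statistics use voiced
frames only (zero if none).

Pitch: biased autocorrelation, F0 search 75–500 Hz, voicing when the
normalized peak is ≥ 0.3, parabolic peak interpolation with a local
unbiasing correction (the biased estimator's `(1 − lag/N)` taper otherwise
skews the vertex). Synthetic tones recover F0 well within 2% across the
band.

A speaker with under 0.5 s of speech in a slice gets zeroed speech features
and a low-speech flag (not counted among the 178). Overlapped speech in the
single-channel signal is included in both speakers' concatenations — the
mixture is the best available stand-in for either voice there.

Audio is canonicalized to 16 kHz mono float; canonicalization happens per
180 s window, which makes chunked (slice-at-a-time, no audio retention) and
whole-file extraction identical by construction.

## Classifiers

Per target (4 signals × 2 roles): features are joined to labels, low rows
discarded, and six families are available — logistic regression, decision
tree, linear SVM (globally interpretable); RBF SVM, random forest, gradient
boosted trees (locally interpretable). Training folds are balanced with
SMOTE (k = min(5, minority − 1) nearest-neighbour interpolation; a singleton
minority is duplicated with a warning). Inputs are z-scored for the linear
and kernel families (scaler fit on training data only); trees see raw
features. Hyperparameters are chosen by an inner stratified 3-fold grid
search on macro-F1, strictly inside the training portion. Default grids: LR
C ∈ {0.01, 0.1, 1, 10}; DTC depth ∈ {3, 5, 8, ∞}; SVM C ∈ {0.1, 1, 10} (RBF
γ ∈ {scale, 0.01, 0.1}); RF/GBDT trees ∈ {100, 300}, depth ∈ {3, 8}.

Evaluation is leave-one-provider-out: the held-out provider's slices never
touch scaling, SMOTE or the grid search of that fold. Macro-F1 (mean of the
two per-class F1s) is the selection metric for its robustness to class
imbalance; exact ties between families break toward the globally
interpretable ones (DTC > LR > linear SVM). Folds whose training labels
collapse to one class are skipped with a warning and excluded from means.

Interpretability export: trees emit their node conditions and leaf classes
as text plus impurity importances; linear models rank features by
|coefficient| with sign; ensembles fall back to impurity importances tagged
"local".

## Score expansion and reports

Predicted classes re-expand to the RIAS scale as low → 1.5, neutral → 3,
high → 5. Since low is discarded before training, emitted predictions only
take {3, 5}; the 1.5 branch is kept because the dashboard mapping defines
it. A role's *overall affect* for a visit is the mean of its four
per-signal means of expanded slice scores (the slice-mean convention; an
alternative — re-expanding the majority class — is not used). Desired
directions: provider dominance low, everything else high; a flag is set when
a visit mean deviates from the desired side of 3. Population summaries
compare visits matching a gender/race/age-range filter (age inclusive
`[min, max]`) against the complement, with no time-series averaging, since
visits progress differently. Reports serialize as versioned JSON
(`visit_report.v1`, `comparison.v1`, `population.v1`).

## Synthetic dyad generator

Real clinic recordings of this kind are private, so validation runs on
simulated dyads. Per slice, latent classes for the eight targets are drawn
from configurable marginals and shift a base dynamics profile, planting the
cues the clinical-communication literature associates with each signal:
dominance-high raises that speaker's talk share (+0.12), interruption
probability (+0.08) and intensity (+4 dB); warmth-high lowers pitch
variability (−10 Hz sd) and raises response latency (+0.4 s);
interactiveness-high shortens turns (−1.6 s) and latencies (−0.3 s), giving
more, briefer turns and fewer pauses; engagement-high shortens latencies
(−0.45 s, i.e. the response time more than halves) and raises the
alternation probability (+0.15). Shifts scale
linearly with `effect_strength` (0 = null model), a low class applies the
opposite shift, conflicts add, and results are clamped to sensible ranges.
Shift magnitudes were calibrated once so that a one-step class change is a
clearly visible behavioural change (standardized feature effects ≥ 0.8),
which the generator's recovery contract requires.

Turns follow an alternating-renewal process (exponential turn lengths with
per-role means rescaled to the target provider share; gamma response-latency
gaps; occasional interruptions starting 0.2–1.5 s before the current turn
ends). Audio renders each turn as a three-harmonic complex with per-turn F0
drawn from the role's pitch distribution (constant within a turn), 10 ms
raised-cosine edges, role-specific amplitude, over a −30 dB white-noise
floor. Turn times are quantized to milliseconds so the WAV/RTTM round trip
is exact. Base profile: provider share 0.55, mean turns 4 s / 3 s,
interruption probability 0.06, latency 0.8 s, alternation 0.8, F0 120 ± 15
Hz (provider) and 210 ± 20 Hz (patient). Scenario defaults mirror a
realistic corpus: 10 providers × 10 visits of 30 minutes.

What the simulator does *not* emulate: lexical content, natural speech
spectra (formants, consonants), channel/room acoustics, diarization errors,
coder disagreement, and correlation between signals beyond what the additive
shifts induce. Passing recovery tests therefore show the pipeline can
detect the planted vocalic cues end-to-end — not that real clinical affect
is equally separable.

## Validation problem sizes

The test suite validates at deliberately modest scales chosen for quick
iteration: a 3-provider × 2-visit × 2-slice corpus for structural and
round-trip checks; 8 providers × 6 visits × 10 slices (480 slices) at
effect strength 0 for null calibration (chance band 0.35–0.65 macro-F1,
set from the fold-to-fold dispersion of chance-level macro-F1 at this n);
8 providers × 3 visits × 4 slices per signal (one signal varied at a time,
50/50 neutral/high) for recovery, where the best of the two globally
interpretable families evaluated (LR, DTC) must reach macro-F1 ≥ 0.8 and
rank a planted cue in its top-5 export. Interval detectors are checked
against an independent 1 ms grid-scan oracle on random turn configurations.

## Numerical and degenerate-input choices

* Same-role diarizer segments separated by < 0.1 s are merged on read.
* A turn may overrun the audio end by ≤ 0.5 s (clipped); more is an error.
* Empty slices yield an all-zero 178-vector with both low-speech flags set;
  models accept all-zero rows and emit a valid class.
* `interruption_rate` divides by max(1, own turn count).
* sd uses the population convention (ddof 0), 0 for fewer than two items.
* Determinism: every stochastic step (SMOTE, grid-search folds, simulator)
  derives from an explicit integer seed; repeated runs are bit-identical.

## Known limitations

* The 13-per-role turn-feature instantiation and the {mean, sd, min, max}
  summary set are reconstructions constrained by the published counts
  (26/152/178), not a published inventory.
* Whether hyperparameter selection in the reference system sat inside or
  across evaluation folds is unknown; here it is strictly inside folds.
* All 178 features feed every target's model; no per-signal subsets.
* Interruptions are plain overlaps; no cooperative/intrusive distinction.
* Overlapped single-channel speech is not source-separated.
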