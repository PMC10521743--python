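# Methods

## The model

`cyclebeat` embeds short ECG subsequences on cyclic latent trajectories.
A trajectory in ℝᵈ rides the unit circle in its first two coordinates and
is constant in the remaining d−2:

ℓ(t) = cos(θ(t))·e₁ + sin(θ(t))·e₂ + Σⱼ₌₃..d bⱼ·eⱼ

with phase θ(t) = 2πf(t−τ) for the full parameterisation, 2πft for the
pace parameterisation (inputs aligned to start at an R-peak, so the shift
τ is structurally zero), and 2πt for the shape parameterisation (inputs
are single heartbeats time-normalised to one unit of phase). A decoder
f_D: ℝᵈ → ℝ maps trajectory points to voltages; reconstruction is
ŝ(t) = f_D(ℓ(t)) on any time grid, which is what makes variable-length
inputs unproblematic. The modelling assumptions are therefore: (i) within
one slice the cycle frequency is constant — which is exactly why long
recordings are sliced before encoding; (ii) morphology is constant along
a slice and lives entirely in the shape coefficients b; (iii) one
heartbeat spans exactly one cycle.

Time is in seconds throughout, so f is in Hz and heart rate is 60·f bpm;
sample k of a record occurs at k/fs. Stored embeddings carry d, d−1 and
d−2 numbers for the full/pace/shape parameterisations; the trajectory
always evolves in d dimensions.

## Slicing

Three strategies convert a record into encoder inputs: random slices with
durations uniform in [1.5, 4.0] s starting at uniformly random samples;
the same duration law anchored at detected R-peaks; and heartbeat
extraction, one slice per consecutive R-peak pair on the half-open
interval [r_k, r_{k+1}) so that beats tile the signal without overlap.
The half-open convention pins endpoint ownership (each beat owns its
starting R); beats with an RR interval outside [0.3, 2.0] s are dropped as
detector glitches. Random durations use a uniform law — the simplest law
consistent with a stated range. Slices are materialised once per seed;
all slicing is a pure function of (record, R-peaks, seed).

## R-peak detection

The Pan–Tompkins chain with its classic constants: 5–15 Hz band-pass
(realised as a zero-phase forward-backward biquad), five-point
derivative, squaring, 150 ms moving-window integration, adaptive
dual-threshold peak picking with a 200 ms refractory period and a
search-back pass at 1.66× the running RR average. Two implementation
choices keep the output deterministic and well-anchored: thresholds are
warmed up from the first 2 s of the integrated signal (0.25·max as the
signal level, 0.5·mean as the noise level), and the integration window is
centred, so detections need no group-delay compensation before the final
refinement to the raw-signal argmax within ±50 ms. Detections are
invariant to constant offsets (the mean is removed first). Records
shorter than 2 s or sampled below 100 Hz are rejected; a record with no
QRS-like activity yields an empty peak list, not an error — noise-only
records are expected inputs whose spurious detections downstream stages
must tolerate.

## Synthetic data

The generator emulates single-lead mobile recordings: 300 Hz sampling, a
few-mV range, and four rhythm classes. Each beat is a sum of five
Gaussian bumps (P, Q, R, S, T) with amplitudes (0.15, −0.1, 1.0, −0.2,
0.3) mV placed at fixed phase fractions of the RR interval (0.88, 0.965,
0, 0.035, 0.30) with widths that are fixed fractions of the RR — so
time-normalising a beat to unit phase makes morphology
duration-invariant, the premise of the shape parameterisation. RR
intervals are i.i.d. log-normal with configurable mean heart rate and
coefficient of variation, clipped to [0.3, 2.0] s. Class construction:
normal sinus rhythm draws CV in [0.01, 0.05] with P-waves; AF draws CV in
[0.15, 0.30] with the P amplitude set to 0 (the two classic AF
signatures); the "other rhythm" class is a bigeminy-like alternating
short/long RR pattern with P-waves; the noisy class is white noise plus
baseline wander with no beats at all. A 0.05 mV sinusoid at 0.3 Hz of
baseline wander and white Gaussian noise (default sd 0.02 mV) are added
to all non-noise records. Every record is reproducible from its seed, and
dataset-level seeds derive deterministically from a master seed.

What the generator does *not* emulate: muscle artefact and electrode
noise with realistic spectra, ectopic beats, morphology drift within a
record, fibrillatory f-waves (AF is approximated by P-wave *absence*),
QT/RR adaptation beyond simple scaling, and inter-patient morphology
variation. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it separates classes whose differences are
the ones the generator encodes — not clinical-grade performance on real
recordings.

## Encoder and decoder

No deep-learning framework is used; the networks run on a small in-repo
reverse-mode autodiff core and are deliberately compact enough to train
on one CPU in seconds. The encoder is an MLP (default hidden widths
64–64, tanh) over the slice resampled to a fixed grid: for the full/pace
parameterisations a 64-point grid spanning the `max_len_s` horizon
(default 2.0 s for heartbeats, 4.0 s for slices), zero beyond the slice
end, with the slice duration appended as an explicit input; for the shape
parameterisation a 64-point grid over cycle phase [0, 1), which makes the
embedding of a beat and of the same beat uniformly time-stretched
identical by construction. Parameter heads: f = softplus(·) + 0.1 Hz
(strict positivity with a floor), τ unconstrained, b linear. The decoder
f_D is an MLP d → 64 → 64 → 1 with tanh hidden units and a linear output.

The loss is the mean over slices of the per-slice mean squared error on
48 points per slice evenly spread over its samples — per-slice averaging
keeps short beats from being down-weighted. Optimisation is Adam
(lr 10⁻³, batch 64); a fixed seed controls initialisation and shuffling,
so fits are bit-reproducible single-threaded. No input filtering or
normalisation is applied anywhere.

### Identifiability of the pace, and the cycle-closure term

On single-heartbeat inputs the reconstruction error alone does not
identify f. A beat of duration T traced with any f = c/T, c ∈ (0, 1],
covers an arc of angle 2πc; the decoder can place the morphology along
that arc and achieve the same loss for every c — empirically the learnt f
correlates almost perfectly with 1/T while the scale c drifts freely.
The missing constraint is the one heartbeat extraction guarantees: a beat
spans *exactly one* cycle, so the trajectory must close over it,
ℓ(0) = ℓ(T). Training therefore adds a closure penalty
2 − 2cos(2πfT), weighted 0.25 by default, applied only to heartbeat
slices (for random or R-peak-aligned slices the slice does not span a
whole number of cycles and the term would be wrong; there, repetition
across multiple beats within the slice is what constrains f). With the
closure term the recovered median heart rate lands within ~1–2% of the
generated rate. Note that a *constant*-rate beat set leaves the closure
constraint satisfiable at any integer multiple per beat duration;
training sets with a modest spread of beat durations (CV ≈ 0.1) are used
for rate-recovery experiments so the pace must track 1/T per beat.

## Aggregation

Mean aggregation averages the flattened stored-parameter vectors
coordinate-wise — averaging f, τ and b jointly, exactly as the embedding
is stored. It is permutation-invariant and discards order and
variability information by design; that loss of information is the
motivation for the alternative. The LSTM aggregator (bidirectional by
default, 32 hidden units per direction, sequences longer than 512
uniformly subsampled) reads the embeddings in temporal order and outputs
the concatenated final hidden states; since no aggregation-only objective
exists it is trained end-to-end with the softmax classifier head.

## Classification and evaluation

The classifier head is a fully connected softmax network (hidden layers
64–32), provided by scikit-learn's MLPClassifier, over record embeddings
(4 rhythm classes) or 30-beat window embeddings (binary). Binary
AF-vs-non-AF metrics — sensitivity, specificity, PPV, F1 (the harmonic
mean of PPV and sensitivity), accuracy — are computed at a 0.5 decision
threshold; AUC is the rank statistic. For a multi-class head, the AF
probability is its AF softmax component. Cross-validation is stratified
10-fold (stratification guards against folds that lack the 3%-scale noisy
class), each fold tested once, hyperparameters fixed across folds,
reported as mean ± std over folds. AUC on single-class labels is
reported as missing, never as zero.

Window labelling over 30-beat sliding windows: *majority* (AF iff ≥ 15 of
30 beats are AF), *middle* (the flag of beat 15, 0-based — an even window
has no true centre, so the index is exposed as an argument), *threshold*
(AF iff the AF fraction reaches p, default 0.8, non-strict so that 24/30
meets p = 0.8 exactly; a strict flag is provided since the convention at
the boundary is genuinely ambiguous).

The noise score of a record is the mean per-heartbeat reconstruction
RMSE under a model trained on clean beats; being a mean it is
duration-invariant, and records with no extractable beats rank most
anomalous (they receive the dataset's maximum observed score). Heart-rate
timelines read 60·f per beat at the beat's midpoint time; the shape
parameterisation stores no f and is rejected for this use.

## Problem sizes and numerical choices

Experiments in the test suite and the acceptance script run at desk
scale, chosen so the whole suite completes in a couple of minutes on one
CPU: detector accuracy on 20 one-minute records; pace recovery with
d = 16 on 2,000 beats for 30 epochs; noise detection on 50 clean vs 50
noise-only half-minute records; end-to-end AF classification on 200
half-minute records (≈ 9,000 beats, 20 epochs) under 10-fold CV. Ties
and degenerate inputs are pinned throughout: sample indices are 0-based;
τ is stored unwrapped (the parameterisation is phase-periodic, so any
canonicalisation would be arbitrary) and compared modulo the period where
needed; WFDB analog conversion uses the header gain/baseline and treats
missing gain as raw-mV integers so toy fixtures degrade gracefully.

## Known limitations

The encoder sees a fixed 64-point resampled grid, which low-pass filters
very sharp QRS detail at long horizons; reconstruction error is dominated
by the R spike. Training the full parameterisation on random slices is
supported but weakly identified (both τ and f must be inferred jointly).
The LSTM aggregator needs enough labelled records to beat mean
aggregation. The generator's AF lacks f-waves, so shape-based AF evidence
reduces to P-wave absence. None of the reported numbers are estimates of
performance on clinical data.
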