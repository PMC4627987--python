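# Methods

This note documents the models implemented in `esoconvert`, the defaults
chosen where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate.

## Front-end

Static features are 13-dimensional: cepstra c1–c12 from a 26-channel
triangular Mel filterbank applied to the power spectrum of pre-emphasized
(coefficient 0.97), 25 ms Hamming-windowed frames shifted by 10 ms, plus
the frame log energy normalized over the utterance.  Conventions the task
leaves open are fixed as follows and exposed on `FrameConfig`:

* FFT size 512, filterbank edges 0–8000 Hz — standard for 16 kHz audio.
* Pre-emphasis boundary: the first sample passes through unchanged
  (HTK convention).
* Energy normalization: subtraction of the per-utterance maximum log
  energy, so max E\* = 0 and a global gain change cancels exactly; a
  z-score variant is selectable.  Frame energy is computed on the
  pre-emphasized, un-windowed frame.
* No cepstral liftering by default (configurable).
* Frame t covers samples [160t, 160t + 400); the frame count is
  ⌊(L − 400)/160⌋ + 1.

Delta coefficients use the regression ΔC(t) = Σᵢ i(C_{t+i} − C_{t−i}) /
(2Σᵢ i²) with a five-frame window (N=2) and replicated edge frames, so the
output has the input's length.  Sequences shorter than the window are
processed on the replicated sequence with a warning rather than rejected —
short utterances still produce stacked features.  Orders 2 and 3 of
stacking give 39- and 52-dim vectors; higher orders re-apply the same
regression to the previous order's output.

## Alignment

Length normalization is a uniform speed change (polyphase resampling, FFT
resampling when the rational factor is extreme); pitch scales with tempo,
which is acceptable because DTW absorbs residual misalignment and no
waveform is ever resynthesized.  DTW uses steps (1,1), (1,0), (0,1) with
unit weights, Euclidean distance over all 13 statics (energy included — it
carries alignment information), no global band by default, and
deterministic tie-breaking (diagonal, then (0,1)).  The cost is verified
against exhaustive monotone-path enumeration for short sequences.

## Joint-density GMM conversion

The mixture over joint vectors is estimated by direct statistical
computation from a hard vector quantization rather than EM: k-means
(seeded, single init) provides initial classes; per class, the weight is
the class frequency, the mean the sample mean, and the covariance the full
26×26 joint sample covariance (population 1/N convention), which yields
all four blocks Σˣˣ, Σʸʸ, Σˣʸ, Σʸˣ at once.  Hard re-assignment to the
nearest class mean alternates with re-estimation until the assignment is
stable (≤ 20 passes).  Empty classes are repaired by re-seeding from the
point farthest from its centroid, so all G classes stay live.

Numerical choices:

* A variance floor (10⁻⁴ of the global per-dimension variance) is added to
  a class's joint diagonal **only** when its source covariance block is
  not safely positive definite.  Unconditional flooring would bias the
  per-class regressions and break the exact closed-form limits the module
  guarantees: with G = 1 the conversion function *is* multivariate
  least-squares regression, and an identity-corpus training must return
  the identity map to near machine precision.
* Posteriors are computed in the log domain via Cholesky factorizations of
  the Σˣˣ blocks.

The outer training loop aligns raw source to target statics in iteration
1; from iteration 2 the DTW runs between *converted* statics F(x) and y
(converted energy included in the distance), pairing the original x frames
through the refined path.  The loop stops after a fixed number of
iterations (default 3) or when the relative MSE improvement falls below
10⁻⁴, and the iteration with the lowest aligned MSE is returned.
Conversion applies to 13-dim statics only; derivatives are computed after
conversion.

## HLDA

The model: a nonsingular Θ (n×n) such that the first p projected
dimensions carry class-dependent diagonal variances and the remaining
n−p a single shared diagonal variance with the global mean.  With ML
variances substituted the objective is

Q(Θ) = N log|Θ| − ½ Σ_{j≤p} Σ_c N_c log(θⱼ W_c θⱼᵀ) − ½ N Σ_{j>p} log(θⱼ T θⱼᵀ) + const,

with W_c the class covariances and T the total covariance.  Rows are
updated in closed form through the cofactor identity
θⱼ ∝ cⱼ Gⱼ⁻¹ (Gⱼ the variance-weighted scatter for row j), which never
decreases Q; the per-sweep objective is asserted non-decreasing in tests.
Initialization is the LDA generalized eigenbasis (eigenvalue-descending,
index tie-break); covariances are diagonally loaded by 10⁻⁶·trace/n before
inversion; iteration stops at 100 sweeps or relative change < 10⁻⁶.
Classes are the phone labels of the frames (36 in the full inventory), not
HMM states.  In the end-to-end experiment the HLDA statistics are gathered
from the features actually fed to the recognizer (converted features when
conversion is on, raw otherwise); both paths go through the same public
API, so either choice can be scripted.

## Recognizer

Each phone, silence included, is a 5-state left-to-right HMM with three
emitting states and diagonal-covariance GMM emissions.  Flat start ties
every state to the global mean/variance; training is embedded Baum-Welch
over phone-concatenated utterance models in the log domain (banded
forward/backward over the chain of emitting states), with a variance floor
of 10⁻² of the global per-dimension variance.  Mixtures grow by binary
splitting (means perturbed ±0.2σ, weights halved, re-estimation between
rounds), 1→2→4→8→16.  Utterances too short to traverse their transcription
are skipped with a warning.

The bigram LM uses add-k smoothing (default k = 1) over the phone
inventory with a separate sentence-start distribution; sentence end is
left unmodeled, so the decoder may terminate in any phone's exit state.
Decoding is token-passing Viterbi over the phone loop; cross-phone arcs
carry lm_scale · log P(next|prev) + insertion penalty.  Scoring aligns
hypothesis to reference with unit substitution/deletion/insertion costs
(HTK's 10/7/7 weighting available), with a backtrace preferring
match/substitution on ties.

## Synthetic study conditions

The generator emulates the data regime of a single-patient clinical study:
a 36-phone SAMPA speaker model (one diagonal Gaussian per phone in the
13-dim static space, unit variances, minimum pairwise mean separation 4σ,
mean phone duration 8 frames, durations 3 + Poisson), 50 parallel
sentences for conversion training, and a 100/20 train/test recognition
corpus — all on the pathological side of the distortion.

`DistortionSpec.default` is the fixed "pathological" condition: affine map
0.85·I + 0.08·N(0,1) with offset, additive noise at 2σ of the within-phone
spread, per-phone-instance jitter 0.5σ, and durations stretched by a
per-utterance factor in [1.2, 1.6].  The severity was calibrated once so
that the *no-conversion baseline* lands in the low-intelligibility regime
(phone accuracy around 40–70 % depending on seed, centred near 60 %)
characteristic of esophageal speech, leaving the conversion stage a
realistic amount of distortion to undo.  The decoder defaults follow the
same logic: lm_scale = 5 and insertion penalty = −10, because with 39-dim
per-frame acoustic scores an unscaled bigram is numerically irrelevant,
and phone decoding without an insertion control degenerates into
segment-chopping (insertion rates near 50 % of N).

What passing the end-to-end comparison shows: on features whose corruption
matches the generator's model class (affine + noise + warp), conversion
denoising plus HLDA discriminant reduction improves phone accuracy over
the raw baseline.  What it does not show: robustness to real esophageal
phenomena outside that model class — non-stationary excitation artifacts,
phone-dependent spectral distortions, speaker variability, or channel
effects.  The generator also produces features directly by default; the
optional pulse-train waveform mode exercises the MFCC front-end but is not
an acoustic model of pathological speech.

The default end-to-end configuration grows emissions to 4 Gaussians per
state and uses 4 Baum-Welch iterations per stage; this keeps a full
experiment around ten seconds while leaving the 16-Gaussian configuration
one config field away.

## Known limitations

* No waveform synthesis, F0/excitation conversion, or trajectory/global-
  variance conversion; the converted features exist only for recognition.
* No triphones, lattices, or LMs beyond the bigram.
* Single-speaker design throughout: the conversion function and the
  recognizer are trained for one source/target pair.
* The length normalizer changes pitch with tempo; a tempo-preserving mode
  is out of scope.
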