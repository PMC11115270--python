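# Methods

## The decoding problem

Three oddball tone sequences are interleaved at a fixed 180 ms stimulus
onset asynchrony (SOA), so each stream cycles every 540 ms and each
stream's cycle tone is a rare deviant with probability 0.1.  A listener
attending one stream produces a parietal P3b (and an enhanced
frontocentral mismatch negativity, MMN) to that stream's deviants; deviants
of unattended streams may evoke only a frontal, exogenous P3a.  Decoding
which stream is attended therefore reduces to three binary
classifications, one per stream, each using only that stream's deviant
epochs.

## Synthetic data generator

The generator exists so every downstream stage can be tested end-to-end
without recordings.  It emulates:

- **Sequences** — cyclic stream interleaving at SOA 0.18 s; independent
  Bernoulli(0.1) deviants per stream per cycle.  An optional
  minimum-separation rule (≥ k standards between deviants within a stream,
  default off) is provided; with it off, per-stream deviant counts are
  exactly binomial, which the test suite verifies by goodness of fit.
- **Evoked components** — Gaussian temporal pulses with fixed scalp maps
  (Gaussian bumps over 2-D projected standard 10-10 electrode positions):
  P3b +5 µV at 300 ms (FWHM 150 ms) centred on Pz; P3a +2 µV at 250 ms on
  Fz; MMN −2 µV at 150 ms on FCz; N1 −1 µV at 100 ms on Cz, on every tone.
  Pulses are truncated at ±4σ so a noiseless epoch equals the template sum
  exactly.  Per-trial latency jitter is Gaussian with SD 20 ms by default
  (0 gives perfectly time-locked trials).
- **Background noise** — 1/f ("pink") sources mixed through a spatial
  mixing matrix, scaled to 10 µV RMS per channel.  The mixing matrix is
  drawn **once per session** and shared across runs: the background spatial
  covariance is a property of the head and montage, and redrawing it per
  run would let covariance features identify the run — and, since the
  attended stream is constant within a run, leak the label.  The ERP
  signal-to-noise ratio is controlled through template amplitudes only.
- **Blink artifacts** — Poisson-scheduled (default 0.1 /s, a plausible
  resting blink rate; 0 disables) biphasic pulses of 0.5–1 s whose EOG peak
  is drawn from [600, 1200] µV with a frontal-EEG projection at 20 % of the
  EOG amplitude, guaranteeing that both amplitude-rejection rules fire.
- **Sessions** — 2 blocks × 3 runs of 300 s, attending streams 1, 2, 3 in
  order within each block.  All run-level seeds derive from one session
  seed.

What the generator does **not** model: tone acoustics and the perceptual
segregation process itself, inter-subject variability beyond the SNR and
jitter knobs, non-stationary noise, alpha rhythms, and non-blink artifacts
(muscle, drift).  Passing tests on this generator therefore demonstrate
correctness of the *pipeline* under the stated statistical assumptions,
not expected accuracy on real recordings — the synthetic signal-to-noise
ratio makes near-ceiling accuracies normal, whereas real subjects in this
paradigm span roughly 0.6–0.9.

The time until every stream has shown at least one deviant (the earliest
moment a 3-way selection is decidable) is exposed as an empirical
distribution (`classification_intervals`); under the independent-Bernoulli
model its mean is ≈ 9.3 s.  No particular expected value is assumed, since
the interval distribution depends on sequencing constraints the plain
Bernoulli model does not impose.

## Preprocessing

Two paths run independently from the raw recording: 0.1–40 Hz for ERP
averaging and 1–40 Hz for classification, each a 2nd-order Butterworth
applied forward and backward (zero net phase; 24 dB/octave effective
slope).  Edge transients are suppressed by reflection padding of at least
three time constants of the low cut.  Epochs span −100 to +500 ms around
tone onset — 600 samples at 1000 Hz, half-open windows, 0-based sample
indexing everywhere — with the −50–0 ms per-channel mean subtracted.

Rejection reads "amplitude exceeded ±100 µV" literally as instantaneous
absolute amplitude (not peak-to-peak): an epoch is dropped iff any EEG
sample exceeds 100 µV or any EOG sample exceeds 500 µV in magnitude,
evaluated after filtering and baseline correction.  Applying rejection
before baseline correction is possible by extracting epochs with
`baseline=None`; order is not dictated by the pipeline.

## ERP statistics

Per stream, attended-deviant epochs (D_t) are compared against the
concatenation of the nonattended streams' deviant epochs (D_nt) with an
independent two-sample pooled-variance (Student's) *t*-test per
(channel, sample) at α = 0.01, deliberately uncorrected for multiple
comparisons; with 64 × 600 cells the mask's expected false-positive
density is about α, which the calibration tests confirm on pure noise.
Zero-variance cells define p = 1 when the group means agree and p = 0
otherwise.  All non-rejected epochs of a subject are pooled across blocks.

## xDAWN

The evoked estimate P₁ is obtained by least squares, P₁ = (D₁ᵀD₁)⁻¹D₁ᵀX,
from the continuous data and the zero/one Toeplitz design D₁ — correctly
attributing overlapping responses, which matters here because the 180 ms
SOA is far shorter than the 600 ms response window (onset averaging is the
fallback when D₁ᵀD₁ is singular).  The SSNR
ρ(**u**) = (**u**ᵀΣ₁**u**)/(**u**ᵀΣₓ**u**), Σ₁ = P₁ᵀ(D₁ᵀD₁)P₁ and
Σₓ = XᵀX (both scaled by the number of samples), is maximized by the
generalized symmetric eigenproblem Σ₁**u** = λΣₓ**u**, solved via Cholesky
whitening of Σₓ after adding a ridge of 10⁻⁸ × trace/n_channels.  Filters
are unit-norm with sign fixed so the filtered evoked estimate has a
positive maximum; three components per class are kept, and an epoch's
projection stacks the attended filters over the nonattended ones (6 rows).

One symbol collision is worth noting: "P₁" denotes both the channel-space
least-squares evoked estimate inside the SSNR derivation and, in the
super-trial construction below, the 2C × N stack of *filtered* class
templates.  The model object keeps both (`p1_channel` and
`stacked_templates`).

## Riemannian classification

Each filtered epoch Xᵢ (6 × 600) is stacked under the filtered class
templates into a super-trial X̃ᵢ = [P₁; Xᵢ] (12 × 600); its sample
covariance Σ̃ᵢ = X̃ᵢX̃ᵢᵀ/(N−1) is **not** mean-centered, following the plain
uncentered estimator (rows are near zero-mean after the 1 Hz high-pass;
centering is exposed as an option).  Geometry uses the affine-invariant
metric; eigenvalue computations go through symmetric eigendecompositions
with eigenvalues clipped at 10⁻¹² × trace.  The Fréchet mean is the
canonical fixed-point iteration — average the matrix logs of the whitened
set, exponentiate back, unit step, initialized at the arithmetic mean —
with convergence declared at a tangent-gradient Frobenius norm ≤ 10⁻⁹
(non-convergence raises, carrying the last iterate).  Tangent
vectorization takes the upper triangle with √2 off-diagonal weighting so
the vector's Euclidean norm equals δ_R to the base point (the weighting is
switchable).  The default classifier is L2-regularized logistic regression
(C = 1, balanced class weights) on tangent vectors; minimum distance to
mean is available as an alternative, with exact ties resolved to
"nonattended".

## Cross-validation protocol

Folds are stratified (the attended:nonattended ratio is ≈ 1:2 under the
default plan) and seeded, so confusion counts are bit-for-bit reproducible
given config + seed.  Within each training fold only: xDAWN filters for
both classes, the stacked templates, the Fréchet mean, and the classifier
are fitted; the frozen transforms are then applied to the held-out fold.
The signal covariance Σₓ is the one exception — it is accumulated once per
session from the continuous filtered EEG, a label-free second-moment
statistic.  This strict refitting protocol makes synthetic accuracies, if
anything, conservative.

Two caveats of pooled-epoch cross-validation are worth stating.  First,
epochs from the same run land in both training and test folds; because the
label is constant within a run, any run-identifiable feature (e.g. the
realized noise spectrum of that run) contributes optimistically.  With the
session-stationary noise model this residual is small — the all-amplitudes-
zero null lands near chance (mean MCC ≈ 0.05, well within 3 SD of 0) — but
it is the reason a `group-by-run` fold option would be needed for real
multi-run recordings.  Second, metrics are aggregated as pooled confusion
counts over folds; fold-weighted mean accuracy equals pooled accuracy by
construction.

## Metrics

MCC follows the standard confusion-count formula with the 0-denominator →
0 convention.  Averaged confusion matrices are row-normalized per subject
first, then averaged.  The information transfer rate is the Wolpaw bound,
bits/selection = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)), scaled by
60/T; below-chance accuracies clip to 0 bits.

## Problem sizes in the shipped tests

The acceptance-level parameter-recovery study runs five full-scale
sessions (2 × 3 × 300 s) plus five zero-amplitude null sessions; unit and
property tests use reduced sessions (1 block × 120 s) and small random SPD
sets (dimension 3–12), which keep the whole suite within a few minutes
while exercising identical code paths.

## Known limitations

- The synthetic generator's simplifications listed above; in particular,
  near-ceiling synthetic accuracies say nothing quantitative about human
  subjects.
- BrainVision support covers the IEEE-float32/INT16 multiplexed layouts MNE
  reads; the bundled writer emits only float32 and exists chiefly for
  round-trip testing and export.
- No EOG regression/ICA cleaning, notch filtering, or re-referencing; the
  recorded (earlobe) reference is taken as given.
- The Fréchet mean uses the fixed-point solver with unit step; for the
  well-conditioned 12 × 12 covariances produced here it converges in a few
  iterations, but no line search is implemented.
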