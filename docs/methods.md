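# Methods

## Discrete fractional Fourier transform

The FrFT of order p (rotation angle α = pπ/2) generalizes the Fourier
transform; its continuous kernel is

K_α(t,u) = √(1 − i·cot α) · exp(iπ(t²+u²)cot α − 2πi·tu·csc α),

with the δ(t−u) and δ(t+u) branches at even and odd multiples of π. We
work in dimensionless coordinates scaled so that the α = π/2 kernel is the
unit-frequency Fourier transform (equivalently, the classical
radian-frequency kernel with its 1/2π factor under t → t√(2π)); signals
live on the symmetric grid t_k = (k − N/2)/√N.

**Discretization.** The transform is the fractional power of the centered
DFT on a discrete Hermite–Gauss basis: the orthonormal eigenvectors of a
Dickinson–Steiglitz-type commuting matrix, built from an order-8
central-difference approximation of the harmonic-oscillator operator
(second difference plus its Fourier dual). Eigenvectors are sorted by
Hermite index; each one's DFT eigenvalue class is identified by projection
and assigned the standard exponent sequence {0,…,N−2, N} (even N). The
resulting operator is unitary and order-additive to machine precision,
reduces exactly to the identity, the centered unitary DFT, and the
(periodic) time reversal at α = 0, π/2, π, and agrees with direct
oversampled quadrature of the continuous kernel to ≤ 8·10⁻⁵ relative L2
on confined signals for N ∈ [32, 256] — an order-2 stencil would only
reach ~10⁻² at N = 32, which motivated the higher-order operator. The
quadrature (`frft_quadrature`, 8× band-limited oversampling) is kept as an
independent validation oracle; note it is accurate only for signals
confined to the grid's time–frequency region and is not unitary as a
matrix on arbitrary sample vectors.

On the even-N centered grid the leftmost sample t = −√N/2 has no positive
partner, so time reversal (α = π) is the periodic mod-N reversal fixing
that sample; for odd N it is the exact antidiagonal flip.

**Phase demonstration.** For windowed cosines cos(ω₀t + θ) the Fourier
magnitude is θ-independent while fractional magnitudes retain θ. The demo
uses a Hann window (pure cosines leak on a finite grid) and unit-L2
normalized magnitude arrays; at n = 512, ω₀ = π/2 the α = π/2 magnitudes
for θ ∈ {0, π/4} agree to ~10⁻⁷ while the α = 0.4π magnitudes differ at
the 10⁻³ level — a ratio above 10⁴.

## FrCC extraction

Pipeline per utterance: pre-emphasis 0.97; 20 ms frames with 10 ms hop
(the recording protocol's geometry), periodic Hamming window; FrFT at α;
magnitude on the nonnegative half of the centered fractional axis, scaled
by √N so that at α = π/2 it coincides with the conventional unnormalized
FFT magnitude (this makes the log floor engage at the same energies in
the FrCC and reference-MFCC paths; because cepstra 1..n are invariant to
global log shifts, the scaling is otherwise neutral); M = 24 triangular
unit-peak filters equally spaced on the Mel axis of u = f·sin α over
(0, (f_s/2)·sin α]; natural log with floor 10⁻¹⁰; orthonormal type-II
DCT (coefficient √(2/M) over the M filter energies), keeping cepstra
1–12 and dropping the pure-energy 0th term; 12 regression deltas
(half-width 2, edge replication). Pre-emphasis and windowing follow MFCC
community defaults so the α = π/2 branch is a conventional MFCC; M = 24
is the common choice for 8 kHz speech. An independent FFT-based MFCC path
(`mfcc_frame`/`extract_mfcc`) verifies the α = π/2 identity to 10⁻⁸ per
coefficient.

## Classifiers

**Fisher LDA** (from scratch): w = d_w⁻¹(μ₁ − μ₂) with d_w the pooled
within-class scatter; when cond(d_w) > 10¹⁰ a ridge 10⁻⁸·tr(d_w)/d·I is
added (24-dimensional cepstra from short recordings can be
rank-deficient). The decision threshold is the midpoint of the projected
class means — the equal-prior choice; the method itself leaves the
threshold free. Each frame vector is classified independently and
accuracy is counted over frames; the projected-mean orientation fixes
which class owns the y ≥ t side.

**Discrete HMM**: one model per class, N = 3 states and M = 4 symbols by
default (both configurable); observations are VQ symbols from a Lloyd
k-means codebook (k-means++ seeding, empty clusters reseeded at the
farthest point, duplicate-only input handled by duplicating centroids)
fit on pooled training frames. Training is multi-sequence Baum–Welch with
per-step scaling, seeded Dirichlet(1) initialization, and a non-decreasing
total log-likelihood; because EM reaches local optima (on a well-separated
2-state/3-symbol recovery problem roughly half of random starts converge
to a clearly inferior likelihood), fits can use several restarts keeping
the best final likelihood — the evaluation pipeline uses 3. Utterances
are classified by comparing forward log-likelihoods (ties to the
truthful model).

LDA decisions are per frame and HMM decisions per utterance, so the two
back-ends answer the question at different granularities; the HMM's
advantage comes both from temporal modeling and from aggregating an
utterance's evidence into one decision. This mirrors the experimental
structure the package emulates.

## Angle sweep and statistics

The sweep grid is the 99 interior points {0.01π, …, 0.99π} (the endpoints
are degenerate: sin α = 0 collapses the fractional frequency axis). One
stratified utterance-level 30/70 split (train share rounded half-down) is
shared by all angles — splitting frames instead would leak overlapping
frames of one recording into both sides. Ties in best accuracy go to the
angle closest to π/2, preferring the conventional transform when
fractional orders offer no gain. The variance ratio
R = Σ‖aᵢ−ā‖²/Σ‖bⱼ−b̄‖² compares clustering concentration of two feature
sets; sensitivity and specificity use the deceptive class as positive.

## Synthetic corpus

Each utterance (default 0.8 s at 8 kHz) is a 5-harmonic carrier with
fundamental drawn from 120–220 Hz, a raised-cosine syllable envelope at
4 syllables/s, white noise at 30 dB SNR (the protocol requires > 25 dB),
and a 16-bit quantization round trip. The class difference is the *slope*
of a triangular frequency modulation with fixed 400 Hz excursion
(defaults 2·10⁴ vs. 1.2·10⁵ Hz/s) plus per-syllable, per-harmonic phase
jitter (0.1 vs. 0.5 rad): both classes visit the same frequency band, so
ordinary magnitude spectra are similar, while the sweep-rate difference is
exactly what fractional orders resolve — a 20 ms frame of a linear sweep
at rate c concentrates near the rotation angle arccot(c/4·10⁵). A
per-syllable one-way ramp was rejected because a realistic syllable is
long enough that the ramp saturates at the harmonic Nyquist cap within
milliseconds, leaving the cue inactive almost all the time. With the
defaults the ordinary-Fourier (MFCC) frame accuracy sits near 86%, the
best fractional order gains ~2–3 points and lies just off π/2, and the
utterance-level HMM separates the test sets completely; the null
construction (zero sweep, equal jitter) keeps every downstream classifier
at chance.

What the generator does *not* emulate: formant structure, coarticulation,
speaker identity, prosody, recording-channel effects, or any genuine
physiological correlate of deception. Passing tests therefore show that
the pipeline detects the class structure it is pointed at, at the stated
sizes and SNR — not that deception is detectable in real speech.

## Problem sizes and determinism

Default experiments use 10 utterances per class (≈ 1 600 frames), chosen
so the five-seed, 99-angle end-to-end suite completes in seconds on one
CPU while keeping both classes' statistics stable. All randomness flows
through explicit integer seeds (utterances derive per-item seeds from
(corpus seed, class, index)); identical seeds reproduce corpora, splits,
codebooks and models bit-exactly. The null-corpus chance check averages
frame accuracies over five seeds because frames within an utterance are
strongly correlated: with 14 test utterances per seed the effective
sample is ~70 utterances, so the acceptance band is 50% ± 12%.

## Known limitations

- The spectral FrFT costs O(N²) per frame batch after an O(N³)
  eigendecomposition per frame length (cached); frame lengths beyond a few
  thousand samples would need a different algorithm.
- The commuting-matrix eigenvalue classification assumes a non-degenerate
  spectrum; it is verified by projection at construction and raises if a
  pathological length breaks the assignment.
- Discrete-symbol HMMs with M = 4 discard most of the 24-dimensional
  feature geometry; continuous-emission models are out of scope.
- Accuracy estimates on 14 test utterances are coarse (±7% at the
  utterance level); the package reports them as computed, without
  confidence intervals.
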