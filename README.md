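# frcc — fractional Mel cepstral coefficients for speaker-state detection

Detecting a speaker's psychophysiological state (e.g. truthful vs.
deceptive speech) from audio alone is hard because the ordinary magnitude
spectrum discards phase: two signals that differ only in phase structure
have identical Fourier magnitudes. The **fractional Fourier transform
(FrFT)** — a rotation of the time–frequency plane by an angle α, with
α = π/2 recovering the ordinary Fourier transform — retains phase and chirp
structure in its magnitude, so cepstral features computed from it can
separate speaker states that MFCC cannot.

This package implements that idea as a tested library and CLI for
two-class utterance classification:

- **FrCC features**: for rotation angle α, take |S_α(u)| of each 20 ms
  frame, project onto triangular filters equally spaced on the Mel scale
  M(u) = 1125 ln(1 + u/700) of the fractional frequency u = f·sin α, and
  apply a type-II DCT, keeping cepstra 1–12 plus 12 regression deltas.
  FrCC ≡ MFCC at α = π/2.
- **FrFT core**: an exactly unitary, exactly order-additive discrete FrFT
  (fractional power of the centered DFT on a discrete Hermite–Gauss
  eigenbasis), validated against direct quadrature of the continuous chirp
  kernel K_α(t,u) ∝ exp(iπ(t²+u²)cot α − 2πi·tu·csc α).
- **Classifiers**: a from-scratch two-class Fisher discriminant
  (w = d_w⁻¹(μ₁−μ₂), threshold at the projected-mean midpoint) deciding
  frame-by-frame, and discrete hidden Markov models (one per class,
  N = 3 states, M = 4 VQ symbols, Baum–Welch/forward/Viterbi) deciding
  per utterance by maximum likelihood.
- **Optimal-order sweep**: accuracy of the full pipeline over the grid
  α ∈ {0.01π, …, 0.99π} on a stratified 30/70 utterance split; the best α
  is the grid point with highest held-out accuracy.
- **Synthetic corpus**: a seeded generator of labeled "speech-like"
  utterances (8 kHz, 16-bit, SNR 30 dB, syllabic envelopes, harmonic
  carriers) whose classes differ in frequency-sweep rate and phase jitter,
  so that some α ≠ π/2 separates them better than the ordinary Fourier
  angle — plus a null construction with identical classes for leakage
  checks.

## Worked example

```python
import numpy as np
from frcc import (SynthConfig, gen_corpus, FrameParams, angle_sweep,
                  default_alpha_grid, split_train_test)
from frcc.metrics import evaluate_at_alpha, accuracy, sensitivity_specificity

corpus = gen_corpus(SynthConfig(seed=1))          # 10 utterances per class
params = FrameParams(sample_rate=8000)            # 20 ms frames, 10 ms hop
sweep = angle_sweep(corpus, default_alpha_grid(), params,
                    classifier="lda", seed=1)
print(f"accuracy at alpha = 0.50*pi (MFCC): {sweep.accuracy_at(np.pi/2):.3f}")
print(f"best alpha = {sweep.best_alpha/np.pi:.2f}*pi, "
      f"accuracy {sweep.best_accuracy:.3f}")

train, test = split_train_test(corpus, seed=1)
counts = evaluate_at_alpha(train, test, sweep.best_alpha, params,
                           classifier="hmm", seed=1)
se, sp = sensitivity_specificity(counts)
print(f"HMM accuracy at best alpha: {accuracy(counts):.3f} "
      f"(sensitivity {se:.2f}, specificity {sp:.2f})")
```

prints

```
accuracy at alpha = 0.50*pi (MFCC): 0.851
best alpha = 0.51*pi, accuracy 0.879
HMM accuracy at best alpha: 1.000 (sensitivity 1.00, specificity 1.00)
```

Frame-level LDA on MFCC (α = π/2) reaches 85.1% here; sweeping the
fractional order finds a better angle (0.51π, 87.9%), and the HMM
back-end — which aggregates evidence over all frames of an utterance and
models their temporal order — separates the test utterances completely.
On the null corpus (identical class parameters) the same pipeline stays
at chance.

The same pipeline is available from the shell:

```sh
frcc synth --out corpus --seed 1
frcc sweep --audio corpus --grid 99 --classifier lda --seed 1 --out sweep.csv
frcc train --audio corpus --alpha 0.51 --classifier hmm --seed 1 --out hmm.yaml
frcc evaluate --audio corpus --model hmm.yaml --seed 1
```

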