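"""Short-time framing and FrCC / MFCC / delta feature extraction.

The fractional Mel cepstral coefficient (FrCC) pipeline mirrors
conventional MFCC extraction with the Fourier transform replaced by the
fractional Fourier transform at rotation angle ``alpha``:

1. pre-emphasis, framing (20 ms frames, 10 ms hop by default) and windowing;
2. FrFT magnitude spectrum on the nonnegative half of the fractional axis;
3. triangular filterbank equally spaced on the Mel scale of the *fractional*
   frequency ``u = f * sin(alpha)``;
4. log filter energies and an orthonormal type-II DCT, keeping cepstra
   1..n_ceps (the 0th, pure-energy term is dropped);
5. first-order regression deltas appended.

At ``alpha = pi/2`` the fractional axis coincides with linear frequency and
the pipeline reduces to ordinary MFCC; :func:`mfcc_frame` /
:func:`extract_mfcc` provide an independent FFT-based reference path used to
verify that identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.signal

from .errors import DegenerateOrderError, ShortSignalError
from .frft import FrftOrder, frft
from .types import Utterance

__all__ = [
    "FrameParams",
    "FrccConfig",
    "FeatureSequence",
    "frame_signal",
    "mel_of",
    "mel_to_u",
    "mel_filterbank",
    "fractional_filterbank",
    "frcc_frame",
    "mfcc_frame",
    "delta",
    "extract_features",
    "extract_mfcc",
    "batch_extract",
]


@dataclass(frozen=True)
class FrameParams:
    """Short-time analysis geometry (defaults: 20 ms frames, 10 ms hop)."""

    sample_rate: int
    frame_len: float = 0.020
    hop: float = 0.010
    window: str = "hamming"
    preemphasis: float = 0.97

    def __post_init__(self) -> None:
        if not self.frame_len > self.hop > 0:
            raise ValueError("frame_len > hop > 0 required")
        for name, seconds in (("frame_len", self.frame_len), ("hop", self.hop)):
            count = seconds * self.sample_rate
            if abs(count - round(count)) > 1e-9:
                raise ValueError(f"{name} must be a whole number of samples "
                                 f"({seconds} s at {self.sample_rate} Hz is {count})")

    @property
    def frame_samples(self) -> int:
        return round(self.frame_len * self.sample_rate)

    @property
    def hop_samples(self) -> int:
        return round(self.hop * self.sample_rate)


@dataclass(frozen=True)
class FrccConfig:
    """FrCC extraction parameters.

    ``n_mels = 24`` triangular filters and 12 cepstra are conventional for
    8 kHz speech; ``alpha`` is the FrFT rotation angle, strictly inside
    (0, pi) so that the fractional frequency axis does not collapse.
    """

    alpha: float = np.pi / 2
    n_ceps: int = 12
    n_mels: int = 24
    delta_window: int = 2
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        alpha = self.alpha.alpha if isinstance(self.alpha, FrftOrder) else float(self.alpha)
        object.__setattr__(self, "alpha", alpha)
        if not 0.0 < alpha < np.pi:
            raise DegenerateOrderError("alpha must lie strictly inside (0, pi)")
        if not 1 <= self.n_ceps <= self.n_mels:
            raise ValueError("require 1 <= n_ceps <= n_mels")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    @property
    def order(self) -> FrftOrder:
        return FrftOrder.from_alpha(self.alpha)


@dataclass
class FeatureSequence:
    """Per-frame feature vectors (n_ceps cepstra followed by their deltas)."""

    vectors: np.ndarray
    alpha: float
    label: int | None = None
    utt_id: str | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("feature vectors must form a 2-D matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors contain non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


def frame_signal(samples: np.ndarray, params: FrameParams) -> np.ndarray:
    """Slice a signal into overlapping windowed frames (rows).

    Yields ``1 + floor((len - frame) / hop)`` frames; a trailing partial
    frame is dropped.  Raises :class:`ShortSignalError` when the signal is
    shorter than one frame.
    """
    x = np.asarray(samples, dtype=np.float64)
    flen, hop = params.frame_samples, params.hop_samples
    if x.size < flen:
        raise ShortSignalError(
            f"signal of {x.size} samples is shorter than one frame "
            f"({flen} samples at {params.sample_rate} Hz)"
        )
    n_frames = 1 + (x.size - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    window = scipy.signal.get_window(params.window, flen, fftbins=True)
    return x[idx] * window


def mel_of(u):
    """Mel value of a (fractional-domain) frequency: 1125 ln(1 + u/700)."""
    u = np.asarray(u, dtype=np.float64)
    if np.any(u < 0):
        raise ValueError("frequency must be nonnegative")
    return 1125.0 * np.log1p(u / 700.0)


def mel_to_u(mel):
    """Inverse of :func:`mel_of`."""
    return 700.0 * np.expm1(np.asarray(mel, dtype=np.float64) / 1125.0)


def mel_filterbank(n_mels: int, n_bins: int, bin_spacing: float, f_max: float) -> np.ndarray:
    """Triangular unit-peak filters equally spaced on the Mel axis.

    ``n_bins`` spectrum bins at ``bin_spacing`` (Hz-like units) cover
    ``[0, f_max)``; filter edges are Mel-equispaced over ``[0, f_max]``.
    Adjacent filters share exactly one edge point.
    """
    edges_mel = np.linspace(0.0, float(mel_of(f_max)), n_mels + 2)
    edges = mel_to_u(edges_mel)
    freqs = np.arange(n_bins) * bin_spacing
    bank = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, center, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / (center - lo)
        down = (hi - freqs) / (hi - center)
        bank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def fractional_filterbank(config: FrccConfig, n_bins: int, sample_rate: int) -> np.ndarray:
    """Mel filterbank on the fractional frequency axis ``u = f * sin(alpha)``.

    At ``alpha = pi/2`` this is the standard Mel bank on linear frequency;
    orders symmetric about pi/2 (equal ``sin``) produce identical banks.
    """
    sin_a = np.sin(config.alpha)
    if sin_a <= 0:
        raise DegenerateOrderError("sin(alpha) must be positive: the fractional "
                                   "axis collapses at alpha = 0 or pi")
    n_fft = 2 * n_bins
    return mel_filterbank(
        config.n_mels,
        n_bins,
        bin_spacing=sample_rate / n_fft * sin_a,
        f_max=sample_rate / 2 * sin_a,
    )


def _cepstra_from_mags(mags: np.ndarray, bank: np.ndarray, config: FrccConfig) -> np.ndarray:
    energies = mags @ bank.T
    log_e = np.log(np.maximum(energies, config.log_floor))
    ceps = scipy.fft.dct(log_e, type=2, norm="ortho", axis=-1)
    return ceps[..., 1:config.n_ceps + 1]


def _frcc_mags(frames: np.ndarray, alpha: float) -> np.ndarray:
    """|FrFT| on the nonnegative half of the centered fractional axis.

    Scaled by sqrt(N) so that at alpha = pi/2 the values coincide with the
    conventional (unnormalized) FFT magnitude — the log floor then engages
    at the same energies as in the reference MFCC path.
    """
    n = frames.shape[-1]
    spectra = frft(frames, alpha)
    return np.sqrt(n) * np.abs(spectra[..., n // 2:])


def frcc_frame(frame: np.ndarray, config: FrccConfig, bank: np.ndarray) -> np.ndarray:
    """FrCC cepstra of a single windowed frame.

    All-zero frames hit the log floor and yield (near-)zero cepstra 1..n;
    non-finite input is rejected.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite samples")
    if bank.shape[1] != frame.size - frame.size // 2:
        raise ValueError("filterbank resolution does not match the frame length")
    return _cepstra_from_mags(_frcc_mags(frame, config.alpha), bank, config)


def mfcc_frame(
    frame: np.ndarray,
    config: FrccConfig,
    sample_rate: int,
    bank: np.ndarray | None = None,
) -> np.ndarray:
    """Reference MFCC path: FFT magnitudes, standard Mel bank, log, DCT.

    Independent of the FrFT machinery; used to verify the
    FrCC(alpha = pi/2) == MFCC identity.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite samples")
    n = frame.size
    mags = np.abs(np.fft.fft(frame))[:n // 2]
    if bank is None:
        bank = mel_filterbank(config.n_mels, n // 2, sample_rate / n, sample_rate / 2)
    return _cepstra_from_mags(mags, bank, config)


def delta(coeffs: np.ndarray, half_width: int = 2) -> np.ndarray:
    """First-order regression deltas with edge replication.

    ``delta_t = sum_k k (c_{t+k} - c_{t-k}) / (2 sum_k k^2)``.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    c = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    padded = np.pad(c, ((half_width, half_width), (0, 0)), mode="edge")
    norm = 2.0 * sum(k * k for k in range(1, half_width + 1))
    out = np.zeros_like(c)
    for k in range(1, half_width + 1):
        out += k * (padded[half_width + k:padded.shape[0] - half_width + k]
                    - padded[half_width - k:-half_width - k])
    return out / norm


def _windowed_frames(utterance: Utterance, params: FrameParams) -> np.ndarray:
    x = utterance.samples
    if params.preemphasis:
        x = np.append(x[0], x[1:] - params.preemphasis * x[:-1])
    return frame_signal(x, params)


def extract_features(
    utterance: Utterance, config: FrccConfig, params: FrameParams
) -> FeatureSequence:
    """FrCC + delta feature matrix (T x 2*n_ceps) for one utterance."""
    frames = _windowed_frames(utterance, params)
    ceps = _cepstra_from_mags(_frcc_mags(frames, config.alpha),
                              fractional_filterbank(config, frames.shape[1] // 2,
                                                    params.sample_rate),
                              config)
    vectors = np.hstack([ceps, delta(ceps, config.delta_window)])
    return FeatureSequence(vectors=vectors, alpha=config.alpha,
                           label=utterance.label, utt_id=utterance.utt_id)


def extract_mfcc(
    utterance: Utterance, config: FrccConfig, params: FrameParams
) -> FeatureSequence:
    """Reference MFCC + delta features via the FFT path (for cross-checks)."""
    frames = _windowed_frames(utterance, params)
    n = frames.shape[1]
    bank = mel_filterbank(config.n_mels, n // 2, params.sample_rate / n,
                          params.sample_rate / 2)
    mags = np.abs(np.fft.fft(frames, axis=-1))[:, :n // 2]
    ceps = _cepstra_from_mags(mags, bank, config)
    vectors = np.hstack([ceps, delta(ceps, config.delta_window)])
    return FeatureSequence(vectors=vectors, alpha=np.pi / 2,
                           label=utterance.label, utt_id=utterance.utt_id)


def batch_extract(
    utterances: Sequence[Utterance],
    config: FrccConfig,
    params: FrameParams,
    alphas: Sequence[float],
) -> dict[float, list[FeatureSequence]]:
    """FrCC features for every utterance at every fractional order.

    Frames are computed once per utterance and transformed in a single
    batched FrFT per order, which is the hot path of the angle sweep.
    """
    frame_list = [_windowed_frames(u, params) for u in utterances]
    bounds = np.cumsum([0] + [f.shape[0] for f in frame_list])
    stacked = np.vstack(frame_list)
    n = stacked.shape[1]
    out: dict[float, list[FeatureSequence]] = {}
    for alpha in alphas:
        cfg = replace(config, alpha=float(alpha))
        bank = fractional_filterbank(cfg, n // 2, params.sample_rate)
        ceps = _cepstra_from_mags(_frcc_mags(stacked, cfg.alpha), bank, cfg)
        seqs = []
        for i, utt in enumerate(utterances):
            c = ceps[bounds[i]:bounds[i + 1]]
            vectors = np.hstack([c, delta(c, cfg.delta_window)])
            seqs.append(FeatureSequence(vectors=vectors, alpha=cfg.alpha,
                                        label=utt.label, utt_id=utt.utt_id))
        out[float(alpha)] = seqs
    return out
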