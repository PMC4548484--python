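"""Discrete-observation hidden Markov models with a VQ front-end.

One HMM is trained per speaker state (normal / deceptive).  Continuous
cepstral feature vectors are discretized into a finite symbol alphabet by
nearest-centroid assignment against a k-means codebook; each class model
(N states, M symbols, transition matrix A, emission matrix B, initial
distribution pi) is fit by Baum–Welch and utterances are classified by
comparing forward log-likelihoods.  Defaults N = 3, M = 4.

All recursions use per-step normalization with accumulated log scale
factors, so sequences of arbitrary length are handled without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError
from .features import FeatureSequence

__all__ = [
    "HmmModel",
    "Codebook",
    "vq_fit",
    "vq_assign",
    "forward_loglik",
    "viterbi",
    "baum_welch_fit",
    "sample",
    "classify",
]

DEFAULT_STATES = 3
DEFAULT_SYMBOLS = 4
_STOCH_TOL = 1e-10


@dataclass
class HmmModel:
    """(N, M, A, B, pi) discrete HMM.  Rows of A and B and pi sum to one."""

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray
    train_history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.B.shape[0] != n or self.pi.shape != (n,):
            raise ValueError("inconsistent HMM parameter shapes")
        for name, arr in (("A", self.A), ("B", self.B), ("pi", self.pi[None, :])):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > _STOCH_TOL):
                raise ValueError(f"rows of {name} must sum to 1 within {_STOCH_TOL}")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]


@dataclass
class Codebook:
    """K-means centroids used to quantize feature vectors into symbols."""

    centroids: np.ndarray
    inertia_history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=np.float64))
        if self.centroids.shape[0] < 2:
            raise ValueError("codebook needs at least 2 centroids")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def n_symbols(self) -> int:
        return self.centroids.shape[0]


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centroids = [X[rng.integers(X.shape[0])]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centroids)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            centroids.append(X[rng.integers(X.shape[0])].copy())
            continue
        centroids.append(X[rng.choice(X.shape[0], p=d2 / total)])
    return np.asarray(centroids, dtype=np.float64)


def vq_fit(features: np.ndarray, k: int, seed: int, max_iter: int = 100,
           tol: float = 1e-8) -> Codebook:
    """Seeded Lloyd k-means codebook on pooled feature vectors.

    Within-cluster squared error is non-increasing across iterations
    (recorded in ``inertia_history``).  An emptied cluster is reseeded at
    the point farthest from its centroid; with fewer distinct points than
    ``k`` the surplus centroids duplicate existing ones (documented
    degenerate-input tie-break).
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[0] < k:
        raise InsufficientDataError(f"k-means needs at least k={k} samples, got {X.shape[0]}")
    rng = np.random.default_rng(seed)
    centroids = _kmeans_pp_init(X, k, rng)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        assign = d2.argmin(axis=1)
        inertia = float(d2[np.arange(X.shape[0]), assign].sum())
        history.append(inertia)
        new = centroids.copy()
        for j in range(k):
            members = assign == j
            if members.any():
                new[j] = X[members].mean(axis=0)
            else:
                new[j] = X[d2.min(axis=1).argmax()]
        if np.allclose(new, centroids, atol=tol):
            centroids = new
            break
        centroids = new
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    history.append(float(d2.min(axis=1).sum()))
    return Codebook(centroids=centroids, inertia_history=history)


def vq_assign(features: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-centroid symbol sequence (0-based symbols)."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    d2 = ((X[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def _check_obs(obs, n_symbols: int) -> np.ndarray:
    o = np.asarray(obs, dtype=np.intp)
    if o.ndim != 1 or o.size == 0:
        raise ValueError("observation sequence must be non-empty and 1-D")
    if o.min() < 0 or o.max() >= n_symbols:
        raise ValueError(f"symbols must lie in [0, {n_symbols})")
    return o


def _forward(obs: np.ndarray, model: HmmModel) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward recursion; returns (alpha_hat, scales, log-likelihood)."""
    T, n = obs.size, model.n_states
    alpha = np.zeros((T, n))
    scales = np.zeros(T)
    a = model.pi * model.B[:, obs[0]]
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ model.A) * model.B[:, obs[t]]
        s = a.sum()
        if s == 0:
            # observation impossible under the model
            return alpha, scales, -np.inf
        alpha[t] = a / s
        scales[t] = s
    return alpha, scales, float(np.log(scales).sum())


def forward_loglik(obs, model: HmmModel) -> float:
    """log P(obs | model) via the scaled forward algorithm."""
    return _forward(_check_obs(obs, model.n_symbols), model)[2]


def viterbi(obs, model: HmmModel) -> tuple[np.ndarray, float]:
    """Most likely state path and its log-probability.

    Ties are broken toward the lower state index.
    """
    o = _check_obs(obs, model.n_symbols)
    T, n = o.size, model.n_states
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logB = np.log(model.B)
        logpi = np.log(model.pi)
    score = logpi + logB[:, o[0]]
    back = np.zeros((T, n), dtype=np.intp)
    for t in range(1, T):
        cand = score[:, None] + logA  # cand[i, j]: from i to j
        back[t] = cand.argmax(axis=0)  # argmax returns the lowest tied index
        score = cand.max(axis=0) + logB[:, o[t]]
    path = np.zeros(T, dtype=np.intp)
    path[-1] = int(score.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(score.max())


def _backward(obs: np.ndarray, model: HmmModel, scales: np.ndarray) -> np.ndarray:
    T, n = obs.size, model.n_states
    beta = np.zeros((T, n))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (model.A @ (model.B[:, obs[t + 1]] * beta[t + 1])) / scales[t + 1]
    return beta


def _random_stochastic(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    rows = rng.dirichlet(np.ones(shape[1]), size=shape[0])
    return rows


def baum_welch_fit(
    sequences: list,
    n_states: int = DEFAULT_STATES,
    n_symbols: int = DEFAULT_SYMBOLS,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_restarts: int = 1,
) -> HmmModel:
    """Multi-sequence Baum–Welch (EM) training from a seeded Dirichlet start.

    Total log-likelihood is non-decreasing across iterations (recorded in
    ``train_history``); iteration stops when the improvement falls below
    ``tol`` or after ``max_iter`` rounds.  ``max_iter = 0`` returns the
    seeded initialization unchanged.  EM converges to local optima; with
    ``n_restarts > 1`` training repeats from distinct seeded starts and the
    model with the best final data log-likelihood is returned.
    """
    if n_restarts > 1:
        candidates = [
            baum_welch_fit(sequences, n_states, n_symbols,
                           seed=[seed, r], max_iter=max_iter, tol=tol)
            for r in range(n_restarts)
        ]
        return max(candidates,
                   key=lambda m: sum(forward_loglik(_check_obs(s, n_symbols), m)
                                     for s in sequences))
    if not sequences:
        raise InsufficientDataError("Baum-Welch needs at least one sequence")
    seqs = [_check_obs(s, n_symbols) for s in sequences]
    # batch sequences of equal length for vectorized recursions
    by_len: dict[int, list[np.ndarray]] = {}
    for o in seqs:
        by_len.setdefault(o.size, []).append(o)
    batches = [np.vstack(group) for group in by_len.values()]
    rng = np.random.default_rng(seed)
    A = _random_stochastic(rng, (n_states, n_states))
    B = _random_stochastic(rng, (n_states, n_symbols))
    pi = rng.dirichlet(np.ones(n_states))
    history: list[float] = []
    for _ in range(max_iter):
        A_num = np.zeros((n_states, n_states))
        B_num = np.zeros((n_states, n_symbols))
        pi_num = np.zeros(n_states)
        total_ll = 0.0
        for obs2d in batches:
            alpha, scales, ll = _forward_batch(obs2d, A, B, pi)
            if not np.all(np.isfinite(ll)):
                # smooth emissions touching an impossible symbol
                B = 0.9 * B + 0.1 / n_symbols
                alpha, scales, ll = _forward_batch(obs2d, A, B, pi)
            total_ll += float(ll.sum())
            beta = _backward_batch(obs2d, A, B, scales)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            pi_num += gamma[:, 0, :].sum(axis=0)
            if obs2d.shape[1] > 1:
                # xi[s,t,i,j] = alpha[s,t,i] A[i,j] B[j,o[s,t+1]]
                #               * beta[s,t+1,j] / c[s,t+1]
                emis = B.T[obs2d[:, 1:]] * beta[:, 1:] / scales[:, 1:, None]
                A_num += A * np.einsum("sti,stj->ij", alpha[:, :-1], emis)
            np.add.at(B_num.T, obs2d.ravel(),
                      gamma.reshape(-1, n_states))
            del gamma
        history.append(total_ll)
        A = A_num / np.maximum(A_num.sum(axis=1, keepdims=True), 1e-300)
        B = B_num / np.maximum(B_num.sum(axis=1, keepdims=True), 1e-300)
        pi = pi_num / pi_num.sum()
        if len(history) >= 2 and history[-1] - history[-2] < tol:
            break
    return HmmModel(A=A, B=B, pi=pi, train_history=history)


def _forward_batch(obs2d: np.ndarray, A, B, pi):
    """Scaled forward recursion over a batch of equal-length sequences."""
    S, T = obs2d.shape
    n = A.shape[0]
    alpha = np.zeros((S, T, n))
    scales = np.zeros((S, T))
    a = pi[None, :] * B.T[obs2d[:, 0]]
    for t in range(T):
        if t > 0:
            a = (alpha[:, t - 1] @ A) * B.T[obs2d[:, t]]
        s = a.sum(axis=1)
        safe = np.maximum(s, 1e-300)
        alpha[:, t] = a / safe[:, None]
        scales[:, t] = s
    with np.errstate(divide="ignore"):
        ll = np.log(scales).sum(axis=1)
    return alpha, scales, ll


def _backward_batch(obs2d: np.ndarray, A, B, scales):
    S, T = obs2d.shape
    n = A.shape[0]
    beta = np.zeros((S, T, n))
    beta[:, -1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = ((B.T[obs2d[:, t + 1]] * beta[:, t + 1]) @ A.T) \
            / scales[:, t + 1, None]
    return beta


def sample(model: HmmModel, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an observation sequence from the model (testing / simulation)."""
    obs = np.zeros(length, dtype=np.intp)
    state = rng.choice(model.n_states, p=model.pi)
    for t in range(length):
        obs[t] = rng.choice(model.n_symbols, p=model.B[state])
        if t + 1 < length:
            state = rng.choice(model.n_states, p=model.A[state])
    return obs


def classify(
    features: "FeatureSequence | np.ndarray",
    codebook: Codebook,
    model_true: HmmModel,
    model_lie: HmmModel,
    labels: tuple = (0, 1),
):
    """Maximum-likelihood class decision for one utterance.

    Quantizes the feature sequence and compares forward log-likelihoods;
    a tie goes to the first label (ω₁, the truthful model).
    """
    if model_true.n_symbols != model_lie.n_symbols:
        raise ValueError("class models must share the symbol alphabet")
    vectors = features.vectors if isinstance(features, FeatureSequence) else features
    obs = vq_assign(vectors, codebook)
    ll_true = forward_loglik(obs, model_true)
    ll_lie = forward_loglik(obs, model_lie)
    return labels[0] if ll_true >= ll_lie else labels[1]
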