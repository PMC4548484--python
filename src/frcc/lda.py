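"""Two-class Fisher linear discriminant, implemented from first principles.

Fisher's criterion J(w) = (w'μ₁ − w'μ₂)² / (w' d_w w) is maximized by
w = d_w⁻¹ (μ₁ − μ₂), where d_w is the pooled within-class scatter
(sum of the two classes' outer-product scatters about their means).
Samples are assigned by thresholding the 1-D projection y = w'x:
y ≥ t gives class ω₁, y < t gives ω₂, with t the midpoint of the
projected class means (equal-prior choice; the threshold is otherwise a
free parameter of the method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateClassesError, InsufficientDataError, SingularScatterError

__all__ = ["LdaModel", "fit", "project", "decide", "fisher_criterion"]

#: Ridge added to an ill-conditioned within-class scatter, as a fraction of
#: its mean diagonal. 24-dim cepstral features from short recordings can be
#: rank-deficient.
REGULARIZATION = 1e-8
_COND_LIMIT = 1e10


@dataclass
class LdaModel:
    """Fitted discriminant: projection vector, threshold and class means.

    ``label_order`` records which label plays ω₁ (the y ≥ t side).
    """

    w: np.ndarray
    threshold: float
    mu1: np.ndarray
    mu2: np.ndarray
    label_order: tuple = (1, 2)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.linalg.norm(self.w) == 0:
            raise ValueError("projection vector must be nonzero")


def fisher_criterion(w: np.ndarray, mu1, mu2, scatter_within) -> float:
    """J(w): squared projected mean separation over projected within-class scatter."""
    w = np.asarray(w, dtype=np.float64)
    num = float(w @ (np.asarray(mu1) - np.asarray(mu2))) ** 2
    den = float(w @ scatter_within @ w)
    return num / den


def _scatter(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    centered = X - mu
    return mu, centered.T @ centered


def fit(X1: np.ndarray, X2: np.ndarray, labels: tuple = (1, 2)) -> LdaModel:
    """Fit the discriminant from per-class sample matrices (rows = samples).

    The model is oriented so that the projected ω₁ mean lies on the
    y ≥ t side.  Raises :class:`InsufficientDataError` for classes with
    fewer than two samples, :class:`DegenerateClassesError` when the class
    means coincide, and :class:`SingularScatterError` when the within-class
    scatter stays singular after ridge regularization.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise InsufficientDataError("each class needs at least 2 samples")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("class matrices must share the feature dimension")
    mu1, d1 = _scatter(X1)
    mu2, d2 = _scatter(X2)
    diff = mu1 - mu2
    if np.allclose(diff, 0.0, atol=1e-12 * max(1.0, np.abs(mu1).max())):
        raise DegenerateClassesError("class means coincide; no discriminant direction")
    d_w = d1 + d2
    dim = d_w.shape[0]
    if np.linalg.cond(d_w) > _COND_LIMIT:
        d_w = d_w + REGULARIZATION * np.trace(d_w) / dim * np.eye(dim)
    try:
        w = np.linalg.solve(d_w, diff)
    except np.linalg.LinAlgError as exc:
        raise SingularScatterError(
            "within-class scatter singular after regularization"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise SingularScatterError("within-class scatter numerically singular")
    # d_w is positive (semi)definite so w already points from mu2 toward mu1
    if w @ diff < 0:  # pragma: no cover - defensive
        w = -w
    threshold = 0.5 * float(w @ mu1 + w @ mu2)
    return LdaModel(w=w, threshold=threshold, mu1=mu1, mu2=mu2, label_order=tuple(labels))


def project(x: np.ndarray, model: LdaModel) -> np.ndarray | float:
    """Project vectors onto the discriminant axis: y = w'x."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != model.w.size:
        raise ValueError(f"dimension mismatch: got {x.shape[-1]}, model has {model.w.size}")
    y = x @ model.w
    return float(y) if y.ndim == 0 else y


def decide(y, model: LdaModel):
    """Threshold the projection: y ≥ t chooses ω₁, y < t chooses ω₂."""
    y = np.asarray(y, dtype=np.float64)
    first, second = model.label_order
    out = np.where(y >= model.threshold, first, second)
    return out.item() if out.ndim == 0 else out


def classify(x, model: LdaModel):
    """Convenience: decide(project(x))."""
    return decide(project(x, model), model)
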