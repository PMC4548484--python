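"""Shared lightweight containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Class labels used throughout: omega_1 = normal speech, omega_2 = deceptive.
LABEL_NORMAL = 0
LABEL_DECEPTIVE = 1


@dataclass
class Utterance:
    """A labeled mono sample sequence — the unit of classification.

    ``samples`` are floats in [-1, 1); ``label`` is ``LABEL_NORMAL``,
    ``LABEL_DECEPTIVE`` or ``None`` for unlabeled audio.
    """

    samples: np.ndarray
    sample_rate: int
    label: int | None = None
    utt_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("utterance samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate
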