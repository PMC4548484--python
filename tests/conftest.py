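import numpy as np
import pytest
from hypothesis import settings

from frcc.features import FrameParams
from frcc.synthetic import SynthConfig, gen_corpus

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frame_params() -> FrameParams:
    return FrameParams(sample_rate=8000)


@pytest.fixture(scope="session")
def small_corpus():
    """Tiny chirp-separated corpus shared by pipeline-level tests."""
    return gen_corpus(SynthConfig(n_utts_per_class=4, utt_duration=0.5, seed=7))


def synthetic_vowel(f0: float, n: int = 160, sample_rate: int = 8000,
                    n_harmonics: int = 6) -> np.ndarray:
    """A voiced, harmonic-stack frame used as a deterministic test signal."""
    t = np.arange(n) / sample_rate
    return sum(np.cos(2 * np.pi * f0 * h * t + 0.3 * h) / h
               for h in range(1, n_harmonics + 1))
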