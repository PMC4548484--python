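"""Audio, feature-table, model and configuration I/O.

Artifacts are plain text first: feature tables and sweep tables are
delimited CSV, models are YAML key-value files, and every artifact records
the configuration hash and package version for provenance.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__
from .errors import ConfigMismatchError, UnsupportedFormatError
from .features import FeatureSequence
from .hmm import Codebook, HmmModel
from .lda import LdaModel
from .types import Utterance

log = logging.getLogger("frcc")

__all__ = [
    "read_wav",
    "write_wav",
    "write_feature_table",
    "read_feature_table",
    "save_lda",
    "load_lda",
    "save_hmm_pair",
    "load_hmm_pair",
    "config_hash",
]

_INT16_SCALE = 32768.0


def read_wav(path) -> Utterance:
    """Read a mono PCM WAV file as an utterance with samples in [-1, 1).

    16-bit integer samples are scaled by 1/32768; float files pass through.
    Stereo or non-PCM content raises :class:`UnsupportedFormatError`.
    Sample rates other than 8 kHz are accepted with a logged warning (no
    resampling is performed; frame geometry adapts through FrameParams).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise UnsupportedFormatError(f"{path}: {exc}") from exc
    if data.ndim != 1:
        raise UnsupportedFormatError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data / _INT16_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise UnsupportedFormatError(f"{path}: unsupported sample format {data.dtype}")
    if rate != 8000:
        log.warning("%s: sample rate %d Hz differs from the 8 kHz protocol; "
                    "no resampling performed", path, rate)
    return Utterance(samples=samples, sample_rate=int(rate), utt_id=path.stem)


def write_wav(path, utterance: Utterance) -> None:
    """Write an utterance as 16-bit mono PCM."""
    data = np.clip(np.round(utterance.samples * _INT16_SCALE),
                   -_INT16_SCALE, _INT16_SCALE - 1).astype(np.int16)
    wavfile.write(Path(path), utterance.sample_rate, data)


def _plain(obj):
    """Recursively convert tuples / numpy scalars for stable YAML dumping."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = yaml.safe_dump(_plain(config), sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_feature_table(path, sequences: list, config: dict | None = None) -> None:
    """Delimited feature table: one row per frame
    (utt_id, frame, alpha, feature columns, label)."""
    frames = []
    for seq in sequences:
        d = seq.vectors.shape[1]
        df = pd.DataFrame(seq.vectors, columns=[f"c{i:02d}" for i in range(d)])
        df.insert(0, "utt_id", seq.utt_id)
        df.insert(1, "frame", np.arange(seq.n_frames))
        df.insert(2, "alpha", seq.alpha)
        df["label"] = seq.label if seq.label is not None else -1
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frcc {__version__} config_hash={config_hash(config or {})}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path) -> list:
    """Inverse of :func:`write_feature_table`."""
    table = pd.read_csv(path, comment="#")
    cols = [c for c in table.columns if c.startswith("c")]
    sequences = []
    for (utt_id, alpha), group in table.groupby(["utt_id", "alpha"], sort=False):
        group = group.sort_values("frame")
        label = int(group["label"].iloc[0])
        sequences.append(FeatureSequence(
            vectors=group[cols].to_numpy(),
            alpha=float(alpha),
            label=None if label == -1 else label,
            utt_id=str(utt_id),
        ))
    return sequences


def _header(config: dict | None) -> dict:
    return {"version": __version__, "config_hash": config_hash(config or {})}


def save_lda(path, model: LdaModel, alpha: float, config: dict | None = None) -> None:
    """Serialize an LDA model as a small key-value text artifact."""
    payload = {
        **_header(config),
        "kind": "lda",
        "alpha": float(alpha),
        "w": model.w.tolist(),
        "threshold": float(model.threshold),
        "mu1": model.mu1.tolist(),
        "mu2": model.mu2.tolist(),
        "label_order": list(model.label_order),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_lda(path) -> tuple[LdaModel, float]:
    payload = yaml.safe_load(Path(path).read_text())
    if payload.get("kind") != "lda":
        raise ConfigMismatchError(f"{path} is not an LDA model artifact")
    model = LdaModel(
        w=np.asarray(payload["w"]),
        threshold=payload["threshold"],
        mu1=np.asarray(payload["mu1"]),
        mu2=np.asarray(payload["mu2"]),
        label_order=tuple(payload["label_order"]),
    )
    return model, float(payload["alpha"])


def save_hmm_pair(path, codebook: Codebook, model_true: HmmModel,
                  model_lie: HmmModel, alpha: float, seed: int,
                  config: dict | None = None) -> None:
    """Serialize the per-class HMM pair plus its VQ codebook as YAML."""
    def as_dict(m: HmmModel) -> dict:
        return {"A": m.A.tolist(), "B": m.B.tolist(), "pi": m.pi.tolist()}

    payload = {
        **_header(config),
        "kind": "hmm_pair",
        "alpha": float(alpha),
        "seed": int(seed),
        "codebook": codebook.centroids.tolist(),
        "model_true": as_dict(model_true),
        "model_lie": as_dict(model_lie),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_hmm_pair(path) -> tuple[Codebook, HmmModel, HmmModel, float]:
    payload = yaml.safe_load(Path(path).read_text())
    if payload.get("kind") != "hmm_pair":
        raise ConfigMismatchError(f"{path} is not an HMM model artifact")
    codebook = Codebook(centroids=np.asarray(payload["codebook"]))
    mt = HmmModel(**{k: np.asarray(v) for k, v in payload["model_true"].items()})
    ml = HmmModel(**{k: np.asarray(v) for k, v in payload["model_lie"].items()})
    return codebook, mt, ml, float(payload["alpha"])
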