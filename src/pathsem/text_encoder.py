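"""Pluggable contextual text encoders producing a fixed-width statement vector.

The contract: ``encode(text)`` wraps the statement in sequence-start/end
markers ([CLS] ... [SEP]) and returns the sequence-start position's final
hidden vector of width ``H``.  Two implementations:

* :class:`StubEncoder` — a deterministic hash-based bag-of-character-n-gram
  projection, L2-normalized.  It has no learned weights, is cheap enough for
  desk-scale tests, and preserves the one property downstream code relies
  on: statements sharing surface tokens have higher cosine similarity than
  unrelated statements.
* :class:`PretrainedEncoder` — an adapter over a HuggingFace transformer
  (frozen feature extraction by default).  Constructing it requires the
  optional ``transformers``/``torch`` extra.

Encoders are interchangeable behind :func:`make_encoder`; every model runs
unchanged under either.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

CLS_MARKER = "[CLS]"
SEP_MARKER = "[SEP]"

__all__ = [
    "EncodedText",
    "StubEncoder",
    "PretrainedEncoder",
    "VectorCache",
    "make_encoder",
    "CLS_MARKER",
    "SEP_MARKER",
]


@dataclass(frozen=True)
class EncodedText:
    """A statement embedding: ``vector`` of width H plus the input text."""

    vector: np.ndarray
    source_text: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("encoded vector contains non-finite entries")


class StubEncoder:
    """Deterministic hashing encoder for desk-scale runs.

    Features are character 3-grams plus word unigrams of the marker-wrapped
    statement, hashed (seeded BLAKE2b) into ``H`` signed buckets and
    L2-normalized.  Identical (H, seed) give identical behavior across
    processes and runs.
    """

    kind = "stub"

    def __init__(self, H: int = 32, seed: int = 0, ngram: int = 3,
                 max_length: int = 512) -> None:
        if H < 2:
            raise ValueError("H must be >= 2")
        self.H = H
        self.seed = seed
        self.ngram = ngram
        self.max_length = max_length
        self._key = f"stub:{seed}".encode()

    @property
    def encoder_id(self) -> str:
        return f"stub-H{self.H}-s{self.seed}-n{self.ngram}"

    def _bucket(self, feature: str) -> tuple[int, float]:
        digest = hashlib.blake2b(feature.encode("utf-8"), key=self._key,
                                 digest_size=8).digest()
        value = int.from_bytes(digest, "big")
        return value % self.H, 1.0 if (value >> 32) & 1 else -1.0

    def encode(self, text: str) -> EncodedText:
        stripped = text.strip()
        if not stripped:
            raise ValueError("cannot encode empty text")
        if len(stripped) > self.max_length:
            warnings.warn(
                f"statement of length {len(stripped)} truncated to "
                f"{self.max_length} characters", stacklevel=2,
            )
            stripped = stripped[: self.max_length]
        marked = f"{CLS_MARKER} {stripped} {SEP_MARKER}"
        vec = np.zeros(self.H)
        for i in range(len(marked) - self.ngram + 1):
            idx, sign = self._bucket("c:" + marked[i : i + self.ngram])
            vec[idx] += sign
        for token in marked.split():
            idx, sign = self._bucket("w:" + token)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:  # adversarial hash cancellation; keep the contract
            vec[0] = 1.0
            norm = 1.0
        return EncodedText(vector=vec / norm, source_text=text)


class PretrainedEncoder:
    """Adapter over a pretrained transformer encoder (e.g. a BERT variant).

    Returns the [CLS] final hidden state.  ``fine_tune=False`` (default)
    treats the encoder as a frozen feature extractor; gradient flow into the
    encoder is only available through the underlying framework and is not
    wired into the NumPy training loop.
    """

    kind = "pretrained"

    def __init__(self, name_or_path: str, H: int = 768, max_length: int = 512,
                 fine_tune: bool = False) -> None:
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PretrainedEncoder requires the optional 'bert' extra "
                "(pip install pathsem[bert])"
            ) from exc
        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(name_or_path)
        self.model = AutoModel.from_pretrained(name_or_path)
        self.model.eval()
        self.H = H
        self.max_length = max_length
        self.fine_tune = fine_tune
        self.name_or_path = name_or_path

    @property
    def encoder_id(self) -> str:
        return f"pretrained-{self.name_or_path}"

    def encode(self, text: str) -> EncodedText:  # pragma: no cover - optional
        if not text.strip():
            raise ValueError("cannot encode empty text")
        torch = self._torch
        inputs = self.tokenizer(text, return_tensors="pt", truncation=True,
                                max_length=self.max_length)
        with torch.no_grad():
            out = self.model(**inputs)
        vec = out.last_hidden_state[0, 0].numpy().astype(float)
        return EncodedText(vector=vec, source_text=text)


class VectorCache:
    """In-memory statement→vector cache keyed by (encoder id, text hash)."""

    def __init__(self, encoder) -> None:
        self.encoder = encoder
        self.H = encoder.H
        self._store: dict[str, np.ndarray] = {}

    @property
    def encoder_id(self) -> str:
        return self.encoder.encoder_id

    def encode(self, text: str) -> EncodedText:
        key = hashlib.sha1(text.encode("utf-8")).hexdigest()
        vec = self._store.get(key)
        if vec is None:
            vec = self.encoder.encode(text).vector
            self._store[key] = vec
        return EncodedText(vector=vec, source_text=text)


def make_encoder(config: dict):
    """Build an encoder from a config mapping.

    Keys: ``kind`` (stub|pretrained), ``H``, ``seed``, ``max_length``,
    ``name`` (pretrained only), ``fine_tune``, ``cache`` (bool).
    """
    kind = config.get("kind", "stub")
    if kind == "stub":
        enc = StubEncoder(
            H=int(config.get("H", 32)),
            seed=int(config.get("seed", 0)),
            max_length=int(config.get("max_length", 512)),
        )
    elif kind == "pretrained":
        enc = PretrainedEncoder(
            config["name"],
            H=int(config.get("H", 768)),
            max_length=int(config.get("max_length", 512)),
            fine_tune=bool(config.get("fine_tune", False)),
        )
    else:
        raise ValueError(f"unknown encoder kind: {kind!r}")
    if config.get("cache", True):
        return VectorCache(enc)
    return enc
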