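"""Provider contracts and deterministic fixture backends.

The pipeline consumes four kinds of model output: static word vectors,
contextual subword vectors, autoregressive token log-probabilities, and
bimodal (image/sentence) embeddings.  Each is specified as a small
protocol; adapters for real models (fastText binaries, transformer
checkpoints, vision-language encoders) can implement the same protocol,
while the fixture classes here are pure functions of ``(inputs, seed)``
so the whole pipeline runs and tests offline.

Fixture vectors are derived from SHA-256 hashes of the token strings, so
identical tokens always map to identical vectors without any stored
vocabulary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "EmbeddedSequence",
    "TokenLogProbs",
    "BimodalPair",
    "StaticEmbedder",
    "ContextualEmbedder",
    "AutoregressiveScorer",
    "BimodalEncoder",
    "HashStaticEmbedder",
    "HashContextualEmbedder",
    "UniformScorer",
    "CertainScorer",
    "GammaSurprisalScorer",
    "FixtureBimodalEncoder",
    "embed_static",
    "embed_contextual",
    "score_token_logprobs",
    "encode_bimodal",
    "stable_rng",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class EmbeddedSequence:
    """Ordered token vectors for one transcript (one row per token)."""

    vectors: np.ndarray  # shape (n, d)
    token_strings: tuple[str, ...]

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array (n_tokens, dim)")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "token_strings", tuple(self.token_strings))
        if len(self.token_strings) != len(vectors):
            raise ValueError("token_strings and vectors must have equal length")

    def __len__(self) -> int:
        return len(self.token_strings)


@dataclass(frozen=True)
class TokenLogProbs:
    """Per-token conditional log-probabilities from an autoregressive model.

    ``base`` declares whether entries are natural-log or base-2.  The
    first token of a sequence has no preceding context and is never
    included; ``len(logprobs)`` is the number of *predicted* tokens.
    """

    logprobs: np.ndarray
    base: str  # "2" or "e"

    def __post_init__(self) -> None:
        lp = np.asarray(self.logprobs, dtype=float)
        object.__setattr__(self, "logprobs", lp)
        if self.base not in ("2", "e"):
            raise ValueError(f"base must be '2' or 'e', got {self.base!r}")
        if np.any(lp > 0):
            raise ValueError("log-probabilities must be <= 0")

    def __len__(self) -> int:
        return len(self.logprobs)


@dataclass(frozen=True)
class BimodalPair:
    """Sentence vectors plus the stimulus-picture vector, same space."""

    sentence_vectors: np.ndarray  # shape (m, d)
    image_vector: np.ndarray  # shape (d,)

    def __post_init__(self) -> None:
        sv = np.atleast_2d(np.asarray(self.sentence_vectors, dtype=float))
        iv = np.asarray(self.image_vector, dtype=float)
        object.__setattr__(self, "sentence_vectors", sv)
        object.__setattr__(self, "image_vector", iv)
        if sv.size and sv.shape[1] != iv.shape[0]:
            raise ValueError("sentence vectors and image vector dimensionality differ")


# ---------------------------------------------------------------------------
# provider contracts


@runtime_checkable
class StaticEmbedder(Protocol):
    """Context-free word-to-vector mapping (fastText-like)."""

    dim: int

    def embed_word(self, word: str) -> np.ndarray: ...


@runtime_checkable
class ContextualEmbedder(Protocol):
    """Joint sequence encoder (BERT-like); context-sensitive vectors."""

    dim: int
    context_limit: int

    def encode(self, tokens: Sequence[str]) -> np.ndarray: ...


@runtime_checkable
class AutoregressiveScorer(Protocol):
    """Left-to-right token probability model (GPT/Mistral-like)."""

    def score(self, tokens: Sequence[str]) -> TokenLogProbs: ...


@runtime_checkable
class BimodalEncoder(Protocol):
    """Shared image/sentence embedding space (CLIP-like)."""

    dim: int

    def encode_image(self, image_id: str) -> np.ndarray: ...

    def encode_sentences(self, sentences: Sequence[str], image_id: str) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# deterministic hashing helpers


def stable_rng(seed: int, *keys) -> np.random.Generator:
    """Generator seeded from SHA-256 of ``(seed, *keys)``; platform-stable."""
    digest = hashlib.sha256(repr((int(seed), *map(str, keys))).encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _hash_unit_vector(dim: int, seed: int, *keys) -> np.ndarray:
    v = stable_rng(seed, *keys).standard_normal(dim)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # pragma: no cover - probability ~0
        v = stable_rng(seed, "retry", *keys).standard_normal(dim)
        norm = np.linalg.norm(v)
    return v / norm


# ---------------------------------------------------------------------------
# fixture providers


class HashStaticEmbedder:
    """Deterministic static embedder: each word hashes to a unit vector."""

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def embed_word(self, word: str) -> np.ndarray:
        if word not in self._cache:
            self._cache[word] = _hash_unit_vector(self.dim, self.seed, "static", word)
        return self._cache[word]


class HashContextualEmbedder:
    """Deterministic contextual embedder.

    A token's vector blends its own hash vector with its immediate
    neighbours' hash vectors, so the same token in a different context
    receives a different vector — the property that distinguishes the
    contextual track from the static one.
    """

    def __init__(
        self,
        dim: int = 64,
        seed: int = 0,
        context_limit: int = 512,
        neighbor_weight: float = 0.5,
    ):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed
        self.context_limit = context_limit
        self.neighbor_weight = neighbor_weight
        self._cache: dict[str, np.ndarray] = {}

    def _base(self, token: str) -> np.ndarray:
        if token not in self._cache:
            self._cache[token] = _hash_unit_vector(self.dim, self.seed, "contextual", token)
        return self._cache[token]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        if len(tokens) > self.context_limit:
            raise ValueError(
                f"sequence of {len(tokens)} tokens exceeds context limit {self.context_limit}"
            )
        base = np.stack([self._base(t) for t in tokens]) if tokens else np.empty((0, self.dim))
        out = base.copy()
        w = self.neighbor_weight
        if len(tokens) > 1:
            out[1:] += w * base[:-1]
            out[:-1] += w * base[1:]
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        return out / norms


class UniformScorer:
    """Assigns every token probability 1/k over a k-symbol alphabet."""

    def __init__(self, alphabet_size: int):
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        self.alphabet_size = alphabet_size

    def score(self, tokens: Sequence[str]) -> TokenLogProbs:
        _require_predictable(tokens)
        lp = np.full(len(tokens) - 1, -np.log2(self.alphabet_size))
        return TokenLogProbs(logprobs=lp, base="2")


class CertainScorer:
    """Assigns probability 1 to every observed token (zero surprisal)."""

    def score(self, tokens: Sequence[str]) -> TokenLogProbs:
        _require_predictable(tokens)
        return TokenLogProbs(logprobs=np.zeros(len(tokens) - 1), base="2")


class GammaSurprisalScorer:
    """Draws per-token surprisal from a Gamma law with a target mean.

    Surprisal (bits) for each predicted token is Gamma(shape,
    entropy_bits/shape), so the expected cross-entropy equals
    ``entropy_bits`` exactly and log-probabilities are guaranteed
    non-positive.  Output is a pure function of (tokens, seed).
    """

    def __init__(self, entropy_bits: float, seed: int = 0, shape: float = 2.0):
        if entropy_bits < 0:
            raise ValueError("entropy_bits must be >= 0")
        self.entropy_bits = entropy_bits
        self.seed = seed
        self.shape = shape

    def score(self, tokens: Sequence[str]) -> TokenLogProbs:
        _require_predictable(tokens)
        n = len(tokens) - 1
        if self.entropy_bits == 0.0:
            return TokenLogProbs(logprobs=np.zeros(n), base="2")
        rng = stable_rng(self.seed, "surprisal", *tokens)
        surprisal = rng.gamma(self.shape, self.entropy_bits / self.shape, size=n)
        return TokenLogProbs(logprobs=-surprisal, base="2")


class FixtureBimodalEncoder:
    """Sentence vectors = alignment-weighted mix of image vector and noise.

    At ``alignment=1`` every sentence vector equals the image vector; at
    ``alignment=0`` they are independent hash vectors (expected cosine to
    the image vector ~ 0 at large dimensionality).
    """

    def __init__(self, dim: int = 64, seed: int = 0, alignment: float = 0.5):
        if not 0.0 <= alignment <= 1.0:
            raise ValueError("alignment must lie in [0, 1]")
        self.dim = dim
        self.seed = seed
        self.alignment = alignment

    def encode_image(self, image_id: str) -> np.ndarray:
        return _hash_unit_vector(self.dim, self.seed, "image", image_id)

    def encode_sentences(self, sentences: Sequence[str], image_id: str) -> np.ndarray:
        img = self.encode_image(image_id)
        a = self.alignment
        rows = []
        for i, sent in enumerate(sentences):
            noise = _hash_unit_vector(self.dim, self.seed, "sentence", image_id, i, sent)
            v = a * img + (1.0 - a) * noise
            norm = np.linalg.norm(v)
            if norm == 0.0:  # a*img exactly cancelling noise; renoise deterministically
                noise = _hash_unit_vector(self.dim, self.seed, "sentence-r", image_id, i, sent)
                v = a * img + (1.0 - a) * noise
                norm = np.linalg.norm(v)
            rows.append(v / norm)
        return np.stack(rows)


def _require_predictable(tokens: Sequence[str]) -> None:
    if len(tokens) < 2:
        raise ValueError(
            "autoregressive scoring needs >= 2 tokens (the first has no context)"
        )


# ---------------------------------------------------------------------------
# track-level operations


def embed_static(words: Sequence[str], provider: StaticEmbedder) -> EmbeddedSequence:
    """One vector per word, order preserved; position-invariant by contract."""
    if not words:
        return EmbeddedSequence(np.empty((0, provider.dim)), ())
    vectors = np.stack([provider.embed_word(w) for w in words])
    return EmbeddedSequence(vectors, tuple(words))


def embed_contextual(subwords: Sequence[str], provider: ContextualEmbedder) -> EmbeddedSequence:
    """Encode a subword sequence, windowing past the provider's limit.

    Sequences longer than ``provider.context_limit`` are encoded in
    overlapping windows (50% overlap); a token covered by several windows
    keeps the vector from the window where it sits most centrally, so the
    output always has one vector per token.
    """
    if not subwords:
        return EmbeddedSequence(np.empty((0, provider.dim)), ())
    n, limit = len(subwords), provider.context_limit
    if n <= limit:
        return EmbeddedSequence(provider.encode(subwords), tuple(subwords))

    stride = max(limit // 2, 1)
    starts = list(range(0, n - limit + 1, stride))
    if starts[-1] + limit < n:
        starts.append(n - limit)

    vectors = np.empty((n, provider.dim))
    best_centrality = np.full(n, np.inf)
    for s in starts:
        enc = provider.encode(subwords[s : s + limit])
        center = s + (limit - 1) / 2.0
        for off in range(limit):
            i = s + off
            centrality = abs(i - center)
            if centrality < best_centrality[i]:
                best_centrality[i] = centrality
                vectors[i] = enc[off]
    return EmbeddedSequence(vectors, tuple(subwords))


def score_token_logprobs(subwords: Sequence[str], provider: AutoregressiveScorer) -> TokenLogProbs:
    """Conditional log-probability of each token given its left context."""
    _require_predictable(subwords)
    return provider.score(subwords)


def encode_bimodal(sentences: Sequence[str], image_id: str, provider: BimodalEncoder) -> BimodalPair:
    """Encode all sentences and the stimulus picture into one shared space."""
    if not sentences:
        raise ValueError("encode_bimodal requires at least one sentence")
    return BimodalPair(
        sentence_vectors=provider.encode_sentences(sentences, image_id),
        image_vector=provider.encode_image(image_id),
    )
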