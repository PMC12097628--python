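"""Semantic measures over embedded transcripts.

Four measures summarize one transcript:

* **LSim** — mean cosine similarity of *consecutive* token-embedding
  pairs, ``(1/(n-1)) * sum_i cos(e_i, e_{i+1})``: local coherence.
* **GSim** — mean cosine similarity over *all* unordered pairs,
  ``(2/(n(n-1))) * sum_{i<j} cos(e_i, e_j)``: how concentrated the
  transcript's semantic cloud is (contraction of semantic space raises
  it).
* **PPL** — cross-entropy ``H = -(1/n) * sum log2 p(t_i | t_1..i-1)`` in
  bits and its base-2 exponentiation ``2^H``, the effective number of
  equally likely continuations (a fair six-sided die: H ~ 2.585 bits,
  PPL = 6).
* **bimodal alignment** — mean cosine between each sentence's embedding
  and the stimulus picture's embedding in a shared space.

Degenerate transcripts (fewer than two tokens, no sentences) yield NaN
missing markers rather than exceptions, so a cohort run never aborts on
one bad transcript.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np

from .corpus_io import TokenizedTranscript, compute_ttr
from .embedding_backends import (
    AutoregressiveScorer,
    BimodalEncoder,
    BimodalPair,
    ContextualEmbedder,
    EmbeddedSequence,
    StaticEmbedder,
    TokenLogProbs,
    embed_contextual,
    embed_static,
    encode_bimodal,
    score_token_logprobs,
)

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors, clipped to [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimensionality mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    if np.array_equal(u, v):
        return 1.0  # short-circuit: identical vectors, no rounding artifact
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _unit_rows(seq: EmbeddedSequence) -> np.ndarray:
    norms = np.linalg.norm(seq.vectors, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("embedded sequence contains a zero vector")
    return seq.vectors / norms


def local_similarity(seq: EmbeddedSequence) -> float:
    """Mean cosine over the n-1 consecutive pairs; NaN when n < 2."""
    if len(seq) < 2:
        return math.nan
    unit = _unit_rows(seq)
    sims = np.clip(np.einsum("ij,ij->i", unit[:-1], unit[1:]), -1.0, 1.0)
    return float(sims.mean())


def global_similarity(seq: EmbeddedSequence) -> float:
    """Mean cosine over all n(n-1)/2 unordered pairs; NaN when n < 2.

    Self-pairs are excluded and each unordered pair counts once, matching
    the 2/(n(n-1)) normalizer.
    """
    n = len(seq)
    if n < 2:
        return math.nan
    unit = _unit_rows(seq)
    gram = np.clip(unit @ unit.T, -1.0, 1.0)
    total = (gram.sum() - np.trace(gram)) / 2.0
    return float(total / (n * (n - 1) / 2.0))


def perplexity(lp: TokenLogProbs) -> tuple[float, float]:
    """Cross-entropy in bits and perplexity ``2^H`` from token log-probs.

    Internally the mean negative log-likelihood is accumulated in nats
    and converted to bits once; base invariance (``e^H_nats ==
    2^H_bits``) is asserted to 1e-10 relative.
    """
    values = np.asarray(lp.logprobs, dtype=float)
    if len(values) == 0:
        raise ValueError("perplexity requires at least one log-probability")
    if np.any(values > 0):
        raise ValueError("log-probabilities must be <= 0")
    nats = values * _LN2 if lp.base == "2" else values
    h_nats = float(-nats.mean())
    h_bits = h_nats / _LN2
    ppl = 2.0**h_bits
    assert math.isclose(math.exp(h_nats), ppl, rel_tol=1e-10)
    return h_bits, ppl


def bimodal_alignment(pair: BimodalPair) -> float:
    """Mean cosine between each sentence vector and the picture vector."""
    if pair.sentence_vectors.size == 0:
        return math.nan
    sims = [cosine_similarity(row, pair.image_vector) for row in pair.sentence_vectors]
    return float(np.mean(sims))


@dataclass
class SemanticFeatures:
    """One subject's feature row (NaN marks a failed precondition)."""

    ft_lsim: float = math.nan
    ft_gsim: float = math.nan
    bert_lsim: float = math.nan
    bert_gsim: float = math.nan
    cross_entropy: float = math.nan
    ppl: float = math.nan
    bimodal_sim: float = math.nan
    add: float = math.nan
    word_count: int = 0
    subword_count: int = 0
    word_ttr: float = math.nan
    content_word_ttr: float = math.nan
    subword_ttr: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


MEASURE_COLUMNS = ("ft_lsim", "ft_gsim", "bert_lsim", "bert_gsim", "ppl", "bimodal_sim", "add")


def extract_features(
    tok: TokenizedTranscript,
    static_provider: StaticEmbedder | None = None,
    contextual_provider: ContextualEmbedder | None = None,
    scorer: AutoregressiveScorer | None = None,
    bimodal_provider: BimodalEncoder | None = None,
    image_id: str = "stimulus",
    add: float = math.nan,
    subject_id: str = "?",
) -> SemanticFeatures:
    """Compose all measures for one tokenized transcript.

    Conceptual (static) similarities are computed on content words only;
    referential (contextual) similarities and PPL on the full subword
    sequence; bimodal alignment per sentence against the picture.  Any
    measure whose precondition fails is recorded as NaN and the rest of
    the row is still produced.
    """
    feats = SemanticFeatures(
        word_count=len(tok.all_words),
        subword_count=len(tok.subwords),
        word_ttr=compute_ttr(tok.all_words),
        content_word_ttr=compute_ttr(tok.content_words),
        subword_ttr=compute_ttr(tok.subwords),
        add=add,
    )
    if static_provider is not None and len(tok.content_words) >= 2:
        seq = embed_static(tok.content_words, static_provider)
        feats.ft_lsim = local_similarity(seq)
        feats.ft_gsim = global_similarity(seq)
    if contextual_provider is not None and len(tok.subwords) >= 2:
        seq = embed_contextual(tok.subwords, contextual_provider)
        feats.bert_lsim = local_similarity(seq)
        feats.bert_gsim = global_similarity(seq)
    if scorer is not None and len(tok.subwords) >= 2:
        try:
            feats.cross_entropy, feats.ppl = perplexity(
                score_token_logprobs(tok.subwords, scorer)
            )
        except ValueError:
            logger.warning("perplexity failed for subject %s; marked missing", subject_id)
    if bimodal_provider is not None and tok.sentences:
        feats.bimodal_sim = bimodal_alignment(
            encode_bimodal(tok.sentences, image_id, bimodal_provider)
        )
    return feats
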