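"""Synthetic cohorts with recoverable ground truth.

The real picture-description corpora behind this kind of study are
access-restricted, so every pipeline stage is exercised instead on
generated cohorts whose statistical structure is controlled knob by
knob:

* demographics drawn per group from the magnitudes typical of such
  cohorts (controls around MMSE 29, patients far lower; transcripts of
  roughly 30-60 words);
* within-transcript embedding clouds drawn as ``normalize(centroid +
  noise/kappa)`` around a per-subject unit centroid, so the
  concentration ``kappa`` controls expected pairwise cosine (higher
  kappa -> higher GSim; patient groups get higher kappa to emulate the
  contraction of semantic space);
* per-token surprisal drawn from a Gamma law whose mean equals the
  group's target cross-entropy ``h`` (expected PPL ~ 2^h);
* sentence/image vectors mixed at a group alignment level ``a``;
* dependency trees whose arc lengths follow a shifted-geometric law
  with a group mean, so ADD is controlled.

A single global seed expands into per-subject substreams
(``numpy.random.SeedSequence`` spawn keys), so cohorts are reproducible
and independent of generation order.  ``write_cohort`` emits the same
CSV / transcript / CoNLL-U formats the loaders read, so generated
cohorts can exercise the full I/O path.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import SubjectRecord, SubwordVocabulary, load_stopwords, tokenize
from .embedding_backends import BimodalPair, EmbeddedSequence, TokenLogProbs
from .semantic_metrics import (
    bimodal_alignment,
    global_similarity,
    local_similarity,
    perplexity,
)
from .syntax_metrics import DependencyParse, ParseToken, averaged_dependency_distance, write_conllu

__all__ = [
    "GroupParams",
    "CohortSpec",
    "SyntheticCohort",
    "default_spec",
    "generate_cohort",
    "features_from_cohort",
    "write_cohort",
    "generate_worked_examples",
]


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters for one diagnostic group."""

    n: int
    age_mean: float
    age_sd: float
    female_prop: float
    education_mean: float
    education_sd: float
    mmse_mean: float
    mmse_sd: float
    words_mean: float
    words_sd: float
    vocab_pool: int  # active lexicon size per subject (drives TTR down as it shrinks)
    kappa: float  # embedding concentration (higher -> tighter cloud -> higher GSim)
    entropy_bits: float  # target mean surprisal per subword token
    alignment: float  # picture-speech alignment in [0, 1]
    arc_mean: float  # mean dependency-arc length (>= 1)
    # between-subject heterogeneity of the effect knobs; without it the
    # within-transcript averages would be nearly noise-free and any group
    # gap would be implausibly easy to detect
    kappa_sd: float = 0.10  # lognormal sigma of the per-subject kappa
    entropy_sd: float = 0.30  # sd (bits) of the per-subject target entropy
    alignment_sd: float = 0.05  # sd of the per-subject alignment level

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.entropy_bits < 0:
            raise ValueError("entropy_bits must be >= 0")
        if not 0.0 <= self.alignment <= 1.0:
            raise ValueError("alignment must lie in [0, 1]")
        if self.arc_mean < 1.0:
            raise ValueError("arc_mean must be >= 1")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ValueError("female_prop must lie in [0, 1]")
        if self.vocab_pool < 2:
            raise ValueError("vocab_pool must be >= 2")


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of one synthetic cohort."""

    language: str
    seed: int
    nc: GroupParams
    pad: GroupParams
    lexicon_size: int = 160
    embedding_dim: int = 64
    min_words: int = 8
    words_per_sentence: int = 8
    image_id: str = "stimulus"

    def __post_init__(self) -> None:
        if self.language not in ("en", "el"):
            raise ValueError(f"unknown language {self.language!r}")
        if self.lexicon_size < max(self.nc.vocab_pool, self.pad.vocab_pool):
            raise ValueError("lexicon_size must cover the largest vocab_pool")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.min_words < 2:
            raise ValueError("min_words must be >= 2")


def default_spec(language: str = "en", seed: int = 0, **overrides) -> CohortSpec:
    """Cohort spec emulating the published English or Greek datasets.

    Demographic means/SDs, group sizes, female proportions and
    transcript lengths follow the study's descriptive table; the effect
    knobs encode the reported directions (patients: tighter embedding
    clouds, slightly higher adjusted surprisal, weaker picture
    alignment, shorter dependency arcs).
    """
    if language == "en":
        nc = GroupParams(
            n=143, age_mean=66.061, age_sd=6.310, female_prop=0.652,
            education_mean=13.983, education_sd=2.377,
            mmse_mean=28.965, mmse_sd=1.169,
            words_mean=57.7, words_sd=27.7, vocab_pool=120,
            kappa=1.0, entropy_bits=6.0, alignment=0.60, arc_mean=2.4,
        )
        pad = GroupParams(
            n=148, age_mean=69.377, age_sd=6.884, female_prop=0.648,
            education_mean=11.967, education_sd=2.635,
            mmse_mean=17.844, mmse_sd=5.482,
            words_mean=51.5, words_sd=28.1, vocab_pool=85,
            kappa=1.05, entropy_bits=6.25, alignment=0.56, arc_mean=2.1,
        )
    elif language == "el":
        nc = GroupParams(
            n=28, age_mean=66.571, age_sd=7.275, female_prop=0.714,
            education_mean=12.000, education_sd=4.028,
            mmse_mean=28.821, mmse_sd=1.156,
            words_mean=29.4, words_sd=15.5, vocab_pool=120,
            kappa=1.0, entropy_bits=6.0, alignment=0.60, arc_mean=2.4,
        )
        pad = GroupParams(
            n=26, age_mean=72.737, age_sd=6.826, female_prop=0.731,
            education_mean=9.500, education_sd=3.922,
            mmse_mean=20.962, mmse_sd=4.574,
            words_mean=30.2, words_sd=14.7, vocab_pool=85,
            kappa=1.05, entropy_bits=6.25, alignment=0.56, arc_mean=2.1,
        )
    else:
        raise ValueError(f"unknown language {language!r}")
    spec = CohortSpec(language=language, seed=seed, nc=nc, pad=pad)
    if overrides:
        base = asdict(spec)
        for key, value in overrides.items():
            if key in ("nc", "pad"):
                if isinstance(value, GroupParams):
                    base[key] = asdict(value)
                else:
                    base[key].update(value)  # partial per-group override
            else:
                base[key] = value
        base["nc"] = GroupParams(**base["nc"])
        base["pad"] = GroupParams(**base["pad"])
        spec = CohortSpec(**base)
    return spec


@dataclass
class SyntheticCohort:
    """All generated artefacts for one cohort, keyed by subject id."""

    spec: CohortSpec
    records: list[SubjectRecord]
    static_sequences: dict[str, EmbeddedSequence]
    contextual_sequences: dict[str, EmbeddedSequence]
    logprobs: dict[str, TokenLogProbs]
    parses: dict[str, list[DependencyParse]]
    bimodal: dict[str, BimodalPair]
    truth: dict


# ---------------------------------------------------------------------------
# building blocks

_SYLLABLES = [
    c + v for c in "bdfgklmnprstvz" for v in ("a", "e", "i", "o", "u", "ai", "ou")
]


def _lexicon(size: int, language: str, rng: np.random.Generator) -> list[str]:
    """Pronounceable synthetic word forms, guaranteed non-stopwords."""
    stop = load_stopwords(language)
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < size:
        n_syll = int(rng.integers(2, 4))
        w = "".join(_SYLLABLES[int(rng.integers(len(_SYLLABLES)))] for _ in range(n_syll))
        if w not in seen and w not in stop:
            seen.add(w)
            words.append(w)
    return words


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low <= v <= high:
            return float(v)
    return float(min(max(mean, low), high))


def _embedding_cloud(
    rng: np.random.Generator, centroid: np.ndarray, n: int, kappa: float
) -> np.ndarray:
    """Unit vectors around ``centroid`` with noise of total scale 1/kappa."""
    d = centroid.shape[0]
    noise = rng.standard_normal((n, d)) / (kappa * math.sqrt(d))
    cloud = centroid + noise
    return cloud / np.linalg.norm(cloud, axis=1, keepdims=True)


def _random_unit(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def _dependency_tree(
    rng: np.random.Generator, words: list[str], arc_mean: float
) -> DependencyParse:
    """Random tree whose arc lengths follow a shifted geometric law.

    Tokens attach, in random order, to an already-attached token whose
    distance best matches a draw ``1 + Geometric`` with mean
    ``arc_mean``; a trailing period attaches to the root (punctuation
    arcs are excluded from ADD downstream).
    """
    n = len(words)
    positions = list(range(1, n + 1))
    root = int(rng.integers(1, n + 1))
    heads = {root: 0}
    attached = [root]
    order = [p for p in positions if p != root]
    rng.shuffle(order)
    p_geom = min(1.0, 1.0 / arc_mean)
    for pos in order:
        target = int(rng.geometric(p_geom)) if p_geom < 1.0 else 1
        best = min(attached, key=lambda h: (abs(abs(pos - h) - target), abs(pos - h)))
        heads[pos] = best
        attached.append(pos)
    tokens = [
        ParseToken(form=words[p - 1], position=p, head=heads[p], is_punct=False)
        for p in positions
    ]
    tokens.append(ParseToken(form=".", position=n + 1, head=root, is_punct=True, deprel="punct"))
    return DependencyParse(tuple(tokens))


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one full cohort: records, embeddings, log-probs, parses,
    bimodal pairs, and the truth record of every generating parameter."""
    root_ss = np.random.SeedSequence(spec.seed)
    lex_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    lexicon = _lexicon(spec.lexicon_size, spec.language, lex_rng)
    vocab = SubwordVocabulary.default(spec.language)
    image_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    image_vector = _random_unit(image_rng, spec.embedding_dim)

    records: list[SubjectRecord] = []
    static_seqs: dict[str, EmbeddedSequence] = {}
    contextual_seqs: dict[str, EmbeddedSequence] = {}
    logprobs: dict[str, TokenLogProbs] = {}
    parses: dict[str, list[DependencyParse]] = {}
    bimodal: dict[str, BimodalPair] = {}

    idx = 0
    for group, params in (("NC", spec.nc), ("pAD", spec.pad)):
        for j in range(params.n):
            idx += 1
            sid = f"{spec.language}-{group}-{j + 1:03d}"
            rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2, idx)))

            # --- demographics
            age = _truncated_normal(rng, params.age_mean, params.age_sd, 40.0, 100.0)
            sex = "female" if rng.random() < params.female_prop else "male"
            education = _truncated_normal(
                rng, params.education_mean, params.education_sd, 0.0, 30.0
            )
            mmse = round(_truncated_normal(rng, params.mmse_mean, params.mmse_sd, 0.0, 30.0))

            # --- transcript: words drawn from a per-subject active pool
            n_words = max(
                spec.min_words, int(round(rng.normal(params.words_mean, params.words_sd)))
            )
            pool_idx = rng.choice(spec.lexicon_size, size=params.vocab_pool, replace=False)
            pool = [lexicon[k] for k in pool_idx]
            words = [pool[int(k)] for k in rng.integers(0, len(pool), size=n_words)]
            sentences = [
                words[k : k + spec.words_per_sentence]
                for k in range(0, n_words, spec.words_per_sentence)
            ]
            transcript = " ".join(" ".join(s).capitalize() + "." for s in sentences)

            record = SubjectRecord(
                subject_id=sid,
                group=group,
                language=spec.language,
                age=age,
                sex=sex,
                education=education,
                mmse=float(mmse),
                transcript=transcript,
            )
            records.append(record)

            # --- embedding clouds around a per-subject centroid; the
            # subject's own concentration scatters around the group level
            kappa_subj = params.kappa * math.exp(rng.normal(0.0, params.kappa_sd))
            centroid = _random_unit(rng, spec.embedding_dim)
            static_seqs[sid] = EmbeddedSequence(
                _embedding_cloud(rng, centroid, n_words, kappa_subj), tuple(words)
            )
            subwords = [p for w in words for p in vocab.segment(w)]
            contextual_seqs[sid] = EmbeddedSequence(
                _embedding_cloud(rng, centroid, len(subwords), kappa_subj), tuple(subwords)
            )

            # --- token surprisal (bits): Gamma with mean = subject entropy
            n_pred = max(len(subwords) - 1, 1)
            h_subj = max(0.0, rng.normal(params.entropy_bits, params.entropy_sd))
            if h_subj > 0:
                surprisal = rng.gamma(4.0, h_subj / 4.0, size=n_pred)
            else:
                surprisal = np.zeros(n_pred)
            logprobs[sid] = TokenLogProbs(logprobs=-surprisal, base="2")

            # --- bimodal pair
            a = float(np.clip(rng.normal(params.alignment, params.alignment_sd), 0.0, 1.0))
            sent_rows = []
            for _ in sentences:
                noise = _random_unit(rng, spec.embedding_dim)
                v = a * image_vector + (1.0 - a) * noise
                sent_rows.append(v / np.linalg.norm(v))
            bimodal[sid] = BimodalPair(
                sentence_vectors=np.stack(sent_rows), image_vector=image_vector
            )

            # --- dependency parses
            parses[sid] = [_dependency_tree(rng, s, params.arc_mean) for s in sentences]

    truth = {
        "language": spec.language,
        "seed": spec.seed,
        "nc": asdict(spec.nc),
        "pad": asdict(spec.pad),
        "lexicon_size": spec.lexicon_size,
        "embedding_dim": spec.embedding_dim,
        "image_id": spec.image_id,
    }
    return SyntheticCohort(
        spec=spec,
        records=records,
        static_sequences=static_seqs,
        contextual_sequences=contextual_seqs,
        logprobs=logprobs,
        parses=parses,
        bimodal=bimodal,
        truth=truth,
    )


def features_from_cohort(cohort: SyntheticCohort) -> pd.DataFrame:
    """Measure every generated subject: one feature row per subject.

    Conceptual similarities come from the static cloud, referential ones
    from the subword cloud, PPL from the generated log-probabilities,
    ADD from the generated parses, and counts/TTRs from tokenizing the
    written transcript — the same code path real transcripts take.
    """
    rows = []
    for rec in cohort.records:
        tok = tokenize(rec.transcript, cohort.spec.language)
        h, ppl = perplexity(cohort.logprobs[rec.subject_id])
        static = cohort.static_sequences[rec.subject_id]
        contextual = cohort.contextual_sequences[rec.subject_id]
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "language": rec.language,
                "group_pad": 1.0 if rec.group == "pAD" else 0.0,
                "language_el": 1.0 if rec.language == "el" else 0.0,
                "age": rec.age,
                "sex_female": 1.0 if rec.sex == "female" else 0.0,
                "education": rec.education,
                "mmse": rec.mmse,
                "word_count": len(tok.all_words),
                "subword_count": len(tok.subwords),
                "word_ttr": len(set(tok.all_words)) / len(tok.all_words),
                "subword_ttr": len(set(tok.subwords)) / len(tok.subwords),
                "ft_lsim": local_similarity(static),
                "ft_gsim": global_similarity(static),
                "bert_lsim": local_similarity(contextual),
                "bert_gsim": global_similarity(contextual),
                "cross_entropy": h,
                "ppl": ppl,
                "bimodal_sim": bimodal_alignment(cohort.bimodal[rec.subject_id]),
                "add": averaged_dependency_distance(cohort.parses[rec.subject_id]),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write metadata CSV, per-subject transcripts and CoNLL-U parses."""
    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    (out / "parses").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in cohort.records:
        (out / "transcripts" / f"{rec.subject_id}.txt").write_text(
            rec.transcript, encoding="utf-8"
        )
        (out / "parses" / f"{rec.subject_id}.conllu").write_text(
            write_conllu(cohort.parses[rec.subject_id]), encoding="utf-8"
        )
        meta_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "language": rec.language,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                "mmse": rec.mmse,
            }
        )
    meta_path = out / "metadata.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return {
        "metadata": meta_path,
        "transcripts": out / "transcripts",
        "parses": out / "parses",
    }


# ---------------------------------------------------------------------------
# in-text computable fixtures


def generate_worked_examples() -> dict:
    """The small fully-determined fixtures used throughout the docs/tests.

    * a fair six-sided-die token model (every conditional probability
      1/6), whose cross-entropy is log2(6) ~ 2.585 bits and PPL exactly 6;
    * the seven-token sentence "Mary ate the juicy red sweet apple",
      where *apple* (position 7) depends on *ate* (position 2), an arc of
      distance 5;
    * a two-sentence bimodal pair with one perfectly aligned and one
      orthogonal sentence vector (mean alignment 0.5).
    """
    die = TokenLogProbs(logprobs=np.full(10, -math.log2(6.0)), base="2")

    mary = DependencyParse(
        (
            ParseToken("Mary", 1, 2, deprel="nsubj"),
            ParseToken("ate", 2, 0, deprel="root"),
            ParseToken("the", 3, 7, deprel="det"),
            ParseToken("juicy", 4, 7, deprel="amod"),
            ParseToken("red", 5, 7, deprel="amod"),
            ParseToken("sweet", 6, 7, deprel="amod"),
            ParseToken("apple", 7, 2, deprel="obj"),
        )
    )

    image = np.array([1.0, 0.0, 0.0, 0.0])
    pair = BimodalPair(
        sentence_vectors=np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]]),
        image_vector=image,
    )
    return {"die_logprobs": die, "mary_parse": mary, "bimodal_pair": pair}
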