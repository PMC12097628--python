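"""Cohort loading, imputation, tokenization, and group descriptives.

Transcripts arrive as one UTF-8 ``.txt`` file per subject plus a metadata
CSV (``subject_id,group,language,age,sex,education,mmse``; missing values
are empty cells).  Tokenization feeds two tracks: a *conceptual* track of
lowercased content words (stopwords and punctuation removed) for static
word embeddings, and a *referential* track of subword tokens for
contextual models.  Group descriptives mirror the usual cohort table:
Mann-Whitney U with rank-biserial correlation for continuous variables and
a 2x2 chi-square with the contingency coefficient for sex.
"""

from __future__ import annotations

import functools
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("NC", "pAD")
LANGUAGES = ("en", "el")
SEXES = ("female", "male")

_METADATA_COLUMNS = ["subject_id", "group", "language", "age", "sex", "education", "mmse"]


class CohortError(ValueError):
    """Raised for malformed metadata or missing transcript files."""


_DEFAULT_VOCABS: dict[str, "SubwordVocabulary"] = {}


@dataclass(frozen=True)
class SubjectRecord:
    """Metadata plus transcript for one participant.

    ``education`` and ``mmse`` may be ``None`` (missing); ``group`` and
    ``language`` are always present and never imputed.
    """

    subject_id: str
    group: str
    language: str
    age: float
    sex: str
    education: float | None
    mmse: float | None
    transcript: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group label {self.group!r} for subject {self.subject_id!r}")
        if self.language not in LANGUAGES:
            raise CohortError(
                f"unknown language label {self.language!r} for subject {self.subject_id!r}"
            )
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex label {self.sex!r} for subject {self.subject_id!r}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise CohortError(
                f"MMSE {self.mmse} out of [0, 30] for subject {self.subject_id!r}"
            )


@dataclass(frozen=True)
class TokenizedTranscript:
    """One transcript split into the two analysis tracks.

    ``content_words`` is a subsequence of ``all_words`` (stopwords
    removed); ``subwords`` segments every word in ``all_words`` against a
    subword vocabulary; ``sentences`` are surface strings split at
    sentence-final punctuation.
    """

    content_words: tuple[str, ...]
    all_words: tuple[str, ...]
    subwords: tuple[str, ...]
    sentences: tuple[str, ...]


class SubwordVocabulary:
    """Greedy longest-match subword segmenter over a frozen vocabulary.

    Characters absent from the vocabulary are emitted as singleton
    subwords so segmentation never fails.  Real wordpiece tokenizers can
    replace this behind the same ``segment`` contract.
    """

    def __init__(self, tokens: Iterable[str]):
        self._tokens = frozenset(t for t in tokens if t)
        self._max_len = max((len(t) for t in self._tokens), default=1)
        self._memo: dict[str, list[str]] = {}

    @classmethod
    def from_file(cls, path: str | Path) -> "SubwordVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(ln.strip() for ln in lines if ln.strip() and not ln.startswith("#"))

    @classmethod
    def default(cls, language: str = "en") -> "SubwordVocabulary":
        if language not in _DEFAULT_VOCABS:
            text = _read_package_data(f"subword_vocab_{language}.txt")
            _DEFAULT_VOCABS[language] = cls(
                ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
            )
        return _DEFAULT_VOCABS[language]

    def __contains__(self, token: str) -> bool:
        return token in self._tokens

    def __len__(self) -> int:
        return len(self._tokens)

    def segment(self, word: str) -> list[str]:
        if word in self._memo:
            return list(self._memo[word])
        pieces: list[str] = []
        i = 0
        while i < len(word):
            for j in range(min(len(word), i + self._max_len), i, -1):
                if word[i:j] in self._tokens:
                    pieces.append(word[i:j])
                    i = j
                    break
            else:
                pieces.append(word[i])  # out-of-vocabulary character
                i += 1
        self._memo[word] = pieces
        return list(pieces)


def _read_package_data(name: str) -> str:
    return resources.files("semspace.data").joinpath(name).read_text(encoding="utf-8")


@functools.lru_cache(maxsize=None)
def load_stopwords(language: str = "en") -> frozenset[str]:
    """Frozen per-language stopword list shipped as package data."""
    text = _read_package_data(f"stopwords_{language}.txt")
    return frozenset(
        ln.strip().lower() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    )


def _parse_optional_float(value, column: str, subject_id: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortError(
            f"non-numeric {column} value {value!r} for subject {subject_id!r}"
        ) from None


def load_cohort(metadata_table: str | Path, transcript_dir: str | Path) -> list[SubjectRecord]:
    """Pair each metadata row with its transcript file.

    Missing education/MMSE cells are kept as ``None`` (not yet imputed).
    A listed subject without a transcript file, or an unknown
    group/language label, is a hard error naming the offender.
    """
    meta = pd.read_csv(metadata_table, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise CohortError(f"metadata table missing columns: {missing_cols}")
    transcript_dir = Path(transcript_dir)
    records: list[SubjectRecord] = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        path = transcript_dir / f"{sid}.txt"
        if not path.is_file():
            raise CohortError(f"no transcript file for subject {sid!r} (expected {path})")
        age = _parse_optional_float(row.age, "age", sid)
        if age is None:
            raise CohortError(f"missing age for subject {sid!r}")
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row.group),
                language=str(row.language),
                age=age,
                sex=str(row.sex),
                education=_parse_optional_float(row.education, "education", sid),
                mmse=_parse_optional_float(row.mmse, "mmse", sid),
                transcript=path.read_text(encoding="utf-8"),
            )
        )
    return records


def impute_missing(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Fill missing education/MMSE with the NC mean of the same language.

    The donor pool is always the normal-control group of the record's own
    language, whatever the recipient's group; non-missing values are
    untouched, so the operation is idempotent.
    """
    out: list[SubjectRecord] = []
    donor_mean: dict[tuple[str, str], float] = {}

    def _mean(language: str, variable: str) -> float:
        key = (language, variable)
        if key not in donor_mean:
            values = [
                getattr(r, variable)
                for r in records
                if r.language == language and r.group == "NC" and getattr(r, variable) is not None
            ]
            if not values:
                raise CohortError(
                    f"cannot impute {variable}: no NC donor values in language {language!r}"
                )
            donor_mean[key] = float(np.mean(values))
        return donor_mean[key]

    for rec in records:
        changes: dict[str, float] = {}
        if rec.education is None:
            changes["education"] = _mean(rec.language, "education")
        if rec.mmse is None:
            changes["mmse"] = _mean(rec.language, "mmse")
        out.append(replace(rec, **changes) if changes else rec)
    return out


_WORD_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*", re.UNICODE)
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?;])\s+")


def split_sentences(text: str) -> list[str]:
    """Split at ``.``, ``!``, ``?`` or ``;`` followed by whitespace.

    Fragments without any word character (stray punctuation) are dropped.
    """
    parts = [p.strip() for p in _SENTENCE_SPLIT_RE.split(text)]
    return [p for p in parts if p and _WORD_RE.search(p)]


def tokenize(
    transcript: str,
    language: str = "en",
    subword_vocab: SubwordVocabulary | None = None,
    stopwords: frozenset[str] | None = None,
) -> TokenizedTranscript:
    """Lowercase and split a transcript into both analysis tracks.

    Words are maximal alphabetic runs (apostrophes kept word-internal),
    so punctuation-only tokens never appear.  Content words additionally
    drop stopwords; subwords segment every word (nothing is removed for
    the contextual track, which needs the full context).
    """
    if subword_vocab is None:
        subword_vocab = SubwordVocabulary.default(language)
    if stopwords is None:
        stopwords = load_stopwords(language)
    all_words = tuple(m.group(0).lower() for m in _WORD_RE.finditer(transcript))
    content_words = tuple(w for w in all_words if w not in stopwords)
    subwords = tuple(piece for w in all_words for piece in subword_vocab.segment(w))
    return TokenizedTranscript(
        content_words=content_words,
        all_words=all_words,
        subwords=subwords,
        sentences=tuple(split_sentences(transcript)),
    )


def compute_ttr(tokens: Sequence[str]) -> float:
    """Type-token ratio: unique tokens / total tokens (NaN if empty)."""
    if len(tokens) == 0:
        return math.nan
    return len(set(tokens)) / len(tokens)


@dataclass(frozen=True)
class GroupDescriptives:
    """One row of the cohort descriptives table."""

    variable: str
    nc_summary: str
    pad_summary: str
    test: str
    p: float
    effect_size: float


def rank_biserial(first: Sequence[float], second: Sequence[float]) -> float:
    """Rank-biserial correlation ``2*U1/(n1*n2) - 1``.

    ``U1`` is the Mann-Whitney statistic of the first-listed group, so
    the result is positive when ``first`` values tend to exceed
    ``second`` values; equivalently (#favorable - #unfavorable) pairs
    over all n1*n2 comparisons.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    u1 = stats.mannwhitneyu(first, second, alternative="two-sided").statistic
    return float(2.0 * u1 / (len(first) * len(second)) - 1.0)


def contingency_coefficient(table: np.ndarray) -> float:
    """Pearson contingency coefficient ``sqrt(chi2 / (chi2 + N))``."""
    table = np.asarray(table, dtype=float)
    chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
    if chi2 <= 0:
        return 0.0
    return math.sqrt(chi2 / (chi2 + table.sum()))


def _mann_whitney_row(
    variable: str, nc: np.ndarray, pad: np.ndarray
) -> GroupDescriptives:
    nc_summary = f"{nc.mean():.3f} ± {nc.std(ddof=1):.3f}"
    pad_summary = f"{pad.mean():.3f} ± {pad.std(ddof=1):.3f}"
    pooled = np.concatenate([nc, pad])
    if np.all(pooled == pooled[0]):
        return GroupDescriptives(variable, nc_summary, pad_summary, "Mann-Whitney", 1.0, 0.0)
    res = stats.mannwhitneyu(nc, pad, alternative="two-sided")
    r = rank_biserial(nc, pad)
    return GroupDescriptives(variable, nc_summary, pad_summary, "Mann-Whitney", float(res.pvalue), r)


def _sex_row(nc_sex: Sequence[str], pad_sex: Sequence[str]) -> GroupDescriptives:
    nc_f = sum(s == "female" for s in nc_sex)
    pad_f = sum(s == "female" for s in pad_sex)
    table = np.array(
        [[nc_f, len(nc_sex) - nc_f], [pad_f, len(pad_sex) - pad_f]], dtype=float
    )
    nc_summary = f"{100.0 * nc_f / len(nc_sex):.3f}%"
    pad_summary = f"{100.0 * pad_f / len(pad_sex):.3f}%"
    if np.any(table.sum(axis=0) == 0):
        return GroupDescriptives("sex", nc_summary, pad_summary, "chi2", 1.0, 0.0)
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupDescriptives("sex", nc_summary, pad_summary, "chi2", float(p), contingency_coefficient(table))


def describe_groups(
    records: Sequence[SubjectRecord],
    features: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Cohort descriptives: NC vs pAD per variable.

    Continuous variables get a two-sided Mann-Whitney U and rank-biserial
    correlation ``2*U1/(n1*n2) - 1`` (U1 for the NC group); sex gets a 2x2
    Pearson chi-square and contingency coefficient ``sqrt(chi2/(chi2+N))``.
    ``features`` maps extra variable names to per-subject values.
    """
    nc = [r for r in records if r.group == "NC"]
    pad = [r for r in records if r.group == "pAD"]
    if not nc or not pad:
        raise CohortError("describe_groups requires both NC and pAD records")

    rows = []
    for variable in ("age", "education", "mmse"):
        nc_vals = np.array([getattr(r, variable) for r in nc], dtype=float)
        pad_vals = np.array([getattr(r, variable) for r in pad], dtype=float)
        if np.isnan(nc_vals).any() or np.isnan(pad_vals).any():
            raise CohortError(f"missing {variable} values; run impute_missing first")
        rows.append(_mann_whitney_row(variable, nc_vals, pad_vals))
    rows.insert(1, _sex_row([r.sex for r in nc], [r.sex for r in pad]))

    if features:
        for name, per_subject in features.items():
            nc_vals = np.array([per_subject[r.subject_id] for r in nc], dtype=float)
            pad_vals = np.array([per_subject[r.subject_id] for r in pad], dtype=float)
            keep = ~np.isnan(nc_vals), ~np.isnan(pad_vals)
            rows.append(_mann_whitney_row(name, nc_vals[keep[0]], pad_vals[keep[1]]))

    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "NC": r.nc_summary,
                "pAD": r.pad_summary,
                "test": r.test,
                "p": r.p,
                "effect_size": r.effect_size,
            }
            for r in rows
        ]
    )
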