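"""Cohort I/O, imputation, tokenization, and descriptive statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semspace.corpus_io import (
    CohortError,
    SubjectRecord,
    SubwordVocabulary,
    compute_ttr,
    contingency_coefficient,
    describe_groups,
    impute_missing,
    load_cohort,
    rank_biserial,
    split_sentences,
    tokenize,
)


def _write_cohort_files(tmp_path, rows, transcripts):
    meta = tmp_path / "metadata.csv"
    header = "subject_id,group,language,age,sex,education,mmse\n"
    meta.write_text(header + "\n".join(rows) + "\n")
    tdir = tmp_path / "transcripts"
    tdir.mkdir()
    for sid, text in transcripts.items():
        (tdir / f"{sid}.txt").write_text(text)
    return meta, tdir


def _record(sid="s1", group="NC", language="en", education=12.0, mmse=29.0):
    return SubjectRecord(
        subject_id=sid,
        group=group,
        language=language,
        age=70.0,
        sex="female",
        education=education,
        mmse=mmse,
        transcript="hello world.",
    )


class TestLoadCohort:
    def test_pairs_rows_with_transcripts(self, tmp_path):
        meta, tdir = _write_cohort_files(
            tmp_path,
            ["S1,NC,en,66,female,12,29", "S2,pAD,en,71,male,10,18"],
            {"S1": "a boy.", "S2": "a girl."},
        )
        records = load_cohort(meta, tdir)
        assert [r.subject_id for r in records] == ["S1", "S2"]
        assert records[0].transcript == "a boy."
        assert records[1].group == "pAD"

    def test_missing_transcript_error_names_subject(self, tmp_path):
        meta, tdir = _write_cohort_files(
            tmp_path, ["S3,NC,en,66,female,12,29"], {}
        )
        with pytest.raises(CohortError, match="S3"):
            load_cohort(meta, tdir)

    def test_empty_education_cell_marked_missing(self, tmp_path):
        meta, tdir = _write_cohort_files(
            tmp_path, ["S1,NC,en,66,female,,29"], {"S1": "hi there."}
        )
        (rec,) = load_cohort(meta, tdir)
        assert rec.education is None
        assert rec.mmse == 29.0

    def test_unknown_group_label_rejected(self, tmp_path):
        meta, tdir = _write_cohort_files(
            tmp_path, ["S1,MCI,en,66,female,12,29"], {"S1": "hi."}
        )
        with pytest.raises(CohortError, match="MCI"):
            load_cohort(meta, tdir)


class TestImputation:
    def test_missing_education_gets_nc_mean(self):
        records = [
            _record("a", education=12.0),
            _record("b", education=14.0),
            _record("c", education=None),
        ]
        imputed = impute_missing(records)
        assert imputed[2].education == 13.0
        assert imputed[0].education == 12.0

    def test_no_missing_values_is_identity(self):
        records = [_record("a"), _record("b", group="pAD")]
        assert impute_missing(records) == records

    def test_pad_recipient_still_uses_nc_donors(self):
        records = [
            _record("a", group="NC", mmse=28.0),
            _record("b", group="NC", mmse=30.0),
            _record("c", group="pAD", mmse=None),
        ]
        assert impute_missing(records)[2].mmse == 29.0

    def test_donors_restricted_to_same_language(self):
        records = [
            _record("a", language="en", mmse=20.0),
            _record("b", language="el", mmse=30.0, group="NC"),
            _record("c", language="el", mmse=None, group="pAD"),
        ]
        assert impute_missing(records)[2].mmse == 30.0

    def test_no_donor_is_hard_error(self):
        records = [
            _record("a", group="pAD", mmse=20.0),
            _record("b", group="pAD", mmse=None),
        ]
        with pytest.raises(CohortError, match="donor"):
            impute_missing(records)

    def test_idempotent(self):
        records = [_record("a", education=10.0), _record("b", education=None)]
        once = impute_missing(records)
        assert impute_missing(once) == once


class TestTokenize:
    def test_stopwords_removed_from_content_track(self):
        tok = tokenize(
            "the boy ate the cookie.",
            subword_vocab=SubwordVocabulary(["a"]),
            stopwords=frozenset({"the"}),
        )
        assert list(tok.content_words) == ["boy", "ate", "cookie"]
        assert list(tok.all_words) == ["the", "boy", "ate", "the", "cookie"]

    def test_longest_match_segmentation(self):
        vocab = SubwordVocabulary(["coo", "kie", "cookie"])
        assert vocab.segment("cookie") == ["cookie"]
        assert vocab.segment("cookiecoo") == ["cookie", "coo"]

    def test_oov_characters_become_singletons(self):
        vocab = SubwordVocabulary(["ab"])
        assert vocab.segment("abq") == ["ab", "q"]

    def test_sentence_split(self):
        assert split_sentences("He ran. She fell.") == ["He ran.", "She fell."]
        assert split_sentences("Stop! Why? Go; now.") == ["Stop!", "Why?", "Go;", "now."]

    def test_content_words_subsequence_of_all_words(self):
        tok = tokenize("The boy, who ran, ate a big cookie!", language="en")
        it = iter(tok.all_words)
        assert all(w in it for w in tok.content_words)

    def test_subword_count_at_least_word_count(self):
        tok = tokenize("overflow water dishes everywhere.", language="en")
        assert len(tok.subwords) >= len(tok.all_words)


class TestTTR:
    @pytest.mark.parametrize(
        "tokens, expected",
        [(["a", "b", "c"], 1.0), (["a"] * 4, 0.25), (["a", "b", "a", "c"], 0.75)],
    )
    def test_examples(self, tokens, expected):
        assert compute_ttr(tokens) == pytest.approx(expected)

    def test_empty_is_missing(self):
        assert math.isnan(compute_ttr([]))

    @given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_order_invariance(self, tokens):
        assert compute_ttr(tokens) == compute_ttr(tokens[::-1])


def _brute_force_rank_biserial(first, second):
    fav = sum(a > b for a, b in itertools.product(first, second))
    unfav = sum(a < b for a, b in itertools.product(first, second))
    return (fav - unfav) / (len(first) * len(second))


class TestGroupDescriptives:
    def test_fully_separated_groups(self):
        r = rank_biserial([1, 2, 3], [4, 5, 6])
        assert abs(r) == pytest.approx(1.0)
        assert r == pytest.approx(-1.0)  # first group uniformly smaller

    def test_identical_distributions_give_zero(self):
        assert rank_biserial([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    @given(
        st.lists(st.integers(0, 10), min_size=2, max_size=8),
        st.lists(st.integers(0, 10), min_size=2, max_size=8),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_pair_counting_oracle(self, first, second):
        assert rank_biserial(first, second) == pytest.approx(
            _brute_force_rank_biserial(first, second), abs=1e-12
        )

    def test_balanced_table_has_zero_association(self):
        assert contingency_coefficient([[10, 10], [10, 10]]) == 0.0

    def test_contingency_coefficient_below_one(self):
        assert 0.0 < contingency_coefficient([[30, 2], [3, 25]]) < 1.0

    def test_table_layout(self):
        nc = [_record(f"n{i}", mmse=29.0) for i in range(4)]
        pad = [_record(f"p{i}", group="pAD", mmse=18.0 + i) for i in range(4)]
        table = describe_groups(nc + pad)
        assert list(table["variable"]) == ["age", "sex", "education", "mmse"]
        mmse_row = table[table["variable"] == "mmse"].iloc[0]
        assert mmse_row["effect_size"] == pytest.approx(1.0)  # NC all higher
        age_row = table[table["variable"] == "age"].iloc[0]
        assert age_row["p"] == 1.0 and age_row["effect_size"] == 0.0  # constant

    def test_extra_features_appended(self):
        nc = [_record(f"n{i}") for i in range(3)]
        pad = [_record(f"p{i}", group="pAD") for i in range(3)]
        wc = {r.subject_id: float(i) for i, r in enumerate(nc + pad)}
        table = describe_groups(nc + pad, features={"word_count": wc})
        assert "word_count" in set(table["variable"])
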