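"""Corpus data model, JSONL round-trips, splitting and count tables."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surgspeech.corpus import (
    Corpus,
    CorpusError,
    Segment,
    load_corpus,
    phase_counts,
    save_corpus,
    split_corpus,
    table2_fixture,
)

# Marginals of the study counts table.  The published row totals for
# videos 3, 8 and 15 (66, 167, 58) disagree with the sums of their own
# cells (63, 161, 56); the column totals and the grand total of 611 are
# consistent with the cells, so marginals are always computed from cells.
ROW_TOTALS = [36, 22, 63, 22, 44, 34, 26, 161, 39, 23, 12, 29, 15, 29, 56]
COL_TOTALS = [59, 102, 104, 42, 50, 54, 22, 178]
GRAND_TOTAL = 611


def _corpus(records):
    return Corpus([Segment(*r) for r in records])


texts = st.text(
    alphabet=st.characters(codec="utf-8", categories=("L", "N"), include_characters="áéíóúñ"),
    min_size=1,
    max_size=12,
).filter(lambda s: s.strip())


@st.composite
def corpora(draw):
    n_videos = draw(st.integers(0, 4))
    segments = []
    for v in range(n_videos):
        length = draw(st.integers(1, 6))
        for i in range(length):
            segments.append(
                Segment(f"v{v}", i, draw(texts), draw(st.integers(1, 8)))
            )
    return Corpus(segments)


class TestSegmentValidation:
    def test_rejects_empty_text(self):
        with pytest.raises(CorpusError):
            Segment("v1", 0, "   ", 1)

    def test_rejects_phase_out_of_range(self):
        with pytest.raises(CorpusError):
            Segment("v1", 0, "hola", 9)

    def test_rejects_non_consecutive_indices(self):
        with pytest.raises(CorpusError):
            Corpus([Segment("v1", 0, "a", 1), Segment("v1", 2, "b", 1)])


class TestRoundTrip:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(corpora())
    def test_save_load_identity(self, tmp_path_factory, corpus):
        path = tmp_path_factory.mktemp("rt") / "c.jsonl"
        save_corpus(corpus, path)
        assert load_corpus(path) == corpus
        # second save is byte-identical
        data1 = path.read_bytes()
        save_corpus(load_corpus(path), path)
        assert path.read_bytes() == data1

    def test_accented_text_preserved(self, tmp_path):
        corpus = _corpus([("v1", 0, "la vesícula está libre", 4)])
        path = tmp_path / "c.jsonl"
        save_corpus(corpus, path)
        assert "vesícula" in path.read_text(encoding="utf-8")
        assert load_corpus(path).segments[0].text == "la vesícula está libre"

    def test_empty_corpus(self, tmp_path):
        path = tmp_path / "c.jsonl"
        save_corpus(Corpus([]), path)
        assert load_corpus(path) == Corpus([])

    def test_order_preserved(self, tmp_path):
        corpus = _corpus([("v1", 0, "uno", 1), ("v1", 1, "dos", 2)])
        path = tmp_path / "c.jsonl"
        save_corpus(corpus, path)
        loaded = load_corpus(path)
        assert [s.index for s in loaded] == [0, 1]


class TestLoadErrors:
    def test_malformed_json_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"video_id": "v1", "index": 0, "text": "a", "phase": 1}\n{oops\n')
        with pytest.raises(CorpusError, match=":2:"):
            load_corpus(path)

    def test_phase_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(
            {"video_id": "v1", "index": 0, "text": "a", "phase": 9}) + "\n")
        with pytest.raises(CorpusError):
            load_corpus(path)

    def test_missing_field_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps({"video_id": "v1", "index": 0, "text": "a"}) + "\n")
        with pytest.raises(CorpusError, match="phase"):
            load_corpus(path)


class TestSplit:
    def test_partition_by_whole_videos(self, fixture_corpus):
        corpus, fix = fixture_corpus
        train, test = split_corpus(corpus, {"1", "2"})
        assert len(train) + len(test) == len(corpus)
        assert set(test.video_ids) == {"1", "2"}
        assert len(train.video_ids) == 13
        assert set(train.video_ids) & set(test.video_ids) == set()

    def test_empty_test_set(self, fixture_corpus):
        corpus, _ = fixture_corpus
        train, test = split_corpus(corpus, set())
        assert train == corpus and len(test) == 0

    def test_all_videos_test(self, fixture_corpus):
        corpus, _ = fixture_corpus
        train, test = split_corpus(corpus, set(corpus.video_ids))
        assert len(train) == 0 and test == corpus

    def test_unknown_video_rejected(self, fixture_corpus):
        corpus, _ = fixture_corpus
        with pytest.raises(CorpusError, match="unknown"):
            split_corpus(corpus, {"nope"})


class TestPhaseCounts:
    def test_single_segment(self):
        table = phase_counts(_corpus([("v1", 0, "hola", 3)]))
        assert table.counts.loc["v1", 3] == 1
        assert table.grand_total == 1

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(corpora())
    def test_marginals_consistent(self, corpus):
        table = phase_counts(corpus)
        m = table.counts.to_numpy()
        assert (table.video_totals.to_numpy() == m.sum(axis=1)).all()
        assert (table.phase_totals.to_numpy() == m.sum(axis=0)).all()
        assert table.grand_total == m.sum() == len(corpus)


class TestStudyFixture:
    def test_every_printed_marginal(self):
        fix = table2_fixture()
        assert fix.video_totals.tolist() == ROW_TOTALS
        assert fix.phase_totals.tolist() == COL_TOTALS
        assert fix.grand_total == GRAND_TOTAL

    def test_individual_cells(self):
        fix = table2_fixture()
        assert fix.counts.loc["8", 8] == 61
        assert fix.video_totals["1"] == 36
        assert fix.test_video_ids == frozenset({"1", "2"})

    def test_csv_export_layout(self, tmp_path):
        fix = table2_fixture()
        path = tmp_path / "counts.csv"
        fix.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("video,phase_1")
        assert lines[-1].endswith(str(GRAND_TOTAL))
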