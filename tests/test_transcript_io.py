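import numpy as np
import pytest

from dyadsync import (
    FrameFeatureMatrix,
    Session,
    Turn,
    merge_adjacent_same_speaker,
    read_feature_csv,
    read_transcript,
    write_feature_csv,
    write_transcript,
)
from dyadsync.transcript_io import TranscriptParseError, tokenize


def _turn(k, speaker, start, end, tokens=(), sid="s1"):
    return Turn(sid, k, speaker, start, end, tokens)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Hello there!", ["hello", "there"]),
            ("  it's   FINE. ", ["it's", "fine"]),
            ("... --- ", []),
            ("don't stop, (really)", ["don't", "stop", "really"]),
        ],
    )
    def test_lowercase_strip_split(self, text, expected):
        assert tokenize(text) == expected


class TestReadTranscript:
    def test_tsv_two_rows(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "session_id\tspeaker\tstart_s\tend_s\ttext\n"
            "s1\tA\t0\t1\thello there\n"
            "s1\tB\t1\t2\thi\n"
        )
        s = read_transcript(p, "tsv")
        assert s.n_turns == 2
        assert s.turns[0].tokens == ("hello", "there")
        assert s.turns[1].tokens == ("hi",)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        with pytest.raises(TranscriptParseError, match="no turns"):
            read_transcript(p, "tsv")

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "session_id\tspeaker\tstart_s\tend_s\ttext\n"
            "s1\tA\t0\t1\tok\n"
            "s1\tB\tnot_a_number\t2\tbad\n"
        )
        with pytest.raises(TranscriptParseError, match=":3"):
            read_transcript(p, "tsv")

    def test_overlapping_same_speaker_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "session_id\tspeaker\tstart_s\tend_s\ttext\n"
            "s1\tA\t0\t2\tx\n"
            "s1\tA\t1\t3\ty\n"
        )
        with pytest.raises(TranscriptParseError, match="overlap"):
            read_transcript(p, "tsv")

    def test_rttm_three_rows(self, tmp_path):
        p = tmp_path / "a.rttm"
        p.write_text(
            "SPEAKER s1 1 0.00 1.50 <NA> <NA> child <NA> <NA>\n"
            "SPEAKER s1 1 1.60 0.90 <NA> <NA> clin <NA> <NA>\n"
            "SPEAKER s1 1 2.60 2.00 <NA> <NA> child <NA> <NA>\n"
        )
        s = read_transcript(p, "rttm")
        assert s.n_turns == 3
        assert [t.speaker for t in s.turns] == ["A", "B", "A"]
        assert all(t.tokens == () for t in s.turns)

    def test_json_dialect(self, tmp_path):
        p = tmp_path / "a.json"
        p.write_text(
            '[{"session_id": "s1", "speaker": "A", "start_s": 0, "end_s": 1, "text": "Hi!"}]'
        )
        s = read_transcript(p, "json")
        assert s.turns[0].tokens == ("hi",)

    def test_sorted_by_onset(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "session_id\tspeaker\tstart_s\tend_s\ttext\n"
            "s1\tB\t1\t2\tsecond\n"
            "s1\tA\t0\t1\tfirst\n"
        )
        s = read_transcript(p, "tsv")
        assert [t.tokens[0] for t in s.turns] == ["first", "second"]


class TestMerge:
    @pytest.mark.parametrize(
        "speakers,expected",
        [("AAB", "AB"), ("ABA", "ABA"), ("A", "A"), ("AABBA", "ABA")],
    )
    def test_merge_patterns(self, speakers, expected):
        turns = [_turn(i, sp, i, i + 1, (f"w{i}",)) for i, sp in enumerate(speakers)]
        merged = merge_adjacent_same_speaker(Session("s1", tuple(turns)))
        assert "".join(t.speaker for t in merged.turns) == expected

    def test_tokens_appended_and_span_unioned(self):
        turns = [_turn(0, "A", 0, 1, ("a",)), _turn(1, "A", 1.5, 2.5, ("b",))]
        merged = merge_adjacent_same_speaker(Session("s1", tuple(turns)))
        assert merged.turns[0].tokens == ("a", "b")
        assert merged.turns[0].end_s == 2.5

    def test_idempotent(self):
        turns = [_turn(i, sp, i, i + 1) for i, sp in enumerate("AABAB")]
        once = merge_adjacent_same_speaker(Session("s1", tuple(turns)))
        twice = merge_adjacent_same_speaker(once)
        assert once == twice


class TestRoundTrip:
    def test_session_round_trip(self, tmp_path):
        turns = (
            _turn(0, "A", 0.0, 1.25, ("hello", "there")),
            _turn(1, "B", 1.5, 2.0, ("hi",)),
        )
        s = Session("s1", turns)
        p = tmp_path / "rt.tsv"
        write_transcript(s, p)
        back = read_transcript(p, "tsv")
        assert back.session_id == s.session_id
        assert back.turns == s.turns

    def test_feature_matrix_round_trip(self, tmp_path):
        mat = FrameFeatureMatrix(np.arange(12.0).reshape(4, 3), ("f1", "f2", "f3"))
        p = tmp_path / "m.csv"
        write_feature_csv(mat, p)
        back = read_feature_csv(p)
        np.testing.assert_array_equal(back.values, mat.values)
        assert back.feature_names == mat.feature_names


class TestFeatureCsv:
    def test_3x2(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n1,2\n3,4\n5,6\n")
        mat = read_feature_csv(p)
        assert mat.values.shape == (3, 2)

    def test_header_only_errors(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n")
        with pytest.raises(TranscriptParseError, match="empty matrix"):
            read_feature_csv(p)

    def test_non_numeric_names_cell(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n1,2\n3,oops\n")
        with pytest.raises(TranscriptParseError, match="row 3.*'b'"):
            read_feature_csv(p)

    def test_nan_rejected_unless_allowed(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n1,2\n3,nan\n")
        with pytest.raises(TranscriptParseError, match="NaN"):
            read_feature_csv(p)
        mat = read_feature_csv(p, allow_nan=True)
        assert np.isnan(mat.values[1, 1])


class TestInvariants:
    def test_turn_times_ordered(self):
        with pytest.raises(ValueError, match="end_s"):
            _turn(0, "A", 1.0, 1.0)

    def test_session_needs_turns(self):
        with pytest.raises(ValueError, match="no turns"):
            Session("s1", ())

    def test_turn_index_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increase"):
            Session("s1", (_turn(1, "A", 0, 1), _turn(0, "B", 1, 2)))
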