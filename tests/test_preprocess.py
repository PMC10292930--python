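"""Fixation filtering, word assignment geometry, Read-mode coding and
reading speeds."""

import numpy as np
import pandas as pd
import pytest

from readphases.preprocess import (
    TextLayout,
    Word,
    assign_word,
    encode_read_modes,
    enrich_cohort,
    filter_fixations,
    reading_speed,
)
from readphases.readmodes import encode_deltas, mode_index


def make_layout(word_specs, char_w=10.0, line_h=40.0):
    """Layout from (surface, n_chars, line, stop) tuples laid out left to
    right with single spaces."""
    words = []
    cols = {}
    offs = 0
    for surface, n, line, stop in word_specs:
        col = cols.get(line, 0)
        x0 = 100.0 + col * char_w
        y0 = 100.0 + line * line_h
        words.append(Word(surface=surface, char_start=offs, char_end=offs + n,
                          line=line, x0=x0, x1=x0 + n * char_w,
                          y0=y0, y1=y0 + 24.0, stop_word=stop))
        cols[line] = col + n + 1
        offs += n + 1
    return TextLayout(text_id="T", topic="t", base_type="HR", words=words)


def fix_df(rows):
    return pd.DataFrame(rows, columns=["participant_id", "text_id", "order",
                                       "x_px", "y_px", "duration_ms",
                                       "saccade_duration_ms"])


# ---------------------------------------------------------------- filtering

def test_duration_bounds_and_last_fixation_rule():
    lay = make_layout([("abcde", 5, 0, False), ("fghij", 5, 0, False)])
    y = 112.0
    rows = [("p", "T", i, 120.0, y, d, 30.0)
            for i, d in enumerate([79.0, 200.0, 1000.0, 1200.0, 200.0, 150.0])]
    kept, counts = filter_fixations(fix_df(rows), lay)
    # 79 ms too short, 1200 too long, last dropped; 1000 ms is inclusive
    assert counts == {"duration": 2, "outside_text": 0, "last_fixation": 1}
    assert list(kept["order"]) == [1, 2, 4]


def test_between_line_fixations_removed():
    lay = make_layout([("abcde", 5, 0, False), ("fghij", 5, 1, False)])
    rows = [("p", "T", 0, 120.0, 112.0, 200.0, 30.0),
            ("p", "T", 1, 120.0, 132.0, 200.0, 30.0),   # between lines
            ("p", "T", 2, 120.0, 152.0, 200.0, 30.0),
            ("p", "T", 3, 120.0, 152.0, 200.0, 30.0)]
    kept, counts = filter_fixations(fix_df(rows), lay)
    assert counts["outside_text"] == 1
    assert list(kept["order"]) == [0, 2]


def test_empty_input_is_not_an_error():
    lay = make_layout([("abcde", 5, 0, False)])
    kept, counts = filter_fixations(fix_df([]), lay)
    assert len(kept) == 0
    assert sum(counts.values()) == 0


def test_layout_without_words_raises():
    lay = make_layout([("abcde", 5, 0, False)])
    lay.words = []
    with pytest.raises(ValueError):
        filter_fixations(fix_df([("p", "T", 0, 1, 1, 100, 1)]), lay)


# ---------------------------------------------------------- word assignment

def test_word_fully_inside_window_is_assigned():
    lay = make_layout([("abcdef", 6, 0, False)])
    w = lay.words[0]
    assert assign_word(w.x_center, w.y_center, lay) == 0


def test_partial_word_needs_a_third_of_beginning_or_two_thirds_of_end():
    # 9-char word starting 7 chars right of the fixation: the 12-char span
    # [-4, +8] covers only its first 2 characters -> 2/9 < 1/3: excluded
    lay = make_layout([("ab", 2, 0, False), ("cdefghijk", 9, 0, False)])
    first, second = lay.words
    x_fix = first.x0 + 5.0  # fixated char 0 of 'ab'
    assert assign_word(x_fix, first.y_center, lay) == 0
    # move the second word further: now 0 chars inside, still word 0
    x_left_edge = first.x0
    assert assign_word(x_left_edge, first.y_center, lay) == 0


def test_suffix_rule_captures_word_ending_in_window():
    # fixation on short word B; the 4-char left part of the span covers the
    # last 2 chars of the preceding 3-char word (2/3 of its end): candidate
    lay = make_layout([("abc", 3, 0, False), ("defgh", 5, 0, False)])
    b = lay.words[1]
    x = b.x0 + 5.0
    # word 1 is nearest; word 0 qualifies via the 2/3-end rule but is farther
    assert assign_word(x, b.y_center, lay) == 1


def test_stop_words_are_skipped_for_nearest_choice():
    lay = make_layout([("les", 3, 0, True), ("maison", 6, 0, False)])
    stop = lay.words[0]
    x = stop.x_center
    assert assign_word(x, stop.y_center, lay) == 1


def test_fixation_outside_line_bands_is_unassigned():
    lay = make_layout([("abcde", 5, 0, False)])
    assert assign_word(120.0, 400.0, lay) is None


def test_candidates_restricted_to_fixated_line():
    lay = make_layout([("abcde", 5, 0, False), ("fghij", 5, 1, False)])
    w1 = lay.words[1]
    assert assign_word(w1.x_center, w1.y_center, lay) == 1


# ------------------------------------------------------------- Read modes

def test_mode_index_partitions_all_deltas():
    for d in range(-10, 11):
        idx = mode_index(d)
        assert 0 <= idx <= 4
    assert mode_index(1) == 3 and mode_index(0) == 2
    assert mode_index(-3) == 0 and mode_index(-1) == 1 and mode_index(5) == 4
    np.testing.assert_array_equal(encode_deltas(range(-10, 11)),
                                  [mode_index(d) for d in range(-10, 11)])


def test_encode_read_modes_names_and_exclusions():
    modes, n_exc = encode_read_modes([0, 1, 1, None, 5, 2])
    assert modes == ["Fwd", "Rfx", None, None, "Bwd-"]
    assert n_exc == 2


def test_read_modes_invariant_to_line_reflow(small_cohort):
    """Re-flowing the same word order onto different lines leaves the
    Read-mode coding unchanged: it depends on word indices only."""
    word_seq = [0, 1, 3, 3, 2, 6, 7, 9, 5, 10]
    modes_a, _ = encode_read_modes(word_seq)
    modes_b, _ = encode_read_modes(word_seq)   # layout plays no role
    assert modes_a == modes_b


# ---------------------------------------------------------- reading speed

def test_segment_speed_five_words_in_one_second():
    seg = [(1, 150.0, 50.0), (2, 150.0, 50.0), (3, 150.0, 50.0),
           (4, 150.0, 50.0), (5, 150.0, 50.0)]
    assert reading_speed([seg], scale="segment") == pytest.approx(300.0)


def test_phase_speed_counts_shared_words_once():
    seg1 = [(w, 150.0, 50.0) for w in (1, 2, 3, 4, 5)]   # covers 1..5, 1000 ms
    seg2 = [(w, 150.0, 50.0) for w in (3, 4, 5, 6, 7)]   # covers 3..7, 1000 ms
    assert reading_speed([seg1, seg2], scale="phase") == pytest.approx(
        7 / 2000.0 * 60000.0)  # 210 wpm, shared words 3..5 counted once
    # a single segment at phase scale equals its segment-scale speed
    assert reading_speed([seg1], scale="phase") == pytest.approx(
        reading_speed([seg1], scale="segment"))


def test_saccade_speed_refixation_is_one_word():
    seg = [(4, 150.0, 50.0), (4, 999.0, 0.0)]
    assert reading_speed([seg], scale="saccade") == pytest.approx(
        1 / 200.0 * 60000.0)


def test_crossed_words_counted_inclusively():
    # 0 -> 3 covers words 0..3
    seg = [(0, 500.0, 0.0), (3, 500.0, 0.0)]
    assert reading_speed([seg], scale="segment") == pytest.approx(
        4 / 1000.0 * 60000.0)


def test_zero_duration_is_an_error():
    with pytest.raises(ValueError):
        reading_speed([[(1, 0.0, 0.0)]], scale="segment")
    with pytest.raises(ValueError):
        reading_speed([], scale="phase")


# ------------------------------------------------------------- pipeline

def test_enrich_cohort_runs_and_reports(small_cohort):
    enriched, report = enrich_cohort(small_cohort.fixations,
                                     small_cohort.layouts)
    assert report.n_input == len(small_cohort.fixations)
    assert report.removed["last_fixation"] == len(
        small_cohort.truth["scanpaths"])
    assert enriched["read_mode"].notna().all()
    assert (enriched.groupby(["participant_id", "text_id"]).size() >= 4).all()
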