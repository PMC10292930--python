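"""From raw fixations to word-indexed, Read-mode-coded scanpaths.

The pipeline mirrors standard practice for reading experiments on short
multi-line texts:

1. fixations shorter than 80 ms or longer than 1000 ms, fixations between
   lines or outside the text zone, and the final fixation of each trial
   (which has no outgoing saccade) are removed;
2. each remaining fixation is assigned at most one word, using a
   word-identification span of 4 characters to the left and 8 to the right
   of the fixated character (35 px high): candidate words on the fixated
   line must have at least 1/3 of their beginning or 2/3 of their end inside
   the span, and the closest non-stop-word candidate to the fixation centre
   wins;
3. the outgoing saccade of each fixation is coded into the five Read modes
   from the signed word-index change;
4. reading speeds in words per minute can be computed at the saccade,
   segment, or phase scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readmodes import READ_MODES, mode_index

#: default French function words ineligible for fixation-word assignment
DEFAULT_STOPWORDS = frozenset(
    "le la les un une de du des et ou en au aux ce se que qui ne pas sur "
    "dans par pour avec il elle ils elles je tu nous vous son sa ses est "
    "sont a ont".split()
)

FIXATION_COLUMNS = ["participant_id", "text_id", "order", "x_px", "y_px",
                    "duration_ms", "saccade_duration_ms"]

#: fixation-duration retention bounds, ms
MIN_FIXATION_MS = 80.0
MAX_FIXATION_MS = 1000.0

#: word-identification span, characters left/right of the fixated character
SPAN_LEFT_CHARS = 4
SPAN_RIGHT_CHARS = 8
SPAN_HEIGHT_PX = 35.0

#: scanpaths shorter than this (after filtering) are dropped
MIN_SCANPATH_FIXATIONS = 4


@dataclass
class Word:
    surface: str
    char_start: int
    char_end: int            # half-open
    line: int
    x0: float
    x1: float
    y0: float
    y1: float
    stop_word: bool = False

    @property
    def n_chars(self) -> int:
        return self.char_end - self.char_start

    @property
    def x_center(self) -> float:
        return 0.5 * (self.x0 + self.x1)

    @property
    def y_center(self) -> float:
        return 0.5 * (self.y0 + self.y1)


@dataclass
class TextLayout:
    """Words of one displayed text with character and pixel extents."""

    text_id: str
    topic: str
    base_type: str                      # HR / MR / UR
    words: list
    extended_type: str | None = None    # set by semantic classification

    def __post_init__(self):
        for w in self.words:
            if w.line < 0:
                raise ValueError("negative line index")
        for line in set(w.line for w in self.words):
            spans = sorted((w.char_start, w.char_end) for w in self.words
                           if w.line == line)
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(
                        f"overlapping character ranges on line {line}")

    @property
    def n_words(self) -> int:
        return len(self.words)

    def line_band(self, line: int):
        ws = [w for w in self.words if w.line == line]
        return min(w.y0 for w in ws), max(w.y1 for w in ws)

    def lines(self) -> list[int]:
        return sorted(set(w.line for w in self.words))

    @classmethod
    def from_dict(cls, d: dict, stopwords=None) -> "TextLayout":
        words = []
        for wd in d["words"]:
            stop = bool(wd.get("stop_word", False))
            if stopwords is not None:
                stop = stop or wd["surface"].lower() in stopwords
            words.append(Word(
                surface=wd["surface"], char_start=int(wd["char_start"]),
                char_end=int(wd["char_end"]), line=int(wd["line"]),
                x0=float(wd["x0"]), x1=float(wd["x1"]),
                y0=float(wd["y0"]), y1=float(wd["y1"]), stop_word=stop,
            ))
        return cls(text_id=str(d["text_id"]), topic=d.get("topic", ""),
                   base_type=d.get("base_type", "HR"), words=words,
                   extended_type=d.get("extended_type"))

    def to_dict(self) -> dict:
        return {
            "text_id": self.text_id, "topic": self.topic,
            "base_type": self.base_type, "extended_type": self.extended_type,
            "words": [vars(w) for w in self.words],
        }


def load_layouts(path, stopwords=None) -> dict:
    """Read a layout JSON file (a list of text objects) into TextLayouts."""
    with open(path) as fh:
        data = json.load(fh)
    out = {}
    for d in data:
        lay = TextLayout.from_dict(d, stopwords=stopwords)
        out[lay.text_id] = lay
    return out


def load_fixations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation table lacks columns: {missing}")
    return df


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def filter_fixations(fixations: pd.DataFrame, layout: TextLayout,
                     min_ms: float = MIN_FIXATION_MS,
                     max_ms: float = MAX_FIXATION_MS,
                     drop_last: bool = True):
    """Apply the standard retention rules to one trial's fixations.

    Retains fixations with ``min_ms <= duration <= max_ms`` falling inside
    some line's vertical text band; drops the final fixation of the trial
    (its outgoing saccade is undefined) unless ``drop_last=False`` — the
    pipeline defers that removal until the final fixation's word has served
    to code the preceding saccade.  Returns ``(filtered DataFrame, counts
    dict)`` with per-rule removal counts.
    """
    counts = {"duration": 0, "outside_text": 0, "last_fixation": 0}
    if len(fixations) == 0:
        return fixations.copy(), counts
    if not layout.words:
        raise ValueError("layout has no words / pixel boxes")
    fx = fixations.sort_values("order")
    last_order = fx["order"].iloc[-1]
    bands = [layout.line_band(line) for line in layout.lines()]
    x_lo = min(w.x0 for w in layout.words)
    x_hi = max(w.x1 for w in layout.words)
    x_margin = 0.1 * (x_hi - x_lo)  # tolerance for overshoot at line edges
    keep = []
    for _, row in fx.iterrows():
        if drop_last and row["order"] == last_order:
            counts["last_fixation"] += 1
            continue
        if not (min_ms <= row["duration_ms"] <= max_ms):
            counts["duration"] += 1
            continue
        y = row["y_px"]
        in_band = any(y0 <= y <= y1 for (y0, y1) in bands)
        if not in_band or not (x_lo - x_margin <= row["x_px"] <= x_hi + x_margin):
            counts["outside_text"] += 1
            continue
        keep.append(row.name)
    return fx.loc[keep], counts


# ----------------------------------------------------------------------
# word assignment
# ----------------------------------------------------------------------

def _fixated_line(y: float, layout: TextLayout):
    for line in layout.lines():
        y0, y1 = layout.line_band(line)
        if y0 <= y <= y1:
            return line
    return None


def assign_word(x: float, y: float, layout: TextLayout):
    """Word index processed during a fixation at pixel (x, y), or None.

    The word-identification span covers ``SPAN_LEFT_CHARS`` characters left
    and ``SPAN_RIGHT_CHARS`` right of the fixated character on the fixated
    line.  A word qualifies when the part of it inside the span covers at
    least 1/3 of its beginning or 2/3 of its end (character-level); among
    qualifying non-stop words the one whose centre is nearest the fixation
    wins, ties toward the earlier word.
    """
    line = _fixated_line(y, layout)
    if line is None:
        return None
    words = [(i, w) for i, w in enumerate(layout.words) if w.line == line]
    if not words:
        return None
    # character grid of the fixated line (fixed-width rendering)
    char_w = np.median([(w.x1 - w.x0) / max(w.n_chars, 1) for _, w in words])
    if char_w <= 0:
        return None
    line_x0 = min(w.x0 for _, w in words)
    first_char = min(w.char_start for _, w in words)
    fix_char = first_char + (x - line_x0) / char_w
    span_lo = fix_char - SPAN_LEFT_CHARS
    span_hi = fix_char + SPAN_RIGHT_CHARS + 1.0  # span includes the fixated char

    best = None
    for i, w in words:
        a = max(float(w.char_start), span_lo)
        b = min(float(w.char_end), span_hi)
        if b <= a:
            continue
        n = w.n_chars
        prefix_ok = (a <= w.char_start + 1e-9) and 3.0 * (b - w.char_start) >= n
        suffix_ok = (b >= w.char_end - 1e-9) and 3.0 * (w.char_end - a) >= 2.0 * n
        if not (prefix_ok or suffix_ok):
            continue
        if w.stop_word:
            continue
        dist = abs(w.x_center - x)
        if best is None or dist < best[0] - 1e-12:
            best = (dist, i)
    return None if best is None else best[1]


# ----------------------------------------------------------------------
# Read-mode encoding
# ----------------------------------------------------------------------

def encode_read_modes(word_indices):
    """Read modes of the outgoing saccades of a word-indexed scanpath.

    ``word_indices`` may contain None for unassigned fixations; transitions
    touching an unassigned fixation are encoded as None and counted.
    Returns ``(modes list of str|None, n_excluded)``; output length is
    ``len(word_indices) - 1``.
    """
    modes = []
    n_excluded = 0
    for a, b in zip(word_indices, word_indices[1:]):
        if a is None or b is None:
            modes.append(None)
            n_excluded += 1
        else:
            modes.append(READ_MODES[mode_index(int(b) - int(a))])
    return modes, n_excluded


# ----------------------------------------------------------------------
# reading speed
# ----------------------------------------------------------------------

def _covered_words(word_indices) -> set:
    """Words covered by a run of fixations: every index between consecutive
    fixated words, inclusive (crossed words count as covered)."""
    out = set()
    idx = [w for w in word_indices if w is not None]
    for w in idx:
        out.add(int(w))
    for a, b in zip(idx, idx[1:]):
        lo, hi = (a, b) if a <= b else (b, a)
        out.update(range(int(lo), int(hi) + 1))
    return out


def reading_speed(segments, scale: str = "segment") -> float:
    """Reading speed in words per minute over fixation runs of one text.

    Each segment is a sequence of ``(word_index, fixation_ms, saccade_ms)``
    triples.  ``scale``:

    - ``"saccade"``: one segment of two fixations; speed is (|crossed
      words| + 1) divided by the first fixation's fixation+saccade time;
    - ``"segment"``: newly covered words of one run over its total time;
    - ``"phase"``: words covered by the union of all segments (each word
      counted once) over their summed durations.
    """
    if not segments:
        raise ValueError("no segments supplied")
    if scale == "saccade":
        if len(segments) != 1 or len(segments[0]) != 2:
            raise ValueError("saccade scale expects one two-fixation segment")
        (w0, f0, s0), (w1, _, _) = segments[0]
        n_words = abs(int(w1) - int(w0)) + 1
        total_ms = f0 + s0
        if total_ms <= 0:
            raise ValueError("non-positive duration")
        return n_words / total_ms * 60000.0

    covered = set()
    total_ms = 0.0
    for seg in segments:
        covered |= _covered_words([w for w, _, _ in seg])
        total_ms += sum(f + s for _, f, s in seg)
    if scale == "segment" and len(segments) != 1:
        raise ValueError("segment scale expects exactly one segment")
    if scale not in ("segment", "phase"):
        raise ValueError(f"unknown scale {scale!r}")
    if total_ms <= 0:
        raise ValueError("non-positive total duration")
    return len(covered) / total_ms * 60000.0


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

@dataclass
class FilterReport:
    """Bookkeeping of the preprocessing removals."""

    n_input: int = 0
    removed: dict = field(default_factory=lambda: {
        "duration": 0, "outside_text": 0, "last_fixation": 0})
    n_short_scanpaths: int = 0
    n_unassigned: int = 0
    n_excluded_transitions: int = 0

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, **self.removed,
                "short_scanpaths": self.n_short_scanpaths,
                "unassigned_fixations": self.n_unassigned,
                "excluded_transitions": self.n_excluded_transitions}


def enrich_cohort(fixations: pd.DataFrame, layouts,
                  min_ms: float = MIN_FIXATION_MS,
                  max_ms: float = MAX_FIXATION_MS,
                  min_fixations: int = MIN_SCANPATH_FIXATIONS):
    """Run the full preprocessing over a cohort fixation table.

    ``layouts`` is a mapping text_id -> TextLayout, or a list of layout
    dicts.  Returns ``(enriched DataFrame, FilterReport)``; the enriched
    table adds ``word_index`` (nullable) and ``read_mode`` (the outgoing
    Read mode; empty for the last retained fixation of each trial).
    Scanpaths with fewer than ``min_fixations`` retained fixations are
    dropped.
    """
    if not isinstance(layouts, dict):
        lays = {}
        for d in layouts:
            lay = d if isinstance(d, TextLayout) else TextLayout.from_dict(d)
            lays[lay.text_id] = lay
        layouts = lays
    report = FilterReport(n_input=len(fixations))
    chunks = []
    for (pid, tid), grp in fixations.groupby(
            ["participant_id", "text_id"], sort=True):
        layout = layouts[str(tid)]
        # the trial-final fixation is kept through word assignment (it codes
        # the preceding saccade) and removed from the output afterwards
        kept, counts = filter_fixations(grp, layout, min_ms, max_ms,
                                        drop_last=False)
        for k, v in counts.items():
            report.removed[k] += v
        if len(kept) - 1 < min_fixations:
            report.n_short_scanpaths += 1
            continue
        widx = [assign_word(r["x_px"], r["y_px"], layout)
                for _, r in kept.iterrows()]
        report.n_unassigned += sum(w is None for w in widx)
        modes, n_exc = encode_read_modes(widx)
        report.n_excluded_transitions += n_exc
        out = kept.iloc[:-1].copy()
        report.removed["last_fixation"] += 1
        out["word_index"] = [w if w is not None else pd.NA for w in widx[:-1]]
        out["read_mode"] = modes
        chunks.append(out)
    if not chunks:
        return fixations.iloc[0:0].assign(word_index=[], read_mode=[]), report
    return pd.concat(chunks, ignore_index=True), report
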