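"""Semantic triggers of phase transitions.

Texts are read to decide their relatedness to a target topic.  Words whose
embedding is maximally (or, for unrelated texts, minimally) cosine-similar
to the topic — *trigger words* — are hypothesized to provoke strategy
changes.  This module classifies extended text types, detects trigger words
from a word-embedding table, measures the distance (in fixations) from each
phase transition to the closest fixed trigger word, fits per-group
frequency-vs-distance regression lines, and assesses the association with
constrained and free permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIMILARITY_THRESHOLD = 0.3


# ----------------------------------------------------------------------
# embeddings
# ----------------------------------------------------------------------

class EmbeddingTable:
    """Word vectors in the standard whitespace-separated text format.

    The file may start with a ``count dim`` header line; every other line is
    ``word v1 v2 ... vd``.
    """

    def __init__(self, vectors: dict):
        dims = {len(v) for v in vectors.values()}
        if len(dims) > 1:
            raise ValueError("inconsistent embedding dimensions")
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}

    @classmethod
    def read(cls, path) -> "EmbeddingTable":
        vectors = {}
        with open(path) as fh:
            first = fh.readline().split()
            if len(first) == 2 and all(t.lstrip("-").isdigit() for t in first):
                pass  # header line: count dim
            elif first:
                vectors[first[0]] = [float(x) for x in first[1:]]
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                vectors[parts[0]] = [float(x) for x in parts[1:]]
        return cls(vectors)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]


def cosine(u, v) -> float:
    """Cosine similarity of two non-zero vectors of equal dimension."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero vector has no direction")
    return float(np.dot(u, v) / (nu * nv))


# ----------------------------------------------------------------------
# text classification and trigger detection
# ----------------------------------------------------------------------

def classify_extended_type(layout, topic_words) -> str:
    """HR texts containing a literal target-topic word become HR+; other
    base types are unchanged."""
    if layout.base_type != "HR":
        return layout.base_type
    topic = {w.lower() for w in topic_words}
    for w in layout.words:
        if w.surface.lower() in topic:
            return "HR+"
    return "HR"


@dataclass
class TriggerWordSet:
    """Trigger words of one text with their similarities and, once resolved
    against a scanpath, the fixation indices at which they are fixed."""

    text_id: str
    extended_type: str
    words: list = field(default_factory=list)          # word indices
    similarities: list = field(default_factory=list)
    excluded: bool = False
    reason: str = ""


def detect_trigger_words(layout, topic_words, embeddings: EmbeddingTable,
                         threshold: float = SIMILARITY_THRESHOLD) -> TriggerWordSet:
    """Type-specific trigger-word rules on cosine similarity to the topic.

    - HR+: the target word(s), plus the second-closest word if its
      similarity reaches the threshold;
    - HR: the two closest words, both required above the threshold,
      otherwise the text is excluded;
    - UR: the two furthest words (no threshold);
    - MR: the closest and the furthest word (no threshold).

    Stop words and words without embeddings are ineligible (the latter are
    reported); the topic vector is the mean of its words' vectors.
    """
    ext = classify_extended_type(layout, topic_words)
    out = TriggerWordSet(text_id=layout.text_id, extended_type=ext)
    topic_vecs = [embeddings[w] for w in topic_words if w in embeddings]
    if not topic_vecs:
        out.excluded = True
        out.reason = "topic words not in embedding table"
        return out
    tvec = np.mean(topic_vecs, axis=0)

    topic_lower = {w.lower() for w in topic_words}
    sims = []
    n_missing = 0
    for i, w in enumerate(layout.words):
        if w.stop_word:
            continue
        if w.surface not in embeddings:
            n_missing += 1
            continue
        sims.append((cosine(embeddings[w.surface], tvec), i))
    if not sims:
        out.excluded = True
        out.reason = f"no embeddable content word ({n_missing} missing)"
        return out
    by_sim = sorted(sims, key=lambda t: (-t[0], t[1]))

    def add(sim, idx):
        out.words.append(idx)
        out.similarities.append(sim)

    if ext == "HR+":
        targets = [(s, i) for s, i in by_sim
                   if layout.words[i].surface.lower() in topic_lower]
        others = [(s, i) for s, i in by_sim
                  if layout.words[i].surface.lower() not in topic_lower]
        add(*targets[0])
        if len(targets) > 1:
            add(*targets[1])
        elif others and others[0][0] >= threshold:
            add(*others[0])
    elif ext == "HR":
        if len(by_sim) < 2 or by_sim[1][0] < threshold:
            out.excluded = True
            out.reason = "no clear trigger words (similarities below threshold)"
            return out
        add(*by_sim[0])
        add(*by_sim[1])
    elif ext == "UR":
        for s, i in by_sim[-2:][::-1]:
            add(s, i)
    elif ext == "MR":
        add(*by_sim[0])
        if len(by_sim) > 1:
            add(*by_sim[-1])
    else:
        raise ValueError(f"unknown text type {ext!r}")
    return out


# ----------------------------------------------------------------------
# transition-to-trigger distances
# ----------------------------------------------------------------------

def trigger_fixation_indices(word_indices, triggers: TriggerWordSet) -> list[int]:
    """First fixation index on each trigger word (unfixed triggers yield
    nothing)."""
    out = []
    for tw in triggers.words:
        for t, w in enumerate(word_indices):
            if w is not None and int(w) == tw:
                out.append(t)
                break
    return out


def transition_trigger_distances(segments, word_indices,
                                 triggers: TriggerWordSet) -> list[dict]:
    """Distance (in fixations) from each phase transition to the closest
    fixed trigger word.

    ``segments`` is the per-scanpath list of ``(start, end, phase)`` runs;
    a transition happens at the first fixation of every segment after the
    first, and its distance is ``min_f |t - f|`` over trigger fixation
    indices ``f``.  Returns one dict per transition; empty if no trigger
    word was fixed.
    """
    trig_fix = trigger_fixation_indices(word_indices, triggers)
    if not trig_fix:
        return []
    out = []
    for start, _end, phase in segments[1:]:
        d = min(abs(start - f) for f in trig_fix)
        out.append({"boundary": start, "incoming_phase": phase,
                    "distance": int(d),
                    "extended_type": triggers.extended_type})
    return out


def cohort_transition_distances(segment_table: pd.DataFrame, enriched: pd.DataFrame,
                                triggers_by_text: dict) -> tuple[pd.DataFrame, dict]:
    """Transition-to-trigger distances for a whole cohort.

    Returns ``(DataFrame, report)``; scanpaths of excluded texts or with no
    fixed trigger word are dropped and counted.
    """
    report = {"excluded_texts": 0, "no_fixed_trigger": 0, "n_scanpaths": 0}
    rows = []
    words_by_key = {
        key: [None if pd.isna(w) else int(w) for w in grp["word_index"]]
        for key, grp in enriched.groupby(["participant_id", "text_id"], sort=True)
    }
    for (pid, tid), segs in segment_table.groupby(
            ["participant_id", "text_id"], sort=True):
        report["n_scanpaths"] += 1
        trig = triggers_by_text.get(str(tid))
        if trig is None or trig.excluded:
            report["excluded_texts"] += 1
            continue
        seg_list = [(int(s), int(e), int(p)) for s, e, p in
                    zip(segs["start"], segs["end"], segs["phase"])]
        recs = transition_trigger_distances(seg_list, words_by_key[(pid, tid)], trig)
        if not recs and len(seg_list) > 1:
            report["no_fixed_trigger"] += 1
        for r in recs:
            rows.append({"participant_id": pid, "text_id": tid, **r})
    cols = ["participant_id", "text_id", "boundary", "incoming_phase",
            "distance", "extended_type"]
    return pd.DataFrame(rows, columns=cols), report


# ----------------------------------------------------------------------
# distance-frequency lines
# ----------------------------------------------------------------------

#: distances whose opportunity count falls below max(this floor, 1% of all
#: boundaries) yield unreliable frequencies and are excluded from lines
MIN_OPPORTUNITIES = 5


def _distance_frequencies(distances: np.ndarray, opportunities: np.ndarray,
                          min_opportunities: float | None = None):
    """Transition frequency per integer distance, normalized by the number
    of fixation boundaries at that distance from the nearest trigger.

    Distances observed at almost no boundaries cannot support a frequency
    estimate; they are dropped below the opportunity threshold.
    """
    if min_opportunities is None:
        min_opportunities = max(MIN_OPPORTUNITIES, 0.01 * opportunities.sum())
    d_max = int(opportunities.size) - 1
    freq = []
    for d in range(d_max + 1):
        if opportunities[d] >= min_opportunities:
            freq.append((d, (distances == d).sum() / opportunities[d]))
    return np.array(freq)


def distance_frequency_lines(dist_table: pd.DataFrame,
                             boundary_distances: dict,
                             min_transitions: int = 10,
                             group_cols=("incoming_phase", "extended_type")) -> pd.DataFrame:
    """Per-group OLS line of transition frequency against distance.

    ``boundary_distances`` maps (participant_id, text_id) to the array of
    distances from every fixation boundary of that scanpath to its nearest
    trigger fixation — the opportunity structure used to normalize raw
    transition counts into frequencies.  Groups with fewer than
    ``min_transitions`` transitions, or fewer than two distinct distances,
    are flagged and get no line.
    """
    all_bd = {}
    for key, arr in boundary_distances.items():
        all_bd[key] = np.asarray(arr, dtype=int)
    rows = []
    for gkey, grp in dist_table.groupby(list(group_cols), sort=True):
        gdict = dict(zip(group_cols, gkey if isinstance(gkey, tuple) else (gkey,)))
        # opportunities: boundary-distance histogram over the group's scanpaths
        keys = set(zip(grp["participant_id"], grp["text_id"]))
        sel = [all_bd[k] for k in all_bd if k in keys]
        if not sel:
            rows.append({**gdict, "slope": np.nan, "intercept": np.nan,
                         "n_transitions": len(grp), "fitted": False,
                         "reason": "no opportunity structure"})
            continue
        d_max = max(int(a.max()) for a in sel)
        opp = np.zeros(d_max + 1)
        for a in sel:
            opp += np.bincount(a, minlength=d_max + 1)
        pts = _distance_frequencies(grp["distance"].to_numpy(), opp)
        if len(grp) < min_transitions or len(pts) < 2:
            rows.append({**gdict, "slope": np.nan, "intercept": np.nan,
                         "n_transitions": len(grp), "fitted": False,
                         "reason": "too few transitions or distances"})
            continue
        slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
        rows.append({**gdict, "slope": float(slope),
                     "intercept": float(intercept),
                     "n_transitions": len(grp), "fitted": True, "reason": ""})
    return pd.DataFrame(rows)


def boundary_distance_structure(segment_table: pd.DataFrame,
                                enriched: pd.DataFrame,
                                triggers_by_text: dict) -> dict:
    """Distances from every fixation boundary to the nearest fixed trigger,
    per scanpath — the denominator ("opportunity") structure for
    frequency normalization."""
    out = {}
    for (pid, tid), grp in enriched.groupby(
            ["participant_id", "text_id"], sort=True):
        trig = triggers_by_text.get(str(tid))
        if trig is None or trig.excluded:
            continue
        words = [None if pd.isna(w) else int(w) for w in grp["word_index"]]
        fixes = trigger_fixation_indices(words, trig)
        if not fixes:
            continue
        T = len(words)
        # boundaries are the starts of potential segments: fixations 1..T-1
        out[(pid, tid)] = np.array(
            [min(abs(t - f) for f in fixes) for t in range(1, T)], dtype=int)
    return out


# ----------------------------------------------------------------------
# permutation tests
# ----------------------------------------------------------------------

def _opportunity_histogram(boundary_distances) -> np.ndarray:
    sel = [np.asarray(a) for a in boundary_distances]
    d_max = max(int(a.max()) for a in sel)
    opp = np.zeros(d_max + 1)
    for a in sel:
        opp += np.bincount(a, minlength=d_max + 1)
    return opp


def pooled_slope(distances, boundary_distances) -> float:
    """OLS slope of pooled transition frequency against distance,
    normalized by boundary opportunities; 0 when degenerate (fewer than two
    observed distinct distances)."""
    opp = _opportunity_histogram(boundary_distances)
    pts = _distance_frequencies(np.asarray(distances, dtype=int), opp)
    if len(pts) < 2 or len(np.unique(pts[:, 0])) < 2:
        return 0.0
    slope, _ = np.polyfit(pts[:, 0], pts[:, 1], 1)
    return float(slope)


def phase_weighted_slope(distances, phases, boundary_distances) -> float:
    """Association statistic: per-incoming-phase pooled slopes, averaged
    with weights proportional to each phase's transition count."""
    distances = np.asarray(distances, dtype=int)
    phases = np.asarray(phases)
    tot_w = 0.0
    acc = 0.0
    for ph in np.unique(phases):
        sel = phases == ph
        s = pooled_slope(distances[sel], boundary_distances)
        acc += sel.sum() * s
        tot_w += sel.sum()
    if tot_w == 0:
        raise ValueError("no transitions")
    return acc / tot_w


def permutation_test(segment_table: pd.DataFrame, enriched: pd.DataFrame,
                     triggers_by_text: dict, scheme: str = "constrained",
                     n_perm: int = 199, seed=None):
    """Permutation null for the distance-transition association.

    ``constrained``: transition boundaries are re-drawn uniformly without
    replacement within each scanpath, preserving the number of transitions
    and their incoming-phase labels.  ``free``: additionally permutes
    incoming-phase labels across the cohort's transitions.  The headline
    statistic is the pooled frequency-vs-distance OLS slope (the quantity
    the per-group regression lines interpret); it is insensitive to the
    label shuffle, so the free scheme differs from the constrained one
    through the phase-weighted statistic, which is also computed and
    returned.  The p-value is the add-one-corrected fraction of null
    statistics at or below the observed one (one-sided toward negative
    association, i.e. transitions clustering around trigger words).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("constrained", "free"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    bd = boundary_distance_structure(segment_table, enriched, triggers_by_text)
    obs_table, _ = cohort_transition_distances(segment_table, enriched,
                                               triggers_by_text)
    bd_list = list(bd.values())
    obs = pooled_slope(obs_table["distance"], bd_list)
    obs_pw = phase_weighted_slope(obs_table["distance"],
                                  obs_table["incoming_phase"], bd_list)

    # per scanpath: boundary distances and incoming-phase labels in order
    per_path = []
    for (pid, tid), segs in segment_table.groupby(
            ["participant_id", "text_id"], sort=True):
        key = (pid, tid)
        if key not in bd:
            continue
        labels = segs["phase"].to_numpy()[1:]
        k = min(len(labels), len(bd[key]))
        if k > 0:
            per_path.append((bd[key], labels[:k]))

    null = np.empty(n_perm)
    null_pw = np.empty(n_perm)
    for b in range(n_perm):
        ds, phs = [], []
        for dists, labels in per_path:
            pick = rng.choice(len(dists), size=len(labels), replace=False)
            pick.sort()
            ds.extend(dists[pick])
            phs.extend(labels)
        phs = np.asarray(phs)
        if scheme == "free":
            phs = phs[rng.permutation(len(phs))]
        ds = np.asarray(ds, dtype=int)
        null[b] = pooled_slope(ds, bd_list)
        null_pw[b] = phase_weighted_slope(ds, phs, bd_list)
    p = (1 + int((null <= obs).sum())) / (n_perm + 1)
    p_pw = (1 + int((null_pw <= obs_pw).sum())) / (n_perm + 1)
    return {"statistic": obs, "null": null, "p_value": float(p),
            "phase_weighted_statistic": obs_pw, "null_phase_weighted": null_pw,
            "p_value_phase_weighted": float(p_pw),
            "scheme": scheme, "n_perm": n_perm}
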