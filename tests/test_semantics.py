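"""Trigger-word detection, transition-to-trigger distances, regression
lines and permutation tests."""

import numpy as np
import pandas as pd
import pytest

from readphases.preprocess import TextLayout, Word
from readphases.semantics import (
    EmbeddingTable,
    classify_extended_type,
    cosine,
    detect_trigger_words,
    distance_frequency_lines,
    permutation_test,
    pooled_slope,
    transition_trigger_distances,
    trigger_fixation_indices,
)


def layout_with(surfaces, base_type="HR", stops=()):
    words = []
    off = 0
    for i, s in enumerate(surfaces):
        n = len(s)
        words.append(Word(surface=s, char_start=off, char_end=off + n, line=0,
                          x0=100.0 + off * 10, x1=100.0 + (off + n) * 10,
                          y0=100.0, y1=124.0, stop_word=s in stops))
        off += n + 1
    return TextLayout(text_id="T", topic="topic", base_type=base_type,
                      words=words)


def embeddings_for(sims, topic_vec=(1.0, 0.0, 0.0)):
    """Vectors in 3-D with prescribed cosine to the topic."""
    t = np.asarray(topic_vec) / np.linalg.norm(topic_vec)
    vecs = {"topic": t}
    rng = np.random.default_rng(0)
    for word, s in sims.items():
        v = rng.normal(size=3)
        v -= (v @ t) * t
        v /= np.linalg.norm(v)
        vecs[word] = s * t + np.sqrt(1 - s * s) * v
    return EmbeddingTable(vecs)


# ------------------------------------------------------------------ cosine

def test_cosine_identities():
    assert cosine([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError):
        cosine([0, 0], [1, 0])
    with pytest.raises(ValueError):
        cosine([1, 0], [1, 0, 0])


# ------------------------------------------------------- type classification

def test_hr_with_topic_word_becomes_hr_plus():
    lay = layout_with(["alpha", "topic", "beta"], base_type="HR")
    assert classify_extended_type(lay, ["topic"]) == "HR+"


def test_hr_without_topic_word_stays_hr():
    lay = layout_with(["alpha", "beta"], base_type="HR")
    assert classify_extended_type(lay, ["topic"]) == "HR"


def test_rule_applies_to_hr_only():
    lay = layout_with(["alpha", "topic"], base_type="UR")
    assert classify_extended_type(lay, ["topic"]) == "UR"


# ------------------------------------------------------------ trigger rules

def test_hr_takes_two_closest_above_threshold():
    lay = layout_with(["alpha", "beta", "gamma"], base_type="HR")
    emb = embeddings_for({"alpha": 0.6, "beta": 0.4, "gamma": 0.1})
    trig = detect_trigger_words(lay, ["topic"], emb)
    assert not trig.excluded
    assert trig.words == [0, 1]
    assert trig.similarities == pytest.approx([0.6, 0.4])


def test_hr_excluded_when_all_below_threshold():
    lay = layout_with(["alpha", "beta"], base_type="HR")
    emb = embeddings_for({"alpha": 0.25, "beta": 0.1})
    trig = detect_trigger_words(lay, ["topic"], emb)
    assert trig.excluded


def test_hr_plus_single_trigger_when_second_below_threshold():
    lay = layout_with(["alpha", "topic", "beta"], base_type="HR")
    emb = embeddings_for({"alpha": 0.2, "beta": 0.1})
    trig = detect_trigger_words(lay, ["topic"], emb)
    assert trig.extended_type == "HR+"
    assert trig.words == [1]          # only the target word


def test_ur_takes_two_furthest_without_threshold():
    lay = layout_with(["a1", "b2", "c3"], base_type="UR")
    emb = embeddings_for({"a1": 0.3, "b2": -0.5, "c3": -0.2})
    trig = detect_trigger_words(lay, ["topic"], emb)
    assert set(trig.words) == {1, 2}


def test_mr_takes_closest_and_furthest():
    lay = layout_with(["a1", "b2", "c3"], base_type="MR")
    emb = embeddings_for({"a1": 0.5, "b2": -0.4, "c3": 0.0})
    trig = detect_trigger_words(lay, ["topic"], emb)
    assert trig.words == [0, 1]


def test_stop_words_ineligible():
    lay = layout_with(["les", "beta", "gamma"], base_type="HR", stops=("les",))
    emb = embeddings_for({"les": 0.9, "beta": 0.6, "gamma": 0.4})
    trig = detect_trigger_words(lay, ["topic"], emb)
    assert trig.words == [1, 2]


def test_detection_invariant_to_embedding_table_order():
    lay = layout_with(["alpha", "beta", "gamma"], base_type="HR")
    sims = {"alpha": 0.6, "beta": 0.4, "gamma": 0.1}
    emb1 = embeddings_for(sims)
    emb2 = EmbeddingTable(dict(reversed(list(emb1.vectors.items()))))
    t1 = detect_trigger_words(lay, ["topic"], emb1)
    t2 = detect_trigger_words(lay, ["topic"], emb2)
    assert t1.words == t2.words


def test_embedding_reader_handles_header(tmp_path):
    path = tmp_path / "vec.txt"
    path.write_text("2 3\nfoo 1 0 0\nbar 0 1 0\n")
    emb = EmbeddingTable.read(path)
    assert "foo" in emb and "bar" in emb
    path2 = tmp_path / "vec2.txt"
    path2.write_text("foo 1 0 0\nbar 0 1 0\n")
    emb2 = EmbeddingTable.read(path2)
    assert np.allclose(emb2["foo"], [1, 0, 0])


# ---------------------------------------------------------------- distances

def _triggerset(words, ext="HR"):
    from readphases.semantics import TriggerWordSet

    return TriggerWordSet(text_id="T", extended_type=ext, words=list(words),
                          similarities=[0.5] * len(words))


def test_distance_zero_at_trigger_fixation():
    trig = _triggerset([4])
    word_idx = [0, 1, 4, 5, 6]       # trigger word fixed at index 2
    segs = [(0, 1, 0), (2, 4, 1)]    # transition at fixation 2
    recs = transition_trigger_distances(segs, word_idx, trig)
    assert recs[0]["distance"] == 0


def test_distance_uses_min_over_triggers():
    trig = _triggerset([7, 9])
    word_idx = [0, 1, 2, 7, 3, 4, 5, 6, 8, 9, 9]
    # triggers fixed at indices 3 and 9; transition at 6 -> distance 3
    fixes = trigger_fixation_indices(word_idx, trig)
    assert fixes == [3, 9]
    segs = [(0, 5, 0), (6, 10, 1)]
    recs = transition_trigger_distances(segs, word_idx, trig)
    assert recs[0]["distance"] == 3


def test_unfixed_triggers_yield_no_records():
    trig = _triggerset([25])
    recs = transition_trigger_distances([(0, 2, 0), (3, 5, 1)],
                                        [0, 1, 2, 3, 4, 5], trig)
    assert recs == []


def test_distances_bounded_by_scanpath_length():
    rng = np.random.default_rng(4)
    for _ in range(20):
        T = int(rng.integers(5, 20))
        words = rng.integers(0, 10, size=T).tolist()
        trig = _triggerset([int(words[rng.integers(T)])])
        segs = [(0, T // 2, 0), (T // 2 + 1, T - 1, 1)]
        for r in transition_trigger_distances(segs, words, trig):
            assert 0 <= r["distance"] < T


# ----------------------------------------------------------------- lines

def test_exact_ols_slope_on_three_points():
    # frequencies 0.4, 0.3, 0.2 at distances 0, 1, 2 -> slope -0.1
    dist_table = pd.DataFrame({
        "participant_id": ["p"] * 9,
        "text_id": ["T"] * 9,
        "incoming_phase": [1] * 9,
        "extended_type": ["HR"] * 9,
        "distance": [0] * 4 + [1] * 3 + [2] * 2,
    })
    bd = {("p", "T"): np.array([0] * 10 + [1] * 10 + [2] * 10)}
    lines = distance_frequency_lines(dist_table, bd, min_transitions=1)
    assert lines.iloc[0]["slope"] == pytest.approx(-0.1)
    assert lines.iloc[0]["intercept"] == pytest.approx(0.4)


def test_flat_frequencies_give_zero_slope():
    dist_table = pd.DataFrame({
        "participant_id": ["p"] * 6,
        "text_id": ["T"] * 6,
        "incoming_phase": [1] * 6,
        "extended_type": ["HR"] * 6,
        "distance": [0, 0, 1, 1, 2, 2],
    })
    bd = {("p", "T"): np.array([0] * 8 + [1] * 8 + [2] * 8)}
    lines = distance_frequency_lines(dist_table, bd, min_transitions=1)
    assert lines.iloc[0]["slope"] == pytest.approx(0.0, abs=1e-12)


def test_rare_groups_are_flagged_not_fitted():
    dist_table = pd.DataFrame({
        "participant_id": ["p"] * 3,
        "text_id": ["T"] * 3,
        "incoming_phase": [3] * 3,
        "extended_type": ["HR"] * 3,
        "distance": [0, 1, 2],
    })
    bd = {("p", "T"): np.arange(5)}
    lines = distance_frequency_lines(dist_table, bd, min_transitions=10)
    assert not lines.iloc[0]["fitted"]
    assert np.isnan(lines.iloc[0]["slope"])


def test_pooled_slope_degenerate_is_zero():
    assert pooled_slope([2, 2, 2], [np.array([2, 2])]) == 0.0


# ------------------------------------------------------- permutation tests

@pytest.fixture(scope="module")
def semantic_cohort():
    """Coupled cohort, preprocessed, with true-phase segments."""
    from readphases.preprocess import enrich_cohort
    from readphases.synthetic import GeneratorConfig, simulate_cohort

    cfg = GeneratorConfig(n_participants=6, n_texts=12, seed=17,
                          trigger_coupling=3.0, trigger_radius=2)
    cohort = simulate_cohort(cfg)
    enriched, _ = enrich_cohort(cohort.fixations, cohort.layouts)
    phase_of = {int(k): v for k, v in cohort.truth["state_phase"].items()}
    rows = []
    for sp in cohort.truth["scanpaths"]:
        phases = [phase_of[s] for s in sp["states"]]
        start = 0
        for t in range(1, len(phases) + 1):
            if t == len(phases) or phases[t] != phases[start]:
                rows.append({"participant_id": sp["participant_id"],
                             "text_id": sp["text_id"],
                             "phase": phases[start], "label": "",
                             "start": start, "end": t - 1,
                             "n_fixations": t - start})
                start = t
    segs = pd.DataFrame(rows)
    emb = EmbeddingTable(cohort.embeddings)
    layouts = {d["text_id"]: TextLayout.from_dict(d) for d in cohort.layouts}
    triggers = {tid: detect_trigger_words(lay, [lay.topic], emb)
                for tid, lay in layouts.items()}
    return cohort, enriched, segs, triggers


def test_permutation_test_reproducible_and_valid(semantic_cohort):
    _, enriched, segs, triggers = semantic_cohort
    r1 = permutation_test(segs, enriched, triggers, scheme="constrained",
                          n_perm=49, seed=5)
    r2 = permutation_test(segs, enriched, triggers, scheme="constrained",
                          n_perm=49, seed=5)
    np.testing.assert_array_equal(r1["null"], r2["null"])
    assert 0.0 < r1["p_value"] <= 1.0
    free = permutation_test(segs, enriched, triggers, scheme="free",
                            n_perm=49, seed=5)
    assert 0.0 < free["p_value"] <= 1.0
    with pytest.raises(ValueError):
        permutation_test(segs, enriched, triggers, n_perm=0)
    with pytest.raises(ValueError):
        permutation_test(segs, enriched, triggers, scheme="bogus")


def test_invariant_statistic_gives_p_one():
    """When every scanpath has a single possible transition position the
    permutation redraw is the identity, so the null equals the observed
    statistic and the p-value is 1."""
    enriched = pd.DataFrame({
        "participant_id": ["p", "p", "q", "q"],
        "text_id": ["T", "T", "T", "T"],
        "word_index": [5, 6, 5, 7],
        "duration_ms": [200.0] * 4,
        "saccade_duration_ms": [30.0] * 4,
    })
    segs = pd.DataFrame({
        "participant_id": ["p", "p", "q", "q"],
        "text_id": ["T"] * 4,
        "phase": [0, 1, 0, 1],
        "label": [""] * 4,
        "start": [0, 1, 0, 1],
        "end": [0, 1, 0, 1],
        "n_fixations": [1, 1, 1, 1],
    })
    triggers = {"T": _triggerset([5, 7])}
    res = permutation_test(segs, enriched, triggers, scheme="constrained",
                           n_perm=19, seed=3)
    assert res["p_value"] == 1.0
    np.testing.assert_allclose(res["null"], res["statistic"])


def test_coupled_cohorts_yield_negative_slopes():
    """With a x3 sojourn-hazard boost within 2 fixations of a fixed trigger
    word, transitions cluster near triggers and the pooled
    frequency-vs-distance slope comes out negative (500-scanpath cohorts)."""
    from readphases.preprocess import enrich_cohort
    from readphases.semantics import (
        boundary_distance_structure,
        cohort_transition_distances,
    )
    from readphases.synthetic import GeneratorConfig, simulate_cohort

    n_negative = 0
    for seed in (1, 4, 7):
        cfg = GeneratorConfig(n_participants=4, n_texts=125, seed=seed,
                              trigger_coupling=3.0, trigger_radius=2)
        cohort = simulate_cohort(cfg)
        enriched, _ = enrich_cohort(cohort.fixations, cohort.layouts)
        phase_of = {int(k): v for k, v in cohort.truth["state_phase"].items()}
        rows = []
        for sp in cohort.truth["scanpaths"]:
            phases = [phase_of[s] for s in sp["states"]]
            start = 0
            for t in range(1, len(phases) + 1):
                if t == len(phases) or phases[t] != phases[start]:
                    rows.append({"participant_id": sp["participant_id"],
                                 "text_id": sp["text_id"],
                                 "phase": phases[start], "label": "",
                                 "start": start, "end": t - 1,
                                 "n_fixations": t - start})
                    start = t
        segs = pd.DataFrame(rows)
        emb = EmbeddingTable(cohort.embeddings)
        lays = {d["text_id"]: TextLayout.from_dict(d) for d in cohort.layouts}
        triggers = {tid: detect_trigger_words(lay, [lay.topic], emb)
                    for tid, lay in lays.items()}
        bd = boundary_distance_structure(segs, enriched, triggers)
        tab, _ = cohort_transition_distances(segs, enriched, triggers)
        slope = pooled_slope(tab["distance"], list(bd.values()))
        n_negative += slope < 0
    assert n_negative >= 2
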