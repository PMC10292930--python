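"""Contingency tables, chi-square independence, correspondence analysis and
phase-level reading speeds."""

import numpy as np
import pandas as pd
import pytest

from readphases.phase_stats import (
    chi2_independence,
    correspondence_analysis,
    mean_phase_speeds,
    phase_contingency,
    phase_distribution_by_type,
    phase_speed_table,
)


def seg_table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "text_id", "phase",
                                       "label", "start", "end", "n_fixations"])


def test_contingency_sums_fixations_per_phase():
    segs = seg_table([
        ("s1", "T0", 0, "NR", 0, 2, 3),
        ("s1", "T0", 1, "IS", 3, 6, 4),
        ("s2", "T0", 0, "NR", 0, 4, 5),
    ])
    tab = phase_contingency(segs)
    assert tab.loc["s1"].tolist() == [3, 4]
    assert tab.loc["s2"].tolist() == [5, 0]
    assert tab.to_numpy().sum() == segs["n_fixations"].sum()


def test_chi2_df_for_15_by_4_table():
    rng = np.random.default_rng(0)
    tab = rng.integers(1, 50, size=(15, 4))
    stat, dof = chi2_independence(tab)
    assert dof == 42


def test_chi2_zero_for_proportional_table():
    tab = np.outer([10, 20, 30], [1, 2, 3])
    stat, _ = chi2_independence(tab)
    assert stat == pytest.approx(0.0, abs=1e-10)


def test_chi2_closed_form_2x2():
    stat, dof = chi2_independence(np.array([[10, 20], [20, 10]]))
    assert stat == pytest.approx(20.0 / 3.0)
    assert dof == 1


def test_chi2_invariant_under_permutations():
    rng = np.random.default_rng(1)
    tab = rng.integers(1, 40, size=(6, 4))
    stat, _ = chi2_independence(tab)
    stat_p, _ = chi2_independence(tab[rng.permutation(6)][:, rng.permutation(4)])
    assert stat_p == pytest.approx(stat, rel=1e-12)


def test_chi2_zero_margin_is_error():
    with pytest.raises(ValueError):
        chi2_independence(np.array([[0, 0], [5, 3]]))


# ------------------------------------------------------------------- CA

def test_ca_total_inertia_equals_chi2_over_n():
    rng = np.random.default_rng(2)
    for _ in range(10):
        tab = rng.integers(1, 60, size=(rng.integers(3, 9), rng.integers(3, 6)))
        ca = correspondence_analysis(tab)
        stat, _ = chi2_independence(tab)
        assert ca.eigenvalues.sum() == pytest.approx(stat / tab.sum(),
                                                     abs=1e-10)
        assert ca.total_inertia == pytest.approx(stat / tab.sum(), abs=1e-10)


def test_ca_clouds_centred_at_origin():
    rng = np.random.default_rng(3)
    tab = rng.integers(1, 60, size=(7, 4))
    ca = correspondence_analysis(tab)
    r = tab.sum(axis=1) / tab.sum()
    c = tab.sum(axis=0) / tab.sum()
    np.testing.assert_allclose(r @ ca.row_coords, 0.0, atol=1e-10)
    np.testing.assert_allclose(c @ ca.col_coords, 0.0, atol=1e-10)


def test_ca_proportional_table_has_zero_inertia():
    tab = np.outer([5, 10, 20], [2, 3, 4])
    ca = correspondence_analysis(tab)
    assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)
    assert ca.eigenvalues.size == 0


def test_ca_matches_eigendecomposition_oracle():
    """Independent route: principal coordinates via the eigendecomposition
    of S S' rather than the SVD of S."""
    tab = np.array([[20, 5, 12], [3, 30, 7], [9, 8, 25]], dtype=float)
    ca = correspondence_analysis(tab)
    P = tab / tab.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1][: ca.eigenvalues.size]
    np.testing.assert_allclose(np.sort(ca.eigenvalues)[::-1],
                               evals[order], atol=1e-10)
    for axis in range(ca.eigenvalues.size):
        u = evecs[:, order[axis]]
        coord = u * np.sqrt(evals[order[axis]]) / np.sqrt(r)
        got = ca.row_coords[:, axis]
        # eigenvectors are sign-ambiguous
        assert (np.allclose(coord, got, atol=1e-8)
                or np.allclose(-coord, got, atol=1e-8))


# ------------------------------------------------------- speeds and types

@pytest.fixture(scope="module")
def enriched_segments(small_cohort):
    from readphases.preprocess import enrich_cohort

    enriched, _ = enrich_cohort(small_cohort.fixations, small_cohort.layouts)
    rows = []
    truth = {(sp["participant_id"], sp["text_id"]): sp
             for sp in small_cohort.truth["scanpaths"]}
    phase_of = {int(k): v for k, v in small_cohort.truth["state_phase"].items()}
    for key, grp in enriched.groupby(["participant_id", "text_id"], sort=True):
        states = truth[key]["states"]
        phases = [phase_of[s] for s in states]
        start = 0
        for t in range(1, len(phases) + 1):
            if t == len(phases) or phases[t] != phases[start]:
                rows.append({"participant_id": key[0], "text_id": key[1],
                             "phase": phases[start], "label": str(phases[start]),
                             "start": start, "end": t - 1,
                             "n_fixations": t - start})
                start = t
    return enriched, pd.DataFrame(rows)


def test_phase_speed_table_is_tidy_and_positive(enriched_segments):
    enriched, segs = enriched_segments
    tab = phase_speed_table(enriched, segs)
    assert set(tab.columns) >= {"participant_id", "text_id", "phase",
                                "speed_wpm"}
    assert (tab["speed_wpm"] > 0).all()
    # durations conserved: per (participant,text) fixation counts add up
    n_by_key = segs.groupby(["participant_id", "text_id"])["n_fixations"].sum()
    m_by_key = enriched.groupby(["participant_id", "text_id"]).size()
    assert (n_by_key == m_by_key).all()
    means = mean_phase_speeds(tab)
    assert means.index.is_monotonic_increasing


def test_generator_phase_speed_ordering(enriched_segments):
    """Default per-phase duration laws imply fast reading faster than normal
    reading, and information search slowest."""
    enriched, segs = enriched_segments
    means = mean_phase_speeds(phase_speed_table(enriched, segs))
    if {0, 1, 2} <= set(means.index):
        assert means[2] > means[0] > means[1]   # FR > NR > IS


def test_phase_distribution_rows_sum_to_one(small_cohort, enriched_segments):
    from readphases.preprocess import TextLayout

    _, segs = enriched_segments
    layouts = {d["text_id"]: TextLayout.from_dict(d)
               for d in small_cohort.layouts}
    tab = phase_distribution_by_type(segs, layouts)
    np.testing.assert_allclose(tab.sum(axis=1), 1.0, atol=1e-12)
    assert set(tab.index) <= {"HR", "HR+", "MR", "UR"}


def test_phase_distribution_unknown_type_raises(enriched_segments, small_cohort):
    from readphases.preprocess import TextLayout

    _, segs = enriched_segments
    layouts = {d["text_id"]: TextLayout.from_dict(d)
               for d in small_cohort.layouts}
    next(iter(layouts.values())).base_type = "XX"
    with pytest.raises(ValueError):
        phase_distribution_by_type(segs, layouts)


def test_phase_distribution_matches_direct_tabulation(enriched_segments, small_cohort):
    from readphases.preprocess import TextLayout

    _, segs = enriched_segments
    layouts = {d["text_id"]: TextLayout.from_dict(d)
               for d in small_cohort.layouts}
    tab = phase_distribution_by_type(segs, layouts)
    # direct oracle for one type and one phase
    t = "MR"
    mr_texts = {tid for tid, lay in layouts.items() if lay.base_type == t}
    sub = segs[segs["text_id"].isin(mr_texts)]
    phase0 = sub.loc[sub["phase"] == 0, "n_fixations"].sum()
    assert tab.loc[t, 0] == pytest.approx(phase0 / sub["n_fixations"].sum())
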