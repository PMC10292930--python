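"""Descriptive statistics of restored phases.

Participant-by-phase contingency tables of fixation counts, the Pearson
chi-square independence test, correspondence analysis of the same table,
per-phase reading speeds, and phase distributions by extended text type.
The mixed-model regressions that typically follow are out of scope here;
the tidy tables this module produces are their intended input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .preprocess import reading_speed


def phase_contingency(segments: pd.DataFrame) -> pd.DataFrame:
    """Participant x phase table of fixation counts from a segment table.

    ``segments`` needs columns participant_id, phase, n_fixations (the
    output of ``HSMCResults.restore_phases``).
    """
    table = segments.pivot_table(index="participant_id", columns="phase",
                                 values="n_fixations", aggfunc="sum",
                                 fill_value=0)
    return table.astype(int)


def chi2_independence(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df for independence of rows/columns."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero margin")
    res = chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof)


@dataclass
class CAResult:
    """Correspondence analysis of a two-way contingency table.

    Principal coordinates use the symmetric (French) scaling: both row and
    column clouds are scaled by the singular values, so distances in the
    joint map approximate chi-square distances.
    """

    row_coords: np.ndarray       # (n_rows, n_axes)
    col_coords: np.ndarray       # (n_cols, n_axes)
    eigenvalues: np.ndarray      # principal inertias per axis
    total_inertia: float
    row_labels: list
    col_labels: list

    @property
    def inertia_proportions(self) -> np.ndarray:
        if self.total_inertia <= 0:
            return np.zeros(0)
        return self.eigenvalues / self.total_inertia


def correspondence_analysis(table, tol: float = 1e-12) -> CAResult:
    """SVD of the standardized residuals of the correspondence matrix.

    Total inertia equals the chi-square statistic divided by the grand
    total; the sum of the eigenvalues (squared singular values) reproduces
    it exactly.  A perfectly independent table yields zero axes.
    """
    if isinstance(table, pd.DataFrame):
        row_labels = list(table.index)
        col_labels = list(table.columns)
    else:
        row_labels = list(range(np.asarray(table).shape[0]))
        col_labels = list(range(np.asarray(table).shape[1]))
    N = np.asarray(table, dtype=float)
    total = N.sum()
    if total <= 0:
        raise ValueError("empty table")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("contingency table has an all-zero margin")
    # standardized residuals S = D_r^{-1/2} (P - r c') D_c^{-1/2}
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > np.sqrt(tol)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    row = (U * sv[None, :]) / np.sqrt(r)[:, None]
    col = (Vt.T * sv[None, :]) / np.sqrt(c)[:, None]
    return CAResult(
        row_coords=row, col_coords=col, eigenvalues=sv**2,
        total_inertia=float((S * S).sum()),
        row_labels=row_labels, col_labels=col_labels,
    )


def _segment_triples(enriched: pd.DataFrame, start: int, end: int):
    seg = enriched.iloc[start: end + 1]
    out = []
    for _, row in seg.iterrows():
        w = row["word_index"]
        out.append((None if pd.isna(w) else int(w),
                    float(row["duration_ms"]),
                    float(row["saccade_duration_ms"])))
    return out


def phase_speed_table(enriched: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, text, phase) reading speed rows, phase scale.

    ``enriched`` is the preprocessed fixation table; ``segments`` the
    restored segment table whose start/end index into each scanpath's
    retained fixations.  Words covered by several same-phase segments of a
    text are counted once.
    """
    rows = []
    grouped = {k: g.reset_index(drop=True) for k, g in
               enriched.groupby(["participant_id", "text_id"], sort=True)}
    for (pid, tid, phase), segs in segments.groupby(
            ["participant_id", "text_id", "phase"], sort=True):
        g = grouped[(pid, tid)]
        triples = [_segment_triples(g, int(s), int(e))
                   for s, e in zip(segs["start"], segs["end"])]
        speed = reading_speed(triples, scale="phase")
        rows.append({"participant_id": pid, "text_id": tid, "phase": phase,
                     "n_segments": len(triples),
                     "n_fixations": int(segs["n_fixations"].sum()),
                     "speed_wpm": speed})
    return pd.DataFrame(rows)


def mean_phase_speeds(speed_table: pd.DataFrame) -> pd.Series:
    """Pooled mean reading speed per phase (wpm)."""
    return speed_table.groupby("phase")["speed_wpm"].mean()


def phase_distribution_by_type(segments: pd.DataFrame, layouts) -> pd.DataFrame:
    """Fixation-weighted phase frequencies per extended text type.

    ``layouts`` maps text_id to a TextLayout whose ``extended_type`` (or
    ``base_type``) is set; rows of the output sum to 1.
    """
    known = {"HR", "HR+", "MR", "UR"}
    types = {}
    for tid, lay in layouts.items():
        et = lay.extended_type or lay.base_type
        if et not in known:
            raise ValueError(f"unknown extended text type {et!r}")
        types[str(tid)] = et
    seg = segments.copy()
    seg["extended_type"] = seg["text_id"].astype(str).map(types)
    if seg["extended_type"].isna().any():
        raise ValueError("segment table references unknown text ids")
    tab = seg.pivot_table(index="extended_type", columns="phase",
                          values="n_fixations", aggfunc="sum", fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0)
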