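"""Macro-states ("phases") built from hidden states.

A pair (or clique) of states linked by short, near-systematic alternation
cycles — each with high mutual transition probabilities and very short mean
sojourns — behaves as a single macroscopic regime.  Such states are merged
into one *phase*; every other state becomes a singleton phase.  Phases are
what gets interpreted as reading strategies (normal reading, information
search, fast reading, slow confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hsmc import HSMCParams, viterbi_restore
from .sojourn import ABSORBING as ABSORBING_FAMILY


@dataclass
class PhaseMap:
    """Many-to-one surjective mapping from state indices to phase indices."""

    mapping: dict                      # state -> phase (0-based, contiguous)
    labels: dict = field(default_factory=dict)   # phase -> free-text label
    evidence: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return max(self.mapping.values()) + 1

    @property
    def n_states(self) -> int:
        return len(self.mapping)

    def apply(self, states) -> np.ndarray:
        states = np.asarray(states, dtype=np.int64)
        lut = np.array([self.mapping[k] for k in range(self.n_states)])
        return lut[states]

    def states_of(self, phase: int) -> list[int]:
        return [s for s, p in self.mapping.items() if p == phase]

    def to_dict(self) -> dict:
        return {
            "mapping": {str(k): int(v) for k, v in self.mapping.items()},
            "labels": {str(k): v for k, v in self.labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseMap":
        return cls(
            mapping={int(k): int(v) for k, v in d["mapping"].items()},
            labels={int(k): v for k, v in d.get("labels", {}).items()},
        )


def detect_phases(
    params: HSMCParams,
    cycle_threshold: float = 0.9,
    max_mean_sojourn: float = 2.0,
) -> PhaseMap:
    """Merge states forming short high-probability alternation cycles.

    States i and j belong to the same cycle when both ``A[i, j]`` and
    ``A[j, i]`` are at least ``cycle_threshold`` and both mean sojourns are
    below ``max_mean_sojourn`` fixations.  Maximal cliques of this relation
    are merged; overlapping cliques are resolved toward the lower state
    index and flagged in the evidence dict.
    """
    import networkx as nx

    K = params.n_states
    A = params.transitions
    means = params.sojourn_means()
    g = nx.Graph()
    g.add_nodes_from(range(K))
    for i in range(K):
        for j in range(i + 1, K):
            if (
                A[i, j] >= cycle_threshold
                and A[j, i] >= cycle_threshold
                and means[i] < max_mean_sojourn
                and means[j] < max_mean_sojourn
            ):
                g.add_edge(i, j)
    cliques = sorted((sorted(c) for c in nx.find_cliques(g) if len(c) > 1))
    assigned = {}
    ambiguous = False
    for c in cliques:
        for s in c:
            if s in assigned:
                ambiguous = True
            else:
                assigned[s] = tuple(c)
    groups = []
    seen = set()
    for s in range(K):
        if s in assigned:
            key = assigned[s]
            if key not in seen:
                seen.add(key)
                groups.append([m for m in key if assigned.get(m) == key])
        else:
            groups.append([s])
    mapping = {}
    for p, grp in enumerate(groups):
        for s in grp:
            mapping[s] = p
    evidence = {
        "cycle_threshold": cycle_threshold,
        "max_mean_sojourn": max_mean_sojourn,
        "sojourn_means": means.tolist(),
        "merged_groups": [g_ for g_ in groups if len(g_) > 1],
        "ambiguous": ambiguous,
        "cycle_probabilities": {
            f"{i}->{j}": float(A[i, j])
            for grp in groups if len(grp) > 1
            for i in grp for j in grp if i != j
        },
    }
    return PhaseMap(mapping=mapping, evidence=evidence)


def label_phases(params: HSMCParams, phase_map: PhaseMap) -> PhaseMap:
    """Attach heuristic strategy labels (reporting only, never computation).

    The phase containing an absorbing (or effectively never-left) state is
    the slow-confirmation phase (SC); a merged alternation cycle is normal
    reading (NR); among the remaining singleton phases the one with the
    longest sojourns and a high long-progression emission is fast reading
    (FR); anything else is information search (IS).
    """
    labels = {}
    means = params.sojourn_means()
    terminal = {j for j in range(params.n_states)
                if params.sojourns[j].family == ABSORBING_FAMILY
                or means[j] > 1e3}
    fwd_plus = params.emissions[:, -1]
    remaining = []
    for p in range(phase_map.n_phases):
        states = phase_map.states_of(p)
        if terminal & set(states):
            labels[p] = "SC"
        elif len(states) > 1:
            labels[p] = "NR"
        else:
            remaining.append(p)
    if remaining:
        by_len = max(
            remaining,
            key=lambda p: float(np.max(
                means[phase_map.states_of(p)] * fwd_plus[phase_map.states_of(p)])),
        )
        labels[by_len] = "FR"
    for p in remaining:
        labels.setdefault(p, "IS")
    phase_map.labels = labels
    return phase_map


def initial_phase_probabilities(params: HSMCParams, phase_map: PhaseMap) -> np.ndarray:
    """Initial probability of each phase: sum of its states' initial masses."""
    out = np.zeros(phase_map.n_phases)
    for s, p in phase_map.mapping.items():
        out[p] += params.initial[s]
    return out


def restore_phases(params: HSMCParams, phase_map: PhaseMap, seq):
    """MAP phase restoration of one sequence.

    Returns ``(phase_sequence, segments)`` where segments is a list of
    ``(start, end, phase)`` with inclusive fixation indices, obtained by
    merging adjacent same-phase runs of the Viterbi state path.
    """
    states = viterbi_restore(params, seq)
    phases = phase_map.apply(states)
    segments = []
    start = 0
    for t in range(1, len(phases) + 1):
        if t == len(phases) or phases[t] != phases[start]:
            segments.append((start, t - 1, int(phases[start])))
            start = t
    return phases, segments
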