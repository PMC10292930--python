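"""Model/Results interface for fitting hidden semi-Markov chains.

`HSMCModel` holds the Read-mode sequences; `HSMCModel.fit` runs EM with
random restarts and returns an `HSMCResults` carrying the estimates,
information criteria, restoration and phase-detection methods, and a
`summary()` table.  `select_states` scans a range of state counts and picks
the BIC minimizer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hsmc
from .phases import PhaseMap, detect_phases, initial_phase_probabilities, label_phases, restore_phases
from .readmodes import N_MODES, READ_MODES


class HSMCModel:
    """Hidden semi-Markov chain for a collection of Read-mode sequences.

    Parameters
    ----------
    sequences : iterable of int arrays
        Read-mode sequences (values 0..4, see `readphases.readmodes`).
    n_states : int
        Number of hidden states K.
    keys : optional list
        Identifier per sequence, e.g. ``(participant_id, text_id)`` tuples;
        carried through to restoration tables.
    """

    def __init__(self, sequences, n_states: int, keys=None, n_symbols: int = N_MODES):
        self.sequences = hsmc._as_sequences(sequences)
        if keys is not None and len(keys) != len(self.sequences):
            raise ValueError("one key per sequence required")
        self.keys = list(keys) if keys is not None else None
        self.n_states = int(n_states)
        self.n_symbols = int(n_symbols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_states: int,
                       participant_col="participant_id", text_col="text_id",
                       mode_col="read_mode"):
        """Build from an enriched fixation table (one row per fixation with a
        Read-mode column naming the outgoing saccade category)."""
        from .readmodes import from_names

        seqs, keys = [], []
        for key, grp in df.groupby([participant_col, text_col], sort=True):
            modes = grp[mode_col].dropna()
            if len(modes) == 0:
                continue
            seqs.append(from_names(modes.tolist()))
            keys.append(key)
        return cls(seqs, n_states, keys=keys)

    @property
    def n_obs(self) -> int:
        return int(sum(len(s) for s in self.sequences))

    def fit(self, n_restarts: int = 10, seed=None, tol: float = 1e-7,
            max_iter: int = 500, init_iter: int = 40,
            transition_mask=None) -> "HSMCResults":
        params, trace = hsmc.em_fit(
            self.sequences, self.n_states, n_restarts=n_restarts, seed=seed,
            tol=tol, max_iter=max_iter, init_iter=init_iter,
            n_symbols=self.n_symbols, transition_mask=transition_mask,
        )
        llf = hsmc.total_log_likelihood(params, self.sequences)
        return HSMCResults(self, params, trace, llf)


class HSMCResults:
    """Estimation results for a fitted hidden semi-Markov chain."""

    def __init__(self, model: HSMCModel, params: hsmc.HSMCParams,
                 trace: hsmc.EMTrace, llf: float):
        self.model = model
        self.params = params
        self.trace = trace
        self.llf = float(llf)

    # -- information criteria ------------------------------------------
    @property
    def df_model(self) -> int:
        return hsmc.n_free_parameters(self.params)

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.df_model * np.log(self.model.n_obs)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    # -- restoration ----------------------------------------------------
    def restore(self, sequences=None) -> list[np.ndarray]:
        """MAP state path per sequence (explicit-duration Viterbi)."""
        seqs = self.model.sequences if sequences is None else hsmc._as_sequences(sequences)
        return [hsmc.viterbi_restore(self.params, s) for s in seqs]

    def smoothed_probabilities(self, seq) -> np.ndarray:
        return hsmc.forward_backward(self.params, seq).smoothed

    def state_entropy(self, seq):
        return hsmc.state_entropy(self.params, seq)

    def mean_state_entropy(self) -> float:
        """Mean smoothed-state entropy over all fixations of the data, used
        to compare alternative observed-variable codings."""
        tot, n = 0.0, 0
        for s in self.model.sequences:
            h, _ = hsmc.state_entropy(self.params, s)
            tot += h.sum()
            n += len(h)
        return tot / n

    # -- phases ---------------------------------------------------------
    def detect_phases(self, cycle_threshold: float = 0.9,
                      max_mean_sojourn: float = 2.0,
                      label: bool = True) -> PhaseMap:
        pm = detect_phases(self.params, cycle_threshold, max_mean_sojourn)
        if label:
            pm = label_phases(self.params, pm)
        return pm

    def initial_phase_probabilities(self, phase_map: PhaseMap) -> np.ndarray:
        return initial_phase_probabilities(self.params, phase_map)

    def restore_phases(self, phase_map: PhaseMap, sequences=None, keys=None) -> pd.DataFrame:
        """Phase segment table: one row per restored segment.

        Columns: participant_id, text_id, phase, label, start, end,
        n_fixations (start/end are inclusive fixation indices).
        """
        seqs = self.model.sequences if sequences is None else hsmc._as_sequences(sequences)
        if keys is None:
            keys = self.model.keys if sequences is None else None
        if keys is None:
            keys = [(i, i) for i in range(len(seqs))]
        rows = []
        for key, s in zip(keys, seqs):
            pid, tid = key
            _, segments = restore_phases(self.params, phase_map, s)
            for start, end, phase in segments:
                rows.append({
                    "participant_id": pid, "text_id": tid, "phase": phase,
                    "label": phase_map.labels.get(phase, str(phase)),
                    "start": start, "end": end,
                    "n_fixations": end - start + 1,
                })
        return pd.DataFrame(rows)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        p = self.params
        K = p.n_states
        lines = []
        lines.append("Hidden semi-Markov chain results")
        lines.append("=" * 64)
        lines.append(f"states: {K}    sequences: {len(self.model.sequences)}"
                     f"    fixations: {self.model.n_obs}")
        lines.append(f"log-likelihood: {self.llf:.2f}    "
                     f"free params: {self.df_model}    BIC: {self.bic:.2f}")
        lines.append("")
        lines.append("initial probabilities:")
        lines.append("  " + "  ".join(f"{v:6.3f}" for v in p.initial))
        lines.append("sojourn laws (mean occupancy in fixations):")
        for j, law in enumerate(p.sojourns):
            mean = "inf" if not np.isfinite(law.mean) else f"{law.mean:.2f}"
            pars = ", ".join(f"{v:.3g}" for v in law.params)
            lines.append(f"  state {j}: {law.family}({pars})  mean={mean}")
        lines.append("emission probabilities (" + " ".join(READ_MODES) + "):")
        for j in range(K):
            lines.append(f"  state {j}: " +
                         "  ".join(f"{v:5.3f}" for v in p.emissions[j]))
        lines.append("transition matrix (rows condition on exit):")
        for j in range(K):
            lines.append(f"  state {j}: " +
                         "  ".join(f"{v:5.3f}" for v in p.transitions[j]))
        if p.absorbing_states():
            lines.append(f"absorbing states: {p.absorbing_states()}")
        trans = p.transitory_states()
        if trans:
            lines.append(f"transitory states: {trans}")
        return "\n".join(lines)


def select_states(sequences, K_range, n_restarts: int = 10, seed=None,
                  keys=None, keep_fits: bool = False, **fit_kwargs):
    """Fit one model per candidate state count and pick the BIC minimizer.

    Returns ``(best_results, table)`` — or ``(best_results, table, fits)``
    with every per-K HSMCResults when ``keep_fits`` — where table is a
    DataFrame with one row per K (log-likelihood, free parameters, BIC); a
    K whose fit fails is recorded with NaNs rather than aborting the scan.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rows, results = [], {}
    ss = np.random.SeedSequence(seed)
    for K, child in zip(K_range, ss.spawn(len(K_range))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        model = HSMCModel(sequences, K, keys=keys)
        try:
            res = model.fit(n_restarts=n_restarts, seed=sub_seed, **fit_kwargs)
        except RuntimeError:
            rows.append({"K": K, "llf": np.nan, "df": np.nan, "bic": np.nan})
            continue
        results[K] = res
        rows.append({"K": K, "llf": res.llf, "df": res.df_model, "bic": res.bic})
    table = pd.DataFrame(rows).set_index("K")
    if not results:
        raise RuntimeError("every candidate K failed to fit")
    best_K = int(table["bic"].idxmin())
    if keep_fits:
        return results[best_K], table, results
    return results[best_K], table
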