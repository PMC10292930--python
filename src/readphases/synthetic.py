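"""Synthetic reading cohorts with the statistical structure the analysis assumes.

The generator serves two purposes: (i) sampling Read-mode sequences from a
known hidden semi-Markov chain for parameter-recovery and model-selection
studies, and (ii) producing full fixation tables and text layouts in exactly
the dialects consumed by :mod:`readphases.preprocess`, so that the complete
pipeline is testable without eye-tracking data.  The ground-truth parameters
are serialized alongside every generated cohort.

The default chain is a five-state model of reading a short text to decide
its relatedness to a topic: two short-sojourn states in near-systematic
alternation (refixations vs long progressions — together the normal-reading
phase), an information-search state mixing refixations and long progressions
with a moderate sojourn, a long-sojourn transitory fast-reading state that
is never re-entered once left, and an absorbing slow-confirmation state rich
in regressions that runs to the end of the trial.  Sequence lengths are
right-censored at a trial length drawn around 17 fixations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsmc import HSMCParams
from .readmodes import N_MODES, READ_MODES, encode_deltas
from .sojourn import SojournLaw, absorbing, shifted_binomial, shifted_negative_binomial

__all__ = [
    "five_state_reading_model",
    "default_length_law",
    "GeneratorConfig",
    "Cohort",
    "sample_state_path",
    "sample_sequences",
    "simulate_cohort",
    "roundtrip_check",
]


def five_state_reading_model() -> HSMCParams:
    """Ground-truth five-state chain used by the synthetic cohort generator.

    The package's reference reading model: two short-sojourn alternating
    normal-reading states, an information-search state (its emission row is
    renormalized to sum to one), a long-sojourn transitory fast-reading
    state (zero re-entry column) and an absorbing slow-confirmation state.
    Recovery studies re-estimate exactly this chain.
    """
    initial = np.array([0.40, 0.35, 0.01, 0.24, 0.00])
    transitions = np.array([
        [0.00, 0.96, 0.03, 0.00, 0.01],
        [0.94, 0.00, 0.05, 0.00, 0.01],
        [0.55, 0.40, 0.00, 0.00, 0.05],
        [0.30, 0.30, 0.10, 0.00, 0.30],
        [0.00, 0.00, 0.00, 0.00, 0.00],
    ])
    # shifted binomial means 1 + n p; shifted NB means 1 + r (1-p)/p
    sojourns = [
        shifted_binomial(2, 0.145),             # mean 1.29
        shifted_binomial(2, 0.110),             # mean 1.22
        shifted_negative_binomial(2.0, 2.0 / 4.38),    # mean 3.38
        shifted_negative_binomial(3.0, 3.0 / 15.37),   # mean 13.37
        absorbing(),
    ]
    emissions = np.array([
        [0.008, 0.029, 0.642, 0.321, 0.000],
        [0.004, 0.012, 0.026, 0.243, 0.715],
        [0.017, 0.000, 0.384, 0.000, 0.444],
        [0.030, 0.025, 0.108, 0.254, 0.583],
        [0.198, 0.047, 0.159, 0.139, 0.457],
    ])
    emissions /= emissions.sum(axis=1, keepdims=True)
    return HSMCParams(initial, transitions, sojourns, emissions)


def default_length_law() -> SojournLaw:
    """Trial length (number of Read modes) law: shifted negative binomial
    with mean 16.6 and standard deviation ~7 fixations."""
    m, v = 15.6, 49.0   # moments of the unshifted part
    p = m / v
    r = m * p / (1.0 - p)
    return shifted_negative_binomial(r, p)


# phase-wise log-scale location/spread for fixation durations (ms); the
# implied phase reading speeds are ordered FR > NR > SC > IS
_PHASE_FIX_MS = {0: (190.0, 0.22), 1: (400.0, 0.22), 2: (140.0, 0.22), 3: (210.0, 0.22)}
_STATE_TO_DEFAULT_PHASE = {0: 0, 1: 0, 2: 1, 3: 2, 4: 3}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    params: HSMCParams = field(default_factory=five_state_reading_model)
    length_law: SojournLaw = field(default_factory=default_length_law)
    min_length: int = 4
    n_participants: int = 15
    n_texts: int = 30
    words_per_text: int = 30
    words_per_line: int = 6
    char_width_px: float = 10.0
    line_height_px: float = 40.0
    mean_word_chars: float = 5.3
    fixation_ms: dict = field(default_factory=lambda: dict(_PHASE_FIX_MS))
    saccade_ms: tuple = (30.0, 0.25)        # log-scale location/spread
    participant_sd: float = 0.18            # sd of log multiplicative effect
    position_jitter: float = 0.0            # fixation jitter, in characters
    trigger_coupling: float = 1.0           # hazard multiplier near triggers
    trigger_radius: int = 2                 # radius in fixations
    seed: int = 0

    def state_phase(self, state: int) -> int:
        return _STATE_TO_DEFAULT_PHASE.get(state, 0)


# ----------------------------------------------------------------------
# pure chain sampling
# ----------------------------------------------------------------------

def _draw_sojourn(law: SojournLaw, rng, cap: int) -> int:
    if law.family == "absorbing":
        return cap
    u = rng.random()
    d = np.arange(1, cap + 1)
    cdf = np.cumsum(law.pmf(d))
    k = int(np.searchsorted(cdf, u))
    return min(k + 1, cap)


def sample_state_path(params: HSMCParams, length: int, rng) -> np.ndarray:
    """Simulate a right-censored hidden state path of a given length."""
    states = np.empty(length, dtype=np.int64)
    t = 0
    j = rng.choice(params.n_states, p=params.initial)
    while t < length:
        d = _draw_sojourn(params.sojourns[j], rng, length - t + 1)
        d = min(d, length - t)
        states[t: t + d] = j
        t += d
        if t < length:
            j = rng.choice(params.n_states, p=params.transitions[j])
    return states


def sample_sequences(params: HSMCParams, n: int, rng, length_law=None,
                     min_length: int = 4):
    """Sample ``n`` (sequence, state-path) pairs from the chain.

    Lengths are drawn from ``length_law`` (default mean ~17) and truncated
    below at ``min_length``; the final sojourn is right-censored at the drawn
    length.
    """
    if length_law is None:
        length_law = default_length_law()
    seqs, paths = [], []
    for _ in range(n):
        T = max(_draw_sojourn(length_law, rng, 200), min_length)
        st = sample_state_path(params, T, rng)
        obs = np.array([rng.choice(params.n_symbols, p=params.emissions[j])
                        for j in st], dtype=np.int64)
        seqs.append(obs)
        paths.append(st)
    return seqs, paths


# ----------------------------------------------------------------------
# full cohort
# ----------------------------------------------------------------------

_STOPWORDS = ("le", "la", "les", "un", "une", "de", "du", "des", "et", "ou",
              "en", "au", "aux", "ce", "se", "que", "qui", "ne", "pas", "sur")


def _make_layout(text_id: str, base_type: str, topic: str, cfg: GeneratorConfig, rng):
    words = []
    col = 0
    line = 0
    x_margin, y_margin = 100.0, 120.0
    char_off = 0
    for i in range(cfg.words_per_text):
        n_chars = max(2, int(round(rng.lognormal(np.log(cfg.mean_word_chars), 0.3))))
        if i > 0 and i % cfg.words_per_line == 0:
            line += 1
            col = 0
        x0 = x_margin + col * cfg.char_width_px
        x1 = x0 + n_chars * cfg.char_width_px
        y0 = y_margin + line * cfg.line_height_px
        words.append({
            "surface": f"{text_id.lower()}w{i:03d}",
            "char_start": char_off,
            "char_end": char_off + n_chars,
            "line": line,
            "x0": x0, "x1": x1,
            "y0": y0, "y1": y0 + cfg.line_height_px * 0.6,
            "stop_word": False,
        })
        char_off += n_chars + 1
        col += n_chars + 1
    return {"text_id": text_id, "topic": topic, "base_type": base_type,
            "words": words}


def _embed_with_cosine(tvec: np.ndarray, sim: float, rng) -> np.ndarray:
    """A unit vector with exactly the requested cosine to ``tvec``."""
    v = rng.normal(size=tvec.size)
    v -= (v @ tvec) * tvec
    v /= np.linalg.norm(v)
    sim = float(np.clip(sim, -0.999, 0.999))
    return sim * tvec + math.sqrt(1.0 - sim * sim) * v


def _make_embeddings(layouts, trigger_positions, rng, dim: int = 8):
    """Word vectors realizing the type-specific trigger structure.

    Designated trigger words get the extreme similarities their text type
    prescribes (closest for related texts, furthest for unrelated ones, one
    of each for moderately related); every other word sits in a mid band.
    Every second related text has its first trigger surface replaced by the
    topic word itself, making it a target word (the text becomes HR+).
    """
    emb = {}
    for i, lay in enumerate(layouts):
        topic = lay["topic"]
        base = lay["base_type"]
        tvec = rng.normal(size=dim)
        tvec /= np.linalg.norm(tvec)
        emb[topic] = tvec
        trig = trigger_positions[lay["text_id"]]
        if base == "HR" and i % 2 == 0:
            # target word: literally the topic word inside the text
            lay["words"][trig[0]]["surface"] = topic
        for j, w in enumerate(lay["words"]):
            if w["surface"] == topic:
                continue
            if j == trig[0]:
                sim = {"HR": 0.75, "MR": 0.7, "UR": -0.6}[base]
            elif j == trig[1]:
                sim = {"HR": 0.45, "MR": -0.6, "UR": -0.5}[base]
            else:
                sim = {"HR": rng.uniform(-0.1, 0.25),
                       "MR": rng.uniform(-0.2, 0.3),
                       "UR": rng.uniform(-0.2, 0.2)}[base]
            emb[w["surface"]] = _embed_with_cosine(tvec, sim, rng)
    return emb


def _word_trajectory(modes: np.ndarray, n_words: int, rng):
    """Integrate Read modes into word indices; returns (indices, realized
    modes, n_clipped).  Moves are clipped at text bounds; when clipping
    changes the category the realized mode is recorded."""
    T = len(modes)
    w = np.empty(T + 1, dtype=np.int64)
    w[0] = 0
    realized = np.empty(T, dtype=np.int64)
    clipped = 0
    for t, m in enumerate(modes):
        if m == 0:
            delta = -int(rng.integers(2, 5))
        elif m == 1:
            delta = -1
        elif m == 2:
            delta = 0
        elif m == 3:
            delta = 1
        else:
            delta = int(rng.integers(2, 5))
        nxt = int(np.clip(w[t] + delta, 0, n_words - 1))
        real = encode_deltas([nxt - w[t]])[0]
        if real != m:
            clipped += 1
        realized[t] = real
        w[t + 1] = nxt
    return w, realized, clipped


@dataclass
class Cohort:
    """A simulated cohort: fixation table, layouts, and serialized truth."""

    fixations: pd.DataFrame
    layouts: list
    truth: dict
    embeddings: dict

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.fixations.to_csv(
            os.path.join(directory, "fixations.tsv"), sep="\t", index=False)
        with open(os.path.join(directory, "layouts.json"), "w") as fh:
            json.dump(self.layouts, fh, indent=1)
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1)
        with open(os.path.join(directory, "embeddings.txt"), "w") as fh:
            for word, vec in self.embeddings.items():
                fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate fixation-level data for every (participant, text) pair.

    For each trial: a censoring length is drawn; a state path is simulated
    (with optional trigger coupling of the sojourn hazard); Read modes are
    emitted per state and integrated into a word-index trajectory clipped at
    the text bounds; fixation coordinates are placed at assigned word
    centres (plus optional jitter) and durations drawn from per-phase
    log-normal laws scaled by a participant-level multiplicative effect.
    One trailing fixation is appended per trial so that, after the standard
    last-fixation removal, re-encoding recovers the emitted sequence.
    """
    cfg = config
    for j in cfg.params.absorbing_states():
        if cfg.params.transitions[j].sum() > 1e-9:
            raise ValueError("absorbing state with outgoing transition mass")
    rng = np.random.default_rng(cfg.seed)
    base_types = ["HR", "MR", "UR"]
    layouts = []
    trigger_positions = {}
    for i in range(cfg.n_texts):
        tid = f"T{i:03d}"
        lay = _make_layout(tid, base_types[i % 3], f"topic{i:03d}", cfg, rng)
        layouts.append(lay)
        # two designated trigger-word positions per text, mid-text
        n = cfg.words_per_text
        trigger_positions[tid] = sorted(
            rng.choice(np.arange(n // 4, 3 * n // 4), size=2, replace=False).tolist())
    embeddings = _make_embeddings(layouts, trigger_positions, rng)

    part_effect = np.exp(rng.normal(0.0, cfg.participant_sd, size=cfg.n_participants))
    rows = []
    truth_scanpaths = []
    n_clip_total = 0
    for p in range(cfg.n_participants):
        pid = f"S{p + 1:02d}"
        for lay in layouts:
            tid = lay["text_id"]
            T = max(_draw_sojourn(cfg.length_law, rng, 200), cfg.min_length)
            trig = trigger_positions[tid]
            if cfg.trigger_coupling != 1.0:
                # joint simulation: word position feeds the hazard
                wtraj = [0]
                states = np.empty(T, dtype=np.int64)
                j = rng.choice(cfg.params.n_states, p=cfg.params.initial)
                d = 0
                recent = -10**9
                modes = np.empty(T, dtype=np.int64)
                for t in range(T):
                    states[t] = j
                    d += 1
                    if wtraj[-1] in trig:
                        recent = t
                    m = rng.choice(N_MODES, p=cfg.params.emissions[j])
                    delta = {0: -int(rng.integers(2, 5)), 1: -1, 2: 0, 3: 1,
                             4: int(rng.integers(2, 5))}[int(m)]
                    nxt = int(np.clip(wtraj[-1] + delta, 0, cfg.words_per_text - 1))
                    real = int(encode_deltas([nxt - wtraj[-1]])[0])
                    if real != m:
                        n_clip_total += 1
                    modes[t] = real
                    wtraj.append(nxt)
                    if t == T - 1:
                        break
                    law = cfg.params.sojourns[j]
                    if law.family != "absorbing":
                        dv = np.array([float(d)])
                        sf_d = law.sf(dv)[0]
                        haz = law.pmf(dv)[0] / sf_d if sf_d > 0 else 1.0
                        if t - recent <= cfg.trigger_radius:
                            haz = min(haz * cfg.trigger_coupling, 0.999)
                        if rng.random() < haz:
                            j = rng.choice(cfg.params.n_states,
                                           p=cfg.params.transitions[j])
                            d = 0
                w = np.array(wtraj)
                realized = modes
            else:
                states = sample_state_path(cfg.params, T, rng)
                emitted = np.array(
                    [rng.choice(N_MODES, p=cfg.params.emissions[j]) for j in states],
                    dtype=np.int64)
                w, realized, nclip = _word_trajectory(emitted, cfg.words_per_text, rng)
                n_clip_total += nclip

            # fixation rows: T+1 fixations; the trailing one is removed by
            # the standard preprocessing (no outgoing saccade)
            fix_states = np.concatenate([states, states[-1:]])
            for t in range(T + 1):
                word = lay["words"][w[t]]
                cx = 0.5 * (word["x0"] + word["x1"])
                cy = 0.5 * (word["y0"] + word["y1"])
                if cfg.position_jitter > 0:
                    cx += rng.uniform(-1, 1) * cfg.position_jitter * cfg.char_width_px
                    cy += rng.uniform(-1, 1) * 5.0
                phase = cfg.state_phase(int(fix_states[t]))
                mu, sg = cfg.fixation_ms[phase]
                dur = float(np.clip(
                    rng.lognormal(np.log(mu), sg) * part_effect[p], 85.0, 990.0))
                sacc = float(rng.lognormal(np.log(cfg.saccade_ms[0]), cfg.saccade_ms[1]))
                rows.append({
                    "participant_id": pid, "text_id": tid, "order": t,
                    "x_px": round(cx, 1), "y_px": round(cy, 1),
                    "duration_ms": round(dur, 1),
                    "saccade_duration_ms": round(sacc, 1),
                })
            truth_scanpaths.append({
                "participant_id": pid, "text_id": tid,
                "states": states.tolist(),
                "modes": realized.tolist(),
                "words": w.tolist(),
                "trigger_words": trig,
            })
    truth = {
        "params": cfg.params.to_dict(),
        "state_phase": {str(k): int(v) for k, v in
                        ((j, cfg.state_phase(j)) for j in range(cfg.params.n_states))},
        "participant_effects": part_effect.tolist(),
        "n_clipped_moves": int(n_clip_total),
        "trigger_positions": trigger_positions,
        "scanpaths": truth_scanpaths,
        "seed": cfg.seed,
    }
    fixations = pd.DataFrame(rows)
    return Cohort(fixations=fixations, layouts=layouts, truth=truth,
                  embeddings=embeddings)


def roundtrip_check(cohort: Cohort) -> dict:
    """Re-encode the generated fixations through the preprocessing pipeline
    and compare with the generator's emitted Read-mode sequences.

    Returns a report with the per-scanpath and per-symbol mismatch rates.
    """
    from .preprocess import enrich_cohort

    enriched, _ = enrich_cohort(cohort.fixations, cohort.layouts)
    truth_map = {(sp["participant_id"], sp["text_id"]): sp["modes"]
                 for sp in cohort.truth["scanpaths"]}
    n_seq = n_seq_bad = n_sym = n_sym_bad = 0
    mismatches = []
    from .readmodes import from_names

    for key, grp in enriched.groupby(["participant_id", "text_id"], sort=True):
        modes = grp["read_mode"].dropna().tolist()
        got = from_names(modes)
        want = np.asarray(truth_map[key])
        n_seq += 1
        L = min(len(got), len(want))
        bad = int((got[:L] != want[:L]).sum()) + abs(len(got) - len(want))
        n_sym += len(want)
        n_sym_bad += bad
        if bad:
            n_seq_bad += 1
            mismatches.append({"key": key, "n_bad": bad})
    return {
        "n_scanpaths": n_seq,
        "n_scanpaths_mismatched": n_seq_bad,
        "symbol_mismatch_rate": (n_sym_bad / n_sym) if n_sym else 0.0,
        "mismatches": mismatches[:20],
    }
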