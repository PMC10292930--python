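"""The 5-category Read-mode alphabet coding outgoing saccades.

The signed word-index change between consecutive fixations is categorized as

====== ======= =========================================
symbol letter  signed word change
====== ======= =========================================
Bwd-   ``m``   regression of more than one word (<= -2)
Bwd    ``b``   one word backward (-1)
Rfx    ``r``   refixation of the same word (0)
Fwd    ``f``   one word forward (+1)
Fwd+   ``F``   progression of more than one word (>= +2)
====== ======= =========================================

This coding depends only on word order, never on screen layout.
"""

from __future__ import annotations

import numpy as np

READ_MODES = ("Bwd-", "Bwd", "Rfx", "Fwd", "Fwd+")
READ_MODE_CHARS = "mbrfF"
N_MODES = 5

_CHAR_TO_INDEX = {c: i for i, c in enumerate(READ_MODE_CHARS)}
_NAME_TO_INDEX = {n: i for i, n in enumerate(READ_MODES)}


def mode_index(delta: int) -> int:
    """Category index of a signed word-index change."""
    if delta <= -2:
        return 0
    if delta == -1:
        return 1
    if delta == 0:
        return 2
    if delta == 1:
        return 3
    return 4


def encode_deltas(deltas) -> np.ndarray:
    """Vectorized category indices for an array of signed word changes."""
    deltas = np.asarray(deltas)
    return np.clip(deltas, -2, 2) + 2


def to_string(seq) -> str:
    """Compact one-letter-per-symbol representation, e.g. ``'fFrfm'``."""
    return "".join(READ_MODE_CHARS[i] for i in np.asarray(seq, dtype=int))


def from_string(s: str) -> np.ndarray:
    try:
        return np.array([_CHAR_TO_INDEX[c] for c in s.strip()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown Read-mode letter {exc.args[0]!r}") from exc


def from_names(names) -> np.ndarray:
    return np.array([_NAME_TO_INDEX[n] for n in names], dtype=np.int64)
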