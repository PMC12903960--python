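"""Information-entropy window-length selection.

Given n mutation-centered windows cut at a series of lengths L, the
Shannon entropy of the pooled symbol distribution (21 symbols: 20 amino
acids plus the padding symbol "X") trades off residue-wise information
density against padding dilution.  Two diagnostics guide the choice of
input length:

* the *valid-residue increasing rate* V_aa across consecutive lengths,
  which approaches zero once longer windows stop adding real residues;
* the relative *entropy change rate* across consecutive lengths.

The recommended length is the smallest grid length at which |V_aa| has
fallen below a threshold while the entropy is non-increasing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import ALPHABET, PAD_SYMBOL, MutationRecord
from .errors import ConfigurationError, RecordValueError, ShapeError
from .windowing import SequenceWindow, window_batch

#: default cut-length grid: odd lengths 21, 41, ..., 501
DEFAULT_LENGTH_GRID = tuple(range(21, 502, 20))


@dataclass
class EntropyProfile:
    """Per-cut-length entropy diagnostics over one window set.

    Rate arrays are aligned with ``lengths``; entries that are undefined
    for the first length are NaN.
    """

    lengths: np.ndarray
    entropies: np.ndarray  # bits
    valid_fraction: np.ndarray
    increasing_rate: np.ndarray
    entropy_change_rate: np.ndarray
    n: int
    orientation: str = "as_printed"
    selected_length: int | None = None
    alphabet: str = ALPHABET

    def to_table(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        return pd.DataFrame(
            {
                "length": self.lengths,
                "entropy_bits": self.entropies,
                "valid_fraction": self.valid_fraction,
                "increasing_rate": self.increasing_rate,
                "entropy_change_rate": self.entropy_change_rate,
            }
        )


def _window_strings(windows: Sequence) -> list[str]:
    out = []
    for w in windows:
        out.append(w.residues if isinstance(w, SequenceWindow) else str(w))
    if not out:
        raise ShapeError("empty window set")
    L = len(out[0])
    for s in out:
        if len(s) != L:
            raise ShapeError(f"unequal window lengths: {len(s)} vs {L}")
        bad = set(s) - set(ALPHABET)
        if bad:
            raise RecordValueError(f"symbols outside alphabet: {sorted(bad)}")
    return out


def shannon_entropy(windows: Sequence, alphabet: str = ALPHABET) -> float:
    """Shannon entropy (bits) of the pooled symbol distribution.

    All n windows of common length L are pooled into one string of L*n
    symbols; H = -sum p log2 p over symbols with nonzero count.
    """
    strings = _window_strings(windows)
    total = len(strings) * len(strings[0])
    counts = Counter("".join(strings))
    h = 0.0
    for sym, c in counts.items():
        if sym not in alphabet:
            raise RecordValueError(f"symbol {sym!r} outside alphabet")
        p = c / total
        h -= p * np.log2(p)
    return float(h)


def valid_fraction(windows: Sequence) -> float:
    """Fraction of non-padding symbols among all L*n window symbols."""
    strings = _window_strings(windows)
    total = len(strings) * len(strings[0])
    n_pad = sum(s.count(PAD_SYMBOL) for s in strings)
    frac = (total - n_pad) / total
    if frac == 0.0:
        warnings.warn("window set is entirely padding; valid fraction is 0")
    return frac


def increasing_rate(
    p_prev: float,
    l_prev: int,
    p_cur: float,
    l_cur: int,
    orientation: str = "as_printed",
) -> float:
    """Valid-residue increasing rate between consecutive cut lengths.

    ``as_printed`` returns P_prev*L_prev / (P_cur*L_cur) - 1 (non-positive
    while valid counts grow); ``conventional`` returns the sign-flipped
    ratio P_cur*L_cur / (P_prev*L_prev) - 1, the reading under which the
    quantity is literally an increasing rate decaying toward zero.  Both
    are exactly 0 once the valid count saturates.
    """
    a = p_prev * l_prev
    b = p_cur * l_cur
    if a <= 0 or b <= 0:
        raise ArithmeticError(
            "zero valid-residue count; shorten the grid or check the windows"
        )
    if orientation == "as_printed":
        return a / b - 1.0
    if orientation == "conventional":
        return b / a - 1.0
    raise ConfigurationError(f"unknown orientation {orientation!r}")


def entropy_change_rate(entropies: Sequence[float]) -> np.ndarray:
    """Relative entropy change (H_k - H_{k-1}) / H_{k-1}; element 0 is NaN,
    as is any element whose predecessor entropy is zero."""
    H = np.asarray(entropies, dtype=float)
    if H.size < 1:
        raise ShapeError("empty entropy array")
    out = np.full(H.size, np.nan)
    for k in range(1, H.size):
        if H[k - 1] != 0.0:
            out[k] = (H[k] - H[k - 1]) / H[k - 1]
    return out


def scan_lengths(
    records: Sequence[MutationRecord],
    sequences: Mapping[str, str],
    lengths: Sequence[int] = DEFAULT_LENGTH_GRID,
    orientation: str = "as_printed",
) -> EntropyProfile:
    """Compute the entropy profile of wild-type windows across a length grid."""
    lengths = list(lengths)
    if any(l % 2 == 0 for l in lengths):
        raise ConfigurationError("all grid lengths must be odd")
    if sorted(lengths) != lengths:
        raise ConfigurationError("length grid must be ascending")

    H, P = [], []
    for L in lengths:
        wt_windows = [wt for wt, _ in window_batch(records, sequences, L)]
        H.append(shannon_entropy(wt_windows))
        P.append(valid_fraction(wt_windows))

    k = len(lengths)
    V = np.full(k, np.nan)
    for i in range(1, k):
        V[i] = increasing_rate(P[i - 1], lengths[i - 1], P[i], lengths[i],
                               orientation)
    return EntropyProfile(
        lengths=np.asarray(lengths),
        entropies=np.asarray(H),
        valid_fraction=np.asarray(P),
        increasing_rate=V,
        entropy_change_rate=entropy_change_rate(H),
        n=len(records),
        orientation=orientation,
    )


def select_length(profile: EntropyProfile, v_threshold: float = 0.01) -> int:
    """Smallest grid length whose |V_aa| is below threshold while the
    entropy is non-increasing; falls back to the last grid length (with a
    warning) when no length qualifies.  An explicit user choice always
    overrides this recommendation.
    """
    for i in range(1, len(profile.lengths)):
        v = profile.increasing_rate[i]
        dh = profile.entropy_change_rate[i]
        if np.isfinite(v) and abs(v) <= v_threshold and (
            not np.isfinite(dh) or dh <= 0
        ):
            profile.selected_length = int(profile.lengths[i])
            return profile.selected_length
    warnings.warn(
        f"no grid length reached |V_aa| <= {v_threshold}; "
        f"falling back to the largest length {int(profile.lengths[-1])}"
    )
    profile.selected_length = int(profile.lengths[-1])
    return profile.selected_length
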