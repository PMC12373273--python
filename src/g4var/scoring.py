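"""Per-nucleotide G4Hunter scoring and sliding-window score tracks.

The G4Hunter score captures G-richness and G-clustering, the primary
sequence determinants of G-quadruplex formation.  Each base in a maximal
run of k consecutive guanines scores ``min(k, 4)``; cytosines score
symmetrically negative (``-min(k, 4)``); A, T/U and ambiguity codes are
neutral (0).  The propensity of a window is the arithmetic mean of its
per-base scores: positive means the plus strand is G-rich, negative means
the G4 would fold on the complementary strand.

This module is pure computation on strings and NumPy arrays; region
calling and variant handling live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# IUPAC nucleotide codes, plus U (scored as T, i.e. neutral).
_IUPAC = set("ACGTURYSWKMBDHVN")

__all__ = [
    "WindowScoreTrack",
    "score_bases",
    "window_scores",
    "max_abs_window_score",
]


class InvalidBaseError(ValueError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


def score_bases(seq: str) -> np.ndarray:
    """Compute the per-base G4Hunter score vector of ``seq``.

    Parameters
    ----------
    seq : str
        DNA (or RNA) sequence over the IUPAC alphabet, case-insensitive.
        ``U`` is accepted and treated like ``T`` (neutral).

    Returns
    -------
    numpy.ndarray of int8, one score per input character, each in
    ``{-4..4}``.  Runs of more than four identical G (or C) score ±4 at
    every position of the run.  Ambiguity codes (N, R, Y, ...) score 0
    and break G/C runs.

    Raises
    ------
    InvalidBaseError
        If a character outside the IUPAC set occurs; the message names
        the offending 0-based position.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    arr = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer("".join(sorted(_IUPAC)).encode(), dtype=np.uint8))
    if not valid.all():
        i = int(np.flatnonzero(~valid)[0])
        raise InvalidBaseError(
            f"invalid nucleotide {seq[i]!r} at position {i} (0-based)"
        )
    out = np.zeros(n, dtype=np.int8)
    for base, sign in ((ord("G"), 1), (ord("C"), -1)):
        mask = arr == base
        if not mask.any():
            continue
        padded = np.concatenate(([0], mask.view(np.int8), [0]))
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        lengths = ends - starts
        values = (sign * np.minimum(lengths, 4)).astype(np.int8)
        out[mask] = np.repeat(values, lengths)
    return out


@dataclass(frozen=True)
class WindowScoreTrack:
    """Sliding-window mean G4Hunter scores over one sequence.

    ``means[i]`` is the mean per-base score of the window starting at
    0-based position ``start_offset + i``; every mean lies in [-4, 4].
    """

    window_size: int
    means: np.ndarray = field(repr=False)
    start_offset: int = 0

    def __len__(self) -> int:  # number of windows
        return len(self.means)


def window_scores(seq: str, window_size: int = 25) -> WindowScoreTrack:
    """Mean per-base score of every ``window_size``-nt window (step 1 nt).

    Returns an empty track when ``len(seq) < window_size``.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    scores = score_bases(seq)
    if len(scores) < window_size:
        return WindowScoreTrack(window_size, np.zeros(0, dtype=np.float64))
    cum = np.concatenate(([0.0], np.cumsum(scores, dtype=np.float64)))
    means = (cum[window_size:] - cum[:-window_size]) / window_size
    return WindowScoreTrack(window_size, means)


def max_abs_window_score(seq: str, window_size: int = 25) -> float:
    """Window mean of greatest absolute value, sign preserved.

    A negative result indicates a C-rich sequence, i.e. a G4 on the
    complementary strand.  Sequences shorter than the window fall back
    to the mean over the entire sequence (a single truncated window), so
    deletion mutants remain scoreable.  Ties on |mean| resolve to the
    leftmost window.
    """
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    track = window_scores(seq, window_size)
    if len(track) == 0:
        return float(np.mean(score_bases(seq)))
    return float(track.means[int(np.argmax(np.abs(track.means)))])
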