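"""G4-prone region calling by window thresholding and merging.

A window whose |mean score| reaches the detection threshold is a
positive window; overlapping positive windows of the same sign are
merged into a region, and the region's score is the merged windows'
mean of greatest absolute value (sign preserved).  G-rich (positive)
and C-rich (negative) windows are never merged with each other, even
when they overlap: they imply G4s on opposite strands.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .scoring import window_scores

if TYPE_CHECKING:  # pragma: no cover
    from .sequences import SequenceStore

__all__ = ["G4Region", "detect_g4_regions", "write_regions_bed", "write_regions_tsv"]


@dataclass(frozen=True)
class G4Region:
    """A called G4-prone interval.

    Coordinates are 0-based half-open on the plus strand; ``region_seq``
    is the reference substring ``[start, end)`` as read from the plus
    strand regardless of ``strand``.  ``strand`` is "+" when the region
    is G-rich (positive scores) and "-" when C-rich; ``max_score`` keeps
    the sign matching the strand.
    """

    seq_name: str
    start: int
    end: int
    strand: str
    region_seq: str
    max_score: float
    window_size: int
    threshold: float

    @property
    def region_id(self) -> str:
        return f"{self.seq_name}:{self.start}-{self.end}:{self.strand}"

    @property
    def width(self) -> int:
        return self.end - self.start


def _call_one_sign(means: np.ndarray, window_size: int, threshold: float, sign: int):
    """Yield (start_window, end_window_exclusive, extreme_mean) groups."""
    if sign > 0:
        hits = np.flatnonzero(means >= threshold)
    else:
        hits = np.flatnonzero(means <= -threshold)
    if hits.size == 0:
        return
    # successive qualifying windows merge while their spans share >= 1 bp,
    # i.e. while the gap between window starts is < window_size
    breaks = np.flatnonzero(np.diff(hits) >= window_size) + 1
    for group in np.split(hits, breaks):
        sub = means[group]
        extreme = sub.max() if sign > 0 else sub.min()
        yield int(group[0]), int(group[-1]) + 1, float(extreme)


def detect_g4_regions(
    store: "SequenceStore",
    window_size: int = 25,
    threshold: float = 1.5,
) -> list[G4Region]:
    """Call G4-prone regions on every sequence of ``store``.

    Parameters
    ----------
    store : SequenceStore
        Reference sequences to scan.
    window_size : int
        Sliding-window width in nt (default 25, the expected span of
        most G4 structures).
    threshold : float
        Minimum |window mean| for a positive window (inclusive).  1.5 is
        the high-confidence value; 1.2 is the permissive floor for DNA.

    Returns
    -------
    list of G4Region sorted by (seq_name, start, strand).  Sequences
    shorter than the window yield no regions.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    regions: list[G4Region] = []
    for name in store.names:
        seq = store.sequence(name)
        track = window_scores(seq, window_size)
        if len(track) == 0:
            continue
        for sign, strand in ((1, "+"), (-1, "-")):
            for w0, w1, extreme in _call_one_sign(
                track.means, window_size, threshold, sign
            ):
                start = w0
                end = (w1 - 1) + window_size
                regions.append(
                    G4Region(
                        seq_name=name,
                        start=start,
                        end=end,
                        strand=strand,
                        region_seq=seq[start:end],
                        max_score=extreme,
                        window_size=window_size,
                        threshold=threshold,
                    )
                )
    regions.sort(key=lambda r: (r.seq_name, r.start, r.strand))
    return regions


def write_regions_bed(regions: list[G4Region], path) -> None:
    """Write regions as 6-column BED (0-based half-open).

    The BED score column is |max_score| x 100 clamped to [0, 1000]; the
    sign is redundant with the strand column.
    """
    with open(path, "w", newline="") as fh:
        for r in regions:
            bed_score = min(1000, max(0, int(round(abs(r.max_score) * 100))))
            fh.write(
                f"{r.seq_name}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{bed_score}\t{r.strand}\n"
            )


def write_regions_tsv(regions: list[G4Region], path) -> None:
    """Write the full region table (scores at two decimals, round-half-even)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["seq_name", "start0", "end0", "strand", "width", "max_score", "region_seq"]
        )
        for r in regions:
            writer.writerow(
                [r.seq_name, r.start, r.end, r.strand, r.width,
                 f"{r.max_score:.2f}", r.region_seq]
            )
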