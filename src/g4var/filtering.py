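"""Stability-transition filtering and reporting of impact records.

A variant is flagged as disruptive when it moves a region from a stable
predicted state (|max score| >= 1.5) to an unstable or less stable one
(|max score| <= 1.2).  Filtering uses absolute scores so C-rich
("-"-strand) G4s are treated symmetrically; comparisons are inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .impact import ImpactRecord
from .scoring import window_scores

__all__ = ["FilterSpec", "filter_impacts", "summarize_impacts",
           "write_summary_tsv", "plot_impact"]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds defining a stable-to-unstable transition.

    ``min_abs_delta`` adds an optional minimum |score change|; the
    default 0 disables it.
    """

    stable_threshold: float = 1.5
    unstable_threshold: float = 1.2
    min_abs_delta: float = 0.0

    def __post_init__(self):
        if self.stable_threshold <= 0 or self.unstable_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.unstable_threshold > self.stable_threshold:
            raise ValueError(
                f"unstable_threshold ({self.unstable_threshold}) must not "
                f"exceed stable_threshold ({self.stable_threshold})"
            )
        if self.min_abs_delta < 0:
            raise ValueError("min_abs_delta must be >= 0")


def filter_impacts(
    records: list[ImpactRecord], spec: FilterSpec = FilterSpec()
) -> list[ImpactRecord]:
    """Keep records whose region was stable and became unstable.

    Keeps records with |wt| >= stable_threshold, |mut| <=
    unstable_threshold and |delta| >= min_abs_delta; input order is
    preserved and the operation is idempotent.
    """
    return [
        r
        for r in records
        if abs(r.wt_max_score) >= spec.stable_threshold
        and abs(r.mut_max_score) <= spec.unstable_threshold
        and abs(r.delta) >= spec.min_abs_delta
    ]


def summarize_impacts(records: list[ImpactRecord]) -> dict:
    """Flat summary of a set of impact records.

    Counts of decreased/unchanged/increased scores (on |score|, so the
    direction is propensity change, not sign change), quantiles of
    |wt| and |mut| max scores, and per-strand record counts.
    """
    deltas = np.array([abs(r.mut_max_score) - abs(r.wt_max_score) for r in records])
    summary: dict = {
        "n_records": len(records),
        "n_decreased": int((deltas < 0).sum()),
        "n_unchanged": int((deltas == 0).sum()),
        "n_increased": int((deltas > 0).sum()),
        "n_plus_strand": sum(1 for r in records if r.strand == "+"),
        "n_minus_strand": sum(1 for r in records if r.strand == "-"),
    }
    for label, values in (
        ("abs_wt", [abs(r.wt_max_score) for r in records]),
        ("abs_mut", [abs(r.mut_max_score) for r in records]),
    ):
        qs = (
            np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])
            if records
            else [float("nan")] * 5
        )
        for q, val in zip(("min", "q25", "median", "q75", "max"), qs):
            summary[f"{label}_{q}"] = float(val)
    return summary


def write_summary_tsv(summary: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["statistic", "value"])
        for key, value in summary.items():
            writer.writerow([key, f"{value:.4f}" if isinstance(value, float) else value])


def plot_impact(record: ImpactRecord, out, window_size: int = 25) -> dict:
    """Render wild-type vs mutant window-score profiles for one record.

    Variant positions (region-relative) are marked when known; the two
    annotated maxima are the wild-type and mutant max scores.  The
    output format (PNG/SVG) follows the file extension.  Returns the
    annotated maxima so callers can verify what was drawn.
    """
    if record.wt_seq is None:
        raise ValueError(
            "record lacks the wild-type sequence (wt_seq); records read "
            "back from TSV cannot be plotted"
        )
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    def profile(seq: str) -> np.ndarray:
        track = window_scores(seq, window_size)
        if len(track) == 0:
            from .scoring import max_abs_window_score
            return np.array([max_abs_window_score(seq, window_size)])
        return track.means

    wt_profile = profile(record.wt_seq)
    mut_profile = profile(record.mut_seq)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(wt_profile, label=f"wild type (max {record.wt_max_score:.2f})",
            color="tab:blue")
    ax.plot(mut_profile, label=f"mutant (max {record.mut_max_score:.2f})",
            color="tab:red", linestyle="--")
    for off in record.variant_offsets:
        ax.axvline(off, color="grey", alpha=0.5, linewidth=0.8)
    ax.set_xlabel("window start (region-relative, nt)")
    ax.set_ylabel("G4Hunter window score")
    ax.set_title(f"{record.region_id}  delta={record.delta:+.2f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return {
        "wt_max": round(record.wt_max_score, 2),
        "mut_max": round(record.mut_max_score, 2),
        "out": str(out),
    }
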