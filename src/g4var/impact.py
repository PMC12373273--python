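"""Variant impact assessment on G4-prone regions.

The effect of a variant is measured by introducing it into the region's
wild-type sequence and recomputing the maximum G4Hunter window score of
the mutated sequence; the delta (mutant - wild type) quantifies the
change in G4 formation propensity.  Re-scoring is restricted to the
mutated region sequence itself (no flanking context), so a variant
cannot reveal a new G4 outside detected regions.

Two assessment modes exist:

* single (variant-centric): each overlapping variant is applied and
  scored independently, ignoring sample identity;
* multi (sample-centric): all variants one sample carries inside one
  region are applied jointly before re-scoring.

C-rich ("-"-strand) regions are handled on the plus strand: alt alleles
are applied as given and the signed score convention carries the strand
information.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .regions import G4Region
from .scoring import max_abs_window_score
from .variants import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ImpactRecord",
    "overlap_variants_with_regions",
    "apply_variants_to_region",
    "assess_impact_single",
    "assess_impact_multi",
    "write_impacts_tsv",
    "read_impacts_tsv",
]


class VariantConflictError(ValueError):
    """Two variants in one application have intersecting ref spans."""


class RefMismatchError(ValueError):
    """A variant's ref allele does not match the region sequence."""


@dataclass(frozen=True)
class ImpactRecord:
    """One (G4 region x variant set) evaluation.

    ``wt_max_score`` equals the region's called max score; ``delta`` is
    ``mut_max_score - wt_max_score``.  ``wt_seq`` and ``variant_offsets``
    (region-relative, 0-based) are carried for plotting and are not part
    of the TSV contract; they may be None when a record is read back
    from disk.
    """

    region_id: str
    strand: str
    variant_ids: tuple[str, ...]
    sample_id: str | None
    wt_max_score: float
    mut_max_score: float
    delta: float
    mut_seq: str
    mode: str  # "single" | "multi"
    wt_seq: str | None = None
    variant_offsets: tuple[int, ...] = ()


def overlap_variants_with_regions(
    variants: list[VariantRecord], regions: list[G4Region]
) -> tuple[dict[G4Region, list[VariantRecord]], list[VariantRecord]]:
    """Assign variants to the regions their ref spans intersect.

    A variant overlaps a region when the 1-based inclusive interval
    covered by its ref allele intersects the region's span.  Returns the
    region -> variants mapping plus the list of unassessed variants
    (those hitting no region).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for region in regions:
        # store 1-based inclusive span as half-open [start+1, end+1)
        trees[region.seq_name].addi(region.start + 1, region.end + 1, region)
    mapping: dict[G4Region, list[VariantRecord]] = defaultdict(list)
    unassessed: list[VariantRecord] = []
    for v in variants:
        lo, hi = v.ref_span
        hits = trees[v.chrom][lo : hi + 1] if v.chrom in trees else ()
        if not hits:
            unassessed.append(v)
            continue
        for hit in hits:
            mapping[hit.data].append(v)
    for vlist in mapping.values():
        vlist.sort(key=lambda v: (v.pos, v.variant_id, v.sample_id or ""))
    return dict(mapping), unassessed


def _trim_to_region(
    region: G4Region, v: VariantRecord
) -> tuple[int, str, str]:
    """Clip a variant's ref/alt to the in-region portion.

    Returns (offset0, ref, alt) where offset0 is 0-based within the
    region sequence.  For length-preserving changes (SNV/MNV) ref and
    alt are clipped positionally; for indels the clipped alt keeps only
    the part matching the removed ref prefix/suffix (so a deletion
    straddling an edge deletes just the in-region bases).
    """
    ref, alt = v.ref, v.alt
    offset0 = v.pos - 1 - region.start
    positional = len(ref) == len(alt)
    if offset0 < 0:
        k = -offset0
        dropped = ref[:k]
        ref = ref[k:]
        if positional:
            alt = alt[k:]
        elif alt.startswith(dropped):
            alt = alt[k:]
        offset0 = 0
    excess = offset0 + len(ref) - region.width
    if excess > 0:
        dropped = ref[-excess:]
        ref = ref[:-excess]
        if positional:
            alt = alt[:-excess]
        elif alt.endswith(dropped):
            alt = alt[:-excess]
    return offset0, ref, alt


def apply_variants_to_region(
    region: G4Region, variants: list[VariantRecord]
) -> str:
    """Introduce ``variants`` into the region sequence and return it.

    Edits are applied in descending position order so earlier edits do
    not shift later coordinates; the result length may change under
    indels.  Raises VariantConflictError when two ref spans intersect
    and RefMismatchError when a ref allele disagrees with the region
    sequence.
    """
    spans = sorted((v.ref_span, v) for v in variants)
    for (span_a, va), (span_b, vb) in zip(spans, spans[1:]):
        if span_b[0] <= span_a[1]:
            raise VariantConflictError(
                f"variants {va.variant_id} and {vb.variant_id} have "
                f"intersecting ref spans in region {region.region_id}"
            )
    seq = region.region_seq
    for _, v in sorted(spans, reverse=True, key=lambda t: t[0]):
        offset0, ref, alt = _trim_to_region(region, v)
        if not ref and not alt:
            continue
        observed = seq[offset0 : offset0 + len(ref)].upper()
        if observed != ref:
            raise RefMismatchError(
                f"variant {v.variant_id}: ref {ref!r} does not match region "
                f"{region.region_id} sequence {observed!r} at offset {offset0}"
            )
        seq = seq[:offset0] + alt + seq[offset0 + len(ref):]
    return seq


def _region_sort_key(region: G4Region):
    return (region.seq_name, region.start, region.strand)


def _make_record(
    region: G4Region,
    group: list[VariantRecord],
    sample_id: str | None,
    mode: str,
    window_size: int,
) -> ImpactRecord:
    mut_seq = apply_variants_to_region(region, group)
    mut = max_abs_window_score(mut_seq, window_size)
    offsets = tuple(
        max(0, v.pos - 1 - region.start) for v in group
    )
    return ImpactRecord(
        region_id=region.region_id,
        strand=region.strand,
        variant_ids=tuple(v.variant_id for v in group),
        sample_id=sample_id,
        wt_max_score=region.max_score,
        mut_max_score=mut,
        delta=mut - region.max_score,
        mut_seq=mut_seq,
        mode=mode,
        wt_seq=region.region_seq,
        variant_offsets=offsets,
    )


def assess_impact_single(
    regions: list[G4Region],
    variants: list[VariantRecord],
    window_size: int = 25,
) -> list[ImpactRecord]:
    """Variant-centric assessment: one record per (region, variant) pair.

    Sample identity is ignored; a variant present under several sample
    tags is evaluated once per distinct variant_id within each region.
    Pairs failing concordance are reported and skipped.
    """
    mapping, unassessed = overlap_variants_with_regions(variants, regions)
    if unassessed:
        logger.info("%d variant record(s) overlap no G4 region", len(unassessed))
    records: list[ImpactRecord] = []
    skipped = 0
    for region in sorted(mapping, key=_region_sort_key):
        seen: set[str] = set()
        for v in mapping[region]:
            if v.variant_id in seen:
                continue
            seen.add(v.variant_id)
            try:
                records.append(_make_record(region, [v], None, "single", window_size))
            except (RefMismatchError, VariantConflictError) as exc:
                skipped += 1
                logger.warning("skipping %s in %s: %s", v.variant_id,
                               region.region_id, exc)
    if skipped:
        logger.warning("skipped %d (region, variant) pair(s) with errors", skipped)
    return records


def assess_impact_multi(
    regions: list[G4Region],
    variants: list[VariantRecord],
    window_size: int = 25,
) -> list[ImpactRecord]:
    """Sample-centric assessment: variants grouped by (region, sample).

    All variants one sample carries inside a region are applied jointly;
    the record lists every contributing variant_id.  Every variant must
    carry a sample_id.  Groups with intra-sample conflicting ref spans
    are skipped with a logged conflict.
    """
    missing = [v.variant_id for v in variants if v.sample_id is None]
    if missing:
        raise ValueError(
            "multi-variant mode requires a sample_id on every variant; "
            f"missing for: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    mapping, unassessed = overlap_variants_with_regions(variants, regions)
    if unassessed:
        logger.info("%d variant record(s) overlap no G4 region", len(unassessed))
    records: list[ImpactRecord] = []
    skipped = 0
    for region in sorted(mapping, key=_region_sort_key):
        by_sample: dict[str, list[VariantRecord]] = defaultdict(list)
        for v in mapping[region]:
            by_sample[v.sample_id].append(v)
        for sample in sorted(by_sample):
            group = by_sample[sample]
            try:
                records.append(
                    _make_record(region, group, sample, "multi", window_size)
                )
            except VariantConflictError as exc:
                skipped += 1
                logger.warning("skipping sample %s in %s: %s", sample,
                               region.region_id, exc)
            except RefMismatchError as exc:
                skipped += 1
                logger.warning("skipping sample %s in %s: %s", sample,
                               region.region_id, exc)
    if skipped:
        logger.warning("skipped %d (region, sample) group(s) with errors", skipped)
    return records


_TSV_COLUMNS = [
    "region_id", "strand", "sample_id", "variant_ids",
    "wt_max_score", "mut_max_score", "delta", "mut_seq", "mode",
]


def write_impacts_tsv(records: list[ImpactRecord], path) -> None:
    """Write impact records; scores at two decimals (round-half-even)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.region_id,
                    r.strand,
                    r.sample_id or ".",
                    ",".join(r.variant_ids),
                    f"{r.wt_max_score:.2f}",
                    f"{r.mut_max_score:.2f}",
                    f"{r.delta:.2f}",
                    r.mut_seq,
                    r.mode,
                ]
            )


def read_impacts_tsv(path) -> list[ImpactRecord]:
    """Read an impact TSV back (plot-only fields come back empty)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                ImpactRecord(
                    region_id=row["region_id"],
                    strand=row["strand"],
                    variant_ids=tuple(row["variant_ids"].split(",")),
                    sample_id=None if row["sample_id"] == "." else row["sample_id"],
                    wt_max_score=float(row["wt_max_score"]),
                    mut_max_score=float(row["mut_max_score"]),
                    delta=float(row["delta"]),
                    mut_seq=row["mut_seq"],
                    mode=row["mode"],
                )
            )
    return records
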