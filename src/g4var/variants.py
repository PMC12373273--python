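"""Variant loading (VCF / MAF) and reference concordance checks.

Records are normalized to one canonical allele representation so that
VCF and MAF encodings of the same mutation compare equal: shared
trailing then leading bases are trimmed, with the constraint that the
reference allele never becomes empty.  Under this rule SNVs are
untouched, deletions become anchorless (ref = deleted bases, alt = ""),
and insertions keep a single anchoring reference base.  No
left-alignment across repeats is attempted; that belongs upstream.

Positions stay 1-based (the native convention of both formats);
conversion to 0-based half-open happens only at interval arithmetic.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .sequences import SequenceStore

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "load_variants",
    "check_reference_concordance",
    "ConcordanceReport",
    "write_variants_tsv",
    "read_variants_tsv",
]

_MAF_REQUIRED = [
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One small-scale variant (SNV or indel), optionally sample-tagged.

    ``pos`` is the 1-based position of the first reference base.  ``alt``
    may be empty after normalization (a pure deletion); ``ref`` never is.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str
    sample_id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("reference allele must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not set(allele) <= _DNA:
                raise ValueError(
                    f"{label} allele {allele!r} contains non-ACGT characters"
                )

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive genomic span covered by the ref allele."""
        return self.pos, self.pos + len(self.ref) - 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared trailing then leading bases; ref stays non-empty."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _make_id(explicit: str | None, chrom: str, pos: int, ref: str, alt: str) -> str:
    if explicit and explicit not in (".", ""):
        return explicit
    return f"{chrom}:{pos}:{ref}>{alt}"


def _is_symbolic(alt: str) -> bool:
    return (
        alt.startswith("<")
        or "[" in alt
        or "]" in alt
        or alt in (".", "*")
        or not set(alt.upper()) <= _DNA  # ambiguous alleles are unscoreable
    )


def _load_vcf(path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    skipped = 0
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports no line numbers
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    for var in vcf:
        genotypes = var.genotypes if samples else []
        for alt_index, alt in enumerate(var.ALT):
            if _is_symbolic(alt) or not set(var.REF.upper()) <= _DNA:
                skipped += 1
                logger.warning(
                    "skipping symbolic/structural/ambiguous allele %r>%r at %s:%d",
                    var.REF, alt, var.CHROM, var.POS,
                )
                continue
            pos, ref, nalt = normalize_alleles(var.POS, var.REF, alt)
            vid = _make_id(var.ID, var.CHROM, pos, ref, nalt)
            carriers = [
                s
                for s, gt in zip(samples, genotypes)
                if (alt_index + 1) in gt[:-1]
            ]
            if carriers:
                for sample in carriers:
                    records.append(
                        VariantRecord(var.CHROM, pos, ref, nalt, vid, sample)
                    )
            else:
                records.append(VariantRecord(var.CHROM, pos, ref, nalt, vid, None))
    if skipped:
        logger.warning("skipped %d symbolic/structural ALT allele(s)", skipped)
    return records


def _load_maf(path, store: SequenceStore | None) -> list[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise ValueError(f"cannot parse MAF {path}: {exc}") from exc
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} lacks required column(s): {', '.join(missing)}")
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            chrom = row["Chromosome"]
            start = int(row["Start_Position"])
            ref = (row["Reference_Allele"] or "").upper()
            alt = (row["Tumor_Seq_Allele2"] or "").upper()
            sample = row["Tumor_Sample_Barcode"]
            explicit_id = row.get("dbSNP_RS")
            if pd.isna(explicit_id):
                explicit_id = None
            if ref == "-":  # MAF insertion: Start_Position is the base before
                if store is None:
                    raise ValueError(
                        "MAF insertion requires reference sequences to resolve "
                        "the anchor base; pass a SequenceStore"
                    )
                anchor = store.fetch(chrom, start - 1, start).upper()
                pos, ref, alt = start, anchor, anchor + alt
            elif alt == "-":  # MAF deletion: already anchorless
                pos, alt = start, ""
            else:
                pos = start
            pos, ref, alt = normalize_alleles(pos, ref, alt)
            vid = _make_id(explicit_id, chrom, pos, ref, alt)
            records.append(VariantRecord(chrom, pos, ref, alt, vid, sample))
        except Exception as exc:
            raise ValueError(f"MAF {path} line {line_no}: {exc}") from exc
    return records


def _sniff_format(path) -> str:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or first.startswith("#CHROM"):
        return "vcf"
    if "Chromosome" in first.split("\t"):
        return "maf"
    raise ValueError(f"cannot auto-detect variant format of {path}")


def load_variants(
    path,
    format: str = "auto",
    store: SequenceStore | None = None,
) -> list[VariantRecord]:
    """Load variants from a VCF or MAF file.

    One record is produced per (site x alt allele x carrier sample):
    multi-allelic VCF sites are split per ALT; when the VCF has sample
    columns, every sample whose genotype carries the ALT yields its own
    record (sites no sample carries produce one sample-less record).
    MAF rows map Tumor_Sample_Barcode to ``sample_id``.  Symbolic or
    structural ALTs (<DEL>, breakends) are skipped with a warning.

    ``store`` is only needed for MAF insertions, whose anchor base must
    be read from the reference.
    """
    path = Path(path)
    if format == "auto":
        suffixes = "".join(path.suffixes).lower()
        if ".vcf" in suffixes:
            format = "vcf"
        elif ".maf" in suffixes:
            format = "maf"
        else:
            format = _sniff_format(path)
    if format == "vcf":
        return _load_vcf(path)
    if format == "maf":
        return _load_maf(path, store)
    raise ValueError(f"unknown variant format {format!r}")


@dataclass(frozen=True)
class ConcordanceReport:
    """One variant whose ref allele disagrees with the reference genome."""

    variant: VariantRecord
    reason: str  # "allele mismatch" | "out of bounds" | "missing sequence"
    observed: str | None = None


def check_reference_concordance(
    variants: list[VariantRecord], store: SequenceStore
) -> list[ConcordanceReport]:
    """Compare each variant's ref allele against the reference sequences."""
    reports = []
    for v in variants:
        if v.chrom not in store:
            reports.append(ConcordanceReport(v, "missing sequence"))
            continue
        start0 = v.pos - 1
        end0 = start0 + len(v.ref)
        if start0 < 0 or end0 > store.lengths[v.chrom]:
            reports.append(ConcordanceReport(v, "out of bounds"))
            continue
        observed = store.fetch(v.chrom, start0, end0).upper()
        if observed != v.ref:
            reports.append(ConcordanceReport(v, "allele mismatch", observed))
    return reports


_TSV_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "sample_id"]
_EMPTY = "-"  # sentinel for empty alt / absent sample in TSV


def write_variants_tsv(variants: list[VariantRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for v in variants:
            writer.writerow(
                [v.variant_id, v.chrom, v.pos, v.ref,
                 v.alt or _EMPTY, v.sample_id or _EMPTY]
            )


def read_variants_tsv(path) -> list[VariantRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt="" if row["alt"] == _EMPTY else row["alt"],
                    variant_id=row["variant_id"],
                    sample_id=None if row["sample_id"] == _EMPTY else row["sample_id"],
                )
            )
    return records
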