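"""Synthetic genomes, planted G4 motifs and matching variant files.

The generator emulates the minimal structure the pipeline needs to be
exercised end to end without downloads: random background sequence,
planted four-tract G4 motifs whose 25-nt window score exceeds the
high-confidence threshold by construction, and SNV/indel variants
placed preferentially on G-run positions inside the plants.  Expected
wild-type/mutant scores in the emitted truth table are computed by the
naive oracle in :mod:`g4var._oracle`, an independent code path from the
optimized scorer.

All outputs are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _oracle

__all__ = ["FixtureSpec", "PlantedG4", "make_genome", "make_variants"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``gc_content`` is the background G+C fraction (0.5 means uniform
    ACGT).  Plants are 25-nt four-tract motifs (runs of 3-4 G or C, at
    least one run of 4, separated by 1-7 A/T loop bases), which
    guarantees a full-window score of at least |43/25| = 1.72.
    """

    n_sequences: int = 2
    seq_length: int = 5000
    n_g4_plants: int = 6
    plant_template: str = "mixed"  # g_rich | c_rich | mixed
    n_variants: int = 40
    fraction_in_g4: float = 0.5
    indel_fraction: float = 0.1
    n_samples: int = 4
    seed: int = 0
    gc_content: float = 0.5
    window_size: int = 25
    detect_threshold: float = 1.5

    def __post_init__(self):
        if not 0 <= self.fraction_in_g4 <= 1:
            raise ValueError("fraction_in_g4 must be in [0, 1]")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")
        if self.plant_template not in ("g_rich", "c_rich", "mixed"):
            raise ValueError(f"unknown plant_template {self.plant_template!r}")
        if self.n_samples < 1 or self.n_sequences < 1:
            raise ValueError("n_samples and n_sequences must be >= 1")


@dataclass(frozen=True)
class PlantedG4:
    seq_name: str
    start0: int
    end0: int
    strand: str


def _plant_motif(rng: np.random.Generator, base: str) -> str:
    """One 25-nt four-tract motif: 4 runs of 3-4 `base`, A/T loops."""
    while True:
        runs = rng.integers(3, 5, size=4)
        if 4 not in runs:
            runs[rng.integers(0, 4)] = 4
        loop_total = 25 - int(runs.sum())
        for _ in range(100):
            cuts = rng.choice(np.arange(1, loop_total), size=2, replace=False)
            c1, c2 = sorted(int(c) for c in cuts)
            loops = (c1, c2 - c1, loop_total - c2)
            if all(1 <= l <= 7 for l in loops):
                break
        else:
            continue
        parts = []
        for i, run in enumerate(runs):
            parts.append(base * int(run))
            if i < 3:
                parts.append("".join(rng.choice(["A", "T"], size=loops[i])))
        motif = "".join(parts)
        assert len(motif) == 25
        return motif


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def make_genome(spec: FixtureSpec, out_dir) -> tuple[Path, list[PlantedG4]]:
    """Write ``genome.fa`` and ``plants.tsv``; return (fasta path, truth).

    Plants are placed non-overlapping, at least two window-widths apart
    and one window-width from sequence ends, so each plant maps to its
    own detected region.  Raises when the requested plants cannot fit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 0])
    w = spec.window_size
    margin, gap = w, 2 * w
    per_seq: dict[str, list[int]] = {}
    names = [f"chr{i + 1}" for i in range(spec.n_sequences)]
    for i in range(spec.n_g4_plants):
        per_seq.setdefault(names[i % spec.n_sequences], []).append(i)
    seqs: dict[str, str] = {}
    plants: list[PlantedG4] = []
    for name in names:
        arr = _background(rng, spec.seq_length, spec.gc_content)
        n_here = len(per_seq.get(name, []))
        starts: list[int] = []
        for _ in range(n_here):
            for _attempt in range(1000):
                s = int(rng.integers(margin, spec.seq_length - margin - 25 + 1))
                if all(abs(s - t) >= 25 + gap for t in starts):
                    starts.append(s)
                    break
            else:
                raise ValueError(
                    f"cannot place {n_here} plants in a {spec.seq_length} nt "
                    "sequence without overlap"
                )
        for k, s in enumerate(sorted(starts)):
            if spec.plant_template == "mixed":
                base = "G" if (len(plants)) % 2 == 0 else "C"
            else:
                base = "G" if spec.plant_template == "g_rich" else "C"
            motif = _plant_motif(rng, base)
            arr[s : s + 25] = list(motif)
            plants.append(PlantedG4(name, s, s + 25, "+" if base == "G" else "-"))
        seqs[name] = "".join(arr)
    fasta = out_dir / "genome.fa"
    _write_fasta(seqs, fasta)
    with open(out_dir / "plants.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["seq_name", "start0", "end0", "strand"])
        for p in plants:
            writer.writerow([p.seq_name, p.start0, p.end0, p.strand])
    return fasta, plants


# ---------------------------------------------------------------------------
# variants


def _pick_alt(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return str(rng.choice(choices))


def make_variants(
    spec: FixtureSpec,
    plants: list[PlantedG4],
    sequences: dict[str, str],
    out_dir,
) -> tuple[Path, Path, list[dict]]:
    """Write matching VCF and MAF plus an oracle truth table.

    ``fraction_in_g4`` of the variants fall inside planted motifs,
    preferentially on G-run (or C-run) positions with the run base
    mutated away; the rest land in background.  ``indel_fraction`` of
    variants are short indels (1-3 nt deletions or insertions, half
    each).  Samples are assigned round-robin.  The truth table holds
    one row per expected impact record in both assessment modes, with
    wild-type and mutant max scores computed by the naive oracle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 1])
    n_in = int(round(spec.n_variants * spec.fraction_in_g4))
    plant_spans = {
        name: [(p.start0, p.end0) for p in plants if p.seq_name == name]
        for name in sequences
    }
    occupied: dict[str, set[int]] = {name: set() for name in sequences}

    # internal normalized representation: (chrom, pos1, ref, alt, vid, sample)
    raw: list[tuple[str, int, str, str, str, str]] = []
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]

    def reserve(chrom: str, lo: int, hi: int) -> bool:
        # exact ref spans; disjointness is all joint application needs
        span = set(range(lo, hi + 1))
        if span & occupied[chrom]:
            return False
        occupied[chrom].update(span)
        return True

    def add_variant(idx: int, chrom: str, pos: int, ref: str, alt: str) -> None:
        vid = f"v{idx + 1:04d}"
        raw.append((chrom, pos, ref, alt, vid, samples[idx % spec.n_samples]))

    made = 0
    for idx in range(spec.n_variants):
        in_g4 = made < n_in and plants
        is_indel = rng.random() < spec.indel_fraction
        for _attempt in range(2000):
            if in_g4:
                plant = plants[int(rng.integers(0, len(plants)))]
                chrom = plant.seq_name
                run_base = "G" if plant.strand == "+" else "C"
                cand = [
                    i
                    for i in range(plant.start0, plant.end0)
                    if sequences[chrom][i] == run_base
                ]
                pos0 = int(rng.choice(cand))
            else:
                chrom = f"chr{int(rng.integers(0, spec.n_sequences)) + 1}"
                pos0 = int(rng.integers(spec.window_size,
                                        len(sequences[chrom]) - spec.window_size))
                if any(lo - 25 <= pos0 < hi + 25 for lo, hi in plant_spans[chrom]):
                    continue
            pos = pos0 + 1  # 1-based
            if is_indel:
                if rng.random() < 0.5:  # deletion
                    dlen = int(rng.integers(1, 4))
                    if pos < 2 or pos0 + dlen > len(sequences[chrom]):
                        continue
                    ref = sequences[chrom][pos0 : pos0 + dlen]
                    alt = ""
                    if not reserve(chrom, pos, pos + dlen - 1):
                        continue
                else:  # insertion, anchored at pos
                    anchor = sequences[chrom][pos0]
                    ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                    ref, alt = anchor, anchor + ins
                    if not reserve(chrom, pos, pos):
                        continue
            else:
                ref = sequences[chrom][pos0]
                alt = _pick_alt(rng, ref)
                if not reserve(chrom, pos, pos):
                    continue
            add_variant(idx, chrom, pos, ref, alt)
            made += 1
            break
        else:
            raise ValueError("could not place all requested variants")

    raw.sort(key=lambda t: (t[0], t[1], t[4]))
    vcf_path = out_dir / "variants.vcf"
    maf_path = out_dir / "variants.maf"
    _write_vcf(raw, sequences, samples, vcf_path)
    _write_maf(raw, maf_path)
    truth = _truth_impacts(spec, sequences, raw)
    with open(out_dir / "impact_truth.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["region_id", "strand", "sample_id", "variant_ids",
             "wt_max_score", "mut_max_score", "mode"]
        )
        for row in truth:
            writer.writerow(
                [row["region_id"], row["strand"], row["sample_id"] or ".",
                 ",".join(row["variant_ids"]),
                 repr(row["wt_max_score"]), repr(row["mut_max_score"]), row["mode"]]
            )
    return vcf_path, maf_path, truth


def _write_vcf(raw, sequences, samples, path: Path) -> None:
    """Anchored VCF representation: indels carry the preceding ref base."""
    with open(path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        rows = []
        for chrom, pos, ref, alt, vid, sample in raw:
            if alt == "":  # deletion -> anchor with preceding base
                anchor = sequences[chrom][pos - 2]
                vcf_pos, vcf_ref, vcf_alt = pos - 1, anchor + ref, anchor
            else:
                vcf_pos, vcf_ref, vcf_alt = pos, ref, alt
            gts = ["0/1" if s == sample else "0/0" for s in samples]
            rows.append((chrom, vcf_pos,
                         f"{chrom}\t{vcf_pos}\t{vid}\t{vcf_ref}\t{vcf_alt}"
                         f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)))
        for _, _, line in sorted(rows, key=lambda t: (t[0], t[1], t[2])):
            fh.write(line + "\n")


def _write_maf(raw, path: Path) -> None:
    """MAF conventions: '-' marks the absent allele side of an indel."""
    cols = ["Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
            "Reference_Allele", "Tumor_Seq_Allele2", "Tumor_Sample_Barcode",
            "dbSNP_RS"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for chrom, pos, ref, alt, vid, sample in raw:
            if alt == "":  # deletion
                start, end, m_ref, m_alt = pos, pos + len(ref) - 1, ref, "-"
            elif len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
                # anchored insertion -> MAF drops the anchor
                start, end, m_ref, m_alt = pos, pos + 1, "-", alt[1:]
            else:
                start, end, m_ref, m_alt = pos, pos + len(ref) - 1, ref, alt
            writer.writerow(["Unknown", chrom, start, end, m_ref, m_alt,
                             sample, vid])


def _truth_impacts(spec: FixtureSpec, sequences, raw) -> list[dict]:
    """Expected impact records in both modes, via the naive oracle."""
    truth: list[dict] = []
    for name in sequences:
        seq = sequences[name]
        regions = _oracle.naive_detect(seq, name, spec.window_size,
                                       spec.detect_threshold)
        for region in regions:
            lo, hi = region["start"] + 1, region["end"]  # 1-based inclusive
            overlapping = [
                (pos, ref, alt, vid, sample)
                for chrom, pos, ref, alt, vid, sample in raw
                if chrom == name
                and pos <= hi
                and pos + max(len(ref), 1) - 1 >= lo
            ]
            if not overlapping:
                continue
            overlapping.sort(key=lambda t: (t[0], t[3]))
            rid = f"{name}:{region['start']}-{region['end']}:{region['strand']}"
            # single mode: each variant independently
            for pos, ref, alt, vid, _sample in overlapping:
                mut_seq = _oracle.naive_mutate(
                    region["start"], region["region_seq"], [(pos, ref, alt)]
                )
                truth.append(
                    {
                        "region_id": rid,
                        "strand": region["strand"],
                        "sample_id": None,
                        "variant_ids": (vid,),
                        "wt_max_score": region["max_score"],
                        "mut_max_score": _oracle.naive_max_abs_score(
                            mut_seq, spec.window_size
                        ),
                        "mode": "single",
                    }
                )
            # multi mode: grouped by sample
            by_sample: dict[str, list] = {}
            for pos, ref, alt, vid, sample in overlapping:
                by_sample.setdefault(sample, []).append((pos, ref, alt, vid))
            for sample in sorted(by_sample):
                group = by_sample[sample]
                mut_seq = _oracle.naive_mutate(
                    region["start"], region["region_seq"],
                    [(p, r, a) for p, r, a, _ in group],
                )
                truth.append(
                    {
                        "region_id": rid,
                        "strand": region["strand"],
                        "sample_id": sample,
                        "variant_ids": tuple(v for _, _, _, v in group),
                        "wt_max_score": region["max_score"],
                        "mut_max_score": _oracle.naive_max_abs_score(
                            mut_seq, spec.window_size
                        ),
                        "mode": "multi",
                    }
                )
    return truth
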