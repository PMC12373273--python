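"""Naive reference implementations used to build fixture truth tables.

Everything here is deliberately written as plain-Python brute force,
sharing no code with the optimized scoring/detection/impact modules, so
that fixture truth tables constitute an independent check of the
pipeline.  Do not import from g4var.scoring / regions / impact here.
"""

from __future__ import annotations


def naive_base_score(seq: str, i: int) -> int:
    """Score of position i computed by scanning its run from scratch."""
    b = seq[i].upper()
    if b == "G":
        sign = 1
    elif b == "C":
        sign = -1
    else:
        return 0
    j = i
    while j > 0 and seq[j - 1].upper() == b:
        j -= 1
    k = i
    while k + 1 < len(seq) and seq[k + 1].upper() == b:
        k += 1
    return sign * min(k - j + 1, 4)


def naive_window_means(seq: str, window_size: int) -> list[float]:
    """Every window mean, each window re-summed independently."""
    means = []
    for start in range(len(seq) - window_size + 1):
        total = 0
        for i in range(start, start + window_size):
            total += naive_base_score(seq, i)
        means.append(total / window_size)
    return means


def naive_max_abs_score(seq: str, window_size: int) -> float:
    """Max-|mean| window score with full-sequence fallback, first-win ties."""
    if len(seq) < window_size:
        total = sum(naive_base_score(seq, i) for i in range(len(seq)))
        return total / len(seq)
    best = None
    for mean in naive_window_means(seq, window_size):
        if best is None or abs(mean) > abs(best):
            best = mean
    return best


def naive_detect(seq: str, seq_name: str, window_size: int, threshold: float):
    """Region calling by exhaustive window scan + interval union.

    Returns dicts with seq_name/start/end/strand/max_score/region_seq,
    sorted by (start, strand).
    """
    means = naive_window_means(seq, window_size)
    regions = []
    for sign, strand in ((1, "+"), (-1, "-")):
        hits = [
            i
            for i, m in enumerate(means)
            if (m >= threshold if sign > 0 else m <= -threshold)
        ]
        group: list[int] = []
        for i in hits + [None]:
            if group and (i is None or i - group[-1] >= window_size):
                start, end = group[0], group[-1] + window_size
                group_means = [means[j] for j in group]
                extreme = max(group_means) if sign > 0 else min(group_means)
                regions.append(
                    {
                        "seq_name": seq_name,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "max_score": extreme,
                        "region_seq": seq[start:end],
                    }
                )
                group = []
            if i is not None:
                group.append(i)
    regions.sort(key=lambda r: (r["start"], r["strand"]))
    return regions


def naive_mutate(region_start0: int, region_seq: str, variants) -> str:
    """Apply (pos, ref, alt) triples (1-based genomic) by string surgery.

    Variants are applied right-to-left; ref/alt portions outside the
    region are clipped (for indels, only alt prefix/suffix matching the
    clipped ref bases is removed).
    """
    seq = region_seq
    for pos, ref, alt in sorted(variants, reverse=True):
        off = pos - 1 - region_start0
        positional = len(ref) == len(alt)
        if off < 0:
            k = -off
            dropped = ref[:k]
            ref = ref[k:]
            if positional or alt.startswith(dropped):
                alt = alt[k:]
            off = 0
        over = off + len(ref) - len(region_seq)
        if over > 0:
            dropped = ref[-over:]
            ref = ref[:-over]
            if positional or alt.endswith(dropped):
                alt = alt[:-over]
        if seq[off : off + len(ref)].upper() != ref:
            raise AssertionError("oracle ref mismatch — fixture generator bug")
        seq = seq[:off] + alt + seq[off + len(ref):]
    return seq
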