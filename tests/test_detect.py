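"""Region calling: thresholding, same-sign merging, strand duality."""

import numpy as np
import pytest

from g4var._oracle import naive_detect
from g4var.regions import detect_g4_regions, write_regions_bed, write_regions_tsv
from g4var.scoring import window_scores
from g4var.sequences import SequenceStore

from conftest import WT_SEQ, revcomp


def random_store(seed, n=2, length=400, gc=0.6):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return SequenceStore(
        {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=length, p=p))
            for i in range(n)
        }
    )


def test_single_window_sequence_gives_one_region(worked_store):
    regions = detect_g4_regions(worked_store, window_size=25, threshold=1.5)
    assert len(regions) == 1
    r = regions[0]
    assert (r.seq_name, r.start, r.end, r.strand) == ("g4", 0, 25, "+")
    assert round(r.max_score, 2) == 1.52
    assert r.region_seq == WT_SEQ
    assert r.region_id == "g4:0-25:+"


def test_neutral_sequence_gives_nothing():
    assert detect_g4_regions(SequenceStore({"a": "A" * 1000})) == []


def test_threshold_validation(worked_store):
    with pytest.raises(ValueError):
        detect_g4_regions(worked_store, threshold=0)
    with pytest.raises(ValueError):
        detect_g4_regions(worked_store, window_size=0)


def test_planted_motifs_called_on_both_strands():
    g_plant = "GGGG" + "TTA" + "GGG" + "AT" + "GGGG" + "TA" + "GGGG"
    c_plant = revcomp(g_plant)
    seq = "AT" * 30 + g_plant + "TA" * 40 + c_plant + "AT" * 30
    regions = detect_g4_regions(SequenceStore({"chr": seq}), 25, 1.5)
    assert [r.strand for r in regions] == ["+", "-"]
    gs, ge = seq.index(g_plant), seq.index(g_plant) + len(g_plant)
    cs, ce = seq.index(c_plant), seq.index(c_plant) + len(c_plant)
    assert regions[0].start < ge and regions[0].end > gs
    assert regions[1].start < ce and regions[1].end > cs
    assert regions[0].max_score > 1.5 and regions[1].max_score < -1.5


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_detection_matches_naive_oracle(seed):
    store = random_store(seed)
    got = detect_g4_regions(store, window_size=10, threshold=1.0)
    for name in store.names:
        expected = naive_detect(store.sequence(name), name, 10, 1.0)
        mine = [r for r in got if r.seq_name == name]
        assert [(r.start, r.end, r.strand) for r in mine] == [
            (e["start"], e["end"], e["strand"]) for e in expected
        ]
        assert [r.max_score for r in mine] == [e["max_score"] for e in expected]
        assert [r.region_seq for r in mine] == [e["region_seq"] for e in expected]


@pytest.mark.parametrize("seed", [5, 6])
def test_region_invariants(seed):
    store = random_store(seed, gc=0.7)
    w, thr = 10, 1.0
    regions = detect_g4_regions(store, w, thr)
    assert regions, "fixture should produce regions at this GC"
    by_key = {}
    for r in regions:
        assert r.end - r.start >= w
        assert abs(r.max_score) >= thr
        assert (r.max_score > 0) == (r.strand == "+")
        assert r.region_seq == store.fetch(r.seq_name, r.start, r.end)
        by_key.setdefault((r.seq_name, r.strand), []).append(r)
        # every region position lies inside a qualifying same-sign window
        means = window_scores(store.sequence(r.seq_name), w).means
        sign = 1 if r.strand == "+" else -1
        qualifying = [
            i for i in range(r.start, r.end - w + 1) if sign * means[i] >= thr
        ]
        covered = set()
        for i in qualifying:
            covered.update(range(i, i + w))
        assert covered == set(range(r.start, r.end))
    for group in by_key.values():
        group.sort(key=lambda r: r.start)
        for a, b in zip(group, group[1:]):
            assert a.end <= b.start, "same-strand regions must not overlap"


@pytest.mark.parametrize("seed", [7, 8])
def test_lowering_threshold_only_grows_regions(seed):
    store = random_store(seed, gc=0.7)
    strict = detect_g4_regions(store, 10, 1.4)
    loose = detect_g4_regions(store, 10, 1.0)
    for r in strict:
        containers = [
            q
            for q in loose
            if q.seq_name == r.seq_name
            and q.strand == r.strand
            and q.start <= r.start
            and q.end >= r.end
        ]
        assert containers, f"region {r.region_id} lost or shrunk at looser threshold"


@pytest.mark.parametrize("seed", [9, 10])
def test_strand_duality_under_reverse_complement(seed):
    store = random_store(seed, gc=0.7)
    fwd = detect_g4_regions(store, 10, 1.0)
    rc_store = SequenceStore(
        {name: revcomp(store.sequence(name)) for name in store.names}
    )
    rev = detect_g4_regions(rc_store, 10, 1.0)
    flip = {"+": "-", "-": "+"}
    expected = sorted(
        (
            r.seq_name,
            store.lengths[r.seq_name] - r.end,
            store.lengths[r.seq_name] - r.start,
            flip[r.strand],
            -r.max_score,
        )
        for r in fwd
    )
    got = sorted((r.seq_name, r.start, r.end, r.strand, r.max_score) for r in rev)
    assert got == expected


def test_writers(worked_store, tmp_path):
    regions = detect_g4_regions(worked_store, 25, 1.5)
    bed, tsv = tmp_path / "r.bed", tmp_path / "r.tsv"
    write_regions_bed(regions, bed)
    write_regions_tsv(regions, tsv)
    assert bed.read_text() == "g4\t0\t25\tg4:0-25:+\t152\t+\n"
    lines = tsv.read_text().splitlines()
    assert lines[0].split("\t") == [
        "seq_name", "start0", "end0", "strand", "width", "max_score", "region_seq",
    ]
    assert lines[1].split("\t") == ["g4", "0", "25", "+", "25", "1.52", WT_SEQ]
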