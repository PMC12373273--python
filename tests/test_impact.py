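"""Variant-to-region overlap, mutation application and the two modes."""

import itertools

import pytest

from g4var.impact import (RefMismatchError, VariantConflictError,
                          apply_variants_to_region, assess_impact_multi,
                          assess_impact_single, overlap_variants_with_regions,
                          read_impacts_tsv, write_impacts_tsv)
from g4var.regions import detect_g4_regions
from g4var.scoring import max_abs_window_score
from g4var.sequences import SequenceStore
from g4var.variants import VariantRecord

from conftest import MUT_SEQ, WT_SEQ


@pytest.fixture
def worked_region(worked_store):
    (region,) = detect_g4_regions(worked_store, 25, 1.5)
    return region


def var(pos, ref, alt, vid=None, sample=None, chrom="g4"):
    return VariantRecord(chrom, pos, ref, alt,
                         vid or f"{chrom}:{pos}:{ref}>{alt}", sample)


class TestOverlap:
    def test_inside_boundary_and_outside(self, worked_region):
        inside = var(23, "G", "A")
        at_start = var(1, "G", "A")
        at_end = var(25, "G", "A")
        past_end = var(26, "G", "A")
        mapping, unassessed = overlap_variants_with_regions(
            [inside, at_start, at_end, past_end], [worked_region]
        )
        assert set(mapping[worked_region]) == {inside, at_start, at_end}
        assert unassessed == [past_end]

    def test_deletion_straddling_edge_is_assigned(self, worked_region):
        # brute-force check over all placements of a 3-nt deletion
        for pos in range(1, 30):
            v = VariantRecord("g4", pos, "NNN".replace("N", "A") , "", "d")
            # ref content irrelevant for overlap
            mapping, unassessed = overlap_variants_with_regions([v], [worked_region])
            expected = pos <= 25 and pos + 2 >= 1
            assert (v in mapping.get(worked_region, [])) == expected

    def test_empty_inputs(self):
        assert overlap_variants_with_regions([], []) == ({}, [])

    def test_wrong_chromosome_unassessed(self, worked_region):
        v = var(5, "G", "A", chrom="elsewhere")
        mapping, unassessed = overlap_variants_with_regions([v], [worked_region])
        assert mapping == {} and unassessed == [v]


class TestApply:
    def test_worked_example_substitution(self, worked_region):
        assert apply_variants_to_region(worked_region, [var(23, "G", "A")]) == MUT_SEQ

    def test_empty_variant_list_is_identity(self, worked_region):
        assert apply_variants_to_region(worked_region, []) == WT_SEQ

    def test_joint_application_is_order_independent(self, worked_region):
        a, b = var(2, "G", "T"), var(23, "G", "C")
        results = {
            apply_variants_to_region(worked_region, list(perm))
            for perm in itertools.permutations([a, b])
        }
        (joint,) = results
        # matches sequential single application in either order
        assert joint == "GTGTGGCGGAGGACGGTCGACGCGG"

    def test_conflicting_spans_raise(self, worked_region):
        with pytest.raises(VariantConflictError):
            apply_variants_to_region(
                worked_region, [var(5, "GGC", "G"), var(6, "G", "A")]
            )

    def test_ref_mismatch_raises(self, worked_region):
        with pytest.raises(RefMismatchError):
            apply_variants_to_region(worked_region, [var(4, "G", "A")])

    def test_deletion_changes_length(self, worked_region):
        out = apply_variants_to_region(worked_region, [var(4, "TGG", "")])
        assert out == "GGG" + WT_SEQ[6:]
        assert len(out) == 22

    def test_insertion_changes_length(self, worked_region):
        out = apply_variants_to_region(worked_region, [var(3, "G", "GAAA")])
        assert out == "GGGAAA" + WT_SEQ[3:]

    def test_deletion_straddling_left_edge_is_trimmed(self, worked_store):
        seq = "TTTT" + WT_SEQ + "TTTT"
        store = SequenceStore({"g4": seq})
        (region,) = detect_g4_regions(store, 25, 1.5)
        # deletion of bases 3-6 (1-based): last two deleted bases are in-region
        v = VariantRecord("g4", region.start - 1, seq[region.start - 2: region.start + 2], "", "d")
        out = apply_variants_to_region(region, [v])
        assert out == region.region_seq[2:]


class TestSingleMode:
    def test_worked_example_scores(self, worked_region):
        (rec,) = assess_impact_single([worked_region], [var(23, "G", "A")], 25)
        assert round(rec.wt_max_score, 2) == 1.52
        assert round(rec.mut_max_score, 2) == 1.08
        assert round(rec.delta, 2) == -0.44
        assert rec.mut_seq == MUT_SEQ
        assert rec.mode == "single" and rec.sample_id is None

    def test_variant_outside_regions_gives_no_record(self, worked_region):
        assert assess_impact_single([worked_region], [var(26, "G", "A")], 25) == []

    def test_three_variants_three_records_samples_ignored(self, worked_region):
        vs = [
            var(23, "G", "A", sample="A"),
            var(13, "A", "C", sample="A"),
            var(7, "C", "G", sample="B"),
        ]
        recs = assess_impact_single([worked_region], vs, 25)
        assert len(recs) == 3
        assert all(r.sample_id is None for r in recs)
        # sorted by variant position within the region
        assert [r.variant_ids[0] for r in recs] == [
            "g4:7:C>G", "g4:13:A>C", "g4:23:G>A",
        ]

    def test_mismatching_variant_skipped_run_continues(self, worked_region):
        recs = assess_impact_single(
            [worked_region], [var(4, "G", "A"), var(23, "G", "A")], 25
        )
        assert [r.variant_ids[0] for r in recs] == ["g4:23:G>A"]

    def test_deletion_below_window_uses_full_length_mean(self):
        store = SequenceStore({"s": WT_SEQ})
        (region,) = detect_g4_regions(store, 25, 1.5)
        v = VariantRecord("s", 4, WT_SEQ[3:13], "", "d10")
        (rec,) = assess_impact_single([region], [v], 25)
        assert len(rec.mut_seq) == 15
        assert rec.mut_max_score == max_abs_window_score(rec.mut_seq, 25)

    def test_g_loss_on_plus_strand_never_gains_score(self, worked_region):
        """Replacing any G with A or T in a G-rich region is destabilizing."""
        for pos0, base in enumerate(WT_SEQ):
            if base != "G":
                continue
            for alt in "AT":
                (rec,) = assess_impact_single(
                    [worked_region], [var(pos0 + 1, "G", alt)], 25
                )
                assert rec.mut_max_score <= rec.wt_max_score


class TestMultiMode:
    def test_grouping_by_sample(self, worked_region):
        vs = [
            var(2, "G", "C", sample="A"),
            var(13, "A", "C", sample="A"),
            var(23, "G", "A", sample="B"),
        ]
        recs = assess_impact_multi([worked_region], vs, 25)
        assert [(r.sample_id, r.variant_ids) for r in recs] == [
            ("A", ("g4:2:G>C", "g4:13:A>C")),
            ("B", ("g4:23:G>A",)),
        ]
        joint = apply_variants_to_region(worked_region, vs[:2])
        assert recs[0].mut_seq == joint
        assert recs[0].mut_max_score == max_abs_window_score(joint, 25)

    def test_missing_sample_id_is_an_error(self, worked_region):
        with pytest.raises(ValueError, match="sample_id"):
            assess_impact_multi([worked_region], [var(23, "G", "A")], 25)

    def test_one_variant_per_sample_matches_single_mode(self, worked_region):
        vs = [
            var(2, "G", "C", sample="A"),
            var(13, "A", "C", sample="B"),
            var(23, "G", "A", sample="C"),
        ]
        multi = assess_impact_multi([worked_region], vs, 25)
        single = assess_impact_single([worked_region], vs, 25)
        assert sorted((r.variant_ids, r.mut_max_score) for r in multi) == sorted(
            (r.variant_ids, r.mut_max_score) for r in single
        )

    def test_intra_sample_conflict_skips_group(self, worked_region):
        vs = [
            var(5, "GGC", "G", sample="A"),
            var(6, "G", "A", sample="A"),
            var(23, "G", "A", sample="B"),
        ]
        recs = assess_impact_multi([worked_region], vs, 25)
        assert [r.sample_id for r in recs] == ["B"]


def test_impacts_tsv_round_trip(worked_region, tmp_path):
    recs = assess_impact_single([worked_region], [var(23, "G", "A")], 25)
    path = tmp_path / "impact.tsv"
    write_impacts_tsv(recs, path)
    lines = path.read_text().splitlines()
    assert lines[1].split("\t") == [
        "g4:0-25:+", "+", ".", "g4:23:G>A", "1.52", "1.08", "-0.44", MUT_SEQ, "single",
    ]
    (back,) = read_impacts_tsv(path)
    assert back.region_id == recs[0].region_id
    assert back.wt_max_score == 1.52 and back.mut_max_score == 1.08
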