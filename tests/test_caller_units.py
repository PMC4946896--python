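"""Operation-level caller semantics: filtering, matching, grouping, scoring."""

import math

import numpy as np
import pytest

from cystseq.caller import (
    ReadRecord, SampleTally, SupermutantCall, UIDFamily,
    build_control_model, call_mutations, compute_maf, filter_reads,
    group_by_uid, haplotype_diff, match_template, score_family,
)
from cystseq.panel import Amplicon, Panel

UID = "A" * 14


def _read(seq, qual=30, uid_qual=30, amplicon=None):
    quals = np.full(len(seq), qual) if np.isscalar(qual) else np.asarray(qual)
    uq = np.full(14, uid_qual) if np.isscalar(uid_qual) else np.asarray(uid_qual)
    return ReadRecord(uid=UID, template_seq=seq, template_quals=quals,
                      uid_quals=uq, matched_amplicon=amplicon)


class TestFilterReads:
    def test_low_uid_quality_discards_whole_read(self):
        uq = [30] * 14
        uq[5] = 14
        kept, _ = filter_reads([_read("ACGT", uid_qual=uq)])
        assert kept == []

    def test_clean_read_retained_without_masks(self):
        kept, masks = filter_reads([_read("ACGTACGT")])
        assert len(kept) == 1
        assert masks[0].all()

    def test_low_template_quality_masks_position_only(self):
        quals = [30, 19, 30, 30]
        kept, masks = filter_reads([_read("ACGT", qual=quals)])
        assert len(kept) == 1
        assert list(masks[0]) == [True, False, True, True]

    def test_retained_count_matches_bruteforce_recount(self, rng):
        reads = []
        for _ in range(1000):
            uq = rng.integers(10, 40, size=14)
            tq = rng.integers(10, 40, size=20)
            seq = "".join(rng.choice(list("ACGT"), size=20))
            reads.append(_read(seq, qual=tq, uid_qual=uq))
        kept, _ = filter_reads(reads)
        expected = sum(1 for r in reads if min(r.uid_quals) >= 15)
        assert len(kept) == expected


class TestMatchTemplate:
    def test_exact_copy_matches(self, toy_panel):
        amp = toy_panel.amplicons[0]
        assert match_template(_read(amp.insert_seq), toy_panel) == amp.amplicon_id

    def test_two_substitutions_still_match(self, toy_panel):
        amp = toy_panel.amplicons[0]
        seq = list(amp.insert_seq)
        seq[10] = "ACGT".replace(seq[10], "")[0]
        seq[50] = "ACGT".replace(seq[50], "")[0]
        assert match_template(_read("".join(seq)), toy_panel) == amp.amplicon_id

    def test_random_sequence_unmatched(self, toy_panel, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        assert match_template(_read(seq), toy_panel) is None


class TestGroupByUid:
    def test_empty_input(self):
        assert group_by_uid([]) == ([], 0)

    def test_partition_by_uid(self):
        reads = [_read("ACGT", amplicon="a") for _ in range(3)]
        reads[2].uid = "C" * 14
        families, dropped = group_by_uid(reads, min_family_size=1)
        assert sorted(f.size for f in families) == [1, 2]
        assert dropped == 0

    def test_min_family_size_drops_singletons(self):
        reads = [_read("ACGT", amplicon="a") for _ in range(3)]
        reads[2].uid = "C" * 14
        families, dropped = group_by_uid(reads, min_family_size=2)
        assert [f.size for f in families] == [2]
        assert dropped == 1

    def test_unmatched_reads_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            group_by_uid([_read("ACGT")])


class TestScoreFamily:
    def _family(self, n_mut, n_wt, ref="A", alt="G"):
        reads = [_read(alt + "CGT", amplicon="a") for _ in range(n_mut)]
        reads += [_read(ref + "CGT", amplicon="a") for _ in range(n_wt)]
        return UIDFamily("a", UID, reads)

    def test_nine_of_ten_is_not_supermutant(self):
        """Exactly 90% mutant fails the strictly-greater-than-90% rule."""
        fam = self._family(9, 1)
        assert score_family(fam, 0, "G", "A") == "ambiguous"

    def test_ten_of_ten_is_supermutant(self):
        assert score_family(self._family(10, 0), 0, "G", "A") == "supermutant"

    def test_ten_of_eleven_is_supermutant(self):
        """10/11 = 0.909... > 0.90 by exact rational comparison."""
        assert score_family(self._family(10, 1), 0, "G", "A") == "supermutant"

    def test_wildtype_family(self):
        assert score_family(self._family(0, 10), 0, "G", "A") == "wildtype"

    def test_masked_positions_excluded_from_denominator(self):
        fam = self._family(10, 0)
        fam.reads.append(_read("ACGT", qual=[10, 30, 30, 30], amplicon="a"))
        # the low-quality wildtype read cannot vote: still 10/10 supermutant
        assert score_family(fam, 0, "G", "A") == "supermutant"

    def test_zero_voting_reads_is_ambiguous(self):
        fam = UIDFamily("a", UID, [_read("ACGT", qual=10, amplicon="a")])
        assert score_family(fam, 0, "G", "A") == "ambiguous"

    def test_order_invariance(self, rng):
        fam = self._family(10, 1)
        before = score_family(fam, 0, "G", "A")
        order = rng.permutation(len(fam.reads))
        fam.reads = [fam.reads[i] for i in order]
        assert score_family(fam, 0, "G", "A") == before


class TestComputeMaf:
    def test_zero_supermutants(self):
        fams = [UIDFamily("a", UID, [_read("ACGT", amplicon="a")] * 2)
                for _ in range(40)]
        call = compute_maf(fams, 0, "G", "A")
        assert call.maf == 0.0
        assert call.n_total_families == 40

    def test_five_in_five_thousand_is_point_one_percent(self):
        sm = [UIDFamily("a", UID, [_read("GCGT", amplicon="a")] * 3) for _ in range(5)]
        wt = [UIDFamily("a", UID, [_read("ACGT", amplicon="a")] * 3) for _ in range(4995)]
        call = compute_maf(sm + wt, 0, "G", "A")
        assert call.maf == pytest.approx(0.001)

    def test_zero_eligible_families_flagged(self):
        fams = [UIDFamily("a", UID, [_read("ACGT", qual=10, amplicon="a")])]
        call = compute_maf(fams, 0, "G", "A")
        assert call.n_total_families == 0
        assert math.isnan(call.maf)


class TestControlModel:
    def _tally(self, frac, n=10000, aid="a", L=4):
        sm = np.zeros((L, 4), np.int64)
        el = np.full((L, 4), n, np.int64)
        sm[0, 2] = round(frac * n)  # allele G at position 0
        t = SampleTally()
        t.sub_supermutant[aid] = sm
        t.sub_eligible[aid] = el
        t.n_families[aid] = n
        return t

    def test_hand_computed_mean_sd_threshold(self):
        """Control fractions {1e-4, 3e-4}: mean 2e-4, sample sd 1.414e-4,
        threshold 9.07e-4."""
        model = build_control_model([self._tally(1e-4), self._tally(3e-4)])
        mean, sd = model.mean_sd("a", 0, "A", "G")
        assert mean == pytest.approx(2e-4)
        assert sd == pytest.approx(1.4142e-4, rel=1e-3)
        assert model.threshold("a", 0, "A", "G") == pytest.approx(9.071e-4, rel=1e-3)

    def test_all_zero_controls_give_zero_threshold(self):
        model = build_control_model([self._tally(0.0), self._tally(0.0)])
        assert model.threshold("a", 0, "A", "G") == 0.0

    def test_fewer_than_two_controls_error(self):
        with pytest.raises(ValueError, match="2 control"):
            build_control_model([self._tally(0.0)])

    def test_unseen_allele_threshold_zero(self):
        model = build_control_model([self._tally(0.0), self._tally(0.0)])
        assert model.threshold("other_amp", 3, "A", "T") == 0.0


@pytest.fixture(scope="module")
def mini_panel():
    # exonic codons AAA CTG AAA plus an intron tail with splice sites
    amp = Amplicon("m1", "TP53", "AAACTGAAA" + "GTAAGT", pool=1, cds_frame=0,
                   exon_intervals=((0, 9),), splice_positions=frozenset({9, 10}),
                   codon_offset=1)
    return Panel([amp])


@pytest.fixture(scope="module")
def empty_controls():
    tallies = []
    for _ in range(2):
        t = SampleTally()
        t.sub_supermutant["m1"] = np.zeros((15, 4), np.int64)
        t.sub_eligible["m1"] = np.full((15, 4), 1000, np.int64)
        t.n_families["m1"] = 1000
        tallies.append(t)
    return build_control_model(tallies)


class TestCallMutations:
    def _call(self, position, ref, alt, n_sm, n_total):
        return SupermutantCall("m1", position, ref, alt, n_sm, n_total)

    def test_maf_below_floor_rejected(self, mini_panel, empty_controls):
        """MAF 0.0009 fails the strict >0.1% gate."""
        vc = call_mutations([self._call(0, "A", "G", 9, 10000)],
                            empty_controls, mini_panel)[0]
        assert not vc.flag_maf_gt_floor
        assert not vc.final_call

    def test_maf_exactly_floor_rejected(self, mini_panel, empty_controls):
        vc = call_mutations([self._call(0, "A", "G", 10, 10000)],
                            empty_controls, mini_panel)[0]
        assert not vc.flag_maf_gt_floor

    def test_synonymous_rejected_despite_high_maf(self, mini_panel, empty_controls):
        # CTG -> TTG is Leu -> Leu
        vc = call_mutations([self._call(3, "C", "T", 3000, 10000)],
                            empty_controls, mini_panel)[0]
        assert vc.flag_maf_gt_floor and vc.flag_exceeds_control
        assert not vc.flag_nonsilent
        assert not vc.final_call

    def test_splice_site_variant_called(self, mini_panel, empty_controls):
        vc = call_mutations([self._call(9, "G", "C", 500, 10000)],
                            empty_controls, mini_panel)[0]
        assert vc.consequence.value == "splice_site"
        assert vc.final_call

    def test_control_gate_blocks_recurrent_artifact(self, mini_panel):
        tallies = []
        for frac in (0.01, 0.012):
            t = SampleTally()
            sm = np.zeros((15, 4), np.int64)
            sm[0, 2] = int(frac * 1000)
            t.sub_supermutant["m1"] = sm
            t.sub_eligible["m1"] = np.full((15, 4), 1000, np.int64)
            t.n_families["m1"] = 1000
            tallies.append(t)
        model = build_control_model(tallies)
        vc = call_mutations([self._call(0, "A", "G", 120, 10000)], model, mini_panel)[0]
        assert vc.flag_maf_gt_floor
        assert not vc.flag_exceeds_control  # 0.012 < 0.011 + 5 * 0.0014 = 0.018
        assert not vc.final_call


class TestHaplotypeDiff:
    def test_identical_is_none(self):
        assert haplotype_diff("ACGT", "ACGT") is None

    def test_substitution(self):
        v = haplotype_diff("ACTT", "ACGT")
        assert (v.position, v.ref, v.alt) == (2, "G", "T")

    def test_deletion_in_repeat_is_left_aligned(self):
        # deleting any TTC repeat unit from TTCTTCTTCA is the same event
        v = haplotype_diff("TTCTTCA", "TTCTTCTTCA")
        v2 = haplotype_diff("TTCTTCA"[:], "TTCTTCTTCA")
        assert v == v2
        ins = "TTCTTCTTCA"
        hap = ins[:v.position] + v.alt + ins[v.position + len(v.ref):]
        assert hap == "TTCTTCA"

    def test_insertion_at_start(self):
        v = haplotype_diff("GGACGT", "ACGT")
        ins = "ACGT"
        hap = ins[:v.position] + v.alt + ins[v.position + len(v.ref):]
        assert hap == "GGACGT"
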