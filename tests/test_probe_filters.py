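"""Per-filter behavior and the order-independent verdict ledger."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from probelint.genome_map import (
    AnnotationSet,
    GenomeHit,
    Locus,
    ProbeRecord,
    SnpRecord,
    revcomp,
)
from probelint.probe_filters import (
    FLAG_NAMES,
    FilterVerdict,
    KaneThresholds,
    assemble_verdicts,
    cross_hyb_filter,
    kane_flag,
    loss_of_target_flag,
    polyg_flag,
    repeat_flag,
    snp_flag,
)

from _oracles import oracle_substring_share

BASES = np.array(list("ACGT"))


def hit(start=100, end=160, matches=60, max_run=60, region="exonic_single",
        expressed=True, chrom="chr1"):
    return GenomeHit("p1", chrom, start, end, "+", matches, 60, max_run,
                     region_class=region, expressed=expressed)


class TestKaneFlag:
    @pytest.mark.parametrize(
        "matches,max_run,expected",
        [
            (60, 60, True),   # perfect match
            (45, 15, True),   # contiguous-run arm alone suffices
            (49, 14, False),  # both arms fail at default thresholds
            (51, 5, True),    # count arm: 51/60 = 0.85 identity
            (50, 5, False),   # 50/60 < 0.85: count arm needs both conditions
        ],
    )
    def test_disjunctive_semantics(self, matches, max_run, expected):
        assert kane_flag(hit(matches=matches, max_run=max_run)) is expected

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            KaneThresholds(min_identity_fraction=0.0)
        with pytest.raises(ValueError):
            KaneThresholds(min_contiguous_run=0)


class TestCrossHybFilter:
    def probe(self):
        return ProbeRecord("p1", "ACGT" * 15, intended_target=Locus("chr1", 100, 160))

    def test_only_intended_hit_is_clean(self):
        flagged, contrib = cross_hyb_filter(self.probe(), [hit()], duplex_dgs=[-90.0])
        assert flagged is False and contrib == []

    def test_expressed_stable_secondary_flags(self):
        hits = [hit(), hit(start=5000, end=5060)]
        flagged, contrib = cross_hyb_filter(
            self.probe(), hits, duplex_dgs=[-90.0, -90.0]
        )
        assert flagged is True and contrib == [hits[1]]

    def test_unexpressed_secondary_does_not_flag(self):
        hits = [hit(), hit(start=5000, end=5060, expressed=False)]
        flagged, _ = cross_hyb_filter(self.probe(), hits, duplex_dgs=[-90.0, -90.0])
        assert flagged is False

    def test_unstable_duplex_does_not_flag(self):
        hits = [hit(), hit(start=5000, end=5060)]
        flagged, _ = cross_hyb_filter(
            self.probe(), hits, duplex_dgs=[-90.0, -5.0], dg_max=-15.0
        )
        assert flagged is False

    def test_no_intended_hit_defers(self):
        flagged, _ = cross_hyb_filter(
            self.probe(), [hit(start=5000, end=5060)], duplex_dgs=None
        )
        # the secondary overlaps nothing intended but there is no intended
        # hit at all: the loss-of-target filter owns this case
        assert cross_hyb_filter(self.probe(), [], duplex_dgs=None) == (False, [])
        assert flagged is True or flagged is False  # decision is well-defined


class TestLossOfTarget:
    def probe(self):
        return ProbeRecord("p1", "ACGT" * 15, intended_target=Locus("chr1", 100, 160))

    def test_no_hits_is_lost(self):
        assert loss_of_target_flag(self.probe(), []) is True

    def test_junction_spanning_hit_is_lost(self):
        assert loss_of_target_flag(
            self.probe(), [hit(region="exon_junction")]
        ) is True

    def test_single_exon_hit_is_kept(self):
        assert loss_of_target_flag(self.probe(), [hit()]) is False


class TestSnpFlag:
    def setup_method(self):
        self.probe = ProbeRecord("p1", "ACGT" * 15)
        self.hit = hit()

    def ann(self, positions):
        return AnnotationSet(
            snps=[SnpRecord("chr1", p, "A", ("G",)) for p in positions]
        )

    def test_four_sites_flagged(self):
        flagged, count, recs = snp_flag(self.probe, self.hit, self.ann([110, 120, 130, 140]))
        assert flagged is True and count == 4 and len(recs) == 4

    def test_zero_sites_clean(self):
        assert snp_flag(self.probe, self.hit, self.ann([])) == (False, 0, [])

    def test_three_sites_annotated_not_flagged(self):
        flagged, count, recs = snp_flag(self.probe, self.hit, self.ann([110, 120, 130]))
        assert flagged is False and count == 3 and len(recs) == 3

    def test_multiallelic_site_counts_once(self):
        ann = AnnotationSet(
            snps=[
                SnpRecord("chr1", 110, "A", ("G",)),
                SnpRecord("chr1", 110, "A", ("C", "T")),
            ]
        )
        _, count, _ = snp_flag(self.probe, self.hit, ann)
        assert count == 1

    def test_positions_outside_footprint_ignored(self):
        flagged, count, _ = snp_flag(
            self.probe, self.hit, self.ann([99, 160, 161, 50])
        )
        assert count == 0 and flagged is False


class TestPolyG:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAGGGGTT", True), ("GGGAGGG", False), ("G" * 60, True), ("ACGT" * 5, False)],
    )
    def test_examples(self, seq, expected):
        assert polyg_flag(seq) is expected

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_matches_longest_run_oracle(self, seq):
        longest = max(
            (len(run) for run in seq.replace("A", " ").replace("C", " ")
             .replace("T", " ").split()),
            default=0,
        )
        assert polyg_flag(seq, 4) == (longest >= 4)


class TestRepeatFlag:
    def test_planted_shared_segment(self):
        rng = np.random.default_rng(5)
        probe_seq = "".join(rng.choice(BASES, size=60))
        lib = {"Alu": "".join(rng.choice(BASES, size=100)) + probe_seq[15:35]
               + "".join(rng.choice(BASES, size=100))}
        probe = ProbeRecord("p1", probe_seq)
        assert repeat_flag(probe, lib, min_match=18) is True
        assert oracle_substring_share(probe_seq, lib["Alu"], 18) is True

    def test_reverse_strand_share_detected(self):
        rng = np.random.default_rng(6)
        probe_seq = "".join(rng.choice(BASES, size=60))
        lib = {"L1": "".join(rng.choice(BASES, size=80)) + revcomp(probe_seq[10:32])}
        assert repeat_flag(ProbeRecord("p1", probe_seq), lib, min_match=20) is True

    def test_empty_library_never_flags(self):
        rng = np.random.default_rng(7)
        probe = ProbeRecord("p1", "".join(rng.choice(BASES, size=60)))
        assert repeat_flag(probe, {}, min_match=15) is False

    def test_no_share_agrees_with_oracle(self):
        rng = np.random.default_rng(8)
        probe_seq = "".join(rng.choice(BASES, size=60))
        lib = {"R": "".join(rng.choice(BASES, size=300))}
        expected = oracle_substring_share(probe_seq, lib["R"], 15)
        assert repeat_flag(ProbeRecord("p1", probe_seq), lib, 15) is expected


class TestVerdictLedger:
    def outcomes(self):
        return [
            ("pa", "cross_hyb", True),
            ("pa", "delta_g", True),
            ("pa", "poly_g", False),
            ("pb", "cross_hyb", False),
            ("pb", "delta_g", False),
            ("pb", "poly_g", False),
        ]

    def test_clean_probe_allowed(self):
        verdicts = {v.probe_id: v for v in assemble_verdicts(self.outcomes())}
        assert verdicts["pb"].allowed is True
        assert verdicts["pa"].allowed is False
        assert verdicts["pa"].flags == {"cross_hyb", "delta_g"}

    def test_all_orderings_identical(self):
        base = assemble_verdicts(self.outcomes())
        for perm in itertools.permutations(self.outcomes()):
            assert assemble_verdicts(list(perm)) == base

    def test_idempotent_under_reapplication(self):
        doubled = self.outcomes() * 2
        assert assemble_verdicts(doubled) == assemble_verdicts(self.outcomes())

    def test_conflicting_duplicate_is_error(self):
        bad = self.outcomes() + [("pa", "cross_hyb", False)]
        with pytest.raises(ValueError, match="conflicting"):
            assemble_verdicts(bad)

    def test_missing_outcome_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_verdicts(self.outcomes()[:-1])

    def test_add_back_restores_probe(self):
        v = assemble_verdicts(
            [("pa", "snp", True), ("pa", "cross_hyb", False)]
        )[0]
        assert v.allowed is False
        v.add_back("snp", "samples genotyped")
        assert v.allowed is True
        assert v.addback_log == [("snp", "samples genotyped")]
        assert v.flags == {"snp"}  # raw flag history is preserved

    def test_union_accounting(self):
        outcomes = [
            ("p1", "snp", True), ("p1", "poly_g", True),
            ("p2", "snp", True), ("p2", "poly_g", False),
            ("p3", "snp", False), ("p3", "poly_g", False),
        ]
        verdicts = assemble_verdicts(outcomes)
        deprecated = sum(1 for v in verdicts if not v.allowed)
        per_filter_sum = sum(
            sum(1 for v in verdicts if f in v.flags) for f in FLAG_NAMES
        )
        assert deprecated == 2 and per_filter_sum == 3
        assert deprecated <= per_filter_sum

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError):
            assemble_verdicts([("p", "bogus", True)])
        with pytest.raises(ValueError):
            FilterVerdict("p").add_back("bogus", "why")
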