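import logging

import numpy as np
import pytest

import tycircle as tc
from tycircle.coverage import (
    DEFAULT_BINS,
    INDETERMINATE,
    NO_EVIDENCE,
    PRODUCER,
    feature_kmers,
    locus_contribution,
)
from tycircle.genome import build_exclusion_set
from tycircle.mapping import MultiMapRecord, Placement


def _rec(read_id, length, placements):
    return MultiMapRecord(read_id, "A" * length, None, [Placement(*p) for p in placements])


def _genome(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    return tc.Genome({"chr1": "".join(rng.choice(list("ACGT"), n))})


class TestWeightedTrack:
    def test_single_placement_full_weight(self):
        g = _genome()
        track = tc.weighted_track([_rec("r", 142, [("chr1", 10, "+", 0)])], g)
        arr = track["chr1"]
        assert np.all(arr[10:152] == 1.0)
        assert arr.sum() == 142.0

    def test_four_placements_quarter_weight_mass_conserved(self):
        g = _genome()
        placements = [("chr1", s, "+", 0) for s in (0, 300, 600, 900)]
        track = tc.weighted_track([_rec("r", 142, placements)], g)
        arr = track["chr1"]
        assert np.all(arr[0:142] == 0.25)
        assert np.isclose(track.mass, 142.0)

    def test_matches_per_read_brute_force_accumulation(self):
        rng = np.random.default_rng(3)
        g = _genome()
        recs = []
        for i in range(20):
            n = int(rng.integers(1, 5))
            pls = [("chr1", int(rng.integers(0, 1800)), "+", 0) for _ in range(n)]
            recs.append(_rec(f"r{i}", 142, pls))
        track = tc.weighted_track(recs, g)
        expect = np.zeros(2000)
        for r in recs:
            for p in r.placements:
                expect[p.start : p.start + 142] += 1.0 / r.n_placements
        assert np.allclose(track["chr1"], expect)

    def test_placement_outside_chromosome_fatal(self):
        g = _genome()
        with pytest.raises(ValueError, match="outside chromosome"):
            tc.weighted_track([_rec("r", 142, [("chr1", 1900, "+", 0)])], g)


def _ann(eid, chrom, start, end, family, cls="solo_ltr", **kw):
    return tc.TyAnnotation(eid, chrom, start, end, "+", family, cls, **kw)


class TestFamilyVenn:
    def test_read_split_between_families_counts_once_in_intersection(self):
        # the worked rule: 10 placements, 8 in Ty1, 2 in Ty2 -> one count in Ty1&Ty2
        anns = [_ann("t1", "chr1", 0, 1000, "Ty1"), _ann("t2", "chr1", 2000, 3000, "Ty2")]
        pls = [("chr1", 100 + i, "+", 0) for i in range(8)]
        pls += [("chr1", 2100 + i, "+", 0) for i in range(2)]
        df = tc.family_venn([_rec("r", 142, pls)], anns)
        assert df.loc["Ty1&Ty2", "count"] == 1
        assert df["count"].sum() == 1

    def test_single_family_read(self):
        anns = [_ann("t1", "chr1", 0, 1000, "Ty1"), _ann("t3", "chr1", 2000, 3000, "Ty3")]
        df = tc.family_venn([_rec("r", 142, [("chr1", 2500, "+", 0)])], anns)
        assert df.loc["Ty3", "count"] == 1

    def test_placement_order_invariance_and_oracle(self):
        rng = np.random.default_rng(5)
        anns = [
            _ann("t1", "chr1", 0, 500, "Ty1"),
            _ann("t2", "chr1", 600, 1100, "Ty2"),
            _ann("t4", "chr1", 1200, 1700, "Ty4"),
        ]
        recs = []
        for i in range(40):
            pls = [("chr1", int(rng.integers(0, 1800)), "+", 0)
                   for _ in range(int(rng.integers(1, 6)))]
            recs.append(_rec(f"r{i}", 100, pls))
        df = tc.family_venn(recs, anns)
        # oracle: recompute the family set per read from first principles
        from collections import Counter

        oracle = Counter()
        for r in recs:
            fams = set()
            for p in r.placements:
                for a in anns:
                    if p.start < a.end and p.start + 100 > a.start:
                        fams.add(a.family)
            if fams:
                oracle["&".join(sorted(fams))] += 1
        for key, n in oracle.items():
            assert df.loc[key, "count"] == n
        assert df["count"].sum() == sum(oracle.values())
        # shuffling placement order changes nothing
        for r in recs:
            r.placements = r.placements[::-1]
        assert tc.family_venn(recs, anns)["count"].equals(df["count"])

    def test_percentages_sum_to_100(self, circle_reads_world):
        genome, annotations, _, dedup = circle_reads_world
        df = tc.family_venn(dedup, annotations)
        assert np.isclose(df["percent"].sum(), 100.0)


class TestExpectedFamilyCoverage:
    def test_kmer_count_is_length_minus_k_plus_one(self):
        assert len(feature_kmers("A" * 150, 142)) == 9
        assert len(feature_kmers("A" * 142, 142)) == 1

    def test_unique_feature_kmers_have_weight_one(self):
        g = _genome(3000, seed=8)
        anns = [_ann("t1", "chr1", 500, 700, "Ty1")]
        venn, track = tc.expected_family_coverage(anns, g, kmer_len=142)
        assert venn.loc["Ty1", "count"] == 200 - 142 + 1
        # middle of the unique feature is covered by all 59 overlapping k-mers
        assert track["chr1"][600] == 59.0

    def test_duplicated_copies_split_weight(self):
        rng = np.random.default_rng(9)
        unit = "".join(rng.choice(list("ACGT"), 200))
        spacer = "".join(rng.choice(list("ACGT"), 500))
        g = tc.Genome({"chr1": spacer + unit + spacer + unit + spacer})
        anns = [
            _ann("t1", "chr1", 500, 700, "Ty1"),
            _ann("t2", "chr1", 1200, 1400, "Ty1"),
        ]
        venn, track = tc.expected_family_coverage(anns, g, kmer_len=142)
        # every k-mer occurs in both copies: weight 1/2 each, two features
        assert venn.loc["Ty1", "count"] == 2 * 59
        assert np.isclose(track["chr1"][600], 59.0)

    def test_short_feature_skipped_with_warning(self, caplog):
        g = _genome(1000, seed=10)
        anns = [_ann("tiny", "chr1", 100, 200, "Ty1")]
        with caplog.at_level(logging.WARNING):
            venn, _ = tc.expected_family_coverage(anns, g, kmer_len=142)
        assert venn.loc["Ty1", "count"] == 0
        assert any("shorter" in r.message for r in caplog.records)


class TestCoverageDistribution:
    def test_zero_track_all_mass_in_lowest_bin(self):
        g = _genome()
        track = tc.weighted_track([], g)
        df = tc.coverage_distribution(track, {"genome": [("chr1", 0, 2000)]})
        assert df.iloc[0, 0] == 1.0
        assert np.isclose(df.iloc[0].sum(), 1.0)

    def test_exclusion_equals_removal(self):
        g = _genome()
        track = tc.weighted_track([_rec("r", 142, [("chr1", 100, "+", 0)])], g)
        excl = build_exclusion_set([("chr1", 100, 242)])
        df = tc.coverage_distribution(track, {"genome": [("chr1", 0, 2000)]}, excl)
        df2 = tc.coverage_distribution(track, {"genome": [("chr1", 242, 2000)]})
        assert np.allclose(df.loc["genome"], df2.loc["genome"])

    def test_two_level_track_hand_counts(self):
        g = _genome(1000, seed=11)
        track = tc.weighted_track([], g)
        track["chr1"][:100] = 4.0  # falls in [4,8)
        df = tc.coverage_distribution(track, {"s": [("chr1", 0, 1000)]})
        assert np.isclose(df.loc["s", "[4,8)"], 0.1)
        assert np.isclose(df.loc["s", "[0,0.015625)"], 0.9)
        assert np.isclose(df.loc["s"].sum(), 1.0)

    def test_nonincreasing_bins_rejected(self):
        g = _genome()
        with pytest.raises(ValueError):
            tc.coverage_distribution(
                tc.weighted_track([], g), {"s": [("chr1", 0, 10)]}, bins=[0, 1, 1]
            )


class TestElementProfile:
    def _element(self):
        return tc.TyAnnotation(
            "e", "chr1", 600, 1560, "+", "Ty1", "full_length",
            ltr5=(600, 700), ltr3=(1460, 1560),
        )

    def test_zero_track_zero_profile(self):
        g = _genome(2500, seed=12)
        prof = tc.element_profile(tc.weighted_track([], g), [self._element()])
        assert np.all(prof["upstream"] == 0) and np.all(prof["internal"] == 0)

    def test_uniform_track_uniform_windows(self):
        g = _genome(2500, seed=12)
        track = tc.weighted_track([], g)
        track["chr1"][:] = 3.0
        prof = tc.element_profile(track, [self._element()])
        assert np.allclose(prof["upstream"], 3.0)
        assert np.allclose(prof["internal"], 3.0)
        assert np.allclose(prof["downstream"], 3.0)

    def test_minus_strand_flank_orientation(self):
        g = _genome(2500, seed=12)
        track = tc.weighted_track([], g)
        # gradient marks genomic left vs right of the element
        track["chr1"][100:600] = 1.0   # genomic left flank
        track["chr1"][1560:2060] = 2.0  # genomic right flank
        el_minus = tc.TyAnnotation(
            "m", "chr1", 600, 1560, "-", "Ty1", "full_length",
            ltr5=(1460, 1560), ltr3=(600, 700),
        )
        prof = tc.element_profile(track, [el_minus])
        # upstream (5' side) of a minus-strand element is the genomic right
        assert np.allclose(prof["upstream"], 2.0)
        assert np.allclose(prof["downstream"], 1.0)

    def test_partial_last_window_averaged_over_actual_width(self):
        g = _genome(2500, seed=12)
        el = tc.TyAnnotation(
            "e", "chr1", 600, 1575, "+", "Ty1", "full_length",
            ltr5=(600, 700), ltr3=(1475, 1575),
        )
        track = tc.weighted_track([], g)
        track["chr1"][600:1575] = 5.0
        prof = tc.element_profile(track, [el])
        assert len(prof["internal"]) == 20  # 19 full windows + 25-bp remainder
        assert np.allclose(prof["internal"], 5.0)


class TestLocusContribution:
    def _world(self, covered_bases, with_unique=True, n=1000):
        rng = np.random.default_rng(13)
        g = tc.Genome({"chr1": "".join(rng.choice(list("ACGT"), n + 1000))})
        el = tc.TyAnnotation(
            "e", "chr1", 500, 500 + n, "+", "Ty1", "full_length",
            ltr5=(500, 600), ltr3=(400 + n, 500 + n),
        )
        recs = []
        # tile single-placement (unique) 10-mers over the covered prefix
        for i, s in enumerate(range(500, 500 + covered_bases, 10)):
            length = min(10, 500 + covered_bases - s)
            recs.append(_rec(f"r{i}", length, [("chr1", s, "+", 0)]))
        if not with_unique:
            for r in recs:
                r.placements = r.placements + [Placement("chr1", 5, "+", 0)]
        return g, el, recs

    def test_full_coverage_with_unique_read_is_producer(self):
        g, el, recs = self._world(1000)
        df = locus_contribution(recs, [el], g)
        assert df.loc["e", "flag"] == PRODUCER

    def test_994_of_1000_bases_is_below_threshold(self):
        g, el, recs = self._world(994)
        df = locus_contribution(recs, [el], g)
        assert np.isclose(df.loc["e", "covered_fraction"], 0.994)
        assert df.loc["e", "flag"] == NO_EVIDENCE

    def test_exact_duplicate_element_is_indeterminate(self):
        # two identical copies: full coverage, no unique k-mer anywhere
        rng = np.random.default_rng(14)
        unit = "".join(rng.choice(list("ACGT"), 400))
        spacer = "".join(rng.choice(list("ACGT"), 600))
        g = tc.Genome({"chr1": spacer + unit + spacer + unit + spacer})
        el = tc.TyAnnotation(
            "dup", "chr1", 600, 1000, "+", "Ty1", "full_length",
            ltr5=(600, 700), ltr3=(900, 1000),
        )
        recs = [
            _rec(f"r{i}", 20, [("chr1", s, "+", 0), ("chr1", s + 1000, "+", 0)])
            for i, s in enumerate(range(600, 1000, 10))
        ]
        df = locus_contribution(recs, [el], g, tc.LocusCriteria(kmer_len=142))
        assert df.loc["dup", "covered_fraction"] == 1.0
        assert df.loc["dup", "flag"] == INDETERMINATE
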